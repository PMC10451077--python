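import numpy as np
import pytest

from mosaicmito.pipeline import build_cohort, qualify_samples
from mosaicmito.simulate import (
    ConfigError,
    SimulationConfig,
    logistic,
    null_config,
    recovery_config,
    simulate_cohort,
)
from mosaicmito.variants import PRE_CULTURE


@pytest.fixture(scope="module")
def small_cohort(reference, marker_table):
    return simulate_cohort(SimulationConfig(n_embryos=15), 2024, reference, marker_table)


def test_determinism(reference, marker_table):
    a = simulate_cohort(SimulationConfig(n_embryos=8), 5, reference, marker_table)
    b = simulate_cohort(SimulationConfig(n_embryos=8), 5, reference, marker_table)
    assert a.truth == b.truth
    assert a.ct_table.equals(b.ct_table)
    assert [p.calls for p in a.profiles] == [p.calls for p in b.profiles]


def test_written_files_byte_identical(tmp_path, reference, marker_table):
    cfg = SimulationConfig(n_embryos=6)
    for run in ("r1", "r2"):
        simulate_cohort(cfg, 99, reference, marker_table).write(tmp_path / run)
    for name in ("karyotype.csv", "variants.tsv", "ct.csv", "culturability.csv", "truth.json"):
        assert (tmp_path / "r1" / name).read_bytes() == (tmp_path / "r2" / name).read_bytes()


def test_config_validation():
    with pytest.raises(ConfigError):
        SimulationConfig(karyotype_probs={"euploid": 0.5, "mosaic": 0.2,
                                          "full_aneuploid": 0.2}).validate()
    with pytest.raises(ConfigError):
        SimulationConfig(lambda_by_group={"euploid": -1.0, "mosaic": 0.5,
                                          "full_aneuploid": 0.5}).validate()
    with pytest.raises(ConfigError):
        SimulationConfig(read_depth=0).validate()
    SimulationConfig().validate()  # defaults are valid


def test_truth_ledger_structure(small_cohort):
    truth = small_cohort.truth
    assert len(truth["embryos"]) == 15
    for e in truth["embryos"]:
        assert e["pre_karyotype"] in ("euploid", "mosaic", "full_aneuploid")
        assert e["true_burden"] == len(e["planted_variants"])
        assert e["culturability"] in ("culturable", "non_culturable", "not_cultured")


def test_planted_mutations_recovered_per_sample(
    small_cohort, reference, marker_table, trna_table
):
    """Oracle: per-sample qualifying counts equal the number of planted
    variants observed at >=90% heteroplasmy in that sample, conditioned on
    no decoy slipping over the threshold (checked explicitly)."""
    truth = {e["embryo_id"]: e for e in small_cohort.truth["embryos"]}
    planted_keys = {
        eid: {(v["position"], v["alt"]) for v in e["planted_variants"]}
        for eid, e in truth.items()
    }
    for s in small_cohort.variant_samples:
        if s.variants is None:
            continue
        expected = sum(
            1
            for v in s.variants
            if (v.position, v.alt_base) in planted_keys[s.embryo_id]
            and v.heteroplasmy >= 90.0
        )
        # run the real pipeline on a deep copy to avoid mutating the fixture
        import copy

        qualified = qualify_samples(
            [copy.deepcopy(s)], reference, marker_table, trna_table
        )
        counts = next(iter(qualified.values()))
        assert counts == (expected,), s.sample_id


def test_karyotype_truth_agreement(small_cohort, reference, marker_table, trna_table):
    """Pre-culture labels match the ledger whenever biopsy noise stayed
    within the planted band (mosaic) / above 80 (full aneuploid)."""
    from mosaicmito.karyotype import classify_sample

    truth = {e["embryo_id"]: e for e in small_cohort.truth["embryos"]}
    from collections import defaultdict

    by_embryo = defaultdict(list)
    for p in small_cohort.profiles:
        if p.stage == PRE_CULTURE:
            by_embryo[p.embryo_id].append(p)
    cohort = build_cohort(
        small_cohort.profiles, small_cohort.variant_samples,
        small_cohort.culturability, reference, marker_table, trna_table,
    )
    records = {e.embryo_id: e for e in cohort}
    for eid, profiles in by_embryo.items():
        true_label = truth[eid]["pre_karyotype"]
        sample_labels = {classify_sample(p).label for p in profiles}
        faithful = (
            (true_label == "euploid" and sample_labels == {"euploid"})
            or (true_label == "mosaic" and "mosaic" in sample_labels)
            or (true_label == "full_aneuploid" and sample_labels == {"aneuploid"})
        )
        if faithful:
            assert records[eid].pre_karyotype == true_label, eid


def test_null_config_has_no_feedback():
    cfg = null_config(50, 1.0)
    assert len(set(cfg.lambda_by_group.values())) == 1
    assert cfg.resolution_beta == 0.0 and cfg.culturability_delta == 0.0


def test_recovery_config_two_groups():
    cfg = recovery_config(100, 0.2, 1.5)
    assert cfg.karyotype_probs["mosaic"] == 0.0
    assert cfg.lambda_by_group["full_aneuploid"] == 1.5


def test_higher_beta_lowers_resolution_rate(reference, marker_table):
    """Monotonicity in expectation: steeper burden penalty -> fewer mosaic
    embryos resolve to euploid."""
    def resolution_rate(beta, seed):
        cfg = SimulationConfig(
            n_embryos=300,
            karyotype_probs={"euploid": 0.0, "mosaic": 1.0, "full_aneuploid": 0.0},
            lambda_by_group={"euploid": 1.5, "mosaic": 1.5, "full_aneuploid": 1.5},
            resolution_beta=beta,
            not_cultured_p=0.0,
        )
        synth = simulate_cohort(cfg, seed, reference, marker_table, with_ct=False)
        labels = [e["post_karyotype"] for e in synth.truth["embryos"]]
        return sum(l == "euploid" for l in labels) / len(labels)

    low = np.mean([resolution_rate(0.0, s) for s in (1, 2, 3)])
    high = np.mean([resolution_rate(2.0, s) for s in (1, 2, 3)])
    assert high < low


def test_decoys_present_but_never_counted(small_cohort):
    """Synthetic samples contain decoy variants (realism), distinct from the
    planted qualifying set."""
    truth = {e["embryo_id"]: e for e in small_cohort.truth["embryos"]}
    n_extra = 0
    for s in small_cohort.variant_samples:
        if s.variants is None:
            continue
        planted = {(v["position"], v["alt"]) for v in truth[s.embryo_id]["planted_variants"]}
        n_extra += sum(1 for v in s.variants if (v.position, v.alt_base) not in planted)
    assert n_extra > 0


def test_logistic():
    assert logistic(0.0) == 0.5
    assert logistic(50.0) == pytest.approx(1.0)
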