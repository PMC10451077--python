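import copy

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mosaicmito.variants import (
    ConfigurationError,
    InconsistentReadError,
    MtVariant,
    NoCoverageError,
    OrderingError,
    SampleVariantSet,
    annotate_variants,
    embryo_mutation_count,
    flag_haplogroup_markers,
    heteroplasmy,
    qualify,
)


# ---------------------------------------------------------------------------
# heteroplasmy

@pytest.mark.parametrize(
    "alt,total,expected", [(0, 100, 0.0), (100, 100, 100.0), (93, 100, 93.0)]
)
def test_heteroplasmy_values(alt, total, expected):
    assert heteroplasmy(alt, total) == expected


def test_heteroplasmy_errors():
    with pytest.raises(NoCoverageError):
        heteroplasmy(0, 0)
    with pytest.raises(InconsistentReadError):
        heteroplasmy(5, 4)
    with pytest.raises(InconsistentReadError):
        heteroplasmy(-1, 10)


@given(total=st.integers(1, 10_000), alt=st.integers(0, 10_000))
def test_heteroplasmy_bounds(total, alt):
    alt = min(alt, total)
    assert 0.0 <= heteroplasmy(alt, total) <= 100.0


def test_variant_needs_reads_or_heteroplasmy():
    with pytest.raises(ValueError):
        MtVariant(100, "A", "G")
    v = MtVariant(100, "A", "G", heteroplasmy=45.0)  # TSV dialect, face value
    assert v.heteroplasmy == 45.0
    v = MtVariant(100, "A", "G", alt_reads=93, total_reads=100, heteroplasmy=5.0)
    assert v.heteroplasmy == 93.0  # read counts are authoritative


# ---------------------------------------------------------------------------
# marker flagging

def _variant_at(reference, pos, alt, het=95.0):
    return MtVariant(pos, reference.base_at(pos), alt, heteroplasmy=het)


def _sample(reference, haplogroup, variants):
    return SampleVariantSet("E1", "E1-pre1", "pre_culture", haplogroup, variants)


def _marker_entries(marker_table, haplogroup):
    return sorted(marker_table[haplogroup].items(), key=lambda kv: kv[0])


def test_marker_at_80_flagged(reference, marker_table):
    (pos, alt), freq = next(
        kv for kv in marker_table["D4"].items() if kv[1] == 80.0
    )
    s = _sample(reference, "D4", [_variant_at(reference, pos, alt)])
    flag_haplogroup_markers(s, marker_table)
    assert s.variants[0].is_haplogroup_marker  # threshold is inclusive


def test_marker_below_80_not_flagged(reference, marker_table):
    (pos, alt), freq = next(
        kv for kv in marker_table["D4"].items() if kv[1] < 80.0
    )
    s = _sample(reference, "D4", [_variant_at(reference, pos, alt)])
    flag_haplogroup_markers(s, marker_table)
    assert not s.variants[0].is_haplogroup_marker


def test_marker_of_other_haplogroup_not_flagged(reference, marker_table):
    (pos, alt), freq = next(
        kv for kv in marker_table["D4"].items() if kv[1] >= 95.0
    )
    s = _sample(reference, "H2a", [_variant_at(reference, pos, alt)])
    flag_haplogroup_markers(s, marker_table)
    assert not s.variants[0].is_haplogroup_marker


def test_variant_absent_from_table_not_flagged(reference, marker_table):
    s = _sample(reference, "H2a", [_variant_at(reference, 3460, "A")])
    flag_haplogroup_markers(s, marker_table)
    assert not s.variants[0].is_haplogroup_marker


def test_unknown_haplogroup_errors(reference, marker_table):
    s = _sample(reference, "Z9", [])
    with pytest.raises(ConfigurationError, match="available"):
        flag_haplogroup_markers(s, marker_table)


def test_flagging_idempotent(reference, marker_table):
    entries = _marker_entries(marker_table, "H2a")
    variants = [_variant_at(reference, pos, alt) for (pos, alt), _ in entries]
    s = _sample(reference, "H2a", variants)
    flag_haplogroup_markers(s, marker_table)
    once = [v.is_haplogroup_marker for v in s.variants]
    flag_haplogroup_markers(s, marker_table)
    assert [v.is_haplogroup_marker for v in s.variants] == once


# ---------------------------------------------------------------------------
# qualification

def _qualified_sample(reference, marker_table, trna_table, variants, haplogroup="H2a"):
    s = _sample(reference, haplogroup, variants)
    annotate_variants(s, reference)
    flag_haplogroup_markers(s, marker_table)
    qualify(s, trna_table)
    return s


def test_nonsynonymous_at_90_qualifies(reference, marker_table, trna_table):
    s = _qualified_sample(
        reference, marker_table, trna_table, [_variant_at(reference, 3460, "A", 90.0)]
    )
    assert s.variants[0].qualifies
    assert s.qualifying_count == 1


def test_below_90_does_not_qualify(reference, marker_table, trna_table):
    s = _qualified_sample(
        reference, marker_table, trna_table, [_variant_at(reference, 3460, "A", 89.9)]
    )
    assert not s.variants[0].qualifies


def test_synonymous_at_100_does_not_qualify(reference, marker_table, trna_table):
    co1 = reference.genes["MT-CO1"]
    for offset in range(2, 300, 3):
        pos = co1.start + offset
        ref = reference.base_at(pos)
        alt = next(
            (b for b in "ACGT" if b != ref
             and reference.classify_consequence(pos, ref, alt_base=b, feature=co1) == "synonymous"),
            None,
        )
        if alt:
            break
    s = _qualified_sample(
        reference, marker_table, trna_table, [_variant_at(reference, pos, alt, 100.0)]
    )
    assert not s.variants[0].qualifies


def test_marker_never_qualifies(reference, marker_table, trna_table):
    (pos, alt), _ = next(kv for kv in marker_table["H2a"].items() if kv[1] >= 95.0)
    s = _qualified_sample(
        reference, marker_table, trna_table, [_variant_at(reference, pos, alt, 99.0)]
    )
    assert not s.variants[0].qualifies


def test_pathogenic_trna_qualifies(reference, marker_table, trna_table):
    (pos, alt), cls = next(iter(trna_table.items()))
    s = _qualified_sample(
        reference, marker_table, trna_table, [_variant_at(reference, pos, alt, 95.0)]
    )
    assert s.variants[0].trna_pathogenicity == cls
    assert s.variants[0].qualifies


def test_unknown_trna_does_not_qualify(reference, marker_table, trna_table):
    tl1 = reference.genes["MT-TL1"]
    pos = next(
        p for p in range(tl1.start, tl1.end + 1)
        if not any((p, a) in trna_table for a in "ACGT")
    )
    ref = reference.base_at(pos)
    alt = next(b for b in "ACGT" if b != ref)
    s = _qualified_sample(
        reference, marker_table, trna_table, [_variant_at(reference, pos, alt, 95.0)]
    )
    assert s.variants[0].trna_pathogenicity == "unknown"
    assert not s.variants[0].qualifies


def test_qualify_before_annotation_errors(reference, marker_table, trna_table):
    s = _sample(reference, "H2a", [_variant_at(reference, 3460, "A")])
    flag_haplogroup_markers(s, marker_table)
    with pytest.raises(OrderingError):
        qualify(s, trna_table)


def test_threshold_monotonicity(reference, marker_table, trna_table):
    # raising the heteroplasmy threshold never increases the qualifying count
    import random

    rng = random.Random(99)
    variants = [
        _variant_at(reference, 3460, "A", rng.uniform(80, 100)) for _ in range(20)
    ]
    s = _sample(reference, "H2a", variants)
    annotate_variants(s, reference)
    flag_haplogroup_markers(s, marker_table)
    counts = []
    for thr in (80.0, 85.0, 90.0, 95.0, 99.0):
        qualify(s, trna_table, het_threshold=thr)
        counts.append(s.qualifying_count)
    assert counts == sorted(counts, reverse=True)


def test_qualification_matches_bruteforce(reference, marker_table, trna_table):
    # oracle: re-derive every qualifies flag from first principles
    import random

    rng = random.Random(7)
    positions = rng.sample(range(3000, 16000), 40)
    variants = []
    for pos in positions:
        ref = reference.base_at(pos)
        alt = rng.choice([b for b in "ACGT" if b != ref])
        variants.append(_variant_at(reference, pos, alt, rng.uniform(70, 100)))
    s = _qualified_sample(reference, marker_table, trna_table, variants, "D4")
    markers = marker_table["D4"]
    for v in s.variants:
        feats = reference.locate(v.position)
        nonsyn = any(
            f.feature_type == "protein_coding"
            and reference.classify_consequence(v.position, v.ref_base, v.alt_base, f)
            == "nonsynonymous"
            for f in feats
        )
        trna = any(f.feature_type == "tRNA" for f in feats)
        pathogenic = trna and trna_table.get((v.position, v.alt_base)) in (
            "confirmed", "likely",
        )
        is_marker = markers.get((v.position, v.alt_base), 0.0) >= 80.0
        expected = (not is_marker) and v.heteroplasmy >= 90.0 and (nonsyn or pathogenic)
        assert v.qualifies == expected, (v.position, v.alt_base)


# ---------------------------------------------------------------------------
# per-embryo counting

def _count_sample(embryo, stage, count_or_none):
    if count_or_none is None:
        return SampleVariantSet(embryo, f"{embryo}-x", stage, "H2a", None)
    variants = [
        MtVariant(3460, "G", "A", heteroplasmy=95.0, annotated=True) for _ in range(count_or_none)
    ]
    for v in variants:
        v.qualifies = True
    return SampleVariantSet(embryo, f"{embryo}-x", stage, "H2a", variants)


def test_embryo_count_worked_examples():
    assert embryo_mutation_count(
        [_count_sample("1", "pre_culture", c) for c in (0, 0, 0)]
    ).mean_count == 0.0
    assert embryo_mutation_count(
        [_count_sample("10", "post_culture", c) for c in (1, 1, 1)]
    ).mean_count == 1.0
    assert embryo_mutation_count(
        [_count_sample("12", "pre_culture", c) for c in (1, 0)]
    ).mean_count == 0.5


def test_embryo_count_excludes_nd_samples():
    result = embryo_mutation_count(
        [_count_sample("3", "pre_culture", None), _count_sample("3", "pre_culture", 2)]
    )
    assert result.mean_count == 2.0
    assert result.sample_counts == (2,)


def test_embryo_count_all_nd_is_not_determinable():
    result = embryo_mutation_count([_count_sample("17", "pre_culture", None)])
    assert result.mean_count is None
    assert not result.determinable


def test_embryo_count_rejects_mixed_embryos():
    with pytest.raises(ValueError):
        embryo_mutation_count(
            [_count_sample("1", "pre_culture", 0), _count_sample("2", "pre_culture", 0)]
        )
    with pytest.raises(ValueError):
        embryo_mutation_count([])
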