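"""Synthetic embryo cohorts with the statistical structure the analysis assumes.

The generator emulates the study design end to end: each embryo gets a true
pre-culture karyotype class, 1-3 trophectoderm biopsies and 0-3 post-culture
outgrowth samples, an intrinsic mtDNA mutation burden drawn per karyotype
class, a post-culture karyotype produced by a logistic aneuploid-resolution
model (mosaic embryos with fewer mutations are more likely to resolve to
euploid), a logistic culturability outcome, per-sample variant tables with
binomial read sampling at configurable depth, haplogroup-marker background
variants and synonymous / sub-threshold decoys, and duplicate qPCR Ct values
with measurement noise. A ground-truth ledger sufficient to recompute every
expected pipeline output is produced alongside.

All randomness flows through one ``numpy`` generator seeded explicitly;
replicate seeds are derived by counter.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .karyotype import ChromosomeCall, ChromosomeProfile
from .reference import NONSYNONYMOUS, SYNONYMOUS, ReferenceGenome
from .variants import (
    POST_CULTURE,
    PRE_CULTURE,
    MarkerTable,
    MtVariant,
    SampleVariantSet,
)

CHROMOSOMES = [str(i) for i in range(1, 23)] + ["X", "Y"]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort generator.

    Defaults emulate the reference cohort: 27 embryos; pre-culture karyotype
    mixture ~15/66/19% euploid/mosaic/full-aneuploid; 2.1 biopsies and 1.2
    outgrowth samples per embryo on average; group mutation burdens around
    0.3 (euploid), 0.6 (mosaic) and 1.2 (full aneuploid) qualifying mutations
    per embryo; ~60% of zero-mutation mosaic embryos resolving to euploid;
    read depth 500x so the >=90% heteroplasmy threshold is exercised by
    binomial sampling.
    """

    n_embryos: int = 27
    karyotype_probs: dict = field(
        default_factory=lambda: {"euploid": 0.15, "mosaic": 0.66, "full_aneuploid": 0.19}
    )
    biopsies_probs: dict = field(default_factory=lambda: {1: 0.25, 2: 0.40, 3: 0.35})
    post_samples_probs: dict = field(
        default_factory=lambda: {0: 0.10, 1: 0.65, 2: 0.20, 3: 0.05}
    )
    mosaicism_range: tuple = (20.0, 80.0)
    biopsy_mosaicism_sd: float = 10.0
    aneuploid_mosaicism_mean: float = 95.0
    aneuploid_mosaicism_sd: float = 3.0
    # per-embryo qualifying-mutation burden ~ Poisson(lambda[pre-culture class])
    lambda_by_group: dict = field(
        default_factory=lambda: {"euploid": 0.3, "mosaic": 0.6, "full_aneuploid": 1.2}
    )
    # P(mosaic -> euploid post-culture) = logistic(alpha - beta * burden)
    resolution_alpha: float = 0.5
    resolution_beta: float = 0.8
    mosaic_to_full_aneuploid_p: float = 0.15
    euploid_to_mosaic_p: float = 0.25
    # P(culturable) = logistic(gamma - delta * burden)
    culturability_gamma: float = 1.2
    culturability_delta: float = 0.8
    not_cultured_p: float = 0.04
    # sequencing model
    read_depth: int = 500
    qualifying_het_range: tuple = (0.95, 1.0)
    synonymous_decoy_rate: float = 1.0
    synonymous_het_range: tuple = (0.90, 1.0)
    subthreshold_decoy_rate: float = 0.5
    subthreshold_het_range: tuple = (0.30, 0.85)
    haplogroups: tuple = ("H2a", "D4", "B4a")
    marker_planting_rate: float = 1.0
    marker_het_range: tuple = (0.97, 1.0)
    mutation_assay_fail_p: float = 0.05
    # qPCR model
    log2_copies_mean: float = 17.2  # 2^17.2 ~ 150k copies per embryo
    log2_copies_sd: float = 1.2
    b2m_ct_mean: float = 24.0
    b2m_ct_sd: float = 1.0
    ct_noise_sd: float = 0.15
    ct_replicates: int = 2
    dissociation_fail_p: float = 0.03

    def validate(self) -> None:
        for name, probs in (
            ("karyotype_probs", self.karyotype_probs),
            ("biopsies_probs", self.biopsies_probs),
            ("post_samples_probs", self.post_samples_probs),
        ):
            vals = list(probs.values())
            if any(p < 0 for p in vals) or not math.isclose(sum(vals), 1.0, abs_tol=1e-9):
                raise ConfigError(f"{name} must be a probability mixture summing to 1")
        if any(lam < 0 for lam in self.lambda_by_group.values()):
            raise ConfigError("mutation burden rates must be non-negative")
        if self.read_depth <= 0:
            raise ConfigError("read_depth must be positive")
        if self.ct_noise_sd < 0 or self.biopsy_mosaicism_sd < 0:
            raise ConfigError("noise SDs must be non-negative")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


def null_config(n_embryos: int = 200, burden: float = 1.5) -> SimulationConfig:
    """The no-association (type-I-error calibration) configuration.

    Burden is equal across karyotype classes and both logistic slopes are
    zero, so mutation counts are independent of every outcome. The burden
    level and balanced culturability are chosen so that the strata of the
    downstream 2x2 tables are well filled and the exact test's discreteness
    does not dominate the measured rejection rate.
    """
    return SimulationConfig(
        n_embryos=n_embryos,
        lambda_by_group={"euploid": burden, "mosaic": burden, "full_aneuploid": burden},
        resolution_beta=0.0,
        culturability_gamma=0.0,
        culturability_delta=0.0,
        not_cultured_p=0.0,
        mutation_assay_fail_p=0.0,
    )


def recovery_config(
    n_embryos: int = 200,
    lambda_euploid: float = 0.3,
    lambda_aneuploid: float = 1.2,
) -> SimulationConfig:
    """Parameter-recovery configuration: two karyotype classes with distinct
    planted burdens and no feedback (slopes zero), so pipeline group means
    estimate the planted rates directly."""
    return SimulationConfig(
        n_embryos=n_embryos,
        karyotype_probs={"euploid": 0.5, "mosaic": 0.0, "full_aneuploid": 0.5},
        lambda_by_group={
            "euploid": lambda_euploid,
            "mosaic": lambda_euploid,
            "full_aneuploid": lambda_aneuploid,
        },
        resolution_beta=0.0,
        culturability_delta=0.0,
        euploid_to_mosaic_p=0.0,
        not_cultured_p=0.0,
        mutation_assay_fail_p=0.0,
    )


@lru_cache(maxsize=4)
def _variant_pools(reference: ReferenceGenome):
    """All (position, ref, alt, genes) single-nucleotide substitutions in
    protein-coding genes, split by consequence. Computed once per reference."""
    nonsyn, syn = [], []
    for f in reference.features:
        if f.feature_type != "protein_coding":
            continue
        for pos in range(f.start, f.end + 1):
            ref = reference.base_at(pos)
            covering = reference.coding_features(pos)
            for alt in "ACGT":
                if alt == ref:
                    continue
                conseq = [
                    reference.classify_consequence(pos, ref, alt, g) for g in covering
                ]
                entry = (pos, ref, alt, tuple(g.name for g in covering))
                if NONSYNONYMOUS in conseq:
                    nonsyn.append(entry)
                elif all(c == SYNONYMOUS for c in conseq):
                    syn.append(entry)
    # overlap genes are scanned once per gene: deduplicate by (pos, alt)
    nonsyn = sorted({(p, r, a): (p, r, a, g) for p, r, a, g in nonsyn}.values())
    syn = sorted({(p, r, a): (p, r, a, g) for p, r, a, g in syn}.values())
    return nonsyn, syn


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground-truth ledger."""

    config: SimulationConfig
    seed: int
    truth: dict
    profiles: list
    variant_samples: list
    ct_table: pd.DataFrame
    culturability: dict

    def write(self, outdir: str | Path) -> None:
        """Emit the cohort in the dialects the pipeline consumes."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from . import io as mio

        mio.write_karyotype_csv(self.profiles, outdir / "karyotype.csv")
        mio.write_variants_tsv(self.variant_samples, outdir / "variants.tsv")
        self.ct_table.to_csv(outdir / "ct.csv", index=False)
        meta = pd.DataFrame(
            sorted(self.culturability.items()), columns=["embryo_id", "culturability"]
        )
        meta.to_csv(outdir / "culturability.csv", index=False)
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=2, sort_keys=True))


def simulate_cohort(
    config: SimulationConfig,
    seed: int,
    reference: ReferenceGenome,
    marker_table: MarkerTable,
    with_ct: bool = True,
) -> SyntheticCohort:
    """Generate one cohort. Deterministic given (config, seed)."""
    config.validate()
    rng = np.random.default_rng(seed)
    nonsyn_pool, syn_pool = _variant_pools(reference)

    kary_labels = list(config.karyotype_probs)
    kary_p = [config.karyotype_probs[k] for k in kary_labels]
    biopsy_n = list(config.biopsies_probs)
    biopsy_p = [config.biopsies_probs[k] for k in biopsy_n]
    post_n = list(config.post_samples_probs)
    post_p = [config.post_samples_probs[k] for k in post_n]

    profiles: list[ChromosomeProfile] = []
    variant_samples: list[SampleVariantSet] = []
    ct_rows: list[dict] = []
    culturability: dict[str, str] = {}
    truth_embryos: list[dict] = []

    for i in range(config.n_embryos):
        embryo_id = f"E{i + 1:03d}"
        pre_class = kary_labels[rng.choice(len(kary_labels), p=kary_p)]
        haplogroup = str(rng.choice(list(config.haplogroups)))
        burden = int(rng.poisson(config.lambda_by_group[pre_class]))

        # ---- post-culture karyotype via the resolution model
        signature = None
        if pre_class == "full_aneuploid":
            signature = (str(rng.choice(CHROMOSOMES[:22])), str(rng.choice(["gain", "loss"])))
            post_class = "full_aneuploid"
        elif pre_class == "mosaic":
            p_resolve = logistic(config.resolution_alpha - config.resolution_beta * burden)
            if rng.random() < p_resolve:
                post_class = "euploid"
            elif rng.random() < config.mosaic_to_full_aneuploid_p:
                post_class = "full_aneuploid"
                signature = (
                    str(rng.choice(CHROMOSOMES[:22])),
                    str(rng.choice(["gain", "loss"])),
                )
            else:
                post_class = "mosaic"
        else:
            post_class = "mosaic" if rng.random() < config.euploid_to_mosaic_p else "euploid"

        # ---- culturability
        if rng.random() < config.not_cultured_p:
            cult = "not_cultured"
        else:
            p_cult = logistic(
                config.culturability_gamma - config.culturability_delta * burden
            )
            cult = "culturable" if rng.random() < p_cult else "non_culturable"
        culturability[embryo_id] = cult

        # ---- chromosome profiles
        n_pre = biopsy_n[rng.choice(len(biopsy_n), p=biopsy_p)]
        if cult == "not_cultured":
            n_post = 0
        else:
            n_post = post_n[rng.choice(len(post_n), p=post_p)]
        mosaic_chrom = str(rng.choice(CHROMOSOMES[:22]))
        mosaic_state = str(rng.choice(["gain", "loss"]))
        true_mosaicism = float(rng.uniform(*config.mosaicism_range))

        def make_profile(sample_id: str, stage: str, klass: str) -> ChromosomeProfile:
            calls: list[ChromosomeCall] = []
            if klass == "mosaic":
                obs = float(
                    np.clip(rng.normal(true_mosaicism, config.biopsy_mosaicism_sd), 0, 100)
                )
                calls.append(ChromosomeCall(mosaic_chrom, mosaic_state, obs))
            elif klass == "full_aneuploid":
                obs = float(
                    np.clip(
                        rng.normal(
                            config.aneuploid_mosaicism_mean, config.aneuploid_mosaicism_sd
                        ),
                        0,
                        100,
                    )
                )
                calls.append(ChromosomeCall(signature[0], signature[1], obs))
            return ChromosomeProfile(sample_id, embryo_id, stage, tuple(calls))

        for j in range(n_pre):
            profiles.append(make_profile(f"{embryo_id}-pre{j + 1}", PRE_CULTURE, pre_class))
        for j in range(n_post):
            profiles.append(make_profile(f"{embryo_id}-post{j + 1}", POST_CULTURE, post_class))

        # ---- mtDNA variants (one embryo-wide set, binomially resampled per sample)
        planted_idx = rng.choice(len(nonsyn_pool), size=burden, replace=False)
        planted = [nonsyn_pool[k] for k in planted_idx]
        planted_het = rng.uniform(*config.qualifying_het_range, size=burden)

        n_syn = int(rng.poisson(config.synonymous_decoy_rate))
        syn_idx = rng.choice(len(syn_pool), size=n_syn, replace=False)
        syn_decoys = [syn_pool[k] for k in syn_idx]
        syn_het = rng.uniform(*config.synonymous_het_range, size=n_syn)

        n_sub = int(rng.poisson(config.subthreshold_decoy_rate))
        taken = set(planted_idx)
        sub_idx = [k for k in rng.choice(len(nonsyn_pool), size=n_sub + burden, replace=False)
                   if k not in taken][:n_sub]
        sub_decoys = [nonsyn_pool[k] for k in sub_idx]
        sub_het = rng.uniform(*config.subthreshold_het_range, size=len(sub_decoys))

        markers = [
            (pos, reference.base_at(pos), alt)
            for (pos, alt), freq in marker_table.get(haplogroup, {}).items()
            if rng.random() < config.marker_planting_rate
        ]
        marker_het = rng.uniform(*config.marker_het_range, size=len(markers))

        embryo_variants = (
            [(p, r, a, h, "planted") for (p, r, a, _), h in zip(planted, planted_het)]
            + [(p, r, a, h, "synonymous_decoy") for (p, r, a, _), h in zip(syn_decoys, syn_het)]
            + [(p, r, a, h, "subthreshold_decoy") for (p, r, a, _), h in zip(sub_decoys, sub_het)]
            + [(p, r, a, h, "haplogroup_marker") for (p, r, a), h in zip(markers, marker_het)]
        )

        def make_variant_sample(sample_id: str, stage: str) -> SampleVariantSet:
            if rng.random() < config.mutation_assay_fail_p:
                return SampleVariantSet(embryo_id, sample_id, stage, haplogroup, None)
            vs = []
            for pos, ref, alt, het, _ in embryo_variants:
                depth = config.read_depth
                alt_reads = int(rng.binomial(depth, het))
                if alt_reads == 0:
                    continue  # variant not observed in this sample
                vs.append(MtVariant(pos, ref, alt, alt_reads, depth))
            return SampleVariantSet(embryo_id, sample_id, stage, haplogroup, vs)

        for j in range(n_pre):
            variant_samples.append(make_variant_sample(f"{embryo_id}-pre{j + 1}", PRE_CULTURE))
        for j in range(n_post):
            variant_samples.append(make_variant_sample(f"{embryo_id}-post{j + 1}", POST_CULTURE))

        # ---- qPCR Ct values
        true_copies: dict[str, float] = {}
        if with_ct:
            for stage, n_samples in ((PRE_CULTURE, n_pre), (POST_CULTURE, n_post)):
                tag = "pre" if stage == PRE_CULTURE else "post"
                for j in range(n_samples):
                    sample_id = f"{embryo_id}-{tag}{j + 1}"
                    log2_copies = rng.normal(config.log2_copies_mean, config.log2_copies_sd)
                    true_copies[sample_id] = float(2.0 ** log2_copies)
                    delta_ct = 1.0 - (log2_copies - math.log2(100.0))
                    b2m = rng.normal(config.b2m_ct_mean, config.b2m_ct_sd)
                    for gene, base_ct in (("B2M", b2m), ("MT_TL1", b2m + delta_ct)):
                        for rep in range(1, config.ct_replicates + 1):
                            ct_rows.append(
                                {
                                    "sample_id": sample_id,
                                    "embryo_id": embryo_id,
                                    "stage": stage,
                                    "gene": gene,
                                    "replicate": rep,
                                    "ct": float(base_ct + rng.normal(0, config.ct_noise_sd)),
                                    "dissociation_ok": bool(
                                        rng.random() >= config.dissociation_fail_p
                                    ),
                                }
                            )

        truth_embryos.append(
            {
                "embryo_id": embryo_id,
                "haplogroup": haplogroup,
                "pre_karyotype": pre_class,
                "post_karyotype": post_class,
                "culturability": cult,
                "true_burden": burden,
                "true_mosaicism": true_mosaicism if pre_class == "mosaic" else None,
                "aneuploidy_signature": list(signature) if signature else None,
                "planted_variants": [
                    {"position": int(p), "ref": r, "alt": a, "genes": list(g)}
                    for (p, r, a, g) in planted
                ],
                "n_pre_samples": int(n_pre),
                "n_post_samples": int(n_post),
                "true_copies_per_sample": true_copies,
            }
        )

    truth = {
        "seed": int(seed),
        "lambda_by_group": dict(config.lambda_by_group),
        "embryos": truth_embryos,
    }
    return SyntheticCohort(
        config=config,
        seed=seed,
        truth=truth,
        profiles=profiles,
        variant_samples=variant_samples,
        ct_table=pd.DataFrame(ct_rows),
        culturability=culturability,
    )
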