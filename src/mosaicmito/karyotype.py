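"""Karyotype classification of biopsy samples and embryos.

A sample is *mosaic* when any chromosome shows 20-80% mosaicism (inclusive
band), *aneuploid* when any non-normal chromosome exceeds 80%, otherwise
*euploid* (abnormal calls below 20% mosaicism are treated as noise). An
embryo is classified from the concordance of its samples: all euploid ->
euploid; all aneuploid with the identical signed signature -> full aneuploid;
any mosaic sample or any disagreement -> mosaic. Mosaic embryos are
stratified by the maximum per-chromosome mosaicism across all their samples:
[20, 50] low, above 50 high (the 50% boundary goes to the low band).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

EUPLOID = "euploid"
MOSAIC = "mosaic"
ANEUPLOID = "aneuploid"  # sample-level label
FULL_ANEUPLOID = "full_aneuploid"  # embryo-level label
NOT_DETERMINABLE = "not_determinable"

MOSAIC_LOW = 20.0
MOSAIC_HIGH = 80.0
LEVEL_SPLIT = 50.0

EMBRYO_LABELS = (EUPLOID, MOSAIC, FULL_ANEUPLOID)


@dataclass(frozen=True)
class ChromosomeCall:
    chromosome: str
    state: str  # normal | gain | loss | segmental
    mosaicism: float  # percent in [0, 100]

    def __post_init__(self) -> None:
        if not 0.0 <= self.mosaicism <= 100.0:
            raise ValueError(f"mosaicism {self.mosaicism} outside [0, 100]")


@dataclass
class ChromosomeProfile:
    """Per-chromosome calls of one biopsy or outgrowth sample."""

    sample_id: str
    embryo_id: str
    stage: str  # pre_culture | post_culture
    calls: Sequence[ChromosomeCall] = ()
    determinable: bool = True

    def __post_init__(self) -> None:
        labels = Counter(c.chromosome for c in self.calls)
        dupes = [c for c, n in labels.items() if n > 1]
        if dupes:
            raise ValueError(f"duplicate chromosome calls: {dupes}")


@dataclass(frozen=True)
class SampleKaryotype:
    sample_id: str
    label: str  # euploid | mosaic | aneuploid | not_determinable
    aneuploidy_signature: tuple[tuple[str, str], ...] = ()  # sorted (chrom, state)
    max_mosaicism: float = 0.0

    @property
    def determinable(self) -> bool:
        return self.label != NOT_DETERMINABLE


@dataclass(frozen=True)
class EmbryoKaryotype:
    embryo_id: str
    stage: str
    label: str  # euploid | mosaic | full_aneuploid | not_determinable
    mosaic_level: str = "not_applicable"  # low | high | not_applicable

    @property
    def determinable(self) -> bool:
        return self.label != NOT_DETERMINABLE


def classify_sample(profile: ChromosomeProfile) -> SampleKaryotype:
    """Karyotype of a single sample from its per-chromosome calls."""
    if not profile.determinable:
        return SampleKaryotype(profile.sample_id, NOT_DETERMINABLE)
    abnormal = [c for c in profile.calls if c.state != "normal"]
    max_mos = max((c.mosaicism for c in abnormal), default=0.0)
    if any(MOSAIC_LOW <= c.mosaicism <= MOSAIC_HIGH for c in abnormal):
        return SampleKaryotype(profile.sample_id, MOSAIC, (), max_mos)
    signature = tuple(
        sorted((c.chromosome, c.state) for c in abnormal if c.mosaicism > MOSAIC_HIGH)
    )
    if signature:
        return SampleKaryotype(profile.sample_id, ANEUPLOID, signature, max_mos)
    return SampleKaryotype(profile.sample_id, EUPLOID, (), max_mos)


def classify_embryo(samples: Iterable[SampleKaryotype]) -> EmbryoKaryotype:
    """Embryo karyotype from the concordance of its sample karyotypes.

    Permutation-invariant. Embryo/stage identity is the caller's bookkeeping;
    this operates on the labels alone (IDs are taken from context elsewhere).
    """
    samples = list(samples)
    if not samples:
        raise ValueError("no samples given")
    usable = [s for s in samples if s.determinable]
    if not usable:
        return EmbryoKaryotype("", "", NOT_DETERMINABLE)
    labels = {s.label for s in usable}
    if labels == {EUPLOID}:
        return EmbryoKaryotype("", "", EUPLOID)
    if labels == {ANEUPLOID}:
        signatures = {s.aneuploidy_signature for s in usable}
        if len(signatures) == 1:
            return EmbryoKaryotype("", "", FULL_ANEUPLOID)
        # discordant full aneuploidies across samples -> mosaic embryo
        return EmbryoKaryotype("", "", MOSAIC)
    return EmbryoKaryotype("", "", MOSAIC)


def classify_embryo_from_profiles(
    profiles: Sequence[ChromosomeProfile],
) -> EmbryoKaryotype:
    """Classify an embryo at one stage directly from its sample profiles."""
    if not profiles:
        raise ValueError("no profiles given")
    ids = {p.embryo_id for p in profiles}
    stages = {p.stage for p in profiles}
    if len(ids) > 1 or len(stages) > 1:
        raise ValueError(f"profiles span embryos {ids} / stages {stages}")
    result = classify_embryo(classify_sample(p) for p in profiles)
    level = "not_applicable"
    if result.label == MOSAIC:
        level = mosaic_level(profiles)
    return EmbryoKaryotype(profiles[0].embryo_id, profiles[0].stage, result.label, level)


def mosaic_level(embryo_profiles: Sequence[ChromosomeProfile]) -> str:
    """Low/high mosaicism stratum of a mosaic embryo.

    Uses the maximum per-chromosome mosaicism across all the embryo's
    samples: [20, 50] -> low, above 50 -> high (values above 80 arise for
    mosaic-by-discordance embryos and fall in the high stratum).
    """
    labels = [classify_sample(p) for p in embryo_profiles if p.determinable]
    if classify_embryo(labels).label != MOSAIC:
        raise RuntimeError("mosaic_level is defined only for mosaic embryos")
    max_mos = max(s.max_mosaicism for s in labels)
    return "low" if max_mos <= LEVEL_SPLIT else "high"


def karyotype_distribution(
    karyotypes: Iterable[EmbryoKaryotype], stage: str
) -> dict[str, dict[str, float | int | None]]:
    """Counts and ratios of embryo karyotype labels at one stage.

    Ratios are over embryos with a determinable karyotype at that stage; with
    zero determinable embryos the ratios are None.
    """
    at_stage = [k for k in karyotypes if k.stage == stage and k.determinable]
    n = len(at_stage)
    counts = Counter(k.label for k in at_stage)
    return {
        label: {
            "count": counts.get(label, 0),
            "ratio": counts.get(label, 0) / n if n else None,
            "n_determinable": n,
        }
        for label in EMBRYO_LABELS
    }
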