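"""Heteroplasmy, haplogroup-marker exclusion, and mutation qualification.

A variant *qualifies* (is counted as a high-impact mtDNA mutation) when it is
not a haplogroup marker, reaches >=90% heteroplasmy, and either changes an
amino acid in at least one covering protein-coding gene or is a
confirmed/likely pathogenic tRNA variant. Thresholds are inclusive
(heteroplasmy >= 90, marker population frequency >= 80).

Per-embryo mutation burden is sample-adjusted: the per-sample qualifying
counts are summed and divided by the number of samples with determinable
data. Variants are counted per sample independently; no cross-sample identity
matching is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .reference import NONSYNONYMOUS, TRNA_VARIANT, ReferenceGenome

PRE_CULTURE = "pre_culture"
POST_CULTURE = "post_culture"

HETEROPLASMY_THRESHOLD = 90.0  # percent, inclusive
MARKER_FREQUENCY_THRESHOLD = 80.0  # percent, inclusive

#: tRNA pathogenicity classes that qualify a tRNA variant
PATHOGENIC_TRNA_CLASSES = frozenset({"confirmed", "likely"})


class NoCoverageError(ValueError):
    """Heteroplasmy requested at a site with zero sequencing depth."""


class InconsistentReadError(ValueError):
    """More alternate reads than total reads."""


class OrderingError(RuntimeError):
    """Qualification requested before annotation."""


class ConfigurationError(ValueError):
    """A sample's haplogroup is missing from the marker table."""


def heteroplasmy(alt_reads: int, total_reads: int) -> float:
    """Percentage of reads carrying the variant at its site."""
    if total_reads <= 0:
        raise NoCoverageError("total_reads must be positive")
    if alt_reads < 0 or alt_reads > total_reads:
        raise InconsistentReadError(
            f"alt_reads {alt_reads} outside 0..total_reads {total_reads}"
        )
    return 100.0 * alt_reads / total_reads


@dataclass
class MtVariant:
    """One mtDNA single-nucleotide substitution in one sample."""

    position: int
    ref_base: str
    alt_base: str
    alt_reads: int | None = None
    total_reads: int | None = None
    heteroplasmy: float | None = None  # percent in [0, 100]
    genes: tuple[str, ...] = ()
    consequences: tuple[str, ...] = ()  # aligned with ``genes``
    is_haplogroup_marker: bool = False
    trna_pathogenicity: str = "not_trna"  # confirmed | likely | unknown | not_trna
    qualifies: bool = False
    annotated: bool = False

    def __post_init__(self) -> None:
        if self.alt_reads is not None and self.total_reads is not None:
            # read counts are authoritative when present
            self.heteroplasmy = heteroplasmy(self.alt_reads, self.total_reads)
        if self.heteroplasmy is None:
            raise ValueError(
                f"variant at {self.position}: need read counts or a heteroplasmy value"
            )
        if not 0.0 <= self.heteroplasmy <= 100.0:
            raise ValueError(f"heteroplasmy {self.heteroplasmy} outside [0, 100]")

    @property
    def key(self) -> tuple[int, str]:
        return (self.position, self.alt_base)

    def nonsynonymous_genes(self) -> tuple[str, ...]:
        return tuple(
            g for g, c in zip(self.genes, self.consequences) if c == NONSYNONYMOUS
        )

    @property
    def is_trna(self) -> bool:
        return TRNA_VARIANT in self.consequences


@dataclass
class SampleVariantSet:
    """All variants observed in one biopsy/outgrowth sample.

    ``variants=None`` marks a sample whose mtDNA assay failed (the cohort
    table's "ND"); such samples are excluded from per-embryo averaging.
    """

    embryo_id: str
    sample_id: str
    stage: str  # pre_culture | post_culture
    haplogroup: str
    variants: list[MtVariant] | None = field(default_factory=list)

    @property
    def determinable(self) -> bool:
        return self.variants is not None

    @property
    def qualifying_count(self) -> int | None:
        if self.variants is None:
            return None
        return sum(v.qualifies for v in self.variants)


@dataclass(frozen=True)
class EmbryoMutationCount:
    """Sample-adjusted qualifying-mutation burden of one embryo at one stage."""

    embryo_id: str
    stage: str
    sample_counts: tuple[int, ...]
    mean_count: float | None  # None = not determinable

    @property
    def determinable(self) -> bool:
        return self.mean_count is not None


def annotate_variants(
    sample: SampleVariantSet, reference: ReferenceGenome
) -> SampleVariantSet:
    """Fill per-variant gene lists and consequences from the reference."""
    if sample.variants is None:
        return sample
    for v in sample.variants:
        feats = reference.locate(v.position)
        v.genes = tuple(f.name for f in feats)
        v.consequences = tuple(
            reference.classify_consequence(v.position, v.ref_base, v.alt_base, f)
            for f in feats
        )
        v.annotated = True
    return sample


MarkerTable = Mapping[str, Mapping[tuple[int, str], float]]
TrnaTable = Mapping[tuple[int, str], str]


def flag_haplogroup_markers(
    sample: SampleVariantSet, marker_table: MarkerTable
) -> SampleVariantSet:
    """Flag variants that are markers of the sample's haplogroup.

    A variant is a marker when its (position, alt) is listed for the sample's
    haplogroup at a population frequency of 80% or higher. Idempotent.
    """
    if sample.haplogroup not in marker_table:
        raise ConfigurationError(
            f"haplogroup {sample.haplogroup!r} not in marker table; available: "
            f"{sorted(marker_table)}"
        )
    markers = marker_table[sample.haplogroup]
    if sample.variants is None:
        return sample
    for v in sample.variants:
        freq = markers.get(v.key)
        v.is_haplogroup_marker = freq is not None and freq >= MARKER_FREQUENCY_THRESHOLD
    return sample


def qualify(
    sample: SampleVariantSet,
    pathogenic_trna_table: TrnaTable,
    het_threshold: float = HETEROPLASMY_THRESHOLD,
) -> SampleVariantSet:
    """Apply the qualification filter to an annotated, marker-flagged sample.

    qualifies <=> not a haplogroup marker, heteroplasmy >= threshold, and
    (nonsynonymous in >=1 covering protein-coding gene, or a confirmed/likely
    pathogenic tRNA variant).
    """
    if sample.variants is None:
        return sample
    for v in sample.variants:
        if not v.annotated:
            raise OrderingError(
                f"variant at {v.position} not annotated; run annotate_variants first"
            )
        if v.is_trna:
            v.trna_pathogenicity = pathogenic_trna_table.get(v.key, "unknown")
        else:
            v.trna_pathogenicity = "not_trna"
        impactful = bool(v.nonsynonymous_genes()) or (
            v.is_trna and v.trna_pathogenicity in PATHOGENIC_TRNA_CLASSES
        )
        v.qualifies = (
            not v.is_haplogroup_marker
            and v.heteroplasmy >= het_threshold
            and impactful
        )
    return sample


def embryo_mutation_count(samples: Iterable[SampleVariantSet]) -> EmbryoMutationCount:
    """Sample-adjusted per-embryo mutation count for one embryo and stage.

    Non-determinable samples are excluded from numerator and denominator;
    if no sample is determinable the result is flagged not-determinable
    (mean_count None) rather than raising, matching the cohort table's "ND".
    """
    samples = list(samples)
    if not samples:
        raise ValueError("no samples given")
    ids = {s.embryo_id for s in samples}
    stages = {s.stage for s in samples}
    if len(ids) > 1 or len(stages) > 1:
        raise ValueError(f"samples span embryos {ids} / stages {stages}")
    counts = tuple(
        s.qualifying_count for s in samples if s.determinable
    )
    if not counts:
        return EmbryoMutationCount(samples[0].embryo_id, samples[0].stage, (), None)
    return EmbryoMutationCount(
        samples[0].embryo_id, samples[0].stage, counts, sum(counts) / len(counts)
    )


def embryo_gene_counts(samples: Iterable[SampleVariantSet]) -> dict[str, float]:
    """Sample-adjusted per-gene qualifying-mutation counts for one embryo.

    A qualifying variant contributes once per protein-coding gene it is
    nonsynonymous in (overlap-gene variants appear under each gene in
    location tallies) and once under each covering tRNA gene if it qualified
    as a pathogenic tRNA variant.
    """
    samples = [s for s in samples if s.determinable]
    if not samples:
        return {}
    totals: dict[str, float] = {}
    for s in samples:
        for v in s.variants:
            if not v.qualifies:
                continue
            genes = v.nonsynonymous_genes()
            if not genes and v.is_trna:
                genes = tuple(
                    g for g, c in zip(v.genes, v.consequences) if c == TRNA_VARIANT
                )
            for g in genes:
                totals[g] = totals.get(g, 0.0) + 1.0
    n = len(samples)
    return {g: c / n for g, c in totals.items()}


# ---------------------------------------------------------------------------
# table loaders

def load_marker_table(path: str | Path) -> dict[str, dict[tuple[int, str], float]]:
    """TSV with columns haplogroup, position, alt, frequency (percent)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    table: dict[str, dict[tuple[int, str], float]] = {}
    for row in df.itertuples(index=False):
        table.setdefault(str(row.haplogroup), {})[
            (int(row.position), str(row.alt))
        ] = float(row.frequency)
    return table


def load_trna_table(path: str | Path) -> dict[tuple[int, str], str]:
    """TSV with columns position, alt, classification (confirmed/likely)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    bad = set(df["classification"]) - {"confirmed", "likely"}
    if bad:
        raise ValueError(f"unknown tRNA pathogenicity classes: {bad}")
    return {
        (int(r.position), str(r.alt)): str(r.classification)
        for r in df.itertuples(index=False)
    }
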