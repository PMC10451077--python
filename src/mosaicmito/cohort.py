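"""Embryo-level cohort container used by the statistical report layer.

An :class:`EmbryoRecord` is the per-embryo summary the upstream modules
produce: stage-wise karyotype labels, culturability, per-sample qualifying
mutation counts, and mean mtDNA copy numbers. "ND" (not determinable) is
represented as None; per-sample ND entries are None inside the count tuples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .karyotype import EmbryoKaryotype, karyotype_distribution
from .variants import PRE_CULTURE, POST_CULTURE

CULTURABLE = "culturable"
NON_CULTURABLE = "non_culturable"
NOT_CULTURED = "not_cultured"

STAGES = (PRE_CULTURE, POST_CULTURE)


def _mean_of_determinable(
    counts: Sequence[float | None] | None,
) -> float | None:
    """Sample-adjusted mean over determinable per-sample counts."""
    if counts is None:
        return None
    usable = [c for c in counts if c is not None]
    if not usable:
        return None
    return sum(usable) / len(usable)


@dataclass
class EmbryoRecord:
    embryo_id: str
    culturability: str | None = None  # culturable | non_culturable | not_cultured
    pre_karyotype: str | None = None  # euploid | mosaic | full_aneuploid | None=ND
    post_karyotype: str | None = None
    pre_sample_counts: tuple[float | None, ...] | None = None
    post_sample_counts: tuple[float | None, ...] | None = None
    pre_mean_copies: float | None = None
    post_mean_copies: float | None = None
    mosaic_level: str = "not_applicable"

    def karyotype(self, stage: str) -> str | None:
        return self.pre_karyotype if stage == PRE_CULTURE else self.post_karyotype

    def sample_counts(self, stage: str) -> tuple[float | None, ...] | None:
        return self.pre_sample_counts if stage == PRE_CULTURE else self.post_sample_counts

    def mean_mutations(self, stage: str) -> float | None:
        return _mean_of_determinable(self.sample_counts(stage))

    def mean_copies(self, stage: str) -> float | None:
        return self.pre_mean_copies if stage == PRE_CULTURE else self.post_mean_copies

    def post_karyotype_group(self) -> str | None:
        """euploid vs aneuploid (mosaic + full aneuploid), by post-culture
        karyotype; None when the post-culture karyotype is not determinable."""
        if self.post_karyotype is None:
            return None
        return "euploid" if self.post_karyotype == "euploid" else "aneuploid"

    def culturability_group(self) -> str | None:
        """culturable vs non-culturable; never-cultured embryos are excluded."""
        if self.culturability in (CULTURABLE, NON_CULTURABLE):
            return self.culturability
        return None


class Cohort:
    """An ordered collection of embryo records."""

    def __init__(self, embryos: Iterable[EmbryoRecord]):
        self.embryos = list(embryos)
        ids = [e.embryo_id for e in self.embryos]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate embryo ids")

    def __len__(self) -> int:
        return len(self.embryos)

    def __iter__(self):
        return iter(self.embryos)

    def karyotypes(self, stage: str) -> list[EmbryoKaryotype]:
        out = []
        for e in self.embryos:
            label = e.karyotype(stage)
            out.append(
                EmbryoKaryotype(
                    e.embryo_id,
                    stage,
                    label if label is not None else "not_determinable",
                    e.mosaic_level if label == "mosaic" else "not_applicable",
                )
            )
        return out

    def karyotype_distribution(self, stage: str):
        return karyotype_distribution(self.karyotypes(stage), stage)

    def mutation_counts(self, stage: str) -> dict[str, float | None]:
        """embryo id -> sample-adjusted mean qualifying count (None = ND)."""
        return {e.embryo_id: e.mean_mutations(stage) for e in self.embryos}

    def groups(self, grouping: str) -> dict[str, str | None]:
        """embryo id -> group label under a grouping scheme."""
        if grouping == "post_karyotype":
            return {e.embryo_id: e.post_karyotype_group() for e in self.embryos}
        if grouping == "culturability":
            return {e.embryo_id: e.culturability_group() for e in self.embryos}
        raise ValueError(f"unknown grouping {grouping!r}")

    def subset(self, predicate) -> "Cohort":
        return Cohort(e for e in self.embryos if predicate(e))
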