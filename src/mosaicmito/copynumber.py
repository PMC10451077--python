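"""Relative mtDNA copy number from paired qPCR Ct values.

The assay measures the nuclear reference gene B2M and the mitochondrial
target MT-TL1 in duplicate wells. Replicates failing the dissociation-curve
check are dropped; the remaining Cts are averaged. With the convention
dCt = Ct(MT-TL1) - Ct(B2M) (more mtDNA -> smaller dCt) and no external
calibrator (ddCt = dCt), the copies per embryo are

    copies = 100 * 2 ** (-ddCt + 1)

where the factor 100 assumes 100 cells per blastocyst. Amplification
efficiency is fixed at perfect doubling. Measurements above 1e6 copies per
embryo are excluded as measurement error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

B2M = "B2M"
MT_TL1 = "MT_TL1"

COPIES_EXCLUSION_LIMIT = 1e6
CELLS_PER_BLASTOCYST = 100.0


@dataclass(frozen=True)
class CtMeasurement:
    """Replicate Ct values of one gene in one sample."""

    sample_id: str
    gene: str  # B2M | MT_TL1
    replicate_cts: tuple[float, ...]
    dissociation_ok: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.replicate_cts) != len(self.dissociation_ok):
            raise ValueError("one dissociation flag per replicate required")
        if any(not (ct > 0 and math.isfinite(ct)) for ct in self.replicate_cts):
            raise ValueError("Ct values must be positive and finite")


@dataclass(frozen=True)
class CopyNumberResult:
    sample_id: str
    delta_ct: float | None
    copies_per_embryo: float | None
    excluded: bool = False
    reason: str = "none"  # none | over_1e6 | no_valid_replicate

    @property
    def usable(self) -> bool:
        return not self.excluded and self.copies_per_embryo is not None


def mean_ct(measurement: CtMeasurement) -> float | None:
    """Mean Ct over replicates that passed the dissociation-curve check.

    Returns None when no replicate is valid (the caller emits an excluded
    result with reason ``no_valid_replicate``).
    """
    valid = [
        ct for ct, ok in zip(measurement.replicate_cts, measurement.dissociation_ok) if ok
    ]
    if not valid:
        return None
    return sum(valid) / len(valid)


def copies_per_embryo(
    ct_target: float | None,
    ct_reference: float | None,
    sample_id: str = "",
    calibrator_delta_ct: float = 0.0,
    orientation: str = "target_minus_reference",
) -> CopyNumberResult:
    """Copies per embryo from mean target (MT-TL1) and reference (B2M) Cts.

    ``orientation`` flips the dCt sign convention; ``calibrator_delta_ct``
    (default 0, i.e. ddCt = dCt) activates a true delta-delta design when a
    calibrator sample is available.
    """
    if ct_target is None or ct_reference is None:
        return CopyNumberResult(sample_id, None, None, True, "no_valid_replicate")
    if orientation == "target_minus_reference":
        delta = ct_target - ct_reference
    elif orientation == "reference_minus_target":
        delta = ct_reference - ct_target
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    ddct = delta - calibrator_delta_ct
    copies = CELLS_PER_BLASTOCYST * 2.0 ** (-ddct + 1.0)
    if copies > COPIES_EXCLUSION_LIMIT:
        return CopyNumberResult(sample_id, delta, copies, True, "over_1e6")
    return CopyNumberResult(sample_id, delta, copies)


def sample_copy_number(
    target: CtMeasurement, reference: CtMeasurement, **kwargs
) -> CopyNumberResult:
    """Full per-sample pipeline: replicate means then the 2^-ddCt formula."""
    if target.gene != MT_TL1 or reference.gene != B2M:
        raise ValueError("expected an MT_TL1 target and a B2M reference measurement")
    return copies_per_embryo(
        mean_ct(target), mean_ct(reference), sample_id=target.sample_id, **kwargs
    )


def embryo_copy_number(results: Iterable[CopyNumberResult]) -> float | None:
    """Mean copies per embryo over non-excluded sample results.

    None (not determinable) when no usable result remains.
    """
    usable = [r.copies_per_embryo for r in results if r.usable]
    if not usable:
        return None
    return sum(usable) / len(usable)
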