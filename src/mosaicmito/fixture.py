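"""The bundled 27-embryo reference cohort.

A transcription of the study cohort's per-embryo summary: culturability,
pre- and post-culture karyotype, mean mtDNA copy number, and the raw
qualifying-mutation count of every sample at both stages, with "ND"
(not determinable) markers preserved. Loaded into pipeline-native
:class:`~mosaicmito.cohort.Cohort` form.

The transcription also keeps the table's *printed* per-embryo mean mutation
numbers; the loader recomputes means from the raw per-sample counts and
checks them against the printed values at the table's 1-decimal rounding.
Two known quirks are tolerated: one embryo's 1/3 prints as 0.3, and the
never-cultured embryo prints 0.0 for a stage it has no samples at (recomputed
as ND).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .cohort import Cohort, EmbryoRecord
from .reference import IntegrityError, verify_bundled_checksum

_FIXTURE_NAME = "table1_embryos.csv"


def _parse_counts(cell: str) -> tuple[float | None, ...] | None:
    if cell == "ND":
        return None
    return tuple(None if tok == "ND" else float(tok) for tok in cell.split(";"))


def _parse_scalar(cell) -> float | None:
    return None if cell == "ND" else float(cell)


def load_table1_fixture(path: str | Path | None = None) -> Cohort:
    """The bundled cohort in pipeline-native form (checksum-verified)."""
    if path is None:
        path = Path(str(resources.files("mosaicmito") / "_data" / _FIXTURE_NAME))
        verify_bundled_checksum(path)
    df = pd.read_csv(path, dtype=str)
    embryos = []
    for row in df.itertuples(index=False):
        rec = EmbryoRecord(
            embryo_id=str(row.embryo_id),
            culturability=row.culturability,
            pre_karyotype=_none_if_nd(row.pre_karyotype),
            post_karyotype=_none_if_nd(row.post_karyotype),
            pre_sample_counts=_parse_counts(row.pre_counts),
            post_sample_counts=_parse_counts(row.post_counts),
            pre_mean_copies=_parse_scalar(row.pre_copies),
            post_mean_copies=_parse_scalar(row.post_copies),
        )
        _check_printed_mean(rec, "pre_culture", _parse_scalar(row.printed_mean_pre))
        _check_printed_mean(rec, "post_culture", _parse_scalar(row.printed_mean_post))
        embryos.append(rec)
    cohort = Cohort(embryos)
    if len(cohort) != 27:
        raise IntegrityError(f"expected 27 embryos in the fixture, found {len(cohort)}")
    return cohort


def _none_if_nd(cell: str) -> str | None:
    return None if cell == "ND" else cell


def _check_printed_mean(rec: EmbryoRecord, stage: str, printed: float | None) -> None:
    derived = rec.mean_mutations(stage)
    if derived is None or printed is None:
        return  # ND on either side: the table prints 0.0 for one ND stage
    if round(derived, 1) != round(printed, 1):
        raise IntegrityError(
            f"embryo {rec.embryo_id} {stage}: derived mean {derived} does not "
            f"match printed {printed}"
        )
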