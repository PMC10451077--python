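"""End-to-end assembly: raw per-sample data -> embryo-level cohort.

Takes the three raw inputs (per-sample chromosome profiles, per-sample
variant sets, per-sample qPCR Ct values) plus the per-embryo culturability
outcome, runs the per-module pipelines (karyotype classification, variant
qualification, copy-number computation), and assembles one
:class:`~mosaicmito.cohort.EmbryoRecord` per embryo. Missing data at any
stage becomes None ("not determinable") rather than an error.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping

import pandas as pd

from .cohort import Cohort, EmbryoRecord
from .copynumber import (
    B2M,
    MT_TL1,
    CtMeasurement,
    embryo_copy_number,
    sample_copy_number,
)
from .karyotype import ChromosomeProfile, classify_embryo_from_profiles
from .reference import ReferenceGenome
from .variants import (
    POST_CULTURE,
    PRE_CULTURE,
    MarkerTable,
    SampleVariantSet,
    TrnaTable,
    annotate_variants,
    flag_haplogroup_markers,
    qualify,
)

STAGES = (PRE_CULTURE, POST_CULTURE)


def classify_karyotypes(
    profiles: Iterable[ChromosomeProfile],
) -> dict[tuple[str, str], tuple[str | None, str]]:
    """(embryo, stage) -> (embryo karyotype label or None, mosaic level)."""
    grouped: dict[tuple[str, str], list[ChromosomeProfile]] = defaultdict(list)
    for p in profiles:
        grouped[(p.embryo_id, p.stage)].append(p)
    out = {}
    for key, group in grouped.items():
        result = classify_embryo_from_profiles(group)
        label = result.label if result.determinable else None
        out[key] = (label, result.mosaic_level)
    return out


def qualify_samples(
    variant_samples: Iterable[SampleVariantSet],
    reference: ReferenceGenome,
    marker_table: MarkerTable,
    trna_table: TrnaTable,
) -> dict[tuple[str, str], tuple[int | None, ...]]:
    """(embryo, stage) -> per-sample qualifying counts (None = assay failed)."""
    grouped: dict[tuple[str, str], list[int | None]] = defaultdict(list)
    for s in variant_samples:
        annotate_variants(s, reference)
        flag_haplogroup_markers(s, marker_table)
        qualify(s, trna_table)
        grouped[(s.embryo_id, s.stage)].append(s.qualifying_count)
    return {k: tuple(v) for k, v in grouped.items()}


def copy_numbers(ct_table: pd.DataFrame) -> dict[tuple[str, str], float | None]:
    """(embryo, stage) -> mean copies per embryo over usable samples.

    Expects long-format rows: sample_id, embryo_id, stage, gene, replicate,
    ct, dissociation_ok.
    """
    out: dict[tuple[str, str], float | None] = {}
    if ct_table is None or ct_table.empty:
        return out
    for (embryo, stage), chunk in ct_table.groupby(["embryo_id", "stage"]):
        results = []
        for sample_id, sample_chunk in chunk.groupby("sample_id"):
            measurements = {}
            for gene, g in sample_chunk.groupby("gene"):
                g = g.sort_values("replicate")
                measurements[gene] = CtMeasurement(
                    str(sample_id),
                    str(gene),
                    tuple(float(x) for x in g["ct"]),
                    tuple(bool(x) for x in g["dissociation_ok"]),
                )
            if MT_TL1 not in measurements or B2M not in measurements:
                continue
            results.append(sample_copy_number(measurements[MT_TL1], measurements[B2M]))
        out[(str(embryo), str(stage))] = embryo_copy_number(results)
    return out


def build_cohort(
    profiles: Iterable[ChromosomeProfile],
    variant_samples: Iterable[SampleVariantSet],
    culturability: Mapping[str, str],
    reference: ReferenceGenome,
    marker_table: MarkerTable,
    trna_table: TrnaTable,
    ct_table: pd.DataFrame | None = None,
) -> Cohort:
    """Assemble per-embryo records from raw per-sample data."""
    karyotypes = classify_karyotypes(profiles)
    counts = qualify_samples(variant_samples, reference, marker_table, trna_table)
    copies = copy_numbers(ct_table) if ct_table is not None else {}

    embryo_ids = sorted(
        {k[0] for k in karyotypes}
        | {k[0] for k in counts}
        | {k[0] for k in copies}
        | set(culturability)
    )
    records = []
    for eid in embryo_ids:
        pre_k, pre_level = karyotypes.get((eid, PRE_CULTURE), (None, "not_applicable"))
        post_k, _ = karyotypes.get((eid, POST_CULTURE), (None, "not_applicable"))
        records.append(
            EmbryoRecord(
                embryo_id=eid,
                culturability=culturability.get(eid),
                pre_karyotype=pre_k,
                post_karyotype=post_k,
                pre_sample_counts=counts.get((eid, PRE_CULTURE)),
                post_sample_counts=counts.get((eid, POST_CULTURE)),
                pre_mean_copies=copies.get((eid, PRE_CULTURE)),
                post_mean_copies=copies.get((eid, POST_CULTURE)),
                mosaic_level=pre_level if pre_k == "mosaic" else "not_applicable",
            )
        )
    return Cohort(records)
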