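"""Readers and writers for the tabular dialects the pipeline consumes.

Karyotype CSV (one row per sample x abnormal chromosome call, plus one
``state=none`` row for samples with no abnormal call, so every sample
appears):

    sample_id, embryo_id, stage, chromosome, state, mosaicism_pct

``state`` is one of normal/gain/loss/segmental/none/not_determinable;
``not_determinable`` marks a failed sample (other columns blank).

Variant TSV (one row per sample x variant; a single ``position=ND`` row marks
a sample whose mtDNA assay failed):

    sample_id, embryo_id, stage, haplogroup, position, ref, alt,
    alt_reads, total_reads

Ct CSV (long format, one row per sample x gene x replicate):

    sample_id, embryo_id, stage, gene, replicate, ct, dissociation_ok

VCF input is supported for single-sample variant calls via
:func:`read_variants_vcf` (needs the AD format field, or AF plus DP).
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd

from .karyotype import ChromosomeCall, ChromosomeProfile
from .variants import MtVariant, SampleVariantSet


class FormatError(ValueError):
    """A data file does not follow its documented dialect."""


# ---------------------------------------------------------------------------
# karyotype CSV

_KARYOTYPE_COLUMNS = ["sample_id", "embryo_id", "stage", "chromosome", "state", "mosaicism_pct"]


def write_karyotype_csv(profiles: list[ChromosomeProfile], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_KARYOTYPE_COLUMNS)
        for p in profiles:
            if not p.determinable:
                w.writerow([p.sample_id, p.embryo_id, p.stage, "", "not_determinable", ""])
                continue
            abnormal = [c for c in p.calls if c.state != "normal"]
            if not abnormal:
                w.writerow([p.sample_id, p.embryo_id, p.stage, "", "none", ""])
            for c in abnormal:
                w.writerow(
                    [p.sample_id, p.embryo_id, p.stage, c.chromosome, c.state, f"{c.mosaicism:.3f}"]
                )


def read_karyotype_csv(path: str | Path) -> list[ChromosomeProfile]:
    df = pd.read_csv(path, dtype=str)
    missing = set(_KARYOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"karyotype CSV missing columns: {sorted(missing)}")
    profiles = []
    for (sample_id, embryo_id, stage), chunk in df.groupby(
        ["sample_id", "embryo_id", "stage"], sort=False
    ):
        states = set(chunk["state"])
        if "not_determinable" in states:
            if len(chunk) > 1:
                raise FormatError(f"sample {sample_id}: not_determinable mixed with calls")
            profiles.append(
                ChromosomeProfile(str(sample_id), str(embryo_id), str(stage), (), False)
            )
            continue
        calls = tuple(
            ChromosomeCall(str(r.chromosome), str(r.state), float(r.mosaicism_pct))
            for r in chunk.itertuples(index=False)
            if r.state not in ("none", "normal")
        )
        profiles.append(ChromosomeProfile(str(sample_id), str(embryo_id), str(stage), calls))
    return profiles


# ---------------------------------------------------------------------------
# variant TSV

_VARIANT_COLUMNS = [
    "sample_id", "embryo_id", "stage", "haplogroup",
    "position", "ref", "alt", "alt_reads", "total_reads",
]


def write_variants_tsv(samples: list[SampleVariantSet], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_VARIANT_COLUMNS)
        for s in samples:
            base = [s.sample_id, s.embryo_id, s.stage, s.haplogroup]
            if s.variants is None:
                w.writerow(base + ["ND", "", "", "", ""])
                continue
            if not s.variants:
                w.writerow(base + ["none", "", "", "", ""])
            for v in s.variants:
                w.writerow(base + [v.position, v.ref_base, v.alt_base, v.alt_reads, v.total_reads])


def read_variants_tsv(path: str | Path) -> list[SampleVariantSet]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"variant TSV missing columns: {sorted(missing)}")
    samples = []
    for (sample_id, embryo_id, stage, haplogroup), chunk in df.groupby(
        ["sample_id", "embryo_id", "stage", "haplogroup"], sort=False
    ):
        positions = set(chunk["position"])
        if "ND" in positions:
            if len(chunk) > 1:
                raise FormatError(f"sample {sample_id}: ND marker mixed with variant rows")
            samples.append(
                SampleVariantSet(str(embryo_id), str(sample_id), str(stage), str(haplogroup), None)
            )
            continue
        variants = [
            MtVariant(
                int(r.position), str(r.ref), str(r.alt), int(r.alt_reads), int(r.total_reads)
            )
            for r in chunk.itertuples(index=False)
            if r.position != "none"
        ]
        samples.append(
            SampleVariantSet(str(embryo_id), str(sample_id), str(stage), str(haplogroup), variants)
        )
    return samples


def read_variants_vcf(
    path: str | Path, embryo_id: str, sample_id: str, stage: str, haplogroup: str
) -> SampleVariantSet:
    """Single-sample VCF -> one SampleVariantSet.

    Read support is taken from the AD format field when present, else from
    AF x DP. Non-SNV records and multi-allelic sites are rejected.
    """
    import pysam

    variants = []
    with pysam.VariantFile(str(path)) as vcf:
        if len(vcf.header.samples) != 1:
            raise FormatError(f"{path}: expected exactly one sample in the VCF")
        for rec in vcf:
            if len(rec.alts or ()) != 1:
                raise FormatError(f"{path}: multi-allelic record at {rec.pos}")
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                raise FormatError(f"{path}: non-SNV record at {rec.pos}")
            call = rec.samples[0]
            if "AD" in call and call["AD"] is not None:
                ad = call["AD"]
                alt_reads, total = int(ad[1]), int(sum(ad))
            elif "AF" in call and "DP" in call:
                total = int(call["DP"])
                alt_reads = round(float(call["AF"][0]) * total)
            else:
                raise FormatError(f"{path}: record at {rec.pos} lacks AD and AF/DP")
            variants.append(MtVariant(rec.pos, ref, alt, alt_reads, total))
    return SampleVariantSet(embryo_id, sample_id, stage, haplogroup, variants)


# ---------------------------------------------------------------------------
# Ct CSV

_CT_COLUMNS = ["sample_id", "embryo_id", "stage", "gene", "replicate", "ct", "dissociation_ok"]


def read_ct_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_CT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"Ct CSV missing columns: {sorted(missing)}")
    df["dissociation_ok"] = df["dissociation_ok"].astype(bool)
    return df


def read_culturability_csv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    missing = {"embryo_id", "culturability"} - set(df.columns)
    if missing:
        raise FormatError(f"culturability CSV missing columns: {sorted(missing)}")
    return dict(zip(df["embryo_id"], df["culturability"]))
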