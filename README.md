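# mosaicmito

Analysis pipeline for studying how mitochondrial DNA (mtDNA) mutations relate
to the post-implantation fate of chromosomally mosaic human embryos.

Mosaic embryos — blastocysts whose trophectoderm biopsies show a mixture of
euploid and aneuploid cells — are sometimes transferred in IVF and often
develop normally, suggesting the aneuploid lineage can be depleted during
early post-implantation development. This package implements the desk-scale
analysis of that phenomenon end to end:

- **Karyotyping** (`mosaicmito.karyotype`): classify each biopsy/outgrowth
  sample from per-chromosome mosaicism calls (euploid / mosaic in the
  inclusive 20–80% band / aneuploid above 80%), combine samples into an
  embryo-level karyotype by concordance, and stratify mosaic embryos into
  low/high mosaicism.
- **mtDNA variant qualification** (`mosaicmito.reference`,
  `mosaicmito.variants`): annotate single-nucleotide variants against the
  rCRS mitochondrial genome (1-based coordinates, vertebrate mitochondrial
  code, light-strand genes reverse-complemented, incomplete stop codons
  poly-A padded), exclude haplogroup markers (≥80% frequency in the sample's
  own haplogroup), and count a variant as a mutation when it reaches ≥90%
  heteroplasmy and is non-synonymous in at least one protein-coding gene or a
  confirmed/likely pathogenic tRNA variant. Per-embryo burden is the
  sample-adjusted mean of per-sample counts.
- **Copy number** (`mosaicmito.copynumber`): relative mtDNA copies per embryo
  from duplicate qPCR Ct values of MT-TL1 vs B2M,
  `copies = 100 × 2^(−ΔΔCt + 1)`, with dissociation-curve replicate dropping
  and exclusion of measurements above 10⁶.
- **Cohort statistics** (`mosaicmito.stats`, `mosaicmito.report`): exact
  two-sided Fisher tests (hypergeometric enumeration with exact integer
  arithmetic), pooled two-sided Student t-tests, mean ± SD group summaries,
  burden-stratified outcome tests, and gene/OXPHOS-complex location tallies.
- **Synthetic cohorts** (`mosaicmito.simulate`, `mosaicmito.calibration`):
  a seeded generator producing cohorts with the full causal structure the
  analysis assumes (karyotype mixtures, burden-dependent aneuploid resolution
  and culturability, binomial read sampling, marker/decoy variants, noisy Ct
  values) plus a ground-truth ledger, used for planted-truth oracles and
  type-I-error calibration of the statistical layer.

A transcribed 27-embryo reference cohort is bundled
(`mosaicmito.fixture.load_table1_fixture`), checksum-verified, with its
printed per-embryo means re-derived from raw per-sample counts at load time.

**Note on bundled data:** the bundled mitochondrial genome is a *synthetic
stand-in* — real rCRS gene coordinates and strands, simulated nucleotide
sequence — and the bundled haplogroup-marker and pathogenic-tRNA tables are
miniature synthetic/test tables. Real analyses should supply the true rCRS
FASTA and full tables via the documented loader/CLI options.

## Worked example

```python
from mosaicmito import load_table1_fixture, run_report

cohort = load_table1_fixture()
rep = run_report(cohort)
print(f"pre-culture euploid: {rep['pre_euploid_count']}/{rep['pre_n_determinable']}"
      f" ({rep['pre_euploid_pct']:.1f}%)")
print(f"post-culture euploid: {rep['post_euploid_count']}/{rep['post_n_determinable']}"
      f" ({rep['post_euploid_pct']:.1f}%), shift p = {rep['fisher_euploid_shift_p']}")
print(f"post-culture burden: euploid {rep['post_euploid_mean_mutations']} ± "
      f"{rep['post_euploid_sd_mutations']} vs aneuploid "
      f"{rep['post_aneuploid_mean_mutations']} ± {rep['post_aneuploid_sd_mutations']}"
      f", t-test p = {rep['t_post_post_karyotype_p']}")
```

Output:

```
pre-culture euploid: 4/27 (14.8%)
post-culture euploid: 14/24 (58.3%), shift p = 0.002
post-culture burden: euploid 0.36 ± 0.61 vs aneuploid 1.22 ± 0.79, t-test p = 0.01
```

The share of euploid embryos rises from 14.8% to 58.3% across the
post-implantation culture window, and embryos that end up euploid carry
significantly fewer high-heteroplasmy non-synonymous mtDNA mutations than
those that remain aneuploid or mosaic.

## Command line

```
mosaicmito simulate --seed 7 --out cohort/           # synthetic cohort + truth ledger
mosaicmito classify-karyotype --profiles cohort/karyotype.csv --out karyotypes.csv
mosaicmito count-mutations --variants cohort/variants.tsv --out mutations.csv
mosaicmito copy-number --ct cohort/ct.csv --out copies.csv
mosaicmito cohort-stats --out report.json            # bundled reference cohort
mosaicmito cohort-stats --karyotypes ... --variants ... --culturability ... \
    [--ct ...] --out report.json                     # raw per-sample files
```

Input dialects (column layouts for the karyotype CSV, variant TSV, Ct CSV,
and single-sample VCF support) are documented in `mosaicmito/io.py`.

## Analysis scripts

Numbered scripts under `analysis/` reproduce the study figures' quantities
and the calibration experiments, writing to `results/`:

1. `01_simulate_cohort.py` — generate the demonstration synthetic cohort.
2. `02_pipeline_on_synthetic.py` — run the file-based pipeline on it and
   compare against the truth ledger.
3. `03_fixture_statistics.py` — the headline statistics of the bundled
   reference cohort (karyotype shift, burden comparisons, copy number).
4. `04_location_tallies.py` — gene/complex location tallies with planted
   truth shown alongside.
5. `05_calibration.py` — null rejection rates and burden recovery
   (`--reps 1000` for the full run).

## Reproduction

```
pip install --no-build-isolation -e ".[test]"
pytest                                   # full suite incl. acceptance tests (~4 min)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`scripts/acceptance.py` recomputes every headline quantity from scratch —
fixture statistics exactly, calibration quantities seeded by `--seed` — and
writes them as JSON. Statistical methodology, parameter choices and known
limitations are documented in `docs/methods.md`.
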