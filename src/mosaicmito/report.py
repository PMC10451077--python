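"""Cohort-level analyses: karyotype shift, mutation burden, copy number.

These functions run the study's statistical comparisons on any
:class:`~mosaicmito.cohort.Cohort` (the bundled reference cohort or a
synthetic one). Group membership for stage-specific statistics is defined by
determinable data at that stage: an embryo joins a comparison at a stage iff
its grouping label and its mean mutation count at that stage are both
determinable. p-values are rounded to 3 decimals only in the flattened
report output; the TestResult objects carry full precision. No
multiple-testing correction is applied; the flattened report records the
number of tests run.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .cohort import Cohort
from .karyotype import EMBRYO_LABELS
from .stats import (
    ContingencyTable2x2,
    GroupSummary,
    TestResult,
    fisher_exact_two_sided,
    group_summary,
    report_p,
    stratified_outcome_test,
    student_t_two_sided,
)
from .variants import POST_CULTURE, PRE_CULTURE


def karyotype_shift_tests(cohort: Cohort) -> dict[str, TestResult]:
    """Fisher tests of each karyotype label's frequency, pre vs post culture.

    For each label the 2x2 table is (stage) x (label vs other), over embryos
    determinable at each stage.
    """
    pre = cohort.karyotype_distribution(PRE_CULTURE)
    post = cohort.karyotype_distribution(POST_CULTURE)
    out = {}
    for label in EMBRYO_LABELS:
        n_pre = pre[label]["n_determinable"]
        n_post = post[label]["n_determinable"]
        a, c = pre[label]["count"], post[label]["count"]
        table = ContingencyTable2x2(a, n_pre - a, c, n_post - c)
        out[label] = fisher_exact_two_sided(table)
    return out


def mutation_burden_comparison(
    cohort: Cohort, grouping: str, stage: str
) -> dict[str, GroupSummary | TestResult]:
    """Group summaries and pooled t-test of per-embryo mutation counts.

    ``grouping`` is ``post_karyotype`` (euploid vs aneuploid by post-culture
    karyotype) or ``culturability`` (culturable vs non-culturable).
    """
    groups = cohort.groups(grouping)
    counts = cohort.mutation_counts(stage)
    values: dict[str, list[float]] = {}
    for embryo, grp in groups.items():
        if grp is None or counts[embryo] is None:
            continue
        values.setdefault(grp, []).append(counts[embryo])
    if len(values) != 2:
        raise ValueError(f"grouping {grouping!r} yields {len(values)} group(s) at {stage}")
    (la, va), (lb, vb) = sorted(values.items())
    return {
        "group_a": group_summary(va, la),
        "group_b": group_summary(vb, lb),
        "test": student_t_two_sided(va, vb),
    }


def stratified_tests(cohort: Cohort, threshold: float = 1.0) -> dict[str, TestResult]:
    """Outcome tests stratified by pre-culture mutation burden.

    ``post_euploid``: among pre-culture mosaic embryos, does a pre-culture
    burden above the threshold associate with failing to resolve to euploid?
    ``culturable``: across the cohort, with culturability as the outcome.
    """
    pre_counts = cohort.mutation_counts(PRE_CULTURE)
    mosaic_pre = cohort.subset(lambda e: e.pre_karyotype == "mosaic")
    resolution_outcome = {
        e.embryo_id: (None if e.post_karyotype is None else e.post_karyotype == "euploid")
        for e in mosaic_pre
    }
    culturability_outcome = {
        e.embryo_id: (
            None
            if e.culturability_group() is None
            else e.culturability_group() == "culturable"
        )
        for e in cohort
    }
    return {
        "post_euploid": stratified_outcome_test(
            {k: pre_counts[k] for k in resolution_outcome}, resolution_outcome, threshold
        ),
        "culturable": stratified_outcome_test(pre_counts, culturability_outcome, threshold),
    }


def copy_number_group_means(
    cohort: Cohort, grouping: str, stage: str = PRE_CULTURE
) -> dict[str, GroupSummary]:
    """Mean +/- SD of per-embryo mean mtDNA copy number by group.

    Computed from per-embryo means; the source study's figure-caption group
    values appear to derive from per-sample data not published per embryo, so
    these recomputations are reported as such rather than matched to the
    captions.
    """
    groups = cohort.groups(grouping)
    out: dict[str, list[float]] = {}
    for e in cohort:
        grp = groups[e.embryo_id]
        copies = e.mean_copies(stage)
        if grp is None or copies is None:
            continue
        out.setdefault(grp, []).append(copies)
    return {grp: group_summary(vals, grp) for grp, vals in sorted(out.items())}


def distribution_frame(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for stage in (PRE_CULTURE, POST_CULTURE):
        dist = cohort.karyotype_distribution(stage)
        for label, d in dist.items():
            rows.append({"stage": stage, "karyotype": label, **d})
    return pd.DataFrame(rows)


def run_report(cohort: Cohort) -> dict:
    """The full statistical report as a flat, JSON-serialisable dict.

    Percentages are on the 0-100 scale; p-values are rounded to 3 decimals.
    """
    report: dict = {}
    for stage, tag in ((PRE_CULTURE, "pre"), (POST_CULTURE, "post")):
        dist = cohort.karyotype_distribution(stage)
        for label, d in dist.items():
            report[f"{tag}_{label}_count"] = d["count"]
            report[f"{tag}_{label}_pct"] = (
                None if d["ratio"] is None else 100.0 * d["ratio"]
            )
        report[f"{tag}_n_determinable"] = dist["euploid"]["n_determinable"]

    shift = karyotype_shift_tests(cohort)
    for label, res in shift.items():
        report[f"fisher_{label}_shift_p"] = report_p(res.p_value)

    n_tests = len(shift)
    for grouping in ("post_karyotype", "culturability"):
        for stage, tag in ((PRE_CULTURE, "pre"), (POST_CULTURE, "post")):
            cmp = mutation_burden_comparison(cohort, grouping, stage)
            for key in ("group_a", "group_b"):
                s: GroupSummary = cmp[key]
                report[f"{tag}_{s.label}_mean_mutations"] = round(s.mean, 2)
                report[f"{tag}_{s.label}_sd_mutations"] = round(s.sd_population, 2)
                report[f"{tag}_{s.label}_n"] = s.n
            report[f"t_{tag}_{grouping}_p"] = report_p(cmp["test"].p_value)
            n_tests += 1

    strat = stratified_tests(cohort)
    for name, res in strat.items():
        report[f"stratified_{name}_p"] = report_p(res.p_value)
        n_tests += 1
    report["n_tests_run"] = n_tests
    return report
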