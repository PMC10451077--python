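"""Statistical calibration of the pipeline on synthetic cohorts.

Two study designs, both frozen ahead of time:

Null calibration. Cohorts are generated with the mutation burden drawn from
the same Poisson rate in every karyotype class and with both logistic slopes
(aneuploid resolution, culturability) set to zero, so burden is independent
of every outcome. Each replicate runs the six burden-association tests (the
pooled t-test for pre/post burden by post-culture karyotype group and by
culturability, and the two burden-stratified exact tests); the per-test
rejection rate at alpha should match alpha. Design choices: 200 embryos per
replicate so group sizes are far from degenerate, and a common burden rate of
1.5 so that the burden>1 stratification splits the cohort well away from the
sparse-table regime where the exact test's discreteness makes it
conservative. With 1000 replicates the binomial 99% acceptance band around
alpha = 0.05 is roughly [0.032, 0.068].

Parameter recovery. Cohorts with two karyotype classes at distinct planted
burden rates and no feedback; the pipeline's group means must recover the
planted rates within sampling error (3 standard errors by default).

p-values are used at full precision here (no report-layer rounding).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .pipeline import build_cohort
from .reference import ReferenceGenome
from .report import mutation_burden_comparison, stratified_tests
from .simulate import null_config, recovery_config, simulate_cohort
from .variants import POST_CULTURE, PRE_CULTURE, MarkerTable, TrnaTable

#: the burden-association tests whose size is calibrated
NULL_TESTS = (
    "t_pre_post_karyotype",
    "t_post_post_karyotype",
    "t_pre_culturability",
    "t_post_culturability",
    "stratified_post_euploid",
    "stratified_culturable",
)


@dataclass(frozen=True)
class CalibrationResult:
    n_reps: int
    alpha: float
    rejection_rates: dict  # test name -> fraction of replicates with p <= alpha
    n_evaluable: dict  # test name -> replicates where the test could run

    def binomial_band(self, confidence_sds: float = 2.576) -> tuple[float, float]:
        """Normal-approximation band around alpha for n_reps replicates."""
        se = math.sqrt(self.alpha * (1 - self.alpha) / self.n_reps)
        return (self.alpha - confidence_sds * se, self.alpha + confidence_sds * se)


def _burden_test_pvalues(cohort) -> dict[str, float | None]:
    out: dict[str, float | None] = {}
    for grouping in ("post_karyotype", "culturability"):
        for stage, tag in ((PRE_CULTURE, "pre"), (POST_CULTURE, "post")):
            try:
                cmp = mutation_burden_comparison(cohort, grouping, stage)
                out[f"t_{tag}_{grouping}"] = cmp["test"].p_value
            except ValueError:
                out[f"t_{tag}_{grouping}"] = None
    strat = stratified_tests(cohort)
    out["stratified_post_euploid"] = strat["post_euploid"].p_value
    out["stratified_culturable"] = strat["culturable"].p_value
    return out


def null_calibration(
    n_reps: int,
    seed: int,
    reference: ReferenceGenome,
    marker_table: MarkerTable,
    trna_table: TrnaTable,
    n_embryos: int = 200,
    burden: float = 1.5,
    alpha: float = 0.05,
) -> CalibrationResult:
    """Measure the type-I error rate of the burden-association tests."""
    config = null_config(n_embryos, burden)
    rejections = {t: 0 for t in NULL_TESTS}
    evaluable = {t: 0 for t in NULL_TESTS}
    seeds = np.random.SeedSequence(seed).generate_state(n_reps)
    for rep_seed in seeds:
        synth = simulate_cohort(config, int(rep_seed), reference, marker_table, with_ct=False)
        cohort = build_cohort(
            synth.profiles, synth.variant_samples, synth.culturability,
            reference, marker_table, trna_table,
        )
        for test, p in _burden_test_pvalues(cohort).items():
            if p is None:
                continue
            evaluable[test] += 1
            if p <= alpha:
                rejections[test] += 1
    rates = {
        t: (rejections[t] / evaluable[t] if evaluable[t] else None) for t in NULL_TESTS
    }
    return CalibrationResult(n_reps, alpha, rates, evaluable)


@dataclass(frozen=True)
class RecoveryResult:
    planted: dict  # group -> planted Poisson rate
    recovered: dict  # group -> pipeline mean burden
    standard_errors: dict  # group -> SE of the mean
    n_embryos: dict

    def within(self, sds: float = 3.0) -> bool:
        return all(
            abs(self.recovered[g] - self.planted[g]) <= sds * self.standard_errors[g]
            for g in self.planted
        )


def burden_recovery(
    seed: int,
    reference: ReferenceGenome,
    marker_table: MarkerTable,
    trna_table: TrnaTable,
    n_embryos: int = 200,
    lambda_low: float = 0.3,
    lambda_high: float = 1.2,
) -> RecoveryResult:
    """Recover two planted group burden rates through the full pipeline."""
    config = recovery_config(n_embryos, lambda_low, lambda_high)
    synth = simulate_cohort(config, seed, reference, marker_table, with_ct=False)
    cohort = build_cohort(
        synth.profiles, synth.variant_samples, synth.culturability,
        reference, marker_table, trna_table,
    )
    truth = {e["embryo_id"]: e["pre_karyotype"] for e in synth.truth["embryos"]}
    counts = cohort.mutation_counts(PRE_CULTURE)
    by_group: dict[str, list[float]] = {"euploid": [], "full_aneuploid": []}
    for eid, group in truth.items():
        if counts.get(eid) is not None:
            by_group[group].append(counts[eid])
    planted = {"euploid": lambda_low, "full_aneuploid": lambda_high}
    recovered, ses, ns = {}, {}, {}
    for g, vals in by_group.items():
        arr = np.asarray(vals)
        recovered[g] = float(arr.mean())
        ses[g] = float(arr.std(ddof=1) / math.sqrt(len(arr)))
        ns[g] = len(arr)
    return RecoveryResult(planted, recovered, ses, ns)
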