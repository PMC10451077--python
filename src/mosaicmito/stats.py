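"""Cohort statistics: Fisher exact tests, pooled t-tests, group summaries,
and per-gene/per-complex mutation-location tallies.

The two-sided Fisher exact p-value is computed from the hypergeometric mass
function with exact integer arithmetic: conditioning on the table margins,
the p-value is the total probability of all tables whose point probability
does not exceed that of the observed table (relative tie tolerance 1e-7).

Group summaries carry both standard-deviation conventions; the population SD
(divisor n) is the headline value printed by the report layer, which is the
convention that reproduces the cohort's published mean +/- SD values. Sample
SD (divisor n-1) is exported alongside. p-values are rounded to 3 decimals at
the report layer only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

FISHER_TIE_RELTOL = Fraction(1, 10**7)

FISHER = "fisher_exact_two_sided"
STUDENT_T = "student_t_two_sided"


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows = condition/stage groups, columns = outcome / non-outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells) or not any(cells):
            raise ValueError(f"invalid 2x2 table {cells}")

    @property
    def degenerate(self) -> bool:
        return (
            self.a + self.b == 0
            or self.c + self.d == 0
            or self.a + self.c == 0
            or self.b + self.d == 0
        )


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sd_population: float  # divisor n
    sd_sample: float | None  # divisor n-1; None for n < 2
    values: tuple[float, ...]


@dataclass(frozen=True)
class TestResult:
    test: str
    p_value: float
    statistic: float | None = None
    df: float | None = None
    degenerate: bool = False
    inputs: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def report_p(p: float) -> float:
    """Report-layer p-value convention: 3 decimals."""
    return round(p, 3)


def fisher_exact_two_sided(table: ContingencyTable2x2) -> TestResult:
    """Exact two-sided Fisher test of a 2x2 table.

    Degenerate margins (an empty row or column) return p = 1 with a
    degenerate flag: no association is estimable.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    inputs = {"table": (a, b, c, d)}
    if table.degenerate:
        return TestResult(FISHER, 1.0, degenerate=True, inputs=inputs)
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    # unnormalised hypergeometric weights, exact integers
    weights = {k: comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)}
    observed = weights[a]
    cutoff = observed + observed * FISHER_TIE_RELTOL  # ties within 1e-7 included
    total = comb(n, c1)
    p = Fraction(sum(w for w in weights.values() if w <= cutoff), total)
    return TestResult(FISHER, float(p), statistic=None, inputs=inputs)


def student_t_two_sided(
    group_a: Sequence[float], group_b: Sequence[float]
) -> TestResult:
    """Two-sided pooled-variance Student t-test (df = n_a + n_b - 2)."""
    x = np.asarray(group_a, dtype=float)
    y = np.asarray(group_b, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least two observations")
    df = len(x) + len(y) - 2
    pooled = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / df
    inputs = {"n_a": len(x), "n_b": len(y)}
    if pooled == 0.0:
        if x.mean() == y.mean():
            return TestResult(STUDENT_T, 1.0, statistic=0.0, df=df,
                              degenerate=True, inputs=inputs)
        return TestResult(STUDENT_T, 0.0, statistic=float("inf"), df=df,
                          degenerate=True, inputs=inputs)
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return TestResult(STUDENT_T, float(p), statistic=float(t), df=df, inputs=inputs)


def group_summary(values: Sequence[float], label: str = "") -> GroupSummary:
    """Mean and both SD conventions of one group."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty group")
    return GroupSummary(
        label=label,
        n=arr.size,
        mean=float(arr.mean()),
        sd_population=float(arr.std(ddof=0)),
        sd_sample=float(arr.std(ddof=1)) if arr.size >= 2 else None,
        values=tuple(arr.tolist()),
    )


def stratified_outcome_test(
    counts: Mapping[str, float | None],
    outcomes: Mapping[str, bool | None],
    threshold: float = 1.0,
) -> TestResult:
    """Fisher test of (mutation count > threshold) against a binary outcome.

    Embryos lacking either a determinable count or a determinable outcome are
    excluded. Row 1 = count above threshold, column 1 = outcome present.
    """
    cells = [0, 0, 0, 0]
    for embryo, count in counts.items():
        outcome = outcomes.get(embryo)
        if count is None or outcome is None:
            continue
        row = 0 if count > threshold else 1
        col = 0 if outcome else 1
        cells[2 * row + col] += 1
    result = fisher_exact_two_sided(ContingencyTable2x2(*cells))
    result.inputs["threshold"] = threshold
    return result


def location_tally(
    gene_counts: Mapping[str, Mapping[str, float]],
    groups: Mapping[str, str],
    gene_complex: Mapping[str, str],
) -> dict[str, pd.DataFrame]:
    """Per-gene and per-OXPHOS-complex mutation tallies by embryo group.

    Parameters
    ----------
    gene_counts
        embryo id -> {gene -> sample-adjusted qualifying count}. Embryos with
        no qualifying mutations must still appear (with an empty mapping) so
        group means are over all embryos.
    groups
        embryo id -> group label; embryos mapped to None are skipped.
    gene_complex
        gene -> OXPHOS complex label (genes absent from the map are tallied
        under complex "none").

    Returns ``{"per_gene": ..., "per_complex": ...}`` DataFrames indexed by
    (group, gene/complex) with the group mean, population SD, the number of
    embryos carrying a mutation there, and that rate. Per-complex values sum
    the constituent genes' per-embryo counts before averaging.
    """
    members: dict[str, list[str]] = {}
    for embryo, grp in groups.items():
        if grp is not None and embryo in gene_counts:
            members.setdefault(grp, []).append(embryo)

    all_genes = sorted({g for counts in gene_counts.values() for g in counts})
    gene_rows, complex_rows = [], []
    for grp, embryos in sorted(members.items()):
        if not embryos:
            continue
        per_gene = {
            g: np.array([gene_counts[e].get(g, 0.0) for e in embryos]) for g in all_genes
        }
        for g, arr in per_gene.items():
            gene_rows.append(
                {
                    "group": grp,
                    "gene": g,
                    "mean": arr.mean(),
                    "sd_population": arr.std(ddof=0),
                    "n_embryos_with_mutation": int((arr > 0).sum()),
                    "rate_embryos_with_mutation": float((arr > 0).mean()),
                    "n_group": len(embryos),
                }
            )
        complexes = sorted({gene_complex.get(g, "none") for g in all_genes})
        for cx in complexes:
            genes_cx = [g for g in all_genes if gene_complex.get(g, "none") == cx]
            arr = np.sum([per_gene[g] for g in genes_cx], axis=0)
            complex_rows.append(
                {
                    "group": grp,
                    "complex": cx,
                    "mean": arr.mean(),
                    "sd_population": arr.std(ddof=0),
                    "n_embryos_with_mutation": int((arr > 0).sum()),
                    "rate_embryos_with_mutation": float((arr > 0).mean()),
                    "n_group": len(embryos),
                }
            )
    per_gene_df = pd.DataFrame(gene_rows)
    per_complex_df = pd.DataFrame(complex_rows)
    if not per_gene_df.empty:
        per_gene_df = per_gene_df.set_index(["group", "gene"])
        per_complex_df = per_complex_df.set_index(["group", "complex"])
    return {"per_gene": per_gene_df, "per_complex": per_complex_df}
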