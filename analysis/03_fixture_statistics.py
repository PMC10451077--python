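"""The headline statistics of the bundled 27-embryo reference cohort.

Loads the bundled cohort, prints the karyotype-shift, mutation-burden and
copy-number analyses in readable form, and writes
results/fixture_report.json plus results/fixture_distributions.csv.

Run from the repository root:  python analysis/03_fixture_statistics.py
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from mosaicmito.fixture import load_table1_fixture  # noqa: E402
from mosaicmito.report import (  # noqa: E402
    copy_number_group_means,
    distribution_frame,
    run_report,
)

OUT = ROOT / "results"


def main() -> None:
    cohort = load_table1_fixture()
    rep = run_report(cohort)

    OUT.mkdir(exist_ok=True)
    (OUT / "fixture_report.json").write_text(json.dumps(rep, indent=2, sort_keys=True) + "\n")
    distribution_frame(cohort).to_csv(OUT / "fixture_distributions.csv", index=False)

    print("Karyotype distribution (determinable embryos)")
    for tag, n in (("pre", rep["pre_n_determinable"]), ("post", rep["post_n_determinable"])):
        parts = ", ".join(
            f"{label} {rep[f'{tag}_{label}_count']}/{n} ({rep[f'{tag}_{label}_pct']:.1f}%)"
            for label in ("euploid", "mosaic", "full_aneuploid")
        )
        print(f"  {tag:>4}-culture: {parts}")
    print(f"  euploid shift p = {rep['fisher_euploid_shift_p']}, "
          f"mosaic shift p = {rep['fisher_mosaic_shift_p']}")

    print("\nMutation burden (mean +/- population SD of sample-adjusted counts)")
    for tag in ("pre", "post"):
        for a, b in (("euploid", "aneuploid"), ("culturable", "non_culturable")):
            grouping = "post_karyotype" if a == "euploid" else "culturability"
            print(
                f"  {tag:>4} {a} {rep[f'{tag}_{a}_mean_mutations']:.2f} +/- "
                f"{rep[f'{tag}_{a}_sd_mutations']:.2f} (n={rep[f'{tag}_{a}_n']}) vs "
                f"{b} {rep[f'{tag}_{b}_mean_mutations']:.2f} +/- "
                f"{rep[f'{tag}_{b}_sd_mutations']:.2f} (n={rep[f'{tag}_{b}_n']}), "
                f"t-test p = {rep[f't_{tag}_{grouping}_p']}"
            )
    print(f"  stratified (>1 pre-culture mutation): post-euploid outcome "
          f"p = {rep['stratified_post_euploid_p']}, culturability "
          f"p = {rep['stratified_culturable_p']}")

    print("\nmtDNA copies per embryo (per-embryo means; see docs/methods.md "
          "on why no external reference values exist for these)")
    for grouping in ("post_karyotype", "culturability"):
        means = copy_number_group_means(cohort, grouping, "pre_culture")
        parts = ", ".join(
            f"{g}: {s.mean:,.0f} +/- {s.sd_population:,.0f} (n={s.n})"
            for g, s in means.items()
        )
        print(f"  pre-culture by {grouping}: {parts}")


if __name__ == "__main__":
    main()
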