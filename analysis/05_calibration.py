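"""Statistical calibration of the burden-association tests.

Null calibration: cohorts with no burden-outcome association (equal Poisson
rates, zero logistic slopes) are simulated and the full pipeline plus the six
burden-association tests run on each; per-test rejection rates at alpha=0.05
are compared to the nominal level. Parameter recovery: a two-group design
with planted rates 0.3 and 1.2 run through the pipeline.

Defaults to 200 replicates for a quick check; pass --reps 1000 for the full
calibration (a few minutes). Writes results/calibration.json.

Run from the repository root:  python analysis/05_calibration.py [--reps N]
"""

import argparse
import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from mosaicmito.calibration import burden_recovery, null_calibration  # noqa: E402
from mosaicmito.reference import load_reference  # noqa: E402
from mosaicmito.variants import load_marker_table, load_trna_table  # noqa: E402

SEED = 20230811
DATA = ROOT / "src" / "mosaicmito" / "_data"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--reps", type=int, default=200)
    args = parser.parse_args()

    reference = load_reference()
    marker_table = load_marker_table(DATA / "haplogroup_markers_mini.tsv")
    trna_table = load_trna_table(DATA / "trna_pathogenic_mini.tsv")

    calib = null_calibration(
        n_reps=args.reps, seed=SEED, reference=reference,
        marker_table=marker_table, trna_table=trna_table,
    )
    lo, hi = calib.binomial_band()
    print(f"null calibration, {args.reps} replicates, alpha 0.05, "
          f"99% band [{lo:.3f}, {hi:.3f}]:")
    for test, rate in calib.rejection_rates.items():
        flag = "ok" if lo <= rate <= hi else "OUTSIDE BAND"
        print(f"  {test:<28} rejection rate {rate:.3f}  {flag}")

    recovery = burden_recovery(
        seed=SEED, reference=reference,
        marker_table=marker_table, trna_table=trna_table,
    )
    print("\nburden recovery (planted -> recovered +/- SE):")
    for group, planted in recovery.planted.items():
        print(f"  {group:<15} {planted:.2f} -> {recovery.recovered[group]:.3f} "
              f"+/- {recovery.standard_errors[group]:.3f} "
              f"(n={recovery.n_embryos[group]})")
    print(f"  within 3 SE: {recovery.within(3.0)}")

    out = ROOT / "results" / "calibration.json"
    out.parent.mkdir(exist_ok=True)
    out.write_text(json.dumps(
        {
            "n_reps": calib.n_reps,
            "alpha": calib.alpha,
            "band_99pct": [lo, hi],
            "rejection_rates": calib.rejection_rates,
            "recovery": {
                "planted": recovery.planted,
                "recovered": recovery.recovered,
                "standard_errors": recovery.standard_errors,
            },
        },
        indent=2, sort_keys=True,
    ) + "\n")
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
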