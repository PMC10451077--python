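"""Generate the demonstration synthetic cohort.

Writes a 27-embryo synthetic cohort (default generator settings, seed 20230811)
to results/synthetic_cohort/: per-sample karyotype CSV, variant TSV, Ct CSV,
culturability CSV, and the ground-truth ledger JSON. Subsequent analysis
scripts consume these files through the ordinary file readers, exactly as a
real dataset would be.

Run from the repository root:  python analysis/01_simulate_cohort.py
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from mosaicmito.reference import load_reference  # noqa: E402
from mosaicmito.simulate import SimulationConfig, simulate_cohort  # noqa: E402
from mosaicmito.variants import load_marker_table  # noqa: E402

SEED = 20230811
OUT = ROOT / "results" / "synthetic_cohort"


def main() -> None:
    data = ROOT / "src" / "mosaicmito" / "_data"
    config = SimulationConfig()  # 27 embryos, defaults documented in docs/methods.md
    cohort = simulate_cohort(
        config, SEED, load_reference(), load_marker_table(data / "haplogroup_markers_mini.tsv")
    )
    cohort.write(OUT)
    n_pre = sum(e["n_pre_samples"] for e in cohort.truth["embryos"])
    n_post = sum(e["n_post_samples"] for e in cohort.truth["embryos"])
    print(f"wrote {config.n_embryos} embryos ({n_pre} biopsies, {n_post} outgrowth "
          f"samples) to {OUT}")


if __name__ == "__main__":
    main()
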