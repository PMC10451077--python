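"""Generate the bundled miniature marker and pathogenic-tRNA tables.

Writes ``haplogroup_markers_mini.tsv`` and ``trna_pathogenic_mini.tsv`` under
``src/mosaicmito/_data/`` and refreshes the checksum manifest (including the
bundled cohort CSV). The marker table is a miniature *synthetic* stand-in for
a full haplogroup-marker database: it covers three haplogroup labels with a
handful of marker sites each, including sub-80%-frequency rows to exercise
the threshold. The tRNA table lists a few well-known pathogenic tRNA
positions (classes confirmed/likely). Both are meant for tests and synthetic
cohorts; real analyses supply full tables via config.

Alt alleles are checked against the bundled synthetic genome so that every
listed alt differs from the reference base at its position.

Run from the repository root:  python scripts/make_tables.py
"""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

DATA = ROOT / "src" / "mosaicmito" / "_data"

# haplogroup -> [(position, preferred_alt, frequency_percent)]
MARKERS = {
    "H2a": [
        (263, "G", 99.0),
        (750, "G", 99.0),
        (1438, "G", 98.0),
        (4769, "G", 97.0),
        (8860, "G", 99.0),
        (15326, "G", 99.0),
        (16189, "C", 62.0),  # below the 80% marker threshold: never flagged
    ],
    "D4": [
        (3010, "A", 95.0),
        (4883, "T", 96.0),
        (5178, "A", 97.0),
        (8414, "T", 92.0),
        (14668, "T", 90.0),
        (9824, "C", 80.0),  # boundary: flagged (threshold is inclusive)
        (12705, "T", 79.9),  # just below: never flagged
    ],
    "B4a": [
        (499, "A", 93.0),
        (827, "G", 91.0),
        (13590, "A", 88.0),
        (15535, "T", 85.0),
        (16217, "C", 90.0),
    ],
}

# (position, preferred_alt, class); positions fall inside tRNA genes
TRNA_PATHOGENIC = [
    (3243, "G", "confirmed"),  # MT-TL1
    (3271, "C", "confirmed"),  # MT-TL1
    (4269, "G", "confirmed"),  # MT-TI
    (8344, "G", "confirmed"),  # MT-TK
    (8356, "C", "confirmed"),  # MT-TK
    (1630, "G", "likely"),     # MT-TV
    (5728, "C", "likely"),     # MT-TN
    (12147, "A", "likely"),    # MT-TH
    (15990, "C", "likely"),    # MT-TP
]


def pick_alt(ref: str, preferred: str) -> str:
    if preferred != ref:
        return preferred
    return next(b for b in "GACT" if b != ref)


def main() -> None:
    from mosaicmito.reference import load_reference

    genome = load_reference()

    marker_path = DATA / "haplogroup_markers_mini.tsv"
    rows = ["# miniature synthetic haplogroup-marker table (tests only)",
            "haplogroup\tposition\talt\tfrequency"]
    for hg, markers in MARKERS.items():
        for pos, preferred, freq in markers:
            alt = pick_alt(genome.base_at(pos), preferred)
            rows.append(f"{hg}\t{pos}\t{alt}\t{freq}")
    marker_path.write_text("\n".join(rows) + "\n")

    trna_path = DATA / "trna_pathogenic_mini.tsv"
    rows = ["# miniature pathogenic-tRNA table (tests only)",
            "position\talt\tclassification"]
    for pos, preferred, cls in TRNA_PATHOGENIC:
        from mosaicmito.reference import TRNA_VARIANT  # sanity: must be tRNA sites
        feats = genome.locate(pos)
        if not any(f.feature_type == "tRNA" for f in feats):
            raise RuntimeError(f"position {pos} is not inside a tRNA gene")
        alt = pick_alt(genome.base_at(pos), preferred)
        rows.append(f"{pos}\t{alt}\t{cls}")
    trna_path.write_text("\n".join(rows) + "\n")

    manifest_path = DATA / "checksums.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    for p in (marker_path, trna_path, DATA / "table1_embryos.csv"):
        manifest[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    print("wrote", marker_path.name, trna_path.name, "and refreshed checksums.json")


if __name__ == "__main__":
    main()
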