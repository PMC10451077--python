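"""Generate the bundled synthetic mitochondrial reference.

Writes ``src/mosaicmito/_data/rcrs_synthetic.fasta`` and
``src/mosaicmito/_data/rcrs_features.gff3`` plus a checksum manifest.

The feature table is the standard 1-based rCRS gene annotation (13
protein-coding genes, 22 tRNAs, 2 rRNAs, control region) of the human
mitochondrial genome. The 16,569-nt *sequence* is synthetic: it is generated
deterministically (seed below) so that every protein-coding gene is a valid
open reading frame under the vertebrate mitochondrial code — correct start
codon, no internal stop in either frame of the overlapping gene pairs
(ATP8/ATP6, ND4L/ND4), and the incomplete-stop (polyadenylation) convention
for genes whose length is not a multiple of three. The codon context at
position 3460 is pinned to the real rCRS context (GCC, alanine) so the
canonical MT-ND1 m.3460G>A change is nonsynonymous, as in the real genome.

Run from the repository root:  python scripts/make_reference.py
"""

from __future__ import annotations

import hashlib
import json
import random
from pathlib import Path

from Bio.Data import CodonTable

MITO = CodonTable.unambiguous_dna_by_id[2]  # vertebrate mitochondrial
STOPS = set(MITO.stop_codons)  # TAA, TAG, AGA, AGG
NON_STOP_CODONS = sorted(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOPS
)
COMP = str.maketrans("ACGT", "TGCA")

GENOME_LENGTH = 16569

# name, type, start, end, strand, OXPHOS complex (1-based inclusive rCRS coords)
FEATURES = [
    ("MT-CR1", "control_region", 1, 576, "heavy", "none"),
    ("MT-TF", "tRNA", 577, 647, "heavy", "none"),
    ("MT-RNR1", "rRNA", 648, 1601, "heavy", "none"),
    ("MT-TV", "tRNA", 1602, 1670, "heavy", "none"),
    ("MT-RNR2", "rRNA", 1671, 3229, "heavy", "none"),
    ("MT-TL1", "tRNA", 3230, 3304, "heavy", "none"),
    ("MT-ND1", "protein_coding", 3307, 4262, "heavy", "I"),
    ("MT-TI", "tRNA", 4263, 4331, "heavy", "none"),
    ("MT-TQ", "tRNA", 4329, 4400, "light", "none"),
    ("MT-TM", "tRNA", 4402, 4469, "heavy", "none"),
    ("MT-ND2", "protein_coding", 4470, 5511, "heavy", "I"),
    ("MT-TW", "tRNA", 5512, 5579, "heavy", "none"),
    ("MT-TA", "tRNA", 5587, 5655, "light", "none"),
    ("MT-TN", "tRNA", 5657, 5729, "light", "none"),
    ("MT-TC", "tRNA", 5761, 5826, "light", "none"),
    ("MT-TY", "tRNA", 5826, 5891, "light", "none"),
    ("MT-CO1", "protein_coding", 5904, 7445, "heavy", "IV"),
    ("MT-TS1", "tRNA", 7446, 7514, "light", "none"),
    ("MT-TD", "tRNA", 7518, 7585, "heavy", "none"),
    ("MT-CO2", "protein_coding", 7586, 8269, "heavy", "IV"),
    ("MT-TK", "tRNA", 8295, 8364, "heavy", "none"),
    ("MT-ATP8", "protein_coding", 8366, 8572, "heavy", "V"),
    ("MT-ATP6", "protein_coding", 8527, 9207, "heavy", "V"),
    ("MT-CO3", "protein_coding", 9207, 9990, "heavy", "IV"),
    ("MT-TG", "tRNA", 9991, 10058, "heavy", "none"),
    ("MT-ND3", "protein_coding", 10059, 10404, "heavy", "I"),
    ("MT-TR", "tRNA", 10405, 10469, "heavy", "none"),
    ("MT-ND4L", "protein_coding", 10470, 10766, "heavy", "I"),
    ("MT-ND4", "protein_coding", 10760, 12137, "heavy", "I"),
    ("MT-TH", "tRNA", 12138, 12206, "heavy", "none"),
    ("MT-TS2", "tRNA", 12207, 12265, "heavy", "none"),
    ("MT-TL2", "tRNA", 12266, 12336, "heavy", "none"),
    ("MT-ND5", "protein_coding", 12337, 14148, "heavy", "I"),
    ("MT-ND6", "protein_coding", 14149, 14673, "light", "I"),
    ("MT-TE", "tRNA", 14674, 14742, "light", "none"),
    ("MT-CYB", "protein_coding", 14747, 15887, "heavy", "III"),
    ("MT-TT", "tRNA", 15888, 15953, "heavy", "none"),
    ("MT-TP", "tRNA", 15956, 16023, "light", "none"),
    ("MT-CR2", "control_region", 16024, 16569, "heavy", "none"),
]

PROTEIN_GENES = [f for f in FEATURES if f[1] == "protein_coding"]


def make_orf(length: int, rng: random.Random) -> str:
    """A coding-orientation ORF: ATG start, non-stop internals, terminal
    stop codon truncated per the incomplete-stop convention."""
    n_full = length // 3
    rem = length % 3
    codons = ["ATG"] + [rng.choice(NON_STOP_CODONS) for _ in range(n_full - 1)]
    orf = "".join(codons)
    if rem == 0:
        orf = orf[:-3] + "TAA"
    elif rem == 1:
        orf += "T"
    else:
        orf += "TA"
    return orf


def revcomp(seq: str) -> str:
    return seq.translate(COMP)[::-1]


def orf_of(seq: list[str], start: int, end: int, strand: str) -> str:
    frag = "".join(seq[start - 1 : end])
    return revcomp(frag) if strand == "light" else frag


def has_internal_stop(orf: str) -> bool:
    n = len(orf) - len(orf) % 3
    last_full = n - 3
    return any(orf[i : i + 3] in STOPS for i in range(0, last_full, 3))


def build_sequence(seed: int = 20230811) -> str:
    rng = random.Random(seed)
    seq = [rng.choice("ACGT") for _ in range(GENOME_LENGTH)]
    pinned = [False] * GENOME_LENGTH

    def pin(gpos0: int, bases: str) -> None:
        for j, b in enumerate(bases):
            seq[gpos0 + j] = b
            pinned[gpos0 + j] = True

    # lay down each protein-coding ORF; later genes overwrite the overlap
    for name, _, start, end, strand, _ in PROTEIN_GENES:
        orf = make_orf(end - start + 1, rng)
        if strand == "light":
            orf = revcomp(orf)
        seq[start - 1 : end] = list(orf)

    # pin start codons and terminal (possibly incomplete) stops of every gene,
    # re-imposing the ones the overlapping neighbour overwrote
    for name, _, start, end, strand, _ in PROTEIN_GENES:
        length = end - start + 1
        term = {0: "TAA", 1: "T", 2: "TA"}[length % 3]
        if strand == "light":
            pin(end - 3, revcomp("ATG"))
            pin(start - 1, revcomp(term))
        else:
            pin(start - 1, "ATG")
            pin(end - len(term), term)

    # pin the real-rCRS codon context of the canonical m.3460G>A example:
    # 3460 is the first base of an MT-ND1 codon; GCC (Ala) -> A gives ACC (Thr)
    pin(3459, "GCC")

    def genome_codon_span(start: int, end: int, strand: str, i: int):
        """0-based genome indices of the codon at ORF offset i (ascending)."""
        if strand == "light":
            g_end0 = end - 1 - i  # genome index of the codon's first base
            return [g_end0 - 2, g_end0 - 1, g_end0]
        g0 = start - 1 + i
        return [g0, g0 + 1, g0 + 2]

    # iterative repair: overlapping pairs may have created stops in the other
    # gene's frame; resample offending codons from non-stop codons compatible
    # with every pinned base, until all frames are clean
    for _ in range(10_000):
        dirty = False
        for name, _, start, end, strand, _ in PROTEIN_GENES:
            orf = orf_of(seq, start, end, strand)
            n = len(orf) - len(orf) % 3
            for i in range(3, n - 3, 3):
                if orf[i : i + 3] not in STOPS:
                    continue
                dirty = True
                span = genome_codon_span(start, end, strand, i)
                choices = []
                for codon in NON_STOP_CODONS:
                    placed = revcomp(codon) if strand == "light" else codon
                    if all(
                        not pinned[g] or seq[g] == placed[k]
                        for k, g in enumerate(span)
                    ):
                        choices.append(placed)
                if not choices:
                    raise RuntimeError(f"over-constrained codon in {name} at offset {i}")
                placed = rng.choice(choices)
                for k, g in enumerate(span):
                    seq[g] = placed[k]
        if not dirty:
            break
    else:
        raise RuntimeError("ORF repair did not converge")

    # final verification of every frame, including overlaps
    for name, _, start, end, strand, _ in PROTEIN_GENES:
        orf = orf_of(seq, start, end, strand)
        pad = {0: "", 1: "AA", 2: "A"}[len(orf) % 3]
        padded = orf + pad
        if has_internal_stop(padded):
            raise RuntimeError(f"internal stop remains in {name}")
        if padded[-3:] not in STOPS:
            raise RuntimeError(f"{name} lacks a (padded) terminal stop")
    return "".join(seq)


def write_outputs(outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    seq = build_sequence()
    assert len(seq) == GENOME_LENGTH

    fasta = outdir / "rcrs_synthetic.fasta"
    lines = [">chrM synthetic stand-in for the rCRS (NC_012920 coordinates)"]
    lines += [seq[i : i + 70] for i in range(0, len(seq), 70)]
    fasta.write_text("\n".join(lines) + "\n")

    gff = outdir / "rcrs_features.gff3"
    rows = ["##gff-version 3", f"##sequence-region chrM 1 {GENOME_LENGTH}"]
    for name, ftype, start, end, strand, cplx in FEATURES:
        strand_sym = "+" if strand == "heavy" else "-"
        attrs = f"ID={name};Name={name};oxphos_complex={cplx}"
        rows.append(
            "\t".join(
                ["chrM", "mosaicmito", ftype, str(start), str(end), ".", strand_sym, ".", attrs]
            )
        )
    gff.write_text("\n".join(rows) + "\n")

    manifest = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in (fasta, gff)
    }
    manifest_path = outdir / "checksums.json"
    if manifest_path.exists():
        existing = json.loads(manifest_path.read_text())
        existing.update(manifest)
        manifest = existing
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    print(f"wrote {fasta} ({fasta.stat().st_size} bytes), {gff}, checksums.json")


if __name__ == "__main__":
    write_outputs(Path(__file__).resolve().parents[1] / "src" / "mosaicmito" / "_data")
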