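"""Offline model of the human mitochondrial reference genome.

Coordinates are 1-based inclusive throughout, following the rCRS convention
(NC_012920). The bundled reference bundled with this package is a *synthetic
stand-in*: the gene annotation (13 protein-coding genes, 22 tRNAs, 2 rRNAs,
control region, strands, OXPHOS complex assignment) is the standard rCRS gene
table, but the nucleotide sequence itself is simulated (see
``scripts/make_reference.py``). Analyses of real data should supply the true
rCRS FASTA via :func:`load_reference`.

Strand is recorded as ``heavy``/``light``; light-strand genes (MT-ND6 and
several tRNAs) are reverse-complemented before codon extraction. Genes whose
length is not a multiple of three end in an incomplete stop codon completed
by polyadenylation; variants in the terminal codon are classified against the
A-padded codon.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from functools import cached_property
from importlib import resources
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

GENOME_LENGTH = 16569

#: consequence labels
SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
TRNA_VARIANT = "trna_variant"
RRNA_VARIANT = "rrna_variant"
NONCODING = "noncoding"

_MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]  # vertebrate mitochondrial


class CoordinateError(ValueError):
    """Position outside 1..16569."""


class ReferenceMismatchError(ValueError):
    """Stated reference base disagrees with the loaded genome — wrong
    coordinates or wrong reference build."""


class IntegrityError(RuntimeError):
    """A bundled data file does not match its recorded checksum."""


def translate_codon(codon: str) -> str:
    """Vertebrate mitochondrial translation of one codon; stops return ``*``.

    All 64 codons are covered (60 sense + 4 stops: TAA, TAG, AGA, AGG).
    """
    codon = codon.upper()
    if codon in _MITO_TABLE.stop_codons:
        return "*"
    return _MITO_TABLE.forward_table[codon]


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature of the mitochondrial genome."""

    name: str
    feature_type: str  # protein_coding | tRNA | rRNA | control_region
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # heavy | light
    oxphos_complex: str  # I | III | IV | V | none

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end <= GENOME_LENGTH):
            raise ValueError(f"feature {self.name} outside genome bounds")
        if self.feature_type == "protein_coding" and self.oxphos_complex == "none":
            raise ValueError(f"protein-coding gene {self.name} lacks an OXPHOS complex")

    def covers(self, position: int) -> bool:
        return self.start <= position <= self.end

    def __len__(self) -> int:
        return self.end - self.start + 1


class ReferenceGenome:
    """Mitochondrial sequence plus feature annotation.

    Parameters
    ----------
    sequence
        The 16,569-nt genome as an upper-case string.
    features
        Annotated features; the 13 protein-coding, 22 tRNA and 2 rRNA genes
        must each be present exactly once.
    """

    def __init__(self, sequence: str, features: list[GeneFeature]):
        sequence = sequence.upper()
        if len(sequence) != GENOME_LENGTH:
            raise ValueError(
                f"expected a {GENOME_LENGTH}-nt genome, got {len(sequence)} nt"
            )
        counts = {"protein_coding": 0, "tRNA": 0, "rRNA": 0}
        names = set()
        for f in features:
            if f.name in names:
                raise ValueError(f"duplicate feature {f.name}")
            names.add(f.name)
            if f.feature_type in counts:
                counts[f.feature_type] += 1
        expected = {"protein_coding": 13, "tRNA": 22, "rRNA": 2}
        if counts != expected:
            raise ValueError(f"feature census {counts} != {expected}")
        self.sequence = sequence
        self.features = sorted(features, key=lambda f: (f.start, f.end))

    @cached_property
    def genes(self) -> dict[str, GeneFeature]:
        return {f.name: f for f in self.features}

    def base_at(self, position: int) -> str:
        self._check_position(position)
        return self.sequence[position - 1]

    @staticmethod
    def _check_position(position: int) -> None:
        if not (1 <= position <= GENOME_LENGTH):
            raise CoordinateError(
                f"position {position} outside 1..{GENOME_LENGTH} (1-based rCRS)"
            )

    def locate(self, position: int) -> list[GeneFeature]:
        """All features whose interval contains ``position``, ascending start."""
        self._check_position(position)
        return [f for f in self.features if f.covers(position)]

    def coding_features(self, position: int) -> list[GeneFeature]:
        return [f for f in self.locate(position) if f.feature_type == "protein_coding"]

    def codon_at(self, position: int, feature: GeneFeature) -> tuple[str, int]:
        """The reference codon of ``feature`` covering ``position``.

        Returns the codon in coding orientation (light-strand genes reverse-
        complemented) and the 0-based offset of ``position`` within it. A
        terminal incomplete codon is A-padded (polyadenylation convention).
        """
        if feature.strand == "light":
            offset = feature.end - position
        else:
            offset = position - feature.start
        codon_start = offset - offset % 3
        bases = []
        for i in range(3):
            cds_idx = codon_start + i
            if cds_idx >= len(feature):
                bases.append("A")  # poly-A completion of the terminal codon
                continue
            if feature.strand == "light":
                g = feature.end - cds_idx
                bases.append(str(Seq(self.sequence[g - 1]).complement()))
            else:
                g = feature.start + cds_idx
                bases.append(self.sequence[g - 1])
        return "".join(bases), offset % 3

    def classify_consequence(
        self, position: int, ref_base: str, alt_base: str, feature: GeneFeature
    ) -> str:
        """Consequence of a single-nucleotide substitution within ``feature``.

        Pure function of its inputs. ``ref_base`` must equal the genome base
        at ``position`` (heavy-strand orientation, as in variant tables).
        """
        self._check_position(position)
        if not feature.covers(position):
            raise ValueError(f"{feature.name} does not cover position {position}")
        ref_base, alt_base = ref_base.upper(), alt_base.upper()
        if self.base_at(position) != ref_base:
            raise ReferenceMismatchError(
                f"reference base at {position} is {self.base_at(position)}, "
                f"not {ref_base}: wrong coordinates or wrong reference"
            )
        if feature.feature_type == "tRNA":
            return TRNA_VARIANT
        if feature.feature_type == "rRNA":
            return RRNA_VARIANT
        if feature.feature_type != "protein_coding":
            return NONCODING
        codon, within = self.codon_at(position, feature)
        if feature.strand == "light":
            alt_cds = str(Seq(alt_base).complement())
        else:
            alt_cds = alt_base
        alt_codon = codon[:within] + alt_cds + codon[within + 1 :]
        return SYNONYMOUS if translate_codon(codon) == translate_codon(alt_codon) else NONSYNONYMOUS

    def coding_sequence(self, gene: str) -> str:
        """A-padded coding sequence of a protein-coding gene."""
        f = self.genes[gene]
        frag = self.sequence[f.start - 1 : f.end]
        if f.strand == "light":
            frag = str(Seq(frag).reverse_complement())
        pad = {0: "", 1: "AA", 2: "A"}[len(frag) % 3]
        return frag + pad


# ---------------------------------------------------------------------------
# loading

_DATA = resources.files("mosaicmito") / "_data"
_STRAND = {"+": "heavy", "-": "light"}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def verify_bundled_checksum(path: Path) -> None:
    """Raise :class:`IntegrityError` if a bundled data file was altered."""
    manifest = json.loads((_DATA / "checksums.json").read_text())
    recorded = manifest.get(path.name)
    if recorded is None:
        raise IntegrityError(f"no recorded checksum for {path.name}")
    if _sha256(path) != recorded:
        raise IntegrityError(f"checksum mismatch for bundled file {path.name}")


def read_features_gff3(path: str | Path) -> list[GeneFeature]:
    """Parse the feature table (GFF3, 1-based inclusive, +/- strand)."""
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="error")
    feats = []
    for rec in db.all_features():
        feats.append(
            GeneFeature(
                name=rec.attributes["Name"][0],
                feature_type=rec.featuretype,
                start=rec.start,
                end=rec.end,
                strand=_STRAND[rec.strand],
                oxphos_complex=rec.attributes.get("oxphos_complex", ["none"])[0],
            )
        )
    return feats


def load_reference(
    fasta: str | Path | None = None, gff3: str | Path | None = None
) -> ReferenceGenome:
    """Load a mitochondrial reference; defaults to the bundled synthetic one.

    Bundled files are checksum-verified; user-supplied paths are not.
    """
    if fasta is None:
        fasta = Path(str(_DATA / "rcrs_synthetic.fasta"))
        verify_bundled_checksum(fasta)
    if gff3 is None:
        gff3 = Path(str(_DATA / "rcrs_features.gff3"))
        verify_bundled_checksum(gff3)
    record = next(SeqIO.parse(str(fasta), "fasta"))
    return ReferenceGenome(str(record.seq), read_features_gff3(gff3))
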