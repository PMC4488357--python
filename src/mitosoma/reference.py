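"""Mitochondrial reference genome, gene annotation and tRNA cloverleaf models.

Coordinates throughout the package are 1-based inclusive on the circular
mitochondrial genome (16,569 nt in the standard human numbering).  The
reference plus strand is designated the light (L) strand; the heavy (H)
strand is its reverse complement.  Features may wrap the origin (the
control region / D-loop does, spanning 16,024..576).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "MitoGenome",
    "GeneFeature",
    "FeatureTable",
    "CloverleafAnnotation",
    "load_genome",
    "load_features",
    "load_cloverleafs",
    "base_composition",
    "translate_codon",
    "reverse_complement",
    "MITO_TABLE",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: Vertebrate mitochondrial genetic code (NCBI translation table 2).
MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]

FEATURE_CLASSES = ("protein", "tRNA", "rRNA", "D-loop", "noncoding")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MitoGenome:
    """Circular mitochondrial reference sequence (plus strand = L strand)."""

    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if re.search(r"[^ACGT]", self.sequence):
            raise ValueError("genome sequence must be over the ACGT alphabet")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Reference (L-strand) base at a 1-based, origin-wrapping position."""
        return self.sequence[(position - 1) % self.length]

    def fetch(self, start: int, end: int) -> str:
        """Plus-strand sequence of the 1-based inclusive interval start..end.

        ``start > end`` denotes an interval wrapping the origin.
        """
        if not (1 <= start <= self.length and 1 <= end <= self.length):
            raise ValueError(f"interval {start}..{end} outside 1..{self.length}")
        if start <= end:
            return self.sequence[start - 1 : end]
        if not self.circular:
            raise ValueError("wrapping interval on a non-circular genome")
        return self.sequence[start - 1 :] + self.sequence[:end]


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature; ``start > end`` encodes an origin-wrapping span."""

    name: str
    start: int
    end: int
    strand: str  # 'L' (reference sense) or 'H' (reverse complement sense)
    feature_class: str

    def __post_init__(self) -> None:
        if self.strand not in ("L", "H"):
            raise ValueError(f"strand must be L or H, got {self.strand!r}")
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")

    def length(self, genome_length: int) -> int:
        if self.start <= self.end:
            return self.end - self.start + 1
        return genome_length - self.start + 1 + self.end

    def contains(self, position: int, genome_length: int) -> bool:
        if not (1 <= position <= genome_length):
            raise ValueError(f"position {position} outside 1..{genome_length}")
        if self.start <= self.end:
            return self.start <= position <= self.end
        return position >= self.start or position <= self.end

    def positions(self, genome_length: int) -> Iterator[int]:
        """Genome positions of the feature in 5'->3' order of the *plus* strand."""
        if self.start <= self.end:
            yield from range(self.start, self.end + 1)
        else:
            yield from range(self.start, genome_length + 1)
            yield from range(1, self.end + 1)

    def local_index(self, position: int, genome_length: int) -> int:
        """0-based offset of ``position`` within the feature, gene-strand sense.

        For L features this counts from ``start``; for H features from ``end``
        (the gene's own 5' end lies at the plus-strand 3' side).
        """
        if not self.contains(position, genome_length):
            raise ValueError(f"position {position} not in feature {self.name}")
        if self.start <= self.end:
            plus_off = position - self.start
        else:
            plus_off = position - self.start if position >= self.start else (
                genome_length - self.start + position
            )
        if self.strand == "L":
            return plus_off
        return self.length(genome_length) - 1 - plus_off

    def genome_position(self, local_index: int, genome_length: int) -> int:
        """Inverse of :meth:`local_index`: genome position of a local offset."""
        if not (0 <= local_index < self.length(genome_length)):
            raise ValueError(f"local index {local_index} outside {self.name}")
        plus_off = (
            local_index
            if self.strand == "L"
            else self.length(genome_length) - 1 - local_index
        )
        return (self.start - 1 + plus_off) % genome_length + 1


class FeatureTable:
    """Ordered collection of gene features with positional lookup."""

    def __init__(self, features: Sequence[GeneFeature], genome_length: int):
        self.features = list(features)
        self.genome_length = genome_length
        self._by_name = {f.name: f for f in self.features}
        if len(self._by_name) != len(self.features):
            raise ValueError("duplicate feature names")

    def __iter__(self) -> Iterator[GeneFeature]:
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def get(self, name: str) -> GeneFeature:
        return self._by_name[name]

    def by_class(self, feature_class: str) -> list[GeneFeature]:
        return [f for f in self.features if f.feature_class == feature_class]

    def feature_at(self, position: int) -> list[GeneFeature]:
        """All features whose (possibly wrapping) interval contains ``position``."""
        if not (1 <= position <= self.genome_length):
            raise ValueError(
                f"position {position} outside 1..{self.genome_length}"
            )
        return [f for f in self.features if f.contains(position, self.genome_length)]

    def gene_sequence(self, name: str, genome: MitoGenome) -> str:
        """Gene-strand (sense) DNA sequence of a named feature."""
        f = self.get(name)
        plus = genome.fetch(f.start, f.end)
        return plus if f.strand == "L" else reverse_complement(plus)


def base_composition(
    genome: MitoGenome, region: Iterable[int] | None = None
) -> dict[str, float]:
    """Frequencies of A/C/G/T on the reference plus strand.

    ``region`` is an optional iterable of 1-based positions; by default the
    whole genome is used.  Frequencies sum to 1.
    """
    if region is None:
        seq = genome.sequence
    else:
        positions = list(region)
        if not positions:
            raise ValueError("empty region")
        seq = "".join(genome.base(p) for p in positions)
    n = len(seq)
    return {b: seq.count(b) / n for b in "ACGT"}


def translate_codon(codon: str, table: CodonTable.CodonTable = MITO_TABLE) -> str:
    """Translate a codon; returns a one-letter amino acid or '*' for stop.

    Uses the vertebrate mitochondrial code by default (AGA/AGG are stops,
    ATA is Met, TGA is Trp).
    """
    codon = codon.upper()
    if len(codon) != 3 or re.search(r"[^ACGT]", codon):
        raise ValueError(f"invalid codon {codon!r}")
    if codon in table.stop_codons:
        return "*"
    return table.forward_table[codon]


# ---------------------------------------------------------------------------
# tRNA cloverleaf annotations
# ---------------------------------------------------------------------------

DOMAIN_CODES = {
    "A": "acceptor stem",
    "D": "D-arm",
    "C": "anticodon arm",
    "T": "T-arm",
    "L": "loop",
    "V": "variable",
}


@dataclass(frozen=True)
class CloverleafAnnotation:
    """Secondary structure of one mt-tRNA in gene-local coordinates."""

    trna_name: str
    sequence: str  # DNA letters, gene (sense) strand
    structure: str  # dot-bracket, same length
    domains: str  # one domain code per position (see DOMAIN_CODES)
    pairs: tuple[tuple[int, int], ...] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.structure) != len(self.sequence):
            raise ValueError(f"{self.trna_name}: structure/sequence length mismatch")
        if len(self.domains) != len(self.sequence):
            raise ValueError(f"{self.trna_name}: domain/sequence length mismatch")
        object.__setattr__(self, "pairs", _parse_dotbracket(self.structure))

    def __len__(self) -> int:
        return len(self.sequence)

    def is_paired(self, local_position: int) -> bool:
        """Whether the 1-based local position is paired in the reference fold."""
        if not (1 <= local_position <= len(self)):
            raise ValueError(f"position {local_position} outside tRNA")
        return self.structure[local_position - 1] != "."

    def domain_label(self, local_position: int) -> str:
        return DOMAIN_CODES[self.domains[local_position - 1]]


def _parse_dotbracket(structure: str) -> tuple[tuple[int, int], ...]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, ch in enumerate(structure, start=1):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            pairs.append((stack.pop(), i))
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket character {ch!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return tuple(sorted(pairs))


# ---------------------------------------------------------------------------
# Packaged fixture loading
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("mitosoma").joinpath("data", name)


def load_genome(path=None) -> MitoGenome:
    """Load the packaged synthetic mitochondrial reference (or a FASTA path)."""
    if path is None:
        path = _data_path("synthetic_mito_genome.fa")
    with open(path) as fh:
        record = next(SeqIO.parse(fh, "fasta"))
    return MitoGenome(str(record.seq).upper())


def load_features(path=None, genome_length: int = 16569) -> FeatureTable:
    """Load the gene feature table (TSV: name, start, end, strand, class)."""
    if path is None:
        path = _data_path("features.tsv")
    df = pd.read_csv(path, sep="\t", comment="#")
    feats = [
        GeneFeature(r["name"], int(r["start"]), int(r["end"]), r["strand"], r["class"])
        for _, r in df.iterrows()
    ]
    return FeatureTable(feats, genome_length)


def load_cloverleafs(directory=None) -> dict[str, CloverleafAnnotation]:
    """Load the 22 packaged mt-tRNA cloverleaf annotations, keyed by gene name."""
    if directory is None:
        directory = resources.files("mitosoma").joinpath("data", "trna")
        names = sorted(p.name for p in directory.iterdir() if p.name.endswith(".txt"))
        paths = [directory.joinpath(n) for n in names]
    else:
        import os

        paths = sorted(
            os.path.join(directory, n)
            for n in os.listdir(directory)
            if n.endswith(".txt")
        )
    out: dict[str, CloverleafAnnotation] = {}
    for p in paths:
        with open(p) as fh:
            lines = [l.rstrip("\n") for l in fh if l.strip()]
        header = lines[0]
        if not header.startswith(">"):
            raise ValueError(f"{p}: expected '>' header")
        name = header[1:].split()[0]
        out[name] = CloverleafAnnotation(name, lines[1], lines[2], lines[3])
    return out
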