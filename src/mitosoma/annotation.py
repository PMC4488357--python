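"""Variant-effect annotation on the mitochondrial genome.

Each mutation gets a genomic region (coding / tRNA / rRNA / D-loop /
noncoding), a coding effect under the vertebrate mitochondrial code where
applicable, and — for SNVs — a strand-resolved substitution class: every
substitution is reported as the change of the pyrimidine of the mutated
Watson-Crick pair, on the strand carrying that pyrimidine (reference plus
strand = L).  A reference G>A, for example, is a C>T change on the H strand.

Genes encoded on the H strand (ND6 and eight tRNAs) are evaluated on the
reverse complement of the reference.  Indels are left-aligned within
homopolymer runs before classification so recurrent slippage events at the
known polyC/polyA hotspot runs collapse onto one canonical position.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .catalogue import Catalogue, MutationRecord
from .reference import (
    FeatureTable,
    GeneFeature,
    MitoGenome,
    translate_codon,
)

__all__ = [
    "AnnotatedMutation",
    "Annotator",
    "strand_class",
    "strand_class_of",
    "left_align_indel",
    "annotate_catalogue",
    "EFFECT_SEVERITY",
    "PYRIMIDINE_CLASSES",
]

_PYR = "CT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

PYRIMIDINE_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

# severity order for the most-severe-across-frames rule
EFFECT_SEVERITY = {
    "nonsense": 4,
    "frameshift": 3,
    "missense": 2,
    "inframe-indel": 1,
    "synonymous": 0,
}

REGION_PRIORITY = ("protein", "tRNA", "rRNA", "D-loop", "noncoding")
REGION_LABEL = {
    "protein": "coding",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "D-loop": "D-loop",
    "noncoding": "noncoding",
}


def strand_class_of(ref: str, alt: str) -> tuple[str, str]:
    """Pyrimidine-normalised (class, strand) of a reference-sense substitution."""
    if ref in _PYR:
        return f"{ref}>{alt}", "L"
    return f"{_COMPLEMENT[ref]}>{_COMPLEMENT[alt]}", "H"


def strand_class(rec: MutationRecord) -> tuple[str, str]:
    """Strand-resolved substitution class of an SNV record."""
    if rec.kind != "SNV":
        raise ValueError("strand class is defined for SNVs only")
    rec = rec.normalized()
    return strand_class_of(rec.ref, rec.alt)


def left_align_indel(position: int, ref: str, alt: str, genome: MitoGenome) -> int:
    """Left-align a simple insertion/deletion within a homopolymer run.

    Handles the common caller representation where one allele extends the
    other (ref ``C``/alt ``CC``, or ref ``CA``/alt ``C``).  The position is
    moved left while the preceding reference base equals the first inserted
    or deleted base, yielding a canonical placement for slippage events in
    mononucleotide runs.
    """
    if len(ref) == 1 and len(alt) == 1:
        return position
    if alt.startswith(ref):
        unit = alt[len(ref)]
    elif ref.startswith(alt):
        unit = ref[len(alt)]
    else:
        return position
    pos = position
    while genome.base(pos - 1 if pos > 1 else genome.length) == unit and pos > 1:
        pos -= 1
    return pos


@dataclass(frozen=True)
class AnnotatedMutation:
    """A mutation record together with its derived annotations."""

    record: MutationRecord
    region: str
    gene: str | None
    effect: str
    strand_class: tuple[str, str] | None


class Annotator:
    """Cached region/effect classifier over one genome + feature table."""

    def __init__(self, genome: MitoGenome, features: FeatureTable):
        self.genome = genome
        self.features = features
        # position -> overlapping features, precomputed once
        self._index: list[list[GeneFeature]] = [[] for _ in range(genome.length + 1)]
        for f in features:
            for pos in f.positions(genome.length):
                self._index[pos].append(f)
        self._gene_seq: dict[str, str] = {
            f.name: features.gene_sequence(f.name, genome)
            for f in features
            if f.feature_class == "protein"
        }

    # -- region ------------------------------------------------------------

    def features_at(self, position: int) -> list[GeneFeature]:
        if not (1 <= position <= self.genome.length):
            raise ValueError(f"position {position} out of range")
        return self._index[position]

    def classify_region(self, rec: MutationRecord) -> tuple[str, str | None]:
        """(region label, gene symbol or None) for a record's position."""
        feats = self.features_at(rec.position)
        for cls in REGION_PRIORITY:
            hits = [f for f in feats if f.feature_class == cls]
            if hits:
                return REGION_LABEL[cls], hits[0].name
        return "noncoding", None

    def coding_positions(self):
        """Sorted genome positions covered by at least one protein gene."""
        out = set()
        for f in self.features.by_class("protein"):
            out.update(f.positions(self.genome.length))
        return sorted(out)

    # -- coding effect -------------------------------------------------------

    def snv_effect(self, position: int, ref: str, alt: str) -> str | None:
        """Most severe coding effect of an SNV across overlapping frames.

        Returns None when the position is not in a complete codon of any
        protein gene.
        """
        best = None
        for f in self.features_at(position):
            if f.feature_class != "protein":
                continue
            eff = self._snv_effect_in_gene(f, position, ref, alt)
            if eff is None:
                continue
            if best is None or EFFECT_SEVERITY[eff] > EFFECT_SEVERITY[best]:
                best = eff
        return best

    def _snv_effect_in_gene(
        self, gene: GeneFeature, position: int, ref: str, alt: str
    ) -> str | None:
        seq = self._gene_seq[gene.name]
        idx = gene.local_index(position, self.genome.length)
        if idx >= 3 * (len(seq) // 3):
            return None  # trailing partial codon
        if gene.strand == "H":
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        codon_start = 3 * (idx // 3)
        codon = seq[codon_start : codon_start + 3]
        if codon[idx % 3] != ref:
            raise ValueError(
                f"reference mismatch in {gene.name} at {position}: "
                f"expected {codon[idx % 3]}, record says {ref}"
            )
        mutant = codon[: idx % 3] + alt + codon[idx % 3 + 1 :]
        aa_ref = translate_codon(codon)
        aa_alt = translate_codon(mutant)
        if aa_ref == aa_alt:
            return "synonymous"
        if aa_alt == "*":
            return "nonsense"
        return "missense"

    def coding_effect(self, rec: MutationRecord) -> str:
        """Effect of a record located in a coding region."""
        if rec.kind == "SNV":
            eff = self.snv_effect(rec.position, rec.ref, rec.alt)
            if eff is None:
                raise ValueError(f"position {rec.position} not in a complete codon")
            return eff
        delta = abs(len(rec.ref) - len(rec.alt))
        return "frameshift" if delta % 3 != 0 else "inframe-indel"

    # -- full annotation ------------------------------------------------------

    def annotate(self, rec: MutationRecord) -> AnnotatedMutation:
        rec_n = rec.normalized()
        if rec_n.is_indel:
            pos = left_align_indel(rec_n.position, rec_n.ref, rec_n.alt, self.genome)
            rec_for_region = MutationRecord(
                rec_n.sample_id, rec_n.cancer_type, pos, rec_n.ref, rec_n.alt,
                rec_n.vaf_dna, rec_n.vaf_normal, rec_n.vaf_rna, rec_n.rna_confirmed,
            )
        else:
            rec_for_region = rec_n
        region, gene = self.classify_region(rec_for_region)
        if region == "coding":
            effect = self.coding_effect(rec_for_region)
        else:
            effect = "noncoding"
        sc = strand_class(rec) if rec.kind == "SNV" else None
        return AnnotatedMutation(rec, region, gene, effect, sc)


def annotate_catalogue(
    cat: Catalogue, genome: MitoGenome, features: FeatureTable,
    annotator: Annotator | None = None,
) -> pd.DataFrame:
    """Catalogue as a DataFrame with appended annotation columns."""
    ann = annotator or Annotator(genome, features)
    rows = []
    for rec in cat:
        a = ann.annotate(rec)
        rows.append(
            {
                "sample_id": rec.sample_id,
                "cancer_type": rec.cancer_type,
                "position": rec.position,
                "ref": rec.ref,
                "alt": rec.alt,
                "kind": rec.kind,
                "vaf_dna": rec.vaf_dna,
                "vaf_normal": rec.vaf_normal,
                "vaf_rna": rec.vaf_rna,
                "region": a.region,
                "gene": a.gene,
                "effect": a.effect,
                "sub_class": a.strand_class[0] if a.strand_class else None,
                "sub_strand": a.strand_class[1] if a.strand_class else None,
            }
        )
    return pd.DataFrame(rows)
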