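"""Strand-resolved mutational spectrum and enrichment analysis.

Substitutions are grouped into 12 classes: the six pyrimidine-normalised
changes (C>A, C>G, C>T, T>A, T>C, T>G) on each strand (L = reference plus
strand, H = its complement).  Expected class frequencies assume every
position mutates with equal probability to each of the three alternative
bases, scaled by the genome's single-base composition: class (P>Q, S)
expects freq(source base on the reference) / 3, where the source base is P
itself for L classes and its complement for H classes.  Enrichment is the
observed/expected fraction ratio; a strong excess of C>T on the H strand
is the hallmark of replication-coupled mtDNA mutagenesis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import PYRIMIDINE_CLASSES, strand_class
from .catalogue import Catalogue
from .reference import MitoGenome

__all__ = [
    "StrandSpectrum",
    "ALL_CLASSES",
    "strand_spectrum",
    "expected_fractions",
    "enrichment",
    "gc_pair_fraction",
    "gc_pair_enrichment",
    "segment_signatures",
    "dipyrimidine_fraction",
]

ALL_CLASSES = tuple(
    (cls, strand) for cls in PYRIMIDINE_CLASSES for strand in ("L", "H")
)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class StrandSpectrum:
    """Counts of SNVs per (pyrimidine class, strand)."""

    counts: Mapping[tuple[str, str], int]

    @property
    def n_snv(self) -> int:
        return sum(self.counts.values())

    def fraction(self, key: tuple[str, str]) -> float:
        if self.n_snv == 0:
            raise ValueError("empty spectrum")
        return self.counts.get(key, 0) / self.n_snv

    def fractions(self) -> dict[tuple[str, str], float]:
        return {k: self.fraction(k) for k in ALL_CLASSES}


def strand_spectrum(cat: Catalogue) -> StrandSpectrum:
    """Strand-resolved substitution spectrum of a catalogue (indels ignored)."""
    counts = {k: 0 for k in ALL_CLASSES}
    for rec in cat:
        if rec.kind != "SNV":
            continue
        counts[strand_class(rec)] += 1
    return StrandSpectrum(counts)


def expected_fractions(composition: Mapping[str, float]) -> dict[tuple[str, str], float]:
    """Expected fraction per class x strand from single-base composition."""
    total = sum(composition.get(b, 0.0) for b in "ACGT")
    if abs(total - 1.0) > 1e-6:
        raise ValueError("composition must sum to 1")
    out = {}
    for cls, strand in ALL_CLASSES:
        pyr = cls[0]
        source = pyr if strand == "L" else _COMPLEMENT[pyr]
        out[(cls, strand)] = composition[source] / 3.0
    return out


def enrichment(
    spec: StrandSpectrum, expected: Mapping[tuple[str, str], float]
) -> pd.DataFrame:
    """Observed vs expected fractions and their ratio per class x strand."""
    if spec.n_snv == 0:
        raise ValueError("spectrum contains no SNVs")
    rows = []
    for key in ALL_CLASSES:
        obs = spec.fraction(key)
        exp = expected[key]
        rows.append(
            {
                "sub_class": key[0],
                "strand": key[1],
                "count": spec.counts.get(key, 0),
                "observed_fraction": obs,
                "expected_fraction": exp,
                "ratio": obs / exp if exp > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def gc_pair_fraction(spec: StrandSpectrum) -> float:
    """Fraction of SNVs occurring at G:C reference base pairs."""
    if spec.n_snv == 0:
        raise ValueError("spectrum contains no SNVs")
    at_gc = sum(
        n for (cls, strand), n in spec.counts.items() if cls.startswith("C")
    )
    return at_gc / spec.n_snv


def gc_pair_enrichment(spec: StrandSpectrum, composition: Mapping[str, float]) -> float:
    """Observed/expected ratio for mutations at G:C base pairs."""
    expected = composition["C"] + composition["G"]
    return gc_pair_fraction(spec) / expected


def segment_signatures(
    cat: Catalogue, genome_length: int = 16569, n_segments: int = 50
) -> pd.DataFrame:
    """Per-segment mutation counts over a circular genome partition.

    The genome is cut into ``n_segments`` near-equal segments starting at
    position 1: all segments have floor(L / n) bases, with the remainder
    distributed one extra base each to the final segments.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    base_len = genome_length // n_segments
    remainder = genome_length - base_len * n_segments
    bounds = []
    start = 1
    for i in range(n_segments):
        length = base_len + (1 if i >= n_segments - remainder else 0)
        bounds.append((start, start + length - 1))
        start += length
    spectra = {k: [0] * n_segments for k in ALL_CLASSES}
    counts = [0] * n_segments
    snvs = [0] * n_segments
    for rec in cat:
        pos = ((rec.position - 1) % genome_length) + 1
        idx = _segment_of(pos, bounds)
        counts[idx] += 1
        if rec.kind == "SNV":
            snvs[idx] += 1
            spectra[strand_class(rec)][idx] += 1
    rows = []
    for i, (s, e) in enumerate(bounds):
        row = {
            "segment": i + 1,
            "start": s,
            "end": e,
            "n_mutations": counts[i],
            "n_snv": snvs[i],
            "n_indel": counts[i] - snvs[i],
        }
        for cls, strand in ALL_CLASSES:
            row[f"{cls}_{strand}"] = spectra[(cls, strand)][i]
        rows.append(row)
    return pd.DataFrame(rows)


def _segment_of(pos: int, bounds: list[tuple[int, int]]) -> int:
    lo, hi = 0, len(bounds) - 1
    while lo < hi:
        mid = (lo + hi) // 2
        if pos > bounds[mid][1]:
            lo = mid + 1
        else:
            hi = mid
    return lo


def dipyrimidine_fraction(cat: Catalogue, genome: MitoGenome) -> float | None:
    """Fraction of C>T events with a 5' pyrimidine neighbour (mutated strand).

    A UV-type mutational process elevates C>T changes at dipyrimidine
    contexts.  For reference-sense C>T the 5' neighbour is the reference
    base upstream; for G>A (a C>T on the H strand) it is the complement of
    the reference base downstream.  Returns None when the catalogue has no
    C>T events.
    """
    n_ct = 0
    n_dipyr = 0
    for rec in cat:
        if rec.kind != "SNV":
            continue
        cls, strand = strand_class(rec)
        if cls != "C>T":
            continue
        n_ct += 1
        if strand == "L":
            neighbour = genome.base(rec.position - 1 if rec.position > 1 else genome.length)
        else:
            neighbour = _COMPLEMENT[
                genome.base(rec.position + 1 if rec.position < genome.length else 1)
            ]
        if neighbour in "CT":
            n_dipyr += 1
    if n_ct == 0:
        return None
    return n_dipyr / n_ct
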