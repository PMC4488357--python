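"""Build the packaged synthetic mitochondrial reference fixtures.

Writes, deterministically (fixed seed):

* ``src/mitosoma/data/synthetic_mito_genome.fa`` — a synthetic 16,569-nt
  circular genome.  Gene coordinates follow the standard human
  mitochondrial annotation (protein-gene ends lightly adjusted so every
  gene is a whole number of codons); protein genes are generated from
  mtDNA-like codon-position base compositions with no in-frame stops;
  tRNA genes carry designed cloverleaf sequences; the known indel-hotspot
  homopolymer runs (polyC at 10,947-52 and 11,867-72 in ND4, polyA at
  12,418-25 in ND5) are written in explicitly.
* ``src/mitosoma/data/features.tsv`` — the gene feature table.
* ``src/mitosoma/data/trna/*.txt`` — per-tRNA cloverleaf annotations
  (sequence, dot-bracket, domain labels), each verified to fold natively
  under the package's energy model.

The sequence is synthetic: it reproduces the statistical structure of the
real genome (length, composition, gene layout, codon-position biases) but
not its actual bases, which keeps the package self-contained.
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from mitosoma.reference import CloverleafAnnotation, reverse_complement
from mitosoma.trna_structure import fold_bpp, native_fold_check

MASTER_SEED = 20150630
GENOME_LENGTH = 16569

DATA = Path(__file__).resolve().parent.parent / "src" / "mitosoma" / "data"

# name, start, end, strand, class (1-based inclusive; D-loop wraps origin)
FEATURES = [
    ("D-loop", 16024, 576, "L", "D-loop"),
    ("TF", 577, 647, "L", "tRNA"),
    ("RNR1", 648, 1601, "L", "rRNA"),
    ("TV", 1602, 1670, "L", "tRNA"),
    ("RNR2", 1671, 3229, "L", "rRNA"),
    ("TL1", 3230, 3304, "L", "tRNA"),
    ("ND1", 3307, 4260, "L", "protein"),
    ("TI", 4263, 4331, "L", "tRNA"),
    ("TQ", 4332, 4400, "H", "tRNA"),
    ("TM", 4402, 4469, "L", "tRNA"),
    ("ND2", 4470, 5510, "L", "protein"),
    ("TW", 5512, 5579, "L", "tRNA"),
    ("TA", 5587, 5655, "H", "tRNA"),
    ("TN", 5657, 5729, "H", "tRNA"),
    ("TC", 5761, 5825, "H", "tRNA"),
    ("TY", 5826, 5891, "H", "tRNA"),
    ("CO1", 5904, 7445, "L", "protein"),
    ("TS1", 7446, 7514, "H", "tRNA"),
    ("TD", 7518, 7585, "L", "tRNA"),
    ("CO2", 7586, 8269, "L", "protein"),
    ("TK", 8295, 8364, "L", "tRNA"),
    ("ATP8", 8366, 8572, "L", "protein"),
    ("ATP6", 8527, 9207, "L", "protein"),
    ("CO3", 9207, 9989, "L", "protein"),
    ("TG", 9991, 10058, "L", "tRNA"),
    ("ND3", 10059, 10403, "L", "protein"),
    ("TR", 10405, 10469, "L", "tRNA"),
    ("ND4L", 10470, 10766, "L", "protein"),
    ("ND4", 10760, 12136, "L", "protein"),
    ("TH", 12138, 12206, "L", "tRNA"),
    ("TS2", 12207, 12265, "L", "tRNA"),
    ("TL2", 12266, 12331, "L", "tRNA"),
    ("ND5", 12337, 14148, "L", "protein"),
    ("ND6", 14149, 14673, "H", "protein"),
    ("TE", 14674, 14742, "H", "tRNA"),
    ("CYB", 14747, 15886, "L", "protein"),
    ("TT", 15888, 15953, "L", "tRNA"),
    ("TP", 15956, 16023, "H", "tRNA"),
]

# base compositions (reference plus strand) --------------------------------
BACKGROUND = {"A": 0.325, "C": 0.305, "G": 0.080, "T": 0.290}
# codon-position compositions for protein genes (sense strand), mirroring
# the strong third-position G depletion of mammalian mtDNA coding sequence
CODON_POS = [
    {"T": 0.25, "C": 0.26, "A": 0.31, "G": 0.18},
    {"T": 0.30, "C": 0.30, "A": 0.27, "G": 0.13},
    {"T": 0.17, "C": 0.35, "A": 0.44, "G": 0.04},
]
STOPS = {"TAA", "TAG", "AGA", "AGG"}
LOOP_COMP = {"A": 0.35, "T": 0.30, "C": 0.25, "G": 0.10}
STEM_PAIRS = [("G", "C"), ("C", "G"), ("A", "T"), ("T", "A")]
STEM_PAIR_P = [0.35, 0.30, 0.175, 0.175]

HOTSPOT_RUNS = [(10947, 10952, "C"), (11867, 11872, "C"), (12418, 12425, "A")]


def sample_bases(n: int, comp: dict[str, float], rng) -> str:
    bases, probs = zip(*comp.items())
    return "".join(rng.choice(bases, size=n, p=probs))


def sample_codon(rng, internal=True) -> str:
    while True:
        codon = "".join(
            str(rng.choice(list(p.keys()), p=list(p.values()))) for p in CODON_POS
        )
        if codon not in STOPS:
            return codon


def protein_sequence(length: int, rng) -> str:
    assert length % 3 == 0, length
    ncod = length // 3
    start = "ATG" if rng.random() < 0.7 else "ATA"
    body = "".join(sample_codon(rng) for _ in range(ncod - 2))
    return start + body + "TAA"


# cloverleaf construction ---------------------------------------------------

def _stem(n: int, rng) -> tuple[str, str]:
    left, right = [], []
    for _ in range(n):
        i = rng.choice(len(STEM_PAIRS), p=STEM_PAIR_P)
        a, b = STEM_PAIRS[i]
        left.append(a)
        right.append(b)
    return "".join(left), "".join(reversed(right))


def _loop(n: int, rng) -> str:
    return sample_bases(n, LOOP_COMP, rng)


def build_cloverleaf(name: str, length: int, rng) -> CloverleafAnnotation:
    """Designed cloverleaf of the requested length (59 drops the D-arm)."""
    if length == 59:  # Ser-AGY type: no D-arm
        var = 5
        acc5, acc3 = _stem(7, rng)
        ac5, ac3 = _stem(5, rng)
        t5, t3 = _stem(5, rng)
        seq = (acc5 + _loop(1, rng) + _loop(4, rng) + ac5 + _loop(7, rng) + ac3
               + _loop(var, rng) + t5 + _loop(7, rng) + t3 + acc3 + _loop(1, rng))
        struct = ("(" * 7 + "." * 5 + "(" * 5 + "." * 7 + ")" * 5 + "." * var
                  + "(" * 5 + "." * 7 + ")" * 5 + ")" * 7 + ".")
        dom = ("A" * 7 + "V" * 5 + "C" * 5 + "L" * 7 + "C" * 5 + "V" * var
               + "T" * 5 + "L" * 7 + "T" * 5 + "A" * 7 + "V")
        return CloverleafAnnotation(name, seq, struct, dom)
    delta = length - 71
    var = min(8, max(3, 4 + delta))
    dloop = 8 + (delta - (var - 4))
    assert 3 <= dloop <= 8, (name, length, var, dloop)
    acc5, acc3 = _stem(7, rng)
    d5, d3 = _stem(4, rng)
    ac5, ac3 = _stem(5, rng)
    t5, t3 = _stem(5, rng)
    seq = (acc5 + _loop(1, rng) + d5 + _loop(dloop, rng) + d3 + _loop(1, rng)
           + ac5 + _loop(7, rng) + ac3 + _loop(var, rng)
           + t5 + _loop(7, rng) + t3 + acc3 + _loop(1, rng))
    struct = ("(" * 7 + "." + "(" * 4 + "." * dloop + ")" * 4 + "."
              + "(" * 5 + "." * 7 + ")" * 5 + "." * var
              + "(" * 5 + "." * 7 + ")" * 5 + ")" * 7 + ".")
    dom = ("A" * 7 + "V" + "D" * 4 + "L" * dloop + "D" * 4 + "V"
           + "C" * 5 + "L" * 7 + "C" * 5 + "V" * var
           + "T" * 5 + "L" * 7 + "T" * 5 + "A" * 7 + "V")
    assert len(seq) == len(struct) == len(dom) == length
    return CloverleafAnnotation(name, seq, struct, dom)


def designed_cloverleaf(name: str, length: int) -> CloverleafAnnotation:
    """Cloverleaf whose wild type verifiably folds natively (retry on seed)."""
    import zlib

    for attempt in range(50):
        rng = np.random.default_rng(
            [MASTER_SEED, zlib.crc32(name.encode()) % 2**31, attempt]
        )
        cl = build_cloverleaf(name, length, rng)
        bpp = fold_bpp(cl.sequence)
        if native_fold_check(bpp, cl, threshold=0.7):
            return cl
    raise RuntimeError(f"could not design a natively folding {name}")


def feature_positions(start: int, end: int) -> list[int]:
    if start <= end:
        return list(range(start, end + 1))
    return list(range(start, GENOME_LENGTH + 1)) + list(range(1, end + 1))


def main() -> None:
    rng = np.random.default_rng(MASTER_SEED)
    genome = list(sample_bases(GENOME_LENGTH, BACKGROUND, rng))

    def write_span(start, end, seq):
        pos = feature_positions(start, end)
        assert len(pos) == len(seq), (start, end, len(pos), len(seq))
        for p, b in zip(pos, seq):
            genome[p - 1] = b

    lengths = {
        n: (len(feature_positions(s, e)))
        for n, s, e, *_ in [(f[0], f[1], f[2]) for f in FEATURES]
    }

    cloverleafs = {}
    for name, start, end, strand, cls in FEATURES:
        length = len(feature_positions(start, end))
        if cls in ("rRNA", "D-loop"):
            write_span(start, end, sample_bases(length, BACKGROUND, rng))
        elif cls == "tRNA":
            cl = designed_cloverleaf(name, length)
            cloverleafs[name] = cl
            seq = cl.sequence if strand == "L" else reverse_complement(cl.sequence)
            write_span(start, end, seq)
        elif cls == "protein":
            sense = protein_sequence(length, rng)
            seq = sense if strand == "L" else reverse_complement(sense)
            write_span(start, end, seq)

    for start, end, base in HOTSPOT_RUNS:
        write_span(start, end, base * (end - start + 1))
    # pin the bases flanking each run so the annotated run is maximal,
    # choosing replacements that keep the host gene free of in-frame stops
    gene_of_run = {10947: "ND4", 11867: "ND4", 12418: "ND5"}
    gene_start = {n: s for n, s, e, *_ in FEATURES}
    for start, end, base in HOTSPOT_RUNS:
        g0 = gene_start[gene_of_run[start]]
        for flank in (start - 1, end + 1):
            if genome[flank - 1] != base:
                continue
            frame_off = (flank - g0) % 3
            codon_start = flank - frame_off
            for candidate in "TCGA":
                if candidate == base:
                    continue
                codon = "".join(genome[codon_start - 1 : codon_start + 2])
                trial = codon[:frame_off] + candidate + codon[frame_off + 1 :]
                if trial not in STOPS:
                    genome[flank - 1] = candidate
                    break

    sequence = "".join(genome)
    assert len(sequence) == GENOME_LENGTH

    DATA.mkdir(parents=True, exist_ok=True)
    (DATA / "trna").mkdir(exist_ok=True)
    with open(DATA / "synthetic_mito_genome.fa", "w") as fh:
        fh.write(">chrM_synthetic synthetic mitochondrial reference "
                 "(16,569 nt, standard gene layout; not the real genome)\n")
        for i in range(0, GENOME_LENGTH, 70):
            fh.write(sequence[i : i + 70] + "\n")

    with open(DATA / "features.tsv", "w") as fh:
        fh.write("# synthetic mitochondrial gene annotation; 1-based inclusive\n")
        fh.write("# coordinates; start > end marks an origin-wrapping feature;\n")
        fh.write("# strand L = reference plus strand, H = reverse complement\n")
        fh.write("name\tstart\tend\tstrand\tclass\n")
        for name, start, end, strand, cls in FEATURES:
            fh.write(f"{name}\t{start}\t{end}\t{strand}\t{cls}\n")

    for name, cl in sorted(cloverleafs.items()):
        with open(DATA / "trna" / f"{name}.txt", "w") as fh:
            fh.write(f">{name} synthetic mt-tRNA cloverleaf (designed fixture)\n")
            fh.write(cl.sequence + "\n")
            fh.write(cl.structure + "\n")
            fh.write(cl.domains + "\n")

    comp = {b: sequence.count(b) / GENOME_LENGTH for b in "ACGT"}
    print("composition:", {k: round(v, 4) for k, v in comp.items()})
    print("tRNAs designed:", len(cloverleafs))


if __name__ == "__main__":
    main()
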