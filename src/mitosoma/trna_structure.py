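"""Structural-impact scoring of mt-tRNA point mutations.

A variant's impact on the tRNA fold is quantified by comparing ensemble
base-pair probability matrices of the wild-type and mutant sequences,
computed with a McCaskill-style partition function under a deliberately
simple nearest-neighbour energy model (Watson-Crick + GU pairs, stacking
energies, minimum hairpin loop of 3, no dangles or special loops).  The
score ``d`` is the maximal Euclidean distance between the two matrices
restricted to a local sequence window; its significance is an empirical
p-value against a null of dinucleotide-preserving shuffles of the tRNA
sequences, each carrying one random substitution.

Absolute free energies are therefore not comparable to full Turner-model
folding engines; the scores are only meaningful relative to the matched
shuffle background, which is how they are used here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .reference import CloverleafAnnotation
from .selection import TestResult

__all__ = [
    "BasePairProbabilityMatrix",
    "StructuralImpactResult",
    "fold_bpp",
    "structural_distance",
    "dinucleotide_shuffle",
    "BackgroundDistribution",
    "background_distribution",
    "empirical_p",
    "native_fold_check",
    "stem_or_loop",
    "compare_groups",
    "PAIR_ENERGY",
    "stack_energy",
]

# --- energy model ----------------------------------------------------------
# Energies in units of kT (so Boltzmann weights are exp(-E)).  Pair formation
# gets a small bonus; most stability comes from stacking of adjacent pairs,
# with per-pair strengths s(GC) > s(AU) > s(GU) combined additively.

PAIR_ENERGY = {
    ("G", "C"): -1.2,
    ("C", "G"): -1.2,
    ("A", "U"): -0.6,
    ("U", "A"): -0.6,
    ("G", "U"): -0.3,
    ("U", "G"): -0.3,
}

_STACK_STRENGTH = {
    ("G", "C"): 1.5,
    ("C", "G"): 1.5,
    ("A", "U"): 0.9,
    ("U", "A"): 0.9,
    ("G", "U"): 0.5,
    ("U", "G"): 0.5,
}

MIN_HAIRPIN = 3  # minimum unpaired bases enclosed by a pair


def stack_energy(outer: tuple[str, str], inner: tuple[str, str]) -> float:
    """Stacking energy (kT) of pair ``inner`` directly inside pair ``outer``."""
    return -(_STACK_STRENGTH[outer] + _STACK_STRENGTH[inner])


def _to_rna(seq: str) -> str:
    seq = seq.upper().replace("T", "U")
    if any(c not in "ACGU" for c in seq):
        raise ValueError(f"invalid RNA sequence {seq!r}")
    return seq


@dataclass(frozen=True)
class BasePairProbabilityMatrix:
    """Ensemble pairing probabilities p(i, j) for 1 <= i < j <= n."""

    sequence: str
    p: np.ndarray  # (n, n) array, upper triangle holds probabilities

    @property
    def n(self) -> int:
        return len(self.sequence)

    def prob(self, i: int, j: int) -> float:
        """Pairing probability of 1-based positions i < j."""
        if not (1 <= i < j <= self.n):
            raise ValueError(f"invalid pair ({i}, {j})")
        return float(self.p[i - 1, j - 1])

    def unpaired_prob(self, i: int) -> float:
        row = self.p[i - 1, :].sum() + self.p[:, i - 1].sum()
        return float(1.0 - row)


def fold_bpp(seq: str) -> BasePairProbabilityMatrix:
    """Ensemble base-pair probabilities of ``seq`` (ACGU; T mapped to U).

    Inside/outside partition-function recursions over all non-crossing
    structures with Watson-Crick/GU pairs and hairpin loops of at least
    :data:`MIN_HAIRPIN` bases, Boltzmann-weighted under the module's energy
    model at beta = 1.
    """
    rna = _to_rna(seq)
    n = len(rna)
    p = np.zeros((n, n))
    if n < MIN_HAIRPIN + 2:
        return BasePairProbabilityMatrix(rna, p)

    # pair weights and stacking weights
    wp = np.zeros((n, n))
    for i in range(n):
        for j in range(i + MIN_HAIRPIN + 1, n):
            e = PAIR_ENERGY.get((rna[i], rna[j]))
            if e is not None:
                wp[i, j] = math.exp(-e)

    def stack_w(i, j, k, l):
        return math.exp(-stack_energy((rna[i], rna[j]), (rna[k], rna[l])))

    # ---- inside ----
    # Z[i, j]: partition function on interval i..j (empty interval -> 1).
    # Zb[i, j]: same, restricted to structures where (i, j) is a pair.
    Z = np.ones((n + 1, n + 1))  # padded so empty intervals read as 1
    Zb = np.zeros((n, n))
    # M[i, k] = Z over interval i..k-1 (empty when k <= i); used for the
    # vectorised "last pair starts at k" decomposition.
    M = np.zeros((n, n + 1))
    for i in range(n):
        M[i, i] = 1.0  # empty interval i..i-1

    for j in range(n):
        # fill Zb[:, j] (needs Z of shorter intervals only)
        for i in range(j - MIN_HAIRPIN - 1, -1, -1):
            if wp[i, j] == 0.0:
                continue
            inner = Z[i + 1, j - 1] if j - 1 >= i + 1 else 1.0
            zb = inner
            if i + 1 < j - 1 and wp[i + 1, j - 1] > 0.0 and Zb[i + 1, j - 1] > 0.0:
                zb += (stack_w(i, j, i + 1, j - 1) - 1.0) * Zb[i + 1, j - 1]
            Zb[i, j] = wp[i, j] * zb
        # Z[:, j] = Z[:, j-1] + sum_k Z(i..k-1) * Zb[k, j]
        col = M[:, : j + 1] @ Zb[: j + 1, j]
        for i in range(j, -1, -1):
            prev = Z[i, j - 1] if j - 1 >= i else 1.0
            Z[i, j] = prev + col[i]
            M[i, j + 1] = Z[i, j]

    z_total = Z[0, n - 1]

    # ---- outside ----
    # Zo[i, j]: weight of everything outside pair (i, j), including the
    # stacking bonus with a directly enclosing pair when present.
    Zo = np.zeros((n, n))
    pair_list = [(i, j) for i in range(n) for j in range(i + MIN_HAIRPIN + 1, n)
                 if wp[i, j] > 0.0]
    pair_list.sort(key=lambda ij: ij[1] - ij[0], reverse=True)
    for i, j in pair_list:
        left = Z[0, i - 1] if i >= 1 else 1.0
        right = Z[j + 1, n - 1] if j + 1 <= n - 1 else 1.0
        Zo[i, j] += left * right
    for k, l in pair_list:  # decreasing span: outer contributions ready
        if Zo[k, l] == 0.0 or l - k < MIN_HAIRPIN + 3:
            continue
        amp = wp[k, l] * Zo[k, l]
        lo, hi = k + 1, l - 1  # nested pairs live in lo..hi
        if lo > hi:
            continue
        u = np.array([Z[lo, i - 1] if i - 1 >= lo else 1.0 for i in range(lo, hi + 1)])
        v = np.array([Z[j + 1, hi] if j + 1 <= hi else 1.0 for j in range(lo, hi + 1)])
        Zo[lo : hi + 1, lo : hi + 1] += amp * np.outer(u, v)
        if wp[lo, hi] > 0.0:  # adjacency: stacked outer pair correction
            Zo[lo, hi] += amp * (stack_w(k, l, lo, hi) - 1.0)

    for i, j in pair_list:
        p[i, j] = Zb[i, j] * Zo[i, j] / z_total
    np.clip(p, 0.0, 1.0, out=p)
    return BasePairProbabilityMatrix(rna, p)


# ---------------------------------------------------------------------------
# distance score
# ---------------------------------------------------------------------------

def structural_distance(
    wt: BasePairProbabilityMatrix,
    mut: BasePairProbabilityMatrix,
    window: int = 100,
) -> tuple[float, tuple[int, int]]:
    """Maximal local Euclidean distance between two pairing matrices.

    Scans every subinterval of length <= ``window`` and computes the
    Euclidean norm of the matrix difference restricted to pairs lying
    entirely within the interval; returns the maximum and its (1-based,
    inclusive) interval.  With ``window >= n`` the maximum is attained on
    the whole sequence.
    """
    if wt.n != mut.n:
        raise ValueError("sequence length mismatch (substitutions only)")
    n = wt.n
    if n == 0:
        return 0.0, (1, 0)
    sq = (wt.p - mut.p) ** 2
    # 2-D prefix sums; interval sum via inclusion-exclusion
    c = np.zeros((n + 1, n + 1))
    c[1:, 1:] = sq.cumsum(axis=0).cumsum(axis=1)
    best = -1.0
    best_iv = (1, n)
    best_len = 0
    w = min(window, n)
    for a in range(n):  # 0-based interval [a, b]
        bmax = min(n - 1, a + w - 1)
        for b in range(a, bmax + 1):
            s = c[b + 1, b + 1] - c[a, b + 1] - c[b + 1, a] + c[a, a]
            length = b - a + 1
            # ties resolved toward the longest (then leftmost) interval
            if s > best + 1e-15 or (abs(s - best) <= 1e-15 and length > best_len):
                best = s
                best_iv = (a + 1, b + 1)
                best_len = length
    return float(math.sqrt(max(best, 0.0))), best_iv


# ---------------------------------------------------------------------------
# dinucleotide-preserving shuffle (Altschul-Erickson Eulerian walk)
# ---------------------------------------------------------------------------

def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Random shuffle of ``seq`` preserving exact dinucleotide counts.

    Samples an Eulerian walk through the dinucleotide multigraph
    (Altschul-Erickson): terminal nucleotides and the full dinucleotide
    count vector of the input are preserved exactly.
    """
    if len(seq) < 2:
        return seq
    letters = sorted(set(seq))
    if len(letters) == 1:
        return seq
    edges: dict[str, list[str]] = {c: [] for c in letters}
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]

    # choose a "last edge" per non-terminal vertex until they form an
    # arborescence directed toward the terminal vertex
    while True:
        last_edge = {
            v: edges[v][rng.integers(len(edges[v]))]
            for v in letters
            if v != last and edges[v]
        }
        ok = True
        for v in last_edge:
            cur, seen = v, {v}
            while cur != last:
                if cur not in last_edge:
                    ok = False
                    break
                cur = last_edge[cur]
                if cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break

    shuffled_edges: dict[str, list[str]] = {}
    for v, outs in edges.items():
        outs = outs.copy()
        if v in last_edge:
            outs.remove(last_edge[v])
        perm = rng.permutation(len(outs))
        ordered = [outs[i] for i in perm]
        if v in last_edge:
            ordered.append(last_edge[v])
        shuffled_edges[v] = ordered

    walk = [seq[0]]
    idx = {v: 0 for v in shuffled_edges}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled_edges[cur][idx[cur]]
        idx[cur] += 1
        walk.append(nxt)
        cur = nxt
    return "".join(walk)


# ---------------------------------------------------------------------------
# empirical null
# ---------------------------------------------------------------------------

@dataclass
class BackgroundDistribution:
    """Pooled null distribution of distance scores for tRNA-length sequences."""

    scores: np.ndarray
    n_per_seq: int
    window: int
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.scores)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# n_per_seq={self.n_per_seq} window={self.window} "
                     f"seed={self.seed} energy_model=stack-v1\n")
            fh.write("score\n")
            for s in self.scores:
                fh.write(f"{s:.6g}\n")

    @classmethod
    def from_tsv(cls, path) -> "BackgroundDistribution":
        meta = {}
        scores = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    for tok in line[1:].split():
                        if "=" in tok:
                            k, v = tok.split("=", 1)
                            meta[k] = v
                elif line and line != "score":
                    scores.append(float(line))
        return cls(
            np.asarray(scores),
            n_per_seq=int(meta.get("n_per_seq", 0)),
            window=int(meta.get("window", 100)),
            seed=None if meta.get("seed") in (None, "None") else int(meta["seed"]),
        )


_ALTS = {"A": "CGU", "C": "AGU", "G": "ACU", "U": "ACG"}


def random_variant(seq: str, rng: np.random.Generator) -> tuple[str, int, str]:
    """Apply one uniform random substitution; returns (mutant, pos1based, alt)."""
    rna = _to_rna(seq)
    pos = int(rng.integers(len(rna)))
    alt = _ALTS[rna[pos]][rng.integers(3)]
    return rna[:pos] + alt + rna[pos + 1 :], pos + 1, alt


def background_distribution(
    trna_seqs: list[str],
    n_per_seq: int,
    rng: np.random.Generator,
    window: int = 100,
) -> BackgroundDistribution:
    """Null distance scores from shuffled tRNA sequences with one substitution.

    For each input sequence, ``n_per_seq`` dinucleotide-preserving shuffles
    are drawn; each shuffle receives one uniform random substitution and the
    wild-type/mutant distance score is recorded.  The pooled scores form the
    empirical null for :func:`empirical_p`.
    """
    if n_per_seq < 1:
        raise ValueError("n_per_seq must be >= 1")
    scores = []
    for seq in trna_seqs:
        rna = _to_rna(seq)
        for _ in range(n_per_seq):
            shuf = dinucleotide_shuffle(rna, rng)
            mut, _, _ = random_variant(shuf, rng)
            d, _ = structural_distance(fold_bpp(shuf), fold_bpp(mut), window)
            scores.append(d)
    return BackgroundDistribution(np.asarray(scores), n_per_seq, window)


def empirical_p(d: float, background: BackgroundDistribution | np.ndarray) -> float:
    """Empirical p-value (1 + #{null >= d}) / (1 + N); never zero."""
    scores = background.scores if isinstance(background, BackgroundDistribution) else np.asarray(background)
    if len(scores) == 0:
        raise ValueError("empty background distribution")
    return float((1 + (scores >= d).sum()) / (1 + len(scores)))


# ---------------------------------------------------------------------------
# native fold check and stem/loop localisation
# ---------------------------------------------------------------------------

def native_fold_check(
    bpp: BasePairProbabilityMatrix,
    reference: CloverleafAnnotation,
    threshold: float = 0.7,
    pair_prob: float = 0.5,
) -> bool:
    """Whether the ensemble fold recovers the reference cloverleaf.

    True iff at least ``threshold`` of the reference base pairs carry an
    ensemble probability of at least ``pair_prob``.  Variants on tRNAs whose
    wild type fails this check are excluded from group comparisons.
    """
    if bpp.n != len(reference):
        raise ValueError("length mismatch between fold and reference")
    if not reference.pairs:
        return False
    good = sum(1 for i, j in reference.pairs if bpp.prob(i, j) >= pair_prob)
    return good / len(reference.pairs) >= threshold


def stem_or_loop(trna: CloverleafAnnotation, local_position: int) -> str:
    """'stem' if the position is paired in the reference cloverleaf else 'loop'."""
    return "stem" if trna.is_paired(local_position) else "loop"


@dataclass(frozen=True)
class StructuralImpactResult:
    """Distance score of one tRNA variant with its local region and p-value."""

    trna_name: str
    local_position: int
    d: float
    region: tuple[int, int]
    p_value: float
    native_ok: bool
    location: str = ""  # stem / loop


# ---------------------------------------------------------------------------
# catalogue-level driver
# ---------------------------------------------------------------------------

def score_trna_variants(
    cat,
    features,
    cloverleafs: dict[str, CloverleafAnnotation],
    background: "BackgroundDistribution",
    window: int = 100,
    native_threshold: float = 0.7,
):
    """Structural-impact scores for every tRNA SNV in a catalogue.

    Returns a DataFrame with one row per tRNA substitution: gene, local
    position, stem/loop location, distance score ``d``, its local region,
    empirical p-value against ``background``, and whether the wild-type
    tRNA passes the native-fold check (rows failing it should be excluded
    from group comparisons).  Indels are skipped (no defined
    substitution-style comparison).
    """
    import pandas as pd

    comp = {"A": "U", "C": "G", "G": "C", "T": "A"}
    genome_length = features.genome_length
    wt_cache: dict[str, BasePairProbabilityMatrix] = {}
    rows = []
    for rec in cat:
        if rec.kind != "SNV":
            continue
        hits = [
            f for f in features.feature_at(rec.position)
            if f.feature_class == "tRNA"
        ]
        if not hits:
            continue
        f = hits[0]
        cl = cloverleafs[f.name]
        local = f.local_index(rec.position, genome_length) + 1
        sense_alt = rec.alt if f.strand == "L" else comp[rec.alt].replace("U", "T")
        if f.strand == "H":
            sense_alt = {"A": "T", "C": "G", "G": "C", "T": "A"}[rec.alt]
        wt_seq = cl.sequence
        mut_seq = wt_seq[: local - 1] + sense_alt + wt_seq[local:]
        if f.name not in wt_cache:
            wt_cache[f.name] = fold_bpp(wt_seq)
        wt_bpp = wt_cache[f.name]
        mut_bpp = fold_bpp(mut_seq)
        d, region = structural_distance(wt_bpp, mut_bpp, window)
        rows.append(
            {
                "sample_id": rec.sample_id,
                "position": rec.position,
                "ref": rec.ref,
                "alt": rec.alt,
                "trna": f.name,
                "local_position": local,
                "location": stem_or_loop(cl, local),
                "d": d,
                "region_start": region[0],
                "region_end": region[1],
                "p_value": empirical_p(d, background),
                "native_ok": native_fold_check(
                    wt_bpp, cl, threshold=native_threshold
                ),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group comparison (Wilcoxon rank-sum)
# ---------------------------------------------------------------------------

def _ranksum(pooled_ranks: np.ndarray, idx: tuple[int, ...]) -> float:
    return float(pooled_ranks[list(idx)].sum())


def compare_groups(x, y, exact_max: int = 10) -> TestResult:
    """Two-sided Wilcoxon rank-sum test with midrank ties.

    The null distribution is enumerated exactly over all assignments of the
    pooled observations to groups when both groups have at most
    ``exact_max`` observations; otherwise the tie-corrected normal
    approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    w_obs = float(ranks[:n1].sum())
    mu = n1 * (n1 + n2 + 1) / 2.0
    if n1 <= exact_max and n2 <= exact_max:
        dev = abs(w_obs - mu)
        count = 0
        total = 0
        for idx in combinations(range(n1 + n2), n1):
            total += 1
            if abs(_ranksum(ranks, idx) - mu) >= dev - 1e-12:
                count += 1
        p = count / total
        method = "wilcoxon-ranksum-exact"
    else:
        tie_counts = np.unique(pooled, return_counts=True)[1]
        n = n1 + n2
        var = n1 * n2 / 12.0 * (n + 1 - (tie_counts**3 - tie_counts).sum() / (n * (n - 1)))
        if var == 0:
            p = 1.0
        else:
            z = (w_obs - mu) / math.sqrt(var)
            p = 2 * stats.norm.sf(abs(z))
        method = "wilcoxon-ranksum-normal"
    return TestResult(statistic=w_obs, p_value=min(1.0, p), method=method, n=(n1, n2))
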