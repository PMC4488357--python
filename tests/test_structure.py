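"""RNA folding, distance scores, shuffles, empirical p-values, group tests."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest
from scipy import stats

from mitosoma.trna_structure import (
    MIN_HAIRPIN,
    PAIR_ENERGY,
    BackgroundDistribution,
    background_distribution,
    compare_groups,
    dinucleotide_shuffle,
    empirical_p,
    fold_bpp,
    native_fold_check,
    random_variant,
    stack_energy,
    stem_or_loop,
    structural_distance,
)

# ---------------------------------------------------------------------------
# exhaustive-enumeration oracle (independent of the DP implementation)
# ---------------------------------------------------------------------------

def enumerate_bpp(seq):
    """Boltzmann-weighted pairing probabilities over ALL legal structures."""
    seq = seq.upper().replace("T", "U")
    n = len(seq)
    cand = [
        (i, j)
        for i in range(n)
        for j in range(i + MIN_HAIRPIN + 1, n)
        if (seq[i], seq[j]) in PAIR_ENERGY
    ]

    structures = []

    def grow(chosen, remaining):
        structures.append(chosen)
        for k, (i, j) in enumerate(remaining):
            ok = True
            for a, b in chosen:
                if len({i, j, a, b}) < 4:
                    ok = False
                    break
                if (a < i < b) != (a < j < b):  # crossing
                    ok = False
                    break
            if ok:
                grow(chosen + [(i, j)], remaining[k + 1 :])

    grow([], cand)

    z = 0.0
    p = np.zeros((n, n))
    for st in structures:
        e = sum(PAIR_ENERGY[(seq[i], seq[j])] for i, j in st)
        pairs = set(st)
        for i, j in st:
            if (i + 1, j - 1) in pairs:
                e += stack_energy((seq[i], seq[j]), (seq[i + 1], seq[j - 1]))
        w = math.exp(-e)
        z += w
        for i, j in st:
            p[i, j] += w
    return p / z


ORACLE_SEQUENCES = [
    "GGGAAAACCC",
    "GCGCAAAAGCGC",
    "ACGUACGUACGU",
    "AUAUAUGCAAAU",
    "GGGGAAAACCCC",
    "CUGAUUGGCCAU",
    "UUUAAAGGGCC",
]


class TestFoldBpp:
    @pytest.mark.parametrize("seq", ORACLE_SEQUENCES)
    def test_matches_exhaustive_enumeration(self, seq):
        got = fold_bpp(seq).p
        want = enumerate_bpp(seq)
        assert np.allclose(got, want, atol=1e-12)

    def test_random_short_sequences_match_enumeration(self, rng):
        for _ in range(10):
            n = int(rng.integers(6, 13))
            seq = "".join(rng.choice(list("ACGU"), size=n))
            assert np.allclose(fold_bpp(seq).p, enumerate_bpp(seq), atol=1e-12)

    def test_strong_hairpin_pairs_dominate(self):
        bpp = fold_bpp("GGGAAAACCC")
        # the three G-C closing pairs carry the highest probabilities
        top = sorted(
            ((bpp.prob(i, j), (i, j)) for i in range(1, 11) for j in range(i + 1, 11)
             if bpp.prob(i, j) > 0),
            reverse=True,
        )[:3]
        assert {ij for _, ij in top} == {(1, 10), (2, 9), (3, 8)}

    def test_single_nucleotide_has_no_pairs(self):
        assert fold_bpp("A").p.sum() == 0.0

    def test_probability_constraints_on_trna_length(self, cloverleafs):
        bpp = fold_bpp(cloverleafs["TI"].sequence)
        assert (bpp.p >= 0).all() and (bpp.p <= 1).all()
        per_base = bpp.p.sum(axis=0) + bpp.p.sum(axis=1)
        assert (per_base <= 1 + 1e-9).all()

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            fold_bpp("ACGN")


class TestStructuralDistance:
    def test_identical_matrices_give_zero(self, cloverleafs):
        bpp = fold_bpp(cloverleafs["TF"].sequence)
        d, region = structural_distance(bpp, bpp)
        assert d == 0.0
        assert region == (1, bpp.n)

    def test_window_at_least_length_spans_whole_sequence(self):
        wt = fold_bpp("GGGAAAACCC")
        mut = fold_bpp("GGGAAAACCA")
        d, region = structural_distance(wt, mut, window=100)
        assert region == (1, 10)
        assert d > 0

    def test_direct_summation_oracle(self, rng):
        wt = fold_bpp("GCGCAAAAGCGC")
        mut = fold_bpp("GCGCAAAAGCGA")
        d, region = structural_distance(wt, mut, window=100)
        direct = math.sqrt(((wt.p - mut.p) ** 2).sum())
        assert d == pytest.approx(direct)

    def test_small_window_restricts_region(self):
        wt = fold_bpp("GGGAAAACCCAAAGGGAAAACCC")
        mut = fold_bpp("GGGAAAACCCAAAGGGAAAACCA")
        d, region = structural_distance(wt, mut, window=10)
        assert region[1] - region[0] + 1 <= 10
        assert d > 0

    def test_metric_properties_on_sampled_matrices(self, cloverleafs):
        seqs = [cloverleafs[n].sequence[:30] for n in ("TF", "TI", "TM")]
        mats = [fold_bpp(s) for s in seqs]
        d01 = structural_distance(mats[0], mats[1])[0]
        d10 = structural_distance(mats[1], mats[0])[0]
        d02 = structural_distance(mats[0], mats[2])[0]
        d12 = structural_distance(mats[1], mats[2])[0]
        assert d01 == pytest.approx(d10)  # symmetry
        assert d02 <= d01 + d12 + 1e-9  # triangle inequality

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            structural_distance(fold_bpp("GGGAAAACCC"), fold_bpp("GGGAAAACC"))


def dinuc_counts(s):
    return Counter(zip(s, s[1:]))


class TestDinucleotideShuffle:
    def test_counts_preserved_over_many_draws(self):
        rng = np.random.default_rng(99)
        seq = "ACGUACGGUACAGUAACCGUAC"
        want = dinuc_counts(seq)
        outputs = set()
        for _ in range(2000):
            sh = dinucleotide_shuffle(seq, rng)
            assert dinuc_counts(sh) == want
            assert sh[0] == seq[0] and sh[-1] == seq[-1]
            outputs.add(sh)
        assert len(outputs) > 10  # non-degenerate sampling

    def test_homopolymer_is_fixed_point(self, rng):
        assert dinucleotide_shuffle("AAAA", rng) == "AAAA"

    def test_seeded_determinism(self):
        seq = "GCAUGGCAUACGUAGCAUGC"
        a = dinucleotide_shuffle(seq, np.random.default_rng(5))
        b = dinucleotide_shuffle(seq, np.random.default_rng(5))
        assert a == b


class TestEmpiricalP:
    def test_zero_distance_gives_one(self):
        bg = BackgroundDistribution(np.linspace(0, 2, 99), 1, 100)
        assert empirical_p(0.0, bg) == 1.0

    def test_exceeding_size_999_background(self):
        bg = np.linspace(0.1, 1.0, 999)
        assert empirical_p(2.0, bg) == pytest.approx(1 / 1000)

    def test_median_score_gives_about_half(self):
        bg = np.linspace(0, 1, 1001)
        assert empirical_p(0.5, bg) == pytest.approx(0.5, abs=0.01)

    def test_antitone_in_distance(self):
        bg = np.sort(np.random.default_rng(3).uniform(size=500))
        ps = [empirical_p(d, bg) for d in (0.1, 0.4, 0.8)]
        assert ps[0] >= ps[1] >= ps[2]

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            empirical_p(0.5, np.array([]))


class TestNativeFoldCheck:
    def test_perfect_reference_support_passes(self, cloverleafs):
        cl = cloverleafs["TF"]
        p = np.zeros((len(cl), len(cl)))
        for i, j in cl.pairs:
            p[i - 1, j - 1] = 1.0
        from mitosoma.trna_structure import BasePairProbabilityMatrix

        bpp = BasePairProbabilityMatrix(cl.sequence.replace("T", "U"), p)
        assert native_fold_check(bpp, cl)

    def test_all_zero_matrix_fails(self, cloverleafs):
        cl = cloverleafs["TF"]
        from mitosoma.trna_structure import BasePairProbabilityMatrix

        bpp = BasePairProbabilityMatrix(
            cl.sequence.replace("T", "U"), np.zeros((len(cl), len(cl)))
        )
        assert not native_fold_check(bpp, cl)

    def test_designed_fixtures_fold_natively(self, cloverleafs):
        for name, cl in cloverleafs.items():
            assert native_fold_check(fold_bpp(cl.sequence), cl), name

    def test_length_mismatch_rejected(self, cloverleafs):
        with pytest.raises(ValueError):
            native_fold_check(fold_bpp("GGGAAAACCC"), cloverleafs["TF"])


class TestStemOrLoop:
    def test_acceptor_stem_position_is_stem(self, cloverleafs):
        cl = cloverleafs["TI"]
        assert stem_or_loop(cl, 1) == "stem"  # first acceptor-stem base

    def test_anticodon_loop_position_is_loop(self, cloverleafs):
        cl = cloverleafs["TI"]
        loop_pos = next(
            i for i in range(1, len(cl) + 1)
            if not cl.is_paired(i) and cl.domain_label(i) == "loop"
        )
        assert stem_or_loop(cl, loop_pos) == "loop"

    def test_out_of_range_rejected(self, cloverleafs):
        with pytest.raises(ValueError):
            stem_or_loop(cloverleafs["TI"], 0)


def wilcoxon_oracle(x, y):
    """Exact two-sided rank-sum p by enumerating group assignments, with an
    independent midrank computation."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def midranks(values):
        order = sorted(range(len(values)), key=lambda i: values[i])
        ranks = [0.0] * len(values)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
                j += 1
            r = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    ranks = midranks(pooled)
    w_obs = sum(ranks[:n1])
    mu = n1 * (len(pooled) + 1) / 2
    dev = abs(w_obs - mu)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(sum(ranks[i] for i in idx) - mu) >= dev - 1e-12:
            hits += 1
    return hits / total


class TestCompareGroups:
    def test_identical_groups_give_one(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_three_vs_three_matches_enumeration(self, rng):
        x = list(rng.uniform(size=3))
        y = list(rng.uniform(size=3) + 0.5)
        res = compare_groups(x, y)
        assert res.method == "wilcoxon-ranksum-exact"
        assert res.p_value == pytest.approx(wilcoxon_oracle(x, y))

    def test_ties_handled_exactly(self):
        x, y = [1.0, 2.0, 2.0], [2.0, 3.0, 4.0]
        res = compare_groups(x, y)
        assert res.p_value == pytest.approx(wilcoxon_oracle(x, y))

    def test_matches_scipy_exact_on_tie_free_data(self, rng):
        x = list(rng.uniform(size=6))
        y = list(rng.uniform(size=7) + 0.2)
        ours = compare_groups(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue)

    def test_large_samples_use_normal_approximation(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.8, 1, 30)
        res = compare_groups(x, y)
        assert res.method == "wilcoxon-ranksum-normal"
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.p_value == pytest.approx(ref.pvalue, rel=0.05)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0])


class TestBackgroundDistribution:
    def test_size_and_nonnegativity(self, cloverleafs, rng):
        seqs = [cloverleafs[n].sequence for n in ("TF", "TI")]
        bg = background_distribution(seqs, 4, rng)
        assert len(bg) == 8
        assert (bg.scores >= 0).all()

    def test_serialisation_round_trip(self, cloverleafs, rng, tmp_path):
        bg = background_distribution([cloverleafs["TF"].sequence], 3, rng)
        path = tmp_path / "bg.tsv"
        bg.to_tsv(path)
        back = BackgroundDistribution.from_tsv(path)
        assert np.allclose(back.scores, bg.scores, atol=1e-6)
        assert back.n_per_seq == bg.n_per_seq

    def test_invalid_n_rejected(self, cloverleafs, rng):
        with pytest.raises(ValueError):
            background_distribution([cloverleafs["TF"].sequence], 0, rng)

    def test_random_variant_is_a_single_substitution(self, rng):
        seq = "GCAUGGCAUACGUAGCAUGC"
        mut, pos, alt = random_variant(seq, rng)
        assert len(mut) == len(seq)
        diffs = [i for i, (a, b) in enumerate(zip(seq, mut)) if a != b]
        assert diffs == [pos - 1]
        assert mut[pos - 1] == alt
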