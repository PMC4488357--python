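"""Heteroplasmy summaries, KS/chi-square tests and the coding-SNV null."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from mitosoma.annotation import Annotator, strand_class_of
from mitosoma.catalogue import Catalogue, MutationRecord
from mitosoma.reference import FeatureTable, GeneFeature, MitoGenome
from mitosoma.selection import (
    chi2_yates,
    expected_nonsyn_fraction,
    heteroplasmy_summary,
    ks_two_sample,
)


def cat_of(vafs):
    return Catalogue(
        [
            MutationRecord(f"T{i}", "X", 100 + i, "C", "T", v)
            for i, v in enumerate(vafs)
        ]
    )


class TestHeteroplasmySummary:
    def test_single_record(self):
        s = heteroplasmy_summary(cat_of([0.4]))
        assert s.mean_vaf == s.max_vaf == 0.4
        assert s.n == 1

    def test_fraction_above_threshold(self):
        s = heteroplasmy_summary(cat_of([0.2, 0.96, 0.99, 0.5]))
        assert s.frac_above(0.95) == pytest.approx(0.5)
        assert s.max_vaf == 0.99

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            heteroplasmy_summary(cat_of([0.4]), selector=lambda r: False)


def exact_ks_p_by_enumeration(x, y):
    """Brute-force permutation null of the two-sample KS statistic."""
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def ks_stat(a, b):
        grid = np.sort(pooled)
        fa = np.searchsorted(np.sort(a), grid, side="right") / len(a)
        fb = np.searchsorted(np.sort(b), grid, side="right") / len(b)
        return np.max(np.abs(fa - fb))

    observed = ks_stat(x, y)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        mask = np.zeros(len(pooled), bool)
        mask[list(idx)] = True
        total += 1
        if ks_stat(pooled[mask], pooled[~mask]) >= observed - 1e-12:
            count += 1
    return count / total


class TestKolmogorovSmirnov:
    def test_identical_samples(self):
        res = ks_two_sample([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_disjoint_supports(self):
        res = ks_two_sample([0.1, 0.2], [0.8, 0.9])
        assert res.statistic == pytest.approx(1.0)

    def test_small_sample_p_matches_enumeration(self, rng):
        x = rng.uniform(size=3)
        y = rng.uniform(size=3) + 0.3
        res = ks_two_sample(x, y)
        assert res.p_value == pytest.approx(exact_ks_p_by_enumeration(x, y))

    def test_symmetry(self, rng):
        x, y = rng.uniform(size=8), rng.uniform(size=5)
        a, b = ks_two_sample(x, y), ks_two_sample(y, x)
        assert a.statistic == b.statistic
        assert a.p_value == b.p_value

    def test_shift_monotonically_decreases_p(self, rng):
        x = rng.uniform(size=40)
        base = rng.uniform(size=40)
        ps = [ks_two_sample(x, base + shift).p_value for shift in (0.0, 0.2, 0.4)]
        assert ps[0] > ps[1] > ps[2]

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [0.5])


class TestChiSquareYates:
    def test_exact_expectation_gives_zero(self):
        res = chi2_yates((50, 50), 0.5)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # E = 50/50; corrected: 2 * (10 - 0.5)^2 / 50 = 3.61
        res = chi2_yates((60, 40), 0.5)
        assert res.statistic == pytest.approx(3.61)
        assert res.p_value == pytest.approx(stats.chi2.sf(3.61, 1))

    def test_degenerate_expected_fraction_rejected(self):
        for bad in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                chi2_yates((10, 10), bad)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            chi2_yates((-1, 10), 0.5)


def toy_reference(gene_seq: str):
    """Circular toy genome with one plus-strand protein gene at position 11."""
    pad5, pad3 = "ACGTACGTAC", "GTACGTACGT"
    genome = MitoGenome(pad5 + gene_seq + pad3)
    features = FeatureTable(
        [GeneFeature("G1", 11, 10 + len(gene_seq), "L", "protein")],
        genome.length,
    )
    return genome, features


def brute_force_expected_nonsyn(annotator, spectrum):
    """Independent oracle: group every possible coding SNV by class, average
    nonsynonymous indicator within class, combine with spectrum weights."""
    per_class: dict = {}
    for pos in annotator.coding_positions():
        ref = annotator.genome.base(pos)
        for alt in "ACGT":
            if alt == ref:
                continue
            eff = annotator.snv_effect(pos, ref, alt)
            if eff is None:
                continue
            per_class.setdefault(strand_class_of(ref, alt), []).append(
                eff in ("missense", "nonsense")
            )
    num = den = 0.0
    for key, w in spectrum.items():
        if key in per_class and w > 0:
            num += w * np.mean(per_class[key])
            den += w
    return num / den


UNIFORM = {(c, s): 1 / 12 for c in ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
           for s in ("L", "H")}


class TestExpectedNonsynFraction:
    def test_toy_gene_matches_enumeration_oracle(self):
        genome, features = toy_reference("ATGCTACGATAA")  # 4 codons
        ann = Annotator(genome, features)
        got = expected_nonsyn_fraction(ann, UNIFORM)
        assert got == pytest.approx(brute_force_expected_nonsyn(ann, UNIFORM))

    def test_single_codon_gene_hand_value(self):
        # TGG (Trp): the only synonymous change is G>A at the wobble position
        # (TGA is also Trp in the mitochondrial code).  Six classes have
        # sites; (C>T, H) is half synonymous, so the expectation is
        # 1 - (1/2)/6 = 11/12.
        genome, features = toy_reference("TGG")
        ann = Annotator(genome, features)
        assert expected_nonsyn_fraction(ann, UNIFORM) == pytest.approx(11 / 12)

    def test_mass_on_class_without_synonymous_sites(self):
        # CAA: Gln; restrict mass to a class whose only possible changes in
        # this gene are nonsynonymous
        genome, features = toy_reference("CAA")
        ann = Annotator(genome, features)
        spectrum = {("C>G", "L"): 1.0}  # C1->G = Glu (missense), only C site
        assert expected_nonsyn_fraction(ann, spectrum) == pytest.approx(1.0)

    def test_packaged_genome_matches_oracle(self, annotator):
        spectrum = dict(UNIFORM)
        spectrum[("C>T", "H")] = 0.4  # unnormalised weights are fine
        got = expected_nonsyn_fraction(annotator, spectrum)
        want = brute_force_expected_nonsyn(annotator, spectrum)
        assert got == pytest.approx(want)

    def test_zero_spectrum_rejected(self, annotator):
        with pytest.raises(ValueError):
            expected_nonsyn_fraction(annotator, {("C>T", "L"): 0.0})
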