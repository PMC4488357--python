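"""Synthetic catalogue and coverage generators: determinism and recovery."""

import numpy as np
import pytest

from mitosoma import base_composition, filter_rna_confirmed
from mitosoma.annotation import Annotator, strand_class
from mitosoma.imbalance import coverage_fold_change, detect_imbalanced
from mitosoma.signature import enrichment, expected_fractions, strand_spectrum
from mitosoma.simulate import (
    HeteroplasmyModel,
    SimulationConfig,
    default_class_probabilities,
    simulate_catalogue,
    simulate_coverage,
    study_catalogue,
)


class TestHeteroplasmyModel:
    def test_truncated_mean_is_calibrated(self, rng):
        model = HeteroplasmyModel(mean=0.396, hi=0.85)
        draws = np.array([model.sample(rng) for _ in range(4000)])
        assert draws.max() <= 0.85
        assert draws.min() >= 0.15
        assert draws.mean() == pytest.approx(0.396, abs=0.01)

    def test_tail_solver_hits_target(self, rng):
        model = HeteroplasmyModel.with_tail(mean=0.58, tail_above_095=0.0837)
        draws = np.array([model.sample(rng) for _ in range(20000)])
        assert draws.mean() == pytest.approx(0.58, abs=0.01)
        assert (draws > 0.95).mean() == pytest.approx(0.0837, abs=0.01)

    def test_unattainable_mean_rejected(self):
        with pytest.raises(ValueError):
            HeteroplasmyModel(mean=0.05)


class TestGenerativeCatalogue:
    def test_seeded_determinism(self, genome, features):
        cfg = SimulationConfig(seed=7, tumors_per_type={"SIM": 60})
        a, _ = simulate_catalogue(cfg, genome, features)
        b, _ = simulate_catalogue(cfg, genome, features)
        assert a == b

    def test_poisson_total_within_three_sigma(self, genome, features):
        n_tumors = 1000
        cfg = SimulationConfig(
            seed=5, tumors_per_type={"SIM": n_tumors}, n_imbalanced=0,
            n_imbalanced_trna=0,
        )
        cat, _ = simulate_catalogue(cfg, genome, features)
        lam = n_tumors * cfg.mutation_rate
        assert abs(len(cat) - lam) <= 3 * np.sqrt(lam)

    def test_injected_imbalance_recovered_exactly(self, genome, features):
        cfg = SimulationConfig(seed=13, tumors_per_type={"SIM": 300})
        cat, truth = simulate_catalogue(cfg, genome, features)
        detected = {
            (r.sample_id, r.position, r.ref, r.alt)
            for r in detect_imbalanced(cat, threshold=0.3)
        }
        injected = {
            (t.sample_id, t.position, t.ref, t.alt)
            for t in truth[truth.injected_imbalance].itertuples()
        }
        assert detected == injected
        assert len(injected) == cfg.n_imbalanced

    def test_frameshift_vafs_truncated_at_085(self, genome, features):
        ann = Annotator(genome, features)
        cfg = SimulationConfig(seed=3, tumors_per_type={"SIM": 800})
        cat, _ = simulate_catalogue(cfg, genome, features)
        fs_vafs = [
            r.vaf_dna
            for r in cat
            if r.is_indel
            and ann.classify_region(r)[0] == "coding"
            and ann.coding_effect(r.normalized()) == "frameshift"
        ]
        assert fs_vafs and max(fs_vafs) <= 0.85

    def test_class_enrichment_recovers_configuration(self, genome, features):
        # ~5,000 SNVs; pipeline-estimated enrichment within 10% of the
        # ratio implied by the configured class probabilities
        cfg = SimulationConfig(
            seed=23, tumors_per_type={"SIM": 4700}, indel_fraction=0.0,
            n_imbalanced=0, n_imbalanced_trna=0,
        )
        cat, _ = simulate_catalogue(cfg, genome, features)
        comp = base_composition(genome)
        exp = expected_fractions(comp)
        df = enrichment(strand_spectrum(cat), exp)
        probs = default_class_probabilities(comp)
        for cls, strand in (("C>T", "H"), ("T>C", "H"), ("C>T", "L")):
            implied = probs[(cls, strand)] / exp[(cls, strand)]
            got = float(
                df[(df.sub_class == cls) & (df.strand == strand)].ratio.iloc[0]
            )
            assert got == pytest.approx(implied, rel=0.10), (cls, strand)

    def test_heteroplasmy_mean_recovered(self, genome, features):
        cfg = SimulationConfig(
            seed=29, tumors_per_type={"SIM": 600}, indel_fraction=0.0,
            n_imbalanced=0, n_imbalanced_trna=0, dloop_multiplier=1.0,
        )
        cat, truth = simulate_catalogue(cfg, genome, features)
        default_vafs = [
            r.vaf_dna
            for r, c in zip(cat, truth.category)
            if c == "default"
        ]
        assert len(default_vafs) >= 500
        assert np.mean(default_vafs) == pytest.approx(0.58, abs=0.02)


class TestStudyCatalogue:
    def test_seeded_determinism(self, genome, features):
        a, _ = study_catalogue(4, genome, features)
        b, _ = study_catalogue(4, genome, features)
        assert a == b

    def test_fixed_marginals(self, study, confirmed):
        cat, truth = study
        assert len(cat) == 644
        assert len(confirmed) == 616
        assert len(confirmed.snvs()) == 564
        assert len(confirmed.indels()) == 52

    def test_truth_table_flags_fifteen_injected(self, study):
        _, truth = study
        inj = truth[truth.injected_imbalance]
        assert len(inj) == 15
        assert (inj.category == "trna_imbalanced").sum() == 12

    def test_hotspot_runs_are_recurrently_mutated(self, study, annotator):
        cat, _ = study
        hot = [r for r in cat if r.is_indel and 10947 <= r.position <= 10952]
        assert len(hot) >= 2


class TestCoverageSimulation:
    def test_fold_one_case_within_noise_of_controls(self, features):
        cfg = SimulationConfig(seed=2)
        case, controls = simulate_coverage(cfg, features, "TI", fold=1.0)
        fc = coverage_fold_change(case, controls)
        assert np.median(fc) == pytest.approx(1.0, abs=0.15)

    def test_hundredfold_accumulation_recovered(self, features):
        cfg = SimulationConfig(seed=2)
        case, controls = simulate_coverage(cfg, features, "TI", fold=100.0)
        fc = coverage_fold_change(case, controls)
        f = features.get("TI")
        pos = np.arange(case.start, case.start + len(case.depths))
        inside = (pos >= f.start) & (pos <= f.end)
        assert np.median(fc[inside]) == pytest.approx(100.0, rel=0.15)
        assert np.median(fc[~inside]) == pytest.approx(1.0, abs=0.15)

    def test_seeded_determinism(self, features):
        cfg = SimulationConfig(seed=9)
        a, _ = simulate_coverage(cfg, features, "TM", fold=5.0)
        b, _ = simulate_coverage(cfg, features, "TM", fold=5.0)
        assert np.array_equal(a.depths, b.depths)

    def test_unknown_gene_rejected(self, features):
        with pytest.raises(ValueError, match="unknown gene"):
            simulate_coverage(SimulationConfig(seed=1), features, "NOPE", 2.0)

    def test_fold_below_one_rejected(self, features):
        with pytest.raises(ValueError):
            simulate_coverage(SimulationConfig(seed=1), features, "TI", 0.5)
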