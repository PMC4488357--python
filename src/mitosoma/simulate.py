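"""Synthetic somatic mtDNA mutation catalogues and coverage profiles.

Two generators are provided.

:func:`simulate_catalogue` draws a catalogue from a fully generative model:
per-tumor Poisson mutation counts, a strand-biased substitution spectrum
(class-first sampling, so the realised spectrum matches the configured
class probabilities), elevated positional density in the D-loop, indels as
single-base slips in mononucleotide runs, effect-conditional heteroplasmy
(Beta mixtures, suppressed and truncated for frameshifts), RNA allele
frequencies equal to DNA plus clipped Gaussian noise, and an injected set
of tRNA processing-defect mutations with a strong RNA excess.

:func:`study_catalogue` instead reproduces the fixed marginals of the
tumor study the model emulates — per-cancer tumor/mutation/indel counts,
the RNA-confirmation split (644 sequenced, 616 confirmed), the coding
effect split, the tRNA imbalance structure — with everything the study
does not pin down (positions, alleles, allele frequencies, assignments)
drawn from the same generative model.  It is the package's stand-in for
the study's deposited mutation table.

All default parameter values are the study conditions (means 58.1%/39.6%/
48.8%/65.8% heteroplasmy, 8.0% near-homoplasmy, frameshift ceiling 0.85,
(C>T, H) enrichment 10.6, 65% of SNVs at G:C pairs, imbalance threshold
margin, Table-style tumor counts); see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import Annotator
from .catalogue import Catalogue, MutationRecord
from .imbalance import CoverageProfile
from .reference import FeatureTable, MitoGenome, base_composition

__all__ = [
    "HeteroplasmyModel",
    "SimulationConfig",
    "default_class_probabilities",
    "simulate_catalogue",
    "study_catalogue",
    "simulate_coverage",
    "TUMORS_PER_TYPE",
    "STUDY_MUTATIONS_PER_TYPE",
    "STUDY_INDELS_PER_TYPE",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# Per-cancer-type study marginals (tumors analysed; confirmed mutations;
# confirmed indels).  These are fixed conditions of the emulated study.
TUMORS_PER_TYPE = {
    "BLCA": 23, "BRCA": 100, "CRC": 42, "GBM": 37, "HNSC": 29, "KICH": 15,
    "KIRC": 29, "LGG": 18, "LUAD": 46, "LUSC": 45, "PRAD": 19, "SKCM": 42,
    "THCA": 35, "UCEC": 47,
}
STUDY_MUTATIONS_PER_TYPE = {
    "BLCA": 43, "BRCA": 123, "CRC": 52, "GBM": 8, "HNSC": 29, "KICH": 17,
    "KIRC": 29, "LGG": 8, "LUAD": 65, "LUSC": 54, "PRAD": 6, "SKCM": 62,
    "THCA": 36, "UCEC": 84,
}
STUDY_INDELS_PER_TYPE = {
    "BLCA": 3, "BRCA": 9, "CRC": 4, "GBM": 0, "HNSC": 4, "KICH": 3,
    "KIRC": 6, "LGG": 1, "LUAD": 2, "LUSC": 3, "PRAD": 1, "SKCM": 5,
    "THCA": 4, "UCEC": 7,
}

STUDY_TOTAL_CONFIRMED = 616
STUDY_TOTAL_SEQUENCED = 644
STUDY_MUTATED_TUMORS = 335

# calibrated effect-category counts of the confirmed study set
STUDY_CATEGORY_COUNTS = {
    "missense": 251,
    "synonymous": 69,
    "nonsense": 16,
    "frameshift": 27,
    "trna_imbalanced": 12,
    "trna_stem": 23,
    "trna_loop": 10,
    "rrna_snv": 78,
    "rrna_indel": 10,
    "dloop_snv": 105,
    "dloop_indel": 15,
    "other_imbalanced": 3,
}


@dataclass(frozen=True)
class HeteroplasmyModel:
    """Effect-conditional DNA-VAF distribution.

    A mixture of a Beta component (concentration ``alpha + beta`` fixed,
    truncated to [lo, hi]) and, with probability ``near_homoplasmy``, a
    near-homoplasmic uniform on (0.951, 1).  ``mean`` is the target mean
    of the whole mixture; the Beta component's raw mean is solved
    numerically so truncation does not bias it.
    """

    mean: float
    concentration: float = 4.0
    lo: float = 0.15
    hi: float = 1.0
    near_homoplasmy: float = 0.0
    _raw_mean: float = field(init=False, default=0.0)

    def __post_init__(self):
        q = self.near_homoplasmy
        target_beta_mean = (self.mean - q * 0.9755) / (1.0 - q)
        if not (self.lo < target_beta_mean < self.hi):
            raise ValueError("unattainable mixture mean")
        from scipy.optimize import brentq

        def trunc_mean(m):
            a, b = m * self.concentration, (1 - m) * self.concentration
            num = stats.beta.cdf(self.hi, a + 1, b) - stats.beta.cdf(self.lo, a + 1, b)
            den = stats.beta.cdf(self.hi, a, b) - stats.beta.cdf(self.lo, a, b)
            return m * num / den

        raw = brentq(
            lambda m: trunc_mean(m) - target_beta_mean, 0.02, 0.98, xtol=1e-10
        )
        object.__setattr__(self, "_raw_mean", raw)

    def sample(self, rng: np.random.Generator, max_vaf: float | None = None) -> float:
        hi = self.hi if max_vaf is None else min(self.hi, max_vaf)
        if rng.random() < self.near_homoplasmy and hi > 0.951:
            return float(rng.uniform(0.951, min(1.0, hi)))
        a = self._raw_mean * self.concentration
        b = (1 - self._raw_mean) * self.concentration
        for _ in range(10000):
            x = float(rng.beta(a, b))
            if self.lo <= x <= hi:
                return x
        raise RuntimeError("truncated Beta sampling failed")

    def beta_tail_above(self, threshold: float) -> float:
        """P(X > threshold) of the truncated Beta component alone."""
        a = self._raw_mean * self.concentration
        b = (1 - self._raw_mean) * self.concentration
        num = stats.beta.cdf(self.hi, a, b) - stats.beta.cdf(threshold, a, b)
        den = stats.beta.cdf(self.hi, a, b) - stats.beta.cdf(self.lo, a, b)
        return max(num, 0.0) / den

    @classmethod
    def with_tail(
        cls, mean: float, tail_above_095: float, **kwargs
    ) -> "HeteroplasmyModel":
        """Model with P(VAF > 0.95) fixed, solving the mixture weight.

        Fixed-point iteration on the near-homoplasmy weight q:
        q + (1 - q) * beta_tail(q) = tail_above_095 (the Beta component's
        own mass above 0.95 depends on q through the mean adjustment).
        """
        q = tail_above_095
        model = cls(mean=mean, near_homoplasmy=q, **kwargs)
        for _ in range(40):
            t_b = model.beta_tail_above(0.95)
            q_new = (tail_above_095 - t_b) / (1.0 - t_b)
            if not (0.0 <= q_new < 1.0):
                raise ValueError("unattainable tail target")
            if abs(q_new - q) < 1e-10:
                break
            q = q_new
            model = cls(mean=mean, near_homoplasmy=q, **kwargs)
        return model


def default_heteroplasmy_models() -> dict[str, HeteroplasmyModel]:
    """Study-condition VAF models per effect category.

    Non-frameshift classes have P(VAF > 0.95) solved to 0.0837, which makes
    the catalogue-wide near-homoplasmy fraction 8.0% once ~4% of mutations
    are frameshifts (whose VAFs never exceed 0.85).
    """
    tail = 0.0837
    return {
        "default": HeteroplasmyModel.with_tail(mean=0.58, tail_above_095=tail),
        "frameshift": HeteroplasmyModel(mean=0.396, hi=0.85),
        "nonsense": HeteroplasmyModel.with_tail(mean=0.488, tail_above_095=tail),
        "dloop": HeteroplasmyModel.with_tail(mean=0.658, tail_above_095=tail),
    }


def default_class_probabilities(composition: dict[str, float]) -> dict:
    """Strand-resolved substitution-class probabilities (study conditions).

    (C>T, H) is set to 10.6 times its composition expectation; classes at
    G:C reference pairs total 0.65; the heavy-strand T>C excess and minor
    transversion classes fill the remainder.
    """
    cth = 10.6 * composition["G"] / 3.0
    gc_rest = 0.65 - cth
    tv = (gc_rest - 0.10) / 4.0
    probs = {
        ("C>T", "H"): cth,
        ("C>T", "L"): 0.10,
        ("C>A", "L"): tv,
        ("C>A", "H"): tv,
        ("C>G", "L"): tv,
        ("C>G", "H"): tv,
        ("T>C", "H"): 0.22,
        ("T>C", "L"): 0.06,
        ("T>A", "L"): 0.02,
        ("T>A", "H"): 0.02,
        ("T>G", "L"): 0.015,
        ("T>G", "H"): 0.015,
    }
    assert abs(sum(probs.values()) - 1.0) < 1e-9
    return probs


@dataclass
class SimulationConfig:
    """All generative parameters of the synthetic catalogue."""

    seed: int
    tumors_per_type: dict = field(default_factory=lambda: dict(TUMORS_PER_TYPE))
    mutation_rate: float = 1.17  # mean mutations per tumor
    indel_fraction: float = 0.084
    class_probabilities: dict | None = None  # default derived from composition
    dloop_multiplier: float = 3.3  # positional density ratio, D-loop vs rest
    heteroplasmy: dict = field(default_factory=default_heteroplasmy_models)
    rna_noise_sd: float = 0.05
    rna_noise_max: float = 0.25  # Gaussian noise clipped here (resampled)
    n_imbalanced: int = 15  # injected processing-defect mutations
    n_imbalanced_trna: int = 12  # of which in tRNA genes
    imbalance_shift: tuple = (0.35, 0.55)  # RNA-excess shift, uniform
    imbalance_max_dna_vaf: float = 0.55  # injected DNA VAFs kept below this

    def validate(self) -> None:
        if self.mutation_rate < 0 or not (0 <= self.indel_fraction <= 1):
            raise ValueError("invalid rate parameters")
        if self.n_imbalanced_trna > self.n_imbalanced:
            raise ValueError("n_imbalanced_trna exceeds n_imbalanced")
        if self.class_probabilities is not None:
            s = sum(self.class_probabilities.values())
            if abs(s - 1.0) > 1e-6:
                raise ValueError("class probabilities must sum to 1")


# ---------------------------------------------------------------------------
# shared sampling machinery
# ---------------------------------------------------------------------------

class _Sampler:
    """Cached position/allele sampling over one genome + annotation."""

    def __init__(self, genome: MitoGenome, features: FeatureTable,
                 cfg: SimulationConfig):
        self.genome = genome
        self.features = features
        self.cfg = cfg
        self.annotator = Annotator(genome, features)
        comp = base_composition(genome)
        self.class_probs = cfg.class_probabilities or default_class_probabilities(comp)
        self.class_keys = list(self.class_probs)
        self.class_p = np.array([self.class_probs[k] for k in self.class_keys])
        self.class_p = self.class_p / self.class_p.sum()

        dloop_pos = set()
        for f in features.by_class("D-loop"):
            dloop_pos.update(f.positions(genome.length))
        # per-source-base position arrays and D-loop density weights
        self.positions_by_base: dict[str, np.ndarray] = {}
        self.weights_by_base: dict[str, np.ndarray] = {}
        for b in "ACGT":
            pos = np.array(
                [p for p in range(1, genome.length + 1) if genome.base(p) == b]
            )
            w = np.where(
                np.isin(pos, list(dloop_pos)), cfg.dloop_multiplier, 1.0
            )
            self.positions_by_base[b] = pos
            self.weights_by_base[b] = w / w.sum()
        # mononucleotide runs (base, start, length >= 4) for indel placement
        self.runs = []
        seq = genome.sequence
        i = 0
        while i < len(seq):
            j = i
            while j < len(seq) and seq[j] == seq[i]:
                j += 1
            if j - i >= 4:
                self.runs.append((seq[i], i + 1, j - i))
            i = j

    def sample_snv(self, rng) -> tuple[int, str, str]:
        cls, strand = self.class_keys[rng.choice(len(self.class_keys), p=self.class_p)]
        pyr_ref, pyr_alt = cls[0], cls[2]
        if strand == "L":
            ref, alt = pyr_ref, pyr_alt
        else:
            ref, alt = _COMPLEMENT[pyr_ref], _COMPLEMENT[pyr_alt]
        pos_arr = self.positions_by_base[ref]
        pos = int(pos_arr[rng.choice(len(pos_arr), p=self.weights_by_base[ref])])
        return pos, ref, alt

    def sample_indel(self, rng, runs=None) -> tuple[int, str, str]:
        runs = runs if runs is not None else self.runs
        base, start, length = runs[rng.integers(len(runs))]
        if rng.random() < 0.5:  # single-base insertion, left-aligned
            return start, base, base + base
        return start, base + base, base

    def vaf_label(self, pos: int, ref: str, alt: str) -> str:
        region, _ = self.annotator.classify_region(
            MutationRecord("x", "x", pos, ref, alt, 0.5)
        )
        if region == "D-loop":
            return "dloop"
        if region == "coding":
            if len(ref) != len(alt):
                delta = abs(len(ref) - len(alt))
                return "frameshift" if delta % 3 else "default"
            eff = self.annotator.snv_effect(pos, ref, alt)
            return "nonsense" if eff == "nonsense" else "default"
        return "default"

    def sample_vaf(self, label: str, rng, max_vaf=None) -> float:
        model = self.cfg.heteroplasmy.get(label) or self.cfg.heteroplasmy["default"]
        return model.sample(rng, max_vaf=max_vaf)

    def rna_noise(self, rng) -> float:
        while True:
            e = rng.normal(0.0, self.cfg.rna_noise_sd)
            if abs(e) <= self.cfg.rna_noise_max:
                return float(e)


def _clip01(x: float) -> float:
    return min(1.0, max(0.0, x))


# ---------------------------------------------------------------------------
# fully generative catalogue
# ---------------------------------------------------------------------------

def simulate_catalogue(
    cfg: SimulationConfig,
    genome: MitoGenome,
    features: FeatureTable,
    rng: np.random.Generator | None = None,
) -> tuple[Catalogue, pd.DataFrame]:
    """Draw a catalogue from the generative model; returns (catalogue, truth).

    The truth table holds one row per record with the generative category
    and an ``injected_imbalance`` flag for evaluating recovery.
    """
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.seed)
    sampler = _Sampler(genome, features, cfg)
    trna_features = features.by_class("tRNA")

    records: list[MutationRecord] = []
    truth_rows = []
    seen = set()

    def add(sample_id, cancer, pos, ref, alt, vaf, rna, label, injected=False):
        key = (sample_id, pos, ref, alt)
        if key in seen:
            return False
        seen.add(key)
        records.append(
            MutationRecord(sample_id, cancer, pos, ref, alt, vaf,
                           0.0, rna, rna is not None and rna >= 0.02)
        )
        truth_rows.append(
            {"sample_id": sample_id, "position": pos, "ref": ref, "alt": alt,
             "category": label, "injected_imbalance": injected}
        )
        return True

    tumor_ids = []
    for cancer, n_tumors in cfg.tumors_per_type.items():
        for i in range(n_tumors):
            tumor_ids.append((f"{cancer}-T{i:03d}", cancer))

    for sample_id, cancer in tumor_ids:
        n_mut = rng.poisson(cfg.mutation_rate)
        for _ in range(n_mut):
            for _attempt in range(100):
                if rng.random() < cfg.indel_fraction:
                    pos, ref, alt = sampler.sample_indel(rng)
                else:
                    pos, ref, alt = sampler.sample_snv(rng)
                label = sampler.vaf_label(pos, ref, alt)
                vaf = sampler.sample_vaf(label, rng)
                rna = _clip01(vaf + sampler.rna_noise(rng))
                if add(sample_id, cancer, pos, ref, alt, vaf, rna, label):
                    break

    # injected processing-defect mutations (RNA excess)
    lo, hi = cfg.imbalance_shift
    for k in range(cfg.n_imbalanced):
        in_trna = k < cfg.n_imbalanced_trna
        for _attempt in range(1000):
            sample_id, cancer = tumor_ids[rng.integers(len(tumor_ids))]
            if in_trna:
                f = trna_features[rng.integers(len(trna_features))]
                local = int(rng.integers(f.length(genome.length)))
                pos = f.genome_position(local, genome.length)
                ref = genome.base(pos)
                alt = rng.choice([b for b in "ACGT" if b != ref])
            else:
                pos, ref, alt = sampler.sample_snv(rng)
                if any(f.feature_class == "tRNA"
                       for f in sampler.annotator.features_at(pos)):
                    continue
            label = sampler.vaf_label(pos, ref, alt)
            vaf = sampler.sample_vaf(label, rng, max_vaf=cfg.imbalance_max_dna_vaf)
            rna = _clip01(vaf + rng.uniform(lo, hi))
            if add(sample_id, cancer, pos, ref, alt, vaf, rna,
                   "trna_injected" if in_trna else "other_injected", True):
                break

    truth = pd.DataFrame(truth_rows)
    return Catalogue(records, provenance=f"simulated(seed={cfg.seed})"), truth


# ---------------------------------------------------------------------------
# calibrated study catalogue
# ---------------------------------------------------------------------------

_DISRUPTIVE_ALT = {"G": "A", "C": "A", "A": "C", "T": "G"}  # break the WC pair
_MILD_STEM_ALT = {"C": "T", "A": "G"}  # create a GU wobble with the partner
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _allocate_mutated_tumors(rng) -> dict[str, int]:
    """Per-type counts of mutated tumors totalling the study's 335.

    Drafted from the Poisson expectation n(1 - exp(-rate)) per type and
    scaled by largest remainder to the fixed total.
    """
    expect = {
        t: TUMORS_PER_TYPE[t]
        * (1 - np.exp(-STUDY_MUTATIONS_PER_TYPE[t] / TUMORS_PER_TYPE[t]))
        for t in TUMORS_PER_TYPE
    }
    scale = STUDY_MUTATED_TUMORS / sum(expect.values())
    raw = {t: expect[t] * scale for t in expect}
    counts = {
        t: min(int(np.floor(raw[t])), TUMORS_PER_TYPE[t], STUDY_MUTATIONS_PER_TYPE[t])
        for t in raw
    }
    remainders = sorted(raw, key=lambda t: raw[t] - np.floor(raw[t]), reverse=True)
    i = 0
    while sum(counts.values()) < STUDY_MUTATED_TUMORS:
        t = remainders[i % len(remainders)]
        if counts[t] < min(TUMORS_PER_TYPE[t], STUDY_MUTATIONS_PER_TYPE[t]):
            counts[t] += 1
        i += 1
    return counts


def study_catalogue(
    seed: int,
    genome: MitoGenome,
    features: FeatureTable,
    cfg: SimulationConfig | None = None,
) -> tuple[Catalogue, pd.DataFrame]:
    """Synthetic catalogue with the study's fixed marginals (644 rows).

    Apply :func:`~mitosoma.catalogue.filter_rna_confirmed` to obtain the
    616-record confirmed set.  The truth table flags the injected
    processing-defect records and records each one's generative category.
    """
    cfg = cfg or SimulationConfig(seed=seed)
    rng = np.random.default_rng([seed, 909090])
    sampler = _Sampler(genome, features, cfg)
    ann = sampler.annotator
    n = STUDY_CATEGORY_COUNTS

    # --- enumerate candidate coding SNVs by (effect, class) ----------------
    coding_sites: dict[str, dict[tuple, list]] = {
        "missense": {}, "synonymous": {}, "nonsense": {}
    }
    from .annotation import strand_class_of

    for pos in ann.coding_positions():
        ref = genome.base(pos)
        for alt in "ACGT":
            if alt == ref:
                continue
            eff = ann.snv_effect(pos, ref, alt)
            if eff in coding_sites:
                coding_sites[eff].setdefault(strand_class_of(ref, alt), []).append(
                    (pos, ref, alt)
                )

    def draw_class(counts, restrict=None):
        """Draw a class without replacement from a fixed count allocation."""
        keys = [
            k for k in counts
            if counts[k] > 0 and (restrict is None or k in restrict)
        ]
        if not keys:  # allocation exhausted for the admissible classes
            keys = [k for k in counts if restrict is None or k in restrict]
            p = np.ones(len(keys))
        else:
            p = np.array([float(counts[k]) for k in keys])
        key = keys[rng.choice(len(keys), p=p / p.sum())]
        if counts.get(key, 0) > 0:
            counts[key] -= 1
        return key

    def draw_coding(effect, probs):
        """Class-first draw of a coding SNV with the requested effect."""
        avail = coding_sites[effect]
        cls = draw_class(probs, restrict={k for k in avail if avail[k]})
        sites = avail[cls]
        return sites[rng.integers(len(sites))]

    drawn: list[dict] = []  # interim rows before tumor assignment

    def push(pos, ref, alt, label, *, vaf=None, rna_shift=None, injected=False,
             vaf_label=None, kind_indel=False, trna=None, local=None,
             stemloop=None):
        vlabel = vaf_label or ("dloop" if label.startswith("dloop") else "default")
        v = vaf if vaf is not None else sampler.sample_vaf(vlabel, rng)
        if rna_shift is not None:
            rna = _clip01(v + rna_shift)
        else:
            # confirmed records stay at/above the RNA confirmation threshold
            rna = max(_clip01(v + sampler.rna_noise(rng)), 0.02)
        drawn.append(
            {"position": pos, "ref": ref, "alt": alt, "category": label,
             "vaf_dna": v, "vaf_rna": rna, "is_indel": kind_indel,
             "injected_imbalance": injected, "trna": trna,
             "trna_local_position": local, "stem_or_loop": stemloop}
        )

    # --- tRNA SNVs (drawn first: their classes are structure-driven, so the
    # remaining class draws are rebalanced to keep the catalogue-wide
    # spectrum at the configured class probabilities) -----------------------
    cloverleafs = _load_cloverleafs_safe()
    trna_feats = {f.name: f for f in features.by_class("tRNA")}

    def trna_site(name, local, sense_alt):
        """Genome-level (pos, ref, alt) of a gene-local substitution."""
        f = trna_feats[name]
        pos = f.genome_position(local - 1, genome.length)
        if f.strand == "L":
            return pos, genome.base(pos), sense_alt
        return pos, genome.base(pos), _COMPLEMENT[sense_alt]

    # injected processing-defect mutations: disruptive internal stem breaks
    defect_genes = ["TI"] * 4 + ["TM", "TM"] + ["TL1", "TK", "TF", "TW", "TN", "TE"]
    used_sites = set()
    for gene in defect_genes[: n["trna_imbalanced"]]:
        cl = cloverleafs[gene]
        internal = _internal_stem_positions(cl)
        for _attempt in range(200):
            local = internal[rng.integers(len(internal))]
            ref_sense = cl.sequence[local - 1]
            alt_sense = _DISRUPTIVE_ALT[ref_sense]
            pos, ref, alt = trna_site(gene, local, alt_sense)
            if (pos, alt) not in used_sites:
                used_sites.add((pos, alt))
                break
        vaf = sampler.sample_vaf("default", rng, max_vaf=cfg.imbalance_max_dna_vaf)
        push(pos, ref, alt, "trna_imbalanced", vaf=vaf,
             rna_shift=rng.uniform(*cfg.imbalance_shift), injected=True,
             trna=gene, local=local, stemloop="stem")

    # background tRNA mutations: mild stem changes and loop changes
    other_genes = [g for g in sorted(trna_feats) ]
    for kind, count in (("stem", n["trna_stem"]), ("loop", n["trna_loop"])):
        for _ in range(count):
            for _attempt in range(500):
                gene = other_genes[rng.integers(len(other_genes))]
                cl = cloverleafs[gene]
                if kind == "stem":
                    cands = [
                        i for i in range(1, len(cl) + 1)
                        if cl.is_paired(i) and cl.sequence[i - 1] in _MILD_STEM_ALT
                    ]
                    if not cands:
                        continue
                    local = cands[rng.integers(len(cands))]
                    alt_sense = _MILD_STEM_ALT[cl.sequence[local - 1]]
                else:
                    cands = [i for i in range(1, len(cl) + 1) if not cl.is_paired(i)]
                    local = cands[rng.integers(len(cands))]
                    alt_sense = _TRANSITION[cl.sequence[local - 1]]
                pos, ref, alt = trna_site(gene, local, alt_sense)
                if (pos, alt) not in used_sites:
                    used_sites.add((pos, alt))
                    break
            push(pos, ref, alt, f"trna_{kind}", trna=gene, local=local,
                 stemloop=kind)

    # --- rebalanced class probabilities for the remaining SNVs -------------
    from .annotation import strand_class_of as _scof

    n_snv_total = 564
    trna_counts: dict[tuple, int] = {}
    for row in drawn:
        if not row["is_indel"]:
            k = _scof(row["ref"][0], row["alt"][0])
            trna_counts[k] = trna_counts.get(k, 0) + 1
    raw = {}
    for key in sampler.class_keys:
        target = sampler.class_probs[key] * n_snv_total
        raw[key] = max(target - trna_counts.get(key, 0), 0.0)
    n_rest = n["missense"] + n["synonymous"] + n["nonsense"] + n["rrna_snv"] + n["dloop_snv"]
    scale = n_rest / sum(raw.values())
    remaining = {k: int(np.floor(v * scale)) for k, v in raw.items()}
    frac_order = sorted(
        raw, key=lambda k: raw[k] * scale - np.floor(raw[k] * scale), reverse=True
    )
    i = 0
    while sum(remaining.values()) < n_rest:
        remaining[frac_order[i % len(frac_order)]] += 1
        i += 1
    # class draws below consume this fixed allocation (sampling without
    # replacement), so the catalogue-wide spectrum hits the configured
    # probabilities up to integer rounding
    adjusted = remaining

    # --- coding SNVs --------------------------------------------------------
    for eff in ("missense", "synonymous", "nonsense"):
        for _ in range(n[eff]):
            pos, ref, alt = draw_coding(eff, adjusted)
            push(pos, ref, alt, eff,
                 vaf_label="nonsense" if eff == "nonsense" else "default")

    # --- coding frameshift indels (hotspot runs + random coding runs) ------
    hotspot = [(10947, "C", 3), (11867, "C", 2), (12418, "A", 4)]
    for start, base, count in hotspot:
        for _ in range(count):
            if rng.random() < 0.7:
                pos, ref, alt = start, base, base + base  # insertion
            else:
                pos, ref, alt = start, base + base, base
            push(pos, ref, alt, "frameshift", vaf_label="frameshift",
                 kind_indel=True)
    coding_pos = set(ann.coding_positions())
    coding_runs = [r for r in sampler.runs if r[1] in coding_pos]
    for _ in range(n["frameshift"] - sum(c for *_, c in hotspot)):
        pos, ref, alt = sampler.sample_indel(rng, coding_runs)
        push(pos, ref, alt, "frameshift", vaf_label="frameshift", kind_indel=True)

    # --- rRNA and D-loop ----------------------------------------------------
    region_pos = {"rRNA": [], "D-loop": []}
    for cls_name in region_pos:
        for f in features.by_class(cls_name):
            region_pos[cls_name].extend(f.positions(genome.length))
    region_by_base = {
        region: {
            b: [p for p in positions if genome.base(p) == b] for b in "ACGT"
        }
        for region, positions in region_pos.items()
    }
    for label, region, count in (
        ("rrna_snv", "rRNA", n["rrna_snv"]),
        ("dloop_snv", "D-loop", n["dloop_snv"]),
    ):
        by_base = region_by_base[region]
        for _ in range(count):
            while True:
                cls, strand = draw_class(adjusted)
                pyr_ref, pyr_alt = cls[0], cls[2]
                ref = pyr_ref if strand == "L" else _COMPLEMENT[pyr_ref]
                alt = pyr_alt if strand == "L" else _COMPLEMENT[pyr_alt]
                if by_base[ref]:
                    break
            pos = by_base[ref][rng.integers(len(by_base[ref]))]
            push(pos, ref, alt, label)
    for label, region, count in (
        ("rrna_indel", "rRNA", n["rrna_indel"]),
        ("dloop_indel", "D-loop", n["dloop_indel"]),
    ):
        runs = [r for r in sampler.runs if r[1] in set(region_pos[region])]
        for _ in range(count):
            pos, ref, alt = sampler.sample_indel(rng, runs)
            push(pos, ref, alt, label, kind_indel=True)

    # --- non-tRNA imbalanced records ---------------------------------------
    converted = 0
    order = rng.permutation(len(drawn))
    for i in order:
        row = drawn[i]
        if converted >= n["other_imbalanced"]:
            break
        if row["category"] in ("rrna_snv", "dloop_snv") and not row["injected_imbalance"]:
            vaf = sampler.sample_vaf(
                "dloop" if row["category"] == "dloop_snv" else "default",
                rng, max_vaf=cfg.imbalance_max_dna_vaf,
            )
            row["vaf_dna"] = vaf
            row["vaf_rna"] = _clip01(vaf + rng.uniform(*cfg.imbalance_shift))
            row["injected_imbalance"] = True
            row["category"] += "_imbalanced"
            converted += 1

    assert len(drawn) == STUDY_TOTAL_CONFIRMED, len(drawn)

    # --- cancer types and tumors -------------------------------------------
    indel_rows = [r for r in drawn if r["is_indel"]]
    snv_rows = [r for r in drawn if not r["is_indel"]]
    rng.shuffle(indel_rows)
    rng.shuffle(snv_rows)
    typed: dict[str, list] = {}
    ii = si = 0
    for t in TUMORS_PER_TYPE:
        k_ind = STUDY_INDELS_PER_TYPE[t]
        k_all = STUDY_MUTATIONS_PER_TYPE[t]
        typed[t] = indel_rows[ii : ii + k_ind] + snv_rows[si : si + (k_all - k_ind)]
        ii += k_ind
        si += k_all - k_ind
    assert ii == len(indel_rows) and si == len(snv_rows)

    mutated_counts = _allocate_mutated_tumors(rng)
    records: list[MutationRecord] = []
    truth_rows = []
    seen = set()
    for t, rows in typed.items():
        k = mutated_counts[t]
        tumor_pool = [f"{t}-T{i:03d}" for i in range(TUMORS_PER_TYPE[t])]
        rng.shuffle(tumor_pool)
        carriers = tumor_pool[:k]
        assignment = carriers + [
            carriers[rng.integers(k)] for _ in range(len(rows) - k)
        ]
        rng.shuffle(assignment)
        for row, sample_id in zip(rows, assignment):
            key = (sample_id, row["position"], row["ref"], row["alt"])
            while key in seen:  # recurrent site in same tumor: move tumor
                sample_id = carriers[rng.integers(k)]
                key = (sample_id, row["position"], row["ref"], row["alt"])
            seen.add(key)
            records.append(
                MutationRecord(
                    sample_id, t, row["position"], row["ref"], row["alt"],
                    row["vaf_dna"], 0.0, row["vaf_rna"], True,
                )
            )
            truth_rows.append({"sample_id": sample_id, "cancer_type": t, **row})

    # --- RNA-unconfirmed extras (sequenced but failing RNA confirmation) ---
    all_tumors = [
        (f"{t}-T{i:03d}", t)
        for t in TUMORS_PER_TYPE
        for i in range(TUMORS_PER_TYPE[t])
    ]
    for _ in range(STUDY_TOTAL_SEQUENCED - STUDY_TOTAL_CONFIRMED):
        for _attempt in range(100):
            sample_id, t = all_tumors[rng.integers(len(all_tumors))]
            pos, ref, alt = sampler.sample_snv(rng)
            key = (sample_id, pos, ref, alt)
            if key not in seen:
                seen.add(key)
                break
        label = sampler.vaf_label(pos, ref, alt)
        vaf = sampler.sample_vaf(label, rng)
        rna = float(rng.uniform(0.0, 0.019))
        records.append(
            MutationRecord(sample_id, t, pos, ref, alt, vaf, 0.0, rna, False)
        )
        truth_rows.append(
            {"sample_id": sample_id, "cancer_type": t, "position": pos,
             "ref": ref, "alt": alt, "category": "unconfirmed",
             "vaf_dna": vaf, "vaf_rna": rna, "is_indel": False,
             "injected_imbalance": False, "trna": None,
             "trna_local_position": None, "stem_or_loop": None}
        )

    truth = pd.DataFrame(truth_rows)
    return (
        Catalogue(records, provenance=f"synthetic-study(seed={seed})"),
        truth,
    )


def _internal_stem_positions(cl) -> list[int]:
    """Paired positions whose helix neighbours are also paired (stem interior)."""
    paired = {i for pair in cl.pairs for i in pair}
    out = [
        i for i in paired
        if (i - 1 in paired) and (i + 1 in paired)
    ]
    return sorted(out) or sorted(paired)


def _load_cloverleafs_safe():
    from .reference import load_cloverleafs

    return load_cloverleafs()


# ---------------------------------------------------------------------------
# coverage simulation
# ---------------------------------------------------------------------------

def simulate_coverage(
    cfg: SimulationConfig,
    features: FeatureTable,
    mutated_trna: str,
    fold: float,
    rng: np.random.Generator | None = None,
    n_controls: int = 12,
    base_depth: float = 200.0,
    pad: int = 300,
    genome_length: int = 16569,
) -> tuple[CoverageProfile, list[CoverageProfile]]:
    """Case and control RNA coverage over a window around one tRNA gene.

    Controls follow a smooth baseline with Poisson noise; the case profile
    has its expected depth multiplied by ``fold`` across the tRNA gene
    (precursor accumulation).  Depths are raw; normalise with
    :func:`~mitosoma.imbalance.normalize_coverage`.
    """
    if fold < 1:
        raise ValueError("fold must be >= 1")
    try:
        f = features.get(mutated_trna)
    except KeyError:
        raise ValueError(f"unknown gene {mutated_trna!r}")
    rng = rng or np.random.default_rng(cfg.seed)
    start = max(1, f.start - pad)
    end = min(genome_length, f.end + pad)
    pos = np.arange(start, end + 1)
    baseline = base_depth * (1.0 + 0.3 * np.sin(2 * np.pi * pos / 2000.0))
    in_gene = (pos >= f.start) & (pos <= f.end)

    def draw(expected, label):
        total = base_depth * genome_length * rng.uniform(0.85, 1.15)
        return CoverageProfile(
            start=start,
            depths=rng.poisson(expected).astype(float),
            total_chrm_reads=total,
            label=label,
        )

    controls = [draw(baseline, f"control-{i}") for i in range(n_controls)]
    case_expected = np.where(in_gene, baseline * fold, baseline)
    case = draw(case_expected, "case")
    return case, controls
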