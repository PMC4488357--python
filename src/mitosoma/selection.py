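"""Heteroplasmy statistics and selection tests.

Heteroplasmy level is operationalised as the tumor-DNA variant allele
frequency; summaries are over mutations (not tumors).  Selection is probed
two ways: (i) distributional comparisons of heteroplasmy between mutation
categories (two-sample Kolmogorov-Smirnov), and (ii) a goodness-of-fit
comparison of the observed synonymous:nonsynonymous split against a null
expectation obtained by enumerating every possible coding SNV, weighted by
the catalogue's strand-resolved substitution spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import numpy as np
from scipy import stats

from .catalogue import Catalogue, MutationRecord

__all__ = [
    "HeteroplasmySummary",
    "TestResult",
    "heteroplasmy_summary",
    "ks_two_sample",
    "chi2_yates",
    "expected_nonsyn_fraction",
]


@dataclass(frozen=True)
class TestResult:
    """Statistic, p-value and method label of one hypothesis test."""

    statistic: float
    p_value: float
    method: str
    n: tuple | int | None = None

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class HeteroplasmySummary:
    """Mean/max/threshold-exceedance summary of DNA VAFs in one category."""

    label: str
    vafs: tuple

    @property
    def n(self) -> int:
        return len(self.vafs)

    @property
    def mean_vaf(self) -> float:
        return float(np.mean(self.vafs))

    @property
    def max_vaf(self) -> float:
        return float(np.max(self.vafs))

    def frac_above(self, threshold: float) -> float:
        return float(np.mean(np.asarray(self.vafs) > threshold))


def heteroplasmy_summary(
    cat: Catalogue,
    selector: Callable[[MutationRecord], bool] | None = None,
    label: str = "all",
) -> HeteroplasmySummary:
    """Summarise tumor-DNA VAFs of the records matching ``selector``."""
    recs = cat.records if selector is None else [r for r in cat if selector(r)]
    if not recs:
        raise ValueError(f"empty selection for category {label!r}")
    return HeteroplasmySummary(label, tuple(r.vaf_dna for r in recs))


def ks_two_sample(x: Iterable[float], y: Iterable[float]) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test.

    Exact null for small samples (< 10 per group), asymptotic otherwise.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    method = "exact" if min(len(x), len(y)) < 10 else "asymp"
    res = stats.ks_2samp(x, y, method=method)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=f"ks-2samp-{method}",
        n=(len(x), len(y)),
    )


def chi2_yates(observed: tuple[int, int], expected_fraction: float) -> TestResult:
    """Continuity-corrected chi-square goodness of fit on a binary split.

    ``observed`` is (count in focal category, count in other); the null
    expects ``expected_fraction`` of the total in the focal category.  The
    statistic is sum of (|O - E| - 0.5)^2 / E with 1 degree of freedom.
    """
    a, b = observed
    if a < 0 or b < 0:
        raise ValueError("counts must be nonnegative")
    if not (0.0 < expected_fraction < 1.0):
        raise ValueError("expected_fraction must be in (0, 1)")
    n = a + b
    e1 = n * expected_fraction
    e2 = n * (1.0 - expected_fraction)
    if e1 == 0 or e2 == 0:
        raise ValueError("zero expected cell")
    stat = sum(
        (max(abs(o - e) - 0.5, 0.0)) ** 2 / e for o, e in ((a, e1), (b, e2))
    )
    return TestResult(
        statistic=float(stat),
        p_value=float(stats.chi2.sf(stat, df=1)),
        method="chi2-yates-gof",
        n=n,
    )


def expected_nonsyn_fraction(
    annotator,
    spectrum: Mapping[tuple[str, str], float],
) -> float:
    """Spectrum-weighted expected nonsynonymous fraction of coding SNVs.

    Enumerates every possible single-nucleotide change at every
    protein-coding position and classifies each with the effect annotator
    (most severe effect across overlapping reading frames).  Each
    strand-resolved substitution class receives total probability mass
    equal to its frequency in ``spectrum`` (a mapping (pyrimidine class,
    strand) -> weight), distributed uniformly over that class's possible
    changes; the returned value is the probability that a mutation drawn
    from this null is nonsynonymous (missense or nonsense).

    Normalising within classes keeps the null's class mix equal to the
    observed spectrum: the observed class frequencies already reflect
    per-class target-site abundance, so weighting sites directly would
    count availability twice.
    """
    from .annotation import strand_class_of

    if sum(spectrum.values()) <= 0:
        raise ValueError("spectrum has no mass")
    n_sites: dict = {}
    n_nonsyn: dict = {}
    for pos in annotator.coding_positions():
        ref = annotator.genome.base(pos)
        for alt in "ACGT":
            if alt == ref:
                continue
            effect = annotator.snv_effect(pos, ref, alt)
            if effect is None:
                continue
            key = strand_class_of(ref, alt)
            n_sites[key] = n_sites.get(key, 0) + 1
            if effect in ("missense", "nonsense"):
                n_nonsyn[key] = n_nonsyn.get(key, 0) + 1
    mass = 0.0
    mass_nonsyn = 0.0
    for key, w in spectrum.items():
        if w <= 0 or n_sites.get(key, 0) == 0:
            continue
        mass += w
        mass_nonsyn += w * n_nonsyn.get(key, 0) / n_sites[key]
    if mass == 0.0:
        raise ValueError("spectrum puts no mass on any possible coding change")
    return mass_nonsyn / mass
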