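"""DNA/RNA allelic imbalance and RNA coverage fold-change analysis.

Mature mt-tRNAs are not polyadenylated and should be depleted from polyA+
RNA-seq; a mutant tRNA allele that fails processing accumulates in the
polyA+ precursor pool and shows an RNA allele frequency well above its DNA
allele frequency.  This module detects such records (RNA - DNA VAF above a
threshold), tests their regional enrichment with Fisher's exact test, and
provides per-base coverage normalisation and case-vs-control fold changes
for visualising precursor accumulation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .catalogue import Catalogue, MutationRecord
from .selection import TestResult

__all__ = [
    "ImbalanceSummary",
    "CoverageProfile",
    "dna_rna_correlation",
    "detect_imbalanced",
    "region_enrichment",
    "normalize_coverage",
    "coverage_fold_change",
]


def _paired(cat: Catalogue) -> list[MutationRecord]:
    return [r for r in cat if r.vaf_rna is not None]


def dna_rna_correlation(cat: Catalogue) -> float:
    """Pearson correlation of (DNA VAF, RNA VAF) over records with both."""
    recs = _paired(cat)
    if len(recs) < 2:
        raise ValueError("need at least two records with both frequencies")
    x = np.array([r.vaf_dna for r in recs])
    y = np.array([r.vaf_rna for r in recs])
    return float(stats.pearsonr(x, y).statistic)


def detect_imbalanced(
    cat: Catalogue, threshold: float = 0.3, direction: str = "rna_excess"
) -> Catalogue:
    """Records whose RNA-DNA VAF difference exceeds ``threshold``.

    ``direction``: 'rna_excess' (RNA - DNA > t), 'rna_deficit'
    (DNA - RNA > t) or 'both' (|RNA - DNA| > t).  Records without an RNA
    frequency are never selected.
    """
    if direction not in ("rna_excess", "rna_deficit", "both"):
        raise ValueError(f"unknown direction {direction!r}")

    def keep(r: MutationRecord) -> bool:
        if r.vaf_rna is None:
            return False
        delta = r.vaf_rna - r.vaf_dna
        if direction == "rna_excess":
            return delta > threshold
        if direction == "rna_deficit":
            return -delta > threshold
        return abs(delta) > threshold

    return cat.subset(keep, provenance=f"{cat.provenance} [imbalanced>{threshold}]")


@dataclass(frozen=True)
class ImbalanceSummary:
    """Correlation plus the detected imbalanced subset at one threshold."""

    r: float
    threshold: float
    imbalanced: Catalogue
    n_total: int


def region_enrichment(
    imbalanced: Catalogue,
    background: Catalogue,
    in_region,
) -> tuple[TestResult, tuple[tuple[int, int], tuple[int, int]]]:
    """Fisher's exact test for regional enrichment of the imbalanced set.

    ``in_region`` is a predicate on records (e.g. "is in a tRNA gene").
    Returns the two-sided test result (odds ratio as the statistic) and the
    2x2 table ((imb_in, imb_out), (bg_in, bg_out)).  The two sets must be
    disjoint and nonempty.
    """
    if len(imbalanced) == 0 or len(background) == 0:
        raise ValueError("both sets must be nonempty")
    keys = {r.key for r in imbalanced} & {r.key for r in background}
    if keys:
        raise ValueError("imbalanced and background sets overlap")
    a = sum(1 for r in imbalanced if in_region(r))
    b = len(imbalanced) - a
    c = sum(1 for r in background if in_region(r))
    d = len(background) - c
    table = ((a, b), (c, d))
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return (
        TestResult(statistic=float(odds), p_value=float(p), method="fisher-exact",
                   n=(len(imbalanced), len(background))),
        table,
    )


# ---------------------------------------------------------------------------
# coverage profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoverageProfile:
    """Per-base read depth over a window, with its normalising constant."""

    start: int  # 1-based first position of the window
    depths: np.ndarray
    total_chrm_reads: float
    normalized: bool = False
    label: str = ""

    def __post_init__(self):
        d = np.asarray(self.depths, dtype=float)
        if (d < 0).any():
            raise ValueError("negative depths")
        object.__setattr__(self, "depths", d)

    @property
    def end(self) -> int:
        return self.start + len(self.depths) - 1


def normalize_coverage(profile: CoverageProfile) -> CoverageProfile:
    """Divide depths by the sample's total mitochondrial read count.

    Idempotent: an already-normalised profile is returned unchanged.
    """
    if profile.normalized:
        return profile
    if profile.total_chrm_reads <= 0:
        raise ValueError("total_chrm_reads must be positive")
    return replace(
        profile,
        depths=profile.depths / profile.total_chrm_reads,
        normalized=True,
    )


def coverage_fold_change(
    case: CoverageProfile,
    controls: list[CoverageProfile],
    pseudocount: float = 1e-9,
) -> np.ndarray:
    """Per-base normalised case depth over the median of normalised controls.

    ``pseudocount`` (in normalised-depth units) is added to numerator and
    denominator so positions with zero control coverage stay finite.
    """
    if not controls:
        raise ValueError("need at least one control profile")
    case_n = normalize_coverage(case)
    ctrl = []
    for c in controls:
        cn = normalize_coverage(c)
        if cn.start != case_n.start or len(cn.depths) != len(case_n.depths):
            raise ValueError("control window does not match case window")
        ctrl.append(cn.depths)
    med = np.median(np.vstack(ctrl), axis=0)
    return (case_n.depths + pseudocount) / (med + pseudocount)
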