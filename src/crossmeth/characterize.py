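"""Genome-wide methylome description.

Sites are categorized from their cross-sample median beta into low (< 20%),
intermediate (20-80%) and high (> 80%) methylation; enrichment of genomic or
CpG-region annotation among the extreme categories is tested against the
intermediate background with Fisher's exact test.  Imprinting analysis asks
whether sites near imprinted genes (or inside imprinting control regions) are
enriched for the hemi-methylated 40-60% band in each tissue -- the expected
somatic signature of parent-of-origin allele-specific methylation, which
should be absent from gametes.  A PCA summary quantifies how strongly tissue
of origin dominates overall variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CategoryThresholds",
    "EnrichmentResult",
    "P_FLOOR",
    "categorize_sites",
    "region_enrichment",
    "imprint_enrichment",
    "interval_overlap",
    "pca_summary",
    "enrichment_frame",
]

#: reporting floor for Fisher p-values ("P < 1e-50" convention); raw values
#: are kept on the result objects.
P_FLOOR = 1e-50


@dataclass
class CategoryThresholds:
    low_max: float = 0.20
    high_min: float = 0.80
    imprint_band: tuple[float, float] = (0.40, 0.60)

    def __post_init__(self):
        if not 0.0 <= self.low_max < self.high_min <= 1.0:
            raise ValueError("need 0 <= low_max < high_min <= 1")
        lo, hi = self.imprint_band
        if not (self.low_max < lo < hi < self.high_min):
            raise ValueError("imprint_band must lie strictly inside "
                             "(low_max, high_min)")


@dataclass
class EnrichmentResult:
    """One 2x2 Fisher test: counts (a, b, c, d), sample odds ratio, raw p."""

    label: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float

    @property
    def p_floored(self) -> float:
        return max(self.p, P_FLOOR)


def _fisher(label: str, a: int, b: int, c: int, d: int) -> EnrichmentResult:
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        orr = np.inf if a * d > 0 else (0.0 if b * c > 0 else np.nan)
    elif b * c == 0:
        orr = np.inf if a * d > 0 else np.nan
    else:
        orr = (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentResult(label, a, b, c, d, float(orr), float(p))


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results as CSV-ready rows (p floored for report)."""
    return pd.DataFrame(
        [(r.label, r.a, r.b, r.c, r.d, r.odds_ratio, r.p_floored)
         for r in results],
        columns=["region", "a", "b", "c", "d", "OR", "p"],
    )


def categorize_sites(beta: pd.DataFrame,
                     thresholds: CategoryThresholds | None = None) -> pd.Series:
    """Per-probe category from the cross-sample median beta.

    Boundary convention: low iff median < low_max, high iff median >
    high_min, intermediate otherwise (boundaries are intermediate).  Medians
    use linear interpolation between order statistics.
    """
    thresholds = thresholds or CategoryThresholds()
    med = beta.median(axis=1)
    cat = np.where(med < thresholds.low_max, "low",
                   np.where(med > thresholds.high_min, "high", "intermediate"))
    return pd.Series(cat, index=beta.index, name="category")


def region_enrichment(
    categories: pd.Series,
    regions: pd.Series,
    target_category: str,
    background_category: str = "intermediate",
) -> list[EnrichmentResult]:
    """Fisher enrichment of each region class among ``target_category`` sites.

    For every region label, the 2x2 table crosses (in region vs not) with
    (target category vs background category); probes in other categories are
    ignored.  Regions with zero probes in the test universe are omitted with
    a warning.
    """
    regions = regions.reindex(categories.index)
    in_target = categories == target_category
    in_background = categories == background_category
    universe = in_target | in_background
    results = []
    for label in pd.unique(regions.dropna()):
        member = (regions == label) & universe
        if member.sum() == 0:
            warnings.warn(f"region {label!r} has no probes; omitted")
            continue
        a = int((member & in_target).sum())
        b = int((~member & universe & in_target).sum())
        c = int((member & in_background).sum())
        d = int((~member & universe & in_background).sum())
        results.append(_fisher(str(label), a, b, c, d))
    return results


def imprint_enrichment(
    beta_blood: pd.DataFrame,
    beta_sperm: pd.DataFrame,
    imprint_class: pd.Series,
    thresholds: CategoryThresholds | None = None,
) -> list[EnrichmentResult]:
    """Hemi-methylation-band enrichment per (tissue x imprint class).

    For each imprint class and tissue, Fisher's exact test of membership in
    the imprint band (default 40-60% median methylation) among class probes
    versus the array-wide background (all other probes).  Empty classes are
    omitted with a warning.
    """
    thresholds = thresholds or CategoryThresholds()
    lo, hi = thresholds.imprint_band
    results = []
    for tissue, beta in (("blood", beta_blood), ("sperm", beta_sperm)):
        med = beta.median(axis=1)
        in_band = (med >= lo) & (med <= hi)
        classes = imprint_class.reindex(beta.index).fillna("none")
        for label in pd.unique(classes):
            if label == "none":
                continue
            member = classes == label
            if member.sum() == 0:
                warnings.warn(f"imprint class {label!r} empty; omitted")
                continue
            a = int((member & in_band).sum())
            b = int((member & ~in_band).sum())
            c = int((~member & in_band).sum())
            d = int((~member & ~in_band).sum())
            results.append(_fisher(f"{tissue}:{label}", a, b, c, d))
    return results


def interval_overlap(annotation: pd.DataFrame,
                     intervals: pd.DataFrame) -> pd.Index:
    """Probes whose (1-based) position falls in a BED interval set.

    ``annotation`` needs ``chrom`` and ``position`` columns; ``intervals``
    is BED-style (chrom, start, end), 0-based half-open.  A probe at 1-based
    position p overlaps [s, e) iff s <= p - 1 < e.
    """
    bad = intervals["end"] <= intervals["start"]
    if bad.any():
        rec = intervals[bad].iloc[0]
        raise ValueError(
            f"malformed interval {rec['chrom']}:{rec['start']}-{rec['end']} "
            "(end <= start)")
    hits = np.zeros(len(annotation), dtype=bool)
    pos0 = annotation["position"].to_numpy(dtype=np.int64) - 1
    chrom = annotation["chrom"].to_numpy(dtype=object)
    for c, sub in intervals.groupby("chrom", sort=False):
        mask = chrom == c
        if not mask.any():
            continue
        starts = np.sort(sub["start"].to_numpy(dtype=np.int64))
        # merge not needed for membership: test each interval via searchsorted
        # over sorted starts paired with ends sorted by start
        order = np.argsort(sub["start"].to_numpy(dtype=np.int64), kind="stable")
        ends = sub["end"].to_numpy(dtype=np.int64)[order]
        p = pos0[mask]
        idx = np.searchsorted(starts, p, side="right")
        inside = np.zeros(len(p), dtype=bool)
        # walk back over candidate intervals (running max of ends makes one
        # lookup suffice)
        running_end = np.maximum.accumulate(ends)
        has_cand = idx > 0
        inside[has_cand] = p[has_cand] < running_end[idx[has_cand] - 1]
        hits[mask] = inside
    return annotation.index[hits]


def pca_summary(beta: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """PCA over samples (columns of ``beta``).

    Returns ``(variance_fractions, scores)``: fractions sum to 1 over all
    non-trivial components; scores are centred per component.
    """
    if beta.shape[1] < 3:
        raise ValueError("need >= 3 samples for a PCA summary")
    X = beta.T.to_numpy(dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    if not np.any(X):
        raise ValueError("constant beta matrix: no principal components")
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    var = S ** 2
    frac = var / var.sum()
    k = len(S)
    scores = pd.DataFrame(U * S, index=beta.columns,
                          columns=[f"PC{i + 1}" for i in range(k)])
    return frac, scores
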