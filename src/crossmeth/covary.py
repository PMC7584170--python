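"""Cross-tissue covariation of DNA methylation.

The pipeline: (1) restrict to "variable" probes -- those whose middle 80% of
samples span at least 5% methylation in BOTH tissues, so single outliers
cannot manufacture correlations; (2) Pearson correlation per probe between
matched blood and sperm values, two-sided p from the t-transform on n - 2 df;
(3) a permutation null obtained by re-pairing sperm samples at random;
(4) two independent modality classifiers for the significant sites -- a 2D
clustering method (generalized-ESD outlier screen, silhouette-selected
k-medoids/k-means at k in {2, 3}, variance-ratio demotion) and a 1D
gap-hunting method per tissue (split sorted values at gaps > 5%); both flag
calls driven by tiny groups of samples; (5) Fisher enrichment of genetic
annotation (SNPs in the probe sequence, CorSIVs, mQTLs) among correlated
sites versus the non-correlated variable background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .characterize import EnrichmentResult, _fisher
from .paired import EPIC_ALPHA

__all__ = [
    "VariabilityCriterion",
    "ModalityConfig",
    "ModalityCall",
    "select_variable_sites",
    "correlate_sites",
    "permutation_null",
    "generalized_esd",
    "classify_modality_kmeans",
    "gap_hunt",
    "annotate_snps",
    "genetic_enrichment",
]


@dataclass
class VariabilityCriterion:
    inner_fraction: float = 0.80
    min_range: float = 0.05

    def __post_init__(self):
        if not 0.0 < self.inner_fraction <= 1.0:
            raise ValueError("inner_fraction must lie in (0, 1]")
        if self.min_range <= 0:
            raise ValueError("min_range must be > 0")


@dataclass
class ModalityConfig:
    gap_cutoff: float = 0.05
    variance_ratio_min: float = 2.0
    outlier_fraction_max: float = 0.05
    esd_alpha: float = 0.05
    esd_max_fraction: float = 0.10
    candidate_k: tuple[int, ...] = (2, 3)
    algorithm: str = "kmedoids"  # or "kmeans"

    def __post_init__(self):
        if self.gap_cutoff <= 0:
            raise ValueError("gap_cutoff must be > 0")
        if self.variance_ratio_min <= 0:
            raise ValueError("variance_ratio_min must be > 0")

    def max_small_group(self, n: int) -> int:
        return max(1, int(np.floor(self.outlier_fraction_max * n)))


@dataclass
class ModalityCall:
    modality: str            # unimodal | bimodal | trimodal | indeterminate
    k: int
    labels: np.ndarray | None
    outlier_driven: bool
    esd_outliers: np.ndarray


def select_variable_sites(
    beta_blood: pd.DataFrame,
    beta_sperm: pd.DataFrame,
    criterion: VariabilityCriterion | None = None,
) -> pd.Index:
    """Probes whose inner-quantile range is >= min_range in BOTH tissues.

    With the default criterion this keeps probes whose 10th-90th percentile
    span (linear-interpolation quantiles) is at least 0.05 beta in blood and
    in sperm; the boundary is inclusive.
    """
    criterion = criterion or VariabilityCriterion()
    common = beta_blood.index.intersection(beta_sperm.index)
    lo = (1.0 - criterion.inner_fraction) / 2.0
    q = [lo, 1.0 - lo]
    keep = np.ones(len(common), dtype=bool)
    for beta in (beta_blood, beta_sperm):
        X = beta.loc[common].to_numpy(dtype=float)
        qs = np.quantile(X, q, axis=1)
        # inclusive boundary, robust to float rounding of the quantile diff
        keep &= (qs[1] - qs[0]) >= criterion.min_range - 1e-12
    return common[keep]


def _rowwise_pearson(B: np.ndarray, S: np.ndarray):
    """Per-row Pearson r between two equally shaped matrices."""
    Bc = B - B.mean(axis=1, keepdims=True)
    Sc = S - S.mean(axis=1, keepdims=True)
    num = (Bc * Sc).sum(axis=1)
    den = np.sqrt((Bc ** 2).sum(axis=1) * (Sc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r[den == 0] = np.nan
    return np.clip(r, -1.0, 1.0)


def correlate_sites(
    beta_blood: pd.DataFrame,
    beta_sperm: pd.DataFrame,
    pairing: dict[str, tuple[str, str]] | None = None,
    alpha: float = EPIC_ALPHA,
) -> pd.DataFrame:
    """Pearson correlation per probe between matched blood and sperm betas.

    Two-sided p from t = r * sqrt((n-2)/(1-r^2)) on n - 2 df.  Zero variance
    in either tissue yields r = NaN.  Returns a frame with r, p, n and a
    significance/negative flag per probe.
    """
    common = beta_blood.index.intersection(beta_sperm.index)
    if pairing is not None:
        bcols = [b for b, _ in pairing.values()]
        scols = [s for _, s in pairing.values()]
    else:
        if beta_blood.shape[1] != beta_sperm.shape[1]:
            raise ValueError("unequal sample counts and no pairing given")
        bcols, scols = list(beta_blood.columns), list(beta_sperm.columns)
    if len(bcols) < 4:
        raise ValueError("need >= 4 complete pairs")
    B = beta_blood.loc[common, bcols].to_numpy(dtype=float)
    S = beta_sperm.loc[common, scols].to_numpy(dtype=float)
    n = B.shape[1]
    r = _rowwise_pearson(B, S)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    sig = np.where(np.isnan(r), False, p < alpha)
    return pd.DataFrame(
        {
            "r": r,
            "p": p,
            "n": n,
            "significant": sig.astype(bool),
            "negative": (r < 0) & ~np.isnan(r),
        },
        index=common,
    )


def permutation_null(
    beta_blood: pd.DataFrame,
    beta_sperm: pd.DataFrame,
    variable_probes: pd.Index | None = None,
    n_perm: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Pooled null correlations from random re-pairings of the two tissues.

    Each permutation applies a uniform random shuffle to the sperm sample
    order and recomputes the per-probe correlation across ``variable_probes``
    (default: all shared probes); the pooled r values over permutations x
    probes form the empirical null.  Identical seed -> identical output.
    """
    rng = np.random.default_rng(seed)
    probes = (variable_probes if variable_probes is not None
              else beta_blood.index.intersection(beta_sperm.index))
    B = beta_blood.loc[probes].to_numpy(dtype=float)
    S = beta_sperm.loc[probes].to_numpy(dtype=float)
    n = B.shape[1]
    out = []
    for _ in range(int(n_perm)):
        perm = rng.permutation(n)
        out.append(_rowwise_pearson(B, S[:, perm]))
    if not out:
        return np.empty(0)
    pooled = np.concatenate(out)
    return pooled[np.isfinite(pooled)]


def generalized_esd(values: np.ndarray, max_outliers: int,
                    alpha: float = 0.05) -> np.ndarray:
    """Indices flagged by the generalized extreme studentized deviate test.

    Iteratively removes the most extreme value (largest |x - mean| / sd) and
    compares each test statistic R_i with its critical value; the number of
    outliers is the largest i with R_i above critical.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    idx = np.arange(n)
    removed: list[int] = []
    stats_r: list[float] = []
    crit: list[float] = []
    work = x.copy()
    widx = idx.copy()
    for i in range(1, max_outliers + 1):
        m = len(work)
        if m < 3:
            break
        sd = work.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(work - work.mean())
        j = int(np.argmax(dev))
        stats_r.append(dev[j] / sd)
        pp = 1.0 - alpha / (2.0 * m)
        tq = stats.t.ppf(pp, m - 2)
        crit.append((m - 1) * tq / np.sqrt((m - 2 + tq ** 2) * m))
        removed.append(int(widx[j]))
        work = np.delete(work, j)
        widx = np.delete(widx, j)
    n_out = 0
    for i in range(len(stats_r)):
        if stats_r[i] > crit[i]:
            n_out = i + 1
    return np.array(removed[:n_out], dtype=int)


# ---------------------------------------------------------------------------
# clustering helpers


def _pam(points: np.ndarray, k: int, max_iter: int = 50) -> np.ndarray:
    """Small deterministic PAM (k-medoids) on a dense distance matrix."""
    n = len(points)
    D = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    # BUILD: greedy medoid initialisation
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        dmin = D[:, medoids].min(axis=1)
        gains = np.maximum(dmin[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = list(medoids)
    # SWAP
    for _ in range(max_iter):
        labels = np.argmin(D[:, medoids], axis=1)
        cost = D[np.arange(n), np.asarray(medoids)[labels]].sum()
        best = (cost, None)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                lab = np.argmin(D[:, trial], axis=1)
                c = D[np.arange(n), np.asarray(trial)[lab]].sum()
                if c < best[0] - 1e-12:
                    best = (c, trial)
        if best[1] is None:
            break
        medoids = best[1]
    return np.argmin(D[:, medoids], axis=1)


def _cluster(points: np.ndarray, k: int, algorithm: str) -> np.ndarray:
    if algorithm == "kmedoids":
        return _pam(points, k)
    if algorithm == "kmeans":
        km = KMeans(n_clusters=k, n_init=10, random_state=0)
        return km.fit_predict(points)
    raise ValueError(f"unknown clustering algorithm {algorithm!r}")


def _variance_ratio(points: np.ndarray, labels: np.ndarray) -> float:
    """Between-cluster to within-cluster sum-of-squares ratio."""
    grand = points.mean(axis=0)
    bss = wss = 0.0
    for lab in np.unique(labels):
        sub = points[labels == lab]
        c = sub.mean(axis=0)
        bss += len(sub) * float(((c - grand) ** 2).sum())
        wss += float(((sub - c) ** 2).sum())
    if wss == 0:
        return np.inf if bss > 0 else 0.0
    return bss / wss


def classify_modality_kmeans(points: np.ndarray,
                             config: ModalityConfig | None = None) -> ModalityCall:
    """Modality of a 2D (blood, sperm) point cloud at one CpG site.

    Procedure: a generalized-ESD screen on Euclidean distances from the
    coordinate-wise median flags candidate outliers; k in ``candidate_k`` is
    chosen by the highest average silhouette width (k-medoids by default);
    a solution whose between/within variance ratio falls below
    ``variance_ratio_min`` is demoted (3 -> 2 -> unimodal).  A multimodal
    site is outlier-driven when its smallest cluster holds at most
    max(1, outlier_fraction_max * n) points; unimodal calls are never
    outlier-driven (there is no cluster structure to drive), though the ESD
    outlier indices are reported.
    """
    config = config or ModalityConfig()
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 8:
        return ModalityCall("indeterminate", 0, None, False, np.empty(0, int))
    center = np.median(points, axis=0)
    dist = np.sqrt(((points - center) ** 2).sum(axis=1))
    max_out = max(1, int(np.ceil(config.esd_max_fraction * n)))
    esd_out = generalized_esd(dist, max_out, config.esd_alpha)
    small_cap = config.max_small_group(n)

    best_k, best_labels, best_sil = 0, None, -np.inf
    for k in config.candidate_k:
        if k >= n:
            continue
        labels = _cluster(points, k, config.algorithm)
        if len(np.unique(labels)) < 2:
            continue
        sil = silhouette_score(points, labels)
        if sil > best_sil:
            best_k, best_labels, best_sil = k, labels, sil

    k, labels = best_k, best_labels
    while k >= 2:
        if labels is not None and _variance_ratio(points, labels) >= config.variance_ratio_min:
            break
        k -= 1
        labels = _cluster(points, k, config.algorithm) if k >= 2 else None

    if k < 2 or labels is None:
        # no multi-cluster structure at all -> nothing for outliers to drive
        return ModalityCall("unimodal", 1, None, False, esd_out)
    sizes = np.bincount(labels)
    outlier = sizes[sizes > 0].min() <= small_cap
    modality = {2: "bimodal", 3: "trimodal"}.get(k, "trimodal")
    return ModalityCall(modality, int(k), labels, bool(outlier), esd_out)


def gap_hunt(values: np.ndarray,
             config: ModalityConfig | None = None) -> ModalityCall:
    """1D gap-based modality call for one tissue at one CpG site.

    Sorts the values and opens a new group wherever consecutive sorted
    values differ by more than ``gap_cutoff`` (default 5% methylation).
    Group count of 3 or more is reported as trimodal (count retained in
    ``k``); a site is outlier-driven when any group holds at most
    max(1, outlier_fraction_max * n) points.
    """
    config = config or ModalityConfig()
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        return ModalityCall("unimodal", 1, np.zeros(n, int), False,
                            np.empty(0, int))
    order = np.argsort(x, kind="stable")
    gaps = np.diff(x[order]) > config.gap_cutoff
    group_sorted = np.concatenate([[0], np.cumsum(gaps)])
    labels = np.empty(n, dtype=int)
    labels[order] = group_sorted
    n_groups = int(group_sorted[-1]) + 1
    sizes = np.bincount(labels)
    outlier = n_groups > 1 and sizes.min() <= config.max_small_group(n)
    modality = {1: "unimodal", 2: "bimodal"}.get(n_groups, "trimodal")
    return ModalityCall(modality, n_groups, labels, bool(outlier),
                        np.empty(0, int))


def annotate_snps(
    snp_offsets: pd.Series,
    probe_type: pd.Series,
    footprint_bp: int = 50,
) -> pd.DataFrame:
    """Nearest-SNP distance and positional category per probe.

    ``snp_offsets`` holds per-probe offsets (bp from the interrogated CpG)
    as iterables or ';'-separated strings.  Categories: ``cpg_site`` when the
    nearest SNP hits the interrogated dinucleotide (offset 0/1 for Type II
    chemistry, exactly 0 for Type I), ``single_base_extension`` for the
    extension base (offset -1, Type I), ``probe_body`` otherwise, ``none``
    for probes without SNPs (distance = inf).
    """
    rows = []
    for probe in snp_offsets.index:
        raw = snp_offsets.loc[probe]
        if isinstance(raw, str):
            offs = [int(v) for v in raw.split(";") if v.strip() not in ("", "nan")]
        elif raw is None or (np.isscalar(raw) and pd.isna(raw)):
            offs = []
        else:
            offs = [int(v) for v in raw]
        ptype = probe_type.loc[probe]
        if any(abs(o) > footprint_bp for o in offs):
            raise ValueError(f"SNP offset outside probe footprint at {probe!r}")
        if not offs:
            rows.append((probe, np.inf, "none"))
            continue
        dist = min(abs(o) for o in offs)
        nearest = min(offs, key=abs)
        if ptype == "II":
            category = "cpg_site" if dist <= 1 else "probe_body"
        else:
            if dist == 0:
                category = "cpg_site"
            elif nearest == -1:
                category = "single_base_extension"
            else:
                category = "probe_body"
        rows.append((probe, float(dist), category))
    return pd.DataFrame(rows, columns=["probe", "distance", "category"]
                        ).set_index("probe")


def genetic_enrichment(
    correlated: pd.Index,
    background: pd.Index,
    flags: pd.Series,
    restrict_to_defined: bool = True,
) -> EnrichmentResult:
    """Fisher enrichment of a binary genetic annotation among correlated sites.

    ``background`` is the non-correlated variable probe set (must be disjoint
    from ``correlated``).  ``flags`` is a boolean Series indexed by the probes
    on which the annotation is defined; with ``restrict_to_defined`` both sets
    are first intersected with that index (needed for annotations defined
    only on a sub-array, e.g. 450K-derived mQTL lists).
    """
    correlated = pd.Index(correlated)
    background = pd.Index(background)
    if len(correlated.intersection(background)):
        raise ValueError("correlated and background sets overlap")
    if restrict_to_defined:
        correlated = correlated.intersection(flags.index)
        background = background.intersection(flags.index)
    if len(correlated) == 0 or len(background) == 0:
        raise ValueError("empty probe set after restriction")
    fl = flags.astype(bool)
    a = int(fl.reindex(correlated, fill_value=False).sum())
    b = len(correlated) - a
    c = int(fl.reindex(background, fill_value=False).sum())
    d = len(background) - c
    return _fisher("flag", a, b, c, d)
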