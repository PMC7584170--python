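"""Paired blood-vs-sperm differential methylation.

Site-wise: one paired t-test per probe across matched individuals, effect =
mean(sperm - blood) on the beta scale (positive = sperm hypermethylated),
two-sided p on n_pairs - 1 degrees of freedom.  Region-wise: the pairing unit
is the probe (its two cross-sample tissue medians), one test per region
class.  Significance defaults to the array-wide threshold P < 9e-8.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EPIC_ALPHA",
    "sitewise_paired_test",
    "regionwise_paired_test",
    "replication_concordance",
]

#: array-wide significance threshold for EPIC-scale analyses
EPIC_ALPHA = 9e-8


def _paired_t(diff: np.ndarray) -> tuple[float, float, int]:
    """(t, p, df) of a one-sample t-test on a difference vector (no NaNs)."""
    n = diff.size
    mean = diff.mean()
    sd = diff.std(ddof=1)
    if sd == 0:
        return (0.0, 1.0, n - 1) if mean == 0 else (np.inf * np.sign(mean), 0.0, n - 1)
    t = mean / (sd / np.sqrt(n))
    return float(t), float(2 * stats.t.sf(abs(t), n - 1)), n - 1


def sitewise_paired_test(
    beta_blood: pd.DataFrame,
    beta_sperm: pd.DataFrame,
    pairing: dict[str, tuple[str, str]] | None = None,
    alpha: float = EPIC_ALPHA,
) -> pd.DataFrame:
    """Paired t-test per probe across matched samples.

    ``pairing`` maps individual -> (blood column, sperm column); omitted
    means positional pairing.  Pairs with a missing value are dropped per
    probe (pairwise-complete); probes with < 4 complete pairs get p = NaN and
    are excluded from significance flags.
    """
    common = beta_blood.index.intersection(beta_sperm.index)
    if pairing is not None:
        bcols = [b for b, _ in pairing.values()]
        scols = [s for _, s in pairing.values()]
    else:
        if beta_blood.shape[1] != beta_sperm.shape[1]:
            raise ValueError("unequal sample counts and no pairing given")
        bcols, scols = list(beta_blood.columns), list(beta_sperm.columns)
    B = beta_blood.loc[common, bcols].to_numpy(dtype=float)
    S = beta_sperm.loc[common, scols].to_numpy(dtype=float)
    D = S - B

    valid = np.isfinite(D)
    n = valid.sum(axis=1)
    Dz = np.where(valid, D, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = Dz.sum(axis=1) / n
        ss = (np.where(valid, (D - mean[:, None]) ** 2, 0.0)).sum(axis=1)
        sd = np.sqrt(ss / np.maximum(n - 1, 1))
        t = mean / (sd / np.sqrt(n))
    df = n - 1
    p = 2 * stats.t.sf(np.abs(t), np.maximum(df, 1))
    # degenerate rows: all differences equal
    zero_sd = sd == 0
    t = np.where(zero_sd & (mean == 0), 0.0, t)
    p = np.where(zero_sd, np.where(mean == 0, 1.0, 0.0), p)
    too_few = n < 4
    p = np.where(too_few, np.nan, p)
    t = np.where(too_few, np.nan, t)
    sig = np.where(np.isnan(p), False, p < alpha)
    return pd.DataFrame(
        {
            "n_pairs": n,
            "effect": mean,
            "t": t,
            "df": df,
            "p": p,
            "significant": sig.astype(bool),
        },
        index=common,
    )


def regionwise_paired_test(
    beta_blood: pd.DataFrame,
    beta_sperm: pd.DataFrame,
    regions: pd.Series,
) -> pd.DataFrame:
    """Paired t-test of per-probe tissue medians within each region class.

    For every region label, each probe contributes its cross-sample median in
    sperm and in blood; the test pairs those two medians across the region's
    probes.  Effect = mean(median_sperm - median_blood).  Regions with < 4
    probes yield NaN with a warning.
    """
    common = beta_blood.index.intersection(beta_sperm.index)
    med_b = beta_blood.loc[common].median(axis=1)
    med_s = beta_sperm.loc[common].median(axis=1)
    regions = regions.reindex(common)
    rows = []
    for label in pd.unique(regions.dropna()):
        probes = common[regions == label]
        if len(probes) < 4:
            warnings.warn(f"region {label!r} has < 4 probes; NA")
            rows.append((str(label), len(probes), np.nan, np.nan, np.nan, np.nan))
            continue
        diff = (med_s.loc[probes] - med_b.loc[probes]).to_numpy()
        t, p, df = _paired_t(diff)
        rows.append((str(label), len(probes), float(diff.mean()), t, df, p))
    return pd.DataFrame(
        rows, columns=["region", "n_probes", "effect", "t", "df", "p"]
    ).set_index("region")


def replication_concordance(
    effects_a: pd.Series,
    effects_b: pd.Series,
    subset: pd.Index | None = None,
) -> tuple[float, float]:
    """Pearson correlation of per-probe effects between two cohorts.

    Computed over the intersection of ``subset`` (e.g. the discovery-
    significant probes) with both effect vectors; returns (r, p).
    """
    common = effects_a.dropna().index.intersection(effects_b.dropna().index)
    if subset is not None:
        common = common.intersection(subset)
    if len(common) < 3:
        raise ValueError("fewer than 3 shared probes for concordance")
    r, p = stats.pearsonr(effects_a.loc[common], effects_b.loc[common])
    return float(r), float(p)
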