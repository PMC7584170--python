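"""Probe and sample quality control for methylation-array beta matrices.

Probe filters (applied in the fixed order detection-p -> bead count ->
SNP-proximity -> exclusion lists, so per-filter counts are reproducible):

* detection-p: drop a probe when *more than* ``detp_sample_fraction`` of
  samples show detection p > ``detp_cutoff``;
* bead count: drop when bead count < ``beadcount_min`` in at least
  ``beadcount_sample_fraction`` of samples;
* SNP proximity: drop probes with an annotated SNP within
  ``snp_proximity_bp`` of the CpG site (when annotation is supplied);
* exclusion lists: externally curated probe-ID sets (cross-reactive probes,
  published SNP lists, ...).

Sample-level QC flags outliers on the leading principal components, and the
non-CpG SNP probes of the array are used to verify that two tissues paired to
the same individual really share a genotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "QcThresholds",
    "QcReport",
    "filter_probes",
    "detect_outlier_samples",
    "normalize_betas",
    "check_genotype_concordance",
]


@dataclass
class QcThresholds:
    detp_cutoff: float = 0.05
    detp_sample_fraction: float = 0.05
    beadcount_min: int = 3
    beadcount_sample_fraction: float = 0.05
    snp_proximity_bp: int = 10

    def __post_init__(self):
        for name in ("detp_sample_fraction", "beadcount_sample_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.beadcount_min < 1:
            raise ValueError("beadcount_min must be >= 1")


@dataclass
class QcReport:
    """Per-filter removal counts; filters were applied in ``order``."""

    n_input: int
    removed: dict[str, int] = field(default_factory=dict)
    order: tuple[str, ...] = ()
    retained: list[str] = field(default_factory=list)
    flagged_samples: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed": self.n_removed,
            "n_retained": self.n_retained,
            "removed": dict(self.removed),
            "order": list(self.order),
            "flagged_samples": list(self.flagged_samples),
            "notes": list(self.notes),
        }


def filter_probes(
    beta: pd.DataFrame,
    detp: pd.DataFrame | None = None,
    beads: pd.DataFrame | None = None,
    exclusion_lists: Mapping[str, Iterable[str]] | None = None,
    thresholds: QcThresholds | None = None,
    annotation: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, QcReport]:
    """Apply the probe filters to ``beta`` and return (filtered, report).

    ``detp``/``beads`` must share shape and indices with ``beta`` when given;
    a missing matrix skips that filter with a logged note.  ``annotation``
    (with a ``snp_offsets`` column of ';'-separated bp offsets) enables the
    SNP-proximity filter.  A probe is removed iff it fails any filter; counts
    attribute each probe to the first filter that removed it.
    """
    thresholds = thresholds or QcThresholds()
    report = QcReport(n_input=beta.shape[0])
    order: list[str] = []
    remaining = beta.index

    for name, mat in (("detp", detp), ("beads", beads)):
        if mat is not None and (mat.shape != beta.shape
                                or not mat.index.equals(beta.index)
                                or not mat.columns.equals(beta.columns)):
            raise ValueError(f"{name} matrix shape/indices differ from beta")

    if detp is not None:
        frac = (detp.loc[remaining] > thresholds.detp_cutoff).mean(axis=1)
        bad = remaining[frac > thresholds.detp_sample_fraction]
        report.removed["detp"] = len(bad)
        remaining = remaining.difference(bad, sort=False)
        order.append("detp")
    else:
        report.notes.append("detection-p matrix missing; filter skipped")
        warnings.warn("detection-p matrix missing; filter skipped")

    if beads is not None:
        frac = (beads.loc[remaining] < thresholds.beadcount_min).mean(axis=1)
        bad = remaining[frac >= thresholds.beadcount_sample_fraction]
        report.removed["beads"] = len(bad)
        remaining = remaining.difference(bad, sort=False)
        order.append("beads")
    else:
        report.notes.append("bead-count matrix missing; filter skipped")
        warnings.warn("bead-count matrix missing; filter skipped")

    if annotation is not None and "snp_offsets" in annotation.columns:
        offsets = annotation["snp_offsets"].reindex(remaining).fillna("")
        def _near(s: str) -> bool:
            vals = [int(v) for v in str(s).split(";") if v.strip() not in ("", "nan")]
            return any(abs(v) <= thresholds.snp_proximity_bp for v in vals)
        bad = remaining[[_near(s) for s in offsets]]
        report.removed["snp_proximity"] = len(bad)
        remaining = remaining.difference(bad, sort=False)
        order.append("snp_proximity")

    for name, probes in (exclusion_lists or {}).items():
        bad = remaining.intersection(pd.Index(list(probes)))
        report.removed[f"exclude:{name}"] = len(bad)
        remaining = remaining.difference(bad, sort=False)
        order.append(f"exclude:{name}")

    kept = beta.index[beta.index.isin(remaining)]  # original order
    report.order = tuple(order)
    report.retained = list(kept)
    report.notes.append(
        "bead filter convention: bead count < min in >= sample_fraction of samples")
    return beta.loc[kept], report


def _pc_scores(beta: pd.DataFrame, n_components: int = 2) -> np.ndarray | None:
    """Sample scores on the leading PCs (samples = columns of beta)."""
    X = beta.T.to_numpy(dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    if not np.any(X):
        return None
    k = min(n_components, min(X.shape) - 1) or 1
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    return U[:, :k] * S[:k]


def detect_outlier_samples(
    beta: pd.DataFrame,
    iqr_multiplier: float = 2.0,
    mad_multiplier: float = 5.0,
    combine: str = "intersection",
) -> list[str]:
    """Flag outlier samples on the leading principal components.

    Two rules: (1) PC1 score outside median +/- ``iqr_multiplier`` * IQR;
    (2) robust distance of the (PC1, PC2) score from the coordinate-wise
    median exceeding ``mad_multiplier`` MADs.  ``combine`` selects
    "intersection" (default: both must agree), "union", "iqr" or "mad".
    """
    if beta.shape[1] < 4:
        raise ValueError("need >= 4 samples for outlier detection")
    scores = _pc_scores(beta)
    if scores is None:
        warnings.warn("constant beta matrix: no principal components; no flags")
        return []
    pc1 = scores[:, 0]
    q1, med, q3 = np.percentile(pc1, [25, 50, 75])
    iqr = q3 - q1
    iqr_flags = np.abs(pc1 - med) > iqr_multiplier * iqr if iqr > 0 else (
        pc1 != med)

    center = np.median(scores, axis=0)
    dist = np.sqrt(((scores - center) ** 2).sum(axis=1))
    mad = np.median(np.abs(dist - np.median(dist)))
    if mad == 0:
        mad_flags = dist > 0
    else:
        mad_flags = np.abs(dist - np.median(dist)) > mad_multiplier * mad

    if combine == "intersection":
        flags = iqr_flags & mad_flags
    elif combine == "union":
        flags = iqr_flags | mad_flags
    elif combine == "iqr":
        flags = iqr_flags
    elif combine == "mad":
        flags = mad_flags
    else:
        raise ValueError(f"unknown combine rule {combine!r}")
    return sorted(np.asarray(beta.columns, dtype=object)[flags])


def normalize_betas(beta: pd.DataFrame, probe_type: pd.Series) -> pd.DataFrame:
    """Between-sample quantile normalization, stratified by probe type.

    Within each probe-type stratum every sample is mapped onto the stratum's
    mean quantile profile, so all samples share the identical sorted-value
    multiset per stratum while within-sample ranks are preserved.  This keeps
    the key property of type-aware array harmonisation (Type I and Type II
    chemistries are normalized separately) while operating on betas.
    """
    probe_type = probe_type.reindex(beta.index)
    if probe_type.isna().any():
        missing = list(beta.index[probe_type.isna()][:10])
        raise ValueError(f"unknown probe type for probes {missing}")
    bad = set(probe_type.unique()) - {"I", "II"}
    if bad:
        raise ValueError(f"unknown probe type label(s) {sorted(bad)}")
    if beta.shape[1] == 1:
        return beta.copy()
    out = beta.copy()
    for stratum in ("I", "II"):
        rows = beta.index[probe_type == stratum]
        if len(rows) == 0:
            continue
        X = beta.loc[rows].to_numpy(dtype=float)
        order = np.argsort(X, axis=0, kind="stable")
        ranks = np.empty_like(order)
        m = len(rows)
        ranks[order, np.arange(X.shape[1])[None, :]] = np.arange(m)[:, None]
        reference = np.sort(X, axis=0).mean(axis=1)
        out.loc[rows] = reference[ranks]
    return out


def check_genotype_concordance(
    beta_blood: pd.DataFrame,
    beta_sperm: pd.DataFrame,
    pairing: Mapping[str, tuple[str, str]] | None = None,
    r_min: float = 0.9,
) -> pd.DataFrame:
    """Verify paired samples share a genotype via SNP-probe betas.

    Inputs are beta matrices restricted to the array's genotyping (non-CpG
    SNP) probes.  ``pairing`` maps individual -> (blood column, sperm
    column); when omitted, columns are paired positionally.  A pair is
    concordant iff the Pearson r of its SNP-probe betas >= ``r_min``;
    constant vectors give the verdict "indeterminate".
    """
    common = beta_blood.index.intersection(beta_sperm.index)
    if len(common) < 5:
        raise ValueError("need >= 5 shared SNP probes")
    if pairing is None:
        if beta_blood.shape[1] != beta_sperm.shape[1]:
            raise ValueError("unequal sample counts and no pairing given")
        pairing = {f"pair{i}": (b, s) for i, (b, s) in
                   enumerate(zip(beta_blood.columns, beta_sperm.columns))}
    rows = []
    for ind, (bcol, scol) in pairing.items():
        if bcol not in beta_blood.columns or scol not in beta_sperm.columns:
            raise ValueError(f"pairing for {ind!r} references missing samples")
        x = beta_blood.loc[common, bcol].to_numpy(dtype=float)
        y = beta_sperm.loc[common, scol].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append((ind, np.nan, "indeterminate"))
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        rows.append((ind, r, "concordant" if r >= r_min else "discordant"))
    return pd.DataFrame(rows, columns=["individual", "r", "verdict"])
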