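"""Epigenetic clocks: DNAm-age prediction, age acceleration, trait associations.

A clock is a sparse linear model over beta values plus an output transform.
The ``log-linear-age`` transform is the piecewise calibration commonly used for
pan-tissue age estimators: ages below ``adult_age`` are modelled on a log scale
(fast epigenetic change during development), adult ages linearly.  Age
acceleration is the residual of DNAm age regressed on chronological age
(optionally with covariates such as estimated blood cell fractions), so a
positive value means "epigenetically older than expected".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClockDefinition",
    "apply_clock",
    "age_acceleration",
    "acceleration_associations",
    "acceleration_association_grid",
    "age_transform",
    "age_inverse_transform",
    "read_clock_csv",
    "write_clock_csv",
]


@dataclass
class ClockDefinition:
    """A linear epigenetic clock.

    Parameters
    ----------
    name : clock label used in outputs.
    intercept : intercept of the linear predictor.
    coefficients : probe -> weight map (pandas Series indexed by probe ID).
    transform : "identity" or "log-linear-age".
    adult_age : breakpoint (years) of the log-linear transform.
    """

    name: str
    intercept: float
    coefficients: pd.Series
    transform: str = "identity"
    adult_age: float = 20.0

    def __post_init__(self):
        self.coefficients = pd.Series(self.coefficients, dtype=float)
        if len(self.coefficients) == 0:
            raise ValueError("clock has no coefficients")
        if self.transform not in ("identity", "log-linear-age"):
            raise ValueError(f"unknown transform {self.transform!r}")


def age_transform(age, adult_age: float = 20.0):
    """Forward log-linear age transform (years -> linear-predictor scale)."""
    age = np.asarray(age, dtype=float)
    lo = np.log(age + 1.0) - np.log(adult_age + 1.0)
    hi = (age - adult_age) / (adult_age + 1.0)
    return np.where(age < adult_age, lo, hi)


def age_inverse_transform(s, adult_age: float = 20.0):
    """Inverse of :func:`age_transform` (linear predictor -> years)."""
    s = np.asarray(s, dtype=float)
    lo = (1.0 + adult_age) * np.exp(s) - 1.0
    hi = (1.0 + adult_age) * s + adult_age
    return np.where(s < 0, lo, hi)


def apply_clock(beta: pd.DataFrame, clock: ClockDefinition,
                min_presence: float = 0.8) -> pd.Series:
    """Predict DNAm age (years) for every sample (column) of ``beta``.

    Probes with missing cells are imputed by their cohort mean; probes absent
    from the matrix entirely are imputed at beta = 0.5 with a warning.  Fails
    if fewer than ``min_presence`` of the clock's probes are present.
    """
    probes = clock.coefficients.index
    present = probes.intersection(beta.index)
    frac = len(present) / len(probes)
    if frac < min_presence:
        missing = sorted(probes.difference(beta.index))
        raise ValueError(
            f"only {frac:.0%} of clock probes present (need >= {min_presence:.0%}); "
            f"missing: {missing[:20]}{'...' if len(missing) > 20 else ''}"
        )
    sub = beta.reindex(probes)
    absent = probes.difference(beta.index)
    if len(absent):
        warnings.warn(
            f"{len(absent)} clock probes absent from matrix; imputed at beta=0.5"
        )
        sub.loc[absent] = 0.5
    if sub.isna().any().any():
        sub = sub.apply(lambda row: row.fillna(row.mean()), axis=1)
    s = clock.intercept + sub.T.to_numpy() @ clock.coefficients.to_numpy()
    if clock.transform == "log-linear-age":
        s = age_inverse_transform(s, clock.adult_age)
    return pd.Series(s, index=beta.columns, name=f"dnam_age_{clock.name}")


def age_acceleration(dnam_age: pd.Series, chron_age: pd.Series,
                     covariates: pd.DataFrame | None = None) -> pd.Series:
    """Residual-based age acceleration (years).

    OLS of DNAm age on chronological age (plus optional covariates, e.g.
    estimated cell fractions); the residuals are orthogonal to the regressors
    and sum to zero.
    """
    idx = dnam_age.index.intersection(chron_age.index)
    if covariates is not None:
        idx = idx.intersection(covariates.index)
    if len(idx) < 4:
        raise ValueError("need >= 4 samples for the acceleration regression")
    y = dnam_age.loc[idx].to_numpy(dtype=float)
    x = chron_age.loc[idx].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("chronological age is constant; residuals undefined")
    cols = [np.ones_like(x), x]
    if covariates is not None:
        cols.extend(covariates.loc[idx, c].to_numpy(dtype=float)
                    for c in covariates.columns)
    X = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return pd.Series(resid, index=idx, name="age_acceleration")


def _simple_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Slope, se, t, two-sided p of y ~ 1 + x, with degenerate-fit conventions."""
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        return np.nan, np.nan, np.nan, np.nan
    slope = float(xc @ yc) / sxx
    resid = yc - slope * xc
    rss = float(resid @ resid)
    if rss <= 0 or n <= 2:
        # degenerate: perfectly flat or perfectly collinear fit
        if slope == 0.0:
            return 0.0, 0.0, 0.0, 1.0
        return slope, 0.0, np.inf, 0.0
    se = np.sqrt(rss / (n - 2) / sxx)
    t = slope / se
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return slope, se, t, p


def acceleration_associations(acceleration: pd.Series,
                              traits: pd.DataFrame) -> pd.DataFrame:
    """Regress age acceleration onto each trait column separately.

    Returns one row per trait: slope (years per trait unit), se, t, p, n.
    Constant traits yield NaN; an all-zero acceleration vector yields the
    slope 0 / p 1 degenerate convention.
    """
    idx = acceleration.index.intersection(traits.index)
    accel = acceleration.loc[idx].to_numpy(dtype=float)
    rows = []
    for trait in traits.columns:
        x = traits.loc[idx, trait].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(accel)
        if ok.sum() < 4 or np.ptp(x[ok]) == 0:
            rows.append((trait, np.nan, np.nan, np.nan, np.nan, int(ok.sum())))
            continue
        slope, se, t, p = _simple_slope(x[ok], accel[ok])
        rows.append((trait, slope, se, t, p, int(ok.sum())))
    return pd.DataFrame(rows, columns=["trait", "slope", "se", "t", "p", "n"])


def acceleration_association_grid(accelerations: dict[tuple[str, str], pd.Series],
                                  traits: pd.DataFrame) -> pd.DataFrame:
    """Trait-association grid over (clock, tissue) combinations.

    ``accelerations`` maps (clock_name, tissue) -> acceleration Series; the
    output stacks one association table per combination (the study layout is
    5 traits x 5 clock/tissue combinations = 25 tests).
    """
    frames = []
    for (clock_name, tissue), accel in accelerations.items():
        tab = acceleration_associations(accel, traits)
        tab.insert(0, "tissue", tissue)
        tab.insert(0, "clock", clock_name)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# clock CSV format: '#key=value' header block, then probe_id,coefficient rows


def write_clock_csv(clock: ClockDefinition, path: str | Path) -> None:
    lines = [
        f"#name={clock.name}",
        f"#intercept={clock.intercept!r}",
        f"#transform={clock.transform}",
        f"#adult_age={clock.adult_age!r}",
        "probe_id,coefficient",
    ]
    for probe, coef in clock.coefficients.items():
        lines.append(f"{probe},{coef!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_clock_csv(path: str | Path) -> ClockDefinition:
    meta = {}
    rows = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            key, _, val = line[1:].partition("=")
            meta[key.strip()] = val.strip()
        elif line and not line.startswith("probe_id"):
            probe, _, coef = line.partition(",")
            rows.append((probe, float(coef)))
    coefs = pd.Series(dict(rows))
    return ClockDefinition(
        name=meta.get("name", "clock"),
        intercept=float(meta.get("intercept", 0.0)),
        coefficients=coefs,
        transform=meta.get("transform", "identity"),
        adult_age=float(meta.get("adult_age", 20.0)),
    )
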