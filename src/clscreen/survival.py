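"""Survival curves, the area-under-curve longevity statistic, and averages.

Each strain×replicate's viability fractions are normalized to the
logarithmic-phase sample (day 0), which is defined as 100% viable; the
area under the resulting piecewise-linear survival curve (trapezoidal rule,
units %·days) is the screen's longevity score. Replicate curves of one
strain are summarised by a locally weighted polynomial regression (loess)
with a pointwise 95% confidence band, and strains that never grew (no
viable day-0 sample) or lost all stationary-phase samples to QC are
excluded with a logged reason.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "SurvivalCurve",
    "AreaStatistic",
    "normalize_curve",
    "curves_from_viability",
    "area_under_curve",
    "areas_table",
    "LoessAverager",
    "average_curve",
    "exclude_strains",
]


@dataclass(frozen=True)
class SurvivalCurve:
    """% survival vs day for one strain×replicate, anchored at 100% at day 0.

    Values above 100% after normalization (measurement noise) are retained
    and flagged via ``over_100`` — clamping would bias areas downward.
    """

    strain: str
    replicate: str
    days: np.ndarray
    survival: np.ndarray  # percent

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        surv = np.asarray(self.survival, dtype=float)
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "survival", surv)
        if days.size != surv.size or days.size < 1:
            raise ValueError("days and survival must be equal-length, non-empty")
        if days[0] != 0.0:
            raise ValueError("first point must be the day-0 (log) sample")
        if np.any(np.diff(days) <= 0):
            raise ValueError("days must be strictly increasing")
        if surv[0] != 100.0:
            raise ValueError("survival at day 0 must be exactly 100")
        if np.any(surv < 0):
            raise ValueError("survival must be non-negative")

    @property
    def over_100(self) -> bool:
        return bool(np.any(self.survival[1:] > 100.0))


@dataclass(frozen=True)
class AreaStatistic:
    """Trapezoidal area under one survival curve, in %·days."""

    strain: str
    replicate: str
    area: float
    span: tuple[float, float]


def normalize_curve(
    points: pd.DataFrame, strain: str = "", replicate: str = ""
) -> SurvivalCurve:
    """Normalize viability fractions to % survival relative to day 0.

    ``points`` needs columns ``day`` and ``fraction_viable``; rows with
    ``qc_pass == False`` are dropped first. survival(t) = 100·f(t)/f(0).

    Raises
    ------
    ValueError
        If no day-0 point survives QC or f(0) = 0 (strain unusable: it
        showed no growth at the logarithmic sample).
    """
    df = points
    if "qc_pass" in df.columns:
        df = df[df["qc_pass"].astype(bool)]
    df = df.sort_values("day")
    days = df["day"].to_numpy(dtype=float)
    frac = df["fraction_viable"].to_numpy(dtype=float)
    if days.size == 0 or days[0] != 0.0:
        raise ValueError(f"strain {strain!r}: missing day-0 (log) sample")
    if frac[0] <= 0.0:
        raise ValueError(f"strain {strain!r}: no viable cells at day 0 (no growth)")
    # divide first so the day-0 anchor is exactly 100 in floating point
    return SurvivalCurve(strain, replicate, days, frac / frac[0] * 100.0)


def curves_from_viability(
    viability: pd.DataFrame, replicate_cols: tuple[str, ...] = ("plate", "well")
) -> tuple[list[SurvivalCurve], pd.DataFrame]:
    """Assemble one curve per strain×replicate from a viability table.

    Returns ``(curves, failures)``; ``failures`` lists strain/replicate
    pairs that could not be normalized, with the reason.
    """
    curves: list[SurvivalCurve] = []
    failures = []
    keys = ["strain", *replicate_cols]
    for key, grp in viability.groupby(keys, observed=True, sort=True):
        strain, rep = str(key[0]), "/".join(str(k) for k in key[1:])
        try:
            curves.append(normalize_curve(grp, strain=strain, replicate=rep))
        except ValueError as err:
            failures.append({"strain": strain, "replicate": rep, "reason": str(err)})
    return curves, pd.DataFrame(failures, columns=["strain", "replicate", "reason"])


def area_under_curve(curve: SurvivalCurve) -> AreaStatistic:
    """Trapezoidal area over the observed days (no extrapolation)."""
    if curve.days.size < 2:
        raise ValueError("need at least 2 points to integrate")
    area = float(np.trapezoid(curve.survival, curve.days))
    return AreaStatistic(
        curve.strain, curve.replicate, area, (float(curve.days[0]), float(curve.days[-1]))
    )


def areas_table(curves: list[SurvivalCurve]) -> pd.DataFrame:
    """Areas of many curves as a tidy table."""
    stats = [area_under_curve(c) for c in curves]
    return pd.DataFrame(
        {
            "strain": [s.strain for s in stats],
            "replicate": [s.replicate for s in stats],
            "area": [s.area for s in stats],
            "span_start": [s.span[0] for s in stats],
            "span_end": [s.span[1] for s in stats],
        }
    )


class LoessAverager(BaseEstimator, RegressorMixin):
    """Locally weighted polynomial regression with pointwise 95% bands.

    At each prediction point the nearest ``ceil(span·n)`` observations get
    tricube weights and a degree-``degree`` weighted least-squares
    polynomial is fitted; the prediction is a linear smoother l(x)'y, so
    its standard error is sigma·||l(x)|| with sigma² estimated from the
    smoother's residuals (df = n − tr(L)). With zero residual variance
    (identical replicates) the band has zero width.

    Parameters
    ----------
    span : float in (0, 1], default 0.75
        Fraction of points in each local neighbourhood.
    degree : int, default 2
        Local polynomial degree.
    conf : float, default 0.95
        Band coverage; the band is fit ± z·SE with z the normal quantile.
    """

    def __init__(self, span: float = 0.75, degree: int = 2, conf: float = 0.95):
        self.span = span
        self.degree = degree
        self.conf = conf

    def _smoother_row(self, x0: float) -> np.ndarray:
        """Equivalent-kernel weights l(x0) with l(x0)'y the fitted value."""
        x, n, deg = self._x, self._x.size, self.degree
        d = np.abs(x - x0)
        q = max(deg + 1, int(np.ceil(self.span * n)))
        q = min(q, n)
        dmax = np.partition(d, q - 1)[q - 1]
        if dmax == 0:
            w = (d == 0).astype(float)
        else:
            w = np.clip(1.0 - (d / dmax) ** 3, 0.0, None) ** 3
        # a neighbourhood with few distinct x cannot support the full degree;
        # drop to an exactly identifiable local polynomial there
        n_distinct = np.unique(x[w > 0]).size
        deg_eff = min(deg, max(n_distinct - 1, 0))
        X = np.vander(x - x0, deg_eff + 1, increasing=True)
        XtW = X.T * w
        beta_map = np.linalg.pinv(XtW @ X) @ XtW
        return beta_map[0]

    def fit(self, X, y) -> "LoessAverager":
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.size != y.size or x.size < self.degree + 1:
            raise ValueError("need at least degree+1 observations")
        if not 0 < self.span <= 1:
            raise ValueError("span must be in (0, 1]")
        order = np.argsort(x, kind="stable")
        self._x, self._y = x[order], y[order]
        n = x.size
        L = np.vstack([self._smoother_row(xi) for xi in self._x])
        fitted = L @ self._y
        resid = self._y - fitted
        df = n - np.trace(L)
        self.sigma2_ = float(resid @ resid / df) if df > 0 else 0.0
        if self.sigma2_ < 0:
            self.sigma2_ = 0.0
        self.n_obs_ = n
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "sigma2_")
        grid = np.asarray(X, dtype=float).reshape(-1)
        return np.array([self._smoother_row(g) @ self._y for g in grid])

    def predict_band(self, X) -> pd.DataFrame:
        """Fit and lower/upper confidence band on a grid."""
        from scipy.stats import norm

        check_is_fitted(self, "sigma2_")
        grid = np.asarray(X, dtype=float).reshape(-1)
        fit = np.empty_like(grid)
        se = np.empty_like(grid)
        for i, g in enumerate(grid):
            l = self._smoother_row(g)
            fit[i] = l @ self._y
            se[i] = np.sqrt(self.sigma2_ * (l @ l))
        z = norm.ppf(0.5 + self.conf / 2)
        return pd.DataFrame(
            {"day": grid, "fitted": fit, "lower": fit - z * se, "upper": fit + z * se}
        )


def average_curve(
    curves: list[SurvivalCurve],
    span: float = 0.75,
    degree: int = 2,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Loess average of one strain's replicate curves with a 95% band.

    Pools all (day, survival) points across replicates; requires at least
    two replicates of the same strain. Returns a table with columns day,
    fitted, lower, upper plus ``strain`` and ``n_replicates``.
    """
    if len(curves) < 2:
        raise ValueError("need at least 2 replicate curves (band undefined otherwise)")
    strains = {c.strain for c in curves}
    if len(strains) > 1:
        raise ValueError(f"curves mix strains: {sorted(strains)}")
    x = np.concatenate([c.days for c in curves])
    y = np.concatenate([c.survival for c in curves])
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 81)
    model = LoessAverager(span=span, degree=degree).fit(x, y)
    out = model.predict_band(grid)
    out.insert(0, "strain", next(iter(strains)))
    out["n_replicates"] = len(curves)
    return out


def exclude_strains(
    viability: pd.DataFrame, growth_flags: dict[str, bool] | None = None
) -> tuple[set[str], pd.DataFrame]:
    """Apply the screen's exclusion rule: drop strains that never grew.

    A strain is excluded when its growth flag is False (no growth or no
    regrowth in stationary phase, supplied externally), when it has no
    viable day-0 sample, or when every post-day-0 sample failed QC.

    Returns ``(retained, log)`` where ``log`` has columns strain, reason.
    """
    growth_flags = growth_flags or {}
    log = []
    retained: set[str] = set()
    for strain, grp in viability.groupby("strain", observed=True, sort=True):
        strain = str(strain)
        if not growth_flags.get(strain, True):
            log.append({"strain": strain, "reason": "no growth or regrowth"})
            continue
        ok = grp["qc_pass"].astype(bool) if "qc_pass" in grp.columns else True
        grp_ok = grp[ok]
        day0 = grp_ok[grp_ok["day"] == 0.0]
        if day0.empty or not (day0["fraction_viable"] > 0).any():
            log.append({"strain": strain, "reason": "no growth"})
            continue
        if grp_ok[grp_ok["day"] > 0.0].empty:
            log.append({"strain": strain, "reason": "all stationary samples failed QC"})
            continue
        retained.add(strain)
    return retained, pd.DataFrame(log, columns=["strain", "reason"])
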