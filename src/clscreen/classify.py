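"""Bayesian three-class longevity assignment against control distributions.

The screen defines three longevity classes from the control strains present
on every plate — average (wild type), short-lived and long-lived — by
fitting the distribution of their area-under-survival-curve statistics.
Each mutant starts with an equal prior over the three classes; the prior is
reallocated by the likelihood of the mutant's area under each control
distribution, and the mutant is assigned to the class with the highest
posterior.

The class likelihood is the Student-t posterior-predictive density for a
new observation from a normal population with unknown mean and variance
estimated from n control replicates: a location-scale t with df = n − 1,
location = sample mean, scale = sd·sqrt(1 + 1/n). This is the
distributional core of the t-test used generatively. A plain-Gaussian mode
is available for sensitivity analysis. All density work happens in log
space so extreme areas cannot underflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import t as student_t, norm
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ControlDistribution",
    "LongevityClassifier",
    "fit_controls",
    "class_likelihood",
    "posterior",
    "classify_screen",
    "CLASS_LABELS",
]

#: Canonical class order used throughout outputs.
CLASS_LABELS = ("average", "short_lived", "long_lived")


@dataclass(frozen=True)
class ControlDistribution:
    """Fitted area distribution of one control class (n, mean, sd)."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"{self.label}: need >= 2 control replicates, got {self.n}")
        if not self.sd > 0:
            raise ValueError(f"{self.label}: degenerate distribution (sd = {self.sd})")

    @property
    def df(self) -> int:
        return self.n - 1

    @property
    def predictive_scale(self) -> float:
        """Scale of the t posterior predictive: sd·sqrt(1 + 1/n)."""
        return self.sd * float(np.sqrt(1.0 + 1.0 / self.n))


def fit_controls(areas_by_label: dict[str, np.ndarray]) -> dict[str, ControlDistribution]:
    """Sample mean and sd (n−1 denominator) of each control class's areas."""
    dists = {}
    for label, areas in areas_by_label.items():
        x = np.asarray(areas, dtype=float)
        if x.size < 2:
            raise ValueError(f"{label}: need >= 2 control areas, got {x.size}")
        dists[label] = ControlDistribution(
            label, int(x.size), float(x.mean()), float(x.std(ddof=1))
        )
    return dists


def class_log_likelihood(
    area, dist: ControlDistribution, likelihood: str = "t"
) -> np.ndarray:
    """Log density of an area under one class's predictive distribution."""
    x = np.asarray(area, dtype=float)
    if likelihood == "t":
        s = dist.predictive_scale
        return student_t.logpdf((x - dist.mean) / s, df=dist.df) - np.log(s)
    if likelihood == "normal":
        return norm.logpdf(x, loc=dist.mean, scale=dist.sd)
    raise ValueError(f"unknown likelihood {likelihood!r}")


def class_likelihood(area, dist: ControlDistribution, likelihood: str = "t"):
    """Density (not log) of an area under one class; strictly positive."""
    return np.exp(class_log_likelihood(area, dist, likelihood))


def posterior(
    area: float,
    dists: dict[str, ControlDistribution],
    priors: dict[str, float] | None = None,
    likelihood: str = "t",
    tie_epsilon: float = 1e-6,
) -> dict:
    """Posterior over classes for one area; assignment by maximum posterior.

    Equal priors by default. Classes with prior 0 are unreachable. When the
    top two posteriors differ by less than ``tie_epsilon`` the strain is
    flagged ambiguous and conservatively assigned ``average`` if that class
    is among the tied ones.
    """
    labels = list(dists)
    if priors is None:
        priors = {lb: 1.0 / len(labels) for lb in labels}
    p = np.array([priors[lb] for lb in labels], dtype=float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("priors must be non-negative and sum to 1")
    with np.errstate(divide="ignore"):
        log_post = np.log(p) + np.array(
            [class_log_likelihood(area, dists[lb], likelihood) for lb in labels]
        )
    finite = np.isfinite(log_post)
    if not finite.any():
        raise ValueError("posterior degenerate: no class has positive mass")
    log_z = logsumexp(log_post[finite])
    post = np.where(finite, np.exp(log_post - log_z), 0.0)
    order = np.argsort(post)[::-1]
    ambiguous = post[order[0]] - post[order[1]] < tie_epsilon if len(post) > 1 else False
    if ambiguous and "average" in labels:
        tied = [labels[i] for i in order if post[order[0]] - post[i] < tie_epsilon]
        assigned = "average" if "average" in tied else labels[order[0]]
    else:
        assigned = labels[order[0]]
    return {
        "posterior": dict(zip(labels, post)),
        "label": assigned,
        "ambiguous": bool(ambiguous),
    }


class LongevityClassifier(BaseEstimator, ClassifierMixin):
    """Assign strains to longevity classes by maximum posterior probability.

    Fit on control areas (X) with their class labels (y); predict on mutant
    areas. Follows the scikit-learn classifier protocol, so it composes
    with pipelines and model-selection utilities.

    Parameters
    ----------
    priors : dict label -> float, optional
        Class priors; equal by default.
    likelihood : {'t', 'normal'}, default 't'
        Predictive density family ('t' = location-scale Student t with
        df = n − 1 and scale sd·sqrt(1 + 1/n)).
    tie_epsilon : float, default 1e-6
        Posterior gap below which an assignment is flagged ambiguous.

    Attributes
    ----------
    classes_ : ndarray of class labels (sorted)
    distributions_ : dict label -> ControlDistribution
    """

    def __init__(
        self,
        priors: dict[str, float] | None = None,
        likelihood: str = "t",
        tie_epsilon: float = 1e-6,
    ):
        self.priors = priors
        self.likelihood = likelihood
        self.tie_epsilon = tie_epsilon

    def fit(self, X, y) -> "LongevityClassifier":
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y)
        if x.size != y.size or x.size == 0:
            raise ValueError("X and y must be equal-length and non-empty")
        self.classes_ = np.unique(y)
        self.distributions_ = fit_controls(
            {str(lb): x[y == lb] for lb in self.classes_}
        )
        return self

    def _priors(self) -> dict[str, float]:
        if self.priors is None:
            k = len(self.classes_)
            return {str(lb): 1.0 / k for lb in self.classes_}
        return dict(self.priors)

    def predict_log_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "distributions_")
        x = np.asarray(X, dtype=float).reshape(-1)
        priors = self._priors()
        with np.errstate(divide="ignore"):
            ll = np.column_stack(
                [
                    np.log(priors[str(lb)])
                    + class_log_likelihood(
                        x, self.distributions_[str(lb)], self.likelihood
                    )
                    for lb in self.classes_
                ]
            )
        return ll - logsumexp(ll, axis=1, keepdims=True)

    def predict_proba(self, X) -> np.ndarray:
        return np.exp(self.predict_log_proba(X))

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        labels = self.classes_[np.argmax(proba, axis=1)].astype(object)
        # conservative tie handling: near-ties fall back to 'average'
        srt = np.sort(proba, axis=1)
        ambiguous = srt[:, -1] - srt[:, -2] < self.tie_epsilon
        if "average" in self.classes_ and ambiguous.any():
            labels[ambiguous] = "average"
        return np.asarray(labels)


def classify_screen(
    areas: pd.DataFrame,
    control_strains: dict[str, str] | None = None,
    priors: dict[str, float] | None = None,
    likelihood: str = "t",
    tie_epsilon: float = 1e-6,
) -> tuple[pd.DataFrame, pd.Series]:
    """Classify every strain of a screen from its replicate areas.

    Parameters
    ----------
    areas : DataFrame with columns strain, area (one row per replicate).
    control_strains : dict class label -> strain name
        Which strains define each control distribution (e.g.
        ``{"average": "666", "short_lived": "sty1d", "long_lived": "pka1d"}``).
        Defaults to those names.
    priors, likelihood, tie_epsilon : see :class:`LongevityClassifier`.

    Returns
    -------
    table, counts
        ``table`` has one row per non-control strain: strain, n_reps,
        area_mean, p_<class>..., label, ambiguous (replicate areas are
        averaged before classification). ``counts`` is label -> n.
    """
    if areas.empty:
        raise ValueError("empty area table")
    from clscreen.syndata import CONTROL_STRAINS

    control_strains = control_strains or dict(CONTROL_STRAINS)
    by_label = {}
    for label, strain in control_strains.items():
        sel = areas.loc[areas["strain"] == strain, "area"].to_numpy()
        if sel.size < 2:
            raise ValueError(
                f"control strain {strain!r} ({label}) has {sel.size} areas; need >= 2"
            )
        by_label[label] = sel
    dists = fit_controls(by_label)

    control_names = set(control_strains.values())
    mutants = areas[~areas["strain"].isin(control_names)]
    summary = (
        mutants.groupby("strain", observed=True, sort=True)["area"]
        .agg(n_reps="size", area_mean="mean")
        .reset_index()
    )
    clf = LongevityClassifier(
        priors=priors, likelihood=likelihood, tie_epsilon=tie_epsilon
    )
    labels_sorted = sorted(dists)
    clf.classes_ = np.asarray(labels_sorted)
    clf.distributions_ = dists
    proba = clf.predict_proba(summary["area_mean"].to_numpy())
    labels = clf.predict(summary["area_mean"].to_numpy())
    srt = np.sort(proba, axis=1)
    table = summary.copy()
    for j, lb in enumerate(labels_sorted):
        table[f"p_{lb}"] = proba[:, j]
    table["label"] = labels
    table["ambiguous"] = srt[:, -1] - srt[:, -2] < tie_epsilon
    counts = table["label"].value_counts().reindex(
        [lb for lb in CLASS_LABELS if lb in labels_sorted], fill_value=0
    )
    return table, counts
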