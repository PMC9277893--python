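"""PI-gating of flow-cytometry events into per-sample viability.

Propidium iodide only stains cells with compromised membranes, so on the
red (PE-A-like) channel dead cells form a bright population and live cells
a dim one. Gating places a single intensity threshold between the two;
events below it count as viable. The default threshold is Otsu's criterion
on pooled log10 intensities across a whole plate batch — pooling keeps
fully dead samples (a single population on their own) gateable — with a
fixed user threshold as override.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["PIGater", "gate_threshold", "fraction_viable", "qc_sample", "read_events_tsv"]

EVENT_COLUMNS = ("plate", "well", "strain", "day", "pi_intensity")


def _check_intensities(intensities: np.ndarray) -> np.ndarray:
    x = np.asarray(intensities, dtype=float)
    if x.size < 1:
        raise ValueError("empty sample: no events")
    if not np.all(x > 0):
        raise ValueError("PI intensities must be positive (log-transform domain)")
    return x


def gate_threshold(intensities, method: str = "otsu") -> float:
    """Estimate the live/dead intensity threshold (linear a.u.).

    ``method='otsu'`` maximises between-class variance of the pooled log10
    intensities (256-bin histogram); the returned threshold is mapped back
    to linear units and lies strictly between the observed min and max.
    """
    x = _check_intensities(intensities)
    if np.unique(x).size < 2:
        raise ValueError("constant intensities: no separable populations")
    if method != "otsu":
        raise ValueError(f"unknown gating method {method!r}")
    log_thr = threshold_otsu(np.log10(x), nbins=256)
    thr = float(10.0 ** log_thr)
    # Histogram-bin edges can land on the extremes; nudge inside the range.
    lo, hi = float(x.min()), float(x.max())
    return min(max(thr, np.nextafter(lo, hi)), np.nextafter(hi, lo))


def fraction_viable(sample: pd.DataFrame | np.ndarray, threshold: float) -> dict:
    """Gate one sample: events with intensity < threshold are viable.

    ``sample`` is either an intensity array or an event-table slice with a
    ``pi_intensity`` column (plus plate/well/strain/day metadata, echoed
    back). Returns a ViabilityPoint-like dict.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    meta = {}
    if isinstance(sample, pd.DataFrame):
        for col in ("strain", "plate", "well", "day"):
            if col in sample.columns:
                vals = sample[col].unique()
                if len(vals) != 1:
                    raise ValueError(f"sample mixes multiple values of {col!r}")
                meta[col] = vals[0]
        x = _check_intensities(sample["pi_intensity"].to_numpy())
    else:
        x = _check_intensities(sample)
    n = x.size
    return {
        **meta,
        "fraction_viable": float(np.count_nonzero(x < threshold)) / n,
        "n_events": int(n),
    }


def qc_sample(n_events: int, min_events: int = 5_000) -> bool:
    """Sample-level QC: enough recorded events to trust the fraction."""
    return int(n_events) >= int(min_events)


def read_events_tsv(path) -> pd.DataFrame:
    """Read the long-format event TSV, rejecting non-positive intensities."""
    df = pd.read_csv(path, sep="\t")
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event table missing columns {sorted(missing)}")
    if not (df["pi_intensity"] > 0).all():
        raise ValueError("event table contains non-positive PI intensities")
    return df


class PIGater(BaseEstimator, TransformerMixin):
    """Gate an event table into per-sample viability fractions.

    Parameters
    ----------
    threshold : 'otsu' or float, default 'otsu'
        'otsu' fits a global threshold on the pooled log10 intensities at
        ``fit`` time; a float is used verbatim (no estimation).
    min_events : int, default 5000
        Samples with fewer events fail QC (``qc_pass=False``); downstream
        curve assembly drops them, it never imputes.

    Attributes
    ----------
    threshold_ : float
        The gating threshold in linear intensity units.
    """

    def __init__(self, threshold: str | float = "otsu", min_events: int = 5_000):
        self.threshold = threshold
        self.min_events = min_events

    def fit(self, events: pd.DataFrame, y=None) -> "PIGater":
        if isinstance(self.threshold, str):
            self.threshold_ = gate_threshold(
                events["pi_intensity"].to_numpy(), method=self.threshold
            )
        else:
            thr = float(self.threshold)
            if not np.isfinite(thr):
                raise ValueError("fixed threshold must be finite")
            self.threshold_ = thr
        return self

    def transform(self, events: pd.DataFrame) -> pd.DataFrame:
        """Per-(plate, well, strain, day) viability table.

        Columns: plate, well, strain, day, fraction_viable, n_events,
        qc_pass.
        """
        check_is_fitted(self, "threshold_")
        x = events["pi_intensity"].to_numpy()
        if x.size and not np.all(x > 0):
            raise ValueError("event table contains non-positive PI intensities")
        viable = x < self.threshold_
        grouped = (
            pd.DataFrame(
                {
                    "plate": events["plate"],
                    "well": events["well"],
                    "strain": events["strain"],
                    "day": events["day"],
                    "viable": viable,
                }
            )
            .groupby(["plate", "well", "strain", "day"], observed=True, sort=True)
            .agg(n_viable=("viable", "sum"), n_events=("viable", "size"))
            .reset_index()
        )
        grouped["fraction_viable"] = grouped["n_viable"] / grouped["n_events"]
        grouped["qc_pass"] = grouped["n_events"] >= self.min_events
        out = grouped[
            ["plate", "well", "strain", "day", "fraction_viable", "n_events", "qc_pass"]
        ].copy()
        for col in ("plate", "well", "strain"):
            if isinstance(out[col].dtype, pd.CategoricalDtype):
                out[col] = out[col].astype(str)
        return out
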