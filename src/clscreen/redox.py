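"""Degree of oxidation (OxD) of a ratiometric H2O2 probe.

HyPer7-family probes have two excitation maxima (~400 and ~499 nm); probe
oxidation raises the 485-excitation signal relative to the 400-excitation
one, so the ratio R = F485/F400 reports the oxidized fraction. Wells
treated with excess DTT (fully reduced) and excess H2O2 (fully oxidized)
calibrate the dynamic range, and

    OxD = (R − R_red) / (F_corr · (R_ox − R) + (R − R_red))

maps R onto the oxidized fraction in [0, 1]; with the instrument
correction factor F_corr = 1 this is linear interpolation between R_red
and R_ox. OxD is scale-invariant: multiplying both channels by any c > 0
leaves R, hence OxD, unchanged. Background (a non-expressing strain) is
subtracted per channel and per cycle before any ratio is formed. OxD0,
the baseline degree of oxidation, is the mean OxD over the pre-treatment
cycles (default 4, ~2 min each).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["subtract_background", "oxd", "oxd0", "calibration_ratio", "process_plate"]

PLATE_COLUMNS = ("well", "condition", "cycle", "time_min", "F400", "F485")
CONDITIONS = ("sample", "reduced_control", "oxidized_control", "background")


def subtract_background(series: pd.DataFrame, background: pd.DataFrame) -> pd.DataFrame:
    """Per-channel, per-cycle background subtraction.

    Both frames need columns cycle, F400, F485 on matching cycle grids.
    Warns if any corrected value is non-positive (ratio becomes unusable
    there).
    """
    s = series.sort_values("cycle").reset_index(drop=True)
    b = background.sort_values("cycle").reset_index(drop=True)
    if len(s) != len(b) or not np.array_equal(
        s["cycle"].to_numpy(), b["cycle"].to_numpy()
    ):
        raise ValueError("series and background cycle grids do not match")
    out = s.copy()
    for ch in ("F400", "F485"):
        out[ch] = s[ch].to_numpy(dtype=float) - b[ch].to_numpy(dtype=float)
    if (out[["F400", "F485"]].to_numpy() <= 0).any():
        warnings.warn(
            "background subtraction produced non-positive fluorescence values",
            stacklevel=2,
        )
    return out


def oxd(R, R_red: float, R_ox: float, F_corr: float = 1.0, clamp: bool = True):
    """Degree of oxidation from the excitation ratio and calibration ratios.

    Returns OxD (scalar or array). Values are clamped to [0, 1] when
    ``clamp`` is True; pass ``clamp=False`` to see the raw value (useful
    for flagging out-of-calibration points).
    """
    if R_red == R_ox:
        raise ValueError("R_red equals R_ox: no dynamic range")
    R = np.asarray(R, dtype=float)
    val = (R - R_red) / (F_corr * (R_ox - R) + (R - R_red))
    return np.clip(val, 0.0, 1.0) if clamp else val


def oxd0(trajectory, n_baseline_cycles: int = 4) -> float:
    """Baseline degree of oxidation: mean over the pre-treatment cycles."""
    x = np.asarray(trajectory, dtype=float)
    if x.size < n_baseline_cycles:
        raise ValueError(
            f"trajectory has {x.size} cycles; need >= {n_baseline_cycles} for baseline"
        )
    return float(x[:n_baseline_cycles].mean())


def calibration_ratio(control: pd.DataFrame, n_plateau_cycles: int = 4) -> float:
    """Calibration ratio of a fully reduced/oxidized control well.

    Median R over the last ``n_plateau_cycles`` cycles — the
    post-treatment plateau — which is robust to the injection transient.
    """
    c = control.sort_values("cycle")
    R = c["F485"].to_numpy(dtype=float) / c["F400"].to_numpy(dtype=float)
    if R.size < n_plateau_cycles:
        raise ValueError("control series shorter than the plateau window")
    return float(np.median(R[-n_plateau_cycles:]))


def process_plate(
    plate: pd.DataFrame,
    n_baseline_cycles: int = 4,
    F_corr: float = 1.0,
    n_plateau_cycles: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full plate-reader workflow: background → calibration → OxD → OxD0.

    ``plate`` is long-format with columns well, condition, cycle,
    time_min, F400, F485; conditions 'background', 'reduced_control' and
    'oxidized_control' must each be present (background is averaged over
    its wells per cycle and subtracted from everything else).

    Returns ``(trajectories, summary)``: per-cycle R/OxD per sample well
    (with an ``out_of_range`` flag where the raw OxD left [0, 1]) and a
    per-well summary with OxD0.
    """
    missing = set(PLATE_COLUMNS) - set(plate.columns)
    if missing:
        raise ValueError(f"plate table missing columns {sorted(missing)}")
    bg = plate[plate["condition"] == "background"]
    if bg.empty:
        raise ValueError("no background wells in plate")
    bg_mean = bg.groupby("cycle", sort=True)[["F400", "F485"]].mean().reset_index()

    def corrected(cond: str, well: str | None = None) -> pd.DataFrame:
        sel = plate["condition"] == cond
        if well is not None:
            sel &= plate["well"] == well
        sub = plate[sel].groupby("cycle", sort=True)[["F400", "F485"]].mean().reset_index()
        if sub.empty:
            raise ValueError(f"no wells with condition {cond!r}")
        return subtract_background(sub, bg_mean)

    R_red = calibration_ratio(corrected("reduced_control"), n_plateau_cycles)
    R_ox = calibration_ratio(corrected("oxidized_control"), n_plateau_cycles)

    samples = plate[plate["condition"] == "sample"]
    traj_rows = []
    summary_rows = []
    for well in samples["well"].unique():
        sub = samples[samples["well"] == well].sort_values("cycle")
        corr = subtract_background(
            sub[["cycle", "F400", "F485"]].reset_index(drop=True),
            bg_mean,
        )
        R = corr["F485"].to_numpy() / corr["F400"].to_numpy()
        raw = oxd(R, R_red, R_ox, F_corr, clamp=False)
        clamped = np.clip(raw, 0.0, 1.0)
        traj_rows.append(
            pd.DataFrame(
                {
                    "well": well,
                    "cycle": corr["cycle"].to_numpy(),
                    "time_min": sub["time_min"].to_numpy(),
                    "R": R,
                    "OxD": clamped,
                    "out_of_range": (raw < 0) | (raw > 1),
                }
            )
        )
        summary_rows.append(
            {
                "well": well,
                "OxD0": oxd0(clamped, n_baseline_cycles),
                "R_red": R_red,
                "R_ox": R_ox,
                "F_corr": F_corr,
            }
        )
    trajectories = (
        pd.concat(traj_rows, ignore_index=True)
        if traj_rows
        else pd.DataFrame(columns=["well", "cycle", "time_min", "R", "OxD", "out_of_range"])
    )
    return trajectories, pd.DataFrame(summary_rows)
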