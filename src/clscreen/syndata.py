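"""Synthetic chronological-lifespan screens with known ground truth.

The generator emulates the structure of a genome-wide deletion-collection
screen read out by propidium-iodide (PI) flow cytometry: strains decay in
stationary phase following a Weibull survival law, each well×timepoint
yields a fixed number of cytometer events whose PI intensities come from a
two-component log-normal mixture (PI-negative live cells vs PI-positive
dead cells), and every 96-well plate carries the three control archetypes
(wild-type "666" = average, sty1d = short-lived, pka1d = long-lived).

True viability of a well at day t is

    v(t) = exp(-(t / tau_r)^k),   tau_r = tau * exp(eps_plate + eps_rep)

with eps_plate ~ N(0, plate_sd^2) shared by all wells of a plate and
eps_rep ~ N(0, rep_sd^2) per well, both acting on log-tau so v stays in
[0, 1] by construction. Randomness is organised as one master seed with
per-(plate, well, timepoint) sub-streams derived via ``SeedSequence`` spawn
keys, so enlarging a design never perturbs the draws of existing wells.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ArchetypeSpec",
    "ScreenDesign",
    "FluorModel",
    "CONTROL_ARCHETYPES",
    "CONTROL_STRAINS",
    "weibull_survival",
    "simulate_viability",
    "emit_events",
    "simulate_screen",
    "simulate_viability_table",
    "write_events_tsv",
    "write_truth_tsv",
]

# Stream-key namespaces for the seed hierarchy.
_KEY_PLATE = 1
_KEY_WELL = 2
_KEY_EVENTS = 3
_KEY_COUNTS = 4


@dataclass(frozen=True)
class ArchetypeSpec:
    """Survival archetype: Weibull scale/shape plus noise on log-tau.

    Parameters
    ----------
    label : str
        Class name (``average``, ``short_lived``, ``long_lived`` or custom).
    tau : float
        Survival time-scale in days; v(tau) = 1/e for any shape.
    k_shape : float
        Weibull shape; k > 1 gives a sigmoidal (initially flat) decline,
        k < 1 a fast-then-slow one.
    plate_sd, rep_sd : float
        Standard deviations of the plate and replicate effects on log-tau.
    """

    label: str
    tau: float
    k_shape: float = 2.0
    plate_sd: float = 0.02
    rep_sd: float = 0.05

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if not self.k_shape > 0:
            raise ValueError(f"k_shape must be positive, got {self.k_shape}")
        if self.plate_sd < 0 or self.rep_sd < 0:
            raise ValueError("plate_sd and rep_sd must be non-negative")


#: Default control archetypes. Time-scales 2 / 4 / 8 days with shape 2 put the
#: three classes at screen-grid areas of roughly 177 / 352 / 594 %·days, about
#: ten pooled SDs apart under the default noise — comfortably separable, like
#: the published control curves.
CONTROL_ARCHETYPES: dict[str, ArchetypeSpec] = {
    "short_lived": ArchetypeSpec("short_lived", tau=2.0),
    "average": ArchetypeSpec("average", tau=4.0),
    "long_lived": ArchetypeSpec("long_lived", tau=8.0),
}

#: Control strain names as they appear on every plate.
CONTROL_STRAINS: dict[str, str] = {
    "average": "666",
    "short_lived": "sty1d",
    "long_lived": "pka1d",
}


@dataclass(frozen=True)
class ScreenDesign:
    """Layout and sampling plan of a synthetic screen."""

    timepoints: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 8.0)
    events_per_sample: int = 10_000
    plates: int = 1
    wells_per_plate: int = 96
    controls: dict[str, str] = field(default_factory=lambda: dict(CONTROL_STRAINS))
    seed: int = 0

    def __post_init__(self) -> None:
        tp = tuple(float(t) for t in self.timepoints)
        if len(tp) < 1 or tp[0] != 0.0:
            raise ValueError("timepoints must start at 0 (the logarithmic sample)")
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("timepoints must be strictly increasing")
        object.__setattr__(self, "timepoints", tp)
        if self.events_per_sample < 1:
            raise ValueError("events_per_sample must be >= 1")
        if self.plates < 1 or self.wells_per_plate < len(self.controls):
            raise ValueError("design must fit at least the control wells per plate")
        missing = set(CONTROL_STRAINS) - set(self.controls)
        if missing:
            raise ValueError(f"controls must cover all three classes; missing {missing}")


@dataclass(frozen=True)
class FluorModel:
    """Two-component log-normal PI-intensity model (log10 a.u.).

    Live (PI-negative) and dead (PI-positive) events each draw log10
    intensity from a normal; dead cells stain brighter on the PE-A-like
    channel because PI only enters compromised membranes.
    """

    live_mu: float = 2.0
    live_sigma: float = 0.25
    dead_mu: float = 3.5
    dead_sigma: float = 0.25

    def __post_init__(self) -> None:
        if not self.dead_mu > self.live_mu:
            raise ValueError("dead_mu must exceed live_mu")
        if self.live_sigma <= 0 or self.dead_sigma <= 0:
            raise ValueError("sigmas must be positive")


def _stream(seed: int, *key: int) -> np.random.Generator:
    """Deterministic sub-stream of the master seed keyed by integers."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def weibull_survival(t, tau: float, k: float):
    """Closed-form survival exp(-(t/tau)^k); scalar or array in, same out."""
    if not tau > 0:
        raise ValueError(f"tau must be positive, got {tau}")
    if not k > 0:
        raise ValueError(f"k must be positive, got {k}")
    t = np.asarray(t, dtype=float)
    return np.exp(-((t / tau) ** k))


def _tau_r(
    arch: ArchetypeSpec, seed: int, plate_index: int, well_index: int
) -> float:
    """Realised time-scale for one well: plate effect shared within a plate."""
    eps_plate = (
        _stream(seed, _KEY_PLATE, plate_index).standard_normal() * arch.plate_sd
        if arch.plate_sd > 0
        else 0.0
    )
    eps_rep = (
        _stream(seed, _KEY_WELL, plate_index, well_index).standard_normal()
        * arch.rep_sd
        if arch.rep_sd > 0
        else 0.0
    )
    return arch.tau * float(np.exp(eps_plate + eps_rep))


def simulate_viability(
    arch: ArchetypeSpec,
    design: ScreenDesign,
    replicate_index: int = 0,
    seed: int | None = None,
    plate_index: int = 0,
):
    """True viability trajectory v(t) over the design's timepoints.

    Returns ``(tau_r, v)`` where ``v`` is an array over
    ``design.timepoints`` with ``v[0] == 1`` and v non-increasing.
    """
    seed = design.seed if seed is None else seed
    tau_r = _tau_r(arch, seed, plate_index, replicate_index)
    return tau_r, weibull_survival(design.timepoints, tau_r, arch.k_shape)


def emit_events(
    v: float,
    fluor: FluorModel,
    n_events: int,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Draw one sample's PI intensities (linear a.u.) given true viability.

    The dead count is Binomial(n_events, 1 - v); live events come first in
    the returned array, dead events after (downstream analysis is
    order-invariant). Returns exactly ``n_events`` intensities.
    """
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"viability must be in [0, 1], got {v}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n_dead = int(rng.binomial(n_events, 1.0 - v))
    n_live = n_events - n_dead
    log10_int = np.empty(n_events)
    log10_int[:n_live] = rng.normal(fluor.live_mu, fluor.live_sigma, n_live)
    log10_int[n_live:] = rng.normal(fluor.dead_mu, fluor.dead_sigma, n_dead)
    return 10.0 ** log10_int


def _well_name(index: int, columns: int = 12) -> str:
    row, col = divmod(index, columns)
    return f"{string.ascii_uppercase[row]}{col + 1:02d}"


def _layouts(
    design: ScreenDesign, assignments: dict[str, str]
) -> list[list[tuple[int, str, str]]]:
    """Per-plate lists of (well_index, strain, archetype_label).

    Controls occupy the first wells of every plate; mutants fill the rest
    sequentially across plates. A strain may not appear twice on one plate.
    """
    controls = [(design.controls[label], label) for label in sorted(design.controls)]
    for strain, _ in controls:
        if strain in assignments:
            raise ValueError(f"control strain {strain!r} also given a mutant assignment")
    mutants = list(assignments.items())
    capacity = design.plates * (design.wells_per_plate - len(controls))
    if len(mutants) > capacity:
        raise ValueError(
            f"{len(mutants)} mutant strains exceed capacity {capacity} "
            f"({design.plates} plates x {design.wells_per_plate} wells)"
        )
    layouts: list[list[tuple[int, str, str]]] = []
    cursor = 0
    per_plate_mutants = design.wells_per_plate - len(controls)
    for _ in range(design.plates):
        plate: list[tuple[int, str, str]] = []
        seen: set[str] = set()
        for w, (strain, label) in enumerate(controls):
            plate.append((w, strain, label))
            seen.add(strain)
        take = mutants[cursor : cursor + per_plate_mutants]
        cursor += len(take)
        for w, (strain, label) in enumerate(take, start=len(controls)):
            if strain in seen:
                raise ValueError(f"duplicate strain {strain!r} on one plate")
            plate.append((w, strain, label))
            seen.add(strain)
        layouts.append(plate)
    return layouts


def _resolve_arch(
    label: str, archetypes: dict[str, ArchetypeSpec]
) -> ArchetypeSpec:
    try:
        return archetypes[label]
    except KeyError:
        raise KeyError(f"no ArchetypeSpec for class {label!r}") from None


def simulate_screen(
    design: ScreenDesign,
    assignments: dict[str, str] | None = None,
    archetypes: dict[str, ArchetypeSpec] | None = None,
    fluor: FluorModel | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full screen at the event level.

    Parameters
    ----------
    design : ScreenDesign
    assignments : dict strain -> archetype label
        Mutant strains only; controls are placed automatically on every
        plate. May be empty (controls-only screen).
    archetypes : dict label -> ArchetypeSpec, optional
        Defaults to :data:`CONTROL_ARCHETYPES`.
    fluor : FluorModel, optional

    Returns
    -------
    events, truth : DataFrame
        ``events`` has columns plate, well, strain, day, event_index,
        pi_intensity (one row per event); ``truth`` has one row per
        well (strain, archetype, plate, well, tau_r and true viability
        ``v_day{t}`` per timepoint).
    """
    assignments = assignments or {}
    archetypes = archetypes if archetypes is not None else CONTROL_ARCHETYPES
    fluor = fluor or FluorModel()
    layouts = _layouts(design, assignments)
    tps = np.asarray(design.timepoints)
    n_ev = design.events_per_sample

    chunks: list[np.ndarray] = []
    meta: list[tuple[str, str, str, float]] = []  # plate, well, strain, day per sample
    truth_rows = []
    for p, plate in enumerate(layouts):
        plate_id = f"P{p + 1}"
        for w, strain, label in plate:
            arch = _resolve_arch(label, archetypes)
            tau_r, v = simulate_viability(
                arch, design, replicate_index=w, plate_index=p
            )
            well_id = _well_name(w)
            truth_rows.append(
                {
                    "strain": strain,
                    "archetype": label,
                    "plate": plate_id,
                    "well": well_id,
                    "tau_r": tau_r,
                    **{f"v_day{t:g}": v[i] for i, t in enumerate(tps)},
                }
            )
            for i, t in enumerate(tps):
                rng = _stream(design.seed, _KEY_EVENTS, p, w, i)
                chunks.append(emit_events(float(v[i]), fluor, n_ev, rng))
                meta.append((plate_id, well_id, strain, float(t)))

    n_samples = len(chunks)
    intensities = np.concatenate(chunks) if chunks else np.empty(0)
    events = pd.DataFrame(
        {
            "plate": pd.Categorical([m[0] for m in meta]).repeat(n_ev),
            "well": pd.Categorical([m[1] for m in meta]).repeat(n_ev),
            "strain": pd.Categorical([m[2] for m in meta]).repeat(n_ev),
            "day": np.repeat([m[3] for m in meta], n_ev),
            "event_index": np.tile(np.arange(n_ev), n_samples),
            "pi_intensity": intensities,
        }
    )
    truth = pd.DataFrame(truth_rows)
    return events, truth


def simulate_viability_table(
    design: ScreenDesign,
    assignments: dict[str, str] | None = None,
    archetypes: dict[str, ArchetypeSpec] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate observed viability fractions without per-event intensities.

    For each well×timepoint the live count is Binomial(events_per_sample,
    v(t)) — the same measurement noise the event layer would induce under a
    perfect gate — making this the fast path for large statistical checks.

    Returns ``(viability, truth)``; ``viability`` has columns plate, well,
    strain, day, fraction_viable, n_events, qc_pass.
    """
    assignments = assignments or {}
    archetypes = archetypes if archetypes is not None else CONTROL_ARCHETYPES
    layouts = _layouts(design, assignments)
    tps = np.asarray(design.timepoints)
    n_ev = design.events_per_sample
    rows = []
    truth_rows = []
    for p, plate in enumerate(layouts):
        plate_id = f"P{p + 1}"
        for w, strain, label in plate:
            arch = _resolve_arch(label, archetypes)
            tau_r, v = simulate_viability(
                arch, design, replicate_index=w, plate_index=p
            )
            well_id = _well_name(w)
            truth_rows.append(
                {
                    "strain": strain,
                    "archetype": label,
                    "plate": plate_id,
                    "well": well_id,
                    "tau_r": tau_r,
                    **{f"v_day{t:g}": v[i] for i, t in enumerate(tps)},
                }
            )
            rng = _stream(design.seed, _KEY_COUNTS, p, w)
            live = rng.binomial(n_ev, v)
            for i, t in enumerate(tps):
                rows.append(
                    {
                        "plate": plate_id,
                        "well": well_id,
                        "strain": strain,
                        "day": float(t),
                        "fraction_viable": live[i] / n_ev,
                        "n_events": n_ev,
                        "qc_pass": True,
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def write_events_tsv(events: pd.DataFrame, path) -> None:
    """Long-format TSV: plate, well, strain, day, event_index, pi_intensity."""
    events.to_csv(path, sep="\t", index=False)


def write_truth_tsv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)
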