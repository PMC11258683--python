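"""Fluorescence observation layer: calibration and signal/concentration maps.

The plate reader watches two channels.  A Cy3-like channel reports the
monomer strand: complexes in which the monomer's fluorophore sits next to a
quencher-bearing blocker (ML, Probe-Lock) emit only a small residual, while
unblocked complexes (MT, MP, MPR, ...) emit fully.  An AlexaFluor-647-like
channel reports opened reporter complexes (MPR, MNR, XPR).  Calibration is
linear: signal = background + sum_s slope_s * [s], with one slope shared by
all complexes carrying the same fluorophore in the same local environment —
so a single calibrated slope inverts the map for a reported species group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .kinetics import Trajectory

__all__ = [
    "CalibrationCurve",
    "SignalTrace",
    "ConcentrationTrace",
    "CHANNELS",
    "concentrations_to_signal",
    "signal_to_concentration",
    "estimate_intermediate_by_subtraction",
    "observable_weights",
]

CHANNELS = ("cy3_like", "af647_like")

#: Default residual emission of a quenched fluorophore, as a fraction of the
#: unquenched slope.  Quenching is strong but not total; the value is
#: configurable on every CalibrationCurve.
QUENCHED_FRACTION = 0.05


@dataclass
class CalibrationCurve:
    """Per-channel signal-per-concentration slopes and background.

    ``slopes`` maps species name -> signal units per nM.  Species absent
    from the map contribute nothing to the channel.
    """

    channel: str
    slopes: dict[str, float]
    background: float = 0.0

    def __post_init__(self):
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; use one of {CHANNELS}")
        if self.background < 0:
            raise ValueError("background must be >= 0")
        if any(v < 0 for v in self.slopes.values()):
            raise ValueError("slopes must be >= 0")
        if not any(v > 0 for v in self.slopes.values()):
            raise ValueError("calibration curve needs at least one positive slope")


@dataclass
class SignalTrace:
    """Raw per-well, per-channel fluorescence time series."""

    well_id: str
    channel: str
    times: np.ndarray
    signal: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times.shape != self.signal.shape:
            raise ValueError("times/signal length mismatch")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("non-finite signal values")


@dataclass
class ConcentrationTrace:
    """A signal trace converted to concentration units (nM)."""

    label: str
    times: np.ndarray
    values: np.ndarray
    species_group: tuple[str, ...] = ()
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times.shape != self.values.shape:
            raise ValueError("times/values length mismatch")


def concentrations_to_signal(
    trajectory: Trajectory,
    calibration: CalibrationCurve,
    well_id: str = "well",
) -> SignalTrace:
    """Forward map: simulated concentrations to a fluorescence signal.

    signal(t) = background + sum over species s of slope_s * [s](t).
    """
    missing = [s for s, v in calibration.slopes.items()
               if v > 0 and s not in trajectory.species_names]
    if missing:
        raise KeyError(f"calibration slopes reference unknown species {missing}")
    signal = np.full_like(trajectory.times, calibration.background)
    for s, slope in calibration.slopes.items():
        if slope > 0:
            signal = signal + slope * trajectory.conc(s)
    return SignalTrace(well_id, calibration.channel, trajectory.times.copy(), signal)


def signal_to_concentration(
    trace: SignalTrace,
    calibration: CalibrationCurve,
    reported_species_group: Sequence[str],
    *,
    slope_tolerance: float = 0.01,
) -> ConcentrationTrace:
    """Invert the calibration for a group of equally-bright species.

    All species in the group must share one slope to within
    ``slope_tolerance`` relative (one complex per fluorophore is calibrated
    because the fluorophore's local environment is identical across them);
    the returned values are (signal - background) / shared_slope, the summed
    concentration of the group.
    """
    group = list(reported_species_group)
    if not group:
        raise ValueError("reported_species_group is empty")
    slopes = []
    for s in group:
        if s not in calibration.slopes:
            raise KeyError(f"species {s!r} has no calibration slope")
        slopes.append(calibration.slopes[s])
    slopes = np.asarray(slopes, dtype=float)
    mean = slopes.mean()
    if mean <= 0:
        raise ValueError("group slope is zero")
    if np.max(np.abs(slopes - mean)) / mean > slope_tolerance:
        raise ValueError(
            f"heterogeneous slopes in group {group}: {slopes.tolist()} "
            f"(must agree within {slope_tolerance:.0%})"
        )
    values = (trace.signal - calibration.background) / mean
    return ConcentrationTrace(
        label=trace.well_id,
        times=trace.times.copy(),
        values=values,
        species_group=tuple(group),
        metadata={"channel": trace.channel, **trace.metadata},
    )


def observable_weights(
    calibration: CalibrationCurve, reported_species_group: Sequence[str]
) -> dict[str, float]:
    """Species weights of the concentration-converted observable.

    Converting a channel's signal with the shared slope of the reported
    group yields sum_s (slope_s / shared_slope) * [s]; species outside the
    group but with nonzero slope (e.g. a quenched complex at its residual
    slope) enter with a fractional weight.  The returned mapping lets model
    predictions be compared with converted data exactly.
    """
    shared = float(np.mean([calibration.slopes[s] for s in reported_species_group]))
    if shared <= 0:
        raise ValueError("group slope is zero")
    return {
        s: slope / shared for s, slope in calibration.slopes.items() if slope > 0
    }


def _resample(times_src, values_src, times_dst):
    return np.interp(times_dst, times_src, values_src)


def estimate_intermediate_by_subtraction(
    unblocked: ConcentrationTrace, waste: ConcentrationTrace
) -> ConcentrationTrace:
    """Estimate the template-bound intermediate as unblocked minus waste.

    The unblocked-monomer channel counts MT + MP(+reported waste); the waste
    channel counts reported MP.  Their difference estimates [MT], up to
    reporter lag (which inflates the estimate) — the result is flagged
    ``crude`` in its metadata accordingly.  Traces on different grids are
    linearly interpolated onto the coarser grid; negative differences are
    clipped to zero.
    """
    lo = max(unblocked.times[0], waste.times[0])
    hi = min(unblocked.times[-1], waste.times[-1])
    if lo >= hi:
        raise ValueError("traces do not overlap in time")
    # coarser grid restricted to the overlap
    grid_src = unblocked if unblocked.times.size <= waste.times.size else waste
    grid = grid_src.times[(grid_src.times >= lo) & (grid_src.times <= hi)]
    u = _resample(unblocked.times, unblocked.values, grid)
    w = _resample(waste.times, waste.values, grid)
    return ConcentrationTrace(
        label=f"{unblocked.label}-intermediate",
        times=grid,
        values=np.clip(u - w, 0.0, None),
        species_group=("MT",),
        metadata={"estimator": "channel_subtraction", "crude": True},
    )
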