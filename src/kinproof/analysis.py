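"""Specificity statistics: discrimination factors, turnover, initial rates.

The discrimination factor D_x:y is the ratio of correct- to
incorrect-variant product yield at the end of matched experiments (equal
monomer inputs).  Without a proofreader, irreversible product formation
levels all variants to the same final yield (D -> 1 at long times);
a discriminating proofreader diverts mismatched monomers into waste and
raises D several-fold — the kinetic-proofreading signature.  Turnover
(waste formed per template added) above one demonstrates catalytic
template recycling.  The idealized Hopfield-cycle reference quantities
live in :mod:`kinproof.hopfield` and are re-exported here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .hopfield import HopfieldCycle, HopfieldResult, hopfield_steady_state  # noqa: F401
from .kinetics import Trajectory, endpoint_yields, integrate
from .networks import RateSet, build_network
from .observe import ConcentrationTrace

__all__ = [
    "DiscriminationResult",
    "discrimination_factor",
    "turnover_number",
    "initial_rate",
    "kp_enhancement_report",
    "endpoint_converged",
    "HopfieldCycle",
    "HopfieldResult",
    "hopfield_steady_state",
]


@dataclass
class DiscriminationResult:
    """Ratio of correct- to incorrect-variant product yield."""

    D: float
    numerator_species: str
    denominator_species: str
    numerator_nM: float
    denominator_nM: float
    condition: dict

    def __post_init__(self):
        if self.denominator_nM <= 0:
            raise ValueError("undefined discrimination factor: zero denominator yield")
        if self.numerator_nM <= 0:
            raise ValueError("undefined discrimination factor: zero numerator yield")
        expected = self.numerator_nM / self.denominator_nM
        if not np.isclose(self.D, expected, rtol=1e-12):
            raise ValueError("D must equal numerator/denominator exactly")


def discrimination_factor(
    yield_x: float,
    yield_y: float,
    *,
    species_x: str = "x",
    species_y: str = "y",
    condition: Mapping | None = None,
) -> DiscriminationResult:
    """D_x:y = endpoint product yield of variant x over variant y.

    Meaningful only when the total input concentration of each monomer is
    equal; record the condition (proofreader identity/concentration) in
    ``condition``.
    """
    if yield_y <= 0:
        raise ValueError("undefined discrimination factor: zero denominator yield")
    return DiscriminationResult(
        D=yield_x / yield_y,
        numerator_species=species_x,
        denominator_species=species_y,
        numerator_nM=float(yield_x),
        denominator_nM=float(yield_y),
        condition=dict(condition or {}),
    )


def turnover_number(waste_nM: float, template_initial_nM: float) -> float:
    """Waste formed per unit template added; > 1 flags catalytic turnover."""
    if template_initial_nM <= 0:
        raise ValueError("template initial concentration must be positive")
    return waste_nM / template_initial_nM


def endpoint_converged(
    trajectory: Trajectory, species: str, *, tail_fraction: float = 0.10,
    rel: float = 0.01,
) -> bool:
    """True when the species' yield changed < ``rel`` (relative) over the
    final ``tail_fraction`` of the run — the endpoint is a real plateau."""
    y = trajectory.conc(species)
    t = trajectory.times
    t_cut = t[-1] - tail_fraction * (t[-1] - t[0])
    tail = y[t >= t_cut]
    ref = max(abs(y[-1]), 1e-12)
    return bool(np.max(np.abs(tail - y[-1])) / ref < rel)


def initial_rate(
    trace: ConcentrationTrace | tuple,
    window: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Least-squares slope of a concentration trace over an early window.

    Returns (slope, standard error) in nM/s.  The default window runs from
    the first sample to the time the trace reaches 10% of its plateau
    (final) value, needing at least 3 points.
    """
    if isinstance(trace, ConcentrationTrace):
        t_all, y_all = trace.times, trace.values
    else:
        t_all, y_all = (np.asarray(a, dtype=float) for a in trace)
    if window is None:
        target = y_all[0] + 0.10 * (y_all[-1] - y_all[0])
        above = np.nonzero(y_all >= target)[0]
        hi = t_all[above[0]] if above.size else t_all[-1]
        window = (t_all[0], max(hi, t_all[min(2, t_all.size - 1)]))
    lo, hi = window
    mask = (t_all >= lo) & (t_all <= hi)
    if mask.sum() < 3:
        raise ValueError(
            f"initial-rate window [{lo}, {hi}] s contains "
            f"{int(mask.sum())} points; need >= 3"
        )
    t, y = t_all[mask], y_all[mask]
    A = np.vstack([t, np.ones_like(t)]).T
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    slope = float(coef[0])
    dof = t.size - 2
    if dof > 0 and res.size:
        s2 = float(res[0]) / dof
        se = float(np.sqrt(s2 / np.sum((t - t.mean()) ** 2)))
    else:
        se = 0.0
    return slope, se


def kp_enhancement_report(
    rates_by_variant: Mapping[str, RateSet],
    *,
    correct: str = "M1",
    ml0_nM: float = 8.0,
    n0_nM: float = 10.0,
    proofreader_nM: float = 50.0,
    template_nM: float = 2.0,
    reporter_nM: float = 20.0,
    duration_s: float = 250_000.0,
    n_times: int = 120,
) -> "pandas.DataFrame":
    """Tabulate discrimination with and without the proofreader.

    Runs matched dimerization simulations for every monomer variant, once
    with the proofreader and once without, and reports endpoint product
    yields, times to half yield, D (correct:variant) in each arm, and the
    improvement factor D_with / D_without.  Endpoint convergence (yield
    change < 1% over the final 10% of the run) is reported alongside.
    """
    import pandas as pd

    net = build_network("dimerization")
    times = np.linspace(0.0, duration_s, n_times + 1)
    rows = []
    yields: dict[tuple[str, bool], float] = {}
    for variant, rates in rates_by_variant.items():
        for with_p in (False, True):
            initial = {"ML": ml0_nM, "N": n0_nM, "RQ": reporter_nM,
                       "T": template_nM,
                       "P": proofreader_nM if with_p else 0.0}
            traj = integrate(net, rates, initial, times)
            product = traj.conc("MNR") + traj.conc("MN")
            y_end = float(product[-1])
            yields[(variant, with_p)] = y_end
            half_idx = np.nonzero(product >= 0.5 * y_end)[0]
            rows.append({
                "variant": variant,
                "proofreader_nM": proofreader_nM if with_p else 0.0,
                "product_yield_nM": y_end,
                "t_half_s": float(times[half_idx[0]]) if half_idx.size else np.nan,
                "endpoint_converged": endpoint_converged(traj, "MN")
                                      or endpoint_converged(traj, "MNR"),
            })
    df = pd.DataFrame(rows)

    d_with, d_without, improvement = {}, {}, {}
    for variant in rates_by_variant:
        if variant == correct:
            continue
        d_without[variant] = yields[(correct, False)] / yields[(variant, False)]
        d_with[variant] = yields[(correct, True)] / yields[(variant, True)]
        improvement[variant] = d_with[variant] / d_without[variant]
    df.attrs["D_without_proofreader"] = d_without
    df.attrs["D_with_proofreader"] = d_with
    df.attrs["improvement_factor"] = improvement
    return df
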