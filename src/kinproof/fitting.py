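"""Weighted least-squares rate-constant estimation from kinetic traces.

The objective is the weighted mean-squared error between predicted and
observed concentrations, summed over traces j and time points t:

    MSE(K_un) = sum_{j,t} w_j(t) * ([M]_j(K_un, t) - [E]_j(t))^2 / sum w

with w_j(t) = w1 (default 1) for t < t1_j and w2 (default 0.2) for
t >= t1_j, where t1_j is the per-trace plateau time — early points are
up-weighted so the fits capture the kinetics, not just the plateau.  The
normalization by total weight does not change the argmin.  Known rates
(K_n, determined by earlier fits to other experiments) stay fixed; unknown
rates (K_un) are searched in log10 space within their bounds, from multiple
seeded starts.

:class:`RateFitModel` / :class:`RateFitResults` are the model/results pair;
:func:`weighted_mse`, :func:`fit_rates`, :func:`staged_fit` and
:func:`select_reporter_set` are the functional surface.  ``staged_fit``
implements the three-stage protocol: (1) fit blocker/template exchange
rates on template-binding data; (2) fit reporter rates once per candidate
total-monomer concentration (eight candidates on a grid around nominal,
since that concentration cannot be pinned down directly); (3) fit the
remaining unknowns simultaneously on template-recovery plus full-discard
data for each candidate, and keep the candidate with the lowest total
error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .networks import NetworkModel, RateSet
from .kinetics import IntegrationError, integrate

__all__ = [
    "ObservedTrace",
    "RateFitModel",
    "FitProblem",
    "RateFitResults",
    "StagedFitResults",
    "SelectionReport",
    "StagedProtocolError",
    "auto_plateau_time",
    "weighted_mse",
    "fit_rates",
    "staged_fit",
    "select_reporter_set",
    "problem_from_datasets",
]

DEFAULT_W1 = 1.0
DEFAULT_W2 = 0.2
_FAIL_RESIDUAL = 1e6  # optimizer-safe stand-in when integration fails


class StagedProtocolError(RuntimeError):
    """A dataset kind required by a protocol stage is missing."""


def auto_plateau_time(times: np.ndarray, values: np.ndarray,
                      rel: float = 0.02) -> float:
    """Earliest time from which the trace stays within ``rel`` of its final
    value — an automated stand-in for a manually chosen plateau time."""
    final = values[-1]
    scale = max(abs(final), 1e-12)
    ok = np.abs(values - final) <= rel * scale
    # last index where the trace is still outside the band
    outside = np.nonzero(~ok)[0]
    if outside.size == 0:
        return float(times[0])
    i = outside[-1] + 1
    return float(times[i]) if i < times.size else float(times[-1])


@dataclass
class ObservedTrace:
    """One concentration-converted kinetic trace plus its model mapping.

    ``weights`` maps species name -> coefficient of the observable (the
    converted channel measures sum_s c_s [s], including fractional residual
    contributions of quenched complexes); ``initial`` is the post-injection
    initial condition of the well.
    """

    times: np.ndarray
    values: np.ndarray
    weights: dict
    initial: dict
    label: str = ""
    t1: float | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size < 2 or np.any(np.diff(self.times) <= 0):
            raise ValueError("trace times must be strictly increasing (>=2 points)")
        if self.times.shape != self.values.shape:
            raise ValueError("times/values length mismatch")
        if self.t1 is None:
            self.t1 = auto_plateau_time(self.times, self.values)
        if not self.times[0] <= self.t1 <= self.times[-1]:
            raise ValueError(
                f"t1={self.t1} outside trace time span "
                f"[{self.times[0]}, {self.times[-1]}]"
            )

    def point_weights(self, w1: float, w2: float) -> np.ndarray:
        """w1 for t < t1, w2 for t >= t1 (w2 applies at the boundary)."""
        return np.where(self.times < self.t1, w1, w2)


class RateFitModel:
    """Multi-trace weighted least-squares model for unknown rate constants.

    Parameters
    ----------
    traces : sequence of ObservedTrace
    network : NetworkModel
    rates : RateSet
        Partitioned rate set; ``rates.unknown`` names are estimated, all
        others held fixed at their values.  Every unknown needs finite
        positive bounds.
    w1, w2 : float
        Early/late point weights.
    """

    def __init__(
        self,
        traces: Sequence[ObservedTrace],
        network: NetworkModel,
        rates: RateSet,
        *,
        w1: float = DEFAULT_W1,
        w2: float = DEFAULT_W2,
        integrator_options: Mapping | None = None,
    ):
        if not traces:
            raise ValueError("need at least one trace")
        self.traces = list(traces)
        self.network = network
        self.rates = rates
        self.w1 = float(w1)
        self.w2 = float(w2)
        self.integrator_options = dict(integrator_options or {})
        self.unknown_names = sorted(rates.unknown)
        for name in self.unknown_names:
            lo, hi = rates.bounds.get(name, (0.0, np.inf))
            if not (0 < lo < hi < np.inf):
                raise ValueError(
                    f"unknown rate {name!r} needs finite positive bounds, "
                    f"got ({lo}, {hi})"
                )
        self._total_weight = float(
            sum(tr.point_weights(self.w1, self.w2).sum() for tr in self.traces)
        )

    @classmethod
    def from_datasets(cls, datasets, unknowns, channel: str = "cy3_like",
                      rates: RateSet | None = None, *,
                      scale_initial: Mapping[str, float] | None = None,
                      subsample: int = 1, **kw) -> "RateFitModel":
        """Build a fit model from synthetic datasets (one channel each)."""
        return problem_from_datasets(
            datasets, unknowns, channel, rates,
            scale_initial=scale_initial, subsample=subsample, **kw)

    # -- objective --------------------------------------------------------
    def predict(self, trace: ObservedTrace, rateset: RateSet) -> np.ndarray:
        grid = trace.times
        if grid[0] > 0.0:
            grid = np.concatenate(([0.0], grid))
            drop = 1
        else:
            drop = 0
        traj = integrate(self.network, rateset, trace.initial, grid,
                         **self.integrator_options)
        return traj.group_total(trace.weights)[drop:]

    def _rateset_for(self, k_un: Mapping[str, float]) -> RateSet:
        missing = set(self.unknown_names) - set(k_un)
        if missing:
            raise KeyError(f"missing unknown rate values for {sorted(missing)}")
        return self.rates.with_values({n: k_un[n] for n in self.unknown_names})

    def weighted_residuals(self, k_un: Mapping[str, float]) -> np.ndarray:
        """sqrt(w/W_tot)-scaled residual vector; sum of squares == MSE."""
        rs = self._rateset_for(k_un)
        out = []
        for tr in self.traces:
            model = self.predict(tr, rs)
            w = tr.point_weights(self.w1, self.w2)
            out.append(np.sqrt(w / self._total_weight) * (model - tr.values))
        return np.concatenate(out)

    def mse(self, k_un: Mapping[str, float]) -> float:
        """Weighted mean-squared error at the given unknown-rate values."""
        try:
            r = self.weighted_residuals(k_un)
        except IntegrationError:
            return np.inf
        return float(r @ r)

    # -- optimization -----------------------------------------------------
    def fit(
        self,
        *,
        n_starts: int = 8,
        seed: int = 0,
        start: Mapping[str, float] | None = None,
        xtol: float = 1e-10,
        ftol: float = 1e-10,
        max_nfev: int | None = None,
    ) -> "RateFitResults":
        """Bounded multi-start least squares over log10-transformed unknowns.

        One start sits at the log-midpoint of the bounds (or at ``start``),
        the rest are drawn uniformly in log space from the seeded generator.
        Returns the best converged start.
        """
        names = self.unknown_names
        lo = np.array([np.log10(self.rates.bounds[n][0]) for n in names])
        hi = np.array([np.log10(self.rates.bounds[n][1]) for n in names])
        rng = np.random.default_rng(seed)

        starts = []
        if start is not None:
            starts.append(np.clip(
                np.log10([start[n] for n in names]), lo, hi))
        else:
            starts.append(0.5 * (lo + hi))
        while len(starts) < n_starts:
            starts.append(lo + rng.uniform(size=len(names)) * (hi - lo))

        def residuals(x):
            k_un = {n: 10.0 ** v for n, v in zip(names, x)}
            try:
                return self.weighted_residuals(k_un)
            except IntegrationError:
                n_pts = sum(tr.times.size for tr in self.traces)
                return np.full(n_pts, _FAIL_RESIDUAL)

        attempts = []
        for i, x0 in enumerate(starts):
            init_cost = float(np.sum(residuals(x0) ** 2))
            sol = least_squares(
                residuals, x0, bounds=(lo, hi), method="trf",
                xtol=xtol, ftol=ftol, max_nfev=max_nfev,
            )
            attempts.append({
                "start": i,
                "x0": x0.copy(),
                "initial_mse": init_cost,
                "final_mse": float(2.0 * sol.cost),
                "nfev": int(sol.nfev),
                "success": bool(sol.success),
                "sol": sol,
            })
        converged = [a for a in attempts if a["success"]]
        if not converged:
            raise RuntimeError(
                "all optimizer starts failed to converge; per-start log: "
                + "; ".join(f"start {a['start']}: nfev={a['nfev']}" for a in attempts)
            )
        best = min(converged, key=lambda a: a["final_mse"])
        sol = best["sol"]
        params = {n: float(10.0 ** v) for n, v in zip(names, sol.x)}

        # Gauss-Newton covariance in log10 space -> relative standard errors
        stderr = {}
        try:
            J = sol.jac
            n_pts = J.shape[0]
            dof = max(n_pts - len(names), 1)
            cov = np.linalg.pinv(J.T @ J) * (2.0 * sol.cost / dof)
            for n, var in zip(names, np.diag(cov)):
                sd_log10 = float(np.sqrt(max(var, 0.0)))
                stderr[n] = params[n] * np.log(10.0) * sd_log10
        except np.linalg.LinAlgError:  # pragma: no cover
            stderr = {n: np.nan for n in names}

        rs = self._rateset_for(params)
        residual_by_trace = {}
        for tr in self.traces:
            residual_by_trace[tr.label] = self.predict(tr, rs) - tr.values

        return RateFitResults(
            model=self,
            params=params,
            stderr=stderr,
            mse=float(2.0 * sol.cost),
            residuals=residual_by_trace,
            diagnostics={
                "n_starts": len(starts),
                "attempts": [
                    {k: v for k, v in a.items() if k != "sol"} for a in attempts
                ],
                "best_start": best["start"],
                "nfev": best["nfev"],
                "converged": True,
            },
            seed=seed,
        )


#: A RateFitModel *is* the fit problem; alias kept for the functional API.
FitProblem = RateFitModel


@dataclass
class RateFitResults:
    """Fitted unknown rates with uncertainties and diagnostics."""

    model: RateFitModel
    params: dict
    stderr: dict
    mse: float
    residuals: dict
    diagnostics: dict
    seed: int

    def __post_init__(self):
        for n, v in self.params.items():
            lo, hi = self.model.rates.bounds[n]
            if not lo <= v <= hi:  # pragma: no cover
                raise ValueError(f"fitted {n}={v} escaped bounds ({lo}, {hi})")
        if self.mse < 0:  # pragma: no cover
            raise ValueError("negative MSE")

    @property
    def fitted_rates(self) -> RateSet:
        return self.model.rates.with_values(self.params)

    def summary(self) -> str:
        lines = [
            "Weighted least-squares rate fit",
            "=" * 46,
            f"traces: {len(self.model.traces)}   "
            f"points: {sum(t.times.size for t in self.model.traces)}   "
            f"weights: w1={self.model.w1:g}, w2={self.model.w2:g}",
            f"weighted MSE: {self.mse:.6g} nM^2   "
            f"(best of {self.diagnostics['n_starts']} starts, seed {self.seed})",
            "-" * 46,
            f"{'rate':<12}{'estimate':>14}{'std err':>12}{'bounds':>18}",
        ]
        for n in sorted(self.params):
            lo, hi = self.model.rates.bounds[n]
            lines.append(
                f"{n:<12}{self.params[n]:>14.4g}{self.stderr.get(n, np.nan):>12.2g}"
                f"{f'[{lo:.1g}, {hi:.1g}]':>18}"
            )
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Overlay data points and fitted model curves per trace."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        rs = self.fitted_rates
        for tr in self.model.traces:
            pts = ax.plot(tr.times, tr.values, ".", ms=3, label=f"{tr.label} data")
            ax.plot(tr.times, self.model.predict(tr, rs), "-",
                    color=pts[0].get_color(), label=f"{tr.label} fit")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("observable (nM)")
        ax.legend(fontsize="x-small")
        return ax


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def weighted_mse(problem: RateFitModel, k_un: Mapping[str, float]) -> float:
    """Eq.-1 weighted MSE of a fit problem at given unknown-rate values."""
    return problem.mse(k_un)


def fit_rates(problem: RateFitModel, *, n_starts: int = 8, seed: int = 0,
              **kw) -> RateFitResults:
    """Minimize the weighted MSE over the problem's unknown rates."""
    return problem.fit(n_starts=n_starts, seed=seed, **kw)


def problem_from_datasets(
    datasets,
    unknowns: Sequence[str],
    channel: str = "cy3_like",
    rates: RateSet | None = None,
    *,
    scale_initial: Mapping[str, float] | None = None,
    set_initial: Mapping[str, float] | None = None,
    subsample: int = 1,
    w1: float = DEFAULT_W1,
    w2: float = DEFAULT_W2,
) -> RateFitModel:
    """Assemble a fit problem from synthetic datasets' converted traces.

    ``scale_initial`` multiplies selected species' initial concentrations;
    ``set_initial`` overrides them absolutely (used by the staged protocol
    to impose a candidate total-monomer concentration); ``subsample`` keeps
    every n-th time point.
    """
    if not datasets:
        raise ValueError("no datasets given")
    network = datasets[0].network
    base = rates if rates is not None else datasets[0].true_rates
    traces = []
    for ds in datasets:
        conc = ds.conc[channel]
        init = dict(ds.design.full_initial())
        for name, f in (scale_initial or {}).items():
            if name in init:
                init[name] = init[name] * f
        for name, v in (set_initial or {}).items():
            if name in init:
                init[name] = float(v)
        traces.append(ObservedTrace(
            conc.times[::subsample], conc.values[::subsample],
            weights=dict(ds.observables[channel]), initial=init,
            label=f"{ds.label}:{channel}",
        ))
    return RateFitModel(traces, network, base.partition(unknowns), w1=w1, w2=w2)


# ---------------------------------------------------------------------------
# staged protocol
# ---------------------------------------------------------------------------

@dataclass
class SelectionReport:
    """Result of the reporter-rate-set selection."""

    index: int
    total_errors: np.ndarray
    tie: bool
    table: list

    def summary(self) -> str:
        lines = ["candidate selection (stage 3 total weighted MSE)",
                 f"{'idx':<5}{'scale':>8}{'total error':>16}{'picked':>9}"]
        for row in self.table:
            mark = "  <--" if row["index"] == self.index else ""
            lines.append(
                f"{row['index']:<5}{row.get('scale', float('nan')):>8.3g}"
                f"{row['total_error']:>16.6g}{mark:>9}")
        if self.tie:
            lines.append("note: tie broken by lowest candidate index")
        return "\n".join(lines)


def select_reporter_set(
    candidates: Sequence,
    problems_by_candidate: Sequence[Sequence[RateFitModel]] | None = None,
    *,
    errors: Sequence[float] | None = None,
    metadata: Sequence[Mapping] | None = None,
) -> SelectionReport:
    """Pick the candidate rate set minimizing the total stage-3 error.

    Either precomputed per-candidate ``errors`` are supplied (the staged
    protocol passes its stage-3 fit MSEs), or ``problems_by_candidate``
    gives, per candidate, the recovery+discard fit problems to evaluate at
    that candidate's rate values; the total error is the sum of their
    weighted MSEs.  Ties are broken by the lowest index and flagged.
    """
    if len(candidates) < 1:
        raise ValueError("need at least one candidate")
    if errors is None:
        if problems_by_candidate is None:
            raise ValueError("supply either errors or problems_by_candidate")
        errors = []
        for cand, problems in zip(candidates, problems_by_candidate):
            total = 0.0
            for p in problems:
                total += p.mse({n: cand.values[n] for n in p.unknown_names})
            errors.append(total)
    errors = np.asarray(errors, dtype=float)
    if errors.size != len(candidates):
        raise ValueError("one error per candidate required")
    best = int(np.argmin(errors))
    tie = bool(np.sum(errors == errors[best]) > 1)
    table = []
    for i, e in enumerate(errors):
        row = {"index": i, "total_error": float(e)}
        if metadata is not None:
            row.update(metadata[i])
        table.append(row)
    return SelectionReport(best, errors, tie, table)


DEFAULT_CANDIDATE_GRID = tuple(np.round(np.arange(0.80, 1.1501, 0.05), 2))


@dataclass
class StagedFitResults:
    """Outcome of the three-stage estimation protocol."""

    stage1: RateFitResults
    stage2: list
    stage3: list
    selection: SelectionReport
    final_rates: RateSet
    candidate_scales: tuple

    @property
    def selected_scale(self) -> float:
        return self.candidate_scales[self.selection.index]

    def summary(self) -> str:
        parts = [
            "Staged rate-constant estimation",
            "=" * 46,
            "stage 1 (template binding):",
            *(f"  {n} = {v:.4g}" for n, v in self.stage1.params.items()),
            f"stage 2/3: {len(self.candidate_scales)} total-monomer candidates "
            f"on scales [{', '.join(f'{s:g}' for s in self.candidate_scales)}]",
            self.selection.summary(),
            f"selected monomer scale: {self.selected_scale:g}",
            "final rates:",
            *(f"  {n} = {v:.4g}" for n, v in sorted(self.final_rates.values.items())),
        ]
        return "\n".join(parts)


def staged_fit(
    study,
    *,
    candidate_scales: Sequence[float] = DEFAULT_CANDIDATE_GRID,
    n_starts: int = 2,
    seed: int = 0,
    subsample: int = 1,
) -> StagedFitResults:
    """Run the three-stage estimation protocol on a staged study.

    Stage 1 fits the blocker/template exchange constants on the binding
    data; those become known rates downstream.  Stage 2 fits the reporter
    rate once per candidate total-monomer concentration (``candidate_scales``
    times nominal).  Stage 3 fits the proofreading constants simultaneously
    on template-recovery and full-discard data for each candidate; the
    candidate minimizing the summed stage-3 error is selected.
    """
    for stage, attr in [("stage 1 (template binding)", "binding"),
                        ("stage 2 (reporter triggering)", "reporter"),
                        ("stage 3 (template recovery)", "recovery"),
                        ("stage 3 (full discard)", "discard")]:
        if not getattr(study, attr, None):
            raise StagedProtocolError(f"{stage}: study has no {attr!r} datasets")

    # --- stage 1: blocker/template exchange ---
    p1 = problem_from_datasets(study.binding, ("k_bind", "k_unbind"),
                               "cy3_like", subsample=subsample)
    r1 = p1.fit(n_starts=n_starts, seed=seed)

    base_disc = study.discard[0].true_rates.with_values(r1.params)
    base_rec = study.recovery[0].true_rates.with_values(
        {k: v for k, v in r1.params.items()
         if k in study.recovery[0].true_rates.values})

    nominal = study.nominal_monomer
    stage2: list[RateFitResults] = []
    stage3: list[RateFitResults] = []
    totals: list[float] = []
    for i, scale in enumerate(candidate_scales):
        # --- stage 2: reporter rate, assuming the monomer stock was really
        # nominal*scale (the wells were prepared at an unknown true scale) --
        p2 = problem_from_datasets(
            study.reporter, ("k_rep",), "af647_like", rates=base_rec,
            set_initial={"MP": nominal * scale}, subsample=subsample)
        r2 = p2.fit(n_starts=n_starts, seed=seed + i)
        stage2.append(r2)

        # --- stage 3: simultaneous recovery + discard fit under the same
        # monomer-concentration assumption; the two experiment classes use
        # different topologies, so they share one unknown vector ---
        cand_rec = base_rec.with_values(r2.params)
        cand_disc = base_disc.with_values(r2.params)
        p3r = problem_from_datasets(study.recovery, ("k_proof", "k_unproof"),
                                    "af647_like", rates=cand_rec,
                                    set_initial={"MT": nominal * scale},
                                    subsample=subsample)
        p3d = problem_from_datasets(study.discard, ("k_proof", "k_unproof"),
                                    "cy3_like", rates=cand_disc,
                                    set_initial={"ML": nominal * scale},
                                    subsample=subsample)
        r3, total = _joint_fit((p3r, p3d), ("k_proof", "k_unproof"),
                               n_starts=n_starts, seed=seed + 100 + i)
        stage3.append(r3)
        totals.append(total)

    selection = select_reporter_set(
        [r.fitted_rates for r in stage3], errors=totals,
        metadata=[{"scale": float(s)} for s in candidate_scales])
    best = selection.index
    final = base_disc.with_values(stage2[best].params).with_values(
        stage3[best].params)
    return StagedFitResults(r1, stage2, stage3, selection, final,
                            tuple(candidate_scales))


def _joint_fit(problems: Sequence[RateFitModel], unknowns, *, n_starts, seed):
    """Multi-start bounded least squares over problems sharing unknowns."""
    names = sorted(unknowns)
    bounds = problems[0].rates.bounds
    lo = np.array([np.log10(bounds[n][0]) for n in names])
    hi = np.array([np.log10(bounds[n][1]) for n in names])
    rng = np.random.default_rng(seed)
    starts = [0.5 * (lo + hi)]
    while len(starts) < n_starts:
        starts.append(lo + rng.uniform(size=len(names)) * (hi - lo))

    def residuals(x):
        k_un = {n: 10.0 ** v for n, v in zip(names, x)}
        out = []
        for p in problems:
            try:
                out.append(p.weighted_residuals(k_un))
            except IntegrationError:
                out.append(np.full(
                    sum(t.times.size for t in p.traces), _FAIL_RESIDUAL))
        return np.concatenate(out)

    best_sol, best_cost = None, np.inf
    attempts = []
    for i, x0 in enumerate(starts):
        sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                            xtol=1e-10, ftol=1e-10)
        attempts.append({"start": i, "final_mse": float(2 * sol.cost),
                         "nfev": int(sol.nfev), "success": bool(sol.success)})
        if sol.success and 2 * sol.cost < best_cost:
            best_sol, best_cost = sol, float(2 * sol.cost)
    if best_sol is None:
        raise RuntimeError(f"joint fit failed to converge: {attempts}")
    params = {n: float(10.0 ** v) for n, v in zip(names, best_sol.x)}

    shell = RateFitResults(
        model=problems[0],
        params=params,
        stderr={n: np.nan for n in names},
        mse=best_cost,
        residuals={},
        diagnostics={"n_starts": len(starts), "attempts": attempts,
                     "best_start": int(np.argmin([a["final_mse"] for a in attempts])),
                     "nfev": attempts[-1]["nfev"], "converged": True,
                     "joint": True},
        seed=seed,
    )
    return shell, best_cost
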