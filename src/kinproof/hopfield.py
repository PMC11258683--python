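"""Idealized kinetic-proofreading reference model (Hopfield's cycle).

A single recognition site c binds competing candidates C (correct) and D
(incorrect).  Each bound complex Xc can either release the candidate or be
driven, by fuel consumption, to an activated state Xc*, from which the
candidate can again be released or be incorporated into product.  The same
binding free-energy difference (off-rate ratio f0) is exploited at both
release steps, so a strongly driven cycle with slow product formation
enriches correct product by up to f0^2, whereas at detailed balance the
enrichment collapses to the equilibrium value f0.

The cycle is linear in the state of the recognition site, so the stationary
distribution over {c, Cc, Cc*, Dc, Dc*} solves a 5-state master equation
exactly; candidate concentrations are folded into the binding pseudo-rates.
Drive is handled as an explicit ratio of clockwise to counter-clockwise
cycle rate products rather than via free energies in physical units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CandidateRates", "HopfieldCycle", "HopfieldResult", "hopfield_steady_state"]


@dataclass(frozen=True)
class CandidateRates:
    """Rates of one candidate's branch of the recognition cycle (all >= 0).

    bind      c + X -> Xc      (pseudo-first-order; concentration folded in)
    unbind    Xc -> c + X
    activate  Xc -> Xc*        (fuel-driven step)
    deactivate Xc* -> Xc
    release   Xc* -> c + X     (the proofreading discard)
    rebind    c + X -> Xc*     (reverse of release)
    product   Xc* -> c + prod  (incorporation; slow in the proofreading limit)
    """

    bind: float
    unbind: float
    activate: float
    deactivate: float
    release: float
    rebind: float
    product: float

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name!r} must be >= 0")

    def cycle_drive(self) -> float:
        """Ratio of clockwise to counter-clockwise rate products.

        1.0 means the c -> Xc -> Xc* -> c loop satisfies detailed balance
        (no net fuel consumption); >> 1 is the strongly driven regime.
        """
        cw = self.bind * self.activate * self.release
        ccw = self.unbind * self.deactivate * self.rebind
        if ccw == 0.0:
            return np.inf if cw > 0 else 1.0
        return cw / ccw


@dataclass
class HopfieldCycle:
    """The full two-candidate recognition cycle."""

    correct: CandidateRates
    incorrect: CandidateRates

    @classmethod
    def idealized(
        cls,
        f0: float,
        drive: float,
        *,
        bind: float = 1.0,
        unbind: float = 1000.0,
        activate: float = 1.0,
        release: float = 1000.0,
        product: float = 1.0,
    ) -> "HopfieldCycle":
        """Build the canonical discrimination scenario.

        Both candidates bind at the same rate; the incorrect candidate
        unbinds ``f0``-fold faster at *both* discrimination steps (Xc and
        Xc*).  ``drive`` sets the clockwise/counter-clockwise cycle ratio by
        scaling the two reverse rates symmetrically (deactivate and rebind
        each carry a factor 1/sqrt(drive)); at drive=1 the loop obeys
        detailed balance for both candidates, and the rebind rate is then
        candidate-independent, as it must be for a diffusion-limited
        association.
        """
        if f0 <= 0 or drive <= 0:
            raise ValueError("f0 and drive must be positive")

        def branch(off_scale: float) -> CandidateRates:
            unb = unbind * off_scale
            rel = release * off_scale
            # detailed-balance reverse rates at drive=1, then tilted
            deact = activate / np.sqrt(drive)
            reb = (bind * activate * rel) / (unb * activate) / np.sqrt(drive)
            return CandidateRates(
                bind=bind,
                unbind=unb,
                activate=activate,
                deactivate=deact,
                release=rel,
                rebind=reb,
                product=product,
            )

        return cls(branch(1.0), branch(f0))

    def detailed_balance_residual(self) -> float:
        """Max |log10 cycle drive| over the two branches (0 at equilibrium)."""
        res = 0.0
        for br in (self.correct, self.incorrect):
            d = br.cycle_drive()
            res = max(res, abs(np.log10(d)) if np.isfinite(d) else np.inf)
        return res


@dataclass
class HopfieldResult:
    """Stationary discrimination statistics of a recognition cycle."""

    enrichment: float        # correct : incorrect product flux ratio
    error_fraction: float    # incorrect flux / total flux
    occupancy: dict          # stationary probabilities of the 5 site states
    flux_correct: float
    flux_incorrect: float


def hopfield_steady_state(cycle: HopfieldCycle) -> HopfieldResult:
    """Exact stationary solution of the 5-state recognition master equation.

    States are {c, Cc, Cc*, Dc, Dc*}.  Product formation returns the site to
    c (the product leaves), so the chain is ergodic whenever each candidate
    branch is reachable.  Returns the correct:incorrect product flux ratio
    (enrichment) and the error fraction.
    """
    C, D = cycle.correct, cycle.incorrect
    # generator: Q[i, j] = rate i -> j
    Q = np.zeros((5, 5))
    for base, br in ((1, C), (3, D)):
        Q[0, base] += br.bind
        Q[0, base + 1] += br.rebind
        Q[base, 0] += br.unbind
        Q[base, base + 1] += br.activate
        Q[base + 1, base] += br.deactivate
        Q[base + 1, 0] += br.release + br.product
    A = Q.T - np.diag(Q.sum(axis=1))
    # replace one balance equation with normalization
    M = np.vstack([A[:-1], np.ones(5)])
    b = np.zeros(5)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(M, b, rcond=None)
    if np.any(pi < -1e-9) or not np.all(np.isfinite(pi)):
        raise ValueError("degenerate cycle: no valid stationary distribution")
    pi = np.clip(pi, 0.0, None)
    flux_c = pi[2] * C.product
    flux_d = pi[4] * D.product
    if flux_c + flux_d == 0.0:
        raise ValueError("degenerate cycle: no stationary product flux")
    if flux_d == 0.0:
        enrich = np.inf
    else:
        enrich = flux_c / flux_d
    return HopfieldResult(
        enrichment=float(enrich),
        error_fraction=float(flux_d / (flux_c + flux_d)),
        occupancy={
            name: float(p)
            for name, p in zip(["c", "Cc", "Cc*", "Dc", "Dc*"], pi)
        },
        flux_correct=float(flux_c),
        flux_incorrect=float(flux_d),
    )
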