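"""Independent oracles used by the test suite.

These re-derive expected values by routes that do not share code with the
implementation: symbolic stationary distributions via sympy, and closed-form
kinetics written out directly.
"""

from fractions import Fraction

import numpy as np
import sympy as sp


def hopfield_enrichment_symbolic(correct, incorrect) -> float:
    """Exact stationary enrichment of the 5-state recognition cycle.

    States {c, Cc, Cc*, Dc, Dc*}; balance equations are written from the
    transition list directly and solved symbolically over the rationals.
    Enrichment is the ratio of product fluxes pi(Cc*)*wC / (pi(Dc*)*wD).
    """
    def rat(x):
        return sp.Rational(Fraction(float(x)).limit_denominator(10**12))

    pis = sp.symbols("p0 p1 p2 p3 p4", positive=True)
    # transitions: (from, to, rate)
    trans = []
    for base, br in ((1, correct), (3, incorrect)):
        trans += [
            (0, base, rat(br.bind)),
            (0, base + 1, rat(br.rebind)),
            (base, 0, rat(br.unbind)),
            (base, base + 1, rat(br.activate)),
            (base + 1, base, rat(br.deactivate)),
            (base + 1, 0, rat(br.release) + rat(br.product)),
        ]
    balance = [sp.Integer(0)] * 5
    for i, j, r in trans:
        balance[i] -= pis[i] * r
        balance[j] += pis[i] * r
    eqs = balance[:4] + [sum(pis) - 1]
    sol = sp.solve(eqs, pis, dict=True)
    assert len(sol) == 1
    pi = sol[0]
    enrich = (pi[pis[2]] * rat(correct.product)) / (pi[pis[4]] * rat(incorrect.product))
    return float(enrich)


def bimolecular_decay_exact(a0: float, b0: float, k_per_nM_s: float,
                            t: np.ndarray) -> np.ndarray:
    """Closed-form [A](t) for A + B -> C with unequal initial amounts."""
    d = b0 - a0
    return a0 * d / (b0 * np.exp(k_per_nM_s * d * t) - a0)
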