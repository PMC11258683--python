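import numpy as np
import pytest

from kinproof import (
    NetworkModel,
    RateSet,
    Reaction,
    Species,
    build_network,
    endpoint_yields,
    gillespie,
    integrate,
    molecule_counts,
)
from kinproof.kinetics import AVOGADRO, IntegrationError
from kinproof.synth import reference_rates

from conftest import STANDARD_CONDITIONS, default_variant
from oracles import bimolecular_decay_exact


def _ab_network(buffered=False):
    """A + B -> C; in the buffered variant B is regenerated, so A decays
    exactly exponentially at rate k[B]0 (true pseudo-first order)."""
    if buffered:
        species = [Species("A", ("a",)), Species("B", ("b",)),
                   Species("C", ("a",))]
        rx = [Reaction(("A", "B"), ("C", "B"), "k")]
    else:
        species = [Species("A", ("a",)), Species("B", ("b",)),
                   Species("C", ("a", "b"))]
        rx = [Reaction(("A", "B"), ("C",), "k")]
    return NetworkModel("template_binding", species, rx)


class TestIntegrate:
    def test_zero_rates_hold_initial_values(self):
        net = build_network("full_discard")
        rates = RateSet({n: 0.0 for n in net.rate_names})
        t = np.linspace(0, 1000, 11)
        traj = integrate(net, rates, {"ML": 8.0, "P": 50.0}, t)
        assert np.allclose(traj.conc("ML"), 8.0, rtol=1e-12)
        assert np.allclose(traj.conc("P"), 50.0, rtol=1e-12)
        assert np.allclose(traj.conc("MT"), 0.0)

    def test_pseudo_first_order_closed_form(self):
        """[A](t) = 8 exp(-k [B]0 t) nM for k=1e5 M^-1 s^-1, [B]0=800 nM."""
        net = _ab_network(buffered=True)
        t = np.linspace(0, 60, 61)
        traj = integrate(net, RateSet({"k": 1e5}), {"A": 8.0, "B": 800.0}, t)
        exact = 8.0 * np.exp(-1e5 * 800e-9 * t)
        assert np.max(np.abs(traj.conc("A") - exact) / exact) < 1e-6

    def test_bimolecular_exact_closed_form(self):
        """Literal A+B->C against the exact two-reactant solution."""
        net = _ab_network(buffered=False)
        t = np.linspace(0, 60, 61)
        traj = integrate(net, RateSet({"k": 1e5}), {"A": 8.0, "B": 800.0}, t)
        exact = bimolecular_decay_exact(8.0, 800.0, 1e5 * 1e-9, t)
        assert np.max(np.abs(traj.conc("A") - exact) / exact) < 1e-6

    @pytest.mark.parametrize("kind", list(STANDARD_CONDITIONS))
    def test_self_convergence_at_tighter_tolerances(self, kind, networks,
                                                    rate_sets):
        """Solution unchanged (1e-6 relative) when tolerances tighten 10x."""
        init, t_end = STANDARD_CONDITIONS[kind]
        t = np.linspace(0.0, t_end, 60)
        a = integrate(networks[kind], rate_sets[kind], init, t)
        b = integrate(networks[kind], rate_sets[kind], init, t,
                      rtol=1e-9, atol=1e-13)
        scale = np.maximum(np.abs(b.concentrations), 1e-6)
        assert np.max(np.abs(a.concentrations - b.concentrations) / scale) < 1e-6

    @pytest.mark.parametrize("kind", list(STANDARD_CONDITIONS))
    def test_conservation_and_sanity(self, kind, networks, rate_sets):
        """Strand totals constant to 1e-6 relative; no NaN; non-negative."""
        init, t_end = STANDARD_CONDITIONS[kind]
        t = np.linspace(0.0, t_end, 80)
        traj = integrate(networks[kind], rate_sets[kind], init, t)
        assert traj.conservation_error(networks[kind]) < 1e-6
        assert np.all(np.isfinite(traj.concentrations))
        assert np.all(traj.concentrations >= 0.0)

    def test_input_validation(self):
        net = build_network("template_binding")
        rates = reference_rates("template_binding")
        with pytest.raises(KeyError, match="unknown species"):
            integrate(net, rates, {"XX": 1.0}, np.linspace(0, 10, 5))
        with pytest.raises(ValueError, match="start at t=0"):
            integrate(net, rates, {"ML": 8.0}, np.linspace(1, 10, 5))
        with pytest.raises(KeyError, match="missing"):
            integrate(net, RateSet({"k_bind": 1e5}), {"ML": 8.0},
                      np.linspace(0, 10, 5))


class TestGillespie:
    def test_zero_propensities_no_events(self):
        net = build_network("template_binding")
        rates = RateSet({n: 0.0 for n in net.rate_names})
        res = gillespie(net, rates, {"ML": 100, "T": 100}, 1e-15, 100.0, seed=0)
        assert res.times.size == 1
        assert res.count("ML")[0] == 100

    def test_seed_reproducibility(self):
        net = build_network("template_binding")
        rates = reference_rates("template_binding")
        counts = {"ML": 500, "T": 600}
        a = gillespie(net, rates, counts, 1e-13, 500.0, seed=42)
        b = gillespie(net, rates, counts, 1e-13, 500.0, seed=42)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.counts, b.counts)

    def test_unimolecular_decay_mean(self):
        """A -> B at k=0.01/s from 1000 copies: mean A(100 s) within 3
        standard errors of 1000/e over replicates."""
        net = NetworkModel("template_binding",
                           [Species("A", ("a",)), Species("B", ("a",))],
                           [Reaction(("A",), ("B",), "k")])
        rates = RateSet({"k": 0.01})
        finals = np.array([
            gillespie(net, rates, {"A": 1000}, 1e-12, 100.0, seed=s)
            .state_at(100.0)[0]
            for s in range(200)
        ])
        expected = 1000.0 * np.exp(-1.0)
        se = finals.std(ddof=1) / np.sqrt(finals.size)
        assert abs(finals.mean() - expected) < 3 * se

    def test_matches_ode_at_high_copy_number_full_discard(self, networks,
                                                          rate_sets):
        """Law of large numbers: SSA replicate mean within 3 SE of the ODE
        solution at >= 1e4 copies per initially present species."""
        kind = "full_discard"
        init, t_end = STANDARD_CONDITIONS[kind]
        t_end = 10_000.0
        vol = 1e4 / (min(init.values()) * 1e-9 * AVOGADRO)
        counts = molecule_counts(init, vol)
        obs_t = np.array([0.25, 0.5, 1.0]) * t_end
        samples = []
        for seed in range(6):
            res = gillespie(networks[kind], rate_sets[kind], counts, vol,
                            t_end, seed=seed)
            i = res.species_names.index("MP")
            samples.append([res.state_at(tt)[i] / (AVOGADRO * vol) * 1e9
                            for tt in obs_t])
        samples = np.array(samples)
        traj = integrate(networks[kind], rate_sets[kind], init,
                         np.concatenate(([0.0], obs_t)))
        ode = np.interp(obs_t, traj.times, traj.conc("MP"))
        se = samples.std(axis=0, ddof=1) / np.sqrt(samples.shape[0])
        assert np.all(np.abs(samples.mean(axis=0) - ode) < 3 * se + 1e-12)

    def test_input_validation(self):
        net = build_network("template_binding")
        rates = reference_rates("template_binding")
        with pytest.raises(ValueError, match="volume"):
            gillespie(net, rates, {"ML": 10}, 0.0, 10.0, seed=1)
        with pytest.raises(ValueError, match="negative"):
            gillespie(net, rates, {"ML": -1}, 1e-12, 10.0, seed=1)


class TestEndpointYields:
    def test_constant_trajectory_returns_initial(self):
        net = build_network("template_binding")
        rates = RateSet({n: 0.0 for n in net.rate_names})
        traj = integrate(net, rates, {"ML": 8.0}, np.linspace(0, 10, 5))
        assert endpoint_yields(traj, ["ML", "MT"]) == {"ML": 8.0, "MT": 0.0}

    def test_dimerization_to_completion_without_proofreader(self):
        """Excess N, no P, irreversible product: all monomer ends as dimer."""
        net = build_network("dimerization")
        rates = reference_rates("dimerization", "M1")
        t = np.linspace(0, 400_000, 101)
        traj = integrate(net, rates, {"ML": 8.0, "N": 20.0, "RQ": 30.0,
                                      "T": 4.0}, t)
        y = endpoint_yields(traj, ["MN", "MNR"])
        assert y["MN"] + y["MNR"] == pytest.approx(8.0, rel=0.01)

    def test_waste_exceeds_template_catalytic_turnover(self, networks,
                                                       rate_sets):
        """Full discard at 8 nM ML / 4 nM T / 50 nM P: final waste above the
        added template — the repeated-catalytic-activity signature."""
        t = np.linspace(0, 20_000, 101)
        traj = integrate(networks["full_discard"], rate_sets["full_discard"],
                         {"ML": 8.0, "P": 50.0, "RQ": 20.0, "T": 4.0}, t)
        waste = traj.endpoint("MP") + traj.endpoint("MPR")
        assert waste > 4.0

    def test_unknown_species_errors(self, networks, rate_sets):
        t = np.linspace(0, 10, 5)
        traj = integrate(networks["template_binding"],
                         rate_sets["template_binding"], {"ML": 8.0}, t)
        with pytest.raises(KeyError):
            endpoint_yields(traj, ["nope"])
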