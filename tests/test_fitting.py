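import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinproof import build_network
from kinproof.fitting import (
    ObservedTrace,
    RateFitModel,
    auto_plateau_time,
    fit_rates,
    select_reporter_set,
    staged_fit,
    weighted_mse,
    problem_from_datasets,
)
from kinproof.networks import RateSet
from kinproof.synth import (
    NOISELESS,
    ExperimentDesign,
    NoiseModel,
    default_calibrations,
    generate_staged_study,
    generate_traces,
    reference_rates,
)
from kinproof.fitting import StagedProtocolError


def _dataset(kind, initial, trigger, trig_c, duration, n_points, variant="M1",
             noise=NOISELESS, seed=0, rates=None):
    net = build_network(kind)
    rates = rates or reference_rates(kind, variant)
    design = ExperimentDesign(kind, initial, trigger, trig_c, duration,
                              duration / n_points, 30.0)
    return generate_traces(design, net, rates, default_calibrations(net),
                           noise, label=f"{kind}_{variant}", variant=variant)


def _constant_problem(values, t1=25.0, w2=0.2):
    """A degenerate problem whose model predicts exactly zero (all rates 0),
    so the data values ARE the residuals."""
    net = build_network("template_binding")
    rates = RateSet({"k_bind": 0.0, "k_unbind": 0.0},
                    known=frozenset({"k_bind", "k_unbind"}))
    trace = ObservedTrace(np.array([10.0, 20.0, 30.0]),
                          np.asarray(values, dtype=float),
                          weights={"MT": 1.0}, initial={}, t1=t1)
    return RateFitModel([trace], net, rates, w2=w2)


class TestWeightedMse:
    def test_hand_computed_three_point_trace(self):
        """Residuals {1,1,2} nM at t={10,20,30} s with t1=25 s: weighted
        squared sum 1*1 + 1*1 + 0.2*4 = 2.8 nM^2, normalized by the total
        weight 2.2."""
        p = _constant_problem([-1.0, -1.0, -2.0], t1=25.0)
        assert p.mse({}) == pytest.approx(2.8 / 2.2, rel=1e-12)

    def test_boundary_point_gets_late_weight(self):
        """w2 applies at t >= t1: putting t1 exactly on the 20 s sample
        moves that point's weight from 1 to 0.2."""
        p = _constant_problem([0.0, 1.0, 0.0], t1=20.0)
        assert p.mse({}) == pytest.approx(0.2 / 1.4, rel=1e-12)
        p2 = _constant_problem([0.0, 1.0, 0.0], t1=25.0)
        assert p2.mse({}) == pytest.approx(1.0 / 2.2, rel=1e-12)

    def test_model_equals_data_gives_zero(self):
        ds = _dataset("template_binding", {"ML": 8.0}, "T", 10.0, 6000.0, 20)
        p = problem_from_datasets([ds], ("k_bind", "k_unbind"))
        truth = reference_rates("template_binding")
        assert weighted_mse(p, {"k_bind": truth["k_bind"],
                                "k_unbind": truth["k_unbind"]}) \
            == pytest.approx(0.0, abs=1e-12)

    def test_doubling_late_weight_doubles_late_contribution(self):
        p1 = _constant_problem([0.0, 0.0, -2.0], t1=25.0, w2=0.2)
        p2 = _constant_problem([0.0, 0.0, -2.0], t1=25.0, w2=0.4)
        # un-normalize to compare raw weighted sums
        assert p2.mse({}) * (1 + 1 + 0.4) == pytest.approx(
            2 * p1.mse({}) * (1 + 1 + 0.2), rel=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(min_value=2, max_value=4),
           st.lists(st.floats(-5, 5), min_size=6, max_size=6))
    def test_invariant_under_trace_partition_and_order(self, split, vals):
        """The weighted MSE depends only on the (time, value, weight)
        multiset: splitting points across traces at any boundary and
        swapping trace order leaves it unchanged (uniform weighting; the
        t1 weighting itself is pinned by the hand-computed cases)."""
        values = np.asarray(vals)
        times = np.array([10.0, 20.0, 30.0, 40.0, 50.0, 60.0])
        net = build_network("template_binding")
        rates = RateSet({"k_bind": 0.0, "k_unbind": 0.0})

        def trace(t, v):
            return ObservedTrace(t, v, weights={"MT": 1.0}, initial={},
                                 t1=float(t[0]))  # every point gets w2

        whole = RateFitModel([trace(times, values)], net, rates).mse({})
        tr_a, tr_b = trace(times[:split], values[:split]), \
            trace(times[split:], values[split:])
        m_ab = RateFitModel([tr_a, tr_b], net, rates).mse({})
        m_ba = RateFitModel([tr_b, tr_a], net, rates).mse({})
        assert m_ab == pytest.approx(m_ba, rel=1e-14, abs=1e-15)
        assert m_ab == pytest.approx(whole, rel=1e-12, abs=1e-15)


class TestAutoPlateau:
    def test_picks_earliest_time_in_final_band(self):
        t = np.linspace(0, 100, 101)
        y = np.minimum(t / 50.0, 1.0)  # ramps to 1.0 at t=50
        t1 = auto_plateau_time(t, y)
        assert 49.0 <= t1 <= 51.0

    def test_flat_trace_gives_first_time(self):
        t = np.linspace(0, 10, 11)
        assert auto_plateau_time(t, np.ones(11)) == 0.0


class TestFitRecovery:
    def test_initialized_at_truth_stays_at_truth(self):
        ds = _dataset("template_binding", {"ML": 8.0}, "T", 10.0, 6000.0, 30)
        p = problem_from_datasets([ds], ("k_bind", "k_unbind"))
        truth = {"k_bind": 2e5, "k_unbind": 1e4}
        res = p.fit(n_starts=1, seed=0, start=truth)
        for n, v in truth.items():
            assert res.params[n] == pytest.approx(v, rel=1e-6)

    IDENTIFIABLE = {
        # kind -> (unknowns, channel, initial, trigger, trig_c, duration)
        "template_binding": (("k_bind", "k_unbind"), "cy3_like",
                             {"ML": 8.0}, "T", 10.0, 6000.0),
        "template_recovery": (("k_proof", "k_rep"), "af647_like",
                              {"MT": 8.0, "RQ": 20.0}, "P", 50.0, 8000.0),
        "full_discard": (("k_proof",), "cy3_like",
                         {"ML": 8.0, "P": 50.0, "RQ": 20.0}, "T", 4.0,
                         20_000.0),
        "dimerization": (("k_dim",), "cy3_like",
                         {"ML": 8.0, "N": 10.0, "P": 50.0, "RQ": 20.0},
                         "T", 2.0, 150_000.0),
        "snp_detection": (("k_probe", "k_rep"), "cy3_like",
                          {"X": 15.0, "RQ": 20.0, "S": 20.0, "Psnp": 20.0},
                          "PL", 10.0, 150_000.0),
    }

    @pytest.mark.parametrize("kind", list(IDENTIFIABLE))
    def test_noiseless_recovery_within_one_percent(self, kind):
        """Noiseless synthetic data: identifiable rates recovered within 1%
        from random multi-starts.  Non-identifiable combinations (e.g.
        reverse proofreading) are deliberately excluded."""
        unknowns, channel, initial, trig, trig_c, dur = self.IDENTIFIABLE[kind]
        variant = "TS" if kind == "snp_detection" else "M1"
        ds = _dataset(kind, initial, trig, trig_c, dur, 25, variant=variant)
        p = problem_from_datasets([ds], unknowns, channel)
        res = fit_rates(p, n_starts=3, seed=1)
        truth = reference_rates(kind, variant)
        for n in unknowns:
            assert res.params[n] == pytest.approx(truth[n], rel=0.01), n

    def test_noisy_recovery_within_25_percent(self):
        """2% proportional noise, 3 template concentrations fitted
        simultaneously: both exchange constants within 25% of truth for
        every seed."""
        truth = reference_rates("template_binding")
        for seed in range(3):
            dss = [
                _dataset("template_binding", {"ML": 8.0}, "T", tc, 9000.0, 25,
                         noise=NoiseModel(proportional_sd=0.02, seed=seed * 17 + i))
                for i, tc in enumerate((2.0, 5.0, 10.0))
            ]
            p = problem_from_datasets(dss, ("k_bind", "k_unbind"))
            res = p.fit(n_starts=2, seed=seed)
            for n in ("k_bind", "k_unbind"):
                assert res.params[n] == pytest.approx(truth[n], rel=0.25)

    def test_accepted_steps_never_increase_mse(self):
        ds = _dataset("template_binding", {"ML": 8.0}, "T", 10.0, 6000.0, 20)
        p = problem_from_datasets([ds], ("k_bind", "k_unbind"))
        res = p.fit(n_starts=3, seed=2)
        for attempt in res.diagnostics["attempts"]:
            assert attempt["final_mse"] <= attempt["initial_mse"] + 1e-15

    def test_stderr_and_summary_available(self):
        ds = _dataset("template_binding", {"ML": 8.0}, "T", 10.0, 6000.0, 20,
                      noise=NoiseModel(proportional_sd=0.02, seed=5))
        res = problem_from_datasets([ds], ("k_bind",)).fit(n_starts=2, seed=0)
        assert res.stderr["k_bind"] >= 0.0
        text = res.summary()
        assert "k_bind" in text and "MSE" in text

    def test_unknown_without_bounds_rejected(self):
        ds = _dataset("template_binding", {"ML": 8.0}, "T", 10.0, 6000.0, 10)
        unbounded = RateSet({"k_bind": 2e5, "k_unbind": 1e4}).partition(
            ("k_bind",))
        with pytest.raises(ValueError, match="bounds"):
            problem_from_datasets([ds], ("k_bind",), rates=unbounded)


class TestSelection:
    def test_single_candidate_returns_index_zero(self):
        rs = reference_rates("template_recovery")
        rep = select_reporter_set([rs], errors=[1.0])
        assert rep.index == 0 and not rep.tie

    def test_argmin_of_error_table(self):
        rs = reference_rates("template_recovery")
        rep = select_reporter_set([rs] * 3, errors=[3.0, 1.5, 2.2])
        assert rep.index == 1

    def test_tie_broken_by_lowest_index_and_reported(self):
        rs = reference_rates("template_recovery")
        rep = select_reporter_set([rs] * 3, errors=[2.0, 2.0, 5.0])
        assert rep.index == 0 and rep.tie
        assert "tie" in rep.summary()


class TestStagedProtocol:
    def test_noiseless_staged_fit_recovers_truth_and_scale(self):
        study = generate_staged_study("M1", NOISELESS, seed=0,
                                      monomer_scale_true=1.0, n_points=25)
        res = staged_fit(study, n_starts=2, seed=0)
        assert res.selected_scale == pytest.approx(1.0)
        truth = reference_rates("full_discard")
        for n in ("k_bind", "k_unbind", "k_proof", "k_rep"):
            assert res.final_rates[n] == pytest.approx(truth[n], rel=0.01), n
        assert "selected monomer scale" in res.summary()

    def test_selects_true_monomer_concentration_under_noise(self):
        study = generate_staged_study(
            "M1", NoiseModel(proportional_sd=0.02, seed=11), seed=11,
            monomer_scale_true=0.90, n_points=25)
        res = staged_fit(study, n_starts=2, seed=1)
        assert res.selected_scale == pytest.approx(0.90)

    def test_missing_stage_dataset_names_the_stage(self):
        study = generate_staged_study("M1", NOISELESS, seed=0, n_points=10)
        study.reporter = []
        with pytest.raises(StagedProtocolError, match="stage 2"):
            staged_fit(study)
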