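import numpy as np
import pytest

from kinproof import build_network, integrate
from kinproof.observe import concentrations_to_signal
from kinproof.synth import (
    MONOMER_VARIANTS,
    NOISELESS,
    SNP_CANDIDATES,
    ExperimentDesign,
    NoiseModel,
    competitive_dimerization,
    default_calibrations,
    generate_staged_study,
    generate_study,
    generate_traces,
    reference_rates,
)


def _binding_dataset(noise=NOISELESS, seed=0):
    net = build_network("template_binding")
    design = ExperimentDesign("template_binding", {"ML": 8.0}, "T", 10.0,
                              6000.0, 60.0, 30.0)
    return generate_traces(design, net, reference_rates("template_binding"),
                           default_calibrations(net), noise, label="w0",
                           variant="M1")


class TestGenerateTraces:
    def test_zero_noise_signals_match_forward_map_exactly(self):
        ds = _binding_dataset()
        cal = default_calibrations(ds.network)["cy3_like"]
        clean = concentrations_to_signal(ds.truth, cal)
        assert np.array_equal(ds.signals["cy3_like"].signal,
                              clean.signal[1:])

    def test_dead_time_drops_early_samples(self):
        ds = _binding_dataset()
        assert ds.signals["cy3_like"].times[0] == pytest.approx(30.0)
        assert ds.truth.times[0] == 0.0

    def test_same_seed_bit_identical(self):
        noise = NoiseModel(additive_sd=5.0, proportional_sd=0.02, seed=7)
        a = _binding_dataset(noise)
        b = _binding_dataset(noise)
        assert np.array_equal(a.signals["cy3_like"].signal,
                              b.signals["cy3_like"].signal)

    def test_replicate_mean_matches_noiseless(self):
        """Per-time-point mean over 200 noisy replicates within 3 SE of the
        noiseless signal."""
        clean = _binding_dataset().signals["cy3_like"].signal
        reps = np.array([
            _binding_dataset(NoiseModel(5.0, 0.02, seed=s)).signals[
                "cy3_like"].signal
            for s in range(200)
        ])
        se = reps.std(axis=0, ddof=1) / np.sqrt(reps.shape[0])
        frac_outside = np.mean(np.abs(reps.mean(axis=0) - clean) > 3 * se)
        assert frac_outside < 0.02  # ~0.3% expected by chance per point

    def test_ground_truth_travels_with_dataset(self):
        ds = _binding_dataset()
        assert ds.truth.conc("MT").shape == (ds.signals["cy3_like"].times.size
                                             + 1,)
        assert ds.true_rates["k_bind"] == reference_rates(
            "template_binding")["k_bind"]


class TestPresets:
    def test_fig2_binding_design(self):
        study = generate_study("fig2_binding", seed=1)
        variants = {ds.variant for ds in study.datasets}
        assert variants == set(MONOMER_VARIANTS)
        t_concs = {ds.design.trigger_nM for ds in study.datasets}
        assert 10.0 in t_concs and len(t_concs) == 3
        assert all(ds.design.initial["ML"] == 8.0 for ds in study.datasets)

    def test_fig3_discard_design(self):
        study = generate_study("fig3_discard", seed=1)
        for ds in study.datasets:
            assert ds.design.initial == {"ML": 8.0, "P": 50.0, "RQ": 20.0}
            assert ds.design.trigger_species == "T"

    def test_fig5_snp_candidates_and_proofreader_arms(self):
        study = generate_study("fig5_snp", seed=1)
        cands = {ds.variant for ds in study.datasets}
        assert cands == set(SNP_CANDIDATES)  # 1 TS + 6 SNPs
        p_concs = {ds.design.initial["Psnp"] for ds in study.datasets}
        assert p_concs == {0.0, 20.0}
        assert all(ds.design.trigger_nM == 10.0 for ds in study.datasets)

    def test_unknown_preset(self):
        with pytest.raises(KeyError, match="unknown preset"):
            generate_study("fig9_nope")

    def test_staged_study_contains_all_stage_kinds(self):
        study = generate_staged_study(seed=1, n_points=10)
        assert study.binding and study.reporter
        assert study.recovery and study.discard


class TestPhenomenology:
    """Default ground-truth rates reproduce the study's qualitative
    behavior."""

    def test_matched_monomer_binds_template_fastest(self):
        study = generate_study("fig2_binding", seed=0)
        half = {}
        for ds in study.datasets:
            if ds.design.trigger_nM != 10.0:
                continue
            mt = ds.truth.conc("MT")
            idx = np.nonzero(mt >= 0.5 * mt[-1])[0]
            half[ds.variant] = ds.truth.times[idx[0]]
        assert half["M1"] < half["M2"] < half["M3"]

    def test_proofreader_removes_mismatched_monomers_faster(self):
        net = build_network("template_recovery")
        t = np.linspace(0, 3000, 61)
        remaining = {}
        for v in MONOMER_VARIANTS:
            rates = reference_rates("template_recovery", v)
            traj = integrate(net, rates, {"MT": 8.0, "P": 50.0, "RQ": 20.0}, t)
            remaining[v] = traj.endpoint("MT")
        assert remaining["M1"] > remaining["M2"] > remaining["M3"]

    def test_dimer_yields_level_without_proofreader(self):
        study = generate_study("fig4_dimerization", seed=0)
        yields = {ds.variant: ds.truth.endpoint("MN") + ds.truth.endpoint("MNR")
                  for ds in study.datasets if ds.design.initial["P"] == 0.0}
        for v in ("M2", "M3"):
            assert yields["M1"] / yields[v] == pytest.approx(1.0, abs=0.15)

    def test_correct_dimer_dominates_with_proofreader(self):
        study = generate_study("fig4_dimerization", seed=0)
        yields = {ds.variant: ds.truth.endpoint("MN") + ds.truth.endpoint("MNR")
                  for ds in study.datasets if ds.design.initial["P"] == 50.0}
        assert yields["M1"] > 2 * yields["M2"]
        assert yields["M1"] > 2 * yields["M3"]


class TestCompetitivePool:
    def test_competitive_network_valid_and_selective(self):
        from kinproof import validate_network

        net, rates = competitive_dimerization()
        assert validate_network(net, rates) == []
        t = np.linspace(0, 250_000, 81)
        traj = integrate(net, rates, {"ML_M1": 5, "ML_M2": 5, "ML_M3": 5,
                                      "N": 15, "P": 50, "RQ": 20, "T": 2}, t)
        y = {v: traj.endpoint(f"MN_{v}") + traj.endpoint(f"MNR_{v}")
             for v in MONOMER_VARIANTS}
        assert y["M1"] > 2 * y["M2"] and y["M1"] > 2 * y["M3"]


class TestDesignValidation:
    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            ExperimentDesign("template_binding", {"ML": -1.0}, "T", 10.0,
                             100.0, 10.0)

    def test_duration_must_exceed_dead_time(self):
        with pytest.raises(ValueError):
            ExperimentDesign("template_binding", {"ML": 8.0}, "T", 10.0,
                             10.0, 1.0, dead_time_s=30.0)

    def test_noise_model_bounds(self):
        with pytest.raises(ValueError):
            NoiseModel(additive_sd=-1.0)
        with pytest.raises(ValueError):
            NoiseModel(proportional_sd=1.5)
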