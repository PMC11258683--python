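"""Synthetic plate-reader studies generated from known ground-truth rates.

Every downstream stage (calibration inversion, weighted fitting, staged
protocol, specificity statistics) is exercised on data produced here: a
design is integrated with the mass-action engine, mapped to two-channel
fluorescence, and corrupted with additive + proportional Gaussian noise.
The ground-truth trajectory and rate set travel with every dataset, so
recovery can always be checked.

The preset designs encode the study conditions:

``fig2_binding``      8 nM blocked monomer variants in separate wells,
                      reactions initiated by injecting template (series
                      including 10 nM).
``fig3_discard``      8 nM M1L/M2L/M3L, 50 nM proofreader, 20 nM waste
                      reporter, triggered by 4 nM template.
``fig4_dimerization`` 8 nM blocked monomers, 10 nM second monomer N,
                      50 nM proofreader (and a no-proofreader arm),
                      triggered by 2 nM template.
``fig5_snp``          10 nM blocked probe injected into 15 nM candidate
                      strand (target or one of six SNPs), 20 nM reporter,
                      20 nM sink, with and without 20 nM proofreader.

Ground-truth rate constants are plausible effective strand-displacement
constants: matched-template binding of order 1e5 M^-1 s^-1 with 5-20x
slower binding for mismatched variants, proofreading 5-20x faster for
mismatched variants, and a dimerization constant of 3.50e5 M^-1 s^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .networks import NetworkModel, RateSet, Reaction, Species, build_network
from .kinetics import Trajectory, integrate
from .observe import (
    CalibrationCurve,
    ConcentrationTrace,
    SignalTrace,
    concentrations_to_signal,
    observable_weights,
    signal_to_concentration,
    QUENCHED_FRACTION,
)

__all__ = [
    "ExperimentDesign",
    "NoiseModel",
    "NOISELESS",
    "SyntheticDataset",
    "Study",
    "StagedStudy",
    "PRESETS",
    "reference_rates",
    "default_calibrations",
    "observed_groups",
    "generate_traces",
    "generate_study",
    "generate_staged_study",
    "competitive_dimerization",
    "MONOMER_VARIANTS",
    "SNP_CANDIDATES",
]

PRESETS = ("fig2_binding", "fig3_discard", "fig4_dimerization", "fig5_snp")

MONOMER_VARIANTS = ("M1", "M2", "M3")
SNP_CANDIDATES = ("TS", "SNP1", "SNP2", "SNP3", "SNP4", "SNP5", "SNP6")

# (template-binding slowdown, proofreading speedup) per monomer variant;
# M1 is the matched monomer.  Chosen once inside the 5-20x band.
_VARIANT_FACTORS = {"M1": (1.0, 1.0), "M2": (5.0, 15.0), "M3": (10.0, 20.0)}

# per-SNP (probe-binding slowdown, proofreading speedup); mismatch position
# and identity modulate both, hence the spread.
_SNP_FACTORS = {
    "TS": (1.0, 1.0),
    "SNP1": (6.0, 8.0),
    "SNP2": (8.0, 10.0),
    "SNP3": (10.0, 12.0),
    "SNP4": (12.0, 15.0),
    "SNP5": (9.0, 10.0),
    "SNP6": (7.0, 9.0),
}

_K_BIND_M1 = 2.0e5      # M^-1 s^-1, matched template invasion
_K_UNBIND = 1.0e4       # blocker rebinding (MT + L)
_K_PROOF_M1 = 1.0e4     # proofreader displacement of matched monomer
_K_UNPROOF = 1.0e2      # reverse proofreading (MP + T)
_K_REP = 1.0e5          # waste/product reporter triggering
_K_DIM = 3.50e5         # handhold-mediated dimerization
_K_LEAK = 5.0e1         # direct reporter-monomer leak
_K_PROBE_TS = 2.0e5     # probe invasion by the matched target strand
_K_UNPROBE = 1.0e4
_K_REP_SNP = 1.0e4      # slow reporter of the SNP network
_K_PROOF_TS = 1.0e4
_K_SINK = 1.0e6


def _bounded(values: Mapping[str, float], span: float = 100.0) -> dict:
    return {k: (v / span, v * span) for k, v in values.items() if v > 0}


def reference_rates(
    kind: str,
    variant: str = "M1",
    *,
    leak: bool = False,
    two_step_binding: bool = False,
) -> RateSet:
    """Ground-truth rate set for one network kind and monomer/candidate.

    All values known; callers re-partition (``RateSet.partition``) to mark
    rates unknown for fitting.  Bounds span a factor 100 either side of the
    truth.
    """
    if kind == "snp_detection":
        try:
            slow, fast = _SNP_FACTORS[variant]
        except KeyError:
            raise KeyError(
                f"unknown SNP candidate {variant!r}; choose from {SNP_CANDIDATES}"
            ) from None
        values = {
            "k_probe": _K_PROBE_TS / slow,
            "k_unprobe": _K_UNPROBE,
            "k_rep": _K_REP_SNP,
            "k_proof": _K_PROOF_TS * fast,
            "k_sink": _K_SINK,
        }
        if leak:
            values["k_leak"] = _K_LEAK
        return RateSet(values, known=frozenset(values), bounds=_bounded(values))

    try:
        slow, fast = _VARIANT_FACTORS[variant]
    except KeyError:
        raise KeyError(
            f"unknown monomer variant {variant!r}; choose from {MONOMER_VARIANTS}"
        ) from None

    values: dict[str, float] = {}
    if kind in ("template_binding", "full_discard", "dimerization"):
        if two_step_binding:
            values.update(
                k_on=3.0e5 / slow, k_off=2.0e-2, k_disp=2.0e-2, k_disp_rev=_K_UNBIND
            )
        else:
            values.update(k_bind=_K_BIND_M1 / slow, k_unbind=_K_UNBIND)
    if kind in ("template_recovery", "full_discard", "dimerization"):
        values.update(k_proof=_K_PROOF_M1 * fast, k_unproof=_K_UNPROOF, k_rep=_K_REP)
    if kind == "dimerization":
        values["k_dim"] = _K_DIM
        if leak:
            values["k_leak"] = _K_LEAK
    if not values:
        raise KeyError(f"unknown network kind {kind!r}")
    return RateSet(values, known=frozenset(values), bounds=_bounded(values))


# ---------------------------------------------------------------------------
# calibration defaults
# ---------------------------------------------------------------------------

_CY3_SLOPE = 100.0    # units / nM, unquenched monomer fluorophore
_AF647_SLOPE = 150.0  # units / nM, opened reporter
_CY3_BG = 200.0
_AF647_BG = 300.0


def default_calibrations(
    network: NetworkModel, *, quenched_fraction: float = QUENCHED_FRACTION
) -> dict[str, CalibrationCurve]:
    """Calibration curves implied by the labeling scheme of a network.

    The monomer strand M carries a Cy3-like fluorophore quenched by the
    blocker L; reporter strand R carries an AlexaFluor-647-like fluorophore
    quenched by Q.  In the SNP network, the reporter itself is the Cy3-like
    label (R quenched by Q).  Quenched complexes keep a small residual slope
    (``quenched_fraction`` of the full slope).
    """
    curves: dict[str, CalibrationCurve] = {}
    if network.kind == "snp_detection":
        slopes = {}
        for sp in network.species:
            if "R" in sp.strands:
                q = "Q" in sp.strands
                slopes[sp.name] = _CY3_SLOPE * (quenched_fraction if q else 1.0)
        curves["cy3_like"] = CalibrationCurve("cy3_like", slopes, _CY3_BG)
        return curves

    cy3 = {}
    af647 = {}
    for sp in network.species:
        if "M" in sp.strands:
            q = "L" in sp.strands
            cy3[sp.name] = _CY3_SLOPE * (quenched_fraction if q else 1.0)
        if "R" in sp.strands:
            q = "Q" in sp.strands
            af647[sp.name] = _AF647_SLOPE * (quenched_fraction if q else 1.0)
    if cy3:
        curves["cy3_like"] = CalibrationCurve("cy3_like", cy3, _CY3_BG)
    if af647:
        curves["af647_like"] = CalibrationCurve("af647_like", af647, _AF647_BG)
    return curves


def observed_groups(kind: str) -> dict[str, tuple[str, ...]]:
    """Reported species group per channel, per network kind.

    The Cy3-like channel tracks unblocked monomer; the AF647-like channel
    tracks opened reporter complexes.
    """
    groups = {
        "template_binding": {"cy3_like": ("MT",)},
        "template_recovery": {"af647_like": ("MPR",)},
        "full_discard": {"cy3_like": ("MT", "MP", "MPR"), "af647_like": ("MPR",)},
        "dimerization": {"cy3_like": ("MT", "MP", "MN", "MNR"),
                         "af647_like": ("MNR",)},
        "snp_detection": {"cy3_like": ("XPR",)},
    }
    try:
        return groups[kind]
    except KeyError:
        raise KeyError(f"unknown network kind {kind!r}") from None


# ---------------------------------------------------------------------------
# designs and noise
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentDesign:
    """One well's experimental design.

    ``initial`` holds pre-mixed concentrations; the trigger species is
    injected at t=0.  The first ``dead_time_s`` seconds (mixing and shaking
    before the first read) produce no samples.
    """

    kind: str
    initial: dict
    trigger_species: str | None
    trigger_nM: float
    duration_s: float
    interval_s: float
    dead_time_s: float = 30.0

    def __post_init__(self):
        if any(c < 0 for c in self.initial.values()) or self.trigger_nM < 0:
            raise ValueError("concentrations must be >= 0")
        if not self.duration_s > self.dead_time_s >= 0:
            raise ValueError("need duration > dead_time >= 0")
        if self.interval_s <= 0:
            raise ValueError("sampling interval must be positive")

    def full_initial(self) -> dict:
        init = dict(self.initial)
        if self.trigger_species is not None:
            init[self.trigger_species] = (
                init.get(self.trigger_species, 0.0) + self.trigger_nM
            )
        return init

    def sample_times(self) -> np.ndarray:
        t = np.arange(self.dead_time_s, self.duration_s + 0.5 * self.interval_s,
                      self.interval_s)
        return t


@dataclass(frozen=True)
class NoiseModel:
    """Additive + proportional Gaussian signal noise.

    sd(t) = sqrt(additive_sd^2 + (proportional_sd * signal(t))^2).
    ``additive_sd=None`` means 0.5% of the dataset's full-scale (maximum
    noiseless) signal.
    """

    additive_sd: float | None = None
    proportional_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.additive_sd is not None and self.additive_sd < 0:
            raise ValueError("additive_sd must be >= 0")
        if not 0 <= self.proportional_sd < 1:
            raise ValueError("proportional_sd must be in [0, 1)")


NOISELESS = NoiseModel(additive_sd=0.0, proportional_sd=0.0)


@dataclass
class SyntheticDataset:
    """One well's synthetic data plus its ground truth."""

    label: str
    variant: str
    design: ExperimentDesign
    network: NetworkModel
    true_rates: RateSet
    truth: Trajectory
    signals: dict
    conc: dict
    observables: dict
    seed: int


@dataclass
class Study:
    """A multi-well, multi-condition synthetic study."""

    preset: str
    seed: int
    noise: NoiseModel
    datasets: list
    metadata: dict = field(default_factory=dict)

    def select(self, **conditions) -> list:
        """Datasets whose design metadata match all given key=value pairs."""
        out = []
        for ds in self.datasets:
            meta = {"variant": ds.variant, **ds.design.initial,
                    "trigger": ds.design.trigger_nM, **(ds.truth.metadata or {})}
            if all(meta.get(k) == v for k, v in conditions.items()):
                out.append(ds)
        return out


def generate_traces(
    design: ExperimentDesign,
    network: NetworkModel,
    true_rates: RateSet,
    calibrations: Mapping[str, CalibrationCurve],
    noise: NoiseModel = NOISELESS,
    *,
    label: str = "well",
    variant: str = "",
) -> SyntheticDataset:
    """Simulate one well and emit noisy per-channel signal traces.

    The network is integrated from the post-injection initial condition;
    samples before the dead time are dropped; each channel's noiseless
    signal receives independent Gaussian noise per the noise model.  The
    noiseless ground-truth trajectory is returned alongside.  Identical
    inputs (including the noise seed) give bit-identical outputs.
    """
    obs_times = design.sample_times()
    grid = np.concatenate(([0.0], obs_times))
    truth = integrate(network, true_rates, design.full_initial(), grid)
    truth.metadata.update(design=design, label=label, variant=variant)

    rng = np.random.default_rng(noise.seed)
    groups = observed_groups(network.kind)
    signals: dict[str, SignalTrace] = {}
    concs: dict[str, ConcentrationTrace] = {}
    observables: dict[str, dict] = {}
    for channel in sorted(calibrations):
        cal = calibrations[channel]
        clean = concentrations_to_signal(truth, cal, well_id=label)
        y = clean.signal[1:]  # drop t=0 (pre-read)
        add = noise.additive_sd
        if add is None:
            add = 0.005 * float(np.max(np.abs(clean.signal)))
        sd = np.sqrt(add**2 + (noise.proportional_sd * y) ** 2)
        noisy = y + rng.normal(0.0, 1.0, size=y.shape) * sd
        trace = SignalTrace(label, channel, obs_times, noisy,
                            metadata={"variant": variant})
        signals[channel] = trace
        if channel in groups:
            group = groups[channel]
            concs[channel] = signal_to_concentration(trace, cal, group)
            observables[channel] = observable_weights(cal, group)
    return SyntheticDataset(
        label, variant, design, network, true_rates, truth, signals, concs,
        observables, noise.seed,
    )


def _child_noise(noise: NoiseModel, master_seed: int, k: int) -> NoiseModel:
    return replace(noise, seed=int((master_seed * 100_003 + 7 * k + 1) % 2**31))


def _dataset(kind, initial, trigger, trig_c, dur, dt, rates, noise, seed, k,
             label, variant, dead=30.0, network=None):
    net = network or build_network(kind)
    design = ExperimentDesign(kind, initial, trigger, trig_c, dur, dt, dead)
    return generate_traces(
        design, net, rates, default_calibrations(net),
        _child_noise(noise, seed, k), label=label, variant=variant,
    )


def generate_study(
    preset: str,
    true_rates: Mapping[str, RateSet] | None = None,
    noise: NoiseModel = NOISELESS,
    seed: int = 0,
) -> Study:
    """Generate a full multi-condition study for one preset design.

    ``true_rates`` maps variant/candidate name to its RateSet; defaults to
    :func:`reference_rates` for the preset's network kind.
    """
    if preset not in PRESETS:
        raise KeyError(f"unknown preset {preset!r}; choose from {PRESETS}")
    datasets: list[SyntheticDataset] = []
    k = 0

    if preset == "fig2_binding":
        kind = "template_binding"
        for variant in MONOMER_VARIANTS:
            rates = (true_rates or {}).get(variant) or reference_rates(kind, variant)
            for t_conc in (2.0, 5.0, 10.0):
                datasets.append(_dataset(
                    kind, {"ML": 8.0}, "T", t_conc, 12_000.0, 60.0, rates,
                    noise, seed, k, f"{variant}_T{t_conc:g}", variant))
                k += 1

    elif preset == "fig3_discard":
        kind = "full_discard"
        for variant in MONOMER_VARIANTS:
            rates = (true_rates or {}).get(variant) or reference_rates(kind, variant)
            for t_conc in (2.0, 4.0):
                datasets.append(_dataset(
                    kind, {"ML": 8.0, "P": 50.0, "RQ": 20.0}, "T", t_conc,
                    20_000.0, 100.0, rates, noise, seed, k,
                    f"{variant}_T{t_conc:g}", variant))
                k += 1

    elif preset == "fig4_dimerization":
        kind = "dimerization"
        for variant in MONOMER_VARIANTS:
            rates = (true_rates or {}).get(variant) or reference_rates(kind, variant)
            for p_conc in (0.0, 50.0):
                datasets.append(_dataset(
                    kind, {"ML": 8.0, "N": 10.0, "P": p_conc, "RQ": 20.0},
                    "T", 2.0, 250_000.0, 2500.0, rates, noise, seed, k,
                    f"{variant}_P{p_conc:g}", variant))
                k += 1

    else:  # fig5_snp
        kind = "snp_detection"
        for cand in SNP_CANDIDATES:
            rates = (true_rates or {}).get(cand) or reference_rates(kind, cand)
            for p_conc in (0.0, 20.0):
                datasets.append(_dataset(
                    kind, {"X": 15.0, "RQ": 20.0, "S": 20.0, "Psnp": p_conc},
                    "PL", 10.0, 250_000.0, 2500.0, rates, noise, seed, k,
                    f"{cand}_P{p_conc:g}", cand))
                k += 1

    return Study(preset, seed, noise, datasets)


@dataclass
class StagedStudy:
    """Datasets for the three-stage rate-estimation protocol.

    ``binding``  — template-binding wells (stage 1: blocker/template
    exchange rates); ``reporter`` — reporter triggering by pre-prepared MP
    duplexes (stage 2, where the total monomer concentration is uncertain);
    ``recovery`` and ``discard`` — template recovery and full discard wells
    (stage 3 simultaneous fit).  ``nominal_monomer`` is the nominal prepared
    monomer concentration (nM); the data were generated at
    ``monomer_scale_true`` times nominal.
    """

    binding: list
    reporter: list
    recovery: list
    discard: list
    nominal_monomer: float
    monomer_scale_true: float
    variant: str
    seed: int
    noise: NoiseModel


def generate_staged_study(
    variant: str = "M1",
    noise: NoiseModel = NOISELESS,
    seed: int = 0,
    *,
    monomer_scale_true: float = 1.0,
    true_rates: RateSet | None = None,
    nominal_monomer: float = 8.0,
    n_points: int = 40,
) -> StagedStudy:
    """Generate the four dataset kinds the staged protocol consumes.

    The true prepared monomer concentration is ``monomer_scale_true`` times
    the nominal value in the reporter, recovery and discard wells — the
    uncertainty the eight-candidate enumeration resolves.
    """
    rates = true_rates or reference_rates("full_discard", variant)
    m0 = nominal_monomer * monomer_scale_true
    net_bind = build_network("template_binding")
    net_rec = build_network("template_recovery")
    net_disc = build_network("full_discard")
    rates_bind = RateSet({k: rates[k] for k in ("k_bind", "k_unbind")},
                         bounds=dict(rates.bounds))
    rates_rec = RateSet(
        {k: rates[k] for k in ("k_proof", "k_unproof", "k_rep")},
        bounds=dict(rates.bounds))

    def grid(duration):
        return duration, duration / n_points

    binding, reporter, recovery, discard = [], [], [], []
    k = 0
    for t_conc in (2.0, 5.0, 10.0):
        dur, dt = grid(12_000.0)
        binding.append(_dataset(
            "template_binding", {"ML": nominal_monomer}, "T", t_conc, dur, dt,
            rates_bind, noise, seed, k, f"bind_T{t_conc:g}", variant,
            network=net_bind))
        k += 1
    dur, dt = grid(6_000.0)
    reporter.append(_dataset(
        "template_recovery", {"MP": m0}, "RQ", 20.0, dur, dt, rates_rec,
        noise, seed, k, "reporter", variant, network=net_rec))
    k += 1
    dur, dt = grid(15_000.0)
    recovery.append(_dataset(
        "template_recovery", {"MT": m0, "RQ": 20.0}, "P", 50.0, dur, dt,
        rates_rec, noise, seed, k, "recovery", variant, network=net_rec))
    k += 1
    for t_conc in (2.0, 4.0):
        dur, dt = grid(20_000.0)
        discard.append(_dataset(
            "full_discard", {"ML": m0, "P": 50.0, "RQ": 20.0}, "T", t_conc,
            dur, dt, rates, noise, seed, k, f"discard_T{t_conc:g}", variant,
            network=net_disc))
        k += 1
    return StagedStudy(binding, reporter, recovery, discard, nominal_monomer,
                       monomer_scale_true, variant, seed, noise)


# ---------------------------------------------------------------------------
# competitive pool
# ---------------------------------------------------------------------------

def competitive_dimerization(
    variants: Sequence[str] = MONOMER_VARIANTS,
    rates_by_variant: Mapping[str, RateSet] | None = None,
) -> tuple[NetworkModel, RateSet]:
    """Dimerization network with all monomer variants sharing one pool.

    Per-variant species (ML_x, MT_x, MP_x, MN_x, MNR_x) compete for the
    shared template, second monomer, proofreader and reporter; per-variant
    rate constants are namespaced (``k_bind_M1`` etc.).  Mirrors the
    competitive-pool experiments in which equimolar blocked monomers are
    triggered together.
    """
    species: dict[str, Species] = {
        "T": Species("T", ("T",), frozenset({"template"})),
        "P": Species("P", ("P",), frozenset({"proofreader"})),
        "N": Species("N", ("N",), frozenset({"second_monomer"})),
        "RQ": Species("RQ", ("R", "Q"), frozenset({"reporter"})),
        "Q": Species("Q", ("Q",), frozenset({"quencher_product"})),
    }
    reactions: list[Reaction] = []
    values: dict[str, float] = {}
    for v in variants:
        rs = (rates_by_variant or {}).get(v) or reference_rates("dimerization", v)
        m, l = f"M{v}", f"L{v}"
        species[f"ML_{v}"] = Species(f"ML_{v}", (m, l), frozenset({"monomer"}))
        species[f"L_{v}"] = Species(f"L_{v}", (l,), frozenset({"blocker"}))
        species[f"MT_{v}"] = Species(f"MT_{v}", (m, "T"), frozenset({"monomer"}))
        species[f"MP_{v}"] = Species(f"MP_{v}", (m, "P"), frozenset({"waste"}))
        species[f"MN_{v}"] = Species(f"MN_{v}", (m, "N"), frozenset({"product"}))
        species[f"MNR_{v}"] = Species(f"MNR_{v}", (m, "N", "R"),
                                      frozenset({"product", "reporter"}))
        pairs = [
            ((f"ML_{v}", "T"), (f"MT_{v}", f"L_{v}"), f"k_bind_{v}", rs["k_bind"]),
            ((f"MT_{v}", f"L_{v}"), (f"ML_{v}", "T"), f"k_unbind_{v}", rs["k_unbind"]),
            ((f"MT_{v}", "P"), (f"MP_{v}", "T"), f"k_proof_{v}", rs["k_proof"]),
            ((f"MP_{v}", "T"), (f"MT_{v}", "P"), f"k_unproof_{v}", rs["k_unproof"]),
            ((f"MT_{v}", "N"), (f"MN_{v}", "T"), f"k_dim_{v}", rs["k_dim"]),
            ((f"MN_{v}", "RQ"), (f"MNR_{v}", "Q"), f"k_rep_{v}", rs["k_rep"]),
        ]
        for lhs, rhs, name, val in pairs:
            reactions.append(Reaction(lhs, rhs, name))
            values[name] = val
    net = NetworkModel("dimerization", list(species.values()), reactions)
    return net, RateSet(values, known=frozenset(values), bounds=_bounded(values))
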