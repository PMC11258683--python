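# Methods

`kinproof` models a family of enzyme-free kinetic-proofreading (KP) motifs
built from DNA strand displacement, and implements the analysis pipeline
such experiments require: mass-action simulation, fluorescence calibration,
synthetic plate-reader data, staged weighted-least-squares rate estimation,
and specificity statistics. This note records the models, the defaults and
their rationale, the numerical choices, and the limitations.

## Reaction networks

All species are single strands or duplexes named by their constituent
strands (ML is monomer M blocked by L; MT is monomer bound to template).
Five effective topologies are built by `build_network`:

| kind | reactions |
|---|---|
| `template_binding` | ML + T ⇌ MT + L |
| `template_recovery` | MT + P ⇌ MP + T; MP + RQ → MPR + Q |
| `full_discard` | union of the two above |
| `dimerization` | binding + proofreading pairs; MT + N → MN + T; MN + RQ → MNR + Q; optional leak ML + RQ → MLR + Q |
| `snp_detection` | PL + X ⇌ XP + Lk; XP + RQ → XPR + Q; XP + Psnp → W + X; W + S → WS |

Design choices:

- **Effective bimolecular steps.** Toehold- and handhold-mediated
  displacement proceed physically through transient three-strand
  intermediates, but fitted rate constants in this field are effective
  second-order constants, so each displacement is one bimolecular reaction.
  A `two_step_binding` option resolves template invasion into association
  (ML + T ⇌ MLT) and displacement (MLT ⇌ MT + L) for sensitivity analysis.
- **Reversibility.** Blocker/template exchange and proofreading are
  reversible (proofread monomers can rebind the template); reporter
  triggering and HMSD dimerization are irreversible, being strongly
  thermodynamically driven by design (hidden mismatches eliminated on
  product formation).
- **Variants are rate values, not topologies.** A matched vs mismatched
  monomer (or target vs SNP) differs only in its rate constants; the second
  toehold revealed by blocker removal is not represented structurally.
- **Conservation structure.** Because every reaction conserves the multiset
  of strands, per-strand copy-number vectors over species are automatic
  conserved quantities. They are validated in exact integer arithmetic at
  build time and monitored (1e-6 relative) on every trajectory.

## Kinetics engine

Internal units are nanomolar and seconds. Bimolecular constants are
accepted in M⁻¹ s⁻¹ (the unit in which such constants are reported, e.g. a
dimerization constant of 3.5×10⁵ M⁻¹ s⁻¹) and converted by 1e-9.
Deterministic integration uses LSODA with rtol 1e-8 and atol 1e-12 nM:
rate constants span several orders of magnitude, so a stiff-capable method
with tight tolerances is the safe default; tolerances are caller-adjustable
and a 10× tightening changes solutions by <1e-6 relative on all five
networks. Negative concentrations are clipped only on output, never during
integration.

The stochastic path is an exact direct-method Gillespie sampler (mandatory
seed; bimolecular propensity constants k/(N_A·V), homodimer factor
n(n−1)/2). It exists as an independent oracle: at ≥1e4 copies of the
scarcest species the ODE solution lies within 3 standard errors of
replicate means. One caveat discovered in testing: the SNP network holds
its probe-candidate intermediate near 0.5 nM, so at 1e4 copies of the
*limiting* species that intermediate is at low copy and the stochastic
mean shows a real finite-size (1/volume) shift of ~0.5%; the equivalence
check therefore runs that network at 1e5 copies, where the shift is gone.

## Observation model

Fluorescence is linear: signal = background + Σ slope·[species]. Two
channels are modeled: a Cy3-like channel reporting the monomer strand
(quenched while the blocker is bound) and an AlexaFluor-647-like channel
reporting opened reporter complexes; in the SNP network the reporter
itself carries the Cy3-like label. One slope is shared by all complexes
with the same fluorophore environment, which makes the calibration map
invertible for a reported species group; inversion requires group slopes
to agree within 1%. Quenched complexes keep a residual slope of 5% of the
unquenched value — quenching is strong but not total, and the unblocked
channel does receive a small blocked-monomer contribution; the fraction is
configurable and its true value is not known, so converted observables
carry the residual weight explicitly (`observable_weights`) and model
predictions use the same weights, keeping fits exact under the assumed
calibration.

The intermediate estimator subtracts the waste-channel concentration from
the unblocked-monomer concentration (linear interpolation onto the coarser
grid, clipped at zero). It is deliberately labeled crude: whenever the
reporter lags, the estimate is an upper bound on the true intermediate —
a bias that simulations in the test suite exhibit and assert.

## Synthetic data

The generator integrates a design (pre-mixed concentrations, a trigger
species injected at t=0, a sampling interval, a 30 s dead time emulating
mixing/shaking before the first read), maps to per-channel signals, and
adds Gaussian noise with sd(t) = sqrt(additive² + (proportional·signal)²).
Defaults: additive = 0.5% of the dataset's full-scale signal, proportional
= 2% — typical of plate-reader kinetics; both configurable, and every
dataset is bit-reproducible from its seed and carries its ground truth.

Preset designs encode the study conditions: binding (8 nM blocked monomer,
template series including 10 nM), full discard (8 nM monomer, 50 nM
proofreader, 20 nM reporter, 4 nM template trigger), dimerization (8 nM
monomer, 10 nM N, 50 nM proofreader or none, 2 nM template trigger, ~3-day
horizon), SNP probing (10 nM blocked probe into 15 nM candidate, 20 nM
reporter, 20 nM sink, with/without 20 nM proofreader), and a staged study
adding reporter-triggering wells from pre-prepared waste duplexes.

Default ground-truth rates are plausible effective constants chosen once:
matched template binding 2×10⁵ M⁻¹ s⁻¹, mismatched variants 5×/10× slower;
proofreading 1×10⁴ M⁻¹ s⁻¹ for the matched monomer, 15×/20× faster for
mismatched; reverse proofreading 1×10² M⁻¹ s⁻¹; reporters 1×10⁵ (waste)
and 1×10⁴ M⁻¹ s⁻¹ (SNP); dimerization 3.5×10⁵ M⁻¹ s⁻¹; sink 1×10⁶
M⁻¹ s⁻¹. These reproduce the qualitative phenomenology (matched monomer
binds fastest; proofreader strips mismatched monomers fastest; dimer
yields level without proofreading; discrimination factors of ~2.6–3.2 with
a discriminating proofreader; SNP discrimination ~2.5–3.3 at 20 nM
proofreader) but make no claim to match any experimentally fitted values.

What the generator does **not** emulate: instrument drift, photobleaching,
well-to-well calibration variation, pipetting error beyond the single
total-monomer scale factor, inner-filter effects, or temperature
variation. Passing recovery tests therefore demonstrates correctness of
the estimation machinery under the stated noise model, not robustness to
every artifact of real plate-reader data.

## Fitting

The objective is the weighted mean-squared error between predicted and
observed concentrations over traces and time points, with weight w1 = 1
for t < t1 and w2 = 0.2 for t ≥ t1; t1 is the per-trace plateau time.
Down-weighting post-plateau points keeps the fit anchored to the kinetics.
t1 defaults to the earliest time from which the trace stays within 2% of
its final value (an automated stand-in for a manual choice) and is
overridable per trace. The MSE is normalized by the total weight — the
argmin is unchanged, and values become comparable across problems.

Unknown rates are searched in log10 space within finite positive bounds
using bounded trust-region least squares from multiple starts (one at the
log-midpoint or a supplied start, the rest drawn uniformly in log space
from a seeded generator; default 8 starts, fewer suffice for 1–2 unknown
problems). Integration failures inside the search yield large finite
residuals so the optimizer retreats. Standard errors come from the
Gauss–Newton covariance in log space.

The staged protocol mirrors a three-stage estimation design:

1. **Binding stage.** Blocker/template exchange constants are fitted on
   template-binding data; they become known rates downstream.
2. **Reporter stage.** Reporter-triggering wells are prepared from waste
   duplexes at an imprecisely known total monomer concentration, so the
   reporter rate is fitted once per candidate concentration — eight
   candidates on an evenly spaced grid from 80% to 115% of nominal (5%
   steps).
3. **Joint stage.** For each candidate, the proofreading constants are
   fitted simultaneously to template-recovery and full-discard data (the
   two topologies share one unknown vector); the candidate minimizing the
   summed weighted MSE is selected, ties broken by lowest index and
   flagged.

Identifiability: with the proofreader in large excess, the reverse
proofreading constant is weakly constrained (its fitted values scatter far
from truth while the forward constants recover well); recovery assertions
therefore cover the identifiable set per network — exchange constants,
forward proofreading, reporter, dimerization and probe constants — and the
reverse constant is reported but not asserted.

## Specificity statistics

- **Discrimination factor** D_x:y = endpoint product yield of variant x
  over variant y at equal inputs. The endpoint is the final simulated or
  observed time; a convergence flag (yield change < 1% over the final 10%
  of the run) is reported with it. One terminological wrinkle: the
  quantity is defined on *product* yields (M′xN, or reported SNP probe),
  which is what equal-input yield ratios mean operationally, even where
  the intermediate's name (M′xT′) appears in prose definitions elsewhere.
- **Turnover number** = waste formed per template added; > 1 demonstrates
  catalytic template recycling.
- **Initial rate**: least-squares slope with standard error over a window
  defaulting to [first sample, time of 10% of plateau].
- **Enhancement report**: matched simulations with and without the
  proofreader, tabulating yields, times to half-yield, D in both arms and
  the improvement factor D_with/D_without.

## Idealized proofreading cycle

The reference model is a single recognition site binding two candidates
whose only difference is an f0-fold faster unbinding of the incorrect one,
applied at both discrimination points (the first bound state and the
activated state). The cycle — bind, activate, release (or incorporate into
product) — is linear in the site state, so the stationary distribution of
the 5-state master equation is solved exactly; enrichment is the
correct:incorrect product flux ratio. Drive is an explicit ratio of
clockwise to counter-clockwise rate products (tilting the two reverse
rates by 1/√drive each), not a free energy in physical units. The
canonical limits hold: enrichment = f0 at detailed balance, → f0² under
strong drive with slow product formation and unbinding fast relative to
activation (within 1% for f0 = 5–20 at drive 1e16; at moderate drive the
residual rebind flux, ∝ 1/√drive, visibly inflates the incorrect branch).

## Problem sizes

Default test and acceptance runs use 25–60 point time grids, 2–3 optimizer
starts for 1–2 unknown fits, 10 noise seeds for recovery and selection
statistics, and 5–6 stochastic replicates at 1e4–1e5 copies — sizes chosen
so the full pipeline (including ten staged-protocol replicates) completes
in minutes on a single core while leaving every statistical check with
adequate power.

## Known limitations

- Effective-rate topologies cannot capture sequence-level effects
  (mismatch position, toehold energetics) except through rate values.
- The competitive-pool builder namespaces per-variant species and rates;
  it shares the template/fuel/reporter pools but not cross-variant leak
  pathways.
- No Bayesian uncertainty or profile likelihoods; standard errors are
  local Gauss–Newton estimates.
- The observation model omits inner-filter effects, photobleaching and
  gain nonlinearity by design.
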