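# kinproof

Mass-action modeling, simulation and rate-constant estimation for
**kinetic-proofreading DNA strand-displacement networks**.

Kinetic proofreading (KP) spends chemical fuel to exploit a single binding
free-energy difference more than once, multiplying the discrimination
between a correct and a nearly-correct target. In an enzyme-free DNA
realization, a template strand T recognizes a blocked monomer ML by
toehold-mediated strand displacement (ML + T ⇌ MT + L); a proofreader fuel
strand P can strip the bound monomer into inert waste and recover the
template (MT + P ⇌ MP + T), while a second monomer N can instead capture
the intermediate into the dimer product (MT + N → MN + T). Mismatched
monomer variants bind the template more slowly *and* are proofread faster,
so the discard cycle suppresses incorrect product at both stages. The same
motif embeds into a single-nucleotide-variant detection network, where a
blocked probe discriminates a target strand from its point mutants.

`kinproof` provides, for this family of systems:

- **Reaction networks** (`kinproof.networks`) — validated builders for the
  five study topologies (template binding, template recovery, full discard,
  templated dimerization, SNP detection), with automatic per-strand
  conservation laws.
- **Kinetics** (`kinproof.kinetics`) — stiff mass-action ODE integration
  (nM/seconds; bimolecular constants in M⁻¹ s⁻¹) and an exact Gillespie
  sampler as an independent stochastic oracle.
- **Observation model** (`kinproof.observe`) — linear two-channel
  fluorescence calibration (Cy3-like monomer channel, AlexaFluor-647-like
  reporter channel), its inversion to concentrations, and the
  intermediate-by-channel-subtraction estimator.
- **Synthetic data** (`kinproof.synth`) — plate-reader-like studies at the
  study designs, with additive + proportional noise, injection-triggered
  time zero, dead time, and ground truth attached to every dataset.
- **Fitting** (`kinproof.fitting`) — the weighted least-squares objective

  MSE(K_un) = Σ_{j,t} w_j(t) ([M]_j(K_un, t) − [E]_j(t))² / Σ w,
  w_j(t) = w₁ = 1 for t < t₁, w₂ = 0.2 for t ≥ t₁,

  minimized over unknown rates K_un in log space with fixed known rates
  K_n (`RateFitModel` / `RateFitResults`, statsmodels-style), plus the
  staged protocol: binding rates first, then eight candidate reporter rate
  sets spanning the uncertain total monomer concentration, then a
  simultaneous recovery+discard fit per candidate and selection by total
  error.
- **Analysis** (`kinproof.analysis`, `kinproof.hopfield`) — discrimination
  factors D_x:y (endpoint product-yield ratios), catalytic turnover, initial
  rates, KP enhancement reports, and the exact steady state of the
  idealized proofreading cycle (enrichment f0 at equilibrium, → f0² under
  strong drive).
- **CLI** (`kinproof` command) — `simulate`, `synth`, `fit`,
  `discriminate`, `report` over CSV/YAML files.

## Worked example

Estimate rate constants from a noisy synthetic staged study whose true
monomer stock was 95% of nominal:

```python
from kinproof import generate_staged_study, staged_fit, NoiseModel

study = generate_staged_study(
    "M1", NoiseModel(proportional_sd=0.02, seed=42), seed=42,
    monomer_scale_true=0.95, n_points=25)
result = staged_fit(study, n_starts=2, seed=0)
print(result.summary())
```

```
Staged rate-constant estimation
==============================================
stage 1 (template binding):
  k_bind = 1.921e+05
  k_unbind = 8767
stage 2/3: 8 total-monomer candidates on scales [0.8, 0.85, 0.9, 0.95, 1, 1.05, 1.1, 1.15]
candidate selection (stage 3 total weighted MSE)
idx     scale     total error   picked
0         0.8         1.41817
1        0.85        0.653743
2         0.9        0.219642
3        0.95       0.0681624      <--
4           1        0.139701
...
selected monomer scale: 0.95
final rates:
  k_bind = 1.921e+05
  k_proof = 1.028e+04
  k_rep = 9.776e+04
  k_unbind = 8767
  k_unproof = 9602
```

The protocol recovers the template-binding constant (truth 2×10⁵ M⁻¹ s⁻¹),
forward proofreading (truth 1×10⁴) and reporter rate (truth 1×10⁵) within a
few percent, and picks the correct 0.95 monomer scale out of the eight
candidates. The reverse proofreading constant `k_unproof` is weakly
identifiable with the proofreader in large excess — its estimate scatters
and should be read as unconstrained (see `docs/methods.md`).

Quantify what proofreading buys in the dimerization network:

```python
from kinproof import kp_enhancement_report, reference_rates

rates = {v: reference_rates("dimerization", v) for v in ("M1", "M2", "M3")}
report = kp_enhancement_report(rates)
print(report.attrs["D_without_proofreader"])  # {'M2': 1.00, 'M3': 1.00}
print(report.attrs["D_with_proofreader"])     # {'M2': 2.64, 'M3': 3.18}
print(report.attrs["improvement_factor"])     # {'M2': 2.64, 'M3': 3.18}
```

Without the proofreader every variant eventually reaches the same dimer
yield (D ≈ 1, thermodynamic leveling); with 50 nM of a discriminating
proofreader the correct dimer dominates ~3-fold — the KP signature.

Or from the shell:

```sh
kinproof synth --preset fig3_discard --seed 7 --out-dir study/
kinproof discriminate --study study/manifest.yaml --out-dir analysis/
```

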