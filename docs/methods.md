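# Methods

## The models

`s100b_pbpk` simulates the whole-body distribution of S100B, a ~10.5 kDa
astrocytic calcium-binding protein used clinically as a blood biomarker of
blood–brain-barrier (BBB) dysfunction and brain injury.  Two
physiologically-based pharmacokinetic (PBPK) models are implemented as
compartmental ODE systems with physiological volumes and blood flows.

**Model 1** (`build_model1`) is a nine-organ whole-body network: lung,
brain, skin, bone, adipose, heart, kidney, muscle and gut, each split into a
parenchymal compartment and a vascular fraction.  Arterial blood perfuses
the vascular fractions, which return to venous blood; venous blood passes
through the lung vascular fraction back to the arterial pool, plus a small
arteriovenous shunt.  Lymphatics drain six organs' vascular fractions into a
12 L central lymph pool that empties into venous blood.  Transcapillary
exchange follows two-pore theory as a conservative antisymmetric flux

    J = (kf·C_par − kr·C_vf) · interstitialFlow        [ng/h]

with `kf = kr × 10,000` enforced on load (the shipped table prints rounded
kr values, e.g. 0.00 for muscle, which would sever re-uptake entirely; the
stated ratio is exact and is taken as authoritative).  The brain's exchange
is additionally gated by `BBB_Index ∈ [0, 1]`.  Renal elimination filters
the kidney parenchyma into urine at `RenalEliminationFactor × GFR`
(100 × 7500 ml/h with defaults).

**Model 2** (`build_model2`) keeps muscle, adipose and gut (interstitium /
vascular space pairs exchanging through first-order vascular-reflection
coefficients σ, with sieving lymphatics), a single-compartment kidney, and a
three-compartment brain: a clamped glial reservoir (50 ng/ml) feeding the
interstitium through `Trauma_Index`, the interstitium leaking into the
cerebral vasculature through `BBB_Index` and draining into central lymph
through a glymphatic flow (8.4 ml/h default).  Arterial blood extravasates
into saliva with no return path, so salivary S100B converges to the
flow-weighted time integral of the arterial level — a genuine plateau that
can exceed blood concentrations.  Urine receives
`EliminationFactor/TissuePartitionKidney × GFR × C_kidney` and loses mass
through a first-order voiding gate.

Both printed equation sets are excerpts of a larger reaction network and
are not mass-consistent as written; three corrections are required to make
the dynamics conservative and bounded, and all are implemented:

1. the brain↔vascular exchange is implemented as an antisymmetric flux
   (the one-sided form would grow without bound when kr = 0);
2. the brain vascular compartment includes its venous efflux at the
   tabulated 42,000 ml/h (without it, it integrates arterial input
   unboundedly);
3. the renal filtration gain printed against the organ balance is assigned
   to urine, with the same flux removed from the kidney.

The algebraic restatement of the trauma route (interstitium = glia ×
Trauma_Index) is treated as a description of the Trauma source term, not as
a constraint; a hard clamp would contradict the simulated recovery
behaviour.

## Numerical core

Every transport process in both models is linear in the source
compartment's concentration, so the right-hand side is assembled as
`dc/dt = A c` with clamped rows zeroed, giving the stiff integrator
(`scipy.integrate.solve_ivp`, BDF, rtol 1e-8 / atol 1e-11) an analytic
Jacobian.  Two auxiliary states accumulate all external inputs (clamped
sources) and outputs (terminal sinks), so the audit identity

    total mass + cumulative out − cumulative in = constant

holds to solver tolerance along every trajectory (residuals are ~1e-15
relative in practice).  Events (step changes of BBB_Index, Trauma_Index,
glymphatic flow, GFR, salivary flow) restart the integration with a rebuilt
matrix; integrating across an event is equivalent to splitting the run at
the event time to ~1e-8 absolute.  A fixed-step fourth-order propagator
(`integrate_fixed_step`; for constant-coefficient linear systems classical
RK4 reduces exactly to the fourth-order Taylor stepper) serves as the
reference oracle: at dt = 2e-4 h (Model 1, whose fastest rate is the
~3100/h lung vascular turnover) and 1e-3 h (Model 2) it agrees with the
adaptive path to better than 1e-5 relative over 25 h.

**Steady state.**  `find_steady_state` implements the criterion
max |dc/dt| / max(|c|, 1e-9) < 1e-6 over non-clamped compartments
(t_max 1000 h).  This criterion is meaningful for systems approaching a
nonzero fixed point, but both full models relax by slow exponential decay,
whose relative rate equals the decay eigenvalue and is scale-invariant — it
never falls below 1e-6 until the state underflows the floor.  The scenario
protocols therefore use an *operational* steady state: the state at a fixed
readout horizon, 10 h unless stated, which is the convention under which
the sensitivity analyses are also reported.  Consequences of this choice
are discussed under Limitations.

## Unit handling

The shipped parameter tables mix milliliters with liters and hours with
minutes.  Configs mirror the tables row for row (name, value, unit); the
loader converts everything to ml / ng / h and logs each conversion.  The
`EliminationFactor` (100 /min) and `TissuePartitionKidney` (0.1 /min)
appear only as a ratio, which is conversion-invariant (1000).  Parameters
that no equation references (TissueFactor, AdiposeTissueFactor, Excretion,
kf_1, BloodFlowArteryToSaliva, the duplicate BloodFlowLungToArterial, BBB
100/min, EmptyingSaliva, SigmaBrainLymphatic, and the whole-organ volumes
of Model 2) are carried as inert values and logged as such on load.

The printed blood-flow table does not balance volumetrically: the lung
returns 313,980 ml/h to the arterial pool while the listed organ outflows
plus the shunt account for 279,739 ml/h (the remainder corresponds to the
circulation of organs deliberately excluded, e.g. the portal bed).  Solute
mass balance is unaffected — every edge carries solute at its source
concentration — so the validator reports the imbalance instead of refusing
the model.  One visible consequence is a ~12 % concentration offset between
arterial and venous pools at quasi-steady state.

## Global sensitivity analysis

Inputs are initial S100B concentrations of selected compartments (for
Model 2 the conventional 11: venous, arterial, central lymph, the four
vascular spaces, and the four interstitia including brain).  Sampling uses
a scrambled Sobol sequence (`scipy.stats.qmc.Sobol`, seeded) arranged in
Saltelli blocks; first-order indices use the Saltelli-2010 estimator and
total-order indices the Jansen estimator; the unexplained fraction is
1 − ΣS1 per output.  Sampling bounds default to [0, 2 × table value] for
compartments with nonzero initial levels and [0, 1] ng/ml otherwise, and
are user-overridable.  Outputs are time-integrated (or terminal)
concentrations of venous/arterial/lymph pools over a 10 h horizon.

Because the dynamics are linear and time-invariant, the map from sampled
initial state to any such output is affine; the default evaluator
reconstructs it exactly from n_inputs + 1 integrations (superposition) and
evaluates the 13,000-run Saltelli design by dot products.  The generic
per-sample evaluator is retained and cross-checked against the fast path;
the estimators themselves are validated against the closed-form variance
decomposition of an additive linear function.  With 1000 samples the
unexplained fraction on the full Model-2 analysis stays within ±0.023 of
zero across seeds, consistent with purely additive (linear) dynamics.

## Scenario protocols

* **BBB disruption** (`scenario_bbbd`): baseline vs disrupted runs, from
  t = 0 or stepped after a settle period.
* **Empty organs** (`scenario_empty_organs`): zeroes muscle/adipose/gut
  S100B and follows their glymphatically-driven reloading over 100 h; the
  all-sources-off control (organs, blood, kidney zeroed; BBB, trauma and
  glymphatics closed) keeps venous blood at exactly zero.
* **GFR sweep** (`scenario_gfr_sweep`): GFR × BBB_Index grid; venous
  steady levels fall monotonically with GFR, and GFR = 0 is flagged as
  unbounded accumulation (rising venous/vascular traces with no steady
  state within 200 h).  Note the *interstitial* muscle pool can still fall
  at GFR = 0 while its vascular space rises: uptake only reverses once
  blood exceeds the interstitial equilibrium level.
* **Saliva** (`scenario_saliva`): crevicular flows of 4 and 2 ml/min; at
  4 ml/min the salivary plateau (~6 ng/ml by 50 h) exceeds every blood
  level reached, with a time-to-90 % two orders slower than venous.
* **Double insult** (`scenario_double_insult`): settle 10 h, first
  sustained barrier opening, second step after a 10 h gap.  The second
  venous increment is non-increasing in the first episode's BBB_Index
  (interstitial depletion) and is restored ~3600-fold by Trauma_Index = 1.
  The gap and settle times are declared defaults, not fitted; the
  depletion ordering is robust to them.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| BBB_Index | 0 | – (1/h gate) | brain→blood permeability, 0 intact … 1 open |
| Trauma_Index | 0 | – (1/h gate) | astrocytic release into brain interstitium |
| Glymphatics | 8.4 | ml/h | brain interstitium → central lymph |
| GFR (Model 1 / 2) | 7500 / 10 | ml/h | renal filtration drive |
| interstitialFlow | 1.0 | ml/h | scales all Model-1 two-pore exchange |
| SalivaryBloodFlow | 60 | ml/h | arterial extravasation into saliva |
| Glia.S100B | 50 | ng/ml | clamped astrocytic reservoir |
| Interstitium brain S100B | 10 (or 1) | ng/ml | the pivotal initial condition |

## Limitations

* The relative-rate steady-state criterion cannot certify the decaying
  late-time regimes of either full model; all "steady-state" readouts are
  horizon-based and say nothing about t → ∞ behaviour.
* Model 1 with an intact BBB has essentially no open elimination route
  (filtration draws on a kidney parenchyma that refills only at
  kr × interstitialFlow ≈ 0.014 ml/h), so venous levels keep accumulating:
  they cross the 0.1 ng/ml clinical ceiling at ~7.8 h and would plateau
  near 1.2 ng/ml only after thousands of hours.  The sub-ceiling behaviour
  reported for this configuration is reproduced only at display horizons
  shorter than ~8 h.
* The Model-1 brain exchange magnitude (kf_brain × interstitialFlow =
  0.02 ml/h) moves ~0.2 ng/h at the tabulated brain level — a strictly
  positive but quantitatively negligible BBBD response compared with
  peripheral organ fluxes; sensitivity rankings therefore never show the
  brain dominating Model-1 outputs.
* GSA rankings depend on the (unpublished) sampling bounds; under the
  declared bounds rule, large zero-initial pools (bone; the fluids' own
  initial levels) carry top indices.  Rankings restricted to nonzero-level
  organ inputs are the more interpretable view.
* No spatial/PDE transport, no saliva swallowing, no S100B degradation or
  metabolism, no molecular-size, sex/age or allometric covariates; portal
  circulation, spleen, thymus and pancreas are excluded by design.
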