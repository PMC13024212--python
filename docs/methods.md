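# Methods

## Model structure and assumptions

The model tracks five lumped intracellular pools (mM): cysteine C, reduced
glutathione G, reactive oxygen species R, hydrogen sulfide S and ATP A.
It is a deliberate reduction: no glycolysis, NADPH metabolism, one-carbon
pathways, oxygen transport, cell growth or death, and no spatial structure.
Extracellular cysteine (Cext) is a constant parameter — medium depletion
over the 24 h window is neglected — and hypoxia enters as a fixed external
level H ∈ [0, 1] rather than a dynamic oxygen balance.

Two structural choices deserve emphasis:

- **Stoichiometric asymmetry.** The cysteine drain toward glutathione in the
  C equation is VG·C/(KG+C) *without* the hypoxia amplification (1+αH),
  while GSH production in the G equation carries it. The amplification is
  read as increased synthetic efficiency under demand, not increased
  substrate consumption; the asymmetry is kept as modelled and not
  "corrected" to conserve cysteine mass.
- **Bilinear detoxification.** ROS removal is kRG·G·R (mass action in both
  species). Because the same product appears in both the G and R equations,
  the vector (0, G, −R, 0, kAO(1−H)G/kAd) is a right null vector of the
  Jacobian at *every* state: rank(J) ≤ 4 always, and each steady state has
  one exactly-zero eigenvalue. Steady states are therefore one-parameter
  families (a hyperbola G·R = const in the (G, R) plane) and at best
  *normally attractive* — transverse perturbations decay, the neutral
  coordinate does not.

A practical consequence of the neutral direction: which point of the family
a trajectory reaches depends on the transient. Warm-started and cold-started
continuations agree exactly in C\*, S\* and in the product G\*·R\*, but the
individual G\* (and hence ATP\* through the kAO·G·(1−H) term) can differ by
a small path-dependent offset (~0.3% at repository defaults). The
continuation tests assert the transverse invariants and bound the neutral
offset rather than demanding bitwise path independence.

## Parameters, units, defaults

| name  | meaning                                   | unit       | default |
|-------|-------------------------------------------|------------|---------|
| kin   | cysteine uptake rate constant             | h⁻¹        | 0.292   |
| Cext  | extracellular cysteine                    | mM         | 0.2626  |
| VG    | max cysteine→GSH flux                     | mM h⁻¹     | 0.1874  |
| KG    | Michaelis constant, GSH branch            | mM         | 0.15    |
| VS    | max cysteine→H₂S flux                     | mM h⁻¹     | 0.2918  |
| KS    | Michaelis constant, H₂S branch            | mM         | 0.25    |
| kC    | basal cysteine consumption                | h⁻¹        | 0.05    |
| α     | hypoxia amplification, GSH synthesis      | –          | 0.5     |
| kRG   | GSH–ROS detoxification constant           | mM⁻¹ h⁻¹   | 10.0    |
| kROS  | basal ROS generation                      | mM h⁻¹     | 0.037140|
| β     | hypoxia amplification, ROS generation     | –          | 0.5     |
| kS    | H₂S clearance                             | h⁻¹        | 0.3     |
| kAO   | redox-permissive oxidative ATP coefficient| h⁻¹        | 0.6     |
| kAS   | H₂S-supported ATP coefficient             | h⁻¹        | 0.4     |
| kAd   | ATP decay                                 | h⁻¹        | 0.25    |
| H     | hypoxia level                             | –          | 1.0     |

These are repository defaults chosen for plausible magnitudes (sub-mM
medium cysteine, mM-scale GSH, hour-scale turnover), not published
estimates. The calibrated subset is {kin, VG, VS, kROS, β}; the rest are
fixed. kRG's units follow from dimensional homogeneity of the triple
product. Units are checked by a scaling property test: multiplying all
concentrations by λ together with (kRG/λ, kROS·λ, VG·λ, VS·λ, KG·λ, KS·λ,
Cext·λ) rescales every flux term by exactly λ.

**Redox-balanced construction of kROS.** A strict steady state requires
(1+αH)·VG·C\*/(KG+C\*) = (1+βH)·kROS, where C\* solves the H-independent
cysteine balance. With α = β this reduces to kROS = VG·C\*/(KG+C\*), one
value valid for *every* H — so the default parameter file sets α = β = 0.5
and kROS to that balanced value (`cysredox.model.balanced_kros`). Off this
manifold, the G−R difference drifts at a constant rate and no equilibrium
exists; `find_steady_state` then reports non-convergence (with the residual
concentrated in the G/R components) instead of raising. Parameter validation
rejects H outside [0, 1] rather than clamping, so configuration errors
surface immediately; the source magnitudes Cext and kROS may be zero (sources
off), all other rates and Michaelis constants must be strictly positive.

## Numerical choices

- **Integration.** Default solver LSODA, rtol 1e-8 / atol 1e-10, with dense
  output (the bilinear G·R term can turn stiff when R grows). A compiled
  fixed-step RK4 (`method="rk4"`, default step 0.02 h) serves
  evaluation-heavy loops — calibration inner iterations, bootstrap
  replicates, Sobol designs — and agrees with the adaptive solution to
  better than 1e-6 (absolute, mM) over 24 h at defaults.
- **Time-averaged fluxes.** Composite Simpson quadrature on a 2001-point
  resampling of the dense solution; refinement to 4001 points moves results
  by < 1e-6 relative. The two state-independent terms (uptake, ROS
  production) are returned exactly without touching the trajectory, which
  also lets the objective skip the ODE solve entirely when every mapped term
  is state-independent (this is exact, not an approximation).
- **Steady states.** Integrate-to-convergence with residual threshold
  max|dX/dt| ≤ 1e-10 mM h⁻¹ and t_max 1e5 h, in geometrically growing
  chunks; root-finding is avoided because plain Newton is singular on the
  neutral direction. An optional pseudo-inverse Newton polish (used by the
  continuation by default) pushes the residual to rounding level.
  Non-convergence is a reported outcome, never an exception.
- **Calibration.** Bounded trust-region least squares (`scipy
  least_squares`, method "trf", tolerances 1e-12) on the vector of relative
  flux errors, restarted from uniform draws within the bounds; 25 starts by
  default, all driven by one seed. A warning is emitted when fewer mapped
  observations than calibrated parameters are available. How ROS-linked
  parameters could be constrained by real extracellular data is left to
  explicit user mappings: no measured metabolite obviously maps onto ROS
  production, so the default mapping covers only cysteine→uptake, and
  synthetic studies that recover kROS/β use a clearly-labelled hypothetical
  `ros_probe` observable.
- **Bootstrap.** Multiplicative Gaussian noise on fluxes, v → v(1+ε),
  ε ~ N(0, σ²), default σ = 0.05 — a documented choice standing in for
  unspecified "observed experimental variability". Percentile CIs use
  linear-interpolation quantiles at 2.5/97.5%; CIs are flagged unreliable
  below 40 replicates; failed replicates are excluded and counted rather
  than retried. CV is reported in percent of the mean.
- **Sobol analysis.** Scrambled Sobol sequences (scipy `qmc`) over a box of
  center±20–30% (wide-scan option ±100% with positivity floor); Saltelli
  pick-freeze design with N(p+2) evaluations, Saltelli-2010 estimator for
  S1 and Jansen for ST, bootstrap error bars from resampling sample rows.
  Negative estimates with magnitude below 1e-3 are reported as zero with a
  clipped flag (raw values retained); indices are direction-free by
  construction, so a separate centered-difference diagnostic
  (`effect_direction`) reports effect signs. A failed model evaluation drops
  its whole pick-freeze sample to preserve estimator pairing; > 1% failures
  aborts.
- **Region classification.** Explicitly heuristic: the slope |dATP\*/dH|,
  normalised by the ATP range of the scan, is thresholded at 5% (plateau)
  and 50% (collapse) of range per unit H, with boundaries placed at first
  crossings and quoted with the grid step as uncertainty. No bifurcation
  detection is claimed or implemented; at balanced defaults the ATP\*(H)
  curve is close to linear and classifies as a single region.
- **Eigenvalues.** Dense general solver on the analytic 5×5 Jacobian;
  structural-zero detection threshold 1e-9 (absolute, h⁻¹), comfortably
  above the ~1e-15 rounding floor and below the slowest transverse rate
  (0.25 h⁻¹ at defaults).

## Synthetic data: what it emulates, what it does not

The generator mirrors a 2×2 exometabolomics design — {normoxia, hypoxia} ×
{control, cysteine-supplemented medium} (Cext 0.2 / 0.6 mM) — observed
through time-averaged fluxes over 24 h with independent multiplicative
Gaussian noise, plus a concentration-pair variant whose stored fluxes are
recomputed from the emitted pairs so the round trip is bit-exact (final
concentrations are kept nonnegative by bounded rejection-resampling). All
randomness flows from one seed; identical specs give byte-identical files.

It does **not** emulate: correlated measurement errors across metabolites,
metabolite-specific noise magnitudes, medium depletion feeding back on
uptake, multi-timepoint kinetics, or cell-line heterogeneity. Passing
recovery tests therefore demonstrates correctness of the inference
machinery under the stated noise model, not robustness to real-data
pathologies.

## Problem sizes used in the shipped checks

Sobol oracle checks run at N = 2¹⁴ (additive) and 2¹⁵ (Ishigami); model
pipeline properties at N = 2¹² with p = 5 (and p = 3 for the
domain-width ranking comparison). The bootstrap CV check uses B = 500; the
CI-coverage study 200 meta-replicates at B = 200 on the closed-form uptake
sub-problem, where each re-calibration is exact and cheap. The coverage band
93–97% around the nominal 95% corresponds to about ±1.3 binomial standard
deviations at 200 replicates, so occasional excursions at other seeds are
expected; the library-level property test uses a wider band accordingly.
The stability scan uses an 11-point H grid.

## Known limitations

- The flux-based objective cannot identify intracellular pool sizes or
  enzyme kinetics; intracellular trajectories are latent constructs
  consistent with extracellular fluxes.
- With the default (cysteine-only) mapping, the five-parameter calibration
  is underdetermined; meaningful recovery requires mappings that expose the
  GSH and H₂S branches, and ROS-parameter recovery requires a hypothetical
  observable.
- Steady-state existence requires the redox balance; generic parameter sets
  have no equilibrium and the continuation reports non-convergence.
- The ATP level depends on the neutral (G, R) coordinate, so steady-state
  ATP carries a small path-dependent component (see above); quantitative
  ATP\*(H) curves should be read with that caveat.
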