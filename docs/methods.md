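# Methods

## Models

Relative inhibition I(D) of cell viability at drug concentration D (nM):

* **monophasic** — I = D/(D + IC50). Single-target binding; the classical
  IC50 readout.
* **modified Hill** — I = I_max · Dⁿ/(IC50\*ⁿ + Dⁿ) with the zero-dose
  intercept fixed at 0 (no inhibition without drug). I_max < 1 signals that
  saturating the target does not abolish viability; n < 1 appears as
  negative cooperativity without a mechanistic basis, which is why the Hill
  fit is reported descriptively but never preferred.
* **biphasic** — I = F₁·D/(D + K_d1) + (1 − F₁)·D/(D + K_d2). Two
  independent inhibition phases: a target-specific fraction F₁ of viability
  with affinity K_d1 and an off-target fraction F₂ = 1 − F₁ with affinity
  K_d2. F₂ is derived, never fitted separately.

The models are nested: biphasic reduces to monophasic at F₁ = 1 or
K_d1 = K_d2; Hill reduces to it at I_max = 1, n = 1. Fitted RMSEs therefore
satisfy RMSE(biphasic) ≤ RMSE(monophasic) and RMSE(hill) ≤ RMSE(monophasic),
which the test suite enforces across hundreds of random curves.

All observed viability is compared to model viability V = 1 − I on the
viability scale; the fitting objective is the RMSE over **all replicate
points** (not replicate means — the stricter choice, configurable via
`use_replicate_means`).

Closed-form ICx inversions exist for all three models; the biphasic one is
the unique positive root of the quadratic obtained by clearing denominators,
(1 − x)D² + [F₁K_d2 + (1 − F₁)K_d1 − x(K_d1 + K_d2)]D − xK_d1K_d2 = 0,
cross-checked against bisection to 1e−9 relative in the tests.

## Fitting

Bounded trust-region least squares (`scipy.optimize.least_squares`, TRF,
x_scale = 1) launched from a deterministic multi-start lattice; the reported
fit is the lowest-RMSE start. To keep fits fast the lattice is prefiltered:
the objective is evaluated at every start and the local optimizer runs only
from the overall best starts plus the best start of every F₁ (or I_max)
branch, so no region of the lattice is silently dropped and the selection is
deterministic and scale-equivariant. Kds are optimized in log10 space.
Bounds:

* IC50 / K_d1: two decades below the lowest tested dose to two decades above
  the highest;
* K_d2: same lower bound, upper bound six decades above the top dose, so
  "largely resistant" plateaus (K_d2 > 1000 µM) are representable. Values
  beyond 1000 µM are displayed as "> 1000 µM"; the numeric value is kept.
* I_max ∈ (0, 1.2], n ∈ [0.05, 10], F₁ ∈ [0, 1].

Parameters ending on a box bound are flagged (`at_bound`), never errors —
a flat curve legitimately pins I_max at its floor or IC50 at its ceiling.

**Identifiability.** Phase 1 is defined as the high-affinity phase
(K_d1 ≤ K_d2); fits arriving in the mirrored orientation are relabeled
(F₁ ↔ 1 − F₁). When the data are effectively single-phase the biphasic
parameters are unidentified along a ridge (K_d1 = K_d2 with arbitrary F₁, or
a zero-weight phase at any Kd). Equal-RMSE ties (within 1e−9) are broken
toward the **largest F₁**, then smallest K_d1, then smallest K_d2, so a
noiseless single-target curve deterministically reports the monophasic limit
F₁ = 100% with K_d1 = IC50 rather than an arbitrary point on the ridge.

Determinism: identical curve + configuration reproduce bit-identical fits
(fixed start lattice, no randomness in the optimizer). Scale equivariance:
rescaling all concentrations by c rescales fitted Kds by c and leaves F₁ and
RMSE unchanged, because the optimization is translation-invariant in log
dose.

Model preference: biphasic is preferred over monophasic only when
RMSE(mono)/RMSE(biphasic) exceeds `rmse_ratio_threshold` (default 2.0);
below that the extra parameters are judged to be fitting noise. When both
RMSEs are below 1e−9 the fits are exact and the ratio is reported as 1.

## Classification

Applied to normalized, QC-passed curves, in order:

1. **LV** — mean dose-wise viability < `lv_threshold` (default 0.35) and
   dose-mean range < 0.2: low readings regardless of dose, not a drug
   effect.
2. **NI** — maximum inhibition < `ni_threshold` (default 0.20).
3. **MP** — the response is effectively single-target: fitted F₁ ≥
   `f1_mp_threshold` (0.85, the canonical cutoff) **or** the monophasic fit
   is not clearly beaten (RMSE ratio ≤ `rmse_ratio_threshold`). The ratio
   guard exists because on noisy single-target data the biphasic fit absorbs
   noise by collapsing the phases or parking a negligible-weight phase at a
   bound, leaving the raw F₁ meaningless; MP responses are exactly those
   that both equations fit similarly well.
4. **BP** — everything else: dose-dependent inhibition with a genuine
   second phase.

The LV and NI thresholds are package choices (the category descriptions are
qualitative); 0.85 for MP is the established cutoff. All are configurable.
K_d2 is flagged unreliable when the top tested dose is below 10·K_d1 — a
9-point screen topping out at 1.28 µM cannot constrain a micromolar second
phase.

**QC.** "Obvious scattering" is operationalized as two rules: reject when
the best of the three model fits leaves RMSE > 0.15, or when viability rises
by more than 0.25 between adjacent doses (replicate means). Each rejection
carries its reason code. Because published screen retention rates depended
on an unstated manual rule, they are not a reproduction target.

## Normalization

Relative viability = raw reading / control. When any drug-treated reading
exceeds the control (low-dose growth stimulation), the highest reading
replaces the control, anchoring viability at 1 at that dose. Output is
scale-free: multiplying all raw readings by a constant changes nothing.

## Synergy

ICx extraction is either log-linear interpolation of replicate-mean
inhibition between the bracketing measured doses (the reproducible analogue
of reading the level off a graph; the default) or the closed-form ICx of the
best biphasic fit. The two agree within 5% on noiseless model data at the
canonical grid densities. Levels never reached by a curve are flagged
unattainable, and the corresponding DRI is reported as not calculated (NC)
rather than extrapolated.

The dose reduction index is the aggregate form
DRI = ICx_a·ICx_b / (ICx_ab·(ICx_a + ICx_b)) with ICx_ab the **total**
combined dose of the 1:1 mixture (per-drug doses are half of it). It is
symmetric in the two drugs and unit-invariant. This is deliberately not the
classical per-drug Chou–Talalay DRI pair: the aggregate form is what the
combination worked examples use (500 nM and 790 nM single-agent IC50s with
a 28 nM combination IC50 give 10.94 ≈ 11-fold). Note DRI = 0.5, not 1, when
the combination curve coincides with both single agents, and ~0.25 under
pure dose-sharing with a single driver; values well above 1 indicate
synergy.

## Synthetic data

`simulate_curve` draws viability = 1 − I_truth(D) + ε, ε ~ N(0, noise_sd)
independently per replicate well, truncated at a −0.05 floor. Defaults
emulate the manual assay: 16-point 2× series from 0.6 nM (top ≈ 20 µM),
noise sd 0.05 on the viability scale (consistent with typical triplicate
error bars), 3 replicates. The GDSC-style layout is the 9-point 2× series
from 5 nM to 1.28 µM with one well per dose. The 16-point grid's endpoints
are honored by a 2× series because 0.6 nM × 2¹⁵ ≈ 19.7 µM.

`simulate_combination` composes independent viability fractions: f_a and
f_b are driven solely by drug A's / B's target, f_shared by both,
f_resistant by neither; a drug inhibits its own fraction(s) with its target
affinity and every other fraction through its off-target Kd; in the 1:1
combination each drug is applied at half the total dose and survival
multiplies across fractions. Single-agent arms are then exactly biphasic.
This construction exists to exercise the pipeline with known ground truth —
it is not a claim about biology. What passing tests show is that the
*analysis* recovers the generating parameters and labels under Gaussian
replicate noise; real screens additionally contain plate effects, edge
artifacts, and non-Gaussian outliers that the generator does not emulate
(the QC rules address these only qualitatively).

`fixture_panel` emits a deterministic labeled panel (LV, NI, MP, BP,
scattered) with parameters placed well away from every classification
threshold, so label-recovery failures indicate analysis defects rather than
borderline draws.

## Problem sizes and numerics

The property and recovery studies in the test suite use 9-point
single-replicate curves for bulk checks (500 random curves for the nesting
property; 50 for the optimizer-vs-lattice comparison at 50 points per axis)
and the 16-point triplicate layout for the noise-recovery study (50 seeds,
sd 0.05), sizes chosen to exercise the estimators at the canonical grid
densities. Optimizer tolerances are xtol = ftol = gtol = 1e−12; RMSE ties
below 1e−9 are treated as exact. Degenerate inputs (constant viability,
levels above a curve's maximum inhibition) are flagged, not raised, except
where the input is unusable (fewer than 4 distinct concentrations, empty
curves, missing controls).

## Known limitations

* No confidence intervals on fitted parameters (bootstrap is future work).
* The biphasic model assumes exactly two phases with Hill slope 1 each;
  genuine cooperativity or three-phase responses will surface as lack of
  fit, not as extra parameters.
* Growth stimulation above control is clipped by renormalization, not
  modeled.
* K_d2 estimates from screens whose top dose is far below K_d2 are reported
  but flagged; they are bound-limited, not measurements.
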