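# Methods

This note records the models implemented in `lumidyn`, the defaults and why
they were chosen, what the synthetic data do and do not emulate, and the
numerical choices that affect results.

## Units

Concentrations in μM, time in s, bimolecular rate constants in μM⁻¹s⁻¹,
unimolecular in s⁻¹, distances in Å. Every reader/writer assumes these; no
unit conversion is performed anywhere.

## Kinetic mechanisms and simulation

Five mass-action presets are exposed (`ONE_STEP`, `INDUCED_FIT`,
`CONF_SELECTION`, `CYCLE_RAPID_EQ`, `CYCLE_IRREV`). The engine is a general
mass-action integrator internally, but only these five schemes are public:
arbitrary user networks are out of scope. Fixed constants encode the
modelling assumptions of the catalytic cycle: substrate binding and product
rebinding are taken as diffusion-limited at 100 μM⁻¹s⁻¹, which makes the
cycle's steady-state constants identities of the remaining rates
(kcat = k₊₂, Km = k₋₁/100, Kp = k₊₃/100) and mimics the rapid-equilibrium
assumption; the irreversible variant (k₋₁ = 0) exposes kcat/Km = k₊₁.

Integration uses LSODA with an analytic Jacobian, rtol 1e-8 and atol
1e-10 μM. Concentration undershoots within 1e3·atol of zero are clamped;
anything larger propagates as a solver failure. Conservation of total
enzyme and substrate moiety holds to 1e-6 relative along all tested
trajectories.

The observed-rate laws are evaluated exactly as written above
(`observed_rates_analytic`). The printed conformational-selection slow-rate
law is dimensionally inconsistent (the leading k₊₁ multiplies the bracket
in the numerator but only the first product of the denominator); it is
nevertheless exposed as-is, without guessing an intended algebra, and
`relaxation_rates_numeric` — exact eigenvalues of the linearized two-state
scheme under pseudo-first-order conditions — is the recommended reference
for conformational selection. For induced fit the two agree within 5% once
k₋₁ ≥ 100·(k₊₂ + k₋₂), the timescale-separation regime in which the
approximate laws are derived.

Cumulative luminescence (f·[P]) is the canonical steady-state observable:
progress curves constrain the signal scale f by their endpoints, avoiding
any quantum-yield calibration of the luminometer. The instantaneous rate
f·d[P]/dt is available for decay work and is computed from the rate law,
not by differencing.

## Global fitting

`fit_global` fits one parameter set jointly to all traces by
Levenberg–Marquardt (lmfit) on residuals normalized per point by sigma.
Choices that were genuinely open:

- **Sigma.** When a trace carries no per-point sigma, a constant per trace
  is estimated from the second differences of its trailing 25% (where the
  curve is smoothest). A floor prevents zero weights on noiseless data.
- **Starting values.** For progress curves, a heuristic seeds the fit: f
  from endpoint/S₀, then an initial-rate Michaelis–Menten analysis of the
  early (<25% completion) curve for kcat and Km seeds, with Kp seeded at
  Km. Because heuristic seeds can land in a wrong χ² basin, the optimizer
  then sweeps three deterministic starts (seeds as-is, ×0.3, ×3) and keeps
  the best optimum; callers who pass explicit starts get a single run. For
  transient data the intended protocol is two-stage: exponential-phase
  analysis (`fit_exponentials`, variable projection over a deterministic
  log-spaced rate grid) feeds `fit_rate_dependence`, whose constants start
  the global fit.
- **Concentration nuisance factors.** One multiplicative factor per trace,
  box-bounded to [0.95, 1.05] and disabled by default, mirrors the practice
  of absorbing small pipetting errors without silently absorbing model
  error.
- **Restarts.** On genuine non-convergence (not an evaluation-budget stop),
  five seeded log-normal perturbations of the starts are tried.

**Confidence contours.** The profile is scanned outward from the estimate
with a geometric step, all other free parameters re-optimized at each grid
point. The acceptable region uses the ratio convention
χ²_min/χ²(θ) ≥ threshold (0.9 steady state, 0.95 transient); the absolute
Δχ² convention is available behind `convention="delta"` since the ratio
convention is a community practice rather than a definition. Crossings are
interpolated on √(χ² − χ²_min), which is linear in θ for a locally
quadratic profile and makes the bounds agree with the closed-form linear
Gaussian interval to ~1e-11 relative; a side that never crosses within the
scan is reported open-ended rather than fabricated.

**Mechanism discrimination.** Candidates are ordered by χ² per degree of
freedom, except that a candidate with *unconstrained* free rate constants —
covariance standard error missing or at least as large as the estimate —
ranks below every fully constrained one. Plain reduced-χ² ranking cannot
separate nested mechanisms: an induced-fit model fitted to one-step data
absorbs roughly one χ² unit of noise per extra parameter, which cancels the
dof penalty exactly, leaving a coin flip. What distinguishes the true
mechanism in practice is that the superfluous constants are undetermined,
which is what the composite criterion tests; profile-contour
bounded/unbounded flags are additionally available via
`contour_params=True` for the stricter version of the same check. Failed
candidates stay in the ranking, last, with their failure recorded.

**Decay.** Exponential I₀e^(−kt) gives t½ = ln2/k. The logistic form is
parameterized as I(t) = I₀/(1 + (t/τ)^h) — chosen because "logistic decay"
has no unique convention — and t½ is solved numerically as the time the
fitted curve reaches half its initial amplitude (equal to τ for this
parameterization). Fitting refuses signals without an overall decreasing
trend.

## Elastic-network cross-correlation

Standard Cα ANM: identical springs (γ = 1) between residues within a 15 Å
cutoff — defaults documented for this model class, since the analysis
defines parameters only through the software it names. The pseudo-inverse
over non-rigid modes gives the 3×3 residue covariance blocks, reduced by
trace to var(x) and r(x,y). Eigenvalues below 1e-6 of the largest count as
rigid-body modes; exactly six are required, and any other count raises a
diagnostic (it indicates a disconnected or degenerate spring network).

Segment averaging weights each residue pair by √(var·var), i.e. it sums
covariances over the block and normalizes by the self-blocks, so
Ccor(i,i) = 1 and |Ccor| ≤ 1 by Cauchy–Schwarz. A segment whose self-block
covariance sum is non-positive has no meaningful normalization; its entries
are reported as NaN with a warning, never silently zeroed. Per-residue rows
of the extended (E+P)×(E+P) layout are one-residue segments, which is the
same quantity as raw r(x,y) up to the fluctuation weighting; the one-residue
-segment convention was chosen for internal consistency.

Cross-structure comparison requires an explicit label mapping (two-column
TSV): no automatic sequence alignment is attempted, because the original
mapping was curated by hand. The difference matrix is antisymmetric under
argument swap and bounded in [−2, 2]. Variant annotation returns 9
position-vs-region plus 9 host-segment-vs-region values; the nine shipped
default region names are placeholders that fix only the count — real
analyses must configure their own regions, and `annotate_variant` enforces
exactly nine.

Segments are 1-based inclusive indices over the structure's residue order,
not author numbering; `CaStructure.residue_keys` is the lookup table back
to source numbering. PDB reading keeps chain/resnum/insertion-code keys and
selects the first altloc.

## Screening statistics

The six-step plate normalization is implemented exactly in its printed
order; two points were under-specified and resolved as follows. The
quartile estimator for the Tukey fences is linear interpolation of order
statistics (numpy's default); the filter is applied once per segment, not
iterated, and within step 3 (after blanking), following the step order.
Pre-injection means all points strictly before the injection time; the
post-injection segment starts at injection + 0.2 s (the settle delay).
Blanking makes the statistic exactly invariant to a global additive offset,
and the positive-control reference makes relative intensities exactly
scale-invariant; both invariances are tested.

PLS runs on autoscaled, centred X and Y (sample sd). The component count
`"auto"` maximizes 7-fold cross-validated Q² up to min(10, rank), since the
original component count is unstated. Fold assignment is a seeded shuffle
followed by contiguous blocks (only the 1/7 fraction is prescribed). VIP
uses the standard weighting by per-component explained Y-variance and
satisfies ΣVIP² = p to 1e-9. Permutation testing re-runs the whole CV with
Y rows re-ordered (999 draws by default); the empirical p-value uses the
(1 + #{null ≥ obs})/(1 + n) estimator. Reproducing any particular study's
R²/Q² values is a non-goal: those depend on the study's own data matrix and
component choice.

## Dynamics descriptors

B = (8π²/3)·RMSF² elementwise; z-standardization uses the sample (n−1)
standard deviation and refuses constant profiles. Averaging per segment
happens on whatever profile is supplied — the default workflow is
standardize-then-average, matching how per-element comparisons are
presented, but both orders are trivially available by composing the two
functions. Tunnel frames with bottleneck radius exactly at the 1.4 Å water
threshold count as open (strict "drops below" reading). Mean residue
ellipticity is Θ_obs·M_w·100/(n·c·l) with c in mg/ml and l in cm.

## Synthetic data: what it emulates, and what not

All generators are pure functions of their arguments and a mandatory
integer seed (fresh `default_rng` per call, no global state; identical
re-runs are byte-identical). Noise is proportional Gaussian by default
(sd = level·|signal| + floor; the floor keeps sigma positive at zero
signal).

Default designs follow the study conditions: progress curves at five
substrate concentrations in triplicate; stopped-flow traces at ten
substrate concentrations with seven replicates; decay traces tagged with
the 2.2 μM substrate / 50 nM enzyme condition; 96-well plates with four
negative and four positive control wells and injection 10 s into the
reading; 25 × 10 descriptor matrices for PLS. Where the study fixes no
value, defaults were set once to plausible bench values (substrate ranges
0.5–10 μM steady state and 5–100 μM transient spanning Km and the
fast-phase range, 1–2% instrument noise, 50 nM–1 μM enzyme) and are the
conditions under which the recovery tolerances in the test suite hold.

The generators emulate the *statistical structure* each stage assumes —
replicate noise, baseline-then-step plate signals, low-rank descriptor
matrices, ideal-geometry Cα traces — not instrument physics: no gain drift,
well cross-talk, photobleaching, dead-time distortion, or real protein
geometry. Passing recovery tests therefore demonstrates the correctness and
calibration of the estimators under their own assumptions, not robustness
to real-instrument artifacts. Toy structures (helix with 1.5 Å rise and
100° twist per residue, a zigzag strand with an out-of-plane wave, a
two-lobe pseudo-domain) are labelled synthetic and exist to exercise the
network code, not to resemble a luciferase fold.

## Problem sizes

The shipped analyses and acceptance run use: 15 progress curves × 80
points; 70 fluorescence traces × 150 points; 20-repetition discrimination
studies at 6 concentrations × 60 points; 50 random fluctuation systems of
up to 12 residues plus 20–40-residue toy structures; 96-well plates with
61 time points; 25 × 10 PLS matrices with 999 permutations. These sizes
were chosen to exercise every code path at study-like dimensions while
keeping a full run in the minutes range on one core.

## Known limitations

- Only the five preset mechanisms are public; no arbitrary networks.
- No Bayesian posteriors or bootstrap intervals — uncertainty is covariance
  S.E. plus profile contours, by design.
- The conformational-selection slow-rate law is exposed as printed despite
  its dimensional inconsistency (see above); use the eigenvalue routine.
- MD, tunnel geometry computation, and secondary-structure assignment are
  upstream tools' jobs: profiles, bottleneck series and segment definitions
  are inputs here.
- PLS assumes complete, finite X/Y; no missing-data handling.
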