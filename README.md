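# lumidyn

Analysis pipeline for studying how backbone dynamics shape luciferase
catalysis: kinetic-mechanism simulation and global fitting, elastic-network
cross-correlation of protein segments, screening-plate statistics with PLS
structure–activity modelling, and small dynamics descriptors. A seeded
synthetic-data module generates study-style inputs for every stage, so the
whole pipeline runs and is tested without any raw instrument data.

It is aimed at enzymologists and protein engineers who want to

- discriminate substrate-binding mechanisms (one-step binding, induced fit,
  conformational selection) from stopped-flow fluorescence traces,
- extract `kcat`, `Km` and the enzyme–product dissociation constant `Kp`
  from full luminescence progress curves by numerical integration, with
  profile-χ² confidence bounds,
- quantify concerted motions of secondary-structure elements from Cα
  elastic-network models and compare two structures,
- normalize injection-based screening plates and validate PLS models with
  cross-validation and permutation testing.

## Models in brief

**Kinetic mechanisms.** Five mass-action schemes (μM, s units throughout).
The steady-state catalytic cycle

    E + S <-> E.S -> E.P <-> E + P

fixes the diffusion-limited constants k₊₁ = k₋₃ = 100 μM⁻¹s⁻¹, so that
kcat = k₊₂, Km = k₋₁/100 and Kp = k₊₃/100; an irreversible variant
(k₋₁ = 0) yields kcat/Km = k₊₁ directly. For transient binding, the
induced-fit scheme E + S ⇌ E.S ⇌ E\*.S has observed rates
k_fast = k₊₁[S] + k₋₁ and k_slow = k₊₂K₁[S]/(K₁[S] + 1) + k₋₂
(K₁ = k₊₁/k₋₁); conformational selection and one-step binding have their
corresponding laws, and an exact linearized-scheme eigenvalue routine is the
reference when the approximate laws' assumptions fail. Traces are observed
either as cumulative luminescence f·[P] or as fluorescence quenching
f·([E] + a·[E.S] + b·[E\*.S]).

**Global fitting.** All traces are fitted jointly by Levenberg–Marquardt on
sigma-normalized residuals with the mechanism integrated numerically
(stiff-capable LSODA, rtol 1e-8). Parameter uncertainty comes from the
covariance matrix and from profile-χ² confidence contours using the ratio
convention χ²_min/χ² ≥ threshold (0.9 steady state, 0.95 transient).

**Segment cross-correlation.** From an anisotropic network model (Cα
springs within 15 Å), the fluctuation-weighted average correlation of two
segments is

    Ccor(i,j) = Σ_{x∈i} Σ_{y∈j} r(x,y)√(var(x)var(y)) /
                √( [self sum of i] · [self sum of j] )

Appending each residue as a one-residue segment gives the (E+P)×(E+P)
extended layout; subtracting a second structure's matrix gives a difference
matrix M with entries in [−2, 2], from which each variant gets 18 annotation
values (9 for its position, 9 for its host segment, against 9 regions of
interest).

**Screening statistics.** Plates are normalized in six steps (average
negatives per time point → blank → split pre/post-injection with a 0.2 s
settle delay and Tukey-fence each segment → raw = mean(post) − mean(pre) →
reference = mean positive raw → relative = raw/reference). PLS on
autoscaled X/Y reports weighted coefficients, R², VIP (ΣVIP² = p),
leave-1/7-out Q² and a 999-permutation null.

## Worked example

The numbered drivers under `analysis/` run each stage end to end on
synthetic data and write tables to `results/`. For example:

```
$ python analysis/02_transient_binding.py
simulated 70 fluorescence traces (10 concentrations x 7 replicates, 2% noise)
double-exponential phases: k_fast 39..230 s^-1, k_slow 5.0..26.0 s^-1
global induced-fit estimates (truth k+1=2, k-1=50, k+2=30, k-2=3):
  k_plus1 = 2.008 +- 0.036
  k_minus1 = 50.303 +- 1.368
  k_plus2 = 29.974 +- 0.125
  k_minus2 = 2.982 +- 0.028
one-step chi2 / induced-fit chi2 = 4.10 (the one-step model cannot describe the biphasic quenching)
```

Each trace is fitted with a double exponential; the fast/slow rates versus
[S] seed the elementary constants; the global fit then recovers all four
within about 1% at 2% noise, and forcing a one-step model on the same data
quadruples χ² — the discrimination logic in action. Similarly,
`analysis/01_steady_state_kinetics.py` recovers kcat = 4.19 s⁻¹,
Km = 2.48 μM, Kp = 0.299 μM (truth 4.2/2.5/0.3) from fifteen noisy progress
curves and prints their 0.9-threshold confidence intervals, and
`analysis/03_decay_half_life.py` contrasts a 30 s flash-type with a 3000 s
glow-type emitter (a 100× half-life ratio).

## Layout

```
src/lumidyn/       library: mechanisms, fitting, anm, screening,
                   descriptors, synth, io
analysis/          numbered end-to-end drivers (write to results/)
tests/             pytest suite incl. the acceptance properties
scripts/           acceptance.py
docs/methods.md    modelling assumptions, parameter choices, limitations
```
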