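# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `fiberfv`, in the spirit of a statistical package's methods
documentation. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The Hill force–velocity model

The concentric force–velocity relation of a maximally activated fiber is
modeled as the rectangular hyperbola (P + a)(V + b) = (Po + a)·b, with Po
the maximal isometric force (µN), a a force constant (µN) and b a velocity
constant (FL·s⁻¹). Shortening velocity is positive throughout; forces above
Po (the eccentric side) are outside the model domain and raise an error
rather than extrapolating — the protocol only measures shortening.

Derived quantities and their exact unit chains:

| quantity | definition | units |
|---|---|---|
| Vmax | b·Po/a | FL·s⁻¹ |
| curvature | k = a/Po | — |
| specific tension | (Po·10⁻⁶ N)/(FCSA·10⁻⁸ cm²) = 100·Po/FCSA | N·cm⁻² |
| maximal power | Po·Vmax·FL·w_max(k)·10⁻³ | µW |
| specific power | 10⁶·P_max/(FCSA·FL) | W·L⁻¹ |

Fiber length FL (mm) converts FL·s⁻¹ to mm·s⁻¹ (µN·mm·s⁻¹ = 10⁻³ µW), and
fiber volume FCSA·FL (µm²·mm) is 10⁻¹² L. With force normalized to Po and
velocity to Vmax, the curve is v(p) = k(1−p)/(p+k) and its power optimum is
closed-form: v_opt = p_opt = √(k(1+k)) − k, w_max = v_opt². w_max is
strictly increasing in k with limits 0 (k→0) and 0.25 (k→∞); under this
normalization peak power depends on curvature only, which is the
normalization under which "same Po and Vmax" isolates the curvature effect.
Because the size of a curvature-driven power advantage depends on what the
power axis is normalized to, `curvature_power_elevation` exposes two
constructions (Po·Vmax normalization, and force-only normalization with
absolute velocity); they can differ by a factor ≈ 2 for realistic
parameters, so no single "percent elevation" is treated as canonical.

## Velocity extraction

Each isotonic release is a uniformly sampled trace (time, force, absolute
length, sarcomere length) starting at clamp onset. Velocity is the negative
least-squares slope of length vs time over the last 100 ms of the 150 ms
step, divided by the fiber's initial length; the associated force is the
mean *measured* force over the same window (the commanded clamp level is
kept only as metadata — the measured mean is what the transducer actually
reports). A constant-length window is reported as zero velocity with R² = 1
(the line fits exactly). Traces shorter than the step, or non-uniformly
sampled, raise errors. Extraction is exact on noiseless linear traces and
unbiased under additive zero-mean length noise; on curved (transient)
traces the regression slope is the least-squares slope of the window, which
is close to but not identical with the window-mean derivative.

A single release that shortens the fiber by more than 20% of its initial
length triggers a warning, not a rejection: the rejection rules are
exactly three (below), and the 20% figure is a protocol constraint the
generator enforces, not a data-quality rule.

## Quality control

A fiber's data are rejected if any of:

* Po drop > 10% — drop = 1 − min(Po)/Po_first over the per-series isometric
  re-measurements (first reading = reference);
* sarcomere-length change > 0.15 µm — max |SL − SL_first|, first reading =
  pre-activation set point;
* Hill-fit R² < 0.96 — computed on the velocity axis, consistent with the
  fit loss.

All three comparisons are strict: a fiber exactly at a threshold passes.
Loosening any threshold can only convert rejections into acceptances
(monotonicity), which the property tests verify.

## Hill fitting

`HillModel.fit()` minimizes Σ(vᵢ − b(Po − Pᵢ)/(Pᵢ + a))² in velocity space.
Velocities are the derived observable (forces are clamped), so velocity
residuals are the natural loss; a force-space loss is available behind
`loss_axis="force"` for sensitivity analysis. Po is fixed at the measured
isometric value by default (`po_mode="fixed"`, only a and b estimated);
`po_mode="free"` additionally estimates Po.

The two-parameter problem is separable — for fixed a the optimal b is a
linear least-squares coefficient — so the fit profiles b out, brackets a on
an 80-point log grid over (10⁻⁴·Po, 5·Po], refines it with a bounded scalar
minimization (xatol 10⁻¹⁴), and polishes (a, b) jointly with a bounded
trust-region least-squares iteration (ftol = xtol = gtol = 10⁻¹⁵,
max 10⁴ evaluations). This makes the solution independent of the starting
point within the documented initialization box (a₀ = 0.15·Po,
b₀ = 0.15·max v; bounds a ∈ (0, 5·Po], b ∈ (0, 10·max v]) and exact to
≤10⁻⁶ relative on noiseless data. R² = 1 − SSE/SStot of velocities;
parameter covariance is the usual Gauss–Newton estimate σ̂²(JᵀJ)⁻¹, with
delta-method errors implied for Vmax and a/Po. At least three distinct
forces are required; all forces must lie below the measured Po in fixed
mode.

## Synthetic studies

The generator's defaults are the study conditions, not tuning knobs.

**Population.** Four groups — human I (n 39), human II (46), bonobo I (18),
bonobo II (31); 85 + 49 fibers. Per group, FCSA, Vmax and a/Po are drawn
from normals centered on the reference group means with SD reconstructed as
SEM·√n (contractile variables use the smaller post-QC n the reference
reports), truncated at 0.05× and 3× the mean to exclude non-physical
values. Because truncation shifts the mean — substantially for bonobo type
I a/Po, whose reconstructed CV is ≈ 0.67 — the generator's *generating
mean* for recovery purposes is the analytic truncated-normal mean
(`generating_means`), not the raw location parameter. Specific tension is
coupled to size, ST = 18.4·e^(−5·10⁻⁵·FCSA) N·cm⁻² with lognormal scatter
(σ = 0.20, giving a CV close to the reference groups'), and Po = ST·FCSA/100;
this reproduces the observed negative size–tension relationship. Fiber
length is uniform on 0.70–3.97 mm (the reference reports only the global
range, an acknowledged emulation approximation), sarcomere set point
uniform on 2.53–2.69 µm. Bonobo muscle labels (VL/BB/SOL/ADD/HAM) are drawn
with probabilities 26:4:1:9:8; human fibers are all VL.

**Protocol and noise.** Four series of four releases at clamp fractions
0.05/0.15/0.30/0.50 of the *current* Po (levels chosen to condition the
hyperbola fit; the protocol itself does not fix them), 150 ms steps sampled
at 1 kHz in 160 ms traces. The true curve scales with rundown at constant
a/Po and Vmax, so a clamp at fraction ℓ shortens at b(1−ℓ)/(ℓ+k)
regardless of rundown. Noise model: multiplicative Gaussian on each
release's velocity (default 3%), relative Gaussian on force samples and Po
readings (1%), additive noise on sarcomere readings (0.01 µm) and on the
length channel (0.1 µm). Po decays between consecutive series at a
per-fiber rundown rate ~ N(0.02, 0.012) truncated to [0, 0.2] (so the
observed drop over 4 series is 1 − (1−r)³), and the sarcomere set point
drifts by a per-fiber N(0, 0.025) µm per series. These dispersions straddle
the QC thresholds, so a realistic minority of fibers is rejected in every
default study, as in real experiments. If a shortening bout within a series
would exceed 20% of initial length (fast type II fibers at low loads), the
fiber is restretched mid-series, mirroring rig practice. Studies are
bit-reproducible: all randomness derives from one `SeedSequence`, spawned
per fiber.

**What the generator does not emulate.** Traces are phenomenological
realizations of the Hill curve — no cross-bridge dynamics, no force
transients at clamp onset, no compliance artifacts, no deviation from the
hyperbola near Po, no temperature effects (everything is implicitly at the
reference 15 °C), and no fiber-within-animal correlation structure. Passing
recovery tests therefore demonstrates that the *analysis* is correct and
unbiased for Hill-consistent data at realistic noise, not that real traces
satisfy the Hill model.

## Statistics

Two-way ANOVA uses sum-to-zero (±1) coding and computes each effect's SS by
explicit nested-model SSE comparison: Type III (default — the convention of
mainstream commercial packages, appropriate for these unbalanced designs)
drops the effect's column from the full interaction model; Type II drops
main effects from the main-effects model. F tests use the residual MS of
the full model; Type III with an empty cell raises an error naming the
cell. On balanced designs Types II and III coincide, and the machinery
reproduces the textbook cell-mean decomposition exactly; an independent
library implementation and a permutation oracle serve as cross-checks in
the test suite, never as the implementation.

Post-hoc contrasts are pooled-variance two-sample t tests between the four
cells of interest (within-type species contrasts and within-species type
contrasts, m = 4), Bonferroni-adjusted as min(1, m·p).

Forward stepwise regression 0/1-codes two-level factors, and at each round
enters the candidate with the smallest partial-F p-value if it is below
`entry_alpha` (default 0.10), reporting entry p and adjusted R² per step
and the final OLS coefficients. A candidate whose addition pushes the
design's condition number above 10⁸ is skipped with a warning. Under a
pure-noise response the chance of at least one spurious entry is
approximately 1 − (1 − α)^m for m candidates (≈ 0.41 at α = 0.10, m = 5),
which the acceptance suite verifies by simulation.

## Pipeline and reproducibility

`run_pipeline` composes generate (or load) → extract → fit → QC → derive →
summarize → compare. Group summaries (mean ± SEM, SEM = SD_{n−1}/√n) use
QC-accepted fibers only; a single-fiber group reports no SEM and an emptied
group keeps its row with n = 0. Size–strength regressions (Po and ST vs
FCSA) are reported in linear, logarithmic and exponential forms, pooled and
per fiber type side by side, with R² in the response's original space (and
log-space R² for the exponential form) — no single form is asserted as the
"right" one. Group-mean curves are sampled at 201 force points from the
group means of Po, Vmax, a/Po and fiber length; their normalized peaks
equal w_max(mean a/Po) up to sampling. All outputs are delimited text with
a fixed float format, and the run log carries the seed and a config hash,
so identical configurations reproduce byte-identical artifacts.

Problem sizes used by the test suite: recovery checks run the full 85 + 49
design over 5 fixed seeds (seed-averaged group means compared to the
analytic generating means within 10%), exactness checks use a 20-fiber
zero-noise study, the stepwise null calibration uses 1000 replicates of
n = 40, and the permutation oracle uses 5000 permutations at n = 60. The
per-seed group mean of bonobo type I a/Po is itself noisy (sampling SEM
≈ 14% of the mean at n = 18), which is why recovery is assessed on
seed-averaged means — the per-fiber estimator is the quantity under test,
not the sampling noise of small groups.

## Known limitations

* Velocity-space unweighted least squares is one defensible loss; weighted
  or force-space fits can shift a and b slightly on noisy data (a
  force-space option is provided, residual weighting is not).
* With rundown, forces from later series are internally referenced to a
  decayed Po while the fit pins Po at the first reading; this induces a
  small (few percent) downward bias in recovered a/Po at default noise,
  bounded by the 10% QC rundown cap. It is a faithful property of the
  measurement design, not a solver artifact.
* No mixed-effects modeling of fiber-within-animal clustering; groups are
  treated as independent fibers (fixed effects), as is standard when one
  animal contributes all fibers of a species.
* The normality of residuals is not tested automatically (the fixed-effects
  tables are exported for external diagnostics).
* The deposited-data reader is a stub; external datasets must be converted
  to the manifest + trace-TSV interchange format.
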