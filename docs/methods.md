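# Methods

## Model

Unfolding is represented as an ordered chain of macroscopic steps starting
from the native state N; state *s* is the species reached after step *s*.
Step kinds:

* **equilibrium** — instantaneous N ⇌ I equilibrium with constant
  K(T) = exp(−ΔG(T)/RT), ΔG = ΔH(T) − TΔS(T). With the constant-ΔC_p
  assumption, ΔH(T) = ΔH(T_m) + ΔC_p(T − T_m) and
  ΔS(T) = ΔH(T_m)/T_m + ΔC_p ln(T/T_m), which pins the ground state:
  ΔG(T_m) = 0 and K(T_m) = 1. An optional van't Hoff enthalpy ΔH_vH
  replaces the calorimetric ΔH inside K (transition sharpness) while the
  calorimetric value keeps setting the heat amplitude; K(T_m) = 1 still
  holds.
* **irreversible** — Arrhenius rate k(T) = exp(−(E/R)(1/T − 1/T_f)), so
  T_f is the temperature where k = 1 s⁻¹ and enthalpies are referenced at
  T_f. Negative ΔH is allowed (exothermic high-temperature steps, e.g.
  aggregation).
* **two_rate** — the first Lumry–Eyring step parameterized by forward and
  reverse Arrhenius rates k₁, k₋₁ sharing one ΔH and ΔC_p (referenced at
  the forward T_f).

Structural rules: equilibrium and two-rate steps may only open a chain; a
two-rate step requires a following irreversible drain. The basic schemes
are A = [equilibrium], B = [irreversible], C = [equilibrium, irreversible],
D = [two_rate, irreversible]; further irreversible steps may be appended to
model additional peaks. Chains that appear to spend three or more steps on
one apparent peak (all reference temperatures within 15 K) draw a warning,
reflecting the conservative two-steps-per-peak practice; the 15 K window is
a heuristic so that legitimate multi-peak chains stay silent.

Assumptions inherited from the modelling framework: all protein starts
native at the program origin (violations are logged, not fatal: the
equilibrium-leading chains start from the equilibrium split at T₀);
ΔC_p of each step is temperature-independent, so a fitted value represents
an average over the transition range; scan segments are ideal linear ramps.

## State propagation

All segment dynamics are written in temperature with the signed rate
v (K s⁻¹, negative on cooling), so equilibrium-shift terms reverse
automatically on cooling and a heat–cool–reheat program is just a sequence
of segments with continuous state fractions.

* Scheme A is algebraic and history-free: x_d = K/(1+K), evaluated via the
  logistic of ln K for overflow safety.
* A single irreversible step has the closed form
  x_n(T) = x_n(T₁)·exp(−(1/v)∫_{T₁}^{T} k dT); the integral is a
  cumulative trapezoid on an 8× refined grid. This reproduces the decay
  factor X(T₂,T₁,v) and its path-reversal identity X(T₁,T₂,−v) = X(T₂,T₁,v)
  by construction.
* The fast-equilibrium chain tracks the pool p = x_n + x_i, which obeys the
  linear ODE dp/dT = −(k₂/v)·f·p with f = K/(1+K); for a single drain this
  is again closed-form (cumulative quadrature of k₂f). The split
  x_n = (1−f)p, x_i = fp is maintained algebraically on every segment,
  including cooling. Chains with further drains integrate the downstream
  states with LSODA (rtol 1e-8, atol 1e-12 for simulation; relaxed during
  fitting, see below).
* The two-rate chain d(x_n,x_i)/dT = M(T)(x_n,x_i)/… is linear but
  nonautonomous. It is advanced by exact matrix exponentials of the
  midpoint matrix over sub-steps (a second-order Magnus scheme, 4 sub-steps
  per output interval, eigen-decomposition in closed form factored around
  the larger eigenvalue so exponentials never overflow). Because the
  exponential is exact for frozen coefficients the scheme is A-stable and
  survives the stiff fast-equilibration limit (rates ×10⁴) that an explicit
  integrator would reject; against LSODA at rtol 1e-10 it agrees to ~2e-6
  in the fractions on a 0.1 K grid. Longer two-rate chains fall back to
  LSODA.

Fraction conservation (Σx_s = 1 to 1e-9) and cross-segment continuity are
enforced by construction and tested as invariants.

## Heat-capacity synthesis

C_p(T) = B₀ + B₁T + d/dT Σ_s x_s H_s(T), with H_s the cumulative enthalpy
of state s relative to N (each step's ΔH(T) referenced at its own T_m/T_f)
and B₀ + B₁T a linear baseline. The derivative is expanded analytically as
Σ_s H_s·dx_s/dT + Σ_s x_s·ΣΔC_p. For the one-step irreversible chain this
reduces exactly to B₀ + B₁T + (1−x_n)ΔC_p + (k/v)x_n ΔH(T) (a pinned test),
and for scheme A to the classical two-state expression with the van't Hoff
option scaling the sharpness term. State derivatives come from the ODE
right-hand sides, except for the two-rate chain where the stiff limit makes
−k₁x_n + k₋₁x_i cancel catastrophically; there dx/dT is obtained by
differentiating the (smooth) solution on the grid.

Only heating segments emit thermograms; cooling is simulated for state
continuity, matching what instruments record.

Where a two-step first peak carries one combined ΔC_p, the package stores
it on the first step (split fraction 1.0 by default) since the data cannot
apportion it; fits therefore fix the second step's ΔC_p at 0.

## Global fitting

One model is fitted to all scans simultaneously; reheat curves are always
produced by propagating the model through the full heat–cool–reheat
program, never fitted with their own parameters. Baselines B₀, B₁ are
shared within a scan-rate group (a first run and its reheats); step
parameters are global. The objective is the unweighted sum of squared
residuals. The optimizer is bounded trust-region least squares (lmfit /
`least_squares`) with a seeded multistart (default 5 starts) over
log-spaced perturbations of the activation-energy and enthalpy parameters;
starts stop early once two consecutive starts fail to improve the best SSR
by 2%. A residual evaluation that raises a simulation error returns a
large constant vector so the optimizer retreats rather than crashes.

Initialization is data-driven when no model is supplied: the baseline from
a linear fit of the pre-transition eighth of the first run, T_m/T_f at the
apparent peak, ΔH from the peak area, irreversible E from the peak-width
relation E ≈ e·R·T_p²·C_p,max/area, and ΔC_p from the post–pre excess
offset. For model comparison, the general scheme D is additionally started
from the fitted simpler schemes embedded as its limiting cases (B: slow
reverse rate, fast silent drain; C: fast first-step rates matching the
fitted K(T)) and from a small factorial grid over the physically
undetermined quantities (reverse-rate magnitude 10⁻³–0.3 of k₁ at the
peak, drain-enthalpy sign). These screening fits run with capped
evaluations and relaxed tolerances; the best start is then polished.

Confidence intervals are linearized: half-width = t(0.975, n−p) × standard
error from the Jacobian at the optimum. Rank-deficient directions are
reported as unavailable rather than as numbers. Monte-Carlo calibration
(200 seeded replicates of a one-step fit at n ≈ 300 points, noise SD
0.5 kJ mol⁻¹ K⁻¹) puts empirical coverage of the 95% interval at ~94%;
coverage degrades below ~150 points per scan where the linearization is
optimistic.

### Model comparison

`compare_models` fits each candidate scheme and applies the reheat-misfit
rejection: a candidate is rejected when its reheat/first residual-SD ratio
reaches 2 or its mean reheat residual exceeds 5% of the first-run peak
amplitude. Among survivors the scheme with the fewest free parameters whose
SSR is within 10% of the best survivor is selected — a parsimony rule
needed because B ⊂ C ⊂ D nest and the richer scheme always matches the
noise floor. AIC is reported informationally only; the primary statistic
follows the residual-ratio reasoning because that is what reheat data
actually discriminate.

## Diagnostics

* **Alternative refolding**: after a global fit, residuals are grouped by
  scan role; each group's signed mean, mean absolute value and SD (about
  its own mean, over the scan's full recorded range) are reported. The
  flag raises when |mean reheat residual| > 5% of the first-run peak
  amplitude (the practical precision of concentration determination) or
  when SD_reheat/SD_first ≥ 2. The residual window is the full range
  because the misfit signature of a wrongly-refolded species is a peak the
  model cannot place anywhere.
* **Reversibility classification**: the surviving native fraction is the
  ratio of baseline-corrected reheat peak height to first-run peak height
  (identical scan rates required); ≥ 99% → scheme A, 20–99% → scheme C
  candidate, < 20% → scheme B candidate.
* **Reheat planning**: point III is the apparent peak temperature, point V
  the post-transition foot — the first temperature past the peak where the
  excess falls below 2% of peak height *measured against the
  post-transition level*, so a positive ΔC_p step cannot hide the foot —
  and point IV their midpoint, the region where the reheat peak height
  declines steepest. Peak detection is the largest baseline-subtracted
  maximum and requires prominence above 5× the pre-transition noise;
  flat thermograms are an error. The 2% foot threshold and the linear
  pre-transition baseline (default: first eighth of the scan) are package
  decisions where the procedure is qualitative.

## Synthetic data

Generators produce the study conditions used throughout the tests: the six
case-study parameter sets (lysozyme, SpA, DbjA, LinB, DhaA, DhaA115) as
ready models; first+reheat experiment sets for arbitrary models (terminal
temperatures chosen by the planning heuristic: summit, mid-decline, foot);
and the alternative-refolding scenario — a one-step irreversible model
(E = 300 kJ mol⁻¹, T_f = 360 K, ΔH = 800 kJ mol⁻¹, 20–100 °C at
1 °C min⁻¹) whose reheat restarts fully "native" with ΔH scaled by the
area fraction f, i.e. refolding into a state with the same kinetics but
reduced heat. Default noise is white Gaussian per point, SD
2.1 kJ mol⁻¹ K⁻¹ for the refolding scenario (matching its first-run
residual scale) and 0.5 kJ mol⁻¹ K⁻¹ for recovery studies; the default
grid is 0.1 K (coarsened in the faster tests).

What the generator does **not** emulate: instrument thermal lag and
feedback transients, buffer-mismatch baselines and their curvature,
correlated (1/f) noise, concentration errors between scans, aggregation
exotherms with concentration dependence, or non-linear cooling profiles.
Passing tests therefore demonstrate correctness of the mathematics and the
estimation machinery under the stated conditions, not robustness to every
instrumental artefact; on real data the residual diagnostics are the guard
rails.

With the stated refolding-scenario conditions, the f = 0.5 case fitted
globally with the one-step model gives a reheat-residual SD of
~11.6 kJ mol⁻¹ K⁻¹ and an SD ratio of ~4.2; the SD is range-dependent
(it is essentially the SD of the half-amplitude peak shape over the
scanned window plus noise), so the ratio is the more portable statistic.

## Numerical choices

* Simulation grid 0.1 K by default; fitting evaluates the model on a
  0.2–0.6 K grid and interpolates onto the data grid (the curves are smooth
  at these scales). Closed-form quadratures refine 8×; the Magnus
  propagator sub-steps 4×.
* Cooling uses the same |v| as heating unless overridden.
* ODE tolerances rtol 1e-8 / atol 1e-12 for simulation; fits relax to
  rtol 1e-7 (and 1e-6 with capped evaluations during model-comparison
  screening) — validated against the acceptance tolerances.
* Arrhenius/equilibrium exponents are clipped at exp(700) and the
  propagator's k·Δt at 1e6, so optimizer excursions saturate instead of
  overflowing.
* Reference temperatures outside 250–500 K are legal but logged
  (poorly-constrained steps fit to values like T_f ≈ 3.2 kK).
* Duplicate temperatures in input files collapse to their mean; unsorted
  rows are sorted with a warning.
* Test problem sizes: recovery fits use 0.15–0.3 K data grids with 2–4
  experiments; the discrimination study uses 0.55 K grids with two reheat
  experiments per dataset and 10 noise replicates; the coverage study uses
  0.4 K grids. These are the package's chosen study sizes; results quoted
  above were computed at exactly these sizes.

## Known limitations

* Linearized confidence intervals only; no bootstrap or posterior
  sampling. Strongly correlated parameters (e.g. E–T_f of a weakly
  constrained drain) get wide, sometimes unstable intervals.
* The ΔC_p of consecutive steps within one apparent peak is not separable
  from these data; only the combined value is estimated.
* Concentration-dependent aggregation kinetics, multi-peak deconvolution
  beyond sequential chains, temperature-dependent ΔC_p(T) and
  free-energy-surface (microstate) models are out of scope.
* Model discrimination inherits the identifiability of the data: with a
  single scan rate and no reheats, B/C/D are practically indistinguishable
  — which is the package's raison d'être for fitting reheats.
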