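# dscfit

Protein unfolding mechanisms and energetics from differential scanning
calorimetry (DSC), using the information in **reheated runs**.

## The problem

A DSC instrument ramps temperature linearly and records the apparent molar
heat capacity C<sub>p</sub>(T) of a protein solution. The resulting
thermogram encodes the unfolding pathway — how many states, which steps are
reversible, and their thermodynamic (ΔH, ΔC<sub>p</sub>, T<sub>m</sub>) and
kinetic (E, T<sub>f</sub>) parameters. When unfolding is (partly)
irreversible, a single heating scan cannot separate the candidate
mechanisms: the common remedies are varying the scan rate and *reheating* —
heating to a terminal temperature T′, cooling back, and heating again. The
second scan reports directly how much protein refolded natively, but most
analyses discard it from curve fitting. `dscfit` fits first, cooling and
reheated scans **globally under one model**, so the reheats constrain the
mechanism instead of merely hinting at it.

## Models

Unfolding is a chain of steps from the native state N. The four basic
single-peak schemes, plus chains with appended (possibly exothermic) steps:

| scheme | mechanism | parameters |
|---|---|---|
| A | N ⇌ D, reversible two-state | T<sub>m</sub>, ΔH (optionally ΔH<sub>vH</sub>), ΔC<sub>p</sub> |
| B | N → D, irreversible two-state | E, T<sub>f</sub>, ΔH, ΔC<sub>p</sub> |
| C | N ⇌ I → D, fast equilibrium then irreversible | T<sub>m</sub>, ΔH<sub>1</sub>, E, T<sub>f</sub>, ΔH<sub>2</sub>, ΔC<sub>p</sub> |
| D | N ⇌ I → D with explicit k₁, k₋₁ (Lumry–Eyring) | E₁, T<sub>f1</sub>, E₋₁, T<sub>f−1</sub>, E₂, T<sub>f2</sub>, ΔH's, ΔC<sub>p</sub> |

Equilibrium constants follow K(T) = exp(−ΔG/RT) with ΔG(T<sub>m</sub>) = 0
and constant ΔC<sub>p</sub>; rate constants follow the Arrhenius form
k(T) = exp(−(E/R)(1/T − 1/T<sub>f</sub>)) with k(T<sub>f</sub>) = 1 s⁻¹.
State fractions propagate in temperature with the signed scan rate v; for an
irreversible step the fraction surviving a ramp is the decay factor
X(T₂,T₁,v) = exp(−(1/v)∫k dT), and a heat–cool–reheat cycle composes these
factors, e.g. x<sub>n</sub><sup>R</sup>(T;T′) = X(T,T₀,v)·X(T′,T₀,v)² for
scheme B. The heat capacity is synthesized as
C<sub>p</sub> = B₀ + B₁T + d/dT Σ<sub>s</sub> x<sub>s</sub>H<sub>s</sub>(T).

Besides fitting, the package plans reheat experiments (terminal
temperatures at the peak summit, mid-decline and post-transition foot),
classifies reversibility from a foot-terminated reheat, ranks the four
schemes by reheat-consistent fit quality, and tests for *alternative
refolding* (a refolded state that no longer matches the model) by comparing
first-run and reheat residual statistics.

## Worked example

Simulate noisy first+reheat experiments for the haloalkane dehalogenase
DbjA (one-step irreversible unfolding; E = 418 kJ/mol, T_f = 337.6 K,
ΔH = 337 kJ/mol, ΔC_p = 5.4 kJ/mol/K) and fit scheme B globally:

```python
from dscfit import (protein_preset, make_reheat_experiments, build_problem,
                    initial_model_from_data, global_fit, FitOptions,
                    confidence_intervals, refold_statistics,
                    flag_alternative_refolding)

model = protein_preset("DbjA").with_baseline(0, 0)
data = make_reheat_experiments(model, 293.15, 363.15, 1/60,
                               T_primes=(327.1, 331.1, 335.1),
                               noise_sd=0.5e3, seed=11, grid_step=0.25)
problem = build_problem(data, initial_model_from_data(data, "B"))
result = global_fit(problem, FitOptions(grid_step=0.3, n_starts=2))
```

Output (95% confidence half-widths):

```
E   =   417.7 +- 1.8 kJ/mol
Tf  =  337.61 +- 0.06 K
dH  =   338.0 +- 1.6 kJ/mol
dCp =    5.43 +- 0.07 kJ/mol/K
residual SD first/reheat: 0.48 / 0.51 kJ/mol/K  (ratio 1.05)
alternative refolding flag: False
```

The fit recovers the generating parameters within their intervals; the
reheat residuals match the first-run residuals (ratio ≈ 1), so nothing
suggests the protein refolds into an alternative conformation. A reheat
residual SD several times the first-run SD would raise the flag.

There is also a CLI for shell use: `dscfit simulate`, `dscfit fit`,
`dscfit diagnose` (add `--compare` to rank the four schemes) and
`dscfit plan`; see `dscfit --help`.

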