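# Methods

## Scope and data model

The package analyses three bench experiment types that together profile a
drug's transport properties: shake-flask solubility vs temperature,
two-phase (organic/aqueous buffer) distribution with and without a
cyclodextrin host, and Franz diffusion-cell permeation through a biomimetic
membrane. All estimators are deterministic given their inputs; the only
randomness in the package lives in the synthetic-experiment generators and
is fully controlled by integer seeds.

## Dissolution thermodynamics

Mole-fraction conversion offers two conventions that differ in the sign of
the solute correction term in the denominator:

* `as_printed` (default): X₂ = M₂S₂ / (S₂(M₁ − M₂) + 1000ρ)
* `mass_balance`: X₂ = M₂S₂ / (1000ρ − S₂(M₁ − M₂))

The second follows from first principles when 1000ρ is read as the total
solution mass per litre minus the dissolved solute's mass contribution; the
first is the form commonly tabulated. For the systems shipped with the
package they differ by under ~4% in X₂ (and ≈1.7 kJ/mol·K⁻¹-slope-equivalent
in the octanol fit); we default to `as_printed` and keep both because the
original convention cannot be inferred from the reported numbers.
Solvent densities default to pure-solvent literature values at 298 K
(1-octanol 0.8262 g·cm⁻³, n-hexane 0.6548 g·cm⁻³) held
temperature-independent; both are overridable per `SolventSpec`. Solution
densities and activity corrections are out of scope.

The van't Hoff regression is unweighted OLS of ln X₂ on 1/T (a single
correlation coefficient and residual σ per line is only meaningful for an
unweighted fit), with R = 8.314 J·mol⁻¹·K⁻¹ and ΔH treated as
temperature-independent over the ~20 K interval (no ΔCp term). Note the
identity TΔS(T) = R·T·A: the entropy term is carried entirely by the
intercept. Standard errors of ΔG/ΔH/TΔS are first-order propagations of the
OLS coefficient covariance (cov(A,B) = −mean(1/T)·se(B)²); no replicate
information enters. ζ_H is undefined (NaN + warning) for an all-zero
process, e.g. a self-transfer.

A caveat established during development: refitting the *printed* 3-digit
molar solubilities does not recover the printed fit coefficients (B ≈ −2247
vs −2469 for octanol, `as_printed`), because the original mole-fraction
inputs and density handling are not recoverable from rounded tables. The
published coefficients are therefore treated as first-class inputs wherever
published thermodynamic functions are reproduced.

## Distribution

`mass_balance` mode, D = (C₀_aq − C_aq)·V_aq / (C_aq·V_org), is the default:
it matches shake-flask practice of assaying only the aqueous phase and is
the dimensionally coherent reading of a volume-bearing concentration-ratio
formula. `direct_ratio` is available when both phases were assayed; the two
agree exactly whenever C_org satisfies the same conservation relation
(tested). No ionization correction is applied — the compounds of interest
are un-ionized at pH 7.4 (pKa₁ ≤ 3.8, pKa₂ ≥ 11.3), so D is P-like.
Replicates are averaged arithmetically with a sample-SD uncertainty.

## Complexation

The working estimator is OLS on log₁₀((D₀ − D)/D₀) vs log₁₀(C_CD); C_CD is
the *total* host concentration and host partitioning into the organic phase
is neglected (valid for highly water-soluble cyclodextrins). The intercept
is reported both as printed (log₁₀ K_C) and as its antilog, because the
field's tables are ambiguous about which is meant; the Fisher criterion is
F = R²(n − 2)/(1 − R²), guarded to +inf on an exact fit, and is
rounding-hypersensitive at n = 3 — treat it as qualitative.

The exact 1:1 model D = D₀/(1 + K_C·C) (bounded least squares, K_C ≥ 0) is
the independent oracle. The linearization equals the exact model only in
the small-saturation limit: its intercept bias is ≈ −mean(log₁₀(1 + K·C)),
about −0.044 at K·C = 0.05 and −0.024 at K·C = 0.02, and α drifts below 1
accordingly. At the saturations of the packaged systems (suppression up to
~87%) the two routes legitimately disagree (e.g. antilog 7.9 vs exact-fit
10.1 M⁻¹ for the octanol/HP-β-CD system); both are surfaced rather than
reconciled. Only 1:1 binding is modelled — no Higuchi–Connors phase
diagrams, 1:2 complexes or competitive binding.

The container admits D = D₀ (no suppression, as produced by a K_C = 0
generator) but the log transform rejects such points; non-monotone series
warn rather than fail, since experimental scatter can produce them.

## Permeation

The sampling correction (withdrawn analyte added back arithmetically,
replacement buffer analyte-free) is standard Franz-cell accounting; it is
on by default and can be disabled. The flux window defaults to `all`
(a single steady-state flux over 5 h at 30-min sampling); `auto` drops
leading lag points greedily while the fit correlation improves and ≥3
points remain. The donor concentration is treated as constant in the
estimator — sink compliance (max C_acc/C₀ ≤ 0.10) is checked and reported,
never silently corrected.

## Synthetic-experiment generators

* Solubility: X₂(T) = exp(A + B/T), optionally noised.
* Suppression: the exact 1:1 model.
* Franz cell: forward Euler on a fixed 1-minute grid of
  dn_acc/dt = P_app·A·(C_donor − C_acc), sampling V_samp every interval with
  blank replacement, recording pre-replacement concentrations; optional
  donor depletion; closing mass balance (donor + acceptor + withdrawn =
  initial) is exact to bookkeeping precision and exposed via
  `FranzBalance`.

Default noise is multiplicative lognormal, σ = 3% (midpoint of the 2–4%
analytical accuracy typical of UV assays), applied to measured
concentrations only. The generators emulate the *statistical* structure the
estimators assume — they do not model membrane lag time,
partition-into-membrane kinetics, host–membrane interaction, cosolvent
effects or temperature drift. Passing round-trip tests therefore
demonstrates estimator correctness under the stated model, not robustness
to every real-data pathology.

### Estimator/simulator closure and its limit

Because the forward model's driving force includes the acceptor
back-concentration while the slope estimator assumes a perfect sink, the
noiseless round trip is biased low by roughly the time-averaged
C_acc/C_donor ratio: ≈0.3% at P_app = 10⁻⁶ cm/s, ≈3% at 10⁻⁵, ≈5% at
2×10⁻⁵ and ≈25% at 10⁻⁴ with the default geometry (0.785 cm², 7/1 mL,
0.5 mL per 30 min, 5 h) — at 10⁻⁴ the sink condition itself fails. The
closure tests assert exactly this behaviour: tight recovery at low
permeability, negative bias bounded by the worst acceptor ratio, and ≤10%
recovery error in ≥95% of 3%-noise replicates at the experimentally
relevant rate. A hypothetical estimator that regressed on the integrated
driving force would remove the bias, but would no longer be the standard
flux/P_app procedure this package implements.

## Problem sizes and numerics

The shipped analyses are desk-scale: 5-point van't Hoff fits, 3-point
suppression regressions, 10-point flux fits; Monte-Carlo properties use
500 (slope-CI coverage) and 200 (noisy P_app recovery) seeded replicates.
The whole suite runs in seconds. OLS is `scipy.stats.linregress`; the
nonlinear binding fit uses bounded `scipy.optimize.least_squares` started
from the most-suppressed point's moment estimate; two-point fits set
standard errors to zero (no residual degrees of freedom). Logarithm
conventions: natural log in the van't Hoff analysis, base-10 in the
suppression linearization and all logD quantities.
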