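# Methods

This note documents the models, defaults, and design choices behind
nitrophys, in the order the pipeline runs them.

## Pigment assays

Chlorophyll a/b and carotenoid concentrations use the standard
multiwavelength (Lichtenthaler-type) equations on extract optical
densities; conversion to a fresh-weight basis multiplies by
extraction volume (mL) and dilution factor and divides by sample
mass (g), giving μg·g⁻¹, then scales by 0.1 to mg·100g⁻¹. That unit
factor is stated explicitly because assay protocols routinely leave
it implicit. Total chlorophyll is defined as the sum of the a and b
fresh-weight contents, so additivity is exact by construction.

Relative anthocyanin content is the A₅₃₀ − A₆₀₀ difference. Because
the reported unit is ΔOD·g⁻¹, the package normalises by sample mass
(and applies volume/dilution scaling, defaults 1); protocols differ
here, and the per-gram reading is an assumption, not a measurement
convention we can verify. Negative pigment values are returned with a
warning rather than clamped: they indicate a bad extract, and
clamping would hide exactly the cases QC needs to see.

## Light-response fitting

Model: Pn(I) = Pg,max·[1 − exp(−α·I/Pg,max)] − Rd. Rd is stored as a
positive magnitude and subtracted; writers that mimic instrument
conventions emit −Rd. This sign convention is what keeps the LSP/LCP
logarithms well defined.

Fitting is trust-region nonlinear least squares with all parameters
bounded below by 0, tolerances 1e-12, and a heuristic start:
Pg,max⁰ = range of Pn, Rd⁰ = −Pn(0) (0.5 if no dark point, with a
warning — Rd is weakly identified without one), α⁰ = slope of the two
lowest light levels clipped to [1e-3, 0.5]. On noiseless curves at
the standard 10-level PPFD sequence the optimizer returns parameters
to ~1e-13 relative error across Pg,max ∈ [2, 30], α ∈ [0.02, 0.09],
Rd ∈ [0.25, 3]; zero-variance responses raise a fit failure rather
than returning a degenerate estimate.

LSP defaults to the literal net-photosynthesis criterion
(Pn = 0.85·Pg,max ⟹ LSP = −(Pg,max/α)·ln(0.15 − Rd/Pg,max)),
undefined when Rd ≥ 0.15·Pg,max; `lsp_basis="gross"` applies the
criterion to gross photosynthesis, −(Pg,max/α)·ln(0.15). The choice
matters: the two differ by tens of μmol·m⁻²·s⁻¹ at typical
parameters, and published table values computed from per-replicate
fits are not reproducible from table-mean parameters under either
reading, so the package exposes both and defaults to the literal
one. LCP is the root of Pn, −(Pg,max/α)·ln(1 − Rd/Pg,max).

## A–Ci analysis

The two window regressions follow the standard linearisations (see
README for the formulas). Choices worth recording:

* **Gas-constant units.** The Arrhenius exponents 38.05 − 79.43/(RT)
  and 20.30 − 36.38/(RT) only give physiological constants when the
  activation energies are read as kJ·mol⁻¹ with
  R = 0.008315 kJ·mol⁻¹·K⁻¹ (Bernacchi-style). With R in J·mol⁻¹·K⁻¹
  the exponents are dimensionally inconsistent. The kJ reading yields
  Kc(25 °C) ≈ 408 μmol·mol⁻¹ and Ko(25 °C) ≈ 277 mmol·mol⁻¹ and is
  the package default.
* **O₂ mole fraction** defaults to 210 mmol·mol⁻¹ (configurable);
  **Γ\*** is fixed at its 25 °C value of 31 μmol·mol⁻¹ regardless of
  leaf temperature (configurable) — a deliberate simplification that
  matches how the constant is typically applied in this workflow.
* **Windows are closed intervals**: a point at exactly
  Ci = 200 μmol·mol⁻¹ enters both regressions.
* **Jmax regression is through the origin** by default (A = g′·Jmax);
  `jmax_intercept=True` adds an Ethier-style intercept.
* **Respiration in light** is the negative of the A–f′ intercept; a
  positive intercept (negative respiration) is reported with a
  warning, not suppressed.
* **Variable-J conductance** is evaluated at the single ambient-CO₂
  steady state. J is an *input* (fluorescence-derived electron
  transport rate); the package does not model absorptance or PSII
  partitioning. The formula requires J > 4(A + Rd) and Ci > Cc;
  violations raise typed errors rather than returning negative
  conductances.

## Derived traits

Ratios (SLA, RWR) are computed per plant before averaging
(mean-of-ratios). This matters: the ratio of cell-mean area to
cell-mean leaf mass is generally not the cell mean of per-plant SLA,
and the per-plant convention is the one consistent with running the
ANOVA on the derived trait.

## Split-plot ANOVA and letters

Replicates are treated as a random blocking factor through the
classical expected-mean-squares decomposition:
y = μ + rep + N + rep×N + cultivar + N×cultivar + ε, with F(N)
against the rep×N mean square and the sub-plot tests against the
residual. For balanced data this coincides with the REML mixed-model
tests while staying exact, dependency-free, and auditable; unbalanced
data are rejected outright rather than approximated. Type-I-error
calibration (10,000 null simulations at r = 5) puts each test's
rejection rate at 0.05 ± 0.01, and the decomposition matches an
independent sequential-ANOVA oracle to 1e-8 on worked data.

Tukey HSD comparisons among the four cell means use the studentized
range with k = 4. Within a main-plot level the comparison variance is
2·MS_e/r with residual df; across main plots it is
2·[(b−1)·MS_e + MS_mpe]/(r·b) with Satterthwaite df — standard
split-plot practice, chosen because the original mixed-model df
method is rarely stated in reports. Letters come from the
insert-and-absorb algorithm, processed in descending mean order, so
the display is deterministic and invariant to cell relabeling.

## Path models

Estimation is per-equation OLS on z-scored data, which equals maximum
likelihood for recursive models with mutually uncorrelated errors —
the only reading under which separate regressions are a valid fitting
strategy, and the package's structural assumption. Exogenous
(co)variances are free parameters fixed at their sample values; the
df accounting df = p(p+1)/2 − (#edges + #exogenous (co)variances +
#error variances) is printed in every summary so identification can
be audited. The χ² uses the (n−1) multiplier of classical SEM.
Saturated models reproduce S exactly (χ² = 0, df = 0), the
OLS-vs-normal-equations discrepancy is < 1e-10, and the χ² rejects a
true model at ≈ 5% in simulation (n = 200).

The built-in ACN spec routes the root-mass effect on leaf N through
total root dry weight (DW_Root → N_Leaf). An alternative reading
routes it through lateral-root mass (DW_LR); the built-in follows the
total-root form, and the one-edge variant can be supplied as a custom
spec. Standardized estimation is the default because path diagrams
report slopes and error boxes on a common scale; a raw-scale mode
exists. Missing data are handled by listwise deletion with a logged
count — no imputation. Latent variables, feedback loops, fit indices
beyond χ², and indirect-effect bootstraps are out of scope.

## Synthetic data

The generator emulates the 2 N-level × 2 cultivar × 5 replicate
split-plot experiment. Defaults:

* **Cell means** are the published-scale least-squares means of a
  poinsettia N-deficiency screen (24 traits across the three scales).
* **Dispersions** are not published, so residual SDs are *calibrated,
  not estimated*: for each trait the target HSD is the geometric mean
  of the largest gap within a Tukey letter group and the smallest gap
  between groups (fallbacks: half the smallest between-group gap when
  all groups are singletons; twice the range when nothing separates),
  and σ_e = HSD·√r/q(0.05; 4, 2(r−1)). The main-plot SD is 0.3·σ_e.
  This makes the printed letter patterns reproducible in most runs
  (the leaf-N c/b/a/a pattern in ≈ 90% of simulations) without
  claiming to know the real within-cell variance. These values were
  fixed once from the means/letters alone.
* **Gas-exchange parameters** per cell are the corresponding
  published-scale fit means; curve noise is Gaussian with σ = 0.3
  μmol·m⁻²·s⁻¹ on both curve types.
* **Grids**: PPFD 1500…0 (10 levels); the A–Ci Ci grid is the cuvette
  CO₂ step sequence (400, 600, 800, 1000, 600, 400, 200, 150, 100,
  50) used directly as Ci — there is no stomatal model.

The A–Ci generator produces A = min(Vcmax·f′ − Rd, Jmax·g′) + noise.
Near the limitation crossover a window can contain a point governed
by the other branch; this contamination is left in deliberately to
exercise the window regressions' robustness (with some parameter
sets, e.g. Vcmax = 100/Jmax = 120, the Ci = 200 point is
electron-transport-limited and biases the Vcmax slope by ≈ 5%).
Pure-branch modes (`limitation="rubisco"|"et"`) are available for
exact round-trip testing. The ambient steady state carries the
electron transport rate that makes the variable-J method return the
cell's target gm exactly, so the noiseless pipeline is
self-consistent end to end.

What the generator does *not* emulate: non-Gaussian trait
distributions, heteroscedasticity across treatments, measurement
drift within a gas-exchange session, stomatal dynamics, and TPU
limitation. Passing tests therefore demonstrate correctness of the
estimators under the stated statistical model, not robustness to
every feature of real instrument data.

## Problem sizes and numerical choices

The test and acceptance runs use: a 200-point noiseless grid for
light-response recovery; 10,000 (tests) / 5,000 (acceptance script)
null simulations for ANOVA calibration; n = 2,000 for path-slope
recovery and 500–1,000 simulations at n = 200 for χ² calibration; and
100 seeded experiments for the end-to-end letter-pattern rate. These
sizes give Monte-Carlo standard errors comfortably inside the
tolerances being checked. Optimizer tolerances are 1e-12
(light-response); covariance singularity is declared at condition
number > 1e12 with the most collinear variable pair named; Tukey-
letter ties are resolved by processing means in descending order.

## Known limitations

* Balanced designs only; no REML, no repeated measures, no
  non-Gaussian responses.
* No full FvCB fit with limitation-state inference; the window
  linearisations inherit their biases (documented above).
* LSP/LCP are derived from fitted parameters; their sampling error is
  not propagated.
* The anthocyanin normalisation convention is an assumption (see
  Pigments).
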