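# Methods

## Problem and model

`storekin` estimates degradation kinetics of the five all-trans
carotenoids of a pumpkin-concentrate-coloured beverage (β-carotene,
antheraxanthin, lutein, violaxanthin, neoxanthin) from isothermal storage
series, in the dark (exposure axis: days) and under accelerated
illumination (exposure axis: cumulative light dose, Mlux·h — a dose axis
is used because chamber illuminance drifts with lamp age and temperature,
so dose, not elapsed time, is the controlled variable).

Three candidate laws describe the concentration C (µg/g beverage) at
exposure x:

| law | form | parameters |
|---|---|---|
| zero order | C = C₀ − k·x | C₀, k |
| first order | C = C₀·e^(−k·x) | C₀, k |
| fractional conversion | C = C∞ + (C₀ − C∞)·e^(−k·x) | C₀, C∞, k |

The fractional-conversion law is first-order decay toward a non-zero
plateau C∞, the behaviour expected when a carotenoid partly protects
itself by quenching its own oxidation. With C∞ = 0 it reduces exactly to
first order (tested as an identity).

Temperature enters through the Arrhenius relation reparameterised about a
reference temperature Tref = 25 °C:

    k(T) = kref · exp[(Ea/R)(1/Tref_K − 1/T_K)],  R = 8.314 J·mol⁻¹·K⁻¹

with Ea in kJ/mol (converted to J/mol at the single point of use) and
Kelvin = °C + 273.15 exactly. Under this convention the package reproduces
the published per-temperature rates of the source study at their printed
precision (see `scripts/acceptance.py`).

## One-step (global) estimation

All temperatures of a group — a (carotenoid, packaging, condition)
combination — are fitted **simultaneously**: k in the law is replaced by
its Arrhenius expression, so the estimated vector is (C₀, [C∞,] kref, Ea),
p = 3 or 4 parameters, against every observation and replicate at once
(m = 56 in the standard design). This avoids the error propagation of the
classical two-step route (per-temperature k, then ln k vs 1/T); on
noise-free data the two routes agree to ≤10⁻⁴ relative (tested). C₀ and
C∞ are shared across temperatures: the source tables print a single C₀
per group, and a temperature-dependent plateau is not identifiable from
36–42-day series. Replicates enter as independent observations
(preserving residual degrees of freedom m − p); pre-averaging is available
as an option but is not the default.

Optimisation: bounded trust-region least squares
(`scipy.optimize.least_squares`, method `trf`) with bounds C₀ > 0,
0 ≤ C∞, kref ≥ 0, 0 ≤ Ea ≤ 300 kJ/mol, tolerances ftol = xtol = 1e−10,
max 10⁴ residual evaluations. A deterministic multi-start (default 8
starts; 4 in the heavier simulation tests, ample for these well-posed
problems) crosses data-derived kref guesses with Ea ∈ {5, 15, 30, 60}
kJ/mol, with small seeded log-normal jitter (default seed 20220207,
configurable); the best converged start wins. The (kref, Ea) surface is
mildly banana-shaped (strong negative correlation), which multi-start
handles robustly.

Standard errors are the linearised MSE·(JᵀJ)⁻¹ at the optimum (pseudo-
inverse, so a rate pinned at zero does not crash the Ea column); derived
per-temperature rates k(T) carry delta-method SEs from the (kref, Ea)
covariance block. Fit statistics: SEE = √(SSQ/(m−p)); r²adj computed
against the grand mean of the whole multi-temperature group (one global
statistic per fit, matching how the source study reports it); and a
two-sided Wald–Wolfowitz runs test (normal approximation, cross-checked
against statsmodels) on residual signs ordered by exposure within
temperature — a numerical stand-in for visual residual-plot inspection,
reported but never used as a hard gate.

Degenerate inputs: m ≤ p is an error; constant observations make r²adj
undefined (reported as NaN inside a fit; the standalone `fit_statistics`
raises); zero-order predictions are never clamped at zero during fitting
(clamping would bias residuals) — a warning flag is set instead.

## Model selection

Candidates are ranked by SEE (ascending). Ties — including the
"numerically perfect fit" regime where every SEE is below 10⁻⁶ of the
data's RMS and differences are optimiser noise — resolve toward fewer
parameters. The fractional-conversion law displaces a simpler converged
law only if it improves SEE by ≥5% (relative, configurable) **and** its
plateau estimate satisfies C∞ > 2·SE(C∞); otherwise the plateau is not
supported by the data and the simpler law is kept. At the study design
with 2% noise this procedure identifies the generating law in ≥90% of
seeded simulations for each of the three laws (tested at 50 seeds each).

## Joint confidence regions

The 90% joint confidence region for (kref, Ea) collects the grid points
whose SSQ satisfies

    SSQ ≤ SSQ_min · [1 + p/(m−p) · F(p, m−p; 1−φ)],   φ = 0.10,

with p the **total** number of simultaneously estimated parameters (3 or
4), not 2 — the nuisance parameters C₀/C∞ were estimated too. Nuisance
handling on the grid is either `fixed_at_optimum` (default) or `profiled`
(re-minimised per grid point; every law here is linear in C₀ and C∞ once
k is fixed, so profiling is an exact linear solve). Profiled SSQ is
pointwise ≤ fixed SSQ, so profiled regions always contain fixed ones
(tested). The grid auto-spans ±6 linearised SEs (≥25×25, default 81×81),
expanding up to three times if the threshold contour is clipped; contours
are extracted by marching squares (`skimage.measure.find_contours`) and
overlap between groups is decided on the actual contour polygons
(shapely), never bounding boxes — these regions are elongated and tilted
by the kref–Ea anti-correlation.

Coverage, measured over 200 seeded replicates of the standard design at
2% noise (zero-order truth): membership of the true parameter point
evaluated at the full truth vector = 93.5% (the construction's exact-
coverage statement in the linear-model limit is for this quantity, and
the Monte-Carlo coverage test asserts it); the fixed-at-optimum 2-D slice
= 80.5% (it ignores nuisance readjustment and understates joint
uncertainty); the profiled region = 97.5% (conservative under the total-p
threshold). Consequently, between-group inference (the same-truth overlap
test) uses profiled regions; the fixed slice remains the drawing default
for speed and for fidelity to the construction as published.

## Shelf-life re-expression and ancillary analyses

A `LightSchedule` (illuminance lux, hours lit per day) converts between
shelf days and dose: dose = days × lux × h/day × 10⁻⁶ Mlux·h. The retail
reference scenario, a 600-lux bulb lit 12 h/day, gives 0.0072 Mlux·h per
day, so 180 days ≈ 1.3 Mlux·h — the full dose span of the illuminated
study. Because every law depends on (k, x) only through k·x, multiplying
a per-dose rate by the daily dose yields a per-day rate whose day-axis
trajectory commutes exactly with the dose-axis one (tested).

Rate comparisons with/without ascorbic acid use a Welch t-test on the two
fitted constants, t = (k₁−k₂)/√(se₁²+se₂²), with Welch–Satterthwaite df
from the two fits' residual dofs — the dofs must be supplied explicitly
(the source tables leave them unstated; the analysis scripts use df = 12,
i.e. a single-temperature 14-point, 2-parameter fit). Significance at
α = 0.05.

Oxygen bookkeeping converts an ascorbic-acid loss (µg/g; beverage density
default 1.0 g/mL bridges the per-mass and per-volume unit systems,
configurable) and a dissolved-O₂ loss (mg/L) to mol/L and applies the
aerobic stoichiometry 0.5 mol O₂ per mol AA (molar masses 176.12 and
32.00 g/mol). The resulting fraction is scale-invariant (homogeneous of
degree zero, tested); a fraction near 1 means AA oxidation fully accounts
for the oxygen consumed, a fraction above 1 implies additional oxygen
sources (headspace) or partly anaerobic AA degradation. The
dissolved-oxygen/carotenoid-loss relation is summarised by ordinary least
squares (`linear_association`).

## Synthetic data

The generator emulates the storage design: dark — 10 and 20 °C followed
for 42 days, 35 and 45 °C for 36 days, seven evenly spaced sampling
points from a time-0 baseline; illuminated — seven doses from 0 to
1.3 Mlux·h at each of the four temperatures; duplicate extractions.
Noise is additive Gaussian, i.i.d., truncated at zero, default
sd = 2% of C₀ — a deliberate idealisation of small, roughly homoscedastic
duplicate-extraction HPLC scatter. Streams are reproducible per
(seed, group) via a stable CRC-based key. Truth parameters default to the
literature estimates (`storekin.reference`); the never-published plateau
C∞ defaults to 0.6·C₀, consistent with the ~36–38% terminal β-carotene
losses reported.

What the generator does **not** emulate: exposure-dependent or
concentration-dependent error, between-bottle variation, quantification
censoring near the detection limit, isomerisation fluxes, or
dissolved-oxygen dynamics. Passing recovery tests therefore demonstrate
correctness of the estimator under the stated error model, not robustness
to real HPLC pathologies.

Two study-conditions notes. First, the literature illuminated first-order
rates (~1–4 ×10⁻² Mlux·h⁻¹) imply only 1–5% total decay across the whole
1.3 Mlux·h span — comparable to the 2% noise — so simulated illuminated
groups at the literal printed scale are weakly identified (visible in
`analysis/02_fit_kinetics.py`); the printed scale is implemented
literally rather than "corrected", and all identification-sensitive tests
(recovery, selection, coverage) run on the dark design, where losses
reach ~50%. Second, the model-selection test needs an identifiable
first-order truth; it uses kref = 1.70×10⁻² day⁻¹ (the day-axis
first-order scale reported for dark β-carotene at 35 °C) with a
representative Ea = 22.55 kJ/mol.

## Problem sizes and determinism

Default test problem sizes: 56-observation groups; 50-seed recovery and
selection studies; 200-replicate coverage; 100-replicate overlap; JCR
grids 41–81 per axis. All randomness flows from explicit integer seeds
(generator default 0; optimiser jitter default 20220207); reruns are
bit-identical on report numbers, and the pipeline writes its seed and
configuration into `run.log`.

## Known limitations

- Uni-response fits only: no joint multi-carotenoid estimation, no
  weighted least squares, no Bayesian alternatives.
- Linearised (Wald) standard errors; for strongly curved (kref, Ea)
  surfaces the JCR is the more trustworthy uncertainty summary.
- The fixed-at-optimum JCR slice under-covers by design of its
  construction (measured 80.5% vs nominal 90%); use profiled regions when
  the scientific question is between-group distinguishability.
- Kinetic constants describe the all-trans pool only; cis-isomer dynamics
  are out of scope.
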