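# storekin

Storage-stability kinetics of carotenoid degradation in a coloured
beverage: one-step global Arrhenius regression, model selection among
degradation laws, F-based joint confidence regions, light-dose ↔
retail-day shelf-life prediction, and ascorbic-acid/oxygen accounting —
with a synthetic-data generator that emulates the underlying isothermal
storage study, so the whole analysis is testable end to end.

Intended users: food chemists and kinetic modellers estimating pigment or
nutrient losses from multi-temperature storage trials, and anyone needing
reproducible shelf-life re-expression of accelerated light-exposure data.

## The model

Concentration C (µg/g) at exposure x (days in the dark, Mlux·h under
light) follows one of three laws —

- zero order: C = C₀ − k·x
- first order: C = C₀·e^(−k·x)
- fractional conversion: C = C∞ + (C₀ − C∞)·e^(−k·x)

— with temperature dependence k(T) = kref·exp[(Ea/R)(1/Tref − 1/T)]
(Tref = 298.15 K, R = 8.314 J·mol⁻¹·K⁻¹). All temperatures of a group are
fitted **simultaneously** ("one-step"): k is substituted by its Arrhenius
expression so (C₀, [C∞,] kref, Ea) are estimated in a single nonlinear
least-squares problem. Joint uncertainty of (kref, Ea) is summarised by
the SSQ contour region SSQ ≤ SSQ_min·[1 + p/(m−p)·F(p, m−p; 1−φ)].
See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
import storekin as sk

# simulate a dark-storage study for one carotenoid (4 T × 7 points × 2 reps)
from storekin.reference import truth_for
from storekin.simulate import dark_design, generate

model, truth = truth_for("antheraxanthin", "glass", "dark")
table = generate(model, truth, dark_design(), sk.NoiseSpec(sd=0.02, seed=7))

fit = sk.fit_one_step(table, model)
print(f"kref = {fit.estimates.kref:.4g} ± {fit.standard_errors['kref']:.2g}")
print(f"Ea   = {fit.estimates.Ea:.4g} ± {fit.standard_errors['Ea']:.2g} kJ/mol")
print(f"r2adj = {fit.r2adj:.3f}, SEE = {fit.see:.4g}")
```

prints

```
kref = 0.006044 ± 0.00025
Ea   = 36.47 ± 1.4 kJ/mol
r2adj = 0.978, SEE = 0.0215
```

i.e. from a simulated 56-observation study (truth kref = 0.0064 µg/g/day,
Ea = 35.48 kJ/mol, 2% noise) the one-step fit recovers the rate at 25 °C
within ~6% and the activation energy within ~3%, with the fit explaining
~98% of the variance. Rate constants at the four study
temperatures, with delta-method SEs, are in `fit.k_by_temperature`.

Shelf-life conversion: a 600-lux shelf lit 12 h/day accumulates
0.0072 Mlux·h per day, so

```python
sk.dose_from_days(180, sk.LightSchedule(600, 12))  # -> 1.296 (≈ 1.3 Mlux·h)
```

— six retail months equal the full dose span of an accelerated
illumination trial.

## Analysis scripts

`analysis/` holds the numbered end-to-end study, each step a thin driver
over the library that writes tables under `results/`:

1. `01_simulate_study.py` — synthetic dark + illuminated studies, all five
   carotenoids × two packagings at 2% noise
2. `02_fit_kinetics.py` — model selection + one-step fits vs truth
3. `03_confidence_regions.py` — 90% joint confidence regions and pairwise
   overlap of the dark zero-order carotenoids
4. `04_shelf_life.py` — per-day rates and 180-day retention at 20 °C
5. `05_ascorbic_acid.py` — rate comparisons with/without ascorbic acid and
   the O₂ stoichiometry budget

There is also a CLI for the individual steps
(`storekin simulate|validate|fit|jcr|convert|compare|run`); see
`storekin --help`.

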