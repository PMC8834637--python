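"""Literature-reported kinetic parameters for the pumpkin-beverage study.

These are the published one-step regression estimates for the five
all-trans carotenoids of a pumpkin-concentrate-coloured beverage stored in
glass or PET bottles, in the dark (rate axis: days) and under accelerated
illumination (rate axis: Mlux·h). They serve two roles:

* default ground-truth parameter sets for the synthetic-data generator, so
  simulated studies share the published effect sizes;
* inputs for desk calculations (per-temperature Arrhenius rates, rate-ratio
  comparisons with/without ascorbic acid).

Conventions: ``kref`` is the rate at Tref = 25 °C on the natural scale
(the tables print kref × 10²); ``Ea`` in kJ/mol; ``C0`` in µg/g beverage.
For zero-order laws k is in µg·g⁻¹ per exposure unit, otherwise per
exposure unit. The plateau C∞ of the fractional-conversion law was never
reported; the generator defaults it to 0.6·C0 (matching the ~36–38 %
terminal β-carotene losses observed).
"""

from __future__ import annotations

from .kinetics import ModelSpec, ParamSet

CAROTENOIDS = (
    "beta-carotene",
    "antheraxanthin",
    "lutein",
    "violaxanthin",
    "neoxanthin",
)

#: Fraction of C0 used as the default fractional-conversion plateau.
DEFAULT_CINF_FRACTION = 0.6

# (carotenoid, packaging) -> dict(order, C0, kref, Ea); dark storage, axis days.
DARK = {
    ("beta-carotene", "glass"): dict(order="fractional", C0=1.22, kref=7.50e-2, Ea=15.13),
    ("beta-carotene", "PET"): dict(order="fractional", C0=1.15, kref=8.40e-2, Ea=22.55),
    ("antheraxanthin", "glass"): dict(order="zero", C0=1.07, kref=0.64e-2, Ea=35.48),
    ("antheraxanthin", "PET"): dict(order="zero", C0=1.04, kref=0.78e-2, Ea=35.23),
    ("lutein", "glass"): dict(order="zero", C0=0.59, kref=0.28e-2, Ea=26.75),
    ("lutein", "PET"): dict(order="zero", C0=0.59, kref=0.31e-2, Ea=41.16),
    ("violaxanthin", "glass"): dict(order="zero", C0=0.10, kref=0.07e-2, Ea=19.48),
    ("violaxanthin", "PET"): dict(order="zero", C0=0.10, kref=0.11e-2, Ea=22.85),
    ("neoxanthin", "glass"): dict(order="zero", C0=0.10, kref=0.07e-2, Ea=12.88),
    ("neoxanthin", "PET"): dict(order="zero", C0=0.10, kref=0.10e-2, Ea=26.20),
}

# Illuminated storage, axis cumulative light dose (Mlux·h).
ILLUMINATED = {
    ("beta-carotene", "glass"): dict(order="fractional", C0=1.19, kref=3.68e-2, Ea=19.25),
    ("beta-carotene", "PET"): dict(order="fractional", C0=1.16, kref=3.69e-2, Ea=17.43),
    ("antheraxanthin", "glass"): dict(order="fractional", C0=1.08, kref=3.79e-2, Ea=16.20),
    ("antheraxanthin", "PET"): dict(order="fractional", C0=1.06, kref=3.51e-2, Ea=11.50),
    ("lutein", "glass"): dict(order="first", C0=0.64, kref=1.21e-2, Ea=7.86),
    ("lutein", "PET"): dict(order="first", C0=0.67, kref=1.50e-2, Ea=8.36),
    ("violaxanthin", "glass"): dict(order="first", C0=0.10, kref=2.49e-2, Ea=22.94),
    ("violaxanthin", "PET"): dict(order="first", C0=0.10, kref=3.25e-2, Ea=27.90),
    ("neoxanthin", "glass"): dict(order="first", C0=0.09, kref=3.29e-2, Ea=21.44),
    ("neoxanthin", "PET"): dict(order="first", C0=0.09, kref=3.43e-2, Ea=22.42),
}

# Rate constants at 35 °C (×10⁻² as printed) without vs with added ascorbic
# acid (300 µg/g), mean ± SE, for each carotenoid and storage condition.
AA_COMPARISON = {
    "dark": {
        "beta-carotene": dict(order="first", k_no_aa=(1.70, 0.20), k_aa=(0.39, 0.01)),
        "antheraxanthin": dict(order="zero", k_no_aa=(1.23, 0.06), k_aa=(0.79, 0.11)),
        "lutein": dict(order="zero", k_no_aa=(0.52, 0.01), k_aa=(0.28, 0.08)),
        "violaxanthin": dict(order="zero", k_no_aa=(0.14, 0.01), k_aa=(0.09, 0.01)),
        "neoxanthin": dict(order="zero", k_no_aa=(0.14, 0.01), k_aa=(0.08, 0.01)),
    },
    "illuminated": {
        "beta-carotene": dict(order="first", k_no_aa=(1.68, 0.10), k_aa=(0.23, 0.03)),
        "antheraxanthin": dict(order="first", k_no_aa=(2.31, 0.10), k_aa=(0.28, 0.05)),
        "lutein": dict(order="first", k_no_aa=(1.34, 0.06), k_aa=(0.26, 0.03)),
        "violaxanthin": dict(order="first", k_no_aa=(2.06, 0.11), k_aa=(0.78, 0.05)),
        "neoxanthin": dict(order="first", k_no_aa=(2.75, 0.17), k_aa=(1.30, 0.12)),
    },
}


def truth_for(
    carotenoid: str,
    packaging: str,
    condition: str,
    cinf_fraction: float = DEFAULT_CINF_FRACTION,
    tref: float = 25.0,
) -> tuple[ModelSpec, ParamSet]:
    """Reference (ModelSpec, ParamSet) for one carotenoid/packaging/condition."""
    table = DARK if condition == "dark" else ILLUMINATED
    axis = "time_days" if condition == "dark" else "dose_Mluxh"
    try:
        entry = table[(carotenoid, packaging)]
    except KeyError:
        raise KeyError(
            f"no reference parameters for ({carotenoid!r}, {packaging!r}, {condition!r})"
        ) from None
    model = ModelSpec(order=entry["order"], axis=axis)
    cinf = cinf_fraction * entry["C0"] if entry["order"] == "fractional" else None
    params = ParamSet(C0=entry["C0"], kref=entry["kref"], Ea=entry["Ea"], Cinf=cinf, Tref=tref)
    return model, params
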