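"""Retail-shelf re-expression, rate comparisons and oxygen accounting.

Illuminated-storage kinetics are estimated on a cumulative light-dose axis
(Mlux·h) because the climatic chamber's illuminance drifts with lamp age
and temperature. To speak in shelf days, a :class:`LightSchedule` fixes a
retail scenario (e.g. a 600-lux bulb lit 12 h/day), making dose and days
mutually convertible: 180 days × 600 lux × 12 h/day = 1.296 ≈ 1.3 Mlux·h.

The module also compares fitted rate constants with and without ascorbic
acid (Welch t-test), converts ascorbic-acid and dissolved-oxygen losses to
a stoichiometric fraction (aerobic AA oxidation consumes 0.5 mol O₂ per
mol AA), and provides the simple linear association used to relate
dissolved-oxygen decline to carotenoid loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "LightSchedule",
    "RateComparison",
    "StoichiometryResult",
    "dose_from_days",
    "days_from_dose",
    "rate_to_perday",
    "compare_rates",
    "aa_oxygen_fraction",
    "linear_association",
]

#: Molar masses, g/mol.
MOLAR_MASS_AA = 176.12
MOLAR_MASS_O2 = 32.00


@dataclass(frozen=True)
class LightSchedule:
    """A retail lighting scenario: illuminance and daily burn hours."""

    illuminance_lux: float = 600.0
    hours_per_day: float = 12.0

    def __post_init__(self) -> None:
        if self.illuminance_lux <= 0:
            raise ValueError("illuminance must be > 0 lux")
        if not 0 < self.hours_per_day <= 24:
            raise ValueError("hours_per_day must be in (0, 24]")

    @property
    def mluxh_per_day(self) -> float:
        """Daily dose in Mlux·h: lux × hours × 10⁻⁶."""
        return self.illuminance_lux * self.hours_per_day * 1e-6


@dataclass(frozen=True)
class RateComparison:
    """Welch t-test between two independently fitted rate constants."""

    k1: float
    se1: float
    k2: float
    se2: float
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    significant: bool  # at alpha = 0.05

    @property
    def ratio(self) -> float:
        return self.k1 / self.k2


@dataclass(frozen=True)
class StoichiometryResult:
    """Oxygen bookkeeping of ascorbic-acid oxidation (per litre beverage)."""

    moles_aa_consumed: float
    moles_o2_required: float
    observed_o2_consumed: float
    fraction_attributable: float


def dose_from_days(days: float | np.ndarray, schedule: LightSchedule) -> float | np.ndarray:
    """Cumulative light dose (Mlux·h) accumulated over ``days`` on a schedule."""
    days = np.asarray(days, dtype=float)
    if np.any(days < 0):
        raise ValueError("days must be >= 0")
    out = days * schedule.mluxh_per_day
    return float(out) if out.ndim == 0 else out


def days_from_dose(dose: float | np.ndarray, schedule: LightSchedule) -> float | np.ndarray:
    """Exact inverse of :func:`dose_from_days`."""
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be >= 0")
    out = dose / schedule.mluxh_per_day
    return float(out) if out.ndim == 0 else out


def rate_to_perday(k_dose: float, schedule: LightSchedule) -> float:
    """Re-express a per-Mlux·h rate constant as a per-day rate.

    Because every law depends on k and exposure only through k·x, scaling k
    by the daily dose makes trajectories over days identical to trajectories
    over dose composed with :func:`dose_from_days` (exact commutation). The
    conversion applies unchanged to zero-order (µg·g⁻¹·Mlux·h⁻¹) and
    first-order/fractional (Mlux·h⁻¹) constants.
    """
    if k_dose < 0:
        raise ValueError("rate constant must be >= 0")
    return k_dose * schedule.mluxh_per_day


def compare_rates(
    k1: float, se1: float, df1: float, k2: float, se2: float, df2: float, alpha: float = 0.05
) -> RateComparison:
    """Welch-type t-test for the difference of two fitted rate constants.

    ``t = (k1−k2)/sqrt(se1²+se2²)`` with Welch–Satterthwaite degrees of
    freedom from the two fits' residual dofs. The dofs must be supplied
    explicitly — there is no safe default for regression-derived SEs.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be > 0")
    if df1 is None or df2 is None or df1 <= 0 or df2 <= 0:
        raise ValueError("degrees of freedom for both rates are required and must be > 0")
    v1, v2 = se1**2, se2**2
    t = (k1 - k2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / df1 + v2**2 / df2)
    p = float(2 * stats.t.sf(abs(t), df))
    return RateComparison(
        k1=k1,
        se1=se1,
        k2=k2,
        se2=se2,
        t_statistic=float(t),
        degrees_of_freedom=float(df),
        p_value=p,
        significant=p <= alpha,
    )


def aa_oxygen_fraction(
    delta_aa_ug_per_g: float,
    delta_o2_mg_per_l: float,
    density_g_per_ml: float = 1.0,
) -> StoichiometryResult:
    """Fraction of consumed dissolved O₂ accounted for by AA oxidation.

    Converts an ascorbic-acid loss (µg per g beverage) and a dissolved-
    oxygen loss (mg/L) to mol/L — the beverage density bridges the per-mass
    and per-volume unit systems — and applies the 0.5 mol O₂ : 1 mol AA
    aerobic-oxidation stoichiometry. A fraction of ~1 means essentially all
    the oxygen went into protecting the matrix via AA oxidation.
    """
    if delta_aa_ug_per_g < 0 or delta_o2_mg_per_l < 0:
        raise ValueError("consumption deltas must be >= 0")
    if density_g_per_ml <= 0:
        raise ValueError("density must be > 0")
    # µg/g × (g/mL) × 1000 mL/L = µg/L ≡ 10⁻³ mg/L; altogether mg/L = µg/g × ρ.
    aa_mg_per_l = delta_aa_ug_per_g * density_g_per_ml
    mol_aa = aa_mg_per_l / 1e3 / MOLAR_MASS_AA
    mol_o2_obs = delta_o2_mg_per_l / 1e3 / MOLAR_MASS_O2
    mol_o2_req = 0.5 * mol_aa
    if mol_aa > 0 and mol_o2_obs == 0:
        raise ZeroDivisionError("observed O2 consumption is zero; fraction undefined")
    frac = 0.0 if mol_aa == 0 else mol_o2_req / mol_o2_obs
    return StoichiometryResult(
        moles_aa_consumed=mol_aa,
        moles_o2_required=mol_o2_req,
        observed_o2_consumed=mol_o2_obs,
        fraction_attributable=frac,
    )


def linear_association(x, y) -> dict:
    """Ordinary least-squares association between two paired series.

    Returns slope, intercept, r², adjusted r² and the two-sided p-value of
    the slope. Used e.g. for dissolved-oxygen decline vs carotenoid loss.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; association undefined")
    res = stats.linregress(x, y)
    n = len(x)
    r2 = res.rvalue**2
    r2adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return dict(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(r2),
        r2adj=float(r2adj),
        p_value=float(res.pvalue),
    )
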