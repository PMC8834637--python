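"""Degradation laws and the Arrhenius temperature relation.

Three candidate laws describe how a carotenoid concentration ``C`` declines
with exposure ``x`` (storage days in the dark, cumulative light dose in
Mlux·h under illumination):

* zero order:            C(x) = C0 − k·x
* first order:           C(x) = C0·exp(−k·x)
* fractional conversion: C(x) = C∞ + (C0 − C∞)·exp(−k·x)

The rate constant at temperature ``T`` follows the Arrhenius relation
reparameterised about a reference temperature ``Tref`` (default 25 °C):

    k(T) = kref · exp[(Ea/R)·(1/Tref_K − 1/T_K)]

with the activation energy ``Ea`` in kJ/mol (converted to J/mol at the
single point of use) and the gas constant R = 8.314 J·mol⁻¹·K⁻¹.

Axis labels (``time_days`` vs ``dose_Mluxh``) are metadata: they tag the
unit of ``x`` and of ``k`` but never change any numeric result.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "R_GAS",
    "KELVIN_OFFSET",
    "ModelOrder",
    "Axis",
    "ModelSpec",
    "ParamSet",
    "arrhenius_k",
    "predict",
]

#: Gas constant, J·mol⁻¹·K⁻¹.
R_GAS = 8.314

#: Exact offset between Celsius and Kelvin used throughout.
KELVIN_OFFSET = 273.15

ModelOrder = Literal["zero", "first", "fractional"]
Axis = Literal["time_days", "dose_Mluxh"]

_ORDERS = ("zero", "first", "fractional")
_AXES = ("time_days", "dose_Mluxh")

#: Exposure-unit tag used in CSV files for each axis.
AXIS_UNIT = {"time_days": "day", "dose_Mluxh": "Mlux_h"}
UNIT_AXIS = {v: k for k, v in AXIS_UNIT.items()}


@dataclass(frozen=True)
class ModelSpec:
    """A degradation law together with the exposure axis it applies to."""

    order: ModelOrder
    axis: Axis = "time_days"

    def __post_init__(self) -> None:
        if self.order not in _ORDERS:
            raise ValueError(f"unknown model order {self.order!r}; expected one of {_ORDERS}")
        if self.axis not in _AXES:
            raise ValueError(f"unknown axis {self.axis!r}; expected one of {_AXES}")

    @property
    def n_params(self) -> int:
        """Number of simultaneously estimated parameters: 3, or 4 with C∞."""
        return 4 if self.order == "fractional" else 3

    @property
    def k_unit(self) -> str:
        """Unit string of the rate constant implied by order and axis."""
        x_unit = "day" if self.axis == "time_days" else "Mlux_h"
        if self.order == "zero":
            return f"ug/g/{x_unit}"
        return f"1/{x_unit}"


@dataclass(frozen=True)
class ParamSet:
    """Kinetic parameters: initial level, rate at Tref, activation energy.

    Parameters
    ----------
    C0 : float
        Initial concentration at exposure 0, µg/g beverage (> 0).
    kref : float
        Rate constant at the reference temperature. Units depend on the
        law: day⁻¹ / Mlux·h⁻¹ for first order and fractional conversion,
        µg·g⁻¹·day⁻¹ / µg·g⁻¹·Mlux·h⁻¹ for zero order.
    Ea : float
        Activation energy, kJ/mol (≥ 0).
    Cinf : float, optional
        Plateau concentration of the fractional conversion law,
        0 ≤ Cinf < C0. ``None`` for zero/first order.
    Tref : float
        Reference temperature, °C. Default 25.
    """

    C0: float
    kref: float
    Ea: float
    Cinf: float | None = None
    Tref: float = 25.0

    def __post_init__(self) -> None:
        vals = [self.C0, self.kref, self.Ea, self.Tref]
        if self.Cinf is not None:
            vals.append(self.Cinf)
        if not np.all(np.isfinite(vals)):
            raise ValueError("kinetic parameters must be finite")
        if self.C0 <= 0:
            raise ValueError(f"C0 must be > 0, got {self.C0}")
        if self.kref < 0:
            raise ValueError(f"kref must be >= 0, got {self.kref}")
        if self.Ea < 0:
            raise ValueError(f"Ea must be >= 0, got {self.Ea}")
        if self.Cinf is not None and not (0 <= self.Cinf < self.C0):
            raise ValueError(f"Cinf must satisfy 0 <= Cinf < C0, got {self.Cinf}")

    def with_(self, **kwargs) -> "ParamSet":
        return replace(self, **kwargs)


def arrhenius_k(params: ParamSet, T: float | np.ndarray) -> float | np.ndarray:
    """Rate constant at temperature ``T`` (°C) from the Arrhenius relation.

    Returns ``kref · exp[(Ea/R)(1/Tref_K − 1/T_K)]`` in the same units as
    ``kref``; strictly increasing in ``T`` whenever ``Ea > 0``.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= -KELVIN_OFFSET):
        raise ValueError("temperature below absolute zero")
    t_k = T + KELVIN_OFFSET
    tref_k = params.Tref + KELVIN_OFFSET
    ea_j = params.Ea * 1e3  # kJ/mol -> J/mol at the single point of use
    out = params.kref * np.exp((ea_j / R_GAS) * (1.0 / tref_k - 1.0 / t_k))
    return float(out) if out.ndim == 0 else out


def predict(
    model: ModelSpec,
    params: ParamSet,
    T: float | np.ndarray,
    x: float | np.ndarray,
) -> float | np.ndarray:
    """Predicted concentration (µg/g) at temperature ``T`` and exposure ``x``.

    At ``x = 0`` every law returns ``C0``. Zero-order predictions may go
    negative at large exposure; they are deliberately not clamped (clamping
    would bias residuals during fitting) — callers can test for it.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("exposure must be non-negative")
    k = arrhenius_k(params, T)
    if model.order == "zero":
        out = params.C0 - k * x
    elif model.order == "first":
        out = params.C0 * np.exp(-k * x)
    else:
        if params.Cinf is None:
            raise ValueError("fractional conversion model requires Cinf")
        out = params.Cinf + (params.C0 - params.Cinf) * np.exp(-k * x)
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


def predictions_negative(
    model: ModelSpec, params: ParamSet, T: float, x_max: float
) -> bool:
    """True if the law predicts a negative concentration inside [0, x_max]."""
    # All three laws are monotone in x, so the minimum is at x_max.
    return bool(predict(model, params, T, x_max) < 0)
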