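"""Synthetic concentration datasets with the storage study's structure.

The generator reproduces the isothermal storage design — four temperatures
(10 and 20 °C followed for 42 days, 35 and 45 °C for 36 days, seven
sampling points from a time-0 baseline, duplicate extractions) and, for
illuminated storage, seven cumulative light doses from 0 to 1.3 Mlux·h —
and overlays additive Gaussian measurement noise, truncated at zero so no
negative concentration is ever produced. Truth parameters default to the
literature estimates in :mod:`storekin.reference`, so simulated studies
carry realistic effect sizes; every table records its truth for recovery
tests. Noise defaults to sd = 2 % of C0 (small, roughly homoscedastic
duplicate-extraction HPLC scatter).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import reference
from .data_io import COLUMNS, StudyDesign, StudyTable
from .kinetics import AXIS_UNIT, ModelSpec, ParamSet, predict

__all__ = [
    "NoiseSpec",
    "generate",
    "make_study_fixture",
    "dark_design",
    "illuminated_design",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian measurement noise.

    ``relative_to_C0`` scales sd by the truth C0 (default, sd = 0.02);
    ``absolute`` uses sd in µg/g directly. A given (seed, group) pair
    always yields the same noise stream.
    """

    mode: str = "relative_to_C0"
    sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("absolute", "relative_to_C0"):
            raise ValueError(f"unknown noise mode {self.mode!r}")
        if self.sd <= 0:
            raise ValueError("noise sd must be > 0")

    def sigma(self, c0: float) -> float:
        return self.sd * c0 if self.mode == "relative_to_C0" else self.sd


def _group_rng(seed: int, group: tuple[str, str, str]) -> np.random.Generator:
    """Reproducible per-(seed, group) stream, independent across groups."""
    # crc32 is a stable string hash (Python's hash() is salted per process).
    return np.random.default_rng([seed, *(zlib.crc32(g.encode()) for g in group)])


def dark_design(replicates: int = 2, n_points: int = 7) -> StudyDesign:
    """Dark-storage layout: 10/20 °C out to 42 d, 35/45 °C out to 36 d."""
    grid = {
        10.0: tuple(np.linspace(0, 42, n_points)),
        20.0: tuple(np.linspace(0, 42, n_points)),
        35.0: tuple(np.linspace(0, 36, n_points)),
        45.0: tuple(np.linspace(0, 36, n_points)),
    }
    return StudyDesign(temperatures=(10.0, 20.0, 35.0, 45.0), exposure_grid=grid, replicates=replicates)


def illuminated_design(replicates: int = 2, n_points: int = 7) -> StudyDesign:
    """Illuminated layout: doses 0–1.3 Mlux·h at each of the 4 temperatures."""
    doses = tuple(np.linspace(0, 1.3, n_points))
    grid = {t: doses for t in (10.0, 20.0, 35.0, 45.0)}
    return StudyDesign(temperatures=(10.0, 20.0, 35.0, 45.0), exposure_grid=grid, replicates=replicates)


def generate(
    model: ModelSpec,
    truth: ParamSet,
    design: StudyDesign,
    noise: NoiseSpec | None = None,
    carotenoid: str = "synthetic",
    packaging: str = "glass",
    condition: str | None = None,
) -> StudyTable:
    """Simulate one group's concentration table under a design.

    concentration = predict(model, truth, T, x) + ε, ε ~ N(0, σ²) i.i.d.,
    clipped at 0. ``noise=None`` gives noise-free data (the zero-sd limit).
    The truth is attached as ``table.truth`` for closure tests.
    """
    if condition is None:
        condition = "dark" if model.axis == "time_days" else "illuminated"
    unit = AXIS_UNIT[model.axis]
    rows = []
    for t in design.temperatures:
        for x in design.exposure_grid[t]:
            c = predict(model, truth, t, float(x))
            for rep in range(1, design.replicates + 1):
                rows.append((carotenoid, packaging, condition, float(t), float(x), unit, rep, c))
    df = pd.DataFrame(rows, columns=list(COLUMNS))
    if noise is not None:
        rng = _group_rng(noise.seed, (carotenoid, packaging, condition))
        eps = rng.normal(0.0, noise.sigma(truth.C0), size=len(df))
        df["concentration_ug_per_g"] = np.clip(df["concentration_ug_per_g"] + eps, 0.0, None)
    else:
        df["concentration_ug_per_g"] = np.clip(df["concentration_ug_per_g"], 0.0, None)
    table = StudyTable(df, model.axis)
    table.truth = {"model": model, "params": truth}  # type: ignore[attr-defined]
    return table


def make_study_fixture(
    scenario: str,
    packaging: str | list[str] = "glass",
    noise: NoiseSpec | None = None,
    carotenoids: list[str] | None = None,
    replicates: int = 2,
    cinf_fraction: float = reference.DEFAULT_CINF_FRACTION,
) -> StudyTable:
    """Full multi-carotenoid fixture of one storage scenario.

    ``scenario`` is "dark" or "illuminated"; truth parameters are the
    literature estimates for the requested carotenoids (default: all five).
    One packaging gives 4 temperatures × 7 points × ``replicates``
    observations per carotenoid (56 with duplicates).
    """
    if scenario not in ("dark", "illuminated"):
        raise ValueError("scenario must be 'dark' or 'illuminated'")
    design = dark_design(replicates) if scenario == "dark" else illuminated_design(replicates)
    packs = [packaging] if isinstance(packaging, str) else list(packaging)
    carots = carotenoids or list(reference.CAROTENOIDS)
    parts = []
    truths = {}
    for pack in packs:
        for carot in carots:
            model, truth = reference.truth_for(carot, pack, scenario, cinf_fraction)
            sub = generate(
                model, truth, design, noise, carotenoid=carot, packaging=pack, condition=scenario
            )
            truths[(carot, pack, scenario)] = sub.truth  # type: ignore[attr-defined]
            parts.append(sub.df)
    axis = "time_days" if scenario == "dark" else "dose_Mluxh"
    table = StudyTable(pd.concat(parts, ignore_index=True), axis)
    table.truth = truths  # type: ignore[attr-defined]
    return table
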