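"""F-based joint confidence regions in the (kref, Ea) plane.

The joint confidence region at level 1−φ collects the parameter pairs
whose residual sum of squares stays below an F-scaled multiple of the
least-squares minimum:

    SSQ(kref, Ea) ≤ SSQ_min · [1 + p/(m−p) · F(p, m−p; 1−φ)]

with p the number of simultaneously estimated parameters of the fit (3 or
4 — not 2: the nuisance parameters C0 and C∞ were estimated too), m the
number of observations. The region is drawn on a (kref, Ea) grid with the
nuisance parameters either frozen at their least-squares estimates
(default) or re-minimised per grid point ("profiled"; since every law here
is linear in C0 and C∞ once k is fixed, profiling is a tiny exact linear
solve). Profiled regions always contain fixed-nuisance ones.

Contours are extracted by marching squares and compared or intersected as
polygons — these regions are elongated and tilted by the strong kref–Ea
anti-correlation, so bounding boxes would badly overstate overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from shapely.geometry import Polygon
from skimage import measure

from .data_io import StudyTable
from .fitting import FitResult
from .kinetics import KELVIN_OFFSET, R_GAS

__all__ = [
    "JCRSpec",
    "JCRRegion",
    "jcr_threshold",
    "jcr_region",
    "regions_overlap",
]


@dataclass(frozen=True)
class JCRSpec:
    """Construction settings for a joint confidence region.

    ``phi`` is the confidence complement (0.10 → a 90 % region).
    Grid bounds default to the estimate ± ``n_se`` linearised standard
    errors and are widened automatically if the contour is clipped.
    """

    phi: float = 0.10
    grid_size: int = 81
    n_se: float = 6.0
    nuisance_mode: str = "fixed_at_optimum"
    max_expansions: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.phi < 1:
            raise ValueError("phi must be in (0, 1)")
        if self.grid_size < 25:
            raise ValueError("grid resolution must be at least 25 per axis")
        if self.nuisance_mode not in ("fixed_at_optimum", "profiled"):
            raise ValueError(f"unknown nuisance_mode {self.nuisance_mode!r}")


@dataclass
class JCRRegion:
    """A joint confidence region: threshold, grid mask and contour polygons."""

    threshold: float
    ssq_min: float
    p: int
    m: int
    phi: float
    kref_grid: np.ndarray
    ea_grid: np.ndarray
    inside: np.ndarray  # boolean mask, shape (len(kref_grid), len(ea_grid))
    contours: list[np.ndarray]  # each (N, 2): columns (kref, Ea)
    estimate: tuple[float, float]
    units: str
    clipped: bool = False

    def contains(self, kref: float, ea: float) -> bool:
        """Point-in-region test against the contour polygons."""
        from shapely.geometry import Point

        pt = Point(kref, ea)
        return any(Polygon(c).buffer(0).covers(pt) for c in self.contours if len(c) >= 3)


def jcr_threshold(ssq_min: float, p: int, m: int, phi: float) -> float:
    """SSQ cutoff of the 1−φ joint confidence region.

    ``ssq_min · [1 + p/(m−p) · F(p, m−p; 1−φ)]`` with F the upper 1−φ
    quantile of the F distribution.
    """
    if p < 1 or m <= p:
        raise ValueError(f"need m > p >= 1, got m={m}, p={p}")
    if not 0 < phi < 1:
        raise ValueError("phi must be in (0, 1)")
    fq = stats.f.ppf(1.0 - phi, p, m - p)
    return float(ssq_min * (1.0 + p / (m - p) * fq))


def _ssq_surface(fit: FitResult, data: StudyTable, nuisance_mode: str):
    """Return ssq(kref_array, ea_scalar) evaluated column-wise on data."""
    t, x, y = data.arrays()
    tref_k = fit.estimates.Tref + KELVIN_OFFSET
    a = 1.0 / tref_k - 1.0 / (t + KELVIN_OFFSET)  # per-observation Arrhenius term
    order = fit.model.order
    c0_hat = fit.estimates.C0
    cinf_hat = fit.estimates.Cinf

    def ssq_fn(kref: float, ea: float) -> float:
        k = kref * np.exp((ea * 1e3 / R_GAS) * a)
        if order == "zero":
            if nuisance_mode == "profiled":
                c0 = float(np.mean(y + k * x))
            else:
                c0 = c0_hat
            r = (c0 - k * x) - y
        elif order == "first":
            e = np.exp(-k * x)
            if nuisance_mode == "profiled":
                c0 = float((e @ y) / (e @ e))
            else:
                c0 = c0_hat
            r = c0 * e - y
        else:
            e = np.exp(-k * x)
            if nuisance_mode == "profiled":
                basis = np.column_stack([e, 1.0 - e])  # C(x) = C0·e + C∞·(1−e)
                coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
                c0, cinf = float(coef[0]), float(coef[1])
            else:
                c0, cinf = c0_hat, cinf_hat
            r = cinf + (c0 - cinf) * e - y
        return float(r @ r)

    return ssq_fn


def _extract_region(
    ssq_fn,
    estimate: tuple[float, float],
    kref_bounds: tuple[float, float],
    ea_bounds: tuple[float, float],
    threshold: float,
    grid_size: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[np.ndarray], bool]:
    """Evaluate the SSQ grid and march the threshold contour."""
    kref_grid = np.linspace(*kref_bounds, grid_size)
    ea_grid = np.linspace(*ea_bounds, grid_size)
    ssq = np.empty((grid_size, grid_size))
    for i, kv in enumerate(kref_grid):
        for j, ev in enumerate(ea_grid):
            ssq[i, j] = ssq_fn(kv, ev)
    inside = ssq <= threshold
    raw = measure.find_contours(ssq, threshold)
    dk = kref_grid[1] - kref_grid[0]
    de = ea_grid[1] - ea_grid[0]
    contours = []
    clipped = False
    for c in raw:
        pts = np.column_stack([kref_grid[0] + c[:, 0] * dk, ea_grid[0] + c[:, 1] * de])
        if not np.allclose(pts[0], pts[-1]):
            clipped = True  # contour leaves the grid: bounds too tight
        contours.append(pts)
    # Region touching the border without any contour found also means clipping.
    if inside[0, :].any() or inside[-1, :].any() or inside[:, 0].any() or inside[:, -1].any():
        clipped = True
    return kref_grid, ea_grid, ssq, inside, contours, clipped


def jcr_region(fit: FitResult, data: StudyTable, spec: JCRSpec | None = None) -> JCRRegion:
    """Construct the joint confidence region of a converged one-step fit.

    The SSQ surface is evaluated on a (kref, Ea) grid with nuisance handling
    per ``spec.nuisance_mode``; bounds start at ±``n_se`` linearised SEs and
    expand (up to ``max_expansions`` times) until the contour closes.
    """
    spec = spec or JCRSpec()
    if not fit.converged:
        raise ValueError("fit did not converge; no region defined")
    kref_hat, ea_hat = fit.estimates.kref, fit.estimates.Ea
    se_k = fit.standard_errors.get("kref", 0.0) or 0.1 * max(kref_hat, 1e-12)
    se_e = fit.standard_errors.get("Ea", 0.0) or 1.0
    threshold = jcr_threshold(fit.ssq, fit.p, fit.m, spec.phi)
    ssq_fn = _ssq_surface(fit, data, spec.nuisance_mode)

    n_se = spec.n_se
    for _ in range(spec.max_expansions + 1):
        k_lo = max(kref_hat - n_se * se_k, 0.0)
        k_hi = kref_hat + n_se * se_k
        e_lo = max(ea_hat - n_se * se_e, 0.0)
        e_hi = ea_hat + n_se * se_e
        if not (k_lo <= kref_hat <= k_hi and e_lo <= ea_hat <= e_hi):
            raise ValueError("estimate outside grid bounds; widen kref/Ea bounds")
        kg, eg, ssq, inside, contours, clipped = _extract_region(
            ssq_fn, (kref_hat, ea_hat), (k_lo, k_hi), (e_lo, e_hi), threshold, spec.grid_size
        )
        if not clipped and contours:
            break
        n_se *= 1.8
    return JCRRegion(
        threshold=threshold,
        ssq_min=fit.ssq,
        p=fit.p,
        m=fit.m,
        phi=spec.phi,
        kref_grid=kg,
        ea_grid=eg,
        inside=inside,
        contours=contours,
        estimate=(kref_hat, ea_hat),
        units=fit.model.k_unit,
        clipped=clipped,
    )


def ssq_at(
    fit: FitResult,
    data: StudyTable,
    kref: float,
    ea: float,
    nuisance_mode: str = "fixed_at_optimum",
) -> float:
    """SSQ at one (kref, Ea) point with the region's nuisance handling.

    ``ssq_at(...) <= jcr_threshold(...)`` is exactly the membership test the
    region mask encodes; exposed for coverage studies that need membership
    of a single point without building the whole grid.
    """
    return _ssq_surface(fit, data, nuisance_mode)(kref, ea)


def regions_overlap(a: JCRRegion, b: JCRRegion) -> bool:
    """True iff the two regions' contour polygons intersect or nest.

    Regions must live on commensurable axes (same rate-constant units);
    comparing a per-day region with a per-Mlux·h region is an error.
    """
    if a.units != b.units:
        raise ValueError(f"incommensurable rate units: {a.units!r} vs {b.units!r}")
    pa = [Polygon(c).buffer(0) for c in a.contours if len(c) >= 3]
    pb = [Polygon(c).buffer(0) for c in b.contours if len(c) >= 3]
    if not pa or not pb:
        raise ValueError("a region has no closed contour; expand its grid")
    return any(x.intersects(y) for x in pa for y in pb)
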