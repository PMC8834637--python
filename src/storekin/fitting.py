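"""One-step (global) nonlinear least squares across temperatures.

All isothermal datasets of a group are fitted simultaneously: the rate
constant in the degradation law is replaced by its Arrhenius expression, so
(kref, Ea) — plus a single shared C0 and, for fractional conversion, a
single shared C∞ — are estimated directly from every observation at once.
This avoids the error propagation of the classical two-step route
(per-temperature k's, then ln k vs 1/T).

Estimation uses bounded trust-region least squares with a deterministic
multi-start over log-spaced rate and activation-energy guesses; standard
errors come from the linearised covariance MSE·(JᵀJ)⁻¹ at the optimum, and
per-temperature rates carry delta-method standard errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .data_io import StudyTable
from .kinetics import KELVIN_OFFSET, R_GAS, ModelSpec, ParamSet, arrhenius_k

__all__ = [
    "FitConfig",
    "FitResult",
    "ModelComparison",
    "FitError",
    "fit_one_step",
    "fit_statistics",
    "select_model",
    "two_step_diagnostic",
]

#: Default jitter seed for multi-start initial guesses.
DEFAULT_SEED = 20220207


class FitError(RuntimeError):
    """Fit could not be completed; carries diagnostics where available."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class FitConfig:
    """Optimiser settings for the one-step regression."""

    tref: float = 25.0
    n_starts: int = 8
    seed: int = DEFAULT_SEED
    ftol: float = 1e-10
    xtol: float = 1e-10
    gtol: float = 1e-12
    max_nfev: int = 10_000
    ea_bounds: tuple[float, float] = (0.0, 300.0)
    average_replicates: bool = False


@dataclass
class FitResult:
    """One-step regression output for a single group and candidate law."""

    model: ModelSpec
    estimates: ParamSet
    standard_errors: dict[str, float]
    covariance: np.ndarray
    param_names: tuple[str, ...]
    k_by_temperature: dict[float, tuple[float, float]]  # T -> (k, SE)
    ssq: float
    see: float
    r2adj: float
    runs_p: float
    residuals: np.ndarray
    m: int
    p: int
    converged: bool
    n_iterations: int
    start_costs: tuple[float, ...] = ()
    negative_prediction_warning: bool = False

    @property
    def aic_like(self) -> float:
        # Gaussian log-likelihood up to constants; for diagnostics only.
        return self.m * math.log(self.ssq / self.m) + 2 * self.p


@dataclass
class ModelComparison:
    """Candidate fits for one group with the selection outcome."""

    candidates: list[FitResult]
    criteria: list[dict]
    selected: int
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def best(self) -> FitResult:
        return self.candidates[self.selected]


def _param_names(model: ModelSpec) -> tuple[str, ...]:
    if model.order == "fractional":
        return ("C0", "Cinf", "kref", "Ea")
    return ("C0", "kref", "Ea")


def _unpack(theta: np.ndarray, model: ModelSpec, tref: float) -> tuple:
    if model.order == "fractional":
        c0, cinf, kref, ea = theta
    else:
        c0, kref, ea = theta
        cinf = None
    return c0, cinf, kref, ea, tref


def _predict_theta(theta, model, tref, inv_t_term, x):
    """Model predictions without ParamSet validation (optimiser hot path)."""
    c0, cinf, kref, ea, _ = _unpack(theta, model, tref)
    k = kref * np.exp((ea * 1e3 / R_GAS) * inv_t_term)
    if model.order == "zero":
        return c0 - k * x
    if model.order == "first":
        return c0 * np.exp(-k * x)
    return cinf + (c0 - cinf) * np.exp(-k * x)


def _starts(model, t, x, y, cfg: FitConfig) -> list[np.ndarray]:
    """Deterministic multi-start grid with seeded multiplicative jitter."""
    baseline = y[x == x.min()]
    c0_0 = float(np.mean(baseline)) if baseline.size else float(np.max(y))
    c0_0 = max(c0_0, 1e-8)
    span = float(np.max(x)) if np.max(x) > 0 else 1.0
    decline = max(c0_0 - float(np.min(y)), 1e-3 * c0_0)
    if model.order == "zero":
        k_scale = decline / span
    else:
        floor = max(float(np.min(y)), 0.02 * c0_0)
        k_scale = max(-math.log(floor / c0_0), 1e-3) / span
    cinf_0 = 0.8 * max(float(np.min(y)), 1e-8)
    rng = np.random.default_rng(cfg.seed)
    ea_grid = [5.0, 15.0, 30.0, 60.0]
    k_mult = [0.5, 2.0]
    combos = [(ea, km) for ea in ea_grid for km in k_mult]
    starts = []
    for i in range(cfg.n_starts):
        ea0, km = combos[i % len(combos)]
        jitter = float(np.exp(rng.normal(0.0, 0.05)))
        kref0 = k_scale * km * jitter
        if model.order == "fractional":
            starts.append(np.array([c0_0, cinf_0, kref0, ea0]))
        else:
            starts.append(np.array([c0_0, kref0, ea0]))
    return starts


def _bounds(model, cfg: FitConfig, c0_hint: float):
    lo_ea, hi_ea = cfg.ea_bounds
    if model.order == "fractional":
        lower = [1e-10, 0.0, 0.0, lo_ea]
        upper = [np.inf, np.inf, np.inf, hi_ea]
    else:
        lower = [1e-10, 0.0, lo_ea]
        upper = [np.inf, np.inf, hi_ea]
    return np.array(lower), np.array(upper)


def fit_one_step(
    group: StudyTable, model: ModelSpec, config: FitConfig | None = None
) -> FitResult:
    """Fit one degradation law to all temperatures of a group at once.

    Minimises Σ [C_obs − C_model(T, x; C0, (C∞,) kref, Ea)]² over every
    observation and replicate, with k(T) given by the Arrhenius relation.
    Deterministic for a given table and configuration.

    Raises
    ------
    FitError
        If m ≤ p, or no start converges.
    """
    cfg = config or FitConfig()
    if model.axis != group.axis:
        raise ValueError(f"model axis {model.axis!r} != table axis {group.axis!r}")
    if cfg.average_replicates:
        group = group.averaged_replicates()
    t, x, y = group.arrays()
    m, p = len(y), model.n_params
    if m <= p:
        raise FitError(f"m={m} observations cannot identify p={p} parameters")

    tref_k = cfg.tref + KELVIN_OFFSET
    inv_t_term = 1.0 / tref_k - 1.0 / (t + KELVIN_OFFSET)

    def resid(theta):
        return _predict_theta(theta, model, cfg.tref, inv_t_term, x) - y

    lower, upper = _bounds(model, cfg, float(np.max(y)))
    best = None
    start_costs = []
    for theta0 in _starts(model, t, x, y, cfg):
        theta0 = np.clip(theta0, lower + 1e-12, None)
        x_scale = np.maximum(np.abs(theta0), 1e-8)
        try:
            sol = optimize.least_squares(
                resid,
                theta0,
                bounds=(lower, upper),
                method="trf",
                x_scale=x_scale,
                ftol=cfg.ftol,
                xtol=cfg.xtol,
                gtol=cfg.gtol,
                max_nfev=cfg.max_nfev,
            )
        except Exception:  # singular start etc.: try the next one
            continue
        start_costs.append(2 * sol.cost)
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("all optimiser starts failed")
    if best.status <= 0:
        raise FitError("optimiser did not converge from any start", best=best)

    theta = best.x
    ssq = float(2 * best.cost)
    residuals = best.fun.copy()

    # Linearised covariance at the optimum; pinv guards rank deficiency
    # (e.g. kref at 0 makes the Ea column vanish).
    jac = best.jac
    dof = m - p
    mse = ssq / dof
    cov = mse * np.linalg.pinv(jac.T @ jac)
    ses = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    names = _param_names(model)

    c0, cinf, kref, ea, _ = _unpack(theta, model, cfg.tref)
    if model.order == "fractional" and cinf >= c0:
        # Plateau estimate collided with C0: degenerate (flat) solution.
        cinf = min(cinf, c0 * (1 - 1e-12))
    params = ParamSet(C0=c0, kref=kref, Ea=ea, Cinf=cinf, Tref=cfg.tref)

    i_k, i_e = names.index("kref"), names.index("Ea")
    k_by_t: dict[float, tuple[float, float]] = {}
    for temp in sorted(set(t.tolist())):
        k_t = arrhenius_k(params, temp)
        a = inv_t_term[t == temp][0]  # 1/Tref_K - 1/T_K
        grad = np.zeros(p)
        grad[i_k] = k_t / kref if kref > 0 else 0.0
        grad[i_e] = k_t * (1e3 / R_GAS) * a
        k_by_t[float(temp)] = (float(k_t), float(np.sqrt(grad @ cov @ grad)))

    try:
        r2adj, see, runs_p = fit_statistics(residuals, y, p, temperature=t, exposure=x)
    except ValueError:
        # Constant observations: r²adj is undefined but the fit itself
        # (k ≈ 0) is legitimate; report NaN rather than failing.
        r2adj, see, runs_p = float("nan"), math.sqrt(ssq / dof), 1.0

    neg = bool(np.any(_predict_theta(theta, model, cfg.tref, inv_t_term, x) < 0))
    return FitResult(
        model=model,
        estimates=params,
        standard_errors=dict(zip(names, ses.tolist())),
        covariance=cov,
        param_names=names,
        k_by_temperature=k_by_t,
        ssq=ssq,
        see=see,
        r2adj=r2adj,
        runs_p=runs_p,
        residuals=residuals,
        m=m,
        p=p,
        converged=True,
        n_iterations=int(best.nfev),
        start_costs=tuple(start_costs),
        negative_prediction_warning=neg,
    )


def _runs_test_p(signs: np.ndarray) -> float:
    """Two-sided Wald–Wolfowitz runs test on a ±1 sequence (normal approx.)."""
    signs = signs[signs != 0]
    n1 = int(np.sum(signs > 0))
    n2 = int(np.sum(signs < 0))
    n = n1 + n2
    if n1 == 0 or n2 == 0 or n < 2:
        return 1.0
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    mu = 2.0 * n1 * n2 / n + 1.0
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n**2 * (n - 1.0))
    if var <= 0:
        return 1.0
    z = (runs - mu) / math.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


def fit_statistics(
    residuals: np.ndarray,
    observations: np.ndarray,
    p: int,
    temperature: np.ndarray | None = None,
    exposure: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """(r²adj, SEE, runs-test p) for a fitted group.

    r²adj is a global statistic: total sum of squares about the grand mean
    of all the group's observations (one value per multi-temperature fit).
    SEE = sqrt(SSQ/(m−p)). The runs test is applied to residual signs
    ordered by exposure within temperature — a numerical stand-in for
    visual inspection of the residual plot.
    """
    residuals = np.asarray(residuals, float)
    observations = np.asarray(observations, float)
    m = len(observations)
    if m <= p:
        raise ValueError("need m > p")
    ssq = float(residuals @ residuals)
    ss_tot = float(np.sum((observations - observations.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("total sum of squares is zero: constant observations")
    see = math.sqrt(ssq / (m - p))
    r2adj = 1.0 - (ssq / (m - p)) / (ss_tot / (m - 1))
    if temperature is not None and exposure is not None:
        order = np.lexsort((np.asarray(exposure), np.asarray(temperature)))
        runs_p = _runs_test_p(np.sign(residuals[order]))
    else:
        runs_p = _runs_test_p(np.sign(residuals))
    return r2adj, see, runs_p


def select_model(
    group: StudyTable,
    candidates: list[ModelSpec] | None = None,
    config: FitConfig | None = None,
    see_margin: float = 0.05,
) -> ModelComparison:
    """Fit candidate laws and pick one.

    Ranking is by SEE (ascending), ties broken toward fewer parameters.
    The fractional-conversion law displaces a simpler converged law only if
    it improves SEE by at least ``see_margin`` (relative) AND its plateau
    estimate C∞ exceeds twice its standard error — otherwise the plateau is
    not supported by the data and the simpler law is kept.
    """
    cfg = config or FitConfig()
    if candidates is None:
        candidates = [ModelSpec(order=o, axis=group.axis) for o in ("zero", "first", "fractional")]
    fits: list[FitResult] = []
    failures: dict[str, str] = {}
    for spec in candidates:
        try:
            fits.append(fit_one_step(group, spec, cfg))
        except Exception as exc:
            failures[spec.order] = str(exc)
    if not fits:
        raise FitError(f"no candidate model converged: {failures}")

    # Candidates arrive simplest-first; demand strict SEE improvement to
    # displace a simpler law. SEEs far below the data scale are numerically
    # perfect fits whose differences are optimiser noise, so they are
    # clamped to a common floor and resolve as ties (toward parsimony).
    _, _, y = group.arrays()
    see_floor = 1e-6 * float(np.sqrt(np.mean(y**2)))
    eff = [max(f.see, see_floor) for f in fits]
    tie_eps = 1e-9
    best_i = 0
    for i in range(1, len(fits)):
        if eff[i] < eff[best_i] * (1 - tie_eps):
            best_i = i

    chosen = fits[best_i]
    if chosen.model.order == "fractional":
        simpler = [f for f in fits if f.model.order != "fractional"]
        if simpler:
            alt = min(simpler, key=lambda f: f.see)
            cinf = chosen.estimates.Cinf or 0.0
            se_cinf = chosen.standard_errors.get("Cinf", np.inf)
            improves = max(chosen.see, see_floor) <= max(alt.see, see_floor) * (1 - see_margin)
            supported = cinf > 2 * se_cinf
            if not (improves and supported):
                best_i = fits.index(alt)

    criteria = [
        dict(order=f.model.order, see=f.see, r2adj=f.r2adj, runs_p=f.runs_p, ssq=f.ssq)
        for f in fits
    ]
    return ModelComparison(candidates=fits, criteria=criteria, selected=best_i, failures=failures)


def two_step_diagnostic(
    group: StudyTable, model: ModelSpec, config: FitConfig | None = None
) -> dict:
    """Classical two-step estimate for comparison with the one-step fit.

    Step 1 fits (C0, k) — and C∞ for fractional conversion — separately at
    each temperature; step 2 regresses ln k on 1/T_K to recover Ea and kref
    at Tref. Reported as a diagnostic only; the one-step fit is the
    estimator of record.
    """
    cfg = config or FitConfig()
    t, x, y = group.arrays()
    ks, inv_t = [], []
    for temp in sorted(set(t.tolist())):
        sel = t == temp
        xs, ys = x[sel], y[sel]
        c0_0 = float(np.mean(ys[xs == xs.min()]))
        if model.order == "zero":
            fun = lambda th: (th[0] - th[1] * xs) - ys
            th0 = [c0_0, max((c0_0 - ys.min()) / max(xs.max(), 1e-9), 1e-6)]
            lb, ub = [1e-10, 0.0], [np.inf, np.inf]
        elif model.order == "first":
            fun = lambda th: th[0] * np.exp(-th[1] * xs) - ys
            th0 = [c0_0, 1e-2]
            lb, ub = [1e-10, 0.0], [np.inf, np.inf]
        else:
            fun = lambda th: (th[2] + (th[0] - th[2]) * np.exp(-th[1] * xs)) - ys
            th0 = [c0_0, 1e-1, 0.5 * c0_0]
            lb, ub = [1e-10, 0.0, 0.0], [np.inf, np.inf, np.inf]
        sol = optimize.least_squares(fun, th0, bounds=(lb, ub), xtol=1e-12, ftol=1e-12)
        if sol.x[1] > 0:
            ks.append(sol.x[1])
            inv_t.append(1.0 / (temp + KELVIN_OFFSET))
    if len(ks) < 2:
        raise FitError("two-step diagnostic needs >=2 positive per-temperature rates")
    slope, intercept, r, _, _ = stats.linregress(inv_t, np.log(ks))
    ea_kj = -slope * R_GAS / 1e3
    kref = float(np.exp(intercept + slope / (cfg.tref + KELVIN_OFFSET)))
    temps_c = [1.0 / v - KELVIN_OFFSET for v in inv_t]
    return dict(
        kref=kref,
        Ea=float(ea_kj),
        r2_arrhenius=float(r**2),
        k_by_temperature={round(tc, 6): float(k) for tc, k in zip(temps_c, ks)},
    )
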