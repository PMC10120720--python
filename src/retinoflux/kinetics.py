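"""Cellular accumulation kinetics: monophasic partitioning and biphasic
uptake with a triggered secondary storage phase.

Model definitions (concentrations uM, time min):

    monophasic:  c_cell(t) = c_f * Kp * (1 - exp(-k1 t))

    biphasic:    c_cell(t) = monophasic(t)
                             + c_f * Kp_star * (1 - exp(-k1_star (t - t_lag)))
                               for t >= t_lag, else no second term,

where the lag is the time at which the primary phase crosses the
intracellular trigger threshold ``ccell_star``:

    t_lag = -ln(1 - ccell_star / (Kp c_f)) / k1.

If the primary phase never reaches the threshold (ccell_star >= Kp*c_f) the
secondary phase never triggers; :func:`lag_time` returns ``math.inf`` and the
curve stays monophasic.

Fitting is bounded nonlinear least squares with seeded random multistarts;
all replicate observations enter the objective individually and parameters
are shared across curves by default (the c_f-dependence of t_lag is what
differentiates concentrations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "Timecourse",
    "KineticParams",
    "FitResult",
    "ModelComparison",
    "predict_monophasic",
    "lag_time",
    "predict_biphasic",
    "fit_accumulation",
    "compare_models",
    "free_contribution_fraction",
]

# optimizer bounds: partition coefficients, rate constants (1/min), threshold
KP_BOUNDS = (0.0, 1e4)
K_BOUNDS = (1e-5, 1.0)


@dataclass(frozen=True)
class KineticParams:
    """Parameters of the accumulation models.

    The monophasic model is the restriction ``kp_star == 0``.
    """

    kp: float  # uM cell per uM fluid
    k1: float  # 1/min
    kp_star: float = 0.0
    k1_star: float = 0.0
    ccell_star: float = 0.0  # uM, secondary-phase trigger threshold

    def __post_init__(self) -> None:
        for name in ("kp", "k1", "kp_star", "k1_star", "ccell_star"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def is_monophasic(self) -> bool:
        return self.kp_star == 0.0


@dataclass
class Timecourse:
    """One accumulation time course at a fixed bulk fluid concentration.

    ``ccell`` may be 1-D (single replicate) or 2-D with shape
    ``(n_times, n_replicates)``.
    """

    cf: float  # bulk fluid concentration, uM, assumed constant
    times: np.ndarray  # minutes, strictly increasing
    ccell: np.ndarray  # accumulated cellular concentration, uM
    label: str = "free"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ccell = np.asarray(self.ccell, dtype=float)
        if not self.cf > 0:
            raise ValueError("cf must be > 0")
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be 1-D and strictly increasing")
        if np.any(self.times < 0):
            raise ValueError("times must be >= 0")
        if self.ccell.ndim == 1:
            self.ccell = self.ccell[:, None]
        if self.ccell.shape[0] != self.times.size:
            raise ValueError("ccell first axis must match times")
        if np.any(self.ccell < 0):
            raise ValueError("ccell must be >= 0")

    @property
    def n_replicates(self) -> int:
        return self.ccell.shape[1]

    def mean(self) -> np.ndarray:
        return self.ccell.mean(axis=1)


@dataclass
class FitResult:
    params: KineticParams
    sse: float
    n_obs: int
    n_params: int
    stderr: dict = field(default_factory=dict)
    converged: bool = True
    model: str = "monophasic"
    weighting: str = "none"
    multistart_log: list = field(default_factory=list)
    seed: int | None = None

    @property
    def aic(self) -> float:
        # least-squares AIC up to an additive constant shared by nested fits
        n = self.n_obs
        return n * math.log(self.sse / n) + 2 * self.n_params


@dataclass(frozen=True)
class ModelComparison:
    f_statistic: float
    p_value: float
    delta_aic: float  # AIC(biphasic) - AIC(monophasic); negative favours biphasic
    preferred: str
    alpha: float = 0.05


def predict_monophasic(params: KineticParams, cf: float, t):
    """c_f * Kp * (1 - exp(-k1 t)); vectorised over ``t``."""
    t = np.asarray(t, dtype=float)
    out = cf * params.kp * -np.expm1(-params.k1 * t)
    return out if out.ndim else float(out)


def lag_time(params: KineticParams, cf: float) -> float:
    """Time for the primary phase to cross ``ccell_star``; ``inf`` if never."""
    if not (params.kp > 0 and params.k1 > 0):
        raise ValueError("lag_time requires kp > 0 and k1 > 0")
    if params.ccell_star == 0.0:
        return 0.0
    plateau = params.kp * cf
    if params.ccell_star >= plateau:
        return math.inf
    return -math.log1p(-params.ccell_star / plateau) / params.k1


def predict_biphasic(params: KineticParams, cf: float, t):
    """Biphasic prediction; continuous at the trigger, monophasic before it."""
    t = np.asarray(t, dtype=float)
    primary = cf * params.kp * -np.expm1(-params.k1 * t)
    if params.kp_star == 0.0:
        return primary if primary.ndim else float(primary)
    tlag = lag_time(params, cf)
    if math.isinf(tlag):
        return primary if primary.ndim else float(primary)
    dt = t - tlag
    secondary = np.where(dt >= 0, cf * params.kp_star * -np.expm1(-params.k1_star * np.maximum(dt, 0.0)), 0.0)
    out = primary + secondary
    return out if out.ndim else float(out)


def _predict(model: str, params: KineticParams, cf: float, t):
    if model == "monophasic":
        return predict_monophasic(params, cf, t)
    return predict_biphasic(params, cf, t)


def _unpack(model: str, x: np.ndarray) -> KineticParams:
    if model == "monophasic":
        return KineticParams(kp=x[0], k1=x[1])
    return KineticParams(kp=x[0], k1=x[1], kp_star=x[2], k1_star=x[3], ccell_star=x[4])


def _heuristic_start(model: str, timecourses: list[Timecourse]) -> np.ndarray:
    # plateau of the normalised curves and a half-rise guess for the rate
    ratios = [tc.mean().max() / tc.cf for tc in timecourses]
    kp0 = min(max(np.median(ratios), 1.0), KP_BOUNDS[1] * 0.5)
    t_mid = float(np.median([tc.times[len(tc.times) // 2] for tc in timecourses]))
    k0 = min(max(math.log(2.0) / max(t_mid, 1.0), K_BOUNDS[0] * 10), K_BOUNDS[1] * 0.5)
    if model == "monophasic":
        return np.array([kp0, k0])
    cstar0 = 0.5 * min(tc.mean().max() for tc in timecourses)
    return np.array([0.7 * kp0, k0, 0.5 * kp0, 0.5 * k0, max(cstar0, 1e-3)])


def fit_accumulation(
    timecourses: list[Timecourse] | Timecourse,
    model: str = "biphasic",
    n_starts: int = 10,
    seed: int = 0,
    weighting: str = "none",
) -> FitResult:
    """Global least-squares fit of one model to one or more time courses.

    All curves share one parameter set; replicates enter the objective as
    individual observations.  ``n_starts`` seeded random multistarts guard
    against the non-smooth trigger; the best candidate by SSE is returned
    (flagged unconverged if no start succeeded).

    ``weighting="relative"`` divides each residual by the model prediction
    (floored at 1% of the largest observation), the appropriate choice under
    multiplicative noise — without it the F test is miscalibrated when
    curves spanning very different magnitudes are fit jointly.
    """
    if isinstance(timecourses, Timecourse):
        timecourses = [timecourses]
    if model not in ("monophasic", "biphasic"):
        raise ValueError(f"unknown model {model!r}")
    if weighting not in ("none", "relative"):
        raise ValueError(f"unknown weighting {weighting!r}")
    n_obs = sum(tc.times.size * tc.n_replicates for tc in timecourses)
    n_params = 2 if model == "monophasic" else 5
    if n_obs <= n_params:
        raise ValueError(f"need more than {n_params} observations, got {n_obs}")
    for tc in timecourses:
        if tc.times.size < 2:
            raise ValueError("each curve needs >= 2 distinct time points")

    cmax = max(float(tc.ccell.max()) for tc in timecourses)
    if model == "monophasic":
        lo = np.array([KP_BOUNDS[0], K_BOUNDS[0]])
        hi = np.array([KP_BOUNDS[1], K_BOUNDS[1]])
    else:
        lo = np.array([KP_BOUNDS[0], K_BOUNDS[0], KP_BOUNDS[0], K_BOUNDS[0], 0.0])
        hi = np.array([KP_BOUNDS[1], K_BOUNDS[1], KP_BOUNDS[1], K_BOUNDS[1], max(cmax, 1e-6)])

    floor = 0.01 * cmax if cmax > 0 else 1.0

    def residuals(x: np.ndarray) -> np.ndarray:
        p = _unpack(model, x)
        parts = []
        for tc in timecourses:
            pred = _predict(model, p, tc.cf, tc.times)
            res = tc.ccell - pred[:, None]
            if weighting == "relative":
                res = res / np.maximum(pred[:, None], floor)
            parts.append(res.ravel())
        return np.concatenate(parts)

    rng = np.random.default_rng(seed)
    starts = [np.clip(_heuristic_start(model, timecourses), lo + 1e-12, hi - 1e-12)]
    for _ in range(max(n_starts - 1, 0)):
        # log-uniform for rates, uniform for the rest
        x = np.empty(n_params)
        x[0] = rng.uniform(1.0, min(500.0, hi[0]))
        x[1] = 10 ** rng.uniform(-3, -0.5)
        if model == "biphasic":
            x[2] = rng.uniform(0.0, min(500.0, hi[2]))
            x[3] = 10 ** rng.uniform(-3, -0.5)
            x[4] = rng.uniform(0.0, hi[4])
        starts.append(np.clip(x, lo + 1e-12, hi - 1e-12))

    best = None
    log = []
    for x0 in starts:
        try:
            sol = optimize.least_squares(
                residuals, x0, bounds=(lo, hi), method="trf", x_scale="jac",
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception as exc:  # pragma: no cover - optimizer failure path
            log.append({"x0": x0.tolist(), "error": str(exc)})
            continue
        sse = float(2.0 * sol.cost)
        log.append({"x0": x0.tolist(), "sse": sse, "success": bool(sol.success)})
        if best is None or sse < best[0]:
            best = (sse, sol)
    if best is None:  # pragma: no cover
        raise RuntimeError("all multistarts failed")
    sse, sol = best

    # approximate standard errors from the Gauss-Newton covariance
    stderr: dict = {}
    dof = n_obs - n_params
    if dof > 0 and sse > 0:
        try:
            jtj = sol.jac.T @ sol.jac
            cov = np.linalg.pinv(jtj) * (sse / dof)
            names = (
                ("kp", "k1") if model == "monophasic"
                else ("kp", "k1", "kp_star", "k1_star", "ccell_star")
            )
            stderr = {n: float(math.sqrt(max(cov[i, i], 0.0))) for i, n in enumerate(names)}
        except np.linalg.LinAlgError:  # pragma: no cover
            pass

    return FitResult(
        params=_unpack(model, sol.x),
        sse=sse,
        n_obs=n_obs,
        n_params=n_params,
        stderr=stderr,
        converged=bool(sol.success),
        model=model,
        weighting=weighting,
        multistart_log=log,
        seed=seed,
    )


def compare_models(fit_mono: FitResult, fit_bi: FitResult, alpha: float = 0.05) -> ModelComparison:
    """Extra-sum-of-squares F test plus AIC for the nested model pair."""
    if fit_mono.model != "monophasic" or fit_bi.model != "biphasic":
        raise ValueError("expected a (monophasic, biphasic) fit pair")
    if fit_mono.n_obs != fit_bi.n_obs:
        raise ValueError("fits must be on identical data")
    if fit_mono.weighting != fit_bi.weighting:
        raise ValueError("fits must use the same residual weighting")
    n = fit_bi.n_obs
    df1 = fit_bi.n_params - fit_mono.n_params
    df2 = n - fit_bi.n_params
    if df2 <= 0:
        raise ValueError("not enough observations for the F test")
    # the biphasic model nests the monophasic one, so sse_bi <= sse_mono up
    # to optimizer tolerance; clamp tiny negatives
    num = max(fit_mono.sse - fit_bi.sse, 0.0)
    if fit_bi.sse == 0.0:
        f_stat = math.inf if num > 0 else 0.0
        p = 0.0 if num > 0 else 1.0
    else:
        f_stat = (num / df1) / (fit_bi.sse / df2)
        p = float(stats.f.sf(f_stat, df1, df2))
    return ModelComparison(
        f_statistic=f_stat,
        p_value=p,
        delta_aic=fit_bi.aic - fit_mono.aic,
        preferred="biphasic" if p < alpha else "monophasic",
        alpha=alpha,
    )


def free_contribution_fraction(
    free_tc: Timecourse, bound_tc: Timecourse, cap: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Percent of protein-sample accumulation attributable to free-ROH uptake.

    Replicate means of both curves are linearly interpolated onto the coarser
    of the two grids restricted to the overlapping time range.  Points with a
    zero denominator are emitted as NaN; values are capped at 100% unless
    ``cap=False``.

    Returns ``(times, percent)``.
    """
    t_lo = max(free_tc.times[0], bound_tc.times[0])
    t_hi = min(free_tc.times[-1], bound_tc.times[-1])
    if t_lo > t_hi:
        raise ValueError("time courses do not overlap")
    grids = sorted(
        (tc.times[(tc.times >= t_lo) & (tc.times <= t_hi)] for tc in (free_tc, bound_tc)),
        key=len,
    )
    grid = grids[0]
    num = np.interp(grid, free_tc.times, free_tc.mean())
    den = np.interp(grid, bound_tc.times, bound_tc.mean())
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(den > 0, 100.0 * num / den, np.nan)
    if cap:
        frac = np.minimum(frac, 100.0)
    return grid, frac
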