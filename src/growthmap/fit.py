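"""Grid-search estimation of growth maps and the comparison fits.

The map parameters are estimated by direct search, not regression: candidate
orbits are generated by iterating the map from each trial initial condition,
both the cumulative target and each orbit are z-standardized, and the
candidate maximizing

    R^2 = (sum Ts^2 - sum (Ts - Tp)^2) / sum Ts^2

is returned (Ts the standardized target, Tp the standardized orbit).  With
both series standardized this score equals ``2*r - 1`` with ``r`` the
Pearson correlation -- the vectorized scanner exploits that identity through
running sums so no orbit matrix is ever materialized -- but the reported
value is always recomputed from the stored series with the explicit formula.

The winning fit is mapped back to the target's scale by the affine rescaling

    F_t = u_t + (x_t - u_j) * ds_t / ds_j

(u, ds the mean and SD of target and orbit respectively), and model
comparison additionally scores first differences of F against the observed
annual rates, i.e. asks whether the *derivative mechanism*, not just the
level curve, matches the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .models import (
    CUBIC,
    LOGISTIC,
    MapParameters,
    iterate_map,
)
from .series import AnnualRateSeries, CumulativeSeries, standardize

__all__ = [
    "GridConfig",
    "FitResult",
    "LinearTrendFit",
    "ExponentialFit",
    "r_squared",
    "rescale_fitted",
    "score_candidate",
    "fit_logistic",
    "fit_cubic",
    "fit_linear_trend",
    "fit_exponential",
    "derivative_fit_r2",
]

# relative variance floor: running-sum variances of near-constant orbits are
# dominated by cancellation error and would yield spurious correlations
_VAR_GUARD = 1e-12


@dataclass(frozen=True)
class GridConfig:
    """Search configuration for the map fits.

    Logistic grid: k on [0, 4] step 0.005, x0 on (0, 0.2] step 0.0005.
    Cubic grid: a coarse box bracketing plausible restrained-growth
    coefficients (k1 near 1, k2 and k3 allowed well beyond the logistic box
    because the cubic recursion is not normalized to [0, 1]).

    Each refinement pass shrinks both steps by ``refine_shrink`` and
    re-scans ``refine_halfwidth`` fine steps either side of the incumbent
    (i.e. +/- 3 coarse cells at the default shrink of 10), clipped to the
    original ranges.
    """

    k_range: tuple[float, float] = (0.0, 4.0)
    k_step: float = 0.005
    x0_range: tuple[float, float] = (0.0, 0.2)  # open at 0: grid starts at x0_step
    x0_step: float = 0.0005

    k1_range: tuple[float, float] = (0.9, 1.3)
    k1_step: float = 0.005
    k2_range: tuple[float, float] = (0.0, 5.0)
    k2_step: float = 0.05
    k3_range: tuple[float, float] = (0.0, 60.0)
    k3_step: float = 0.5
    cubic_x0_range: tuple[float, float] = (0.0, 0.05)
    cubic_x0_step: float = 0.0005

    refinements: int = 2
    refine_shrink: float = 10.0
    refine_halfwidth: int = 30

    blowup_bound: float = 10.0
    #: which candidate sequence is compared to the target: "orbit" aligns
    #: the states [x0 .. x_{n-1}] with the window years (the convention the
    #: reference results follow), "image" aligns the map images [x1 .. x_n].
    alignment: str = "orbit"
    min_length: int = 10

    def __post_init__(self) -> None:
        if self.alignment not in ("orbit", "image"):
            raise ValueError("alignment must be 'orbit' or 'image'")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a grid-search map fit."""

    params: MapParameters
    r2: float
    years: np.ndarray
    fitted_values: np.ndarray
    fitted_derivatives: np.ndarray
    target_mean: float
    target_sd: float
    orbit_mean: float
    orbit_sd: float
    alignment: str
    search_log: dict = field(repr=False)

    def orbit_series(self) -> np.ndarray:
        """The candidate sequence that was scored (length = window length)."""
        orbit = iterate_map(self.params,
                            blowup_bound=self.search_log.get("blowup_bound"))
        return orbit[1:] if self.alignment == "image" else orbit

    def recompute_fitted(self) -> np.ndarray:
        """Step-5 rescaling re-derived from the stored parameters."""
        return rescale_fitted(self.orbit_series(), self.target_mean,
                              self.target_sd, self.orbit_mean, self.orbit_sd)


@dataclass(frozen=True)
class LinearTrendFit:
    slope: float
    intercept: float
    r2: float
    fitted_values: np.ndarray


@dataclass(frozen=True)
class ExponentialFit:
    a: float
    ln_intercept: float
    r2: float  # on the ln scale
    base: float
    fitted_values: np.ndarray  # on the natural scale


def r_squared(ts, tp) -> float:
    """Goodness of fit between a mean-zero target and a predictor.

    (sum ts^2 - sum (ts - tp)^2) / sum ts^2; may be negative for
    worse-than-mean predictors and is never clamped.
    """
    ts = np.asarray(ts, dtype=float)
    tp = np.asarray(tp, dtype=float)
    if ts.shape != tp.shape:
        raise ValueError(f"length mismatch: {ts.shape} vs {tp.shape}")
    if len(ts) < 2:
        raise ValueError("need at least 2 observations")
    if abs(ts.mean()) > 1e-8:
        raise ValueError("target series must have mean 0 (standardize it first)")
    sst = float(np.sum(ts * ts))
    sse = float(np.sum((ts - tp) ** 2))
    return (sst - sse) / sst


def rescale_fitted(orbit, target_mean: float, target_sd: float,
                   orbit_mean: float, orbit_sd: float) -> np.ndarray:
    """Affine map of an orbit into the target's mean/SD frame."""
    if orbit_sd <= 0:
        raise ValueError("orbit_sd must be positive")
    orbit = np.asarray(orbit, dtype=float)
    return target_mean + (orbit - orbit_mean) * (target_sd / orbit_sd)


def score_candidate(target: CumulativeSeries, params: MapParameters,
                    alignment: str = "orbit",
                    blowup_bound: float | None = None) -> float:
    """Step-4 R^2 of a single candidate against a cumulative target.

    Independent of the vectorized scanners; used as their oracle in tests.
    """
    n = target.n_obs
    need = n + 1 if alignment == "image" else n
    p = replace(params, n_steps=need)
    orbit = iterate_map(p, blowup_bound=blowup_bound)
    traj = orbit[1:] if alignment == "image" else orbit
    ts = standardize(target.values).z_values
    tp = standardize(traj).z_values
    return r_squared(ts, tp)


# ---------------------------------------------------------------------------
# vectorized scanners (running-sum Pearson form of the Step-4 score)

def _scan_logistic(Ts: np.ndarray, ks: np.ndarray, x0s: np.ndarray,
                   alignment: str):
    n = len(Ts)
    k = ks[:, None]
    x = np.broadcast_to(x0s[None, :], (len(ks), len(x0s))).copy()
    if alignment == "image":
        x = k * x * (1.0 - x)
    sx = np.zeros_like(x)
    sxx = np.zeros_like(x)
    stx = np.zeros_like(x)
    for t in range(n):
        sx += x
        sxx += x * x
        stx += Ts[t] * x
        if t < n - 1:
            x = k * x * (1.0 - x)
    m = sx / n
    var = sxx / n - m * m
    ok = var > _VAR_GUARD * (sxx / n + 1e-300)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = 2.0 * (stx / n) / (np.sqrt(var) * np.sqrt(np.sum(Ts * Ts) / n)) - 1.0
    r2[~ok | ~np.isfinite(r2)] = -np.inf
    i, j = np.unravel_index(np.argmax(r2), r2.shape)  # first max: smallest k, then x0
    return float(ks[i]), float(x0s[j]), float(r2[i, j]), r2.size


def _scan_cubic(Ts: np.ndarray, k1s: np.ndarray, k2s: np.ndarray,
                k3s: np.ndarray, x0s: np.ndarray, bound: float,
                alignment: str):
    n = len(Ts)
    sTs = np.sqrt(np.sum(Ts * Ts) / n)
    K2, K3, X0 = np.meshgrid(k2s, k3s, x0s, indexing="ij")
    K2, K3, X0 = K2.ravel(), K3.ravel(), X0.ravel()
    best = (-np.inf, None, None, None, None)
    n_eval = 0
    n_div = 0
    for k1 in k1s:  # ascending: ties resolve to smallest k1 first
        x = X0.copy()
        dead = np.zeros(x.shape, bool)
        if alignment == "image":
            x2 = x * x
            x = k1 * x - K2 * x2 + K3 * x2 * x
        sx = np.zeros_like(x)
        sxx = np.zeros_like(x)
        stx = np.zeros_like(x)
        for t in range(n):
            sx += x
            sxx += x * x
            stx += Ts[t] * x
            if t < n - 1:
                x2 = x * x
                x = k1 * x - K2 * x2 + K3 * x2 * x
                d = np.abs(x) > bound
                if d.any():
                    dead |= d
                    x[dead] = 0.0  # freeze divergent candidates, exclude below
        m = sx / n
        var = sxx / n - m * m
        ok = (var > _VAR_GUARD * (sxx / n + 1e-300)) & ~dead
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = 2.0 * (stx / n) / (np.sqrt(var) * sTs) - 1.0
        r2[~ok | ~np.isfinite(r2)] = -np.inf
        n_eval += r2.size
        n_div += int(dead.sum())
        j = int(np.argmax(r2))  # first max: k2, then k3, then x0 ascending
        if r2[j] > best[0]:
            best = (float(r2[j]), float(k1), float(K2[j]), float(K3[j]), float(X0[j]))
    return best, n_eval, n_div


def _grid(lo: float, hi: float, step: float) -> np.ndarray:
    return np.arange(lo, hi + step * 1e-9, step)


def _refine_axis(center: float, step: float, halfwidth: int,
                 lo: float, hi: float, open_lo: bool = False) -> np.ndarray:
    g = center + step * np.arange(-halfwidth, halfwidth + 1)
    g = g[(g >= lo) & (g <= hi)]
    if open_lo:
        g = g[g > lo]
    return g


def _validate_target(target: CumulativeSeries, config: GridConfig) -> np.ndarray:
    if target.n_obs < config.min_length:
        raise ValueError(
            f"target has {target.n_obs} observations; "
            f"need at least {config.min_length}")
    return standardize(target.values).z_values  # raises on zero variance


def fit_logistic(target: CumulativeSeries,
                 config: GridConfig | None = None) -> FitResult:
    """Exhaustive (k, x0) grid search for the logistic map, with refinement.

    Scans the full coarse grid, then re-scans progressively finer grids
    around the incumbent; the returned candidate maximizes the Step-4 R^2
    over everything evaluated, with ties broken toward smaller k, then
    smaller x0.
    """
    config = config or GridConfig()
    Ts = _validate_target(target, config)
    ks = _grid(config.k_range[0], config.k_range[1], config.k_step)
    x0s = _grid(config.x0_step, config.x0_range[1], config.x0_step)

    passes = []
    k_b, x_b, r2_b, n_eval = _scan_logistic(Ts, ks, x0s, config.alignment)
    passes.append({"k_step": config.k_step, "x0_step": config.x0_step,
                   "n_candidates": n_eval,
                   "best": {"k": k_b, "x0": x_b, "r2": r2_b}})
    dk, dx = config.k_step, config.x0_step
    for _ in range(config.refinements):
        dk /= config.refine_shrink
        dx /= config.refine_shrink
        kk = _refine_axis(k_b, dk, config.refine_halfwidth, *config.k_range)
        xx = _refine_axis(x_b, dx, config.refine_halfwidth,
                          config.x0_range[0], config.x0_range[1], open_lo=True)
        k_b, x_b, r2_b, n_e = _scan_logistic(Ts, kk, xx, config.alignment)
        n_eval += n_e
        passes.append({"k_step": dk, "x0_step": dx, "n_candidates": n_e,
                       "best": {"k": k_b, "x0": x_b, "r2": r2_b}})

    return _build_result(
        target, config,
        MapParameters(LOGISTIC, x0=x_b, k=k_b,
                      n_steps=target.n_obs + (config.alignment == "image")),
        {"family": LOGISTIC, "passes": passes, "n_candidates": n_eval,
         "n_divergent": 0, "alignment": config.alignment,
         "blowup_bound": None,
         "tie_break": "smallest k, then smallest x0"})


def fit_cubic(target: CumulativeSeries, config: GridConfig | None = None,
              quadratic_only: bool = False) -> FitResult:
    """Coarse-to-fine search for the cubic recursion.

    Divergent candidates (orbit magnitude beyond ``config.blowup_bound``)
    are discarded, never fatal.  With ``quadratic_only=True`` the search is
    restricted to the logistic sub-family (k1 = k2 = k, k3 = 0) on the
    logistic grid -- the nesting used to check that the cubic machinery
    reproduces :func:`fit_logistic` exactly.
    """
    config = config or GridConfig()
    Ts = _validate_target(target, config)

    if quadratic_only:
        ks = _grid(config.k_range[0], config.k_range[1], config.k_step)
        x0s = _grid(config.x0_step, config.x0_range[1], config.x0_step)

        def scan(kk, xx):
            best = (-np.inf, None, None, None, None)
            tot = 0
            for k in kk:
                (r2, _, k2, k3, x0), ne, _ = _scan_cubic(
                    Ts, np.array([k]), np.array([k]), np.array([0.0]), xx,
                    config.blowup_bound, config.alignment)
                tot += ne
                if r2 > best[0]:
                    best = (r2, float(k), k2, k3, x0)
            return best, tot, 0

        best, n_eval, n_div = scan(ks, x0s)
        passes = [{"best": {"k1": best[1], "x0": best[4], "r2": best[0]},
                   "n_candidates": n_eval}]
        dk, dx = config.k_step, config.x0_step
        for _ in range(config.refinements):
            dk /= config.refine_shrink
            dx /= config.refine_shrink
            kk = _refine_axis(best[1], dk, config.refine_halfwidth, *config.k_range)
            xx = _refine_axis(best[4], dx, config.refine_halfwidth,
                              config.x0_range[0], config.x0_range[1], open_lo=True)
            b, ne, _ = scan(kk, xx)
            n_eval += ne
            if b[0] >= best[0]:
                best = b
            passes.append({"best": {"k1": best[1], "x0": best[4], "r2": best[0]},
                           "n_candidates": ne})
        r2_b, k1_b, k2_b, k3_b, x_b = best
        n_div_total = 0
    else:
        k1s = _grid(config.k1_range[0], config.k1_range[1], config.k1_step)
        k2s = _grid(config.k2_range[0], config.k2_range[1], config.k2_step)
        k3s = _grid(config.k3_range[0], config.k3_range[1], config.k3_step)
        x0s = _grid(config.cubic_x0_step, config.cubic_x0_range[1],
                    config.cubic_x0_step)
        best, n_eval, n_div_total = _scan_cubic(
            Ts, k1s, k2s, k3s, x0s, config.blowup_bound, config.alignment)
        passes = [{"steps": (config.k1_step, config.k2_step,
                             config.k3_step, config.cubic_x0_step),
                   "n_candidates": n_eval, "n_divergent": n_div_total,
                   "best": dict(zip(("r2", "k1", "k2", "k3", "x0"), best))}]
        steps = np.array([config.k1_step, config.k2_step,
                          config.k3_step, config.cubic_x0_step])
        for _ in range(config.refinements):
            steps = steps / config.refine_shrink
            r2_b, k1_b, k2_b, k3_b, x_b = best
            g1 = _refine_axis(k1_b, steps[0], config.refine_halfwidth,
                              *config.k1_range)
            g2 = _refine_axis(k2_b, steps[1], config.refine_halfwidth,
                              *config.k2_range)
            g3 = _refine_axis(k3_b, steps[2], config.refine_halfwidth,
                              *config.k3_range)
            g4 = _refine_axis(x_b, steps[3], config.refine_halfwidth,
                              config.cubic_x0_range[0],
                              config.cubic_x0_range[1], open_lo=True)
            b, ne, nd = _scan_cubic(Ts, g1, g2, g3, g4,
                                    config.blowup_bound, config.alignment)
            n_eval += ne
            n_div_total += nd
            if b[0] >= best[0]:
                best = b
            passes.append({"steps": tuple(steps), "n_candidates": ne,
                           "n_divergent": nd,
                           "best": dict(zip(("r2", "k1", "k2", "k3", "x0"), b))})
        r2_b, k1_b, k2_b, k3_b, x_b = best

    if not np.isfinite(r2_b):
        raise ValueError("all cubic candidates divergent or degenerate")
    return _build_result(
        target, config,
        MapParameters(CUBIC, x0=x_b, poly_coeffs=(k1_b, k2_b, k3_b),
                      n_steps=target.n_obs + (config.alignment == "image")),
        {"family": CUBIC, "passes": passes, "n_candidates": n_eval,
         "n_divergent": n_div_total, "alignment": config.alignment,
         "blowup_bound": config.blowup_bound,
         "tie_break": "smallest k1, then k2, k3, x0"})


def _build_result(target: CumulativeSeries, config: GridConfig,
                  params: MapParameters, log: dict) -> FitResult:
    orbit = iterate_map(params, blowup_bound=log.get("blowup_bound"))
    traj = orbit[1:] if config.alignment == "image" else orbit
    tz = standardize(target.values)
    oz = standardize(traj)
    r2 = r_squared(tz.z_values, oz.z_values)
    fitted = rescale_fitted(traj, tz.mean, tz.sd, oz.mean, oz.sd)
    return FitResult(
        params=params, r2=r2, years=target.years.copy(),
        fitted_values=fitted, fitted_derivatives=np.diff(fitted),
        target_mean=tz.mean, target_sd=tz.sd,
        orbit_mean=oz.mean, orbit_sd=oz.sd,
        alignment=config.alignment, search_log=log)


def fit_linear_trend(target: CumulativeSeries) -> LinearTrendFit:
    """OLS of the cumulative level on the 0-based time index."""
    S = target.values
    n = target.n_obs
    if n < 3:
        raise ValueError("need at least 3 observations")
    t = np.arange(n, dtype=float)
    sst = float(np.sum((S - S.mean()) ** 2))
    if sst == 0.0:
        return LinearTrendFit(0.0, float(S.mean()), 0.0, np.full(n, S.mean()))
    slope, intercept = np.polyfit(t, S, 1)
    fitted = intercept + slope * t
    r2 = 1.0 - float(np.sum((S - fitted) ** 2)) / sst
    return LinearTrendFit(float(slope), float(intercept), r2, fitted)


def fit_exponential(target: CumulativeSeries) -> ExponentialFit:
    """Malthusian fit: OLS of ln(S) on the 0-based time index.

    Returns the growth constant ``a`` (slope on the ln scale), the
    ln-intercept, the R^2 on the ln scale, and the per-year base e**a.
    """
    S = target.values
    if np.any(S <= 0):
        raise ValueError("exponential fit requires strictly positive values")
    if target.n_obs < 3:
        raise ValueError("need at least 3 observations")
    t = np.arange(target.n_obs, dtype=float)
    lnS = np.log(S)
    a, c = np.polyfit(t, lnS, 1)
    pred = c + a * t
    sst = float(np.sum((lnS - lnS.mean()) ** 2))
    r2 = 1.0 - float(np.sum((lnS - pred) ** 2)) / sst if sst > 0 else 0.0
    return ExponentialFit(float(a), float(c), r2, float(np.exp(a)),
                          np.exp(pred))


def derivative_fit_r2(observed_rates: AnnualRateSeries, fitted_values,
                      years) -> float:
    """Score fitted first differences against the observed annual rates.

    The fitted derivative for year y is F(y) - F(y-1), so the first window
    year carries no fitted derivative; the observed rates are standardized
    over the compared years and the predicted derivatives are expressed in
    that same frame before applying the Step-4 formula.
    """
    fitted_values = np.asarray(fitted_values, dtype=float)
    years = np.asarray(years, dtype=int)
    if fitted_values.shape != years.shape:
        raise ValueError("fitted_values and years must align")
    if len(years) < 3:
        raise ValueError("need at least 3 fitted values")
    cmp_years = years[1:]
    obs = observed_rates.window(int(cmp_years[0]), int(cmp_years[-1]))
    if len(obs) != len(cmp_years) or np.any(obs.years != cmp_years):
        raise ValueError(
            f"observed series does not cover fitted years "
            f"{cmp_years[0]}-{cmp_years[-1]} contiguously")
    oz = standardize(obs.rates)
    pred_std = (np.diff(fitted_values) - oz.mean) / oz.sd
    return r_squared(oz.z_values, pred_std)
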