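"""Variance-component LMM for gene-environment interaction and its
parametric-bootstrap test.

The model for individual ``i`` in exposure ``j`` and family ``k`` is

    y_ijk = mu + alpha * x_j + b_k + c_k * x_j + eps_ijk

with ``b_k ~ N(0, sigma2_G)`` (family intercept), ``c_k ~ N(0,
sigma2_GxE)`` (family-specific response to exposure — the GxE term) and
``eps ~ N(0, sigma2_E)``, all independent.  ``x_j`` is the numeric
exposure code (concentration in uM, ordinal 0/1/2, or a per-cell variant
where the interaction is an effect per family x exposure combination).

Estimation is REML over the relative SDs ``theta_G = sd_G/sd_E`` and
``theta_GxE = sd_GxE/sd_E`` with the fixed effects and ``sigma2_E``
profiled out at every evaluation.  Significance of ``sigma2_GxE`` is
assessed with a parametric bootstrap: simulate from the fitted model,
refit, and take the percentile interval of the refit interaction
variances; the effect is called significant when that interval excludes
zero.

With families nested in exposures the intercept and slope variances are
separated only by the heteroscedasticity pattern across exposure levels
(the family-level variance at code ``x`` is ``sigma2_G + x^2 *
sigma2_GxE``); the fit warns when the design offers almost no leverage
for that separation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from ._reml import (
    FamilyStats,
    build_family_stats,
    criterion_and_grad,
    profiled_criterion,
)
from .types import (
    DegenerateDataError,
    FamGxeError,
    exposure_codes,
    validate_phenotypes,
)

logger = logging.getLogger(__name__)

#: multistart grid for the primary fit, on the (theta_G, theta_GxE) scale
DEFAULT_STARTS = (0.1, 1.0, 10.0)
#: a boundary candidate within this criterion slack of the interior optimum
#: is preferred, so null fits report exactly zero variance
BOUNDARY_TOL = 1e-6


@dataclass
class GxeLmmFit:
    """REML fit of the family + family-by-exposure variance model."""

    mu_hat: float
    alpha_hat: float
    se_mu: float
    se_alpha: float
    sigma2_G: float
    sigma2_GxE: float
    sigma2_E: float
    reml_loglik: float
    converged: bool
    coding: str
    n_obs: int
    n_families: int
    criterion: float = np.nan
    design: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def sd_G(self) -> float:
        return float(np.sqrt(self.sigma2_G))

    @property
    def sd_GxE(self) -> float:
        return float(np.sqrt(self.sigma2_GxE))

    @property
    def sd_E(self) -> float:
        return float(np.sqrt(self.sigma2_E))

    @property
    def theta_G(self) -> float:
        return self.sd_G / self.sd_E if self.sd_E > 0 else np.inf

    @property
    def theta_GxE(self) -> float:
        return self.sd_GxE / self.sd_E if self.sd_E > 0 else np.inf


@dataclass
class GxETestResult:
    """Parametric-bootstrap confidence interval for ``sigma2_GxE``."""

    sigma2_gxe_hat: float
    ci_low: float
    ci_high: float
    ci_level: float
    n_boot: int
    n_failed_refits: int
    significant: bool
    boot_seed: int
    replicates: np.ndarray | None = field(default=None, repr=False)


def _interaction_a(theta: np.ndarray, x2_fam: np.ndarray, coding: str) -> np.ndarray:
    """Per-family variance ratio a_k = Var(family effect at x_k)/sigma2_E."""
    tg2, ts2 = theta[0] ** 2, theta[1] ** 2
    if coding == "cell":
        # one interaction effect per family x exposure cell; nested design
        # makes the cell coincide with the family, so the ratio is additive
        return np.full_like(x2_fam, tg2 + ts2)
    return tg2 + ts2 * x2_fam


def _prepare(table: pd.DataFrame, coding: str):
    table = validate_phenotypes(table)
    y = table["value"].to_numpy(dtype=float)
    x = exposure_codes(table["exposure"], coding)
    fams = table["family_id"].to_numpy(dtype=object)
    if table["exposure"].nunique() < 2:
        raise FamGxeError("need at least 2 exposure environments")
    if len(pd.unique(fams)) < 2:
        raise FamGxeError("need at least 2 families")
    if len(y) < 3:
        raise FamGxeError("fewer observations than fixed effects")
    if np.ptp(y) <= 1e-10 * max(1.0, float(np.abs(y).max())):
        raise DegenerateDataError("constant response: residual variance "
                                  "unidentifiable")
    stats = build_family_stats(y, fams, covariates=x[:, None])
    return table, stats


def _fit_from_stats(stats: FamilyStats, coding: str,
                    starts=None, extra_start=None) -> dict:
    """Minimize the profiled criterion over (theta_G, theta_GxE) >= 0.

    Candidates: Nelder-Mead from each start (parameterized through
    ``|theta|`` so the boundary is reachable), 1-D Brent profiles along
    each axis, and the origin; the best boundary candidate wins ties
    within ``BOUNDARY_TOL`` so null components come back exactly zero.
    """
    x_fam = stats.xf[:, 1]
    x2_fam = x_fam**2
    if coding != "cell" and np.ptp(x2_fam) <= 1e-12 * max(1.0, x2_fam.max()):
        warnings.warn(
            "exposure codes give no leverage to separate the family "
            "intercept from the interaction variance (x^2 constant across "
            "families)", UserWarning, stacklevel=3,
        )

    def obj(t) -> float:
        theta = np.abs(np.asarray(t, dtype=float))
        return profiled_criterion(_interaction_a(theta, x2_fam, coding),
                                  stats)[0]

    candidates: list[tuple[float, np.ndarray, bool]] = []  # (crit, theta, boundary)
    converged = False
    start_points = [np.array([a, b], dtype=float)
                    for a in (starts or DEFAULT_STARTS)
                    for b in (starts or DEFAULT_STARTS)]
    if extra_start is not None:
        start_points.insert(0, np.asarray(extra_start, dtype=float))
    for s in start_points:
        res = minimize(obj, s, method="Nelder-Mead",
                       options={"fatol": 1e-8, "xatol": 1e-6, "maxiter": 400})
        if np.isfinite(res.fun):
            candidates.append((float(res.fun), np.abs(res.x), False))
            converged = converged or bool(res.success)

    def profile_axis(axis: int):
        def f1(t: float) -> float:
            theta = np.zeros(2)
            theta[axis] = abs(t)
            return obj(theta)
        r = minimize_scalar(f1, bounds=(0.0, 1e3), method="bounded",
                            options={"xatol": 1e-8})
        theta = np.zeros(2)
        theta[axis] = abs(float(r.x))
        return float(r.fun), theta

    for axis in (0, 1):
        c, theta = profile_axis(axis)
        if np.isfinite(c):
            candidates.append((c, theta, True))
    c0 = obj(np.zeros(2))
    if np.isfinite(c0):
        candidates.append((float(c0), np.zeros(2), True))
    if not candidates:
        raise FamGxeError(
            "GxE REML fit failed to converge from every start "
            f"(families={len(stats.families)}, N={stats.n_total})"
        )
    best = min(c for c, _, _ in candidates)
    boundary = [(c, t) for c, t, is_b in candidates if is_b
                and c <= best + BOUNDARY_TOL]
    if boundary:
        crit, theta = min(boundary, key=lambda ct: ct[0])
        # the boundary profile is at least as good within tolerance; keep
        # the exact zeros
        crit = min(crit, best)
    else:
        crit, theta, _ = min(candidates, key=lambda ct: ct[0])
    a = _interaction_a(theta, x2_fam, coding)
    c, beta, sigma2_e, xhx_inv = profiled_criterion(a, stats, need_cov=True)
    if not np.isfinite(c) or sigma2_e is None or sigma2_e <= 0:
        raise DegenerateDataError("residual variance unidentifiable "
                                  "(constant response within the design?)")
    cov_beta = sigma2_e * xhx_inv if xhx_inv is not None else np.full((2, 2), np.nan)
    return {
        "theta": theta,
        "criterion": float(crit),
        "beta": beta,
        "sigma2_e": float(sigma2_e),
        "cov_beta": cov_beta,
        "converged": converged or bool(boundary),
    }


def fit_gxe_lmm(table: pd.DataFrame, coding: str = "concentration",
                starts=None) -> GxeLmmFit:
    """Fit the three-variance-component interaction LMM by REML.

    ``coding`` selects the numeric exposure code for the fixed slope and
    the random family slope: ``concentration`` (uM), ``ordinal`` (0/1/2)
    or ``cell`` (interaction effect per family x exposure cell).  The
    returned fit carries the design (family sizes, exposure codes) so the
    parametric bootstrap can resimulate from it.
    """
    table, stats = _prepare(table, coding)
    sol = _fit_from_stats(stats, coding, starts=starts)
    theta = sol["theta"]
    sigma2_e = sol["sigma2_e"]
    design = pd.DataFrame({
        "family_id": stats.families,
        "n": stats.n.astype(int),
        "x": stats.xf[:, 1],
    })
    fit = GxeLmmFit(
        mu_hat=float(sol["beta"][0]),
        alpha_hat=float(sol["beta"][1]),
        se_mu=float(np.sqrt(sol["cov_beta"][0, 0])),
        se_alpha=float(np.sqrt(sol["cov_beta"][1, 1])),
        sigma2_G=float(theta[0] ** 2 * sigma2_e),
        sigma2_GxE=float(theta[1] ** 2 * sigma2_e),
        sigma2_E=sigma2_e,
        reml_loglik=-0.5 * sol["criterion"],
        converged=sol["converged"],
        coding=coding,
        n_obs=stats.n_total,
        n_families=len(stats.families),
        criterion=sol["criterion"],
        design=design,
    )
    if not fit.converged:
        raise FamGxeError(
            "GxE REML fit did not converge from any start; criterion="
            f"{sol['criterion']:.6g}, theta={theta}"
        )
    return fit


def reml_criterion(table: pd.DataFrame, theta_g: float, theta_gxe: float,
                   coding: str = "concentration") -> float:
    """Profiled REML criterion (-2 log-lik up to a constant) at given
    relative SDs; exposed for grid checks and model comparison."""
    _, stats = _prepare(table, coding)
    x2 = stats.xf[:, 1] ** 2
    return profiled_criterion(
        _interaction_a(np.array([theta_g, theta_gxe]), x2, coding), stats
    )[0]


def summarize_fit(fit: GxeLmmFit) -> dict[str, pd.DataFrame]:
    """Summary tables of a fit: variances with their SDs, relative-SD
    parameter estimates (each random-effect SD over the residual SD, with
    the residual row reporting the residual SD itself), and fixed effects.
    """
    variances = pd.DataFrame({
        "group": ["family", "family_x_exposure", "residual"],
        "variance": [fit.sigma2_G, fit.sigma2_GxE, fit.sigma2_E],
        "sd": [fit.sd_G, fit.sd_GxE, fit.sd_E],
    })
    relative = pd.DataFrame({
        "group": ["family", "family_x_exposure", "residual"],
        "estimate": [fit.theta_G, fit.theta_GxE, fit.sd_E],
    })
    fixed = pd.DataFrame({
        "term": ["intercept", "exposure"],
        "estimate": [fit.mu_hat, fit.alpha_hat],
        "se": [fit.se_mu, fit.se_alpha],
    })
    return {"variances": variances, "relative": relative, "fixed": fixed}


def simulate_from_fit(fit: GxeLmmFit, design: pd.DataFrame | None = None,
                      seed: int | None = None,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw a phenotype table from the fitted model (parametric resample).

    Fresh family intercepts, family slopes and residuals at the fitted
    variances, on the original design (family layout, group sizes,
    exposure codes).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if design is None:
        design = fit.design
    if design is None:
        raise FamGxeError("no design attached to fit; pass one explicitly")
    n = design["n"].to_numpy(dtype=int)
    x_fam = design["x"].to_numpy(dtype=float)
    K = len(design)
    b = rng.normal(0.0, np.sqrt(fit.sigma2_G), size=K)
    c = rng.normal(0.0, np.sqrt(fit.sigma2_GxE), size=K)
    fam_idx = np.repeat(np.arange(K), n)
    x = x_fam[fam_idx]
    if fit.coding == "cell":
        fam_effect = b[fam_idx] + c[fam_idx]
    else:
        fam_effect = b[fam_idx] + c[fam_idx] * x
    y = (fit.mu_hat + fit.alpha_hat * x + fam_effect
         + rng.normal(0.0, np.sqrt(fit.sigma2_E), size=len(x)))
    fam_ids = np.asarray(design["family_id"], dtype=object)[fam_idx]
    return pd.DataFrame({
        "individual_id": [f"sim_{i}" for i in range(len(y))],
        "family_id": fam_ids,
        "exposure_code": x,
        "value": y,
    })


def _fit_fast(stats: FamilyStats, coding: str, starts_gs) -> tuple[float, float, float]:
    """Bounded quasi-Newton fit on the variance-ratio scale.

    Minimizes the profiled criterion over ``(g, s) = (theta_G^2,
    theta_GxE^2)`` with the analytic gradient and box bounds at zero;
    L-BFGS-B lands exactly on the boundary for null components, which the
    CI-excludes-zero rule relies on.  Used for bootstrap refits, where
    the full multistart would dominate runtime; a boundary candidate
    within ``BOUNDARY_TOL`` of the optimum is still preferred.
    Returns ``(sigma2_G, sigma2_GxE, sigma2_E)``.
    """
    x2 = stats.xf[:, 1] ** 2
    K = len(stats.n)
    ones = np.ones(K)
    m = ones if coding == "cell" else x2
    da = np.vstack([ones, m])

    def fg(p):
        c, grad = criterion_and_grad(p[0] + p[1] * m, da, stats)
        if not np.isfinite(c):
            return 1e300, np.zeros(2)
        return c, grad

    best = None
    for s0 in starts_gs:
        res = minimize(fg, np.asarray(s0, dtype=float), jac=True,
                       method="L-BFGS-B", bounds=[(0.0, None), (0.0, None)],
                       options={"ftol": 1e-12, "gtol": 1e-9, "maxiter": 200})
        if np.isfinite(res.fun) and res.fun < 1e299 and (
                best is None or res.fun < best[0]):
            best = (float(res.fun), np.maximum(res.x, 0.0))
    if best is None:
        raise FamGxeError("bootstrap refit failed to converge")
    crit, gs = best
    # prefer exact-zero boundary solutions when they are as good
    for cand in ((gs[0], 0.0), (0.0, gs[1]), (0.0, 0.0)):
        if cand[0] == gs[0] and cand[1] == gs[1]:
            continue
        c = profiled_criterion(cand[0] + cand[1] * m, stats)[0]
        if c <= crit + BOUNDARY_TOL:
            gs = np.asarray(cand)
            crit = min(crit, c)
    _, _, sigma2_e, _ = profiled_criterion(gs[0] + gs[1] * m, stats)
    if sigma2_e is None or sigma2_e <= 0:
        raise DegenerateDataError("degenerate bootstrap refit")
    return float(gs[0] * sigma2_e), float(gs[1] * sigma2_e), float(sigma2_e)


def parametric_bootstrap_ci(table: pd.DataFrame, coding: str = "concentration",
                            n_boot: int = 1000, ci_level: float = 0.95,
                            seed: int | None = None,
                            fit: GxeLmmFit | None = None,
                            keep_replicates: bool = False) -> GxETestResult:
    """Percentile bootstrap CI for the interaction variance ``sigma2_GxE``.

    Simulates ``n_boot`` datasets from the fitted model, refits each, and
    takes the percentile interval of the refit interaction variances.
    Failed refits are replaced with fresh draws (up to ``2 * n_boot``
    total attempts); more than 50% failures aborts.  The effect is
    significant when the lower bound exceeds zero.
    """
    if fit is None:
        fit = fit_gxe_lmm(table, coding=coding)
    _, stats = _prepare(table, coding)
    seed = 0 if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    design = fit.design
    n = design["n"].to_numpy(dtype=int)
    x_fam = design["x"].to_numpy(dtype=float)
    K = len(design)
    fam_idx = np.repeat(np.arange(K), n)
    x_obs = x_fam[fam_idx]
    slope_mult = np.ones_like(x_obs) if coding == "cell" else x_obs
    fixed = fit.mu_hat + fit.alpha_hat * x_obs
    sd_g, sd_c, sd_e = fit.sd_G, fit.sd_GxE, fit.sd_E
    parent_gs = (fit.theta_G**2, fit.theta_GxE**2)
    starts = [np.maximum(parent_gs, 1e-4), (0.25, 0.25)]
    reps: list[float] = []
    n_failed = 0
    attempts = 0
    while len(reps) < n_boot and attempts < 2 * n_boot:
        attempts += 1
        b = rng.normal(0.0, sd_g, size=K)
        c = rng.normal(0.0, sd_c, size=K)
        y = (fixed + b[fam_idx] + c[fam_idx] * slope_mult
             + rng.normal(0.0, sd_e, size=len(x_obs)))
        try:
            reps.append(_fit_fast(stats.with_response(y), coding, starts)[1])
        except (FamGxeError, DegenerateDataError):
            n_failed += 1
    if len(reps) < n_boot and n_failed > attempts / 2:
        raise FamGxeError(
            f"unstable model: {n_failed}/{attempts} bootstrap refits failed"
        )
    reps_arr = np.asarray(reps)
    alpha = (1.0 - ci_level) / 2.0
    ci_low = float(np.percentile(reps_arr, 100 * alpha))
    ci_high = float(np.percentile(reps_arr, 100 * (1 - alpha)))
    result = GxETestResult(
        sigma2_gxe_hat=fit.sigma2_GxE,
        ci_low=ci_low,
        ci_high=ci_high,
        ci_level=ci_level,
        n_boot=len(reps),
        n_failed_refits=n_failed,
        significant=bool(ci_low > 0.0),
        boot_seed=seed,
        replicates=reps_arr if keep_replicates else None,
    )
    logger.info(
        "sigma2_GxE=%.4g, %.0f%% CI [%.4g, %.4g], significant=%s "
        "(%d replicates, %d failed refits)",
        fit.sigma2_GxE, 100 * ci_level, ci_low, ci_high,
        result.significant, len(reps), n_failed,
    )
    return result
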