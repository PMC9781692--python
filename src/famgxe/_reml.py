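"""Profiled REML machinery for family-block covariance structures.

Both the one-way family model and the family x exposure interaction LMM
have marginal covariance ``V = sigma2_E * H`` with ``H`` block diagonal
over families and each block ``I + a_k J`` (``J`` the all-ones matrix):
``a_k`` collects the family-level variance ratios (e.g.
``theta_G^2 + theta_GxE^2 * x_k^2`` for a random slope on the exposure
code).  Because covariates are constant within a family, the restricted
likelihood depends on the data only through per-family sufficient
statistics (size, sum, sum of squares), making each evaluation O(number
of families).

With ``a`` fixed, the GLS fixed effects and the residual variance have
closed forms; the profiled criterion minimized here is

    (N - p) * log(Q / (N - p)) + sum_k log(1 + a_k n_k)
        + log det(X' H^-1 X) + (N - p)

i.e. -2 * restricted log-likelihood up to an additive constant, where
``Q`` is the GLS residual quadratic form.  The design matrix has at most
two columns (intercept, exposure code), so the GLS algebra is hand-rolled
2x2 scalar arithmetic — profiling showed LAPACK call overhead dominating
bootstrap refits otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log

import numpy as np
import pandas as pd

_INF = float("inf")


@dataclass
class FamilyStats:
    """Per-family sufficient statistics for a family-block REML fit."""

    families: list  # family IDs, defining block order
    n: np.ndarray  # observations per family
    sum_y: np.ndarray
    sum_y2: np.ndarray
    xf: np.ndarray  # (K, p) covariate row per family (constant within)
    fam_index: np.ndarray  # per-observation family position

    @property
    def n_total(self) -> int:
        return int(self.n.sum())

    @property
    def p(self) -> int:
        return self.xf.shape[1]

    def with_response(self, y: np.ndarray) -> "FamilyStats":
        """Same design, new response (used by bootstrap refits)."""
        y = np.asarray(y, dtype=float)
        sums = np.bincount(self.fam_index, weights=y, minlength=len(self.n))
        sums2 = np.bincount(self.fam_index, weights=y * y, minlength=len(self.n))
        return FamilyStats(self.families, self.n, sums, sums2, self.xf,
                           self.fam_index)


def build_family_stats(y, family_ids, covariates=None) -> FamilyStats:
    """Aggregate observations into per-family sufficient statistics.

    ``covariates``: at most one design column beyond the intercept; it
    must be constant within each family (true for exposure codes under a
    nested design).
    """
    y = np.asarray(y, dtype=float)
    fam = pd.Series(np.asarray(family_ids, dtype=object))
    codes, families = pd.factorize(fam, sort=True)
    K = len(families)
    n = np.bincount(codes, minlength=K).astype(float)
    sum_y = np.bincount(codes, weights=y, minlength=K)
    sum_y2 = np.bincount(codes, weights=y * y, minlength=K)
    if covariates is None:
        xf = np.ones((K, 1))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 2:
            if cov.shape[1] != 1:
                raise ValueError("at most one covariate column is supported")
            cov = cov[:, 0]
        lo = np.full(K, np.inf)
        hi = np.full(K, -np.inf)
        np.minimum.at(lo, codes, cov)
        np.maximum.at(hi, codes, cov)
        if np.any(hi - lo > 1e-12 * np.maximum(1.0, np.abs(hi))):
            bad = families[np.argmax(hi - lo)]
            raise ValueError(
                "covariates must be constant within each family "
                f"(family {bad!r} varies)"
            )
        xf = np.column_stack([np.ones(K), lo])
    return FamilyStats(list(families), n, sum_y, sum_y2, xf, codes)


def profiled_criterion(a: np.ndarray, stats: FamilyStats, need_cov: bool = False):
    """Evaluate the profiled REML criterion at family variance ratios ``a``.

    Returns ``(criterion, beta, sigma2_e, xhx_inv)``; ``criterion`` is
    ``inf`` for inadmissible points (non-positive residual quadratic form
    or singular GLS normal matrix).  ``xhx_inv`` (the unscaled fixed-effect
    covariance factor) is computed only when ``need_cov``.
    """
    n, sy, syy, xf = stats.n, stats.sum_y, stats.sum_y2, stats.xf
    a = np.asarray(a, dtype=float)
    denom = 1.0 + a * n
    w = n / denom  # weight of each family mean in the GLS normal equations
    u = sy / denom
    yhy = float((syy - (a / denom) * sy * sy).sum())
    dof = stats.n_total - stats.p
    if stats.p == 1:
        a00 = float(w.sum())
        if a00 <= 0:
            return _INF, None, None, None
        b0 = float(u.sum())
        beta = np.array([b0 / a00])
        q = yhy - beta[0] * b0
        logdet_xhx = log(a00)
        xhx_inv = np.array([[1.0 / a00]]) if need_cov else None
    else:
        x = xf[:, 1]
        a00 = float(w.sum())
        a01 = float((w * x).sum())
        a11 = float((w * x * x).sum())
        det = a00 * a11 - a01 * a01
        if det <= 0:
            return _INF, None, None, None
        b0 = float(u.sum())
        b1 = float((u * x).sum())
        beta = np.array([(a11 * b0 - a01 * b1) / det,
                         (a00 * b1 - a01 * b0) / det])
        q = yhy - beta[0] * b0 - beta[1] * b1
        logdet_xhx = log(det)
        xhx_inv = (np.array([[a11, -a01], [-a01, a00]]) / det
                   if need_cov else None)
    if q <= 0 or dof <= 0:
        return _INF, beta, 0.0, xhx_inv
    sigma2_e = q / dof
    crit = (dof * log(sigma2_e)
            + float(np.log(denom).sum())
            + logdet_xhx
            + dof)
    return crit, beta, sigma2_e, xhx_inv


def criterion_and_grad(a: np.ndarray, da_dparams: np.ndarray,
                       stats: FamilyStats):
    """Profiled criterion and its gradient in variance-ratio parameters.

    ``a`` is the per-family variance ratio; ``da_dparams`` has shape
    (n_params, K) holding ``da_k / d param_m`` (e.g. rows ``1`` and
    ``x_k^2`` for the intercept/slope ratios).  Only the two-column design
    is supported.  The gradient combines, per family,

        d crit / d a_k = (dof / Q) * (-R_k^2 / denom_k^2)
                         + n_k / denom_k
                         - (n_k^2 / denom_k^2) * xf_k' (X'H^-1X)^-1 xf_k

    where ``R_k`` is the family sum of GLS residuals (envelope theorem:
    the GLS fixed effects need not be differentiated).
    """
    n, sy, xf = stats.n, stats.sum_y, stats.xf
    a = np.asarray(a, dtype=float)
    denom = 1.0 + a * n
    w = n / denom
    u = sy / denom
    yhy = float((stats.sum_y2 - (a / denom) * sy * sy).sum())
    dof = stats.n_total - stats.p
    x = xf[:, 1]
    a00 = float(w.sum())
    a01 = float((w * x).sum())
    a11 = float((w * x * x).sum())
    det = a00 * a11 - a01 * a01
    if det <= 0:
        return _INF, np.full(da_dparams.shape[0], np.nan)
    b0 = float(u.sum())
    b1 = float((u * x).sum())
    beta0 = (a11 * b0 - a01 * b1) / det
    beta1 = (a00 * b1 - a01 * b0) / det
    q = yhy - beta0 * b0 - beta1 * b1
    if q <= 0 or dof <= 0:
        return _INF, np.full(da_dparams.shape[0], np.nan)
    crit = (dof * log(q / dof)
            + float(np.log(denom).sum())
            + log(det)
            + dof)
    r = sy - n * (beta0 + beta1 * x)  # family sums of GLS residuals
    inv_d2 = 1.0 / (denom * denom)
    quad = (a11 - 2.0 * a01 * x + a00 * x * x) / det  # xf' A^-1 xf
    dcrit_da = (-(dof / q) * r * r * inv_d2
                + n / denom
                - n * n * inv_d2 * quad)
    grad = da_dparams @ dcrit_da
    return crit, grad
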