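"""One-way random-effects model and intraclass correlation.

The model for an individual ``i`` of family ``k`` within a single
environment is ``Y_ik = mu + S_k + E_ik`` with ``S_k ~ N(0, sigma2_S)``
and ``E_ik ~ N(0, sigma2_E)``.  The intraclass correlation

    ICC = sigma2_S / (sigma2_S + sigma2_E)

measures how much more full siblings resemble each other than unrelated
larvae; it is the heritability-style statistic compared across exposure
environments.  Estimation is REML via a 1-D search on the variance ratio
``lambda = sigma2_S / sigma2_E`` with everything else profiled out in
closed form; the classical ANOVA (method-of-moments) estimator is kept as
an internal oracle and a cheap alternative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from ._reml import build_family_stats, profiled_criterion
from .types import DegenerateDataError, validate_phenotypes

logger = logging.getLogger(__name__)

LAMBDA_MAX = 1e6
_REL_EPS = 1e-12


@dataclass
class OneWayFit:
    """Variance components of a one-way random-effects fit."""

    sigma2_S: float
    sigma2_E: float
    icc: float
    n_groups: int
    n_total: int
    loglik_reml: float
    converged: bool
    method: str
    degenerate: bool = False

    @property
    def sigma2_T(self) -> float:
        return self.sigma2_S + self.sigma2_E

    @property
    def share_family(self) -> float:
        return self.icc

    @property
    def share_residual(self) -> float:
        return 1.0 - self.icc


def _group_arrays(table: pd.DataFrame):
    values = table["value"].to_numpy(dtype=float)
    fams = table["family_id"].to_numpy(dtype=object)
    return values, fams


def _check_input(values: np.ndarray, fams: np.ndarray) -> None:
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite phenotype values")
    n_groups = len(pd.unique(fams))
    if n_groups < 2:
        raise DegenerateDataError("need at least 2 families to separate "
                                  "between- from within-family variance")
    if len(values) < n_groups + 2:
        raise DegenerateDataError("too few observations beyond group count")


def anova_oneway(table: pd.DataFrame) -> OneWayFit:
    """Method-of-moments (ANOVA) variance components.

    ``sigma2_E = MSW``; ``sigma2_S = max(0, (MSB - MSW) / n0)`` with the
    standard unbalanced coefficient ``n0 = (N - sum n_k^2 / N) / (K - 1)``.
    Serves as the closed-form oracle for the REML fit: on balanced data
    with MSB >= MSW the two coincide.
    """
    values, fams = _group_arrays(validate_phenotypes(table))
    _check_input(values, fams)
    codes, families = pd.factorize(pd.Series(fams), sort=True)
    K = len(families)
    N = len(values)
    n_k = np.bincount(codes).astype(float)
    sums = np.bincount(codes, weights=values)
    means = sums / n_k
    grand = values.mean()
    ssb = float(np.sum(n_k * (means - grand) ** 2))
    ssw = float(np.sum((values - means[codes]) ** 2))
    msb = ssb / (K - 1)
    grand_scale = max(1.0, float(np.abs(values).max()))
    if ssw <= _REL_EPS * grand_scale**2 * N:
        if ssb <= _REL_EPS * grand_scale**2 * N:
            raise DegenerateDataError("constant response: sigma2_E unidentifiable")
        n0 = (N - float(np.sum(n_k**2)) / N) / (K - 1)
        return OneWayFit(msb / n0, 0.0, 1.0, K, N, np.nan, True, "anova",
                         degenerate=True)
    msw = ssw / (N - K)
    n0 = (N - float(np.sum(n_k**2)) / N) / (K - 1)
    sigma2_s = max(0.0, (msb - msw) / n0)
    icc = sigma2_s / (sigma2_s + msw)
    return OneWayFit(sigma2_s, msw, icc, K, N, np.nan, True, "anova")


def fit_oneway_reml(table: pd.DataFrame, lambda_max: float = LAMBDA_MAX,
                    xatol: float = 1e-10) -> OneWayFit:
    """REML fit of the one-way random-effects model.

    Profiles the grand mean and ``sigma2_E`` out of the restricted
    likelihood, leaving a 1-D bounded minimization over the ratio
    ``lambda = sigma2_S / sigma2_E`` on ``[0, lambda_max]``.  The boundary
    ``sigma2_S = 0`` is admissible.  A response with zero within-family
    variance but distinct family means is degenerate (``sigma2_E -> 0``)
    and is reported as ICC = 1 with the degenerate flag rather than an
    error, because per-gene scans routinely meet near-constant genes;
    a globally constant response raises :class:`DegenerateDataError`.
    """
    values, fams = _group_arrays(validate_phenotypes(table))
    _check_input(values, fams)
    stats = build_family_stats(values, fams)
    K, N = len(stats.families), stats.n_total

    grand_scale = max(1.0, float(np.abs(values).max()))
    codes = stats.fam_index
    means = stats.sum_y / stats.n
    ssw = float(np.sum((values - means[codes]) ** 2))
    ssb = float(np.sum(stats.n * (means - values.mean()) ** 2))
    if ssw <= _REL_EPS * grand_scale**2 * N:
        if ssb <= _REL_EPS * grand_scale**2 * N:
            raise DegenerateDataError("constant response: sigma2_E unidentifiable")
        n0 = (N - float(np.sum(stats.n**2)) / N) / (K - 1)
        sigma2_s = (ssb / (K - 1)) / n0
        return OneWayFit(sigma2_s, 0.0, 1.0, K, N, np.inf, True, "reml",
                         degenerate=True)

    def crit(lam: float) -> float:
        return profiled_criterion(np.full(K, max(lam, 0.0)), stats)[0]

    res = minimize_scalar(crit, bounds=(0.0, lambda_max), method="bounded",
                          options={"xatol": xatol})
    lam = float(res.x)
    best = float(res.fun)
    # the moment estimator is the exact optimum on balanced designs and a
    # strong candidate elsewhere; the criterion can be too flat for the
    # bounded search to localize lambda to full precision on its own
    msw = ssw / (N - K)
    n0 = (N - float(np.sum(stats.n**2)) / N) / (K - 1)
    lam_anova = max(0.0, (ssb / (K - 1) - msw) / n0) / msw
    if crit(lam_anova) <= best + 1e-9:
        lam, best = lam_anova, crit(lam_anova)
    # the bounded minimizer never lands exactly on 0; accept the boundary
    # when it is at least as good
    if crit(0.0) <= best + 1e-9:
        lam = 0.0
    c, _beta, sigma2_e, _ = profiled_criterion(np.full(K, lam), stats)
    sigma2_s = lam * sigma2_e
    icc = sigma2_s / (sigma2_s + sigma2_e) if (sigma2_s + sigma2_e) > 0 else 0.0
    return OneWayFit(sigma2_s, sigma2_e, icc, K, N, -0.5 * c,
                     bool(res.success), "reml")


def icc_by_environment(table: pd.DataFrame, method: str = "reml") -> pd.DataFrame:
    """Independent one-way fits per exposure environment.

    Returns one row per environment with the ICC and both variance shares
    (family and residual fractions of the total).  Environments with fewer
    than two families are skipped with a warning.
    """
    validate_phenotypes(table)
    fit = fit_oneway_reml if method == "reml" else anova_oneway
    rows = []
    for env, sub in table.groupby("exposure", sort=True):
        if sub["family_id"].nunique() < 2:
            warnings.warn(
                f"exposure {env!r} has fewer than 2 families; skipped",
                UserWarning, stacklevel=2,
            )
            continue
        f = fit(sub)
        rows.append({
            "exposure": env,
            "icc": f.icc,
            "sigma2_S": f.sigma2_S,
            "sigma2_E": f.sigma2_E,
            "share_family": f.share_family,
            "share_residual": f.share_residual,
            "n_families": f.n_groups,
            "n_individuals": f.n_total,
            "degenerate": f.degenerate,
        })
        logger.info("exposure %s: ICC=%.3f (K=%d, N=%d)", env, f.icc,
                    f.n_groups, f.n_total)
    return pd.DataFrame(rows)
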