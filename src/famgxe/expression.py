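"""Per-gene application of the variance-partitioning framework to
RNA-seq counts.

Stages: low-expression filtering, normalization (log2-CPM by default),
per-gene per-environment ICC with a paired Wilcoxon comparison between
environments, a global gene+family variance apportionment, and the
per-gene parametric-bootstrap GxE scan.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from .config import child_seed
from .gxe import fit_gxe_lmm, parametric_bootstrap_ci
from .oneway import fit_oneway_reml
from .types import (
    CountMatrix,
    DegenerateDataError,
    ExpressionMatrix,
    FamGxeError,
)

logger = logging.getLogger(__name__)


def filter_genes(counts: CountMatrix, min_count: int = 20,
                 min_frac: float = 0.25, strict: bool = False) -> CountMatrix:
    """Remove unexpressed and low-count genes.

    A gene is retained iff it has a nonzero count somewhere AND, in at
    least one treatment group, at least ``min_frac`` of that group's
    samples reach ``min_count`` (the permissive reading, so genes
    expressed in only one treatment survive).  ``strict=True`` requires
    the threshold in every treatment group instead.  Gene order is
    preserved.
    """
    meta = counts.meta
    if not len(meta):
        raise FamGxeError("count matrix has no sample metadata")
    groups = meta.groupby("exposure", sort=True).indices
    for env, idx in groups.items():
        if len(idx) == 0:
            raise FamGxeError(f"treatment group {env!r} has zero samples")
    nonzero = counts.counts.sum(axis=1) > 0
    per_group = []
    for env, idx in groups.items():
        frac = (counts.counts[:, idx] >= min_count).mean(axis=1)
        per_group.append(frac >= min_frac)
    per_group = np.column_stack(per_group)
    passing = per_group.all(axis=1) if strict else per_group.any(axis=1)
    keep = nonzero & passing
    kept = [g for g, k in zip(counts.gene_ids, keep) if k]
    logger.info("filter: %d of %d genes retained (min_count=%d, "
                "min_frac=%.2f, strict=%s)", len(kept), counts.n_genes,
                min_count, min_frac, strict)
    return CountMatrix(kept, list(counts.sample_ids),
                       counts.counts[keep], counts.meta.copy())


def normalize_counts(counts: CountMatrix,
                     scheme: str = "log-cpm") -> ExpressionMatrix:
    """Normalize counts for modeling.

    ``log-cpm`` (default): ``log2(1e6 * count / libsize + 1)``;
    ``cpm``: counts per million (columns sum to 1e6);
    ``median-of-ratios``: counts divided by median-of-ratios size factors
    (geometric-mean reference over genes with no zero counts).
    """
    libsize = counts.counts.sum(axis=0).astype(float)
    zero = np.nonzero(libsize == 0)[0]
    if len(zero):
        raise FamGxeError(
            f"zero library size for sample(s) "
            f"{[counts.sample_ids[i] for i in zero[:5]]}"
        )
    c = counts.counts.astype(float)
    if scheme == "cpm":
        values = 1e6 * c / libsize
    elif scheme == "log-cpm":
        values = np.log2(1e6 * c / libsize + 1.0)
    elif scheme == "median-of-ratios":
        allpos = (counts.counts > 0).all(axis=1)
        if not allpos.any():
            raise FamGxeError("median-of-ratios undefined: every gene has "
                              "a zero count in some sample")
        ref = np.exp(np.mean(np.log(c[allpos]), axis=1))
        size = np.median(c[allpos] / ref[:, None], axis=0)
        values = c / size
    else:
        raise FamGxeError(f"unknown normalization scheme {scheme!r}")
    return ExpressionMatrix(list(counts.gene_ids), list(counts.sample_ids),
                            values, counts.meta.copy(), scheme)


def per_gene_icc(normmat: ExpressionMatrix,
                 meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """One-way family fit per (gene, environment).

    Degenerate genes (near-constant within an environment) are flagged,
    never dropped, and a per-gene failure never aborts the scan.  Returns
    a long frame: gene_id, exposure, icc, share_family, share_residual,
    degenerate, error.
    """
    meta = normmat.meta if meta is None else meta
    rows = []
    for env, idx in meta.groupby("exposure", sort=True).indices.items():
        fam = meta["family_id"].to_numpy(dtype=object)[idx]
        ids = meta["individual_id"].to_numpy(dtype=object)[idx]
        for g, gene in enumerate(normmat.gene_ids):
            sub = pd.DataFrame({
                "individual_id": ids,
                "family_id": fam,
                "exposure": env,
                "value": normmat.values[g, idx],
            })
            row = {"gene_id": gene, "exposure": env, "icc": np.nan,
                   "share_family": np.nan, "share_residual": np.nan,
                   "degenerate": False, "error": ""}
            try:
                f = fit_oneway_reml(sub)
                row.update(icc=f.icc, share_family=f.share_family,
                           share_residual=f.share_residual,
                           degenerate=f.degenerate)
            except (DegenerateDataError, FamGxeError, ValueError) as exc:
                row.update(degenerate=True, error=str(exc))
            rows.append(row)
    return pd.DataFrame(rows)


def compare_icc(icc_table: pd.DataFrame, env_a: str, env_b: str,
                column: str = "icc") -> dict:
    """Paired Wilcoxon signed-rank test of per-gene ICC between two
    environments.

    Pairs genes present (non-degenerate, finite) in both environments;
    zero differences are discarded (zero-discard convention); the exact
    null distribution is used for up to 25 effective pairs, the normal
    approximation with continuity correction above.  Returns the
    two-sided p together with the median difference (a - b) and the
    effective pair count.
    """
    wide = (icc_table
            .loc[~icc_table["degenerate"].astype(bool)]
            .pivot(index="gene_id", columns="exposure", values=column))
    for env in (env_a, env_b):
        if env not in wide.columns:
            raise FamGxeError(f"environment {env!r} absent from ICC table")
    paired = wide[[env_a, env_b]].dropna()
    if not len(paired):
        raise FamGxeError("no genes shared between the two environments")
    diff = (paired[env_a] - paired[env_b]).to_numpy()
    n_eff = int(np.sum(diff != 0))
    median_diff = float(np.median(diff))
    if n_eff == 0:
        warnings.warn("all paired differences are zero; p = 1",
                      UserWarning, stacklevel=2)
        return {"p_value": 1.0, "median_diff": 0.0, "n_pairs": len(paired),
                "n_effective": 0, "direction": "none"}
    method = "exact" if n_eff <= 25 else "approx"
    res = wilcoxon(diff, zero_method="wilcox", alternative="two-sided",
                   correction=(method == "approx"), method=method)
    direction = (f"{env_a} > {env_b}" if median_diff > 0
                 else f"{env_a} < {env_b}" if median_diff < 0 else "none")
    return {"p_value": float(res.pvalue), "median_diff": median_diff,
            "n_pairs": int(len(paired)), "n_effective": n_eff,
            "direction": direction}


@dataclass
class GlobalApportionment:
    """Percent of total expression variance per source, one environment."""

    exposure: str
    pct_gene: float
    pct_family: float
    pct_residual: float
    method: str

    def as_dict(self) -> dict:
        return {"exposure": self.exposure, "pct_gene": self.pct_gene,
                "pct_family": self.pct_family,
                "pct_residual": self.pct_residual, "method": self.method}


def global_apportion(normmat: ExpressionMatrix, environment: str,
                     meta: pd.DataFrame | None = None,
                     method: str = "henderson3") -> GlobalApportionment:
    """Apportion all expression variance in one environment into gene,
    family and residual components.

    The model on the long view (one observation per gene x sample) is
    ``y = mu + gene_i + family_j + error`` with gene and family crossed
    random effects.  ``henderson3`` solves the Henderson Method III
    moment equations, which are exact here because every sample measures
    every gene (proportional cell frequencies make the two-way additive
    sums of squares orthogonal):

        E[SS_gene]   = (G-1) * (S * s2_gene + s2_e)
        E[SS_family] = (J-1) * s2_e + G * (S - sum s_j^2 / S) * s2_family
        E[SS_resid]  = (N - G - J + 1) * s2_e

    with G genes, J families, S samples and s_j samples in family j.
    ``method='reml'`` fits the same model by REML (statsmodels variance
    components) and is practical only for small instances.
    """
    meta = normmat.meta if meta is None else meta
    idx = np.nonzero((meta["exposure"] == environment).to_numpy())[0]
    if len(idx) == 0:
        raise FamGxeError(f"no samples in environment {environment!r}")
    fam = pd.factorize(meta["family_id"].to_numpy(dtype=object)[idx])[0]
    J = fam.max() + 1
    G = normmat.n_genes
    S = len(idx)
    if G < 2 or J < 2:
        raise FamGxeError("need at least 2 genes and 2 families")
    y = normmat.values[:, idx]  # G x S
    N = G * S
    grand = y.mean()
    gene_means = y.mean(axis=1)
    s_j = np.bincount(fam).astype(float)
    fam_sums = np.zeros(J)
    for j in range(J):
        fam_sums[j] = y[:, fam == j].sum()
    fam_means = fam_sums / (G * s_j)
    ss_gene = float(S * np.sum((gene_means - grand) ** 2))
    ss_family = float(G * np.sum(s_j * (fam_means - grand) ** 2))
    ss_total = float(np.sum((y - grand) ** 2))
    ss_resid = ss_total - ss_gene - ss_family

    if method == "henderson3":
        s2_e = ss_resid / (N - G - J + 1)
        s2_gene = max(0.0, (ss_gene / (G - 1) - s2_e) / S)
        coef = G * (S - float(np.sum(s_j**2)) / S)
        s2_family = max(0.0, (ss_family - (J - 1) * s2_e) / coef)
    elif method == "reml":
        import statsmodels.api as sm

        long = pd.DataFrame({
            "y": y.ravel(),
            "gene": np.repeat(np.arange(G), S),
            "family": np.tile(fam, G),
            "one": 1,
        })
        model = sm.MixedLM.from_formula(
            "y ~ 1", data=long, groups="one",
            vc_formula={"gene": "0 + C(gene)", "family": "0 + C(family)"},
            re_formula="0",
        )
        res = model.fit(reml=True, method="lbfgs")
        vc = dict(zip(model.exog_vc.names, res.vcomp))
        s2_gene = float(vc["gene"])
        s2_family = float(vc["family"])
        s2_e = float(res.scale)
    else:
        raise FamGxeError(f"unknown apportionment method {method!r}")
    total = s2_gene + s2_family + s2_e
    return GlobalApportionment(
        exposure=environment,
        pct_gene=100.0 * s2_gene / total,
        pct_family=100.0 * s2_family / total,
        pct_residual=100.0 * s2_e / total,
        method=method,
    )


def gxe_scan(normmat: ExpressionMatrix, coding: str = "ordinal",
             n_boot: int = 1000, ci_level: float = 0.95, seed: int = 0,
             meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-gene parametric-bootstrap GxE scan.

    Each gene gets a child seed derived from the master seed and the gene
    ID (not its position), so results are invariant to gene order and
    reproducible per gene.  Genes whose base fit fails are reported as
    unfit, never significant.  Returns a frame with one row per gene:
    sigma2_gxe_hat, ci_low, ci_high, significant, n_failed_refits, unfit.
    """
    meta = normmat.meta if meta is None else meta
    ids = meta["individual_id"].to_numpy(dtype=object)
    fams = meta["family_id"].to_numpy(dtype=object)
    envs = meta["exposure"].to_numpy(dtype=object)
    rows = []
    for g, gene in enumerate(normmat.gene_ids):
        sub = pd.DataFrame({
            "individual_id": ids,
            "family_id": fams,
            "exposure": envs,
            "value": normmat.values[g],
        })
        gene_seed = child_seed(seed, f"gxe_scan:{gene}")
        row = {"gene_id": gene, "sigma2_gxe_hat": np.nan, "ci_low": np.nan,
               "ci_high": np.nan, "significant": False,
               "n_failed_refits": 0, "unfit": False, "error": ""}
        try:
            fit = fit_gxe_lmm(sub, coding=coding)
            res = parametric_bootstrap_ci(sub, coding=coding, n_boot=n_boot,
                                          ci_level=ci_level, seed=gene_seed,
                                          fit=fit)
            row.update(sigma2_gxe_hat=res.sigma2_gxe_hat, ci_low=res.ci_low,
                       ci_high=res.ci_high, significant=res.significant,
                       n_failed_refits=res.n_failed_refits)
        except (FamGxeError, DegenerateDataError, ValueError) as exc:
            row.update(unfit=True, error=str(exc))
        rows.append(row)
    table = pd.DataFrame(rows)
    n_sig = int(table["significant"].sum())
    logger.info("GxE scan: %d of %d genes significant at %.0f%% CI "
                "(n_boot=%d)", n_sig, len(table), 100 * ci_level, n_boot)
    return table
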