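"""Synthetic data with the statistical structure the analyses assume.

Three generators mirror the three data layers of the study design:

* :func:`simulate_phenotypes` — endpoint values from the variance-component
  model ``y = mu + alpha x_j + b_k + c_k x_j + eps`` with family intercepts
  ``b_k``, family exposure slopes ``c_k`` (the GxE signal) and residual
  noise, on a nested families-in-exposures layout;
* :func:`simulate_trace` — per-bin movement traces whose dark-phase
  endpoint reproduces a given phenotype value exactly (target-matched), so
  endpoint-extraction tests are exact; a free-running mode drops the
  matching;
* :func:`simulate_counts` — negative-binomial RNA-seq counts with per-
  (gene, family) intercepts and exposure slopes for designated gene
  fractions, returning ground-truth labels for scan benchmarking.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import DARK, AssaySchedule, classify_bins
from .types import CountMatrix, FamGxeError

DEFAULT_EXPOSURES: tuple[str, ...] = ("control", "medium", "high")


@dataclass
class BehaviorSimParams:
    """Parameters of the behavioral phenotype generator.

    Defaults follow the study design: 3 exposure environments with 4
    full-sib families each and 35-48 retained larvae per family.  The
    exposure codes default to ordinal 0/1/2; variances are on the scale
    of the endpoint.
    """

    n_exposures: int = 3
    exposure_labels: tuple[str, ...] = DEFAULT_EXPOSURES
    exposure_codes: tuple[float, ...] = (0.0, 1.0, 2.0)
    families_per_exposure: int = 4
    n_per_family: tuple[int, int] = (35, 48)
    mu: float = 0.0
    alpha: float = 0.0
    sigma2_G: float = 1.0
    sigma2_GxE: float = 0.0
    sigma2_E: float = 1.0
    exclusion_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.exposure_labels) != self.n_exposures:
            raise FamGxeError("exposure_labels must match n_exposures")
        if len(self.exposure_codes) != self.n_exposures:
            raise FamGxeError("exposure_codes must match n_exposures")
        for v in (self.sigma2_G, self.sigma2_GxE, self.sigma2_E):
            if v < 0:
                raise FamGxeError("variances must be >= 0")
        lo, hi = self._range()
        if lo < 1:
            raise FamGxeError("n_per_family must be >= 1")
        if hi < lo:
            raise FamGxeError("n_per_family range inverted")
        if not (0.0 <= self.exclusion_prob < 1.0):
            raise FamGxeError("exclusion_prob must lie in [0, 1)")
        if self.families_per_exposure < 1:
            raise FamGxeError("families_per_exposure must be >= 1")

    def _range(self) -> tuple[int, int]:
        n = self.n_per_family
        if isinstance(n, (int, np.integer)):
            return int(n), int(n)
        return int(n[0]), int(n[1])


@dataclass
class SimulatedPhenotypes:
    """Generator output: the analysis table plus the generating truth."""

    table: pd.DataFrame  # retained individuals only (phenotype table)
    meta: pd.DataFrame  # all individuals incl. excluded
    truth: pd.DataFrame  # per family: exposure code, b (intercept), c (slope)


def simulate_phenotypes(params: BehaviorSimParams) -> SimulatedPhenotypes:
    """Draw a nested-design phenotype table from the variance-component
    model; same seed, same output."""
    rng = np.random.default_rng(params.seed)
    lo, hi = params._range()
    fams = []
    for j, (label, code) in enumerate(
            zip(params.exposure_labels, params.exposure_codes)):
        for f in range(params.families_per_exposure):
            fams.append((f"F{j * params.families_per_exposure + f + 1:03d}",
                         label, float(code)))
    K = len(fams)
    b = rng.normal(0.0, np.sqrt(params.sigma2_G), size=K)
    c = rng.normal(0.0, np.sqrt(params.sigma2_GxE), size=K)
    sizes = rng.integers(lo, hi + 1, size=K)
    fam_ids = np.array([f for f, _, _ in fams], dtype=object)
    labels = np.array([e for _, e, _ in fams], dtype=object)
    codes = np.array([x for _, _, x in fams])
    idx = np.repeat(np.arange(K), sizes)
    n_total = len(idx)
    eps = rng.normal(0.0, np.sqrt(params.sigma2_E), size=n_total)
    y = (params.mu + params.alpha * codes[idx] + b[idx] + c[idx] * codes[idx]
         + eps)
    excl = rng.random(n_total) < params.exclusion_prob
    within = np.concatenate([np.arange(nk) for nk in sizes])
    meta = pd.DataFrame({
        "individual_id": [f"{fam_ids[k]}_{i:03d}"
                          for k, i in zip(idx, within)],
        "family_id": fam_ids[idx],
        "exposure": labels[idx],
        "value": y,
        "excluded": excl,
    })
    table = (meta.loc[~meta["excluded"],
                      ["individual_id", "family_id", "exposure", "value"]]
             .reset_index(drop=True))
    truth = pd.DataFrame({
        "family_id": [f for f, _, _ in fams],
        "exposure": [e for _, e, _ in fams],
        "x": [x for _, _, x in fams],
        "b": b,
        "c": c,
    })
    return SimulatedPhenotypes(table=table, meta=meta, truth=truth)


def simulate_trace(phenotypes: pd.DataFrame,
                   schedule: AssaySchedule | None = None,
                   seed: int = 0,
                   dark_mean: float = 2.0,
                   light_mean: float = 0.5,
                   shape: float = 2.0,
                   target_matched: bool = True) -> pd.DataFrame:
    """Generate per-bin movement traces for each phenotype row.

    Distances are gamma-distributed around phase-specific activity levels
    (dark > light, the stereotyped photomotor response).  In the default
    target-matched mode the dark bins of the retained cycles are rescaled
    so the extracted endpoint equals each individual's ``value`` exactly;
    the free-running mode (``target_matched=False``) skips the rescale.
    """
    schedule = schedule or AssaySchedule()
    labels = classify_bins(schedule)
    is_dark = (labels["phase"] == DARK).to_numpy()
    retained_dark = is_dark & (labels["cycle"].to_numpy() >= 2)
    rng = np.random.default_rng(seed)
    n_bins = schedule.n_bins
    frames = []
    for _, row in phenotypes.iterrows():
        target = float(row["value"])
        if target_matched and target < 0:
            raise FamGxeError(
                f"target endpoint for {row['individual_id']!r} is negative"
            )
        means = np.where(is_dark, dark_mean, light_mean)
        dist = rng.gamma(shape, means / shape, size=n_bins)
        if target_matched:
            cur = dist[retained_dark].sum()
            dist[retained_dark] *= target / cur if cur > 0 else 0.0
        frames.append(pd.DataFrame({
            "individual_id": row["individual_id"],
            "bin_index": np.arange(n_bins),
            "distance": dist,
        }))
    return pd.concat(frames, ignore_index=True)


@dataclass
class CountsSimParams:
    """Parameters of the RNA-seq count generator.

    Counts are negative binomial (variance = mu + dispersion * mu^2)
    with log mean ``baseline_g + log(libsize_s / libsize_median) + u_{g,k}
    + v_{g,k} x_j``: ``u`` is a per-(gene, family) intercept (family
    effect, SD ``family_sd``) and ``v`` a per-(gene, family) exposure
    slope (GxE effect, SD ``gxe_sd``).  The effect classes partition the
    genes: ``frac_gxe_genes`` get slopes only, ``frac_family_genes`` get
    intercepts only, the rest are null.  ``gxe_sd_relative``, when set,
    overrides ``gxe_sd`` per gene with that multiple of the gene's own
    log-scale residual SD (delta method, ``sqrt(dispersion + 1/mu_g)``),
    so the effect strength is uniform on the analysis scale across the
    expression range.  Baselines are normal on the log scale of counts at
    the median library size; library sizes are log-normal with median
    ``libsize_median``.
    """

    n_genes: int = 2000
    samples_per_family: int = 6
    baseline_log_mean: float = 3.4  # ~exp(3.4) ~ 30 counts at median libsize
    baseline_log_sd: float = 1.2
    libsize_median: float = 1e6
    libsize_log_sd: float = 0.15
    dispersion: float = 0.1
    frac_family_genes: float = 0.0
    family_sd: float = 0.4
    frac_gxe_genes: float = 0.0
    gxe_sd: float = 0.7
    gxe_sd_relative: float | None = None
    seed: int = 0
    exposure_labels: tuple[str, ...] = DEFAULT_EXPOSURES
    exposure_codes: tuple[float, ...] = (0.0, 1.0, 2.0)
    families_per_exposure: int = 4

    def __post_init__(self) -> None:
        for f in (self.frac_family_genes, self.frac_gxe_genes):
            if not (0.0 <= f <= 1.0):
                raise FamGxeError("gene-effect fractions must lie in [0, 1]")
        if self.frac_family_genes + self.frac_gxe_genes > 1.0:
            raise FamGxeError("gene-effect fractions overlap")
        if self.dispersion <= 0:
            raise FamGxeError("dispersion must be > 0")
        if self.n_genes < 1 or self.samples_per_family < 1:
            raise FamGxeError("n_genes and samples_per_family must be >= 1")


@dataclass
class SimulatedCounts:
    counts: CountMatrix
    truth: pd.DataFrame  # gene_id, has_family_effect, has_gxe


def _default_design(params: CountsSimParams) -> pd.DataFrame:
    rows = []
    for j, (label, code) in enumerate(
            zip(params.exposure_labels, params.exposure_codes)):
        for f in range(params.families_per_exposure):
            rows.append({
                "family_id": f"F{j * params.families_per_exposure + f + 1:03d}",
                "exposure": label,
                "x": float(code),
            })
    return pd.DataFrame(rows)


def simulate_counts(params: CountsSimParams,
                    design: pd.DataFrame | None = None) -> SimulatedCounts:
    """Draw a truth-labeled count matrix on the nested family design.

    ``design`` may supply a custom family layout (columns ``family_id,
    exposure, x``); the default is 3 exposures x 4 families, giving
    72 samples at 6 per family.  Effect genes are the first
    ``floor(frac * n_genes)`` positions of a seeded shuffle: GxE genes
    first, then family-effect-only genes; labels partition the genes and
    are returned alongside the counts.
    """
    rng = np.random.default_rng(params.seed)
    if design is None:
        design = _default_design(params)
    G = params.n_genes
    gene_ids = [f"gene{g:05d}" for g in range(G)]
    order = rng.permutation(G)
    n_gxe = int(params.frac_gxe_genes * G)
    n_fam = int(params.frac_family_genes * G)
    has_gxe = np.zeros(G, dtype=bool)
    has_fam = np.zeros(G, dtype=bool)
    has_gxe[order[:n_gxe]] = True
    has_fam[order[n_gxe:n_gxe + n_fam]] = True

    K = len(design)
    S = K * params.samples_per_family
    fam_of_sample = np.repeat(np.arange(K), params.samples_per_family)
    x_fam = design["x"].to_numpy(dtype=float)
    baseline = rng.normal(params.baseline_log_mean, params.baseline_log_sd,
                          size=G)
    libsize = params.libsize_median * np.exp(
        rng.normal(0.0, params.libsize_log_sd, size=S))
    u = np.zeros((G, K))
    v = np.zeros((G, K))
    u[has_fam] = rng.normal(0.0, params.family_sd, size=(n_fam, K))
    if params.gxe_sd_relative is not None:
        # slope SD pinned per gene to a multiple of its own residual SD on
        # the log scale (NB delta method: Var(log y) ~ dispersion + 1/mu)
        resid_sd = np.sqrt(params.dispersion + 1.0 / np.exp(baseline))
        v[has_gxe] = (rng.standard_normal((n_gxe, K))
                      * (params.gxe_sd_relative * resid_sd[has_gxe])[:, None])
    else:
        v[has_gxe] = rng.normal(0.0, params.gxe_sd, size=(n_gxe, K))

    log_mu = (baseline[:, None]
              + u[:, fam_of_sample]
              + v[:, fam_of_sample] * x_fam[fam_of_sample][None, :]
              + np.log(libsize / params.libsize_median)[None, :])
    mu = np.exp(log_mu)
    r = 1.0 / params.dispersion  # NB size; variance = mu + mu^2 / r
    counts = rng.negative_binomial(r, r / (r + mu))

    sample_ids = []
    meta_rows = []
    for s in range(S):
        fam = design["family_id"].iloc[fam_of_sample[s]]
        sid = f"{fam}_s{s % params.samples_per_family:02d}"
        sample_ids.append(sid)
        meta_rows.append({
            "individual_id": sid,
            "family_id": fam,
            "exposure": design["exposure"].iloc[fam_of_sample[s]],
            "excluded": False,
        })
    cm = CountMatrix(gene_ids, sample_ids, counts.astype(np.int64),
                     pd.DataFrame(meta_rows))
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "has_family_effect": has_fam,
        "has_gxe": has_gxe,
    })
    return SimulatedCounts(counts=cm, truth=truth)
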