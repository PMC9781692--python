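"""End-to-end orchestration: simulate -> endpoint -> ICC -> GxE test ->
expression scan, with a reproducibility manifest.

Each stage reads and writes files in a run directory; no stage mutates
another stage's inputs.  The manifest records the config snapshot, SHA-256
digests of inputs and outputs, per-stage wall times and the seed ledger,
so a rerun with the same config and inputs can be checked for identity.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import pandas as pd

from . import behavior, expression, gxe, io, oneway, simulate
from .config import RunConfig, child_seed
from .types import FamGxeError

logger = logging.getLogger(__name__)


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    seeds: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)


def run_pipeline(config: RunConfig, outdir: str,
                 sim_behavior: simulate.BehaviorSimParams | None = None,
                 sim_counts: simulate.CountsSimParams | None = None,
                 traces_path: str | None = None,
                 meta_path: str | None = None,
                 counts_path: str | None = None) -> RunManifest:
    """Run the pipeline stages in dependency order.

    Inputs come either from files (``traces_path``/``meta_path``/
    ``counts_path``) or from the simulation parameter blocks; supplying
    neither for a stage is an error raised before any compute.  Outputs
    land in ``outdir``; a stage failure renames its partial outputs with a
    ``.partial`` suffix and re-raises with the stage named.
    """
    if traces_path is None and sim_behavior is None:
        raise FamGxeError("no behavior input: give traces/meta paths or a "
                          "behavior simulation block")
    if counts_path is None and sim_counts is None:
        raise FamGxeError("no expression input: give a counts path or a "
                          "counts simulation block")
    os.makedirs(outdir, exist_ok=True)
    manifest = RunManifest(config=config.to_dict())
    for p in (traces_path, meta_path, counts_path):
        if p:
            manifest.inputs[os.path.basename(p)] = _digest(p)

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            out_paths = fn()
        except Exception:
            for f in os.listdir(outdir):
                full = os.path.join(outdir, f)
                if os.path.getmtime(full) >= t0 and not f.endswith(".partial"):
                    os.rename(full, full + ".partial")
            logger.error("stage %r failed", name)
            raise
        manifest.timings[name] = round(time.perf_counter() - t0, 4)
        for p in out_paths:
            manifest.outputs[os.path.basename(p)] = _digest(p)

    state: dict = {}

    def _simulate_or_load_behavior():
        paths = []
        if traces_path is not None:
            traces = io.read_traces(traces_path)
            meta = io.read_metadata(meta_path)
        else:
            seed = child_seed(config.seed, "simulate_behavior")
            manifest.seeds["simulate_behavior"] = seed
            params = sim_behavior
            params.seed = seed
            sim = simulate.simulate_phenotypes(params)
            traces = simulate.simulate_trace(
                sim.meta.loc[~sim.meta["excluded"]],
                seed=child_seed(config.seed, "simulate_trace"))
            meta = sim.meta[["individual_id", "family_id", "exposure",
                             "excluded"]]
            mp = os.path.join(outdir, "meta.tsv")
            io.write_results(meta, mp, sort_by="individual_id")
            paths.append(mp)
        state["traces"], state["meta"] = traces, meta
        return paths

    def _lpr():
        pheno = behavior.build_phenotype_table(state["traces"], state["meta"])
        path = os.path.join(outdir, "phenotypes.tsv")
        io.write_phenotypes(pheno, path)
        state["pheno"] = pheno
        return [path]

    def _icc():
        table = oneway.icc_by_environment(state["pheno"])
        path = os.path.join(outdir, "icc.tsv")
        io.write_results(table, path, sort_by="exposure")
        return [path]

    def _gxe():
        seed = child_seed(config.seed, "gxe_test")
        manifest.seeds["gxe_test"] = seed
        fit = gxe.fit_gxe_lmm(state["pheno"], coding=config.coding)
        res = gxe.parametric_bootstrap_ci(
            state["pheno"], coding=config.coding, n_boot=config.n_boot,
            ci_level=config.ci_level, seed=seed, fit=fit)
        path = os.path.join(outdir, "gxe_test.json")
        with open(path, "w") as fh:
            json.dump({
                "sigma2_G": fit.sigma2_G,
                "sigma2_GxE": fit.sigma2_GxE,
                "sigma2_E": fit.sigma2_E,
                "mu_hat": fit.mu_hat,
                "alpha_hat": fit.alpha_hat,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "ci_level": res.ci_level,
                "n_boot": res.n_boot,
                "n_failed_refits": res.n_failed_refits,
                "significant": res.significant,
                "coding": config.coding,
            }, fh, indent=2)
        return [path]

    def _expression():
        paths = []
        if counts_path is not None:
            cm = io.read_counts(counts_path, meta=io.read_metadata(meta_path))
        else:
            seed = child_seed(config.seed, "simulate_counts")
            manifest.seeds["simulate_counts"] = seed
            params = sim_counts
            params.seed = seed
            sim = simulate.simulate_counts(params)
            cm = sim.counts
            tp = os.path.join(outdir, "truth_labels.tsv")
            io.write_results(sim.truth, tp)
            paths.append(tp)
        cm = expression.filter_genes(cm, config.min_count, config.min_frac,
                                     strict=config.strict_filter)
        norm = expression.normalize_counts(cm, config.normalization)
        seed = child_seed(config.seed, "expression_scan")
        manifest.seeds["expression_scan"] = seed
        scan = expression.gxe_scan(norm, coding=config.coding,
                                   n_boot=config.n_boot,
                                   ci_level=config.ci_level, seed=seed)
        path = os.path.join(outdir, "gxe_scan.tsv")
        io.write_results(scan, path)
        paths.append(path)
        sig = scan.loc[scan["significant"], "gene_id"]
        sub = norm.to_frame().loc[sig]
        sub_path = os.path.join(outdir, "significant_genes_normalized.tsv")
        sub.to_csv(sub_path, sep="\t", index_label="gene_id")
        paths.append(sub_path)
        return paths

    stage("simulate_or_load", _simulate_or_load_behavior)
    stage("lpr", _lpr)
    stage("icc", _icc)
    stage("gxe_test", _gxe)
    stage("expression_scan", _expression)

    manifest_path = os.path.join(outdir, "manifest.json")
    manifest.to_json(manifest_path)
    return manifest
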