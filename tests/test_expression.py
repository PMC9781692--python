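import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famgxe import (
    CountMatrix,
    FamGxeError,
    compare_icc,
    filter_genes,
    global_apportion,
    gxe_scan,
    normalize_counts,
    per_gene_icc,
)
from famgxe.simulate import CountsSimParams, simulate_counts
from famgxe.types import ExpressionMatrix


def toy_counts(rows, n_groups=2, per_group=3):
    rows = np.atleast_2d(np.asarray(rows))
    n = rows.shape[1]
    assert n == n_groups * per_group
    labels = ["control", "medium", "high"][:n_groups]
    meta = pd.DataFrame({
        "individual_id": [f"s{j}" for j in range(n)],
        "family_id": [f"F{j // per_group}" for j in range(n)],
        "exposure": np.repeat(labels, per_group),
        "excluded": False,
    })
    return CountMatrix([f"g{i}" for i in range(rows.shape[0])],
                       [f"s{j}" for j in range(n)], rows, meta)


class TestFilterGenes:
    def test_all_zero_gene_removed(self):
        cm = toy_counts([[0, 0, 0, 0, 0, 0], [5, 30, 30, 0, 0, 0]])
        kept = filter_genes(cm)
        assert kept.gene_ids == ["g1"]

    def test_threshold_everywhere_retained(self):
        cm = toy_counts([[20, 20, 20, 20, 20, 20]])
        assert filter_genes(cm).gene_ids == ["g0"]

    def test_boundary_rule_on_toy_matrix(self):
        # one sample of three at the threshold in one group is enough
        cm = toy_counts([[19, 19, 19, 20, 19, 19],
                         [19, 19, 19, 19, 19, 19]])
        assert filter_genes(cm, min_count=20, min_frac=0.25).gene_ids == ["g0"]

    def test_strict_mode_requires_every_group(self):
        cm = toy_counts([[20, 20, 20, 19, 19, 19]])
        assert filter_genes(cm, strict=False).gene_ids == ["g0"]
        assert filter_genes(cm, strict=True).gene_ids == []

    def test_gene_order_preserved(self, rng):
        counts = rng.integers(0, 60, size=(30, 6))
        cm = toy_counts(counts)
        kept = filter_genes(cm)
        original_order = [g for g in cm.gene_ids if g in set(kept.gene_ids)]
        assert kept.gene_ids == original_order

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(10, 40),
           st.integers(20, 30), st.sampled_from([0.25, 0.5, 0.75]))
    def test_monotone_in_thresholds(self, seed, min2, min1, frac):
        rng = np.random.default_rng(seed)
        cm = toy_counts(rng.integers(0, 50, size=(15, 6)))
        lo, hi = sorted([min1, min2])
        kept_lo = set(filter_genes(cm, min_count=hi, min_frac=frac).gene_ids)
        kept_hi = set(filter_genes(cm, min_count=lo, min_frac=frac).gene_ids)
        assert kept_lo <= kept_hi
        loose = set(filter_genes(cm, min_count=hi, min_frac=0.25).gene_ids)
        tight = set(filter_genes(cm, min_count=hi, min_frac=0.75).gene_ids)
        assert tight <= loose


class TestNormalize:
    def test_cpm_proportions_single_sample(self):
        cm = CountMatrix(["a", "b", "c"], ["s1"], np.array([[1], [1], [2]]),
                         pd.DataFrame({"individual_id": ["s1"],
                                       "family_id": ["F1"],
                                       "exposure": ["control"],
                                       "excluded": [False]}))
        out = normalize_counts(cm, "cpm")
        np.testing.assert_allclose(out.values[:, 0],
                                   [250000.0, 250000.0, 500000.0])

    def test_cpm_columns_sum_to_one_million(self, rng):
        cm = toy_counts(rng.integers(0, 500, size=(40, 6)) + 1)
        out = normalize_counts(cm, "cpm")
        np.testing.assert_allclose(out.values.sum(axis=0), 1e6, rtol=1e-12)

    def test_log_cpm_formula(self):
        cm = toy_counts(np.full((4, 6), 25))
        out = normalize_counts(cm)  # default log-cpm
        np.testing.assert_allclose(out.values, np.log2(1e6 * 0.25 + 1))

    def test_median_of_ratios_factor_two(self, rng):
        base = rng.integers(10, 200, size=(50, 1))
        counts = np.hstack([base, 2 * base, base])
        cm = toy_counts(counts, n_groups=1, per_group=3)
        out = normalize_counts(cm, "median-of-ratios")
        # sample 2 has exactly double depth; size factors cancel it
        np.testing.assert_allclose(out.values[:, 1], out.values[:, 0],
                                   rtol=1e-12)

    def test_zero_library_errors_with_sample_name(self):
        cm = toy_counts([[0, 5, 5, 5, 5, 5], [0, 5, 5, 5, 5, 5]])
        with pytest.raises(FamGxeError, match="s0"):
            normalize_counts(cm)


def sim_norm(n_genes=40, seed=0, **kwargs):
    p = CountsSimParams(n_genes=n_genes, seed=seed, **kwargs)
    out = simulate_counts(p)
    return normalize_counts(filter_genes(out.counts)), out.truth


class TestPerGeneIcc:
    def test_family_constant_gene_degenerate_icc_one(self):
        # two families in one environment, expression constant within each
        meta = pd.DataFrame({
            "individual_id": [f"s{j}" for j in range(6)],
            "family_id": ["F0"] * 3 + ["F1"] * 3,
            "exposure": "control",
            "excluded": False,
        })
        values = np.array([[1.0, 1.0, 1.0, 5.0, 5.0, 5.0]])
        mat = ExpressionMatrix(["g0"], meta["individual_id"].tolist(),
                               values, meta)
        out = per_gene_icc(mat)
        assert bool(out.loc[0, "degenerate"])
        assert out.loc[0, "icc"] == 1.0

    def test_iid_noise_genes_have_small_icc(self, rng):
        n_genes, n_fam, per_fam = 500, 4, 6
        meta = pd.DataFrame({
            "individual_id": [f"s{j}" for j in range(n_fam * per_fam)],
            "family_id": [f"F{j // per_fam}" for j in range(n_fam * per_fam)],
            "exposure": "control",
            "excluded": False,
        })
        mat = ExpressionMatrix([f"g{i}" for i in range(n_genes)],
                               meta["individual_id"].tolist(),
                               rng.normal(size=(n_genes, len(meta))), meta)
        out = per_gene_icc(mat)
        assert out["icc"].median() <= 0.1

    def test_shares_sum_to_one(self):
        norm, _ = sim_norm(seed=5)
        out = per_gene_icc(norm)
        ok = ~out["degenerate"]
        np.testing.assert_allclose(
            out.loc[ok, "share_family"] + out.loc[ok, "share_residual"], 1.0,
            atol=1e-12)
        assert set(out["exposure"]) == {"control", "medium", "high"}


class TestCompareIcc:
    @staticmethod
    def icc_frame(a, b, env_a="medium", env_b="high"):
        genes = [f"g{i}" for i in range(len(a))]
        return pd.DataFrame({
            "gene_id": genes * 2,
            "exposure": [env_a] * len(a) + [env_b] * len(b),
            "icc": list(a) + list(b),
            "degenerate": False,
        })

    def test_identical_vectors_give_p_one(self):
        table = self.icc_frame([0.2, 0.3, 0.4], [0.2, 0.3, 0.4])
        with pytest.warns(UserWarning, match="all paired differences"):
            res = compare_icc(table, "medium", "high")
        assert res["p_value"] == 1.0

    def test_exact_enumeration_five_positive_pairs(self):
        # all 5 differences positive: the exact two-sided signed-rank p is
        # 2/2^5 = 1/16 (only the all-plus and all-minus assignments reach
        # rank sum 15)
        b = [0.1, 0.2, 0.3, 0.4, 0.5]
        a = [x + d for x, d in zip(b, [0.01, 0.02, 0.03, 0.04, 0.05])]
        res = compare_icc(self.icc_frame(a, b), "medium", "high")
        assert res["p_value"] == pytest.approx(1.0 / 16.0)
        assert res["n_effective"] == 5
        assert res["direction"] == "medium > high"

    def test_detects_simulated_shift(self, rng):
        base = rng.uniform(0.05, 0.6, size=1000)
        noise = rng.normal(0, 0.05, size=1000)
        shifted = np.clip(base + 0.1 + noise, 0, 1)
        res = compare_icc(self.icc_frame(shifted, base), "medium", "high")
        assert res["p_value"] < 0.01
        assert res["direction"] == "medium > high"


class TestGlobalApportion:
    def test_percentages_sum_to_100(self):
        norm, _ = sim_norm(seed=6)
        out = global_apportion(norm, "control")
        assert out.pct_gene + out.pct_family + out.pct_residual == \
            pytest.approx(100.0, abs=0.01)
        assert 0 <= out.pct_family <= 100

    def test_gene_spread_dominates_without_family_effects(self):
        norm, _ = sim_norm(n_genes=120, seed=7, baseline_log_sd=2.0)
        out = global_apportion(norm, "medium")
        assert out.pct_gene > 90.0
        assert out.pct_family <= 1.0

    def test_method_iii_close_to_reml(self):
        p = CountsSimParams(n_genes=60, frac_family_genes=0.3, seed=8)
        sim = simulate_counts(p)
        norm = normalize_counts(filter_genes(sim.counts))
        h3 = global_apportion(norm, "high", method="henderson3")
        reml = global_apportion(norm, "high", method="reml")
        assert h3.pct_gene == pytest.approx(reml.pct_gene, rel=0.05)
        assert h3.pct_residual == pytest.approx(reml.pct_residual, rel=0.05)

    def test_too_few_levels_error(self):
        norm, _ = sim_norm(seed=9)
        with pytest.raises(FamGxeError):
            global_apportion(norm, "nothere")


@pytest.fixture(scope="module")
def small_scan():
    p = CountsSimParams(n_genes=30, frac_gxe_genes=0.2,
                        gxe_sd_relative=2.0, seed=4)
    sim = simulate_counts(p)
    norm = normalize_counts(filter_genes(sim.counts))
    scan = gxe_scan(norm, coding="ordinal", n_boot=60, seed=99)
    return norm, scan


class TestGxeScan:

    def test_deterministic_under_master_seed(self, small_scan):
        norm, scan = small_scan
        again = gxe_scan(norm, coding="ordinal", n_boot=60, seed=99)
        pd.testing.assert_frame_equal(scan, again)

    def test_invariant_to_gene_order(self, small_scan):
        norm, scan = small_scan
        rev = ExpressionMatrix(norm.gene_ids[::-1], norm.sample_ids,
                               norm.values[::-1], norm.meta)
        scan_rev = gxe_scan(rev, coding="ordinal", n_boot=60, seed=99)
        merged = scan.set_index("gene_id").join(
            scan_rev.set_index("gene_id"), rsuffix="_rev")
        np.testing.assert_allclose(merged["ci_low"], merged["ci_low_rev"])
        assert (merged["significant"] == merged["significant_rev"]).all()

    def test_constant_gene_reported_unfit(self):
        meta = toy_counts(np.ones((1, 6))).meta
        values = np.vstack([np.full(6, 3.0),
                            np.array([1.0, 2.0, 1.5, 4.0, 3.0, 5.0])])
        # need >= 2 exposures for the scan model
        meta = meta.assign(exposure=["control", "control", "control",
                                     "medium", "medium", "medium"],
                           family_id=["F0", "F0", "F1", "F2", "F2", "F3"])
        mat = ExpressionMatrix(["flat", "ok"], meta["individual_id"].tolist(),
                               values, meta)
        scan = gxe_scan(mat, coding="ordinal", n_boot=10, seed=0)
        flat = scan.set_index("gene_id").loc["flat"]
        assert bool(flat["unfit"])
        assert not bool(flat["significant"])
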