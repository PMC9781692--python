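"""Per-gene GxE scan on a truth-labeled synthetic count matrix.

Simulates negative-binomial counts for 12 families x 6 larvae with 10%
of genes carrying a family-specific exposure slope, filters low-count
genes, log2-CPM normalizes, and bootstraps the interaction variance gene
by gene.  Because the generator labels which genes truly interact, the
scan's sensitivity and false-positive rate can be read off directly.
"""

from famgxe import filter_genes, gxe_scan, normalize_counts
from famgxe.simulate import CountsSimParams, simulate_counts

params = CountsSimParams(n_genes=120, frac_gxe_genes=0.10,
                         frac_family_genes=0.10, gxe_sd_relative=2.0,
                         seed=5)
sim = simulate_counts(params)
filtered = filter_genes(sim.counts)          # low-expression filter
norm = normalize_counts(filtered)            # log2-CPM

scan = gxe_scan(norm, coding="ordinal", n_boot=100, seed=5)
merged = scan.set_index("gene_id").join(sim.truth.set_index("gene_id"))
ok = merged.loc[~merged["unfit"]]
sens = ok.loc[ok["has_gxe"], "significant"].mean()
fpr = ok.loc[~ok["has_gxe"], "significant"].mean()

print(f"{filtered.n_genes} of {params.n_genes} genes pass the filter")
print(f"{int(merged['significant'].sum())} genes called significant "
      f"(95% bootstrap CI excludes zero)")
print(f"sensitivity on true-GxE genes: {sens:.2f}; "
      f"false-positive rate on null genes: {fpr:.3f}")
print("\nEach call means that gene's family-specific exposure response")
print("variance is distinguishable from zero at the 12-family design.")
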