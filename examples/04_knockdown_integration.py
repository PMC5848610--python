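"""Join binding status to knockdown differential expression.

Two analyses: the bound-vs-unbound expression contrast at active promoters,
and the down/up-regulated × bound contingency table — first on the published
worked-example counts, then on the synthetic knockdown tables where a
planted set of genes responds only to the double knockdown (redundancy).
"""

from promoter_architect import (
    classify_promoters,
    combinatorial_kd_overlap,
    de_binding_overlap,
    expression_by_binding,
    select_de_genes,
)
from promoter_architect.synthetic_data import SimConfig, generate

# Worked example: counts printed for the C4-2B knockdown contrast.
down = [f"d{i}" for i in range(1271)]
up = [f"u{i}" for i in range(1249)]
bound = set(down[:744]) | set(up[:143])
res = de_binding_overlap(down, up, bound)
print(f"worked example: {res.pct_down_bound}% of down- vs "
      f"{res.pct_up_bound}% of up-regulated genes bound "
      f"(odds ratio {res.odds_ratio:.2f}, p = {res.p_value:.2e})")
# Down-regulated genes are ~10x enriched for bound promoters: the factor
# behaves as a direct transcriptional activator.

bundle = generate(SimConfig(seed=11))
statuses = classify_promoters(
    bundle.tss, bundle.cpg_islands, bundle.peaks, bundle.expression
)
bound_genes = {s.tss.gene_id for s in statuses if "ZFX" in s.bound_by}

contrast = expression_by_binding(statuses, bundle.expression, "ZFX")
print(f"expression medians: bound {contrast.median_bound:.2f} vs "
      f"unbound {contrast.median_unbound:.2f} (rank-sum p = {contrast.p_value:.1e})")

d1, _ = select_de_genes(bundle.de_single)
d2, _ = select_de_genes(bundle.de_second_single)
dd, _ = select_de_genes(bundle.de_double)
comb = combinatorial_kd_overlap([d1, d2], dd, bound_genes)
print(f"bound genes down only in the double knockdown: {comb.n_additional} "
      f"(planted: {len(bundle.truth.redundant_genes)})")
# The second factor substitutes for the first at shared promoters; its loss
# is only visible when both are depleted.
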