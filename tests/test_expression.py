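"""Knockdown DE selection and binding-contingency statistics."""

import numpy as np
import pytest
from scipy import stats

from promoter_architect.annotate import PromoterStatus
from promoter_architect.expression_integration import (
    combinatorial_kd_overlap,
    de_binding_overlap,
    expression_by_binding,
    round_half_away,
    select_de_genes,
)
from promoter_architect.io_formats import DEGene, TssRecord


def gene(gid, lfc, fdr, expr=1.0):
    return DEGene(gid, expr, lfc, fdr)


def test_select_de_genes_thresholds():
    table = [
        gene("down", -1.0, 0.01),
        gene("weak", -0.5, 0.01),     # |FC| = 1.41 < 1.5: neither
        gene("up", 1.0, 0.01),
        gene("ns", -2.0, 0.2),        # fails FDR
        gene("edge", -np.log2(1.5), 0.01),  # strict inequality: excluded
    ]
    down, up = select_de_genes(table)
    assert [g.gene_id for g in down] == ["down"]
    assert [g.gene_id for g in up] == ["up"]


def test_select_de_genes_matches_bruteforce_filter():
    rng = np.random.default_rng(11)
    table = [
        gene(f"g{i}", float(rng.normal(0, 1.2)), float(rng.uniform(0, 1)))
        for i in range(1000)
    ]
    down, up = select_de_genes(table)
    cut = np.log2(1.5)
    brute_down = {g.gene_id for g in table if g.fdr < 0.05 and g.log2fc < -cut}
    brute_up = {g.gene_id for g in table if g.fdr < 0.05 and g.log2fc > cut}
    assert {g.gene_id for g in down} == brute_down
    assert {g.gene_id for g in up} == brute_up


def test_de_binding_overlap_reported_counts():
    """The worked example: 744 of 1271 down-regulated and 143 of 1249
    up-regulated genes bound gives 58.5% vs 11.4% and an odds ratio ~10.92."""
    down = [f"d{i}" for i in range(1271)]
    up = [f"u{i}" for i in range(1249)]
    bound = set(down[:744]) | set(up[:143])
    res = de_binding_overlap(down, up, bound)
    assert (res.pct_down_bound, res.pct_up_bound) == (58.5, 11.4)
    assert res.odds_ratio == pytest.approx((744 * 1106) / (527 * 143))
    assert res.odds_ratio == pytest.approx(10.92, abs=0.005)
    assert res.p_value < 1e-100


def test_de_binding_overlap_edge_cases():
    res = de_binding_overlap(["a"], ["b"], set())
    assert res.pct_down_bound == 0.0 and res.pct_up_bound == 0.0
    assert res.odds_ratio == 0.0
    with pytest.raises(ValueError):
        de_binding_overlap([], ["b"], set())


def test_de_binding_overlap_order_invariant():
    rng = np.random.default_rng(5)
    down = [f"d{i}" for i in range(50)]
    up = [f"u{i}" for i in range(40)]
    bound = set(rng.choice(down, 20, replace=False)) | set(rng.choice(up, 5, replace=False))
    r1 = de_binding_overlap(down, up, bound)
    r2 = de_binding_overlap(list(reversed(down)), list(reversed(up)), bound)
    assert r1 == r2


def test_rounding_convention():
    assert round_half_away(58.536, 1) == 58.5
    assert round_half_away(11.449, 1) == 11.4
    assert round_half_away(11.45, 1) == 11.5   # half away from zero, not banker's
    assert round_half_away(2.5, 0) == 3.0
    pct = round_half_away(100 * 744 / 1271)
    assert pct + (100 - pct) == 100.0


def _statuses(n_bound, n_unbound, expr):
    out = []
    for i in range(n_bound + n_unbound):
        tss = TssRecord("chr1", 1000 + i, "+", f"g{i}")
        out.append(
            PromoterStatus(tss, False, {"ZFX"} if i < n_bound else set(), True)
        )
    return out


def test_expression_by_binding_shifted_lognormal():
    rng = np.random.default_rng(21)
    expr = {}
    statuses = _statuses(500, 500, expr)
    for i in range(500):
        expr[f"g{i}"] = float(rng.lognormal(2.0, 1.0))
    for i in range(500, 1000):
        expr[f"g{i}"] = float(rng.lognormal(1.0, 1.0))
    res = expression_by_binding(statuses, expr, "ZFX")
    assert res.median_bound > res.median_unbound
    assert res.p_value < 0.05


def test_expression_by_binding_null_and_degenerate():
    expr = {f"g{i}": float(v) for i, v in enumerate([3.0, 1.0, 4.0, 1.5] * 25)}
    statuses = _statuses(50, 50, expr)
    res = expression_by_binding(statuses, expr, "ZFX")
    assert res.median_bound == res.median_unbound
    assert res.p_value > 0.5
    with pytest.raises(ValueError):
        expression_by_binding(_statuses(1, 50, expr), {f"g{i}": 1.0 for i in range(51)}, "ZFX")


def test_combinatorial_kd_examples():
    bound = {"a", "b", "c", "d", "e", "f", "g"}
    single = [{"a", "b"}, {"c"}]
    assert combinatorial_kd_overlap(single, {"a", "b", "c"}, bound).n_additional == 0
    res = combinatorial_kd_overlap(single, {"a", "b", "c", "d", "e", "f", "g", "zz"}, bound)
    assert res.n_additional == 4
    assert res.additional_bound_down == {"d", "e", "f", "g"}
    assert res.membership["double_and_single"] == {"a", "b", "c"}


def test_combinatorial_kd_recovers_planted_redundancy(default_bundle):
    """The generator plants a fixed set of bound genes down-regulated only in
    the double knockdown; the set difference recovers exactly that set."""
    b = default_bundle
    bound = b.truth.bound_genes
    down_single, _ = select_de_genes(b.de_single)
    down_second, _ = select_de_genes(b.de_second_single)
    down_double, _ = select_de_genes(b.de_double)
    res = combinatorial_kd_overlap(
        [down_single, down_second], down_double, bound
    )
    planted = b.truth.redundant_genes
    # the tiny second-factor knockdown response can steal a planted gene
    assert res.additional_bound_down == planted - {
        g.gene_id for g in down_second
    }


def test_pct_complement_closes_to_100():
    res = de_binding_overlap([f"d{i}" for i in range(7)], ["u0"], {"d0", "d1", "d2"})
    assert res.pct_down_bound + round_half_away(100 - res.pct_down_bound) == 100.0
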