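"""Binding × expression integration.

Joins promoter binding status to expression and knockdown
differential-expression tables: the bound-vs-unbound expression contrast at
active promoters, down/up-regulated × bound contingency statistics, and the
extra bound-down genes revealed by a combinatorial (double) knockdown.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from math import log2
from typing import Iterable, Mapping, Sequence, Set

import numpy as np
from scipy import stats

from promoter_architect.io_formats import DEGene
from promoter_architect.annotate import PromoterStatus


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention used for reported
    percentages; Python's round() is banker's rounding)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ExpressionContrast:
    bound: np.ndarray
    unbound: np.ndarray
    median_bound: float
    median_unbound: float
    p_value: float


def expression_by_binding(
    promoter_statuses: Sequence[PromoterStatus],
    expression: Mapping[str, float],
    factor: str,
) -> ExpressionContrast:
    """Expression of genes with active promoters bound by ``factor`` versus
    active promoters not bound, with a two-sided rank-sum p-value.

    Restricted to active promoters; either group having fewer than two genes
    is an error (the contrast is undefined).
    """
    bound, unbound = [], []
    for ps in promoter_statuses:
        if not ps.is_active:
            continue
        expr = expression.get(ps.tss.gene_id)
        if expr is None:
            continue
        (bound if factor in ps.bound_by else unbound).append(expr)
    if len(bound) < 2 or len(unbound) < 2:
        raise ValueError(
            f"expression_by_binding needs >= 2 genes per group "
            f"(bound={len(bound)}, unbound={len(unbound)})"
        )
    b, u = np.asarray(bound, float), np.asarray(unbound, float)
    _, p = stats.mannwhitneyu(b, u, alternative="two-sided")
    return ExpressionContrast(b, u, float(np.median(b)), float(np.median(u)), float(p))


def select_de_genes(
    de_table: Sequence[DEGene],
    fdr_max: float = 0.05,
    min_abs_fc: float = 1.5,
) -> tuple[list[DEGene], list[DEGene]]:
    """Split a knockdown contrast into (down, up) gene lists.

    Down: fdr < fdr_max and fold change < 1/min_abs_fc (log2fc < −log2(1.5));
    up: fdr < fdr_max and log2fc > +log2(1.5). Both thresholds strict.
    """
    cut = log2(min_abs_fc)
    down = [g for g in de_table if g.fdr < fdr_max and g.log2fc < -cut]
    up = [g for g in de_table if g.fdr < fdr_max and g.log2fc > cut]
    return down, up


@dataclass
class DEOverlapResult:
    n_down: int
    n_up: int
    n_down_bound: int
    n_up_bound: int
    pct_down_bound: float
    pct_up_bound: float
    odds_ratio: float
    p_value: float


def de_binding_overlap(
    down: Iterable,
    up: Iterable,
    bound_gene_set: Set[str],
    test: str = "fisher",
) -> DEOverlapResult:
    """Fraction of down- and up-regulated genes whose promoters are bound.

    Builds the 2×2 table with rows (down, up) and columns (bound, unbound);
    odds ratio is (a·d)/(b·c) on that table and the p-value comes from a
    two-sided Fisher exact test (``test="hypergeom"`` gives the one-sided
    hypergeometric enrichment p instead). Percentages are rounded to one
    decimal, half away from zero, at reporting only.
    """
    down_ids = [g.gene_id if isinstance(g, DEGene) else g for g in down]
    up_ids = [g.gene_id if isinstance(g, DEGene) else g for g in up]
    n_down, n_up = len(down_ids), len(up_ids)
    if n_down == 0 or n_up == 0:
        raise ValueError("de_binding_overlap: empty down or up gene list")
    a = sum(1 for g in down_ids if g in bound_gene_set)   # down, bound
    b = n_down - a                                         # down, unbound
    c = sum(1 for g in up_ids if g in bound_gene_set)      # up, bound
    d = n_up - c                                           # up, unbound
    if b * c == 0:
        odds = 0.0 if a * d == 0 else float("inf")
    else:
        odds = (a * d) / (b * c)
    table = [[a, b], [c, d]]
    if test == "fisher":
        _, p = stats.fisher_exact(table, alternative="two-sided")
    elif test == "hypergeom":
        # enrichment of bound among down-regulated genes
        p = stats.hypergeom.sf(a - 1, n_down + n_up, a + c, n_down)
    else:
        raise ValueError(f"unknown test {test!r}")
    return DEOverlapResult(
        n_down=n_down,
        n_up=n_up,
        n_down_bound=a,
        n_up_bound=c,
        pct_down_bound=round_half_away(100.0 * a / n_down),
        pct_up_bound=round_half_away(100.0 * c / n_up),
        odds_ratio=float(odds),
        p_value=float(p),
    )


@dataclass
class CombinatorialKDResult:
    additional_bound_down: set
    n_additional: int
    membership: dict  # region -> gene set of the bound-down three-way split


def combinatorial_kd_overlap(
    single_kd_down: Sequence[Iterable],
    double_kd_down: Iterable,
    bound_gene_set: Set[str],
) -> CombinatorialKDResult:
    """Bound down-regulated genes seen only in the double knockdown.

    ``single_kd_down`` is the list of per-factor single-knockdown
    down-regulated gene collections; the result is the set of bound genes
    down in the double knockdown but in none of the singles (the redundancy
    signature), plus the three-way membership table over bound-down genes.
    """
    def ids(genes):
        return {g.gene_id if isinstance(g, DEGene) else g for g in genes}

    singles = [ids(s) for s in single_kd_down]
    double = ids(double_kd_down)
    union_single = set().union(*singles) if singles else set()
    bound_double = double & bound_gene_set
    additional = bound_double - union_single
    membership = {
        "double_only": additional,
        "double_and_single": bound_double & union_single,
        "single_only": (union_single & bound_gene_set) - double,
    }
    return CombinatorialKDResult(additional, len(additional), membership)
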