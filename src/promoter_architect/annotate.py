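"""Peak and promoter annotation.

Assigns each ChIP-seq peak to exactly one genomic category — promoter
(overlapping a ±2 kb TSS window), distal enhancer (H3K27ac), distal insulator
(CTCF not in an enhancer) or other — and classifies promoters by CpG-island
status, binding and activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from promoter_architect.io_formats import (
    GenomicInterval,
    Peak,
    TssRecord,
)

log = logging.getLogger(__name__)

CATEGORIES = ("promoter", "distal_enhancer", "distal_insulator", "other")


@dataclass
class PeakAnnotation:
    peak: Peak
    category: str
    nearest_tss: str | None = None
    signed_offset: int | None = None


@dataclass
class PromoterStatus:
    tss: TssRecord
    is_cpg_island: bool
    bound_by: set = field(default_factory=set)
    is_active: bool | None = None  # None when expression is unavailable


def promoter_window(tss: TssRecord, half_width: int = 2000) -> GenomicInterval:
    """±half_width window around the TSS, left-clipped at 0.

    The window is strand-symmetric; the strand is carried along so that
    downstream consumers can orient offsets.
    """
    if half_width <= 0:
        raise ValueError("half_width must be > 0")
    return GenomicInterval(
        tss.chrom,
        max(0, tss.pos - half_width),
        tss.pos + half_width,
        tss.strand,
        tss.gene_id,
    )


def _interval_tree(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for i, iv in enumerate(intervals):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)
    return trees


def _peak_intervals(peaks: Sequence[Peak] | Sequence[GenomicInterval]) -> list[GenomicInterval]:
    return [p.interval if isinstance(p, Peak) else p for p in peaks]


def _overlaps_any(trees: dict[str, IntervalTree], iv: GenomicInterval) -> bool:
    tree = trees.get(iv.chrom)
    return bool(tree is not None and tree.overlap(iv.start, iv.end))


def nearest_tss_assignment(
    peak: Peak, tss_by_chrom: Mapping[str, list[TssRecord]]
) -> tuple[str | None, int | None]:
    """Nearest TSS by summit distance; equidistant ties break toward the
    5'-most (lowest-coordinate) TSS. Returns (gene_id, signed offset) where
    the offset is summit − TSS, sign-flipped on − strand so that positive
    means downstream in the direction of transcription."""
    candidates = tss_by_chrom.get(peak.interval.chrom)
    if not candidates:
        return None, None
    summit = peak.summit
    best = min(candidates, key=lambda t: (abs(summit - t.pos), t.pos))
    offset = summit - best.pos
    if best.strand == "-":
        offset = -offset
    return best.gene_id, offset


def classify_peaks(
    peaks: Sequence[Peak],
    tss_list: Sequence[TssRecord],
    enhancer_peaks: Sequence[Peak] | Sequence[GenomicInterval] = (),
    insulator_peaks: Sequence[Peak] | Sequence[GenomicInterval] = (),
    half_width: int = 2000,
    summit_only: bool = False,
) -> list[PeakAnnotation]:
    """Partition peaks into promoter / distal_enhancer / distal_insulator / other.

    Priority: a peak overlapping any promoter window is a promoter regardless
    of other marks; a distal peak overlapping an H3K27ac (enhancer) region is
    a distal enhancer even when CTCF is also present; a distal insulator
    requires CTCF overlap and *no* enhancer overlap.

    Parameters
    ----------
    summit_only:
        When True, promoter assignment requires the summit itself to fall in
        a window rather than any-bp overlap of the whole peak.
    """
    if not tss_list:
        raise ValueError("classify_peaks requires a non-empty TSS list")
    windows = [promoter_window(t, half_width) for t in tss_list]
    window_trees = _interval_tree(windows)
    enhancer_trees = _interval_tree(_peak_intervals(enhancer_peaks))
    insulator_trees = _interval_tree(_peak_intervals(insulator_peaks))

    tss_by_chrom: dict[str, list[TssRecord]] = {}
    for t in tss_list:
        tss_by_chrom.setdefault(t.chrom, []).append(t)

    out = []
    for peak in peaks:
        iv = peak.interval
        if summit_only:
            s = peak.summit
            probe = GenomicInterval(iv.chrom, s, s + 1)
        else:
            probe = iv
        if _overlaps_any(window_trees, probe):
            category = "promoter"
        elif _overlaps_any(enhancer_trees, iv):
            category = "distal_enhancer"
        elif _overlaps_any(insulator_trees, iv):
            category = "distal_insulator"
        else:
            category = "other"
        gene, offset = nearest_tss_assignment(peak, tss_by_chrom)
        out.append(PeakAnnotation(peak, category, gene, offset))
    return out


def classify_promoters(
    tss_list: Sequence[TssRecord],
    cpg_islands: Sequence[GenomicInterval],
    peaks_by_factor: Mapping[str, Sequence[Peak]],
    expression: Mapping[str, float] | None = None,
    active_threshold: float = 0.0,
    half_width: int = 2000,
) -> list[PromoterStatus]:
    """Classify each promoter by CpG-island status, binding and activity.

    A promoter is CpG-island if its TSS position falls inside an island
    interval (point test, not the whole window). ``bound_by`` contains factor
    F iff some F peak overlaps the ±half_width window. ``is_active`` is
    expression > active_threshold; promoters missing from the expression
    table get ``is_active = None`` with a warning.
    """
    island_trees = _interval_tree(cpg_islands)
    factor_trees = {
        factor: _interval_tree(_peak_intervals(peaks))
        for factor, peaks in peaks_by_factor.items()
    }
    missing = []
    out = []
    for tss in tss_list:
        window = promoter_window(tss, half_width)
        point = GenomicInterval(tss.chrom, tss.pos, tss.pos + 1)
        is_island = _overlaps_any(island_trees, point)
        tss.is_cpg_island = is_island
        bound = {
            factor
            for factor, trees in factor_trees.items()
            if _overlaps_any(trees, window)
        }
        if expression is None:
            active = None
        elif tss.gene_id in expression:
            active = expression[tss.gene_id] > active_threshold
        else:
            active = None
            missing.append(tss.gene_id)
        out.append(PromoterStatus(tss, is_island, bound, active))
    if missing:
        log.warning(
            "%d promoters missing from the expression table (is_active unset), e.g. %s",
            len(missing),
            missing[:5],
        )
    return out


@dataclass
class OverlapResult:
    fraction: float
    n_a: int
    n_a_overlapping: int
    n_a_unique: int
    n_b: int
    n_b_overlapping: int
    n_b_unique: int


def peak_set_overlap(
    a: Sequence[Peak] | Sequence[GenomicInterval],
    b: Sequence[Peak] | Sequence[GenomicInterval],
) -> OverlapResult:
    """Fraction of intervals in ``a`` sharing >= 1 bp with any interval in ``b``.

    Also reports the reciprocal counts so Venn-style summaries can be built
    from one call.
    """
    ivs_a = _peak_intervals(a)
    ivs_b = _peak_intervals(b)
    if not ivs_a:
        raise ValueError("peak_set_overlap: set a is empty; fraction undefined")
    trees_b = _interval_tree(ivs_b)
    trees_a = _interval_tree(ivs_a)
    n_a_hit = sum(1 for iv in ivs_a if _overlaps_any(trees_b, iv))
    n_b_hit = sum(1 for iv in ivs_b if _overlaps_any(trees_a, iv))
    return OverlapResult(
        fraction=n_a_hit / len(ivs_a),
        n_a=len(ivs_a),
        n_a_overlapping=n_a_hit,
        n_a_unique=len(ivs_a) - n_a_hit,
        n_b=len(ivs_b),
        n_b_overlapping=n_b_hit,
        n_b_unique=len(ivs_b) - n_b_hit,
    )
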