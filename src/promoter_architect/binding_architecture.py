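"""Summit-to-TSS binding architecture.

Where does a factor sit relative to the start sites it binds? This module
computes signed summit offsets (downstream positive), restricts to promoters
with a single TSS in the window (so bidirectional promoters cannot masquerade
as upstream binding), clusters promoters into upstream-only / downstream-only
/ both classes, and builds average-signal metaplots and between-sample tag
correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from sklearn.cluster import KMeans

from promoter_architect.io_formats import Peak, SignalPoint, TssRecord

log = logging.getLogger(__name__)

CLUSTER_LABELS = ("upstream_only", "downstream_only", "both")


@dataclass
class PromoterArchitecture:
    tss: TssRecord
    summit_offsets: list[int] = field(default_factory=list)
    cluster: str | None = None


@dataclass
class Metaplot:
    offsets: np.ndarray      # bin-center grid, symmetric about 0
    mean_signal: np.ndarray
    n_anchors: int


def summit_offsets(
    peaks: Sequence[Peak],
    tss_list: Sequence[TssRecord],
    half_width: int = 2000,
) -> list[tuple[str, int]]:
    """Signed summit−TSS offsets, one per (peak, promoter) pair whose summit
    lies within ±half_width of the TSS.

    The sign is flipped for − strand TSSs so positive always means downstream
    in transcription direction. Peaks without a called summit fall back to
    the interval midpoint (logged).
    """
    n_fallback = sum(1 for p in peaks if not p.has_summit)
    if n_fallback:
        log.info("%d peaks without summits use the interval midpoint", n_fallback)
    summits: dict[str, list[int]] = {}
    for p in peaks:
        summits.setdefault(p.interval.chrom, []).append(p.summit)
    arrays = {c: np.array(sorted(v)) for c, v in summits.items()}

    out: list[tuple[str, int]] = []
    for tss in tss_list:
        arr = arrays.get(tss.chrom)
        if arr is None:
            continue
        lo = np.searchsorted(arr, tss.pos - half_width, side="left")
        hi = np.searchsorted(arr, tss.pos + half_width, side="right")
        for s in arr[lo:hi]:
            off = int(s) - tss.pos
            if tss.strand == "-":
                off = -off
            if abs(off) <= half_width:
                out.append((tss.gene_id, off))
    return out


def select_single_tss_promoters(
    tss_list: Sequence[TssRecord], half_width: int = 2000
) -> list[TssRecord]:
    """Keep a TSS iff no other TSS lies within ±half_width of it on the same
    chromosome (both members of a close pair are dropped)."""
    by_chrom: dict[str, list[TssRecord]] = {}
    for t in tss_list:
        by_chrom.setdefault(t.chrom, []).append(t)
    keep = []
    for chrom, recs in by_chrom.items():
        recs = sorted(recs, key=lambda t: t.pos)
        pos = [t.pos for t in recs]
        for i, t in enumerate(recs):
            left_ok = i == 0 or t.pos - pos[i - 1] > half_width
            right_ok = i == len(recs) - 1 or pos[i + 1] - t.pos > half_width
            if left_ok and right_ok:
                keep.append(t)
    order = {id(t): i for i, t in enumerate(tss_list)}
    return sorted(keep, key=lambda t: order[id(t)])


def build_architectures(
    peaks: Sequence[Peak],
    tss_list: Sequence[TssRecord],
    half_width: int = 2000,
) -> list[PromoterArchitecture]:
    """Group summit offsets per promoter (promoters with no in-window summit
    are omitted)."""
    offsets = summit_offsets(peaks, tss_list, half_width)
    per_gene: dict[str, list[int]] = {}
    for gene, off in offsets:
        per_gene.setdefault(gene, []).append(off)
    by_gene = {t.gene_id: t for t in tss_list}
    return [
        PromoterArchitecture(by_gene[g], sorted(offs))
        for g, offs in per_gene.items()
    ]


def cluster_promoters(
    architectures: Sequence[PromoterArchitecture],
    method: str = "rule",
    boundary: int = 50,
    half_width: int = 2000,
    bin_size: int = 100,
    seed: int = 0,
) -> dict[str, str]:
    """Label each promoter upstream_only / downstream_only / both.

    rule
        upstream_only when every summit offset < −boundary, downstream_only
        when every offset > +boundary, both otherwise. Offsets within the
        ±boundary dead zone straddle the TSS and force "both".
    kmeans
        k=3 k-means (10 restarts, seeded) on per-promoter binned offset
        histograms; clusters are mapped to the three labels by the sign of
        their mean offset.

    Returns {gene_id: label}; promoters with no offsets are excluded and
    logged.
    """
    archs = [a for a in architectures if a.summit_offsets]
    n_empty = len(architectures) - len(archs)
    if n_empty:
        log.info("%d promoters with no summit offsets excluded from clustering", n_empty)
    if method == "rule":
        labels = {}
        for a in archs:
            if all(o < -boundary for o in a.summit_offsets):
                lab = "upstream_only"
            elif all(o > boundary for o in a.summit_offsets):
                lab = "downstream_only"
            else:
                lab = "both"
            a.cluster = lab
            labels[a.tss.gene_id] = lab
        return labels
    if method == "kmeans":
        if len(archs) < 3:
            raise ValueError("kmeans clustering needs >= 3 promoters")
        edges = np.arange(-half_width, half_width + bin_size, bin_size)
        X = np.stack(
            [np.histogram(a.summit_offsets, bins=edges)[0] for a in archs]
        ).astype(float)
        # smooth each promoter's offset histogram (peaks are point events;
        # without smoothing, one-hot rows in different bins are all
        # equidistant and k-means cannot see positional nearness), then
        # L1-normalize so two-peak promoters are not split off by total count
        k = np.exp(-0.5 * (np.arange(-4, 5) / 1.5) ** 2)
        X = np.apply_along_axis(lambda r: np.convolve(r, k, mode="same"), 1, X)
        X /= np.maximum(X.sum(axis=1, keepdims=True), 1e-12)
        km = KMeans(n_clusters=3, n_init=10, random_state=seed).fit(X)
        mean_off = np.array(
            [
                np.mean([np.mean(a.summit_offsets) for a, l in zip(archs, km.labels_) if l == k])
                if np.any(km.labels_ == k) else 0.0
                for k in range(3)
            ]
        )
        mapping = {}
        for k in range(3):
            if mean_off[k] < -boundary:
                mapping[k] = "upstream_only"
            elif mean_off[k] > boundary:
                mapping[k] = "downstream_only"
            else:
                mapping[k] = "both"
        labels = {}
        for a, l in zip(archs, km.labels_):
            a.cluster = mapping[int(l)]
            labels[a.tss.gene_id] = a.cluster
        return labels
    raise ValueError(f"unknown clustering method {method!r}")


def cluster_fractions(labels: Mapping[str, str]) -> dict[str, float]:
    n = len(labels)
    if n == 0:
        return {lab: 0.0 for lab in CLUSTER_LABELS}
    return {
        lab: sum(1 for v in labels.values() if v == lab) / n for lab in CLUSTER_LABELS
    }


# ---------------------------------------------------------------------------
# metaplots
# ---------------------------------------------------------------------------

def _as_anchor(a) -> tuple[str, int, str]:
    if isinstance(a, TssRecord):
        return a.chrom, a.pos, a.strand
    chrom, pos, strand = a
    return chrom, int(pos), strand


def metaplot(
    signal: Sequence[SignalPoint],
    anchors: Sequence,
    half_width: int = 2000,
    bin_size: int = 20,
) -> Metaplot:
    """Per-bin mean signal over stranded anchors, oriented downstream-positive.

    Each anchor contributes a ±half_width per-base vector (zero where the
    track has no value — absence of signal is zero coverage, not missing
    data), strand-flipped, then averaged across anchors and within bins.
    Signal records within a track are assumed non-overlapping.
    """
    if (2 * half_width) % bin_size != 0:
        raise ValueError("bin size does not divide the window width")
    trees: dict[str, IntervalTree] = {}
    for s in signal:
        trees.setdefault(s.chrom, IntervalTree()).addi(s.start, s.end, s.value)

    width = 2 * half_width
    total = np.zeros(width, dtype=float)
    n_anchors = 0
    for a in anchors:
        chrom, pos, strand = _as_anchor(a)
        n_anchors += 1
        vec = np.zeros(width, dtype=float)
        tree = trees.get(chrom)
        lo, hi = pos - half_width, pos + half_width
        if tree is not None:
            for iv in tree.overlap(lo, hi):
                a0 = max(iv.begin, lo) - lo
                a1 = min(iv.end, hi) - lo
                vec[a0:a1] = iv.data
        if strand == "-":
            vec = vec[::-1]
        total += vec
    if n_anchors == 0:
        raise ValueError("metaplot requires >= 1 anchor")
    per_base = total / n_anchors
    n_bins = width // bin_size
    binned = per_base.reshape(n_bins, bin_size).mean(axis=1)
    centers = np.arange(-half_width, half_width, bin_size) + bin_size / 2.0
    return Metaplot(centers, binned, n_anchors)


def tag_correlation(count_matrix) -> pd.DataFrame:
    """Pairwise Spearman correlation between samples (columns) over shared
    regions (rows).

    Ties are mid-ranked; zero-variance samples get NaN against every other
    sample (correlation undefined) but 1.0 on the diagonal.
    """
    df = pd.DataFrame(count_matrix)
    if df.shape[0] < 3:
        raise ValueError("tag_correlation requires >= 3 regions")
    corr = df.corr(method="spearman")
    constant = df.std(ddof=0) == 0
    for col in df.columns[constant]:
        corr.loc[col, :] = np.nan
        corr.loc[:, col] = np.nan
    np.fill_diagonal(corr.values, 1.0)
    return corr
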