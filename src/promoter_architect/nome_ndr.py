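"""NOMe-seq accessibility analysis: NDR calling and methylation metaplots.

In NOMe-seq, an exogenous GpC methyltransferase marks accessible chromatin,
so elevated GCH methylation flags nucleosome-depleted regions (NDRs), while
HCG methylation reports endogenous CpG methylation. The caller slides a
window over GCH calls, tests pooled counts against the genome-wide
background rate with a one-sided binomial test, BH-adjusts across windows,
merges significant windows, and keeps merged regions at least 140 bp long.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from promoter_architect.binding_architecture import Metaplot
from promoter_architect.io_formats import GenomicInterval, MethylCall, Peak, TssRecord

log = logging.getLogger(__name__)


@dataclass
class NDR:
    """A nucleosome-depleted region: GCH methylation elevated over background
    across >= min_length bp."""

    interval: GenomicInterval
    mean_gch: float
    background_gch: float
    q_value: float

    def __post_init__(self):
        if not self.mean_gch > self.background_gch:
            raise ValueError("NDR requires mean_gch > background_gch")


def methylation_level(
    calls: Sequence[MethylCall], window: GenomicInterval, context: str
) -> float | None:
    """Pooled methylation (sum methylated / sum total) of in-window calls of
    one context; None when the window has no such calls."""
    if context not in {"HCG", "GCH"}:
        raise ValueError("context must be HCG or GCH")
    k = n = 0
    for c in calls:
        if (
            c.context == context
            and c.chrom == window.chrom
            and window.start <= c.pos < window.end
        ):
            k += c.n_methylated
            n += c.n_total
    if n == 0:
        return None
    return k / n


def pooled_background(calls: Sequence[MethylCall], context: str = "GCH") -> float:
    """Genome-wide pooled methylation rate for one context."""
    k = sum(c.n_methylated for c in calls if c.context == context)
    n = sum(c.n_total for c in calls if c.context == context)
    if n == 0:
        raise ValueError(f"no {context} calls; background undefined")
    return k / n


def call_ndrs(
    calls: Sequence[MethylCall],
    min_length: int = 140,
    window: int = 100,
    step: int = 20,
    q_max: float = 0.05,
    min_calls: int = 3,
    background: float | None = None,
    trim_call_alpha: float = 0.05,
    trim_min_run: int = 3,
) -> list[NDR]:
    """Call NDRs from GCH accessibility calls.

    Procedure: background = genome-wide pooled GCH rate (unless given);
    slide a ``window``-bp window by ``step`` over each chromosome's calls;
    windows with >= ``min_calls`` calls get a one-sided binomial test of
    pooled methylated counts against the background rate; BH-adjust across
    all tested windows; merge significant windows that overlap or sit within
    one step; trim each merged span to the outermost run of
    >= ``trim_min_run`` consecutive calls individually above background
    (per-call binomial p < ``trim_call_alpha``), so isolated noisy calls
    cannot stretch a region; keep regions >= ``min_length`` bp. Deterministic.
    """
    gch = sorted(
        (c for c in calls if c.context == "GCH"), key=lambda c: (c.chrom, c.pos)
    )
    if not gch:
        return []
    bg = pooled_background(gch) if background is None else background

    by_chrom: dict[str, list[MethylCall]] = {}
    for c in gch:
        by_chrom.setdefault(c.chrom, []).append(c)

    # sliding-window binomial scan, vectorized per chromosome
    win_records = []  # (chrom, start, end, k, n)
    pvals = []
    for chrom, cs in by_chrom.items():
        pos = np.array([c.pos for c in cs])
        meth = np.array([c.n_methylated for c in cs])
        tot = np.array([c.n_total for c in cs])
        cm = np.concatenate([[0], np.cumsum(meth)])
        ct = np.concatenate([[0], np.cumsum(tot)])
        starts = np.arange(pos[0] - window + 1, pos[-1] + 1, step)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window, side="left")
        n_calls = hi - lo
        ok = n_calls >= min_calls
        if n_calls[~ok].sum() and (~ok & (n_calls > 0)).any():
            log.debug(
                "%s: %d windows skipped with <%d calls",
                chrom, int((~ok & (n_calls > 0)).sum()), min_calls,
            )
        k = cm[hi[ok]] - cm[lo[ok]]
        n = ct[hi[ok]] - ct[lo[ok]]
        p = stats.binom.sf(k - 1, n, bg)  # P(X >= k) under background
        for s, kk, nn, pp in zip(starts[ok], k, n, p):
            win_records.append((chrom, int(s), int(s) + window, int(kk), int(nn)))
            pvals.append(pp)
    if not win_records:
        return []

    reject, qvals, _, _ = multipletests(pvals, alpha=q_max, method="fdr_bh")
    sig = [
        (rec, q)
        for rec, q, rej in zip(win_records, qvals, reject)
        if rej and rec[3] / rec[4] > bg
    ]
    if not sig:
        return []

    # merge significant windows (overlapping or within one step)
    sig.sort(key=lambda item: (item[0][0], item[0][1]))
    merged: list[list] = []  # [chrom, start, end, min_q]
    for (chrom, s, e, _, _), q in sig:
        if merged and merged[-1][0] == chrom and s <= merged[-1][2] + step:
            merged[-1][2] = max(merged[-1][2], e)
            merged[-1][3] = min(merged[-1][3], q)
        else:
            merged.append([chrom, s, e, q])

    out: list[NDR] = []
    for chrom, s, e, q in merged:
        cs = [c for c in by_chrom[chrom] if s <= c.pos < e]
        span = _trim_to_elevated_run(cs, bg, trim_call_alpha, trim_min_run)
        if span is None:
            continue
        lo_pos, hi_pos = span
        length = hi_pos - lo_pos + 1
        if length < min_length:
            continue
        k = sum(c.n_methylated for c in cs if lo_pos <= c.pos <= hi_pos)
        n = sum(c.n_total for c in cs if lo_pos <= c.pos <= hi_pos)
        mean_gch = k / n if n else 0.0
        if not mean_gch > bg:
            continue
        out.append(
            NDR(
                GenomicInterval(chrom, lo_pos, hi_pos + 1, ".", "NDR", float(mean_gch)),
                mean_gch=float(mean_gch),
                background_gch=float(bg),
                q_value=float(q),
            )
        )
    return out


def _trim_to_elevated_run(
    calls: Sequence[MethylCall], bg: float, alpha: float, min_run: int
) -> tuple[int, int] | None:
    """Outermost positions of runs of >= min_run consecutive calls each
    individually above background (one-sided binomial p < alpha)."""
    flags = [
        stats.binomtest(c.n_methylated, c.n_total, bg, alternative="greater").pvalue < alpha
        for c in calls
    ]
    first = last = None
    run = 0
    for i, f in enumerate(flags):
        run = run + 1 if f else 0
        if run >= min_run:
            if first is None:
                first = calls[i - run + 1].pos
            last = calls[i].pos
    if first is None:
        return None
    return first, last


def peak_ndr_overlap(
    peaks: Sequence[Peak],
    ndrs: Sequence[NDR] | Sequence[GenomicInterval],
    signed_offsets: Sequence[int | None] | None = None,
    offset_range: tuple[int, int] | None = (140, 340),
) -> float:
    """Fraction of peaks sharing >= 1 bp with any NDR.

    When ``signed_offsets`` (per-peak summit-to-TSS offsets, downstream
    positive) are given, the peak set is first restricted to summits "near
    +240" — offsets inside ``offset_range`` (default [140, 340]). An empty
    filtered set is an error.
    """
    if signed_offsets is not None and offset_range is not None:
        if len(signed_offsets) != len(peaks):
            raise ValueError("signed_offsets must parallel peaks")
        lo, hi = offset_range
        peaks = [
            p
            for p, off in zip(peaks, signed_offsets)
            if off is not None and lo <= off <= hi
        ]
    if not peaks:
        raise ValueError("peak_ndr_overlap: no peaks after summit filtering")
    intervals = [n.interval if isinstance(n, NDR) else n for n in ndrs]
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    n_hit = 0
    for p in peaks:
        iv = p.interval
        for s, e in by_chrom.get(iv.chrom, ()):
            if iv.start < e and s < iv.end:
                n_hit += 1
                break
    return n_hit / len(peaks)


def nome_metaplot(
    calls: Sequence[MethylCall],
    anchors: Sequence[TssRecord],
    half_width: int = 1000,
    bin_size: int = 20,
) -> tuple[Metaplot, Metaplot]:
    """Per-bin pooled HCG and GCH methylation across stranded anchors,
    oriented downstream-positive.

    Bins with no calls are NaN. Returns (HCG metaplot, GCH metaplot).
    """
    if (2 * half_width) % bin_size != 0:
        raise ValueError("bin size does not divide the window width")
    n_bins = (2 * half_width) // bin_size
    k = {ctx: np.zeros(n_bins) for ctx in ("HCG", "GCH")}
    n = {ctx: np.zeros(n_bins) for ctx in ("HCG", "GCH")}

    by_chrom: dict[str, list[MethylCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda c: c.pos)
    pos_arrays = {
        chrom: np.array([c.pos for c in cs]) for chrom, cs in by_chrom.items()
    }

    n_anchors = 0
    for tss in anchors:
        n_anchors += 1
        cs = by_chrom.get(tss.chrom)
        if not cs:
            continue
        pos = pos_arrays[tss.chrom]
        lo = np.searchsorted(pos, tss.pos - half_width, side="left")
        hi = np.searchsorted(pos, tss.pos + half_width, side="left")
        for c in cs[lo:hi]:
            off = c.pos - tss.pos
            if tss.strand == "-":
                off = -off
            if not (-half_width <= off < half_width):
                continue
            b = (off + half_width) // bin_size
            k[c.context][b] += c.n_methylated
            n[c.context][b] += c.n_total
    centers = np.arange(-half_width, half_width, bin_size) + bin_size / 2.0
    plots = []
    for ctx in ("HCG", "GCH"):
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(n[ctx] > 0, k[ctx] / np.maximum(n[ctx], 1), np.nan)
        plots.append(Metaplot(centers, mean, n_anchors))
    return plots[0], plots[1]
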