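"""Peak categorisation, promoter classing and interval-set overlap."""

import numpy as np
import pytest

from promoter_architect.annotate import (
    classify_peaks,
    classify_promoters,
    peak_set_overlap,
    promoter_window,
)
from promoter_architect.io_formats import GenomicInterval, Peak, TssRecord


def mk_peak(chrom, start, end, summit=None):
    return Peak(GenomicInterval(chrom, start, end), summit)


def test_promoter_window_basic_and_clipped():
    t = TssRecord("chr1", 5000, "+", "g")
    w = promoter_window(t)
    assert (w.start, w.end) == (3000, 7000)
    w = promoter_window(TssRecord("chr1", 500, "+", "g"))
    assert (w.start, w.end) == (0, 2500)
    # the window is strand-symmetric; strand is carried
    w = promoter_window(TssRecord("chr1", 5000, "-", "g"))
    assert (w.start, w.end, w.strand) == (3000, 7000, "-")
    with pytest.raises(ValueError):
        promoter_window(t, 0)


def test_classify_peaks_priority_order():
    tss = [TssRecord("chr1", 10_000, "+", "g1")]
    enhancers = [GenomicInterval("chr1", 9_000, 9_500), GenomicInterval("chr1", 50_000, 51_000)]
    insulators = [GenomicInterval("chr1", 50_200, 50_600), GenomicInterval("chr1", 70_000, 70_500)]
    peaks = [
        mk_peak("chr1", 9_100, 9_400),     # promoter window AND enhancer -> promoter
        mk_peak("chr1", 50_100, 50_400),   # CTCF AND H3K27ac, distal -> enhancer
        mk_peak("chr1", 70_100, 70_300),   # CTCF only, distal -> insulator
        mk_peak("chr1", 200_000, 200_300),
    ]
    cats = [a.category for a in classify_peaks(peaks, tss, enhancers, insulators)]
    assert cats == ["promoter", "distal_enhancer", "distal_insulator", "other"]


def test_classify_peaks_empty_tss_is_error():
    with pytest.raises(ValueError):
        classify_peaks([mk_peak("chr1", 0, 100)], [])


def test_classify_peaks_partition_and_order_invariance():
    rng = np.random.default_rng(0)
    tss = [TssRecord("chr1", int(p), "+", f"g{i}") for i, p in enumerate(rng.integers(0, 100_000, 10))]
    peaks = [mk_peak("chr1", int(s), int(s) + 300) for s in rng.integers(0, 100_000, 40)]
    ann = classify_peaks(peaks, tss)
    counts = {}
    for a in ann:
        counts[a.category] = counts.get(a.category, 0) + 1
    assert sum(counts.values()) == len(peaks)
    shuffled = list(peaks)
    rng.shuffle(shuffled)
    ann2 = {id(a.peak): a.category for a in classify_peaks(shuffled, tss)}
    assert all(ann2[id(a.peak)] == a.category for a in ann)


def brute_force_categories(peaks, tss, enh, ins, half=2000):
    out = []
    for p in peaks:
        iv = p.interval
        def hit(others):
            return any(
                iv.chrom == o.chrom and iv.start < o.end and o.start < iv.end
                for o in others
            )
        windows = [
            GenomicInterval(t.chrom, max(0, t.pos - half), t.pos + half) for t in tss
        ]
        if hit(windows):
            out.append("promoter")
        elif hit(enh):
            out.append("distal_enhancer")
        elif hit(ins):
            out.append("distal_insulator")
        else:
            out.append("other")
    return out


@pytest.mark.parametrize("seed", range(20))
def test_classify_peaks_matches_quadratic_oracle(seed):
    rng = np.random.default_rng(seed)
    chroms = ["chr1", "chr2"]
    tss = [
        TssRecord(rng.choice(chroms), int(p), "+", f"g{i}")
        for i, p in enumerate(rng.integers(0, 80_000, 8))
    ]
    enh = [
        GenomicInterval(rng.choice(chroms), int(s), int(s) + int(rng.integers(200, 900)))
        for s in rng.integers(0, 80_000, 10)
    ]
    ins = [
        GenomicInterval(rng.choice(chroms), int(s), int(s) + int(rng.integers(200, 900)))
        for s in rng.integers(0, 80_000, 10)
    ]
    peaks = [
        mk_peak(rng.choice(chroms), int(s), int(s) + int(rng.integers(100, 600)))
        for s in rng.integers(0, 80_000, 30)
    ]
    got = [a.category for a in classify_peaks(peaks, tss, enh, ins)]
    assert got == brute_force_categories(peaks, tss, enh, ins)


def test_classify_promoters_island_binding_activity():
    tss = [
        TssRecord("chr1", 5000, "+", "g1"),
        TssRecord("chr1", 50_000, "-", "g2"),
    ]
    islands = [GenomicInterval("chr1", 4800, 5600)]
    peaks = {"ZFX": [mk_peak("chr1", 5100, 5400)]}
    expr = {"g1": 3.0, "g2": 0.0}
    s1, s2 = classify_promoters(tss, islands, peaks, expr)
    assert s1.is_cpg_island and s1.bound_by == {"ZFX"} and s1.is_active
    assert not s2.is_cpg_island and s2.bound_by == set()
    assert s2.is_active is False  # zero expression is inactive at any positive threshold


def test_classify_promoters_missing_expression_warns(caplog):
    tss = [TssRecord("chr1", 5000, "+", "g1")]
    with caplog.at_level("WARNING"):
        (s,) = classify_promoters(tss, [], {}, {})
    assert s.is_active is None
    assert "missing" in caplog.text


def test_bound_fraction_recovered_on_default_bundle(default_bundle):
    """The generator plants a 60% bound fraction among active CpG-island
    promoters; classification should recover it within binomial error."""
    b = default_bundle
    statuses = classify_promoters(
        b.tss, b.cpg_islands, b.peaks, b.expression
    )
    primary = {
        g for g, p in b.truth.promoters.items() if not p.is_partner
    }
    active_cpg = [
        s for s in statuses
        if s.tss.gene_id in primary and s.is_cpg_island and s.is_active
    ]
    frac = np.mean(["ZFX" in s.bound_by for s in active_cpg])
    n = len(active_cpg)
    tol = 3 * np.sqrt(0.6 * 0.4 / n)
    assert abs(frac - 0.6) < tol
    # and the bound flags agree with the planted truth
    called_bound = {
        s.tss.gene_id for s in statuses
        if s.tss.gene_id in primary and "ZFX" in s.bound_by
    }
    assert called_bound == {g for g in primary if b.truth.promoters[g].bound}


def test_peak_set_overlap_edge_cases():
    a = [mk_peak("chr1", 0, 100), mk_peak("chr1", 500, 700)]
    assert peak_set_overlap(a, a).fraction == 1.0
    b = [mk_peak("chr1", 1000, 1100)]
    assert peak_set_overlap(a, b).fraction == 0.0
    with pytest.raises(ValueError):
        peak_set_overlap([], a)


@pytest.mark.parametrize("seed", range(20))
def test_peak_set_overlap_matches_quadratic_oracle(seed):
    rng = np.random.default_rng(100 + seed)
    def random_set(n):
        return [
            mk_peak(rng.choice(["chr1", "chr2"]), int(s), int(s) + int(rng.integers(50, 400)))
            for s in rng.integers(0, 20_000, n)
        ]
    a, b = random_set(30), random_set(10)
    res = peak_set_overlap(a, b)
    brute = sum(
        1
        for p in a
        if any(
            p.interval.chrom == q.interval.chrom
            and p.interval.start < q.interval.end
            and q.interval.start < p.interval.end
            for q in b
        )
    )
    assert res.n_a_overlapping == brute
    assert res.fraction == brute / len(a)


def test_peak_set_overlap_monotone_under_widening():
    rng = np.random.default_rng(3)
    a = [mk_peak("chr1", int(s), int(s) + 100) for s in rng.integers(0, 50_000, 25)]
    b = [mk_peak("chr1", int(s), int(s) + 100) for s in rng.integers(0, 50_000, 10)]
    fracs = []
    for grow in (0, 200, 1000, 5000):
        wb = [
            mk_peak("chr1", max(0, p.interval.start - grow), p.interval.end + grow)
            for p in b
        ]
        fracs.append(peak_set_overlap(a, wb).fraction)
    assert fracs == sorted(fracs)
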