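"""Summit-to-TSS offsets, single-TSS selection, clustering, metaplots and
tag correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from promoter_architect.binding_architecture import (
    PromoterArchitecture,
    build_architectures,
    cluster_fractions,
    cluster_promoters,
    metaplot,
    select_single_tss_promoters,
    summit_offsets,
    tag_correlation,
)
from promoter_architect.io_formats import GenomicInterval, Peak, SignalPoint, TssRecord


def mk_peak(chrom, start, end, summit_offset):
    return Peak(GenomicInterval(chrom, start, end), summit_offset)


def test_summit_offsets_strand_flip():
    plus = TssRecord("chr1", 5000, "+", "gp")
    minus = TssRecord("chr1", 5000, "-", "gm")
    peak_down = mk_peak("chr1", 5100, 5400, 140)   # summit 5240
    peak_up = mk_peak("chr1", 4600, 4900, 160)     # summit 4760
    assert summit_offsets([peak_down], [plus]) == [("gp", 240)]
    assert summit_offsets([peak_up], [minus]) == [("gm", 240)]


def test_summit_offsets_translation_equivariance():
    rng = np.random.default_rng(0)
    tss = [TssRecord("chr1", int(p), "+", f"g{i}") for i, p in enumerate(rng.integers(10_000, 90_000, 10))]
    peaks = [mk_peak("chr1", int(s), int(s) + 300, 150) for s in rng.integers(10_000, 90_000, 25)]
    base = sorted(summit_offsets(peaks, tss))
    shift = 1_000_000
    tss2 = [TssRecord(t.chrom, t.pos + shift, t.strand, t.gene_id) for t in tss]
    peaks2 = [
        mk_peak(p.interval.chrom, p.interval.start + shift, p.interval.end + shift, p.summit_offset)
        for p in peaks
    ]
    assert sorted(summit_offsets(peaks2, tss2)) == base


def test_summit_offset_mode_recovered_on_default_bundle(default_bundle):
    """Planted summits N(+240, 60) put the offset histogram mode at +240
    within one 20-bp bin."""
    b = default_bundle
    offs = np.array([o for _, o in summit_offsets(b.peaks["ZFX"], b.tss)])
    edges = np.arange(-2000, 2020, 20)
    counts, _ = np.histogram(offs, bins=edges)
    smooth = np.convolve(counts, np.ones(5) / 5, mode="same")
    mode_center = edges[int(np.argmax(smooth))] + 10
    assert abs(mode_center - 240) <= 20


def test_select_single_tss_examples():
    a = TssRecord("chr1", 10_000, "+", "a")
    b = TssRecord("chr1", 11_500, "+", "b")  # 1500 bp apart: both excluded
    c = TssRecord("chr1", 50_000, "+", "c")
    assert select_single_tss_promoters([a, b, c]) == [c]


@pytest.mark.parametrize("seed", range(20))
def test_select_single_tss_matches_quadratic_oracle(seed):
    rng = np.random.default_rng(seed)
    tss = [
        TssRecord(rng.choice(["chr1", "chr2"]), int(p), "+", f"g{i}")
        for i, p in enumerate(rng.integers(0, 60_000, 50))
    ]
    got = {t.gene_id for t in select_single_tss_promoters(tss)}
    brute = {
        t.gene_id
        for t in tss
        if not any(
            u is not t and u.chrom == t.chrom and abs(u.pos - t.pos) <= 2000
            for u in tss
        )
    }
    assert got == brute


def arch(gene, offsets, strand="+"):
    return PromoterArchitecture(TssRecord("chr1", 10_000, strand, gene), list(offsets))


def test_cluster_rule_examples():
    labels = cluster_promoters(
        [arch("down", [240]), arch("both", [-240, 240]), arch("up", [-240]),
         arch("dead", [10])], method="rule"
    )
    assert labels == {
        "down": "downstream_only", "both": "both", "up": "upstream_only",
        "dead": "both",
    }


def test_cluster_rule_order_invariance_and_empty_exclusion():
    archs = [arch("a", [300]), arch("b", [-300]), arch("c", [])]
    l1 = cluster_promoters(archs, "rule")
    l2 = cluster_promoters(list(reversed(archs)), "rule")
    assert l1 == l2 and "c" not in l1


def test_cluster_kmeans_deterministic_and_sign_consistent():
    rng = np.random.default_rng(4)
    archs = (
        [arch(f"d{i}", [int(rng.normal(240, 40))]) for i in range(30)]
        + [arch(f"u{i}", [int(rng.normal(-240, 40))]) for i in range(10)]
        + [arch(f"b{i}", [int(rng.normal(-240, 40)), int(rng.normal(240, 40))]) for i in range(10)]
    )
    l1 = cluster_promoters(archs, "kmeans", seed=0)
    l2 = cluster_promoters(archs, "kmeans", seed=0)
    assert l1 == l2
    # well-separated synthetic classes map to the right labels
    assert all(l1[f"d{i}"] == "downstream_only" for i in range(30))
    assert all(l1[f"u{i}"] == "upstream_only" for i in range(10))


def test_cluster_fractions_recover_planted_architecture(default_bundle):
    """Generator plants 82/8/10 downstream/upstream/both among bound
    promoters; the rule classifier recovers the proportions within binomial
    error, and upstream_only stays below 10%."""
    b = default_bundle
    single = select_single_tss_promoters(b.tss)
    archs = build_architectures(b.peaks["ZFX"], single)
    bound = {g for g, p in b.truth.promoters.items() if p.bound}
    archs = [a for a in archs if a.tss.gene_id in bound]
    labels = cluster_promoters(archs, "rule")
    fracs = cluster_fractions(labels)
    n = len(archs)
    for label, planted in (("downstream_only", 0.82), ("upstream_only", 0.08), ("both", 0.10)):
        tol = 3 * np.sqrt(planted * (1 - planted) / n) + 0.02
        assert abs(fracs[label] - planted) < tol
    # the recovered labels agree with the planted architecture classes
    planted_labels = {
        a.tss.gene_id: b.truth.promoters[a.tss.gene_id].architecture for a in archs
    }
    agree = np.mean([labels[g] == planted_labels[g] for g in labels])
    assert agree > 0.97
    assert b.truth.config.frac_upstream < 0.10


def test_metaplot_constant_signal_is_flat():
    sig = [SignalPoint("chr1", 0, 100_000, 1.0)]
    anchors = [TssRecord("chr1", 50_000, "+", "g")]
    mp = metaplot(sig, anchors, 1000, 20)
    assert np.allclose(mp.mean_signal, 1.0)
    assert mp.offsets[0] == -990 and mp.offsets[-1] == 990


def test_metaplot_single_block_downstream():
    sig = [SignalPoint("chr1", 50_200, 50_280, 2.0)]
    anchors = [TssRecord("chr1", 50_000, "+", "g")]
    mp = metaplot(sig, anchors, 1000, 20)
    inside = (mp.offsets > 200) & (mp.offsets < 280)
    assert np.allclose(mp.mean_signal[inside], 2.0)
    assert mp.mean_signal[mp.offsets < 200].sum() == 0.0


@pytest.mark.parametrize("seed", range(20))
def test_metaplot_matches_per_base_oracle(seed):
    rng = np.random.default_rng(300 + seed)
    half, bin_size = 500, 20
    sig = []
    cursor = 0
    while cursor < 40_000:
        w = int(rng.integers(50, 300))
        if rng.random() < 0.5:
            sig.append(SignalPoint("chr1", cursor, cursor + w, float(rng.uniform(0, 5))))
        cursor += w + int(rng.integers(10, 100))
    anchors = [
        TssRecord("chr1", int(p), rng.choice(["+", "-"]), f"g{i}")
        for i, p in enumerate(rng.integers(600, 39_000, 20))
    ]
    mp = metaplot(sig, anchors, half, bin_size)
    # per-base brute force
    base = np.zeros(40_500)
    for s in sig:
        base[s.start:s.end] = s.value
    acc = np.zeros(2 * half)
    for a in anchors:
        vec = base[a.pos - half:a.pos + half].copy()
        if a.strand == "-":
            vec = vec[::-1]
        acc += vec
    expected = (acc / len(anchors)).reshape(-1, bin_size).mean(axis=1)
    assert np.allclose(mp.mean_signal, expected, atol=1e-9)


def test_tag_correlation_identity_negation_and_textbook():
    rng = np.random.default_rng(9)
    x = rng.normal(size=30)
    df = pd.DataFrame({"a": x, "b": -x, "c": rng.normal(size=30)})
    corr = tag_correlation(df)
    assert corr.loc["a", "a"] == 1.0
    assert corr.loc["a", "b"] == pytest.approx(-1.0)
    # textbook definition: Pearson on mid-ranks
    ranks = df[["a", "c"]].rank()
    expected = np.corrcoef(ranks["a"], ranks["c"])[0, 1]
    assert corr.loc["a", "c"] == pytest.approx(expected, abs=1e-12)
    assert np.allclose(corr.values, corr.values.T, equal_nan=True)


def test_tag_correlation_zero_variance_and_min_regions():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
    corr = tag_correlation(df)
    assert np.isnan(corr.loc["a", "flat"])
    assert corr.loc["flat", "flat"] == 1.0
    with pytest.raises(ValueError):
        tag_correlation(df.iloc[:2])


def test_tag_correlation_high_between_shared_factor_peaks(default_bundle):
    """Tag counts over the shared binding sites of two factors that bind the
    same places (the second factor weaker) are strongly rank-correlated."""
    b = default_bundle
    rng = np.random.default_rng(0)
    rows = [
        (
            p.interval.score * rng.lognormal(0, 0.25),
            0.4 * p.interval.score * rng.lognormal(0, 0.25),
        )
        for p in b.peaks["ZNF711"]  # nearly all shared with the first factor
    ]
    corr = tag_correlation(pd.DataFrame(rows, columns=["ZFX", "ZNF711"]))
    assert corr.loc["ZFX", "ZNF711"] > 0.7
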