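"""IUPAC scanning, scrambled nulls and TSS-relative positional profiles."""

from collections import Counter

import numpy as np
import pytest

from promoter_architect.io_formats import GenomicInterval, Peak, TssRecord
from promoter_architect.motif_positional import (
    IUPAC,
    Motif,
    compare_motif_groups,
    motif_peak_stats,
    motifs_per_promoter,
    positional_profile,
    profile_from_offsets,
    profile_modes,
    scan_motif,
    scramble_motif,
)

CONSENSUS = Motif("AGGCCTAG")


def brute_scan(seq, motif):
    """Position-by-position IUPAC matcher, both strands."""
    def matches(text, pattern):
        return all(
            (t in IUPAC[p]) if p != "N" else (t in "ACGTN")
            for t, p in zip(text, pattern)
        )
    hits = []
    for pattern, strand in ((motif.consensus, "+"), (motif.reverse_complement, "-")):
        if pattern == motif.consensus and strand == "-":
            hits += [(pos, "-") for pos, s in hits if s == "+"]
            continue
        for i in range(len(seq) - len(pattern) + 1):
            if matches(seq[i:i + len(pattern)], pattern):
                hits.append((i, strand))
    return sorted(hits)


def test_scan_motif_forward_and_reverse_examples():
    assert scan_motif("TTAGGCCTAGTT", CONSENSUS) == [(2, "+")]
    # CTAGGCCT is the reverse complement of AGGCCTAG
    assert scan_motif("CTAGGCCT", CONSENSUS) == [(0, "-")]


def test_scan_motif_n_and_ambiguity_codes():
    assert scan_motif("AGGCCTAGN" + "AGGNCTAG", CONSENSUS) == [(0, "+")]
    m = Motif("ARGCCTAG")  # R = A or G
    assert scan_motif("AAGCCTAG", m) == [(0, "+")]
    assert scan_motif("AGGCCTAG", m) == [(0, "+")]
    mn = Motif("AGNC")
    assert (0, "+") in scan_motif("AGNC", mn)  # motif N matches sequence N


@pytest.mark.parametrize("seed", range(20))
def test_scan_motif_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    motifs = [CONSENSUS, Motif("AGGCCT"), Motif("RYSWKA"), Motif("AGCT")]
    for _ in range(15):
        seq = "".join(rng.choice(list("ACGTN"), size=60, p=[0.24] * 4 + [0.04]))
        m = motifs[rng.integers(0, len(motifs))]
        assert scan_motif(seq, m) == brute_scan(seq, m)


def test_scan_motif_strand_swap_symmetry():
    rng = np.random.default_rng(42)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    for _ in range(30):
        seq = "".join(rng.choice(list("ACGT"), size=80))
        rc = "".join(comp[c] for c in reversed(seq))
        assert len(scan_motif(seq, CONSENSUS)) == len(scan_motif(rc, CONSENSUS))


def test_scramble_motif_composition_and_determinism():
    scrambles = scramble_motif(CONSENSUS, n=10, seed=5)
    assert len(scrambles) == 10
    want = Counter("AGGCCTAG")
    for s in scrambles:
        assert Counter(s.consensus) == want
        assert s.consensus != CONSENSUS.consensus
        assert s.consensus != CONSENSUS.reverse_complement
    again = scramble_motif(CONSENSUS, n=10, seed=5)
    assert [s.consensus for s in scrambles] == [s.consensus for s in again]


def test_scramble_homopolymer_is_error():
    with pytest.raises(ValueError):
        scramble_motif(Motif("AAAA"))


def test_positional_profile_planted_at_240():
    tss = [TssRecord("chr1", 10_000, "+", "g1"), TssRecord("chr1", 50_000, "-", "g2")]
    pts = [("chr1", 10_240), ("chr1", 49_760)]  # both +240 downstream
    prof = positional_profile(pts, tss)
    assert prof.modal_bin() == (240, 260)
    assert prof.counts.sum() == 2
    assert (prof.counts > 0).sum() == 1


def test_positional_profile_mirror_equivariance():
    rng = np.random.default_rng(1)
    tss = [TssRecord("chr1", 100_000, "+", "g")]
    # odd offsets keep items off the 20-bp bin edges, where the half-open
    # binning convention would otherwise break exact mirror symmetry
    offs = rng.integers(-950, 950, 50) * 2 + 1
    pts = [("chr1", int(100_000 + o)) for o in offs]
    fwd = positional_profile(pts, tss)
    flipped = [TssRecord("chr1", 100_000, "-", "g")]
    rev = positional_profile(pts, flipped)
    assert np.array_equal(rev.counts, fwd.counts[::-1])


def test_positional_profile_count_conservation_and_bin_check():
    rng = np.random.default_rng(2)
    tss = [TssRecord("chr1", int(p), "+", f"g{i}") for i, p in enumerate(rng.integers(5_000, 500_000, 20))]
    pts = [("chr1", int(p)) for p in rng.integers(0, 510_000, 400)]
    prof = positional_profile(pts, tss, 2000, 20)
    in_window = sum(
        1
        for t in tss
        for c, p in pts
        if -2000 <= (p - t.pos) < 2000
    )
    assert prof.counts.sum() == in_window
    with pytest.raises(ValueError):
        positional_profile(pts, tss, 2000, 30)


def test_profile_modes_two_sided_mixture():
    rng = np.random.default_rng(3)
    offs = np.concatenate([rng.normal(-240, 50, 400), rng.normal(240, 50, 400)]).astype(int)
    prof = profile_from_offsets(offs, n_anchors=100)
    neg, pos = profile_modes(prof)
    assert abs(neg + 240) <= 20 and abs(pos - 240) <= 20


def test_motifs_per_promoter_planted_counts():
    # three planted non-overlapping motifs around one TSS, none elsewhere
    seq = list("T" * 30_000)
    tss_pos = 15_000
    for off in (-400, 100, 800):
        start = tss_pos + off - 4
        seq[start:start + 8] = "AGGCCTAG"
    genome = {"chr1": "".join(seq)}
    tss = [TssRecord("chr1", tss_pos, "+", "g1"), TssRecord("chr1", 25_000, "+", "g2")]
    df = motifs_per_promoter(tss, genome, CONSENSUS)
    counts = dict(zip(df.gene_id, df.n_motifs))
    assert counts == {"g1": 3, "g2": 0}


def test_motif_group_comparison_recovers_planted_rates(default_bundle):
    """CpG-island promoters carry Poisson(4) planted motifs vs Poisson(1)
    elsewhere: group medians order 4 > 1 with adjusted p < 0.05."""
    b = default_bundle
    statuses = {
        g: (p.is_cpg_island, p.bound)
        for g, p in b.truth.promoters.items()
        if not p.is_partner
    }
    primary_tss = [t for t in b.tss if t.gene_id in statuses]
    df = motifs_per_promoter(primary_tss, b.genome, CONSENSUS, statuses=statuses)
    med_cpg = df[df.is_cpg_island.astype(bool)].n_motifs.median()
    med_non = df[~df.is_cpg_island.astype(bool)].n_motifs.median()
    assert med_cpg == pytest.approx(4, abs=1)
    assert med_non == pytest.approx(1, abs=1)
    assert med_cpg > med_non
    df["group"] = np.where(df.is_cpg_island.astype(bool), "cpg", "non_cpg")
    res = compare_motif_groups(df, ["group"])
    assert (res.p_adjusted < 0.05).all()


def test_motif_peak_stats_planted_and_free():
    genome = {"chr1": "T" * 1000 + "AGGCCTAG" + "T" * 1000}
    with_motif = [Peak(GenomicInterval("chr1", 900, 1200))]
    stats_hit = motif_peak_stats(with_motif, genome, CONSENSUS)
    assert stats_hit.fraction_with_hit == 1.0
    assert stats_hit.histogram[1] == 1
    free = [Peak(GenomicInterval("chr1", 0, 500))]
    assert motif_peak_stats(free, genome, CONSENSUS).fraction_with_hit == 0.0


def test_motif_count_width_correlation_positive():
    """Peaks constructed so width grows with planted motif count give a
    positive Spearman correlation."""
    rng = np.random.default_rng(8)
    chrom = []
    peaks = []
    cursor = 0
    for i in range(200):
        n_mot = int(rng.integers(0, 5))
        width = 150 + 100 * n_mot + int(rng.integers(0, 40))
        block = list("".join(rng.choice(list("AT"), size=width)))
        for j in range(n_mot):
            block[10 + 20 * j:18 + 20 * j] = "AGGCCTAG"
        peaks.append(Peak(GenomicInterval("chr1", cursor, cursor + width)))
        chrom.extend(block)
        chrom.extend("T" * 50)
        cursor += width + 50
    res = motif_peak_stats(peaks, {"chr1": "".join(chrom)}, CONSENSUS)
    assert res.spearman_rho > 0.5
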