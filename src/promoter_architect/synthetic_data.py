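"""Seeded synthetic-data generator for the whole pipeline.

Produces a miniature genome plus every input the analysis consumes — FASTA,
TSS table, CpG-island BED, per-factor narrowPeak files, enhancer/insulator
BEDs, a methylation call table, a bedGraph signal track and
single/double-knockdown DE tables — with planted ground truth:

* peak summits concentrated at +240 bp downstream of bound TSSs (a small
  upstream-only class and a symmetric both-sides class);
* motif occurrences placed in a symmetric ±240 bp mixture, denser at
  CpG-island promoters, with background sequence scrubbed of chance exact
  matches inside promoter windows;
* nucleosome-depleted regions (elevated GCH methylation) planted just
  downstream of the TSS at most bound promoters;
* higher expression for bound genes and preferential down-regulation of
  bound genes on knockdown, with a set of redundancy-only genes that go
  down only in the double knockdown;
* a second factor whose peaks are almost entirely a subset of the first
  factor's peaks.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from promoter_architect.io_formats import (
    DEGene,
    GenomicInterval,
    MethylCall,
    Peak,
    SignalPoint,
    TssRecord,
    write_bed,
    write_bedgraph,
    write_de_table,
    write_fasta,
    write_methyl_calls,
    write_narrowpeak,
    write_tss,
)
from promoter_architect.motif_positional import Motif, scan_motif

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SimConfig:
    """Generator parameters. Defaults are the study conditions the pipeline
    is designed around: summits at N(+240, 60) bp downstream of the TSS, a
    symmetric ±240 bp motif mixture, 300-bp NDRs of GCH 0.7 over a 0.1
    background at depth 20, and knockdown down-regulation concentrated on
    bound genes."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    n_promoters: int = 400
    frac_cpg_island: float = 0.6
    frac_bound_cpg: float = 0.6       # bound fraction among CpG-island promoters
    frac_bound_noncpg: float = 0.15
    frac_bidirectional: float = 0.05  # promoters given a close opposite-strand partner TSS

    # binding architecture
    summit_offset_mean: float = 240.0
    summit_offset_sd: float = 60.0
    frac_upstream: float = 0.08       # bound promoters with the peak only upstream
    frac_both: float = 0.10           # bound promoters with symmetric ±240 peaks

    # motif placement
    motif_consensus: str = "AGGCCTAG"
    motif_mixture: tuple[float, float] = (0.5, 0.5)  # weights for (−240, +240)
    motif_offset_sd: float = 50.0
    motif_rate_cpg: float = 4.0       # Poisson mean per CpG-island promoter
    motif_rate_noncpg: float = 1.0
    motif_background_per_kb: float = 0.0

    # NOMe-seq
    ndr_width: int = 300
    ndr_start_offset: int = 40        # NDR spans [+40, +40+width) downstream
    ndr_frac: float = 0.85            # bound promoters carrying an NDR
    ndr_gch: float = 0.7
    background_gch: float = 0.1
    call_spacing: int = 10
    call_depth: int = 20
    call_half_width: int = 1500       # methylation coverage around each TSS

    # expression / knockdown
    expr_mu_unbound: float = 1.0      # log-normal location (natural log)
    expr_mu_bound: float = 2.0        # one log-unit higher for bound genes
    expr_sigma: float = 1.0
    inactive_prob: float = 0.05
    kd_down_prob_bound: float = 0.5
    kd_down_prob_unbound: float = 0.05
    kd_up_prob: float = 0.08
    n_redundant: int = 30             # bound genes down only in the double KD

    # factors and distal elements
    factor: str = "ZFX"
    second_factor: str = "ZNF711"
    second_factor_shared_frac: float = 0.3   # of first-factor peaks copied
    second_factor_unique: int = 1            # distal peaks unique to the second factor
    n_distal_enhancer: int = 30
    n_distal_insulator: int = 20
    n_distal_other: int = 20

    def __post_init__(self):
        for name in (
            "frac_cpg_island", "frac_bound_cpg", "frac_bound_noncpg",
            "frac_bidirectional", "frac_upstream", "frac_both", "ndr_frac",
            "ndr_gch", "background_gch", "inactive_prob",
            "kd_down_prob_bound", "kd_down_prob_unbound", "kd_up_prob",
            "second_factor_shared_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not 0 < self.summit_offset_mean < 2000:
            raise ValueError("summit_offset_mean must lie inside the promoter half-width")
        if self.frac_upstream + self.frac_both > 1.0:
            raise ValueError("architecture fractions exceed 1")


@dataclass
class PromoterTruth:
    gene_id: str
    chrom: str
    pos: int
    strand: str
    is_cpg_island: bool
    bound: bool
    architecture: str | None          # downstream_only / upstream_only / both / None
    summit_offsets: list[int] = field(default_factory=list)  # TSS-relative, downstream +
    motif_offsets: list[int] = field(default_factory=list)
    ndr: GenomicInterval | None = None
    expression: float = 0.0
    down_single: bool = False
    up_single: bool = False
    down_double: bool = False
    redundant: bool = False           # down only in the double knockdown
    is_partner: bool = False          # bidirectional-partner decoy TSS


@dataclass
class SimTruth:
    config: SimConfig
    promoters: dict[str, PromoterTruth]

    @property
    def bound_genes(self) -> set[str]:
        return {g for g, p in self.promoters.items() if p.bound}

    @property
    def planted_ndrs(self) -> list[GenomicInterval]:
        return [p.ndr for p in self.promoters.values() if p.ndr is not None]

    @property
    def redundant_genes(self) -> set[str]:
        return {g for g, p in self.promoters.items() if p.redundant}


@dataclass
class SimBundle:
    """In-memory pipeline inputs plus the planted truth."""

    genome: dict[str, str]
    tss: list[TssRecord]
    cpg_islands: list[GenomicInterval]
    peaks: dict[str, list[Peak]]              # factor -> peaks
    enhancers: list[GenomicInterval]          # H3K27ac
    insulators: list[GenomicInterval]         # CTCF
    methyl_calls: list[MethylCall]
    signal: list[SignalPoint]
    de_single: list[DEGene]                   # first-factor knockdown
    de_second_single: list[DEGene]
    de_double: list[DEGene]
    truth: SimTruth
    paths: dict[str, str] = field(default_factory=dict)

    @property
    def expression(self) -> dict[str, float]:
        return {g.gene_id: g.expression for g in self.de_single}


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _cg_rich_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    """CG-rich sequence (G+C ≈ 0.65) with CpG-dinucleotide enrichment, so
    CpG-island classification against background is non-trivial."""
    probs = np.array([0.175, 0.325, 0.325, 0.175])
    idx = rng.choice(4, size=n, p=probs)
    seq = _BASES[idx].copy()
    # boost CpG dinucleotides: after a C, make the next base G half the time
    is_c = seq[:-1] == ord("C")
    flip = rng.random(n - 1) < 0.5
    seq[1:][is_c & flip] = ord("G")
    return seq


def _scrub_matches(
    seq: np.ndarray, lo: int, hi: int, motif: Motif, rng: np.random.Generator,
    protected: list[tuple[int, int]] | None = None, max_rounds: int = 12,
) -> None:
    """Resample bases so the window [lo, hi) contains no exact motif match on
    either strand (outside protected spans)."""
    protected = protected or []
    for _ in range(max_rounds):
        text = seq[lo:hi].tobytes().decode()
        hits = scan_motif(text, motif)
        dirty = False
        for pos, _strand in hits:
            g0, g1 = lo + pos, lo + pos + len(motif)
            if any(g0 < pe and ps < g1 for ps, pe in protected):
                continue
            seq[g0:g1] = _random_seq(rng, len(motif))
            dirty = True
        if not dirty:
            return
    log.warning("motif scrub did not converge in %d rounds", max_rounds)


def generate(config: SimConfig, outdir: str | Path | None = None) -> SimBundle:
    """Build the full synthetic bundle; optionally write it to ``outdir``.

    Deterministic for a fixed config (byte-identical files on rerun).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    motif = Motif(cfg.motif_consensus, label="consensus")
    mlen = len(motif)
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    seqs = {c: _random_seq(rng, cfg.chrom_length) for c in chrom_names}

    # --- promoter placement: one slot per ~spacing bp, jittered ------------
    per_chrom = int(np.ceil(cfg.n_promoters / cfg.n_chroms))
    spacing = cfg.chrom_length // (per_chrom + 1)
    if spacing < 2 * (cfg.call_half_width + 2000):
        raise ValueError("chromosomes too short for the requested promoter count")
    promoters: list[PromoterTruth] = []
    tss_records: list[TssRecord] = []
    islands: list[GenomicInterval] = []
    gene_no = 0
    for ci, chrom in enumerate(chrom_names):
        n_here = min(per_chrom, cfg.n_promoters - ci * per_chrom)
        for slot in range(n_here):
            pos = (slot + 1) * spacing + int(rng.integers(-1500, 1500))
            strand = "+" if rng.random() < 0.5 else "-"
            gene = f"GENE{gene_no:04d}"
            gene_no += 1
            is_island = rng.random() < cfg.frac_cpg_island
            p = PromoterTruth(gene, chrom, pos, strand, is_island, False, None)
            promoters.append(p)
            tss_records.append(TssRecord(chrom, pos, strand, gene))
            if is_island:
                start = pos - int(rng.integers(400, 800))
                end = pos + int(rng.integers(600, 1000))
                islands.append(GenomicInterval(chrom, max(0, start), end, ".", f"CpG_{gene}"))
                seqs[chrom][max(0, start):end] = _cg_rich_seq(rng, end - max(0, start))

    # bidirectional partners: opposite-strand decoy TSSs ~1 kb away
    partners: list[PromoterTruth] = []
    for p in promoters:
        if rng.random() < cfg.frac_bidirectional:
            off = int(rng.integers(600, 1400))
            ppos = p.pos - off if p.strand == "+" else p.pos + off
            gene = f"GENE{gene_no:04d}"
            gene_no += 1
            q = PromoterTruth(
                gene, p.chrom, ppos, "-" if p.strand == "+" else "+",
                p.is_cpg_island, False, None, is_partner=True,
            )
            partners.append(q)
            tss_records.append(TssRecord(q.chrom, q.pos, q.strand, gene))
    promoters.extend(partners)

    # --- scrub chance motif matches inside promoter windows ---------------
    for p in promoters:
        lo = max(0, p.pos - 2000 - mlen)
        hi = min(cfg.chrom_length, p.pos + 2000 + mlen)
        _scrub_matches(seqs[p.chrom], lo, hi, motif, rng)

    # --- binding, architecture, summits ------------------------------------
    arch_choices = ["upstream_only", "both", "downstream_only"]
    arch_probs = [cfg.frac_upstream, cfg.frac_both, 1 - cfg.frac_upstream - cfg.frac_both]
    factor_peaks: list[Peak] = []
    for p in promoters:
        if p.is_partner:
            continue
        frac = cfg.frac_bound_cpg if p.is_cpg_island else cfg.frac_bound_noncpg
        if rng.random() >= frac:
            continue
        p.bound = True
        p.architecture = arch_choices[rng.choice(3, p=arch_probs)]
        if p.architecture == "downstream_only":
            offs = [cfg.summit_offset_mean]
        elif p.architecture == "upstream_only":
            offs = [-cfg.summit_offset_mean]
        else:
            offs = [-cfg.summit_offset_mean, cfg.summit_offset_mean]
        for mean in offs:
            off = int(round(rng.normal(mean, cfg.summit_offset_sd)))
            off = int(np.clip(off, -1900, 1900))
            p.summit_offsets.append(off)
            summit = p.pos + off if p.strand == "+" else p.pos - off
            w_left = int(rng.integers(120, 280))
            w_right = int(rng.integers(120, 280))
            start = max(0, summit - w_left)
            iv = GenomicInterval(
                p.chrom, start, summit + w_right, ".",
                f"{cfg.factor}_{p.gene_id}", float(rng.uniform(5, 50)),
            )
            factor_peaks.append(Peak(iv, summit - start))

    # --- distal elements ----------------------------------------------------
    enhancers: list[GenomicInterval] = []
    insulators: list[GenomicInterval] = []
    distal_factor_peaks: list[Peak] = []

    def _distal_pos(i: int) -> tuple[str, int]:
        chrom = chrom_names[i % cfg.n_chroms]
        slot = (i // cfg.n_chroms) % per_chrom
        # halfway between promoter slots, ≥ ~3 kb from any TSS
        return chrom, (slot + 1) * spacing + spacing // 2

    di = 0
    for _ in range(cfg.n_distal_enhancer):
        chrom, pos = _distal_pos(di); di += 1
        enhancers.append(GenomicInterval(chrom, pos - 500, pos + 500, ".", "H3K27ac"))
        if rng.random() < 0.5:  # half the enhancers carry a factor peak
            start = pos - int(rng.integers(150, 250))
            end = pos + int(rng.integers(150, 250))
            distal_factor_peaks.append(
                Peak(GenomicInterval(chrom, start, end, ".", f"{cfg.factor}_enh{di}",
                                     float(rng.uniform(5, 30))), pos - start)
            )
            if rng.random() < 0.3:  # some enhancers also have CTCF: still enhancers
                insulators.append(GenomicInterval(chrom, pos - 300, pos + 300, ".", "CTCF"))
    for _ in range(cfg.n_distal_insulator):
        chrom, pos = _distal_pos(di); di += 1
        insulators.append(GenomicInterval(chrom, pos - 400, pos + 400, ".", "CTCF"))
        if rng.random() < 0.5:
            start = pos - int(rng.integers(150, 250))
            end = pos + int(rng.integers(150, 250))
            distal_factor_peaks.append(
                Peak(GenomicInterval(chrom, start, end, ".", f"{cfg.factor}_ins{di}",
                                     float(rng.uniform(5, 30))), pos - start)
            )
    for _ in range(cfg.n_distal_other):
        chrom, pos = _distal_pos(di); di += 1
        start = pos - int(rng.integers(150, 250))
        end = pos + int(rng.integers(150, 250))
        distal_factor_peaks.append(
            Peak(GenomicInterval(chrom, start, end, ".", f"{cfg.factor}_oth{di}",
                                 float(rng.uniform(5, 30))), pos - start)
        )
    all_factor_peaks = factor_peaks + distal_factor_peaks

    # second factor: peaks nearly all shared with the first factor
    n_shared = int(round(cfg.second_factor_shared_frac * len(factor_peaks)))
    if n_shared > 0:
        shared_idx = rng.choice(len(factor_peaks), size=n_shared, replace=False)
        second_peaks = [factor_peaks[i] for i in sorted(shared_idx)]
    else:
        second_peaks = []
    for j in range(cfg.second_factor_unique):
        chrom, pos = _distal_pos(di); di += 1
        start, end = pos - 200, pos + 200
        second_peaks.append(
            Peak(GenomicInterval(chrom, start, end, ".", f"{cfg.second_factor}_uniq{j}",
                                 5.0), pos - start)
        )

    # --- motif planting -----------------------------------------------------
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    sign = np.array([-1.0, 1.0])
    for p in promoters:
        if p.is_partner:
            continue
        rate = cfg.motif_rate_cpg if p.is_cpg_island else cfg.motif_rate_noncpg
        n_mot = int(rng.poisson(rate))
        placed = 0
        attempts = 0
        while placed < n_mot and attempts < 50 * max(1, n_mot):
            attempts += 1
            s = sign[rng.choice(2, p=list(cfg.motif_mixture))]
            off = int(round(s * abs(rng.normal(cfg.summit_offset_mean, cfg.motif_offset_sd))))
            if not (-2000 + mlen <= off <= 2000 - mlen):
                continue
            mid = p.pos + off if p.strand == "+" else p.pos - off
            g0 = mid - mlen // 2
            g1 = g0 + mlen
            if g0 < 0 or g1 > cfg.chrom_length:
                continue
            if any(g0 < e and s0 < g1 for s0, e in occupied[p.chrom]):
                continue
            text = motif.consensus if rng.random() < 0.5 else "".join(
                _COMP[c] for c in reversed(motif.consensus)
            )
            seqs[p.chrom][g0:g1] = np.frombuffer(text.encode(), dtype=np.uint8)
            occupied[p.chrom].append((g0, g1))
            p.motif_offsets.append(off)
            placed += 1

    # optional genome-wide background occurrences
    if cfg.motif_background_per_kb > 0:
        n_bg = int(cfg.motif_background_per_kb * cfg.chrom_length / 1000)
        for chrom in chrom_names:
            for pos in rng.integers(0, cfg.chrom_length - mlen, size=n_bg):
                seqs[chrom][pos:pos + mlen] = np.frombuffer(
                    motif.consensus.encode(), dtype=np.uint8
                )

    # --- NDRs and methylation calls ----------------------------------------
    calls: list[MethylCall] = []
    for p in promoters:
        if p.is_partner:
            continue
        if p.bound and rng.random() < cfg.ndr_frac:
            if p.strand == "+":
                s0 = p.pos + cfg.ndr_start_offset
                ndr = GenomicInterval(p.chrom, s0, s0 + cfg.ndr_width, ".", f"NDR_{p.gene_id}")
            else:
                e0 = p.pos - cfg.ndr_start_offset
                ndr = GenomicInterval(p.chrom, e0 - cfg.ndr_width, e0, ".", f"NDR_{p.gene_id}")
            p.ndr = ndr
        lo = p.pos - cfg.call_half_width
        hi = p.pos + cfg.call_half_width
        for pos in range(lo, hi, cfg.call_spacing):
            in_ndr = p.ndr is not None and p.ndr.start <= pos < p.ndr.end
            rate = cfg.ndr_gch if in_ndr else cfg.background_gch
            k = int(rng.binomial(cfg.call_depth, rate))
            calls.append(MethylCall(p.chrom, pos, "+", "GCH", k, cfg.call_depth))
            # endogenous CpG methylation: low near an active island TSS
            near_tss = abs(pos - p.pos) <= 500
            hcg_rate = 0.05 if (p.is_cpg_island and near_tss) else 0.7
            kh = int(rng.binomial(cfg.call_depth, hcg_rate))
            calls.append(MethylCall(p.chrom, pos + 3, "+", "HCG", kh, cfg.call_depth))

    # --- ChIP signal track: Gaussian bumps at planted summits --------------
    signal: list[SignalPoint] = []
    sig_bin = 20
    for pk in all_factor_peaks:
        summit = pk.summit
        amp = pk.interval.score / 5.0
        lo = max(0, summit - 500)
        for s0 in range(lo - lo % sig_bin, summit + 500, sig_bin):
            d = s0 + sig_bin // 2 - summit
            v = amp * float(np.exp(-(d ** 2) / (2 * 120.0 ** 2)))
            if v > 0.05:
                signal.append(SignalPoint(pk.interval.chrom, s0, s0 + sig_bin, round(v, 4)))
    # collapse duplicate bins (overlapping bumps) by summing
    agg: dict[tuple[str, int], float] = {}
    for s in signal:
        agg[(s.chrom, s.start)] = agg.get((s.chrom, s.start), 0.0) + s.value
    signal = [
        SignalPoint(c, s0, s0 + sig_bin, round(v, 4)) for (c, s0), v in sorted(agg.items())
    ]

    # --- expression and knockdown tables ------------------------------------
    de_single: list[DEGene] = []
    de_second: list[DEGene] = []
    de_double: list[DEGene] = []
    bound_not_down: list[PromoterTruth] = []
    for p in promoters:
        if rng.random() < cfg.inactive_prob and not p.bound:
            p.expression = 0.0
        else:
            mu = cfg.expr_mu_bound if p.bound else cfg.expr_mu_unbound
            p.expression = float(rng.lognormal(mu, cfg.expr_sigma))
        p_down = cfg.kd_down_prob_bound if p.bound else cfg.kd_down_prob_unbound
        if rng.random() < p_down:
            p.down_single = True
            p.down_double = True
        elif rng.random() < cfg.kd_up_prob:
            p.up_single = True
        if p.bound and not p.down_single:
            bound_not_down.append(p)

    # redundancy-only genes: down in the double knockdown only
    n_red = min(cfg.n_redundant, len(bound_not_down))
    red_idx = rng.choice(len(bound_not_down), size=n_red, replace=False)
    for i in sorted(red_idx):
        bound_not_down[i].redundant = True
        bound_not_down[i].down_double = True
        bound_not_down[i].up_single = False

    def _de_row(p: PromoterTruth, down: bool, up: bool) -> DEGene:
        if down:
            lfc = -(0.585 + float(rng.exponential(0.5)))
            fdr = float(rng.uniform(1e-4, 0.04))
        elif up:
            lfc = 0.585 + float(rng.exponential(0.5))
            fdr = float(rng.uniform(1e-4, 0.04))
        else:
            lfc = float(np.clip(rng.normal(0, 0.2), -0.55, 0.55))
            fdr = float(rng.uniform(0.06, 1.0))
        return DEGene(p.gene_id, p.expression, lfc, fdr)

    for p in promoters:
        de_single.append(_de_row(p, p.down_single, p.up_single))
        # the second factor alone barely changes the transcriptome
        de_second.append(_de_row(p, rng.random() < 0.02, False))
        de_double.append(_de_row(p, p.down_double, p.up_single))

    genome = {c: seqs[c].tobytes().decode() for c in chrom_names}
    truth = SimTruth(cfg, {p.gene_id: p for p in promoters})
    bundle = SimBundle(
        genome=genome,
        tss=tss_records,
        cpg_islands=islands,
        peaks={cfg.factor: all_factor_peaks, cfg.second_factor: second_peaks},
        enhancers=enhancers,
        insulators=insulators,
        methyl_calls=calls,
        signal=signal,
        de_single=de_single,
        de_second_single=de_second,
        de_double=de_double,
        truth=truth,
    )
    if outdir is not None:
        bundle.paths = write_bundle(bundle, outdir)
    return bundle


def write_bundle(bundle: SimBundle, outdir: str | Path) -> dict[str, str]:
    """Write every input file of the bundle; returns {key: path}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = bundle.truth.config
    paths = {
        "genome": outdir / "genome.fa",
        "tss": outdir / "tss.tsv",
        "cpg_islands": outdir / "cpg_islands.bed",
        "enhancers": outdir / "enhancers_H3K27ac.bed",
        "insulators": outdir / "insulators_CTCF.bed",
        "methyl_calls": outdir / "methyl_calls.tsv",
        "signal": outdir / f"signal_{cfg.factor}.bedGraph",
        "de_single": outdir / f"de_{cfg.factor}_kd.tsv",
        "de_second_single": outdir / f"de_{cfg.second_factor}_kd.tsv",
        "de_double": outdir / "de_double_kd.tsv",
    }
    write_fasta(paths["genome"], bundle.genome)
    write_tss(paths["tss"], bundle.tss)
    write_bed(paths["cpg_islands"], bundle.cpg_islands)
    write_bed(paths["enhancers"], bundle.enhancers)
    write_bed(paths["insulators"], bundle.insulators)
    write_methyl_calls(paths["methyl_calls"], bundle.methyl_calls)
    write_bedgraph(paths["signal"], bundle.signal)
    write_de_table(paths["de_single"], bundle.de_single)
    write_de_table(paths["de_second_single"], bundle.de_second_single)
    write_de_table(paths["de_double"], bundle.de_double)
    for factor, peaks in bundle.peaks.items():
        p = outdir / f"peaks_{factor}.narrowPeak"
        write_narrowpeak(p, peaks)
        paths[f"peaks_{factor}"] = p
    return {k: str(v) for k, v in paths.items()}


def generate_de_only(
    seed: int,
    n_genes: int = 20_000,
    frac_bound: float = 0.4,
    p_down: float = 0.15,
    p_up: float = 0.15,
    p_down_bound: float | None = None,
) -> tuple[list[DEGene], set[str]]:
    """Lightweight generator of a DE table plus a bound-gene set, without the
    genome. With ``p_down_bound`` left None, binding and differential
    expression are independent — the null used for calibration checks of the
    exact test. The exact test's p-value is discretely conservative and only
    asymptotically uniform, so the default table is large (~3000 genes per
    DE margin), where the residual bias is far below what a 200-replicate
    KS check can resolve.
    """
    rng = np.random.default_rng(seed)
    is_bound = rng.random(n_genes) < frac_bound
    pd_ = np.full(n_genes, p_down)
    if p_down_bound is not None:
        pd_[is_bound] = p_down_bound
    u = rng.random(n_genes)
    down = u < pd_
    up = ~down & (u < pd_ + p_up)
    de = down | up
    mag = 0.585 + rng.exponential(0.5, n_genes)
    lfc = np.clip(rng.normal(0, 0.2, n_genes), -0.55, 0.55)
    lfc[down] = -mag[down]
    lfc[up] = mag[up]
    fdr = rng.uniform(0.06, 1.0, n_genes)
    fdr[de] = rng.uniform(1e-4, 0.04, n_genes)[de]
    expr = rng.lognormal(1.0, 1.0, n_genes)
    genes = [
        DEGene(f"G{i:05d}", float(expr[i]), float(lfc[i]), float(fdr[i]))
        for i in range(n_genes)
    ]
    bound = {f"G{i:05d}" for i in np.flatnonzero(is_bound)}
    return genes, bound


# ---------------------------------------------------------------------------
# truth comparison
# ---------------------------------------------------------------------------

def _interval_match(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Overlap of at least half the shorter interval."""
    if a.chrom != b.chrom:
        return False
    ov = min(a.end, b.end) - max(a.start, b.start)
    return ov >= 0.5 * min(len(a), len(b))


def _set_pr(called: set, truth: set) -> tuple[float, float]:
    tp = len(called & truth)
    precision = tp / len(called) if called else (1.0 if not truth else 0.0)
    recall = tp / len(truth) if truth else 1.0
    return precision, recall


def truth_compare(outputs: Mapping[str, object], truth: SimTruth) -> dict[str, dict[str, float]]:
    """Precision/recall of pipeline outputs against the planted truth.

    Recognized output keys (any subset): ``bound_genes`` (set of gene ids),
    ``down_genes``, ``up_genes``, ``additional_bound_down`` (sets), and
    ``ndrs`` (list of called intervals/NDRs; matching = overlap of at least
    half the shorter interval).
    """
    report: dict[str, dict[str, float]] = {}
    set_truths = {
        "bound_genes": truth.bound_genes,
        "down_genes": {g for g, p in truth.promoters.items() if p.down_single},
        "up_genes": {g for g, p in truth.promoters.items() if p.up_single},
        "additional_bound_down": truth.redundant_genes,
    }
    for key, t in set_truths.items():
        if key in outputs:
            called = set(outputs[key])  # type: ignore[arg-type]
            unknown = called - set(truth.promoters)
            if unknown:
                raise ValueError(f"{key}: unknown gene ids {sorted(unknown)[:5]}")
            p, r = _set_pr(called, t)
            report[key] = {"precision": p, "recall": r, "n_called": len(called), "n_true": len(t)}
    if "ndrs" in outputs:
        called_ivs = [
            n.interval if hasattr(n, "interval") else n for n in outputs["ndrs"]  # type: ignore[union-attr]
        ]
        planted = truth.planted_ndrs
        tp_called = sum(1 for c in called_ivs if any(_interval_match(c, t) for t in planted))
        tp_truth = sum(1 for t in planted if any(_interval_match(c, t) for c in called_ivs))
        report["ndrs"] = {
            "precision": tp_called / len(called_ivs) if called_ivs else (1.0 if not planted else 0.0),
            "recall": tp_truth / len(planted) if planted else 1.0,
            "n_called": len(called_ivs),
            "n_true": len(planted),
        }
    return report
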