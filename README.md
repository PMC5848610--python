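# promoter-architect

Analysis toolkit for **promoter architecture of CpG-island–binding
transcription factors**, built around the kind of question raised by
ZFX/ZNF711-class zinc-finger activators: where does a factor sit relative to
the transcription start sites it regulates, and what does that position mean
for chromatin and expression?

The package is aimed at regulatory genomicists who have ChIP-seq peaks,
a TSS annotation, knockdown RNA-seq contrasts and (optionally) NOMe-seq
methylation calls, and want the integrative promoter-centric analyses:

- **Peak annotation** — each peak assigned to exactly one of
  promoter (±2 kb of a TSS), distal enhancer (H3K27ac), distal insulator
  (CTCF not in an enhancer) or other; promoters classed by CpG-island
  status, binding and activity.
- **Motif positional profiling** — both-strand IUPAC scanning of a consensus
  (e.g. the 8-nt AGGCCTAG), TSS-relative frequency profiles oriented
  downstream-positive, and scrambled-motif nulls with identical nucleotide
  composition, assessed against a dinucleotide-composition–controlled
  expectation.
- **Summit architecture** — signed summit→TSS offsets, selection of
  promoters with a single TSS in ±2 kb, and clustering into
  upstream-only / downstream-only / both classes; metaplots and
  between-sample Spearman tag correlation.
- **Knockdown integration** — down/up-regulated gene selection
  (FDR < 0.05, |fold change| > 1.5), the bound × regulated 2×2 contingency
  with odds ratio and Fisher exact p, the bound-vs-unbound expression
  contrast, and the combinatorial (double) knockdown set difference that
  exposes redundancy between related factors.
- **NOMe-seq NDR calling** — nucleosome-depleted regions from GCH
  (GpC) accessibility methylation: sliding-window binomial test against the
  pooled background rate, BH correction, merging, and a 140-bp minimum
  length; peak–NDR overlap restricted to summits near +240 bp.
- **Synthetic data** — a seeded generator that emits a miniature genome and
  every input file with planted ground truth (summits at N(+240, 60) bp,
  motifs in a symmetric ±240 mixture, ≥140-bp NDRs at bound promoters,
  preferential down-regulation of bound genes), so the whole pipeline is
  testable without any download.

The central quantity is the signed TSS-relative offset
`o = s · (x − t)` for a genomic position `x`, TSS `t` and strand sign
`s ∈ {+1, −1}`, binned into positional profiles; the binding×response
statistic is the odds ratio `(a·d)/(b·c)` on the (down, up) × (bound,
unbound) table with a two-sided Fisher exact p-value.

## Worked example

```sh
python examples/04_knockdown_integration.py
```

prints

```
worked example: 58.5% of down- vs 11.4% of up-regulated genes bound (odds ratio 10.92, p = 4.12e-144)
expression medians: bound 6.73 vs unbound 2.40 (rank-sum p = 3.5e-17)
bound genes down only in the double knockdown: 30 (planted: 30)
```

The first line is the contingency summary for a knockdown contrast with
1271 down-regulated genes (744 of them with factor-bound promoters) and
1249 up-regulated (143 bound): down-regulated genes are ~10× enriched for
bound promoters, the signature of a direct activator. The second line is the
bound-vs-unbound expression contrast on synthetic data; the third recovers
the planted set of genes that respond only when both redundant factors are
knocked down.

The other examples cover annotation (`01`), motif profiles with scrambled
nulls (`02`), summit architecture (`03`) and NDR calling (`05`) — e.g. `03`
prints `modal summit bin: [+240, +260) bp`, the downstream binding
preference, and `05` prints NDR precision/recall of 1.00 against planted
truth with ~90% of +240-summit peaks inside an NDR.

## Command line

The same stages run from a shell:

```sh
promoter-architect simulate --seed 1 --out bundle/
promoter-architect run-all --config cfg.yaml --out results/
promoter-architect report --out results/
```

`cfg.yaml` names the input files (`inputs:` with `genome`, `tss`,
`cpg_islands`, `peaks: {ZFX: ...}`, `methyl_calls`, `de_single`, ...) and
any stage parameters; every run writes TSV/BED outputs plus a
`manifest.json` recording all parameters, the seed and input checksums, so
reruns are reproducible byte for byte.

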