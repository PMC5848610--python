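# Methods

This note documents the models, conventions and numerical choices behind
`promoter_architect`, and what the synthetic-data tests do and do not show
about real data.

## Coordinates and conventions

All coordinates are 0-based half-open (BED convention); any 1-based source
would be converted exactly once, at its reader. Methylation call positions
are 0-based single-bp sites. Chromosome names are compared verbatim — there
is no `chr` prefix munging — and a validation pass warns when peak
chromosomes are absent from the TSS annotation, because silent namespace
mismatches are the classic interval-analysis failure. Unsorted inputs are
accepted everywhere; sorting is internal.

TSS-relative offsets are always *downstream-positive*: for a genomic
position `x`, a TSS at `t` with strand sign `s` the offset is `s·(x − t)`.
Profiles, metaplots and summit offsets all share this orientation, so a
− strand promoter's downstream peak appears at +240 like a + strand one.

## Peak and promoter annotation

A promoter window is the ±`half_width` (default 2000 bp) interval around a
TSS, clipped at zero. Peak categories are assigned with a strict priority:

1. **promoter** — the peak shares ≥ 1 bp with any promoter window
   (whole-peak overlap by default; a summit-only mode is a switch);
2. **distal_enhancer** — otherwise, overlap with an H3K27ac interval;
3. **distal_insulator** — otherwise, overlap with CTCF (i.e. CTCF *not* in
   an enhancer);
4. **other**.

Categories therefore partition the peak set exactly. A promoter is
CpG-island if its TSS *point* lies in an island interval (the window is not
used), matching the binary promoter classing the analysis needs. `bound_by`
contains a factor iff one of its peaks overlaps the window; a gene with
several TSSs counts as bound if any of its windows is. Activity defaults to
expression > 0 ("detectable"), with the threshold configurable. Nearest-TSS
ties break toward the 5′-most (lowest-coordinate) TSS for determinism.

## Motif scanning and positional profiles

IUPAC consensus matching uses per-letter character classes with a regex
lookahead so overlapping occurrences are all reported; reverse-strand hits
are matches of the reverse-complement pattern on the forward sequence,
reported at the leftmost base. An `N` in the sequence satisfies only the
motif code `N`. For non-palindromic motifs a forward and a reverse hit at
the same leftmost base are collapsed to one by default (switchable), so
palindromic positions are not double-counted.

A hit's position for profiling is its **midpoint** (leftmost base +
⌊len/2⌋), which symmetrizes forward/reverse occurrences of the same site.
Promoter windows are scanned padded by one motif length and hits kept by the
midpoint-in-window rule; windows with > 10% `N` are dropped and logged.
Profiles bin offsets into 20-bp bins tiling [−half_width, +half_width);
counts are conserved (sum over bins = in-window hits). Modal bins can be
estimated from a centered moving average (default 5 bins ≈ 100 bp) because
a point process whose density peaks on a bin edge — e.g. summits at
N(+240, 60) with edges at multiples of 20 — splits its mass evenly between
two adjacent bins and the raw argmax flips between them by sampling noise.
Containment of a target in the modal bin is edge-inclusive for the same
reason.

**Scrambled nulls.** Scrambles are seeded letter permutations with the
original and its reverse complement rejected; a motif with no other
permutation (homopolymer) is an error. Flatness of a scrambled profile is
*not* assessed on raw 20-bp bins: at desk scale a scramble has only ~50
chance occurrences across 1.6 Mb of promoter sequence, so 200-bin counts
are Poisson-sparse and max/mean is large even under perfect uniformity.
Instead the profile is coarsened to 4 one-kilobase super-bins and each
observed count is divided by its **composition-controlled expectation**: a
per-window first-order Markov (dinucleotide) model of the segment sequence
(`expected_coarse_counts`). This control matters because CpG-island
promoters are CG-rich around the TSS, so CG-containing scrambles are
genuinely denser there — and CC/CT-containing ones sparser — with no
positional signal involved; the controlled max/mean ratio isolates
position-specific enrichment and sits below 2 for every scramble while the
true consensus concentrates an order of magnitude more mass in the ±240
bins than any scramble reaches anywhere.

## Summit architecture

Summit offsets are one record per (peak, promoter) pair whose summit — or
interval midpoint when the caller reported none (logged) — lies within
±half_width of the TSS; this keeps every reported offset inside the profile
window. Single-TSS promoters are those with no other TSS within
±half_width on the same chromosome (both members of a close pair drop).

The rule classifier labels a promoter `upstream_only` when all offsets are
< −50 bp, `downstream_only` when all are > +50 bp, and `both` otherwise;
the ±50-bp dead zone avoids knife-edge labels at the TSS. The k-means
alternative (k = 3, 10 restarts, fixed seed) operates on per-promoter
offset histograms that are Gaussian-smoothed (σ ≈ 1.5 bins) and
L1-normalized: without smoothing, single-peak promoters are one-hot vectors
that are mutually equidistant regardless of offset — a degenerate geometry —
and without normalization two-peak promoters separate by total count alone.
Clusters are mapped to the three labels by the sign of their mean offset.

Metaplots are raw per-base means over anchors (zero where a track has no
value), strand-flipped, then bin-averaged; no library-size scaling is
applied — input tracks are assumed pre-normalized upstream. Tag correlation
is Spearman with mid-ranks; zero-variance samples yield undefined (NaN)
off-diagonal entries and 1.0 on the diagonal.

## Knockdown integration

Down-regulated: `fdr < 0.05` and `log2fc < −log2(1.5)`; up-regulated
symmetric; both inequalities strict. The binding contingency uses the
(down, up) × (bound, unbound) table: odds ratio `(a·d)/(b·c)` (0 when the
numerator is also degenerate) and a two-sided Fisher exact p-value; a
one-sided hypergeometric enrichment p is a config option. Reported
percentages are rounded once, at reporting, to one decimal, half away from
zero. The double-knockdown analysis returns bound genes down-regulated in
the combined knockdown but in neither single knockdown — the redundancy
signature — plus the three-way membership table.

The Fisher exact p-value is discretely conservative (mean ≈ 0.54, KS
D ≈ 0.12 against uniform at ~200-gene DE margins) and only asymptotically
uniform. The null-calibration check therefore uses tables of ~3000 genes
per DE margin (20 000 genes, 15% down / 15% up), where the residual bias
(D ≈ 0.03) is far below what a 200-replicate KS test at α = 0.01 can
resolve. This is a property of exact tests, not of the implementation.

## NOMe-seq NDR calling

Methylation levels are pooled (Σ methylated / Σ total), never averaged
per-site. The caller: background = genome-wide pooled GCH rate (a ±5 kb
local variant is a config option); slide a 100-bp window by 20 bp over each
chromosome's calls; windows with ≥ 3 calls get a one-sided binomial test of
pooled counts against the background rate; BH-adjust across all tested
windows (q < 0.05); merge significant windows that overlap or sit within
one step; trim each merged span to the outermost run of ≥ 3 consecutive
calls individually above background (per-call binomial p < 0.05); keep
regions ≥ 140 bp. The run-based trimming is load-bearing: with single-call
trimming, an isolated noisy background call can stretch a sub-140-bp open
region past the length floor, whereas three consecutive elevated background
calls are a ~10⁻⁵ event. Every reported NDR satisfies mean GCH >
background strictly. The NDR count is monotone non-increasing in
`min_length`; tightening `q_max` usually reduces the count but can split a
long merged region into two reportable ones, so that direction is checked
empirically rather than asserted universally.

## Synthetic data: what it emulates and what it does not

The generator plants, per promoter: CpG-island status (60%), binding (60%
of island promoters, 15% of others), architecture class (82% downstream /
8% upstream / 10% both), summit offsets N(±240, 60), motif counts
Poisson(4) at island promoters vs Poisson(1) (symmetric ±240 placement,
σ = 50, verbatim insertion into scrubbed background), 300-bp NDRs at
[+40, +340) for 85% of bound promoters (GCH 0.7 vs 0.1 background, depth
20, 10-bp call spacing), log-normal expression one log-unit higher for
bound genes, knockdown down-regulation of 50% of bound vs 5% of unbound
genes, a fixed redundancy set down only in the double knockdown, and a
second factor whose peaks are a near-subset of the first's. Background
sequence is i.i.d. uniform except CpG islands (G+C ≈ 0.65 with CpG
dinucleotide boost); chance exact occurrences of the consensus are scrubbed
from promoter windows so planted counts are ground truth. Default scale is
2 chromosomes × 2 Mb with 400 promoters (plus ~5% bidirectional-partner
decoy TSSs), chosen so a full generate-analyse-verify cycle runs in
seconds on one CPU; everything is byte-deterministic for a fixed seed.

It does **not** emulate: mappability and coverage nonuniformity, peak-width
and summit-error correlation with signal strength, replicate structure,
batch effects, isoform-level TSS ambiguity, partially methylated domains,
or copy-number variation. Passing recovery tests on this generator shows
the *operations* are correct at realistic effect sizes; it does not certify
performance on real libraries, where thresholds (active-expression cutoff,
NDR window/step, q-value) may need retuning.

## Known limitations

- NDR calling assumes roughly even call spacing; very uneven coverage will
  make window evidence heterogeneous (the ≥ 3-call rule guards the worst
  cases).
- The first-order Markov composition control for scramble flatness ignores
  longer-range composition (e.g. CpG-island edges inside a coarse bin).
- `peak_set_overlap` counts any-bp overlap, so nested or book-ended
  interval sets with very different widths should be interpreted with the
  reciprocal counts it also reports.
- The CLI reruns the orchestration per subcommand and filters the summary;
  stages are cheap at package scale, but very large inputs would warrant
  stage caching.
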