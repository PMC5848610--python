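"""Domain types and readers/writers for the external file formats.

All coordinates inside the package are 0-based half-open (BED convention);
any 1-based source column would be converted exactly once, at the reader.
Methylation call positions are 0-based single-bp sites. Chromosome names are
matched verbatim between files — no "chr" stripping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

STRANDS = {"+", "-", "."}
METHYL_CONTEXTS = {"HCG", "GCH"}

SUMMIT_ABSENT = None  # sentinel for narrowPeak column 10 == -1


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    score: float = 0.0

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {sorted(STRANDS)}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """>= 1 bp shared."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq peak with an optional single-bp summit.

    ``summit_offset`` is the bp distance from ``interval.start`` to the point
    of maximal enrichment (narrowPeak column 10), or ``None`` when the caller
    reported no summit.
    """

    interval: GenomicInterval
    summit_offset: int | None = None

    def __post_init__(self):
        if self.summit_offset is not None:
            if self.summit_offset < 0:
                raise ValueError("summit_offset must be >= 0 or None")
            if self.summit_offset >= len(self.interval):
                raise ValueError(
                    f"summit_offset {self.summit_offset} outside peak of length "
                    f"{len(self.interval)}"
                )

    @property
    def summit(self) -> int:
        """Genomic summit position; falls back to the interval midpoint."""
        if self.summit_offset is None:
            return self.interval.midpoint
        return self.interval.start + self.summit_offset

    @property
    def has_summit(self) -> bool:
        return self.summit_offset is not None


@dataclass
class TssRecord:
    """A stranded transcription start site anchoring a promoter window."""

    chrom: str
    pos: int
    strand: str
    gene_id: str
    is_cpg_island: bool = False

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValueError(f"TSS strand must be + or -, got {self.strand!r}")
        if self.pos < 0:
            raise ValueError("TSS pos must be >= 0")


@dataclass(frozen=True)
class MethylCall:
    """One cytosine observation in HCG (endogenous CpG) or GCH (GpC
    accessibility) context, as emitted by a bisulfite caller."""

    chrom: str
    pos: int
    strand: str
    context: str
    n_methylated: int
    n_total: int

    def __post_init__(self):
        if self.context not in METHYL_CONTEXTS:
            raise ValueError(f"context must be HCG or GCH, got {self.context!r}")
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        if not 0 <= self.n_methylated <= self.n_total:
            raise ValueError(
                f"n_methylated ({self.n_methylated}) must be in [0, n_total={self.n_total}]"
            )

    @property
    def level(self) -> float:
        return self.n_methylated / self.n_total


@dataclass(frozen=True)
class DEGene:
    """A gene with normalized expression and a knockdown-contrast result."""

    gene_id: str
    expression: float
    log2fc: float
    fdr: float

    def __post_init__(self):
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError(f"fdr must be in [0,1], got {self.fdr}")
        if self.expression < 0:
            raise ValueError("expression must be non-negative")


@dataclass(frozen=True)
class SignalPoint:
    """One bedGraph record: constant signal over [start, end)."""

    chrom: str
    start: int
    end: int
    value: float

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("end must exceed start")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _data_lines(path):
    """Yield (lineno, stripped line), skipping blanks and '#' comments."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("track"):
                continue
            yield lineno, line


def _int_field(path, lineno, text: str, what: str) -> int:
    try:
        return int(text)
    except ValueError:
        raise ParseError(path, lineno, f"non-integer {what}: {text!r}") from None


def _float_field(path, lineno, text: str, what: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise ParseError(path, lineno, f"non-numeric {what}: {text!r}") from None


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals, preserving input order.

    Strand defaults to "." when column 6 is absent.
    """
    out = []
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) < 3:
            raise ParseError(path, lineno, f"expected >=3 tab-separated columns, got {len(cols)}")
        start = _int_field(path, lineno, cols[1], "start")
        end = _int_field(path, lineno, cols[2], "end")
        if end <= start:
            raise ParseError(path, lineno, f"end ({end}) <= start ({start})")
        name = cols[3] if len(cols) > 3 else ""
        score = _float_field(path, lineno, cols[4], "score") if len(cols) > 4 and cols[4] != "." else 0.0
        strand = cols[5] if len(cols) > 5 else "."
        if strand not in STRANDS:
            raise ParseError(path, lineno, f"bad strand {strand!r}")
        try:
            out.append(GenomicInterval(cols[0], start, end, strand, name, score))
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    return out


def read_narrowpeak(path) -> list[Peak]:
    """Read 10-column ENCODE narrowPeak. Column 10 == -1 means "no summit"."""
    out = []
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) != 10:
            raise ParseError(path, lineno, f"narrowPeak requires 10 columns, got {len(cols)}")
        start = _int_field(path, lineno, cols[1], "start")
        end = _int_field(path, lineno, cols[2], "end")
        if end <= start:
            raise ParseError(path, lineno, f"end ({end}) <= start ({start})")
        strand = cols[5] if cols[5] in STRANDS else "."
        summit = _int_field(path, lineno, cols[9], "summit offset")
        try:
            interval = GenomicInterval(
                cols[0], start, end, strand, cols[3],
                _float_field(path, lineno, cols[6], "signalValue"),
            )
            out.append(Peak(interval, None if summit == -1 else summit))
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    return out


def read_tss(path) -> list[TssRecord]:
    """Read a TSS table: chrom, pos, strand, gene_id (tab-separated)."""
    out = []
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) < 4:
            raise ParseError(path, lineno, f"TSS table requires 4 columns, got {len(cols)}")
        pos = _int_field(path, lineno, cols[1], "pos")
        try:
            out.append(TssRecord(cols[0], pos, cols[2], cols[3]))
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    return out


def read_methyl_calls(path) -> list[MethylCall]:
    """Read a per-cytosine methylation call table.

    Columns: chrom, pos, strand, context (HCG|GCH), n_methylated, n_total.
    An optional header line starting with '#' is skipped.
    """
    out = []
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) < 6:
            raise ParseError(path, lineno, f"methylation table requires 6 columns, got {len(cols)}")
        pos = _int_field(path, lineno, cols[1], "pos")
        n_meth = _int_field(path, lineno, cols[4], "n_methylated")
        n_total = _int_field(path, lineno, cols[5], "n_total")
        if cols[3] not in METHYL_CONTEXTS:
            raise ParseError(path, lineno, f"unknown methylation context {cols[3]!r}")
        try:
            out.append(MethylCall(cols[0], pos, cols[2], cols[3], n_meth, n_total))
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    return out


def read_de_table(path) -> list[DEGene]:
    """Read a differential-expression table: gene_id, expression, log2fc, fdr.

    Duplicate gene ids are an error (binding joins are keyed by gene_id).
    """
    out = []
    seen: dict[str, int] = {}
    dups = []
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) < 4:
            raise ParseError(path, lineno, f"DE table requires 4 columns, got {len(cols)}")
        gene = cols[0]
        if gene in seen:
            dups.append(gene)
        seen[gene] = lineno
        try:
            out.append(
                DEGene(
                    gene,
                    _float_field(path, lineno, cols[1], "expression"),
                    _float_field(path, lineno, cols[2], "log2fc"),
                    _float_field(path, lineno, cols[3], "fdr"),
                )
            )
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    if dups:
        raise ParseError(path, seen[dups[0]], f"duplicate gene ids: {sorted(set(dups))}")
    return out


def read_bedgraph(path) -> list[SignalPoint]:
    out = []
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) < 4:
            raise ParseError(path, lineno, f"bedGraph requires 4 columns, got {len(cols)}")
        start = _int_field(path, lineno, cols[1], "start")
        end = _int_field(path, lineno, cols[2], "end")
        value = _float_field(path, lineno, cols[3], "value")
        try:
            out.append(SignalPoint(cols[0], start, end, value))
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    return out


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into {name: sequence}, upper-casing all bases."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# writers — sorted, tab-separated, newline-terminated
# ---------------------------------------------------------------------------

def _interval_sort_key(iv: GenomicInterval):
    return (iv.chrom, iv.start, iv.end)


def write_bed(path, intervals: Iterable[GenomicInterval], bed6: bool = True) -> None:
    ivs = sorted(intervals, key=_interval_sort_key)
    with open(path, "w") as fh:
        for iv in ivs:
            if bed6:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                    f"{iv.score:g}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_narrowpeak(path, peaks: Iterable[Peak]) -> None:
    ps = sorted(peaks, key=lambda p: _interval_sort_key(p.interval))
    with open(path, "w") as fh:
        for p in ps:
            iv = p.interval
            summit = -1 if p.summit_offset is None else p.summit_offset
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\t"
                f"{iv.score:g}\t-1\t-1\t{summit}\n"
            )


def write_tss(path, records: Iterable[TssRecord]) -> None:
    recs = sorted(records, key=lambda t: (t.chrom, t.pos, t.gene_id))
    with open(path, "w") as fh:
        for t in recs:
            fh.write(f"{t.chrom}\t{t.pos}\t{t.strand}\t{t.gene_id}\n")


def write_methyl_calls(path, calls: Iterable[MethylCall]) -> None:
    cs = sorted(calls, key=lambda c: (c.chrom, c.pos, c.context))
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tstrand\tcontext\tn_methylated\tn_total\n")
        for c in cs:
            fh.write(
                f"{c.chrom}\t{c.pos}\t{c.strand}\t{c.context}\t"
                f"{c.n_methylated}\t{c.n_total}\n"
            )


def write_de_table(path, genes: Iterable[DEGene]) -> None:
    gs = sorted(genes, key=lambda g: g.gene_id)
    with open(path, "w") as fh:
        fh.write("#gene_id\texpression\tlog2fc\tfdr\n")
        for g in gs:
            fh.write(f"{g.gene_id}\t{g.expression:.6g}\t{g.log2fc:.6g}\t{g.fdr:.6g}\n")


def write_bedgraph(path, points: Iterable[SignalPoint]) -> None:
    ps = sorted(points, key=lambda s: (s.chrom, s.start, s.end))
    with open(path, "w") as fh:
        for s in ps:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.value:.6g}\n")


def write_fasta(path, genome: dict[str, str], width: int = 80) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sorted(genome.items())
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_table(path, rows: Sequence[Sequence], header: Sequence[str] | None = None) -> None:
    """Generic TSV writer for report tables."""
    with open(path, "w") as fh:
        if header is not None:
            fh.write("#" + "\t".join(map(str, header)) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def validate_chrom_namespace(
    peaks: Sequence[Peak], tss_list: Sequence[TssRecord]
) -> set[str]:
    """Warn about peak chromosomes absent from the TSS annotation.

    Returns the set of unmatched chromosome names. Silent chromosome-name
    mismatches (chr1 vs 1) are the classic interval-analysis bug; names are
    compared verbatim.
    """
    tss_chroms = {t.chrom for t in tss_list}
    missing = {p.interval.chrom for p in peaks} - tss_chroms
    if missing:
        log.warning(
            "peak chromosomes absent from TSS annotation: %s", sorted(missing)
        )
    return missing
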