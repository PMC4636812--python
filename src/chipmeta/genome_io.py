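"""Genomic data model and readers/writers for the plain-text formats the
pipeline exchanges: BED (reads, peaks, enhancers), GTF/BED12 (gene models),
chrom-sizes TSV and FPKM expression tables.

All coordinates are held internally as 0-based half-open intervals (the BED
convention); conversion to 1-based happens only where a format demands it
(fixedStep wiggle, GTF).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd


class ParseError(ValueError):
    """A line of an input file could not be interpreted."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChromSizes:
    """Chromosome name -> length in bp."""

    entries: Mapping[str, int]

    def __post_init__(self) -> None:
        for name, length in self.entries.items():
            if not name:
                raise ValueError("empty chromosome name")
            if int(length) <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    def __getitem__(self, chrom: str) -> int:
        return self.entries[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.entries

    def items(self):
        return self.entries.items()

    @property
    def total(self) -> int:
        return sum(self.entries.values())

    @classmethod
    def read(cls, path: str | os.PathLike) -> "ChromSizes":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
        if df["chrom"].duplicated().any():
            raise ParseError(f"{path}: duplicate chromosome names")
        return cls(dict(zip(df["chrom"], df["length"].astype(int))))

    def write(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for name, length in self.entries.items():
                fh.write(f"{name}\t{length}\n")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval; strand is '+', '-' or '.' (unstranded)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (start >= end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class ReadRecord:
    """A uniquely aligned sequencing read; strand is mandatory."""

    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError("a read must have strand '+' or '-'")

    @property
    def five_prime(self) -> int:
        """5' position: start on '+', end-1 on '-'."""
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1


@dataclass
class GeneModel:
    """A gene with a strand-aware TSS and exon structure."""

    gene_id: str
    name: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        prev_end = None
        for ex in self.exons:
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"gene {self.gene_id}: exon outside gene body")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
            prev_end = ex.end

    @property
    def tss(self) -> int:
        """Strand-aware 5' end of the gene."""
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1

    @property
    def tts(self) -> int:
        """Strand-aware 3' end (transcription termination site)."""
        iv = self.interval
        return iv.end - 1 if iv.strand == "+" else iv.start


@dataclass
class PeakRecord:
    """A called peak with its summit and tag density t."""

    interval: GenomicInterval
    summit: int
    tag_density: float
    peak_id: str = ""
    score: float | None = None

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(f"peak {self.peak_id or '?'}: summit outside interval")
        if self.tag_density < 0:
            raise ValueError(f"peak {self.peak_id or '?'}: negative tag density")


@dataclass
class PeakSet:
    """A named collection of peaks for one factor."""

    name: str
    peaks: list[PeakRecord]

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    fpkm: float

    def __post_init__(self) -> None:
        if self.fpkm < 0:
            raise ValueError(f"gene {self.gene_id}: negative FPKM {self.fpkm}")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def _check_chrom(chrom, start, end, chrom_sizes, on_unknown, lineno, path):
    if chrom_sizes is None:
        return True
    if chrom not in chrom_sizes:
        if on_unknown == "error":
            raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        return False  # drop
    if end > chrom_sizes[chrom]:
        raise ParseError(
            f"{path}:{lineno}: interval end {end} beyond {chrom} length {chrom_sizes[chrom]}"
        )
    return True


def read_bed(
    path: str | os.PathLike,
    chrom_sizes: ChromSizes | None = None,
    as_reads: bool = False,
    on_unknown_chrom: str = "drop",
) -> list[GenomicInterval] | list[ReadRecord]:
    """Parse BED3/BED6 into intervals, or into ReadRecords when ``as_reads``.

    Records on chromosomes absent from ``chrom_sizes`` are dropped (default)
    or rejected (``on_unknown_chrom='error'``).
    """
    out: list = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end or start < 0:
                raise ParseError(
                    f"{path}:{lineno}: invalid interval {chrom}:{start}-{end}"
                )
            strand = fields[5] if len(fields) >= 6 else "."
            if not _check_chrom(chrom, start, end, chrom_sizes, on_unknown_chrom, lineno, path):
                continue
            iv = GenomicInterval(chrom, start, end, strand)
            out.append(ReadRecord(iv) if as_reads else iv)
    return out


def write_bed(
    records: Iterable[GenomicInterval | ReadRecord],
    path: str | os.PathLike,
    names: Sequence[str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for i, rec in enumerate(records):
            iv = rec.interval if isinstance(rec, ReadRecord) else rec
            name = names[i] if names is not None else f"r{i + 1}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_peaks_bed(
    path: str | os.PathLike,
    name: str = "",
    chrom_sizes: ChromSizes | None = None,
) -> PeakSet:
    """Peaks as BED with tag density in the score column (column 5).

    The summit defaults to the interval midpoint; a 7th column, when present,
    is taken as an absolute summit coordinate.
    """
    peaks: list[PeakRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split()
            if len(f) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            if start >= end:
                raise ParseError(f"{path}:{lineno}: invalid interval")
            if chrom_sizes is not None and chrom not in chrom_sizes:
                continue
            peak_id = f[3] if len(f) >= 4 else f"peak{lineno}"
            tag = float(f[4]) if len(f) >= 5 else 0.0
            iv = GenomicInterval(chrom, start, end)
            summit = int(f[6]) if len(f) >= 7 else iv.midpoint
            peaks.append(PeakRecord(iv, summit, tag, peak_id))
    return PeakSet(name or os.path.basename(os.fspath(path)), peaks)


def write_peaks_bed(peak_set: PeakSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for p in peak_set:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.peak_id}\t{p.tag_density:g}"
                f"\t.\t{p.summit}\n"
            )


# ---------------------------------------------------------------------------
# gene annotation (GTF / BED12)
# ---------------------------------------------------------------------------

def _parse_gtf_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def _read_gtf(path) -> list[GeneModel]:
    # feature rows keyed by gene_id; GTF is 1-based inclusive
    spans: dict[str, tuple[str, int, int, str, str]] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    utr5: dict[str, list[GenomicInterval]] = {}
    utr3: dict[str, list[GenomicInterval]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _, feature, start1, end1, _, strand, _, attr_text = f[:9]
            attrs = _parse_gtf_attributes(attr_text)
            gid = attrs.get("gene_id")
            if not gid:
                raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
            start, end = int(start1) - 1, int(end1)
            if gid not in spans and feature in ("gene", "transcript", "exon"):
                order.append(gid)
                spans[gid] = (chrom, start, end, strand, attrs.get("gene_name", gid))
            elif feature in ("gene", "transcript", "exon"):
                c, s, e, st, nm = spans[gid]
                spans[gid] = (c, min(s, start), max(e, end), st, nm)
            if feature == "exon":
                exons.setdefault(gid, []).append(GenomicInterval(chrom, start, end, strand))
            elif feature in ("five_prime_utr", "5UTR"):
                utr5.setdefault(gid, []).append(GenomicInterval(chrom, start, end, strand))
            elif feature in ("three_prime_utr", "3UTR"):
                utr3.setdefault(gid, []).append(GenomicInterval(chrom, start, end, strand))
    genes = []
    for gid in order:
        chrom, start, end, strand, name = spans[gid]
        genes.append(
            GeneModel(
                gene_id=gid,
                name=name,
                interval=GenomicInterval(chrom, start, end, strand),
                exons=_merge_exons(exons.get(gid, [])),
                utr5=utr5.get(gid, []),
                utr3=utr3.get(gid, []),
            )
        )
    return genes


def _merge_exons(exons: list[GenomicInterval]) -> list[GenomicInterval]:
    """Union overlapping exon records (multiple transcripts) into a flat set."""
    if not exons:
        return []
    exons = sorted(exons, key=lambda e: e.start)
    merged = [exons[0]]
    for ex in exons[1:]:
        last = merged[-1]
        if ex.start <= last.end:
            if ex.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, ex.end, last.strand)
        else:
            merged.append(ex)
    return merged


def _read_bed12(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split()
            if len(f) < 12:
                raise ParseError(f"{path}:{lineno}: expected 12 BED12 columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            gid, strand = f[3], f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [
                GenomicInterval(chrom, start + o, start + o + s, strand)
                for o, s in zip(offsets, sizes)
            ]
            utr_left, utr_right = [], []
            for ex in exons:
                if ex.start < thick_start:
                    utr_left.append(
                        GenomicInterval(chrom, ex.start, min(ex.end, thick_start), strand)
                    )
                if ex.end > thick_end:
                    utr_right.append(
                        GenomicInterval(chrom, max(ex.start, thick_end), ex.end, strand)
                    )
            u5, u3 = (utr_left, utr_right) if strand == "+" else (utr_right, utr_left)
            genes.append(
                GeneModel(gid, gid, GenomicInterval(chrom, start, end, strand), exons, u5, u3)
            )
    return genes


def read_gene_annotation(path: str | os.PathLike, fmt: str | None = None) -> list[GeneModel]:
    """Read gene models from a GTF or BED12 file.

    The format is auto-detected from the extension unless ``fmt`` forces it.
    """
    if fmt is None:
        ext = os.path.splitext(os.fspath(path))[1].lower()
        fmt = "GTF" if ext in (".gtf", ".gff") else "BED12"
    fmt = fmt.upper()
    if fmt == "GTF":
        return _read_gtf(path)
    if fmt == "BED12":
        return _read_bed12(path)
    raise ValueError(f"unknown annotation format {fmt!r}")


def write_gene_annotation_gtf(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.name}";'
            fh.write(
                f"{iv.chrom}\tchipmeta\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
            )
            for ex in g.exons:
                fh.write(
                    f"{iv.chrom}\tchipmeta\texon\t{ex.start + 1}\t{ex.end}\t.\t{iv.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

def read_expression_table(path: str | os.PathLike) -> list[ExpressionRecord]:
    """TSV with header columns ``gene_id`` and ``fpkm``."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "fpkm"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ParseError(f"{path}: duplicate gene id {dup!r}")
    if (df["fpkm"] < 0).any():
        raise ParseError(f"{path}: negative FPKM values")
    return [ExpressionRecord(g, float(v)) for g, v in zip(df["gene_id"], df["fpkm"])]


def write_expression_table(records: Iterable[ExpressionRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tfpkm\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.fpkm:.6g}\n")
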