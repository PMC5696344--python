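"""Genomic interval data model and plain-text format I/O.

All coordinates inside the package are 0-based half-open (BED convention);
GTF/GFF's 1-based closed coordinates are converted at the I/O boundary and
nowhere else.  Chromosome-name dialects ("2L" vs "chr2L") are reconciled by
stripping a configurable prefix before comparison.

Supported formats: BED3/BED6 (intervals / peaks), bedGraph (stepped signal),
GTF2.2/GFF3 (gene models, one representative transcript per gene).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "ParseError",
    "normalize_chrom",
    "read_intervals",
    "write_intervals",
    "read_bed_frame",
    "write_bed_frame",
    "sort_intervals",
]

_STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """Malformed record in an interval file; carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A located genome region, 0-based half-open.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval", min_bp: int = 1) -> bool:
        if normalize_chrom(self.chrom) != normalize_chrom(other.chrom):
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_bp


@dataclass(frozen=True)
class Peak:
    """A called enrichment region with a nonnegative score (producer units)."""

    interval: GenomicInterval
    name: str
    score: float = 0.0

    def __post_init__(self):
        if self.score < 0:
            raise ValueError(f"peak score must be >= 0, got {self.score}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass(frozen=True)
class GeneModel:
    """One gene with the exon chain of a single representative transcript.

    Exons are stored sorted 5'->3' in transcription direction; ``tss``/``tes``
    are derived from strand.  ``exons`` are plain genomic intervals on the
    gene's strand.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    transcript_id: str = ""

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError("gene strand must be '+' or '-'")
        if not self.exons:
            raise ValueError("gene must have at least one exon")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise ValueError(f"exons overlap in gene {self.gene_id}")
        want = tuple(genomic if self.strand == "+" else genomic[::-1])
        if tuple(self.exons) != want:
            object.__setattr__(self, "exons", want)

    @property
    def tss(self) -> int:
        return self.exons[0].start if self.strand == "+" else self.exons[0].end

    @property
    def tes(self) -> int:
        return self.exons[-1].end if self.strand == "+" else self.exons[-1].start

    @property
    def first_exon(self) -> GenomicInterval:
        return self.exons[0]

    @property
    def span(self) -> GenomicInterval:
        start = min(e.start for e in self.exons)
        end = max(e.end for e in self.exons)
        return GenomicInterval(self.chrom, start, end, self.strand)


def normalize_chrom(name: str, strip_prefix: str = "chr") -> str:
    """Canonical chromosome name: comparison happens after prefix stripping."""
    if strip_prefix and name.startswith(strip_prefix):
        return name[len(strip_prefix):]
    return name


def sort_intervals(records: Sequence) -> list:
    """Stable total sort by (chrom, start, end, name)."""

    def key(rec):
        if isinstance(rec, Peak):
            return (rec.chrom, rec.start, rec.end, rec.name)
        if isinstance(rec, GeneModel):
            s = rec.span
            return (s.chrom, s.start, s.end, rec.gene_id)
        if isinstance(rec, tuple):  # bedGraph (interval, value)
            iv = rec[0]
            return (iv.chrom, iv.start, iv.end, "")
        return (rec.chrom, rec.start, rec.end, "")

    return sorted(records, key=key)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

_FORMAT_BY_EXT = {
    ".bed": "bed",
    ".bedgraph": "bedgraph",
    ".bg": "bedgraph",
    ".gtf": "gtf",
    ".gff": "gff",
    ".gff3": "gff",
}

_ATTR_GTF = re.compile(r'(\w+)\s+"([^"]*)"')
_ATTR_GFF3 = re.compile(r"(\w+)=([^;]+)")


def _infer_format(path, fmt: str | None) -> str:
    if fmt is not None:
        f = fmt.lower().replace("bed3", "bed").replace("bed6", "bed")
        if f in ("bed", "bedgraph", "gtf", "gff", "gff3"):
            return "gff" if f == "gff3" else f
        raise ValueError(f"unknown format {fmt!r}")
    ext = Path(path).suffix.lower()
    if ext not in _FORMAT_BY_EXT:
        raise ValueError(f"cannot infer format from extension {ext!r} of {path}")
    return _FORMAT_BY_EXT[ext]


def _data_lines(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def read_intervals(path, format: str | None = None, strip_prefix: str | None = None):
    """Read an interval file into domain objects.

    Returns a list of :class:`GenomicInterval` (BED3), :class:`Peak` (BED6),
    ``(GenomicInterval, value)`` tuples (bedGraph) or :class:`GeneModel`
    (GTF/GFF3, one representative transcript per gene).  Records with
    ``start >= end`` are rejected with a warning and counted; any other
    malformed line raises :class:`ParseError` with its line number.
    Output is sorted by (chrom, start).
    """
    fmt = _infer_format(path, format)
    if fmt == "bed":
        return _read_bed(path)
    if fmt == "bedgraph":
        return _read_bedgraph(path)
    return _read_gene_models(path, fmt, strip_prefix=strip_prefix)


def _reject(n_rejected, path):
    if n_rejected:
        warnings.warn(
            f"{path}: rejected {n_rejected} record(s) with start >= end",
            stacklevel=3,
        )


def _read_bed(path):
    out, rejected = [], 0
    six = None
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        if len(f) < 3:
            raise ParseError(path, lineno, f"BED line has {len(f)} fields, need >= 3")
        try:
            start, end = int(f[1]), int(f[2])
        except ValueError as exc:
            raise ParseError(path, lineno, f"non-integer coordinate: {exc}") from None
        if start >= end or start < 0:
            rejected += 1
            continue
        if six is None:
            six = len(f) >= 6
        if six and len(f) >= 6:
            try:
                score = float(f[4])
            except ValueError:
                raise ParseError(path, lineno, f"non-numeric score {f[4]!r}") from None
            if f[5] not in _STRANDS:
                raise ParseError(path, lineno, f"bad strand {f[5]!r}")
            out.append(Peak(GenomicInterval(f[0], start, end, f[5]), name=f[3], score=score))
        else:
            out.append(GenomicInterval(f[0], start, end))
    _reject(rejected, path)
    return sort_intervals(out)


def _read_bedgraph(path):
    out, rejected = [], 0
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        if len(f) != 4:
            raise ParseError(path, lineno, f"bedGraph line has {len(f)} fields, need 4")
        try:
            start, end, value = int(f[1]), int(f[2]), float(f[3])
        except ValueError as exc:
            raise ParseError(path, lineno, f"bad bedGraph fields: {exc}") from None
        if start >= end or start < 0:
            rejected += 1
            continue
        out.append((GenomicInterval(f[0], start, end), value))
    _reject(rejected, path)
    return sort_intervals(out)


def _read_gene_models(path, fmt, strip_prefix=None):
    """Parse GTF/GFF3 exon records and pick one representative transcript.

    Representative transcript: most 5' TSS; tie -> longest first exon;
    tie -> lexicographically smallest transcript id.
    """
    attr_re = _ATTR_GTF if fmt == "gtf" else _ATTR_GFF3
    # transcripts[(gene, tx)] = dict(chrom, strand, exons=[...])
    transcripts: dict[tuple[str, str], dict] = {}
    rejected = 0
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        if len(f) != 9:
            raise ParseError(path, lineno, f"GTF/GFF line has {len(f)} fields, need 9")
        if f[2].lower() != "exon":
            continue
        try:
            start1, end1 = int(f[3]), int(f[4])
        except ValueError as exc:
            raise ParseError(path, lineno, f"non-integer coordinate: {exc}") from None
        start, end = start1 - 1, end1  # 1-based closed -> 0-based half-open
        if start >= end or start < 0:
            rejected += 1
            continue
        strand = f[6]
        if strand not in ("+", "-"):
            raise ParseError(path, lineno, f"exon needs explicit strand, got {strand!r}")
        attrs = dict(attr_re.findall(f[8]))
        gene = attrs.get("gene_id") or attrs.get("gene")
        tx = attrs.get("transcript_id") or attrs.get("Parent") or gene
        if not gene:
            raise ParseError(path, lineno, "exon record lacks gene_id")
        chrom = normalize_chrom(f[0], strip_prefix) if strip_prefix is not None else f[0]
        rec = transcripts.setdefault(
            (gene, tx), {"chrom": chrom, "strand": strand, "exons": []}
        )
        if rec["strand"] != strand or rec["chrom"] != chrom:
            raise ParseError(path, lineno, f"transcript {tx} mixes chrom/strand")
        rec["exons"].append(GenomicInterval(chrom, start, end, strand))
    _reject(rejected, path)

    by_gene: dict[str, list[tuple[str, dict]]] = {}
    for (gene, tx), rec in transcripts.items():
        by_gene.setdefault(gene, []).append((tx, rec))

    genes = []
    for gene, txs in by_gene.items():
        def tx_key(item):
            tx, rec = item
            exons = sorted(rec["exons"], key=lambda e: e.start)
            if rec["strand"] == "+":
                tss = exons[0].start
                first_len = exons[0].length
                pos = tss  # smaller = more 5'
            else:
                tss = exons[-1].end
                first_len = exons[-1].length
                pos = -tss  # larger coordinate = more 5'
            return (pos, -first_len, tx)

        tx, rec = min(txs, key=tx_key)
        genes.append(
            GeneModel(
                gene_id=gene,
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=tuple(rec["exons"]),
                transcript_id=tx,
            )
        )
    return sort_intervals(genes)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_intervals(records: Iterable, path, format: str | None = None) -> None:
    """Write domain objects back to BED/bedGraph/GTF; deterministic output.

    Peak sets with duplicate names are refused.  bedGraph records are written
    as sorted steps and must not overlap.
    """
    records = list(records)
    fmt = _infer_format(path, format)
    lines: list[str] = []
    if fmt == "bed":
        names = [r.name for r in records if isinstance(r, Peak)]
        if len(set(names)) != len(names):
            raise ValueError("duplicate peak names in BED output")
        for r in records:
            if isinstance(r, Peak):
                score = r.score
                stext = f"{int(score)}" if float(score).is_integer() else f"{score:g}"
                lines.append(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{stext}\t{r.interval.strand}"
                )
            else:
                lines.append(f"{r.chrom}\t{r.start}\t{r.end}")
    elif fmt == "bedgraph":
        recs = sort_intervals(records)
        prev = {}
        for iv, value in recs:
            if prev.get(iv.chrom, -1) > iv.start:
                raise ValueError("overlapping bedGraph steps")
            prev[iv.chrom] = iv.end
            lines.append(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{value:g}")
        records = recs
    elif fmt in ("gtf", "gff"):
        for g in records:
            tx = g.transcript_id or f"{g.gene_id}.t1"
            for e in sorted(g.exons, key=lambda e: e.start):
                if fmt == "gtf":
                    attrs = f'gene_id "{g.gene_id}"; transcript_id "{tx}";'
                else:
                    attrs = f"gene_id={g.gene_id};Parent={tx}"
                lines.append(
                    f"{g.chrom}\tcochip\texon\t{e.start + 1}\t{e.end}\t.\t{g.strand}\t.\t{attrs}"
                )
    else:  # pragma: no cover
        raise ValueError(f"unknown format {fmt!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Bulk read (fragment) tables
# ---------------------------------------------------------------------------

_BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed_frame(path) -> pd.DataFrame:
    """Read a (possibly large) BED3/6 file of sequencing reads as a DataFrame.

    Columns: chrom, start, end, name, score, strand (missing BED3 fields are
    filled with '.', 0, '.').
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise ParseError(path, 1, "BED file needs >= 3 columns")
    df = df.iloc[:, : min(6, df.shape[1])]
    df.columns = _BED6_COLS[: df.shape[1]]
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in df.columns:
            df[col] = default
    bad = (df["start"] >= df["end"]) | (df["start"] < 0)
    if bad.any():
        warnings.warn(f"{path}: rejected {int(bad.sum())} record(s) with start >= end")
        df = df[~bad]
    return df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


def write_bed_frame(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=[c for c in _BED6_COLS if c in df.columns])


def peaks_to_frame(peaks: Sequence[Peak]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [p.chrom for p in peaks],
            "start": [p.start for p in peaks],
            "end": [p.end for p in peaks],
            "name": [p.name for p in peaks],
            "score": [p.score for p in peaks],
            "strand": [p.interval.strand for p in peaks],
        }
    )
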