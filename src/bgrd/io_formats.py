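"""Readers and writers for the external formats the pipeline touches.

All coordinates are 0-based, half-open (BED convention) internally.  The only
1-based source is GTF, which is converted on read and never afterward.
Supported formats: BED6/BED12 and GTF-lite for gene annotations, BED or
DANPOS-style TSV for peaks, bedGraph or fixedStep wiggle for signal tracks,
tab-delimited tables (gene_id in the first column) for expression / Q-value /
width matrices, and plain text one-gene-per-line for gene sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "Peak",
    "SignalTrack",
    "GeneSet",
    "ParseError",
    "FormatError",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_peaks",
    "write_peaks",
    "read_signal",
    "write_bedgraph",
    "read_gene_set",
    "write_gene_set",
    "read_table",
]


class ParseError(ValueError):
    """A record could not be parsed; the message names the offending line."""


class FormatError(ValueError):
    """The file does not satisfy the format's structural requirements."""


@dataclass(frozen=True)
class GeneModel:
    """A gene interval with strand, optional exon structure and biotype."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str = "coding"
    exons: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.exons is not None:
            prev_end = self.start
            for s, e in self.exons:
                if s >= e:
                    raise ValueError(f"gene {self.gene_id}: empty exon ({s},{e})")
                if s < self.start or e > self.end:
                    raise ValueError(
                        f"gene {self.gene_id}: exon ({s},{e}) outside gene bounds"
                    )
                if s < prev_end:
                    raise ValueError(
                        f"gene {self.gene_id}: exons overlap or are unsorted"
                    )
                prev_end = e

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Transcription start: `start` on +, `end` on - strand."""
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass(frozen=True)
class Peak:
    """One enrichment peak; height is the maximal read density within it."""

    chrom: str
    start: int
    end: int
    height: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak {self.chrom}:{self.start}-{self.end} empty")
        if self.height < 0:
            raise ValueError("peak height must be >= 0")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class SignalTrack:
    """Per-chromosome signal at a fixed step, stored as dense arrays.

    ``values[chrom][i]`` is the signal on ``[i*step, (i+1)*step)``.
    """

    values: dict[str, np.ndarray]
    step: int = 1

    def chrom_length(self, chrom: str) -> int:
        return len(self.values[chrom]) * self.step

    def at(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-step values over [start, end); out-of-bounds positions are 0."""
        arr = self.values.get(chrom)
        n = (end - start) // self.step
        out = np.zeros(max(n, 0), dtype=float)
        if arr is None or n <= 0:
            return out
        i0 = start // self.step
        lo, hi = max(i0, 0), min(i0 + n, len(arr))
        if hi > lo:
            out[lo - i0 : hi - i0] = arr[lo:hi]
        return out


@dataclass
class GeneSet:
    """A named collection of unique gene identifiers."""

    name: str
    gene_ids: set[str] = field(default_factory=set)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.gene_ids

    def __len__(self) -> int:
        return len(self.gene_ids)


# ---------------------------------------------------------------------------
# gene annotations


def _parse_bed_blocks(line_no: int, fields: list[str], start: int) -> tuple:
    n_blocks = int(fields[9])
    sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
    starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    if len(sizes) != n_blocks or len(starts) != n_blocks:
        raise ParseError(f"line {line_no}: blockCount disagrees with block lists")
    return tuple((start + bs, start + bs + sz) for bs, sz in zip(starts, sizes))


def read_gene_annotation(path, format: str = "bed6") -> list[GeneModel]:
    """Read gene models from BED6, BED12 or GTF-lite.

    GTF-lite rows are 1-based inclusive and converted to 0-based half-open on
    read; the gene_id is taken from a ``gene_id "X"`` attribute.  Duplicate
    gene ids are rejected.
    """
    if format not in ("bed6", "bed12", "gtf-lite"):
        raise ValueError(f"unknown annotation format: {format}")
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if format in ("bed6", "bed12"):
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    gene_id, strand = fields[3], fields[5]
                    exons = None
                    if format == "bed12":
                        exons = _parse_bed_blocks(line_no, fields, start)
                else:
                    chrom = fields[0]
                    start, end = int(fields[3]) - 1, int(fields[4])
                    strand = fields[6]
                    attr = fields[8]
                    key = 'gene_id "'
                    if key not in attr:
                        raise ParseError(f"line {line_no}: no gene_id attribute")
                    gene_id = attr.split(key, 1)[1].split('"', 1)[0]
                    exons = None
            except (IndexError, ValueError) as exc:
                if isinstance(exc, ParseError):
                    raise
                raise ParseError(f"line {line_no}: malformed record: {line!r}") from exc
            if end <= start:
                raise ParseError(f"line {line_no}: end <= start for {gene_id}")
            if gene_id in seen:
                raise ParseError(f"line {line_no}: duplicate gene_id {gene_id}")
            seen.add(gene_id)
            genes.append(GeneModel(gene_id, chrom, strand, start, end, exons=exons))
    return genes


def write_gene_annotation(path, genes: list[GeneModel]) -> None:
    """Write gene models as BED6 (no exons) or BED12 (with exons)."""
    with open(path, "w") as fh:
        for g in genes:
            if g.exons is None:
                fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
            else:
                sizes = ",".join(str(e - s) for s, e in g.exons)
                starts = ",".join(str(s - g.start) for s, e in g.exons)
                fh.write(
                    f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}"
                    f"\t{g.start}\t{g.end}\t0\t{len(g.exons)}\t{sizes}\t{starts}\n"
                )


# ---------------------------------------------------------------------------
# peaks


def read_peaks(path, format: str = "bed") -> list[Peak]:
    """Read peaks from BED (height in the score column) or a DANPOS-style TSV.

    The TSV must have a header with ``chr``/``chrom``, ``start``, ``end`` and a
    height column (``height`` or ``summit_height``).  Widths are always
    recomputed from coordinates; a disagreeing width column is only warned
    about (coordinate truth).
    """
    peaks: list[Peak] = []
    if format == "bed":
        with open(path) as fh:
            for line_no, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 5:
                    raise FormatError(
                        f"line {line_no}: BED peaks need a score column for height"
                    )
                try:
                    peaks.append(
                        Peak(fields[0], int(fields[1]), int(fields[2]), float(fields[4]))
                    )
                except ValueError as exc:
                    raise ParseError(f"line {line_no}: {exc}") from exc
    elif format == "danpos_tsv":
        df = pd.read_csv(path, sep="\t")
        if df.empty and df.columns.size == 0:
            return []
        cols = {c.lower(): c for c in df.columns}
        chrom_col = cols.get("chr") or cols.get("chrom")
        height_col = cols.get("height") or cols.get("summit_height")
        if chrom_col is None or height_col is None or "start" not in cols:
            raise FormatError("DANPOS TSV needs chr/start/end and a height column")
        for _, row in df.iterrows():
            start, end = int(row[cols["start"]]), int(row[cols["end"]])
            if "width" in cols and int(row[cols["width"]]) != end - start:
                log.warning(
                    "peak %s:%d-%d: width column %s != end-start %d; using coordinates",
                    row[chrom_col], start, end, row[cols["width"]], end - start,
                )
            peaks.append(Peak(str(row[chrom_col]), start, end, float(row[height_col])))
    else:
        raise ValueError(f"unknown peak format: {format}")
    return peaks


def write_peaks(path, peaks: list[Peak]) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tpeak{i}\t{p.height:g}\n")


# ---------------------------------------------------------------------------
# signal tracks


def read_signal(path, format: str = "bedgraph", step: int = 1) -> SignalTrack:
    """Read a bedGraph or fixedStep wiggle into a dense fixed-step track.

    Gaps are filled with 0.  Intervals must not overlap within a chromosome
    (after resampling to the track step); the last covered position sets each
    chromosome's length.
    """
    cover: dict[str, list[tuple[int, int, float]]] = {}
    if format == "bedgraph":
        with open(path) as fh:
            for line_no, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                try:
                    chrom, s, e, v = f[0], int(f[1]), int(f[2]), float(f[3])
                except (IndexError, ValueError) as exc:
                    raise ParseError(f"line {line_no}: malformed bedGraph") from exc
                cover.setdefault(chrom, []).append((s, e, v))
    elif format == "wiggle":
        chrom, pos, wstep, span = None, 0, 1, 1
        with open(path) as fh:
            for line_no, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                if line.startswith("fixedStep"):
                    kv = dict(tok.split("=") for tok in line.split()[1:])
                    chrom = kv["chrom"]
                    pos = int(kv["start"]) - 1  # wiggle is 1-based
                    wstep = int(kv.get("step", 1))
                    span = int(kv.get("span", wstep))
                    continue
                if chrom is None:
                    raise FormatError(f"line {line_no}: data before fixedStep header")
                cover.setdefault(chrom, []).append((pos, pos + span, float(line)))
                pos += wstep
    else:
        raise ValueError(f"unknown signal format: {format}")

    values: dict[str, np.ndarray] = {}
    for chrom, ivals in cover.items():
        ivals.sort()
        for (s1, e1, _), (s2, _, _) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise FormatError(f"{chrom}: overlapping intervals at {s2} < {e1}")
        n = -(-ivals[-1][1] // step)  # ceil
        arr = np.zeros(n, dtype=float)
        for s, e, v in ivals:
            arr[s // step : -(-e // step)] = v
        values[chrom] = arr
    return SignalTrack(values=values, step=step)


def write_bedgraph(path, track: SignalTrack) -> None:
    """Write a track as bedGraph, run-length collapsing equal adjacent bins."""
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            arr = track.values[chrom]
            if len(arr) == 0:
                continue
            edges = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], edges))
            ends = np.concatenate((edges, [len(arr)]))
            for s, e in zip(starts, ends):
                if arr[s] != 0:
                    fh.write(
                        f"{chrom}\t{s * track.step}\t{e * track.step}\t{arr[s]:g}\n"
                    )


# ---------------------------------------------------------------------------
# gene sets and tables


def read_gene_set(path, name: str | None = None) -> GeneSet:
    """Read a plain-text one-gene-per-line list; duplicates collapse silently."""
    ids: set[str] = set()
    with open(path) as fh:
        for line in fh:
            gene = line.strip()
            if gene and not gene.startswith("#"):
                ids.add(gene)
    return GeneSet(name=name or str(path), gene_ids=ids)


def write_gene_set(path, gene_set: GeneSet) -> None:
    with open(path, "w") as fh:
        for gid in sorted(gene_set.gene_ids):
            fh.write(gid + "\n")


def read_table(path, value_column: str | None = None) -> pd.Series | pd.DataFrame:
    """Read a TSV with gene_id in the first column.

    With ``value_column`` (or a two-column table) a float Series indexed by
    gene_id is returned; otherwise the full DataFrame.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if value_column is not None:
        return df[value_column].astype(float)
    if df.shape[1] == 1:
        return df.iloc[:, 0].astype(float)
    return df
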