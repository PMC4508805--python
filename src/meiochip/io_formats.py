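"""Readers/writers for the genomic file formats the pipeline touches.

Every coordinate in this package is 0-based, half-open (BED native). The
only place a conversion could happen is here, at the I/O boundary; no
other module is allowed to reinterpret coordinates.

Gene anchors are strand-aware: the TSS of a minus-strand gene is its last
base (``end - 1``), not ``end``, so that windows are always anchored on a
real base. Tag positions are the 5'-most base of the read on its own
strand (``start`` for plus reads, ``end - 1`` for minus reads).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GeneAnnotation",
    "TagCollection",
    "read_annotation",
    "write_annotation",
    "read_tags",
    "write_tags",
    "read_bam_tags",
    "write_profile_track",
    "read_profile_track",
]

_STRANDS = ("+", "-")


def _norm_strand(s: str) -> str:
    # tolerate the typographic minus sign occasionally found in tables
    s = s.replace("−", "-")
    if s not in _STRANDS:
        raise ValueError(f"invalid strand {s!r}; expected '+' or '-'")
    return s


@dataclass(frozen=True)
class GeneAnnotation:
    """A single gene model: interval, strand, and derived TSS/TES anchors."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    is_x: bool = False

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"{self.gene_id}: negative start {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"{self.gene_id}: start {self.start} must be < end {self.end}"
            )
        object.__setattr__(self, "strand", _norm_strand(self.strand))

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TagCollection:
    """One mark x stage set of aligned tag 5' positions with strand.

    ``library_size`` defaults to the number of tags but may be overridden
    (e.g. when a collection is a subset of a larger sequenced library).
    """

    mark: str = ""
    stage: str = ""
    chrom: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))
    pos5: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    strand: np.ndarray = field(default_factory=lambda: np.empty(0, dtype="<U1"))
    library_size: int | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos5 = np.asarray(self.pos5, dtype=np.int64)
        self.strand = np.asarray(self.strand, dtype="<U1")
        if not (len(self.chrom) == len(self.pos5) == len(self.strand)):
            raise ValueError("chrom/pos5/strand arrays must have equal length")
        if self.library_size is None:
            self.library_size = len(self.pos5)

    def __len__(self) -> int:
        return len(self.pos5)

    def positions_by_chrom(self, strand: str | None = None) -> dict[str, np.ndarray]:
        """Sorted tag positions per chromosome, optionally one strand only."""
        mask = np.ones(len(self), dtype=bool)
        if strand is not None:
            mask = self.strand == _norm_strand(strand)
        out: dict[str, np.ndarray] = {}
        chroms = self.chrom[mask]
        pos = self.pos5[mask]
        for c in np.unique(chroms.astype(str)):
            out[c] = np.sort(pos[chroms == c])
        return out

    def with_positions(self, pos5: np.ndarray) -> "TagCollection":
        return TagCollection(
            mark=self.mark,
            stage=self.stage,
            chrom=self.chrom.copy(),
            pos5=np.asarray(pos5, dtype=np.int64),
            strand=self.strand.copy(),
            library_size=self.library_size,
        )


def _split_bed_line(line: str, lineno: int, path: str, min_cols: int) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) == 1:  # tolerate space-separated toy files
        fields = line.split()
    if len(fields) < min_cols:
        raise ValueError(
            f"{path}:{lineno}: expected >= {min_cols} BED columns, got {len(fields)}"
        )
    return fields


def read_annotation(path: str, x_chrom_name: str = "chrX") -> list[GeneAnnotation]:
    """Read a BED6 gene annotation (chrom, start, end, name, score, strand).

    Raises on malformed lines (naming the line number), on ``start >= end``,
    and on duplicate gene ids.
    """
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = _split_bed_line(line, lineno, path, 6)
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            gene_id = f[3]
            if gene_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            try:
                gene = GeneAnnotation(
                    gene_id=gene_id,
                    chrom=f[0],
                    start=start,
                    end=end,
                    strand=f[5],
                    is_x=(f[0] == x_chrom_name),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            genes.append(gene)
    return genes


def write_annotation(genes: Sequence[GeneAnnotation], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def collapse_duplicates(tags: TagCollection) -> TagCollection:
    """Keep one tag per (chrom, pos5, strand); library_size is recounted.

    Whether duplicate tags should be collapsed before density calculation
    is a judgement call; nothing in this package does it implicitly.
    """
    seen: set[tuple] = set()
    keep = np.zeros(len(tags), dtype=bool)
    for i, key in enumerate(zip(tags.chrom, tags.pos5, tags.strand)):
        if key not in seen:
            seen.add(key)
            keep[i] = True
    return TagCollection(
        mark=tags.mark,
        stage=tags.stage,
        chrom=tags.chrom[keep],
        pos5=tags.pos5[keep],
        strand=tags.strand[keep],
        library_size=int(keep.sum()),
    )


def read_tags(
    path: str, mark: str = "", stage: str = "", dedup: bool = False
) -> TagCollection:
    """Read aligned tags from a BED file (strand column required).

    The tag position recorded is the 5' end of the read on its own strand:
    ``start`` for plus reads and ``end - 1`` for minus reads. With
    ``dedup`` duplicate (chrom, pos5, strand) tags are collapsed to one.
    """
    chroms: list[str] = []
    pos: list[int] = []
    strands: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = _split_bed_line(line, lineno, path, 6)
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            strand = _norm_strand(f[5])
            chroms.append(f[0])
            pos.append(start if strand == "+" else end - 1)
            strands.append(strand)
    if not pos:
        warnings.warn(f"{path}: no tags found; empty collection", stacklevel=2)
    tc = TagCollection(
        mark=mark,
        stage=stage,
        chrom=np.array(chroms, dtype=object),
        pos5=np.array(pos, dtype=np.int64),
        strand=np.array(strands, dtype="<U1"),
        library_size=len(pos),
    )
    return collapse_duplicates(tc) if dedup else tc


def write_tags(tags: TagCollection, path: str, read_length: int = 1) -> None:
    """Write tags as BED6 with ``read_length``-bp intervals anchored at pos5.

    With the default 1-bp interval the file round-trips exactly through
    :func:`read_tags` on both strands.
    """
    with open(path, "w") as fh:
        for c, p, s in zip(tags.chrom, tags.pos5, tags.strand):
            if s == "+":
                start, end = p, p + read_length
            else:
                start, end = p - read_length + 1, p + 1
            fh.write(f"{c}\t{max(0, start)}\t{end}\ttag\t0\t{s}\n")


def read_bam_tags(path: str, mark: str = "", stage: str = "") -> TagCollection:
    """Optional BAM reader mapped onto the same contract as :func:`read_tags`.

    Requires :mod:`pysam`; BED remains the reference format.
    """
    import pysam  # deferred: optional dependency

    chroms: list[str] = []
    pos: list[int] = []
    strands: list[str] = []
    with pysam.AlignmentFile(path, "rb") as bam:
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped:
                continue
            if read.is_reverse:
                chroms.append(read.reference_name)
                pos.append(read.reference_end - 1)
                strands.append("-")
            else:
                chroms.append(read.reference_name)
                pos.append(read.reference_start)
                strands.append("+")
    return TagCollection(
        mark=mark,
        stage=stage,
        chrom=np.array(chroms, dtype=object),
        pos5=np.array(pos, dtype=np.int64),
        strand=np.array(strands, dtype="<U1"),
        library_size=len(pos),
    )


_TRACK_HEADER = 'track type=bedGraph name="{name}"\n'


def write_profile_track(
    profile,
    path: str,
    chrom: str = "profile",
    name: str = "meiochip",
) -> None:
    """Write a binned profile as bedGraph (0-based half-open bins).

    ``profile`` is either an object with ``x_offsets`` (bin centers, evenly
    spaced) and ``values``, or a ``(starts, ends, values)`` triple of equal
    length. Offsets that would produce negative starts are shifted up by a
    constant so the track is valid bedGraph; values are never altered.
    Overlapping bins raise.
    """
    if hasattr(profile, "x_offsets"):
        centers = np.asarray(profile.x_offsets, dtype=float)
        values = np.asarray(profile.values, dtype=float)
        if centers.size == 0:
            starts = ends = np.empty(0, dtype=np.int64)
        else:
            step = int(round(centers[1] - centers[0])) if centers.size > 1 else 1
            if step <= 0:
                raise ValueError("x_offsets must be increasing")
            starts = np.round(centers - step / 2).astype(np.int64)
            shift = -min(0, int(starts.min()))
            starts = starts + shift
            ends = starts + step
    else:
        starts, ends, values = (np.asarray(a) for a in profile)
        starts = starts.astype(np.int64)
        ends = ends.astype(np.int64)
    if not (len(starts) == len(ends) == len(values)):
        raise ValueError("starts/ends/values must have equal length")
    if np.any(ends <= starts):
        raise ValueError("empty or inverted bin")
    order = np.argsort(starts, kind="stable")
    if np.any(ends[order][:-1] > starts[order][1:]):
        raise ValueError("overlapping bins")
    with open(path, "w") as fh:
        fh.write(_TRACK_HEADER.format(name=name))
        for s, e, v in zip(starts, ends, np.asarray(values, dtype=float)):
            fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")


def read_profile_track(path: str):
    """Read a bedGraph written by :func:`write_profile_track`.

    Returns ``(chroms, starts, ends, values)`` as numpy arrays.
    """
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if len(f) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chroms.append(f[0])
            starts.append(int(f[1]))
            ends.append(int(f[2]))
            values.append(float(f[3]))
    return (
        np.array(chroms, dtype=object),
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
        np.array(values, dtype=float),
    )
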