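"""Simple-repeat annotation: homopolymer scanning and tandem-repeat tables.

Microsatellite instability manifests as somatic length changes in *simple
repeats*: mononucleotide runs (homopolymers, here of length >= 5) and short
tandem repeats with 2-4 bp units. This module builds the repeat annotation
used to decide whether a mutation lies "in a simple repeat": homopolymers
are scanned directly from reference sequence, tandem repeats are imported
from a UCSC-``simpleRepeats``-style table, and both are merged into a single
queryable track.

All coordinates are 0-based half-open internally; conversions to and from
1-based or other conventions happen only at file boundaries.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

HOMOPOLYMER = "homopolymer"
TANDEM = "tandem"

_NUC = frozenset(b"ACGTN")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two half-open intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def scan_homopolymers(
    sequence: str, chrom: str, min_len: int = 5
) -> list[GenomicInterval]:
    """Find maximal single-base runs of length >= ``min_len``.

    The scan is case-insensitive (soft-masked references must not hide
    repeats) and runs of N are never reported: an ambiguity base is not
    evidence of a repeat, and it breaks any run it interrupts.

    Parameters
    ----------
    sequence
        Nucleotide string over {A,C,G,T,N}, either case.
    chrom
        Chromosome name attached to the reported intervals.
    min_len
        Minimum run length, >= 2. The default of 5 is the conventional
        lower bound for a mononucleotide microsatellite.

    Raises
    ------
    ValueError
        If a non-nucleotide character is present (the position is named).
    """
    if min_len < 2:
        raise ValueError(f"min_len must be >= 2, got {min_len}")
    if not sequence:
        return []
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    valid = np.isin(arr, np.frombuffer(b"ACGTN", dtype=np.uint8))
    if not valid.all():
        pos = int(np.flatnonzero(~valid)[0])
        raise ValueError(
            f"non-nucleotide character {sequence[pos]!r} at position {pos}"
        )
    boundaries = np.flatnonzero(arr[1:] != arr[:-1]) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [arr.size]))
    keep = ((ends - starts) >= min_len) & (arr[starts] != ord("N"))
    return [
        GenomicInterval(chrom, int(s), int(e))
        for s, e in zip(starts[keep], ends[keep])
    ]


def load_tandem_repeat_table(path) -> list[GenomicInterval]:
    """Read a UCSC-``simpleRepeats``-style TSV, keeping periods 2, 3 and 4.

    The table must carry at least ``chrom``, ``chromStart``, ``chromEnd``
    and ``period`` columns (0-based half-open coordinates). Only rows whose
    repeat-unit size (``period``) is 2, 3 or 4 — di-, tri- and
    tetranucleotide microsatellites — are retained; coordinates are passed
    through unchanged.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["chrom", "chromStart", "chromEnd", "period"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"tandem-repeat table missing required column {col!r}")
    out: list[GenomicInterval] = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            start = int(getattr(row, "chromStart"))
            end = int(getattr(row, "chromEnd"))
            period = int(getattr(row, "period"))
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"malformed tandem-repeat row at line {line_no}: {exc}"
            ) from None
        if period in (2, 3, 4):
            out.append(GenomicInterval(normalize_chrom(row.chrom), start, end))
    return out


def normalize_chrom(chrom: str) -> str:
    """Strip a leading 'chr' so UCSC- and Ensembl-style names interoperate."""
    chrom = str(chrom).strip()
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


class RepeatTrack:
    """A merged, sorted, binary-searchable set of repeat intervals.

    Intervals are merged on construction so that no two intervals on the
    same chromosome overlap or abut; a merged interval keeps the union of
    the source tags of its constituents. Overlap queries are answered by
    binary search over per-chromosome start/end arrays.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval],
        tags: Iterable[str] | None = None,
    ) -> None:
        intervals = list(intervals)
        if tags is None:
            tag_list = [frozenset() for _ in intervals]
        else:
            tag_list = [
                t if isinstance(t, frozenset) else frozenset([t]) for t in tags
            ]
            if len(tag_list) != len(intervals):
                raise ValueError("tags must match intervals one-to-one")
        by_chrom: dict[str, list[tuple[int, int, frozenset]]] = {}
        for iv, tg in sorted(
            zip(intervals, tag_list), key=lambda p: (p[0].chrom, p[0].start)
        ):
            merged = by_chrom.setdefault(iv.chrom, [])
            if merged and iv.start <= merged[-1][1]:  # overlap or abut
                s, e, t = merged[-1]
                merged[-1] = (s, max(e, iv.end), t | tg)
            else:
                merged.append((iv.start, iv.end, tg))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._tags: dict[str, list[frozenset]] = {}
        for chrom, merged in by_chrom.items():
            self._starts[chrom] = np.array([m[0] for m in merged], dtype=np.int64)
            self._ends[chrom] = np.array([m[1] for m in merged], dtype=np.int64)
            self._tags[chrom] = [m[2] for m in merged]

    def __len__(self) -> int:
        return sum(a.size for a in self._starts.values())

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in sorted(self._starts):
            for s, e in zip(self._starts[chrom], self._ends[chrom]):
                yield GenomicInterval(chrom, int(s), int(e))

    @property
    def intervals(self) -> list[GenomicInterval]:
        return list(self)

    def tags(self) -> list[frozenset]:
        return [t for chrom in sorted(self._tags) for t in self._tags[chrom]]

    @property
    def total_bp(self) -> int:
        return int(
            sum((self._ends[c] - self._starts[c]).sum() for c in self._starts)
        )

    def overlaps(self, query: GenomicInterval) -> bool:
        """True iff at least one base of ``query`` is covered by the track."""
        starts = self._starts.get(query.chrom)
        if starts is None or starts.size == 0:
            return False
        ends = self._ends[query.chrom]
        # rightmost interval starting before query.end; merged+sorted means
        # only that one can reach back into the query
        i = int(np.searchsorted(starts, query.end, side="left"))
        return i > 0 and int(ends[i - 1]) > query.start

    def overlapping_index_range(self, query: GenomicInterval) -> tuple[int, int]:
        """Half-open index range of this track's intervals overlapping ``query``.

        Indices refer to the track's chromosome-local merged interval list
        and support counting distinct repeat intervals across many regions.
        """
        starts = self._starts.get(query.chrom)
        if starts is None or starts.size == 0:
            return (0, 0)
        ends = self._ends[query.chrom]
        hi = int(np.searchsorted(starts, query.end, side="left"))
        lo = int(np.searchsorted(ends, query.start, side="right"))
        return (lo, hi) if lo < hi else (0, 0)

    def count_overlapping(self, regions: Sequence[GenomicInterval]) -> int:
        """Number of distinct track intervals overlapping any of ``regions``."""
        seen: set[tuple[str, int]] = set()
        for region in regions:
            lo, hi = self.overlapping_index_range(region)
            seen.update((region.chrom, i) for i in range(lo, hi))
        return len(seen)

    def to_bed(self, path) -> None:
        """Write the merged track as BED (0-based half-open), tag in column 4."""
        with open(path, "w") as fh:
            for chrom in sorted(self._starts):
                for s, e, t in zip(
                    self._starts[chrom], self._ends[chrom], self._tags[chrom]
                ):
                    tag = ",".join(sorted(t)) or "."
                    fh.write(f"{chrom}\t{s}\t{e}\t{tag}\n")

    @classmethod
    def from_bed(cls, path) -> "RepeatTrack":
        intervals: list[GenomicInterval] = []
        tags: list[frozenset] = []
        with open(path) as fh:
            for line_no, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"BED line {line_no}: fewer than 3 columns")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                intervals.append(
                    GenomicInterval(normalize_chrom(chrom), start, end)
                )
                if len(parts) >= 4 and parts[3] != ".":
                    tags.append(frozenset(parts[3].split(",")))
                else:
                    tags.append(frozenset())
        return cls(intervals, tags)


def merge_tracks(
    a: Iterable[GenomicInterval] | RepeatTrack,
    b: Iterable[GenomicInterval] | RepeatTrack,
    tag_a: str = HOMOPOLYMER,
    tag_b: str = TANDEM,
) -> RepeatTrack:
    """Union two interval sources into one merged track.

    Coverage is preserved: a base is covered in the result iff it is
    covered in ``a`` or in ``b``. Plain interval iterables receive
    ``tag_a`` / ``tag_b`` as their source tags; RepeatTrack inputs keep
    their own tags.
    """

    def _items(src, default_tag):
        if isinstance(src, RepeatTrack):
            return list(src), src.tags()
        ivs = list(src)
        return ivs, [frozenset([default_tag])] * len(ivs)

    ivs_a, tags_a = _items(a, tag_a)
    ivs_b, tags_b = _items(b, tag_b)
    return RepeatTrack(ivs_a + ivs_b, tags_a + tags_b)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Sort and merge overlapping or abutting intervals."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda v: (v.chrom, v.start)):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out
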