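"""Somatic mutation catalogs (MAF dialect) and capture designs (BED).

A somatic mutation catalog is the list of cancer-specific mutations called
from a tumor/normal pair, grouped per tumor sample. MSI assessment here
needs only two mutation classes: single-nucleotide substitutions (SNS) and
microindels (small insertions and deletions). Multi-nucleotide
substitutions (DNP/TNP/ONP) and any other variant types are excluded —
conservatively, with a per-type tally rather than silent dropping.

MAF coordinates are 1-based inclusive; for insertions the MAF convention
``End_Position = Start_Position + 1`` records the two flanking bases. BED
capture designs are 0-based half-open. ``mutation_span`` converts every
mutation to the internal half-open convention for overlap tests.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .repeats import GenomicInterval, merge_intervals, normalize_chrom

SNS = "SNS"
INS = "INS"
DEL = "DEL"

_MAF_TYPE_MAP = {"SNP": SNS, "INS": INS, "DEL": DEL}

MSI_HIGH = "MSI-H"
NON_MSI_HIGH = "Non-MSI-H"
LAB_STATUSES = ("MSI-H", "MSI-L", "MSS")


@dataclass(frozen=True)
class SomaticMutation:
    """One somatic mutation in MAF coordinates (1-based inclusive)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    variant_class: str  # SNS | INS | DEL
    cancer_type: Optional[str] = None

    def __post_init__(self) -> None:
        if self.variant_class not in (SNS, INS, DEL):
            raise ValueError(f"invalid variant_class {self.variant_class!r}")
        if self.variant_class in (SNS, DEL) and self.start > self.end:
            raise ValueError(
                f"start {self.start} > end {self.end} for {self.variant_class}"
            )


def mutation_span(m: SomaticMutation) -> GenomicInterval:
    """Half-open genomic span of a mutation for overlap testing.

    SNS and DEL map 1-based inclusive [start, end] to half-open
    [start-1, end). An INS sits between two bases; its span covers both
    flanking positions, which is again [start-1, end) under the MAF
    convention end = start + 1.
    """
    return GenomicInterval(m.chrom, m.start - 1, m.end)


@dataclass
class MutationCatalog:
    """Per-sample somatic mutations plus a tally of skipped records."""

    mutations: list[SomaticMutation] = field(default_factory=list)
    cancer_types: dict[str, str] = field(default_factory=dict)
    skipped: Counter = field(default_factory=Counter)

    @property
    def samples(self) -> list[str]:
        seen = dict.fromkeys(m.sample_id for m in self.mutations)
        return list(seen)

    def by_sample(self) -> dict[str, list[SomaticMutation]]:
        groups: dict[str, list[SomaticMutation]] = {}
        for m in self.mutations:
            groups.setdefault(m.sample_id, []).append(m)
        return groups

    def __len__(self) -> int:
        return len(self.mutations)


@dataclass
class CaptureDesign:
    """The genomic regions targeted for sequencing.

    ``regions`` is the merged, sorted interval set whose summed length is
    the per-Mb denominator for all mutation rates. ``raw_regions`` keeps
    the regions in file order (pre-merge): consecutive-group statistics and
    region-subsampling experiments operate on the original target regions,
    typically individual exons.
    """

    regions: list[GenomicInterval]
    raw_regions: list[GenomicInterval]

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval]) -> "CaptureDesign":
        raw = list(intervals)
        return cls(regions=merge_intervals(raw), raw_regions=raw)

    @property
    def total_length_bp(self) -> int:
        return sum(iv.length for iv in self.regions)

    @property
    def total_length_mb(self) -> float:
        return self.total_length_bp / 1e6


def read_maf(path) -> MutationCatalog:
    """Read a TCGA-dialect MAF into a :class:`MutationCatalog`.

    Requires at least the columns Chromosome, Start_Position (the
    Start_position spelling is also accepted, likewise End_Position),
    Variant_Type and Tumor_Sample_Barcode. Lines starting with ``#`` are
    skipped. Variant_Type SNP maps to SNS; INS and DEL map to themselves;
    every other type (DNP, TNP, ONP, ...) is skipped and tallied.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.empty:
        raise ValueError(f"MAF file {path} contains no mutation records")
    cols = {c.lower(): c for c in df.columns}

    def _col(*names: str) -> str:
        for n in names:
            if n.lower() in cols:
                return cols[n.lower()]
        raise ValueError(f"MAF file missing required column {names[0]!r}")

    c_chrom = _col("Chromosome")
    c_start = _col("Start_Position", "Start_position")
    c_end = _col("End_Position", "End_position")
    c_type = _col("Variant_Type")
    c_sample = _col("Tumor_Sample_Barcode")

    catalog = MutationCatalog()
    for row in df.itertuples(index=False):
        vt = str(getattr(row, c_type)).upper()
        cls = _MAF_TYPE_MAP.get(vt)
        if cls is None:
            catalog.skipped[vt] += 1
            continue
        catalog.mutations.append(
            SomaticMutation(
                sample_id=str(getattr(row, c_sample)),
                chrom=normalize_chrom(getattr(row, c_chrom)),
                start=int(getattr(row, c_start)),
                end=int(getattr(row, c_end)),
                variant_class=cls,
            )
        )
    return catalog


def write_maf(catalog: MutationCatalog, path) -> None:
    """Write a minimal MAF (the columns :func:`read_maf` requires)."""
    inv = {v: k for k, v in _MAF_TYPE_MAP.items()}
    with open(path, "w") as fh:
        fh.write(
            "Chromosome\tStart_Position\tEnd_Position\tVariant_Type\t"
            "Tumor_Sample_Barcode\n"
        )
        for m in catalog.mutations:
            fh.write(
                f"{m.chrom}\t{m.start}\t{m.end}\t{inv[m.variant_class]}\t"
                f"{m.sample_id}\n"
            )


def read_regions(path) -> CaptureDesign:
    """Read a BED capture design; merge regions before summing lengths."""
    raw: list[GenomicInterval] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"BED line {line_no}: fewer than 3 columns")
            start, end = int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(
                    f"BED line {line_no}: end {end} <= start {start}"
                )
            raw.append(GenomicInterval(normalize_chrom(parts[0]), start, end))
    return CaptureDesign.from_intervals(raw)


def write_regions(design: CaptureDesign, path) -> None:
    """Write the raw (file-order) regions of a capture design as BED."""
    with open(path, "w") as fh:
        for iv in design.raw_regions:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_sample_metadata(path) -> pd.DataFrame:
    """Read a sample-metadata TSV indexed by sample_id.

    Expected columns: ``sample_id``, ``cancer_type`` and optionally
    ``lab_msi_status`` (MSI-H / MSI-L / MSS).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise ValueError("metadata file missing required column 'sample_id'")
    if "lab_msi_status" in df.columns:
        bad = set(df["lab_msi_status"].dropna()) - set(LAB_STATUSES)
        if bad:
            raise ValueError(f"unknown lab_msi_status values: {sorted(bad)}")
    return df.set_index("sample_id")
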