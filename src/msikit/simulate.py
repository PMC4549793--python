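"""Synthetic cohorts and reference substrates for MSI classification.

Everything here is synthetic test substrate generated from a seed: no real
tumor or genome data is shipped or downloaded. The generator emulates the
statistical structure the classifier assumes:

* **non-MSI-H** tumors: low overall burden and very few repeat microindels
  (mean T.sns 3.0/Mb, mean S.ind 0.05/Mb);
* **MSI-H** tumors: mismatch-repair-deficient hypermutators with many
  somatic length changes in simple repeats (mean T.sns 30/Mb, mean S.ind
  1.5/Mb);
* **POLE-like** tumors: proofreading-deficient ultramutators with extreme
  substitution burden but few repeat indels (mean T.sns 80/Mb, mean S.ind
  0.05/Mb).

Per-sample mutation counts are negative-binomially distributed around the
class means (tumor burdens are overdispersed relative to Poisson);
in-repeat mutations are placed uniformly on repeat bases and the rest
uniformly on non-repeat capture bases, so a feature computation over the
generated files recovers each sample's drawn counts exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .mutations import (
    DEL,
    INS,
    SNS,
    CaptureDesign,
    MutationCatalog,
    SomaticMutation,
    write_maf,
    write_regions,
)
from .repeats import HOMOPOLYMER, TANDEM, GenomicInterval, RepeatTrack

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ClassRates:
    """Per-Mb mutation-rate means for one tumor class."""

    t_sns: float  # mean total SNS burden per Mb
    s_ind: float  # mean in-repeat microindel rate per Mb
    offrepeat_ind: float  # mean off-repeat microindel rate per Mb


@dataclass
class CohortSpec:
    """Parameters of a synthetic tumor cohort.

    Defaults put non-MSI-H S.ind far below the 0.395/Mb exome cutoff and
    MSI-H far above it, and give the POLE-like class the flag signature
    (T.sns above 60/Mb with S.ind below 0.18/Mb) with high probability.
    """

    n_msih: int = 20
    n_non: int = 75
    n_pole: int = 5
    capture_mb: float = 30.0
    repeat_density_per_kb: float = 5.6
    rates_non: ClassRates = field(default_factory=lambda: ClassRates(3.0, 0.05, 0.3))
    rates_msih: ClassRates = field(default_factory=lambda: ClassRates(30.0, 1.5, 3.0))
    rates_pole: ClassRates = field(default_factory=lambda: ClassRates(80.0, 0.05, 0.5))
    dispersion: float = 10.0  # negative-binomial size; larger -> closer to Poisson
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_msih, self.n_non, self.n_pole) < 0:
            raise ValueError("class counts must be >= 0")
        if self.n_msih + self.n_non + self.n_pole == 0:
            raise ValueError("cohort must contain at least one sample")
        if self.capture_mb <= 0:
            raise ValueError("capture_mb must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


# ---------------------------------------------------------------------------
# reference sequence with planted repeats


@dataclass
class ReferenceSim:
    """A synthetic reference chromosome plus its planted repeat truth set."""

    chrom: str
    sequence: str
    truth: RepeatTrack
    planted_homopolymers: list[GenomicInterval]
    planted_tandems: list[GenomicInterval]

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.chrom}\n")
            for i in range(0, len(self.sequence), 60):
                fh.write(self.sequence[i : i + 60] + "\n")


def _other_base(rng: np.random.Generator, exclude: set[int]) -> int:
    choices = np.array([b for b in _BASES if b not in exclude], dtype=np.uint8)
    return int(choices[rng.integers(choices.size)])


def generate_reference(
    length_bp: int,
    repeat_density_per_kb: float,
    seed: int,
    chrom: str = "1",
) -> ReferenceSim:
    """Random nucleotide sequence with repeats planted at a known density.

    ``repeat_density_per_kb`` is the number of planted repeat elements per
    kilobase; roughly 60% are homopolymer runs (length 5-12) and the rest
    di-/tri-/tetranucleotide tandem arrays (4-10 copies). Planted
    homopolymers have non-matching flanking bases, so a run scanner
    reports them at exactly their planted coordinates. The surrounding
    random sequence can of course contain chance runs as well; the truth
    track contains only the planted elements.
    """
    if length_bp < 10_000:
        raise ValueError("reference length must be >= 10 kb")
    if repeat_density_per_kb < 0:
        raise ValueError("repeat density must be >= 0")
    rng = np.random.default_rng(seed)
    seq = _BASES[rng.integers(4, size=length_bp)].copy()

    n_elements = int(round(repeat_density_per_kb * length_bp / 1000.0))
    homos: list[GenomicInterval] = []
    tandems: list[GenomicInterval] = []
    if n_elements:
        is_homo = rng.random(n_elements) < 0.6
        lengths = np.where(
            is_homo,
            rng.integers(5, 13, size=n_elements),
            rng.integers(2, 5, size=n_elements)
            * rng.integers(4, 11, size=n_elements),
        )
        total = int(lengths.sum())
        # one spacer base between consecutive elements, one at each end
        slack = length_bp - total - (n_elements + 1)
        if slack < 0:
            raise ValueError(
                f"repeat density {repeat_density_per_kb}/Kb is infeasible "
                f"for a {length_bp} bp sequence"
            )
        gaps = rng.multinomial(slack, np.full(n_elements + 1, 1 / (n_elements + 1)))
        pos = 0
        run_base: list[Optional[int]] = []
        for i in range(n_elements):
            pos += int(gaps[i]) + 1
            start, end = pos, pos + int(lengths[i])
            if is_homo[i]:
                base = int(_BASES[rng.integers(4)])
                seq[start:end] = base
                homos.append(GenomicInterval(chrom, start, end))
                run_base.append(base)
            else:
                period = int(rng.integers(2, 5))
                unit = _BASES[rng.integers(4, size=period)]
                seq[start:end] = np.resize(np.tile(unit, (end - start) // period + 1),
                                           end - start)
                tandems.append(GenomicInterval(chrom, start, end))
                run_base.append(None)
            pos = end
        # fix flanks so planted homopolymer runs are maximal as planted
        for iv, base in zip(homos, [b for b in run_base if b is not None]):
            if iv.start > 0 and seq[iv.start - 1] == base:
                seq[iv.start - 1] = _other_base(
                    rng, {base, int(seq[iv.start - 2]) if iv.start > 1 else base}
                )
            if iv.end < length_bp and seq[iv.end] == base:
                exclude = {base}
                if iv.end + 1 < length_bp:
                    exclude.add(int(seq[iv.end + 1]))
                seq[iv.end] = _other_base(rng, exclude)

    truth = RepeatTrack(
        homos + tandems,
        [HOMOPOLYMER] * len(homos) + [TANDEM] * len(tandems),
    )
    return ReferenceSim(
        chrom=chrom,
        sequence=seq.tobytes().decode("ascii"),
        truth=truth,
        planted_homopolymers=homos,
        planted_tandems=tandems,
    )


# ---------------------------------------------------------------------------
# cohort generator


@dataclass
class Cohort:
    """An in-memory synthetic cohort plus writers for its file forms."""

    catalog: MutationCatalog
    capture: CaptureDesign
    repeats: RepeatTrack
    metadata: pd.DataFrame  # sample_id index; cancer_type, lab_msi_status
    truth: pd.DataFrame  # sample_id index; true_class, plus drawn counts
    spec: CohortSpec

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "maf": outdir / "cohort.maf",
            "capture": outdir / "capture.bed",
            "repeats": outdir / "repeats.bed",
            "metadata": outdir / "samples.tsv",
            "truth": outdir / "truth.tsv",
        }
        write_maf(self.catalog, paths["maf"])
        write_regions(self.capture, paths["capture"])
        self.repeats.to_bed(paths["repeats"])
        self.metadata.to_csv(paths["metadata"], sep="\t", index=True)
        self.truth.to_csv(paths["truth"], sep="\t", index=True)
        return paths


def _build_capture(rng: np.random.Generator, capture_mb: float) -> CaptureDesign:
    """Exon-like target regions (150-1500 bp) over a handful of synthetic
    chromosomes, totalling ``capture_mb``."""
    target_bp = int(round(capture_mb * 1e6))
    regions: list[GenomicInterval] = []
    chroms = [str(c) for c in range(1, 6)]
    per_chrom = math.ceil(target_bp / len(chroms))
    remaining = target_bp
    for chrom in chroms:
        pos = 1000
        chrom_bp = 0
        while chrom_bp < min(per_chrom, remaining):
            size = int(rng.integers(150, 1501))
            size = min(size, remaining - chrom_bp) or 150
            regions.append(GenomicInterval(chrom, pos, pos + size))
            pos += size + int(rng.integers(200, 5000))
            chrom_bp += size
        remaining -= chrom_bp
        if remaining <= 0:
            break
    return CaptureDesign.from_intervals(regions)


def _plant_repeats(
    rng: np.random.Generator, capture: CaptureDesign, density_per_kb: float
) -> RepeatTrack:
    """Plant repeat intervals inside capture regions at a target density.

    Per region the element count is Poisson with mean density x region
    length; elements are placed non-overlapping and non-abutting (at least
    one spacer base), so the merged track retains exactly the planted
    element count and the realized density matches the request in
    expectation.
    """
    intervals: list[GenomicInterval] = []
    tags: list[str] = []
    for region in capture.regions:
        n = int(rng.poisson(density_per_kb * region.length / 1000.0))
        if n == 0:
            continue
        lengths = rng.integers(5, 21, size=n)
        while n > 0 and int(lengths[:n].sum()) + n + 1 > region.length:
            n -= 1  # density infeasible for this region; drop elements
        if n == 0:
            continue
        slack = region.length - int(lengths[:n].sum()) - (n + 1)
        gaps = rng.multinomial(slack, np.full(n + 1, 1 / (n + 1)))
        pos = region.start
        for i in range(n):
            pos += int(gaps[i]) + 1
            rep_len = int(lengths[i])
            intervals.append(GenomicInterval(region.chrom, pos, pos + rep_len))
            tags.append(HOMOPOLYMER if rep_len <= 12 else TANDEM)
            pos += rep_len
    return RepeatTrack(intervals, tags)


class _Placer:
    """Uniform placement of mutations on repeat / non-repeat capture bases.

    Both interval sets are addressed through cumulative-length arrays, so
    drawing a base uniformly over the covered sequence is a single random
    number plus a binary search.
    """

    def __init__(self, capture: CaptureDesign, repeats: RepeatTrack):
        self.repeats = repeats
        self.regions = capture.regions
        self._region_cum = np.cumsum([iv.length for iv in self.regions])
        self.rep_intervals = repeats.intervals
        self._rep_cum = (
            np.cumsum([iv.length for iv in self.rep_intervals])
            if self.rep_intervals
            else None
        )

    @staticmethod
    def _uniform_base(rng, intervals, cum) -> tuple[GenomicInterval, int]:
        u = int(rng.integers(int(cum[-1])))
        i = int(np.searchsorted(cum, u, side="right"))
        iv = intervals[i]
        offset = u - (int(cum[i - 1]) if i else 0)
        return iv, iv.start + offset

    def in_repeat_pos(self, rng: np.random.Generator) -> GenomicInterval:
        """One base chosen uniformly over repeat bases."""
        iv, pos = self._uniform_base(rng, self.rep_intervals, self._rep_cum)
        return GenomicInterval(iv.chrom, pos, pos + 1)

    def off_repeat_span(
        self, rng: np.random.Generator, span_len: int
    ) -> GenomicInterval:
        """A span of ``span_len`` bases inside one capture region touching
        no repeat (rejection sampling; the repeat fraction is small)."""
        for _ in range(10_000):
            region, pos = self._uniform_base(rng, self.regions, self._region_cum)
            if pos + span_len > region.end:
                continue
            candidate = GenomicInterval(region.chrom, pos, pos + span_len)
            if not self.repeats.overlaps(candidate):
                return candidate
        raise RuntimeError("could not place an off-repeat mutation")


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Negative-binomial count with the given mean and size (dispersion)."""
    if mean <= 0:
        return 0
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a synthetic tumor cohort from a :class:`CohortSpec`.

    The same seed always yields the identical cohort (and byte-identical
    files from :meth:`Cohort.write`).
    """
    rng = np.random.default_rng(spec.seed)
    capture = _build_capture(rng, spec.capture_mb)
    repeats = _plant_repeats(rng, capture, spec.repeat_density_per_kb)
    placer = _Placer(capture, repeats)
    mb = capture.total_length_mb
    repeat_fraction = repeats.total_bp / capture.total_length_bp

    cancer_types = ["colon", "rectal", "endometrial", "gastric"]
    classes = (
        [("MSI-H", spec.rates_msih)] * spec.n_msih
        + [("Non-MSI-H", spec.rates_non)] * spec.n_non
        + [("POLE", spec.rates_pole)] * spec.n_pole
    )
    catalog = MutationCatalog()
    meta_rows, truth_rows, sample_ids = [], [], []
    counters = {"MSI-H": 0, "Non-MSI-H": 0, "POLE": 0}
    for true_class, rates in classes:
        counters[true_class] += 1
        sid = f"SIM-{true_class.replace('-', '')}-{counters[true_class]:03d}"
        sample_ids.append(sid)

        n_sns = _nb_draw(rng, rates.t_sns * mb, spec.dispersion)
        n_s_sns = int(rng.binomial(n_sns, repeat_fraction)) if n_sns else 0
        n_s_ind = _nb_draw(rng, rates.s_ind * mb, spec.dispersion)
        n_off_ind = _nb_draw(rng, rates.offrepeat_ind * mb, spec.dispersion)
        if n_s_ind and not placer.rep_intervals:
            raise ValueError(
                "spec requests in-repeat microindels but the planted repeat "
                "density is zero"
            )

        for _ in range(n_s_sns):  # SNS on a repeat base
            iv = placer.in_repeat_pos(rng)
            catalog.mutations.append(
                SomaticMutation(sid, iv.chrom, iv.start + 1, iv.start + 1, SNS)
            )
        for _ in range(n_sns - n_s_sns):  # SNS off repeat
            iv = placer.off_repeat_span(rng, 1)
            catalog.mutations.append(
                SomaticMutation(sid, iv.chrom, iv.start + 1, iv.start + 1, SNS)
            )
        for _ in range(n_s_ind):  # microindel touching a repeat
            iv = placer.in_repeat_pos(rng)
            if rng.random() < 0.5:  # insertion between iv.start and iv.start+1
                catalog.mutations.append(
                    SomaticMutation(sid, iv.chrom, iv.start + 1, iv.start + 2, INS)
                )
            else:  # 1-bp deletion of the repeat base
                catalog.mutations.append(
                    SomaticMutation(sid, iv.chrom, iv.start + 1, iv.start + 1, DEL)
                )
        for _ in range(n_off_ind):  # microindel away from any repeat
            if rng.random() < 0.5:
                iv = placer.off_repeat_span(rng, 2)
                catalog.mutations.append(
                    SomaticMutation(sid, iv.chrom, iv.start + 1, iv.start + 2, INS)
                )
            else:
                del_len = int(rng.integers(1, 4))
                iv = placer.off_repeat_span(rng, del_len)
                catalog.mutations.append(
                    SomaticMutation(
                        sid, iv.chrom, iv.start + 1, iv.start + del_len, DEL
                    )
                )

        ctype = cancer_types[int(rng.integers(len(cancer_types)))]
        if true_class == "MSI-H":
            lab = "MSI-H"
        else:  # non-MSI-H and POLE-like tumors carry MSS or MSI-L lab labels
            lab = "MSS" if rng.random() < 0.7 else "MSI-L"
        meta_rows.append({"cancer_type": ctype, "lab_msi_status": lab})
        truth_rows.append(
            {
                "true_class": true_class,
                "n_sns": n_sns,
                "n_s_sns": n_s_sns,
                "n_s_ind": n_s_ind,
                "n_off_ind": n_off_ind,
            }
        )
        catalog.cancer_types[sid] = ctype

    index = pd.Index(sample_ids, name="sample_id")
    return Cohort(
        catalog=catalog,
        capture=capture,
        repeats=repeats,
        metadata=pd.DataFrame(meta_rows, index=index),
        truth=pd.DataFrame(truth_rows, index=index),
        spec=spec,
    )
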