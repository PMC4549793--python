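"""Per-tumor mutation-rate features over simple repeats.

For each tumor the feature vector consists of ten candidate classifier
inputs, all mutation counts normalized by the total targeted sequence
length in Mb:

========== =========================================================
T.sns      SNSs anywhere in the targeted sequence, per Mb
S.sns      SNSs in simple sequence repeats, per Mb
T.ind      microindels anywhere, per Mb
S.ind      microindels in simple sequence repeats, per Mb
T          all mutations (SNS + microindel), per Mb
S          all mutations in simple repeats, per Mb
ratio.sns  S.sns / T.sns
ratio.ind  S.ind / T.ind
ratio      S / T
cancer_type  categorical tumor-type label
========== =========================================================

S.ind — the rate of somatic length changes in simple repeats — is the
single feature the default classifier uses; it is the direct molecular
readout of microsatellite instability.

A mutation counts toward the S-variables iff its half-open span overlaps
the repeat track (any-overlap rule: a length change touching a repeat
changes the repeat's length). Mutations entirely outside the capture
design are excluded from all counts and tallied in a warning, because the
denominator is the targeted length. A ratio with zero denominator is
missing (NaN), never 0 or infinity.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .mutations import DEL, INS, SNS, CaptureDesign, MutationCatalog, mutation_span
from .repeats import GenomicInterval, RepeatTrack

logger = logging.getLogger(__name__)

RATE_COLUMNS = ["T.sns", "S.sns", "T.ind", "S.ind", "T", "S"]
RATIO_COLUMNS = ["ratio.sns", "ratio.ind", "ratio"]
FEATURE_COLUMNS = RATE_COLUMNS + RATIO_COLUMNS + ["cancer_type"]


def compute_features(
    catalog: MutationCatalog,
    repeats: RepeatTrack,
    capture: CaptureDesign,
    metadata: Optional[pd.DataFrame] = None,
    insertion_rule: str = "any",
    pad: int = 0,
    warn_off_target: bool = True,
) -> pd.DataFrame:
    """Compute the ten classifier input variables for every sample.

    Parameters
    ----------
    catalog, repeats, capture
        The somatic mutation catalog, merged simple-repeat track, and
        capture design whose total length is the per-Mb denominator.
    metadata
        Optional sample metadata (indexed by sample_id) supplying
        ``cancer_type``. Samples present in the metadata but absent from
        the catalog receive all-zero rates (and missing ratios).
    insertion_rule
        "any" (default): an insertion is in-repeat if either flanking base
        touches the repeat. "within": both flanks must lie inside.
    pad
        Optional symmetric padding (bp) applied to each mutation span
        before the repeat-overlap test.
    warn_off_target
        Log a warning when off-target mutations are excluded.

    Returns
    -------
    pandas.DataFrame
        One row per sample_id with columns T.sns, S.sns, T.ind, S.ind, T,
        S, ratio.sns, ratio.ind, ratio, cancer_type. The per-sample count
        of excluded off-target mutations is stored in
        ``df.attrs["off_target"]``.
    """
    if insertion_rule not in ("any", "within"):
        raise ValueError(f"insertion_rule must be 'any' or 'within', got {insertion_rule!r}")
    if capture.total_length_bp == 0:
        raise ValueError("capture design is empty; per-Mb rates are undefined")
    mb = capture.total_length_mb
    capture_track = RepeatTrack(capture.regions)

    sample_ids = list(catalog.samples)
    if metadata is not None:
        for sid in metadata.index:
            if sid not in sample_ids:
                sample_ids.append(sid)

    counts = {
        sid: {"t_sns": 0, "s_sns": 0, "t_ind": 0, "s_ind": 0} for sid in sample_ids
    }
    off_target: dict[str, int] = {sid: 0 for sid in sample_ids}

    for m in catalog.mutations:
        span = mutation_span(m)
        if not capture_track.overlaps(span):
            off_target[m.sample_id] += 1
            continue
        q = span
        if pad:
            q = GenomicInterval(span.chrom, max(0, span.start - pad), span.end + pad)
        if m.variant_class == INS and insertion_rule == "within":
            in_repeat = repeats.overlaps(
                GenomicInterval(q.chrom, q.start, q.start + 1)
            ) and repeats.overlaps(GenomicInterval(q.chrom, q.end - 1, q.end))
        else:
            in_repeat = repeats.overlaps(q)
        c = counts[m.sample_id]
        if m.variant_class == SNS:
            c["t_sns"] += 1
            c["s_sns"] += in_repeat
        else:
            c["t_ind"] += 1
            c["s_ind"] += in_repeat

    total_off = sum(off_target.values())
    if total_off and warn_off_target:
        logger.warning(
            "%d mutation(s) outside the capture design were excluded "
            "from all counts", total_off,
        )

    rows = []
    for sid in sample_ids:
        c = counts[sid]
        t_sns, s_sns = c["t_sns"] / mb, c["s_sns"] / mb
        t_ind, s_ind = c["t_ind"] / mb, c["s_ind"] / mb
        row = {
            "T.sns": t_sns,
            "S.sns": s_sns,
            "T.ind": t_ind,
            "S.ind": s_ind,
            "T": t_sns + t_ind,
            "S": s_sns + s_ind,
            "ratio.sns": s_sns / t_sns if c["t_sns"] else np.nan,
            "ratio.ind": s_ind / t_ind if c["t_ind"] else np.nan,
            "ratio": (s_sns + s_ind) / (t_sns + t_ind)
            if (c["t_sns"] + c["t_ind"])
            else np.nan,
        }
        if metadata is not None and sid in metadata.index and "cancer_type" in metadata.columns:
            row["cancer_type"] = metadata.loc[sid, "cancer_type"]
        else:
            row["cancer_type"] = catalog.cancer_types.get(sid)
        rows.append(row)

    df = pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample_id"))
    df = df[FEATURE_COLUMNS]
    df.attrs["off_target"] = off_target
    return df


def write_features(df: pd.DataFrame, path) -> None:
    """Write a feature table as TSV (one row per sample)."""
    df.to_csv(path, sep="\t", index=True)


def read_features(path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_features`."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    missing = [c for c in RATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing column(s): {missing}")
    return df
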