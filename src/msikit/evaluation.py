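"""Evaluation machinery: Fisher's exact test, ROC/AUC, concordance,
repeat-density summaries, and the random capture-subset robustness
experiment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact as _scipy_fisher
from sklearn.metrics import roc_auc_score, roc_curve

from .classifier import ClassifierBundle, PoleFlagRule, classify
from .features import compute_features
from .mutations import (
    MSI_HIGH,
    NON_MSI_HIGH,
    CaptureDesign,
    MutationCatalog,
)
from .repeats import GenomicInterval, RepeatTrack


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cell counts with rows = condition present/absent, columns =
    outcome present/absent."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table must contain observations")


def fisher_exact_one_sided(t: ContingencyTable2x2) -> float:
    """One-sided Fisher's exact p-value for enrichment in cell ``a``.

    The p-value is the hypergeometric tail probability of a table at
    least as extreme in the direction of larger ``a``, with all margins
    fixed — exact summation, no normal approximation. Degenerate margins
    give p = 1.
    """
    return float(
        _scipy_fisher([[t.a, t.b], [t.c, t.d]], alternative="greater").pvalue
    )


@dataclass
class RocResult:
    auc: float
    points: pd.DataFrame  # columns threshold, fpr, tpr


def _binarize_labels(labels: Sequence[str]) -> np.ndarray:
    """Map laboratory labels to binary: MSI-H positive; MSI-L and MSS are
    grouped as non-MSI-H."""
    out = []
    for lbl in labels:
        if lbl == MSI_HIGH:
            out.append(1)
        elif lbl in ("MSI-L", "MSS", NON_MSI_HIGH):
            out.append(0)
        else:
            raise ValueError(f"unknown MSI status label {lbl!r}")
    return np.asarray(out)


def roc_auc(scores: Sequence[float], labels: Sequence[str]) -> RocResult:
    """ROC curve and AUC for ranking samples by score (typically S.ind).

    AUC is the probability that a random positive outscores a random
    negative, with ties counted 1/2 (pair-count definition). Curve points
    are (FPR, TPR) at every distinct threshold.
    """
    y = _binarize_labels(labels)
    scores = np.asarray(scores, dtype=float)
    if scores.size != y.size:
        raise ValueError("scores and labels must have equal length")
    if np.unique(y).size < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thresholds = roc_curve(y, scores)
    return RocResult(
        auc=float(roc_auc_score(y, scores)),
        points=pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr}),
    )


def concordance(
    predicted: pd.Series | dict, laboratory: pd.Series | dict
) -> float:
    """Percentage agreement between classifier calls and laboratory status.

    Laboratory MSI-L and MSS both map to Non-MSI-H before comparison. The
    two inputs must cover exactly the same samples.
    """
    pred = pd.Series(predicted)
    lab = pd.Series(laboratory)
    missing = sorted(set(pred.index) ^ set(lab.index))
    if missing:
        raise ValueError(f"sample sets differ; unmatched samples: {missing}")
    lab_grouped = lab.map(
        lambda s: MSI_HIGH if s == MSI_HIGH else NON_MSI_HIGH
    )
    n = len(pred)
    matches = int((pred == lab_grouped.loc[pred.index]).sum())
    return 100.0 * matches / n


@dataclass
class SubsetExperimentResult:
    """Accuracy of subset-based MSI calls at each requested target length."""

    lengths_mb: list[float]
    mean_accuracy: list[float]
    sd_accuracy: list[float]
    n_reps: int
    achieved_lengths_mb: list[list[float]]  # per length, per replicate


def subset_experiment(
    catalog: MutationCatalog,
    capture: CaptureDesign,
    repeats: RepeatTrack,
    bundle: ClassifierBundle,
    lab_status: pd.Series,
    lengths_mb: Sequence[float],
    n_reps: int,
    seed: int,
    metadata: Optional[pd.DataFrame] = None,
    pole_rule: Optional[PoleFlagRule] = None,
) -> SubsetExperimentResult:
    """Classification accuracy on random subsets of the capture design.

    Each replicate draws whole target regions (typically exons) without
    replacement until the accumulated length first reaches the requested
    length; the final region may overshoot, and the achieved length is
    recorded and used as the per-Mb denominator. Features are recomputed
    on the subset, samples are classified with ``bundle``, and accuracy is
    the concordance of the subset-based calls with the laboratory labels.
    The whole experiment is determined by ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    total_bp = capture.total_length_bp
    for length in lengths_mb:
        if length * 1e6 > total_bp + 0.5:
            raise ValueError(
                f"requested subset length {length} Mb exceeds the capture "
                f"total of {total_bp / 1e6:.3f} Mb"
            )
    rng = np.random.default_rng(seed)
    regions = list(capture.raw_regions)
    mean_acc: list[float] = []
    sd_acc: list[float] = []
    achieved_all: list[list[float]] = []
    for length in lengths_mb:
        target_bp = int(round(length * 1e6))
        accs = np.empty(n_reps)
        achieved: list[float] = []
        for rep in range(n_reps):
            order = rng.permutation(len(regions))
            chosen: list[GenomicInterval] = []
            acc_bp = 0
            for idx in order:
                chosen.append(regions[idx])
                acc_bp += regions[idx].length
                if acc_bp >= target_bp:
                    break
            sub = CaptureDesign.from_intervals(chosen)
            feats = compute_features(
                catalog, repeats, sub, metadata=metadata, warn_off_target=False
            )
            calls = classify(feats, bundle, pole_rule)
            accs[rep] = concordance(
                calls["predicted_status"], lab_status
            )
            achieved.append(sub.total_length_mb)
        mean_acc.append(float(accs.mean()))
        sd_acc.append(float(accs.std(ddof=0)))
        achieved_all.append(achieved)
    return SubsetExperimentResult(
        lengths_mb=list(map(float, lengths_mb)),
        mean_accuracy=mean_acc,
        sd_accuracy=sd_acc,
        n_reps=n_reps,
        achieved_lengths_mb=achieved_all,
    )


@dataclass
class RepeatDensityResult:
    per_group: list[float]  # repeat intervals per Kb of grouped region length
    mean: float
    sd: float


def repeat_density(
    repeats: RepeatTrack,
    regions: Sequence[GenomicInterval],
    group_size: int = 1000,
) -> RepeatDensityResult:
    """Simple-repeat density over consecutive groups of target regions.

    Regions are taken in file order and chunked into consecutive groups of
    ``group_size``; for each group the density is the number of distinct
    repeat intervals overlapping the group's regions divided by the
    group's summed length in Kb.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    densities: list[float] = []
    regions = list(regions)
    for i in range(0, len(regions), group_size):
        group = regions[i : i + group_size]
        kb = sum(iv.length for iv in group) / 1000.0
        count = repeats.count_overlapping(group)
        densities.append(count / kb if kb > 0 else 0.0)
    arr = np.asarray(densities)
    return RepeatDensityResult(
        per_group=densities,
        mean=float(arr.mean()) if arr.size else 0.0,
        sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
    )
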