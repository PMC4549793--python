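"""MSI classification: packaged decision stumps, retraining, cross-validation.

The default classifier is deliberately simple: a tumor is called MSI-H iff
S.ind — somatic microindels in simple repeats per Mb of targeted sequence —
exceeds a fixed cutoff (0.395/Mb for exome data; 0.909/Mb for whole
genomes, where simple repeats are denser). Both cutoffs are packaged
verbatim; the inequality is strict, so a value exactly at the cutoff is
Non-MSI-H.

Independently of MSI status, samples with very high substitution burden but
few repeat indels (T.sns > 60/Mb and S.ind < 0.18/Mb, both strict) are
flagged as possible POLE-exonuclease-deficient ultramutators. The flag is
reported alongside the MSI call and never overrides it.

Retraining uses a C4.5-flavored decision-tree induction: greedy top-down
splits chosen by information-gain ratio over midpoint thresholds, with
one-vs-rest splits for the categorical cancer type, and bottom-up pruning
that replaces any subtree by its majority-class leaf when that does not
increase training error. It is a documented, reproducible procedure, not a
bit-exact clone of any particular toolkit's tree learner.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .mutations import MSI_HIGH, NON_MSI_HIGH

LABELS = (MSI_HIGH, NON_MSI_HIGH)


# ---------------------------------------------------------------------------
# tree structure


@dataclass
class TreeNode:
    """A decision-tree node.

    ``kind`` is "leaf", "numeric" or "categorical". A numeric node sends
    feature <= threshold left and feature > threshold right. A categorical
    node sends feature == category left and everything else right
    (one-vs-rest).
    """

    kind: str
    label: Optional[str] = None  # leaves
    feature: Optional[str] = None  # internal nodes
    threshold: Optional[float] = None  # numeric nodes
    category: Optional[str] = None  # categorical nodes
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    def predict(self, row, sample_id: str = "?", on_missing: str = "raise") -> str:
        """Route one sample to a leaf.

        ``on_missing`` controls what happens when a required numeric
        feature is absent or NaN: "raise" (default, names the sample and
        feature) or "right" (route down the > branch, the convention used
        internally during induction and pruning).
        """
        node = self
        while node.kind != "leaf":
            value = row.get(node.feature) if hasattr(row, "get") else row[node.feature]
            if node.kind == "numeric":
                missing = value is None or (
                    isinstance(value, float) and math.isnan(value)
                )
                if missing:
                    if on_missing == "raise":
                        raise ValueError(
                            f"sample {sample_id!r}: feature {node.feature!r} "
                            f"required by the classifier is missing"
                        )
                    node = node.right
                else:
                    node = node.left if float(value) <= node.threshold else node.right
            else:
                node = node.left if value == node.category else node.right
        return node.label

    def depth(self) -> int:
        if self.kind == "leaf":
            return 0
        return 1 + max(self.left.depth(), self.right.depth())

    def to_dict(self) -> dict:
        if self.kind == "leaf":
            return {"kind": "leaf", "label": self.label}
        d = {"kind": self.kind, "feature": self.feature,
             "left": self.left.to_dict(), "right": self.right.to_dict()}
        if self.kind == "numeric":
            d["threshold"] = self.threshold
        else:
            d["category"] = self.category
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        for key in ("kind",):
            if key not in d:
                raise ValueError(f"tree node missing field {key!r}")
        if d["kind"] == "leaf":
            if "label" not in d:
                raise ValueError("tree leaf missing field 'label'")
            return cls(kind="leaf", label=d["label"])
        for key in ("feature", "left", "right"):
            if key not in d:
                raise ValueError(f"tree node missing field {key!r}")
        if d["kind"] == "numeric":
            if "threshold" not in d:
                raise ValueError("numeric tree node missing field 'threshold'")
            return cls(
                kind="numeric", feature=d["feature"],
                threshold=float(d["threshold"]),
                left=cls.from_dict(d["left"]), right=cls.from_dict(d["right"]),
            )
        if d["kind"] == "categorical":
            if "category" not in d:
                raise ValueError("categorical tree node missing field 'category'")
            return cls(
                kind="categorical", feature=d["feature"], category=d["category"],
                left=cls.from_dict(d["left"]), right=cls.from_dict(d["right"]),
            )
        raise ValueError(f"unknown tree node kind {d['kind']!r}")


def stump(feature: str, threshold: float, above: str, below: str) -> TreeNode:
    """A single numeric split: feature > threshold -> ``above``."""
    return TreeNode(
        kind="numeric", feature=feature, threshold=threshold,
        left=TreeNode(kind="leaf", label=below),
        right=TreeNode(kind="leaf", label=above),
    )


@dataclass
class ClassifierBundle:
    """A decision tree plus its provenance."""

    tree: TreeNode
    regime: str  # "exome" | "genome"
    provenance: str = ""
    version: str = "1"


@dataclass(frozen=True)
class PoleFlagRule:
    """Flag possible POLE-deficient ultramutators.

    A sample is flagged iff T.sns > t_sns_cutoff and S.ind < s_ind_cutoff,
    both inequalities strict.
    """

    t_sns_cutoff: float = 60.0
    s_ind_cutoff: float = 0.18

    def __post_init__(self) -> None:
        if self.t_sns_cutoff <= 0 or self.s_ind_cutoff <= 0:
            raise ValueError("POLE-flag cutoffs must be positive")

    def applies(self, t_sns: float, s_ind: float) -> bool:
        return t_sns > self.t_sns_cutoff and s_ind < self.s_ind_cutoff


@dataclass(frozen=True)
class ClassificationResult:
    sample_id: str
    predicted_status: str  # MSI-H | Non-MSI-H
    pole_flag: bool
    s_ind_used: float


def default_exome_classifier() -> ClassifierBundle:
    """The packaged whole-exome classifier: MSI-H iff S.ind > 0.395/Mb."""
    return ClassifierBundle(
        tree=stump("S.ind", 0.395, above=MSI_HIGH, below=NON_MSI_HIGH),
        regime="exome",
        provenance=(
            "packaged decision stump on S.ind for whole-exome somatic "
            "mutation catalogs; cutoff 0.395 microindels in simple "
            "repeats per Mb"
        ),
    )


def default_genome_classifier() -> ClassifierBundle:
    """The packaged whole-genome classifier: MSI-H iff S.ind > 0.909/Mb.

    Simple repeats are denser genome-wide (about 7.4/Kb) than in exome
    target regions (about 5.6/Kb), so the whole-genome cutoff is higher.
    """
    return ClassifierBundle(
        tree=stump("S.ind", 0.909, above=MSI_HIGH, below=NON_MSI_HIGH),
        regime="genome",
        provenance=(
            "packaged decision stump on S.ind for whole-genome somatic "
            "mutation catalogs; cutoff 0.909 microindels in simple "
            "repeats per Mb"
        ),
    )


def classify(
    features: pd.DataFrame,
    bundle: ClassifierBundle,
    pole_rule: Optional[PoleFlagRule] = None,
) -> pd.DataFrame:
    """Classify every sample in a feature table.

    Returns a DataFrame indexed by sample_id with columns
    ``predicted_status``, ``pole_flag`` and ``S.ind``. MSI status and the
    POLE flag are independent outputs. A tree that needs a feature missing
    for some sample raises, naming the sample and feature.
    """
    if pole_rule is None:
        pole_rule = PoleFlagRule()
    rows = []
    for sid, row in features.iterrows():
        status = bundle.tree.predict(row, sample_id=str(sid))
        rows.append(
            {
                "predicted_status": status,
                "pole_flag": bool(
                    pole_rule.applies(float(row["T.sns"]), float(row["S.ind"]))
                )
                if "T.sns" in row and "S.ind" in row
                else False,
                "S.ind": float(row["S.ind"]) if "S.ind" in row else np.nan,
            }
        )
    return pd.DataFrame(rows, index=features.index.rename("sample_id"))


def write_classification(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=True)


# ---------------------------------------------------------------------------
# training (C4.5-flavored induction)


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _label_counts(y: np.ndarray) -> np.ndarray:
    return np.array([(y == lbl).sum() for lbl in LABELS])


def _majority(y: np.ndarray) -> str:
    counts = _label_counts(y)
    # ties break toward MSI-H (first label) deterministically
    return LABELS[int(np.argmax(counts))]


@dataclass
class _Split:
    gain_ratio: float
    gain: float
    kind: str
    feature: str
    threshold: float = math.nan
    category: str = ""
    mask_left: np.ndarray = field(default_factory=lambda: np.array([], bool))


def _best_numeric_split(x: np.ndarray, y: np.ndarray, feature: str,
                        min_leaf: int) -> Optional[_Split]:
    ok = ~np.isnan(x)
    if ok.sum() < 2 * min_leaf:
        return None
    xv, yv = x[ok], y[ok]
    order = np.argsort(xv, kind="stable")
    xs = xv[order]
    distinct = np.unique(xs)
    if distinct.size < 2:
        return None
    thresholds = (distinct[:-1] + distinct[1:]) / 2.0
    parent = _entropy(_label_counts(yv))
    n = yv.size
    best: Optional[_Split] = None
    for thr in thresholds:  # ascending: ties in gain keep smallest threshold
        left = xv <= thr
        nl = int(left.sum())
        if nl < min_leaf or n - nl < min_leaf:
            continue
        child = (
            nl * _entropy(_label_counts(yv[left]))
            + (n - nl) * _entropy(_label_counts(yv[~left]))
        ) / n
        gain = parent - child
        if gain <= 1e-12:
            continue
        split_info = _entropy(np.array([nl, n - nl]))
        gr = gain / split_info if split_info > 0 else 0.0
        if best is None or gr > best.gain_ratio + 1e-12:
            mask = np.zeros(y.size, bool)
            mask[np.flatnonzero(ok)[left]] = True
            best = _Split(gr, gain, "numeric", feature, threshold=float(thr),
                          mask_left=mask)
    return best


def _best_categorical_split(values: np.ndarray, y: np.ndarray, feature: str,
                            min_leaf: int) -> Optional[_Split]:
    parent = _entropy(_label_counts(y))
    n = y.size
    best: Optional[_Split] = None
    for cat in sorted({v for v in values if v is not None and v == v}):
        left = values == cat
        nl = int(left.sum())
        if nl < min_leaf or n - nl < min_leaf:
            continue
        child = (
            nl * _entropy(_label_counts(y[left]))
            + (n - nl) * _entropy(_label_counts(y[~left]))
        ) / n
        gain = parent - child
        if gain <= 1e-12:
            continue
        split_info = _entropy(np.array([nl, n - nl]))
        gr = gain / split_info if split_info > 0 else 0.0
        if best is None or gr > best.gain_ratio + 1e-12:
            best = _Split(gr, gain, "categorical", feature, category=str(cat),
                          mask_left=left.copy())
    return best


def _grow(
    X: dict[str, np.ndarray],
    cat: Optional[np.ndarray],
    y: np.ndarray,
    depth: int,
    min_leaf: int,
    max_depth: int,
) -> TreeNode:
    if np.unique(y).size == 1 or depth >= max_depth or y.size < 2 * min_leaf:
        return TreeNode(kind="leaf", label=_majority(y))
    candidates: list[_Split] = []
    for feature, x in X.items():
        s = _best_numeric_split(x, y, feature, min_leaf)
        if s is not None:
            candidates.append(s)
    if cat is not None:
        s = _best_categorical_split(cat, y, "cancer_type", min_leaf)
        if s is not None:
            candidates.append(s)
    if not candidates:
        return TreeNode(kind="leaf", label=_majority(y))
    best = max(
        candidates,
        key=lambda s: (s.gain_ratio, -s.threshold if s.kind == "numeric" else 0.0),
    )
    left_mask = best.mask_left
    kwargs = dict(depth=depth + 1, min_leaf=min_leaf, max_depth=max_depth)
    left = _grow({f: v[left_mask] for f, v in X.items()},
                 cat[left_mask] if cat is not None else None, y[left_mask], **kwargs)
    right = _grow({f: v[~left_mask] for f, v in X.items()},
                  cat[~left_mask] if cat is not None else None, y[~left_mask], **kwargs)
    if best.kind == "numeric":
        return TreeNode(kind="numeric", feature=best.feature,
                        threshold=best.threshold, left=left, right=right)
    return TreeNode(kind="categorical", feature=best.feature,
                    category=best.category, left=left, right=right)


def _training_errors(node: TreeNode, rows: list[dict], y: np.ndarray) -> int:
    return sum(
        node.predict(r, on_missing="right") != lbl for r, lbl in zip(rows, y)
    )


def _prune(node: TreeNode, rows: list[dict], y: np.ndarray) -> TreeNode:
    """Bottom-up: replace a subtree by its majority leaf when training
    error does not increase."""
    if node.kind == "leaf" or y.size == 0:
        return node
    if node.kind == "numeric":
        vals = np.array(
            [r.get(node.feature, math.nan) for r in rows], dtype=float
        )
        left_mask = vals <= node.threshold
    else:
        left_mask = np.array([r.get(node.feature) == node.category for r in rows])
    rows_arr = np.array(rows, dtype=object)
    node.left = _prune(node.left, list(rows_arr[left_mask]), y[left_mask])
    node.right = _prune(node.right, list(rows_arr[~left_mask]), y[~left_mask])
    subtree_err = _training_errors(node, rows, y)
    leaf = TreeNode(kind="leaf", label=_majority(y))
    if _training_errors(leaf, rows, y) <= subtree_err:
        return leaf
    return node


def train(
    features: pd.DataFrame,
    labels: Sequence[str] | pd.Series,
    min_leaf: int = 2,
    max_depth: int = 5,
    seed: Optional[int] = None,
    use_cancer_type: bool = True,
) -> ClassifierBundle:
    """Induce a decision tree from labeled feature vectors.

    Greedy top-down induction on the numeric rate and ratio features
    (candidate thresholds are midpoints between consecutive distinct
    values, scored by information-gain ratio, ties broken toward the
    smallest threshold) plus one-vs-rest splits on cancer_type. Growth
    stops at ``min_leaf`` instances per leaf, at ``max_depth``, or at zero
    gain; bottom-up pruning then collapses any subtree whose majority-class
    leaf does no worse on the training data. Features that are missing
    (NaN) for a sample are skipped for that sample when scoring splits.

    ``seed`` is accepted for interface symmetry; induction is
    deterministic.
    """
    labels = np.asarray(list(labels), dtype=object)
    if labels.size == 0:
        raise ValueError("cannot train on an empty feature table")
    if labels.size != len(features):
        raise ValueError("labels must match the feature table row-for-row")
    bad = set(labels) - set(LABELS)
    if bad:
        raise ValueError(f"labels must be in {LABELS}, got {sorted(bad)}")
    classes, class_counts = np.unique(labels, return_counts=True)
    if classes.size == 1:
        warnings.warn(
            f"training data contains a single class {classes[0]!r}; "
            "returning a single-leaf tree",
            stacklevel=2,
        )
        tree = TreeNode(kind="leaf", label=str(classes[0]))
    else:
        if class_counts.min() < 2:
            raise ValueError("need at least 2 samples per class to train")
        numeric_cols = [
            c for c in features.columns
            if c != "cancer_type" and pd.api.types.is_numeric_dtype(features[c])
        ]
        X = {c: features[c].to_numpy(dtype=float) for c in numeric_cols}
        cat = None
        if use_cancer_type and "cancer_type" in features.columns:
            cat = features["cancer_type"].to_numpy(dtype=object)
        tree = _grow(X, cat, labels, depth=0, min_leaf=min_leaf,
                     max_depth=max_depth)
        rows = features.to_dict("records")
        tree = _prune(tree, rows, labels)
    return ClassifierBundle(
        tree=tree,
        regime="custom",
        provenance=(
            f"trained on {labels.size} samples "
            f"(min_leaf={min_leaf}, max_depth={max_depth})"
        ),
    )


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CrossValidationResult:
    concordance: float  # pooled percentage over all folds
    fold_concordance: list[float]
    fold_assignment: np.ndarray  # test-fold index per sample
    n: int


def stratified_folds(
    labels: Sequence[str], k: int, seed: int
) -> np.ndarray:
    """Assign each sample a test-fold index in [0, k), stratified by class.

    Within each class, samples are shuffled by the seeded generator and
    dealt round-robin to folds; the assignment is fully determined by the
    seed. A class with fewer members than k simply leaves some folds
    without that class (stratification degrades gracefully, with a
    warning).
    """
    labels = np.asarray(list(labels), dtype=object)
    n = labels.size
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < k:
            warnings.warn(
                f"class {cls!r} has only {idx.size} sample(s) for {k} folds; "
                "stratification is partial",
                stacklevel=2,
            )
        rng.shuffle(idx)
        assignment[idx] = np.arange(idx.size) % k
    return assignment


def cross_validate(
    features: pd.DataFrame,
    labels: Sequence[str] | pd.Series,
    k: int = 5,
    seed: int = 0,
    min_leaf: int = 2,
    max_depth: int = 5,
    use_cancer_type: bool = True,
) -> CrossValidationResult:
    """k-fold cross-validated concordance of the retrainable tree.

    Concordance is 100 x (correct predictions / n), pooled over all test
    folds. Folds are stratified by class and fully determined by ``seed``.
    """
    labels = np.asarray(list(labels), dtype=object)
    assignment = stratified_folds(labels, k, seed)
    correct = 0
    fold_conc: list[float] = []
    for fold in range(k):
        test = assignment == fold
        bundle = train(
            features.loc[~test], labels[~test], min_leaf=min_leaf,
            max_depth=max_depth, use_cancer_type=use_cancer_type,
        )
        preds = np.array(
            [
                bundle.tree.predict(row, sample_id=str(sid))
                for sid, row in features.loc[test].iterrows()
            ],
            dtype=object,
        )
        fold_correct = int((preds == labels[test]).sum())
        correct += fold_correct
        fold_conc.append(100.0 * fold_correct / max(1, int(test.sum())))
    return CrossValidationResult(
        concordance=100.0 * correct / labels.size,
        fold_concordance=fold_conc,
        fold_assignment=assignment,
        n=int(labels.size),
    )


# ---------------------------------------------------------------------------
# serialization


def serialize(bundle: ClassifierBundle) -> str:
    """Encode a classifier bundle as a JSON document."""
    return json.dumps(
        {
            "format": "msikit-classifier",
            "version": bundle.version,
            "regime": bundle.regime,
            "provenance": bundle.provenance,
            "tree": bundle.tree.to_dict(),
        },
        indent=2,
    )


def deserialize(text: str) -> ClassifierBundle:
    """Decode a classifier bundle; missing fields are named in the error."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed classifier document: {exc}") from None
    for key in ("regime", "tree", "version", "provenance"):
        if key not in doc:
            raise ValueError(f"classifier document missing field {key!r}")
    return ClassifierBundle(
        tree=TreeNode.from_dict(doc["tree"]),
        regime=doc["regime"],
        provenance=doc["provenance"],
        version=doc["version"],
    )


def save_classifier(bundle: ClassifierBundle, path) -> None:
    with open(path, "w") as fh:
        fh.write(serialize(bundle) + "\n")


def load_classifier(path) -> ClassifierBundle:
    with open(path) as fh:
        return deserialize(fh.read())
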