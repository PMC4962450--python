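"""Spectral histopathology: from annotated Raman maps to a validated
classifier.

The workflow links hyperspectral pixels to a pathologist's region
diagnosis and evaluates a weighted k-nearest-neighbour (KKNN) classifier
with individual-out cross-validation (IO-CV):

1. every scan is partitioned by k-means (k between 9 and 15) and each
   cluster is mapped to a diagnostic class or excluded (muscle,
   connective tissue, background, spikes, hyperplasia);
2. the retained spectra (classes normal / adenoma / carcinoma) with
   their PCA-score features form the dataset;
3. a KKNN model — one neighbour, Minkowski distance, 'optimal' kernel by
   default — is evaluated leaving all spectra of one individual out per
   fold, which folds the between-individual biological variance into the
   performance estimate;
4. confusion statistics (per-class sensitivity/specificity, macro mean
   sensitivity, merged tumor-vs-normal table) summarize the result at
   region level (majority vote of spectrum predictions within each
   annotated region) or spectrum level.

A two-sample Wilcoxon rank-sum screen of principal-component scores
checks univariate group separation before the multivariate model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

#: diagnostic classes, in reporting order
CLASSES = ("adenoma", "carcinoma", "normal")

#: annotation classes removed before model building
EXCLUDED_CLASSES = frozenset(
    {"muscle", "connective", "background", "spikes", "hyperplasia"}
)

#: published individual-out CV confusion matrix for the three-class colon
#: task (rows = annotated adenoma/carcinoma/normal, columns = predicted);
#: packaged as a worked example for the reporting utilities.
EXAMPLE_CONFUSION = pd.DataFrame(
    [[4, 1, 0], [3, 5, 0], [0, 0, 16]], index=CLASSES, columns=CLASSES
)


# --------------------------------------------------------------------------
# annotation transfer
# --------------------------------------------------------------------------


def cluster_scan(features: np.ndarray, k: int = 9, seed: int = 0) -> np.ndarray:
    """k-means partition of one scan's spectra (labels 0..k-1).

    k-means++ initialization, 10 restarts, best inertia kept; fixed seed
    for reproducibility.
    """
    X = np.asarray(features, dtype=float)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of spectra {X.shape[0]}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed).fit(X)
    return km.labels_


def transfer_annotation(cluster_labels: np.ndarray, mapping: dict) -> np.ndarray:
    """Assign each spectrum its cluster's diagnostic class.

    ``mapping`` sends every observed cluster id to a class name; classes
    in :data:`EXCLUDED_CLASSES` mark spectra for removal.
    """
    cluster_labels = np.asarray(cluster_labels)
    observed = np.unique(cluster_labels)
    missing = [int(c) for c in observed if c not in mapping]
    if missing:
        raise KeyError(f"unmapped cluster ids: {missing}")
    return np.array([mapping[c] for c in cluster_labels], dtype=object)


def majority_truth_mapping(
    cluster_labels: np.ndarray, truth_labels: np.ndarray
) -> dict:
    """Simulated pathologist: map each cluster to the majority ground-truth
    class of its member pixels (mirrors blinded annotation on the
    parallel H&E section)."""
    cluster_labels = np.asarray(cluster_labels)
    truth_labels = np.asarray(truth_labels, dtype=object)
    mapping = {}
    for c in np.unique(cluster_labels):
        members = truth_labels[cluster_labels == c]
        vals, counts = np.unique(members.astype(str), return_counts=True)
        mapping[c] = str(vals[np.argmax(counts)])
    return mapping


@dataclass
class ShpDataset:
    """Classification-ready spectra: features, labels and provenance IDs."""

    features: np.ndarray  # (n, d) PCA scores
    labels: np.ndarray  # (n,) class names, drawn from CLASSES
    individuals: np.ndarray  # (n,) individual ids
    regions: np.ndarray  # (n,) annotated-region ids

    def __post_init__(self) -> None:
        n = self.features.shape[0]
        if not (len(self.labels) == len(self.individuals) == len(self.regions) == n):
            raise ValueError("field lengths disagree")

    @property
    def n_individuals(self) -> int:
        return np.unique(self.individuals).size


def assemble_dataset(
    score_blocks: list[np.ndarray],
    label_blocks: list[np.ndarray],
    individual_ids: list[str],
    scan_ids: list[str],
) -> ShpDataset:
    """Concatenate annotated scans into one dataset, dropping excluded
    classes.

    A region is one annotated class area within one scan (the granularity
    at which the diagnosis is made), identified as
    ``individual|scan|class``.  Requires >= 2 individuals after
    exclusions; warns when a class occurs in a single individual (CV
    folds will lack it).
    """
    feats, labs, inds, regs = [], [], [], []
    for X, y, ind, scan in zip(score_blocks, label_blocks, individual_ids, scan_ids):
        y = np.asarray(y, dtype=object)
        keep = np.array([lab in CLASSES for lab in y])
        if not keep.any():
            continue
        feats.append(np.asarray(X, dtype=float)[keep])
        labs.append(y[keep])
        inds.append(np.full(keep.sum(), ind, dtype=object))
        regs.append(np.array([f"{ind}|{scan}|{lab}" for lab in y[keep]], dtype=object))
    if not feats:
        raise ValueError("empty dataset: no spectra with retained classes")
    ds = ShpDataset(
        features=np.vstack(feats),
        labels=np.concatenate(labs),
        individuals=np.concatenate(inds),
        regions=np.concatenate(regs),
    )
    if ds.n_individuals < 2:
        raise ValueError("individual-out CV needs >= 2 individuals")
    for cls in np.unique(ds.labels.astype(str)):
        n_ind = np.unique(ds.individuals[ds.labels == cls]).size
        if n_ind < 2:
            warnings.warn(
                f"class {cls!r} present in a single individual; CV folds "
                "will lack it in training",
                stacklevel=2,
            )
    return ds


# --------------------------------------------------------------------------
# weighted k-nearest neighbours
# --------------------------------------------------------------------------


@dataclass
class KknnModel:
    """Weighted k-NN training set and hyperparameters.

    Defaults follow the screening protocol: one neighbour, Minkowski
    order 2, kernel 'optimal' (with k=1 every kernel reduces to plain
    nearest-neighbour).
    """

    features: np.ndarray
    labels: np.ndarray
    k: int = 1
    p: float = 2.0
    kernel: str = "optimal"
    classes: tuple = ()

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features/labels length mismatch")
        if self.features.shape[0] == 0:
            raise ValueError("empty training set")
        if self.k < 1 or self.p < 1:
            raise ValueError("require k >= 1 and p >= 1")
        if not self.classes:
            self.classes = tuple(sorted(np.unique(self.labels.astype(str))))


def _minkowski_chunk(Q: np.ndarray, X: np.ndarray, p: float) -> np.ndarray:
    if p == 2.0:
        d2 = (
            np.sum(Q**2, axis=1)[:, None]
            + np.sum(X**2, axis=1)[None, :]
            - 2.0 * (Q @ X.T)
        )
        return np.sqrt(np.maximum(d2, 0.0))
    return np.sum(np.abs(Q[:, None, :] - X[None, :, :]) ** p, axis=2) ** (1.0 / p)


def _neighbor_search(
    X: np.ndarray, Q: np.ndarray, n_take: int, p: float
) -> tuple[np.ndarray, np.ndarray]:
    """Indices/distances of the ``n_take`` nearest training rows per query,
    ordered by (distance, training-row index).

    A small candidate buffer is selected first (optimized library search
    for the Euclidean case, argpartition otherwise) and re-sorted with
    the documented tie-break; exact distance ties are therefore resolved
    toward earlier training rows.
    """
    n = X.shape[0]
    m = min(n, n_take + 8)  # buffer absorbs ties at the cut
    if p == 2.0 and n > 64:
        from sklearn.neighbors import NearestNeighbors

        dist, idx = (
            NearestNeighbors(n_neighbors=m).fit(X).kneighbors(Q)
        )
    else:
        dist = np.empty((Q.shape[0], m))
        idx = np.empty((Q.shape[0], m), dtype=int)
        chunk = max(1, int(2**25 // max(n, 1)))
        for start in range(0, Q.shape[0], chunk):
            D = _minkowski_chunk(Q[start : start + chunk], X, p)
            if m < n:
                part = np.argpartition(D, m - 1, axis=1)[:, :m]
            else:
                part = np.broadcast_to(np.arange(n), D.shape).copy()
            idx[start : start + chunk] = part
            dist[start : start + chunk] = np.take_along_axis(D, part, axis=1)
    order = np.lexsort((idx, dist), axis=1)
    idx = np.take_along_axis(idx, order, axis=1)[:, :n_take]
    dist = np.take_along_axis(dist, order, axis=1)[:, :n_take]
    return dist, idx


def _kernel_weights(
    d_norm: np.ndarray, ranks: np.ndarray, kernel: str, k: int, dim: int
) -> np.ndarray:
    """Neighbour weights from rank-normalized distances.

    'optimal' uses the published rank-based optimal weighting scheme for
    k-NN (depends on k and the feature dimension, not the distances);
    'rectangular' is uniform; 'triangular' and 'inv' decay with the
    normalized distance.
    """
    if kernel == "rectangular":
        return np.ones_like(d_norm)
    if kernel == "triangular":
        return np.clip(1.0 - d_norm, 0.0, None)
    if kernel == "inv":
        return 1.0 / np.maximum(d_norm, 1e-12)
    if kernel == "optimal":
        i = ranks + 1.0  # 1-based neighbour rank
        d = float(dim)
        w = (1.0 / k) * (
            1.0
            + d / 2.0
            - (d / (2.0 * k ** (2.0 / d)))
            * (i ** (1.0 + 2.0 / d) - (i - 1.0) ** (1.0 + 2.0 / d))
        )
        return np.clip(np.broadcast_to(w, d_norm.shape), 0.0, None)
    raise ValueError(f"unknown kernel {kernel!r}")


def kknn_predict(
    model: KknnModel, queries: np.ndarray, return_weights: bool = False
):
    """Classify query spectra by kernel-weighted nearest neighbours.

    For each query the k nearest training rows by Minkowski-p distance
    are found (stable sort: distance ties broken by training-row order);
    distances are rank-normalized by the (k+1)-th neighbour distance,
    kernel weights applied, and the class with the largest summed weight
    wins (remaining ties go to the smallest class index).
    """
    Q = np.asarray(queries, dtype=float)
    if Q.ndim != 2 or Q.shape[1] != model.features.shape[1]:
        raise ValueError(
            f"query dimension {Q.shape} does not match training "
            f"{model.features.shape}"
        )
    X, y = model.features, model.labels
    n = X.shape[0]
    k = min(model.k, n)
    cls_index = {c: i for i, c in enumerate(model.classes)}
    y_idx = np.array([cls_index[str(lab)] for lab in y])
    dsort, take = _neighbor_search(X, Q, min(k + 1, n), model.p)
    if n > k:
        norm = np.maximum(dsort[:, [k]], 1e-12)
        d_norm = dsort[:, :k] / norm
        nn = take[:, :k]
    else:
        norm = np.maximum(dsort[:, [-1]], 1e-12)
        d_norm = dsort / norm
        nn = take
    ranks = np.arange(nn.shape[1], dtype=float)
    w = _kernel_weights(d_norm, ranks, model.kernel, k, X.shape[1])
    votes = np.zeros((Q.shape[0], len(model.classes)))
    np.add.at(
        votes,
        (np.repeat(np.arange(Q.shape[0]), nn.shape[1]), y_idx[nn].ravel()),
        w.ravel(),
    )
    preds = np.array([model.classes[i] for i in votes.argmax(axis=1)], dtype=object)
    if return_weights:
        return preds, votes
    return preds


# --------------------------------------------------------------------------
# confusion statistics
# --------------------------------------------------------------------------


def confusion_stats(confusion: pd.DataFrame | np.ndarray, labels=None) -> dict:
    """Per-class sensitivity/specificity (%) and macro mean sensitivity.

    Rows are annotated classes, columns predicted.  Sensitivity is the
    class's diagonal count over its row sum; specificity is the
    one-vs-rest true-negative rate.  A zero row yields a missing (NaN)
    sensitivity that is excluded from the macro mean.
    """
    if isinstance(confusion, pd.DataFrame):
        M = confusion.to_numpy(dtype=float)
        labels = list(confusion.index)
    else:
        M = np.asarray(confusion, dtype=float)
        labels = list(labels) if labels is not None else list(range(M.shape[0]))
    if M.shape[0] != M.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(M < 0):
        raise ValueError("confusion matrix must be non-negative")
    total = M.sum()
    sens, spec = {}, {}
    for i, lab in enumerate(labels):
        row = M[i].sum()
        sens[lab] = 100.0 * M[i, i] / row if row > 0 else float("nan")
        fp = M[:, i].sum() - M[i, i]
        tn = total - row - fp
        spec[lab] = 100.0 * tn / (tn + fp) if tn + fp > 0 else float("nan")
    defined = [v for v in sens.values() if np.isfinite(v)]
    return {
        "sensitivity": sens,
        "specificity": spec,
        "mean_sensitivity": float(np.mean(defined)) if defined else float("nan"),
    }


def merge_confusion(confusion: pd.DataFrame, groups: dict) -> pd.DataFrame:
    """Merge classes by summing rows and columns of grouped classes.

    ``groups`` maps each class name to its group name (e.g. adenoma and
    carcinoma to "tumor"); classes not mentioned keep their own name.
    Preserves the total count.
    """
    mapping = {c: groups.get(c, c) for c in confusion.index}
    merged = confusion.rename(index=mapping, columns=mapping)
    merged = merged.groupby(level=0, sort=False).sum()
    merged = merged.T.groupby(level=0, sort=False).sum().T
    order = list(dict.fromkeys(mapping[c] for c in confusion.index))
    return merged.loc[order, order]


# --------------------------------------------------------------------------
# individual-out cross-validation
# --------------------------------------------------------------------------


@dataclass
class CVReport:
    """Pooled individual-out cross-validation result."""

    confusion: pd.DataFrame  # rows annotated, columns predicted
    sensitivity: dict
    specificity: dict
    mean_sensitivity: float
    merged_confusion: pd.DataFrame  # tumor vs normal
    merged_sensitivity: dict
    merged_mean_sensitivity: float
    folds: list = field(default_factory=list)
    level: str = "region"

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "confusion": {
                "labels": list(self.confusion.index),
                "matrix": self.confusion.to_numpy().tolist(),
            },
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "mean_sensitivity": self.mean_sensitivity,
            "merged_confusion": {
                "labels": list(self.merged_confusion.index),
                "matrix": self.merged_confusion.to_numpy().tolist(),
            },
            "merged_sensitivity": self.merged_sensitivity,
            "merged_mean_sensitivity": self.merged_mean_sensitivity,
            "folds": self.folds,
        }


def _majority(values: np.ndarray, classes: tuple) -> str:
    counts = {c: 0 for c in classes}
    for v in values:
        counts[str(v)] = counts.get(str(v), 0) + 1
    return max(classes, key=lambda c: counts.get(c, 0))  # ties -> class order


def individual_out_cv(
    dataset: ShpDataset,
    k: int = 1,
    p: float = 2.0,
    kernel: str = "optimal",
    level: str = "region",
) -> CVReport:
    """Leave-one-individual-out evaluation of a KKNN model.

    Every individual's spectra form one test fold while the others
    train; pooled predictions are scored either per annotated region
    (majority vote of its spectrum predictions; default) or per
    spectrum.  Reports the three-class confusion plus the merged
    tumor-vs-normal statistics.
    """
    if level not in ("region", "spectrum"):
        raise ValueError("level must be 'region' or 'spectrum'")
    individuals = np.unique(dataset.individuals)
    if individuals.size < 2:
        raise ValueError("individual-out CV needs >= 2 individuals")
    classes = tuple(c for c in CLASSES if c in set(dataset.labels.astype(str)))
    pred = np.empty(dataset.labels.shape[0], dtype=object)
    folds = []
    for ind in individuals:
        test = dataset.individuals == ind
        train = ~test
        train_classes = set(dataset.labels[train].astype(str))
        missing = sorted(set(dataset.labels[test].astype(str)) - train_classes)
        model = KknnModel(
            features=dataset.features[train],
            labels=dataset.labels[train],
            k=k,
            p=p,
            kernel=kernel,
            classes=tuple(sorted(train_classes)),
        )
        pred[test] = kknn_predict(model, dataset.features[test])
        folds.append(
            {
                "individual": str(ind),
                "n_test": int(test.sum()),
                "n_train": int(train.sum()),
                "missing_train_classes": missing,
            }
        )
    if level == "region":
        ann, prd = [], []
        for reg in np.unique(dataset.regions):
            sel = dataset.regions == reg
            ann.append(str(dataset.labels[sel][0]))
            prd.append(_majority(pred[sel], classes))
    else:
        ann = dataset.labels.astype(str).tolist()
        prd = [str(x) for x in pred]
    conf = pd.DataFrame(0, index=list(classes), columns=list(classes), dtype=int)
    for a, q in zip(ann, prd):
        conf.loc[a, q] += 1
    stats3 = confusion_stats(conf)
    groups = {"adenoma": "tumor", "carcinoma": "tumor"}
    merged = merge_confusion(conf, groups)
    stats2 = confusion_stats(merged)
    return CVReport(
        confusion=conf,
        sensitivity=stats3["sensitivity"],
        specificity=stats3["specificity"],
        mean_sensitivity=stats3["mean_sensitivity"],
        merged_confusion=merged,
        merged_sensitivity=stats2["sensitivity"],
        merged_mean_sensitivity=stats2["mean_sensitivity"],
        folds=folds,
        level=level,
    )


# --------------------------------------------------------------------------
# univariate screening
# --------------------------------------------------------------------------


def wilcoxon_screen(
    pc_scores: np.ndarray,
    group_labels: np.ndarray,
    components: list[int],
) -> dict[int, float]:
    """Two-sided two-sample Wilcoxon rank-sum test per principal component.

    ``components`` uses 1-based PC numbers (PC 3 is the third column of
    ``pc_scores``).  Exact null distribution for small samples without
    ties, normal approximation with tie correction otherwise.  Returns
    {component: p-value}.
    """
    scores = np.asarray(pc_scores, dtype=float)
    labels = np.asarray(group_labels)
    groups = np.unique(labels.astype(str))
    if groups.size != 2:
        raise ValueError(f"need exactly two groups, got {list(groups)}")
    a = labels.astype(str) == groups[0]
    if a.sum() < 2 or (~a).sum() < 2:
        raise ValueError("each group needs n >= 2")
    out = {}
    for comp in components:
        if not 1 <= comp <= scores.shape[1]:
            raise ValueError(f"component {comp} out of range")
        x, y = scores[a, comp - 1], scores[~a, comp - 1]
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
        out[int(comp)] = float(res.pvalue)
    return out
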