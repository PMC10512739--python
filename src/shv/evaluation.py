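"""Selection-quality metrics for voxel sets and EVR maps.

Stability across subjects is measured by the corrected pairwise relative
overlap of the selected-voxel sets,

    O(S1, S2) = | |S1 ^ S2| - |S1||S2|/N_V | / max(|S1|, |S2|)

which subtracts the expected overlap of two random sets of the same sizes;
identical sets score 1 - |S|/N_V.  On synthetic data with planted
discriminative clusters, precision and recall of the retrieved cluster set
are reported directly.  Finally, the practical value of an EVR ranking is
probed by training an l2-regularized linear classifier on the top-c voxels
for increasing c and cross-validating its accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .sparse_logistic import SubjectFeatures

__all__ = [
    "SelectionSet",
    "pairwise_overlap",
    "mean_overlap",
    "precision_recall",
    "accuracy_vs_voxels",
]


@dataclass(frozen=True)
class SelectionSet:
    """A subject's selected voxels (nonzero-EVR indices) out of ``n_total``."""

    voxels: frozenset
    n_total: int

    def __post_init__(self) -> None:
        voxels = frozenset(int(v) for v in self.voxels)
        if voxels and (min(voxels) < 0 or max(voxels) >= self.n_total):
            raise ValueError("voxel indices must lie in [0, n_total)")
        object.__setattr__(self, "voxels", voxels)

    @classmethod
    def from_evr(cls, evr: np.ndarray, atol: float = 0.0) -> "SelectionSet":
        evr = np.asarray(evr, dtype=float)
        return cls(voxels=frozenset(np.flatnonzero(evr > atol).tolist()), n_total=evr.size)

    def __len__(self) -> int:
        return len(self.voxels)


def pairwise_overlap(s1: SelectionSet, s2: SelectionSet) -> float:
    """Chance-corrected relative overlap of two selected-voxel sets."""
    if s1.n_total != s2.n_total:
        raise ValueError("selection sets live on different voxel spaces")
    if len(s1) == 0 or len(s2) == 0:
        raise ValueError("overlap is undefined for empty selections")
    inter = len(s1.voxels & s2.voxels)
    expected = len(s1) * len(s2) / s1.n_total
    return abs(inter - expected) / max(len(s1), len(s2))


def mean_overlap(selections: list[SelectionSet]) -> float:
    """Average of ``pairwise_overlap`` over all unordered subject pairs."""
    if len(selections) < 2:
        raise ValueError("need at least two subjects")
    vals = [pairwise_overlap(a, b) for a, b in combinations(selections, 2)]
    return float(np.mean(vals))


def precision_recall(
    selected_clusters,
    truth,
) -> tuple[float, float]:
    """Precision and recall of a retrieved cluster set against ground truth.

    Precision is the fraction of retrieved clusters that are truly
    discriminative; recall the fraction of discriminative clusters
    retrieved.  An empty selection yields precision 0 (undefined, flagged by
    a warning-free convention of 0).
    """
    selected = set(int(c) for c in selected_clusters)
    truth = set(int(c) for c in truth)
    if not truth:
        raise ValueError("truth set must be non-empty")
    hit = len(selected & truth)
    precision = hit / len(selected) if selected else 0.0
    recall = hit / len(truth)
    return float(precision), float(recall)


def accuracy_vs_voxels(
    evr_map: np.ndarray,
    data: SubjectFeatures,
    voxel_counts,
    k_folds: int = 4,
    seed: int = 0,
    C: float = 1.0,
) -> pd.DataFrame:
    """Cross-validated accuracy of a linear l2-SVM on the top-EVR voxels.

    For each requested count ``c``, the ``c`` voxels with highest EVR (ties
    toward the lower index) feed a ``LinearSVC`` with fixed regularization;
    features are z-scored per fold from the training folds.  Counts beyond
    the number of nonzero-EVR voxels are padded with the next-ranked
    (zero-EVR) voxels and flagged in the ``padded`` column.

    Returns a DataFrame with columns ``n_voxels, train_acc, test_acc,
    padded``, accuracies averaged over the stratified folds.
    """
    evr_map = np.asarray(evr_map, dtype=float)
    counts = [int(c) for c in voxel_counts]
    if any(b <= a for a, b in zip(counts, counts[1:])):
        raise ValueError("voxel_counts must be strictly increasing")
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if evr_map.size != data.n_voxels:
        raise ValueError("EVR map and features disagree on N_V")
    order = np.lexsort((np.arange(evr_map.size), -evr_map))
    n_nonzero = int((evr_map > 0).sum())
    y01 = (data.y > 0).astype(int)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(data.X, y01))

    rows = []
    for c in counts:
        cols = order[: min(c, evr_map.size)]
        tr_accs, te_accs = [], []
        for tr, te in splits:
            Xtr, Xte = data.X[np.ix_(tr, cols)], data.X[np.ix_(te, cols)]
            mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
            sd = np.where(sd == 0, 1.0, sd)
            Xtr, Xte = (Xtr - mu) / sd, (Xte - mu) / sd
            clf = LinearSVC(C=C)
            clf.fit(Xtr, data.y[tr])
            tr_accs.append(clf.score(Xtr, data.y[tr]))
            te_accs.append(clf.score(Xte, data.y[te]))
        rows.append(
            {
                "n_voxels": c,
                "train_acc": float(np.mean(tr_accs)),
                "test_acc": float(np.mean(te_accs)),
                "padded": c > n_nonzero,
            }
        )
    return pd.DataFrame(rows)
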