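import numpy as np
import pytest

from shv import (
    ClusterFeatures,
    Parcellation,
    SubjectFeatures,
    VoxelMask,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20230907)


@pytest.fixture
def toy_mask():
    """5x4x3 grid, fully in-mask (60 voxels)."""
    return VoxelMask.full((5, 4, 3))


@pytest.fixture
def toy_parcellation(toy_mask):
    """6 clusters of 10 voxels each over the toy mask, contiguous in linear order."""
    labels = np.repeat(np.arange(6), 10)
    return Parcellation(labels=labels, n_clusters=6)


def make_separable_subject(rng, parcellation, informative=(0, 3), n_trials=40,
                           noise=0.3, subject_id="sub"):
    """Subject whose labels follow the difference of two cluster means."""
    n_v = parcellation.n_voxels
    signal = rng.uniform(0, 1, size=(n_trials, parcellation.n_clusters))
    score = signal[:, informative[0]] - signal[:, informative[1]]
    y = np.where(score > np.median(score), 1, -1)
    # force exact balance by flipping boundary trials
    while (y == 1).sum() != n_trials // 2:
        idx = np.argmin(np.abs(score - np.median(score)))
        y[idx] = -y[idx] if (y == 1).sum() > n_trials // 2 else y[idx]
    X = np.zeros((n_trials, n_v))
    for j in range(parcellation.n_clusters):
        X[:, parcellation.labels == j] = signal[:, [j]]
    X += noise * rng.standard_normal(X.shape)
    return SubjectFeatures(X=X, y=y, subject_id=subject_id)


@pytest.fixture
def random_cluster_problem(rng):
    """2 subjects x 30 trials x 8 clusters with a sparse ground truth."""
    feats, ys = [], []
    w_true = np.array([1.5, -2.0, 0, 0, 0, 1.0, 0, 0])
    for i in range(2):
        D = rng.standard_normal((30, 8))
        y = np.where(D @ w_true + 0.3 * rng.standard_normal(30) > 0, 1, -1)
        if abs(int(y.sum())) == 30:  # degenerate single-class draw
            y[0] = -y[0]
        feats.append(ClusterFeatures(D=D, cluster_ids=np.arange(8),
                                     trial_ids=np.arange(30)))
        ys.append(y)
    return feats, ys
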