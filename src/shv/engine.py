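"""Stable hierarchical voting (SHV) over randomized group-sparse fits.

The engine runs a two-level nested resampling scheme:

* an outer loop (``n_k`` spatial randomizations) draws a constrained block
  subsample of voxels, shared by all subjects, and averages the sampled
  voxels within each parcellation cluster;
* an inner loop (``n_l`` cross-verifications) subsamples trials per
  subject, fits the groupwise mixed l1/l2 logistic model on the training
  trials, and scores test accuracy on the held-out trials.

Per subject and outer loop, the score vector ``s_{i,k}`` averages absolute
cluster weights over the inner fits.  Because uniform spatial sampling often
lands on uninformative voxels, only the top ``alpha_k`` fraction of outer
loops by test accuracy are *qualified* to vote.  Votes are aggregated
hierarchically: a top-``n_sel`` selector per qualified loop, per-subject
vote frequencies across qualified loops, a per-subject top-``n_sel``
selector on those frequencies, and finally the across-subject average --
the cluster vote rate ``phi_C``.  Per voxel, the sampling-conditional vote
rate is multiplied by its cluster's ``phi_C`` to give the effective vote
ratio (EVR), the method's output map.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .mask import VoxelMask
from .parcellation import Parcellation
from .sparse_logistic import (
    ClusterFeatures,
    SubjectFeatures,
    average_features,
    fit_group_logistic,
    fit_lasso_stack,
    lambda_max,
    predict_accuracy,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ShvConfig",
    "SamplingPlan",
    "ShvResult",
    "block_subsample_voxels",
    "subsample_trials",
    "make_sampling_plan",
    "score_vector",
    "top_n_selector",
    "select_qualified_loops",
    "cluster_vote_rate",
    "voxel_vote_rate",
    "effective_vote_ratio",
    "run_shv",
    "select_lambda",
]


@dataclass(frozen=True)
class ShvConfig:
    """Parameters of the SHV procedure.

    Attributes
    ----------
    n_k, n_l : int
        Outer spatial-randomization and inner cross-verification loop counts.
    alpha_col, alpha_row : float in (0, 1)
        Voxel and trial subsampling fractions.
    alpha_k : float in (0, 1]
        Quality-control ratio: only the top ``floor(alpha_k * n_k)`` outer
        loops by test accuracy vote.
    n_sel : int
        Number of clusters each selector marks.
    lambda_grid : tuple of float, optional
        Candidate penalty weights for :func:`select_lambda`.  ``None`` means
        derive a 3-point grid as fixed fractions of the data's lambda_max.
    block_size : 3 ints
        Edge lengths of the spatial sampling blocks (voxels).
    seed : int
        Master seed; every random stream derives from it.
    min_precision : float, optional
        Extra quality filter: qualified loops must also reach this test
        accuracy.
    fit_tol, fit_max_iter : solver tolerance / iteration cap per fit.
    """

    n_k: int = 200
    n_l: int = 20
    alpha_col: float = 0.01
    alpha_row: float = 0.9
    alpha_k: float = 0.3
    n_sel: int = 15
    lambda_grid: tuple[float, ...] | None = None
    block_size: tuple[int, int, int] = (3, 3, 3)
    seed: int = 0
    min_precision: float | None = None
    fit_tol: float = 1e-6
    fit_max_iter: int = 2000

    def __post_init__(self) -> None:
        if self.n_k < 1 or self.n_l < 1:
            raise ValueError("n_k and n_l must be >= 1")
        if not 0 < self.alpha_col < 1:
            raise ValueError("alpha_col must be in (0, 1)")
        if not 0 < self.alpha_row < 1:
            raise ValueError("alpha_row must be in (0, 1)")
        if not 0 < self.alpha_k <= 1:
            raise ValueError("alpha_k must be in (0, 1]")
        if self.n_sel < 1:
            raise ValueError("n_sel must be >= 1")
        if len(self.block_size) != 3 or any(b < 1 for b in self.block_size):
            raise ValueError("block_size must be 3 positive integers")


@dataclass(frozen=True)
class SamplingPlan:
    """Pre-drawn randomizations: voxel set per outer loop, trial split per
    (outer loop, inner loop, subject).

    Generated from the master seed alone, so penalty candidates compared on
    the same plan see identical randomizations (common random numbers).
    """

    voxel_sets: list
    trial_splits: list  # [k][l][i] -> (train_idx, test_idx)
    seed: int

    @property
    def n_k(self) -> int:
        return len(self.voxel_sets)


@dataclass
class ShvResult:
    """Everything a finished SHV run produced.

    ``scores[i, k]`` is the score vector s_{i,k} over all ``n_clusters``
    (zeros at clusters unsampled in loop k); ``test_acc[i, k]`` the mean
    inner-loop test accuracy; ``qualified_loops[i]`` the retained outer-loop
    indices; ``cluster_votes`` phi_C; ``voxel_votes[i]`` the
    sampling-conditional per-voxel rate; ``evr[i]`` the effective vote
    ratio, and ``mean_evr`` its across-subject average.  ``r_bar`` is the
    qualified-loop average test accuracy used for penalty selection.
    """

    scores: np.ndarray
    test_acc: np.ndarray
    qualified_loops: list
    cluster_votes: np.ndarray
    voxel_votes: np.ndarray
    evr: np.ndarray
    mean_evr: np.ndarray
    r_bar: float
    lam: float
    method: str
    failed_loops: list
    voxel_sets: list = field(repr=False)

    @property
    def n_subjects(self) -> int:
        return self.scores.shape[0]

    def selection_sets(self, atol: float = 0.0) -> list[np.ndarray]:
        """Per subject, the voxels with nonzero EVR (the sets S_i)."""
        return [np.flatnonzero(self.evr[i] > atol) for i in range(self.n_subjects)]


def block_subsample_voxels(
    mask: VoxelMask,
    alpha_col: float,
    block_size: tuple[int, int, int] = (3, 3, 3),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw whole spatial blocks until >= ``alpha_col * N_V`` voxels are covered.

    The grid is tiled into axis-aligned ``block_size`` blocks anchored at
    the origin; blocks containing at least one in-mask voxel are drawn
    uniformly without replacement, and the in-mask voxels of the drawn
    blocks are returned (sorted linear indices).
    """
    if not 0 < alpha_col < 1:
        raise ValueError("alpha_col must be in (0, 1)")
    rng = np.random.default_rng() if rng is None else rng
    bs = np.asarray(block_size, dtype=np.intp)
    block_of = mask.coords // bs  # (N_V, 3) block coordinates
    n_blocks_grid = tuple(-(-s // b) for s, b in zip(mask.shape, block_size))
    block_flat = np.ravel_multi_index(block_of.T, n_blocks_grid)
    blocks, inverse = np.unique(block_flat, return_inverse=True)
    counts = np.bincount(inverse)
    target = alpha_col * mask.n_voxels
    order = rng.permutation(blocks.size)
    cum = np.cumsum(counts[order])
    n_take = int(np.searchsorted(cum, target) + 1)
    n_take = min(n_take, blocks.size)
    if n_take == 1 and counts[order[0]] > target:
        warnings.warn(
            "alpha_col target smaller than a single block; returning one block",
            RuntimeWarning,
        )
    chosen = np.zeros(blocks.size, dtype=bool)
    chosen[order[:n_take]] = True
    return np.flatnonzero(chosen[inverse])


def subsample_trials(
    labels: np.ndarray,
    alpha_row: float,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test split: ``round(alpha_row * n_c)`` training
    trials per class (clamped so both classes appear in train and test);
    the test set is the complement."""
    if not 0 < alpha_row < 1:
        raise ValueError("alpha_row must be in (0, 1)")
    rng = np.random.default_rng() if rng is None else rng
    labels = np.asarray(labels, dtype=int).ravel()
    train_parts = []
    for cls in (+1, -1):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls:+d} needs at least 2 trials")
        k = int(round(alpha_row * idx.size))
        k = min(max(k, 1), idx.size - 1)
        train_parts.append(rng.choice(idx, size=k, replace=False))
    train = np.sort(np.concatenate(train_parts))
    test = np.setdiff1d(np.arange(labels.size), train)
    return train, test


def make_sampling_plan(
    mask: VoxelMask,
    labels_list: list[np.ndarray],
    config: ShvConfig,
) -> SamplingPlan:
    """Materialize all random draws of a run from the master seed."""
    ss = np.random.SeedSequence(config.seed)
    voxel_ss, trial_ss = ss.spawn(2)
    voxel_rngs = [np.random.default_rng(s) for s in voxel_ss.spawn(config.n_k)]
    trial_rngs = np.array(
        [np.random.default_rng(s) for s in trial_ss.spawn(config.n_k * config.n_l * len(labels_list))]
    ).reshape(config.n_k, config.n_l, len(labels_list))
    voxel_sets = [
        block_subsample_voxels(mask, config.alpha_col, config.block_size, voxel_rngs[k])
        for k in range(config.n_k)
    ]
    trial_splits = [
        [
            [
                subsample_trials(labels_list[i], config.alpha_row, trial_rngs[k, l, i])
                for i in range(len(labels_list))
            ]
            for l in range(config.n_l)
        ]
        for k in range(config.n_k)
    ]
    return SamplingPlan(voxel_sets=voxel_sets, trial_splits=trial_splits, seed=config.seed)


def score_vector(fits: list, subject_index: int, n_clusters: int) -> np.ndarray:
    """Mean absolute cluster weight across inner-loop fits.

    ``s_{i,k}(j) = (1/N_L) * sum_l |W_l(j, i)|``; clusters absent from the
    fits (unsampled this loop) contribute 0.
    """
    if not fits:
        raise ValueError("need at least one fit")
    s = np.zeros(n_clusters)
    for fit in fits:
        s[fit.cluster_ids] += np.abs(fit.W[:, subject_index])
    return s / len(fits)


def top_n_selector(scores: np.ndarray, n_sel: int) -> np.ndarray:
    """Binary selector marking the top ``n_sel`` strictly positive entries.

    Ties break toward the lower cluster id; if fewer than ``n_sel`` entries
    are positive, fewer are marked.  Never marks a zero entry.
    """
    if n_sel < 1:
        raise ValueError("n_sel must be >= 1")
    s = np.asarray(scores, dtype=float)
    order = np.lexsort((np.arange(s.size), -s))  # descending, lower id first on ties
    order = order[s[order] > 0][:n_sel]
    sel = np.zeros(s.size)
    sel[order] = 1.0
    return sel


def select_qualified_loops(
    test_acc: np.ndarray,
    alpha_k: float,
    min_precision: float | None = None,
) -> np.ndarray:
    """Indices of the ``max(1, floor(alpha_k * n_k))`` most accurate loops.

    Ties break toward the earlier loop.  When ``min_precision`` is given,
    loops below it are additionally dropped; if nothing survives, the single
    best loop is kept with a warning.
    """
    if not 0 < alpha_k <= 1:
        raise ValueError("alpha_k must be in (0, 1]")
    acc = np.asarray(test_acc, dtype=float).ravel()
    n_keep = max(1, int(np.floor(alpha_k * acc.size)))
    order = np.lexsort((np.arange(acc.size), -acc))
    kept = order[:n_keep]
    if min_precision is not None:
        ok = kept[acc[kept] >= min_precision]
        if ok.size == 0:
            warnings.warn(
                "min_precision filtered out every loop; keeping the single best",
                RuntimeWarning,
            )
            ok = order[:1]
        kept = ok
    return np.sort(kept)


def cluster_vote_rate(selected_scores: list, n_sel: int) -> np.ndarray:
    """Across-subject cluster vote rate phi_C.

    For each subject: apply the top-``n_sel`` selector to every qualified
    loop's score vector, average the binary selections over loops, apply the
    selector again to the frequencies, then average the per-subject binary
    outcomes over subjects.  Entries are exact multiples of 1/N_S.
    """
    outer = []
    for s_mat in selected_scores:
        s_mat = np.atleast_2d(np.asarray(s_mat, dtype=float))
        if s_mat.shape[0] < 1:
            raise ValueError("each subject needs at least one qualified loop")
        inner = np.stack([top_n_selector(s, n_sel) for s in s_mat])
        outer.append(top_n_selector(inner.mean(axis=0), n_sel))
    return np.mean(outer, axis=0)


def voxel_vote_rate(subject_loops: list, parcellation: Parcellation) -> np.ndarray:
    """Sampling-conditional per-voxel vote rate for one subject.

    ``subject_loops`` holds, for each qualified loop, the sampled voxel
    index set and that loop's cluster selector.  A voxel's rate is the
    number of loops in which it was sampled *and* its cluster selected,
    divided by the number of loops in which it was sampled; voxels never
    sampled get 0.
    """
    if not subject_loops:
        raise ValueError("need at least one qualified loop")
    num = np.zeros(parcellation.n_voxels)
    den = np.zeros(parcellation.n_voxels)
    for sampled, selector in subject_loops:
        sampled = np.asarray(sampled, dtype=np.intp)
        selector = np.asarray(selector, dtype=float)
        den[sampled] += 1.0
        num[sampled] += selector[parcellation.labels[sampled]]
    rate = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return rate


def effective_vote_ratio(
    voxel_votes: np.ndarray,
    cluster_votes: np.ndarray,
    parcellation: Parcellation,
) -> np.ndarray:
    """EVR: per-voxel product of its vote rate and its cluster's phi_C."""
    voxel_votes = np.asarray(voxel_votes, dtype=float)
    cluster_votes = np.asarray(cluster_votes, dtype=float)
    if voxel_votes.size != parcellation.n_voxels:
        raise ValueError("voxel_votes length must equal N_V")
    if cluster_votes.size != parcellation.n_clusters:
        raise ValueError("cluster_votes length must equal N_C")
    return voxel_votes * cluster_votes[parcellation.labels]


def _zscore_split(D: np.ndarray, train: np.ndarray, test: np.ndarray):
    """Column z-score using training moments; constant columns pass through
    centered."""
    mu = D[train].mean(axis=0)
    sd = D[train].std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (D[train] - mu) / sd, (D[test] - mu) / sd


def run_shv(
    data: list[SubjectFeatures],
    parcellation: Parcellation,
    config: ShvConfig,
    lam: float,
    mask: VoxelMask | None = None,
    plan: SamplingPlan | None = None,
    method: str = "group",
) -> ShvResult:
    """Execute the full SHV procedure at one penalty weight.

    Parameters
    ----------
    data : per-subject trial features on a common voxel space.
    parcellation : shared cluster assignment of the in-mask voxels.
    config : loop counts, sampling fractions, quality control, seed.
    lam : penalty weight of the sparse logistic fits.
    mask : voxel grid geometry for block sampling.  Required unless ``plan``
        is given.
    plan : optional pre-drawn :class:`SamplingPlan` (for comparing penalties
        or estimators on identical randomizations).
    method : ``"group"`` fits the joint mixed l1/l2 model; ``"single"`` fits
        every subject's l1 model independently on the same sampling plan
        (the single-subject alternative).

    Notes
    -----
    Voxel subsamples are shared across subjects within an outer loop, so the
    group fit sees aligned cluster columns.  Within an outer loop the solver
    warm-starts from the previous inner loop's solution (same active
    clusters), which changes nothing at convergence.  A failed loop is
    recorded with accuracy 0 and excluded from qualification.
    """
    if method not in ("group", "single"):
        raise ValueError("method must be 'group' or 'single'")
    n_s = len(data)
    n_v = parcellation.n_voxels
    for d in data:
        if d.n_voxels != n_v:
            raise ValueError("all subjects must share the parcellation voxel space")
    if plan is None:
        if mask is None:
            raise ValueError("either mask or plan must be given")
        if mask.n_voxels != n_v:
            raise ValueError("mask and parcellation disagree on N_V")
        plan = make_sampling_plan(mask, [d.y for d in data], config)
    if plan.n_k != config.n_k:
        raise ValueError("plan was drawn for a different n_k")

    n_c = parcellation.n_clusters
    scores = np.zeros((n_s, config.n_k, n_c))
    test_acc = np.zeros((n_s, config.n_k))
    failed = []

    for k in range(config.n_k):
        sampled = plan.voxel_sets[k]
        try:
            feats = [average_features(d, parcellation, sampled) for d in data]
            ids = feats[0].cluster_ids
            abs_w = np.zeros((ids.size, n_s))
            acc_kl = np.zeros((config.n_l, n_s))
            warm = None
            for l in range(config.n_l):
                train_feats, test_feats, test_labels = [], [], []
                for i, d in enumerate(data):
                    tr, te = plan.trial_splits[k][l][i]
                    Dtr, Dte = _zscore_split(feats[i].D, tr, te)
                    train_feats.append(ClusterFeatures(D=Dtr, cluster_ids=ids, trial_ids=tr))
                    test_feats.append(ClusterFeatures(D=Dte, cluster_ids=ids, trial_ids=te))
                    test_labels.append(d.y[te])
                if method == "group":
                    fit = fit_group_logistic(
                        train_feats, [d.y[plan.trial_splits[k][l][i][0]] for i, d in enumerate(data)],
                        lam, tol=config.fit_tol, max_iter=config.fit_max_iter, warm_start=warm,
                    )
                else:
                    fit = fit_lasso_stack(
                        train_feats, [d.y[plan.trial_splits[k][l][i][0]] for i, d in enumerate(data)],
                        lam, tol=config.fit_tol, max_iter=config.fit_max_iter, warm_start=warm,
                    )
                warm = fit
                abs_w += np.abs(fit.W)
                for i in range(n_s):
                    acc_kl[l, i] = predict_accuracy(fit, test_feats[i], test_labels[i], i)
            scores[:, k, ids] = (abs_w / config.n_l).T
            test_acc[:, k] = acc_kl.mean(axis=0)
        except Exception as exc:  # failed loop: accuracy 0, never qualifies
            logger.warning("outer loop %d failed: %s", k, exc)
            failed.append(k)
            test_acc[:, k] = 0.0
            scores[:, k, :] = 0.0

    acc_for_rank = test_acc.copy()
    if failed:
        acc_for_rank[:, failed] = -np.inf
    qualified = [
        select_qualified_loops(acc_for_rank[i], config.alpha_k, config.min_precision)
        for i in range(n_s)
    ]
    phi_c = cluster_vote_rate([scores[i, qualified[i]] for i in range(n_s)], config.n_sel)
    voxel_votes = np.zeros((n_s, n_v))
    evr = np.zeros((n_s, n_v))
    for i in range(n_s):
        loops = [
            (plan.voxel_sets[k], top_n_selector(scores[i, k], config.n_sel))
            for k in qualified[i]
        ]
        voxel_votes[i] = voxel_vote_rate(loops, parcellation)
        evr[i] = effective_vote_ratio(voxel_votes[i], phi_c, parcellation)
    r_bar = float(np.mean([test_acc[i, qualified[i]].mean() for i in range(n_s)]))

    return ShvResult(
        scores=scores,
        test_acc=test_acc,
        qualified_loops=qualified,
        cluster_votes=phi_c,
        voxel_votes=voxel_votes,
        evr=evr,
        mean_evr=evr.mean(axis=0),
        r_bar=r_bar,
        lam=float(lam),
        method=method,
        failed_loops=failed,
        voxel_sets=plan.voxel_sets,
    )


def default_lambda_grid(
    data: list[SubjectFeatures],
    parcellation: Parcellation,
    method: str = "group",
    fractions: tuple[float, ...] = (0.05, 0.15, 0.4),
) -> tuple[float, ...]:
    """Anchor a candidate grid at the full-data lambda_max.

    Cluster features from *all* voxels are z-scored per subject and the
    smallest all-zero penalty computed; the grid is fixed fractions of it,
    the usual practice for lasso-type paths.
    """
    all_vox = np.arange(parcellation.n_voxels)
    feats = []
    for d in data:
        f = average_features(d, parcellation, all_vox)
        mu, sd = f.D.mean(axis=0), f.D.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        feats.append(ClusterFeatures(D=(f.D - mu) / sd, cluster_ids=f.cluster_ids,
                                     trial_ids=f.trial_ids))
    lmax = lambda_max(feats, [d.y for d in data],
                      penalty="group" if method == "group" else "l1")
    return tuple(float(f * lmax) for f in fractions)


def select_lambda(
    data: list[SubjectFeatures],
    parcellation: Parcellation,
    config: ShvConfig,
    mask: VoxelMask | None = None,
    method: str = "group",
) -> tuple[float, dict, dict]:
    """Pick the penalty maximizing the qualified-loop mean test accuracy.

    Every candidate runs on the *same* sampling plan (common random
    numbers), so candidates differ only through the fits.  Ties go to the
    larger penalty (the sparser model).

    Returns
    -------
    best_lam : float
    r_bar : dict mapping candidate -> averaged prediction accuracy
    results : dict mapping candidate -> full :class:`ShvResult`
    """
    grid = config.lambda_grid
    if grid is None:
        grid = default_lambda_grid(data, parcellation, method=method)
    if not grid:
        raise ValueError("lambda_grid is empty")
    if mask is None:
        raise ValueError("mask is required")
    plan = make_sampling_plan(mask, [d.y for d in data], config)
    r_bar: dict[float, float] = {}
    results: dict[float, ShvResult] = {}
    for lam in grid:
        res = run_shv(data, parcellation, config, lam, plan=plan, method=method)
        r_bar[float(lam)] = res.r_bar
        results[float(lam)] = res
    best = max(r_bar, key=lambda l: (r_bar[l], l))  # ties -> larger penalty
    return best, r_bar, results
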