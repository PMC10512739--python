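"""Multi-subject synthetic fMRI benchmark with planted discriminative regions.

The generator emulates a small-sample aversive-conditioning decoding study.
A 3D grid is partitioned into atlas-like contiguous regions.  Three
*discriminative* regions, common to every subject, carry per-trial base
values M_j ~ U(0, 1) shared by all voxels of the region; the class label is
tied to the weighted sum

    y1 = sum_{j in G1} w_j * alpha_j * M_j,       alpha_j ~ U(0.5, 1.5)

by requiring CS+ trials to fall in the top 40% and CS- trials in the bottom
40% of the unconditional y1 distribution, so the classes are separable by a
linear readout of the three region means but no single region determines
the label.  Each subject additionally receives its own set of
*interference* regions whose base value correlates with the label through a
looser top/bottom-80% rule: per subject they mimic idiosyncratic nuisance
structure, and because the sets differ across subjects, methods that pool
subjects can suppress them.  All remaining voxels are pure noise.
Observations add i.i.d. Gaussian noise per voxel and trial.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, replace

import numpy as np

from .mask import VoxelMask
from .parcellation import Parcellation
from .sparse_logistic import SubjectFeatures

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "make_region_map",
    "generate_subject",
    "generate_dataset",
    "reduced_spec",
    "full_scale_spec",
]

_PILOT_DRAWS = 100_000
_MAX_REJECTION_DRAWS = 1_000_000


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of the benchmark generator.

    Subject ``i`` (0-based) receives interference regions
    ``interference_base + i*interference_stride`` through
    ``... + n_interference - 1``; region ids are 0-based.
    """

    grid_shape: tuple[int, int, int] = (20, 22, 20)
    n_regions: int = 40
    discriminative_regions: tuple[int, ...] = (4, 14, 24)
    init_weights: tuple[float, ...] = (1.0, 1.0, -2.0)
    n_interference: int = 5
    interference_base: int = 26
    interference_stride: int = 1
    alpha_range: tuple[float, float] = (0.5, 1.5)
    n_subjects: int = 9
    n_trials_per_class: int = 20
    label_quantile_discr: float = 0.40
    label_quantile_interf: float = 0.80
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.discriminative_regions) != len(self.init_weights):
            raise ValueError("one initial weight per discriminative region")
        if not 0 < self.label_quantile_discr <= 0.5:
            raise ValueError("discriminative quantile must be in (0, 0.5] for separable classes")
        if not 0 < self.label_quantile_interf <= 1:
            raise ValueError("interference quantile must be in (0, 1]")
        if self.alpha_range[0] <= 0 or self.alpha_range[0] > self.alpha_range[1]:
            raise ValueError("invalid alpha_range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for i in range(self.n_subjects):
            regs = self.interference_regions(i)
            if regs and (min(regs) < 0 or max(regs) >= self.n_regions):
                raise ValueError(
                    f"interference rule yields region ids outside [0, {self.n_regions}) "
                    f"for subject {i}"
                )
            if set(regs) & set(self.discriminative_regions):
                raise ValueError(
                    f"interference and discriminative regions overlap for subject {i}"
                )

    def interference_regions(self, subject_index: int) -> tuple[int, ...]:
        start = self.interference_base + subject_index * self.interference_stride
        return tuple(range(start, start + self.n_interference))


def reduced_spec(**overrides) -> SyntheticSpec:
    """Desk-scale benchmark: 20x22x20 grid (8,800 voxels), 40 regions,
    9 subjects, 20+20 trials, 3 planted regions with weights (1, 1, -2),
    5 interference regions per subject."""
    return replace(SyntheticSpec(), **overrides) if overrides else SyntheticSpec()


def full_scale_spec(**overrides) -> SyntheticSpec:
    """Full-scale benchmark: 53x63x52 grid, 116 atlas-like regions,
    discriminative regions {32, 44, 62} (1-based: ids 31, 43, 61),
    15 interference regions per subject shifted by 3 between subjects."""
    spec = SyntheticSpec(
        grid_shape=(53, 63, 52),
        n_regions=116,
        discriminative_regions=(31, 43, 61),
        init_weights=(1.0, 1.0, -2.0),
        n_interference=15,
        interference_base=74,
        interference_stride=3,
    )
    return replace(spec, **overrides) if overrides else spec


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated benchmark: per-subject features, ground truth, and the
    region map both as a label array and as a :class:`Parcellation`."""

    subjects: list[SubjectFeatures]
    spec: SyntheticSpec
    truth: list[dict]
    region_map: np.ndarray
    mask: VoxelMask
    parcellation_truth: Parcellation


def make_region_map(
    grid_shape: tuple[int, int, int],
    n_regions: int,
    seed: int = 0,
) -> np.ndarray:
    """Contiguous space-filling partition of the grid into balanced regions.

    Regions grow by breadth-first search from randomly seeded voxels; at
    each step the currently smallest region with a non-empty frontier
    claims one voxel, which keeps region sizes close to the mean.  Returns
    a label array over the in-grid voxels in mask linear (C) order.
    """
    mask = VoxelMask.full(tuple(int(s) for s in grid_shape))
    n_vox = mask.n_voxels
    if not 1 <= n_regions <= n_vox:
        raise ValueError(f"n_regions must be in [1, {n_vox}]")
    rng = np.random.default_rng(seed)
    labels = np.full(n_vox, -1, dtype=np.intp)
    seeds = rng.choice(n_vox, size=n_regions, replace=False)

    shape = np.asarray(mask.shape)
    strides = np.array([shape[1] * shape[2], shape[2], 1])
    coords = mask.coords
    neighbors_of = []  # 6-connectivity neighbor linear indices
    offsets = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]])
    for v in range(n_vox):
        nb = coords[v] + offsets
        ok = ((nb >= 0) & (nb < shape)).all(axis=1)
        neighbors_of.append((nb[ok] @ strides).astype(np.intp))

    frontiers = []
    sizes = np.zeros(n_regions, dtype=int)
    for r, s in enumerate(seeds):
        labels[s] = r
        sizes[r] = 1
        frontiers.append(deque(neighbors_of[s]))

    import heapq

    heap = [(1, r) for r in range(n_regions)]
    heapq.heapify(heap)
    n_assigned = n_regions
    while n_assigned < n_vox and heap:
        size, r = heapq.heappop(heap)
        if size != sizes[r]:
            continue  # stale entry
        fr = frontiers[r]
        claimed = None
        while fr:
            v = fr.popleft()
            if labels[v] == -1:
                claimed = v
                break
        if claimed is None:
            continue  # region is walled in; drop it from growth
        labels[claimed] = r
        sizes[r] += 1
        fr.extend(neighbors_of[claimed])
        heapq.heappush(heap, (sizes[r], r))
        n_assigned += 1

    if (labels == -1).any():  # unreachable only if all frontiers died; attach greedily
        for v in np.flatnonzero(labels == -1):
            lab = next((labels[n] for n in neighbors_of[v] if labels[n] != -1), 0)
            labels[v] = lab
    return labels


def _y1_thresholds(weights: np.ndarray, quantile: float, rng: np.random.Generator):
    """Monte-Carlo lower/upper cutoffs of the unconditional y1 distribution."""
    m = rng.random((_PILOT_DRAWS, weights.size))
    y1 = m @ weights
    return np.quantile(y1, quantile), np.quantile(y1, 1.0 - quantile)


def generate_subject(
    spec: SyntheticSpec,
    subject_index: int,
    rng: np.random.Generator,
    region_map: np.ndarray,
) -> tuple[SubjectFeatures, dict]:
    """Generate one subject's trials-by-voxels matrix and its ground truth.

    Per trial, region base values are redrawn until the class's quantile
    conditions hold: CS+ needs y1 in the top ``label_quantile_discr`` of its
    unconditional distribution and every interference value in its top
    ``label_quantile_interf`` (CS-: the mirrored bottom conditions).  All
    voxels of a region share the accepted base value; Gaussian noise with
    ``noise_sd`` is then added to every voxel independently.
    """
    g1 = np.asarray(spec.discriminative_regions)
    g0 = np.asarray(spec.interference_regions(subject_index))
    alphas = rng.uniform(*spec.alpha_range, size=g1.size)
    weights = np.asarray(spec.init_weights) * alphas
    lo, hi = _y1_thresholds(weights, spec.label_quantile_discr, rng)
    interf_lo = 1.0 - spec.label_quantile_interf  # CS+ : M_j >= this
    interf_hi = spec.label_quantile_interf        # CS- : M_j <= this

    n_per = spec.n_trials_per_class
    y = np.concatenate([np.ones(n_per, dtype=int), -np.ones(n_per, dtype=int)])
    rng.shuffle(y)

    base_vals = np.zeros((y.size, g1.size + g0.size))
    draws = 0
    for t, label in enumerate(y):
        while True:
            draws += 1
            if draws > _MAX_REJECTION_DRAWS:
                raise RuntimeError(
                    "rejection sampling exceeded the draw budget; quantile "
                    "conditions are likely mis-specified"
                )
            m1 = rng.random(g1.size)
            m0 = rng.random(g0.size)
            y1 = m1 @ weights
            if label > 0:
                ok = y1 >= hi and (m0 >= interf_lo).all()
            else:
                ok = y1 <= lo and (m0 <= interf_hi).all()
            if ok:
                base_vals[t] = np.concatenate([m1, m0])
                break

    n_vox = region_map.size
    X = np.zeros((y.size, n_vox))
    for col, region in enumerate(np.concatenate([g1, g0])):
        members = region_map == region
        X[:, members] = base_vals[:, col][:, None]
    if spec.noise_sd > 0:
        X += spec.noise_sd * rng.standard_normal(X.shape)

    truth = {
        "subject_index": subject_index,
        "alphas": dict(zip(g1.tolist(), alphas.tolist())),
        "weights": dict(zip(g1.tolist(), weights.tolist())),
        "interference_regions": g0.tolist(),
        "y1_thresholds": (float(lo), float(hi)),
        "y1_values": (base_vals[:, : g1.size] @ weights).tolist(),
    }
    return SubjectFeatures(X=X, y=y, subject_id=f"sub-{subject_index:02d}"), truth


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate all subjects of the benchmark, reproducibly from ``spec.seed``.

    Subjects share the region map and the discriminative region set G1 but
    draw their own weight scalings and interference regions.
    """
    region_map = make_region_map(spec.grid_shape, spec.n_regions, seed=spec.seed)
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_subjects)
    subjects, truth = [], []
    for i in range(spec.n_subjects):
        subj, rec = generate_subject(spec, i, np.random.default_rng(streams[i]), region_map)
        subjects.append(subj)
        truth.append(rec)
    return SyntheticDataset(
        subjects=subjects,
        spec=spec,
        truth=truth,
        region_map=region_map,
        mask=VoxelMask.full(spec.grid_shape),
        parcellation_truth=Parcellation(labels=region_map, n_clusters=spec.n_regions),
    )
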