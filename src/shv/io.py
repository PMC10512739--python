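"""NIfTI / CSV input-output and run manifests.

Conventions: 4D NIfTI volumes carry trials (or scans) on the 4th axis; 3D
masks are nonzero inside the brain; voxel coordinates are 0-based array
indices and feature columns follow the mask's C-order linear indexing.
Affines are carried through to outputs but never used for resampling --
inputs are assumed co-registered in a common (e.g. MNI) space.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .mask import VoxelMask
from .parcellation import Parcellation
from .sparse_logistic import SubjectFeatures

__all__ = [
    "read_mask",
    "read_features",
    "write_features",
    "write_brain_map",
    "read_parcellation",
    "write_parcellation",
    "RunManifest",
]


def read_mask(path) -> tuple[VoxelMask, np.ndarray]:
    """Load a 3D mask NIfTI; returns the mask and its affine."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"mask must be 3D, got shape {data.shape}")
    return VoxelMask.from_array(data != 0), img.affine


def _read_labels(path, label_column: str, pos_label):
    table = pd.read_csv(path)
    if label_column not in table.columns:
        raise ValueError(f"label table lacks a '{label_column}' column")
    raw = table[label_column]
    if pos_label is None:
        y = raw.astype(int).to_numpy()
        if not set(np.unique(y)) <= {-1, 1}:
            raise ValueError(
                "labels are not +/-1; pass pos_label to declare the positive class"
            )
        return y
    uniq = pd.unique(raw)
    if len(uniq) != 2 or pos_label not in set(uniq):
        raise ValueError(
            f"need exactly two label values including pos_label={pos_label!r}, got {list(uniq)}"
        )
    return np.where(raw.to_numpy() == pos_label, 1, -1)


def read_features(
    path_4d,
    mask: VoxelMask | str | Path,
    path_labels,
    label_column: str = "label",
    pos_label=None,
    subject_id: str = "",
) -> SubjectFeatures:
    """Load a subject: 4D volume + mask + label CSV -> trials x voxels matrix.

    The 4th axis indexes trials and must match the label table length;
    columns follow mask linear order.  Labels are +/-1, or mapped by
    declaring ``pos_label``.
    """
    if not isinstance(mask, VoxelMask):
        mask, _ = read_mask(mask)
    img = nib.load(str(path_4d))
    vol = np.asanyarray(img.dataobj, dtype=float)
    if vol.ndim != 4:
        raise ValueError(f"feature volume must be 4D, got shape {vol.shape}")
    if vol.shape[:3] != mask.shape:
        raise ValueError(f"volume grid {vol.shape[:3]} != mask grid {mask.shape}")
    y = _read_labels(path_labels, label_column, pos_label)
    if vol.shape[3] != y.size:
        raise ValueError(f"{vol.shape[3]} volumes but {y.size} labels")
    X = vol[tuple(mask.coords.T)].T  # (trials, N_V) in mask linear order
    if not np.isfinite(X).all():
        raise ValueError("non-finite voxel values inside the mask")
    return SubjectFeatures(X=X, y=y, subject_id=subject_id or Path(path_4d).stem)


def write_features(
    subject: SubjectFeatures,
    mask: VoxelMask,
    affine: np.ndarray,
    path_4d,
    path_labels,
) -> None:
    """Write a subject as a 4D NIfTI (trials on axis 4) + labels CSV."""
    vol = np.zeros(mask.shape + (subject.n_trials,), dtype=np.float32)
    vol[tuple(mask.coords.T)] = subject.X.T
    nib.save(nib.Nifti1Image(vol, affine), str(path_4d))
    pd.DataFrame({"trial": np.arange(subject.n_trials), "label": subject.y}).to_csv(
        path_labels, index=False
    )


def write_brain_map(values, mask: VoxelMask, affine: np.ndarray, path) -> None:
    """Write per-voxel values as a 3D NIfTI, zeros outside the mask.

    Values are written unthresholded; zeros in the output are true zeros.
    """
    vol = mask.unmask(np.asarray(values, dtype=float), fill=0.0).astype(np.float32)
    nib.save(nib.Nifti1Image(vol, affine), str(path))


def write_parcellation(
    parcellation: Parcellation,
    mask: VoxelMask,
    affine: np.ndarray,
    path_nii,
    path_csv=None,
) -> None:
    """Label image with 0 outside the mask and 1..N_C inside, plus an
    optional (cluster_id, size) table."""
    vol = mask.unmask(parcellation.labels + 1.0, fill=0.0).astype(np.int32)
    nib.save(nib.Nifti1Image(vol, affine), str(path_nii))
    if path_csv is not None:
        pd.DataFrame(
            {"cluster_id": np.arange(parcellation.n_clusters), "size": parcellation.sizes()}
        ).to_csv(path_csv, index=False)


def read_parcellation(path_nii, mask: VoxelMask) -> Parcellation:
    """Inverse of :func:`write_parcellation` (labels 1..N_C inside mask)."""
    img = nib.load(str(path_nii))
    vol = np.asanyarray(img.dataobj)
    if vol.shape != mask.shape:
        raise ValueError("parcellation grid does not match the mask")
    labels = vol[tuple(mask.coords.T)].astype(np.intp) - 1
    if labels.min() < 0:
        raise ValueError("in-mask voxels with label 0 (outside-mask code)")
    return Parcellation(labels=labels, n_clusters=int(labels.max()) + 1)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Replay record of a run: config, seeds, versions, input digests."""

    command: str
    config: dict
    master_seed: int
    input_digests: dict = field(default_factory=dict)
    versions: dict = field(default_factory=dict)
    timing_seconds: float | None = None

    def __post_init__(self) -> None:
        if not self.versions:
            import nibabel
            import scipy
            import sklearn

            from . import __version__

            self.versions = {
                "python": platform.python_version(),
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "scikit-learn": sklearn.__version__,
                "nibabel": nibabel.__version__,
                "shv": __version__,
            }

    def add_input(self, name: str, path) -> None:
        self.input_digests[str(name)] = _sha256(path)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        payload = json.loads(Path(path).read_text())
        return cls(**payload)
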