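"""Accuracy-vs-voxel-count validation of an EVR map.

Trains a linear l2-SVM on the top-c voxels ranked by EVR for growing c and
cross-validates the decoding accuracy: a good ranking reaches high accuracy
with few voxels, then degrades as noise voxels are padded in.
"""

import warnings

import numpy as np

from shv import ShvConfig, accuracy_vs_voxels, generate_dataset, reduced_spec, run_shv
from shv.engine import default_lambda_grid

warnings.filterwarnings("ignore", category=RuntimeWarning)

ds = generate_dataset(reduced_spec(seed=2))
config = ShvConfig(n_k=30, n_l=8, alpha_col=0.05, alpha_row=0.9, alpha_k=0.3,
                   n_sel=4, block_size=(3, 3, 3), seed=10_002)
lam = default_lambda_grid(ds.subjects, ds.parcellation_truth)[1]
res = run_shv(ds.subjects, ds.parcellation_truth, config, lam, mask=ds.mask)

counts = [10, 50, 200, 600, 2000]
curves = []
for i, subj in enumerate(ds.subjects[:4]):
    curves.append(accuracy_vs_voxels(res.evr[i], subj, voxel_counts=counts,
                                     k_folds=4, seed=i))

print("voxels  train_acc  test_acc   (averaged over 4 subjects, 4 folds)")
for row in range(len(counts)):
    tr = np.mean([c.loc[row, "train_acc"] for c in curves])
    te = np.mean([c.loc[row, "test_acc"] for c in curves])
    pad = " (padded with zero-EVR voxels)" if curves[0].loc[row, "padded"] else ""
    print(f"{counts[row]:6d}  {tr:9.3f}  {te:8.3f}{pad}")
print("\n-> the EVR ranking front-loads informative voxels: accuracy peaks")
print("   with a few hundred voxels and falls once padding adds noise.")
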