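"""Group regularization vs single-subject fits: selection stability.

Runs both estimators on identical sampling plans and compares the
chance-corrected mean pairwise overlap of the selected-voxel sets across
subjects (higher = selections agree more between subjects).
"""

import warnings

from shv import (
    SelectionSet,
    ShvConfig,
    generate_dataset,
    mean_overlap,
    reduced_spec,
    select_lambda,
)

warnings.filterwarnings("ignore", category=RuntimeWarning)

ds = generate_dataset(reduced_spec(seed=1))
config = ShvConfig(n_k=50, n_l=10, alpha_col=0.05, alpha_row=0.9, alpha_k=0.3,
                   n_sel=4, block_size=(3, 3, 3), seed=10_001)

for method, label in (("group", "groupwise mixed l1/l2"),
                      ("single", "single-subject l1 (alternative)")):
    best, _, results = select_lambda(ds.subjects, ds.parcellation_truth, config,
                                     mask=ds.mask, method=method)
    res = results[best]
    sels = [SelectionSet.from_evr(res.evr[i]) for i in range(len(ds.subjects))]
    o_bar = mean_overlap(sels)
    sizes = [len(s) for s in sels]
    print(f"{label}:")
    print(f"  selected-voxel sets: {min(sizes)}-{max(sizes)} voxels per subject")
    print(f"  stability index O_bar = {o_bar:.3f}, "
          f"qualified test accuracy R_bar = {res.r_bar:.3f}")

print("\n-> coupling subjects through the row-wise l2 penalty concentrates")
print("   the selections on the shared discriminative clusters, raising the")
print("   across-subject overlap relative to independent l1 fits.")
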