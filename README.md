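# shv — stable hierarchical voting for discriminative voxel selection

`shv` identifies the voxels that carry condition information in
multi-subject fMRI decoding studies with *small* sample sizes — the typical
regime of psychophysiological paradigms (e.g. aversive conditioning, where
a CS+ stimulus predicts a noxious outcome and a CS− does not, and ethics
limits trial counts to a few dozen per subject). In that regime many
different sparse weight maps decode equally well, so the selected voxels of
any single fit are unstable and hard to interpret. `shv` addresses this by
combining three ingredients:

1. **Data-driven parcellation.** In-mask voxels are grouped into N_C small
   clusters by normalized-cut spectral clustering of the affinity

   A(v₁, v₂) = |corr(X(:,v₁), X(:,v₂))| · exp(−dist(v₁, v₂)² / σ_d²),

   computed on the subjects' combined data so one segmentation serves the
   whole group. Cluster averages replace single voxels as predictors,
   shrinking the problem from N_V voxels to N_C ≈ 200 unknowns.

2. **Groupwise structured sparsity.** All subjects are fit jointly with a
   mixed l1/l2 (group-lasso) logistic model on cluster features D^i
   (trials × clusters):

   min_W Σᵢ Σₜ log(1 + exp(−yⁱ(t)(Dⁱ(t,:)W(:,i) + bᵢ))) + λ Σⱼ ‖W(j,:)‖₂

   The row-wise l2 penalty selects or discards each cluster *for all
   subjects at once* while letting weight magnitudes differ per subject.
   The solver is a monotone accelerated proximal-gradient (FISTA) method
   with backtracking; the single-subject l1 model (the "alternative
   method") is the one-column special case.

3. **Stable hierarchical voting (SHV).** An outer loop (N_K repeats) draws
   constrained 3×3×3-block subsamples of voxels; an inner loop (N_L
   repeats) subsamples trials, fits the group model and scores held-out
   accuracy. Only the top α_K fraction of outer loops by test accuracy are
   *qualified* to vote. Votes pass through nested top-N_sel selectors —
   per loop, per subject, then across subjects — yielding the cluster vote
   rate φ^C, and each voxel's sampling-conditional vote rate φ̃^V is scaled
   by its cluster's φ^C to give the **effective vote ratio (EVR)**, the
   method's per-voxel output map. The penalty λ is chosen to maximize the
   qualified-loop mean test accuracy R̄.

Stability is quantified by the chance-corrected mean pairwise overlap of
the selected-voxel sets across subjects,
O(S₁, S₂) = ||S₁∩S₂| − |S₁||S₂|/N_V| / max(|S₁|, |S₂|), and — on synthetic
data with planted signal — by precision/recall of the retrieved clusters
and cross-validated accuracy of a linear l2-SVM on the top-EVR voxels.

A built-in generator reproduces the benchmark design used to validate the
method: atlas-like contiguous regions on a 3D grid, three discriminative
regions common to all subjects whose weighted uniform base values determine
the labels through top/bottom-40% quantile rules, per-subject interference
regions with a looser 80% rule, per-subject weight scalings α ~ U(0.5, 1.5)
and unit Gaussian observation noise.

## Worked example

```sh
python examples/03_run_shv.py
```

generates the nine-subject benchmark (8,800 voxels, 40 regions, planted
regions {4, 14, 24}), selects λ from a three-point grid and runs SHV with
N_K=50, N_L=10, α_col=0.05, α_row=0.9, α_K=0.3, N_sel=4:

```
penalty selection (qualified-loop mean test accuracy):
  lambda =   2.477: R_bar = 0.883
  lambda =   7.431: R_bar = 0.897  <- selected
  lambda =  19.815: R_bar = 0.877

top-4 clusters by group vote rate phi_C:
  cluster  4: phi_C = 1.00  (planted)
  cluster 14: phi_C = 1.00  (planted)
  cluster 24: phi_C = 1.00  (planted)
  cluster 33: phi_C = 0.56  (distractor)

precision = 0.75, recall = 1.00 against the planted regions (4, 14, 24)
mean EVR map: 1125 of 8800 voxels nonzero, max = 1.00
```

All three planted clusters receive unanimous votes (φ^C = 1 means every
subject's hierarchical selector kept them); the one distractor sneaks in at
a visibly lower rate. The other examples cover the generator
(`01_simulate_benchmark.py`), NCut parcellation (`02_parcellate.py`), the
group-vs-single stability comparison (`04_stability_comparison.py`, where
the group estimator's O̅ ≈ 0.53 clearly exceeds the single-subject
alternative's ≈ 0.31), and the accuracy-vs-voxel-count curve
(`05_accuracy_curve.py`).

For shell use the same pipeline is exposed as a thin CLI:

```sh
shv simulate --out sim --seed 0
shv parcellate --data sim/sub-00_features.nii --mask sim/mask.nii \
    --n-clusters 40 --sigma-d 3 --seed 0 --out parc.nii
shv run --features sim/sub-*_features.nii --labels sim/sub-*_labels.csv \
    --mask sim/mask.nii --parcellation sim/regions.nii \
    --config config.txt --lam 7.4 --out results/
shv evaluate --evr results/sub-*_evr.nii --mask sim/mask.nii --out results/
```

Every run writes a `manifest.json` with the configuration, master seed,
input digests and library versions needed to replay it.

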