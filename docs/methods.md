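# Methods

## Problem setting and model

We consider binary decoding of multi-subject fMRI trial features: subject
i contributes a matrix X^i (N_T trials × N_V voxels) and labels
y^i(t) ∈ {+1, −1}. N_V is 10⁴–10⁵ while N_T is a few dozen, so any
single sparse fit is one of many near-equivalent solutions and the set of
selected voxels varies wildly with the data perturbation. The package's
output is therefore not one weight map but a *vote-rate* map aggregated
over many randomized fits, with quality control on the randomizations.

### Parcellation

Voxels are partitioned once, for the whole group, into N_C clusters.
The affinity between voxels v₁, v₂ is
|corr(X(:,v₁), X(:,v₂))| · exp(−dist²/σ_d²) on a user-chosen data matrix —
raw time series, trial features, or (default in the CLI) their row-wise
concatenation after per-subject column z-scoring. The literature behind
the method lists both correlation cues but displays a single correlation
term; we apply the formula verbatim to whichever matrix is supplied and
let concatenation bring both cues in. Graph edges are restricted to pairs
within `support_radius` = 3σ_d (the kernel is < e⁻⁹ there), keeping the
graph sparse. Normalized cuts are realized as spectral clustering: the
symmetric normalized Laplacian's leading eigenvectors (dense `eigh`, so the
embedding is deterministic), row-normalized, then k-means with a fixed
seed. Empty clusters — rare, but possible when centroids collapse — are
repaired by splitting the largest cluster at the sign of its subgraph's
Fiedler vector. Spatial contiguity is *encouraged* by the distance kernel
but not enforced. A graph with more connected components than clusters is
rejected with a pointer to enlarge the support radius.

### Group-sparse logistic model

On cluster averages D^i (trials × clusters), subjects are fit jointly:

    min_{W,b} Σ_i Σ_t log(1+exp(−y^i(t)(D^i(t,:)W(:,i)+b_i))) + λ Σ_j ‖W(j,:)‖₂

Intercepts are never penalized. Columns of D are z-scored per subject from
the training trials (test trials reuse training moments) so that λ is
comparable across subsamples. The solver is monotone FISTA with
backtracking: the prox of the row-norm penalty is block soft-thresholding
`r ↦ r·max(0, 1−t/‖r‖)`; a candidate that would increase the objective is
rejected (the previous iterate is kept and momentum restarts), which makes
the recorded objective trace non-increasing by construction. Convergence
is declared after two consecutive relative objective changes below `tol`
(default 1e−6, `max_iter` 2000; non-convergence returns the best iterate
with a warning). `lambda_max` — the largest row norm of the smooth-loss
gradient at W = 0 with intercepts at their closed-form optimum
b_i = log(n⁺/n⁻) — bounds the useful penalty range. The single-subject
"alternative" model is the one-column case, where the row norm reduces to
|w(j)| (an l1 penalty); because the l1 objective separates across subjects,
the engine fits all subjects' alternative models in one stacked solve with
an elementwise prox, which is exactly equivalent to per-subject fits (and
tested to be).

### Stable hierarchical voting

Outer loop k = 1..N_K: draw whole 3×3×3 blocks of the voxel grid uniformly
without replacement until ≥ α_col·N_V in-mask voxels are covered (block
sampling respects the local correlation structure; the block size trades
false positives against false negatives and 3×3×3 is the package default).
The voxel set is shared by all subjects within a loop so the group fit sees
aligned cluster columns; clusters with no sampled voxel are dropped from
that loop (their score contribution is zero). Inner loop l = 1..N_L: per
subject, a stratified trial subsample of round(α_row·n_c) per class trains
the model; the complement tests it. Stratification is used because with
α_row = 0.9 on 40 trials the test set has only 4 trials and would otherwise
often be single-class. Within a loop the solver warm-starts from the
previous inner fit (same active clusters), which changes nothing at
convergence but saves most iterations.

Scores and votes:

* s_{i,k}(j) = (1/N_L) Σ_l |W_l(j,i)| — model averaging over inner fits;
* selector π(·, N_sel) marks the top-N_sel *strictly positive* entries
  (ties break toward the lower cluster id, for reproducibility);
* per subject, only the top ⌊α_K·N_K⌋ loops by mean test accuracy qualify
  (at least one; an optional `min_precision` filter can drop loops below an
  absolute accuracy, falling back to the single best loop);
* φ^C = (1/N_S) Σ_i π((1/N_i) Σ_k π(s_{i,k}, N_sel), N_sel) — entries are
  exact multiples of 1/N_S and at most N_sel·N_S clusters are positive;
* φ̃^V_i(m) = (#qualified loops where m sampled and its cluster selected) /
  (#qualified loops where m sampled), defined as 0 for never-sampled
  voxels (no evidence → conservative);
* EVR φ^V_i(m) = φ̃^V_i(m)·φ^C(cluster(m)), so 0 ≤ φ^V ≤ φ̃^V ≤ 1.

λ is chosen from a candidate grid to maximize R̄, the across-subject mean
of qualified-loop test accuracy, with all candidates evaluated on the
*same* pre-drawn sampling plan (common random numbers) and ties going to
the larger (sparser) λ. When no grid is given, candidates are fixed
fractions (0.05, 0.15, 0.4) of the full-data `lambda_max` — the standard
anchoring for lasso-type paths, chosen a priori.

All randomness derives from one master seed through `SeedSequence` spawns
(one stream per outer loop for voxels, one per (k, l, subject) for trials),
so a run is bit-identically reproducible and sampling plans are identical
across λ candidates and across estimators being compared.

### Evaluation

Stability: corrected pairwise overlap
O(S₁,S₂) = ||S₁∩S₂| − |S₁||S₂|/N_V| / max(|S₁|,|S₂|) of the nonzero-EVR
sets, averaged over subject pairs; identical sets score 1 − |S|/N_V, two
random sets ≈ 0. Planted-truth benchmarks additionally report precision
and recall of the retrieved cluster set. The practical value of an EVR
ranking is probed by 4-fold cross-validated accuracy of a linear l2-SVM
(fixed C = 1, per-fold z-scoring from training folds; the underlying
validation protocol names the classifier but no hyperparameters) on the
top-c EVR voxels for increasing c, padding with next-ranked zero-EVR voxels
(flagged) when c exceeds the selection.

## Synthetic benchmark

The generator plants a known answer in a realistic geometry. Defaults
(desk scale): 20×22×20 grid (8,800 voxels) partitioned into 40 contiguous
regions by balanced multi-source breadth-first growth from random seed
voxels; 9 subjects × (20 CS+ + 20 CS−) trials; discriminative regions
G₁ = {4, 14, 24} with initial weights (1, 1, −2) scaled per subject and
region by α ~ U(0.5, 1.5); 5 interference regions per subject, subject i
getting the consecutive window {26+i … 30+i} so neighbouring subjects share
most but not all of them; observation noise sd 1. A full-scale preset
mirrors the original design (53×63×52 grid, 116 regions, G₁ ids
{31, 43, 61} 0-based, 15-region interference windows shifted by 3).

Per trial all voxels of a region share one base value M_j ~ U(0, 1).
Class conditioning is by rejection sampling: a CS+ trial's region draws are
redrawn until the weighted sum y₁ = Σ_{j∈G₁} W̃_j M_j lies in the top 40%
of its unconditional distribution (Monte-Carlo thresholds from 10⁵ pilot
draws) *and* every interference value lies in its top 80% (exact uniform
quantiles); CS− mirrors both conditions at the bottom. The two class-
conditional y₁ ranges are disjoint by construction, so the three region
means support a perfect linear readout, while the interference rule gives
each interference region a point-biserial label correlation of
0.1/√(4/75 + 0.01) ≈ 0.40 — strong enough to distract a per-subject fit,
but inconsistent across subjects. Voxels outside signal regions are pure
N(0, noise_sd²) noise; we deliberately do not add noise on top of a second
Gaussian "base" draw, which would double the background variance.

What the generator does *not* emulate: hemodynamic temporal structure,
spatially correlated noise beyond the region blocks, inter-subject
misregistration, and partial-region signals (whole regions are
discriminative). Passing benchmarks therefore demonstrates correct
recovery under the stated generative model, not performance on real BOLD
data.

## Problem sizes and numerical choices

The test suite and the reproduction script run the benchmark at
N_K = 50, N_L = 10, α_col = 0.05, α_row = 0.9, α_K = 0.3, N_sel = 4 with a
3-point λ grid — 1,500 group fits per estimator and seed, a few seconds
each thanks to the stacked-subject solver and warm starts. ShvConfig
defaults mirror a full-scale analysis (N_K = 200, N_L = 20, α_col = 0.01,
N_sel = 15, σ_d = 3, N_C = 200 clusters recommended).

Degenerate inputs and tie-breaks: constant data columns get correlation 0
in the affinity (warned); zero rows pass through the prox unchanged;
selector ties and EVR-ranking ties break toward the lower index; sign(0)
predicts +1; an outer loop whose fit fails is recorded with accuracy 0 and
never qualifies; trial splits clamp per-class training counts to
[1, n_c − 1] so both classes always appear on both sides.

## Known limitations

* The qualified-loop accuracy R̄ is an *optimistically biased* estimate by
  construction: it averages the top α_K order statistics of noisy per-loop
  accuracies. With 4-trial test sets (benchmark scale) the bias under a
  label-permutation null is ≈ +1.16 × the per-loop accuracy sd (measured
  ≈ +0.12 at chance level 0.5, for every λ). R̄ is a model-*selection*
  criterion, not an unbiased performance estimate; report held-out
  accuracy from the validation curve instead.
* Cluster vote normalization divides by N_i unconditionally, including
  loops where a cluster was never sampled; with small α_col this caps
  per-subject vote frequencies well below 1 and makes φ^C conservative.
* Binary labels only; no multinomial extension.
* The NCut implementation densifies the Laplacian (fine for N_V up to a
  few thousand per spectral solve; full-brain parcellations should supply
  a coarser mask or precomputed parcellation).
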