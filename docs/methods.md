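# Methods

## Problem setting

`pathagg` aggregates a genes × samples log₂-scale expression matrix with a
two-class phenotype (`class1` = control, `class2` = case) into a
pathways × samples activity matrix, one row per gene set of a GMT
catalogue, and benchmarks competing aggregation methods by classification
accuracy and by the reproducibility of pathway-level differential-expression
signatures between related datasets.

## Aggregation methods

Let `Z` be the per-gene z-scaled matrix (mean 0, unit sample SD across all
samples of the fitted dataset), and `t_g` the pooled-variance two-sample
Student t of gene g with the convention t > 0 ⇔ up-regulated in case.

* **mean_all** — pathway profile is the arithmetic mean of all measured
  member z-rows.
* **mean_top50** — the mean of the ⌈m/2⌉ members with largest |t| on the
  training data (ties by gene id). A `directional` variant orders by signed
  t in the pathway's net direction instead; |t| is the default because it
  captures strong changes of either sign.
* **mean_corgs** — condition-responsive genes. The pathway's net direction
  d is the sign of the mean member t (+1 on an exact zero, logged);
  members are sorted with the most strongly d-regulated genes first; the
  member prefix is grown greedily while the |t| of the prefix-mean profile
  strictly increases, stopping at the first non-improvement. Non-strict
  improvement terminates the search so that ties cannot inflate the set.
  The profile is the plain mean of the selected z-rows (not a √k-normalised
  sum).
* **pca** — the first eigenvector `w` of the member-gene correlation matrix
  (equivalently the first right singular direction of the samples × genes
  z-matrix); profile = c·Zᵀw. Because eigenvector orientation is
  arbitrary, the sign factor c ∈ {±1} forces a non-negative Pearson
  correlation between the training scores and the pathway's mean member
  profile. Single-member pathways fall back to w = (1); all-zero member
  submatrices are dropped with a warning. An exact top-eigenvalue tie keeps
  whichever vector the solver returns first, then sign-corrects.
* **pls** — first latent component for a univariate response: with
  ỹ the centered 0/1 class coding (0 = control, 1 = case),
  w = Zᵀỹ/‖Zᵀỹ‖ and profile = c·Zᵀ…w with the same sign correction, which
  makes the 0/1 vs 1/0 coding choice immaterial. Pathways where no member
  covaries with the class (Zᵀỹ = 0) are dropped with a warning.
* **assess** — ASSESS-style per-sample enrichment. The per-gene,
  per-sample class evidence is an explicit Gaussian-KDE log-likelihood
  ratio Λ = log f̂_case(x) − log f̂_control(x) with a 10⁻¹² density floor;
  bandwidths use Silverman's rule h = 0.9·min(s, IQR/1.34)·n^(−1/5),
  floored at 10⁻³ of the gene's training range (10⁻⁸ for constant genes).
  Per sample, genes are ranked by Λ descending (ties by id) and a weighted
  KS walk gives the enrichment score: member steps +|Λ|^p/Σ_members|Λ|^p
  (p = 1 by default), non-member steps −1/(N−m); the score is the signed
  walk value at maximum |deviation|; the walk provably ends at 0, and the
  score is 0 when all member weights vanish. ASSESS operates on raw,
  not z-scaled, input. The gene-level probability model of the original
  ASSESS program is not reconstructible from its description alone, so the
  KDE log-likelihood ratio is this package's explicit, testable stand-in
  with the same contract.

All methods follow a strict fit/transform contract: scaling parameters,
subsets, weights, signs and densities come from the training samples only;
held-out samples are transformed with that state unchanged.

## Evaluation

Pathways are ranked by the p-value of a pooled-variance t on the pathway
activity matrix (ties by |t|, then id) and the top k = 1…10 are fed to an
RBF-kernel SVM. Tuning is a grid search over C ∈ {2⁻⁴…2⁶} (11 values) ×
γ ∈ {C/k}, selected by inner stratified 5-fold CV minimising the average
classification error ACE = (FPR + FNR)/2; ties prefer smaller C, then
smaller γ (smallest-capacity preference). Class weights are proportional
to inverse class proportion, normalised to average 1, computed once from
the supplied training labels. The reported metric is balanced accuracy
BA = (TPR + TNR)/2, so any constant classifier scores exactly 0.5
regardless of imbalance.

Internal validation is stratified 5-fold CV repeated twice (configurable),
with z-scaling, aggregation, feature ranking and tuning redone inside every
fold; inner tuning folds are seeded per fold (outer seed XOR fold index),
independent of the outer split. External validation restricts both
datasets to their common genes, fits everything on the training dataset
and scores the other. Datasets with fewer than 10 samples in a class are
rejected for internal CV.

## Rank aggregation

Per dataset and feature-set size, methods are ranked by BA (ties by tag).
The combined ranking minimises Φ = Σ_lists Σ_methods W(x)·|rank_candidate(x)
− rank_list(x)| over all permutations by exhaustive enumeration (720 for
six methods; guarded at 8). W is the method's BA min-max normalised within
its list, so a list with equal accuracies degrades to the unweighted
Spearman footrule and uniformly strong datasets cannot dominate. The
original rank-aggregation package's exact weighting formula is not public
in closed form; this multiplicative weighting is the package's own choice,
chosen for its graceful unweighted limit.

## Concordance

A pathway signature is the vector of pathway-level t statistics of one
dataset (aggregator fitted and applied to the whole dataset — no CV).
Related datasets are compared by the Pearson r of their signatures over
common pathways; a pathway with t_A·t_B < 0 is discordant (scatter
quadrants II/IV). "Strongly discordant" reporting uses |t| > 2 in both
datasets by default (configurable; a conventional choice, not an inferred
one). Pooling concatenates the per-pair scatter points before correlating.

## Synthetic data

The generator emulates two-class log-scale expression as i.i.d. Normal
noise (SD 1 by default) with additive class-conditional mean shifts —
log-scale data justify additive rather than fold-change effects, and the
truth stays analytically known. Gene sets draw members without replacement
within each set; overlap with the preceding set is pinned to
`overlap_fraction` (default 0), overlap with earlier sets is left to
chance, as in real catalogues. A planted pathway has a responsive subset
(fraction ρ) shifted by +d·δ in case samples and an opposing, homeostatic
subset (fraction ω) shifted by −d·δ; net direction follows the dominant
subset. `simulate_pair` draws two datasets with independent noise from
child seeds (seed + 101, seed + 202, mod 2³¹) over a shared catalogue and
shared subset assignments; pathways in `flip_set` exchange the shift signs
of their two subsets in dataset B, flipping the net direction while a
coherent strongly-shifted subset persists — the mechanism that makes
direction-dependent methods (CORGs, PLS) produce large opposite-sign
signatures between the pair while the plain mean is diluted.

Reference study conditions (`standard_config`): 1,000 genes, 40 sets of
20–60 members, 30 + 30 samples, unit noise, effect δ = 2 SD for planted
pathways, ρ = 1 for concordant plants; the flip scenario uses ρ = 0.6,
ω = 0.3 so the opposing subset is strong but subordinate. These sizes make
one external validation run take seconds while keeping per-gene effects in
the regime where a t-test at n = 30 + 30 is near-certain to recover the
planted sign.

What the generator does **not** emulate: probe-level noise, batch and
platform effects, gene–gene correlation beyond the planted shifts, and
fold-change (multiplicative) effects. Passing benchmarks on this data
therefore demonstrate correctness of the algorithms and their leakage-free
validation wiring, not performance on real microarray cohorts.

## Numerical choices

* Sample SD (n−1) throughout, including z-scaling.
* Pooled SD and z-scaling variance floor ε = 10⁻⁸; z-rows with SD < ε
  become all-zero rather than exploding.
* Student's pooled-variance t (not Welch); no gene-level multiple-testing
  correction (none is used downstream).
* Catalogue size filter (default 20–300 members) counts catalogue members,
  not measured ones; restriction to measured genes happens at aggregation.
* Grid-search and permutation ties resolve deterministically (smaller
  C/γ; lexicographic permutation; gene/pathway id order), so every
  pipeline stage is reproducible from its seed.

## Known limitations

* The ASSESS stand-in reproduces the published contract, not the original
  Java implementation bit-for-bit.
* The weighted-footrule weighting is one defensible reading of
  "accuracies as weights"; other monotone weightings would reorder some
  near-tied aggregates.
* Single-component PCA/PLS only; no sparse/kernel variants.
* The classification benchmark uses an RBF SVM exclusively, by design.
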