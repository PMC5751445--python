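# Methods

## Model

The package treats drug repositioning as transductive learning on a pair
graph. Every drug–disease pair `s = (i, j)` is a node; the edge weight
between pairs `s = (i, j)` and `t = (i′, j′)` is the product
`W_st = S_c(i,i′)·S_d(j,j′)` of the comprehensive drug–drug and
disease–disease similarities, with `W_ss = 0`. Under the row-major
flattening `s = i·n + j` this is `W = kron(S_c, S_d) − I_q`. The degree of
a pair node therefore factorizes,
`a_s = Σ_{i′} S_c(i,i′) · Σ_{j′} S_d(j,j′) − 1`, which is what makes the
implicit operator possible.

The score vector `f ∈ R^q` minimizes a smoothness-plus-fit objective over
the normalized pair-graph Laplacian `L̄ = I_q − S`,
`S = A^(−1/2) W A^(−1/2)`:

    Loss(f) = ½ fᵀL̄f + (μ/2)‖∧_L f − y‖² + (ξ/2)‖∧_U f − p‖²

`∧_L` and `∧_U = I_q − ∧_L` are diagonal indicators of labeled (observed
treatment) and unlabeled pairs; `y` is the binary label vector; `p` is a
prior for unlabeled pairs, the kernel-cosine between the drug's and the
disease's gene profiles under the gene kernel (zero on labeled pairs). The
stationarity condition `(I_q + μ∧_L + ξ∧_U − S) f = μy + ξp` is solved by
the damped fixed-point iteration

    f^(k+1) = α[(μ−ξ)∧_U + S] f^(k) + (1−α)ŷ,  α = 1/(1+μ),  ŷ = y + (ξ/μ)p

started at `f^(0) = ŷ`. Since `S` is the degree-normalized adjacency of a
non-negatively weighted graph its spectral radius is at most 1, so the
iteration matrix has spectral radius ≤ α(μ−ξ+1) = (1+μ−ξ)/(1+μ) < 1
whenever ξ > 0: convergence is geometric, and the test suite verifies the
radius numerically on every random instance it solves. Because the
iteration map and `ŷ` are entrywise non-negative, all iterates and the
fixed point are non-negative.

`S·f` is evaluated without forming any q×q object: with `F` the m×n matrix
view of `f`, `Â_ij = √a_s` and `Ã = Â⊗Â`,

    (Sf)_s = [S_c (F⊘Â) S_d ⊘ Â − F⊘Ã]_ij

(the subtracted term removes the self-loop contribution). A dense
closed-form solver doubles as an independent oracle for problems with
q ≤ 2500.

## Assumptions

* **Guilt-by-association**: similar drugs treat similar diseases. The
  diagnostic `gba_ratio` quantifies it as mean similarity among
  disease-sharing entity pairs over non-sharing pairs; values above 1
  support the assumption.
* Labels are positive-only; unobserved pairs are treated as presumed
  negatives for ranking purposes, never as hard negatives in training.
* The relaxation `f_s ∈ [0,1]` of the binary cut indicator is solved
  unconstrained: no clipping or projection is applied, matching the
  gradient iteration exactly. Fixed points can in principle exceed 1 on
  pathological inputs; they are reported as-is, and rankings (the primary
  output) are unaffected by monotone rescaling. A `threshold_cut` utility
  exposes the hard two-group reading.

## Parameters

| parameter | default | meaning |
|---|---|---|
| gene kernel a, b | 0.3, 1.0 | amplitude/decay of `a·e^(−b·d)` on gene-graph hop distances |
| treatment kernel a, b | 0.9, 1.0 | same kernel on bipartite indication-graph hop distances |
| thresholds τ (S_bc, S_gc, S_bd, S_gd, S_tc, S_td) | 0.1, 0.01, 0.14, 0.01, 0, 0 | off-diagonal entries strictly below τ are zeroed (entries equal to τ survive) |
| fusion weights | inverse-mean | weight_k ∝ 1/mean_k over off-diagonal entries, so each layer contributes equally on average |
| μ, ξ | 4, 0.67 | fidelity to observations vs to the prior; μ > ξ > 0 so observations outrank the prior |
| tol, max_iter | 1e−6, 1000 | stop when the max-abs update falls below tol |
| degree_floor | 1e−12 | floor for isolated pair-node degrees (see below) |
| k_neighbors | 5 | neighbors used when projecting treatment similarities onto uncovered entities |

## Numerical choices

* **Convergence criterion.** Max-abs change between iterates below `tol`.
  Since one update step equals `−α∇Loss`, a final update below tol bounds
  the gradient norm by `(1+μ)·tol`.
* **Degree flooring.** Aggressive thresholding can isolate a pair node
  (`a_s ≤ 0` after the self-loop subtraction). Degrees are floored at
  `degree_floor` with a logged warning rather than failing; the node then
  simply holds its injected value.
* **Kernel-cosine clipping.** The exponential-decay gene kernel is not
  guaranteed positive semidefinite, so the kernel-cosine can marginally
  exceed 1 on adversarial inputs; values are clipped to [0, 1] to keep the
  similarity-matrix invariants exact. Entities with empty gene profiles
  get similarity 0 to everything (the 0/0 limit resolved conservatively)
  and 1 to themselves.
* **Diagonal convention.** Every similarity matrix has diagonal exactly 1,
  including the exponential kernel (whose literal value at distance 0
  would be `a < 1`): self-similarity is unit by definition.
* **Tie-breaking.** Ranked outputs order by score descending, then by
  (drug id, disease id) lexicographically; the top-percentile retrieval
  uses the same rule.
* **Unreachable distances.** Shortest-path distance +∞ maps to similarity
  0 (`exp(−∞)`), the continuous limit of the kernel.
* **Threshold boundary.** Entries exactly equal to τ survive; only
  strictly smaller entries are cut.

## Design choices where the design was open

* **Treatment-layer projection.** Entities without any known indication
  have no bipartite distances. They are projected into the treatment
  similarity space by k-nearest-neighbor averaging: an uncovered entity's
  row is the reference-similarity-weighted average of the rows of its k=5
  most similar covered entities in the base-layer matrix (pairs of
  uncovered entities use the double-weighted average); covered entries are
  copied unchanged, the result is symmetrized, diagonal 1. This is one
  reasonable realization of "projecting into a unified similarity space";
  the strategy is isolated in `project_to_full` and replaceable.
* **Layer means for weighting** use off-diagonal entries only: the
  diagonal is constant 1 in every layer and carries no information.
  Thresholding is applied before the means are taken, matching the order
  in which the pipeline runs.
* **HGBI mode** keeps the pair-graph self-loops (`W_ss = 1`), sets the
  prior to zero and uses μ = ξ, under which the iteration collapses to
  `f ← αSf + (1−α)y` — the propagation family it reduces to. The
  `SSGCParams` invariant μ > ξ is relaxed to a warning for this mode.
* **Cross-validation recomputes** the treatment layer and the prior from
  training labels only; base and gene layers are fold-invariant because
  they never read the label matrix. Pooled (all folds' scores together)
  and per-fold-averaged AUCs are both reported, since either convention is
  defensible.
* **A confusion matrix at score threshold 0.05** is exposed alongside the
  full ROC sweep (`confusion_at_threshold`), serving users who want a
  single operating point rather than a curve.

## Synthetic benchmark

`synthetic_data.generate` emulates the relational structure of a real
repositioning corpus at desk scale: 60 drugs, 40 diseases and 200 genes
partitioned into 4 latent groups; a stochastic block model gene graph
(within/between edge probability 0.15/0.01); drug and disease gene
profiles sampled preferentially from the own group's genes (0.20/0.02);
96-bit fingerprints sharing group-characteristic bits (0.35 within, 0.15
background); a phenotype matrix with group means 0.35/0.15 and Gaussian
noise (sd 0.15); and treatment positives drawn at rate 0.25 among
group-matched pairs only. The per-layer noise is deliberately graded —
base noisiest, gene intermediate, treatment sharpest — the ordering real
corpora show when probed with the guilt-by-association ratio, and the
regime in which fusing layers is informative. All randomness flows from a
single seed through named child generators, so each stage's draws are
independent of the others and every run is exactly reproducible.

What the generator does **not** emulate: real pharmacology (no chemistry
behind the fingerprints), hub/degree heterogeneity of biological networks,
overlapping or hierarchical disease categories, and the size of real
corpora (1186×449 runs, but is not the default). Passing end-to-end tests
therefore demonstrates that the pipeline recovers planted
block-structured signal through all of its stages — not that it would
reach any particular accuracy on a real corpus.

## Problem sizes and runtime

The default test and acceptance runs use m=60, n=40, l=200 (q = 2400
pairs) with 10 generated corpora, and random operator/solver instances
with m, n ≤ 10 (q ≤ 100) where dense q×q oracles are built. These sizes
were chosen so every dual-route check (implicit operator vs dense algebra,
iteration vs closed form) is exhaustive yet the whole suite runs in
seconds; the implicit operator itself scales to the real-corpus regime
since it only ever touches m×m, n×n and m×n matrices.

## Known limitations

* The projection of treatment similarities onto uncovered entities is a
  stand-in for an under-specified construction; different choices will
  change S_tc/S_td for sparse corpora.
* Scores are comparable within a run but are not calibrated
  probabilities; only their ranking is meaningful.
* With extremely aggressive thresholds, entire rows of S_c/S_d can become
  isolated; the degree floor keeps the solver running but such nodes carry
  no propagated signal.
* The PU evaluation treats unobserved pairs as negatives, so reported
  AUCs underestimate performance to the extent that true-but-unknown
  indications sit among the "negatives".
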