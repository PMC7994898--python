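# Methods

## Model

Each subject is described by up to K modality blocks (defaults mirror a
three-modality dementia cohort: 90 MRI ROI volumes, 90 PET ROI means, 3 CSF
biomarkers); a block is either fully observed or fully absent.  Subjects
are partitioned into groups by exact availability pattern, so every group
m carries a complete matrix `X_m ∈ R^{D_m×N_m}` with samples as columns.
Because groups are modality-complete, the per-group membership indicator
is all ones and the joint objective over groups decouples; each group is
solved independently.

Per group the representation program is

    min_{Z,E}  ||Z||_* + λ||Z||_1 + β tr(Z L Z^T) + γ||E||_1
    s.t.       X = XZ + E,  Z ≥ 0.

The self-expressive constraint `X = XZ + E` writes every subject as a
combination of the other subjects in its group; the nuclear norm promotes
a low-rank `Z` whose block structure follows the (unknown) union of class
subspaces; `E` absorbs entrywise gross errors; the `l1` term and the
nonnegativity sharpen `Z` into a sparse nonnegative affinity.  `L` is the
normalized hyper-Laplacian of a hypergraph over the group's subjects:
hyperedge j is centred on subject j and contains every subject whose
coefficient in j's sparse code exceeds a threshold θ, plus j itself, with
incidence weight |s_{ji}|.  The trace term pulls the representations of
subjects that share hyperedges together — a higher-order smoothness that a
pairwise graph cannot express.

### Sparse-representation hypergraph

Sparse codes solve, per subject i,

    min_s ||x_i − X s||² + sr_beta ||s||_1   s.t.  1ᵀs = 1,  s_i = 0.

The loss is squared Euclidean (making each column problem lasso-like) and
the sum-to-one constraint is on by default.  Rather than the folk
reformulation that appends a penalty row of ones to the design — which we
found numerically ill-conditioned (coordinate descent stalls and the
constraint is satisfied only to ~1e-3) — all N column problems are solved
simultaneously by FISTA with an exact prox of the l1 norm restricted to
the constraint hyperplane: a per-column soft-threshold shift found by
vectorized bisection plus an exact affine correction on the active set.
Row sums then hold to machine precision and the objective matches an
SLSQP oracle to ≤5e-8 on small instances.  With the constraint off the
columns are plain lassos solved by scikit-learn's coordinate descent.

Hyperedge weights are uniform by default (`incidence_sum` available);
θ defaults to 1e-4 on z-scored data; an optional `max_edge_size` caps
hyperedge membership at the largest coefficients (the "number of nearest
neighbours" knob).  Centroid self-membership H(j,j)=1 guarantees every
hyperedge and vertex has positive degree, so

    L = I − D_v^{−1/2} H W D_e^{−1} Hᵀ D_v^{−1/2}

is well defined, symmetric, PSD, with null vector d_v^{1/2}.  A singleton
group receives the 1×1 zero Laplacian.

### Solver

The program is split with an auxiliary `J` carrying the l1 term and the
nonnegativity (`Z = J`), giving the augmented Lagrangian with multipliers
G (reconstruction) and Q (splitting) and penalty μ.  One iteration:

* **Z-step** — linearize the smooth part f(Z) = β tr(Z L Zᵀ) + ⟨G, X−XZ−E⟩
  + ⟨Q, Z−J⟩ + (μ/2)(||X−XZ−E||² + ||Z−J||²) around the iterate and apply
  singular value thresholding:
  `Z ← svt(Z − ∇f(Z)/(ημ), 1/(ημ))` with linearization constant
  `η = σ_max(X)² + 1 + 2β λ_max(L)/μ` (recomputed as μ changes; σ_max and
  λ_max computed once), which majorizes the gradient's Lipschitz constant
  and keeps the SVT step valid.
* **E-step** — `E ← shrink(X − XZ + G/μ, γ/μ)`.
* **J-step** — `J ← max(Z + Q/μ − λ/μ, 0)` (plain shrinkage when
  nonnegativity is off).
* **Multipliers** — `G += μ(X−XZ−E)`, `Q += μ(Z−J)`.
* **Penalty** — μ ← min(μ_max, ρμ).  The adaptive rule uses the original
  linearized-ADM trigger, ρ = ρ₀ when
  `μ·max(√η‖ΔZ‖, ‖ΔJ‖, ‖ΔE‖)/‖X‖_F ≤ ε₂`; when the trigger does not fire
  the default still applies mild growth ρ_idle = 1.1, the geometric
  schedule classical inexact-ALM implementations use.  A strictly literal
  variant of the trigger (`penalty_rule="literal"`) is provided; under the
  hypergraph term its η-scaling keeps μ near μ₀ and the program cannot
  reach tolerance within the iteration cap, which is why it is not the
  default.

Stopping requires both `‖X−XZ−E‖_F/‖X‖_F ≤ ε₁` and
`max(‖ΔZ‖,‖ΔJ‖,‖ΔE‖)_F/‖X‖_F ≤ ε₂`.  The iterate-change test is applied
relative to ‖X‖_F (like the feasibility test); the absolute form would
make the criterion scale-dependent and unattainable at realistic data
norms.  Z initializes at 0 (as do E, J, G, Q) for determinism.  Defaults:
λ=0.05, β=2.0, γ=5.0, μ₀=1e-6, μ_max=1e6, ρ₀=3, ε₁=ε₂=1e-6, max_iter=500.
Hitting the cap returns `converged=False` with the full trace rather than
raising; in small groups (N ≲ 15) the change test has a slow tail even
when the feasibility residual is at 1e-8–1e-16, which is why pipeline
summaries may show unconverged groups with essentially exact
representations.

The representation handed to the classifier is `J` — exactly nonnegative
and sparse; `Z ≈ J` at convergence is kept for diagnostics (the
subspace-clustering checks use Z).

### Classification

Per group, a linear SVM with C=1 (configurable) is trained on the columns
of `J`, labels coded ±1.  Groups containing a single class are skipped
with a warning.  Prediction is transductive by default: for each
applicable ensemble member the group program is re-solved on the member's
training columns plus the test columns (restricted to the member's
modality pattern), the SVM is refit on the training columns of the joint
solution and scores the test columns.  An inductive mode instead
sparse-codes each test subject against the member's training columns.
A member votes only when the subject's available modalities include the
member's full pattern; the label is the sign of the mean vote, exact ties
resolved by the summed real-valued margins, then by the training majority
class (the sign of a zero mean is otherwise undefined).  Subjects no
member can score receive the training-majority label and are flagged with
`n_votes = 0`.  The mean margin over applicable members is the ranking
score used for AUC.

## Synthetic data

The generator draws, per subject i of class c and modality k,

    x_i^{(k)} = U_{c,k} (√f a_i + √(1−f) b_i^{(k)}) + noise + corruption,

with `U_{c,k}` a random orthonormal basis (rank r = 3 by default), shared
latent `a_i`, modality-private latents `b_i^{(k)}` and shared fraction
f (`shared_frac`).  Dense noise is N(0, (noise_sd·scale)²) and, with
probability `corrupt_prob` per entry, ±`corrupt_scale`·scale is added,
where scale is the clean block's empirical standard deviation.  Class
separation is purely subspace-based — distinct bases per class, equal
means — matching the low-rank modelling assumption; a `mean_shift` option
creates easier, linearly separable problems.  Availability patterns are
drawn from a categorical distribution over the 2^K−1 non-empty patterns.

The default configuration mirrors the three-modality cohort layout:
dims (90, 90, 3), class sizes (186, 393, 226), modality-1 availability
1.0 and modality-2/3 availability ≈0.49/0.50 (patterns lacking modality 1
get zero mass, and modality-2/3 membership is drawn independently).
Remaining defaults, chosen once as a moderate regime: rank 3,
shared_frac 0.5, noise_sd 0.05, corrupt_prob 0.01, corrupt_scale 0.25.

What the generator does **not** emulate: real ROI covariance structure,
site/scanner effects, heavier-tailed biological variation, label noise,
or informative missingness (availability is independent of class and
features).  Passing tests therefore demonstrate the pipeline's mechanics
and its advantage under the stated model assumptions, not clinical
performance.

## Evaluation protocol

Seven metrics from the pooled outer-fold confusion counts: ACC, SEN, SPE,
BAC=(SEN+SPE)/2, PPV, NPV and the rank-based AUC (probability a random
positive's score exceeds a random negative's, ties ½).  Nested stratified
CV: outer 10-fold, inner 10-fold grid search on each outer training set
selecting by inner accuracy (the selection criterion is configurable; the
full decade grid 10^-7..10^7 per penalty is available, with a 5-point
logarithmic sub-grid as the default and a single-point "grid" collapsing
to the defaults when search is not wanted).  Baselines: zero imputation,
and KNN imputation that fills a subject's absent block with the mean
block of its k1=5 nearest neighbours (distance on jointly observed
features, per-feature normalized; only donors observing the block
qualify; zero fill as last resort).  Method comparison across datasets
uses the Friedman chi-square computed from mean ranks and the Nemenyi
critical difference CD = q_α √(k(k+1)/(6N)) with the standard q table
embedded for k ≤ 20, α ∈ {0.05, 0.10}.

## Verification experiments and their sizes

All experiment sizes are chosen for single-CPU desk-scale runs:

* **Proximal operators** — 50 random 5×5 instances against a scalar grid
  search (shrinkage) and the Moreau-dual projection (SVT).
* **Plain-program equivalence** — with β=0, λ=0, nonnegativity off, the
  solver's objective on 20×30 rank-3 instances matches the classical
  inexact-ALM solution to better than 1e-3 relative.
* **Subspace recovery** — noiseless union of 3 rank-3 subspaces in R³⁰,
  60 samples; spectral clustering of (|Z|+|Zᵀ|)/2 recovers labels ≥95%.
* **Gross-error recovery** — 30×60 rank-3 data, 5% entries corrupted at
  5× the dense-noise scale; the support of E, detected by the 3σ rule
  (|E| > 3·noise_sd — with dense noise present E legitimately carries the
  noise floor, so a noise-level threshold is the principled detector),
  attains F1 ≥ 0.9.  The experiment runs on the solver's plain low-rank
  path, where the error mechanism is isolated from the representation
  constraints; under the full constrained objective part of the
  corruption is absorbed by the nonnegative sparse representation and F1
  falls to ~0.85–0.91.
* **Comparative cross-validation** — ten simulated two-class cohorts
  (30+30 subjects, dims (20, 20, 3), shared_frac 0.8, subspace-only
  separation, the default 7-pattern missingness), outer 10-fold CV with
  the paper-default penalties as the single grid point and the solver
  capped at 300 iterations inside CV; the pipeline's median accuracy is
  compared against the zero- and KNN-imputation SVM baselines.

## Known limitations

* Transductive prediction re-solves a group program per ensemble member
  and test batch — O(members) solver calls per prediction.
* The iterate-change stopping test converges slowly for very small groups
  (N ≲ 15); feasibility is reached long before.
* Binary tasks only (three-way classification is out of scope); no
  probability calibration.
* Hypergraph construction is O(N²)–O(N³) per group via the all-columns
  sparse-coding solve; groups of a few hundred subjects are comfortable,
  thousands are not.
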