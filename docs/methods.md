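# Methods

## Problem setting

Given `n` drugs, a symmetric binary known-interaction matrix `J`
(`J_ij = 1` iff drugs i and j are known to interact, zero diagonal), and
`m` binary feature matrices `H^i` (`n x n_i`; entry 1 iff a descriptor —
a pathway, an enzyme, a target protein, or a chemical substructure —
applies to the drug), the model predicts (a) unobserved interactions among
the networked drugs and (b) interactions of a drug with descriptors but no
known interactions (cold start). Severity of a predicted interaction is
inferred separately from molecular structure.

## Relation structure (self-representation of the network)

Each row of `J` is a drug's interaction profile. The relation structure
`M` (non-negative, zero diagonal) rebuilds each profile from the others:

    min_{M >= 0, (N o M) e = e}   1/2 ||(N o M) J − J||_F²
                                  + θ_drr/2 ||(N o M) e||₂²

with `N` the off-diagonal mask and `e` the all-ones vector, so
`(N o M) e` is the vector of row sums and the constraint makes the active
rows of `M` stochastic. A constant term `1/2 ||N J − J||²` is reported with
the objective but excluded from convergence ratios.

Fitting uses a multiplicative update derived from the KKT conditions,

    M_ij <- M_ij · (μ eeᵀ(I + JJᵀ) + JJᵀ)_ij
                 / ((N o M)(θ_drr eeᵀ + θ_drr eeᵀ JJᵀ + JJᵀ))_ij ,

followed by exact row rescaling of the active rows to unit sum. The
multiplier μ of the row-sum constraint has no closed-form update; we set
μ = θ_drr and let the rescaling enforce the constraint directly — it
preserves non-negativity and the update's fixed points, and the constraint
(not the multiplier) is what the downstream penalty uses. Because the
rescale step has no monotonicity proof, a halving line search damps any
sweep that would increase the objective toward the previous iterate
(feasible, since both endpoints are row-stochastic); in practice it almost
never triggers. Drugs with no known interactions have nothing to
reconstruct from: their rows are frozen at zero and excluded from the
constraint. Initialization is strictly positive uniform noise (multiplicative
updates cannot leave exact zeros), row-normalized, seeded.

Defaults: `θ_drr = 1e-2`, `tol = 1e-6` (relative change of the non-constant
objective), `max_iter = 200`. After fitting, active row sums equal 1 to
machine precision (the checked tolerance is 1e-3).

## Joint objective

    f(Z, S) = θ Σ_i (||S − H^i Z^i||_F² + ||J − H^i Z^i||_F²)
            + λ Σ_i (tr((Z^i)ᵀ O Z^i) + tr((H^i)ᵀ O H^i))
            + ||S − J||_F²
            + σ ||(I − M) S||_F²,      Z^i >= 0,

with `O` the all-ones matrix, so `tr(Zᵀ O Z)` is the sum of squared column
sums — a group-level sparsity pressure on each drug's projected
representation. The `H` terms are data constants kept for reporting and
excluded from convergence ratios. The features are data: `H` is never
optimized.

Two formulation choices deserve note, both made so that the solver, the
objective and the method's observed behaviour are mutually consistent:

* **Sparsity form.** The column-wise norm penalty and the `tr(Zᵀ O Z)` form
  differ (sum of squared column norms vs. squared column sums); the solver
  algebra uses the latter, and that is what the package implements and
  reports.
* **Relation penalty.** The requirement is that each score row be close to
  its M-reconstruction, `S_i· ≈ Σ_l M_il S_l·`; the faithful quadratic
  penalty is the squared residual `||(I − M) S||_F²`. A product-form
  variant `⟨(I − M)S, MS⟩` is not bounded below, penalizes exactly the
  propagation the relation structure is meant to provide (on the planted
  fixture it inverts the ranking: within-network AUC drops to ~0.22), and
  contradicts the observed improvement of AUPR with σ. The residual form
  is convex, makes the score system positive definite, and recovers the
  planted signal; it is the one implemented.

## Solver

The objective is quadratic in `S`; its stationarity condition gives the
closed form

    ((1 + mθ) I + σ (I − M)ᵀ(I − M)) S = θ Σ_i H^i Z^i + J,

solved as a linear system (SPD; never an explicit inverse). At σ = 0 this
is the plain `(1 + mθ)^{-1}(θ Σ H^i Z^i + J)` resolvent.

For the projections, substituting the closed-form `S*(Z)` gives a reduced
objective `g(Z) = f(Z, S*(Z))`. Because `S*` is stationary in `S`, the
gradient of `g` with respect to `Z^i` is the partial gradient of `f`
evaluated at `S*` (envelope identity), a linear form `C Z^i − B` with

    C = 4θ (H^i)ᵀH^i + 2λ O − 2θ² (H^i)ᵀ Y H^i
    B = 2θ (H^i)ᵀ ((I + Y) J + θ Y Σ_{j≠i} H^j Z^j),

where `Y` is the resolvent of the score system. The update is the standard
sign-split multiplicative rule

    Z^i <- Z^i ⊙ (C⁻ Z^i + B⁺) / (C⁺ Z^i + B⁻),   X± = (|X| ± X)/2,

applied in one sweep over i = 1..m with cross terms recomputed per view;
entries with a vanishing denominator are left unchanged. Non-negativity is
closed under the rule. The mixed-sign block of `C` is the `θ²` term, an
order `θ` fraction of the non-negative blocks at the grid values used
(θ ≤ 0.1), and the exact `S`-solve after every sweep re-anchors the
objective; monotonicity of the alternating rounds is asserted by the test
suite to 1e-8 relative slack rather than assumed.

`fit` alternates one `Z` sweep and one `S` solve per round, records the
constant-free objective, and stops when its relative change drops below
`tol` (default 1e-4, `max_iter` 100). `Z^i` starts from seeded uniform
noise scaled by `1/sqrt(n_i)`. All randomness flows from the single seed in
the hyperparameter block; repeated fits are bitwise identical.

## Hyperparameters

| name | role | default (within-network) | default (cold-start) |
|------|------|--------------------------|----------------------|
| λ | projection sparsity weight | 1e-1 | 1e-3 |
| θ | projection-error weight | 1e-5 | 1e-2 |
| σ | relation-penalty weight | 1e-3 | 0 |
| θ_drr | row-sum weight in relation learning | 1e-2 | — |

The two presets are the best grid points of the published sensitivity
sweep over {1e-5 … 1e-1}; σ is pinned at 0 for cold-start because a drug
outside the network has no rows for the relation structure to reconstruct.
The θ appearing in relation learning plays a different role from the
objective's θ and is exposed as the independent `theta_drr`. The sweep
itself is available as `grid_search` / the `tune` subcommand.

Cold-start scores use the printed normalization `(Σ_i h^i Z^i)/(m + 1)`;
a config switch `goal2_denominator` also accepts the `m` reading. Pair
scores are symmetrized, `(S_ij + S_ji)/2`, since interactions are
unordered; ranking ties break lexicographically on the pair identifiers.

## Evaluation

Two 5-fold protocols: fold over known unordered pairs (removed from both
triangles of the training network; candidates = held-out positives plus all
never-interacting pairs) or fold over drugs (training restricted to the
induced subnetwork and sub-tables; test drugs scored cold-start against
training drugs). Negatives are never sampled, preserving the task's class
imbalance, which is why AUPR is primary. A 66.67/16.67/16.67
train/validation/test drug split is available as a named preset
(`CASE_STUDY_FRACTIONS`).

AUC is the rank statistic (ties count half), AUPR is step-summed average
precision over descending unique thresholds — no linear PR interpolation,
which is known to be optimistic. Both are computed by scikit-learn behind
the module surface and cross-checked in the tests against exhaustive
pairwise-comparison and threshold-sweep oracles. Recall/precision/F1/
accuracy need a decision threshold the protocol leaves open; the default
predicts as many positives as the training prevalence implies, and a
`threshold` override is exposed. Degenerate denominators yield 0 with a
warning.

## Severity

Fingerprints are 2048-bit Morgan (radius 2) hashes computed from SMILES
via RDKit; parsing to a molecular graph first makes different spellings of
the same molecule identical. The family and length of the "hashed
substructure fingerprint" are otherwise unspecified upstream, so published
similarity values for specific drug pairs are not reproduction targets;
what matters is that the choice is explicit and deterministic. The MSSD
similarity is `α·Tanimoto + β·Dice + (1−α−β)·cosine` on the bit sets
(`α = 0.5`, `β = 0.2`); on 0/1 vectors the cosine term equals
`|A∩B|/sqrt(|A||B|)`. It is symmetric and bounded in [0, 1] whenever
α, β ≥ 0 and α + β ≤ 1.

Severity transfer is a similarity-weighted average: for a predicted C–B
pair, the known interactors A of B with `MSSD(C, A) ≥ cutoff` (default 0.5)
contribute their known A–B severity scores weighted by similarity; if none
pass, the single most similar interactor is used and the result flagged
low-confidence. The estimator behind the upstream severity scores is not
specified there; the weighted average implements its stated rationale
(proximity-weighted transfer) and is documented as a heuristic. Scores are
real-valued, clipped to [1, 100], and rounded half-up only for banding:
1–30 MINOR, 31–60 MODERATE, 61–100 MAJOR.

## Synthetic data

The generator emulates DrugBank-shaped inputs with a planted low-rank
mechanism: sparse non-negative latent profiles `U` (Dirichlet rows,
concentration 0.3, rank 10), feature matrices binarized from `U W^i` at a
15% density threshold with independent bit flips at the noise rate, and a
network from the top-density quantile of `U Uᵀ`. Features and network share
the latent structure, so the model has signal to recover, and the noise dial
degrades it monotonically.

Default conditions are the real datasets' magnitudes scaled down so a fit
takes about a second: n = 200 drugs, m = 4 feature spaces with
(120, 100, 150, 300) descriptors, 5% edge density (~1000 interactions), 5%
feature noise. The real exports are an order of magnitude larger (1278–2142
drugs, 90k–216k interaction records, up to 881 substructure descriptors);
the 881-dimensional substructure descriptor list is packaged for working
with wide-form tables at full dimensionality. What the generator does *not*
emulate: real descriptor marginals, degree heterogeneity beyond density,
correlated noise, or false-negative structure in the network — so passing
tests demonstrate correct mechanics and recoverable planted signal, not
performance on real pharmacological data.

## Numerical choices and degenerate inputs

* Score systems are SPD by construction; a condition estimate above 1e12
  still raises with the estimate in the message.
* Multiplicative updates leave entries with zero denominators unchanged
  (isolated drugs, empty views); zero projections stay zero.
* `σ → 0` continuously recovers the unregularized model (tested at
  σ = 1e-12 against σ = 0).
* Self-pairs are rejected in prediction and dropped with a warning on read;
  networks are always symmetrized on read since interactions are unordered.
* Unknown drugs in feature files get zero rows by default (ragged exports);
  a strict mode errors instead.

## Known limitations

* The relation structure is learned from `J` only; no feature-similarity
  graph variant.
* No GPU path, no minibatching; dense linear algebra sized for up to a few
  thousand drugs.
* Severity inference depends entirely on the supplied known-severity table
  and fingerprint family; it is a transfer heuristic, not a trained model.
* Grid tuning refits per grid point; the full 5×5×5 sweep at real-data
  scale is expensive and left to the user's budget.
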