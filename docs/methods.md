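# Methods

## Model

All regressors are kernel ridge regression (KRR) models with the Matérn
kernel of order ν = 3/2 on the Euclidean distance between molecular
descriptors:

    k(X_i, X_j) = exp(−√3 d_ij / σ) (1 + √3 d_ij / σ),   d_ij = ‖X_i − X_j‖₂.

Training solves (K + λI) α = y; prediction is P(X_q) = Σ_i α_i k(X_q, X_i).
σ is a length scale in descriptor units; λ ≥ 0 (default 10⁻¹⁰) controls
overfitting and conditioning.

Given an ordered fidelity hierarchy f = 1..F (cheapest → target), the
multi-fidelity families are:

* **Δ-ML** — KRR on y^(F) − y^(f_b^QC) over molecules labeled at both
  levels; prediction adds the query's computed baseline energy. The
  baseline energy is an *input* to `predict` — performing the QC
  calculation is the caller's responsibility (the synthetic generator
  plays that role in tests).
* **MFML** — a signed combination Σ_s β_s P_s(X_q) of KRR sub-models
  s = (f, η_f), each trained on 2^η_f samples of fidelity f. The
  sub-model set for (F, η_F; f_b) contains one "positive" model per level
  f = f_b..F with η_f = η_F + F − f (so β_s = +1 exactly when
  f + η_f = F + η_F) and one "negative" model per level f = f_b..F−1 with
  η_f one lower (β_s = −1). Adjacent positive/negative pairs telescope:
  with identical labels at all fidelities the whole model collapses
  exactly to plain KRR on 2^(η_F + F − f_b) target samples, which is a
  unit test.
* **o-MFML** — the same sub-models with β refit by minimizing
  Σ_v |y_v − Σ_s β_s P_s(X_v)|^p over a validation set labeled at the
  target fidelity. The norm exponent defaults to p = 2, which makes the
  fit an ordinary least-squares problem with a closed-form global
  optimum — hence the optimized validation error can never exceed the
  fixed-β error, another tested invariant. p = 1 is available through a
  derivative-free minimizer as an extension point.
* **MFΔML** — all labels are centered by the lowest fidelity
  (y^(f) → y^(f) − y^(1)) and an MFML model is built on the centered
  labels, so each sub-model is a Δ-ML model; prediction adds one computed
  fidelity-1 energy per query. Algebraically MFΔML(X_q) ≡
  MFML-on-centered-labels(X_q) + y_q^(1), asserted to 10⁻⁹ in tests.

### Nested training draws

Training sets are *nested*: one seeded shuffle orders the eligible
molecules, and the set at fidelity f is the first 2^(η_F + F − f) entries,
so each more expensive level trains on a prefix of the next cheaper one
and sample counts halve exactly per level up. When top-fidelity labels
are only partially available, molecules are ordered by their highest
labeled fidelity (descending, shuffled within tiers) so the expensive
prefixes are guaranteed to be labeled. Every stochastic operation takes an
explicit integer seed and is bit-reproducible.

## Descriptors

* **Coulomb matrix**: M_ii = 0.5 Z_i^2.4, M_ij = Z_i Z_j / d_ij with d in
  Bohr (1 Å = 1.8897259886 Bohr, the standard convention; configurable),
  zero-padded to `max_atoms` and flattened in full. The sorted variant
  reorders rows/columns by descending row L2 norm (ties: descending Z,
  then original index), restoring atom-index invariance at the price of
  sorting discontinuities.
* **SLATM** (global variant): element counts, then for each element pair a
  Gaussian-smeared (0.05 Å) spectrum of pair distances on a radial
  midpoint grid over (0, 4.8 Å] with step 0.03 Å, each peak weighted by
  the London factor 0.5 Z_a Z_b / r⁶ at the grid point (r in Bohr) and
  scaled by the grid step; then for each element triple (apex in the
  middle) a smeared (0.05 rad) spectrum of triangle angles on an angular
  midpoint grid over [0, π] with step 0.03 rad, weighted by the
  Axilrod–Teller–Muto factor Z_a Z_b Z_c (1 + cos θ cos θ_a cos θ_c) /
  (d_ab d_bc d_ca)³ (distances in Bohr). All three triangle legs must lie
  within the cutoff. Channel order is fixed by the ascending element
  universe with pairs/triples in lexicographic order. Grid resolution is
  not standardized in the literature; the 0.03 steps are this package's
  documented defaults and the oracle tests pin exactly this convention.

Cutoff (4.8 Å) and smear widths (0.05 Å / 0.05 rad) follow the values
commonly prescribed for transferable SLATM models of small organic
molecules.

## Hyperparameters

| parameter | default | meaning |
|---|---|---|
| σ | median pairwise training distance | kernel length scale; `DEFAULT_SIGMA` records grid-searched values (3200 SLATM, 9000 sorted CM, 9500 unsorted CM) from the small-organic-molecule energy task, but these are dataset-specific |
| λ | 10⁻¹⁰ | ridge regularizer |
| p | 2 | o-MFML coefficient norm |
| N_val | 32 | o-MFML validation-set size |
| n_runs | 10 | shuffled training draws averaged per learning-curve point |

A `grid_search_sigma` helper performs the σ grid search on a seeded
holdout split, intended for the target fidelity only.

## Numerical choices

The regularized kernel system is solved by Cholesky factorization with up
to five steps of iterative refinement; the residual must satisfy
‖(K+λI)α − y‖_∞ ≤ 10⁻⁸ max(1, ‖y‖_∞). On factorization failure the
solver falls back to least squares with a warning, and a
`ConditioningError` is raised if the residual bound still cannot be met
(e.g., duplicate descriptor rows with λ = 0 and inconsistent labels).
With λ = 10⁻¹⁰ this bound limits usable training-set sizes on data with
many near-duplicate geometries to a few hundred points per sub-model; the
shipped benchmark sizes respect that envelope.

Degenerate structure f_b = F is permitted everywhere and defined as plain
single-fidelity KRR, which keeps learning-curve sweeps uniform.

## Time-cost ledger

Costs are abstract per-calculation time units supplied by the
`FidelityHierarchy` (real QC timings are hardware-specific). For one
model: KRR pays 2^η_F target calculations; MFML pays the whole nested
structure Σ_f 2^(η_F+F−f) c_f; o-MFML adds N_val target calculations;
Δ-ML pays its training samples at both levels plus one QC-baseline
calculation *per evaluated query*; MFΔML pays the MFML structure (plus
fidelity-1 centering energies for the baseline-level set when f_b > 1)
plus one fidelity-1 calculation per query. Consequently the Δ-variants'
total cost grows linearly with the number of predictions while
KRR/MFML/o-MFML are flat — the crossover that makes MFML the method of
choice for large prediction campaigns, asserted by direct arithmetic in
the tests.

## Synthetic benchmark

The generator emulates the statistical regime the methods assume, not
chemistry:

* **Geometries** — five CHNO templates (methane, water, ammonia,
  formaldehyde, ethane) with per-atom Gaussian jitter (default 0.05 Å,
  clash-rejected below 0.3 Å) and randomly permuted atom order. The
  permutation reflects the absence of a canonical atom order in real
  geometry files and is what makes the unsorted Coulomb matrix measurably
  worse than the index-invariant descriptors.
* **Target surface** — per-element energy terms plus Gaussian pair-distance
  wells of width 0.35 Å with seeded random amplitudes/centers:
  size-extensive, smooth, and rich enough that tens of training samples
  do not saturate it.
* **Fidelity gaps** — y^(f) = y^(F) + Σ_{g=f}^{F−1} Δ_g + ε with each Δ_g
  a *smoother* surface of the same form (well width 1.2 Å plus a
  per-element offset), rescaled so the generated population's mean |Δ_g|
  equals `difference_scales[g−1]` exactly (defaults 25, 10, 4 kcal/mol —
  a systematic decrease toward the target, the regime in which
  multi-fidelity modeling pays off). ε is i.i.d. Gaussian label noise
  (default sd 0.5 kcal/mol) applied to every fidelity below the target.
  The rescaling constant depends on the generated molecule set, which is
  why the mean-gap contract holds by construction rather than only in
  expectation.
* **Costs** — default unit costs (1, 30, 300, 3000), strictly increasing.
* A masking utility drops target-fidelity labels for a chosen fraction of
  molecules to emulate partially labeled datasets.

Deliberate smoothness asymmetry (wide-well gaps vs. narrow-well target)
guarantees learnability of the differences, so the statistical tests
(multi-fidelity benefit over ten seeds, descriptor-quality ordering,
Δ-ML reaching the noise floor) probe the methods rather than the
generator. What the benchmark does **not** emulate: physically meaningful
energies, conformational diversity beyond Gaussian jitter, heavy-atom
counts above eight, systematic (non-smooth) errors of real QC methods,
and correlations between noise and molecular size. Passing tests
therefore demonstrate the correctness and qualitative behavior of the
methods, not their accuracy on real coupled-cluster data.

### Problem sizes used in the shipped experiments

Learning curves in the tests and the acceptance script use 700 molecules,
a 100–128-molecule holdout, ten shuffled runs, and target-fidelity
training sizes up to 2⁹ (single-fidelity) or 2⁵ with the full
multi-fidelity structure (2⁸ at the cheapest level) — sizes chosen to sit
comfortably inside the conditioning envelope of λ = 10⁻¹⁰ on jittered
template data while exercising every code path.

## Known limitations

* Only the global SLATM variant is implemented (no atomic/local SLATM).
* No sparse or low-rank KRR approximations; kernel solves are dense and
  O(N³).
* The o-MFML p = 1 path uses a derivative-free optimizer and is a
  convenience, not a performance path.
* One-dimensional fidelity ladders only (no theory × basis-set grids).
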