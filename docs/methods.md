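# Methods

## Model

The package predicts binary compound–protein interaction (CPI) with a
single support vector machine over pairs. A pair (c, p) is conceptually
the tensor product x = c ⊗ p of a compound descriptor vector and a protein
descriptor vector; because the inner product of tensor products factorizes,
the pair kernel is computed as the product of a compound kernel and a
protein kernel, K(x, x') = K_C(c, c')·K_P(p, p'), and the tensor product is
never formed. Gram matrices are assembled by factorization: the compound
and protein blocks are computed once over the unique ids on each axis and
combined elementwise, which makes screening one target against a large
library cost one protein-kernel column plus one compound-kernel block.
Factorized assembly is verified against naive pairwise evaluation to
1e−12 in the tests.

Kernel assignment follows the descriptor family:

| descriptor | kernel | default parameter |
|---|---|---|
| dense tables (imported physicochemical/string descriptors) | Gaussian exp(−γ‖xi−xj‖²) | γ = 1/n_features, CV-searchable |
| binary circular fingerprints (2048 bits, radius 2) | Tanimoto | — |
| MSA eigen-features | linear | — |

Fingerprints are never standardized; dense imported tables are column-wise
standardized (zero-variance columns dropped) and optionally compressed by
PCA keeping the fewest leading components whose cumulative explained
variance reaches 99% (the projection is retained so held-out entities can
be mapped into the fitted space).

## MSA eigen-descriptor

The protein-side contribution is a descriptor built from a pairwise
sequence-identity matrix S (unit diagonal, symmetric, entries in [0, 1]),
obtained either from a precomputed aligner percent-identity matrix (values
above 1 are interpreted as percent and divided by 100) or from the built-in
pairwise global aligner (identity = identical columns / columns where at
least one sequence has a residue; both-gap columns excluded). S is
eigendecomposed, S = UΛUᵀ; eigenpairs with eigenvalue below 1e−10 × λ_max
are removed (identity matrices of real protein sets occasionally have small
negative eigenvalues because percent-identity is not an inner product), and
the per-protein feature vectors are the columns of

    X = Λ₊^{1/2} U₊ᵀ .

The square root is essential: with it, the linear kernel XᵀX equals the
eigenvalue-truncated matrix, which is exactly S when S is PSD and otherwise
the unique Frobenius-nearest PSD approximation of S. Without the square
root the reconstruction property that motivates the construction would not
hold. The number of feature dimensions is at most the number of proteins.
Orphan targets keep their column in S: sequence similarity is knowledge
about the protein, not about its ligands, so computing protein features
over all proteins (including an orphan) leaks no interaction information.

## Training and calibration

Activity records carry potency in μM and/or an explicit label; potency
≤ 1 μM is labeled positive and ≥ 3 μM negative, the open (1, 3) gap is
marked unlabeled and excluded from training. Duplicated (compound, protein)
measurements keep the most potent value (minimum μM); pairs with
conflicting explicit labels and no potency to arbitrate are dropped with a
warning. Agonist/antagonist mode is not modeled.

The SVM dual problem on the precomputed Gram matrix is solved by
scikit-learn's SVC; the package owns kernel construction, cross-validation
orchestration, calibration and scoring. The regularization constant C is
selected from a grid (default {0.1, 1, 10, 100}) by maximizing mean
accuracy over stratified 5-fold cross-validation, ties broken toward
smaller C (stronger regularization). Training records are canonically
sorted before fitting, so results are invariant to input record order
(checked to 1e−9).

Decision values are mapped to probabilities by a Platt sigmoid
P = 1/(1 + exp(a·s + b)) fitted by penalized maximum likelihood on
*out-of-fold* decision values from 3 internal stratified folds, so the
calibrator never sees scores produced by a model trained on the same
records. A fitted slope a ≥ 0 (probability not increasing with the
decision score) is rejected as a degenerate fit. The calibration is
strictly monotone, so rankings — and hence EF and AUROC — are identical
whether computed on decision values or probabilities.

## Evaluation protocols

A *virtual orphan* is made by deleting every interaction record of one
target from training while keeping the target's sequence. The screening
library is the full compound table; truth labels follow the
treat-missing-as-inactive rule: a compound is active only if a positive
record exists for (compound, target), and everything else — negative,
absent, or gap-potency — counts as inactive. Gap-potency compounds are
flagged in the output and can be excluded via `gap_policy="exclude"`.

The *half-sampled* control keeps a random half of the target's records in
training (stratified by label; floor(n/2) of each stratum to train, the
remainder held out) and omits train-side compounds from the test library.

Metrics: the enrichment factor at fraction f (default 1%) with
N_subset = floor(f·N_total), minimum 1 — so a 280,648-compound screen at 1%
selects 2,806 compounds — and AUROC computed by threshold sweep with
trapezoidal integration, which equals the Mann–Whitney pair statistic with
half credit for ties (verified exactly against brute-force pair counting).
EF is 1 in expectation under random ranking and at most
min(1/f, N_total/A_total).

## Applicability index

Orphan screening succeeds when related targets contribute ligand knowledge.
The index aggregates this as A(p_i) = Σ_{j≠i} w(K_P(p_i, p_j))·N_j, where
N_j is neighbor j's active-ligand count and w is the sigmoid
1/(1 + exp(−α(x − r))). The target's own count is excluded: for a true
orphan it is zero by definition, and including it for benchmark targets
would leak the answer. log A uses the natural log, fixed rather than
configurable so thresholds stay comparable across runs.

(α, r) are fitted to maximize Spearman's correlation between log A and
observed orphan AUROC across benchmark targets. The objective is piecewise
constant (it depends only on ranks), so the optimizer is a deterministic
coarse 25×25 grid (α geometric on [0.1, 200], r linear on [0, 1]) followed
by three zoomed grid refinements around the incumbent; by construction the
result is never below the best coarse-grid value and is reproducible under
a fixed seed. On the planted benchmark the fit lands within 0.02 of a dense
200×200 grid oracle. The log A decision threshold is then chosen to
maximize the accuracy of predicting which targets exceed the AUROC cutoff
(default 0.8), scanning midpoints between sorted distinct log A values plus
one candidate beyond each end, ties broken toward the larger threshold
(fewer predicted positives). Prediction quality is reported as confusion
counts, PPV, accuracy and a two-sided Fisher exact p-value (conditional
hypergeometric convention).

## Synthetic benchmarks

`generate_protein_family` realizes a block identity design by mutation from
shared ancestors: members mutate from a family ancestor at rate
1 − √q_in and family ancestors from a common root at rate
1 − √(q_out/q_in), so expected pairwise identities multiply out to the
intra/inter design values; the realized matrix (recomputed from the
sequences) matches the design within about ±0.05 at the default sequence
length of 300.

`generate_cpi_dataset` plants a motif rule: each family reserves a disjoint
block of fingerprint bits; each member reuses each family-motif bit with
probability `sharing_rate` (a private bit otherwise); a target's actives
are sparse background vectors (density 0.05) with the target's motif bits
all set, inactives are background only, and actives of one member are
cross-recorded on related members with probability sharing_rate × identity
(shared ligands carry both motifs). At noise 0 a nearest-motif rule is
exact by construction; `noise_rate` flips labels. Compounds carry a
placeholder SMILES ("C") — the planted chemistry lives entirely in the
generated bit vectors, which feed the Tanimoto kernel through the same
imported-descriptor path real fingerprints would use.

Default study conditions: 6 targets in two families of 3, intra-family
identity 0.8, inter-family 0.3, 100 actives and 100 inactives per target,
2,000 compounds, sharing 0.8, noise 0. These sizes exercise the full
pipeline (orphan EF1% ≈ 5–10 for family members versus ≈ 0–1 for the
sharing-0 control) while a complete end-to-end evaluation stays under a
minute per target on one CPU. The applicability benchmark simulates AUROC
as a strictly monotone squashing of the standardized planted log A
(0.5 + 0.5·sigmoid(2z)) plus Gaussian noise, clipped to [0.5, 1]; 50
targets at noise 0.05 are the default fitting conditions.

What the generators deliberately do not emulate: real chemistry (no
meaningful structures behind the planted fingerprints), realistic potency
distributions, assay heterogeneity, or the scale of public bioactivity
extractions. Passing tests therefore demonstrate the correctness of the
machinery and the qualitative family-transfer behavior, not performance
levels on real screening corpora.

## Numerical choices and edge cases

- Eigenvalue drop tolerance 1e−10 relative to the largest eigenvalue;
  symmetry tolerance 1e−8 and unit-diagonal tolerance 1e−6 on identity
  matrices.
- Tanimoto of two all-zero vectors is 0 with a warning (no shared
  structure evidence), not an error mid-training.
- A(p) = 0 yields a −inf log A sentinel with a warning rather than an
  exception.
- Screening ties are broken by compound id ascending — deterministic and
  unbiased with respect to activity.
- Matrix CSVs are written with `repr` floats so write/read round-trips are
  exact.
- Potency is treated as an opaque μM value; no distinction between
  IC50/EC50/Ki measurement types is attempted.

## Known limitations

- The built-in pairwise aligner uses simple match/mismatch/gap scoring;
  for production use, import a percent-identity matrix from a dedicated
  MSA tool instead.
- One global CPI model per training set; no per-target or multi-task
  variants, and no class weighting by default (a future config switch).
- Proprietary or service-computed descriptor sets enter only as imported
  matrices; the package does not reimplement them.
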