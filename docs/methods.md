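# Methods

## Problem setting

A missense substitution in a structurally resolved protein–protein complex
changes the binding free energy of the interaction by

    ΔΔG = ΔG_mut − ΔG_wt,        ΔG = R·T·ln(K_d)

with R = 1.9872 × 10⁻³ kcal·mol⁻¹·K⁻¹ and K_d the equilibrium dissociation
constant in mol/L. More negative ΔG means tighter binding, so positive ΔΔG
destabilizes the interaction. Mutations are discretized into three
interaction-effect classes by thresholding ΔΔG:

* **beneficial** — ΔΔG < lower threshold (binding significantly strengthened);
* **neutral** — lower ≤ ΔΔG ≤ upper (no significant change; the neutral band
  is treated as a closed interval so that "no significant change" is
  inclusive at the boundaries);
* **detrimental** — ΔΔG > upper threshold (interaction disrupted).

The default band is ±0.5 kcal/mol, the community-standard choice for
calling interface hot spots; ±2.0 kcal/mol is the conservative alternative.
The 3-class labels induce two binary problems: *strengthening vs weakening*
(beneficial vs detrimental, neutral excluded) and *preserving vs
disruptive* (beneficial ∪ neutral vs detrimental). When a record carries no
temperature, the standard state 298 K is assumed. Deduplication treats the
same substitution in the same complex reported by different references as
redundant and keeps the first occurrence in file order. Entries describing
more than one simultaneous substitution are rejected at parse time (single
substitutions are the scope of the method). For every labeled mutation the
18 remaining substitutions at the same site (20 amino acids minus the
wild-type and characterized mutant residues) form the unlabeled complement
used by the semi-supervised learners.

## Feature representation

Each mutation is a 33-dimensional vector of wild-type-minus-mutant term
differences: 22 empirical force-field energy terms, three
orientation-dependent statistical-potential terms, the accessible surface
area of the mutated residue, the inter-chain interaction energy of the
mutated chain, three all-atom statistical-potential terms, a geometric
interface score, and two distance-dependent potential scores. The external
programs that produce the raw terms are represented only by an adapter
contract (a per-state term table with a failure sentinel); this package
differences, validates and consumes the tables but does not model
structures. The differencing orientation (wild type minus mutant) is a
package convention recorded in the file header; classifiers are
orientation-agnostic as long as the orientation is consistent, and an
antisymmetry test guards against mixing. Examples with any failed term are
dropped with a logged count.

## Learners

* **Random forest** — 100 trees, √33 candidate features per split, no depth
  limit, mandatory seed. Class scores are the forest's vote fractions
  (trees are grown to purity, so averaged tree probabilities coincide with
  vote fractions).
* **SVM** — per-feature standardization fitted on training rows, then a
  C-SVM with linear, polynomial (degree 3 by default) or RBF kernel.
  Scores are a deterministic squashing of decision values: logistic for
  binary problems, softmax over one-vs-rest margins for the 3-class
  problem. No internal cross-validated calibration is used, keeping
  training fully deterministic.
* **Self-learning forest (rf_sl)** — exactly one pseudo-labeling round: fit
  the supervised forest, assign a class to *every* unlabeled row (no
  confidence filter), merge at equal weight, refit. With an empty unlabeled
  pool the procedure is identical to the supervised forest under the same
  seed, which is asserted prediction-for-prediction in the tests.
* **Low-density separation (lds)** — a symmetrized k-nearest-neighbor graph
  over labeled ∪ unlabeled points carries the soft path metric

      d_ρ(i,j) = (1/ρ)·ln(1 + min_paths Σ_edges (e^{ρ‖e‖} − 1)),

  which interpolates between Euclidean shortest-path distance (ρ→0) and
  the bottleneck-edge path length (ρ→∞) and inflates across low-density
  gaps. Because the per-edge transform is positive and additive, the inner
  minimum is computed exactly by Dijkstra on transformed weights. The
  squared distance matrix is double-centered (classical scaling) and the
  negative eigenvalues of the resulting Gram matrix are clipped to zero —
  connectivity kernels are not positive semidefinite in general, and the
  clipped spectrum guarantees a valid kernel. A linear-kernel SVM on the
  labeled block of the spectral embedding is equivalent to a precomputed-
  kernel SVM on the corrected kernel and is what the implementation fits.
  Predictions for points inside the training graph reuse their stored
  embedding (transductive path); new points are grafted onto the graph via
  their k nearest nodes, a single-source Dijkstra gives their ρ-path
  distances, and a Nyström projection places them in the embedding. If the
  graph is disconnected at the configured k, k is raised to the smallest
  value restoring connectivity and the change is logged. The full
  transductive-SVM gradient descent of the original low-density-separation
  scheme is intentionally out of scope; the connectivity-kernel stage is
  the part retained.
* **Stacked 3-class forest (rf_sl_2f)** — the 33 features are augmented
  with the two binary classifiers' *scaled prediction values*: the
  positive-class score when the prediction is positive, one minus the
  predicted class's score otherwise, so larger values always favor the
  positive class. The self-learning forest is then trained on the 35-wide
  table. Prediction recomputes the two augmentation features from the
  embedded binary models, so callers supply only the 33 base features.

Ties in the per-class score vector resolve to the first class in the
problem's declared class order; scores are non-negative and sum to one.

## Evaluation

Per-class recall, precision and f-measure come from the leave-one-out
confusion matrix. Aggregates are the class-size-weighted f-measure
f_W = Σ N_i f_i / Σ N_i and the average accuracy Acc = Σ NC_i / Σ N_i
(identically trace/total, an identity asserted by a property test). The
Matthews correlation coefficient uses the multi-category covariance
generalization, which reduces to the standard 2×2 formula for binary
problems; degenerate denominators yield 0 by convention. Rank agreement
between predicted preserving-class scores and measured ΔΔG uses the
Pearson coefficient and tie-corrected Kendall τ-b. Metrics are stored at
full precision; comparisons against two-decimal published values round
half away from zero.

LOO details: the unlabeled pool is fixed across folds; pseudo-labeling is
re-run in every fold. For the stacked learner the two binary
feature-generating models are refit *inside* each fold without the held-out
example — the honest nested protocol — with an explicit
`stacking_leaky` switch that instead fits them once on all labeled data
(faster, risks optimistic estimates; off by default).

## Synthetic data generator

The generator defines the package's study conditions. Mutations are
grouped into complexes (3–7 per complex by default); class draws follow
the 208/670/1076 proportions of the reference compendium
(≈ 0.106/0.343/0.551); each mutation's latent ΔΔG is drawn from its class
component — Gaussians at −1.5, 0.0 and +2.0 kcal/mol with spreads 0.4, 0.2
and 1.0 — truncated to the class's threshold interval, so labels re-derive
exactly from the latent ΔΔG with no boundary leakage. Features:

* **linear regime** — each of the `n_informative_features` (default 8)
  planted features equals loading·ΔΔG plus Gaussian noise (`noise_sd`,
  default 1.0), with loadings scaled by `separability`; the remaining
  features are unit Gaussian noise. This is the regime for forest and
  information-gain tests.
* **cluster regime** — planted features get class-specific Gaussian
  centroids whose per-dimension offsets scale with `separability`, giving
  dense clusters separated by low-density gaps; used for the
  graph-based learner. Because downstream standardization equalizes
  per-feature variance, graph tests use many informative dimensions
  (cluster structure spread over a few of 33 dimensions does not survive
  standardization — a property of high-dimensional noise, not a defect).

An unlabeled pool (twice the labeled size by default) is drawn by the same
process with labels withheld; the truth sidecar is never visible to
learners. Optional per-complex random intercepts (off by default) can
emulate complex-level correlation. What the generator does **not** emulate:
the marginal distributions and inter-term covariances of real
force-field/potential outputs, shared-complex feature correlation (by
default), or measurement noise in affinities. Passing tests therefore
demonstrate that the algorithms recover planted structure under controlled
conditions, not field performance on real mutagenesis data.

## Fixed study conditions used in tests and the acceptance script

Chosen once as realistic desk-scale analogues and not tuned afterwards:

* supervised-forest recovery: 400 training / 100 held-out rows at
  separability 3 (strong signal);
* chance-level control: separability 0, compared to the majority-class rate;
* pseudo-label agreement: separability 3, unlabeled pool 2× labeled;
* stacking comparison: separability 0.6 with the imbalanced default
  proportions — the regime where beneficial-class recall of the plain
  self-learning forest sits near 0.2–0.3, matching the difficulty regime in
  which stacking was reported to help — averaged over 10 seeds;
* information-gain recovery: 8 planted features among 33, 400 rows,
  separability 3.

Problem sizes were selected so the full suite and the acceptance script
each run in a few minutes on a single CPU.

## Numerical choices and degenerate inputs

* ρ-path distances use `expm1`/`log1p` to stay accurate at small ρ; the
  returned matrix is exactly symmetrized.
* Triangle inequality is *not* asserted for d_ρ (it holds only in the ρ→0
  limit); symmetry, non-negativity and the two limits are.
* Spectral clipping keeps eigenvalues above max(1e−10, 1e−12·λ_max).
* Constant feature columns are tolerated everywhere (standardization maps
  them to zero).
* Zero-variance inputs to correlation metrics raise errors rather than
  returning NaN; all-tied rankings likewise.
* Empty labeled sets are errors for every trainer; an empty *unlabeled*
  set is a documented degenerate case, not an error.
* Model files embed a format version and refuse to load mismatches.

## Known limitations

* No adapters for structure-modeling or energy programs are included; real
  feature tables must be produced externally in the documented TSV dialect.
* The LDS classifier omits the transductive-SVM objective optimization; on
  data without cluster structure it degrades gracefully but is not expected
  to match the forest-based learners (consistent with the published
  comparison, where it trailed the forests).
* Published headline values on the real compendium (weighted f-measures
  0.87/0.78/0.70–0.75) are not reproducible here because they require the
  external database and proprietary term producers; the package instead
  verifies the metric formulas on the published per-class values and the
  algorithmic properties on synthetic data.
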