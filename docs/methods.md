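# Methods

## Problem and model

Known lncRNA–disease associations form a sparse bipartite graph, encoded as
a Boolean matrix **LD** (nl lncRNAs × nd diseases). The prediction task is
to score every unobserved (lncRNA, disease) pair by its plausibility of
being a true association. The method rests on the premise that lncRNAs with
similar functions tend to associate with similar diseases, so it first
turns the Boolean graph into a weighted heterogeneous network through four
similarity layers, then counts walks in that network, and finally refines
the walk scores geometrically.

### Similarity layers

**Disease semantic similarity (DD).** Each disease owns a DAG: itself plus
its ancestor closure in a disease ontology. The contribution of ancestor
*t* to disease *i* is `D_i(i) = 1` and, for strict ancestors,
`D_i(t) = max over children t' of t (within the closure) of Δ · D_i(t')`,
computed by one reverse-topological pass (the owner is the unique sink of
its closure, so children are always finished first). Pairwise similarity is

    dd_ij = Σ_{t ∈ T_i ∩ T_j} (D_i(t) + D_j(t)) / (Σ_t D_i(t) + Σ_t D_j(t)).

Δ (`decay`, dimensionless, default 0.5) controls how fast ancestry loses
weight per generation; 0.5 is the conventional choice in the disease-DAG
similarity literature and halves a contribution per ancestor step.

**lncRNA functional similarity (LL).** Best-match average: each disease
associated with one lncRNA is matched to its most similar disease (under
DD) in the other lncRNA's set, and matched similarities are averaged over
both set sizes. An lncRNA with no associations has no defined disease set;
its off-diagonal functional similarity is set to 0 (avoiding 0/0) and every
diagonal is forced to 1.

**Gaussian interaction profile (GIP) kernels.**
`exp(-γ ‖profile_i − profile_j‖²)` on rows (lncRNAs) or columns (diseases)
of LD, with bandwidth γ the reciprocal of the mean squared profile norm.
GIP is defined for any entity with a profile, which is what makes it a
usable fallback wherever ontology or association evidence is missing.

**Integration.** `DD_f = DD where nonzero, else DD_gip`, and likewise for
`LL_f`. The zero test is exact equality: semantic and functional zeros are
structural (no shared ancestry, no associated diseases), not numerical
noise. Diseases absent from the ontology get an all-zero semantic row and
column — diagonal included — so integration falls back to GIP everywhere
for them, and the integrated diagonal returns to 1 through the GIP branch.

### KATZ stage

The integrated similarities and LD form the symmetric adjacency

    A = [[LL_f, LD], [LD^T, DD_f]]    ((nl+nd) × (nl+nd)).

The KATZ score of a node pair sums all connecting walks, a walk of length w
weighted by β^w; for β·λ_max(A) < 1 the sum converges to
`S = (I − βA)^{-1} − I`. We parameterise β = K / λ_max(A) with K ∈ (0, 1)
(default 0.1, the optimum found by the LOOCV sweep on both the original
study's data and the synthetic benchmark here). Numerical choices:

* λ_max is computed on the symmetrised (A + Aᵀ)/2 by `scipy.linalg.eigvalsh`;
  because A is nonnegative, its Perron eigenvalue dominates the spectrum in
  magnitude, so the eigenvalue bound and the spectral-norm bound on β
  coincide — this is asserted at run time (tolerance 1e-8 relative).
* S is obtained by solving `(I − βA) X = βA` rather than inverting and
  subtracting I: one factorization, the same result in exact arithmetic.
* Everything is dense; the sizes this method targets (≈ 10²–10³ nodes)
  never justify a sparse path.

The lncRNA-by-disease block of S (rows 0..nl−1, columns nl..nl+nd−1) is
the primary score matrix `LD_p`. The truncated finite-length walk sum is
deliberately not a user-facing mode; it exists in the test suite as the
brute-force oracle against which the closed form is checked.

### Space projection refinement

    lncRNA space:  pl_ij = LL_f(i,:) · LD_p(:,j) / ‖LD_p(:,j)‖
    disease space: pd_ji = DD_f(j,:) · LD_p(i,:) / ‖LD_p(i,:)‖
    final:         LD_final = (pl + pd^T) / 2

Both projections are invariant to positive rescaling of LD_p (numerator and
denominator scale together). Any zero normalising vector yields zeros for
the affected entries rather than NaN; this arises routinely in SP-variant
runs on sparse matrices and in cold-start protocols. No intermediate score
matrix is ever thresholded or re-binarised.

### Variants

* `KATZSP` (default): KATZ, then projection refinement.
* `KATZ`: primary block only.
* `SP`: projection applied directly to the Boolean LD — with no KATZ stage
  there is no other score matrix to project onto.
* `SPKATZ`: the SP score matrix replaces LD in the off-diagonal blocks of
  A, then one KATZ pass. The composition of the two order-reversed hybrids
  is not pinned down by their names alone; these two wirings are this
  package's explicit reading (projection-first must feed its output into
  the only LD-shaped slot the KATZ stage has).

## Evaluation protocol

**LOOCV.** Each known association is masked in turn; association-dependent
similarities (GIP, functional) are recomputed from the masked matrix while
the semantic layer — which never sees LD — is cached across folds; the
variant is rerun; the masked pair's score is ranked against all never-known
pairs (pairs that are 0 in the *full* matrix, the standard negative pool in
this model family). The pooled AUC is the candidate-count-weighted mean of
per-fold normalised ranks, and the reported ROC curve is the step curve of
those per-fold exceedance fractions, so its trapezoidal area equals the
pooled AUC by construction. Per-fold ranks (global and within-column) are
emitted so any alternative pooling can be recomputed.

Setting `refold_similarities=False` computes all similarities once from the
full matrix. This is optimistic — the test pair leaks into the similarity
layers — and is intended for exploratory runs and for reproducing protocols
that distribute precomputed similarity matrices alongside the associations.

**Cold start.** `novel_entity_cv` zeroes an entity's entire row (new
lncRNA) or column (isolated disease), reruns the pipeline, and ranks the
removed associations against the entity's never-known pairs. With full
refolding the two sides behave very differently, and the package's own
benchmark quantifies this (see Limitations).

**ROC/AUC.** `roc_auc` sweeps thresholds over the union of observed scores;
ties contribute half credit, so the trapezoidal area equals the
rank-based (Mann–Whitney) estimate. The implementation is independent of
scikit-learn, which serves as a cross-check in the test suite only.

**Rankings.** Candidate lists per disease exclude known associates, sort by
descending score with lexicographic id tie-breaks (determinism for
regression tests), and report 1-based ranks.

## Synthetic benchmark

The generator encodes the method's premise as a planted block model:
lncRNAs and diseases are partitioned into aligned blocks; within-block
pairs link with probability `within_block_density` (default 0.5),
cross-block with `background_density` (default 0.005). The ontology mirrors
the blocks: a global root disease, per-block subtrees (branching factor 3,
depth capped at 3) so same-block diseases share deep ancestors while
different blocks share only the root, plus sparse extra shallow-to-deep
edges so the graph is a proper multi-path DAG. Defaults are 40 lncRNAs ×
50 diseases with 4 blocks — large enough that block recovery is
non-trivial, small enough that a full LOOCV takes seconds on one CPU.
`SyntheticConfig.curated_2013_scale()` reproduces the dimensions and
density (156 × 190, ≈ 352 links) of the smallest public lncRNA–disease
collection for scale tests. Setting the two densities equal yields a
signal-free null benchmark used for calibration; the config validates
`background ≤ within` (equality = null) rather than strict inequality for
exactly this reason.

Randomness: one root seed spawns independent substreams per stage
(`numpy.random.SeedSequence`), so the ontology and the association draw can
be regenerated independently; the structure (not the bitstream) is what a
port in another language should match.

What the generator does *not* emulate: real degree heterogeneity (hub
diseases with dozens of associations), overlapping or nested disease
categories, curation biases, and name-space noise. Passing recovery tests
therefore demonstrates that the pipeline extracts planted block signal
through every stage — not that it attains any particular AUC on curated
databases.

## Known limitations

* **New-lncRNA cold start needs external similarity.** When a lncRNA's row
  is removed *and* similarities are refolded, nothing in the data
  identifies that lncRNA's block: its functional similarity collapses to
  the GIP of an empty profile, which carries only degree information.
  Worse, the removal leaves the lncRNA's block with one fewer active
  member, slightly depressing the connectivity of exactly the diseases it
  was linked to, so measured cold-start AUC on the symmetric benchmark sits
  below 0.5 (≈ 0.41–0.47 across seeds) — an anti-signal, not noise. Under
  the fixed-similarity protocol the same benchmark gives ≈ 0.91. The
  isolated-disease side does not suffer from this: the ontology survives
  column removal, and refolded isolated-disease AUC is ≈ 0.90. Genuinely
  honest new-lncRNA prediction requires an association-independent lncRNA
  similarity (sequence- or expression-based), which is out of scope here.
* The null-calibration band (AUC within 3 standard errors of 0.5) treats
  per-fold ranks as independent; folds share one network draw, so the
  nominal standard error is approximate.
* The prediction scores favour well-connected entities (more walks); no
  degree correction is applied, matching the original formulation.
* MAT-container variable discovery is heuristic (shape- and
  binarity-based) with an explicit override map, because deposited
  containers do not standardise variable names.
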