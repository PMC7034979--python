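# Methods

## The model

`txstate` interprets a catalog of bulk RNA-seq profiles measured from
genetically defined cell populations. The central assumption is that each
gene is, in any given cell type, either *on* or *off*, and that its relative
transcript abundance (TPM) is log-normally distributed around a
state-specific level. For a gene `g` observed across samples `s`:

    log E_gs | z = N(mu_gz, sigma_g),   z in {off, on}

The two components share one standard deviation `sigma_g`. This is a
deliberate restriction: with a shared spread, the posterior probability of
the on state is monotone in abundance. If each component had its own spread,
the wider component would dominate at *both* extremes of abundance and a
very high observation could be assigned to the "off" state.

Given component parameters and a mixing weight `pi_g`, the posterior
probability that a unit (sample, driver, or cell type) expresses the gene is

    P(z = on) = pi * prod_s p(E_gs | on) /
                [ pi * prod_s p(E_gs | on) + (1 - pi) * prod_s p(E_gs | off) ]

where the product runs over the unit's replicate samples — replicates are
treated as independent probes of one underlying state, so their likelihoods
multiply. A cell type pools all samples of all its drivers.

### Priors and sampling

Both component means carry the same weak prior, Normal(7, 5) on natural-log
TPM, with an ordering constraint `mu_off <= mu_on`. Priors the model also
needs but that are a free choice here: `sigma ~ Half-Normal(3)` (weak on the
log-abundance scale) and `pi ~ Uniform(0, 1)`.

The posterior is sampled by a Gibbs sampler vectorized across genes:

* latent state indicators, component means and the mixing weight have
  conjugate full conditionals;
* the shared sigma takes a few Metropolis steps on `log sigma` per sweep
  (proposal sd 0.3, two sub-steps);
* the ordering constraint is imposed by relabeling draws. Because the two
  means share one prior and the Beta(1,1) prior on `pi` is symmetric, the
  unconstrained posterior is exchangeable under label swap, so sorting the
  means (and flipping `pi` and the indicators with them) yields the
  ordered-model posterior exactly, not approximately.

Defaults are 4 chains x 500 iterations, first half warmup, thinned to at
most 500 draws for predictive evaluation. Split-Rhat above 1.05 is flagged
per gene, never fatal. Genes whose observations are all identical are
flagged degenerate under the bimodal model. Sigma draws are floored at 1e-3
to keep likelihood ratios finite on degenerate data. Zeros are floored at
0.01 TPM before taking logs so off-state observations remain finite; the
floor is configurable and sits far below any biologically meaningful
abundance.

The held-out log predictive densities produced by this sampler were checked
against dense numerical quadrature of the posterior predictive (a 2-D grid
for the single-normal model; a 4-D grid with the ordering constraint for the
mixture): agreement is within ~0.02 nats per point at the default settings.

### Model selection

Some genes never switch state within a catalog — housekeeping genes are on
everywhere, silent genes off everywhere — and fitting them with a forced
two-component mixture would hallucinate states. Each gene is therefore also
fit with a single log-normal, and the two models are compared by 10-fold
cross-validated expected log pointwise predictive density (elpd):

* One sample-level fold partition is drawn per run and shared by all genes,
  so elpds are comparable across genes and each training fit is reused for
  every gene. Samples of the same driver are spread over distinct folds
  (a driver's sole sample is never held out), so every training set retains
  at least one replicate per driver.
* Per fold, both models are refit on the training samples; each held-out
  point contributes `log(1/S * sum_s p(y_i | theta_s))` over the posterior
  draws. The per-fold sums are added to give the model's elpd.
* The bimodal model is chosen only when
  `delta = elpd_bim - elpd_uni > 2 * se(delta)` with
  `se = sqrt(K * Var_fold(delta_k))` over the K = 10 fold-level differences.
  The pointwise variant of the standard error (variance over held-out points
  scaled by their number) was also implemented and compared; decisions agree
  for >99% of genes on large synthetic catalogs, so the fold-level form was
  kept.

This rule deliberately prefers the simpler model on ties. A consequence
worth knowing: at small catalog sizes (tens of samples) and component
separations near 3 sigma, the *true* predictive advantage of the mixture is
only a few hundredths of a nat per observation, so `delta` often fails to
clear `2 * se` even for genuinely bimodal genes. The calibration experiment
in `scripts/acceptance.py` quantifies this conservatism; it fades as
catalogs grow (the productive regime is a few hundred samples).

### Unimodal genes and global components

A gene selected unimodal still needs an on/off call. Confidently bimodal
genes (`delta > 10`) donate their datapoints: sample-level points with
`P(on) > 0.9` form a pooled "on" normal distribution, points with
`P(on) < 0.1` a pooled "off" distribution, and the fraction of on points
becomes a global mixing weight. A unimodal gene's posterior-mean level is
scored against these two densities, and the resulting single probability is
broadcast to every unit for that gene.

### Dummy samples

Dissected mixed-tissue samples are excluded from fitting (their cellular
heterogeneity would produce intermediate abundances that violate the binary
assumption), but they carry dynamic-range information. Each gene's fit is
therefore augmented with exactly two pseudo-observations: the minimum and
the maximum observed level across catalog *and* dissected samples. Dummies
participate in every training likelihood, are never held out in
cross-validation, and never appear in reported probabilities. After fitting,
dissected samples are scored post hoc against the fitted parameters, which
is how markers for unprofiled cells are found (genes on in every dissected
sample and off in every catalog cell type).

## Discretization, concordance, markers

Probabilities discretize at `P >= 0.8` (on) and `P <= 0.2` (off), ambiguous
between. Replicate concordance is, per driver, the fraction of genes whose
state labels agree across all replicates, with all three labels counted as
distinct (the strictest reading). Benchmark concordance counts matches over
matches + mismatches; pairs with ambiguous model calls are excluded from the
denominator and reported separately, as are pairs missing from the matrix.

Group markers require `P >= 0.9` in every group cell, at most two outside
cells reaching the same 0.9 cut (the threshold for "outside" counting is not
fixed by convention; using the same cut keeps the rule symmetric), and a
higher mean abundance in every group cell than in any outside cell (mean
TPM per cell type across its samples).

Expression breadth is the count of cells calling a gene on; grouped
summaries only include gene groups with at least 10 members present in the
matrix.

## Expression trees

Cell types are encoded as character sequences over {A, C, N} — one position
per informative gene (bimodal, on-mean >= 3 log-units ~ 21 TPM, separation
>= 1.5 log-units ~ 4.5-fold; boundaries inclusive). The encoding thresholds
are unified with the discretization cuts (inclusive 0.8/0.2). Distances are
mismatch proportions over positions where both sequences are unambiguous
(pairwise deletion); a pair with no comparable position is NaN and tree
building refuses the matrix with a hard error.

Trees minimize the balanced tree length (Pauplin's formula:
`L = sum_{i<j} 2^(1 - t_ij) D_ij` with `t_ij` the topological distance).
Construction is greedy taxon insertion — each new taxon goes on the edge
minimizing the balanced length, with ties broken by the lowest edge index —
followed by best-improvement NNI and SPR hill climbing. Hill climbing from
one start can stall in local optima on noisy matrices, so the greedy phase
restarts from rotated insertion orders (one per taxon, capped at 8) and the
shortest tree wins; with that schedule the builder matched exhaustive
topology enumeration on hundreds of random matrices with up to 7 taxa.
Everything is deterministic given the input order; cell types are sorted
lexicographically at encoding time.

Branch lengths are balanced least-squares estimates computed from balanced
(topology-halving) average distances between the four subtrees around each
edge; negative estimates are clamped to zero and flagged. The sum of the
balanced branch lengths equals the Pauplin length (before clamping), which
is asserted in tests. Bootstrap support resamples gene positions with
replacement (1000 replicates by default), rebuilds each replicate tree with
a single greedy start and NNI polish only (replicates estimate split
frequencies, not optima), and reports for each internal branch the fraction
of successful replicates containing its bipartition. Replicates that leave
some pair without comparable sites are skipped and counted.

## Deconvolution against single-cell clusters

Single-cell counts are normalized to counts per million per cell, then
averaged per cluster. Genes are selected reciprocally: for every column of
both matrices (bulk cell types and single-cell clusters), the top-50 genes
by enrichment against the mean of the other columns and the top-50 against
the maximum of the other columns, all unioned. Enrichment is
`(value + 1) / (other + 1)`; the pseudocount guards division by zero and
damps ratios between near-zero values. A matrix with a single column has no
"other columns" and is skipped on its side of the reciprocal selection.

Each bulk profile is then modeled as a non-negative weighted sum of cluster
means by Lawson-Hanson NNLS (scipy's implementation), with no intercept; the
residual is the least-squares residual, not a fitted term. The heatmap
variant divides each cluster's coefficients by their maximum across bulk
profiles. The reverse regression (clusters on bulk profiles) is available
behind a flag but is degenerate in practice: bulk profiles of related cell
types are collinear, and NNLS's sparsity zeroes whole profiles out.

Observed/expected ratios compare cluster sizes with anatomical counts:
`(size_X / size_ref) / (count_X / count_ref)`.

## Connectome overlay

For one presynaptic cell type, the instance with the most distinct synaptic
partners is the representative; partner types with fewer than 5 synapses to
it are dropped. Each postsynaptic process at each active zone is labeled
*expressing* (its cell type calls at least one of the queried receptor genes
on), *non-expressing* (all queried receptors off), or *unknown* (cell type
not profiled). Discretization here is binary — on at `P >= 0.8`, off below —
so a three-state ambiguous call maps to off; this section is the only place
the binary rule is used. Candidate interaction counts between two cell
types count each undirected protein pair at most once, in either
orientation; homotypic queries are allowed.

## The synthetic-data generator

The generator exists so that every stage is testable against a known truth
without downloads. It emulates the statistical structure the model assumes,
at a default scale of 2000 genes x 30 cell types, 1-2 drivers per type and
2-3 replicates per driver (about 100-150 samples — a compact version of a
catalog with a few hundred libraries).

Per-gene defaults, chosen once as biologically plausible magnitudes:

* 60% of genes are bimodal: off level `mu_off ~ U(0, 2)` natural-log TPM
  (silent states at ~1-7 TPM), on level
  `mu_on = mu_off + max(sep * sigma, 2.0)` with `sep ~ U(3, 6)` sigma-units
  and `sigma ~ U(0.3, 0.8)`; the 2.0-log floor (~7-fold) keeps "on" states
  distinguishable from silence even for quiet genes, as real switched genes
  are. Per-gene on-fraction `pi ~ U(0.15, 0.85)`; true states per cell type
  are Bernoulli(pi).
* The remainder split evenly into always-on genes (`mu ~ U(4.5, 7.5)`,
  housekeeping-like levels) and silent genes (`mu ~ U(-1, 1)`).
* Transcript carryover: one designated photoreceptor-like cell type
  contributes contamination. Ten of its exclusive genes sit at very high
  abundance (`mu_on ~ U(7.5, 9)`, roughly 2-8 thousand TPM); every other
  sample observes `(1 - f) * own + f_s * contaminant` with `f = 0.05` and a
  lognormal jitter (sd 1.0) on `f_s`, reproducing carryover that spans
  orders of magnitude across preparations. Only contaminant transcripts
  above 1000 TPM carry over, reflecting that carryover is detectable only
  for very abundant transcripts.
* Dissected pseudo-samples are convex Dirichlet(1) mixtures of the expected
  cell-type profiles with mild lognormal noise (sd 0.2), appended with
  `sample_class = dissected`.
* Columns are renormalized to one million, as TPM requires. A side effect
  worth knowing: at small gene counts the renormalization factor varies
  across samples (composition noise), inflating the effective within-state
  spread; at the 2000-gene default this inflation is ~5%.
* A `student_t` noise switch (df 4) exists for misspecification testing.

What the generator does **not** emulate: batch effects and library-size
artifacts beyond composition noise, gene-gene correlation within samples,
annotation errors, partially penetrant drivers, and count-level (UMI/read)
noise — the single-cell fixture uses plain multinomial sampling around
cell-type profiles. Passing tests therefore demonstrate correctness of the
inference machinery under the model's own assumptions plus carryover and
mixed-tissue contamination, not robustness to every artifact of real
libraries.

Companion fixtures derived from the truth table: a protein-expression
benchmark (configurable error rate, default 0), toy synapse and interaction
tables over the same cell-type universe, and a synthetic single-cell data
set whose last two cell types are deliberately merged into one cluster to
exercise one-cluster/many-types matching. Cluster sizes are emitted with
anatomical counts exactly proportional to them, so observed/expected ratios
are 1 by construction.

## Numerical conventions

* Natural logarithms throughout.
* All probability arithmetic in log space; posterior odds use the
  shared-sigma identity `logit = logit(pi) + (mu_on - mu_off) / sigma^2 *
  sum_s (y_s - (mu_on + mu_off)/2)`, finite for observations 30 sigma out.
* Plug-in parameters: reported probabilities are evaluated at posterior-mean
  parameters, which preserves the monotonicity guarantee; a draw-averaged
  variant exists behind a flag.
* Pooled global components use maximum-likelihood normal fits with the
  standard deviation floored at 1e-6 (degenerate pools).
* TSV output uses 17 significant digits; reading uses round-trip float
  parsing, so write-then-read is the identity.
* Ties: top-k enrichment breaks ties by gene order; tree insertion by lowest
  edge index; cell types sort lexicographically.

## Problem sizes used in the shipped experiments

The test suite and the acceptance script run the full pipeline at
2000 genes x 30 cell types with 2 chains x 300 iterations (about 40 s), the
calibration experiment at 200 genes x 40 samples, tree-builder validation on
matrices of 5-7 taxa against exhaustive search, and NNLS validation on 200
random 6x4 problems against active-set enumeration. Unit tests use compact
catalogs (80-150 genes, 6-8 cell types) where composition noise is
substantial; their thresholds are set accordingly and the full-scale
behavior is asserted in the acceptance tests.

## Known limitations

* Binary states only; graded expression is represented only through the
  probability scale, not as additional states.
* Model selection is conservative at small sample counts (see above); genes
  expressed in very few profiled cell types may be called unimodal and then
  broadcast a single probability, hiding their specificity. The carryover
  regime (a gene on in one heavily contaminated cell type) is the worst
  case.
* The shared fold partition trades a little per-gene optimality for
  cross-gene comparability and speed.
* Bootstrap replicate trees are NNI-polished single starts; supports near
  0.5 can wobble by a few percent between seeds at large taxon counts.
* The reverse deconvolution direction is exposed but not recommended (see
  above).
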