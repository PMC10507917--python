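# Methods

## The model

Bulk RNA-seq expression is a mixture of cell-type-specific expression.
For a sample with gene vector `Y_g` and a reference of K cell types
with signature matrix `θ_kg` (per-type relative mean expression, rows
summing to 1), the package fits

    Y_g = Σ_k p_k θ_kg + r_g,        p_k ≥ 0,

by non-negative least squares and reports `p_k / Σ p_k` as cell-type
proportions. NNLS produces exact zeros for inactive types, which is
what makes zero-call counting in the evaluation well defined.

### Iterated gene weighting

A single NNLS fit treats all genes equally, but genes differ in how
reliable they are as cell-type markers. After each solve, per-gene
weights are recomputed as

    w_g = 1 / (σ_g + r_g² + ν),      σ_g = Σ_k (S_k θ_kg)² σ_kg,

where `σ_kg` is the cross-subject variance of gene g's relative
expression in type k, `S_k` the mean per-cell library size of type k
(focusing the variance on the types where the gene is actually
expressed), `r_g` the current residual, and `ν` (default 1e-4) a
regularisation floor bounding the weights by `1/ν`. Both the bulk
vector and the signature columns are rescaled by `√w_g` and the solve
repeats until the largest absolute change in any proportion falls
below `eps` (default 0.01) or `max_iter` (default 1000) is reached.
This is the "music" mode.

### Capture-bias penalty ("detrem" mode)

Single-nuclei references capture only nuclear transcripts, so many
genes are systematically over- or under-represented relative to
whole-cell bulk sequencing. The per-gene capture quotient

    Q_g = (bulk totals, normalized to sum 1) / (reference totals, normalized to sum 1)

is computed once per bulk dataset on the shared expressed genes. Each
iteration's weights are then divided by

    D_g = max(1, penalty_scale · |log2 Q_g|),      penalty_scale = 10,

so capture-discordant genes lose influence while concordant genes
(D_g = 1) are untouched. With a flat quotient (Q_g ≡ 1 everywhere)
detrem mode is exactly, bitwise, music mode — a property the tests
assert.

The clamp direction deserves a note: a divisor *capped above* at 1
would amplify the weights of concordant genes without bound as
Q_g → 1. The package uses the non-amplifying `max(1, ·)` form, which
matches the penalty's purpose (never increase a gene's weight); the
amplifying variant remains available behind `literal_clamp` /
`--literal-e18` purely for auditing the alternative reading.

### Design-matrix scale

The NNLS design is `θ` itself; the cell-size factor `S_k` enters only
through the variance term `σ_g`. Under this convention the recovered
proportions are mRNA-fraction proportions: a noiseless mixture
`y = θᵀ p*` is recovered exactly (a fixed point after the first
solve), which the test suite verifies to 1e-6. Implementations that
scale design columns by `S_k` instead estimate cell-count proportions;
the two differ by a per-type rescaling and coincide when cell sizes
are equal.

Bulk columns are library-size normalized before fitting (configurable)
so bulk and signature live on comparable relative scales. On that
scale, with ~1000 genes, `r_g²` and `σ_g` are typically small against
`ν`, so the variance weighting is gentle; the quotient penalty acts
multiplicatively on the weights and is scale-independent.

### Degenerate inputs

An all-zero bulk vector is an error naming the sample. An NNLS
solution that collapses to all zeros is reported as a non-converged
NaN proportion row rather than silently imputed — imputation would
corrupt the zero-call statistics downstream. Genes with an undefined
quotient (zero on either side) are dropped from the detrem working set
with a logged count.

## Signature construction

From labelled multi-subject single-nuclei counts: per subject j and
type k, the subject-level relative profile is the per-gene mean count
over that subject's type-k cells divided by its gene sum. `θ` is the
cross-subject mean, `σ` the population (1/n) variance (defined as zero
for a single subject), and `S_k` the cross-subject mean of the mean
per-cell library size. Missing (subject, type) combinations are
skipped. Genes silent in every cell are dropped at build time with a
logged count: they carry no signal and break quotient computation. The
simulator uses the pooled profile instead — per-type summed counts
normalized to sum 1 — whose construction (sum vs mean over cells) is
immaterial after normalization.

## Pseudo-bulk simulation

Ground-truth proportions are drawn per sample from per-type uniform
ranges with the last type taking the residual `1 − Σ`; infeasible
vectors (negative residual) are rejected and redrawn, which preserves
the uniform marginals conditional on feasibility. The shipped brain
ranges are plausible human-cortex abundance bounds and are defaults,
not published values — studies should supply their own ranges table.

Per sample, the per-gene relative abundance is the proportion-weighted
mixture of the (optionally biased, then renormalized) per-type
profiles, and counts are one multinomial draw of the sample's read
depth — exactly equivalent to assigning each read independently, just
faster. Depths are drawn as integers uniformly from an inclusive
range, default 8–12 million reads per sample.

Three capture-bias designs perturb the per-type profiles before
mixing: none; `B_g = log2(1 + Gamma(shape, rate))` with presets
(0.25, 0.025), (0.75, 0.25), (1.0, 0.5); and `B_g = Q_g`, the
empirical quotient against a real (or companion) bulk dataset, which
ties the simulation's bias to the exact discordance the detrem penalty
measures.

## Evaluation

Lin's concordance correlation coefficient,

    CCC = 2 cov(x, y) / (var x + var y + (mean x − mean y)²),

with population (1/n) moments (the sample-variance alternative differs
by O(1/n)), is the primary accuracy metric: unlike Pearson's r it
penalizes location and scale shifts and equals 1 only for identity
agreement. Pearson r and RMSE are reported alongside; aggregate means
across types are unweighted and skip NA cells. Zero calls are counted
as exact zeros over non-NaN samples. Concordance against external
measurements (IHC protein levels, marker-gene expression, cell
density) excludes zero-estimate samples first (separately quantified),
then min–max scales both retained vectors to [0, 1] and reports
Pearson r with the retained n; fewer than 3 pairs yields NA with a
reason. GABAergic and glutamatergic estimates can be summed into a
combined neuron column for markers that do not distinguish the two.

## Synthetic data generator

The generator plants known structure: a shared log-normal baseline
over genes with disjoint per-type marker blocks boosted 8-fold;
per-(subject, type, gene) log-normal factors (log-sd 0.15) creating
genuine cross-subject variance; log-normal per-cell library sizes
(mean 2000, log-sd 0.3) with Poisson counts. The companion "real bulk"
applies multiplicative log-normal per-gene capture factors (log-sd
0.5) recorded as ground truth, emulating nuclei-vs-whole-cell capture
differences.

Default sizes — 5 types, 1000 genes, 4 subjects, 100 cells per
(subject, type), 50 bulk samples at 1e5 reads — keep an end-to-end run
under a few seconds while leaving recovery CCC above 0.9. What passing
tests show: the estimator recovers proportions generated by its own
mixture model, and the quotient penalty improves accuracy when the
simulation's bias is quotient-derived. What they do not show:
robustness to features the generator omits — negative-binomial
overdispersion beyond the optional config, transcript-length and
ambient-RNA artifacts, doublets, mismatched cell-type granularity
between reference and tissue — so real-data performance must be
validated against external measurements via the evaluation module.

At 50 samples the detrem−music mean-CCC difference on quotient-biased
data is positive for most random seeds but is itself a noisy quantity;
larger sample counts tighten it.

## Numerical choices

- RNG: a single `numpy.random.Generator` threaded through every
  stochastic operation; integer seeds are recorded in outputs and the
  same seed reproduces simulations bit-for-bit.
- Convergence is declared on `max_k |Δp_k| < eps` between successive
  normalized solutions; the first iteration never converges (there is
  no previous solution).
- Initial weights are 1 (unweighted first pass).
- Centering/normalization (the MuSiC_C / MuSiC_N variants) operate
  per working vector — the weighted bulk vector and each weighted
  signature column — immediately before each solve; negative entries
  produced by centering are passed to NNLS as-is (the constraint is on
  coefficients, not data).
- Ties and degenerate uniforms (a = b) are handled naturally by the
  samplers; point-mass ranges produce deterministic proportions.
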