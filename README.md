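# detrem

Cell-type deconvolution of bulk RNA-seq against a single-nuclei
reference, with correction for the capture bias between the two
technologies.

## The problem

Bulk RNA-seq measures a tissue's mixed expression; estimating the
underlying cell-type fractions (deconvolution) requires a reference of
per-type expression profiles, today usually built from single-nuclei
RNA-seq. But nuclei-only sequencing captures a systematically different
transcript population than whole-cell bulk sequencing, so many genes
disagree between reference and target for technical rather than
biological reasons — and deconvolution methods that trust those genes
produce distorted fractions and spurious exact-zero estimates for
cell types that are certainly present.

This package targets researchers estimating cell-type composition in
bulk tissue (e.g. brain cortex) from a labelled multi-subject snRNA-seq
reference, and anyone benchmarking deconvolution methods on simulations
with known ground truth.

## The method

Proportions are estimated per sample by iterated weighted non-negative
least squares on the model `Y_g = Σ_k p_k θ_kg + r_g`, where `θ_kg` is
the signature matrix (cross-subject mean relative expression of gene
*g* in type *k*). After each solve, gene weights are recomputed as

    w_g = 1 / (σ_g + r_g² + ν),   σ_g = Σ_k (S_k θ_kg)² σ_kg,

downweighting genes with high residuals or high between-subject
variance (`σ_kg`), and the system is rescaled by `√w_g` until the
proportions stabilize — the classic variance-weighting scheme
(`method="music"`). The bias-corrected mode (`method="detrem"`)
additionally computes the per-gene capture quotient
`Q_g = bulk'_g / reference'_g` (both normalized to sum 1) once per
dataset and divides every iteration's weights by

    D_g = max(1, 10·|log2 Q_g|),

so capture-discordant genes lose influence while concordant genes are
untouched. See `docs/methods.md` for assumptions, parameter defaults
and numerical details.

The package also ships the matching pseudo-bulk simulator (known
proportions; unbiased, gamma-distributed, or quotient-derived per-gene
bias), an evaluation suite (Lin's CCC, Pearson r, RMSE, zero-call
quantification, min–max-scaled concordance with IHC/marker vectors,
neuron aggregation), a synthetic multi-subject reference generator, and
a CLI tying the pipeline together.

## Worked example

Build a synthetic 5-type, 1000-gene, 4-subject reference, derive the
signature, simulate 50 unbiased pseudo-bulk samples at 100k reads, and
deconvolute:

```python
from detrem import (SyntheticReferenceSpec, make_reference, build_signature,
                    simulate_bulk, deconvolute, evaluate_against_truth)
from detrem.synthetic import default_ranges_for

spec = SyntheticReferenceSpec(seed=0)
synth = make_reference(spec)
sig = build_signature(synth.reference)
ranges = default_ranges_for(list(sig.type_labels))
sim = simulate_bulk(sig.pooled_normalized, ranges, 50, rng=11,
                    depth_range=(100_000, 100_000))
res = deconvolute(sim.counts, sig)
report = evaluate_against_truth(res.proportions,
                                sim.true_proportions[res.proportions.columns])
print(report.per_type.round(4))
print(f"mean CCC = {report.mean_ccc:.4f}")
```

prints

```
              ccc  pearson_r    rmse  n_samples
cell_type
AST        0.9981     0.9983  0.0049         50
GAB        0.9985     0.9986  0.0040         50
GLU        0.9980     0.9981  0.0041         50
MIC        0.9960     0.9963  0.0063         50
OLI        0.9993     0.9993  0.0047         50
mean CCC = 0.9980
```

Each row scores one cell type across the 50 samples: CCC near 1 means
the estimated fractions agree with the known simulated fractions in
both correlation and absolute level (RMSE here is ~0.5 percentage
points of composition). On capture-biased data the two methods
separate: `deconvolute(..., DeconvolutionConfig(method="detrem"))`
retains high CCC while plain variance weighting degrades — this
comparison is exactly what `scripts/acceptance.py` recomputes.

The same pipeline from the shell:

```sh
detrem synth --out data --seed 0
detrem signature --counts data/reference --metadata data/reference/metadata.tsv --out sig
detrem simulate --signature sig --ranges ranges.tsv --n-samples 50 --out sim
detrem deconv --bulk sim/counts.tsv --signature sig --method detrem --out est
detrem evaluate --estimates est/proportions.tsv --truth sim/true_proportions.tsv --out eval
```

Every subcommand writes a `manifest.json` (config, seed, input
checksums, package version) next to its outputs.

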