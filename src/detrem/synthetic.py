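"""Fully synthetic multi-subject single-nuclei references and biased bulk companions.

The generator plants known structure so every stage of the pipeline can
be checked against ground truth without any download:

* distinct per-type expression profiles — a shared log-normal baseline
  with disjoint marker-gene blocks boosted per type;
* cross-subject variation — per-(subject, type, gene) log-normal
  factors, so the signature builder sees genuine between-subject
  variance;
* per-cell library-size variation (log-normal) with Poisson counts;
* a companion "real bulk" dataset with multiplicative log-normal
  per-gene capture factors, emulating the gene-level capture
  differences between whole-cell bulk sequencing and nuclei-only
  single-cell sequencing that the capture-quotient correction targets.

Default sizes (5 types, 1000 genes, 4 subjects, 100 cells per
subject-type pair, 50 bulk samples at 1e5 reads) keep end-to-end runs
fast while leaving enough signal for proportion recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .reference import ReferenceCounts
from .simulate import ProportionRanges

__all__ = [
    "SyntheticReferenceSpec",
    "SyntheticReference",
    "BiasedBulkCompanion",
    "make_reference",
    "make_biased_bulk_companion",
    "default_ranges_for",
]

_TYPE_POOL = ["AST", "GAB", "MIC", "OLI", "OPC", "END", "GLU"]


@dataclass
class SyntheticReferenceSpec:
    """Sizes and noise levels of the planted synthetic reference."""

    n_types: int = 5
    n_genes: int = 1000
    n_subjects: int = 4
    cells_per_subject_type: int = 100
    marker_genes_per_type: int = 30
    marker_boost: float = 8.0
    baseline_log_sd: float = 1.0
    type_jitter_log_sd: float = 0.3
    subject_dispersion: float = 0.15
    library_size_mean: float = 2000.0
    library_size_log_sd: float = 0.3
    capture_log_sd: float = 0.5
    n_bulk_samples: int = 50
    bulk_depth_range: tuple[int, int] = (80_000, 120_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_types, self.n_genes, self.n_subjects,
               self.cells_per_subject_type) < 1:
            raise ValueError("all sizes must be >= 1")
        if self.n_types * self.marker_genes_per_type > self.n_genes:
            raise ValueError("marker blocks exceed the gene count")
        if self.subject_dispersion < 0 or self.capture_log_sd < 0:
            raise ValueError("dispersions must be >= 0")

    @property
    def type_labels(self) -> list:
        if self.n_types <= len(_TYPE_POOL):
            # residual-style neuron label last, as in cortical references
            labels = _TYPE_POOL[: self.n_types - 1] + [_TYPE_POOL[-1]]
            return labels
        return [f"type{i}" for i in range(self.n_types)]

    @property
    def subject_labels(self) -> list:
        return [f"subj{i}" for i in range(self.n_subjects)]


@dataclass
class SyntheticReference:
    """A synthetic reference with its planted ground truth."""

    reference: ReferenceCounts
    planted_profiles: pd.DataFrame  # type x gene, rows sum to 1
    marker_blocks: dict = field(default_factory=dict)


@dataclass
class BiasedBulkCompanion:
    """Pseudo-bulk companion with known capture factors and proportions."""

    counts: pd.DataFrame  # gene x sample
    true_proportions: pd.DataFrame  # sample x type
    capture_factors: pd.Series  # per gene


def default_ranges_for(type_labels: list) -> ProportionRanges:
    """Uniform (0.05, 0.30) bounds for all but the last (residual) type."""
    return ProportionRanges(
        bounds={k: (0.05, 0.30) for k in type_labels[:-1]},
        residual_type=type_labels[-1],
    )


def _planted_profiles(spec: SyntheticReferenceSpec, rng: np.random.Generator):
    G, K = spec.n_genes, spec.n_types
    baseline = rng.lognormal(0.0, spec.baseline_log_sd, size=G)
    profiles = np.empty((K, G))
    blocks = {}
    for i, label in enumerate(spec.type_labels):
        block = np.arange(
            i * spec.marker_genes_per_type, (i + 1) * spec.marker_genes_per_type
        )
        blocks[label] = block
        prof = baseline * rng.lognormal(0.0, spec.type_jitter_log_sd, size=G)
        prof[block] *= spec.marker_boost
        profiles[i] = prof / prof.sum()
    gene_ids = np.array([f"gene_{g:04d}" for g in range(G)], dtype=object)
    return (
        pd.DataFrame(profiles, index=spec.type_labels, columns=gene_ids),
        blocks,
    )


def make_reference(
    spec: SyntheticReferenceSpec, rng: np.random.Generator | None = None
) -> SyntheticReference:
    """Generate labelled single-nuclei counts with planted type profiles.

    Per (subject, type), the planted profile is perturbed by
    independent log-normal factors (sd ``subject_dispersion`` in log
    space) and renormalized; each cell draws a log-normal library size
    and Poisson counts around ``library_size * profile``.
    """
    rng = rng or np.random.default_rng(spec.seed)
    planted, blocks = _planted_profiles(spec, rng)
    gene_ids = np.asarray(planted.columns, dtype=object)
    G = spec.n_genes
    n_cells = spec.n_types * spec.n_subjects * spec.cells_per_subject_type

    counts = np.zeros((G, n_cells), dtype=np.int64)
    cell_types = np.empty(n_cells, dtype=object)
    subjects = np.empty(n_cells, dtype=object)

    # mean-one log-normal factors keep expected library sizes stable
    lib_mu = np.log(spec.library_size_mean) - spec.library_size_log_sd**2 / 2

    col = 0
    for k, label in enumerate(spec.type_labels):
        base = planted.iloc[k].to_numpy()
        for subj in spec.subject_labels:
            factors = rng.lognormal(
                -spec.subject_dispersion**2 / 2, spec.subject_dispersion, size=G
            )
            prof = base * factors
            prof = prof / prof.sum()
            n = spec.cells_per_subject_type
            lib = rng.lognormal(lib_mu, spec.library_size_log_sd, size=n)
            lam = np.outer(prof, lib)  # gene x cell
            counts[:, col : col + n] = rng.poisson(lam)
            cell_types[col : col + n] = label
            subjects[col : col + n] = subj
            col += n

    ref = ReferenceCounts(
        counts=sp.csr_matrix(counts),
        gene_ids=gene_ids,
        cell_type_of=cell_types,
        subject_of=subjects,
    )
    return SyntheticReference(
        reference=ref, planted_profiles=planted, marker_blocks=blocks
    )


def make_biased_bulk_companion(
    spec: SyntheticReferenceSpec,
    synth: SyntheticReference,
    rng: np.random.Generator | None = None,
    capture_factors: np.ndarray | None = None,
) -> BiasedBulkCompanion:
    """Pseudo-bulk built on the planted profiles with per-gene capture bias.

    Each gene's expression in the companion bulk is multiplied by a
    log-normal capture factor (sd ``capture_log_sd`` in log space;
    pass ``capture_factors`` to plant specific values).  Proportions
    are drawn from the default per-type ranges and recorded as ground
    truth alongside the factors.
    """
    rng = rng or np.random.default_rng(spec.seed + 1)
    planted = synth.planted_profiles
    gene_ids = planted.columns
    if capture_factors is None:
        capture_factors = rng.lognormal(0.0, spec.capture_log_sd, size=spec.n_genes)
    capture_factors = np.asarray(capture_factors, dtype=float)
    if capture_factors.shape != (spec.n_genes,):
        raise ValueError("capture_factors length must equal n_genes")

    biased = planted.to_numpy() * capture_factors[np.newaxis, :]
    biased = biased / biased.sum(axis=1, keepdims=True)

    ranges = default_ranges_for(list(planted.index))
    from .simulate import draw_proportions

    props = draw_proportions(ranges, spec.n_bulk_samples, rng)
    mix = props[planted.index].to_numpy() @ biased
    mix = mix / mix.sum(axis=1, keepdims=True)

    lo, hi = spec.bulk_depth_range
    depths = rng.integers(lo, hi + 1, size=spec.n_bulk_samples)
    counts = np.empty((spec.n_bulk_samples, spec.n_genes), dtype=np.int64)
    for j in range(spec.n_bulk_samples):
        counts[j] = rng.multinomial(depths[j], mix[j])

    return BiasedBulkCompanion(
        counts=pd.DataFrame(counts.T, index=gene_ids, columns=props.index),
        true_proportions=props,
        capture_factors=pd.Series(capture_factors, index=gene_ids, name="capture"),
    )
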