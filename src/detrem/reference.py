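"""Build deconvolution signatures from labelled multi-subject single-nuclei counts.

The signature of a cell type is its relative mean expression profile.
Two related summaries are produced from a labelled count matrix:

* a *pooled profile* ``X'_kg`` — per-type summed counts normalized to sum
  to one over genes — used by the pseudo-bulk simulator; and
* a *signature set* (``theta``, ``sigma``, ``cell_size``) — the
  cross-subject mean and variance of subject-level relative expression,
  plus the mean per-cell library size of each type — used by the
  weighted-NNLS deconvolution.

Cross-subject variance is what lets the estimator downweight genes that
are unreliable cell-type markers; it is only informative with two or
more reference subjects (with a single subject it is identically zero).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceCounts",
    "SignatureSet",
    "build_pooled_profile",
    "build_signature",
]


@dataclass
class ReferenceCounts:
    """Gene x cell non-negative counts with per-cell type and subject labels.

    Parameters
    ----------
    counts
        Gene x cell matrix of non-negative counts (dense ndarray or any
        scipy sparse matrix; stored as CSR).
    gene_ids
        Ordered unique gene identifiers, length = number of rows.
    cell_type_of
        Per-cell type label, length = number of columns.
    subject_of
        Per-cell subject label, length = number of columns.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cell_type_of: np.ndarray
    subject_of: np.ndarray

    def __post_init__(self) -> None:
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts, dtype=np.float64))
        else:
            self.counts = self.counts.tocsr().astype(np.float64)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_type_of = np.asarray(self.cell_type_of, dtype=object)
        self.subject_of = np.asarray(self.subject_of, dtype=object)

        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"gene_ids length {len(self.gene_ids)} != matrix rows {n_genes}"
            )
        if len(self.cell_type_of) != n_cells or len(self.subject_of) != n_cells:
            raise ValueError("cell_type_of/subject_of length must equal matrix columns")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene ids in reference")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts in reference")
        if n_cells == 0:
            raise ValueError("reference has no cells")

    @property
    def type_labels(self) -> list:
        return sorted(set(self.cell_type_of))

    @property
    def subject_labels(self) -> list:
        return sorted(set(self.subject_of))

    def drop_silent_genes(self) -> "ReferenceCounts":
        """Return a copy without genes that are zero in every cell.

        Silent genes carry no signal and make downstream capture-quotient
        computation ill-defined, so they are removed at build time.
        """
        expressed = np.asarray(self.counts.sum(axis=1)).ravel() > 0
        n_dropped = int((~expressed).sum())
        if n_dropped:
            logger.info("dropping %d genes with zero counts in all cells", n_dropped)
            return ReferenceCounts(
                self.counts[expressed],
                self.gene_ids[expressed],
                self.cell_type_of,
                self.subject_of,
            )
        return self


@dataclass
class SignatureSet:
    """Per-type signature used by the deconvolution and the simulator.

    Attributes
    ----------
    theta
        K x G cross-subject mean of subject-level relative expression.
    sigma
        K x G cross-subject (population, 1/n) variance of the same
        quantity; all zeros with a single reference subject.
    cell_size
        Length-K mean per-cell library size of each type, averaged
        across subjects.
    pooled_profile
        K x G per-type pooled raw expression ``X_kg``.
    pooled_normalized
        K x G per-type pooled profile normalized to row sums of one.
    """

    theta: pd.DataFrame
    sigma: pd.DataFrame
    cell_size: pd.Series
    pooled_profile: pd.DataFrame
    pooled_normalized: pd.DataFrame
    type_labels: list = field(default_factory=list)
    gene_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))

    def __post_init__(self) -> None:
        if not self.type_labels:
            self.type_labels = list(self.theta.index)
        if len(self.gene_ids) == 0:
            self.gene_ids = np.asarray(self.theta.columns, dtype=object)
        for df in (self.sigma, self.pooled_profile, self.pooled_normalized):
            if not df.columns.equals(self.theta.columns):
                raise ValueError("signature matrices must share gene ordering")
        if (self.sigma.to_numpy() < 0).any():
            raise ValueError("sigma must be non-negative")
        if (self.cell_size.to_numpy() <= 0).any():
            raise ValueError("cell_size must be positive")
        row_sums = self.pooled_normalized.sum(axis=1).to_numpy()
        if not np.allclose(row_sums, 1.0):
            raise ValueError("pooled_normalized rows must sum to 1")

    def write(self, outdir) -> None:
        """Write theta/sigma/cell_size TSVs (types x genes) to a directory."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.theta.to_csv(outdir / "theta.tsv", sep="\t")
        self.sigma.to_csv(outdir / "sigma.tsv", sep="\t")
        self.cell_size.rename("cell_size").to_csv(outdir / "cell_size.tsv", sep="\t")
        self.pooled_normalized.to_csv(outdir / "pooled_profile.tsv", sep="\t")

    @classmethod
    def read(cls, indir) -> "SignatureSet":
        from pathlib import Path

        indir = Path(indir)
        theta = pd.read_csv(indir / "theta.tsv", sep="\t", index_col=0)
        sigma = pd.read_csv(indir / "sigma.tsv", sep="\t", index_col=0)
        cell_size = pd.read_csv(indir / "cell_size.tsv", sep="\t", index_col=0)[
            "cell_size"
        ]
        pooled_path = indir / "pooled_profile.tsv"
        if pooled_path.exists():
            pooled_norm = pd.read_csv(pooled_path, sep="\t", index_col=0)
        else:
            # reconstruct a normalized pooled profile from theta
            pooled_norm = theta.div(theta.sum(axis=1), axis=0)
        return cls(
            theta=theta,
            sigma=sigma,
            cell_size=cell_size,
            pooled_profile=pooled_norm.copy(),
            pooled_normalized=pooled_norm,
        )


def _type_masks(ref: ReferenceCounts) -> dict:
    return {k: np.asarray(ref.cell_type_of == k) for k in ref.type_labels}


def build_pooled_profile(ref: ReferenceCounts) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pool counts over the cells of each type and normalize per type.

    Returns ``(X_kg, X'_kg)`` as types x genes DataFrames, where
    ``X_kg`` is the per-type column sum of the count matrix and
    ``X'_kg = X_kg / sum_g X_kg`` so each type's profile sums to one.

    Raises
    ------
    ValueError
        If any declared cell type has zero total counts (its profile
        cannot be normalized).
    """
    types = ref.type_labels
    pooled = np.zeros((len(types), len(ref.gene_ids)))
    for i, (k, mask) in enumerate(_type_masks(ref).items()):
        pooled[i] = np.asarray(ref.counts[:, mask].sum(axis=1)).ravel()
    totals = pooled.sum(axis=1)
    zero_types = [k for k, t in zip(types, totals) if t == 0]
    if zero_types:
        raise ValueError(f"cell type(s) with zero total counts: {zero_types}")
    pooled_df = pd.DataFrame(pooled, index=types, columns=ref.gene_ids)
    normalized = pooled_df.div(pooled_df.sum(axis=1), axis=0)
    return pooled_df, normalized


def build_signature(ref: ReferenceCounts, drop_silent: bool = True) -> SignatureSet:
    """Build the (theta, sigma, cell_size) signature from labelled counts.

    For each subject *j* and type *k* present in the data, the
    subject-level relative profile is the per-gene mean count over that
    subject's type-*k* cells divided by its sum over genes.  ``theta``
    is the mean and ``sigma`` the population (1/n) variance of these
    profiles across the subjects in which the type occurs; missing
    (subject, type) combinations are skipped.  ``cell_size`` is the mean
    across subjects of the mean per-cell library size of type-*k* cells.

    With a single subject ``sigma`` is all zeros (the variance of one
    observation is defined as zero).
    """
    if drop_silent:
        ref = ref.drop_silent_genes()
    types = ref.type_labels
    subjects = ref.subject_labels
    G = len(ref.gene_ids)

    theta = np.zeros((len(types), G))
    sigma = np.zeros((len(types), G))
    cell_size = np.zeros(len(types))

    counts = ref.counts.tocsc()
    for i, k in enumerate(types):
        profiles = []
        sizes = []
        for j in subjects:
            mask = np.asarray((ref.cell_type_of == k) & (ref.subject_of == j))
            if not mask.any():
                continue
            sub = counts[:, mask]
            mean_counts = np.asarray(sub.mean(axis=1)).ravel()
            total = mean_counts.sum()
            if total == 0:
                continue
            profiles.append(mean_counts / total)
            sizes.append(np.asarray(sub.sum(axis=0)).ravel().mean())
        if not profiles:
            raise ValueError(f"cell type {k!r} has no expressing cells in any subject")
        prof = np.vstack(profiles)
        theta[i] = prof.mean(axis=0)
        sigma[i] = prof.var(axis=0)  # ddof=0; zero for a single subject
        cell_size[i] = float(np.mean(sizes))

    pooled, pooled_norm = build_pooled_profile(ref)
    return SignatureSet(
        theta=pd.DataFrame(theta, index=types, columns=ref.gene_ids),
        sigma=pd.DataFrame(sigma, index=types, columns=ref.gene_ids),
        cell_size=pd.Series(cell_size, index=types, name="cell_size"),
        pooled_profile=pooled,
        pooled_normalized=pooled_norm,
    )
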