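"""Readers and writers for the package's on-disk formats.

Canonical dense format: TSV with a header row and gene (or sample) ids
in the first column, matching RSEM-style expected-count tables; gzip is
handled transparently by pandas.  Sparse single-cell input uses the
10x-style Matrix Market triplet (``matrix.mtx`` plus ``features.tsv``
or ``genes.tsv`` and ``barcodes.tsv``), read via :func:`scipy.io.mmread`.
Cell metadata is a TSV with columns ``barcode``, ``cell_type``,
``subject``.

Every CLI run also writes a :class:`RunManifest` JSON recording the
subcommand, full configuration, seed, input checksums and package
version, sufficient to re-run deterministic stages bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .reference import ReferenceCounts

__all__ = [
    "read_counts",
    "read_dense_tsv",
    "read_mtx_triplet",
    "read_reference",
    "write_dense_tsv",
    "write_mtx_triplet",
    "RunManifest",
]


def read_dense_tsv(path) -> pd.DataFrame:
    """Read a dense counts table (ids in first column, header row).

    Separator is inferred from the extension (``.csv`` → comma,
    otherwise tab).  Duplicate ids and non-numeric cells are rejected.
    """
    path = Path(path)
    sep = "," if path.name.endswith((".csv", ".csv.gz")) else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate ids in {path}: {dupes}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cells in {path}: {exc}") from exc
    return df


def read_mtx_triplet(directory) -> tuple[sp.csr_matrix, np.ndarray, np.ndarray]:
    """Read a 10x-style MTX triplet; returns (matrix, gene_ids, barcodes).

    The matrix is gene x cell.  Gene ids come from the first column of
    ``features.tsv`` (or ``genes.tsv``).  Dimension mismatches between
    the matrix header and the id files are an error.
    """
    directory = Path(directory)

    def _find(*names):
        for n in names:
            for cand in (directory / n, directory / (n + ".gz")):
                if cand.exists():
                    return cand
        raise FileNotFoundError(f"none of {names} found in {directory}")

    mtx = scipy.io.mmread(_find("matrix.mtx")).tocsr()
    feats = pd.read_csv(_find("features.tsv", "genes.tsv"), sep="\t", header=None)
    barcodes = pd.read_csv(_find("barcodes.tsv"), sep="\t", header=None)
    gene_ids = feats.iloc[:, 0].to_numpy(dtype=object)
    cell_ids = barcodes.iloc[:, 0].to_numpy(dtype=object)
    if mtx.shape != (len(gene_ids), len(cell_ids)):
        raise ValueError(
            f"matrix dims {mtx.shape} != ids ({len(gene_ids)} genes, "
            f"{len(cell_ids)} barcodes)"
        )
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("duplicate gene ids in features file")
    return mtx, gene_ids, cell_ids


def read_counts(path, layout: str = "auto"):
    """Read a counts matrix in either supported layout.

    ``layout``: ``"dense_tsv"``, ``"mtx_triplet"``, or ``"auto"``
    (directory → MTX triplet, file → dense TSV).  Returns a DataFrame
    for dense input, or ``(sparse matrix, gene_ids, barcodes)`` for MTX.
    """
    path = Path(path)
    if layout == "auto":
        layout = "mtx_triplet" if path.is_dir() else "dense_tsv"
    if layout == "dense_tsv":
        return read_dense_tsv(path)
    if layout == "mtx_triplet":
        return read_mtx_triplet(path)
    raise ValueError(f"unknown layout {layout!r}")


def read_reference(counts_path, metadata_path) -> ReferenceCounts:
    """Assemble a :class:`ReferenceCounts` from counts plus cell metadata.

    Metadata TSV needs columns ``barcode``, ``cell_type``, ``subject``;
    only barcodes present in both files are kept, in count-file order.
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    for col in ("barcode", "cell_type", "subject"):
        if col not in meta.columns:
            raise ValueError(f"metadata missing column {col!r}")
    meta = meta.set_index("barcode")

    data = read_counts(counts_path)
    if isinstance(data, tuple):
        mtx, gene_ids, barcodes = data
    else:
        mtx = sp.csr_matrix(data.to_numpy())
        gene_ids = data.index.to_numpy(dtype=object)
        barcodes = data.columns.to_numpy(dtype=object)

    keep = np.array([b in meta.index for b in barcodes])
    if not keep.any():
        raise ValueError("no barcodes shared between counts and metadata")
    barcodes = barcodes[keep]
    sub = meta.loc[barcodes]
    return ReferenceCounts(
        counts=mtx[:, keep],
        gene_ids=gene_ids,
        cell_type_of=sub["cell_type"].to_numpy(dtype=object),
        subject_of=sub["subject"].to_numpy(dtype=object),
    )


def write_dense_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t")


def write_mtx_triplet(
    matrix, gene_ids, barcodes, directory, cell_types=None, subjects=None
) -> None:
    """Write a gene x cell matrix as a 10x-style triplet (+ optional metadata)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), sp.coo_matrix(matrix))
    pd.Series(gene_ids).to_csv(
        directory / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(barcodes).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False
    )
    if cell_types is not None and subjects is not None:
        pd.DataFrame(
            {"barcode": barcodes, "cell_type": cell_types, "subject": subjects}
        ).to_csv(directory / "metadata.tsv", sep="\t", index=False)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written alongside every CLI output directory."""

    subcommand: str
    config: dict
    seed: int | None = None
    inputs: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        from . import __version__

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        payload = {
            "subcommand": self.subcommand,
            "config": self.config,
            "seed": self.seed,
            "input_checksums": {
                name: _sha256(p) for name, p in self.inputs.items() if Path(p).exists()
            },
            "package_version": __version__,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(payload, fh, indent=2)
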