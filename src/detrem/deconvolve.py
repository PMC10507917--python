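"""Iterated weighted-NNLS estimation of cell-type proportions.

The bulk expression of gene *g* in a sample is modelled as a
non-negative mixture of cell-type signature profiles,

    y_g = sum_k p_k * theta_kg + r_g,

solved by non-negative least squares and iterated: after each solve the
per-gene weights

    w_g = 1 / (sigma_g + r_g**2 + nu),    sigma_g = sum_k (S_k theta_kg)**2 sigma_kg

are recomputed from the residuals and the cross-subject variance of the
signature, both sides of the system are rescaled by sqrt(w), and the
solve repeats until the largest proportion change falls below ``eps``.
This downweights genes with poor fit or high between-subject
variability ("music" mode).

"detrem" mode additionally divides each iteration's weights by a
capture-discordance penalty derived from the per-gene quotient ``Q_g``
of normalized bulk over normalized reference expression:

    D_g = max(1, penalty_scale * |log2 Q_g|),    w'_g = w_g / D_g,

so genes captured very differently by the two technologies lose
influence while concordant genes (Q near 1) are untouched.  The clamp
direction guarantees no gene weight is ever increased; the alternative
reading that caps the divisor at 1 (which would amplify concordant
genes without bound) is available via ``literal_clamp`` for audit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .reference import SignatureSet
from .simulate import quotient_bias

logger = logging.getLogger(__name__)

__all__ = [
    "DeconvolutionConfig",
    "DeconvolutionResult",
    "common_genes",
    "music_weights",
    "detrem_penalty",
    "deconvolute_sample",
    "deconvolute",
]


@dataclass
class DeconvolutionConfig:
    """Settings for the iterated weighted-NNLS solver.

    Parameters
    ----------
    method
        ``"music"`` (variance weighting only) or ``"detrem"``
        (variance weighting plus the capture-quotient penalty).
    center, normalize
        When set, each working vector (the weighted bulk vector and
        each weighted signature column) is mean-centered and/or divided
        by its standard deviation immediately before each NNLS solve.
    nu
        Regularisation constant guarding the weight denominator;
        default 1e-4.
    eps
        Convergence threshold on the maximum absolute change of any
        proportion between iterations; default 0.01.
    max_iter
        Iteration cap; default 1000.
    penalty_scale
        Multiplier on ``|log2 Q_g|`` in the capture penalty; default 10.
    literal_clamp
        Use the weight-amplifying clamp variant (divisor capped at 1)
        instead of the default non-amplifying ``max(1, .)`` form.
    normalize_bulk
        Library-size normalize each bulk column (divide by its sum)
        before deconvolution so bulk and signature are both on a
        relative scale; default True.
    """

    method: str = "music"
    center: bool = False
    normalize: bool = False
    nu: float = 1e-4
    eps: float = 0.01
    max_iter: int = 1000
    penalty_scale: float = 10.0
    literal_clamp: bool = False
    normalize_bulk: bool = True

    def __post_init__(self) -> None:
        if self.method not in ("music", "detrem"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.nu <= 0:
            raise ValueError("nu must be positive")
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class DeconvolutionResult:
    """Per-sample proportion estimates with convergence traces.

    ``proportions`` rows sum to one (NaN rows mark samples whose NNLS
    solution collapsed to all zeros); ``raw_coefficients`` holds the
    pre-normalization NNLS solutions; ``final_weights`` the per-gene
    weights at the last iteration of each sample.
    """

    proportions: pd.DataFrame
    raw_coefficients: pd.DataFrame
    converged: pd.Series
    n_iterations: pd.Series
    final_weights: pd.DataFrame
    gene_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))


def common_genes(signature: SignatureSet, bulk: pd.DataFrame) -> pd.Index:
    """Working gene set: expressed in the signature and present in the bulk.

    Returns, in signature order, the genes with a positive signature in
    at least one type and a positive grand total in the bulk table.
    """
    sig_genes = pd.Index(signature.theta.columns)
    expressed = signature.theta.max(axis=0) > 0
    bulk_totals = bulk.sum(axis=1)
    keep = [
        g
        for g in sig_genes[expressed]
        if g in bulk_totals.index and bulk_totals[g] > 0
    ]
    if not keep:
        raise ValueError("no shared expressed genes between signature and bulk")
    return pd.Index(keep)


def pooled_signature_variance(
    signature: SignatureSet, genes: pd.Index | None = None
) -> np.ndarray:
    """Per-gene variance pooled over types: ``sigma_g = sum_k (S_k theta_kg)^2 sigma_kg``."""
    theta = signature.theta
    sigma = signature.sigma
    if genes is not None:
        theta = theta[genes]
        sigma = sigma[genes]
    s = signature.cell_size.loc[theta.index].to_numpy()[:, None]
    return ((s * theta.to_numpy()) ** 2 * sigma.to_numpy()).sum(axis=0)


def music_weights(
    residuals: np.ndarray,
    signature: SignatureSet,
    nu: float = 1e-4,
    genes: pd.Index | None = None,
    sigma_g: np.ndarray | None = None,
) -> np.ndarray:
    """Gene weights ``w_g = 1 / (sigma_g + r_g^2 + nu)``; strictly positive.

    ``sigma_g`` may be passed precomputed (it does not change across
    iterations); otherwise it is derived from the signature.
    """
    if sigma_g is None:
        sigma_g = pooled_signature_variance(signature, genes)
    r = np.asarray(residuals, dtype=float)
    return 1.0 / (sigma_g + r**2 + nu)


def detrem_penalty(
    quotient: np.ndarray | pd.Series,
    penalty_scale: float = 10.0,
    literal_clamp: bool = False,
) -> np.ndarray:
    """Per-gene weight divisor from the capture quotient.

    Default form ``D_g = max(1, penalty_scale * |log2 Q_g|)`` divides
    down the weights of capture-discordant genes and leaves concordant
    genes (``D_g = 1``) untouched.  ``literal_clamp`` instead caps the
    divisor at 1 (``D_g = min(penalty_scale * |log2 Q_g|, 1)``), which
    amplifies concordant-gene weights; kept only for audit.

    Raises
    ------
    ValueError
        If any quotient is non-positive or non-finite (such genes must
        be excluded upstream).
    """
    q = np.asarray(quotient, dtype=float)
    if (q <= 0).any() or not np.isfinite(q).all():
        raise ValueError("quotients must be positive and finite")
    scaled = penalty_scale * np.abs(np.log2(q))
    if literal_clamp:
        return np.minimum(scaled, 1.0)
    return np.maximum(scaled, 1.0)


def _prep_vector(v: np.ndarray, center: bool, normalize: bool) -> np.ndarray:
    if center:
        v = v - v.mean()
    if normalize:
        sd = v.std()
        if sd > 0:
            v = v / sd
    return v


def deconvolute_sample(
    y: pd.Series | np.ndarray,
    signature: SignatureSet,
    config: DeconvolutionConfig | None = None,
    quotient: np.ndarray | pd.Series | None = None,
    genes: pd.Index | None = None,
) -> tuple[np.ndarray, np.ndarray, bool, int, np.ndarray]:
    """Estimate one sample's cell-type proportions by iterated weighted NNLS.

    ``y`` must already be restricted to the working gene set (aligned
    with ``genes`` or the full signature gene order).  Returns
    ``(proportions, raw_coefficients, converged, n_iterations,
    final_weights)``; proportions are the NNLS coefficients normalized
    to sum to one, or a NaN vector if the solution collapsed to zero.
    """
    config = config or DeconvolutionConfig()
    theta = signature.theta if genes is None else signature.theta[genes]
    A = theta.to_numpy().T  # genes x types
    y = np.asarray(y, dtype=float)
    if y.shape != (A.shape[0],):
        raise ValueError(f"bulk vector length {y.shape} != {A.shape[0]} genes")
    if y.sum() <= 0:
        raise ValueError("all-zero bulk vector")
    if config.normalize_bulk:
        y = y / y.sum()

    K = A.shape[1]
    sigma_g = pooled_signature_variance(signature, genes)
    penalty = None
    if config.method == "detrem":
        if quotient is None:
            raise ValueError("detrem requires a capture quotient vector")
        penalty = detrem_penalty(
            quotient, config.penalty_scale, config.literal_clamp
        )

    w = np.ones_like(y)
    p_old = None
    p = np.full(K, np.nan)
    q = np.zeros(K)
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        sw = np.sqrt(w)
        A_w = A * sw[:, None]
        y_w = y * sw
        if config.center or config.normalize:
            y_w = _prep_vector(y_w, config.center, config.normalize)
            A_w = np.column_stack(
                [
                    _prep_vector(A_w[:, k], config.center, config.normalize)
                    for k in range(K)
                ]
            )
        q, _ = nnls(A_w, y_w)
        if q.sum() == 0:
            logger.warning("NNLS solution collapsed to all zeros")
            return np.full(K, np.nan), q, False, it, w
        p = q / q.sum()
        r = y - A @ q
        w = music_weights(r, signature, config.nu, sigma_g=sigma_g)
        if penalty is not None:
            w = w / penalty
        if p_old is not None and np.max(np.abs(p - p_old)) < config.eps:
            converged = True
            break
        p_old = p
    return p, q, converged, it, w


def deconvolute(
    bulk: pd.DataFrame,
    signature: SignatureSet,
    config: DeconvolutionConfig | None = None,
    reference_totals: pd.Series | None = None,
    quotient: pd.Series | None = None,
) -> DeconvolutionResult:
    """Deconvolute every column (sample) of a gene x sample bulk table.

    In ``detrem`` mode the capture quotient is computed once from the
    whole bulk dataset against the reference and shared by all samples:
    pass either a precomputed ``quotient`` (per-gene series) or
    ``reference_totals`` (per-gene summed reference expression; defaults
    to the signature's pooled profile summed over types).  Genes whose
    quotient is undefined (zero on either side) are dropped from the
    working set with a logged count.
    """
    config = config or DeconvolutionConfig()
    genes = common_genes(signature, bulk)

    q_vec = None
    if config.method == "detrem":
        if quotient is None:
            if reference_totals is None:
                reference_totals = signature.pooled_profile.sum(axis=0)
            bulk_totals = bulk.sum(axis=1)
            quotient = quotient_bias(reference_totals, bulk_totals)
        quotient = pd.Series(quotient, dtype=float)
        defined = quotient.index[(quotient > 0) & np.isfinite(quotient)]
        before = len(genes)
        genes = pd.Index([g for g in genes if g in defined])
        if len(genes) < before:
            logger.info(
                "dropped %d genes with undefined capture quotient", before - len(genes)
            )
        if len(genes) == 0:
            raise ValueError("no genes with a defined capture quotient")
        q_vec = quotient.loc[genes].to_numpy()

    types = list(signature.theta.index)
    n = bulk.shape[1]
    props = np.empty((n, len(types)))
    coefs = np.empty((n, len(types)))
    conv = np.zeros(n, dtype=bool)
    iters = np.zeros(n, dtype=int)
    weights = np.empty((n, len(genes)))

    sub = bulk.loc[genes]
    for j, sample in enumerate(bulk.columns):
        y = sub[sample]
        try:
            p, q, c, it, w = deconvolute_sample(
                y, signature, config, quotient=q_vec, genes=genes
            )
        except ValueError as exc:
            raise ValueError(f"sample {sample!r}: {exc}") from exc
        props[j], coefs[j], conv[j], iters[j], weights[j] = p, q, c, it, w

    return DeconvolutionResult(
        proportions=pd.DataFrame(props, index=bulk.columns, columns=types),
        raw_coefficients=pd.DataFrame(coefs, index=bulk.columns, columns=types),
        converged=pd.Series(conv, index=bulk.columns, name="converged"),
        n_iterations=pd.Series(iters, index=bulk.columns, name="n_iterations"),
        final_weights=pd.DataFrame(weights, index=bulk.columns, columns=genes),
        gene_ids=np.asarray(genes, dtype=object),
    )
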