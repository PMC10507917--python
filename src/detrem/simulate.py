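"""Pseudo-bulk simulation with known cell-type fractions and optional capture bias.

A simulated bulk sample mixes per-type normalized expression profiles at
proportions drawn from per-type uniform ranges (the last type takes the
residual ``1 - sum``), then assigns a uniformly drawn number of reads to
genes by multinomial sampling from the mixed relative abundances.

Capture bias between technologies is emulated by multiplying the
per-type profiles by a per-gene bias vector before renormalization.
Three bias designs are supported:

* ``none`` — unbiased;
* ``gamma`` — ``B_g = log2(1 + Gamma(shape, rate))``, with shipped
  parameter presets (0.25, 0.025), (0.75, 0.25), (1.0, 0.5);
* ``quotient`` — ``B_g = Q_g``, the per-gene ratio of normalized bulk
  to normalized reference totals, reproducing the empirical capture
  difference between a real bulk dataset and the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProportionRanges",
    "BiasModel",
    "SimulatedBulkSet",
    "GAMMA_BIAS_PRESETS",
    "draw_proportions",
    "gamma_bias",
    "quotient_bias",
    "apply_bias",
    "simulate_bulk",
]

#: (shape, rate) presets for the gamma bias designs (simulations 1-3).
GAMMA_BIAS_PRESETS = {1: (0.25, 0.025), 2: (0.75, 0.25), 3: (1.0, 0.5)}

#: Default per-sample read-depth range (inclusive), 8-12 million reads.
DEFAULT_DEPTH_RANGE = (8_000_000, 12_000_000)


@dataclass
class ProportionRanges:
    """Uniform bounds for K-1 free cell types plus a residual type.

    ``bounds`` maps each free type label to its ``(a, b)`` uniform
    bounds; ``residual_type`` receives ``1 - sum`` of the free draws.
    Draws with a negative residual are rejected and redrawn.
    """

    bounds: dict
    residual_type: str

    def __post_init__(self) -> None:
        if self.residual_type in self.bounds:
            raise ValueError("residual type must not have explicit bounds")
        for k, (a, b) in self.bounds.items():
            if not (0 <= a <= b <= 1):
                raise ValueError(f"invalid bounds for {k!r}: ({a}, {b})")
        if sum(a for a, _ in self.bounds.values()) > 1:
            raise ValueError("sum of lower bounds exceeds 1; ranges infeasible")

    @property
    def type_labels(self) -> list:
        return list(self.bounds) + [self.residual_type]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProportionRanges":
        """Build from a table with columns ``type``, ``a``, ``b``.

        The residual type is marked by empty/NaN bounds.
        """
        bounds = {}
        residual = None
        for _, row in df.iterrows():
            if pd.isna(row["a"]) or pd.isna(row["b"]):
                if residual is not None:
                    raise ValueError("more than one residual type in ranges table")
                residual = str(row["type"])
            else:
                bounds[str(row["type"])] = (float(row["a"]), float(row["b"]))
        if residual is None:
            raise ValueError("ranges table must mark one residual type (empty a,b)")
        return cls(bounds=bounds, residual_type=residual)


#: Default human-cortex proportion ranges. These are plausible abundance
#: bounds for the seven major cortical cell types (glutamatergic neurons
#: take the residual); they are package defaults, not published values,
#: and should be replaced by study-specific ranges where available.
DEFAULT_BRAIN_RANGES = ProportionRanges(
    bounds={
        "AST": (0.05, 0.25),
        "GAB": (0.05, 0.20),
        "MIC": (0.02, 0.12),
        "OLI": (0.10, 0.30),
        "OPC": (0.01, 0.08),
        "END": (0.01, 0.08),
    },
    residual_type="GLU",
)


@dataclass
class BiasModel:
    """Per-gene capture-bias specification.

    ``kind`` is one of ``"none"``, ``"gamma"`` (requires ``shape`` and
    ``rate``), or ``"quotient"`` (requires a precomputed ``quotient``
    vector aligned to the simulation's genes).
    """

    kind: str = "none"
    shape: float | None = None
    rate: float | None = None
    quotient: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gamma", "quotient"):
            raise ValueError(f"unknown bias kind {self.kind!r}")
        if self.kind == "gamma":
            if self.shape is None or self.rate is None:
                raise ValueError("gamma bias requires shape and rate")
            if self.shape <= 0 or self.rate <= 0:
                raise ValueError("gamma shape and rate must be positive")
        if self.kind == "quotient":
            if self.quotient is None:
                raise ValueError("quotient bias requires a quotient vector")
            q = np.asarray(self.quotient, dtype=float)
            if not np.isfinite(q).all() or (q < 0).any():
                raise ValueError("quotient entries must be finite and non-negative")
            self.quotient = q

    def draw(self, n_genes: int, rng: np.random.Generator) -> np.ndarray:
        """Realize the per-gene bias vector ``B_g``."""
        if self.kind == "none":
            return np.ones(n_genes)
        if self.kind == "gamma":
            return gamma_bias(self.shape, self.rate, n_genes, rng)
        if len(self.quotient) != n_genes:
            raise ValueError(
                f"quotient length {len(self.quotient)} != n_genes {n_genes}"
            )
        return self.quotient


@dataclass
class SimulatedBulkSet:
    """A simulated bulk dataset with its ground truth.

    Attributes
    ----------
    counts
        Gene x sample integer counts.
    true_proportions
        Sample x type ground-truth proportion matrix (rows sum to 1).
    bias_vector
        The per-gene bias ``B_g`` applied to the signature (ones if
        unbiased).
    depths
        Per-sample total read counts actually drawn.
    seed
        Seed recorded for reproducibility (None when an external rng
        was supplied).
    """

    counts: pd.DataFrame
    true_proportions: pd.DataFrame
    bias_vector: pd.Series
    depths: pd.Series
    seed: int | None = None


def draw_proportions(
    ranges: ProportionRanges,
    n_samples: int,
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> pd.DataFrame:
    """Draw sample x type proportion vectors from per-type uniform ranges.

    Each free type is drawn uniformly from its bounds; the residual type
    receives ``1 - sum``.  Whole vectors whose free draws exceed 1 are
    rejected and redrawn, preserving the uniform marginals conditional
    on feasibility.

    Raises
    ------
    RuntimeError
        If a feasible vector is not found within ``max_attempts``
        rejection rounds (the ranges leave almost no feasible mass).
    """
    free = list(ranges.bounds)
    a = np.array([ranges.bounds[k][0] for k in free])
    b = np.array([ranges.bounds[k][1] for k in free])

    rows = np.empty((n_samples, len(free) + 1))
    pending = np.arange(n_samples)
    for _ in range(max_attempts):
        draws = rng.uniform(a, b, size=(len(pending), len(free)))
        residual = 1.0 - draws.sum(axis=1)
        ok = residual >= 0
        idx = pending[ok]
        rows[idx, :-1] = draws[ok]
        rows[idx, -1] = residual[ok]
        pending = pending[~ok]
        if pending.size == 0:
            break
    else:
        raise RuntimeError(
            f"could not draw feasible proportions for {pending.size} samples "
            f"within {max_attempts} rejection rounds"
        )
    return pd.DataFrame(
        rows,
        index=[f"sample_{i}" for i in range(n_samples)],
        columns=free + [ranges.residual_type],
    )


def gamma_bias(
    shape: float, rate: float, n_genes: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-gene bias ``B_g = log2(1 + Gamma(shape, rate))``; non-negative."""
    if shape <= 0 or rate <= 0:
        raise ValueError("gamma shape and rate must be positive")
    draws = rng.gamma(shape, scale=1.0 / rate, size=n_genes)
    return np.log2(draws + 1.0)


def quotient_bias(
    ref_totals: pd.Series, bulk_totals: pd.Series
) -> pd.Series:
    """Per-gene capture quotient between a bulk dataset and the reference.

    Both per-gene grand totals are normalized to sum to one over their
    shared genes; the quotient is ``Q_g = bulk'_g / ref'_g`` on genes
    with positive reference expression.  Computed on the gene
    intersection of the two inputs.

    Raises
    ------
    ValueError
        If the gene sets are disjoint, or totals are negative.
    """
    ref_totals = pd.Series(ref_totals, dtype=float)
    bulk_totals = pd.Series(bulk_totals, dtype=float)
    shared = ref_totals.index.intersection(bulk_totals.index)
    if len(shared) == 0:
        raise ValueError("reference and bulk gene sets are disjoint")
    x = ref_totals.loc[shared]
    y = bulk_totals.loc[shared]
    if (x < 0).any() or (y < 0).any():
        raise ValueError("totals must be non-negative")
    expressed = x > 0
    x = x[expressed]
    y = y.loc[x.index]
    x_norm = x / x.sum()
    y_norm = y / y.sum()
    return y_norm / x_norm


def apply_bias(profile: pd.DataFrame, bias: np.ndarray | pd.Series) -> pd.DataFrame:
    """Multiply each type's profile elementwise by the per-gene bias vector.

    Renormalization (per-type rows summing to 1) is the caller's
    responsibility and happens before simulation.
    """
    bias = np.asarray(bias, dtype=float)
    if bias.shape != (profile.shape[1],):
        raise ValueError(
            f"bias length {bias.shape} does not match {profile.shape[1]} genes"
        )
    return profile * bias[np.newaxis, :]


def simulate_bulk(
    profile: pd.DataFrame,
    ranges: ProportionRanges,
    n_samples: int,
    rng: np.random.Generator | int,
    depth_range: tuple[int, int] = DEFAULT_DEPTH_RANGE,
    bias: BiasModel | None = None,
    proportions: pd.DataFrame | None = None,
) -> SimulatedBulkSet:
    """Simulate a pseudo-bulk dataset from per-type normalized profiles.

    Per sample, the per-gene relative abundance is ``R_g = sum_k P_k
    X'_kg`` (renormalized), and counts are one multinomial draw of the
    sample's read depth over genes — exactly equivalent to assigning
    each read independently.  Depths are drawn as integers uniformly
    from the inclusive ``depth_range``.

    If ``bias`` is set, the profile is multiplied by the realized bias
    vector and renormalized per type before mixing.  Pass
    ``proportions`` to reuse fixed ground-truth proportions instead of
    drawing fresh ones.
    """
    seed = None
    if isinstance(rng, (int, np.integer)):
        seed = int(rng)
        rng = np.random.default_rng(seed)
    bias = bias or BiasModel("none")

    genes = profile.columns
    bias_vec = bias.draw(len(genes), rng)
    biased = apply_bias(profile, bias_vec)
    row_sums = biased.sum(axis=1)
    if (row_sums <= 0).any():
        raise ValueError("bias annihilated the whole profile of some cell type")
    biased = biased.div(row_sums, axis=0)

    if proportions is None:
        proportions = draw_proportions(ranges, n_samples, rng)
    else:
        proportions = proportions.copy()
    props = proportions[biased.index].to_numpy()  # sample x K, aligned

    mix = props @ biased.to_numpy()  # sample x G
    mix_sums = mix.sum(axis=1, keepdims=True)
    if (mix_sums <= 0).any():
        raise ValueError("all-zero relative-abundance vector in some sample")
    mix /= mix_sums

    lo, hi = depth_range
    depths = rng.integers(lo, hi + 1, size=len(proportions))
    counts = np.empty((len(proportions), len(genes)), dtype=np.int64)
    for j in range(len(proportions)):
        counts[j] = rng.multinomial(depths[j], mix[j])

    return SimulatedBulkSet(
        counts=pd.DataFrame(counts.T, index=genes, columns=proportions.index),
        true_proportions=proportions,
        bias_vector=pd.Series(bias_vec, index=genes, name="bias"),
        depths=pd.Series(depths, index=proportions.index, name="depth"),
        seed=seed,
    )
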