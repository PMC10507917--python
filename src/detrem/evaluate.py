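"""Accuracy metrics for deconvolution output.

Lin's concordance correlation coefficient (CCC) is the primary metric
when estimates and truth are two measurements of the same quantity: it
penalises location and scale shifts that Pearson's r ignores, so it is
1 only for identity agreement.  Pearson r and RMSE are reported
alongside, plus exact-zero call quantification (NNLS produces exact
zeros for inactive types, so a zero call is unambiguous) and min-max
scaled concordance against external per-sample measurements such as IHC
protein levels or marker-gene expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EvaluationReport",
    "ccc",
    "pearson",
    "rmse",
    "zero_calls",
    "scaled_concordance",
    "aggregate_neurons",
    "evaluate_against_truth",
]


def ccc(x, y) -> float:
    """Lin's concordance correlation coefficient with population (1/n) moments.

    ``2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2)``.
    Returns NaN when the denominator is zero (both vectors constant
    with equal means).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("ccc requires two equal-length 1-d vectors of length >= 2")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("ccc requires finite inputs")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()  # population variance
    cov = ((x - mx) * (y - my)).mean()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        return float("nan")
    return float(2 * cov / denom)


def pearson(x, y) -> float:
    """Product-moment correlation; NaN if either input is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def rmse(x, y) -> float:
    """Root mean squared difference between two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("rmse requires equal-length vectors")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def zero_calls(proportions: pd.DataFrame) -> pd.DataFrame:
    """Count exact-zero estimates per cell type.

    Returns a table with ``zero_count``, ``n_samples`` (non-NaN) and
    ``zero_fraction`` per type.  NaN rows (failed samples) are excluded
    from both numerator and denominator.
    """
    out = []
    for col in proportions.columns:
        vals = proportions[col].dropna()
        zeros = int((vals == 0).sum())
        out.append(
            {
                "cell_type": col,
                "zero_count": zeros,
                "n_samples": len(vals),
                "zero_fraction": zeros / len(vals) if len(vals) else float("nan"),
            }
        )
    return pd.DataFrame(out).set_index("cell_type")


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def scaled_concordance(
    estimates: pd.Series,
    external: pd.Series,
    drop_zeros: bool = True,
) -> dict:
    """Pearson r between min-max scaled estimates and external measurements.

    Samples are matched by id (intersection); samples with NaN on
    either side are dropped, and — when ``drop_zeros`` — samples whose
    estimate is exactly zero are excluded before scaling, mirroring the
    convention of evaluating concordance on non-zero estimates only.
    Both retained vectors are min-max scaled to [0, 1] (an affine map,
    so r itself is unchanged; scaling matters for plotting and for
    comparability of the vectors).  Returns ``{"r": ..., "n": ...,
    "reason": ...}``; r is NaN with a reason when fewer than 3 pairs
    remain.
    """
    est = pd.Series(estimates, dtype=float)
    ext = pd.Series(external, dtype=float)
    shared = est.index.intersection(ext.index)
    est = est.loc[shared]
    ext = ext.loc[shared]
    keep = est.notna() & ext.notna()
    if drop_zeros:
        keep &= est != 0
    est = est[keep]
    ext = ext[keep]
    if len(est) < 3:
        return {"r": float("nan"), "n": int(len(est)), "reason": "fewer than 3 retained pairs"}
    r = pearson(_minmax(est.to_numpy()), _minmax(ext.to_numpy()))
    return {"r": r, "n": int(len(est)), "reason": None}


def aggregate_neurons(
    proportions: pd.DataFrame,
    glutamatergic: str = "GLU",
    gabaergic: str = "GAB",
    combined: str = "NEU",
) -> pd.DataFrame:
    """Add a combined-neuron column ``NEU = GLU + GAB``.

    Original columns are retained; rows still sum to one when the
    combined column replaces its two parts in the sum.  Useful when an
    external measurement (e.g. NeuN) does not distinguish neuron
    subclasses.
    """
    for label in (glutamatergic, gabaergic):
        if label not in proportions.columns:
            raise ValueError(f"missing cell type {label!r}")
    out = proportions.copy()
    out[combined] = out[glutamatergic] + out[gabaergic]
    return out


@dataclass
class EvaluationReport:
    """Per-type metric table plus aggregate summaries."""

    per_type: pd.DataFrame  # columns: ccc, pearson_r, rmse, n_samples
    zero_table: pd.DataFrame
    mean_ccc: float
    mean_pearson: float
    mean_rmse: float

    def to_json_dict(self) -> dict:
        return {
            "per_type": self.per_type.reset_index().to_dict(orient="records"),
            "zero_calls": self.zero_table.reset_index().to_dict(orient="records"),
            "mean_ccc": self.mean_ccc,
            "mean_pearson": self.mean_pearson,
            "mean_rmse": self.mean_rmse,
        }


def evaluate_against_truth(
    estimates: pd.DataFrame,
    truth: pd.DataFrame,
) -> EvaluationReport:
    """Score sample x type estimates against ground-truth proportions.

    Samples are matched by index; per type, CCC, Pearson r and RMSE are
    computed over samples with a non-NaN estimate.  Aggregate means are
    unweighted arithmetic means across types, skipping NaN cells.
    """
    shared = estimates.index.intersection(truth.index)
    if len(shared) == 0:
        raise ValueError("no shared samples between estimates and truth")
    est = estimates.loc[shared]
    tru = truth.loc[shared]

    rows = []
    for col in est.columns:
        if col not in tru.columns:
            continue
        mask = est[col].notna() & tru[col].notna()
        e = est.loc[mask, col].to_numpy()
        t = tru.loc[mask, col].to_numpy()
        if len(e) >= 2:
            rows.append(
                {
                    "cell_type": col,
                    "ccc": ccc(t, e),
                    "pearson_r": pearson(t, e),
                    "rmse": rmse(t, e),
                    "n_samples": len(e),
                }
            )
        else:
            rows.append(
                {
                    "cell_type": col,
                    "ccc": float("nan"),
                    "pearson_r": float("nan"),
                    "rmse": float("nan"),
                    "n_samples": len(e),
                }
            )
    per_type = pd.DataFrame(rows).set_index("cell_type")
    return EvaluationReport(
        per_type=per_type,
        zero_table=zero_calls(est),
        mean_ccc=float(np.nanmean(per_type["ccc"])),
        mean_pearson=float(np.nanmean(per_type["pearson_r"])),
        mean_rmse=float(np.nanmean(per_type["rmse"])),
    )
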