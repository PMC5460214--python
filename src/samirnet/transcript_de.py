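"""Two-condition differential expression on single-replicate RPKM values.

The transcriptome compares one self-renewing (SR) and one senescent (SEN)
profile per gene, so the statistics are descriptive rather than inferential:
a log2 fold change FC = log2(SEN/SR), the plain RPKM difference
dRPKM = SEN - SR, and a composite ranking statistic

    D = sqrt(FC^2 + log2(|dRPKM|)^2)

that rewards genes which move strongly on both the ratio and the absolute
scale. For |dRPKM| < 1 the log term is clamped to 0 so D degrades to |FC|
and stays real near the origin. Genes are then assigned to the down/up
quadrants of an FC-vs-dRPKM plot using symmetric thresholds on both axes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DEThresholds",
    "compute_fc",
    "compute_drpkm",
    "compute_distance",
    "classify_quadrant",
    "rank_by_distance",
    "differential_expression",
    "round_half_away",
]


@dataclass(frozen=True)
class DEThresholds:
    """Quadrant-selection thresholds.

    fc_min : minimum |log2 fold change| (default 0.58, i.e. 1.5-fold)
    drpkm_min : minimum |RPKM difference| (default 5.0 RPKM)
    pseudocount : RPKM added to values below it before the ratio (default 0.01)
    """

    fc_min: float = 0.58
    drpkm_min: float = 5.0
    pseudocount: float = 0.01

    def __post_init__(self):
        if not (self.fc_min >= 0 and self.drpkm_min >= 0):
            raise ValueError("thresholds must be non-negative")
        if not self.pseudocount > 0:
            raise ValueError("pseudocount must be positive")


def _validate_nonneg(a, name):
    a = np.asarray(a, dtype=float)
    if not np.all(np.isfinite(a)) or np.any(a < 0):
        raise ValueError(f"{name} must be finite and non-negative")
    return a


def compute_fc(sr_rpkm, sen_rpkm, pseudocount: float = 0.01):
    """log2 fold change SEN/SR; a pseudocount guards near-zero inputs.

    The pseudocount is added to *both* values only when either falls below
    it, so well-expressed genes keep the exact ratio.
    """
    sr = _validate_nonneg(sr_rpkm, "sr_rpkm")
    sen = _validate_nonneg(sen_rpkm, "sen_rpkm")
    if not pseudocount > 0:
        raise ValueError("pseudocount must be positive")
    low = (sr < pseudocount) | (sen < pseudocount)
    fc = np.where(
        low,
        np.log2((sen + pseudocount) / (sr + pseudocount)),
        np.log2(np.where(low, 1.0, sen) / np.where(low, 1.0, sr)),
    )
    return fc if fc.ndim else float(fc)


def compute_drpkm(sr_rpkm, sen_rpkm):
    """Plain expression difference SEN - SR in RPKM."""
    sr = _validate_nonneg(sr_rpkm, "sr_rpkm")
    sen = _validate_nonneg(sen_rpkm, "sen_rpkm")
    d = sen - sr
    return d if d.ndim else float(d)


def compute_distance(fc, drpkm):
    """Euclidean ranking statistic combining FC and the log-scaled difference.

    D = sqrt(fc^2 + log2(|drpkm|)^2) with the log term clamped to 0 for
    |drpkm| < 1 (including 0), keeping D real and equal to |fc| near the
    origin.
    """
    fc = np.asarray(fc, dtype=float)
    drpkm = np.asarray(drpkm, dtype=float)
    mag = np.abs(drpkm)
    logterm = np.where(mag >= 1.0, np.log2(np.where(mag >= 1.0, mag, 1.0)), 0.0)
    d = np.sqrt(fc**2 + logterm**2)
    return d if d.ndim else float(d)


def classify_quadrant(fc, drpkm, thresholds: DEThresholds = DEThresholds()):
    """Assign 'down', 'up' or 'neither' from sign-concordant thresholds."""
    fc = np.asarray(fc, dtype=float)
    drpkm = np.asarray(drpkm, dtype=float)
    down = (fc <= -thresholds.fc_min) & (drpkm <= -thresholds.drpkm_min)
    up = (fc >= thresholds.fc_min) & (drpkm >= thresholds.drpkm_min)
    q = np.where(down, "down", np.where(up, "up", "neither"))
    return q if q.ndim else str(q)


def rank_by_distance(records: pd.DataFrame) -> pd.DataFrame:
    """Stable descending sort on D; ties broken by gene then transcript."""
    cols = ["distance", "gene_symbol"]
    ascending = [False, True]
    if "transcript_id" in records.columns:
        cols.append("transcript_id")
        ascending.append(True)
    return records.sort_values(cols, ascending=ascending, kind="mergesort").reset_index(
        drop=True
    )


def differential_expression(
    expression: pd.DataFrame, thresholds: DEThresholds = DEThresholds()
) -> pd.DataFrame:
    """Compute FC, dRPKM, D and quadrant for an expression table.

    Parameters
    ----------
    expression : DataFrame
        Columns ``gene_symbol, transcript_id (optional), sr_rpkm, sen_rpkm``.
    thresholds : DEThresholds

    Returns
    -------
    DataFrame ranked by descending D with added columns
    ``fc, drpkm, distance, quadrant``.
    """
    out = expression.copy()
    out["fc"] = compute_fc(out["sr_rpkm"], out["sen_rpkm"], thresholds.pseudocount)
    out["drpkm"] = compute_drpkm(out["sr_rpkm"], out["sen_rpkm"])
    out["distance"] = compute_distance(out["fc"], out["drpkm"])
    out["quadrant"] = classify_quadrant(out["fc"], out["drpkm"], thresholds)
    return rank_by_distance(out)


def round_half_away(x, ndigits: int = 2):
    """Round half away from zero, matching printed-table formatting."""
    x = np.asarray(x, dtype=float)
    scale = 10.0**ndigits
    r = np.copysign(np.floor(np.abs(x) * scale + 0.5) / scale, x)
    return r if r.ndim else float(r)
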