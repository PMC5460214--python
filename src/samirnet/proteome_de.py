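"""Replicate-level differential protein abundance between SR and SEN.

Each protein is tested with a two-tailed unpaired Student's t test
(pooled variance by default; Welch optional). Rows are summarised by the
-log10 p ranking and per-row z-scores across all samples for heatmap-style
display. No multiple-testing correction is applied by default because the
downstream integration consumes the raw p ranking; Benjamini-Hochberg is
available as a flag.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger("samirnet")

__all__ = [
    "protein_t_test",
    "row_zscores",
    "differential_abundance",
    "select_down_proteins",
]

_TINY_P = np.nextafter(0.0, 1.0)


def protein_t_test(sr_values, sen_values, equal_var: bool = True):
    """Two-tailed unpaired t test for one protein; returns (t, p).

    t is oriented as SEN - SR. Degenerate zero-variance rows yield
    (0, 1) when the group means agree and (+/-inf, smallest positive p)
    otherwise.
    """
    sr = np.asarray(sr_values, dtype=float)
    sen = np.asarray(sen_values, dtype=float)
    if sr.size < 2 or sen.size < 2:
        raise ValueError("need >=2 replicates per group")
    if not (np.all(np.isfinite(sr)) and np.all(np.isfinite(sen))):
        raise ValueError("intensities must be finite; imputation is not supported")
    if np.var(sr, ddof=1) == 0.0 and np.var(sen, ddof=1) == 0.0:
        if np.mean(sen) == np.mean(sr):
            return 0.0, 1.0
        log.warning("zero pooled variance with unequal means; p set to smallest positive")
        return float(np.sign(np.mean(sen) - np.mean(sr)) * np.inf), _TINY_P
    t, p = stats.ttest_ind(sen, sr, equal_var=equal_var)
    return float(t), float(max(p, _TINY_P))


def row_zscores(values):
    """Per-row z-scores across all samples (sample sd, n-1 denominator).

    An all-equal row maps to all zeros.
    """
    x = np.asarray(values, dtype=float)
    if x.shape[-1] < 2:
        raise ValueError("need >=2 values for a z-score")
    mu = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return z


def differential_abundance(
    matrix: pd.DataFrame,
    design: dict[str, str],
    equal_var: bool = True,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Test every protein row and attach summary statistics.

    Parameters
    ----------
    matrix : DataFrame
        Proteins x samples, index = protein id.
    design : dict
        Sample column -> group ("SR"/"SEN").
    equal_var : bool
        Pooled (True, default) vs Welch test.
    bh_correct : bool
        If True, an extra ``p_adj`` column holds Benjamini-Hochberg
        adjusted p-values (off by default).

    Returns
    -------
    DataFrame indexed by protein with columns ``mean_sr, mean_sen, t_stat,
    p_value, neg_log10_p, direction`` plus ``z_<sample>`` per sample,
    sorted by descending ``neg_log10_p``.
    """
    sr_cols = [c for c in matrix.columns if design.get(c) == "SR"]
    sen_cols = [c for c in matrix.columns if design.get(c) == "SEN"]
    if len(sr_cols) < 2 or len(sen_cols) < 2:
        raise ValueError("each group needs >=2 replicate columns")
    sr = matrix[sr_cols].to_numpy(float)
    sen = matrix[sen_cols].to_numpy(float)
    if not (np.all(np.isfinite(sr)) and np.all(np.isfinite(sen))):
        raise ValueError("missing/non-finite intensities are not allowed")

    t, p = stats.ttest_ind(sen, sr, axis=1, equal_var=equal_var)
    degen = (np.var(sr, axis=1, ddof=1) == 0) & (np.var(sen, axis=1, ddof=1) == 0)
    mean_sr, mean_sen = sr.mean(axis=1), sen.mean(axis=1)
    same = degen & (mean_sen == mean_sr)
    diff = degen & ~same
    t = np.where(same, 0.0, t)
    p = np.where(same, 1.0, np.where(diff, _TINY_P, p))
    t = np.where(diff, np.sign(mean_sen - mean_sr) * np.inf, t)
    if diff.any():
        log.warning("%d rows with zero pooled variance and unequal means", int(diff.sum()))
    p = np.clip(p, _TINY_P, 1.0)

    out = pd.DataFrame(
        {
            "mean_sr": mean_sr,
            "mean_sen": mean_sen,
            "t_stat": t,
            "p_value": p,
            "neg_log10_p": -np.log10(p),
            "direction": np.where(mean_sen < mean_sr, "down", "up"),
        },
        index=matrix.index,
    )
    if bh_correct:
        out["p_adj"] = _benjamini_hochberg(p)
    z = row_zscores(matrix[sr_cols + sen_cols].to_numpy(float))
    for j, col in enumerate(sr_cols + sen_cols):
        out[f"z_{col}"] = z[:, j]
    # ties on p broken by protein id for a reproducible ranking
    out = out.sort_index().sort_values("neg_log10_p", ascending=False, kind="mergesort")
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.clip(adj, 0, 1)
    return out


def select_down_proteins(records: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Proteins significantly lower in SEN, ranked by -log10 p descending."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    hit = records[(records["direction"] == "down") & (records["p_value"] < alpha)]
    hit = hit.sort_index().sort_values("neg_log10_p", ascending=False, kind="mergesort")
    return list(hit.index)
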