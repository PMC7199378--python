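"""Expression-side preprocessing and pseudo-time sanity statistics.

Pseudo-time itself is consumed as an input column (it is estimated upstream
from scRNA-seq by trajectory tools); this module covers the checks run
around it: TPM-based gene filtering, the log2(TPM+1) transform, Spearman /
Pearson correlation of gene expression with pseudo-time, and the Wilcoxon
rank-sum comparison of pseudo-times between culture groups.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TPM matrix (TSV, header row of sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError("TPM values must be non-negative")
    return df


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet (sample_id, group, pseudo_time)."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError("sample sheet must have a sample_id column")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in sample sheet")
    return df


def filter_genes_by_tpm(
    expr: pd.DataFrame, threshold: float = 1.0, min_fraction: float = 0.5
) -> pd.DataFrame:
    """Keep genes expressed above ``threshold`` in strictly more than
    ``min_fraction`` of samples (default: TPM > 1 in more than half)."""
    if expr.shape[1] < 1:
        raise ValueError("need at least one sample")
    n = expr.shape[1]
    keep = (expr > threshold).sum(axis=1) > min_fraction * n
    return expr.loc[keep]


def log_transform(expr: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2(TPM + 1)."""
    if (expr.to_numpy() < 0).any():
        raise ValueError("negative expression values")
    return np.log2(expr + 1.0)


def correlate_with_pseudotime(
    values: Sequence[float], y: Sequence[float], method: str = "spearman"
) -> float:
    """Correlation of one per-sample vector with pseudo-time.

    Spearman uses midranks for ties.  Returns NaN when either vector has zero
    variance (the coefficient is undefined there).
    """
    v = np.asarray(values, float)
    t = np.asarray(y, float)
    if v.shape != t.shape or v.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(v) == 0 or np.std(t) == 0:
        return float("nan")
    if method == "spearman":
        return float(stats.spearmanr(v, t).statistic)
    if method == "pearson":
        return float(stats.pearsonr(v, t).statistic)
    raise ValueError(f"unknown method {method!r}")


def correlate_genes(
    log_expr: pd.DataFrame, y: Sequence[float], method: str = "spearman"
) -> pd.Series:
    """Per-gene correlation with pseudo-time, sorted descending."""
    t = np.asarray(y, float)
    out = {
        gene: correlate_with_pseudotime(row.to_numpy(float), t, method=method)
        for gene, row in log_expr.iterrows()
    }
    return pd.Series(out, name=f"{method}_r").sort_values(ascending=False)


def compare_groups_ranksum(
    y: Sequence[float], group: Sequence[str]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of pseudo-time between two groups.

    Uses the exact null distribution when both groups have <= 10 observations
    and there are no ties, otherwise the normal approximation with continuity
    correction.  Returns ``(statistic, p_value)`` where the statistic is the
    Mann-Whitney U of the first group.
    """
    t = np.asarray(y, float)
    g = np.asarray(group)
    labels = pd.unique(g)
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {list(labels)}")
    a = t[g == labels[0]]
    b = t[g == labels[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(t)) < len(t)
    method = "exact" if (len(a) <= 10 and len(b) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)
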