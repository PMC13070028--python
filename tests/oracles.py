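"""Independent brute-force oracles used by the tests.

Everything here is written from the textbook definitions with explicit
loops, deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import numpy as np


def anova_two_way(table: np.ndarray) -> dict:
    """Two-way ANOVA (subjects x raters, one observation per cell) by loops."""
    t = np.asarray(table, dtype=float)
    n, k = t.shape
    grand = t.sum() / (n * k)
    ss_rows = 0.0
    for p in range(n):
        ss_rows += k * (t[p].sum() / k - grand) ** 2
    ss_cols = 0.0
    for s in range(k):
        ss_cols += n * (t[:, s].sum() / n - grand) ** 2
    ss_err = 0.0
    for p in range(n):
        for s in range(k):
            row_m = t[p].sum() / k
            col_m = t[:, s].sum() / n
            ss_err += (t[p, s] - row_m - col_m + grand) ** 2
    return {
        "ms_rows": ss_rows / (n - 1),
        "ms_cols": ss_cols / (k - 1),
        "ms_err": ss_err / ((n - 1) * (k - 1)),
        "ss_rows": ss_rows,
        "ss_cols": ss_cols,
        "ss_err": ss_err,
    }


def icc_c1_oracle(table: np.ndarray) -> float:
    """Raw ICC(C,1): (MS_rows - MS_err) / (MS_rows + (k-1) MS_err)."""
    t = np.asarray(table, dtype=float)
    k = t.shape[1]
    a = anova_two_way(t)
    return (a["ms_rows"] - a["ms_err"]) / (a["ms_rows"] + (k - 1) * a["ms_err"])


def wscv_k2_oracle(x1: float, x2: float) -> float:
    """Closed-form within-subject CV (%) for one subject with 2 scanners."""
    sd = abs(x1 - x2) / np.sqrt(2.0)
    denom = (abs(x1) + abs(x2)) / 2.0
    return sd / denom * 100.0


def ems_components_oracle(table: np.ndarray) -> tuple[float, float, float]:
    """Expected-mean-squares variance components with zero truncation:
    (sigma2_subject, sigma2_scanner, sigma2_residual)."""
    t = np.asarray(table, dtype=float)
    n, k = t.shape
    a = anova_two_way(t)
    s2e = a["ms_err"]
    s2p = max(0.0, (a["ms_rows"] - s2e) / k)
    s2s = max(0.0, (a["ms_cols"] - s2e) / n)
    return s2p, s2s, s2e


def pearson_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r from the raw definition."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))
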