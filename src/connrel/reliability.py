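"""Edge-level subject reliability: ICC(C,1) and within-subject CV.

ICC(C,1) is the two-way random-effects, consistency, single-measurement
intraclass correlation: from the two-way ANOVA of the n_subjects x
n_scanners table,

    ICC = (MS_subjects - MS_error) / (MS_subjects + (k - 1) MS_error)

with k scanners and MS_error the residual mean square after removing both
main effects. Consistency means per-scanner constant offsets do not hurt
the estimate. Negative estimates are truncated at zero (the raw value is
retained for audit, since truncation inflates apparent reliability).

The within-subject coefficient of variation (wsCV) is, per subject, the
sample SD across scanners divided by the mean of absolute values across
scanners, expressed in percent, then averaged over subjects. With k = 2
the per-subject value is |x1 - x2| / sqrt(2) / ((|x1| + |x2|) / 2) * 100.
Subjects whose mean absolute value is zero have an undefined ratio and are
dropped from the average with a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .data import BlockMatrix, CohortDataset, Partition, block_aggregate
from .errors import ValidationError


def _check_table(table: np.ndarray) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValidationError(f"expected a subjects x scanners table, got {t.ndim}-D")
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValidationError(f"need >= 2 subjects and >= 2 scanners, got {t.shape}")
    if np.isnan(t).any():
        raise ValidationError("table contains NaN (crossed design must be complete)")
    return t


def _anova_ss(tables: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-way ANOVA sums of squares for a stack of balanced tables.

    ``tables`` is (..., n_subjects, n_scanners); returns (SS_subjects,
    SS_scanners, SS_error) with matching leading shape."""
    grand = tables.mean(axis=(-2, -1), keepdims=True)
    row = tables.mean(axis=-1, keepdims=True)
    col = tables.mean(axis=-2, keepdims=True)
    k = tables.shape[-1]
    s = tables.shape[-2]
    ss_sub = k * ((row - grand) ** 2).sum(axis=(-2, -1))
    ss_sca = s * ((col - grand) ** 2).sum(axis=(-2, -1))
    resid = tables - row - col + grand
    ss_err = (resid**2).sum(axis=(-2, -1))
    return ss_sub, ss_sca, ss_err


def icc_c1(table: np.ndarray) -> tuple[float, float]:
    """ICC(C,1) for one fully crossed table.

    Returns ``(icc_raw, icc)`` where icc = max(icc_raw, 0). A table with
    zero total variance has an undefined ICC and returns (nan, nan)."""
    t = _check_table(table)
    raw = _icc_raw_stack(t[None, :, :])[0]
    if np.isnan(raw):
        return float("nan"), float("nan")
    return float(raw), float(max(raw, 0.0))


def _icc_raw_stack(tables: np.ndarray) -> np.ndarray:
    s, k = tables.shape[-2], tables.shape[-1]
    ss_sub, ss_sca, ss_err = _anova_ss(tables)
    total = ss_sub + ss_sca + ss_err
    ms_sub = ss_sub / (s - 1)
    ms_err = ss_err / ((s - 1) * (k - 1))
    denom = ms_sub + (k - 1) * ms_err
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = (ms_sub - ms_err) / denom
    raw = np.where(total <= 0, np.nan, raw)
    # perfectly consistent tables (MS_err == 0, MS_sub > 0) -> ICC = 1
    raw = np.where((total > 0) & (denom == 0), np.nan, raw)
    return raw


def wscv(table: np.ndarray) -> float:
    """Within-subject CV in percent for one fully crossed table (see module
    docstring). Returns nan when no subject has a defined ratio."""
    t = _check_table(table)
    sd = t.std(axis=1, ddof=1)
    denom = np.abs(t).mean(axis=1)
    valid = denom > 0
    if not valid.any():
        return float("nan")
    return float(np.mean(sd[valid] / denom[valid]) * 100.0)


def _wscv_stack(tables: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised wsCV over (E, S, K) stacks; returns (wscv%, n_dropped)."""
    sd = tables.std(axis=-1, ddof=1)
    denom = np.abs(tables).mean(axis=-1)
    valid = denom > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(valid, sd / np.where(valid, denom, 1.0), np.nan)
    n_valid = valid.sum(axis=-1)
    out = np.where(n_valid > 0, np.nansum(ratio, axis=-1) / np.maximum(n_valid, 1), np.nan)
    return out * 100.0, tables.shape[-2] - n_valid


@dataclass
class EdgeReliability:
    """Per-edge reliability metrics over a cohort, with QC flags."""

    icc_raw: np.ndarray        # may be negative or nan
    icc: np.ndarray            # truncated at 0; nan where undefined
    wscv_percent: np.ndarray   # nan where undefined
    n_subjects: int
    n_scanners: int
    zero_variance: np.ndarray  # bool, ICC undefined (no total variance)
    wscv_dropped_subjects: np.ndarray  # per edge, subjects dropped for zero |x| mean

    @property
    def n_truncated(self) -> int:
        return int(np.sum(self.icc_raw < 0))

    def summary(self) -> dict:
        out: dict = {"n_subjects": self.n_subjects, "n_scanners": self.n_scanners}
        for name, arr in (("icc", self.icc), ("wscv_percent", self.wscv_percent)):
            good = arr[~np.isnan(arr)]
            out[name] = {
                "mean": float(np.mean(good)) if good.size else None,
                "sd": float(np.std(good, ddof=1)) if good.size > 1 else None,
                "min": float(np.min(good)) if good.size else None,
                "max": float(np.max(good)) if good.size else None,
                "n_defined": int(good.size),
            }
        out["n_icc_truncated"] = self.n_truncated
        return out


def reliability_table(data: CohortDataset) -> EdgeReliability:
    """ICC(C,1) and wsCV for every edge of a crossed cohort.

    Per-edge degeneracies (zero variance, zero-mean subjects) are flagged,
    never fatal."""
    edges = np.moveaxis(data.edges, 2, 0)  # (E, S, K)
    icc_raw = _icc_raw_stack(edges)
    icc = np.where(np.isnan(icc_raw), np.nan, np.maximum(icc_raw, 0.0))
    ws, dropped = _wscv_stack(edges)
    return EdgeReliability(
        icc_raw=icc_raw,
        icc=icc,
        wscv_percent=ws,
        n_subjects=data.n_subjects,
        n_scanners=data.n_scanners,
        zero_variance=np.isnan(icc_raw),
        wscv_dropped_subjects=dropped,
    )


def reliability_blocks(
    rel: EdgeReliability,
    partition: Partition,
    by: Literal["network", "lobe"] = "network",
    reducer: Literal["mean", "median"] = "mean",
) -> dict[str, BlockMatrix]:
    """Block-aggregated ICC and wsCV heat-map matrices."""
    return {
        "icc": block_aggregate(rel.icc, partition, by=by, reducer=reducer),
        "wscv_percent": block_aggregate(rel.wscv_percent, partition, by=by, reducer=reducer),
    }
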