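"""Group-level agreement and pattern similarity between scanners.

Bland-Altman analysis on edge values: differences d = x_a - x_b against
means m = (x_a + x_b) / 2, with the limits of agreement md +/- 1.96 * sd(d)
(large-sample normal quantile, standard Bland-Altman practice) and a
proportional-bias slope from the ordinary least-squares regression of d on
m. By default one point per edge, using subject-averaged values per
scanner; the difference direction is first-listed scanner minus second.

Pattern similarity is the Pearson correlation (PCC) between two vectorised
connectomes — at the group level between subject-averaged connectomes, at
the subject level per participant (reported per subject plus the mean) —
optionally restricted to the edge set of a network/lobe block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .data import CohortDataset, Partition, edge_block_labels
from .errors import ValidationError

LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class AgreementSummary:
    """Bland-Altman summary for one stratum of edges."""

    stratum: str
    mean_difference: float
    sd_difference: float
    lower_loa: float
    upper_loa: float
    bias_slope: float          # nan when undefined (constant means or n < 3)
    bias_intercept: float
    n_points: int

    @property
    def slope_defined(self) -> bool:
        return not np.isnan(self.bias_slope)


def _ba_one(d: np.ndarray, m: np.ndarray, stratum: str) -> AgreementSummary:
    md = float(np.mean(d))
    sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    slope = intercept = float("nan")
    if d.size >= 3 and np.ptp(m) > 0:
        slope, intercept = np.polyfit(m, d, 1)
    return AgreementSummary(
        stratum=stratum,
        mean_difference=md,
        sd_difference=sd,
        lower_loa=md - LOA_MULTIPLIER * sd,
        upper_loa=md + LOA_MULTIPLIER * sd,
        bias_slope=float(slope),
        bias_intercept=float(intercept),
        n_points=int(d.size),
    )


def bland_altman(
    x_a: np.ndarray,
    x_b: np.ndarray,
    strata: np.ndarray | None = None,
) -> dict[str, AgreementSummary]:
    """Bland-Altman per stratum (plus 'full' over all points).

    ``strata`` is an optional per-point label array; without it only the
    full-sample summary is returned."""
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    if x_a.shape != x_b.shape or x_a.ndim != 1:
        raise ValidationError(
            f"inputs must be equal-length 1-D vectors, got {x_a.shape} and {x_b.shape}"
        )
    if x_a.size < 1:
        raise ValidationError("empty input vectors")
    d = x_a - x_b
    m = (x_a + x_b) / 2.0
    out = {"full": _ba_one(d, m, "full")}
    if strata is not None:
        strata = np.asarray(strata)
        if strata.shape != x_a.shape:
            raise ValidationError("strata labels must align with the input vectors")
        for lab in sorted(set(strata.tolist())):
            sel = strata == lab
            out[str(lab)] = _ba_one(d[sel], m[sel], str(lab))
    return out


def bland_altman_cohort(
    data: CohortDataset,
    scanner_a: str | None = None,
    scanner_b: str | None = None,
    by: Literal["network", "lobe", None] = None,
    pooled: bool = False,
) -> dict[str, AgreementSummary]:
    """Bland-Altman between two scanners of a cohort.

    Default: one point per edge from subject-averaged connectomes; with
    ``pooled=True`` every (subject, edge) pair contributes a point. ``by``
    stratifies edges by the network/lobe block of their endpoints
    (within-block as 'NET', between-block as 'NET1-NET2')."""
    a, b = _resolve_scanners(data, scanner_a, scanner_b)
    ia, ib = data.scanners.index(a), data.scanners.index(b)
    if pooled:
        x_a = data.edges[:, ia, :].reshape(-1)
        x_b = data.edges[:, ib, :].reshape(-1)
    else:
        x_a = data.edges[:, ia, :].mean(axis=0)
        x_b = data.edges[:, ib, :].mean(axis=0)
    strata = None
    if by is not None:
        strata = _edge_strata(data.partition, by)
        if pooled:
            strata = np.tile(strata, data.n_subjects)
    return bland_altman(x_a, x_b, strata)


def _edge_strata(partition: Partition, by: Literal["network", "lobe"]) -> np.ndarray:
    lo, hi, uniq = edge_block_labels(partition, by)
    labs = np.asarray(uniq)
    return np.where(
        lo == hi, labs[lo], np.char.add(np.char.add(labs[lo], "-"), labs[hi])
    )


def _resolve_scanners(
    data: CohortDataset, scanner_a: str | None, scanner_b: str | None
) -> tuple[str, str]:
    if scanner_a is None and scanner_b is None:
        if data.n_scanners != 2:
            raise ValidationError(
                "scanner pair must be named explicitly when the cohort has "
                f"{data.n_scanners} scanners"
            )
        return data.scanners[0], data.scanners[1]
    if scanner_a is None or scanner_b is None:
        raise ValidationError("name both scanners or neither")
    for s in (scanner_a, scanner_b):
        if s not in data.scanners:
            raise ValidationError(f"unknown scanner {s!r}; cohort has {data.scanners}")
    return scanner_a, scanner_b


# ---------------------------------------------------------------------------
# Pattern similarity


@dataclass(frozen=True)
class SimilaritySummary:
    """PCC pattern similarity between two scanners for one edge scope."""

    level: Literal["group", "subject"]
    scope: str                       # 'full' or a block label
    pcc: float                       # group-level r, or mean over subjects
    per_subject: dict[str, float] = field(default_factory=dict)
    n_edges: int = 0


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def pattern_similarity(
    data: CohortDataset,
    level: Literal["group", "subject"] = "group",
    scanner_a: str | None = None,
    scanner_b: str | None = None,
    edge_mask: np.ndarray | None = None,
    scope: str = "full",
) -> SimilaritySummary:
    """PCC between the two scanners' connectomes.

    group: r between subject-averaged edge vectors. subject: per-subject r
    between that subject's two connectomes, aggregated as the mean.
    ``edge_mask`` restricts the computation to a block's edge set."""
    a, b = _resolve_scanners(data, scanner_a, scanner_b)
    ia, ib = data.scanners.index(a), data.scanners.index(b)
    mask = np.ones(data.n_edges, dtype=bool) if edge_mask is None else np.asarray(edge_mask, bool)
    if mask.shape != (data.n_edges,):
        raise ValidationError("edge_mask must align with the edge vector")
    if level == "group":
        r = _safe_pearson(
            data.edges[:, ia, mask].mean(axis=0), data.edges[:, ib, mask].mean(axis=0)
        )
        return SimilaritySummary(level="group", scope=scope, pcc=r, n_edges=int(mask.sum()))
    if level == "subject":
        per = {
            subj: _safe_pearson(data.edges[p, ia, mask], data.edges[p, ib, mask])
            for p, subj in enumerate(data.subjects)
        }
        vals = np.array([v for v in per.values() if not np.isnan(v)])
        mean_r = float(np.mean(vals)) if vals.size else float("nan")
        return SimilaritySummary(
            level="subject", scope=scope, pcc=mean_r, per_subject=per, n_edges=int(mask.sum())
        )
    raise ValidationError(f"unknown level {level!r}")


def pattern_similarity_blocks(
    data: CohortDataset,
    by: Literal["network", "lobe"] = "network",
    level: Literal["group", "subject"] = "group",
    scanner_a: str | None = None,
    scanner_b: str | None = None,
) -> pd.DataFrame:
    """PCC per network/lobe block pair (within- and between-block edge sets).

    Returns a tidy frame with columns block_a, block_b, within, pcc, n_edges."""
    lo, hi, uniq = edge_block_labels(data.partition, by)
    rows = []
    for a_i in range(len(uniq)):
        for b_i in range(a_i, len(uniq)):
            mask = (lo == a_i) & (hi == b_i)
            if not mask.any():
                continue
            sim = pattern_similarity(
                data,
                level=level,
                scanner_a=scanner_a,
                scanner_b=scanner_b,
                edge_mask=mask,
                scope=f"{uniq[a_i]}-{uniq[b_i]}",
            )
            rows.append(
                {
                    "block_a": uniq[a_i],
                    "block_b": uniq[b_i],
                    "within": a_i == b_i,
                    "pcc": sim.pcc,
                    "n_edges": sim.n_edges,
                }
            )
    return pd.DataFrame(rows)
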