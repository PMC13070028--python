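"""Functional-connectivity construction and motion QC.

From cleaned regional BOLD series to a Fisher-z connectivity matrix:
pairwise Pearson correlation between region time series, r-to-z transform,
with high-motion volumes (framewise displacement > 0.5 mm) censored before
correlation and an exclusion rule for acquisitions with more than 30% of
volumes scrubbed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import ConnMatrix
from .errors import DegenerateSignalError, ValidationError

FD_THRESHOLD_MM = 0.5
MAX_SCRUB_FRACTION = 0.30


def pearson_fc(
    series: np.ndarray, region_ids: Sequence[str] | None = None
) -> np.ndarray:
    """Pairwise Pearson correlation matrix of regional time series.

    ``series`` is (n_regions, n_timepoints); the diagonal is set to 0 by
    convention (self-connections carry no information)."""
    ts = np.asarray(series, dtype=float)
    if ts.ndim != 2:
        raise ValidationError(f"time series must be 2-D (region x time), got {ts.ndim}-D")
    n, t = ts.shape
    if t < 3:
        raise ValidationError(f"need at least 3 timepoints, got {t}")
    if np.isnan(ts).any():
        raise ValidationError("time series contains NaN")
    sd = ts.std(axis=1)
    if np.any(sd == 0):
        ids = list(region_ids) if region_ids is not None else [str(i) for i in range(n)]
        bad = [ids[i] for i in np.flatnonzero(sd == 0)]
        raise DegenerateSignalError(f"zero-variance time series for region(s): {bad}")
    r = np.corrcoef(ts)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return r


def fisher_z(r):
    """Fisher r-to-z transform, z = atanh(r); odd and strictly increasing.

    Defined for |r| < 1 only (the diagonal r = 1 is excluded upstream)."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValidationError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ScrubResult:
    """Outcome of the motion-censoring rule for one acquisition."""

    flagged: np.ndarray          # indices of volumes with FD > threshold
    n_volumes: int
    fd_threshold: float
    scrub_fraction: float
    max_scrub_fraction: float
    keep_dataset: bool


def scrub_qc(
    fd: np.ndarray,
    fd_threshold: float = FD_THRESHOLD_MM,
    max_scrub_fraction: float = MAX_SCRUB_FRACTION,
) -> ScrubResult:
    """Flag volumes with FD strictly greater than the threshold and decide
    whether to keep the acquisition.

    The dataset is discarded only when the flagged fraction is strictly
    greater than ``max_scrub_fraction`` — exactly 30% scrubbed is kept."""
    fd = np.asarray(fd, dtype=float)
    if fd.ndim != 1 or fd.size < 1:
        raise ValidationError("FD trace must be a nonempty 1-D array")
    if np.any(fd < 0) or np.isnan(fd).any():
        raise ValidationError("FD values must be nonnegative and finite")
    flagged = np.flatnonzero(fd > fd_threshold)
    frac = flagged.size / fd.size
    return ScrubResult(
        flagged=flagged,
        n_volumes=int(fd.size),
        fd_threshold=float(fd_threshold),
        scrub_fraction=float(frac),
        max_scrub_fraction=float(max_scrub_fraction),
        keep_dataset=bool(frac <= max_scrub_fraction),
    )


def fc_from_timeseries(
    series: np.ndarray,
    fd: np.ndarray | None = None,
    region_ids: Sequence[str] | None = None,
    subject_id: str = "",
    scanner_id: str = "",
    fd_threshold: float = FD_THRESHOLD_MM,
    max_scrub_fraction: float = MAX_SCRUB_FRACTION,
) -> tuple[ConnMatrix, ScrubResult | None]:
    """Full FC construction for one acquisition.

    High-motion volumes are removed (censored, no interpolation) under a
    single joint mask for all regions, then pairwise Pearson r and the
    Fisher r-to-z transform produce the z-scale connectivity matrix. When
    the scrub fraction exceeds the exclusion limit the acquisition fails QC
    and a ValidationError is raised; callers wanting the decision without
    the exception should call :func:`scrub_qc` directly."""
    ts = np.asarray(series, dtype=float)
    qc = None
    if fd is not None:
        fd = np.asarray(fd, dtype=float)
        if fd.size != ts.shape[1]:
            raise ValidationError(
                f"FD trace length {fd.size} does not match {ts.shape[1]} volumes"
            )
        qc = scrub_qc(fd, fd_threshold, max_scrub_fraction)
        if not qc.keep_dataset:
            raise ValidationError(
                f"acquisition fails motion QC: {qc.scrub_fraction:.1%} of volumes "
                f"scrubbed (> {max_scrub_fraction:.0%})"
            )
        keep = np.ones(ts.shape[1], dtype=bool)
        keep[qc.flagged] = False
        ts = ts[:, keep]
    r = pearson_fc(ts, region_ids)
    iu = np.triu_indices(r.shape[0], k=1)
    z = np.zeros_like(r)
    z[iu] = fisher_z(r[iu])
    z += z.T
    m = ConnMatrix(values=z, modality="FC", subject_id=subject_id, scanner_id=scanner_id)
    return m, qc
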