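"""One-facet G-theory variance decomposition.

Each edge's observed score X_ps for participant p on scanner s is modelled
with crossed random intercepts,

    sigma^2(X_ps) = sigma^2_p + sigma^2_s + sigma^2_ps,e

where sigma^2_p is true inter-subject variance, sigma^2_s the systematic
scanner effect, and sigma^2_ps,e the confounded participant x scanner
interaction plus random error (a one-facet crossed design cannot separate
the two). Components are reported as percentages of the total.

Two estimators:

* ``mom`` — expected-mean-squares (ANOVA) solution: sigma^2_res = MS_E,
  sigma^2_p = (MS_P - MS_E)/k, sigma^2_s = (MS_S - MS_E)/n, each truncated
  at zero (truncation is recorded, since with k = 2 scanners the raw
  per-edge scanner estimate is very noisy and goes negative about half the
  time under a null scanner effect).
* ``reml`` — restricted maximum likelihood with components bounded at zero,
  the mixed-model estimator. For a balanced crossed design the restricted
  likelihood is diagonal in the ANOVA strata

      -2 lR = (n-1) ln lP + SS_P / lP + (k-1) ln lS + SS_S / lS
              + (n-1)(k-1) ln lE + SS_E / lE      (+ const)

  with lP = k sigma^2_p + sigma^2_e, lS = n sigma^2_s + sigma^2_e,
  lE = sigma^2_e, so the optimum is closed-form: the ANOVA estimates when
  they are interior, otherwise the best of the boundary profiles
  (sigma^2_p = 0 and/or sigma^2_s = 0), each of which is itself
  closed-form. No iteration is needed, and the result matches lme4's REML
  fit of the same model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .data import BlockMatrix, CohortDataset, Partition, block_aggregate
from .errors import ValidationError
from .reliability import _anova_ss, _check_table

Estimator = Literal["reml", "mom"]


@dataclass
class VarianceComponents:
    """Per-edge (or per-table) variance decomposition."""

    sigma2_p: np.ndarray
    sigma2_s: np.ndarray
    sigma2_res: np.ndarray
    estimator: Estimator
    truncated_p: np.ndarray      # raw subject estimate was negative (mom)
    truncated_s: np.ndarray      # raw scanner estimate was negative (mom)
    zero_variance: np.ndarray    # all values identical; components undefined

    @property
    def total(self) -> np.ndarray:
        return self.sigma2_p + self.sigma2_s + self.sigma2_res

    @property
    def fractions_percent(self) -> np.ndarray:
        """(..., 3) array of (subject, scanner, residual) percentages."""
        total = self.total
        with np.errstate(invalid="ignore", divide="ignore"):
            out = (
                np.stack([self.sigma2_p, self.sigma2_s, self.sigma2_res], axis=-1)
                / total[..., None]
                * 100.0
            )
        out = np.where((total > 0)[..., None], out, np.nan)
        return np.where(self.zero_variance[..., None], np.nan, out)


def _mom_stack(ss_p, ss_s, ss_e, n, k):
    ms_p = ss_p / (n - 1)
    ms_s = ss_s / (k - 1)
    ms_e = ss_e / ((n - 1) * (k - 1))
    raw_p = (ms_p - ms_e) / k
    raw_s = (ms_s - ms_e) / n
    return np.maximum(raw_p, 0.0), np.maximum(raw_s, 0.0), ms_e, raw_p < 0, raw_s < 0


def _reml_crit(ss_p, ss_s, ss_e, n, k, s2p, s2s, s2e):
    """-2 x restricted log-likelihood (up to a constant) on the ANOVA strata."""
    lp = k * s2p + s2e
    ls = n * s2s + s2e
    le = s2e
    with np.errstate(divide="ignore", invalid="ignore"):
        return (
            (n - 1) * np.log(lp)
            + ss_p / lp
            + (k - 1) * np.log(ls)
            + ss_s / ls
            + (n - 1) * (k - 1) * np.log(le)
            + ss_e / le
        )


def _reml_stack(ss_p, ss_s, ss_e, n, k):
    """Closed-form bounded REML for stacks of balanced tables.

    Evaluates the four candidate optima (interior, sigma_s = 0, sigma_p = 0,
    both zero) and keeps the feasible one with the best restricted
    likelihood."""
    ms_p = ss_p / (n - 1)
    ms_s = ss_s / (k - 1)
    ms_e = ss_e / ((n - 1) * (k - 1))

    cand = []  # (s2p, s2s, s2e, criterion)

    # interior: ANOVA estimates (valid where both components nonnegative)
    s2e = ms_e
    s2p = (ms_p - ms_e) / k
    s2s = (ms_s - ms_e) / n
    crit = _reml_crit(ss_p, ss_s, ss_e, n, k, np.maximum(s2p, 0), np.maximum(s2s, 0), s2e)
    crit = np.where((s2p >= 0) & (s2s >= 0), crit, np.inf)
    cand.append((np.maximum(s2p, 0), np.maximum(s2s, 0), s2e, crit))

    # sigma_s = 0: scanner and error strata share lE
    s2e = (ss_s + ss_e) / ((k - 1) + (n - 1) * (k - 1))
    s2p = np.maximum((ms_p - s2e) / k, 0.0)
    cand.append(
        (s2p, np.zeros_like(s2e), s2e, _reml_crit(ss_p, ss_s, ss_e, n, k, s2p, 0.0, s2e))
    )

    # sigma_p = 0
    s2e = (ss_p + ss_e) / ((n - 1) + (n - 1) * (k - 1))
    s2s = np.maximum((ms_s - s2e) / n, 0.0)
    cand.append(
        (np.zeros_like(s2e), s2s, s2e, _reml_crit(ss_p, ss_s, ss_e, n, k, 0.0, s2s, s2e))
    )

    # sigma_p = sigma_s = 0
    s2e = (ss_p + ss_s + ss_e) / (n * k - 1)
    zero = np.zeros_like(s2e)
    cand.append((zero, zero, s2e, _reml_crit(ss_p, ss_s, ss_e, n, k, 0.0, 0.0, s2e)))

    crits = np.stack([c[3] for c in cand], axis=0)
    crits = np.where(np.isfinite(crits), crits, np.inf)
    best = np.argmin(crits, axis=0)
    s2p = np.choose(best, [c[0] for c in cand])
    s2s = np.choose(best, [c[1] for c in cand])
    s2e = np.choose(best, [c[2] for c in cand])
    return s2p, s2s, s2e


def gstudy_edge(table: np.ndarray, estimator: Estimator = "reml") -> VarianceComponents:
    """Variance components for one n_subjects x n_scanners table."""
    t = _check_table(table)
    return _gstudy_stack(t[None, :, :], estimator)


def _gstudy_stack(tables: np.ndarray, estimator: Estimator) -> VarianceComponents:
    if estimator not in ("reml", "mom"):
        raise ValidationError(f"unknown estimator {estimator!r}")
    n, k = tables.shape[-2], tables.shape[-1]
    ss_p, ss_s, ss_e = _anova_ss(tables)
    total_ss = ss_p + ss_s + ss_e
    zero = total_ss <= 0

    raw_p, raw_s, _, trunc_p, trunc_s = _mom_stack(ss_p, ss_s, ss_e, n, k)
    ms_e = ss_e / ((n - 1) * (k - 1))
    if estimator == "mom":
        s2p, s2s, s2e = raw_p, raw_s, ms_e
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            s2p, s2s, s2e = _reml_stack(ss_p, ss_s, ss_e, n, k)
        # degenerate error stratum (SS_E = 0): the restricted likelihood is
        # unbounded at sigma_e -> 0; the ANOVA solution is the limit
        degen = ss_e <= 0
        if np.any(degen):
            s2p = np.where(degen, raw_p, s2p)
            s2s = np.where(degen, raw_s, s2s)
            s2e = np.where(degen, ms_e, s2e)
    s2p = np.where(zero, np.nan, s2p)
    s2s = np.where(zero, np.nan, s2s)
    s2e = np.where(zero, np.nan, s2e)
    return VarianceComponents(
        sigma2_p=s2p,
        sigma2_s=s2s,
        sigma2_res=s2e,
        estimator=estimator,
        truncated_p=trunc_p & ~zero,
        truncated_s=trunc_s & ~zero,
        zero_variance=zero,
    )


@dataclass
class GStudyResult:
    """Cohort-level G-study: per-edge components plus summaries."""

    components: VarianceComponents
    n_subjects: int
    n_scanners: int

    def summary(self) -> dict:
        """Mean +/- SD of the per-edge percentage fractions over defined edges
        (per-edge percentages first, then averaged)."""
        frac = self.components.fractions_percent
        good = ~np.isnan(frac[:, 0])
        out = {}
        for i, name in enumerate(("subject", "scanner", "residual")):
            vals = frac[good, i]
            out[f"{name}_pct"] = {
                "mean": float(np.mean(vals)) if vals.size else None,
                "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else None,
            }
        out["n_edges_defined"] = int(good.sum())
        out["n_truncated_subject"] = int(self.components.truncated_p.sum())
        out["n_truncated_scanner"] = int(self.components.truncated_s.sum())
        out["estimator"] = self.components.estimator
        return out

    def pooled_fractions_percent(self) -> np.ndarray:
        """Alternative summary: fractions of the pooled (summed) components."""
        c = self.components
        good = ~c.zero_variance
        comp = np.array(
            [c.sigma2_p[good].sum(), c.sigma2_s[good].sum(), c.sigma2_res[good].sum()]
        )
        return comp / comp.sum() * 100.0


def gstudy_table(data: CohortDataset, estimator: Estimator = "reml") -> GStudyResult:
    """Per-edge variance decomposition for a crossed cohort."""
    tables = np.moveaxis(data.edges, 2, 0)  # (E, S, K)
    comp = _gstudy_stack(tables, estimator)
    return GStudyResult(components=comp, n_subjects=data.n_subjects, n_scanners=data.n_scanners)


def gstudy_blocks(
    result: GStudyResult,
    partition: Partition,
    by: Literal["network", "lobe"] = "network",
) -> dict[str, BlockMatrix]:
    """Block-aggregated mean percentage per component."""
    frac = result.components.fractions_percent
    return {
        name: block_aggregate(frac[:, i], partition, by=by, reducer="mean")
        for i, name in enumerate(("subject_pct", "scanner_pct", "residual_pct"))
    }


def scanner_variance_report(
    before: CohortDataset,
    after: CohortDataset,
    estimator: Estimator = "mom",
) -> dict:
    """Paired scanner-variance fractions before vs after harmonisation."""
    if before.edges.shape != after.edges.shape or before.scanners != after.scanners:
        raise ValidationError("before/after datasets must share the same design")
    g_before = gstudy_table(before, estimator)
    g_after = gstudy_table(after, estimator)
    fb = g_before.components.fractions_percent[:, 1]
    fa = g_after.components.fractions_percent[:, 1]
    return {
        "scanner_pct_before": fb,
        "scanner_pct_after": fa,
        "mean_before": float(np.nanmean(fb)),
        "mean_after": float(np.nanmean(fa)),
        "summary_before": g_before.summary(),
        "summary_after": g_after.summary(),
    }
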