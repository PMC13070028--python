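"""Empirical-Bayes location-scale harmonisation (ComBat) of edge tables.

The model for edge v of observation j in batch (scanner) i is

    y_ijv = alpha_v + X_j beta_v + gamma_iv + delta_iv eps_ijv

where alpha_v is the edge intercept, X the covariate design (age, sex,
days between scans, scan daytime), gamma_iv and delta_iv the additive and
multiplicative batch effects, and eps ~ N(0, sigma^2_v). Batch-effect
estimates are stabilised by shrinking them across edges toward common
batch priors — normal for locations, inverse-gamma for scales, with
moment-matched hyperparameters — via iterated conditional posterior means
(parametric empirical Bayes). The adjusted data are

    y*_ijv = sigma_v / delta*_iv * (z_ijv - gamma*_iv) + alpha_v + X_j beta_v

with z the standardised residuals, so covariate effects are preserved and
the per-batch affine adjustment keeps the rank order of observations
within a batch.

``eb=False`` skips the shrinkage (gamma* = gamma_hat, delta*^2 = the
within-batch sample variance of z) and yields the exact standardisation
property: per-edge batch means and variances equalised across batches.
This mode doubles as the oracle for the EB path. The estimation flow
(pooled variance, standardisation, moment-matched priors, iteration on
relative change) follows the canonical parametric ComBat algorithm, so
reference implementations agree with it numerically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import CohortDataset
from .errors import BatchError, CollinearityError, ModelMismatchError, ValidationError


@dataclass
class CombatModel:
    """Fitted harmonisation parameters for one edge table.

    Arrays are indexed (edge,) or (batch, edge); ``covariate_names`` fixes
    the beta column order. ``ok_edges`` marks edges with nonzero pooled
    variance; the rest are passed through unadjusted and flagged."""

    batches: list[str]
    n_per_batch: np.ndarray            # (B,)
    covariate_names: list[str]
    alpha: np.ndarray                  # (E,)
    beta: np.ndarray                   # (C, E)
    sigma2: np.ndarray                 # (E,) pooled residual variance
    gamma_hat: np.ndarray              # (B, E) raw batch locations
    delta2_hat: np.ndarray             # (B, E) raw batch scales
    gamma_star: np.ndarray             # (B, E) shrunk locations
    delta2_star: np.ndarray            # (B, E) shrunk scales (> 0)
    gamma_bar: np.ndarray              # (B,) location prior mean
    tau2_bar: np.ndarray               # (B,) location prior variance
    lambda_prior: np.ndarray           # (B,) inverse-gamma shape
    theta_prior: np.ndarray            # (B,) inverse-gamma scale
    eb: bool
    n_iterations: np.ndarray           # (B,) EB iterations to convergence
    tolerance: float
    ok_edges: np.ndarray               # (E,) bool

    def to_dict(self) -> dict:
        """JSON-ready dump of every fitted parameter (audit trail)."""
        return {
            "batches": self.batches,
            "n_per_batch": self.n_per_batch.tolist(),
            "covariate_names": self.covariate_names,
            "eb": self.eb,
            "tolerance": self.tolerance,
            "n_iterations": self.n_iterations.tolist(),
            "alpha": self.alpha.tolist(),
            "beta": self.beta.tolist(),
            "sigma2": self.sigma2.tolist(),
            "gamma_hat": self.gamma_hat.tolist(),
            "delta2_hat": self.delta2_hat.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta2_star": self.delta2_star.tolist(),
            "gamma_bar": self.gamma_bar.tolist(),
            "tau2_bar": self.tau2_bar.tolist(),
            "lambda_prior": self.lambda_prior.tolist(),
            "theta_prior": self.theta_prior.tolist(),
            "n_excluded_edges": int((~self.ok_edges).sum()),
        }


def _design(batch_codes: np.ndarray, n_batch: int, mod: np.ndarray | None) -> np.ndarray:
    onehot = np.eye(n_batch)[batch_codes]
    if mod is None or mod.size == 0:
        return onehot
    return np.column_stack([onehot, mod])


def fit_combat_arrays(
    values: np.ndarray,
    batch: Sequence[str],
    mod: np.ndarray | None = None,
    covariate_names: Sequence[str] | None = None,
    eb: bool = True,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> CombatModel:
    """Fit the harmonisation model on a (samples, edges) value matrix.

    ``batch`` gives one label per sample, ``mod`` the (samples, C) covariate
    design to preserve. Identifiability uses the weighted constraint
    sum_i n_i gamma_iv = 0, making alpha the batch-size-weighted grand mean.
    """
    Y = np.asarray(values, dtype=float)
    if Y.ndim != 2:
        raise ValidationError(f"values must be (samples, edges), got {Y.ndim}-D")
    if np.isnan(Y).any():
        raise ValidationError("values contain NaN")
    n_samples, n_edges = Y.shape
    batch = [str(b) for b in batch]
    if len(batch) != n_samples:
        raise ValidationError("one batch label per sample required")
    batches = list(dict.fromkeys(batch))
    if len(batches) < 2:
        raise BatchError(f"harmonisation requires >= 2 batches, got {batches}")
    codes = np.array([batches.index(b) for b in batch])
    n_i = np.bincount(codes, minlength=len(batches))
    if np.any(n_i < 2):
        small = [batches[i] for i in np.flatnonzero(n_i < 2)]
        raise BatchError(f"every batch needs >= 2 observations; too small: {small}")

    if mod is not None:
        mod = np.asarray(mod, dtype=float)
        if mod.ndim != 2 or mod.shape[0] != n_samples:
            raise ValidationError("covariate design must be (samples, C)")
    names = list(covariate_names) if covariate_names is not None else (
        [f"x{i}" for i in range(mod.shape[1])] if mod is not None else []
    )

    X = _design(codes, len(batches), mod)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        cols = [f"batch:{b}" for b in batches] + names
        offending = _collinear_columns(X, cols)
        raise CollinearityError(
            f"design matrix is rank deficient ({rank}/{X.shape[1]}); "
            f"offending columns: {offending}"
        )

    # feature-wise least squares; batch coefficients absorb the intercept
    B_hat, *_ = np.linalg.lstsq(X, Y, rcond=None)
    gamma_full = B_hat[: len(batches)]                       # (B, E)
    beta = B_hat[len(batches):]                              # (C, E)
    alpha = (n_i / n_samples) @ gamma_full                   # weighted grand mean
    gamma_hat = gamma_full - alpha[None, :]                  # sum_i n_i gamma = 0

    fitted_mean = alpha[None, :] + (mod @ beta if mod is not None else 0.0)
    sigma2 = np.mean((Y - fitted_mean - gamma_hat[codes]) ** 2, axis=0)
    # constant edges (possible for SC) carry no information to standardise;
    # ptp catches them exactly where lstsq residue leaves sigma2 > 0
    ok = (np.ptp(Y, axis=0) > 0) & (sigma2 > 0)

    Z = np.zeros_like(Y)
    Z[:, ok] = (Y[:, ok] - fitted_mean[..., ok]) / np.sqrt(sigma2[ok])[None, :]
    # standardised data include the batch shifts; re-estimate batch stats on Z
    gamma_hat_z = np.vstack([Z[codes == i].mean(axis=0) for i in range(len(batches))])
    delta2_hat = np.vstack(
        [Z[codes == i].var(axis=0, ddof=1) for i in range(len(batches))]
    )

    gamma_bar = np.full(len(batches), np.nan)
    tau2_bar = np.full(len(batches), np.nan)
    lam = np.full(len(batches), np.nan)
    theta = np.full(len(batches), np.nan)
    n_iter = np.zeros(len(batches), dtype=int)
    gamma_star = gamma_hat_z.copy()
    delta2_star = delta2_hat.copy()

    if eb:
        for i in range(len(batches)):
            g = gamma_hat_z[i, ok]
            d2 = delta2_hat[i, ok]
            gamma_bar[i] = g.mean()
            tau2_bar[i] = g.var(ddof=1)
            m, s2 = d2.mean(), d2.var(ddof=1)
            lam[i] = (2 * s2 + m**2) / s2
            theta[i] = (m * s2 + m**3) / s2
            g_star, d2_star, it = _it_sol(
                Z[codes == i][:, ok], g, d2, gamma_bar[i], tau2_bar[i], lam[i], theta[i],
                tol=tol, max_iter=max_iter,
            )
            gamma_star[i, ok] = g_star
            delta2_star[i, ok] = d2_star
            n_iter[i] = it

    return CombatModel(
        batches=batches,
        n_per_batch=n_i,
        covariate_names=names,
        alpha=alpha,
        beta=beta,
        sigma2=sigma2,
        gamma_hat=gamma_hat_z,
        delta2_hat=delta2_hat,
        gamma_star=gamma_star,
        delta2_star=delta2_star,
        gamma_bar=gamma_bar,
        tau2_bar=tau2_bar,
        lambda_prior=lam,
        theta_prior=theta,
        eb=eb,
        n_iterations=n_iter,
        tolerance=tol,
        ok_edges=ok,
    )


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Greedy scan for columns that do not increase the design rank."""
    out = []
    kept: list[int] = []
    rank = 0
    for j in range(X.shape[1]):
        r = np.linalg.matrix_rank(X[:, kept + [j]])
        if r > rank:
            kept.append(j)
            rank = r
        else:
            out.append(names[j])
    return out


def _it_sol(Z_b, g_hat, d2_hat, g_bar, t2, lam, theta, tol, max_iter):
    """Iterated conditional posterior means for one batch.

    Convergence on the maximum relative change of the location and scale
    estimates (matching the canonical parametric algorithm)."""
    n = Z_b.shape[0]
    g_old = g_hat.copy()
    d2_old = d2_hat.copy()
    it = 0
    while it < max_iter:
        it += 1
        g_new = (t2 * n * g_hat + d2_old * g_bar) / (t2 * n + d2_old)
        sum2 = ((Z_b - g_new[None, :]) ** 2).sum(axis=0)
        d2_new = (0.5 * sum2 + theta) / (n / 2.0 + lam - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.abs(g_old)),
            np.max(np.abs(d2_new - d2_old) / d2_old),
        )
        g_old, d2_old = g_new, d2_new
        if change < tol:
            break
    return g_old, d2_old, it


def _cohort_mod(data: CohortDataset) -> tuple[np.ndarray, list[str], np.ndarray, list[str]]:
    """Flatten a cohort to (samples, edges) with per-sample batch labels and
    the covariate design (subject covariates repeated across scanners)."""
    n_s, n_k, n_e = data.edges.shape
    Y = data.edges.reshape(n_s * n_k, n_e)
    batch = [data.scanners[j] for _ in range(n_s) for j in range(n_k)]
    X_sub = data.covariates.design_matrix(data.subjects)     # (n_s, 4)
    mod = np.repeat(X_sub, n_k, axis=0)
    names = ["age", "sex", "days_between_scans", "daytime_of_scan"]
    return Y, batch, mod, names


def fit_combat(
    data: CohortDataset,
    eb: bool = True,
    use_covariates: bool = True,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> CombatModel:
    """Fit harmonisation on a cohort with scanner as the batch variable.

    FC and SC are harmonised in separate calls (one model per modality)."""
    Y, batch, mod, names = _cohort_mod(data)
    if not use_covariates:
        mod, names = None, []
    return fit_combat_arrays(
        Y, batch, mod=mod, covariate_names=names, eb=eb, tol=tol, max_iter=max_iter
    )


def apply_combat_arrays(
    values: np.ndarray,
    batch: Sequence[str],
    model: CombatModel,
    mod: np.ndarray | None = None,
) -> np.ndarray:
    """Adjust a (samples, edges) matrix with a fitted model."""
    Y = np.asarray(values, dtype=float)
    batch = [str(b) for b in batch]
    unseen = sorted(set(batch) - set(model.batches))
    if unseen:
        raise ModelMismatchError(f"batches not seen at fit time: {unseen}")
    if Y.shape[1] != model.alpha.size:
        raise ModelMismatchError(
            f"model fitted on {model.alpha.size} edges, data has {Y.shape[1]}"
        )
    if (mod is None) != (len(model.covariate_names) == 0):
        raise ModelMismatchError("covariate design must match the fitted model")
    codes = np.array([model.batches.index(b) for b in batch])
    fitted_mean = model.alpha[None, :] + (mod @ model.beta if mod is not None else 0.0)
    ok = model.ok_edges
    out = Y.copy()
    Z = (Y[:, ok] - fitted_mean[..., ok]) / np.sqrt(model.sigma2[ok])[None, :]
    adj = (Z - model.gamma_star[codes][:, ok]) / np.sqrt(model.delta2_star[codes][:, ok])
    out[:, ok] = adj * np.sqrt(model.sigma2[ok])[None, :] + fitted_mean[..., ok]
    return out


def apply_combat(data: CohortDataset, model: CombatModel) -> CohortDataset:
    """Harmonise a cohort; shape, design, covariates and modality preserved.

    SC values may dip marginally below zero after the affine adjustment;
    they are clipped at 0 to preserve the modality invariant."""
    Y, batch, mod, names = _cohort_mod(data)
    if model.covariate_names and model.covariate_names != names:
        raise ModelMismatchError(
            f"model covariates {model.covariate_names} do not match cohort {names}"
        )
    out = apply_combat_arrays(Y, batch, model, mod=mod if model.covariate_names else None)
    out = out.reshape(data.edges.shape)
    if data.modality == "SC":
        out = np.clip(out, 0.0, None)
    return data.with_edges(out)
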