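"""Harmonisation: exact standardisation, EB shrinkage, reference agreement."""

import shutil
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pytest

import connrel as cr
from connrel.combat import _cohort_mod, apply_combat_arrays, fit_combat_arrays
from connrel.errors import BatchError, CollinearityError, ModelMismatchError


def _batch_stats(Y, batch, ddof=1):
    labs = list(dict.fromkeys(batch))
    means = np.vstack([Y[np.array(batch) == b].mean(axis=0) for b in labs])
    var = np.vstack([Y[np.array(batch) == b].var(axis=0, ddof=ddof) for b in labs])
    return means, var


def test_constant_offset_two_batches_closed_form(rng):
    """Batch 2 = batch 1 + c: locations split as +-c/2 under the weighted
    zero-sum constraint (equal batch sizes) and harmonised means agree."""
    c = 0.8
    base = rng.normal(size=(6, 40))
    Y = np.vstack([base, base + c])
    batch = ["A"] * 6 + ["B"] * 6
    model = fit_combat_arrays(Y, batch, eb=False)
    # gamma is on the standardised scale; convert back to data units
    gamma_data = model.gamma_hat * np.sqrt(model.sigma2)[None, :]
    assert np.allclose(gamma_data[0], -c / 2, atol=1e-10)
    assert np.allclose(gamma_data[1], +c / 2, atol=1e-10)
    out = apply_combat_arrays(Y, batch, model)
    means, _ = _batch_stats(out, batch)
    assert np.allclose(means[0], means[1], atol=1e-10)


def test_no_eb_exact_standardisation(rng):
    """Direct (non-EB) mode equalises per-edge batch means and variances."""
    Y = rng.normal(size=(20, 100)) * rng.uniform(0.5, 2.0, size=(1, 100))
    Y[10:] = Y[10:] * 1.7 + 0.4  # location-scale distortion of batch B
    batch = ["A"] * 10 + ["B"] * 10
    model = fit_combat_arrays(Y, batch, eb=False)
    out = apply_combat_arrays(Y, batch, model)
    means, var = _batch_stats(out, batch)
    assert np.allclose(means[0], means[1], atol=1e-8)
    assert np.allclose(var[0], var[1], atol=1e-8)


def test_null_batch_effect_estimates(rng):
    """Data with no batch effect: locations near 0, scales near 1."""
    Y = rng.normal(size=(60, 300))
    batch = ["A"] * 30 + ["B"] * 30
    model = fit_combat_arrays(Y, batch, eb=False)
    # batch means of standardised data have SE ~ 1/sqrt(30) = 0.18, so the
    # mean |gamma| under the null is ~ 0.15; scales fluctuate ~ sqrt(2/29)
    assert np.abs(model.gamma_hat).mean() < 0.18
    assert np.abs(model.delta2_hat - 1.0).mean() < 0.25
    out = apply_combat_arrays(Y, batch, model)
    # adjustment is within sampling noise of the identity
    assert np.mean(np.abs(out - Y)) < 0.2


def test_eb_shrinks_location_estimates(small_cohort):
    model_eb = cr.fit_combat(small_cohort, eb=True)
    for i in range(len(model_eb.batches)):
        ok = model_eb.ok_edges
        assert np.var(model_eb.gamma_star[i, ok]) <= np.var(model_eb.gamma_hat[i, ok]) + 1e-12


def test_idempotence_of_direct_mode(small_cohort):
    model = cr.fit_combat(small_cohort, eb=False, use_covariates=False)
    harmonised = cr.apply_combat(small_cohort, model)
    refit = cr.fit_combat(harmonised, eb=False, use_covariates=False)
    assert np.abs(refit.gamma_hat).max() < 1e-6
    # batch scales are exactly equalised; their common level sits slightly
    # above 1 because the pooled variance divides by N while the per-batch
    # variance uses n-1 (small-sample degrees-of-freedom ratio)
    assert np.allclose(refit.delta2_hat[0], refit.delta2_hat[1], atol=1e-8)
    assert np.allclose(refit.delta2_hat, 1.0, atol=0.35)


def test_rank_order_preserved_within_batch(small_cohort):
    # the per-(batch, edge) adjustment is affine with positive scale, so it
    # preserves subject order exactly; checked without covariate columns,
    # whose re-added predictions are subject-specific
    model = cr.fit_combat(small_cohort, eb=True, use_covariates=False)
    harmonised = cr.apply_combat(small_cohort, model)
    for s in range(small_cohort.n_scanners):
        before = np.argsort(small_cohort.edges[:, s, :], axis=0)
        after = np.argsort(harmonised.edges[:, s, :], axis=0)
        assert np.array_equal(before, after)


def test_covariate_effect_preserved():
    cfg = cr.SimConfig(n_regions=40, beta_sex=0.25, rng_seed=21)
    d = cr.simulate_cohort(cfg)
    model = cr.fit_combat(d, eb=False)
    harmonised = cr.apply_combat(d, model)
    X = d.covariates.design_matrix(d.subjects)
    design = np.column_stack([np.ones(d.n_subjects * 2), np.repeat(X, 2, axis=0)])
    Y = harmonised.edges.reshape(-1, d.n_edges)
    beta_sex = np.linalg.lstsq(design, Y, rcond=None)[0][2]
    assert np.mean(beta_sex) == pytest.approx(0.25, abs=0.04)


def test_scanner_variance_reduced(small_cohort):
    model = cr.fit_combat(small_cohort, eb=False)
    harmonised = cr.apply_combat(small_cohort, model)
    rep = cr.scanner_variance_report(small_cohort, harmonised)
    assert rep["mean_after"] < rep["mean_before"]
    assert rep["mean_after"] < 2.0


def test_single_batch_rejected(rng):
    with pytest.raises(BatchError):
        fit_combat_arrays(rng.normal(size=(6, 10)), ["A"] * 6)


def test_collinear_design_rejected(rng):
    Y = rng.normal(size=(8, 10))
    batch = ["A"] * 4 + ["B"] * 4
    # covariate perfectly confounded with batch
    mod = np.array([[1.0]] * 4 + [[0.0]] * 4)
    with pytest.raises(CollinearityError):
        fit_combat_arrays(Y, batch, mod=mod, covariate_names=["confounded"])


def test_unseen_batch_rejected(small_cohort):
    model = cr.fit_combat(small_cohort, eb=False)
    Y, batch, mod, _ = _cohort_mod(small_cohort)
    batch = ["scanner-Z"] * len(batch)
    with pytest.raises(ModelMismatchError):
        apply_combat_arrays(Y, batch, model, mod=mod)


def test_zero_variance_edge_passed_through(rng):
    Y = rng.normal(size=(10, 5))
    Y[:, 2] = 7.0  # constant edge
    batch = ["A"] * 5 + ["B"] * 5
    model = fit_combat_arrays(Y, batch, eb=False)
    assert not model.ok_edges[2]
    out = apply_combat_arrays(Y, batch, model)
    assert np.array_equal(out[:, 2], Y[:, 2])


def test_matches_sva_combat_reference():
    """Agreement with the canonical empirical-Bayes implementation
    (Bioconductor sva::ComBat) on a small cohort with covariates."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript is required for the sva cross-check")
    d = cr.simulate_cohort(
        cr.SimConfig(n_subjects=8, n_regions=12, rng_seed=7, beta_sex=0.1, beta_age=0.01)
    )
    Y, batch, mod, names = _cohort_mod(d)
    model = fit_combat_arrays(Y, batch, mod=mod, covariate_names=names, eb=True)
    out = apply_combat_arrays(Y, batch, model, mod=mod)
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        np.savetxt(tmp / "Y.tsv", Y.T, delimiter="\t", fmt="%.17g")
        (tmp / "batch.tsv").write_text("\n".join(batch) + "\n")
        np.savetxt(tmp / "mod.tsv", mod, delimiter="\t", fmt="%.17g")
        script = tmp / "combat.R"
        script.write_text(
            """
suppressMessages(library(sva))
args <- commandArgs(TRUE)
dat <- as.matrix(read.table(file.path(args[1], "Y.tsv"), sep="\\t"))
batch <- readLines(file.path(args[1], "batch.tsv"))
mod <- model.matrix(~as.matrix(read.table(file.path(args[1], "mod.tsv"), sep="\\t")))
res <- ComBat(dat=dat, batch=batch, mod=mod)
write.table(res, file.path(args[1], "out.tsv"), sep="\\t",
            row.names=FALSE, col.names=FALSE)
"""
        )
        subprocess.run(["Rscript", str(script), str(tmp)], check=True, capture_output=True)
        ref = np.loadtxt(tmp / "out.tsv").T
    assert np.max(np.abs(out - ref)) < 1e-8
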