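"""One-facet variance decomposition: EMS oracle, REML vs lme4, recovery."""

import shutil
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pytest

import connrel as cr
from connrel.gstudy import gstudy_edge, gstudy_table
from oracles import ems_components_oracle


def _frac(components, i=None):
    f = components.fractions_percent
    return f if i is None else f[..., i]


def test_pure_subject_variance():
    rng = np.random.default_rng(0)
    col = rng.normal(size=6)
    t = np.column_stack([col, col])
    for est in ("mom", "reml"):
        f = gstudy_edge(t, est).fractions_percent[0]
        assert np.allclose(f, [100.0, 0.0, 0.0], atol=1e-10)


def test_pure_scanner_offset_hand_worked():
    # [[0,1],[0,1],[0,1]]: MS_subjects = 0, scanner SS = 3 * 0.5^2 * 2 = 1.5
    t = np.array([[0.0, 1.0], [0.0, 1.0], [0.0, 1.0]])
    for est in ("mom", "reml"):
        c = gstudy_edge(t, est)
        assert c.sigma2_p[0] == 0.0
        assert c.sigma2_res[0] == pytest.approx(0.0, abs=1e-12)
        assert c.sigma2_s[0] > 0
        assert np.allclose(c.fractions_percent[0], [0.0, 100.0, 0.0], atol=1e-8)


def test_mom_equals_ems_oracle(rng):
    for _ in range(200):
        t = rng.normal(size=(10, 2))
        c = gstudy_edge(t, "mom")
        s2p, s2s, s2e = ems_components_oracle(t)
        assert c.sigma2_p[0] == pytest.approx(s2p, abs=1e-10)
        assert c.sigma2_s[0] == pytest.approx(s2s, abs=1e-10)
        assert c.sigma2_res[0] == pytest.approx(s2e, abs=1e-10)


def test_reml_equals_mom_when_interior(rng):
    """For balanced designs the REML optimum is the ANOVA solution whenever
    the ANOVA estimates are nonnegative."""
    found = 0
    for _ in range(100):
        t = rng.normal(size=(8, 3)) + rng.normal(size=(8, 1)) + 0.5 * rng.normal(size=(1, 3))
        mom = gstudy_edge(t, "mom")
        if mom.truncated_p[0] or mom.truncated_s[0]:
            continue
        reml = gstudy_edge(t, "reml")
        assert reml.sigma2_p[0] == pytest.approx(mom.sigma2_p[0], abs=1e-12)
        assert reml.sigma2_s[0] == pytest.approx(mom.sigma2_s[0], abs=1e-12)
        assert reml.sigma2_res[0] == pytest.approx(mom.sigma2_res[0], abs=1e-12)
        found += 1
    assert found > 20


def test_reml_matches_lme4():
    """Independent mixed-model oracle: lme4 REML fit of
    y ~ 1 + (1|subject) + (1|scanner) on a mix of interior and boundary
    tables."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript is required for the lme4 cross-check")
    rng = np.random.default_rng(31)
    tabs = []
    for i in range(8):
        t = (
            rng.normal(size=(10, 2))
            + [0.4, 1.2][i % 2] * rng.normal(size=(10, 1))
            + 0.3 * rng.normal(size=(1, 2))
        )
        tabs.append(t)
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        with open(tmp / "tabs.tsv", "w") as fh:
            fh.write("tab\tsubj\tscan\ty\n")
            for k, t in enumerate(tabs):
                for p in range(t.shape[0]):
                    for s in range(t.shape[1]):
                        fh.write(f"{k}\t{p}\t{s}\t{t[p, s]:.17g}\n")
        script = tmp / "fit.R"
        script.write_text(
            """
suppressMessages(library(lme4))
d <- read.table(file.path(commandArgs(TRUE)[1], "tabs.tsv"), header=TRUE)
out <- NULL
for (k in unique(d$tab)) {
  dk <- d[d$tab == k,]
  m <- suppressWarnings(lmer(y ~ 1 + (1|subj) + (1|scan), data=dk,
        control=lmerControl(check.conv.singular="ignore")))
  vc <- as.data.frame(VarCorr(m))
  out <- rbind(out, c(vc$vcov[vc$grp=="subj"], vc$vcov[vc$grp=="scan"],
                      vc$vcov[vc$grp=="Residual"]))
}
write.table(out, file.path(commandArgs(TRUE)[1], "reml.tsv"),
            sep="\\t", row.names=FALSE, col.names=FALSE)
"""
        )
        subprocess.run(
            ["Rscript", str(script), str(tmp)], check=True, capture_output=True
        )
        ref = np.loadtxt(tmp / "reml.tsv")
    for t, row in zip(tabs, ref):
        c = gstudy_edge(t, "reml")
        got = np.array([c.sigma2_p[0], c.sigma2_s[0], c.sigma2_res[0]])
        # lme4 converges iteratively; agreement to its optimiser tolerance
        assert np.max(np.abs(got - row)) < 1e-3


def test_fractions_sum_to_100_and_affine_invariant(small_cohort):
    res = gstudy_table(small_cohort, estimator="reml")
    frac = res.components.fractions_percent
    good = ~np.isnan(frac[:, 0])
    assert np.allclose(frac[good].sum(axis=1), 100.0, atol=1e-6)
    scaled = small_cohort.with_edges(3.0 * small_cohort.edges + 1.0)
    frac2 = gstudy_table(scaled, estimator="reml").components.fractions_percent
    assert np.allclose(frac, frac2, atol=1e-6, equal_nan=True)


def test_recovery_of_generative_fractions():
    truth = np.array([20.0, 12.0, 68.0])
    d = cr.simulate_cohort(
        cr.SimConfig(n_regions=101, f_subject=0.20, f_scanner=0.12, f_residual=0.68,
                     batch=None, rng_seed=17)
    )
    frac = gstudy_table(d, estimator="mom").components.fractions_percent
    means = np.nanmean(frac, axis=0)
    assert np.all(np.abs(means - truth) < 3.0), means
    # REML's zero bound redistributes mass when a component is truncated,
    # which biases the small-component averages slightly more than MoM at
    # n = 10 x 2; the recovered profile is still close
    frac_reml = gstudy_table(d, estimator="reml").components.fractions_percent
    means_reml = np.nanmean(frac_reml, axis=0)
    assert np.all(np.abs(means_reml - truth) < 6.0), means_reml


def test_null_scanner_truncation_rate():
    """With no scanner effect, the raw per-edge scanner MoM estimate is
    negative roughly half the time — exactly P(F(1, 9) < 1), since
    MS_scanner / MS_error is F-distributed under the null."""
    from scipy import stats

    d = cr.simulate_cohort(
        cr.SimConfig(n_regions=101, f_subject=0.5, f_scanner=0.0, f_residual=0.5,
                     batch=None, rng_seed=19)
    )
    res = gstudy_table(d, estimator="mom")
    rate = res.components.truncated_s.mean()
    expected = stats.f.cdf(1.0, 1, 9)
    assert rate == pytest.approx(expected, abs=0.05)


def test_duplicated_scanner_gives_zero_scanner_and_residual(small_cohort):
    edges = small_cohort.edges.copy()
    edges[:, 1, :] = edges[:, 0, :]
    dup = small_cohort.with_edges(edges)
    res = gstudy_table(dup, estimator="mom")
    assert np.allclose(res.components.sigma2_s, 0.0, atol=1e-12)
    assert np.allclose(res.components.sigma2_res, 0.0, atol=1e-12)
    assert np.allclose(res.components.fractions_percent[:, 0], 100.0, atol=1e-8)


def test_zero_variance_edge_flagged():
    t = np.ones((4, 2))
    c = gstudy_edge(t, "reml")
    assert c.zero_variance[0]
    assert np.isnan(c.fractions_percent[0]).all()


def test_gstudy_blocks_and_report(small_cohort):
    res = gstudy_table(small_cohort, estimator="mom")
    blocks = cr.gstudy_blocks(res, small_cohort.partition, by="lobe")
    assert set(blocks) == {"subject_pct", "scanner_pct", "residual_pct"}
    assert blocks["subject_pct"].values.shape == (7, 7)
    pooled = res.pooled_fractions_percent()
    assert pooled.sum() == pytest.approx(100.0, abs=1e-9)
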