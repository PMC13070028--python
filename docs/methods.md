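# Methods

This note documents the statistical models implemented in `connrel`, the
defaults and why they were chosen, what the synthetic cohort does and does
not emulate, and the numerical decisions that a maintainer would otherwise
have to reverse-engineer from the code.

## The measurement model

The unit of analysis is the connectome **edge**: one unordered region pair
of a parcellation (n regions → n(n−1)/2 edges; the whole-brain default of
246 regions gives 30,135). Functional connectivity (FC) edges are
Fisher-z-transformed Pearson correlations between regional BOLD series —
signed, roughly z-scale; structural connectivity (SC) edges are
streamline-weight sums — nonnegative and right-skewed. Self-connections
carry no information (the Fisher z of r = 1 is infinite) and are excluded
everywhere; matrices store a structural zero on the diagonal.

A travelling cohort observes every subject p on every scanner s, so each
edge yields a balanced crossed table X_ps. All estimators in the package
assume this complete crossing and reject missing cells, because both the
consistency ICC and the variance decomposition are ill-defined on
incomplete two-way layouts at this sample size.

## Reliability estimators

**ICC(C,1)** uses the two-way ANOVA of the subjects × scanners table:
ICC = (MS_subjects − MS_error) / (MS_subjects + (k−1) MS_error), with
MS_error the residual after removing both main effects. The consistency
definition deliberately ignores per-scanner constant offsets: a scanner
that shifts every subject equally does not reduce ICC(C,1). Negative
estimates — common when residual variance dominates and n is small — are
truncated at zero, and the raw value is kept alongside so the prevalence
of truncation is auditable (truncation inflates apparent reliability).
Tables with zero total variance return missing, never 0 or 1.

**wsCV** is computed per subject as the sample SD across scanners (n−1
denominator) divided by the mean of absolute values across scanners, in
percent, then averaged over subjects. The n−1 SD makes the k = 2 case
reduce to the closed form |x₁−x₂|/√2 ÷ ((|x₁|+|x₂|)/2) × 100. Absolute
values in the denominator keep the ratio meaningful for signed FC edges;
subjects whose mean absolute value is exactly zero have an undefined
ratio and are dropped from that edge's average with a flag (an edge with
no valid subject is missing). wsCV is scale-invariant but not
shift-invariant — it is a relative-error measure.

## Agreement and similarity

Bland–Altman analysis works on one point per edge by default, using
subject-averaged values per scanner (group-level agreement); a pooled
subject × edge mode exists behind a flag. Differences are first-listed
scanner minus second, recorded in the output. Limits of agreement use the
fixed 1.96 normal quantile — standard practice, no small-sample t
correction. The proportional-bias slope is the OLS slope of difference on
pair mean; it is undefined (flagged, not zero) when means are constant or
fewer than three points fall in a stratum.

Pattern similarity is the Pearson correlation between two vectorised
connectomes: group level correlates the subject-averaged edge vectors of
the two scanners; subject level correlates each subject's own pair of
vectors and reports the per-subject values plus their mean. Restriction
to within- or between-block edge sets gives the network/lobe-level
variants. Averaging over subjects cancels subject-independent noise, so
group-level PCC systematically exceeds the mean subject-level PCC when
residual noise dominates — a property the tests verify by simulation.

## One-facet G-theory

Each edge is modelled with crossed random intercepts,
σ²(X_ps) = σ²_p + σ²_s + σ²_ps,e, where the residual term confounds the
participant × scanner interaction with random error — a one-facet design
cannot separate them, and no attempt is made to. Two estimators:

- **mom** (expected mean squares): σ²_res = MS_E,
  σ²_p = (MS_P − MS_E)/k, σ²_s = (MS_S − MS_E)/n, truncated at zero with
  the truncation recorded. With k = 2 the raw per-edge scanner estimate
  is negative with probability P(F(1, (n−1)(k−1)) < 1) ≈ 0.65 under a
  null scanner effect — individual edges are noisy; the mean over edges
  is the interpretable quantity.
- **reml** (default): restricted maximum likelihood with components
  bounded at zero. For balanced crossed data the restricted likelihood is
  diagonal in the three ANOVA strata, so the bounded optimum is closed
  form: the ANOVA solution when interior, otherwise the best of the
  boundary profiles (σ²_p = 0 and/or σ²_s = 0), each itself closed form.
  No iteration, deterministic, and it matches lme4's REML fit of the same
  model (cross-checked in the tests). The zero bound means REML's
  per-edge averages are slightly more biased than MoM's when a small
  component is frequently truncated; recovery tests therefore use MoM,
  while REML is the default for reporting because it mirrors the
  mixed-model convention.

Fractions are reported per edge as percentages of that edge's total and
then averaged over edges (consistent with per-block heat-map reporting);
pooled-component fractions are available as an alternative summary.

## ComBat harmonisation

The batch model for edge v of observation j in batch (scanner vendor) i is
y_ijv = α_v + X_j β_v + γ_iv + δ_iv ε_ijv. Fitting follows the canonical
parametric empirical-Bayes algorithm: feature-wise least squares with
batch dummies under the weighted constraint Σᵢ nᵢ γ̂_iv = 0; pooled
variance σ̂²_v from the full-model residuals (1/N denominator);
standardisation; per-batch location/scale statistics of the standardised
data (scale with n−1 denominator); normal and inverse-gamma priors with
moment-matched hyperparameters; iterated conditional posterior means with
convergence on the maximum *relative* change (default 1e-4, max 100
iterations — the convention of the reference implementations, which the
test suite exploits by requiring agreement with Bioconductor `sva::ComBat`
to 1e-8). The adjusted value is
y* = σ̂_v/δ*_iv (z_ijv − γ*_iv) + α̂_v + X_j β̂_v.

`eb=False` skips shrinkage (γ* = γ̂, δ*² = within-batch sample variance)
and yields the exact standardisation property — per-edge batch means and
variances equalised to numerical precision — which serves as the oracle
for the EB path. Note that exact equalisation holds for the no-covariate
adjustment; with covariates, the re-added subject-specific predictions
X β̂ carry batch-dependent cross-terms with the residuals, which is the
intended behaviour (covariate effects are preserved, not equalised).
Likewise, the per-(batch, edge) adjustment is affine with positive scale
and so preserves subject rank order within a batch exactly in the
no-covariate case.

Covariates are age and days-between-scans (numeric as-is), sex (single
dummy), and scan daytime (continuous hour of day; a categorical encoding
of the covariate table is equally accepted since the design matrix just
takes the columns). FC and SC are harmonised in separate calls. Edges
with zero variance (possible for sparse SC) are excluded from EB pooling
and passed through unadjusted with a flag; SC output is clipped at zero,
since the affine adjustment can push near-zero weights marginally
negative. Single-batch input, rank-deficient designs (with the offending
columns named) and unseen batch ids at apply time are hard errors.
Longitudinal ComBat, ComBat-GAM and reference-batch variants are out of
scope.

## The synthetic cohort

`simulate_cohort` draws x_pse = μ_e + β·cov_p + u_pe + v_se + ε_pse with
Var(u) = f_subject σ²_total, Var(v) = f_scanner σ²_total,
Var(ε) = f_residual σ²_total, then (by default) applies a per-scanner
location–scale distortion around the biological mean:
γ_iv ~ Normal(±0.05, 0.05²), δ²_iv ~ InverseGamma(18, 17) (mean 1, ~25%
spread). Defaults encode the study conditions of a two-vendor travelling
cohort: 10 subjects, 2 scanners, 246 regions, variance fractions
0.20/0.12/0.68 matching the empirical FC profile, σ²_total = 0.04
(edge SD 0.2 on the z scale), edge means ~ Normal(0.25, 0.15²).
Covariates mimic the cohort: age ~ Normal(27.2, 3.1²) truncated at 18,
sex balanced 1:1, days between scans uniform integers 0–7, scan daytime
uniform in 8–18 h. Covariate effect sizes default to zero and, when set,
apply uniformly across edges — sufficient for effect-preservation
oracles. The SC link exponentiates the latent Gaussian (lognormal), times
a scale of 30, giving nonnegative right-skewed weights.

What the generator does **not** emulate: spatial autocorrelation between
edges (edges are independent given the components), network-specific
reliability differences (per-network variance overrides are uniform by
default since no quantitative generative values are established),
distance- or SNR-dependent scanner effects, temporal dynamics of FC, and
any image-level artefact. Passing tests therefore demonstrate estimator
correctness and pipeline behaviour under the assumed variance structure,
not performance on real acquisitions. `simulate_bold` provides
multivariate-normal series with an exact target population correlation
(190 volumes, TR 2.5 s nominal) for exercising FC construction, with a
framewise-displacement trace whose exceedance rate over the 0.5 mm
threshold is controlled; there is no haemodynamic or motion forward model.

## FC construction and motion QC

Volumes with FD strictly greater than 0.5 mm are censored (removed, no
interpolation) under a single joint mask for all regions before the
pairwise Pearson correlation; an acquisition with strictly more than 30%
of volumes flagged fails QC (exactly 30% is kept). The strict inequality
at both thresholds follows the printed rule "FD > 0.5 mm" / "more than
30%". Upstream cleaning (bandpass, nuisance regression, standardisation)
is assumed done; inputs are cleaned regional series. Fisher z = atanh(r)
requires |r| < 1 and errors otherwise rather than emitting infinities.

## Numerical and interface decisions

- Edge order is the row-major strict upper triangle with 0-based indices;
  persisted files always carry region ids, never bare indices.
- All TSV floats are written with 17 significant digits and parsed in
  round-trip mode, so write→read is bit-exact.
- Block aggregates over network/lobe pairs skip undefined (flagged) edge
  values; blocks with no edges or no defined values are reported missing
  and flagged, never silently zero.
- Symmetry tolerance for input matrices is 1e-10; diagonals must be
  exactly zero.
- Per-edge computations are vectorised but sequential over a single
  process for determinism; identical seeds give byte-identical outputs
  end to end, including the pipeline's TSV/JSON bundle (config hash and
  seed recorded in `report.json`).
- SC edges with zero weight on one scanner are retained in edge-level
  metrics by default; degenerate cases (zero variance, zero denominators)
  are flagged per edge rather than excluded wholesale.
- Problem sizes in the test and acceptance runs use reduced parcellations
  (20–101 regions, i.e. 190–5,050 edges) — large enough for the
  statistical tolerances asserted, chosen so the whole suite runs in well
  under a minute of compute; the estimators are O(edges) and run the full
  30,135-edge connectome unchanged.

## Known limitations

Two-facet designs (scanner × session) are not supported — the one-facet
residual confounds session effects with error. No ICC confidence
intervals, no D-study coefficients, no repeated-measures Bland–Altman
variance correction, no dynamic FC. The pipeline trusts its inputs to be
preprocessed; it performs no image handling of any kind.
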