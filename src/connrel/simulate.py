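"""Synthetic travelling-cohort generator.

Emulates the statistical structure of a crossed subject x scanner
connectome study so the whole pipeline is testable without real MRI data:

* per-edge additive variance components — subject (true inter-individual
  signal), scanner (systematic vendor effect), and residual
  (interaction + noise) — with fractions that default to the empirical FC
  profile of a two-vendor travelling cohort (~20% subject, ~12% scanner,
  ~68% residual);
* a location-scale batch model on top (per-scanner, per-edge shift and
  scale drawn from normal / inverse-gamma feature distributions), the kind
  of distortion empirical-Bayes harmonisation is built to remove;
* FC-like values (signed, Fisher-z scale, identity link) or SC-like values
  (nonnegative, right-skewed, via a lognormal link);
* subject covariates matched to a small healthy-adult cohort: age
  ~ Normal(27.2, 3.1^2) truncated to adults, 1:1 sex ratio, 0-7 days
  between scans, scan daytime in working hours.

The generative model per subject p, scanner s, edge e is

    x_pse = mu_e + beta . cov_p + u_pe + v_se + eps_pse

with Var(u) = f_subject * sigma2_total, Var(v) = f_scanner * sigma2_total,
Var(eps) = f_residual * sigma2_total, followed (when the batch model is
enabled) by y = m + gamma_se + delta_se * (x - m) around the biological
mean m = mu_e + beta . cov_p.

All randomness flows from a single explicitly seeded generator per call;
identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import (
    LOBE_LABELS,
    NETWORK_LABELS,
    CohortDataset,
    CovariateTable,
    Partition,
    edge_count,
)
from .errors import ConfigError
import pandas as pd


@dataclass
class BatchModel:
    """Location-scale scanner distortion, per scanner i and edge v:
    gamma_iv ~ Normal(location_mean_i, location_sd_i^2),
    delta2_iv ~ InverseGamma(scale_shape_i, scale_scale_i).

    Defaults give opposite mean shifts of +-0.05 on the edge scale and
    multiplicative scale factors centred on 1 with ~25% spread."""

    location_mean: tuple[float, ...] = (0.05, -0.05)
    location_sd: tuple[float, ...] = (0.05, 0.05)
    scale_shape: tuple[float, ...] = (18.0, 18.0)
    scale_scale: tuple[float, ...] = (17.0, 17.0)

    def validate(self, n_scanners: int) -> None:
        for name in ("location_mean", "location_sd", "scale_shape", "scale_scale"):
            if len(getattr(self, name)) != n_scanners:
                raise ConfigError(
                    f"batch model field {name} must have one entry per scanner "
                    f"({n_scanners}), got {len(getattr(self, name))}"
                )
        if any(s <= 0 for s in self.scale_shape) or any(s <= 0 for s in self.scale_scale):
            raise ConfigError("inverse-gamma scale hyperparameters must be positive")
        if any(s <= 1 for s in self.scale_shape):
            raise ConfigError("scale_shape must exceed 1 for a finite mean delta^2")


@dataclass
class SimConfig:
    """Configuration of one synthetic travelling cohort.

    Variance fractions must be nonnegative and sum to 1; they partition
    ``sigma2_total`` into the subject, scanner and residual components of
    the one-facet crossed design."""

    n_subjects: int = 10
    n_scanners: int = 2
    n_regions: int = 246
    modality: str = "FC"
    f_subject: float = 0.20
    f_scanner: float = 0.12
    f_residual: float = 0.68
    sigma2_total: float = 0.04
    edge_mean: float = 0.25
    edge_mean_sd: float = 0.15
    beta_age: float = 0.0
    beta_sex: float = 0.0
    beta_days: float = 0.0
    beta_daytime: float = 0.0
    batch: BatchModel | None = field(default_factory=BatchModel)
    sc_scale: float = 30.0
    rng_seed: int = 0

    def validate(self) -> None:
        f = (self.f_subject, self.f_scanner, self.f_residual)
        if any(x < 0 for x in f):
            raise ConfigError(f"variance fractions must be nonnegative, got {f}")
        if abs(sum(f) - 1.0) > 1e-12:
            raise ConfigError(f"variance fractions must sum to 1, got sum={sum(f)!r}")
        if self.sigma2_total < 0:
            raise ConfigError("sigma2_total must be nonnegative")
        if self.n_subjects < 2 or self.n_scanners < 2:
            raise ConfigError("need at least 2 subjects and 2 scanners")
        if self.modality not in ("FC", "SC"):
            raise ConfigError(f"modality must be 'FC' or 'SC', got {self.modality!r}")
        edge_count(self.n_regions)
        if self.batch is not None:
            self.batch.validate(self.n_scanners)


def default_partition(n_regions: int) -> Partition:
    """Synthetic partition: regions assigned round-robin to the 8 canonical
    networks and 7 lobes. Real atlas-to-network mappings are user-supplied
    via the partition file."""
    ids = tuple(f"R{i:03d}" for i in range(n_regions))
    return Partition(
        region_ids=ids,
        network_of={r: NETWORK_LABELS[i % len(NETWORK_LABELS)] for i, r in enumerate(ids)},
        lobe_of={r: LOBE_LABELS[i % len(LOBE_LABELS)] for i, r in enumerate(ids)},
    )


def simulate_covariates(n_subjects: int, rng: np.random.Generator) -> CovariateTable:
    """Covariates mimicking a small healthy-adult travelling cohort:
    age ~ N(27.2, 3.1^2) truncated at 18 years, balanced 1:1 sex,
    days between scans uniform on 0..7, scan daytime uniform on 8-18 h."""
    age = rng.normal(27.2, 3.1, size=n_subjects)
    while np.any(age < 18):
        bad = age < 18
        age[bad] = rng.normal(27.2, 3.1, size=int(bad.sum()))
    sex = np.array(["F", "M"] * (n_subjects // 2 + 1))[:n_subjects]
    sex = sex[rng.permutation(n_subjects)]
    days = rng.integers(0, 8, size=n_subjects)
    daytime = rng.uniform(8.0, 18.0, size=n_subjects)
    df = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "days_between_scans": days,
            "daytime_of_scan": daytime,
        },
        index=pd.Index([f"sub-{i + 1:02d}" for i in range(n_subjects)], name="subject"),
    )
    return CovariateTable(table=df)


def simulate_cohort(cfg: SimConfig) -> CohortDataset:
    """Draw one fully crossed cohort under the additive variance-components
    model, optionally distorted by the per-scanner location-scale batch model."""
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    n_s, n_k = cfg.n_subjects, cfg.n_scanners
    n_e = edge_count(cfg.n_regions)

    partition = default_partition(cfg.n_regions)
    covariates = simulate_covariates(n_s, rng)
    subjects = covariates.subjects
    scanners = [f"scanner-{chr(ord('A') + k)}" for k in range(n_k)]

    mu = rng.normal(cfg.edge_mean, cfg.edge_mean_sd, size=n_e)
    X = covariates.design_matrix(subjects)  # (n_s, 4)
    beta = np.array([cfg.beta_age, cfg.beta_sex, cfg.beta_days, cfg.beta_daytime])
    bio_mean = mu[None, None, :] + (X @ beta)[:, None, None]  # (n_s, 1, n_e)

    sd_u = np.sqrt(cfg.f_subject * cfg.sigma2_total)
    sd_v = np.sqrt(cfg.f_scanner * cfg.sigma2_total)
    sd_e = np.sqrt(cfg.f_residual * cfg.sigma2_total)
    u = rng.normal(0.0, 1.0, size=(n_s, 1, n_e)) * sd_u
    v = rng.normal(0.0, 1.0, size=(1, n_k, n_e)) * sd_v
    eps = rng.normal(0.0, 1.0, size=(n_s, n_k, n_e)) * sd_e
    x = bio_mean + u + v + eps

    if cfg.batch is not None:
        b = cfg.batch
        gamma = np.empty((n_k, n_e))
        delta = np.empty((n_k, n_e))
        for k in range(n_k):
            gamma[k] = rng.normal(b.location_mean[k], b.location_sd[k], size=n_e)
            # InverseGamma(shape, scale): 1 / Gamma(shape, rate=scale)
            delta[k] = np.sqrt(1.0 / rng.gamma(b.scale_shape[k], 1.0 / b.scale_scale[k], size=n_e))
        x = bio_mean + gamma[None, :, :] + delta[None, :, :] * (x - bio_mean)

    if cfg.modality == "SC":
        # lognormal link: latent Gaussian scale -> nonnegative, right-skewed
        # streamline-weight-like values
        x = cfg.sc_scale * np.exp(x)

    return CohortDataset(
        edges=x,
        subjects=subjects,
        scanners=scanners,
        partition=partition,
        covariates=covariates,
        modality=cfg.modality,  # type: ignore[arg-type]
    )


# ---------------------------------------------------------------------------
# BOLD-like series and motion traces, to exercise FC construction and the
# scrubbing rule.


@dataclass(frozen=True)
class BoldSim:
    """One simulated resting-state acquisition: region x timepoint series
    plus a framewise-displacement trace (mm) per volume."""

    series: np.ndarray  # (n_regions, n_timepoints)
    fd: np.ndarray      # (n_timepoints,)
    region_ids: tuple[str, ...]


def simulate_bold(
    target_corr: np.ndarray,
    n_timepoints: int = 190,
    seed: int | np.random.Generator = 0,
    fd_spike_rate: float = 0.0,
    fd_spike_scale: float = 1.0,
) -> BoldSim:
    """Multivariate normal series with the requested population correlation.

    The default 190 timepoints match a ~8 min acquisition at TR 2.5 s. The
    sample correlation converges to ``target_corr`` as the series grows."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    C = np.asarray(target_corr, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ConfigError(f"target correlation must be square, got {C.shape}")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ConfigError("target correlation must be symmetric")
    if n_timepoints < 2:
        raise ConfigError("need at least 2 timepoints")
    w, V = np.linalg.eigh(C)
    if np.min(w) < -1e-10:
        raise ConfigError(f"target correlation not positive semi-definite (min eig {np.min(w):.3g})")
    root = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    n = C.shape[0]
    series = root @ rng.standard_normal(size=(n, n_timepoints))
    fd = simulate_fd(n_timepoints, fd_spike_rate, fd_spike_scale, rng)
    return BoldSim(
        series=series, fd=fd, region_ids=tuple(f"R{i:03d}" for i in range(n))
    )


def simulate_fd(
    n_volumes: int,
    spike_rate: float = 0.1,
    spike_scale: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Framewise-displacement trace: a low baseline (|N(0, 0.1^2)| mm, always
    below the 0.5 mm censoring threshold) plus motion spikes above the
    threshold at the given rate. The expected exceedance fraction over the
    0.5 mm threshold equals ``spike_rate``."""
    if not 0.0 <= spike_rate <= 1.0:
        raise ConfigError("spike_rate must be in [0, 1]")
    if spike_scale <= 0:
        raise ConfigError("spike_scale must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = np.abs(rng.normal(0.0, 0.1, size=n_volumes))
    base = np.minimum(base, 0.49)
    spikes = rng.random(n_volumes) < spike_rate
    fd = base.copy()
    fd[spikes] = 0.5 + np.abs(rng.normal(0.0, spike_scale, size=int(spikes.sum()))) + 1e-9
    return fd
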