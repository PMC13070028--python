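"""End-to-end pipeline: load or simulate a cohort, compute reliability and
agreement on the raw data, harmonise, recompute everything on the
harmonised data, and write a single auditable report bundle.

Every analysis is run on both the unharmonised and (when enabled) the
harmonised dataset, so scanner-effect removal can be judged side by side.
Outputs are TSV tables plus one ``report.json`` carrying all summaries,
the fitted harmonisation parameters, the seed, and a config hash for
provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from . import __version__
from .agreement import bland_altman_cohort, pattern_similarity, pattern_similarity_blocks
from .combat import apply_combat, fit_combat
from .data import (
    FLOAT_FMT,
    CohortDataset,
    read_covariates,
    read_edge_table,
    read_partition,
    write_covariates,
    write_edge_table,
    write_partition,
)
from .errors import ComputationError, ConfigError, ConnRelError
from .gstudy import gstudy_blocks, gstudy_table, scanner_variance_report
from .reliability import reliability_blocks, reliability_table
from .simulate import BatchModel, SimConfig, simulate_cohort


@dataclass
class RunConfig:
    """One pipeline run: either simulate a cohort or load one from files."""

    output_dir: str = "connrel-run"
    seed: int = 0
    simulate: dict | None = None          # SimConfig fields; None -> load inputs
    edge_table: str | None = None
    covariates: str | None = None
    partition: str | None = None
    modality: str = "FC"
    harmonize: bool = True
    eb: bool = True
    estimator: Literal["reml", "mom"] = "reml"

    def validate(self) -> None:
        if self.simulate is None:
            for name in ("edge_table", "covariates", "partition"):
                p = getattr(self, name)
                if p is None:
                    raise ConfigError(f"either 'simulate' or input path {name!r} is required")
                if not Path(p).exists():
                    raise ConfigError(f"{name} path does not exist: {p}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_or_simulate(cfg: RunConfig) -> CohortDataset:
    if cfg.simulate is not None:
        sim_kwargs = dict(cfg.simulate)
        batch = sim_kwargs.pop("batch", "default")
        if batch is None or batch == "default":
            batch_model = BatchModel() if batch == "default" else None
        elif isinstance(batch, dict):
            batch_model = BatchModel(**{k: tuple(v) for k, v in batch.items()})
        else:
            raise ConfigError(f"unrecognised batch model spec: {batch!r}")
        sim_kwargs.setdefault("rng_seed", cfg.seed)
        return simulate_cohort(SimConfig(batch=batch_model, **sim_kwargs))
    partition = read_partition(cfg.partition)
    covariates = read_covariates(cfg.covariates)
    return read_edge_table(cfg.edge_table, partition, covariates, cfg.modality)  # type: ignore[arg-type]


def _analysis_block(data: CohortDataset, estimator: str) -> dict:
    """All per-dataset analyses: reliability, G-study, agreement, similarity."""
    rel = reliability_table(data)
    gs = gstudy_table(data, estimator=estimator)  # type: ignore[arg-type]
    ba = bland_altman_cohort(data, by="network")
    sim_group = pattern_similarity(data, level="group")
    sim_subject = pattern_similarity(data, level="subject")
    return {
        "reliability": rel.summary(),
        "gstudy": gs.summary(),
        "bland_altman": {
            k: {f: getattr(v, f) for f in (
                "mean_difference", "sd_difference", "lower_loa", "upper_loa",
                "bias_slope", "bias_intercept", "n_points")}
            for k, v in ba.items()
        },
        "pattern_similarity": {
            "group_pcc": sim_group.pcc,
            "subject_pcc_mean": sim_subject.pcc,
            "subject_pcc": sim_subject.per_subject,
        },
        "_objects": {"rel": rel, "gstudy": gs},
    }


def _write_tables(outdir: Path, tag: str, data: CohortDataset, block: dict) -> None:
    rel = block["_objects"]["rel"]
    gs = block["_objects"]["gstudy"]
    ei = data.edge_index
    ids = np.asarray(data.partition.region_ids)
    frac = gs.components.fractions_percent
    per_edge = pd.DataFrame(
        {
            "region_i": ids[ei[:, 0]],
            "region_j": ids[ei[:, 1]],
            "icc_raw": rel.icc_raw,
            "icc": rel.icc,
            "wscv_percent": rel.wscv_percent,
            "subject_pct": frac[:, 0],
            "scanner_pct": frac[:, 1],
            "residual_pct": frac[:, 2],
        }
    )
    per_edge.to_csv(outdir / f"edge_metrics_{tag}.tsv", sep="\t", index=False,
                    float_format=FLOAT_FMT)
    for by in ("network", "lobe"):
        blocks = reliability_blocks(rel, data.partition, by=by)
        for metric, bm in blocks.items():
            bm.to_frame().to_csv(
                outdir / f"block_{metric}_{by}_{tag}.tsv", sep="\t", float_format=FLOAT_FMT
            )
        for metric, bm in gstudy_blocks(gs, data.partition, by=by).items():
            bm.to_frame().to_csv(
                outdir / f"block_{metric}_{by}_{tag}.tsv", sep="\t", float_format=FLOAT_FMT
            )
    pattern_similarity_blocks(data, by="network", level="group").to_csv(
        outdir / f"similarity_network_group_{tag}.tsv", sep="\t", index=False,
        float_format=FLOAT_FMT,
    )


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis sequence and write the report bundle.

    Returns the report dict (also written to ``<output_dir>/report.json``).
    On any stage failure the partially written output directory is cleared
    of result files before the error propagates."""
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        data = _load_or_simulate(cfg)
        report: dict = {
            "version": __version__,
            "seed": cfg.seed,
            "config": asdict(cfg),
            "config_hash": cfg.config_hash(),
            "modality": data.modality,
            "design": {
                "n_subjects": data.n_subjects,
                "n_scanners": data.n_scanners,
                "n_regions": data.n_regions,
                "n_edges": data.n_edges,
                "scanners": data.scanners,
            },
        }
        if cfg.simulate is not None:
            write_edge_table(data, outdir / "edges_unharmonised.tsv")
            write_covariates(data.covariates, outdir / "covariates.tsv")
            write_partition(data.partition, outdir / "partition.tsv")
            written += [outdir / "edges_unharmonised.tsv", outdir / "covariates.tsv",
                        outdir / "partition.tsv"]

        unharm = _analysis_block(data, cfg.estimator)
        _write_tables(outdir, "unharmonised", data, unharm)
        report["unharmonised"] = {k: v for k, v in unharm.items() if k != "_objects"}

        if cfg.harmonize:
            model = fit_combat(data, eb=cfg.eb)
            harmonised = apply_combat(data, model)
            write_edge_table(harmonised, outdir / "edges_harmonised.tsv")
            harm = _analysis_block(harmonised, cfg.estimator)
            _write_tables(outdir, "harmonised", harmonised, harm)
            report["harmonised"] = {k: v for k, v in harm.items() if k != "_objects"}
            report["combat_model"] = model.to_dict()
            report["scanner_variance"] = {
                k: v
                for k, v in scanner_variance_report(data, harmonised, estimator=cfg.estimator).items()
                if not isinstance(v, np.ndarray)
            }

        with open(outdir / "report.json", "w") as fh:
            json.dump(_sanitize(report), fh, indent=2)
        return report
    except ConnRelError:
        _cleanup(outdir)
        raise
    except Exception as exc:  # numerics gone wrong -> stage-named diagnostic
        _cleanup(outdir)
        raise ComputationError(f"pipeline failed: {exc}") from exc


def _cleanup(outdir: Path) -> None:
    for p in outdir.glob("*.tsv"):
        p.unlink(missing_ok=True)
    (outdir / "report.json").unlink(missing_ok=True)


def _sanitize(obj):
    """Make a report JSON-clean: numpy scalars to Python, NaN to null."""
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _sanitize(obj.tolist())
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj
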