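"""Core data model for edge-level connectomes.

A connectome for one (subject, scanner) observation is a symmetric
region x region matrix with a zero diagonal: functional connectivity (FC)
carries Fisher-z transformed Pearson correlations (signed, z-scale),
structural connectivity (SC) carries nonnegative streamline-weight sums.
Self-connections are excluded everywhere — they carry no information and
the Fisher z of r = 1 is infinite — so the diagonal is stored as exactly 0.

Everything downstream works on the strict upper triangle vectorised in
row-major (i < j) order; with 246 regions that is 30,135 unique edges.
``CohortDataset`` holds the fully crossed travelling-cohort design:
every subject observed on every scanner, as an array indexed
(subject, scanner, edge).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DesignError,
    IntegrityError,
    InvalidParcellationError,
    PartitionError,
    ShapeError,
    ValidationError,
)

#: Canonical large-scale network labels (Yeo7 + subcortex) and anatomical lobes
#: used by the synthetic partition. User partitions may use other labels but
#: are bounded to <= 8 networks and <= 7 lobes.
NETWORK_LABELS = ("CEN", "DAN", "DMN", "LIM", "SMN", "SUBC", "VAN", "VIS")
LOBE_LABELS = ("Fro", "Ins", "Lim", "Occ", "Par", "Subc", "Tem")

SYMMETRY_TOL = 1e-10

#: All floats are persisted with 17 significant digits so that TSV round
#: trips are bit-exact for IEEE doubles.
FLOAT_FMT = "%.17g"

Modality = Literal["FC", "SC"]


def edge_count(n_regions: int) -> int:
    """Number of unique edges (unordered region pairs) for a parcellation.

    A parcellation into n regions yields n(n-1)/2 edges; the 246-region
    atlas used for whole-brain connectomes yields 30,135.
    """
    n = int(n_regions)
    if n < 2:
        raise InvalidParcellationError(
            f"a parcellation needs at least 2 regions, got {n_regions}"
        )
    return n * (n - 1) // 2


def edge_index(n_regions: int) -> np.ndarray:
    """(E, 2) array of 0-based (i, j) region index pairs, i < j, row-major."""
    n = int(n_regions)
    if n < 2:
        raise InvalidParcellationError(
            f"a parcellation needs at least 2 regions, got {n_regions}"
        )
    iu = np.triu_indices(n, k=1)
    return np.column_stack(iu)


def _check_square_symmetric(values: np.ndarray, tol: float = SYMMETRY_TOL) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ShapeError(f"connectivity matrix must be square, got shape {values.shape}")
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValidationError(f"NaN entry in connectivity matrix at cell ({i}, {j})")
    asym = np.max(np.abs(values - values.T)) if values.size else 0.0
    if asym > tol:
        raise ShapeError(
            f"matrix asymmetric beyond tolerance: max |A - A.T| = {asym:.3g} > {tol:g}"
        )
    return values


def vectorize_upper(values: np.ndarray, tol: float = SYMMETRY_TOL) -> np.ndarray:
    """Strict upper triangle of a symmetric matrix, row-major (i < j) order."""
    values = _check_square_symmetric(values, tol)
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu].copy()


def devectorize(vec: np.ndarray, n_regions: int) -> np.ndarray:
    """Inverse of :func:`vectorize_upper`: rebuild the symmetric zero-diagonal matrix."""
    vec = np.asarray(vec, dtype=float)
    expected = edge_count(n_regions)
    if vec.shape != (expected,):
        raise ShapeError(
            f"edge vector of length {vec.shape} does not match "
            f"{n_regions} regions ({expected} edges)"
        )
    out = np.zeros((n_regions, n_regions), dtype=float)
    iu = np.triu_indices(n_regions, k=1)
    out[iu] = vec
    out += out.T
    return out


@dataclass(frozen=True)
class ConnMatrix:
    """One symmetric connectivity matrix for one (subject, scanner) observation."""

    values: np.ndarray
    modality: Modality
    subject_id: str = ""
    scanner_id: str = ""

    def __post_init__(self) -> None:
        values = _check_square_symmetric(self.values)
        if values.shape[0] < 2:
            raise InvalidParcellationError(
                f"a parcellation needs at least 2 regions, got {values.shape[0]}"
            )
        if np.any(np.diag(values) != 0.0):
            raise ValidationError("diagonal must be exactly 0 (self-connections excluded)")
        if self.modality not in ("FC", "SC"):
            raise ValidationError(f"modality must be 'FC' or 'SC', got {self.modality!r}")
        if self.modality == "SC" and np.any(values < 0):
            raise ValidationError("SC matrices must be nonnegative")
        object.__setattr__(self, "values", values)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def vectorize(self) -> np.ndarray:
        return vectorize_upper(self.values)


@dataclass(frozen=True)
class Partition:
    """Mapping from regions to large-scale networks and anatomical lobes.

    Every region carries exactly one network label (<= 8 distinct) and one
    lobe label (<= 7 distinct). Region order is authoritative: edge tables
    and matrices are aligned to ``region_ids`` order.
    """

    region_ids: tuple[str, ...]
    network_of: dict[str, str]
    lobe_of: dict[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "region_ids", tuple(str(r) for r in self.region_ids))
        if len(set(self.region_ids)) != len(self.region_ids):
            raise PartitionError("duplicate region ids in partition")
        missing_net = [r for r in self.region_ids if r not in self.network_of]
        missing_lobe = [r for r in self.region_ids if r not in self.lobe_of]
        if missing_net or missing_lobe:
            raise PartitionError(
                f"regions without labels: network={missing_net[:5]} lobe={missing_lobe[:5]}"
            )
        n_net = len(set(self.network_of[r] for r in self.region_ids))
        n_lobe = len(set(self.lobe_of[r] for r in self.region_ids))
        if n_net > 8:
            raise PartitionError(f"{n_net} distinct network labels (max 8)")
        if n_lobe > 7:
            raise PartitionError(f"{n_lobe} distinct lobe labels (max 7)")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def labels(self, by: Literal["network", "lobe"]) -> np.ndarray:
        """Per-region label array aligned with ``region_ids``."""
        if by == "network":
            return np.array([self.network_of[r] for r in self.region_ids])
        if by == "lobe":
            return np.array([self.lobe_of[r] for r in self.region_ids])
        raise ValidationError(f"unknown aggregation level {by!r}")


COVARIATE_COLUMNS = ("age", "sex", "days_between_scans", "daytime_of_scan")


@dataclass(frozen=True)
class CovariateTable:
    """Per-subject covariates: age (years), sex (binary), days between the
    two scans (integer days), and daytime of scan (hour of day).

    These are the four covariates preserved by harmonisation.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"covariate table missing columns: {missing}")
        df = df[list(COVARIATE_COLUMNS)]
        if df.index.has_duplicates:
            raise IntegrityError("duplicate subject rows in covariate table")
        if df.isna().any().any():
            bad = df.columns[df.isna().any()].tolist()
            raise ValidationError(f"missing covariate values in columns: {bad}")
        sex_levels = sorted(pd.unique(df["sex"].astype(str)))
        if len(sex_levels) > 2:
            raise ValidationError(f"sex must be binary, got levels {sex_levels}")
        df.index = df.index.astype(str)
        object.__setattr__(self, "table", df)

    @property
    def subjects(self) -> list[str]:
        return list(self.table.index)

    def design_matrix(self, subjects: Sequence[str]) -> np.ndarray:
        """Numeric (n, 4) design: age, sex dummy (second sorted level = 1),
        days_between_scans, daytime_of_scan."""
        unknown = [s for s in subjects if str(s) not in self.table.index]
        if unknown:
            raise ValidationError(f"subjects without covariates: {unknown}")
        sub = self.table.loc[[str(s) for s in subjects]]
        sex_levels = sorted(pd.unique(self.table["sex"].astype(str)))
        sex = (sub["sex"].astype(str) == sex_levels[-1]).astype(float).to_numpy()
        return np.column_stack(
            [
                sub["age"].astype(float).to_numpy(),
                sex,
                sub["days_between_scans"].astype(float).to_numpy(),
                sub["daytime_of_scan"].astype(float).to_numpy(),
            ]
        )


@dataclass
class CohortDataset:
    """Fully crossed travelling-cohort design.

    ``edges`` is indexed (subject, scanner, edge); the design is rejected if
    any (subject, scanner) cell is missing, since both the reliability
    metrics and the variance decomposition require the complete crossing.
    """

    edges: np.ndarray
    subjects: list[str]
    scanners: list[str]
    partition: Partition
    covariates: CovariateTable
    modality: Modality

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.subjects = [str(s) for s in self.subjects]
        self.scanners = [str(s) for s in self.scanners]
        n_e = edge_count(self.partition.n_regions)
        expected = (len(self.subjects), len(self.scanners), n_e)
        if self.edges.shape != expected:
            raise DesignError(
                f"edges array shape {self.edges.shape} does not match the "
                f"crossed design {expected} (subjects x scanners x edges)"
            )
        if np.isnan(self.edges).any():
            raise DesignError("edges array contains NaN — crossed design incomplete")
        if self.modality == "SC" and np.any(self.edges < 0):
            raise ValidationError("SC edge values must be nonnegative")
        missing_cov = [s for s in self.subjects if s not in self.covariates.table.index]
        if missing_cov:
            raise ValidationError(f"subjects without covariates: {missing_cov}")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_scanners(self) -> int:
        return len(self.scanners)

    @property
    def n_edges(self) -> int:
        return self.edges.shape[2]

    @property
    def n_regions(self) -> int:
        return self.partition.n_regions

    @property
    def edge_index(self) -> np.ndarray:
        return edge_index(self.n_regions)

    def to_matrix(self, subject: str, scanner: str) -> ConnMatrix:
        p = self.subjects.index(str(subject))
        s = self.scanners.index(str(scanner))
        return ConnMatrix(
            values=devectorize(self.edges[p, s], self.n_regions),
            modality=self.modality,
            subject_id=str(subject),
            scanner_id=str(scanner),
        )

    def scanner_mean(self, scanner: str) -> np.ndarray:
        """Subject-averaged edge vector for one scanner (the group connectome)."""
        s = self.scanners.index(str(scanner))
        return self.edges[:, s, :].mean(axis=0)

    def with_edges(self, edges: np.ndarray) -> "CohortDataset":
        return CohortDataset(
            edges=edges,
            subjects=list(self.subjects),
            scanners=list(self.scanners),
            partition=self.partition,
            covariates=self.covariates,
            modality=self.modality,
        )


# ---------------------------------------------------------------------------
# Block aggregation


@dataclass(frozen=True)
class BlockMatrix:
    """Symmetric block aggregate of an edge-level metric.

    Cell (A, B) is the reducer over edges with one endpoint in block A and
    the other in B; A = B uses within-block edges. Blocks with no edges (or
    only undefined metric values) are reported as NaN and flagged in
    ``empty``, never silently zero.
    """

    labels: tuple[str, ...]
    values: np.ndarray       # (L, L), NaN where empty
    n_edges: np.ndarray      # (L, L) total edges in block
    n_valid: np.ndarray      # (L, L) edges with a defined metric

    @property
    def empty(self) -> np.ndarray:
        return self.n_valid == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))


def edge_block_labels(
    partition: Partition, by: Literal["network", "lobe"]
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Per-edge (block_a, block_b) integer label indices, block_a <= block_b."""
    region_labels = partition.labels(by)
    uniq = tuple(sorted(set(region_labels)))
    lab_idx = {l: k for k, l in enumerate(uniq)}
    codes = np.array([lab_idx[l] for l in region_labels])
    ei = edge_index(partition.n_regions)
    a = codes[ei[:, 0]]
    b = codes[ei[:, 1]]
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    return lo, hi, uniq


def block_aggregate(
    edge_metric: np.ndarray,
    partition: Partition,
    by: Literal["network", "lobe"] = "network",
    reducer: Literal["mean", "median"] = "mean",
) -> BlockMatrix:
    """Aggregate an edge-level metric into a network x network (or lobe x lobe)
    block matrix. NaN metric values (flagged edges) are skipped by the reducer."""
    edge_metric = np.asarray(edge_metric, dtype=float)
    n_e = edge_count(partition.n_regions)
    if edge_metric.shape != (n_e,):
        raise ShapeError(
            f"edge metric length {edge_metric.shape} does not match partition "
            f"({n_e} edges)"
        )
    if reducer not in ("mean", "median"):
        raise ValidationError(f"unknown reducer {reducer!r}")
    lo, hi, uniq = edge_block_labels(partition, by)
    n_lab = len(uniq)
    values = np.full((n_lab, n_lab), np.nan)
    n_edges_m = np.zeros((n_lab, n_lab), dtype=int)
    n_valid_m = np.zeros((n_lab, n_lab), dtype=int)
    flat = lo * n_lab + hi
    order = np.argsort(flat, kind="stable")
    flat_sorted = flat[order]
    bounds = np.flatnonzero(np.r_[True, np.diff(flat_sorted) != 0, True])
    for k in range(len(bounds) - 1):
        sl = order[bounds[k]: bounds[k + 1]]
        a, b = divmod(int(flat_sorted[bounds[k]]), n_lab)
        vals = edge_metric[sl]
        good = vals[~np.isnan(vals)]
        n_edges_m[a, b] = n_edges_m[b, a] = sl.size
        n_valid_m[a, b] = n_valid_m[b, a] = good.size
        if good.size:
            agg = float(np.mean(good) if reducer == "mean" else np.median(good))
            values[a, b] = values[b, a] = agg
    return BlockMatrix(labels=uniq, values=values, n_edges=n_edges_m, n_valid=n_valid_m)


# ---------------------------------------------------------------------------
# File I/O — TSV throughout, floats at 17 significant digits for lossless
# round trips, deterministic row ordering.


def write_partition(partition: Partition, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "region_id": list(partition.region_ids),
            "network": [partition.network_of[r] for r in partition.region_ids],
            "lobe": [partition.lobe_of[r] for r in partition.region_ids],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_partition(path: str | Path) -> Partition:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"region_id", "network", "lobe"}
    if not required.issubset(df.columns):
        raise ValidationError(f"partition file must have columns {sorted(required)}")
    if df[["region_id", "network", "lobe"]].isna().any().any():
        raise PartitionError("partition file has missing labels")
    return Partition(
        region_ids=tuple(df["region_id"]),
        network_of=dict(zip(df["region_id"], df["network"])),
        lobe_of=dict(zip(df["region_id"], df["lobe"])),
    )


def write_covariates(cov: CovariateTable, path: str | Path) -> None:
    df = cov.table.copy()
    df.insert(0, "subject", df.index)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_covariates(path: str | Path) -> CovariateTable:
    df = pd.read_csv(path, sep="\t", dtype={"subject": str, "sex": str},
                     float_precision="round_trip")
    if "subject" not in df.columns:
        raise ValidationError("covariates file must have a 'subject' column")
    df = df.set_index("subject")
    return CovariateTable(table=df)


def write_matrix(m: ConnMatrix, path: str | Path, region_ids: Sequence[str] | None = None) -> None:
    ids = list(region_ids) if region_ids is not None else [f"R{i:03d}" for i in range(m.n_regions)]
    pd.DataFrame(m.values, index=ids, columns=ids).to_csv(
        path, sep="\t", float_format=FLOAT_FMT
    )


def read_matrix(
    path: str | Path, modality: Modality, subject_id: str = "", scanner_id: str = ""
) -> ConnMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValidationError(
            f"NaN cell in matrix file at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    return ConnMatrix(values=values, modality=modality, subject_id=subject_id, scanner_id=scanner_id)


def write_edge_table(data: CohortDataset, path: str | Path) -> None:
    """Long-format TSV: subject, scanner, region_i, region_j, value.

    Rows ordered by (subject, scanner, edge) following dataset order."""
    ei = data.edge_index
    ids = np.asarray(data.partition.region_ids)
    n_s, n_k, n_e = data.edges.shape
    df = pd.DataFrame(
        {
            "subject": np.repeat(data.subjects, n_k * n_e),
            "scanner": np.tile(np.repeat(data.scanners, n_e), n_s),
            "region_i": np.tile(ids[ei[:, 0]], n_s * n_k),
            "region_j": np.tile(ids[ei[:, 1]], n_s * n_k),
            "value": data.edges.reshape(-1),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_edge_table(
    path: str | Path,
    partition: Partition,
    covariates: CovariateTable,
    modality: Modality,
) -> CohortDataset:
    """Read a long-format edge table into a CohortDataset.

    Region order comes from the partition (files carry region ids, never bare
    indices). Duplicate (subject, scanner, edge) rows raise IntegrityError;
    incomplete crossings raise DesignError."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"subject": str, "scanner": str, "region_i": str, "region_j": str},
        float_precision="round_trip",
    )
    required = {"subject", "scanner", "region_i", "region_j", "value"}
    if not required.issubset(df.columns):
        raise ValidationError(f"edge table must have columns {sorted(required)}")
    if df["value"].isna().any():
        row = df.index[df["value"].isna()][0]
        raise ValidationError(f"NaN value in edge table at row {row}")

    ids = list(partition.region_ids)
    pos = {r: k for k, r in enumerate(ids)}
    unknown = set(df["region_i"]).union(df["region_j"]) - set(ids)
    if unknown:
        raise PartitionError(f"edge table references regions absent from partition: {sorted(unknown)[:5]}")

    n = partition.n_regions
    i = df["region_i"].map(pos).to_numpy()
    j = df["region_j"].map(pos).to_numpy()
    lo = np.minimum(i, j)
    hi = np.maximum(i, j)
    if np.any(lo == hi):
        raise ValidationError("edge table contains self-connections (region_i == region_j)")
    # row-major upper-triangle linear index of the (lo, hi) pair
    eidx = lo * n - lo * (lo + 1) // 2 + (hi - lo - 1)

    subjects = list(dict.fromkeys(df["subject"]))
    scanners = list(dict.fromkeys(df["scanner"]))
    s_pos = {s: k for k, s in enumerate(subjects)}
    k_pos = {s: k for k, s in enumerate(scanners)}
    n_e = edge_count(n)

    key = (
        df["subject"].map(s_pos).to_numpy() * len(scanners) + df["scanner"].map(k_pos).to_numpy()
    ) * n_e + eidx
    if len(np.unique(key)) != len(key):
        raise IntegrityError("duplicate (subject, scanner, edge) rows in edge table")

    edges = np.full((len(subjects), len(scanners), n_e), np.nan)
    edges.reshape(-1)[key] = df["value"].to_numpy(dtype=float)
    if np.isnan(edges).any():
        p, s, _ = np.argwhere(np.isnan(edges))[0]
        raise DesignError(
            f"incomplete crossed design: subject {subjects[p]!r} on scanner "
            f"{scanners[s]!r} is missing edges"
        )
    return CohortDataset(
        edges=edges,
        subjects=subjects,
        scanners=scanners,
        partition=partition,
        covariates=covariates,
        modality=modality,
    )
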