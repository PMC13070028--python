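"""Data model: edge vectorisation, partitions, block aggregation, file I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import connrel as cr
from connrel.errors import (
    DesignError,
    IntegrityError,
    InvalidParcellationError,
    PartitionError,
    ShapeError,
    ValidationError,
)


@pytest.mark.parametrize(
    "n, expected", [(246, 30135), (2, 1), (8, 28), (3, 3), (100, 4950)]
)
def test_edge_count(n, expected):
    assert cr.edge_count(n) == expected


def test_edge_count_rejects_degenerate_parcellation():
    with pytest.raises(InvalidParcellationError):
        cr.edge_count(1)


def _random_symmetric(rng, n):
    a = rng.normal(size=(n, n))
    m = (a + a.T) / 2
    np.fill_diagonal(m, 0.0)
    return m


def test_vectorize_upper_definition():
    m = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
    assert np.array_equal(cr.vectorize_upper(m), [1.0, 2.0, 3.0])


def test_vectorize_length_matches_edge_count():
    rng = np.random.default_rng(0)
    m = _random_symmetric(rng, 246)
    assert cr.vectorize_upper(m).shape == (30135,)
    for n in range(2, 40):
        assert cr.vectorize_upper(_random_symmetric(rng, n)).size == cr.edge_count(n)


@settings(max_examples=50, deadline=None)
@given(st.integers(min_value=2, max_value=25), st.integers(min_value=0, max_value=2**31 - 1))
def test_vectorize_devectorize_roundtrip(n, seed):
    m = _random_symmetric(np.random.default_rng(seed), n)
    assert np.array_equal(cr.devectorize(cr.vectorize_upper(m), n), m)


def test_vectorize_rejects_asymmetry():
    m = np.array([[0.0, 1.0], [1.1, 0.0]])
    with pytest.raises(ShapeError):
        cr.vectorize_upper(m)


def test_connmatrix_invariants():
    with pytest.raises(ValidationError):
        cr.ConnMatrix(values=np.array([[1.0, 0.5], [0.5, 0.0]]), modality="FC")
    with pytest.raises(ValidationError):
        cr.ConnMatrix(values=np.array([[0.0, -0.5], [-0.5, 0.0]]), modality="SC")
    # FC may be signed
    cr.ConnMatrix(values=np.array([[0.0, -0.5], [-0.5, 0.0]]), modality="FC")


def _four_region_partition():
    return cr.Partition(
        region_ids=("r1", "r2", "r3", "r4"),
        network_of={"r1": "N1", "r2": "N1", "r3": "N2", "r4": "N2"},
        lobe_of={r: "Fro" for r in ("r1", "r2", "r3", "r4")},
    )


def test_block_aggregate_hand_worked():
    # edges in row-major order: (r1,r2)=1.0 within N1, (r3,r4)=3.0 within N2,
    # four between edges each 2.0
    part = _four_region_partition()
    metric = np.array([1.0, 2.0, 2.0, 2.0, 2.0, 3.0])
    bm = cr.block_aggregate(metric, part, by="network", reducer="mean")
    df = bm.to_frame()
    assert df.loc["N1", "N1"] == 1.0
    assert df.loc["N2", "N2"] == 3.0
    assert df.loc["N1", "N2"] == 2.0 == df.loc["N2", "N1"]


def test_block_aggregate_constant_and_single_label(small_cohort):
    part = small_cohort.partition
    metric = np.full(small_cohort.n_edges, 3.25)
    bm = cr.block_aggregate(metric, part, by="network")
    assert np.allclose(bm.values[~bm.empty], 3.25)
    # single-label partition equals the global reducer
    one = cr.Partition(
        region_ids=part.region_ids,
        network_of={r: "ALL" for r in part.region_ids},
        lobe_of={r: part.lobe_of[r] for r in part.region_ids},
    )
    rng = np.random.default_rng(5)
    metric = rng.normal(size=small_cohort.n_edges)
    bm = cr.block_aggregate(metric, one, by="network", reducer="median")
    assert bm.values.shape == (1, 1)
    assert bm.values[0, 0] == pytest.approx(np.median(metric), abs=0)


def test_block_aggregate_flags_empty_blocks():
    # N3 has a single region -> no within-N3 edges
    part = cr.Partition(
        region_ids=("a", "b", "c"),
        network_of={"a": "N1", "b": "N1", "c": "N3"},
        lobe_of={r: "Fro" for r in ("a", "b", "c")},
    )
    bm = cr.block_aggregate(np.array([1.0, 2.0, 3.0]), part, by="network")
    df = bm.to_frame()
    assert np.isnan(df.loc["N3", "N3"])
    assert bm.empty[list(bm.labels).index("N3"), list(bm.labels).index("N3")]


def test_block_count_for_eight_networks(small_cohort):
    bm = cr.block_aggregate(
        np.ones(small_cohort.n_edges), small_cohort.partition, by="network"
    )
    n = len(bm.labels)
    assert n == 8
    assert n * (n + 1) // 2 == 36  # 8 within + 28 between cells


def test_partition_label_limits():
    with pytest.raises(PartitionError):
        cr.Partition(
            region_ids=tuple(f"r{i}" for i in range(9)),
            network_of={f"r{i}": f"NET{i}" for i in range(9)},  # 9 networks
            lobe_of={f"r{i}": "Fro" for i in range(9)},
        )
    with pytest.raises(PartitionError):
        cr.Partition(
            region_ids=("a", "b"),
            network_of={"a": "N1"},  # b unlabeled
            lobe_of={"a": "Fro", "b": "Fro"},
        )


def test_cohort_io_roundtrip(tmp_path, small_cohort):
    p = tmp_path / "edges.tsv"
    cr.write_edge_table(small_cohort, p)
    back = cr.read_edge_table(
        p, small_cohort.partition, small_cohort.covariates, small_cohort.modality
    )
    assert np.array_equal(back.edges, small_cohort.edges)  # bit-exact round trip
    assert back.subjects == small_cohort.subjects
    assert back.scanners == small_cohort.scanners

    cp = tmp_path / "cov.tsv"
    cr.write_covariates(small_cohort.covariates, cp)
    cov2 = cr.read_covariates(cp)
    pd.testing.assert_frame_equal(cov2.table, small_cohort.covariates.table)

    pp = tmp_path / "part.tsv"
    cr.write_partition(small_cohort.partition, pp)
    part2 = cr.read_partition(pp)
    assert part2 == small_cohort.partition


def test_matrix_io_roundtrip(tmp_path, small_cohort):
    m = small_cohort.to_matrix(small_cohort.subjects[0], small_cohort.scanners[0])
    p = tmp_path / "m.tsv"
    cr.write_matrix(m, p, region_ids=small_cohort.partition.region_ids)
    back = cr.read_matrix(p, "FC")
    assert np.array_equal(back.values, m.values)


def test_matrix_io_rejects_nan(tmp_path, small_cohort):
    m = small_cohort.to_matrix(small_cohort.subjects[0], small_cohort.scanners[0])
    p = tmp_path / "m.tsv"
    cr.write_matrix(m, p, region_ids=small_cohort.partition.region_ids)
    text = p.read_text().splitlines()
    fields = text[1].split("\t")
    fields[2] = "nan"
    text[1] = "\t".join(fields)
    p.write_text("\n".join(text))
    with pytest.raises(ValidationError, match="R00"):
        cr.read_matrix(p, "FC")


def test_edge_table_missing_cell_is_design_error(tmp_path, small_cohort):
    p = tmp_path / "edges.tsv"
    cr.write_edge_table(small_cohort, p)
    df = pd.read_csv(p, sep="\t")
    df = df[~((df.subject == small_cohort.subjects[0]) & (df.scanner == small_cohort.scanners[1]))]
    df.to_csv(p, sep="\t", index=False)
    with pytest.raises(DesignError):
        cr.read_edge_table(
            p, small_cohort.partition, small_cohort.covariates, small_cohort.modality
        )


def test_edge_table_duplicate_rows_is_integrity_error(tmp_path, small_cohort):
    p = tmp_path / "edges.tsv"
    cr.write_edge_table(small_cohort, p)
    df = pd.read_csv(p, sep="\t")
    df = pd.concat([df, df.iloc[[0]]])
    df.to_csv(p, sep="\t", index=False)
    with pytest.raises(IntegrityError):
        cr.read_edge_table(
            p, small_cohort.partition, small_cohort.covariates, small_cohort.modality
        )
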