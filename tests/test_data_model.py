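"""Domain types, CSV ingestion, pooling and round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rootstage import (
    STAGES,
    InducedLRPRecord,
    RootObservation,
    SchemaError,
    StageCountVector,
    StageOntology,
    ValidationError,
    pool_by_genotype,
    read_induced_table,
    read_root_table,
    write_induced_table,
    write_result_table,
    write_root_table,
)

HEADER = "root_id,genotype,pr_length_cm,emerged_count," + ",".join(f"stage_{s}" for s in STAGES)


def test_ontology_structure():
    ont = StageOntology()
    assert len(ont.levels) == 8
    assert ont.early_set == {"I", "II", "III", "IV"}
    assert ont.late_set == {"VII", "E"}
    assert not ont.early_set & ont.late_set
    with pytest.raises(ValidationError):
        ont.index("IX")


def test_stage_count_vector_invariants():
    v = StageCountVector((1, 0, 0, 0, 0, 0, 0, 2))
    assert v.n == 3
    assert v["E"] == 2 and v[0] == 1
    with pytest.raises(ValidationError):
        StageCountVector((1, 2, 3))  # wrong length
    with pytest.raises(ValidationError):
        StageCountVector((1, -1, 0, 0, 0, 0, 0, 0))


def test_root_observation_contracts():
    counts = StageCountVector((0, 0, 0, 0, 0, 0, 0, 1))
    with pytest.raises(ValidationError):
        RootObservation("r", "g", -1.0, 1, counts)
    with pytest.raises(ValidationError):  # emerged_count disagreeing with stage_E
        RootObservation("r", "g", 5.0, 2, counts)
    with pytest.raises(ValidationError):  # position beyond root tip
        RootObservation("r", "g", 5.0, 1, counts, lr_positions_cm=(6.0,))


def test_read_root_table_parses_counts(tmp_path):
    p = tmp_path / "roots.csv"
    p.write_text(HEADER + "\nr1,Col0,5.0,2,1,0,0,0,0,0,0,2\n")
    obs = read_root_table(p)
    assert len(obs) == 1
    assert obs[0].stage_counts.n == 3
    assert obs[0].emerged_count == 2


def test_read_root_table_empty_file(tmp_path):
    p = tmp_path / "roots.csv"
    p.write_text(HEADER + "\n")
    assert read_root_table(p) == []


def test_read_root_table_reports_bad_row(tmp_path):
    p = tmp_path / "roots.csv"
    p.write_text(
        HEADER + "\nr1,Col0,5.0,0,1,0,0,0,0,0,0,0\nr2,Col0,5.0,0,0,0,-1,0,0,0,0,0\n"
    )
    with pytest.raises(ValidationError, match="row 2"):
        read_root_table(p)


def test_read_root_table_missing_column(tmp_path):
    p = tmp_path / "roots.csv"
    p.write_text("root_id,genotype\nr1,Col0\n")
    with pytest.raises(SchemaError, match="stage_I"):
        read_root_table(p)


def test_induced_table_rejects_unknown_stage(tmp_path):
    p = tmp_path / "induced.csv"
    p.write_text("seedling_id,genotype,observation_time_h,stage\ns1,Col0,18,IX\n")
    with pytest.raises(ValidationError, match="row 1"):
        read_induced_table(p)


def test_pool_by_genotype_examples():
    def root(rid, g, counts):
        return RootObservation(rid, g, 5.0, counts[-1], StageCountVector(tuple(counts)))

    a = root("r1", "Col0", [1, 0, 0, 0, 0, 0, 0, 0])
    b = root("r2", "Col0", [0, 1, 0, 0, 0, 0, 0, 0])
    (table,) = pool_by_genotype([a, b])
    assert table.pooled.counts == (1, 1, 0, 0, 0, 0, 0, 0)
    assert table.n_roots == 2
    (single,) = pool_by_genotype([a])
    assert single.pooled == a.stage_counts
    with pytest.raises(ValidationError):
        pool_by_genotype([])


@given(
    st.lists(
        st.tuples(
            st.sampled_from(["g1", "g2", "g3"]),
            st.lists(st.integers(0, 9), min_size=8, max_size=8),
        ),
        min_size=1,
        max_size=15,
    )
)
def test_pooling_conserves_totals(rows):
    obs = [
        RootObservation(f"r{i}", g, 5.0, c[-1], StageCountVector(tuple(c)))
        for i, (g, c) in enumerate(rows)
    ]
    tables = pool_by_genotype(obs)
    assert sum(t.pooled.n for t in tables) == sum(o.stage_counts.n for o in obs)
    # element-wise: pooled counts are brute-force sums
    for t in tables:
        brute = np.sum(
            [o.stage_counts.as_array() for o in obs if o.genotype == t.genotype], axis=0
        )
        assert np.array_equal(t.pooled.as_array(), brute)


def test_root_table_round_trip(tmp_path, small_observations):
    p = tmp_path / "roots.csv"
    write_root_table(small_observations, p)
    back = read_root_table(p)
    assert back == small_observations


def test_induced_table_round_trip(tmp_path):
    records = [
        InducedLRPRecord("s1", "Col0", 18.0, "III"),
        InducedLRPRecord("s2", "Col0", 42.0, "E"),
        InducedLRPRecord("s3", "mutant", 18.0, "NONE"),
    ]
    p = tmp_path / "induced.csv"
    write_induced_table(records, p)
    assert read_induced_table(p) == records


def test_write_result_table_formatting(tmp_path):
    p = tmp_path / "out.csv"
    write_result_table([{"genotype": "mutant", "p_value": 0.0317}], p)
    text = p.read_text()
    assert "p_value" in text.splitlines()[0]
    assert "0.0317" in text
    # header-only for an empty result set
    p2 = tmp_path / "empty.csv"
    write_result_table(pd.DataFrame(columns=["genotype", "p_value"]), p2)
    assert p2.read_text().strip() == "genotype,p_value"
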