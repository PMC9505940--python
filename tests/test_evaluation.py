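"""Table ingestion, condition filters and scoring metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pspgnm.config import RunConfig
from pspgnm.errors import DegenerateInputError
from pspgnm.evaluation import (
    MutationTableRecord,
    antisymmetry,
    bias,
    filter_conditions,
    parameter_scan,
    pearson,
    read_mutation_table,
    rmse,
    summarize,
)
from pspgnm.fixtures import FixtureSpec, make_benchmark_table, make_toy_chain
from pspgnm.structure_io import MutationSpec

from oracles import bias_brute, pearson_brute, rmse_brute

CSV = """pdb_id,chain_id,mutation,temperature,ph,exp_ddg
1ABC,A,D89E,25,7.0,-1.2
2XYZ,B,G45W,24.5,6.9,0.8
3DEF,A,K10A,37,2.0,-3.1
"""


def test_three_row_table_reads_exactly():
    result = read_mutation_table(CSV)
    assert len(result.records) == 3 and not result.rejects
    first = result.records[0]
    assert first.pdb_id == "1ABC" and first.chain_id == "A"
    assert (first.mutation.wt_res, first.mutation.position.number,
            first.mutation.mut_res) == ("D", 89, "E")
    assert first.temperature == 25.0 and first.ph == 7.0
    assert first.exp_ddg == -1.2


def test_malformed_rows_collected_not_dropped_silently():
    bad = CSV + "4GHI,A,notamutation,25,7,0.5\n5JKL,A,D3D,25,7,\n"
    result = read_mutation_table(bad)
    assert len(result.records) == 3
    assert [row for row, _ in result.rejects] == [5, 6]


def test_missing_columns_raise():
    with pytest.raises(ValueError, match="missing columns"):
        read_mutation_table("pdb_id,chain_id\n1ABC,A\n")


def test_benchmark_table_roundtrip():
    bench = make_benchmark_table(40, seed=3)
    result = read_mutation_table(bench.csv_text)
    assert len(result.records) == 40 and not result.rejects
    for record, row in zip(result.records, bench.rows):
        assert record.pdb_id == row["pdb_id"]
        assert str(record.mutation) == row["mutation"]
        assert record.temperature == row["temperature"]
        assert record.ph == row["ph"]
    # determinism
    assert make_benchmark_table(40, seed=3).csv_text == bench.csv_text


def test_filter_conditions_rules():
    records = read_mutation_table(CSV).records
    kept = filter_conditions(records, (24, 26), (6.8, 7.2))
    assert [r.pdb_id for r in kept] == ["1ABC", "2XYZ"]
    # missing values are dropped even with infinite ranges
    inf = (float("-inf"), float("inf"))
    bench = make_benchmark_table(60, seed=1)
    records = read_mutation_table(bench.csv_text).records
    kept = filter_conditions(records, inf, inf)
    assert all(r.temperature is not None and r.ph is not None for r in kept)
    n_missing = sum(1 for row in bench.rows
                    if row["temperature"] is None or row["ph"] is None)
    assert len(kept) == 60 - n_missing


def test_filter_matches_generator_bookkeeping():
    bench = make_benchmark_table(100, seed=9)
    records = read_mutation_table(bench.csv_text).records
    kept = filter_conditions(records, (24, 26), (6.8, 7.2))
    assert len(kept) == sum(bench.in_range)
    kept_ids = {r.pdb_id for r in kept}
    expected = {row["pdb_id"] for row, ok in zip(bench.rows, bench.in_range) if ok}
    assert kept_ids == expected


def test_metric_trivial_identities():
    x = [1.0, 2.0, 3.5, -1.0]
    assert pearson(x, x) == pytest.approx(1.0, abs=1e-12)
    assert pearson(x, [-v for v in x]) == pytest.approx(-1.0, abs=1e-12)
    assert rmse(x, x) == 0.0
    assert antisymmetry(x, [-v for v in x]) == pytest.approx(-1.0, abs=1e-12)
    assert antisymmetry(x, x) == pytest.approx(1.0, abs=1e-12)
    assert bias(x, [-v for v in x]) == 0.0
    assert bias([1.0] * 4, [1.0] * 4) == 1.0


def test_metrics_match_textbook_oracles(rng):
    x = list(rng.normal(size=40))
    y = list(rng.normal(size=40))
    assert pearson(x, y) == pytest.approx(pearson_brute(x, y), abs=1e-12)
    assert rmse(x, y) == pytest.approx(rmse_brute(x, y), abs=1e-12)
    assert bias(x, y) == pytest.approx(bias_brute(x, y), abs=1e-12)
    assert antisymmetry(x, y) == pytest.approx(pearson_brute(x, y), abs=1e-12)


def test_metric_degenerate_inputs():
    with pytest.raises(DegenerateInputError):
        pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(DegenerateInputError):
        pearson([1.0], [2.0])
    with pytest.raises(DegenerateInputError):
        bias([], [])
    with pytest.raises(DegenerateInputError):
        rmse([1.0, float("nan")], [0.0, 0.0])


@settings(deadline=None, derandomize=True, max_examples=30)
@given(
    a=st.floats(min_value=0.1, max_value=50),
    b=st.floats(min_value=-100, max_value=100),
    seed=st.integers(min_value=0, max_value=2**16),
)
def test_pearson_affine_invariance_rmse_translation(a, b, seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=12)
    y = rng.normal(size=12)
    if np.std(a * x + b) == 0:
        return
    assert pearson(a * x + b, y) == pytest.approx(pearson(x, y), abs=1e-9)
    assert rmse(x + b, y + b) == pytest.approx(rmse(x, y), abs=1e-9)


def _fixture_provider(n_residues=20):
    cache = {}

    def provider(record):
        if record.pdb_id not in cache:
            seed = int(record.pdb_id.replace("SYN", ""))
            st_, _ = make_toy_chain(
                FixtureSpec(n_residues=n_residues, seed=seed),
                with_bfactors=False,
            )
            cache[record.pdb_id] = st_
        return cache[record.pdb_id]

    return provider


def _scan_records(mj, n=5, n_residues=20):
    provider = _fixture_provider(n_residues)
    records = []
    for i in range(n):
        st_, _ = make_toy_chain(FixtureSpec(n_residues=n_residues, seed=i),
                                with_bfactors=False)
        wt_res = st_.residues[9][1]
        mut_res = "W" if wt_res != "W" else "F"
        records.append(MutationTableRecord(
            pdb_id=f"SYN{i}", chain_id="A",
            mutation=MutationSpec("A", st_.residues[9][0], wt_res, mut_res),
            temperature=25.0, ph=7.0, exp_ddg=float(i) - 2.0,
        ))
    return records, provider


def test_parameter_scan_single_point_bookkeeping(mj):
    records, provider = _scan_records(mj)
    frame = parameter_scan(records, provider, mj, rc_grid=[9.0], mode_grid=[10])
    assert len(frame) == 1
    row = frame.iloc[0]
    assert row.rc == 9.0 and row.n_modes == 10
    assert 0 <= row.pct_predictions <= 100
    assert row.n_scored == len(records)  # zeros included by default


def test_parameter_scan_all_defaulted_zero(mj):
    # extended chains have no contacts: every record defaults to zero
    provider = _fixture_provider()

    def ext_provider(record):
        st_, _ = make_toy_chain(
            FixtureSpec(n_residues=10, geometry="extended", seed=0),
            with_bfactors=False,
        )
        return st_

    records, _ = _scan_records(mj, n=3, n_residues=10)
    ext, _ = make_toy_chain(FixtureSpec(n_residues=10, geometry="extended",
                                        seed=0), with_bfactors=False)
    fixed = []
    for i, r in enumerate(records):
        wt_res = ext.residues[4][1]
        mut_res = "W" if wt_res != "W" else "F"
        fixed.append(MutationTableRecord(
            pdb_id=r.pdb_id, chain_id="A",
            mutation=MutationSpec("A", ext.residues[4][0], wt_res, mut_res),
            temperature=25.0, ph=7.0, exp_ddg=float(i),
        ))
    frame = parameter_scan(fixed, ext_provider, mj, rc_grid=[9.0],
                           mode_grid=[10])
    assert frame.iloc[0].pct_predictions == 0.0


def test_parameter_scan_grid_equals_pointwise_runs(mj):
    records, provider = _scan_records(mj, n=4)
    grid = parameter_scan(records, provider, mj, rc_grid=[8.0, 9.0],
                          mode_grid=[5, 10])
    assert len(grid) == 4
    assert list(grid.pcc) == sorted(grid.pcc, reverse=True)
    for rc in (8.0, 9.0):
        for m in (5, 10):
            single = parameter_scan(records, provider, mj, rc_grid=[rc],
                                    mode_grid=[m]).iloc[0]
            row = grid[(grid.rc == rc) & (grid.n_modes == m)].iloc[0]
            for col in ("pcc", "rmse", "pct_predictions"):
                got, exp = row[col], single[col]
                assert (np.isnan(got) and np.isnan(exp)) or got == exp


def test_summarize_bundles_metrics(rng):
    pred = list(rng.normal(size=15))
    expv = list(rng.normal(size=15))
    fwd = list(rng.normal(size=15))
    rev = [-v for v in fwd]
    s = summarize(pred, expv, fwd, rev)
    assert s.n == 15
    assert s.pcc == pytest.approx(pearson_brute(pred, expv), abs=1e-12)
    assert s.rmse == pytest.approx(rmse_brute(pred, expv), abs=1e-12)
    assert s.antisymmetry == pytest.approx(-1.0, abs=1e-12)
    assert s.bias == 0.0
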