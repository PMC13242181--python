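"""Table engine: relational semantics, storage modes, persistence."""

import os

import numpy as np
import pytest

import mzkit.table as T
from mzkit.expressions import ExpressionError, col, lit
from mzkit.peakmap import PeakMap, Spectrum

from conftest import make_random_peakmap, make_random_table
from oracle_table import OracleTable, eval_expr


class TestCreate:
    def test_zero_row_table(self):
        t = T.create_table(["a"], ["integer"])
        assert len(t) == 0 and t.col_names == ["a"]

    def test_duplicate_names_rejected(self):
        with pytest.raises(T.SchemaError):
            T.create_table(["a", "a"], ["integer", "integer"])

    def test_type_mismatch_names_row_and_column(self):
        with pytest.raises(TypeError, match=r"row 1.*'a'"):
            T.create_table(["a"], ["integer"], [(1,), ("oops",)])

    def test_bool_is_not_an_integer(self):
        with pytest.raises(TypeError):
            T.create_table(["a"], ["integer"], [(True,)])

    def test_row_multiset_preserved(self):
        names, types, rows = make_random_table(5, n_rows=1000)
        t = T.create_table(names, types, rows)
        assert list(t.rows()) == rows


class TestFilter:
    def test_always_true_is_identity(self, small_table):
        assert T.tables_equal(T.filter(small_table, lit(True)), small_table)

    def test_always_false_empties(self, small_table):
        assert len(T.filter(small_table, lit(False))) == 0

    def test_missing_predicate_excludes_row(self, small_table):
        # mz is missing in row 2: a comparison with missing is not true
        t = T.filter(small_table, col("mz") > 0.0)
        assert [r[0] for r in t.rows()] == [1, 3, 4]

    def test_unknown_column_raises(self, small_table):
        with pytest.raises(ExpressionError, match="nope"):
            T.filter(small_table, col("nope") > 1)

    def test_non_boolean_predicate_rejected(self, small_table):
        with pytest.raises(ExpressionError):
            T.filter(small_table, col("mz") + 1.0)

    def test_input_unchanged(self, small_table):
        before = small_table.checksum()
        T.filter(small_table, col("id") > 2)
        assert small_table.checksum() == before


class TestJoin:
    def test_false_predicate(self, small_table):
        other = T.create_table(["k"], ["integer"], [(1,), (2,)])
        assert len(T.join(small_table, other, lit(False))) == 0
        lj = T.left_join(small_table, other, lit(False))
        assert len(lj) == len(small_table)
        assert all(r[-1] is None for r in lj.rows())

    def test_self_join_on_unique_key(self, small_table):
        j = T.join(small_table, small_table, col("id") == col("id__1"))
        assert len(j) == len(small_table)

    def test_collision_postfix(self, small_table):
        j = T.join(small_table, small_table, col("id") == col("id__1"))
        assert j.col_names.count("id") == 1 and "id__1" in j.col_names


class TestGroupAggregate:
    def test_whole_table_aggregate(self, small_table):
        g = T.group_aggregate(small_table, [], [("mz", "mean"), ("id", "count"),
                                                ("mz", "median"), ("name", "first")])
        row = list(g.rows())[0]
        assert row[0] == pytest.approx((100.5 + 300.25 + 100.5) / 3)
        assert row[1] == 4
        assert row[3] == "a"

    def test_unique_key_keeps_row_count(self, small_table):
        g = T.group_aggregate(small_table, ["id"], [("mz", "max")])
        assert len(g) == len(small_table)

    def test_missing_keys_group_together(self):
        t = T.create_table(["k", "v"], ["text", "integer"],
                           [(None, 1), ("a", 2), (None, 3)])
        g = T.group_aggregate(t, ["k"], [("v", "sum")])
        assert list(g.rows()) == [(None, 4), ("a", 2)]

    def test_sum_of_text_is_type_error(self, small_table):
        with pytest.raises(TypeError):
            T.group_aggregate(small_table, [], [("name", "sum")])


class TestSortAddColumn:
    def test_sort_is_idempotent(self, small_table):
        once = T.sort(small_table, "mz")
        twice = T.sort(once, "mz")
        assert T.tables_equal(once, twice)

    def test_stable_on_ties(self):
        t = T.create_table(["k", "i"], ["integer", "integer"],
                           [(1, 0), (0, 1), (1, 2), (0, 3)])
        s = T.sort(t, "k")
        assert [r[1] for r in s.rows()] == [1, 3, 0, 2]

    def test_computed_column_matches_row_oracle(self, small_table):
        t = T.add_column(small_table, "halved", col("mz") / 2)
        for row in t:
            expected = None if row["mz"] is None else row["mz"] / 2
            assert row["halved"] == expected

    def test_name_collision_rejected(self, small_table):
        with pytest.raises(T.SchemaError):
            T.add_column(small_table, "mz", lit(1.0))

    def test_apply_is_memory_only(self, small_table):
        d = T.set_storage_mode(small_table, "disk")
        with pytest.raises(ValueError, match="memory"):
            d.apply("x", lambda r: 1, "integer")
        m = small_table.apply("x", lambda r: (r["id"] or 0) * 2, "integer")
        assert m.col_values("x") == [2, 4, 6, 8]


class TestStorageModes:
    def test_mode_switch_roundtrip(self, small_table):
        d = T.set_storage_mode(small_table, "disk")
        m = T.set_storage_mode(d, "memory")
        assert d.storage_mode == "disk" and m.storage_mode == "memory"
        assert T.tables_equal(small_table, m)

    def test_disk_file_backing(self, small_table, tmp_path):
        path = tmp_path / "t.db"
        d = T.set_storage_mode(small_table, "disk", path)
        assert path.exists()
        assert T.tables_equal(small_table, d)

    def test_all_operations_agree_across_modes(self):
        names, types, rows = make_random_table(9, n_rows=60)
        mem = T.create_table(names, types, rows)
        disk = T.set_storage_mode(mem, "disk")
        pred = (col("c0") > 0) | col("c2").is_missing()
        for op in (
            lambda t: T.filter(t, pred),
            lambda t: T.add_column(t, "d", col("c1") * 2 - col("c0")),
            lambda t: T.sort(t, ["c2", "c0"], [False, True]),
            lambda t: T.group_aggregate(t, ["c3"], [("c1", "mean"), ("c0", "count")]),
        ):
            assert list(op(mem).rows()) == list(op(disk).rows())

    def test_streaming_filter_large_disk_table(self):
        n = 20000
        rows = ((i, float(i % 97)) for i in range(n))
        t = T.create_table(["i", "v"], ["integer", "real"], rows)
        d = T.set_storage_mode(t, "disk")
        f = T.filter(d, col("v") < 10.0)
        assert len(f) == sum(1 for i in range(n) if i % 97 < 10)


def _random_expression(rng, names, types):
    """A random boolean predicate over the table's columns."""
    numeric = [n for n, t in zip(names, types) if t in ("integer", "real")]
    text = [n for n, t in zip(names, types) if t == "text"]

    def leaf():
        r = rng.random()
        if r < 0.45 and numeric:
            name = str(rng.choice(numeric))
            op = rng.choice(["<", "<=", ">", ">=", "==", "!="])
            value = float(np.round(rng.normal(0, 10), 2))
            left = col(name) if rng.random() < 0.7 else col(name) + float(rng.integers(-3, 4))
            return {"<": left < value, "<=": left <= value, ">": left > value,
                    ">=": left >= value, "==": left == value, "!=": left != value}[op]
        if r < 0.7 and text:
            name = str(rng.choice(text))
            value = str(rng.choice(["aa", "bb", "zz"]))
            return (col(name) == value) if rng.random() < 0.5 else (col(name) < value)
        name = str(rng.choice(names))
        return col(name).is_missing() if rng.random() < 0.5 else col(name).is_not_missing()

    e = leaf()
    for _ in range(int(rng.integers(0, 3))):
        other = leaf()
        r = rng.random()
        if r < 0.4:
            e = e & other
        elif r < 0.8:
            e = e | other
        else:
            e = ~e
    return e


def run_differential_sequence(seed: int, n_rows: int = 30) -> bool:
    """One randomized op sequence on memory, disk and oracle engines."""
    rng = np.random.default_rng(seed)
    names, types, rows = make_random_table(seed, n_rows=int(rng.integers(0, n_rows + 1)))
    mem = T.create_table(names, types, rows)
    disk = T.set_storage_mode(mem, "disk")
    oracle = OracleTable(names, types, rows)
    versions = [(mem, disk, oracle)]
    for _ in range(int(rng.integers(1, 4))):
        m, d, o = versions[-1]
        choice = rng.random()
        if choice < 0.3:
            e = _random_expression(rng, m.col_names, m.col_types)
            nxt = (T.filter(m, e), T.filter(d, e), o.filter(e))
        elif choice < 0.45:
            numeric = [n for n, t in zip(m.col_names, m.col_types)
                       if t in ("integer", "real")]
            if not numeric:
                continue
            a = str(rng.choice(numeric))
            e = col(a) * 2 + 1
            name = f"x{len(m.col_names)}"
            type_ = "real" if m.col_types[m.col_names.index(a)] == "real" else "integer"
            nxt = (T.add_column(m, name, e), T.add_column(d, name, e),
                   o.add_column(name, e, type_))
        elif choice < 0.6:
            k = str(rng.choice(m.col_names))
            desc = bool(rng.integers(0, 2))
            nxt = (T.sort(m, k, desc), T.sort(d, k, desc), o.sort(k, desc))
        elif choice < 0.8:
            keys = [str(rng.choice(m.col_names))]
            aggs = []
            for n2, t2 in zip(m.col_names, m.col_types):
                if n2 in keys:
                    continue
                funcs = ["count", "min", "max", "first"]
                if t2 in ("integer", "real"):
                    funcs += ["sum", "mean", "median"]
                aggs.append((n2, str(rng.choice(funcs))))
            if not aggs:
                continue
            nxt = (T.group_aggregate(m, keys, aggs), T.group_aggregate(d, keys, aggs),
                   o.group_aggregate(keys, aggs))
        else:
            ints = [n for n, t2 in zip(m.col_names, m.col_types) if t2 == "integer"]
            if not ints:
                continue
            rn, rt_, rr = make_random_table(seed + 1000, n_rows=int(rng.integers(0, 10)))
            rn = [f"r{len(m.col_names)}_{n}" for n in rn]  # keep names unique
            rm = T.create_table(rn, rt_, rr)
            ro = OracleTable(rn, rt_, rr)
            e = col(str(rng.choice(ints))) == col(rn[0])
            outer = bool(rng.integers(0, 2))
            if outer:
                nxt = (T.left_join(m, rm, e), T.left_join(d, rm, e), o.left_join(ro, e))
            else:
                nxt = (T.join(m, rm, e), T.join(d, rm, e), o.join(ro, e))
        versions.append(nxt)
    m, d, o = versions[-1]
    rows_m, rows_d, rows_o = list(m.rows()), list(d.rows()), o.rows
    if not (rows_m == rows_d and m.col_names == d.col_names == o.col_names):
        return False
    # engine vs oracle: float aggregates may differ in the last ulp because
    # SQLite sums with compensation; everything else must match exactly
    if len(rows_m) != len(rows_o):
        return False
    for rm, ro in zip(rows_m, rows_o):
        for vm, vo in zip(rm, ro):
            if isinstance(vm, float) and isinstance(vo, float):
                if vm != pytest.approx(vo, rel=1e-12, abs=1e-12):
                    return False
            elif vm != vo:
                return False
    return True


class TestDifferential:
    @pytest.mark.parametrize("seed", range(60))
    def test_memory_disk_and_oracle_agree(self, seed):
        assert run_differential_sequence(seed)


class TestPersistence:
    def test_empty_table_roundtrip(self, tmp_path):
        t = T.create_table(["a", "b"], ["integer", "text"])
        p = tmp_path / "t.table"
        T.save_table(t, p)
        assert T.tables_equal(t, T.load_table(p))

    @pytest.mark.parametrize("seed", range(5))
    def test_random_tables_roundtrip(self, seed, tmp_path):
        names, types, rows = make_random_table(seed, n_rows=40)
        t = T.create_table(names, types, rows, meta={"seed": seed})
        p = tmp_path / "t.table"
        T.save_table(t, p)
        t2 = T.load_table(p)
        assert T.tables_equal(t, t2)
        assert t2.meta == {"seed": seed}

    def test_shared_peakmap_stored_once(self, tmp_path):
        pm = make_random_peakmap(1, n_spectra=50, n_peaks=200)
        single = T.create_table(["i", "pm"], ["integer", "peakmap"], [(0, pm)])
        shared = T.create_table(["i", "pm"], ["integer", "peakmap"],
                                [(i, pm) for i in range(10)])
        p1, p2 = tmp_path / "one.table", tmp_path / "ten.table"
        T.save_table(single, p1)
        T.save_table(shared, p2)
        # ten references to one peakmap must not store ten copies
        assert os.path.getsize(p2) < 1.5 * os.path.getsize(p1)
        loaded = T.load_table(p2)
        assert T.tables_equal(shared, loaded)
        assert loaded[0]["pm"] is loaded[9]["pm"]

    def test_nested_table_roundtrip(self, tmp_path):
        inner = T.create_table(["x"], ["integer"], [(1,), (2,)])
        outer = T.create_table(["name", "sub"], ["text", "table"],
                               [("first", inner), ("none", None)])
        p = tmp_path / "nested.table"
        T.save_table(outer, p)
        assert T.tables_equal(outer, T.load_table(p))

    def test_version_mismatch_is_explicit(self, tmp_path):
        import json
        import sqlite3

        t = T.create_table(["a"], ["integer"], [(1,)])
        p = tmp_path / "t.table"
        T.save_table(t, p)
        conn = sqlite3.connect(p)
        header = json.loads(conn.execute(
            "SELECT value FROM __meta__ WHERE key='header'").fetchone()[0])
        header["format_version"] = 999
        conn.execute("UPDATE __meta__ SET value=? WHERE key='header'",
                     (json.dumps(header),))
        conn.commit()
        conn.close()
        with pytest.raises(T.UnsupportedVersionError, match="999"):
            T.load_table(p)


class TestCsv:
    def test_roundtrip_with_explicit_types(self, small_table, tmp_path):
        p = tmp_path / "t.csv"
        T.table_to_csv(small_table, p)
        t2 = T.table_from_csv(p, small_table.col_types)
        assert list(t2.rows()) == list(small_table.rows())

    def test_object_columns_rejected(self, tmp_path):
        pm = make_random_peakmap(0, n_spectra=1)
        t = T.create_table(["pm"], ["peakmap"], [(pm,)])
        with pytest.raises(TypeError):
            T.table_to_csv(t, tmp_path / "no.csv")


class TestExpressionAlgebra:
    """x op missing = missing; filter never selects missing predicates."""

    @pytest.mark.parametrize("make_expr", [
        lambda: (col("v") + lit(None)) > 0,
        lambda: (lit(None) * col("v")) == col("v"),
        lambda: col("v") > lit(None),
        lambda: (col("v") > 0) & lit(None) & lit(True),
    ])
    def test_missing_propagates_and_is_not_selected(self, make_expr):
        t = T.create_table(["v"], ["integer"], [(1,), (2,)])
        assert len(T.filter(t, make_expr())) == 0

    def test_division_by_zero_is_missing(self):
        t = T.create_table(["v"], ["integer"], [(0,), (2,)])
        t2 = T.add_column(t, "r", lit(10) / col("v"))
        assert t2.col_values("r") == [None, 5.0]

    def test_missing_test_beats_propagation(self):
        t = T.create_table(["v"], ["integer"], [(None,), (2,)])
        assert len(T.filter(t, col("v").is_missing())) == 1
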