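"""Relational Table container over an embedded SQLite store.

A :class:`Table` has typed, named columns and rows addressed by stable
insertion order.  The backing SQLite database lives in memory by default
or, for out-of-core processing of large peak lists, in a file: every
operation behaves identically in both modes and streams rows in bounded
batches, so working-set memory does not grow with row count.

Cells are values of the column's type or missing (``None``).  Missing
values follow three-valued logic (see :mod:`mzkit.expressions`).
Columns of type ``peakmap`` and ``table`` hold references to
:class:`~mzkit.peakmap.PeakMap` / nested :class:`Table` objects; on
persistence each referenced object is stored once and shared.

All operations are pure: they return a new table and leave their inputs
unchanged.
"""

from __future__ import annotations

import hashlib
import json
import os
import sqlite3
import statistics

from .expressions import Expression, ExpressionError, col, lit  # noqa: F401 (re-export)

__all__ = [
    "Table",
    "SchemaError",
    "create_table",
    "filter",
    "join",
    "left_join",
    "group_aggregate",
    "add_column",
    "sort",
    "save_table",
    "load_table",
    "set_storage_mode",
    "tables_equal",
]

FORMAT_VERSION = 1
BATCH = 1024

COLUMN_TYPES = ("integer", "real", "text", "boolean", "peakmap", "table")

_SQL_TYPE = {
    "integer": "INTEGER",
    "real": "REAL",
    "text": "TEXT",
    "boolean": "INTEGER",
    "peakmap": "INTEGER",
    "table": "INTEGER",
}

_DEFAULT_FORMAT = {
    "integer": "%d",
    "real": "%.5f",
    "text": "%s",
    "boolean": "%s",
    "peakmap": "<peakmap>",
    "table": "<table>",
}


class SchemaError(ValueError):
    pass


class UnsupportedVersionError(ValueError):
    pass


def _q(name: str) -> str:
    return '"' + name.replace('"', '""') + '"'


def _valid_identifier(name: str) -> bool:
    return isinstance(name, str) and name.isidentifier()


class _MedianAgg:
    def __init__(self):
        self.values = []

    def step(self, value):
        if value is not None:
            self.values.append(value)

    def finalize(self):
        if not self.values:
            return None
        return float(statistics.median(self.values))


class _FirstAgg:
    """First non-missing value in insertion (_idx) order."""

    def __init__(self):
        self.best_idx = None
        self.best = None

    def step(self, value, idx):
        if value is not None and (self.best_idx is None or idx < self.best_idx):
            self.best_idx, self.best = idx, value

    def finalize(self):
        return self.best


def _connect(mode: str, path=None) -> sqlite3.Connection:
    if mode == "memory":
        conn = sqlite3.connect(":memory:")
    elif mode == "disk":
        # path None -> private on-disk temporary database, removed on close
        conn = sqlite3.connect("" if path is None else str(path))
    else:
        raise ValueError(f"storage mode must be 'memory' or 'disk', got {mode!r}")
    conn.execute("PRAGMA temp_store=FILE" if mode == "disk" else "PRAGMA temp_store=MEMORY")
    conn.create_aggregate("py_median", 1, _MedianAgg)
    conn.create_aggregate("py_first", 2, _FirstAgg)
    return conn


class Table:
    """Typed relational table; construct via :func:`create_table` or I/O."""

    def __init__(self, col_names, col_types, col_formats, conn, mode, path=None,
                 objects=None, meta=None):
        self.col_names = list(col_names)
        self.col_types = list(col_types)
        self.col_formats = list(col_formats)
        self._conn = conn
        self._mode = mode
        self._path = path
        self._objects = objects if objects is not None else {}
        self.meta = dict(meta or {})

    # -- basics --------------------------------------------------------

    @property
    def storage_mode(self) -> str:
        return self._mode

    @property
    def path(self):
        return self._path

    def schema(self) -> dict[str, str]:
        return dict(zip(self.col_names, self.col_types))

    def __len__(self) -> int:
        return self._conn.execute("SELECT COUNT(*) FROM data").fetchone()[0]

    def _cols_sql(self) -> str:
        return ", ".join(_q(c) for c in self.col_names)

    def _from_sql(self, values) -> tuple:
        out = []
        for v, t in zip(values, self.col_types):
            if v is None:
                out.append(None)
            elif t == "boolean":
                out.append(bool(v))
            elif t in ("peakmap", "table"):
                out.append(self._objects[v])
            else:
                out.append(v)
        return tuple(out)

    def rows(self):
        """Iterate rows as tuples in stable insertion order."""
        cur = self._conn.execute(f"SELECT {self._cols_sql()} FROM data ORDER BY _idx")
        while True:
            batch = cur.fetchmany(BATCH)
            if not batch:
                return
            for raw in batch:
                yield self._from_sql(raw)

    def __iter__(self):
        for row in self.rows():
            yield dict(zip(self.col_names, row))

    def __getitem__(self, i: int):
        n = len(self)
        if i < 0:
            i += n
        if not 0 <= i < n:
            raise IndexError(i)
        raw = self._conn.execute(
            f"SELECT {self._cols_sql()} FROM data ORDER BY _idx LIMIT 1 OFFSET ?", (i,)
        ).fetchone()
        return dict(zip(self.col_names, self._from_sql(raw)))

    def col_values(self, name: str) -> list:
        if name not in self.col_names:
            raise ExpressionError(f"unknown column {name!r}")
        idx = self.col_names.index(name)
        return [row[idx] for row in self.rows()]

    def checksum(self) -> str:
        """Content hash of schema plus rows (object cells hashed by identity)."""
        h = hashlib.sha1()
        h.update(repr((self.col_names, self.col_types, self.col_formats)).encode())
        for row in self.rows():
            h.update(repr([id(v) if isinstance(v, (Table,)) or hasattr(v, "spectra")
                           else v for v in row]).encode())
        return h.hexdigest()

    def close(self):
        self._conn.close()

    def __del__(self):
        try:
            self._conn.close()
        except Exception:
            pass

    def __repr__(self):
        return (f"<Table {len(self.col_names)} cols x {len(self)} rows,"
                f" mode={self._mode}>")

    # -- internal construction -----------------------------------------

    @staticmethod
    def _new(col_names, col_types, col_formats, mode, path=None, objects=None, meta=None):
        conn = _connect(mode, path)
        cols = ", ".join(
            f"{_q(n)} {_SQL_TYPE[t]}" for n, t in zip(col_names, col_types)
        )
        body = f"_idx INTEGER PRIMARY KEY" + (f", {cols}" if cols else "")
        conn.execute("DROP TABLE IF EXISTS data")
        conn.execute(f"CREATE TABLE data ({body})")
        return Table(col_names, col_types, col_formats, conn, mode, path,
                     dict(objects or {}), meta)

    def _next_object_key(self) -> int:
        return max(self._objects, default=0) + 1

    def _to_sql_value(self, value, col_type: str, register=True):
        if value is None:
            return None
        if col_type == "boolean":
            return int(value)
        if col_type in ("peakmap", "table"):
            for key, obj in self._objects.items():
                if obj is value:
                    return key
            if not register:
                raise ValueError("unregistered object reference")
            key = self._next_object_key()
            self._objects[key] = value
            return key
        return value

    def _insert_rows(self, raw_rows, start_idx=0):
        ph = ", ".join("?" for _ in range(len(self.col_names) + 1))
        cur = self._conn.cursor()
        cur.executemany(
            f"INSERT INTO data VALUES ({ph})",
            ((i,) + tuple(r) for i, r in enumerate(raw_rows, start=start_idx)),
        )
        self._conn.commit()

    # -- convenience wrappers (module functions do the work) -----------

    def filter(self, expression):
        return filter(self, expression)

    def add_column(self, name, expression, type_=None, format=None):
        return add_column(self, name, expression, type_, format)

    def sort(self, by, descending=False):
        return sort(self, by, descending)

    def join(self, other, on, postfix="__1"):
        return join(self, other, on, postfix)

    def left_join(self, other, on, postfix="__1"):
        return left_join(self, other, on, postfix)

    def group_aggregate(self, keys, aggregations):
        return group_aggregate(self, keys, aggregations)

    def apply(self, name, func, type_, format=None):
        """Row-wise escape hatch: compute a new column with a Python callable.

        Only available in memory mode; the engine's own operations (and
        disk mode) use the closed expression set.
        """
        if self._mode != "memory":
            raise ValueError("apply() is only available for memory-mode tables")
        _check_new_column(self, name, type_)
        out = Table._new(self.col_names + [name], self.col_types + [type_],
                         self.col_formats + [_DEFAULT_FORMAT[type_] if format is None else format],
                         self._mode, None, self._objects, self.meta)
        raw = []
        for i, row in enumerate(self):
            value = func(row)
            _check_value(value, type_, name, i)
            raw.append([out._to_sql_value(v, t) for v, t in
                        zip(list(row.values()) + [value], out.col_types)])
        out._insert_rows(raw)
        return out

    def to_pandas(self):
        import pandas as pd

        plain = [n for n, t in zip(self.col_names, self.col_types)
                 if t not in ("peakmap", "table")]
        data = {n: self.col_values(n) for n in plain}
        return pd.DataFrame(data, columns=plain)


# -- validation ---------------------------------------------------------

def _check_value(value, col_type, col_name, row_index):
    from .peakmap import PeakMap

    if value is None:
        return
    ok = {
        "integer": lambda v: isinstance(v, int) and not isinstance(v, bool),
        "real": lambda v: isinstance(v, (int, float)) and not isinstance(v, bool),
        "text": lambda v: isinstance(v, str),
        "boolean": lambda v: isinstance(v, bool),
        "peakmap": lambda v: isinstance(v, PeakMap),
        "table": lambda v: isinstance(v, Table),
    }[col_type](value)
    if not ok:
        raise TypeError(
            f"row {row_index}, column {col_name!r}: {value!r} is not of type {col_type}"
        )


def _check_new_column(t: Table, name: str, type_: str):
    if not _valid_identifier(name):
        raise SchemaError(f"invalid column name {name!r}")
    if name in t.col_names:
        raise SchemaError(f"column {name!r} already exists")
    if type_ not in COLUMN_TYPES:
        raise SchemaError(f"unknown column type {type_!r}")


# -- public operations ---------------------------------------------------

def create_table(col_names, col_types, rows=(), col_formats=None, meta=None,
                 path=None) -> Table:
    """Build a table from rows (sequences matching the column order).

    ``path=None`` keeps the table in memory; a path stores it on disk.
    """
    col_names = list(col_names)
    col_types = list(col_types)
    if len(col_names) != len(set(col_names)):
        raise SchemaError("duplicate column names")
    for n in col_names:
        if not _valid_identifier(n):
            raise SchemaError(f"invalid column name {n!r}")
    for t in col_types:
        if t not in COLUMN_TYPES:
            raise SchemaError(f"unknown column type {t!r}")
    if len(col_names) != len(col_types):
        raise SchemaError("col_names and col_types differ in length")
    if col_formats is None:
        col_formats = [_DEFAULT_FORMAT[t] for t in col_types]
    mode = "memory" if path is None else "disk"
    out = Table._new(col_names, col_types, list(col_formats), mode, path, None, meta)
    raw = []
    for i, row in enumerate(rows):
        row = tuple(row)
        if len(row) != len(col_names):
            raise SchemaError(f"row {i} has {len(row)} cells, expected {len(col_names)}")
        for v, n, t in zip(row, col_names, col_types):
            _check_value(v, t, n, i)
        raw.append([out._to_sql_value(v, t) for v, t in zip(row, col_types)])
        if len(raw) >= BATCH:
            out._insert_rows(raw, start_idx=i + 1 - len(raw))
            raw = []
    if raw:
        out._insert_rows(raw, start_idx=i + 1 - len(raw))
    return out


def _stream_query(src: Table, out: Table, sql: str, params=(), drop_last=0):
    cur = src._conn.execute(sql, params)
    idx = 0
    ph = ", ".join("?" for _ in range(len(out.col_names) + 1))
    while True:
        batch = cur.fetchmany(BATCH)
        if not batch:
            break
        rows = [(idx + k,) + tuple(r[: len(r) - drop_last] if drop_last else r)
                for k, r in enumerate(batch)]
        out._conn.executemany(f"INSERT INTO data VALUES ({ph})", rows)
        idx += len(batch)
    out._conn.commit()


def _colmap(t: Table) -> dict[str, str]:
    return {n: _q(n) for n in t.col_names}


def filter(t: Table, expression: Expression) -> Table:
    """Rows where the expression is true (missing is not true); order kept."""
    if not isinstance(expression, Expression):
        raise ExpressionError("filter() requires an Expression")
    if expression.infer_type(t.schema()) not in ("boolean", "missing"):
        raise ExpressionError("filter predicate must be boolean")
    params: list = []
    where = expression.sql(_colmap(t), params)
    out = Table._new(t.col_names, t.col_types, t.col_formats, t._mode, None,
                     t._objects, t.meta)
    _stream_query(t, out,
                  f"SELECT {t._cols_sql()} FROM data WHERE {where} ORDER BY _idx",
                  params)
    return out


def add_column(t: Table, name: str, expression, type_=None, format=None) -> Table:
    """Append a computed column (expression or constant)."""
    if not isinstance(expression, Expression):
        expression = lit(expression)
    inferred = expression.infer_type(t.schema())
    if type_ is None:
        type_ = "real" if inferred == "missing" else inferred
    elif inferred not in ("missing", type_) and not (inferred == "integer" and type_ == "real"):
        raise ExpressionError(
            f"expression has type {inferred}, cannot store in {type_} column"
        )
    _check_new_column(t, name, type_)
    params: list = []
    value_sql = expression.sql(_colmap(t), params)
    if type_ == "real":
        value_sql = f"CAST({value_sql} AS REAL)"
    out = Table._new(t.col_names + [name], t.col_types + [type_],
                     t.col_formats + [_DEFAULT_FORMAT[type_] if format is None else format],
                     t._mode, None, t._objects, t.meta)
    _stream_query(t, out,
                  f"SELECT {t._cols_sql()}{',' if t.col_names else ''} {value_sql} "
                  f"FROM data ORDER BY _idx",
                  params)
    return out


def sort(t: Table, by, descending=False) -> Table:
    """Stable sort by one or more columns (ties keep their input order).

    Missing values follow the SQL convention: first when ascending,
    last when descending.
    """
    if isinstance(by, str):
        by = [by]
    if isinstance(descending, bool):
        descending = [descending] * len(by)
    if len(by) != len(descending):
        raise ValueError("by and descending differ in length")
    for name in by:
        if name not in t.col_names:
            raise ExpressionError(f"unknown column {name!r}")
    order = ", ".join(
        f"{_q(n)} {'DESC' if d else 'ASC'}" for n, d in zip(by, descending)
    )
    out = Table._new(t.col_names, t.col_types, t.col_formats, t._mode, None,
                     t._objects, t.meta)
    _stream_query(t, out,
                  f"SELECT {t._cols_sql()} FROM data ORDER BY {order}, _idx ASC")
    return out


def _join(left: Table, right: Table, on: Expression, postfix: str, outer: bool) -> Table:
    right_out_names = []
    for n in right.col_names:
        out_n = n + postfix if n in left.col_names else n
        if out_n in left.col_names or out_n in right_out_names:
            raise SchemaError(f"column collision on {out_n!r} even after postfix")
        right_out_names.append(out_n)
    names = left.col_names + right_out_names
    types = left.col_types + right.col_types
    formats = left.col_formats + right.col_formats

    # expression resolves left names first, right names via their output name
    colmap = {n: f"l.{_q(n)}" for n in left.col_names}
    for orig, out_n in zip(right.col_names, right_out_names):
        colmap.setdefault(orig, f"r.{_q(orig)}")
        colmap[out_n] = f"r.{_q(orig)}"
    schema = dict(zip(left.col_names, left.col_types))
    for orig, out_n, tt in zip(right.col_names, right_out_names, right.col_types):
        schema.setdefault(orig, tt)
        schema[out_n] = tt
    if on.infer_type(schema) not in ("boolean", "missing"):
        raise ExpressionError("join predicate must be boolean")

    objects = dict(left._objects)
    remap: dict[int, int] = {}
    for key, obj in right._objects.items():
        new_key = max(objects, default=0) + 1
        objects[new_key] = obj
        remap[key] = new_key

    out = Table._new(names, types, formats, left._mode, None, objects, left.meta)
    conn = out._conn
    ldef = ", ".join(f"{_q(n)} {_SQL_TYPE[t]}" for n, t in zip(left.col_names, left.col_types))
    rdef = ", ".join(f"{_q(n)} {_SQL_TYPE[t]}" for n, t in zip(right.col_names, right.col_types))
    conn.execute(f"CREATE TEMP TABLE ljoin (_idx INTEGER{', ' + ldef if ldef else ''})")
    conn.execute(f"CREATE TEMP TABLE rjoin (_idx INTEGER{', ' + rdef if rdef else ''})")

    def _copy(src: Table, dest_name: str, key_remap):
        cur = src._conn.execute(f"SELECT _idx, {src._cols_sql()} FROM data ORDER BY _idx"
                                if src.col_names else "SELECT _idx FROM data ORDER BY _idx")
        ph = ", ".join("?" for _ in range(len(src.col_names) + 1))
        obj_cols = [i + 1 for i, tt in enumerate(src.col_types) if tt in ("peakmap", "table")]
        while True:
            batch = cur.fetchmany(BATCH)
            if not batch:
                break
            if key_remap and obj_cols:
                batch = [tuple(key_remap.get(v, v) if j in obj_cols and v is not None else v
                               for j, v in enumerate(row)) for row in batch]
            conn.executemany(f"INSERT INTO {dest_name} VALUES ({ph})", batch)

    _copy(left, "ljoin", None)
    _copy(right, "rjoin", remap)

    params: list = []
    pred = on.sql(colmap, params)
    lsel = ", ".join(f"l.{_q(n)}" for n in left.col_names)
    rsel = ", ".join(f"r.{_q(n)}" for n in right.col_names)
    sel = ", ".join(x for x in (lsel, rsel) if x)
    jointype = "LEFT JOIN" if outer else "JOIN"
    conn.execute(
        f"INSERT INTO data ({out._cols_sql()}) "
        f"SELECT {sel} FROM ljoin l {jointype} rjoin r ON {pred} "
        f"ORDER BY l._idx, r._idx",
        params,
    )
    # _idx was omitted from the INSERT, so SQLite assigns ascending rowids
    # in SELECT order -- (left, right) nested order is preserved.
    conn.execute("DROP TABLE ljoin")
    conn.execute("DROP TABLE rjoin")
    conn.commit()
    return out


def join(left: Table, right: Table, on: Expression, postfix: str = "__1") -> Table:
    """Inner join: all row pairs satisfying ``on``, in (left, right) order.

    Right-side columns whose names collide with left ones are suffixed
    with ``postfix``; reference them by the suffixed name in ``on``.
    """
    return _join(left, right, on, postfix, outer=False)


def left_join(left: Table, right: Table, on: Expression, postfix: str = "__1") -> Table:
    """Like :func:`join` but unmatched left rows appear with missing right cells."""
    return _join(left, right, on, postfix, outer=True)


_AGG_NUMERIC_ONLY = {"sum", "mean", "median"}


def _agg_sql(func: str, name: str) -> str:
    q = _q(name)
    return {
        "count": f"COUNT({q})",
        "sum": f"SUM({q})",
        "mean": f"AVG({q})",
        "min": f"MIN({q})",
        "max": f"MAX({q})",
        "median": f"py_median({q})",
        "first": f"py_first({q}, _idx)",
    }[func]


def _agg_result_type(func: str, src_type: str) -> str:
    if func == "count":
        return "integer"
    if func in ("mean", "median"):
        return "real"
    if func == "sum":
        return "integer" if src_type in ("integer", "boolean") else "real"
    return src_type  # min, max, first


def group_aggregate(t: Table, keys, aggregations) -> Table:
    """One row per distinct key tuple, ordered by first appearance.

    ``aggregations`` is a list of ``(column, func)`` or
    ``(column, func, output_name)`` with func in
    {count, sum, mean, min, max, median, first}; aggregates ignore
    missing values and ``count`` counts non-missing cells.  Missing keys
    group together.
    """
    if isinstance(keys, str):
        keys = [keys]
    keys = list(keys)
    for k in keys:
        if k not in t.col_names:
            raise ExpressionError(f"unknown column {k!r}")
    schema = t.schema()
    out_names = list(keys)
    out_types = [schema[k] for k in keys]
    selects = [f"{_q(k)}" for k in keys]
    for agg in aggregations:
        if len(agg) == 2:
            src, func = agg
            out_n = f"{src}_{func}"
        else:
            src, func, out_n = agg
        if src not in schema:
            raise ExpressionError(f"unknown column {src!r}")
        if func not in ("count", "sum", "mean", "min", "max", "median", "first"):
            raise ValueError(f"unknown aggregation {func!r}")
        src_type = schema[src]
        if func in _AGG_NUMERIC_ONLY and src_type not in ("integer", "real", "boolean"):
            raise TypeError(f"cannot {func} column {src!r} of type {src_type}")
        if src_type in ("peakmap", "table") and func not in ("count", "first"):
            raise TypeError(f"cannot {func} column {src!r} of type {src_type}")
        if out_n in out_names:
            raise SchemaError(f"duplicate output column {out_n!r}")
        out_names.append(out_n)
        out_types.append(_agg_result_type(func, src_type))
        selects.append(_agg_sql(func, src))
    out_formats = [_DEFAULT_FORMAT[tt] for tt in out_types]
    out = Table._new(out_names, out_types, out_formats, t._mode, None,
                     t._objects, t.meta)
    group = f" GROUP BY {', '.join(_q(k) for k in keys)}" if keys else ""
    sql = (f"SELECT {', '.join(selects)}, MIN(_idx) AS __ord FROM data"
           f"{group} ORDER BY __ord")
    _stream_query(t, out, sql, drop_last=1)
    return out


def set_storage_mode(t: Table, mode: str, path=None) -> Table:
    """Copy the table into the given storage mode ('memory' or 'disk')."""
    if mode not in ("memory", "disk"):
        raise ValueError("mode must be 'memory' or 'disk'")
    out = Table._new(t.col_names, t.col_types, t.col_formats, mode, path,
                     t._objects, t.meta)
    _stream_query(t, out, f"SELECT {t._cols_sql()} FROM data ORDER BY _idx")
    return out


# -- persistence ---------------------------------------------------------

def _save_into(t: Table, conn: sqlite3.Connection):
    from .mzml import peakmap_to_bytes

    conn.execute("CREATE TABLE __meta__ (key TEXT PRIMARY KEY, value TEXT)")
    conn.execute("CREATE TABLE __peakmaps__ (id INTEGER PRIMARY KEY, sha1 TEXT UNIQUE, blob BLOB)")
    conn.execute("CREATE TABLE __subtables__ (id INTEGER PRIMARY KEY, sha1 TEXT UNIQUE, blob BLOB)")
    cols = ", ".join(f"{_q(n)} {_SQL_TYPE[tt]}" for n, tt in zip(t.col_names, t.col_types))
    conn.execute(f"CREATE TABLE data (_idx INTEGER PRIMARY KEY{', ' + cols if cols else ''})")
    header = {
        "format_version": FORMAT_VERSION,
        "col_names": t.col_names,
        "col_types": t.col_types,
        "col_formats": t.col_formats,
        "meta": t.meta,
    }
    conn.execute("INSERT INTO __meta__ VALUES ('header', ?)", (json.dumps(header),))

    # serialize each referenced object once, deduplicated by content hash
    obj_cols = [(i, tt) for i, tt in enumerate(t.col_types) if tt in ("peakmap", "table")]
    key_to_file_id: dict[tuple[str, int], int] = {}

    def _file_id(kind: str, key: int) -> int:
        if (kind, key) in key_to_file_id:
            return key_to_file_id[(kind, key)]
        obj = t._objects[key]
        blob = peakmap_to_bytes(obj) if kind == "peakmap" else obj.to_bytes()
        sha = hashlib.sha1(blob).hexdigest()
        tab = "__peakmaps__" if kind == "peakmap" else "__subtables__"
        row = conn.execute(f"SELECT id FROM {tab} WHERE sha1 = ?", (sha,)).fetchone()
        if row is None:
            cur = conn.execute(f"INSERT INTO {tab} (sha1, blob) VALUES (?, ?)",
                               (sha, sqlite3.Binary(blob)))
            fid = cur.lastrowid
        else:
            fid = row[0]
        key_to_file_id[(kind, key)] = fid
        return fid

    cur = t._conn.execute(
        f"SELECT _idx{', ' if t.col_names else ''}{t._cols_sql()} FROM data ORDER BY _idx"
    )
    ph = ", ".join("?" for _ in range(len(t.col_names) + 1))
    while True:
        batch = cur.fetchmany(BATCH)
        if not batch:
            break
        conv = []
        for row in batch:
            row = list(row)
            for i, tt in obj_cols:
                if row[i + 1] is not None:
                    row[i + 1] = _file_id(tt, row[i + 1])
            conv.append(row)
        conn.executemany(f"INSERT INTO data VALUES ({ph})", conv)
    conn.commit()


def save_table(t: Table, path) -> None:
    """Persist schema, rows, metadata and referenced peakmaps to one file."""
    path = str(path)
    if os.path.exists(path):
        os.remove(path)
    conn = sqlite3.connect(path)
    try:
        _save_into(t, conn)
    finally:
        conn.close()


def _load_from(conn: sqlite3.Connection, mode: str, path=None) -> Table:
    from .mzml import peakmap_from_bytes

    try:
        raw = conn.execute("SELECT value FROM __meta__ WHERE key='header'").fetchone()
    except sqlite3.OperationalError:
        raise UnsupportedVersionError("not an mzkit table file") from None
    header = json.loads(raw[0])
    version = header.get("format_version")
    if version != FORMAT_VERSION:
        raise UnsupportedVersionError(
            f"unsupported table format version {version!r} (supported: {FORMAT_VERSION})"
        )
    names, types_, formats = header["col_names"], header["col_types"], header["col_formats"]
    out = Table._new(names, types_, formats, mode, path, None, header.get("meta"))
    obj_cols = [(i, tt) for i, tt in enumerate(types_) if tt in ("peakmap", "table")]
    cache: dict[tuple[str, int], int] = {}

    def _resolve(kind: str, fid: int) -> int:
        if (kind, fid) in cache:
            return cache[(kind, fid)]
        tab = "__peakmaps__" if kind == "peakmap" else "__subtables__"
        blob = conn.execute(f"SELECT blob FROM {tab} WHERE id=?", (fid,)).fetchone()[0]
        obj = peakmap_from_bytes(bytes(blob)) if kind == "peakmap" else table_from_bytes(bytes(blob))
        key = out._next_object_key()
        out._objects[key] = obj
        cache[(kind, fid)] = key
        return key

    sel_cols = ", ".join(_q(n) for n in names)
    cur = conn.execute(f"SELECT _idx{', ' if names else ''}{sel_cols} FROM data ORDER BY _idx")
    ph = ", ".join("?" for _ in range(len(names) + 1))
    while True:
        batch = cur.fetchmany(BATCH)
        if not batch:
            break
        conv = []
        for row in batch:
            row = list(row)
            for i, tt in obj_cols:
                if row[i + 1] is not None:
                    row[i + 1] = _resolve(tt, row[i + 1])
            conv.append(row)
        out._conn.executemany(f"INSERT INTO data VALUES ({ph})", conv)
    out._conn.commit()
    return out


def load_table(path, mode: str = "memory", storage_path=None) -> Table:
    """Load a table saved by :func:`save_table`."""
    if not os.path.exists(str(path)):
        raise FileNotFoundError(f"no such table file: {path}")
    conn = sqlite3.connect(str(path))
    try:
        return _load_from(conn, mode, storage_path)
    finally:
        conn.close()


def table_to_bytes(t: Table) -> bytes:
    conn = sqlite3.connect(":memory:")
    try:
        _save_into(t, conn)
        return bytes(conn.serialize())
    finally:
        conn.close()


def table_from_bytes(data: bytes) -> Table:
    conn = sqlite3.connect(":memory:")
    try:
        conn.deserialize(data)
        return _load_from(conn, "memory")
    finally:
        conn.close()


Table.to_bytes = table_to_bytes  # type: ignore[attr-defined]


# -- CSV interop ----------------------------------------------------------

def table_to_csv(t: Table, path, delimiter: str = ",") -> None:
    """Export to delimited text; peakmap/table columns are not exportable."""
    import csv

    for n, tt in zip(t.col_names, t.col_types):
        if tt in ("peakmap", "table"):
            raise TypeError(f"cannot export object column {n!r} to CSV")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(t.col_names)
        for row in t.rows():
            w.writerow(["" if v is None else repr(v) if isinstance(v, float) else v
                        for v in row])


def table_from_csv(path, col_types, delimiter: str = ",", meta=None) -> Table:
    """Import delimited text with explicit column types (no sniffing)."""
    import csv

    def conv(cell: str, tt: str):
        if cell == "":
            return None
        if tt == "integer":
            return int(cell)
        if tt == "real":
            return float(cell)
        if tt == "boolean":
            if cell in ("True", "true", "1"):
                return True
            if cell in ("False", "false", "0"):
                return False
            raise ValueError(f"invalid boolean {cell!r}")
        return cell

    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        names = next(reader)
        if len(names) != len(col_types):
            raise SchemaError("column count of file does not match col_types")
        rows = [tuple(conv(c, tt) for c, tt in zip(row, col_types)) for row in reader]
    return create_table(names, col_types, rows, meta=meta)


# -- equality -------------------------------------------------------------

def tables_equal(a: Table, b: Table, compare_meta: bool = True) -> bool:
    """Deep equality: schema, formats, row values (recursing into objects)."""
    if (a.col_names, a.col_types, a.col_formats) != (b.col_names, b.col_types, b.col_formats):
        return False
    if compare_meta and a.meta != b.meta:
        return False
    if len(a) != len(b):
        return False
    for ra, rb in zip(a.rows(), b.rows()):
        for va, vb, tt in zip(ra, rb, a.col_types):
            if tt == "table":
                if (va is None) != (vb is None):
                    return False
                if va is not None and not tables_equal(va, vb, compare_meta):
                    return False
            elif va != vb:
                return False
    return True
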