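"""Naive list-of-rows reference engine for differential table tests.

Implements the same relational semantics as the SQLite-backed engine —
three-valued logic, first-appearance grouping, stable sorts, nested-loop
joins — by direct row-by-row evaluation in Python, with no SQL involved.
"""

from __future__ import annotations

import math
import statistics

from mzkit.expressions import _BinOp, _Col, _Lit, _MissingTest, _Not


def eval_expr(expr, row: dict):
    """Three-valued evaluation of an expression on one row dict."""
    if isinstance(expr, _Col):
        return row[expr.name]
    if isinstance(expr, _Lit):
        return expr.value
    if isinstance(expr, _MissingTest):
        v = eval_expr(expr.operand, row)
        return (v is not None) if expr.negate else (v is None)
    if isinstance(expr, _Not):
        v = eval_expr(expr.operand, row)
        return None if v is None else (not v)
    if isinstance(expr, _BinOp):
        lv = eval_expr(expr.left, row)
        rv = eval_expr(expr.right, row)
        op = expr.op
        if op == "and":
            if lv is False or rv is False:
                return False
            if lv is None or rv is None:
                return None
            return True
        if op == "or":
            if lv is True or rv is True:
                return True
            if lv is None or rv is None:
                return None
            return False
        if lv is None or rv is None:
            return None
        if op == "+":
            return lv + rv
        if op == "-":
            return lv - rv
        if op == "*":
            return lv * rv
        if op == "/":
            return None if rv == 0 else lv / rv
        if op == "==":
            return lv == rv
        if op == "!=":
            return lv != rv
        if op == "<":
            return lv < rv
        if op == "<=":
            return lv <= rv
        if op == ">":
            return lv > rv
        if op == ">=":
            return lv >= rv
    raise TypeError(f"unknown expression node {expr!r}")


class OracleTable:
    """Plain-Python rows with the engine's relational semantics."""

    def __init__(self, col_names, col_types, rows):
        self.col_names = list(col_names)
        self.col_types = list(col_types)
        self.rows = [tuple(r) for r in rows]

    def _dicts(self):
        return [dict(zip(self.col_names, r)) for r in self.rows]

    def filter(self, expr):
        kept = [r for r, d in zip(self.rows, self._dicts())
                if eval_expr(expr, d) is True]
        return OracleTable(self.col_names, self.col_types, kept)

    def add_column(self, name, expr, type_):
        rows = [r + (eval_expr(expr, d),)
                for r, d in zip(self.rows, self._dicts())]
        return OracleTable(self.col_names + [name], self.col_types + [type_], rows)

    def sort(self, by, descending=False):
        if isinstance(by, str):
            by = [by]
        if isinstance(descending, bool):
            descending = [descending] * len(by)
        rows = list(self.rows)
        for name, desc in reversed(list(zip(by, descending))):
            i = self.col_names.index(name)
            if desc:
                # SQL: NULLs last when descending; stable for ties
                rows.sort(key=lambda r: (0, 0) if r[i] is None else (1, r[i]),
                          reverse=True)
            else:
                # SQL: NULLs first when ascending
                rows.sort(key=lambda r: (0, 0) if r[i] is None else (1, r[i]))
        return OracleTable(self.col_names, self.col_types, rows)

    def _join(self, other, on, postfix, outer):
        right_names = [n + postfix if n in self.col_names else n
                       for n in other.col_names]
        names = self.col_names + right_names
        types = self.col_types + other.col_types
        out = []
        for lrow in self.rows:
            matched = False
            ld = dict(zip(self.col_names, lrow))
            for rrow in other.rows:
                d = dict(ld)
                for orig, out_n, v in zip(other.col_names, right_names, rrow):
                    d.setdefault(orig, v)
                    d[out_n] = v
                if eval_expr(on, d) is True:
                    matched = True
                    out.append(lrow + rrow)
            if outer and not matched:
                out.append(lrow + (None,) * len(other.col_names))
        return OracleTable(names, types, out)

    def join(self, other, on, postfix="__1"):
        return self._join(other, on, postfix, outer=False)

    def left_join(self, other, on, postfix="__1"):
        return self._join(other, on, postfix, outer=True)

    def group_aggregate(self, keys, aggregations):
        if isinstance(keys, str):
            keys = [keys]
        key_idx = [self.col_names.index(k) for k in keys]
        groups: dict[tuple, list[tuple]] = {}
        order: list[tuple] = []
        for r in self.rows:
            key = tuple(r[i] for i in key_idx)
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(r)
        if not keys and not self.rows:
            groups[()] = []
            order.append(())

        def agg(func, values):
            present = [v for v in values if v is not None]
            if func == "count":
                return len(present)
            if not present:
                return None
            if func == "sum":
                if any(isinstance(v, float) for v in present):
                    return math.fsum(present)  # compensated, like SQLite >= 3.44
                return sum(present)
            if func == "mean":
                return math.fsum(present) / len(present)
            if func == "median":
                return float(statistics.median(present))
            if func == "min":
                return min(present)
            if func == "max":
                return max(present)
            if func == "first":
                return present[0]
            raise ValueError(func)

        names = list(keys)
        types = [self.col_types[i] for i in key_idx]
        specs = []
        for a in aggregations:
            src, func = a[0], a[1]
            out_n = a[2] if len(a) == 3 else f"{src}_{func}"
            names.append(out_n)
            src_type = self.col_types[self.col_names.index(src)]
            if func == "count":
                types.append("integer")
            elif func in ("mean", "median"):
                types.append("real")
            elif func == "sum":
                types.append("integer" if src_type in ("integer", "boolean") else "real")
            else:
                types.append(src_type)
            specs.append((self.col_names.index(src), func))
        out_rows = []
        for key in order:
            cells = list(key)
            for i, func in specs:
                cells.append(agg(func, [r[i] for r in groups[key]]))
            out_rows.append(tuple(cells))
        return OracleTable(names, types, out_rows)
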