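"""Column expressions for the table engine.

Expressions are trees over column references, literals, arithmetic,
comparisons, boolean connectives and missing-value tests.  They follow
three-valued logic: any operator applied to a missing value yields
missing, except the explicit ``is_missing``/``is_not_missing`` tests.
The engine compiles them to SQL, whose NULL semantics match.

>>> from mzkit.expressions import col
>>> predicate = (col("mz") > 100.0) & col("name").is_not_missing()
"""

from __future__ import annotations

from typing import Any

__all__ = ["Expression", "ExpressionError", "col", "lit"]


class ExpressionError(ValueError):
    """Unknown column or operator/type mismatch in an expression."""


_NUMERIC = {"integer", "real", "boolean"}

# SQL fragments; '/' is true division (see _BinOp.sql)
_SQL_OP = {
    "+": "+", "-": "-", "*": "*",
    "==": "=", "!=": "!=", "<": "<", "<=": "<=", ">": ">", ">=": ">=",
    "and": "AND", "or": "OR",
}

_COMPARISONS = {"==", "!=", "<", "<=", ">", ">="}
_ARITH = {"+", "-", "*", "/"}


class Expression:
    """Base class; builds trees via operator overloading."""

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        return _BinOp("+", self, _wrap(other))

    def __radd__(self, other):
        return _BinOp("+", _wrap(other), self)

    def __sub__(self, other):
        return _BinOp("-", self, _wrap(other))

    def __rsub__(self, other):
        return _BinOp("-", _wrap(other), self)

    def __mul__(self, other):
        return _BinOp("*", self, _wrap(other))

    def __rmul__(self, other):
        return _BinOp("*", _wrap(other), self)

    def __truediv__(self, other):
        return _BinOp("/", self, _wrap(other))

    def __rtruediv__(self, other):
        return _BinOp("/", _wrap(other), self)

    def __neg__(self):
        return _BinOp("-", lit(0), self)

    # -- comparisons ---------------------------------------------------
    def __eq__(self, other):  # type: ignore[override]
        return _BinOp("==", self, _wrap(other))

    def __ne__(self, other):  # type: ignore[override]
        return _BinOp("!=", self, _wrap(other))

    def __lt__(self, other):
        return _BinOp("<", self, _wrap(other))

    def __le__(self, other):
        return _BinOp("<=", self, _wrap(other))

    def __gt__(self, other):
        return _BinOp(">", self, _wrap(other))

    def __ge__(self, other):
        return _BinOp(">=", self, _wrap(other))

    __hash__ = None  # type: ignore[assignment]

    # -- boolean -------------------------------------------------------
    def __and__(self, other):
        return _BinOp("and", self, _wrap(other))

    def __rand__(self, other):
        return _BinOp("and", _wrap(other), self)

    def __or__(self, other):
        return _BinOp("or", self, _wrap(other))

    def __ror__(self, other):
        return _BinOp("or", _wrap(other), self)

    def __invert__(self):
        return _Not(self)

    # -- missing tests -------------------------------------------------
    def is_missing(self):
        return _MissingTest(self, negate=False)

    def is_not_missing(self):
        return _MissingTest(self, negate=True)

    # -- interface for the engine --------------------------------------
    def infer_type(self, schema: dict[str, str]) -> str:
        raise NotImplementedError

    def sql(self, colmap: dict[str, str], params: list) -> str:
        raise NotImplementedError

    def columns(self) -> set[str]:
        raise NotImplementedError


def _wrap(value) -> Expression:
    return value if isinstance(value, Expression) else lit(value)


class _Col(Expression):
    def __init__(self, name: str):
        self.name = name

    def infer_type(self, schema):
        try:
            return schema[self.name]
        except KeyError:
            raise ExpressionError(f"unknown column {self.name!r}") from None

    def sql(self, colmap, params):
        try:
            return colmap[self.name]
        except KeyError:
            raise ExpressionError(f"unknown column {self.name!r}") from None

    def columns(self):
        return {self.name}

    def __repr__(self):
        return f"col({self.name!r})"


class _Lit(Expression):
    def __init__(self, value: Any):
        if value is not None and not isinstance(value, (bool, int, float, str)):
            raise ExpressionError(f"unsupported literal {value!r}")
        self.value = value

    def infer_type(self, schema):
        if self.value is None:
            return "missing"
        if isinstance(self.value, bool):
            return "boolean"
        if isinstance(self.value, int):
            return "integer"
        if isinstance(self.value, float):
            return "real"
        return "text"

    def sql(self, colmap, params):
        if self.value is None:
            return "NULL"
        params.append(int(self.value) if isinstance(self.value, bool) else self.value)
        return "?"

    def columns(self):
        return set()

    def __repr__(self):
        return f"lit({self.value!r})"


def _check_operand_types(op: str, lt: str, rt: str) -> str:
    """Result type of `lt op rt`; 'missing' literals adapt to the other side."""
    if lt == "missing":
        lt = rt
    if rt == "missing":
        rt = lt
    if lt == "missing":  # both missing
        return "boolean" if op in _COMPARISONS or op in ("and", "or") else "missing"
    if op in _ARITH:
        if lt in ("integer", "real") and rt in ("integer", "real"):
            if op == "/":
                return "real"
            return "real" if "real" in (lt, rt) else "integer"
        raise ExpressionError(f"operator {op!r} not defined for {lt}/{rt}")
    if op in _COMPARISONS:
        if lt in _NUMERIC and rt in _NUMERIC:
            return "boolean"
        if lt == rt == "text":
            return "boolean"
        raise ExpressionError(f"cannot compare {lt} with {rt}")
    if op in ("and", "or"):
        if lt == rt == "boolean":
            return "boolean"
        raise ExpressionError(f"{op!r} requires boolean operands, got {lt}/{rt}")
    raise ExpressionError(f"unknown operator {op!r}")


class _BinOp(Expression):
    def __init__(self, op: str, left: Expression, right: Expression):
        self.op, self.left, self.right = op, left, right

    def infer_type(self, schema):
        return _check_operand_types(
            self.op, self.left.infer_type(schema), self.right.infer_type(schema)
        )

    def sql(self, colmap, params):
        ls = self.left.sql(colmap, params)
        rs = self.right.sql(colmap, params)
        if self.op == "/":
            # true division; division by zero yields NULL (missing)
            return f"(CAST({ls} AS REAL) / {rs})"
        return f"({ls} {_SQL_OP[self.op]} {rs})"

    def columns(self):
        return self.left.columns() | self.right.columns()

    def __repr__(self):
        return f"({self.left!r} {self.op} {self.right!r})"


class _Not(Expression):
    def __init__(self, operand: Expression):
        self.operand = operand

    def infer_type(self, schema):
        t = self.operand.infer_type(schema)
        if t not in ("boolean", "missing"):
            raise ExpressionError(f"'~' requires a boolean operand, got {t}")
        return "boolean"

    def sql(self, colmap, params):
        return f"(NOT {self.operand.sql(colmap, params)})"

    def columns(self):
        return self.operand.columns()

    def __repr__(self):
        return f"(~{self.operand!r})"


class _MissingTest(Expression):
    def __init__(self, operand: Expression, negate: bool):
        self.operand, self.negate = operand, negate

    def infer_type(self, schema):
        self.operand.infer_type(schema)  # validates columns
        return "boolean"

    def sql(self, colmap, params):
        tail = "IS NOT NULL" if self.negate else "IS NULL"
        return f"({self.operand.sql(colmap, params)} {tail})"

    def columns(self):
        return self.operand.columns()

    def __repr__(self):
        kind = "is_not_missing" if self.negate else "is_missing"
        return f"{self.operand!r}.{kind}()"


def col(name: str) -> Expression:
    """Reference a table column by name."""
    if not isinstance(name, str):
        raise ExpressionError("column name must be a string")
    return _Col(name)


def lit(value) -> Expression:
    """A literal (int, float, bool, str or None for missing)."""
    return _Lit(value)
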