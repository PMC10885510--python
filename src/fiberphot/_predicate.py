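"""A bounded predicate grammar for per-timestep event conditions.

Conditions gate candidate events on other variables in the same recording,
e.g. ``"time < 360 and speed > 2"``.  The grammar is deliberately small:
comparisons (<, <=, ==, !=, >=, >) between channel names, the ``time``
variable and numeric literals, combined with ``and`` / ``or`` / ``not`` and
parentheses.  Function calls, attribute access, subscripts and any other
host-language construct are rejected — this is a data-driven filter, not a
script hook.
"""

from __future__ import annotations

import ast

import numpy as np

__all__ = ["PredicateError", "compile_predicate"]


class PredicateError(ValueError):
    """Raised when a condition expression falls outside the supported grammar."""


_CMP_OPS = {
    ast.Lt: np.less,
    ast.LtE: np.less_equal,
    ast.Eq: np.equal,
    ast.NotEq: np.not_equal,
    ast.Gt: np.greater,
    ast.GtE: np.greater_equal,
}


class _Compiler:
    def __init__(self, names: set[str]):
        self.allowed = names
        self.used: set[str] = set()

    def value(self, node: ast.expr):
        """Compile a scalar/vector-valued sub-expression."""
        if isinstance(node, ast.Constant):
            if isinstance(node.value, bool) or not isinstance(node.value, (int, float)):
                raise PredicateError(
                    f"only numeric literals are allowed, got {node.value!r}"
                )
            v = float(node.value)
            return lambda env, v=v: v
        if isinstance(node, ast.Name):
            if node.id not in self.allowed:
                raise PredicateError(
                    f"unknown identifier {node.id!r}; available: {sorted(self.allowed)}"
                )
            self.used.add(node.id)
            return lambda env, n=node.id: env[n]
        if isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.USub):
            inner = self.value(node.operand)
            return lambda env, f=inner: -f(env)
        raise PredicateError(
            f"unsupported expression element {ast.dump(node, annotate_fields=False)}; "
            "only channel names, 'time' and numeric literals may be compared"
        )

    def boolean(self, node: ast.expr):
        """Compile a boolean-valued sub-expression."""
        if isinstance(node, ast.BoolOp):
            parts = [self.boolean(v) for v in node.values]
            if isinstance(node.op, ast.And):
                return lambda env, ps=parts: np.logical_and.reduce([p(env) for p in ps])
            return lambda env, ps=parts: np.logical_or.reduce([p(env) for p in ps])
        if isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.Not):
            inner = self.boolean(node.operand)
            return lambda env, f=inner: np.logical_not(f(env))
        if isinstance(node, ast.Compare):
            left = self.value(node.left)
            chain = []
            cur = left
            for op, comp in zip(node.ops, node.comparators):
                if type(op) not in _CMP_OPS:
                    raise PredicateError(f"unsupported comparison operator {type(op).__name__}")
                right = self.value(comp)
                chain.append((_CMP_OPS[type(op)], cur, right))
                cur = right
            def run(env, chain=chain):
                acc = None
                for fn, lhs, rhs in chain:
                    with np.errstate(invalid="ignore"):
                        part = fn(lhs(env), rhs(env))
                    acc = part if acc is None else np.logical_and(acc, part)
                return acc
            return run
        raise PredicateError(
            "condition must be comparisons combined with and/or/not; got "
            f"{ast.dump(node, annotate_fields=False)}"
        )


def compile_predicate(expression: str, channel_names):
    """Compile a condition string into ``f(env) -> bool array``.

    ``env`` maps each referenced name (channel names plus ``time``) to a
    numeric vector; all vectors must share a length.  Samples where any
    referenced channel is missing evaluate to False.  Returns
    ``(fn, used_names)``.
    """
    allowed = set(channel_names) | {"time"}
    try:
        tree = ast.parse(expression, mode="eval")
    except SyntaxError as exc:
        raise PredicateError(f"cannot parse condition {expression!r}: {exc.msg}") from exc
    compiler = _Compiler(allowed)
    fn = compiler.boolean(tree.body)
    used = frozenset(compiler.used)

    def evaluate(env: dict) -> np.ndarray:
        result = np.asarray(fn(env), dtype=bool)
        finite = np.ones_like(result)
        for name in used:
            finite &= np.isfinite(env[name])
        return result & finite

    return evaluate, used
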