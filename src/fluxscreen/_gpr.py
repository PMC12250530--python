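"""Parser and evaluator for gene-protein-reaction (GPR) boolean rules.

Grammar (infix, case-insensitive keywords)::

    expr   := term  ("or"  term)*
    term   := factor ("and" factor)*
    factor := "(" expr ")" | GENE

An empty rule means the reaction is not enzyme-constrained.
Evaluation maps AND to min (complex: limited by scarcest subunit) and OR to
sum (isozymes: capacities add).
"""

from __future__ import annotations

import math
import re

from .errors import GPRSyntaxError

_TOKEN = re.compile(r"\(|\)|[^\s()]+")

# tree node: ("and", [children]) | ("or", [children]) | ("gene", name)


def tokenize(text: str) -> list[str]:
    return _TOKEN.findall(text)


def parse(text: str):
    """Parse a GPR rule into an AND/OR tree; ``None`` for an empty rule."""
    if text is None or not text.strip():
        return None
    tokens = tokenize(text)
    tree, pos = _parse_or(tokens, 0, text)
    if pos != len(tokens):
        raise GPRSyntaxError(f"trailing tokens in GPR {text!r}: {tokens[pos:]}")
    return tree


def _parse_or(tokens, pos, src):
    node, pos = _parse_and(tokens, pos, src)
    children = [node]
    while pos < len(tokens) and tokens[pos].lower() == "or":
        node, pos = _parse_and(tokens, pos + 1, src)
        children.append(node)
    if len(children) == 1:
        return children[0], pos
    return ("or", children), pos


def _parse_and(tokens, pos, src):
    node, pos = _parse_factor(tokens, pos, src)
    children = [node]
    while pos < len(tokens) and tokens[pos].lower() == "and":
        node, pos = _parse_factor(tokens, pos + 1, src)
        children.append(node)
    if len(children) == 1:
        return children[0], pos
    return ("and", children), pos


def _parse_factor(tokens, pos, src):
    if pos >= len(tokens):
        raise GPRSyntaxError(f"unexpected end of GPR {src!r}")
    tok = tokens[pos]
    if tok == "(":
        node, pos = _parse_or(tokens, pos + 1, src)
        if pos >= len(tokens) or tokens[pos] != ")":
            raise GPRSyntaxError(f"unbalanced parentheses in GPR {src!r}")
        return node, pos + 1
    if tok == ")" or tok.lower() in ("and", "or"):
        raise GPRSyntaxError(f"unexpected token {tok!r} in GPR {src!r}")
    return ("gene", tok), pos + 1


def genes(tree) -> set[str]:
    """All gene identifiers appearing in a parsed rule."""
    if tree is None:
        return set()
    kind, payload = tree
    if kind == "gene":
        return {payload}
    out: set[str] = set()
    for child in payload:
        out |= genes(child)
    return out


def evaluate(tree, gene_levels, missing: float = 0.0) -> float:
    """Aggregate gene abundances over a rule: AND -> min, OR -> sum.

    ``None`` (empty rule) evaluates to +inf, the "unbounded" sentinel.
    Genes absent from ``gene_levels`` contribute ``missing``.
    """
    if tree is None:
        return math.inf
    kind, payload = tree
    if kind == "gene":
        return float(gene_levels.get(payload, missing))
    values = [evaluate(child, gene_levels, missing) for child in payload]
    if kind == "and":
        return min(values)
    return sum(values)
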