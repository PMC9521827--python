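"""Gene-protein-reaction (GPR) rule parsing, evaluation and OR-decomposition.

A GPR rule is a Boolean expression over gene identifiers using ``and`` (all
subunits of a complex required) and ``or`` (alternative isozymes).  Draft
reconstruction from template models hinges on four evaluation principles:

* a single-gene rule requires its homolog to be present;
* an OR-only rule is satisfied by any one homolog;
* an AND-only rule requires every homolog;
* a mixed rule is decomposed by OR into isozyme clauses (conjunctions),
  each of which is evaluated like an AND-only rule.

The decomposition produced by :func:`decompose_or` is the minimal disjunctive
normal form (duplicate clauses collapsed, superset clauses absorbed), so a
rule is satisfied by a gene set iff at least one clause is fully contained in
that set.  :func:`assemble_partial_gpr` applies these principles against an
ortholog mapping and rewrites the surviving clauses onto query-gene ids.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

__all__ = [
    "GeneRule",
    "GeneRef",
    "And",
    "Or",
    "IsozymeClause",
    "AssembledGpr",
    "GprParseError",
    "GprExplosionError",
    "parse_gpr",
    "render",
    "genes",
    "evaluate",
    "decompose_or",
    "clauses_to_rule",
    "assemble_partial_gpr",
    "MAX_CLAUSES",
]

#: A single isozyme clause: a conjunction of gene ids, satisfied iff all present.
IsozymeClause = FrozenSet[str]

#: Hard cap on the number of DNF clauses per rule; exceeded caps fail loudly.
MAX_CLAUSES = 10_000

_KEYWORDS = frozenset({"and", "or"})
_TOKEN_RE = re.compile(r"\(|\)|[^()\s]+")


class GprParseError(ValueError):
    """Raised for malformed GPR strings; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class GprExplosionError(RuntimeError):
    """Raised when DNF expansion of a rule exceeds :data:`MAX_CLAUSES`."""


class GeneRule:
    """Base class for nodes of a GPR Boolean tree."""

    __slots__ = ()


@dataclass(frozen=True)
class GeneRef(GeneRule):
    """Leaf node referencing one gene identifier."""

    gene_id: str


@dataclass(frozen=True)
class And(GeneRule):
    """Conjunction node; children are two or more sub-rules."""

    children: Tuple[GeneRule, ...]


@dataclass(frozen=True)
class Or(GeneRule):
    """Disjunction node; children are two or more sub-rules."""

    children: Tuple[GeneRule, ...]


def _combine(cls, children: Sequence[GeneRule]) -> GeneRule:
    """Build an n-ary node, flattening nested nodes of the same kind and
    collapsing duplicate children; a single distinct child is returned as-is."""
    flat: List[GeneRule] = []
    seen = set()
    for child in children:
        parts = child.children if isinstance(child, cls) else (child,)
        for part in parts:
            if part not in seen:
                seen.add(part)
                flat.append(part)
    if not flat:
        raise ValueError("boolean node requires at least one child")
    if len(flat) == 1:
        return flat[0]
    return cls(tuple(flat))


def and_(children: Sequence[GeneRule]) -> GeneRule:
    return _combine(And, children)


def or_(children: Sequence[GeneRule]) -> GeneRule:
    return _combine(Or, children)


def _is_keyword(token: str) -> bool:
    return token.lower() in _KEYWORDS


def parse_gpr(text: Optional[str]) -> Optional[GeneRule]:
    """Parse a COBRA/BiGG-dialect GPR string into a :class:`GeneRule`.

    ``and`` binds tighter than ``or``; keywords are matched case-insensitively
    as whole words; gene tokens are any run of characters excluding
    whitespace and parentheses (BiGG gene ids contain dots and dashes).
    Empty or whitespace-only text yields ``None`` (no gene association).

    Raises :class:`GprParseError` with the offending character position for
    unbalanced parentheses, dangling operators, or adjacent gene tokens.
    """
    if text is None or not text.strip():
        return None
    tokens = [(m.group(), m.start()) for m in _TOKEN_RE.finditer(text)]
    pos = 0

    def current() -> Tuple[Optional[str], int]:
        if pos < len(tokens):
            return tokens[pos]
        return None, len(text)

    def parse_disjunction() -> GeneRule:
        nonlocal pos
        terms = [parse_conjunction()]
        while True:
            tok, _ = current()
            if tok is not None and tok.lower() == "or":
                pos += 1
                terms.append(parse_conjunction())
            else:
                return or_(terms)

    def parse_conjunction() -> GeneRule:
        nonlocal pos
        factors = [parse_atom()]
        while True:
            tok, _ = current()
            if tok is not None and tok.lower() == "and":
                pos += 1
                factors.append(parse_atom())
            else:
                return and_(factors)

    def parse_atom() -> GeneRule:
        nonlocal pos
        tok, at = current()
        if tok is None:
            raise GprParseError("unexpected end of rule", at)
        if tok == "(":
            pos += 1
            inner = parse_disjunction()
            tok, at = current()
            if tok != ")":
                raise GprParseError("unbalanced parenthesis: expected ')'", at)
            pos += 1
            return inner
        if tok == ")":
            raise GprParseError("unbalanced parenthesis: unexpected ')'", at)
        if _is_keyword(tok):
            raise GprParseError(f"dangling operator {tok!r}", at)
        pos += 1
        return GeneRef(tok)

    rule = parse_disjunction()
    tok, at = current()
    if tok is not None:
        raise GprParseError(f"unexpected token {tok!r}", at)
    return rule


def render(rule: Optional[GeneRule]) -> str:
    """Serialize a rule with lowercase operators and minimal parentheses."""
    if rule is None:
        return ""
    if isinstance(rule, GeneRef):
        return rule.gene_id
    if isinstance(rule, And):
        parts = []
        for child in rule.children:
            text = render(child)
            if isinstance(child, Or):
                text = f"({text})"
            parts.append(text)
        return " and ".join(parts)
    if isinstance(rule, Or):
        return " or ".join(render(child) for child in rule.children)
    raise TypeError(f"not a GeneRule node: {rule!r}")


def genes(rule: Optional[GeneRule]) -> FrozenSet[str]:
    """All gene ids referenced by the rule."""
    if rule is None:
        return frozenset()
    if isinstance(rule, GeneRef):
        return frozenset({rule.gene_id})
    out: set = set()
    for child in rule.children:  # type: ignore[union-attr]
        out |= genes(child)
    return frozenset(out)


def evaluate(rule: GeneRule, present: Iterable[str]) -> bool:
    """Standard Boolean semantics: a leaf is true iff its gene is present."""
    present = set(present)

    def _eval(node: GeneRule) -> bool:
        if isinstance(node, GeneRef):
            return node.gene_id in present
        if isinstance(node, And):
            return all(_eval(c) for c in node.children)
        if isinstance(node, Or):
            return any(_eval(c) for c in node.children)
        raise TypeError(f"not a GeneRule node: {node!r}")

    return _eval(rule)


def _absorb(clauses: Iterable[IsozymeClause]) -> List[IsozymeClause]:
    """Minimal antichain under inclusion: drop duplicates and superset clauses."""
    unique = sorted(set(clauses), key=lambda c: (len(c), tuple(sorted(c))))
    kept: List[IsozymeClause] = []
    for clause in unique:
        if not any(prev <= clause for prev in kept):
            kept.append(clause)
    return kept


def decompose_or(
    rule: GeneRule,
    max_clauses: int = MAX_CLAUSES,
    context: str = "",
) -> List[IsozymeClause]:
    """Decompose a rule by OR into its minimal DNF isozyme clauses.

    The result is deterministic (clauses sorted by size then lexicographically)
    and an antichain under inclusion.  Rules whose expansion would exceed
    ``max_clauses`` raise :class:`GprExplosionError`; ``context`` (typically a
    reaction id) is included in the message.
    """

    def _expand(node: GeneRule) -> List[IsozymeClause]:
        if isinstance(node, GeneRef):
            return [frozenset({node.gene_id})]
        if isinstance(node, Or):
            out: List[IsozymeClause] = []
            for child in node.children:
                out.extend(_expand(child))
                if len(out) > max_clauses:
                    raise GprExplosionError(
                        f"DNF expansion exceeds {max_clauses} clauses"
                        + (f" for {context}" if context else "")
                    )
            return out
        if isinstance(node, And):
            acc: List[IsozymeClause] = [frozenset()]
            for child in node.children:
                child_clauses = _expand(child)
                acc = [a | b for a in acc for b in child_clauses]
                if len(acc) > max_clauses:
                    raise GprExplosionError(
                        f"DNF expansion exceeds {max_clauses} clauses"
                        + (f" for {context}" if context else "")
                    )
            return acc
        raise TypeError(f"not a GeneRule node: {node!r}")

    return _absorb(_expand(rule))


def clauses_to_rule(clauses: Sequence[IsozymeClause]) -> Optional[GeneRule]:
    """Rebuild a rule as an OR over AND-clauses (deterministic ordering)."""
    ordered = sorted(set(clauses), key=lambda c: (len(c), tuple(sorted(c))))
    if not ordered:
        return None
    terms: List[GeneRule] = []
    for clause in ordered:
        members = [GeneRef(g) for g in sorted(clause)]
        terms.append(members[0] if len(members) == 1 else And(tuple(members)))
    return terms[0] if len(terms) == 1 else Or(tuple(terms))


@dataclass(frozen=True)
class AssembledGpr:
    """Result of rewriting a template GPR onto query genes.

    ``complete`` is True when at least one isozyme clause was fully mapped;
    a False flag marks a partial assembly (non-strict mode only).
    """

    rule: GeneRule
    complete: bool


def assemble_partial_gpr(
    rule: GeneRule,
    ortholog: Mapping[str, Iterable[str]],
    strict: bool = True,
    max_clauses: int = MAX_CLAUSES,
    context: str = "",
) -> Optional[AssembledGpr]:
    """Evaluate a template rule against an ortholog map and rewrite it.

    ``ortholog`` maps template gene ids to one or more query gene ids.  Each
    isozyme clause is kept when all its genes are mapped (a *complete* clause);
    in non-strict mode a clause with at least one mapped gene contributes its
    mapped subset as a partial conjunction.  Surviving clauses are rewritten
    onto query ids — a template gene with several query orthologs expands into
    one clause per combination of choices — re-joined by OR and minimised by
    absorption.  Returns ``None`` when no clause survives.
    """
    multimap = {t: sorted(set(qs)) for t, qs in ortholog.items() if qs}
    out: List[IsozymeClause] = []
    complete = False
    for clause in decompose_or(rule, max_clauses=max_clauses, context=context):
        mapped = {g: multimap[g] for g in clause if g in multimap}
        if not mapped:
            continue
        if len(mapped) < len(clause):
            if strict:
                continue
        else:
            complete = True
        rewritten: List[IsozymeClause] = [frozenset()]
        for choices in mapped.values():
            rewritten = [c | {q} for c in rewritten for q in choices]
            if len(rewritten) > max_clauses:
                raise GprExplosionError(
                    f"ortholog rewriting exceeds {max_clauses} clauses"
                    + (f" for {context}" if context else "")
                )
        out.extend(rewritten)
    if not out:
        return None
    new_rule = clauses_to_rule(_absorb(out))
    assert new_rule is not None
    return AssembledGpr(rule=new_rule, complete=complete)
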