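"""Read and write the curated tab-delimited reaction-table dialect.

A table has columns ``id  equation  gpr  subsystem  [lb]  [ub]``; a header
row is permitted and ``#``-prefixed lines are comments. Equations use
``-->`` for irreversible and ``<=>`` for reversible reactions, with
``+``-separated ``coef metabolite_id`` terms (coefficient defaults to 1).
A blank side (or the empty-set symbol ``∅``) denotes a boundary
pseudo-reaction such as a reserve-mobilization pool or a sink.
"""

from __future__ import annotations

import re
import warnings
from typing import Dict, List, Tuple

from .model import GprRule, MetabolicModel, ModelValidationError, Reaction

__all__ = [
    "EquationParseError",
    "GprParseError",
    "TableParseError",
    "parse_equation",
    "parse_gpr",
    "parse_reaction_table",
    "read_reaction_table",
    "write_reaction_table",
]

IRREVERSIBLE_ARROW = "-->"
REVERSIBLE_ARROW = "<=>"
EMPTY_SET_TOKENS = {"", "∅", "nothing", "null"}

CANONICAL_COLUMNS = ["id", "equation", "gpr", "subsystem", "lb", "ub"]


class EquationParseError(ValueError):
    pass


class GprParseError(ValueError):
    pass


class TableParseError(ValueError):
    pass


_COEF_RE = re.compile(r"^[0-9]*\.?[0-9]+(?:[eE][+-]?[0-9]+)?$")


def _parse_side(side: str, equation: str) -> Dict[str, float]:
    """Parse one side of an equation into metabolite → positive coefficient."""
    side = side.strip()
    if side in EMPTY_SET_TOKENS:
        return {}
    coeffs: Dict[str, float] = {}
    for term in side.split("+"):
        tokens = term.split()
        if not tokens:
            raise EquationParseError(f"empty term in equation {equation!r}")
        if len(tokens) == 1:
            coef, met = 1.0, tokens[0]
        elif len(tokens) == 2:
            if not _COEF_RE.match(tokens[0]):
                raise EquationParseError(
                    f"malformed coefficient {tokens[0]!r} in equation {equation!r}"
                )
            coef, met = float(tokens[0]), tokens[1]
        else:
            raise EquationParseError(f"malformed term {term.strip()!r} in {equation!r}")
        if _COEF_RE.match(met):
            raise EquationParseError(
                f"term {term.strip()!r} in {equation!r} has no metabolite id"
            )
        coeffs[met] = coeffs.get(met, 0.0) + coef
    return coeffs


def parse_equation(equation: str) -> Tuple[Dict[str, float], bool]:
    """Parse an equation string into signed stoichiometry and reversibility.

    Left-side metabolites get negative coefficients, right-side positive;
    a metabolite appearing on both sides is net-summed. The arrow decides
    reversibility: ``-->`` irreversible, ``<=>`` reversible.

    >>> parse_equation("fum_m + h2o_m <=> mal_m")
    ({'fum_m': -1.0, 'h2o_m': -1.0, 'mal_m': 1.0}, True)
    """
    arrows = [a for a in (IRREVERSIBLE_ARROW, REVERSIBLE_ARROW) if a in equation]
    n_arrows = equation.count(IRREVERSIBLE_ARROW) + equation.count(REVERSIBLE_ARROW)
    if not arrows:
        raise EquationParseError(f"no arrow ('-->' or '<=>') in equation {equation!r}")
    if n_arrows > 1:
        raise EquationParseError(f"more than one arrow in equation {equation!r}")
    arrow = arrows[0]
    left_text, right_text = equation.split(arrow)
    left = _parse_side(left_text, equation)
    right = _parse_side(right_text, equation)
    if not left and not right:
        raise EquationParseError(f"both sides empty in equation {equation!r}")
    stoich: Dict[str, float] = {}
    for met, coef in left.items():
        stoich[met] = stoich.get(met, 0.0) - coef
    for met, coef in right.items():
        stoich[met] = stoich.get(met, 0.0) + coef
    stoich = {m: c for m, c in stoich.items() if abs(c) > 1e-9}
    if not stoich:
        raise EquationParseError(f"equation {equation!r} nets to nothing")
    return stoich, arrow == REVERSIBLE_ARROW


# ---------------------------------------------------------------------------
# GPR grammar: expr := term ("or" term)* ; term := factor ("and" factor)* ;
# factor := "(" expr ")" | GENE.  "and" binds tighter than "or".
# ---------------------------------------------------------------------------

_GPR_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(rule: str) -> GprRule:
    """Parse a boolean gene-association rule; empty string → empty rule."""
    text = rule.strip()
    if not text:
        return GprRule.empty()
    tokens = _GPR_TOKEN_RE.findall(text)
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        token = tokens[pos]
        pos += 1
        return token

    def parse_or() -> GprRule:
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else GprRule.or_(*terms)

    def parse_and() -> GprRule:
        factors = [parse_factor()]
        while peek() is not None and peek().lower() == "and":
            take()
            factors.append(parse_factor())
        return factors[0] if len(factors) == 1 else GprRule.and_(*factors)

    def parse_factor() -> GprRule:
        token = peek()
        if token is None:
            raise GprParseError(f"dangling connective in GPR rule {rule!r}")
        if token == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise GprParseError(f"unbalanced parentheses in GPR rule {rule!r}")
            take()
            return node
        if token == ")" or token.lower() in ("and", "or"):
            raise GprParseError(f"unexpected {token!r} in GPR rule {rule!r}")
        return GprRule.leaf(take())

    tree = parse_or()
    if pos != len(tokens):
        raise GprParseError(f"trailing tokens in GPR rule {rule!r}")
    return tree


# ---------------------------------------------------------------------------
# Table reading / writing
# ---------------------------------------------------------------------------


def _format_coefficient(coef: float) -> str:
    if abs(coef - round(coef)) < 1e-9:
        return f"{coef:.1f}"
    return f"{coef:.10g}"


def write_equation(reaction: Reaction) -> str:
    """Serialize stoichiometry back to an equation string (coefficient 1 omitted)."""

    def side(coeffs: Dict[str, float]) -> str:
        parts = []
        for met in sorted(coeffs):
            coef = coeffs[met]
            parts.append(met if abs(coef - 1.0) < 1e-9 else f"{_format_coefficient(coef)} {met}")
        return " + ".join(parts)

    arrow = REVERSIBLE_ARROW if reaction.reversible else IRREVERSIBLE_ARROW
    return f"{side(reaction.reactants)} {arrow} {side(reaction.products)}".strip()


def parse_reaction_table(text: str, name: str = "model") -> MetabolicModel:
    """Parse the tab-delimited reaction table into a validated model.

    Default bounds are ``(0, 1000)`` for irreversible and ``(-1000, 1000)``
    for reversible reactions; explicit ``lb``/``ub`` columns override them.
    Unknown header columns are preserved as reaction annotations.
    """
    lines = text.splitlines()
    columns = list(CANONICAL_COLUMNS)
    reactions: List[Reaction] = []
    seen_header = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if not seen_header and fields[0].strip().lower() == "id":
            columns = [f.strip().lower() for f in fields]
            seen_header = True
            continue
        seen_header = True
        row = {col: fields[i].strip() if i < len(fields) else ""
               for i, col in enumerate(columns)}
        try:
            reaction = _row_to_reaction(row, fields, columns)
        except (EquationParseError, GprParseError, ModelValidationError) as exc:
            raise TableParseError(f"line {lineno}: {exc}") from exc
        if any(reaction.id == r.id for r in reactions):
            raise TableParseError(f"line {lineno}: duplicate reaction id {reaction.id!r}")
        reactions.append(reaction)
    if not reactions:
        warnings.warn(f"reaction table for {name!r} is empty", stacklevel=2)
    return MetabolicModel(name=name, reactions=reactions)


def _row_to_reaction(row: Dict[str, str], fields: List[str], columns: List[str]) -> Reaction:
    reaction_id = row.get("id", "")
    if not reaction_id:
        raise EquationParseError("missing reaction id")
    stoich, reversible = parse_equation(row.get("equation", ""))
    gpr = parse_gpr(row.get("gpr", ""))
    lower_default, upper_default = (-1000.0, 1000.0) if reversible else (0.0, 1000.0)
    lb_text, ub_text = row.get("lb", ""), row.get("ub", "")
    lower = float(lb_text) if lb_text else lower_default
    upper = float(ub_text) if ub_text else upper_default
    annotations = {
        col: fields[i].strip()
        for i, col in enumerate(columns)
        if col not in CANONICAL_COLUMNS and i < len(fields) and fields[i].strip()
    }
    return Reaction(
        id=reaction_id,
        stoichiometry=stoich,
        reversible=reversible,
        lower_bound=lower,
        upper_bound=upper,
        gpr=gpr,
        subsystem=row.get("subsystem", ""),
        annotations=annotations,
    )


def write_reaction_table(model: MetabolicModel) -> str:
    """Serialize a model to the same dialect accepted by :func:`parse_reaction_table`."""
    extra_cols: List[str] = []
    for reaction in model.reactions:
        for key in reaction.annotations:
            if key not in extra_cols:
                extra_cols.append(key)
    columns = CANONICAL_COLUMNS + extra_cols
    lines = ["\t".join(columns)]
    for reaction in model.reactions:
        row = [
            reaction.id,
            write_equation(reaction),
            reaction.gpr.to_string(),
            reaction.subsystem,
            _format_coefficient(reaction.lower_bound),
            _format_coefficient(reaction.upper_bound),
        ]
        row.extend(reaction.annotations.get(col, "") for col in extra_cols)
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def read_reaction_table(path: str, name: str | None = None) -> MetabolicModel:
    """Read a reaction table from a file path."""
    with open(path, "r", encoding="utf-8") as handle:
        text = handle.read()
    if name is None:
        name = str(path)
    return parse_reaction_table(text, name=name)
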