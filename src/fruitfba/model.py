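"""Core domain types for compartmented metabolic networks.

The network representation is deliberately small: metabolites carry a
compartment suffix (``_c`` cytosol, ``_m`` mitochondrion, ``_v`` vacuole),
reactions carry signed stoichiometry (negative = consumed), flux bounds in
mmol·gDW⁻¹·h⁻¹, and an optional boolean gene–protein–reaction (GPR) rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Set

__all__ = [
    "COMPARTMENTS",
    "GprRule",
    "Metabolite",
    "MetabolicModel",
    "ModelValidationError",
    "Reaction",
]

#: Recognised compartment suffixes and their names.
COMPARTMENTS = {"c": "cytosol", "m": "mitochondrion", "v": "vacuole"}

#: Comparison tolerance for stoichiometric coefficients.
COEFF_TOL = 1e-9


class ModelValidationError(ValueError):
    """Raised when a model, reaction or metabolite violates an invariant."""


def split_compartment(metabolite_id: str) -> tuple[str, str]:
    """Split ``"quinate_c"`` into ``("quinate", "c")``.

    The compartment is derived from the suffix and nowhere else; an id
    without a recognised suffix is an error.
    """
    if "_" in metabolite_id:
        base, _, suffix = metabolite_id.rpartition("_")
        if base and suffix in COMPARTMENTS:
            return base, suffix
    raise ModelValidationError(
        f"metabolite id {metabolite_id!r} lacks a compartment suffix "
        f"(expected one of {sorted('_' + s for s in COMPARTMENTS)})"
    )


@dataclass(frozen=True)
class Metabolite:
    """A compartment-specific metabolite, e.g. ``quinate_c``."""

    id: str

    def __post_init__(self) -> None:
        split_compartment(self.id)

    @property
    def base_name(self) -> str:
        return split_compartment(self.id)[0]

    @property
    def compartment(self) -> str:
        return split_compartment(self.id)[1]


class GprRule:
    """Boolean expression tree over gene identifiers.

    Nodes are either a leaf (gene id), an ``and`` node, or an ``or`` node.
    An empty rule (``GprRule.empty()``) means the reaction has no gene
    association. Trees serialize back to the conventional
    ``"gA and (gB or gC)"`` grammar, with ``and`` binding tighter than
    ``or``.
    """

    __slots__ = ("op", "gene", "children")

    def __init__(self, op: str, gene: Optional[str] = None,
                 children: Optional[List["GprRule"]] = None):
        if op not in ("leaf", "and", "or", "empty"):
            raise ValueError(f"unknown GPR node kind {op!r}")
        if op == "leaf" and not gene:
            raise ModelValidationError("GPR leaf requires a nonempty gene id")
        if op in ("and", "or") and not children:
            raise ModelValidationError(f"GPR {op} node requires children")
        self.op = op
        self.gene = gene
        self.children = children or []

    # -- constructors -------------------------------------------------
    @classmethod
    def empty(cls) -> "GprRule":
        return cls("empty")

    @classmethod
    def leaf(cls, gene: str) -> "GprRule":
        return cls("leaf", gene=gene)

    @classmethod
    def and_(cls, *children: "GprRule") -> "GprRule":
        return cls("and", children=list(children))

    @classmethod
    def or_(cls, *children: "GprRule") -> "GprRule":
        return cls("or", children=list(children))

    # -- queries ------------------------------------------------------
    @property
    def is_empty(self) -> bool:
        return self.op == "empty"

    def genes(self) -> Set[str]:
        """Set of gene ids appearing as leaves."""
        if self.op == "empty":
            return set()
        if self.op == "leaf":
            return {self.gene}  # type: ignore[arg-type]
        out: Set[str] = set()
        for child in self.children:
            out |= child.genes()
        return out

    def evaluate(self, active: Dict[str, bool]) -> bool:
        """Evaluate the rule under a truth assignment (missing genes False)."""
        if self.op == "empty":
            return True
        if self.op == "leaf":
            return bool(active.get(self.gene, False))
        values = (c.evaluate(active) for c in self.children)
        return all(values) if self.op == "and" else any(values)

    def to_string(self) -> str:
        """Serialize with minimal parentheses (``and`` over ``or``)."""
        if self.op == "empty":
            return ""
        if self.op == "leaf":
            return self.gene  # type: ignore[return-value]
        parts = []
        for child in self.children:
            text = child.to_string()
            if self.op == "and" and child.op == "or":
                text = f"({text})"
            parts.append(text)
        return f" {self.op} ".join(parts)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"GprRule({self.to_string()!r})" if not self.is_empty else "GprRule(empty)"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GprRule):
            return NotImplemented
        return (self.op, self.gene, self.children) == (other.op, other.gene, other.children)

    def __hash__(self) -> int:
        return hash((self.op, self.gene, tuple(self.children)))


@dataclass
class Reaction:
    """A flux-carrying reaction with signed stoichiometry and bounds."""

    id: str
    stoichiometry: Dict[str, float]
    reversible: bool = False
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: GprRule = field(default_factory=GprRule.empty)
    subsystem: str = ""
    annotations: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stoichiometry = {
            met: float(coef)
            for met, coef in self.stoichiometry.items()
            if abs(coef) > COEFF_TOL
        }
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r} has no nonzero coefficient")
        if self.lower_bound > self.upper_bound + COEFF_TOL:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if not self.reversible and self.lower_bound < -COEFF_TOL:
            raise ModelValidationError(
                f"irreversible reaction {self.id!r} has negative lower bound"
            )
        for met in self.stoichiometry:
            split_compartment(met)

    @property
    def is_exchange(self) -> bool:
        """True for boundary pseudo-reactions (all-substrate or all-product)."""
        signs = {coef > 0 for coef in self.stoichiometry.values()}
        return len(signs) == 1

    @property
    def is_pool(self) -> bool:
        """True for reserve-mobilization pool reactions (``POOL_`` prefix)."""
        return self.id.startswith("POOL_")

    @property
    def reactants(self) -> Dict[str, float]:
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    @property
    def products(self) -> Dict[str, float]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry),
                       annotations=dict(self.annotations))


@dataclass
class MetabolicModel:
    """A validated reaction network.

    Invariants (enforced by :meth:`validate`, called on construction):
    metabolite and reaction ids are unique; every metabolite referenced by
    a reaction is present; the gene set equals the union of GPR leaves.
    """

    name: str
    reactions: List[Reaction] = field(default_factory=list)
    metabolites: List[Metabolite] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.metabolites and self.reactions:
            self.metabolites = [
                Metabolite(met_id)
                for met_id in sorted({m for r in self.reactions for m in r.stoichiometry})
            ]
        self.validate()

    # -- lookups ------------------------------------------------------
    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites]

    @property
    def genes(self) -> Set[str]:
        out: Set[str] = set()
        for reaction in self.reactions:
            out |= reaction.gpr.genes()
        return out

    def get_reaction(self, reaction_id: str) -> Reaction:
        for reaction in self.reactions:
            if reaction.id == reaction_id:
                return reaction
        raise KeyError(f"no reaction {reaction_id!r} in model {self.name!r}")

    def has_reaction(self, reaction_id: str) -> bool:
        return any(r.id == reaction_id for r in self.reactions)

    def has_metabolite(self, metabolite_id: str) -> bool:
        return any(m.id == metabolite_id for m in self.metabolites)

    # -- editing (copy-on-write style helpers) ------------------------
    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            name=self.name,
            reactions=[r.copy() for r in self.reactions],
            metabolites=list(self.metabolites),
        )

    def add_reaction(self, reaction: Reaction) -> None:
        if self.has_reaction(reaction.id):
            raise ModelValidationError(f"duplicate reaction id {reaction.id!r}")
        known = set(self.metabolite_ids)
        for met in reaction.stoichiometry:
            if met not in known:
                self.metabolites.append(Metabolite(met))
                known.add(met)
        self.reactions.append(reaction)

    def remove_reaction(self, reaction_id: str) -> "MetabolicModel":
        """Return a copy of the model without the named reaction."""
        self.get_reaction(reaction_id)
        return MetabolicModel(
            name=self.name,
            reactions=[r.copy() for r in self.reactions if r.id != reaction_id],
        )

    def validate(self) -> None:
        seen_r: Set[str] = set()
        for reaction in self.reactions:
            if reaction.id in seen_r:
                raise ModelValidationError(f"duplicate reaction id {reaction.id!r}")
            seen_r.add(reaction.id)
        seen_m: Set[str] = set()
        for metabolite in self.metabolites:
            if metabolite.id in seen_m:
                raise ModelValidationError(f"duplicate metabolite id {metabolite.id!r}")
            seen_m.add(metabolite.id)
        for reaction in self.reactions:
            missing = set(reaction.stoichiometry) - seen_m
            if missing:
                raise ModelValidationError(
                    f"reaction {reaction.id!r} references unknown metabolites "
                    f"{sorted(missing)}"
                )

    def subsystems(self) -> Set[str]:
        return {r.subsystem for r in self.reactions if r.subsystem}

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return (f"MetabolicModel({self.name!r}: {len(self.reactions)} reactions, "
                f"{len(self.metabolites)} metabolites, {len(self.genes)} genes)")


def models_equal(a: MetabolicModel, b: MetabolicModel, tol: float = COEFF_TOL) -> bool:
    """Structural equality: same ids, stoichiometries, bounds and GPR semantics."""
    if sorted(a.reaction_ids) != sorted(b.reaction_ids):
        return False
    if sorted(a.metabolite_ids) != sorted(b.metabolite_ids):
        return False
    for ra in a.reactions:
        rb = b.get_reaction(ra.id)
        if ra.reversible != rb.reversible or ra.subsystem != rb.subsystem:
            return False
        if abs(ra.lower_bound - rb.lower_bound) > tol:
            return False
        if abs(ra.upper_bound - rb.upper_bound) > tol:
            return False
        mets = set(ra.stoichiometry) | set(rb.stoichiometry)
        for met in mets:
            if abs(ra.stoichiometry.get(met, 0.0) - rb.stoichiometry.get(met, 0.0)) > tol:
                return False
        if not gpr_equivalent(ra.gpr, rb.gpr):
            return False
    return True


def gpr_equivalent(a: GprRule, b: GprRule) -> bool:
    """Boolean equivalence by truth table (practical for rules with ≤ ~16 genes)."""
    genes = sorted(a.genes() | b.genes())
    if not genes:
        return a.is_empty == b.is_empty
    if len(genes) > 16:  # pragma: no cover - guard, rules this large never occur here
        raise ValueError("GPR too large for truth-table comparison")
    for mask in range(1 << len(genes)):
        assign = {g: bool(mask >> i & 1) for i, g in enumerate(genes)}
        if a.evaluate(assign) != b.evaluate(assign):
            return False
    return True
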