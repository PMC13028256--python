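"""Differential-expression contrasts → per-reaction penalty weights.

A contrast holds one log2 fold-change (and a significance flag) per gene
for one variety × postharvest transition (e.g. ``MG_E1vsE2``). Genes are
classified up / down / neutral by a symmetric log2FC threshold; classes
propagate to reactions through GPR rules (isoenzymes = OR, complexes =
AND), and a reaction's class maps to a soft penalty weight used by the
weighted minimum-flux problem. Down-regulated reactions are penalized
hardest, up-regulated ones least, with mixed evidence in between — the
weights bias but never forbid flux.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, Mapping, Optional, Tuple

import pandas as pd

from .model import GprRule, MetabolicModel, ModelValidationError

__all__ = [
    "DEFAULT_LFC_THRESHOLD",
    "DEFAULT_WEIGHT_SCHEME",
    "ExpressionContrast",
    "GeneClass",
    "ReactionClass",
    "ReactionWeightSet",
    "classify_genes",
    "classify_reaction",
    "classify_model_reactions",
    "weights_from_classes",
]

logger = logging.getLogger(__name__)

#: Conventional |log2FC| cutoff for calling a gene differentially expressed.
DEFAULT_LFC_THRESHOLD = 1.0

#: Default penalty scheme; only the ordering down > mixed > neutral > up is
#: fixed by the method — any scheme respecting it yields the same lever set.
DEFAULT_WEIGHT_SCHEME: Dict[str, float] = {
    "down": 2.0,
    "mixed": 1.5,
    "neutral": 1.0,
    "up": 0.5,
}


class GeneClass(str, Enum):
    UP = "up"
    DOWN = "down"
    NEUTRAL = "neutral"


class ReactionClass(str, Enum):
    UP = "up"
    DOWN = "down"
    NEUTRAL = "neutral"
    MIXED = "mixed"


#: Penalty rank used for AND/OR aggregation (higher = more penalized).
_PENALTY_RANK = {
    ReactionClass.DOWN: 3,
    ReactionClass.MIXED: 2,
    ReactionClass.NEUTRAL: 1,
    ReactionClass.UP: 0,
}


@dataclass
class ExpressionContrast:
    """Per-gene log2 fold-change and significance for one contrast."""

    contrast_id: str
    records: Dict[str, Tuple[float, bool]]

    def __post_init__(self) -> None:
        for gene, (lfc, _) in self.records.items():
            if not gene:
                raise ModelValidationError("empty gene id in expression contrast")
            if not pd.notna(lfc) or abs(lfc) == float("inf"):
                raise ModelValidationError(f"non-finite log2FC for gene {gene!r}")

    @classmethod
    def from_frame(cls, contrast_id: str, frame: pd.DataFrame) -> "ExpressionContrast":
        """Build from a DataFrame with columns gene_id, log2fc, significant."""
        records = {
            str(row.gene_id): (float(row.log2fc), bool(int(row.significant)))
            for row in frame.itertuples()
        }
        return cls(contrast_id=contrast_id, records=records)

    @classmethod
    def read_tsv(cls, path: str, contrast_id: Optional[str] = None) -> "ExpressionContrast":
        frame = pd.read_csv(path, sep="\t", comment="#")
        return cls.from_frame(contrast_id or str(path), frame)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"gene_id": g, "log2fc": lfc, "significant": int(sig)}
                for g, (lfc, sig) in self.records.items()
            ]
        )

    def write_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def classify_genes(
    contrast: ExpressionContrast,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    require_significance: bool = True,
) -> Dict[str, GeneClass]:
    """Call each gene up / down / neutral from its log2FC.

    A gene is up if log2FC ≥ threshold, down if ≤ −threshold (in either
    case only when flagged significant, if required), else neutral.
    """
    if lfc_threshold <= 0:
        raise ModelValidationError("log2FC threshold must be positive")
    classes: Dict[str, GeneClass] = {}
    for gene, (lfc, significant) in contrast.records.items():
        if require_significance and not significant:
            classes[gene] = GeneClass.NEUTRAL
        elif lfc >= lfc_threshold:
            classes[gene] = GeneClass.UP
        elif lfc <= -lfc_threshold:
            classes[gene] = GeneClass.DOWN
        else:
            classes[gene] = GeneClass.NEUTRAL
    return classes


def classify_reaction(
    gpr: GprRule, gene_classes: Mapping[str, GeneClass]
) -> ReactionClass:
    """Aggregate gene classes through a GPR rule.

    AND (enzyme complex): the most-penalized child dominates — a complex
    is only as available as its scarcest subunit. OR (isoenzymes): the
    least-penalized child wins, except that strictly conflicting children
    (some up, some down) give ``mixed``. Genes missing from the mapping
    and empty rules are neutral.
    """
    if gpr.is_empty:
        return ReactionClass.NEUTRAL
    if gpr.op == "leaf":
        gene_class = gene_classes.get(gpr.gene, GeneClass.NEUTRAL)
        return ReactionClass(gene_class.value)
    child_classes = [classify_reaction(child, gene_classes) for child in gpr.children]
    if gpr.op == "and":
        return max(child_classes, key=_PENALTY_RANK.__getitem__)
    # OR node
    has_up = any(c is ReactionClass.UP for c in child_classes)
    has_down = any(c is ReactionClass.DOWN for c in child_classes)
    if has_up and has_down:
        return ReactionClass.MIXED
    return min(child_classes, key=_PENALTY_RANK.__getitem__)


def classify_model_reactions(
    model: MetabolicModel,
    gene_classes: Mapping[str, GeneClass],
    warn_missing: bool = True,
) -> Dict[str, ReactionClass]:
    """Classify every reaction in a model; GPR-less reactions are neutral."""
    missing = model.genes - set(gene_classes)
    if missing and warn_missing:
        logger.warning(
            "%d model gene(s) absent from the contrast, treated as neutral: %s",
            len(missing), ", ".join(sorted(missing)[:5]) + ("…" if len(missing) > 5 else ""),
        )
    return {r.id: classify_reaction(r.gpr, gene_classes) for r in model.reactions}


@dataclass
class ReactionWeightSet:
    """Per-reaction (class, weight) pairs plus the generating scheme."""

    weights: Dict[str, Tuple[ReactionClass, float]]
    scheme: Dict[str, float]

    def weight(self, reaction_id: str) -> float:
        return self.weights[reaction_id][1]

    def reaction_class(self, reaction_id: str) -> ReactionClass:
        return self.weights[reaction_id][0]


def validate_scheme(scheme: Mapping[str, float]) -> None:
    """Check positivity and the ordering down > mixed > neutral > up."""
    for cls in ("down", "mixed", "neutral", "up"):
        if cls not in scheme:
            raise ModelValidationError(f"weight scheme lacks class {cls!r}")
        if scheme[cls] <= 0:
            raise ModelValidationError(f"weight for class {cls!r} must be positive")
    if not scheme["down"] > scheme["neutral"] > scheme["up"]:
        raise ModelValidationError(
            "weight scheme must satisfy weight(down) > weight(neutral) > weight(up)"
        )
    if not scheme["down"] > scheme["mixed"] > scheme["neutral"]:
        raise ModelValidationError(
            "weight(mixed) must lie strictly between weight(neutral) and weight(down)"
        )


def weights_from_classes(
    model: MetabolicModel,
    reaction_classes: Mapping[str, ReactionClass],
    scheme: Optional[Mapping[str, float]] = None,
) -> ReactionWeightSet:
    """Assign every model reaction its (class, weight); unclassified → neutral."""
    scheme = dict(scheme or DEFAULT_WEIGHT_SCHEME)
    validate_scheme(scheme)
    weights: Dict[str, Tuple[ReactionClass, float]] = {}
    for reaction in model.reactions:
        cls = reaction_classes.get(reaction.id, ReactionClass.NEUTRAL)
        weights[reaction.id] = (cls, scheme[cls.value])
    return ReactionWeightSet(weights=weights, scheme=scheme)
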