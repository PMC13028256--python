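"""Transcriptome-penalized flux minimization and regulatory-lever detection.

With the ripening-quality sink (RQS) fixed at a unit flux, the weighted
minimum-flux problem

    minimize  Σ_i w_i |v_i|   subject to   S·v = 0,  bounds,  v_RQS = target

is the parsimonious-FBA objective with per-reaction transcript penalties
(|v_i| linearized through auxiliary variables). A *regulatory lever* is a
reaction whose genes are transcriptionally down-regulated in a contrast
yet which must carry flux in every steady state that sustains the RQS:
physiological demand overrides the transcriptional trend. Requiredness is
established by flux-variability LPs, never by inspecting one optimum, so
the lever set is immune to alternate optima and to the choice of
(admissible) weight scheme.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .expression import (
    DEFAULT_LFC_THRESHOLD,
    ExpressionContrast,
    ReactionClass,
    ReactionWeightSet,
    classify_genes,
    classify_model_reactions,
    weights_from_classes,
)
from .fba import (
    FLUX_SNAP_TOL,
    RQS_ID,
    FluxSolution,
    RipeningConfig,
    add_rqs_objective,
    apply_ripening_constraints,
    build_stoich_matrix,
    min_required_flux,
    solve_fba,
)
from .model import MetabolicModel, ModelValidationError

__all__ = [
    "AnalysisConfig",
    "LeverRecord",
    "LeverReport",
    "detect_levers",
    "min_weighted_flux",
    "normalize_solution",
    "run_contrast_analysis",
]

#: Post-snap activity threshold separating numerical noise from real flux.
DEFAULT_EPS = 1e-6


def min_weighted_flux(
    model: MetabolicModel,
    weights: ReactionWeightSet | Mapping[str, float],
    rqs_target: float,
) -> FluxSolution:
    """Solve the transcript-penalized minimum-total-flux LP at fixed RQS.

    ``minimize Σ w_i·(v_i⁺ + v_i⁻)`` with ``v = v⁺ − v⁻`` is implemented
    with auxiliary magnitude variables ``t_i ≥ |v_i|``; with all-positive
    weights both formulations have the same optima.
    """
    if rqs_target <= 0:
        raise ModelValidationError("rqs_target must be positive")
    matrix = build_stoich_matrix(model)
    if RQS_ID not in matrix.reaction_index:
        raise ModelValidationError(f"model has no {RQS_ID} reaction")
    n = len(matrix.reaction_ids)
    weight_of = weights.weight if isinstance(weights, ReactionWeightSet) else (
        lambda rid: weights[rid]  # type: ignore[index]
    )
    w = np.array([weight_of(rid) for rid in matrix.reaction_ids])
    if np.any(w <= 0):
        raise ModelValidationError("all penalty weights must be positive")

    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    j_rqs = matrix.reaction_index[RQS_ID]
    lb[j_rqs] = ub[j_rqs] = rqs_target

    # Variables: [v (n), t (n)]; minimize w·t, S v = 0, ±v − t ≤ 0.
    c = np.concatenate([np.zeros(n), w])
    A_eq = np.hstack([matrix.S, np.zeros_like(matrix.S)])
    eye = np.eye(n)
    A_ub = np.vstack([
        np.hstack([eye, -eye]),
        np.hstack([-eye, -eye]),
    ])
    b_ub = np.zeros(2 * n)
    t_upper = np.maximum(np.abs(lb), np.abs(ub))
    bounds = np.vstack([
        np.column_stack([lb, ub]),
        np.column_stack([np.zeros(n), t_upper]),
    ])
    result = linprog(
        c,
        A_eq=A_eq,
        b_eq=np.zeros(A_eq.shape[0]),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=bounds,
        method="highs",
        options={"presolve": True},
    )
    if result.status != 0:
        status = {2: "infeasible", 3: "unbounded"}.get(result.status, "infeasible")
        return FluxSolution(fluxes={}, objective_value=float("nan"), status=status)
    v = np.asarray(result.x[:n])
    v[np.abs(v) < FLUX_SNAP_TOL] = 0.0
    return FluxSolution(
        fluxes=dict(zip(matrix.reaction_ids, v.tolist())),
        objective_value=float(result.fun),
        status="optimal",
    )


def normalize_solution(solution: FluxSolution, rqs_flux: float) -> Dict[str, float]:
    """Flux magnitudes per unit RQS flux; the RQS itself maps to 1."""
    if rqs_flux <= 0:
        raise ModelValidationError("rqs_flux must be positive")
    if not solution.optimal:
        raise ModelValidationError("cannot normalize a non-optimal solution")
    return {rid: abs(v) / rqs_flux for rid, v in solution.fluxes.items()}


@dataclass(frozen=True)
class LeverRecord:
    """One required-but-transcriptionally-down reaction in one contrast."""

    reaction_id: str
    contrast_id: str
    normalized_magnitude: float
    direction: str  # "forward" | "reverse" | "irreversible"
    reaction_class: ReactionClass = ReactionClass.DOWN
    required: bool = True

    def __post_init__(self) -> None:
        if self.normalized_magnitude <= 0:
            raise ModelValidationError("lever magnitude must be positive")
        if self.reaction_class is not ReactionClass.DOWN or not self.required:
            raise ModelValidationError("a lever must be a required, down-classified reaction")


def _direction(reaction_reversible: bool, flux: float) -> str:
    if not reaction_reversible:
        return "irreversible"
    return "forward" if flux >= 0 else "reverse"


def detect_levers(
    model: MetabolicModel,
    weights: ReactionWeightSet,
    reaction_classes: Mapping[str, ReactionClass],
    rqs_target: float = 1.0,
    eps: float = DEFAULT_EPS,
    contrast_id: str = "",
    solution: Optional[FluxSolution] = None,
) -> List[LeverRecord]:
    """Reactions that are down-classified yet structurally required.

    A reaction is a lever iff its class is ``down`` and its minimum
    attainable |flux| under ``v_RQS ≥ rqs_target`` exceeds ``eps``.
    Direction and magnitude are read from the weighted minimum-flux
    solution (the requiredness itself is weight-independent).
    """
    if eps <= 0:
        raise ModelValidationError("eps must be positive")
    if solution is None:
        solution = min_weighted_flux(model, weights, rqs_target)
    if not solution.optimal:
        raise ModelValidationError(f"weighted min-flux solve was {solution.status}")
    levers: List[LeverRecord] = []
    for reaction in model.reactions:
        if reaction_classes.get(reaction.id, ReactionClass.NEUTRAL) is not ReactionClass.DOWN:
            continue
        magnitude = min_required_flux(model, reaction.id, rqs_target)
        if magnitude <= eps:
            continue
        flux = solution.fluxes[reaction.id]
        levers.append(
            LeverRecord(
                reaction_id=reaction.id,
                contrast_id=contrast_id,
                normalized_magnitude=abs(flux) / rqs_target,
                direction=_direction(reaction.reversible, flux),
            )
        )
    return levers


@dataclass(frozen=True)
class AnalysisConfig:
    """End-to-end pipeline settings (constraints + classification + weights)."""

    ripening: RipeningConfig = field(default_factory=RipeningConfig)
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD
    require_significance: bool = True
    weight_scheme: Optional[Mapping[str, float]] = None
    rqs_target: float = 1.0
    eps: float = DEFAULT_EPS


@dataclass
class LeverReport:
    """Per-contrast lever lists plus solver metadata."""

    levers_by_contrast: Dict[str, List[LeverRecord]]
    metadata: Dict[str, object]

    @property
    def lever_union(self) -> set[str]:
        return {
            record.reaction_id
            for records in self.levers_by_contrast.values()
            for record in records
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "reaction_id": record.reaction_id,
                "contrast": record.contrast_id,
                "class": record.reaction_class.value,
                "required": record.required,
                "normalized_magnitude": record.normalized_magnitude,
                "direction": record.direction,
            }
            for records in self.levers_by_contrast.values()
            for record in records
        ]
        return pd.DataFrame(
            rows,
            columns=["reaction_id", "contrast", "class", "required",
                     "normalized_magnitude", "direction"],
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "metadata": self.metadata,
                "levers": {
                    contrast: [
                        {
                            "reaction_id": r.reaction_id,
                            "normalized_magnitude": r.normalized_magnitude,
                            "direction": r.direction,
                        }
                        for r in records
                    ]
                    for contrast, records in self.levers_by_contrast.items()
                },
            },
            indent=2,
        )

    def merge(self, other: "LeverReport") -> "LeverReport":
        merged = dict(self.levers_by_contrast)
        merged.update(other.levers_by_contrast)
        return LeverReport(levers_by_contrast=merged, metadata=self.metadata)


def run_contrast_analysis(
    model: MetabolicModel,
    contrast: ExpressionContrast,
    config: Optional[AnalysisConfig] = None,
) -> LeverReport:
    """Full pipeline for one contrast: classify → weight → solve → levers.

    The model may be raw (RQS/constraints are added here) or already
    prepared. The RQS maximum is computed first as a feasibility gate;
    an rqs_target above it is reported as infeasible.
    """
    config = config or AnalysisConfig()
    prepared = model if model.has_reaction(RQS_ID) else add_rqs_objective(model)
    prepared = apply_ripening_constraints(prepared, config.ripening)

    gate = solve_fba(prepared, RQS_ID, direction="max")
    if not gate.optimal or gate.objective_value < config.rqs_target - FLUX_SNAP_TOL:
        raise ModelValidationError(
            f"RQS target {config.rqs_target} is not sustainable "
            f"(FBA optimum: {gate.objective_value!r}, status {gate.status})"
        )

    gene_classes = classify_genes(
        contrast, config.lfc_threshold, config.require_significance
    )
    reaction_classes = classify_model_reactions(prepared, gene_classes)
    weights = weights_from_classes(prepared, reaction_classes, config.weight_scheme)
    solution = min_weighted_flux(prepared, weights, config.rqs_target)
    levers = detect_levers(
        prepared,
        weights,
        reaction_classes,
        rqs_target=config.rqs_target,
        eps=config.eps,
        contrast_id=contrast.contrast_id,
        solution=solution,
    )
    metadata = {
        "model": model.name,
        "rqs_target": config.rqs_target,
        "rqs_fba_maximum": gate.objective_value,
        "lfc_threshold": config.lfc_threshold,
        "require_significance": config.require_significance,
        "weight_scheme": dict(weights.scheme),
        "eps": config.eps,
        "ngam_lower_bound": config.ripening.ngam_lower_bound,
        "pool_upper_bound": config.ripening.pool_upper_bound,
        "blocked_pools": sorted(config.ripening.blocked_pools),
    }
    return LeverReport(
        levers_by_contrast={contrast.contrast_id: levers}, metadata=metadata
    )
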