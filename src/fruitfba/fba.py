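"""Stoichiometric matrix construction, ripening constraints and FBA.

Flux balance analysis here is the standard steady-state linear program

    optimize  c·v   subject to   S·v = 0,   lb ≤ v ≤ ub,

solved with scipy's HiGHS backend. The ripening scenario replaces a growth
objective with (i) a strictly positive non-growth-associated maintenance
(NGAM) ATP demand and (ii) a ripening-quality sink (RQS) pseudo-reaction
consuming chlorogenate, cyanidin, ethylene and galacturonate; stored
reserves enter through pool-mobilization reactions capped at a common
upper bound, with citrate and chlorogenate mobilization blocked so the
network cannot bypass de-novo synthesis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel, ModelValidationError, Reaction

__all__ = [
    "FluxSolution",
    "RipeningConfig",
    "RQS_ID",
    "RQS_METABOLITES",
    "StoichMatrix",
    "add_rqs_objective",
    "apply_ripening_constraints",
    "build_stoich_matrix",
    "min_required_flux",
    "flux_range",
    "solve_fba",
]

#: Reported fluxes below this magnitude are snapped to zero.
FLUX_SNAP_TOL = 1e-6

#: Identifier of the ripening-quality sink pseudo-reaction.
RQS_ID = "RQS"

#: The four ripening-trait metabolites the RQS consumes, one unit each.
RQS_METABOLITES = ("chlorogenate_c", "cyanidin_c", "ethylene_c", "galacturonate_c")


@dataclass
class StoichMatrix:
    """Dense metabolite × reaction stoichiometric matrix with index maps."""

    S: np.ndarray
    metabolite_ids: List[str]
    reaction_ids: List[str]

    @property
    def metabolite_index(self) -> Dict[str, int]:
        return {m: i for i, m in enumerate(self.metabolite_ids)}

    @property
    def reaction_index(self) -> Dict[str, int]:
        return {r: j for j, r in enumerate(self.reaction_ids)}


def build_stoich_matrix(model: MetabolicModel) -> StoichMatrix:
    """One row per metabolite, one column per reaction; zeros elsewhere."""
    met_ids = model.metabolite_ids
    rxn_ids = model.reaction_ids
    met_index = {m: i for i, m in enumerate(met_ids)}
    S = np.zeros((len(met_ids), len(rxn_ids)))
    for j, reaction in enumerate(model.reactions):
        for met, coef in reaction.stoichiometry.items():
            S[met_index[met], j] = coef
    return StoichMatrix(S=S, metabolite_ids=met_ids, reaction_ids=rxn_ids)


@dataclass(frozen=True)
class RipeningConfig:
    """Constraint set for the maintenance-only ripening regime.

    ``ngam_lower_bound`` is the maintenance ATP demand floor in
    mmol·gDW⁻¹·h⁻¹ (must be strictly positive); ``pool_upper_bound`` caps
    every reserve-mobilization pool reaction; ``blocked_pools`` are pools
    fixed to zero flux (citrate and chlorogenate by default, so neither
    the TCA cycle nor the RQS can be fed from reserves directly).
    """

    ngam_reaction_id: str = "NGAM_c"
    ngam_lower_bound: float = 1.0
    pool_upper_bound: float = 10.0
    blocked_pools: FrozenSet[str] = frozenset({"POOL_CITRATE", "POOL_CHLOROGENATE"})

    def __post_init__(self) -> None:
        if self.ngam_lower_bound <= 0:
            raise ModelValidationError("NGAM lower bound must be strictly positive")
        if self.pool_upper_bound < 0:
            raise ModelValidationError("pool upper bound must be non-negative")
        object.__setattr__(self, "blocked_pools", frozenset(self.blocked_pools))

    # -- JSON round trip ----------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "ngam_reaction_id": self.ngam_reaction_id,
                "ngam_lower_bound": self.ngam_lower_bound,
                "pool_upper_bound": self.pool_upper_bound,
                "blocked_pools": sorted(self.blocked_pools),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "RipeningConfig":
        data = json.loads(text)
        return cls(
            ngam_reaction_id=data.get("ngam_reaction_id", "NGAM_c"),
            ngam_lower_bound=data.get("ngam_lower_bound", 1.0),
            pool_upper_bound=data.get("pool_upper_bound", 10.0),
            blocked_pools=frozenset(data.get("blocked_pools",
                                             ["POOL_CITRATE", "POOL_CHLOROGENATE"])),
        )


@dataclass
class FluxSolution:
    """An optimal (or failed) steady-state flux distribution."""

    fluxes: Dict[str, float]
    objective_value: float
    status: str  # "optimal" | "infeasible" | "unbounded"

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]


def add_rqs_objective(model: MetabolicModel) -> MetabolicModel:
    """Append the ripening-quality sink pseudo-reaction.

    RQS consumes one unit each of chlorogenate_c, cyanidin_c, ethylene_c
    and galacturonate_c and produces nothing, so maximizing it enforces
    simultaneous output of all four ripening traits.
    """
    if model.has_reaction(RQS_ID):
        raise ModelValidationError(f"model {model.name!r} already has an {RQS_ID} reaction")
    missing = [m for m in RQS_METABOLITES if not model.has_metabolite(m)]
    if missing:
        raise ModelValidationError(
            f"cannot add {RQS_ID}: model lacks metabolite(s) {', '.join(missing)}"
        )
    out = model.copy()
    out.add_reaction(
        Reaction(
            id=RQS_ID,
            stoichiometry={m: -1.0 for m in RQS_METABOLITES},
            reversible=False,
            lower_bound=0.0,
            upper_bound=1000.0,
            subsystem="Ripening quality objective",
        )
    )
    return out


def apply_ripening_constraints(
    model: MetabolicModel, config: Optional[RipeningConfig] = None
) -> MetabolicModel:
    """Impose NGAM floor, pool caps, and blocked mobilizations on a copy."""
    if config is None:
        config = RipeningConfig()
    out = model.copy()
    ngam = out.get_reaction(config.ngam_reaction_id)  # KeyError if unknown
    ngam.lower_bound = config.ngam_lower_bound
    if ngam.upper_bound < ngam.lower_bound:
        ngam.upper_bound = ngam.lower_bound
    for pool_id in config.blocked_pools:
        out.get_reaction(pool_id)
    for reaction in out.reactions:
        if reaction.is_pool:
            reaction.upper_bound = config.pool_upper_bound
    for pool_id in config.blocked_pools:
        blocked = out.get_reaction(pool_id)
        blocked.lower_bound = 0.0
        blocked.upper_bound = 0.0
    return out


# ---------------------------------------------------------------------------
# LP plumbing
# ---------------------------------------------------------------------------

_STATUS_MAP = {0: "optimal", 2: "infeasible", 3: "unbounded"}

_LINPROG_OPTIONS = {"presolve": True}


def _bounds_arrays(model: MetabolicModel) -> tuple[np.ndarray, np.ndarray]:
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    return lb, ub


def _snap(values: np.ndarray) -> np.ndarray:
    out = values.copy()
    out[np.abs(out) < FLUX_SNAP_TOL] = 0.0
    return out


def _solve_lp(
    model: MetabolicModel,
    objective: np.ndarray,
    fixed: Optional[Dict[str, tuple[float, float]]] = None,
) -> tuple[str, Optional[np.ndarray], float]:
    """Minimize ``objective·v`` subject to S·v = 0 and (possibly overridden) bounds."""
    matrix = build_stoich_matrix(model)
    lb, ub = _bounds_arrays(model)
    if fixed:
        index = matrix.reaction_index
        for rxn_id, (lo, hi) in fixed.items():
            j = index[rxn_id]
            lb[j], ub[j] = max(lb[j], lo), min(ub[j], hi)
    result = linprog(
        objective,
        A_eq=matrix.S,
        b_eq=np.zeros(matrix.S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options=_LINPROG_OPTIONS,
    )
    status = _STATUS_MAP.get(result.status, "infeasible")
    if status != "optimal":
        return status, None, float("nan")
    return status, np.asarray(result.x), float(result.fun)


def solve_fba(
    model: MetabolicModel,
    objective_id: str,
    direction: str = "max",
    extra_bounds: Optional[Dict[str, tuple[float, float]]] = None,
) -> FluxSolution:
    """Optimize flux through one reaction at steady state.

    Infeasible or unbounded problems are reported through ``status``,
    never by a silent zero.
    """
    if direction not in ("max", "min"):
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")
    matrix = build_stoich_matrix(model)
    try:
        j = matrix.reaction_index[objective_id]
    except KeyError:
        raise KeyError(f"objective reaction {objective_id!r} not in model") from None
    c = np.zeros(len(matrix.reaction_ids))
    c[j] = -1.0 if direction == "max" else 1.0
    status, x, fun = _solve_lp(model, c, fixed=extra_bounds)
    if status != "optimal":
        return FluxSolution(fluxes={}, objective_value=float("nan"), status=status)
    x = _snap(x)
    objective_value = x[j]
    return FluxSolution(
        fluxes=dict(zip(matrix.reaction_ids, x.tolist())),
        objective_value=float(objective_value),
        status="optimal",
    )


def flux_range(
    model: MetabolicModel,
    reaction_id: str,
    fixed: Optional[Dict[str, tuple[float, float]]] = None,
) -> tuple[float, float]:
    """Minimum and maximum attainable flux through one reaction (two LPs)."""
    matrix = build_stoich_matrix(model)
    j = matrix.reaction_index[reaction_id]
    c = np.zeros(len(matrix.reaction_ids))
    c[j] = 1.0
    status_min, x_min, _ = _solve_lp(model, c, fixed=fixed)
    status_max, x_max, _ = _solve_lp(model, -c, fixed=fixed)
    if status_min != "optimal" or status_max != "optimal":
        raise ModelValidationError(
            f"flux range for {reaction_id!r} is {status_min}/{status_max}"
        )
    return float(x_min[j]), float(x_max[j])


def min_required_flux(model: MetabolicModel, reaction_id: str, rqs_floor: float) -> float:
    """Smallest attainable |flux| through a reaction while sustaining the RQS.

    Solved as a flux-variability pair of LPs under ``v_RQS ≥ rqs_floor``:
    if even the widest flux range excludes zero, the reaction is
    structurally required and the returned magnitude is the distance of
    the range from zero; otherwise 0.
    """
    if not model.has_reaction(RQS_ID):
        raise ModelValidationError(f"model has no {RQS_ID} reaction")
    lo, hi = flux_range(model, reaction_id, fixed={RQS_ID: (rqs_floor, np.inf)})
    magnitude = max(0.0, lo, -hi)
    return 0.0 if magnitude < FLUX_SNAP_TOL else magnitude


def steady_state_residual(model: MetabolicModel, solution: FluxSolution) -> float:
    """max |S·v| for a solution, in the model's reaction order."""
    matrix = build_stoich_matrix(model)
    v = np.array([solution.fluxes.get(r, 0.0) for r in matrix.reaction_ids])
    return float(np.max(np.abs(matrix.S @ v))) if len(v) else 0.0
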