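"""Flux balance analysis as a linear program.

Maximize the biomass objective v_bio subject to steady state S v = 0 and
flux bounds l <= v <= u, solved with the HiGHS backend of
``scipy.optimize.linprog``.  Only the objective value is contractually
deterministic; the flux vector may be any optimum of the (generally
degenerate) LP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel, knockout, set_medium, stoichiometric_matrix

__all__ = ["FbaConfig", "FluxSolution", "SolverError", "CompiledProblem",
           "maximize_growth", "growth_on"]

logger = logging.getLogger(__name__)


class SolverError(RuntimeError):
    """The LP solver failed numerically (never silently mapped to zero)."""


@dataclass(frozen=True)
class FbaConfig:
    """Numerical knobs for the LP solve.

    ``feasibility_tolerance`` is handed to HiGHS; ``zero_threshold`` is the
    flux magnitude below which a flux is reported as zero in flux tables.
    Growth-threshold comparisons in the screening layer always use the raw
    objective value, not ``zero_threshold``.
    """

    feasibility_tolerance: float = 1e-9
    zero_threshold: float = 1e-6

    def __post_init__(self) -> None:
        if self.feasibility_tolerance <= 0 or self.zero_threshold <= 0:
            raise ValueError("FbaConfig tolerances must be positive")


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    growth_rate: float
    fluxes: Dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


class CompiledProblem:
    """A model frozen into LP arrays for repeated solves under bound edits.

    Used heavily by the knockout screen: the stoichiometric matrix is
    assembled once, and each knockout only zeroes entries of the bound
    vectors.
    """

    def __init__(self, model: MetabolicModel, config: Optional[FbaConfig] = None):
        self.config = config or FbaConfig()
        self.reaction_ids = list(model.reaction_ids)
        self.index = {rid: j for j, rid in enumerate(self.reaction_ids)}
        self.S = stoichiometric_matrix(model).to_numpy()
        self.lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
        self.ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
        self.c = np.zeros(len(self.reaction_ids))
        self.c[self.index[model.objective_reaction_id]] = 1.0

    def solve(self, zero_flux: Iterable[int] = ()) -> FluxSolution:
        lb, ub = self.lb, self.ub
        zero = list(zero_flux)
        if zero:
            lb = lb.copy()
            ub = ub.copy()
            lb[zero] = 0.0
            ub[zero] = 0.0
        res = linprog(
            -self.c,
            A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            bounds=np.column_stack([lb, ub]),
            method="highs",
            options={
                "primal_feasibility_tolerance": self.config.feasibility_tolerance,
                "dual_feasibility_tolerance": self.config.feasibility_tolerance,
            },
        )
        if res.status == 0:
            fluxes = {
                rid: (0.0 if abs(v) < self.config.zero_threshold else float(v))
                for rid, v in zip(self.reaction_ids, res.x)
            }
            return FluxSolution("optimal", float(-res.fun) + 0.0, fluxes)
        if res.status == 2:
            return FluxSolution("infeasible", float("nan"))
        if res.status == 3:
            return FluxSolution("unbounded", float("inf"))
        raise SolverError(f"LP solver failed (status {res.status}): {res.message}")

    def growth(self, zero_flux: Iterable[int] = ()) -> float:
        """Objective value with infeasible mapped to 0 growth (warned)."""
        sol = self.solve(zero_flux)
        if sol.status == "infeasible":
            logger.warning("infeasible LP mapped to zero growth")
            return 0.0
        if sol.status == "unbounded":
            raise SolverError("LP is unbounded; check exchange bounds")
        return sol.growth_rate

    def indices(self, reaction_ids: Iterable[str]) -> Tuple[int, ...]:
        return tuple(self.index[r] for r in reaction_ids)


def maximize_growth(
    model: MetabolicModel, config: Optional[FbaConfig] = None
) -> FluxSolution:
    """Maximal biomass flux of the model as bounded, with full flux vector."""
    return CompiledProblem(model, config).solve()


def growth_on(
    model: MetabolicModel,
    carbon_sources: Iterable[str],
    uptake_rate: float = 7.0,
    gene_knockouts: Iterable[str] = (),
    reaction_knockouts: Iterable[str] = (),
    config: Optional[FbaConfig] = None,
) -> float:
    """Growth rate on a medium after knockouts; infeasible maps to 0.

    Convenience composition: ``maximize_growth(knockout(set_medium(...)))``
    returning only the objective value.
    """
    edited = knockout(
        set_medium(model, carbon_sources, uptake_rate),
        genes=gene_knockouts,
        reactions=reaction_knockouts,
    )
    problem = CompiledProblem(edited, config)
    return problem.growth()
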