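"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from meflux.fba import CompiledProblem
from meflux.model import MetabolicModel, Metabolite, Reaction, set_medium
from meflux.search import SearchConfig
from meflux.synthetic import build_core_model
from meflux.model import add_heterologous_reactions


@pytest.fixture(scope="session")
def core_model() -> MetabolicModel:
    return build_core_model()


@pytest.fixture(scope="session")
def augmented_model(core_model) -> MetabolicModel:
    return add_heterologous_reactions(core_model)


@pytest.fixture(scope="session")
def search_config() -> SearchConfig:
    return SearchConfig()


# ---------------------------------------------------------------------------
# oracle 1: brute-force vertex enumeration for tiny LPs
# ---------------------------------------------------------------------------

def vertex_enumeration_optimum(S: np.ndarray, lb, ub, c) -> float:
    """Maximize c.v over {S v = 0, lb <= v <= ub} by enumerating vertices.

    At a vertex of the polytope, n - rank(S) variables sit at a bound.  For
    toy networks (n <= 6) we enumerate every choice of fixed variables and
    bound sides, solve the remaining square system, and keep the best
    feasible point.  Completely independent of the linprog-based solver.
    """
    S = np.asarray(S, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    c = np.asarray(c, dtype=float)
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S) if S.size else 0
    n_fixed = n - rank
    best = None
    for fixed in itertools.combinations(range(n), n_fixed):
        free = [j for j in range(n) if j not in fixed]
        for sides in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            rhs = -S[:, list(fixed)] @ np.array(sides) if fixed else np.zeros(S.shape[0])
            A = S[:, free]
            sol, residual, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            v = np.empty(n)
            for j, s in zip(fixed, sides):
                v[j] = s
            v[free] = sol
            if np.max(np.abs(S @ v)) > 1e-8:
                continue
            if np.any(v < lb - 1e-9) or np.any(v > ub + 1e-9):
                continue
            val = float(c @ v)
            if best is None or val > best:
                best = val
    return best


# ---------------------------------------------------------------------------
# oracle 2: exhaustive knockout-set enumeration (independent of beam search)
# ---------------------------------------------------------------------------

def enumerate_minimum_essential_sets(model, co_substrate, config, max_size=3):
    """All minimum-cardinality methanol-essential reaction sets, by brute force.

    Enumerates knockout subsets of internal reactions by increasing size and
    stops at the first size with solutions, re-deriving the classification
    from raw growth rates rather than going through the search module's
    classifier.
    """
    eps = config.growth_threshold
    rate = config.uptake_rate
    p_co = CompiledProblem(set_medium(model, {co_substrate}, rate))
    p_mix = CompiledProblem(
        set_medium(model, {co_substrate, config.methanol_exchange}, rate)
    )
    p_meoh = CompiledProblem(set_medium(model, {config.methanol_exchange}, rate))
    ids = sorted(r.id for r in model.internal_reactions())
    for size in range(1, max_size + 1):
        found = []
        for combo in itertools.combinations(ids, size):
            idx = p_co.indices(combo)
            if p_co.growth(idx) > eps:
                continue
            mu_mix = p_mix.growth(idx)
            if mu_mix <= eps:
                continue
            mu_meoh = p_meoh.growth(idx)
            if mu_meoh <= eps and config.require_methylotrophy:
                continue
            if mu_mix - mu_meoh > config.coupling_margin:
                found.append(frozenset(combo))
        if found:
            return size, sorted(found, key=sorted)
    return max_size, []


# ---------------------------------------------------------------------------
# tiny hand-built models
# ---------------------------------------------------------------------------

def toy_linear_chain(uptake_cap: float = 5.0) -> MetabolicModel:
    """EX_a (uptake <= cap) -> A -> biomass; optimum equals the cap."""
    mets = [Metabolite("a", n_carbon=1)]
    rxns = [
        Reaction("EX_a", {"a": -1.0}, -uptake_cap, 1000.0, is_exchange=True),
        Reaction("CONV", {"a": -1.0}, 0.0, 1000.0, name="a -> biomass drain"),
    ]
    return MetabolicModel(mets, rxns, objective_reaction_id="CONV", id="toy_chain")


def two_reaction_chain() -> MetabolicModel:
    """A -> B, B -> (exchange): the stoichiometric-matrix example."""
    mets = [Metabolite("A", n_carbon=1), Metabolite("B", n_carbon=1)]
    rxns = [
        Reaction("R1", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
        Reaction("EX_B", {"B": -1.0}, 0.0, 1000.0, is_exchange=True),
    ]
    return MetabolicModel(mets, rxns, objective_reaction_id="EX_B", id="toy2")
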