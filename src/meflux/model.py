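"""Stoichiometric metabolic models: containers, validation, and edits.

A :class:`MetabolicModel` is a list of metabolites and reactions plus a
biomass objective.  Reactions carry flux bounds (mmol gCDW^-1 h^-1) and a
gene-protein-reaction (GPR) rule; exchange reactions move a single
metabolite across the system boundary with the usual sign convention
(negative flux = uptake).  The editing operations -- gene/reaction
knockouts, medium composition, and addition of the heterologous methanol
assimilation reactions (Mdh/Hps/Phi) -- all return new models and leave
their input untouched.
"""

from __future__ import annotations

import ast
import copy
import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ModelValidationError",
    "Metabolite",
    "GeneRule",
    "Reaction",
    "MetabolicModel",
    "knockout",
    "set_medium",
    "add_heterologous_reactions",
    "stoichiometric_matrix",
    "carbon_balance",
    "minimal_gene_sets",
    "DEFAULT_BOUND",
]

#: Conventional "unbounded" flux magnitude.
DEFAULT_BOUND = 1000.0


class ModelValidationError(ValueError):
    """Raised when a model (or model file) violates a structural invariant."""


@dataclass(frozen=True)
class Metabolite:
    """A chemical species in one compartment.

    ``n_carbon`` counts skeleton carbon atoms and drives both the carbon
    balance audit and the medium logic (exchanges of carbon-free nutrients
    stay open for uptake).  Carrier moieties (CoA, NAD(P), adenosine) are
    conventionally assigned zero carbons.
    """

    id: str
    name: str = ""
    compartment: str = "c"
    n_carbon: int = 0

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("metabolite with empty id")
        if self.n_carbon < 0:
            raise ModelValidationError(f"metabolite {self.id!r}: n_carbon must be >= 0")


_ALLOWED_AST = (ast.Expression, ast.BoolOp, ast.And, ast.Or, ast.Name, ast.Load)


class GeneRule:
    """Boolean gene-protein-reaction rule, e.g. ``"rpiA or rpiB"``.

    ``and`` encodes complexes (all subunits required), ``or`` isozymes.
    The empty rule means spontaneous / not gene-associated and always
    evaluates active.
    """

    __slots__ = ("expression", "_tree")

    def __init__(self, expression: str = "") -> None:
        self.expression = expression.strip()
        if self.expression:
            try:
                tree = ast.parse(self.expression, mode="eval")
            except SyntaxError as exc:
                raise ModelValidationError(f"unparsable gene rule {expression!r}") from exc
            for node in ast.walk(tree):
                if not isinstance(node, _ALLOWED_AST):
                    raise ModelValidationError(
                        f"gene rule {expression!r}: only gene ids, 'and', 'or' and "
                        f"parentheses are allowed (found {type(node).__name__})"
                    )
            self._tree = tree.body
        else:
            self._tree = None

    @property
    def genes(self) -> FrozenSet[str]:
        if self._tree is None:
            return frozenset()
        return frozenset(
            node.id for node in ast.walk(self._tree) if isinstance(node, ast.Name)
        )

    def is_active(self, deleted_genes: Iterable[str] = ()) -> bool:
        """Evaluate the rule with the given genes absent; total and deterministic."""
        if self._tree is None:
            return True
        deleted = set(deleted_genes)

        def ev(node: ast.AST) -> bool:
            if isinstance(node, ast.Name):
                return node.id not in deleted
            if isinstance(node, ast.BoolOp):
                vals = (ev(v) for v in node.values)
                return all(vals) if isinstance(node.op, ast.And) else any(vals)
            raise AssertionError("unreachable: rule was validated at parse time")

        return ev(self._tree)

    def minimal_knockout_sets(self, max_genes: int = 12) -> List[FrozenSet[str]]:
        """All inclusion-minimal gene sets whose deletion inactivates the rule.

        Empty rules cannot be inactivated (returns ``[]``).  Enumeration is
        over subsets of the rule's own genes, which GPRs keep small.
        """
        genes = sorted(self.genes)
        if not genes or len(genes) > max_genes:
            return []
        found: List[FrozenSet[str]] = []
        for size in range(1, len(genes) + 1):
            for combo in itertools.combinations(genes, size):
                cand = frozenset(combo)
                if any(prev <= cand for prev in found):
                    continue
                if not self.is_active(cand):
                    found.append(cand)
        return found

    def __repr__(self) -> str:  # pragma: no cover
        return f"GeneRule({self.expression!r})"

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneRule) and self.expression == other.expression

    def __hash__(self) -> int:
        return hash(self.expression)


@dataclass
class Reaction:
    """A (pseudo-)reaction: stoichiometry, flux bounds and GPR rule.

    Exchange reactions touch exactly one metabolite; by convention their
    stoichiometric coefficient is -1 so that positive flux secretes and
    negative flux takes the species up.
    """

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gene_rule: GeneRule = field(default_factory=GeneRule)
    is_exchange: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("reaction with empty id")
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        if self.is_exchange and len(self.stoichiometry) != 1:
            raise ModelValidationError(
                f"exchange reaction {self.id!r} must touch exactly one metabolite"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


class MetabolicModel:
    """A validated stoichiometric model with a biomass objective."""

    def __init__(
        self,
        metabolites: Sequence[Metabolite],
        reactions: Sequence[Reaction],
        objective_reaction_id: str,
        genes: Optional[Iterable[str]] = None,
        id: str = "model",
    ) -> None:
        self.id = id
        self.metabolites: List[Metabolite] = list(metabolites)
        self.reactions: List[Reaction] = list(reactions)
        self.objective_reaction_id = objective_reaction_id
        rule_genes: Set[str] = set()
        for rxn in self.reactions:
            rule_genes |= rxn.gene_rule.genes
        self.genes: Set[str] = set(genes) if genes is not None else rule_genes
        self.validate()

    # -- lookups ---------------------------------------------------------
    @property
    def metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self._met_index[met_id]
        except KeyError:
            raise KeyError(f"unknown metabolite id {met_id!r}") from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self._rxn_index[rxn_id]
        except KeyError:
            raise KeyError(f"unknown reaction id {rxn_id!r}") from None

    def exchanges(self) -> List[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def internal_reactions(self) -> List[Reaction]:
        """Non-exchange, non-objective reactions (the knockout candidates)."""
        return [
            r
            for r in self.reactions
            if not r.is_exchange and r.id != self.objective_reaction_id
        ]

    def exchange_carbon(self, rxn_id: str) -> int:
        """Carbon count of the single species an exchange moves."""
        rxn = self.reaction(rxn_id)
        if not rxn.is_exchange:
            raise ValueError(f"reaction {rxn_id!r} is not an exchange")
        (met_id,) = rxn.stoichiometry
        return self.metabolite(met_id).n_carbon

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        dup = {m for m in met_ids if met_ids.count(m) > 1}
        if dup:
            raise ModelValidationError(f"duplicate metabolite ids: {sorted(dup)}")
        rxn_ids = [r.id for r in self.reactions]
        dup = {r for r in rxn_ids if rxn_ids.count(r) > 1}
        if dup:
            raise ModelValidationError(f"duplicate reaction ids: {sorted(dup)}")
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}
        dangling = sorted(
            {
                met_id
                for rxn in self.reactions
                for met_id in rxn.stoichiometry
                if met_id not in self._met_index
            }
        )
        if dangling:
            raise ModelValidationError(
                f"reactions reference unknown metabolite ids: {dangling}"
            )
        if self.objective_reaction_id not in self._rxn_index:
            raise ModelValidationError(
                f"objective reaction {self.objective_reaction_id!r} not in model"
            )
        loose = sorted(
            g for rxn in self.reactions for g in rxn.gene_rule.genes if g not in self.genes
        )
        if loose:
            raise ModelValidationError(f"gene rules use genes not in model.genes: {loose}")

    # -- copies ----------------------------------------------------------
    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=[copy.copy(r) for r in self.reactions],
            objective_reaction_id=self.objective_reaction_id,
            genes=set(self.genes),
            id=self.id,
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<MetabolicModel {self.id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions, {len(self.genes)} genes>"
        )


# ---------------------------------------------------------------------------
# editing operations (pure: input model is never modified)
# ---------------------------------------------------------------------------

def knockout(
    model: MetabolicModel,
    genes: Iterable[str] = (),
    reactions: Iterable[str] = (),
) -> MetabolicModel:
    """Return a copy with the given deletions applied.

    Reactions listed directly, plus every reaction whose GPR rule evaluates
    inactive once ``genes`` are absent, get both bounds set to zero.  All
    other bounds are untouched, which makes the operation idempotent and
    monotone in its arguments.
    """
    genes = set(genes)
    reactions = set(reactions)
    unknown_genes = sorted(genes - model.genes)
    if unknown_genes:
        raise KeyError(f"unknown gene ids: {unknown_genes}")
    unknown_rxns = sorted(r for r in reactions if r not in model._rxn_index)
    if unknown_rxns:
        raise KeyError(f"unknown reaction ids: {unknown_rxns}")
    out = model.copy()
    for rxn in out.reactions:
        if rxn.id in reactions or not rxn.gene_rule.is_active(genes):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return out


def deactivated_reactions(model: MetabolicModel, genes: Iterable[str]) -> FrozenSet[str]:
    """Reaction ids whose GPR evaluates inactive with ``genes`` deleted."""
    genes = set(genes)
    return frozenset(
        r.id for r in model.reactions if not r.gene_rule.is_active(genes)
    )


def set_medium(
    model: MetabolicModel,
    carbon_sources: Iterable[str],
    uptake_rate: float = 7.0,
) -> MetabolicModel:
    """Return a copy constrained to the given carbon sources.

    Each listed carbon exchange gets its uptake bound set to
    ``-uptake_rate`` (independently per source); every other carbon
    exchange is closed to uptake.  Exchanges of carbon-free nutrients (O2,
    NH4+, Pi, H2O, H+, ...) are left open for uptake, and secretion stays
    allowed for all exchanges.
    """
    sources = set(carbon_sources)
    for rxn_id in sources:
        rxn = model.reaction(rxn_id)
        if not rxn.is_exchange:
            raise ValueError(f"medium component {rxn_id!r} is not an exchange reaction")
    out = model.copy()
    for rxn in out.reactions:
        if not rxn.is_exchange:
            continue
        if rxn.id in sources:
            rxn.lower_bound = -abs(uptake_rate)
        elif out.exchange_carbon(rxn.id) > 0:
            rxn.lower_bound = 0.0
        else:
            rxn.lower_bound = -DEFAULT_BOUND
        rxn.upper_bound = max(rxn.upper_bound, 0.0)
    return out


#: Default ids of the species the heterologous reactions connect to.
HETEROLOGOUS_SPECIES = {
    "methanol": "meoh",
    "formaldehyde": "fald",
    "nad": "nad",
    "nadh": "nadh",
    "h": "h",
    "ru5p": "ru5p",
    "h6p": "h6p",
    "f6p": "f6p",
}

HETEROLOGOUS_REACTION_IDS = ("MDH", "HPS", "PHI")


def add_heterologous_reactions(
    model: MetabolicModel,
    species: Optional[Mapping[str, str]] = None,
) -> MetabolicModel:
    """Add the NAD-dependent Mdh, Hps and Phi reactions of the RuMP entry.

    MDH: methanol + NAD+ -> formaldehyde + NADH + H+
    HPS: formaldehyde + ribulose 5-phosphate -> hexulose 6-phosphate
    PHI: hexulose 6-phosphate -> fructose 6-phosphate

    The hexulose 6-phosphate species is created if absent.  All three
    reactions are carbon-balanced by construction; the original model is
    not modified.
    """
    ids = dict(HETEROLOGOUS_SPECIES)
    if species:
        ids.update(species)
    required = ["methanol", "formaldehyde", "nad", "nadh", "ru5p", "f6p"]
    missing = sorted(
        ids[key] for key in required if ids[key] not in {m.id for m in model.metabolites}
    )
    if missing:
        raise ModelValidationError(
            f"cannot add Mdh/Hps/Phi: model lacks required species {missing}"
        )
    collisions = sorted(set(HETEROLOGOUS_REACTION_IDS) & set(model.reaction_ids))
    if collisions:
        raise ModelValidationError(
            f"heterologous reaction ids already present: {collisions}"
        )
    out = model.copy()
    met_ids = {m.id for m in out.metabolites}
    if ids["h6p"] not in met_ids:
        out.metabolites.append(
            Metabolite(ids["h6p"], "D-arabino-3-hexulose 6-phosphate", "c", 6)
        )
    if ids["h"] not in met_ids:
        out.metabolites.append(Metabolite(ids["h"], "H+", "c", 0))
    mdh_stoich = {ids["methanol"]: -1.0, ids["nad"]: -1.0,
                  ids["formaldehyde"]: 1.0, ids["nadh"]: 1.0, ids["h"]: 1.0}
    new = [
        Reaction("MDH", mdh_stoich, 0.0, DEFAULT_BOUND,
                 GeneRule("mdh"), name="methanol dehydrogenase (NAD-dependent)"),
        Reaction("HPS", {ids["formaldehyde"]: -1.0, ids["ru5p"]: -1.0, ids["h6p"]: 1.0},
                 0.0, DEFAULT_BOUND, GeneRule("hps"),
                 name="3-hexulose-6-phosphate synthase"),
        Reaction("PHI", {ids["h6p"]: -1.0, ids["f6p"]: 1.0},
                 0.0, DEFAULT_BOUND, GeneRule("phi"),
                 name="6-phospho-3-hexuloisomerase"),
    ]
    out.reactions.extend(new)
    out.genes |= {"mdh", "hps", "phi"}
    out.validate()
    for rxn in new:
        imbalance = carbon_balance(out, rxn.id)
        if abs(imbalance) > 1e-9:
            raise AssertionError(f"{rxn.id} not carbon balanced: {imbalance}")
    return out


# ---------------------------------------------------------------------------
# matrix views and audits
# ---------------------------------------------------------------------------

def stoichiometric_matrix(model: MetabolicModel) -> pd.DataFrame:
    """Dense S matrix (metabolites x reactions) as a labelled DataFrame."""
    S = np.zeros((len(model.metabolites), len(model.reactions)))
    met_pos = {m.id: i for i, m in enumerate(model.metabolites)}
    for j, rxn in enumerate(model.reactions):
        for met_id, coeff in rxn.stoichiometry.items():
            S[met_pos[met_id], j] = coeff
    return pd.DataFrame(S, index=model.metabolite_ids, columns=model.reaction_ids)


def carbon_balance(model: MetabolicModel, rxn_id: str) -> float:
    """Net skeleton carbon produced by one unit of flux (0 = balanced)."""
    rxn = model.reaction(rxn_id)
    return math.fsum(
        coeff * model.metabolite(met_id).n_carbon
        for met_id, coeff in rxn.stoichiometry.items()
    )


# ---------------------------------------------------------------------------
# gene-level reporting of reaction knockouts
# ---------------------------------------------------------------------------

def minimal_gene_sets(
    model: MetabolicModel, reaction_ids: Iterable[str]
) -> List[FrozenSet[str]]:
    """All minimal gene deletion sets that deactivate *exactly* the given reactions.

    Combines one minimal cut set per target reaction, then discards
    combinations that would collaterally deactivate any other reaction, and
    keeps the inclusion-minimal survivors (sorted for determinism).
    Returns ``[]`` when some target reaction has no gene association.
    """
    targets = sorted(set(reaction_ids))
    per_reaction: List[List[FrozenSet[str]]] = []
    for rxn_id in targets:
        cuts = model.reaction(rxn_id).gene_rule.minimal_knockout_sets()
        if not cuts:
            return []
        per_reaction.append(cuts)
    target_set = frozenset(targets)
    candidates: Set[FrozenSet[str]] = set()
    for combo in itertools.product(*per_reaction):
        union: FrozenSet[str] = frozenset().union(*combo)
        if deactivated_reactions(model, union) == target_set:
            candidates.add(union)
    minimal = [
        c for c in candidates if not any(o < c for o in candidates)
    ]
    return sorted(minimal, key=lambda s: (len(s), sorted(s)))
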