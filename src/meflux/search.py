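"""Knockout screening for methanol-essential genotypes.

A knockout genotype is *methanol-essential* for a co-substrate when FBA
predicts (i) no growth on the co-substrate alone (mu_co <= eps, with eps
the 0.01 h^-1 growth threshold), (ii) growth restored when methanol is
additionally available, with methanol genuinely rescuing co-substrate
utilization rather than merely substituting for it (mu_co+MeOH exceeds
mu_MeOH by a coupling margin), and (iii) retained potential for pure
methylotrophic growth (mu_MeOH > eps).  Deletions that methanol cannot
rescue in this sense -- e.g. a co-substrate transporter knockout, after
which growth with methanol is indistinguishable from growth on methanol
alone -- are classified non-rescuable and discarded, and everything else
is neutral with a recorded differential fitness score
mu_co+MeOH - mu_co.

The search itself is a beam search over reaction-deletion sets: at each
depth the highest differential-fitness candidates are extended by one
further deletion, every methanol-essential genotype encountered is
re-verified by direct FBA calls, and the search stops at the minimal
depth at which solutions exist.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Tuple

from .fba import CompiledProblem, FbaConfig
from .model import MetabolicModel, minimal_gene_sets, set_medium

__all__ = [
    "SearchConfig",
    "KnockoutGenotype",
    "SearchReport",
    "classify_knockout",
    "screen_single_knockouts",
    "rank_differential_fitness",
    "iterative_search",
    "verify_reaction_dispensability",
    "METHANOL_ESSENTIAL",
    "NON_RESCUABLE",
    "NEUTRAL",
]

logger = logging.getLogger(__name__)

METHANOL_ESSENTIAL = "methanol_essential"
NON_RESCUABLE = "non_rescuable"
NEUTRAL = "neutral"

#: The eight co-substrates screened against methanol.
DEFAULT_CO_SUBSTRATES = (
    "EX_ac", "EX_glcn", "EX_glc", "EX_glyc",
    "EX_pyr", "EX_rib", "EX_xyl", "EX_succ",
)


@dataclass(frozen=True)
class SearchConfig:
    """Screening parameters.

    ``growth_threshold`` is the no-growth cutoff eps (0.01 h^-1);
    ``uptake_rate`` bounds each carbon source independently at 7 mmol
    gCDW^-1 h^-1; ``coupling_margin`` is the minimal growth advantage of
    the mixed medium over methanol alone for a rescue to count as
    co-substrate coupling (well above LP tolerance, well below any real
    substrate contribution).
    """

    growth_threshold: float = 0.01
    uptake_rate: float = 7.0
    co_substrates: Tuple[str, ...] = DEFAULT_CO_SUBSTRATES
    max_depth: int = 4
    beam_width: int = 16
    require_methylotrophy: bool = True
    coupling_margin: float = 1e-4
    methanol_exchange: str = "EX_meoh"

    def __post_init__(self) -> None:
        if self.growth_threshold <= 0:
            raise ValueError("growth_threshold must be > 0")
        if self.max_depth < 1 or self.beam_width < 1:
            raise ValueError("max_depth and beam_width must be >= 1")


@dataclass(frozen=True)
class KnockoutGenotype:
    """A deletion set with its growth rates under the three diagnostic media."""

    deleted_reactions: FrozenSet[str]
    deleted_genes: FrozenSet[str]
    mu_co: float
    mu_co_meoh: float
    mu_meoh: float
    classification: str

    @property
    def differential_score(self) -> float:
        """Growth advantage of methanol co-consumption, mu_co+MeOH - mu_co."""
        return self.mu_co_meoh - self.mu_co

    def sort_key(self) -> Tuple[str, ...]:
        return tuple(sorted(self.deleted_reactions))

    def to_dict(self) -> dict:
        return {
            "deleted_reactions": sorted(self.deleted_reactions),
            "deleted_genes": sorted(self.deleted_genes),
            "mu_co": self.mu_co,
            "mu_co_meoh": self.mu_co_meoh,
            "mu_meoh": self.mu_meoh,
            "classification": self.classification,
            "differential_score": self.differential_score,
        }


@dataclass
class SearchReport:
    """Outcome of one iterative search: genotypes plus the iteration trace."""

    co_substrate: str
    genotypes: List[KnockoutGenotype]
    trace: List[dict]
    config: SearchConfig

    def to_json(self) -> str:
        """Deterministic serialization (byte-identical for identical inputs)."""
        doc = {
            "co_substrate": self.co_substrate,
            "config": asdict(self.config),
            "genotypes": [g.to_dict() for g in self.genotypes],
            "trace": self.trace,
        }
        doc["config"]["co_substrates"] = list(self.config.co_substrates)
        return json.dumps(doc, indent=1, sort_keys=True)


class _Screener:
    """Compiled LPs for the three diagnostic media of one co-substrate."""

    def __init__(self, model: MetabolicModel, co_substrate: str, config: SearchConfig,
                 fba_config: Optional[FbaConfig] = None):
        self.model = model
        self.config = config
        rate = config.uptake_rate
        meoh = config.methanol_exchange
        self.p_co = CompiledProblem(set_medium(model, {co_substrate}, rate), fba_config)
        self.p_mix = CompiledProblem(
            set_medium(model, {co_substrate, meoh}, rate), fba_config
        )
        self.p_meoh = CompiledProblem(set_medium(model, {meoh}, rate), fba_config)

    def rates(self, ko: FrozenSet[str]) -> Tuple[float, float, float]:
        idx = self.p_co.indices(ko)
        return (
            self.p_co.growth(idx),
            self.p_mix.growth(idx),
            self.p_meoh.growth(idx),
        )

    def classify(self, ko: FrozenSet[str]) -> KnockoutGenotype:
        mu_co, mu_mix, mu_meoh = self.rates(ko)
        cfg = self.config
        eps = cfg.growth_threshold
        if mu_mix <= eps:
            label = NON_RESCUABLE
        elif mu_co <= eps:
            coupled = (mu_mix - mu_meoh) > cfg.coupling_margin
            methylotrophic = (not cfg.require_methylotrophy) or (mu_meoh > eps)
            label = METHANOL_ESSENTIAL if (coupled and methylotrophic) else NON_RESCUABLE
        else:
            label = NEUTRAL
        gene_sets = minimal_gene_sets(self.model, ko) if ko else []
        genes = gene_sets[0] if gene_sets else frozenset()
        return KnockoutGenotype(
            deleted_reactions=frozenset(ko),
            deleted_genes=genes,
            mu_co=mu_co,
            mu_co_meoh=mu_mix,
            mu_meoh=mu_meoh,
            classification=label,
        )


def classify_knockout(
    model: MetabolicModel,
    ko_set: Iterable[str],
    co_substrate: str,
    config: Optional[SearchConfig] = None,
) -> KnockoutGenotype:
    """Growth rates and classification of one reaction-deletion set.

    ``model`` must already carry the Mdh/Hps/Phi reactions for methanol to
    be assimilable.
    """
    config = config or SearchConfig()
    ko = frozenset(ko_set)
    for rxn_id in ko:
        model.reaction(rxn_id)  # raises KeyError on unknown ids
    return _Screener(model, co_substrate, config).classify(ko)


def screen_single_knockouts(
    model: MetabolicModel,
    fixed_kos: Iterable[str],
    co_substrate: str,
    config: Optional[SearchConfig] = None,
    _screener: Optional[_Screener] = None,
) -> List[KnockoutGenotype]:
    """Classify every single additional internal-reaction deletion.

    Each candidate is the fixed set plus one internal (non-exchange,
    non-biomass) reaction not already fixed; results are ordered by
    reaction id for determinism.
    """
    config = config or SearchConfig()
    fixed = frozenset(fixed_kos)
    screener = _screener or _Screener(model, co_substrate, config)
    out = []
    for rxn in sorted(model.internal_reactions(), key=lambda r: r.id):
        if rxn.id in fixed:
            continue
        out.append(screener.classify(fixed | {rxn.id}))
    return out


def rank_differential_fitness(
    candidates: Iterable[KnockoutGenotype],
) -> List[KnockoutGenotype]:
    """Neutral candidates by descending differential fitness.

    Non-rescuable (and essential) genotypes are excluded; ties break
    lexicographically on the sorted reaction ids.
    """
    neutral = [g for g in candidates if g.classification == NEUTRAL]
    return sorted(neutral, key=lambda g: (-g.differential_score, g.sort_key()))


def iterative_search(
    model: MetabolicModel,
    co_substrate: str,
    config: Optional[SearchConfig] = None,
) -> SearchReport:
    """Beam search for minimal methanol-essential deletion sets.

    At each depth the ``beam_width`` best fixed sets (by differential
    fitness ranking) are each extended by one further deletion; all
    methanol-essential genotypes encountered are collected.  The search
    stops at the first depth with solutions (or at ``max_depth`` with an
    empty genotype list, trace retained).  Every reported genotype is
    re-verified with fresh FBA calls.
    """
    config = config or SearchConfig()
    screener = _Screener(model, co_substrate, config)
    frontier: List[FrozenSet[str]] = [frozenset()]
    trace: List[dict] = []
    found: List[KnockoutGenotype] = []
    for depth in range(1, config.max_depth + 1):
        seen: Dict[FrozenSet[str], KnockoutGenotype] = {}
        for fixed in frontier:
            for genotype in screen_single_knockouts(
                model, fixed, co_substrate, config, _screener=screener
            ):
                seen.setdefault(genotype.deleted_reactions, genotype)
        candidates = sorted(seen.values(), key=KnockoutGenotype.sort_key)
        essentials = [g for g in candidates if g.classification == METHANOL_ESSENTIAL]
        trace.append(
            {
                "depth": depth,
                "fixed_sets": sorted(sorted(f) for f in frontier),
                "n_candidates": len(candidates),
                "essential": sorted(sorted(g.deleted_reactions) for g in essentials),
            }
        )
        if essentials:
            found = essentials
            break
        ranked = rank_differential_fitness(candidates)
        frontier = [g.deleted_reactions for g in ranked[: config.beam_width]]
        if not frontier:
            logger.info("search exhausted at depth %d with no extendable candidates", depth)
            break

    verified = []
    for genotype in found:
        check = classify_knockout(model, genotype.deleted_reactions, co_substrate, config)
        if check.classification != METHANOL_ESSENTIAL:
            raise AssertionError(
                f"re-verification failed for {sorted(genotype.deleted_reactions)}"
            )
        verified.append(check)
    return SearchReport(
        co_substrate=co_substrate,
        genotypes=sorted(verified, key=KnockoutGenotype.sort_key),
        trace=trace,
        config=config,
    )


def verify_reaction_dispensability(
    model: MetabolicModel,
    ko_set: Iterable[str],
    carbon_sources: Iterable[str],
    config: Optional[SearchConfig] = None,
) -> Tuple[bool, float]:
    """Does the model still grow on the stated medium with ``ko_set`` applied?

    Returns ``(growth > eps, growth)``.  Used e.g. to confirm that the
    NAD-dependent malate dehydrogenase is dispensable on gluconate +
    methanol (a closed oxidative TCA cycle is not required), the rationale
    behind the Delta-maldh strain design.
    """
    config = config or SearchConfig()
    medium = set_medium(model, set(carbon_sources), config.uptake_rate)
    problem = CompiledProblem(medium)
    growth = problem.growth(problem.indices(frozenset(ko_set)))
    return growth > config.growth_threshold, growth
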