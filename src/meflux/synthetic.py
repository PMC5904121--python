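"""Synthetic inputs: the packaged core model and seeded culture/labeling data.

The core model is a hand-built reduced *E. coli* network (~70 reactions)
reproducing the pathway topology relevant to methanol-essential strain
design: gluconate entry, Entner-Doudoroff pathway, oxidative and
non-oxidative pentose phosphate pathway, glycolysis/gluconeogenesis, TCA
cycle with glyoxylate shunt and both malate dehydrogenase activities
(NAD-dependent Maldh and the quinone-linked Mqo), anaplerosis, a lumped
respiratory chain (P/O = 2), and a lumped biomass reaction drawing the
canonical precursors.  The heterologous Mdh/Hps/Phi reactions are *not*
part of the core model; they are added by
:func:`meflux.model.add_heterologous_reactions`.

Culture and isotopologue generators are pure functions of their
:class:`SimulationSpec` (seed included).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.stats import binom

from .labeling import IsotopologueDistribution, correction_matrix
from .model import GeneRule, MetabolicModel, Metabolite, Reaction
from .physiology import DEFAULT_CDW_FACTOR, TimeSeries

__all__ = ["SimulationSpec", "build_core_model", "simulate_culture",
           "simulate_isotopologues"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic cultivation / labeling experiment.

    Defaults emulate the methanol-essential strain conditions: specific
    growth rate 0.081 h^-1, methanol uptake 13 mmol gCDW^-1 h^-1, 500 mM
    initial methanol with a linear abiotic evaporation component, and 1%
    multiplicative measurement noise.  ``true_labeled_fraction`` 1/6
    corresponds to equimolar co-assimilation of methanol (C1) with a C6
    co-substrate.
    """

    seed: int = 0
    mu: float = 0.081                 # h^-1
    X0: float = 0.08                  # gCDW L^-1 at t = 0
    q_true: float = 13.0              # mmol gCDW^-1 h^-1
    evap_rate: float = 0.5            # mM h^-1 abiotic loss
    noise_cv: float = 0.01            # multiplicative noise CV
    n_points: int = 8
    t_end: float = 36.0               # h
    s0: float = 500.0                 # mM methanol at t = 0
    true_labeled_fraction: float = 1.0 / 6.0
    natural_abundance: float = 0.0107

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if not 0 <= self.true_labeled_fraction <= 1:
            raise ValueError("true_labeled_fraction must be in [0, 1]")
        if not 0 <= self.natural_abundance < 1:
            raise ValueError("natural_abundance must be in [0, 1)")


# ---------------------------------------------------------------------------
# core metabolic model
# ---------------------------------------------------------------------------

# id, name, compartment, carbon count (skeleton carbons; carriers = 0)
_METABOLITES = [
    # boundary species
    ("glc_e", "D-glucose (external)", "e", 6),
    ("glcn_e", "D-gluconate (external)", "e", 6),
    ("ac_e", "acetate (external)", "e", 2),
    ("glyc_e", "glycerol (external)", "e", 3),
    ("pyr_e", "pyruvate (external)", "e", 3),
    ("rib_e", "D-ribose (external)", "e", 5),
    ("xyl_e", "D-xylose (external)", "e", 5),
    ("succ_e", "succinate (external)", "e", 4),
    ("meoh_e", "methanol (external)", "e", 1),
    # central carbon
    ("glcn", "D-gluconate", "c", 6),
    ("g6p", "glucose 6-phosphate", "c", 6),
    ("f6p", "fructose 6-phosphate", "c", 6),
    ("fdp", "fructose 1,6-bisphosphate", "c", 6),
    ("dhap", "dihydroxyacetone phosphate", "c", 3),
    ("g3p", "glyceraldehyde 3-phosphate", "c", 3),
    ("13dpg", "1,3-bisphosphoglycerate", "c", 3),
    ("3pg", "3-phosphoglycerate", "c", 3),
    ("2pg", "2-phosphoglycerate", "c", 3),
    ("pep", "phosphoenolpyruvate", "c", 3),
    ("pyr", "pyruvate", "c", 3),
    ("accoa", "acetyl-CoA (acetyl moiety)", "c", 2),
    ("ac", "acetate", "c", 2),
    ("cit", "citrate", "c", 6),
    ("icit", "isocitrate", "c", 6),
    ("akg", "2-oxoglutarate", "c", 5),
    ("succoa", "succinyl-CoA (succinyl moiety)", "c", 4),
    ("succ", "succinate", "c", 4),
    ("fum", "fumarate", "c", 4),
    ("mal", "L-malate", "c", 4),
    ("oaa", "oxaloacetate", "c", 4),
    ("glx", "glyoxylate", "c", 2),
    ("6pg", "6-phosphogluconate", "c", 6),
    ("2ddg6p", "2-keto-3-deoxy-6-phosphogluconate", "c", 6),
    ("ru5p", "ribulose 5-phosphate", "c", 5),
    ("r5p", "ribose 5-phosphate", "c", 5),
    ("x5p", "xylulose 5-phosphate", "c", 5),
    ("s7p", "sedoheptulose 7-phosphate", "c", 7),
    ("e4p", "erythrose 4-phosphate", "c", 4),
    ("rib", "D-ribose", "c", 5),
    ("xyl", "D-xylose", "c", 5),
    ("xylu", "D-xylulose", "c", 5),
    ("glyc", "glycerol", "c", 3),
    ("glyc3p", "glycerol 3-phosphate", "c", 3),
    ("meoh", "methanol", "c", 1),
    ("fald", "formaldehyde", "c", 1),
    ("mlthf", "5,10-methylene-tetrahydrofolate (C1 unit)", "c", 1),
    ("gly", "glycine", "c", 2),
    ("ser", "L-serine", "c", 3),
    ("co2", "CO2", "c", 1),
    # carriers and inorganics (carbon conventionally 0)
    ("o2", "O2", "c", 0),
    ("nh4", "ammonium", "c", 0),
    ("pi", "inorganic phosphate", "c", 0),
    ("h2o", "water", "c", 0),
    ("h", "H+", "c", 0),
    ("coa", "coenzyme A", "c", 0),
    ("thf", "tetrahydrofolate", "c", 0),
    ("nad", "NAD+", "c", 0),
    ("nadh", "NADH", "c", 0),
    ("nadp", "NADP+", "c", 0),
    ("nadph", "NADPH", "c", 0),
    ("atp", "ATP", "c", 0),
    ("adp", "ADP", "c", 0),
]

_R = 1000.0

# id, name, stoichiometry, lb, ub, gene rule
_REACTIONS = [
    # substrate entry
    ("GLCpts", "glucose PTS transport/phosphorylation",
     {"glc_e": -1, "pep": -1, "g6p": 1, "pyr": 1}, 0, _R, "ptsG"),
    ("GNTt", "gluconate transport",
     {"glcn_e": -1, "glcn": 1}, 0, _R, "gntT"),
    ("GNTK", "gluconokinase",
     {"glcn": -1, "atp": -1, "6pg": 1, "adp": 1}, 0, _R, "gntK"),
    ("ACt", "acetate transport (reversible: uptake and overflow secretion)",
     {"ac_e": -1, "ac": 1}, -_R, _R, "actP"),
    ("ACKR", "phosphotransacetylase + acetate kinase (lumped, reversible)",
     {"accoa": -1, "adp": -1, "pi": -1, "ac": 1, "atp": 1, "coa": 1}, -_R, _R,
     "pta and ackA"),
    ("GLYCt", "glycerol facilitator", {"glyc_e": -1, "glyc": 1}, 0, _R, "glpF"),
    ("GLYK", "glycerol kinase",
     {"glyc": -1, "atp": -1, "glyc3p": 1, "adp": 1}, 0, _R, "glpK"),
    ("G3PD", "glycerol-3-phosphate dehydrogenase (NAD-lumped)",
     {"glyc3p": -1, "nad": -1, "dhap": 1, "nadh": 1, "h": 1}, 0, _R, "glpD"),
    ("PYRt", "pyruvate transport", {"pyr_e": -1, "pyr": 1}, 0, _R, "cstA"),
    ("RIBt", "ribose ABC transport",
     {"rib_e": -1, "atp": -1, "h2o": -1, "rib": 1, "adp": 1, "pi": 1}, 0, _R, "rbsC"),
    ("RBK", "ribokinase", {"rib": -1, "atp": -1, "r5p": 1, "adp": 1}, 0, _R, "rbsK"),
    ("XYLt", "xylose transport", {"xyl_e": -1, "xyl": 1}, 0, _R, "xylE"),
    ("XYLI", "xylose isomerase", {"xyl": -1, "xylu": 1}, -_R, _R, "xylA"),
    ("XYLK", "xylulokinase", {"xylu": -1, "atp": -1, "x5p": 1, "adp": 1}, 0, _R, "xylB"),
    ("SUCCt", "succinate transport (reversible: uptake and overflow secretion)",
     {"succ_e": -1, "succ": 1}, -_R, _R, "dctA"),
    ("MEOHt", "methanol diffusion", {"meoh_e": -1, "meoh": 1}, -_R, _R, ""),
    # glycolysis / gluconeogenesis
    ("PGI", "glucose-6-phosphate isomerase", {"g6p": -1, "f6p": 1}, -_R, _R, "pgi"),
    ("PFK", "phosphofructokinase",
     {"f6p": -1, "atp": -1, "fdp": 1, "adp": 1}, 0, _R, "pfkA or pfkB"),
    ("FBP", "fructose-1,6-bisphosphatase",
     {"fdp": -1, "h2o": -1, "f6p": 1, "pi": 1}, 0, _R, "fbp"),
    ("FBA", "fructose-bisphosphate aldolase",
     {"fdp": -1, "dhap": 1, "g3p": 1}, -_R, _R, "fbaA"),
    ("TPI", "triose-phosphate isomerase", {"dhap": -1, "g3p": 1}, -_R, _R, "tpiA"),
    ("GAPD", "glyceraldehyde-3-phosphate dehydrogenase",
     {"g3p": -1, "nad": -1, "pi": -1, "13dpg": 1, "nadh": 1, "h": 1}, -_R, _R, "gapA"),
    ("PGK", "phosphoglycerate kinase",
     {"13dpg": -1, "adp": -1, "3pg": 1, "atp": 1}, -_R, _R, "pgk"),
    ("PGM", "phosphoglycerate mutase", {"3pg": -1, "2pg": 1}, -_R, _R, "gpmA or gpmM"),
    ("ENO", "enolase", {"2pg": -1, "pep": 1, "h2o": 1}, -_R, _R, "eno"),
    ("PYK", "pyruvate kinase",
     {"pep": -1, "adp": -1, "pyr": 1, "atp": 1}, 0, _R, "pykA or pykF"),
    ("PPS", "PEP synthetase (2 ATP-equivalents)",
     {"pyr": -1, "atp": -2, "h2o": -1, "pep": 1, "adp": 2, "pi": 2}, 0, _R, "ppsA"),
    ("PDH", "pyruvate dehydrogenase",
     {"pyr": -1, "coa": -1, "nad": -1, "accoa": 1, "co2": 1, "nadh": 1}, 0, _R,
     "aceE and aceF and lpd"),
    # pentose phosphate + Entner-Doudoroff
    ("ZWF", "G6P dehydrogenase + lactonase (lumped)",
     {"g6p": -1, "nadp": -1, "h2o": -1, "6pg": 1, "nadph": 1, "h": 1}, 0, _R,
     "zwf and pgl"),
    ("GND", "6-phosphogluconate dehydrogenase (reversible)",
     {"6pg": -1, "nadp": -1, "ru5p": 1, "co2": 1, "nadph": 1}, -_R, _R, "gnd"),
    ("EDD", "phosphogluconate dehydratase",
     {"6pg": -1, "2ddg6p": 1, "h2o": 1}, 0, _R, "edd"),
    ("EDA", "KDPG aldolase", {"2ddg6p": -1, "pyr": 1, "g3p": 1}, 0, _R, "eda"),
    ("RPI", "ribose-5-phosphate isomerase", {"ru5p": -1, "r5p": 1}, -_R, _R,
     "rpiA or rpiB"),
    ("RPE", "ribulose-5-phosphate 3-epimerase", {"ru5p": -1, "x5p": 1}, -_R, _R, "rpe"),
    ("TKT1", "transketolase (R5P + X5P)",
     {"x5p": -1, "r5p": -1, "g3p": 1, "s7p": 1}, -_R, _R, "tktA or tktB"),
    ("TAL", "transaldolase",
     {"g3p": -1, "s7p": -1, "f6p": 1, "e4p": 1}, -_R, _R, "talA or talB"),
    ("TKT2", "transketolase (E4P + X5P)",
     {"x5p": -1, "e4p": -1, "f6p": 1, "g3p": 1}, -_R, _R, "tktA or tktB"),
    # TCA cycle, glyoxylate shunt, anaplerosis
    ("CS", "citrate synthase",
     {"accoa": -1, "oaa": -1, "h2o": -1, "cit": 1, "coa": 1}, 0, _R, "gltA"),
    ("ACONT", "aconitase", {"cit": -1, "icit": 1}, -_R, _R, "acnA or acnB"),
    ("ICDH", "isocitrate dehydrogenase (NADP)",
     {"icit": -1, "nadp": -1, "akg": 1, "co2": 1, "nadph": 1}, 0, _R, "icd"),
    ("AKGDH", "2-oxoglutarate dehydrogenase",
     {"akg": -1, "coa": -1, "nad": -1, "succoa": 1, "co2": 1, "nadh": 1}, 0, _R,
     "sucA and sucB and lpd"),
    ("SUCOAS", "succinyl-CoA synthetase",
     {"succoa": -1, "adp": -1, "pi": -1, "succ": 1, "atp": 1, "coa": 1}, -_R, _R,
     "sucC and sucD"),
    ("SUCDH", "succinate dehydrogenase (respiration-lumped, P/O 1)",
     {"succ": -1, "o2": -0.5, "adp": -1, "pi": -1, "fum": 1, "atp": 1, "h2o": 1},
     0, _R, "sdhA"),
    ("FUM", "fumarase", {"fum": -1, "h2o": -1, "mal": 1}, -_R, _R,
     "fumA or fumB or fumC"),
    ("MALDH", "malate dehydrogenase (NAD-dependent)",
     {"mal": -1, "nad": -1, "oaa": 1, "nadh": 1, "h": 1}, -_R, _R, "maldh"),
    ("MQO", "malate:quinone oxidoreductase (respiration-lumped, P/O 1)",
     {"mal": -1, "o2": -0.5, "adp": -1, "pi": -1, "oaa": 1, "atp": 1, "h2o": 1},
     0, _R, "mqo"),
    ("PPC", "PEP carboxylase",
     {"pep": -1, "co2": -1, "h2o": -1, "oaa": 1, "pi": 1}, 0, _R, "ppc"),
    ("PCK", "PEP carboxykinase",
     {"oaa": -1, "atp": -1, "pep": 1, "co2": 1, "adp": 1}, 0, _R, "pck"),
    ("ME", "malic enzyme (NADP)",
     {"mal": -1, "nadp": -1, "pyr": 1, "co2": 1, "nadph": 1}, 0, _R, "maeB"),
    ("ICL", "isocitrate lyase", {"icit": -1, "succ": 1, "glx": 1}, 0, _R, "aceA"),
    ("MALS", "malate synthase",
     {"glx": -1, "accoa": -1, "h2o": -1, "mal": 1, "coa": 1}, 0, _R, "aceB"),
    # energy and redox
    ("NADHOX", "respiratory NADH oxidation (lumped, P/O 2)",
     {"nadh": -1, "o2": -0.5, "adp": -2, "pi": -2, "nad": 1, "atp": 2, "h2o": 2},
     0, _R, "nuoA"),
    ("THD", "soluble transhydrogenase (NADPH -> NADH overflow)",
     {"nadph": -1, "nad": -1, "nadp": 1, "nadh": 1}, 0, _R, "sthA"),
    # tetrahydrofolate-linked C1 metabolism: formaldehyde binds THF
    # spontaneously; with the glycine cleavage system reversed this gives a
    # pentose-cycle-independent (serine) route from formaldehyde to pyruvate
    ("FALDTHF", "spontaneous formaldehyde-THF condensation",
     {"fald": -1, "thf": -1, "mlthf": 1}, -_R, _R, ""),
    ("GCS", "glycine cleavage system (reversible)",
     {"gly": -1, "thf": -1, "nad": -1, "mlthf": 1, "co2": 1, "nh4": 1, "nadh": 1},
     -_R, _R, "gcvT and gcvH and gcvP"),
    ("GHMT", "serine hydroxymethyltransferase",
     {"ser": -1, "thf": -1, "gly": 1, "mlthf": 1, "h2o": 1}, -_R, _R, "glyA"),
    ("SERD", "L-serine deaminase", {"ser": -1, "pyr": 1, "nh4": 1}, 0, _R, "sdaA"),
]

#: Lumped biomass composition, mmol precursor per gCDW (ATP/NADPH in
#: mmol gCDW^-1); flux through the reaction is the growth rate in h^-1.
BIOMASS_COMPOSITION = {
    "pep": -1.5, "pyr": -2.4, "accoa": -3.0, "oaa": -1.8, "akg": -0.9,
    "nh4": -10.0, "atp": -40.0, "nadph": -18.0, "h2o": -30.0,
    "adp": 40.0, "pi": 40.0, "nadp": 18.0, "coa": 3.0, "h": 10.0,
}

_EXCHANGES = [
    ("EX_glc", "glc_e"), ("EX_glcn", "glcn_e"), ("EX_ac", "ac_e"),
    ("EX_glyc", "glyc_e"), ("EX_pyr", "pyr_e"), ("EX_rib", "rib_e"),
    ("EX_xyl", "xyl_e"), ("EX_succ", "succ_e"), ("EX_meoh", "meoh_e"),
    ("EX_o2", "o2"), ("EX_co2", "co2"), ("EX_nh4", "nh4"),
    ("EX_pi", "pi"), ("EX_h2o", "h2o"), ("EX_h", "h"),
]

BIOMASS_ID = "BIOMASS"


def build_core_model() -> MetabolicModel:
    """The packaged reduced core model, pre-augmentation.

    Ships in a no-carbon medium: carbon exchanges are closed to uptake,
    carbon-free nutrient exchanges are open; use
    :func:`meflux.model.set_medium` to define the carbon sources.
    Formaldehyde and cytosolic methanol are present as species so the
    heterologous Mdh/Hps/Phi reactions can be attached.
    """
    mets = [Metabolite(i, n, comp, c) for i, n, comp, c in _METABOLITES]
    carbon = {i: c for i, n, comp, c in _METABOLITES}
    rxns = [
        Reaction(rid, {k: float(v) for k, v in stoich.items()}, float(lb), float(ub),
                 GeneRule(rule), name=name)
        for rid, name, stoich, lb, ub, rule in _REACTIONS
    ]
    for ex_id, met_id in _EXCHANGES:
        uptake_open = carbon[met_id] == 0
        rxns.append(
            Reaction(ex_id, {met_id: -1.0}, -_R if uptake_open else 0.0, _R,
                     GeneRule(), is_exchange=True, name=f"{met_id} exchange")
        )
    rxns.append(
        Reaction(BIOMASS_ID, {k: float(v) for k, v in BIOMASS_COMPOSITION.items()},
                 0.0, _R, GeneRule(), name="biomass (lumped)")
    )
    return MetabolicModel(mets, rxns, objective_reaction_id=BIOMASS_ID,
                          id="ecoli_core_meflux")


# ---------------------------------------------------------------------------
# cultivation data generator
# ---------------------------------------------------------------------------

def simulate_culture(
    spec: SimulationSpec,
) -> Tuple[TimeSeries, TimeSeries, TimeSeries]:
    """Seeded synthetic (OD600, culture substrate, evaporation control) series.

    OD grows exponentially with multiplicative noise; the culture substrate
    declines by a linear evaporation term plus the biomass-integral
    consumption term; the evaporation control (a non-consuming culture)
    sees the linear term only.  Substrate values driven negative are
    truncated at zero with a warning.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.linspace(0.0, spec.t_end, spec.n_points)
    od_true = (spec.X0 / DEFAULT_CDW_FACTOR) * np.exp(spec.mu * t)
    consumed = spec.q_true * (spec.X0 / spec.mu) * (np.exp(spec.mu * t) - 1.0)
    substrate_true = spec.s0 - spec.evap_rate * t - consumed
    evap_true = spec.s0 - spec.evap_rate * t

    def noisy(values: np.ndarray) -> np.ndarray:
        if spec.noise_cv == 0:
            return values.copy()
        return values * (1.0 + spec.noise_cv * rng.standard_normal(values.shape))

    od = noisy(od_true)
    substrate = noisy(substrate_true)
    evap = noisy(evap_true)
    if np.any(substrate_true < 0) or np.any(substrate < 0) or np.any(evap < 0):
        logger.warning("substrate driven negative; truncating at 0")
        substrate = np.maximum(substrate, 0.0)
        evap = np.maximum(evap, 0.0)
    return (
        TimeSeries(t, od, kind="od"),
        TimeSeries(t, substrate, kind="substrate"),
        TimeSeries(t, evap, kind="substrate"),
    )


# ---------------------------------------------------------------------------
# isotopologue generator
# ---------------------------------------------------------------------------

def simulate_isotopologues(
    spec: SimulationSpec,
    n_carbon: int,
    n_labeled_positions: int,
    metabolite_id: str = "synthetic",
) -> IsotopologueDistribution:
    """Isotopologue distribution for a metabolite with ``n_labeled_positions``
    carbons drawn from the labeled (methanol) pool.

    Each tracer position carries 13C with probability
    ``true_labeled_fraction * n_carbon / n_labeled_positions`` (so the
    molecule-average tracer-derived labeled fraction equals
    ``true_labeled_fraction``); every carbon not carrying a tracer label --
    including tracer positions that happen to be unlabeled -- additionally
    carries 13C at natural abundance.  Noise is multiplicative per
    isotopologue intensity, seeded.
    """
    if n_labeled_positions > n_carbon:
        raise ValueError("n_labeled_positions cannot exceed n_carbon")
    rng = np.random.default_rng(spec.seed + 1)  # decouple from culture noise
    true = np.zeros(n_carbon + 1)
    if n_labeled_positions > 0:
        p = spec.true_labeled_fraction * n_carbon / n_labeled_positions
        if p > 1.0 + 1e-12:
            raise ValueError(
                f"per-position labeling probability {p:.4f} exceeds 1; "
                f"too few labelable positions for the requested fraction"
            )
        p = min(p, 1.0)
        true[: n_labeled_positions + 1] = binom.pmf(
            np.arange(n_labeled_positions + 1), n_labeled_positions, p
        )
    else:
        true[0] = 1.0
    abundances = correction_matrix(n_carbon, spec.natural_abundance) @ true
    if spec.noise_cv > 0:
        abundances = np.maximum(
            abundances * (1.0 + spec.noise_cv * rng.standard_normal(abundances.shape)),
            0.0,
        )
    return IsotopologueDistribution(metabolite_id, n_carbon, abundances)
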