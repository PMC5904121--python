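"""Reading and writing metabolic models.

Two formats are supported:

* the package's own JSON dialect (documented in ``docs/model_schema.md``),
  read and written losslessly, and
* SBML Level 3 with the FBC extension, read-only, via python-libsbml.

JSON validation reports the offending field by name; dangling metabolite
references are listed explicitly.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Optional, Union

from .model import (
    DEFAULT_BOUND,
    GeneRule,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
)

__all__ = ["load_model", "save_model", "model_to_dict", "model_from_dict",
           "packaged_core_model_path"]


def packaged_core_model_path() -> Path:
    """Path of the core-model JSON shipped with the package."""
    return Path(__file__).parent / "data" / "core_model.json"

FORMAT_TAG = "meflux-model"
FORMAT_VERSION = 1


def model_to_dict(model: MetabolicModel) -> dict:
    """JSON-ready representation (stable key order for byte-identical dumps)."""
    return {
        "format": FORMAT_TAG,
        "version": FORMAT_VERSION,
        "id": model.id,
        "objective": model.objective_reaction_id,
        "genes": sorted(model.genes),
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "n_carbon": m.n_carbon,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_rule": r.gene_rule.expression,
                "is_exchange": r.is_exchange,
            }
            for r in model.reactions
        ],
    }


def _require(mapping: dict, key: str, types, where: str):
    if key not in mapping:
        raise ModelValidationError(f"{where}: missing required field {key!r}")
    value = mapping[key]
    if not isinstance(value, types):
        raise ModelValidationError(
            f"{where}: field {key!r} has type {type(value).__name__}, "
            f"expected {types if isinstance(types, type) else '/'.join(t.__name__ for t in types)}"
        )
    return value


def model_from_dict(data: dict) -> MetabolicModel:
    if not isinstance(data, dict):
        raise ModelValidationError("model document must be a JSON object")
    if data.get("format") != FORMAT_TAG:
        raise ModelValidationError(
            f"field 'format' must be {FORMAT_TAG!r}, got {data.get('format')!r}"
        )
    mets = []
    for i, entry in enumerate(_require(data, "metabolites", list, "model")):
        where = f"metabolites[{i}]"
        if not isinstance(entry, dict):
            raise ModelValidationError(f"{where}: expected an object")
        mets.append(
            Metabolite(
                id=_require(entry, "id", str, where),
                name=entry.get("name", ""),
                compartment=entry.get("compartment", "c"),
                n_carbon=int(_require(entry, "n_carbon", (int, float), where)),
            )
        )
    rxn_entries = _require(data, "reactions", list, "model")
    if not rxn_entries:
        raise ModelValidationError("model: field 'reactions' is empty, no objective resolvable")
    rxns = []
    for i, entry in enumerate(rxn_entries):
        where = f"reactions[{i}]"
        if not isinstance(entry, dict):
            raise ModelValidationError(f"{where}: expected an object")
        stoich = _require(entry, "stoichiometry", dict, where)
        rxns.append(
            Reaction(
                id=_require(entry, "id", str, where),
                name=entry.get("name", ""),
                stoichiometry={str(k): float(v) for k, v in stoich.items()},
                lower_bound=float(entry.get("lower_bound", -DEFAULT_BOUND)),
                upper_bound=float(entry.get("upper_bound", DEFAULT_BOUND)),
                gene_rule=GeneRule(str(entry.get("gene_rule", ""))),
                is_exchange=bool(entry.get("is_exchange", False)),
            )
        )
    genes = data.get("genes")
    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        objective_reaction_id=_require(data, "objective", str, "model"),
        genes=genes,
        id=str(data.get("id", "model")),
    )


def save_model(model: MetabolicModel, path: Union[str, Path]) -> None:
    """Write the JSON dialect; round-trips to a flux-equivalent model."""
    Path(path).write_text(
        json.dumps(model_to_dict(model), indent=1, sort_keys=False) + "\n"
    )


def load_model(path: Union[str, Path], format: Optional[str] = None) -> MetabolicModel:
    """Load a model from JSON (native dialect) or SBML L3 FBC.

    The format is inferred from the file extension unless given explicitly
    as ``"json"`` or ``"sbml"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in {".xml", ".sbml"} else "json"
    if format == "json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ModelValidationError(f"{path}: not valid JSON ({exc})") from exc
        return model_from_dict(data)
    if format == "sbml":
        return _load_sbml(path)
    raise ValueError(f"unknown model format {format!r}")


_FORMULA_C = re.compile(r"C(\d*)(?![a-z])")


def _carbon_from_formula(formula: Optional[str]) -> int:
    if not formula:
        return 0
    total = 0
    for count in _FORMULA_C.findall(formula):
        total += int(count) if count else 1
    return total


def _load_sbml(path: Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msg = doc.getErrorLog().toString()
        raise ModelValidationError(f"{path}: SBML parse errors:\n{msg}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelValidationError(f"{path}: SBML document contains no model")
    fbc = sbml_model.getPlugin("fbc")

    mets = []
    for sp in sbml_model.getListOfSpecies():
        if sp.getBoundaryCondition():
            continue
        formula = None
        sp_fbc = sp.getPlugin("fbc")
        if sp_fbc is not None and sp_fbc.isSetChemicalFormula():
            formula = sp_fbc.getChemicalFormula()
        mets.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or "",
                compartment=sp.getCompartment() or "c",
                n_carbon=_carbon_from_formula(formula),
            )
        )
    met_ids = {m.id for m in mets}

    def param_value(pid: str, fallback: float) -> float:
        param = sbml_model.getParameter(pid) if pid else None
        return param.getValue() if param is not None else fallback

    rxns = []
    for rx in sbml_model.getListOfReactions():
        stoich: dict = {}
        boundary = False
        for sr in rx.getListOfReactants():
            if sr.getSpecies() in met_ids:
                stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
            else:
                boundary = True
        for sr in rx.getListOfProducts():
            if sr.getSpecies() in met_ids:
                stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
            else:
                boundary = True
        rx_fbc = rx.getPlugin("fbc")
        lb, ub = -DEFAULT_BOUND, DEFAULT_BOUND
        if rx_fbc is not None:
            lb = param_value(rx_fbc.getLowerFluxBound(), lb)
            ub = param_value(rx_fbc.getUpperFluxBound(), ub)
        rule = ""
        if rx_fbc is not None:
            gpa = rx_fbc.getGeneProductAssociation()
            if gpa is not None:
                rule = _gpa_to_rule(gpa.getAssociation(), sbml_model)
        if not stoich:
            continue
        rxns.append(
            Reaction(
                id=rx.getId(),
                name=rx.getName() or "",
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gene_rule=GeneRule(rule),
                is_exchange=boundary or len(stoich) == 1,
            )
        )

    objective_id = ""
    if fbc is not None and fbc.getNumObjectives() > 0:
        active = fbc.getActiveObjective() or fbc.getObjective(0)
        if active is not None and active.getNumFluxObjectives() > 0:
            objective_id = active.getFluxObjective(0).getReaction()
    if not objective_id:
        raise ModelValidationError(f"{path}: no FBC objective reaction defined")
    return MetabolicModel(mets, rxns, objective_id, id=sbml_model.getId() or path.stem)


def _gene_label(gp_id: str, sbml_model) -> str:
    fbc = sbml_model.getPlugin("fbc")
    gp = fbc.getGeneProduct(gp_id) if fbc is not None else None
    if gp is not None and gp.isSetLabel():
        return gp.getLabel()
    return gp_id


def _gpa_to_rule(assoc, sbml_model) -> str:
    import libsbml

    if assoc is None:
        return ""
    if isinstance(assoc, libsbml.GeneProductRef):
        return _gene_label(assoc.getGeneProduct(), sbml_model)
    if isinstance(assoc, libsbml.FbcAnd):
        parts = [_gpa_to_rule(assoc.getAssociation(i), sbml_model)
                 for i in range(assoc.getNumAssociations())]
        return "(" + " and ".join(p for p in parts if p) + ")"
    if isinstance(assoc, libsbml.FbcOr):
        parts = [_gpa_to_rule(assoc.getAssociation(i), sbml_model)
                 for i in range(assoc.getNumAssociations())]
        return "(" + " or ".join(p for p in parts if p) + ")"
    return ""
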