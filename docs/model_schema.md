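# Model JSON schema (version 1)

`meflux` reads and writes stoichiometric models as a single JSON object.
The dialect is deliberately small; `meflux.io.load_model` /
`meflux.io.save_model` round-trip it losslessly, and SBML Level 3 + FBC
files can be imported (read-only) through the same `load_model` entry
point.

```json
{
 "format": "meflux-model",
 "version": 1,
 "id": "ecoli_core_meflux",
 "objective": "BIOMASS",
 "genes": ["edd", "gnd", "rpiA", "rpiB", "..."],
 "metabolites": [
  {"id": "6pg", "name": "6-phosphogluconate", "compartment": "c", "n_carbon": 6}
 ],
 "reactions": [
  {
   "id": "GND",
   "name": "6-phosphogluconate dehydrogenase (reversible)",
   "stoichiometry": {"6pg": -1.0, "nadp": -1.0, "co2": 1.0, "nadph": 1.0, "ru5p": 1.0},
   "lower_bound": -1000.0,
   "upper_bound": 1000.0,
   "gene_rule": "gnd",
   "is_exchange": false
  }
 ]
}
```

## Fields

| field | type | required | meaning |
|---|---|---|---|
| `format` | string | yes | must be `"meflux-model"` |
| `version` | integer | yes | schema version, currently `1` |
| `id` | string | no | model name |
| `objective` | string | yes | reaction id of the biomass objective |
| `genes` | array of string | no | gene inventory; defaults to the union of all rule genes |
| `metabolites[].id` | string | yes | unique species id |
| `metabolites[].name` | string | no | free text |
| `metabolites[].compartment` | string | no | tag, default `"c"` |
| `metabolites[].n_carbon` | integer ≥ 0 | yes | skeleton carbon atoms (carriers: 0) |
| `reactions[].id` | string | yes | unique reaction id |
| `reactions[].stoichiometry` | object | yes | metabolite id → signed coefficient (negative = consumed); stored as decimal numbers |
| `reactions[].lower_bound` / `upper_bound` | number | no | flux bounds in mmol gCDW⁻¹ h⁻¹; default ±1000 (conventional "unbounded") |
| `reactions[].gene_rule` | string | no | boolean GPR over gene ids with `and`/`or`/parentheses; empty = spontaneous |
| `reactions[].is_exchange` | boolean | no | boundary pseudo-reaction moving exactly one metabolite; negative flux = uptake |

## Validation

`load_model` enforces, with errors naming the offending field:

* unique metabolite and reaction ids; non-empty reaction list;
* every stoichiometry key resolves to a declared metabolite (dangling ids
  are listed);
* the objective reaction exists;
* `lower_bound ≤ upper_bound`; exchanges touch exactly one metabolite;
* gene rules parse as pure and/or expressions and use only declared genes.

Carbon balance is *not* part of schema validation (a model may legitimately
lump cofactor carbons away); use `meflux.model.carbon_balance` to audit it.
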