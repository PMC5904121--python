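"""Model container, gene rules, knockouts, media and matrix views."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from meflux.fba import maximize_growth
from meflux.model import (
    GeneRule,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    add_heterologous_reactions,
    carbon_balance,
    knockout,
    minimal_gene_sets,
    set_medium,
    stoichiometric_matrix,
)

from conftest import two_reaction_chain


class TestGeneRule:
    @pytest.mark.parametrize(
        "rule, deleted, active",
        [
            ("", {"anything"}, True),                       # spontaneous
            ("edd", set(), True),
            ("edd", {"edd"}, False),
            ("rpiA or rpiB", {"rpiA"}, True),               # isozymes
            ("rpiA or rpiB", {"rpiA", "rpiB"}, False),
            ("sucA and sucB and lpd", {"sucB"}, False),     # complex
            ("(a and b) or c", {"a", "c"}, False),
            ("(a and b) or c", {"a"}, True),
        ],
    )
    def test_evaluation(self, rule, deleted, active):
        assert GeneRule(rule).is_active(deleted) is active

    def test_rejects_non_boolean_syntax(self):
        with pytest.raises(ModelValidationError):
            GeneRule("a + b")
        with pytest.raises(ModelValidationError):
            GeneRule("__import__('os')")

    def test_minimal_knockout_sets(self):
        assert GeneRule("rpiA or rpiB").minimal_knockout_sets() == [
            frozenset({"rpiA", "rpiB"})
        ]
        assert GeneRule("a and b").minimal_knockout_sets() == [
            frozenset({"a"}), frozenset({"b"})
        ]
        assert GeneRule("").minimal_knockout_sets() == []

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.sets(st.sampled_from(["a", "b", "c", "d"])))
    def test_evaluation_is_deterministic_and_total(self, deleted):
        rule = GeneRule("(a and b) or (c and d)")
        assert rule.is_active(deleted) == rule.is_active(set(deleted))


class TestInvariants:
    def test_reaction_bounds_ordering(self):
        with pytest.raises(ModelValidationError):
            Reaction("R", {"a": -1.0}, lower_bound=1.0, upper_bound=-1.0)

    def test_exchange_touches_one_metabolite(self):
        with pytest.raises(ModelValidationError):
            Reaction("EX", {"a": -1.0, "b": 1.0}, is_exchange=True)

    def test_empty_stoichiometry_rejected(self):
        with pytest.raises(ModelValidationError):
            Reaction("R", {})

    def test_negative_carbon_rejected(self):
        with pytest.raises(ModelValidationError):
            Metabolite("x", n_carbon=-1)

    def test_dangling_metabolite_listed(self):
        with pytest.raises(ModelValidationError, match="ghost"):
            MetabolicModel(
                [Metabolite("a")],
                [Reaction("R", {"a": -1.0, "ghost": 1.0})],
                objective_reaction_id="R",
            )


class TestKnockout:
    def test_gene_deletion_zeroes_reaction_bounds(self, core_model):
        ko = knockout(core_model, genes={"edd"})
        edd = ko.reaction("EDD")
        assert edd.lower_bound == edd.upper_bound == 0.0
        untouched = [r.id for r in core_model.reactions
                     if (ko.reaction(r.id).lower_bound, ko.reaction(r.id).upper_bound)
                     != (r.lower_bound, r.upper_bound)]
        assert untouched == ["EDD"]

    def test_isozyme_survives_single_gene_deletion(self, core_model):
        ko = knockout(core_model, genes={"rpiA"})
        assert ko.reaction("RPI").upper_bound > 0

    def test_empty_knockout_is_identity(self, core_model):
        ko = knockout(core_model)
        for rxn in core_model.reactions:
            assert ko.reaction(rxn.id).lower_bound == rxn.lower_bound
            assert ko.reaction(rxn.id).upper_bound == rxn.upper_bound

    def test_unknown_ids_raise(self, core_model):
        with pytest.raises(KeyError):
            knockout(core_model, genes={"nonexistent_gene"})
        with pytest.raises(KeyError):
            knockout(core_model, reactions={"NOPE"})

    def test_input_model_unmodified(self, core_model):
        before = core_model.reaction("EDD").upper_bound
        knockout(core_model, genes={"edd"})
        assert core_model.reaction("EDD").upper_bound == before

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.data())
    def test_monotone_and_idempotent(self, core_model, data):
        genes = sorted(core_model.genes)
        a = data.draw(st.sets(st.sampled_from(genes), max_size=4))
        b = data.draw(st.sets(st.sampled_from(genes), max_size=4))
        dead = lambda m: {r.id for r in m.reactions
                          if r.lower_bound == r.upper_bound == 0.0}
        ko_a = knockout(core_model, genes=a)
        ko_ab = knockout(core_model, genes=a | b)
        assert dead(ko_a) <= dead(ko_ab)
        twice = knockout(ko_a, genes=a)
        assert dead(twice) == dead(ko_a)


class TestSetMedium:
    def test_sources_opened_others_closed(self, core_model):
        m = set_medium(core_model, {"EX_glcn", "EX_meoh"}, 7.0)
        assert m.reaction("EX_glcn").lower_bound == -7.0
        assert m.reaction("EX_meoh").lower_bound == -7.0
        assert m.reaction("EX_glc").lower_bound == 0.0      # carbon, unlisted
        assert m.reaction("EX_co2").lower_bound == 0.0      # CO2 is carbon
        assert m.reaction("EX_o2").lower_bound == -1000.0   # nutrient stays open
        assert all(r.upper_bound >= 0 for r in m.exchanges())  # secretion allowed

    def test_empty_sources_means_no_growth(self, core_model):
        m = set_medium(core_model, set(), 7.0)
        assert maximize_growth(m).growth_rate == pytest.approx(0.0, abs=1e-9)

    def test_zero_rate_equivalent_to_no_sources(self, core_model):
        m = set_medium(core_model, {"EX_glcn"}, 0.0)
        assert maximize_growth(m).growth_rate == pytest.approx(0.0, abs=1e-9)

    def test_non_exchange_rejected(self, core_model):
        with pytest.raises(ValueError):
            set_medium(core_model, {"PGI"}, 7.0)


class TestHeterologousPathway:
    def test_adds_three_carbon_balanced_reactions(self, core_model):
        aug = add_heterologous_reactions(core_model)
        assert len(aug.reactions) == len(core_model.reactions) + 3
        for rid in ("MDH", "HPS", "PHI"):
            assert carbon_balance(aug, rid) == pytest.approx(0.0, abs=1e-12)
        # MDH chemistry: methanol + NAD+ -> formaldehyde + NADH + H+
        mdh = aug.reaction("MDH").stoichiometry
        assert mdh["meoh"] == -1 and mdh["nad"] == -1
        assert mdh["fald"] == 1 and mdh["nadh"] == 1 and mdh["h"] == 1

    def test_double_application_collides(self, core_model):
        aug = add_heterologous_reactions(core_model)
        with pytest.raises(ModelValidationError, match="MDH"):
            add_heterologous_reactions(aug)

    def test_missing_species_reported(self, core_model):
        stripped = MetabolicModel(
            [m for m in core_model.metabolites if m.id != "fald"],
            [r for r in core_model.reactions if "fald" not in r.stoichiometry],
            core_model.objective_reaction_id,
            genes=core_model.genes,
        )
        with pytest.raises(ModelValidationError, match="fald"):
            add_heterologous_reactions(stripped)


class TestStoichiometricMatrix:
    def test_two_reaction_chain(self):
        S = stoichiometric_matrix(two_reaction_chain())
        assert S.loc["A", "R1"] == -1 and S.loc["B", "R1"] == 1
        assert S.loc["B", "EX_B"] == -1 and S.loc["A", "EX_B"] == 0
        np.testing.assert_array_equal(S.to_numpy(), [[-1, 0], [1, -1]])

    def test_one_column_per_reaction(self, core_model):
        S = stoichiometric_matrix(core_model)
        assert list(S.columns) == core_model.reaction_ids
        assert S.shape == (len(core_model.metabolites), len(core_model.reactions))

    def test_internal_reactions_carbon_balanced(self, augmented_model):
        """Carbon-weighted column sums vanish for every internal reaction."""
        m = augmented_model
        for rxn in m.internal_reactions():
            assert carbon_balance(m, rxn.id) == pytest.approx(0.0, abs=1e-9), rxn.id


class TestGeneLevelReporting:
    def test_edd_rpi_maps_to_three_genes(self, core_model):
        sets = minimal_gene_sets(core_model, {"EDD", "RPI"})
        assert sets[0] == frozenset({"edd", "rpiA", "rpiB"})

    def test_overkilling_combinations_excluded(self, core_model):
        # tktA/tktB deactivate both TKT1 and TKT2; deleting TKT1 "exactly"
        # is therefore impossible at gene level
        assert minimal_gene_sets(core_model, {"TKT1"}) == []

    def test_spontaneous_reaction_has_no_gene_set(self, core_model):
        assert minimal_gene_sets(core_model, {"MEOHt"}) == []
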