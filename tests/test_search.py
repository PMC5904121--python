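"""Methanol-essentiality classification, screening, ranking and beam search."""

import numpy as np
import pytest

from meflux.search import (
    METHANOL_ESSENTIAL,
    NEUTRAL,
    NON_RESCUABLE,
    KnockoutGenotype,
    SearchConfig,
    classify_knockout,
    iterative_search,
    rank_differential_fitness,
    screen_single_knockouts,
    verify_reaction_dispensability,
)


class TestClassification:
    def test_edd_rpi_is_methanol_essential(self, augmented_model, search_config):
        g = classify_knockout(augmented_model, {"EDD", "RPI"}, "EX_glcn", search_config)
        assert g.classification == METHANOL_ESSENTIAL
        assert g.mu_co <= search_config.growth_threshold
        assert g.mu_co_meoh > search_config.growth_threshold
        assert g.mu_meoh > search_config.growth_threshold
        assert g.deleted_genes == frozenset({"edd", "rpiA", "rpiB"})

    def test_transporter_knockout_is_non_rescuable(self, augmented_model, search_config):
        """Cutting gluconate entry is not rescued: the strain merely grows
        methylotrophically, with no benefit from the co-substrate."""
        for rid in ("GNTt", "GNTK"):
            g = classify_knockout(augmented_model, {rid}, "EX_glcn", search_config)
            assert g.classification == NON_RESCUABLE
            assert g.mu_co_meoh == pytest.approx(g.mu_meoh, abs=1e-6)

    def test_empty_knockout_is_neutral(self, augmented_model, search_config):
        g = classify_knockout(augmented_model, set(), "EX_glcn", search_config)
        assert g.classification == NEUTRAL
        assert g.mu_co > search_config.growth_threshold
        assert g.differential_score == pytest.approx(g.mu_co_meoh - g.mu_co)

    def test_both_6pg_exits_cut_blocks_gluconate(self, augmented_model, search_config):
        g = classify_knockout(augmented_model, {"EDD", "GND"}, "EX_glcn", search_config)
        assert g.mu_co <= search_config.growth_threshold
        assert g.classification == NON_RESCUABLE  # gluconate unusable even with MeOH

    def test_unknown_reaction_raises(self, augmented_model, search_config):
        with pytest.raises(KeyError):
            classify_knockout(augmented_model, {"NOPE"}, "EX_glcn", search_config)


class TestSingleKnockoutScreen:
    def test_no_single_knockout_is_methanol_essential(self, augmented_model, search_config):
        singles = screen_single_knockouts(augmented_model, set(), "EX_glcn", search_config)
        assert len(singles) == len(augmented_model.internal_reactions())
        assert not any(g.classification == METHANOL_ESSENTIAL for g in singles)

    def test_rpi_completes_a_fixed_edd_background(self, augmented_model, search_config):
        completions = screen_single_knockouts(
            augmented_model, {"EDD"}, "EX_glcn", search_config
        )
        by_id = {g.deleted_reactions: g for g in completions}
        assert by_id[frozenset({"EDD", "RPI"})].classification == METHANOL_ESSENTIAL

    def test_results_ordered_by_reaction_id(self, augmented_model, search_config):
        singles = screen_single_knockouts(augmented_model, set(), "EX_glcn", search_config)
        ids = [sorted(g.deleted_reactions)[0] for g in singles]
        assert ids == sorted(ids)

    def test_blocked_carbon_entry_leaves_no_rescuable_candidates(
        self, augmented_model, search_config
    ):
        singles = screen_single_knockouts(
            augmented_model, {"GNTt", "GNTK"}, "EX_glcn", search_config
        )
        assert all(g.classification == NON_RESCUABLE for g in singles)


class TestRanking:
    @staticmethod
    def _genotype(rxns, mu_co, mu_mix, label=NEUTRAL):
        return KnockoutGenotype(frozenset(rxns), frozenset(), mu_co, mu_mix, 0.2, label)

    def test_descending_score_with_lexicographic_ties(self):
        a = self._genotype({"B"}, 0.5, 0.8)
        b = self._genotype({"A"}, 0.5, 0.8)
        c = self._genotype({"C"}, 0.5, 0.6)
        assert rank_differential_fitness([c, a, b]) == [b, a, c]

    def test_non_rescuable_excluded(self):
        dead = self._genotype({"X"}, 0.0, 0.0, NON_RESCUABLE)
        live = self._genotype({"Y"}, 0.5, 0.7)
        assert rank_differential_fitness([dead, live]) == [live]

    def test_all_non_rescuable_gives_empty_ranking(self):
        dead = self._genotype({"X"}, 0.0, 0.0, NON_RESCUABLE)
        assert rank_differential_fitness([dead]) == []


class TestIterativeSearch:
    def test_gluconate_yields_the_edd_rpi_design(self, augmented_model, search_config):
        report = iterative_search(augmented_model, "EX_glcn", search_config)
        sets = {g.deleted_reactions for g in report.genotypes}
        assert frozenset({"EDD", "RPI"}) in sets
        anchor = next(g for g in report.genotypes
                      if g.deleted_reactions == frozenset({"EDD", "RPI"}))
        assert anchor.deleted_genes == frozenset({"edd", "rpiA", "rpiB"})
        # solutions appear at the minimal depth (pairs), so the trace has 2 levels
        assert len(report.trace) == 2
        assert all(len(g.deleted_reactions) == 2 for g in report.genotypes)

    @pytest.mark.parametrize("source", ["EX_glc", "EX_xyl"])
    def test_most_co_substrates_lack_single_knockout_solutions(
        self, augmented_model, source
    ):
        config = SearchConfig(max_depth=1)
        report = iterative_search(augmented_model, source, config)
        assert report.genotypes == []
        assert len(report.trace) == 1  # trace retained on failure

    def test_acetate_exception_tca_exit_cuts(self, augmented_model):
        """Acetate is the one co-substrate with single-reaction solutions:
        the glyoxylate shunt's net output (succinate) must re-enter C4
        metabolism through succinate dehydrogenase and fumarase, so cutting
        either couples acetate growth to methanol-fed anaplerosis."""
        config = SearchConfig(max_depth=1)
        report = iterative_search(augmented_model, "EX_ac", config)
        sets = sorted(sorted(g.deleted_reactions) for g in report.genotypes)
        assert sets == [["FUM"], ["SUCDH"]]

    def test_determinism_byte_identical_reports(self, augmented_model, search_config):
        r1 = iterative_search(augmented_model, "EX_glcn", search_config)
        r2 = iterative_search(augmented_model, "EX_glcn", search_config)
        assert r1.to_json() == r2.to_json()

    def test_reported_genotypes_reverify_soundness(self, augmented_model, search_config):
        report = iterative_search(augmented_model, "EX_glcn", search_config)
        eps = search_config.growth_threshold
        for g in report.genotypes:
            check = classify_knockout(
                augmented_model, g.deleted_reactions, "EX_glcn", search_config
            )
            assert check.classification == METHANOL_ESSENTIAL
            assert check.mu_co <= eps < check.mu_co_meoh
            assert check.mu_meoh > eps


class TestMonotonicity:
    def test_adding_methanol_never_reduces_growth(self, augmented_model, search_config):
        """mu_co <= mu_co+MeOH: an extra substrate only relaxes the LP."""
        rng = np.random.default_rng(7)
        ids = sorted(r.id for r in augmented_model.internal_reactions())
        for _ in range(20):
            ko = set(rng.choice(ids, size=2, replace=False))
            g = classify_knockout(augmented_model, ko, "EX_glcn", search_config)
            assert g.mu_co <= g.mu_co_meoh + 1e-7


class TestDispensability:
    def test_maldh_dispensable_on_gluconate_plus_methanol(
        self, augmented_model, search_config
    ):
        """A closed oxidative TCA cycle is not required for mixed growth:
        the Delta-maldh design on top of Delta-edd Delta-rpi still grows."""
        ok, mu = verify_reaction_dispensability(
            augmented_model, {"MALDH", "EDD", "RPI"}, {"EX_glcn", "EX_meoh"},
            search_config,
        )
        assert ok and mu > search_config.growth_threshold

    def test_sole_precursor_route_not_dispensable(self, augmented_model, search_config):
        # citrate synthase is the only path to 2-oxoglutarate
        ok, mu = verify_reaction_dispensability(
            augmented_model, {"CS"}, {"EX_glcn", "EX_meoh"}, search_config
        )
        assert not ok and mu <= search_config.growth_threshold

    def test_empty_set_dispensable_when_base_grows(self, augmented_model, search_config):
        ok, _ = verify_reaction_dispensability(
            augmented_model, set(), {"EX_glcn"}, search_config
        )
        assert ok
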