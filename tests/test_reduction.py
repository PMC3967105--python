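import cobra
import pytest

import fastpros as fp
from fastpros.reduction import _gpr_dnf


def _chain_model():
    """X --(R_a)--> 2 Y --(R_b)--> Z chain feeding a drain, for lumping."""
    model = cobra.Model("CHAIN")
    X = cobra.Metabolite("X_c", compartment="c")
    Y = cobra.Metabolite("Y_c", compartment="c")
    Z = cobra.Metabolite("Z_c", compartment="c")
    for rid, stoich, lb, ub, gene in [
        ("EX_X", {X: -1}, -10, 0, ""),
        ("R_a", {X: -1, Y: 2}, 0, fp.BIG, "ga"),
        ("R_b", {Y: -1, Z: 1}, 0, fp.BIG, "gb"),
        ("GROWTH", {Z: -1}, 0, fp.BIG, ""),
    ]:
        rxn = cobra.Reaction(rid, lower_bound=lb, upper_bound=ub)
        model.add_reactions([rxn])
        rxn.add_metabolites(stoich)
        if gene:
            rxn.gene_reaction_rule = gene
    model.objective = "GROWTH"
    return model


class TestFluxVariability:
    def test_toy1_growth_range(self, toy1, toy_env):
        fva = fp.flux_variability(toy1, toy_env)
        assert fva.at["GROWTH", "maximum"] == pytest.approx(10.0, abs=1e-6)
        assert (fva["minimum"] <= fva["maximum"] + 1e-9).all()

    def test_dead_end_reaction_blocked(self, toy1, toy_env):
        X = cobra.Metabolite("X_c", compartment="c")
        dead = cobra.Reaction("DEAD", lower_bound=0, upper_bound=fp.BIG)
        toy1.add_reactions([dead])
        dead.add_metabolites({toy1.metabolites.B_c: -1, X: 1})
        fva = fp.flux_variability(toy1, toy_env)
        assert fva.at["DEAD", "minimum"] == pytest.approx(0.0, abs=1e-9)
        assert fva.at["DEAD", "maximum"] == pytest.approx(0.0, abs=1e-9)

    def test_infeasible_model_raises(self, toy1, toy_env):
        toy1.reactions.GROWTH.lower_bound = 100.0
        with pytest.raises(fp.InfeasibleModelError):
            fp.flux_variability(toy1, toy_env)


class TestRemoveBlocked:
    def test_dead_end_removed_and_optima_preserved(self, toy1, toy_env):
        X = cobra.Metabolite("X_c", compartment="c")
        dead = cobra.Reaction("DEAD", lower_bound=0, upper_bound=fp.BIG)
        toy1.add_reactions([dead])
        dead.add_metabolites({toy1.metabolites.B_c: -1, X: 1})
        fva = fp.flux_variability(toy1, toy_env)
        reduced, rmap = fp.remove_blocked(toy1, fva)
        assert rmap.removed_blocked == ["DEAD"]
        assert "DEAD" not in [r.id for r in reduced.reactions]
        before = fp.maximize_biomass(toy1, toy_env).objective_value
        after = fp.maximize_biomass(reduced, toy_env).objective_value
        assert after == pytest.approx(before, abs=1e-6)

    def test_unblocked_model_unchanged(self, toy1, toy_env):
        fva = fp.flux_variability(toy1, toy_env)
        reduced, rmap = fp.remove_blocked(toy1, fva)
        assert rmap.removed_blocked == []
        assert len(reduced.reactions) == len(toy1.reactions)

    def test_mismatched_fva_table_rejected(self, toy1, toy_env):
        fva = fp.flux_variability(toy1, toy_env)
        other = _chain_model()
        with pytest.raises(KeyError):
            fp.remove_blocked(other, fva)


class TestLumpLinearPathways:
    def test_chain_with_stoichiometry_merges_with_scale(self, toy_env):
        model = _chain_model()
        env = fp.toy_environment()
        env.glucose_exchange = "EX_X"
        reduced, rmap = fp.lump_linear_pathways(model)
        lumps = [rid for rid in rmap.lumped_to_original]
        assert len(lumps) == 1
        members = dict(rmap.lumped_to_original[lumps[0]])
        # v_Rb = 2 v_Ra through the unbranched Y node
        assert members["R_a"] == pytest.approx(1.0)
        assert members["R_b"] == pytest.approx(2.0)
        # X -> 2 Z overall and the growth optimum is preserved
        lump = reduced.reactions.get_by_id(lumps[0])
        coeffs = {m.id: c for m, c in lump.metabolites.items()}
        assert coeffs == {"X_c": pytest.approx(-1.0), "Z_c": pytest.approx(2.0)}
        g0 = model.slim_optimize()
        g1 = reduced.slim_optimize()
        assert g1 == pytest.approx(g0, abs=1e-6)

    def test_toy1_has_nothing_to_lump(self, toy1):
        reduced, rmap = fp.lump_linear_pathways(toy1)
        assert rmap.lumped_to_original == {}
        assert len(reduced.reactions) == len(toy1.reactions)

    def test_fixpoint(self):
        model = _chain_model()
        once, _ = fp.lump_linear_pathways(model)
        twice, rmap = fp.lump_linear_pathways(once)
        assert rmap.lumped_to_original == {}
        assert len(twice.reactions) == len(once.reactions)

    def test_lumped_gene_rule_requires_both_genes(self):
        model = _chain_model()
        reduced, rmap = fp.lump_linear_pathways(model)
        lump = reduced.reactions.get_by_id(next(iter(rmap.lumped_to_original)))
        assert {g.id for g in lump.genes} == {"ga", "gb"}


class TestKnockoutUnits:
    def test_same_gene_set_reactions_grouped(self, toy1, toy_env):
        # two transketolase-style reactions sharing an identical gene set
        toy1.reactions.R2.gene_reaction_rule = "tktA and tktB"
        toy1.reactions.R3.gene_reaction_rule = "tktA and tktB"
        units = fp.build_knockout_units(toy1, toy_env)
        grouped = [u for u in units if u.member_reactions == {"R2", "R3"}]
        assert len(grouped) == 1
        assert grouped[0].knockable
        assert grouped[0].gene_sets == frozenset({frozenset({"tktA", "tktB"})})

    def test_isozyme_rules_with_same_dnf_group(self, toy1, toy_env):
        toy1.reactions.R2.gene_reaction_rule = "g9 or g8"
        toy1.reactions.R3.gene_reaction_rule = "g8 or g9"
        units = fp.build_knockout_units(toy1, toy_env)
        assert any(u.member_reactions == {"R2", "R3"} for u in units)

    def test_protected_genes_mark_unit_non_knockable(self, toy1, toy_env):
        toy1.reactions.R2.gene_reaction_rule = "gapA"
        units = fp.build_knockout_units(toy1, toy_env)
        unit = next(u for u in units if "R2" in u.member_reactions)
        assert not unit.knockable

    def test_structural_reactions_not_knockable(self, toy1, toy_env):
        units = fp.build_knockout_units(toy1, toy_env)
        knockable = {u.unit_id for u in units if u.knockable}
        assert knockable == {"R1", "R2", "R3", "R5"}
        non_knockable = {u.unit_id for u in units if not u.knockable}
        assert {"GROWTH", "EX_A", "EX_O2", "EX_T", "EX_F"} <= non_knockable

    def test_unit_partition_is_disjoint_and_complete(self, random_toys_20):
        env, models = random_toys_20
        for model in models[:5]:
            units = fp.build_knockout_units(model, env)
            seen = set()
            for unit in units:
                assert not (unit.member_reactions & seen)
                seen |= unit.member_reactions
            assert seen == {r.id for r in model.reactions}


class TestGprDnf:
    @pytest.mark.parametrize(
        "rule,expected",
        [
            ("g1", {frozenset({"g1"})}),
            ("g1 or g2", {frozenset({"g1"}), frozenset({"g2"})}),
            ("g1 and g2", {frozenset({"g1", "g2"})}),
            (
                "(g1 and g2) or (g3 and g4)",
                {frozenset({"g1", "g2"}), frozenset({"g3", "g4"})},
            ),
            (
                "g1 and (g2 or g3)",
                {frozenset({"g1", "g2"}), frozenset({"g1", "g3"})},
            ),
        ],
    )
    def test_dnf_expansion(self, rule, expected):
        rxn = cobra.Reaction("R")
        model = cobra.Model("m")
        model.add_reactions([rxn])
        rxn.gene_reaction_rule = rule
        assert _gpr_dnf(rxn) == frozenset(expected)


class TestReductionEquivalence:
    def test_full_reduction_preserves_optima_and_knockout_phenotypes(
        self, random_toys_20
    ):
        """Growth and lexicographic target optima agree before/after
        reduction, for the wild type and for every single knockout unit
        mapped back to the original reactions."""
        env, models = random_toys_20
        for model in models[:8]:
            reduced = fp.reduce_model(model, env)
            g0 = fp.maximize_biomass(model, env).objective_value
            g1 = fp.maximize_biomass(reduced.model, env).objective_value
            assert g1 == pytest.approx(g0, abs=1e-6)
            l0 = fp.lexicographic_target_max(model, env, "T_c")
            l1 = fp.lexicographic_target_max(reduced.model, env, "T_c")
            assert l1[0] == pytest.approx(l0[0], abs=1e-6)
            assert l1[1] == pytest.approx(l0[1], abs=1e-6)
            for unit in reduced.knockable_units:
                original = fp.map_knockouts_to_original(reduced.map, [unit])
                a = fp.lexicographic_target_max(
                    reduced.model, env, "T_c", unit.member_reactions
                )
                b = fp.lexicographic_target_max(model, env, "T_c", original)
                assert a[0] == pytest.approx(b[0], abs=1e-6, nan_ok=True)
                assert a[1] == pytest.approx(b[1], abs=1e-6, nan_ok=True)
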