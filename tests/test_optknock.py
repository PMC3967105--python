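import math

import pytest

import fastpros as fp

THIRD = 10.0 / 3.0


def knockable(model):
    return [u for u in fp.default_toy_units(model) if u.knockable]


class TestOptKnockToy1:
    @pytest.mark.parametrize("backend", ["enumeration", "milp"])
    def test_k1_selects_the_vent(self, toy1, toy_env, backend):
        res = fp.optknock(toy1, toy_env, "T_c", knockable(toy1), 1, backend=backend)
        assert res.status == "optimal"
        assert res.knockout_units == {"R2"}
        assert res.target_flux_at_biomass_max == pytest.approx(THIRD, abs=1e-6)
        assert res.yield_fraction_tmy == pytest.approx(0.5, abs=1e-6)

    def test_k0_wild_type_not_coupled(self, toy1, toy_env):
        res = fp.optknock(toy1, toy_env, "T_c", knockable(toy1), 0)
        assert res.status == "optimal"
        assert res.knockout_units == frozenset()
        assert res.target_flux_at_biomass_max == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("backend", ["enumeration", "milp"])
    def test_withholding_the_vent_gives_no_coupling(self, toy1, toy_env, backend):
        units = [u for u in knockable(toy1) if u.unit_id != "R2"]
        res = fp.optknock(toy1, toy_env, "T_c", units, 1, backend=backend)
        assert res.target_flux_at_biomass_max == pytest.approx(0.0, abs=1e-6)

    def test_negative_k_rejected(self, toy1, toy_env):
        with pytest.raises(ValueError):
            fp.optknock(toy1, toy_env, "T_c", knockable(toy1), -1)

    def test_audit_matches_plain_fba(self, toy1, toy_env):
        res = fp.optknock(toy1, toy_env, "T_c", knockable(toy1), 1)
        growth, flux = fp.lexicographic_target_max(
            toy1, toy_env, "T_c", res.knockout_reactions, enforce_min_growth=True
        )
        assert res.growth == pytest.approx(growth, abs=1e-9)
        assert res.target_flux_at_biomass_max == pytest.approx(flux, abs=1e-9)

    def test_monotone_in_k(self, toy1, toy_env):
        fluxes = [
            fp.optknock(toy1, toy_env, "T_c", knockable(toy1), k).target_flux_at_biomass_max
            for k in (0, 1, 2, 3)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(fluxes, fluxes[1:]))

    def test_restriction_dominance(self, toy1, toy_env):
        all_units = knockable(toy1)
        subset = [u for u in all_units if u.unit_id in {"R3", "R5"}]
        small = fp.optknock(toy1, toy_env, "T_c", subset, 2)
        big = fp.optknock(toy1, toy_env, "T_c", all_units, 2)
        assert small.target_flux_at_biomass_max <= big.target_flux_at_biomass_max + 1e-9


class TestMilpEqualsEnumeration:
    def test_exact_objective_match_on_random_toys(self, random_toys_20):
        """Strong-duality MILP and exhaustive lexicographic FBA agree on
        the optimal growth-coupled production flux for K <= 3."""
        env, models = random_toys_20
        for model in models[:6]:
            units = knockable(model)
            for k in (1, 3):
                enum = fp.optknock(model, env, "T_c", units, k, backend="enumeration")
                milp = fp.optknock(model, env, "T_c", units, k, backend="milp")
                assert milp.status == enum.status
                assert milp.target_flux_at_biomass_max == pytest.approx(
                    enum.target_flux_at_biomass_max, abs=1e-6
                )

    def test_auto_backend_uses_enumeration_at_small_scale(self, toy1, toy_env):
        res = fp.optknock(toy1, toy_env, "T_c", knockable(toy1), 2, backend="auto")
        assert res.backend == "enumeration"


class TestCandidateSelection:
    def test_toy1_selects_the_single_coupling_unit(self, toy1, toy_env):
        units = fp.default_toy_units(toy1)
        screening = fp.screen(toy1, toy_env, "T_c", units)
        selected = fp.select_candidate_reactions(
            screening, toy1, toy_env, "T_c", units
        )
        ids = [u.unit_id for u in selected]
        assert ids[0] == "R2"  # best yield contributor ranks first
        assert set(ids) <= {"R2", "R3"}

    def test_top_n_truncates(self, toy1, toy_env):
        units = fp.default_toy_units(toy1)
        screening = fp.screen(toy1, toy_env, "T_c", units)
        selected = fp.select_candidate_reactions(
            screening, toy1, toy_env, "T_c", units, top_n=1
        )
        assert [u.unit_id for u in selected] == ["R2"]

    def test_empty_screening_returns_empty_list(self, toy1, toy_env):
        empty = fp.ScreeningResult(target="T_c")
        units = fp.default_toy_units(toy1)
        assert fp.select_candidate_reactions(empty, toy1, toy_env, "T_c", units) == []


class TestPipelineCombination:
    def test_toy1_yield_fraction_half(self, toy1, toy_env):
        results = fp.fastpros_then_optknock(
            toy1, toy_env, "T_c", fp.default_toy_units(toy1), k_list=[1]
        )
        assert results[1].status == "optimal"
        assert results[1].yield_fraction_tmy == pytest.approx(0.5, abs=1e-6)

    def test_k_list_produces_one_result_per_k(self, toy1, toy_env):
        results = fp.fastpros_then_optknock(
            toy1, toy_env, "T_c", fp.default_toy_units(toy1), k_list=[1, 2, 3]
        )
        assert sorted(results) == [1, 2, 3]

    def test_uncoupled_target_reports_no_candidates(self, toy1):
        # with a growth floor close to the wild-type optimum, every
        # knockout that could couple substrate export is infeasible and
        # the screen stores no candidate
        env = fp.toy_environment()
        env.min_growth = 9.0
        fp.add_target_exporter(toy1, "A_c")
        results = fp.fastpros_then_optknock(
            toy1, env, "A_c", fp.default_toy_units(toy1), k_list=[1]
        )
        assert results[1].status == "no_candidates"
        assert results[1].yield_fraction_tmy == 0.0
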