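import pytest

import fastpros as fp


class TestScreenToy1:
    def test_finds_the_minimal_vent_knockout(self, toy1, toy_env):
        units = fp.default_toy_units(toy1)
        result = fp.screen(toy1, toy_env, "T_c", units)
        assert frozenset({"R2"}) in result.candidate_units
        assert result.min_knockouts == 1
        # the unique size-1 producing set was found in the seed generation
        assert all(len(s) >= 1 for s in result.candidate_units)

    def test_every_candidate_confirmed_by_direct_fba(self, toy1, toy_env):
        units = fp.default_toy_units(toy1)
        by_id = {u.unit_id: u for u in units}
        result = fp.screen(toy1, toy_env, "T_c", units)
        for rec in result.candidates:
            reactions = frozenset(
                r for uid in rec.knockouts for r in by_id[uid].member_reactions
            )
            _, flux = fp.lexicographic_target_max(
                toy1, toy_env, "T_c", reactions, enforce_min_growth=True
            )
            if rec.classification == "positive":
                assert flux > 1e-9
            else:  # zero class: production free of growth cost
                assert flux >= -1e-9

    def test_candidate_scores_non_negative(self, toy1, toy_env):
        units = fp.default_toy_units(toy1)
        result = fp.screen(toy1, toy_env, "T_c", units)
        for rec in result.candidates:
            assert rec.f_target >= -1e-9

    def test_deterministic(self, toy1, toy_env):
        units = fp.default_toy_units(toy1)
        a = fp.screen(toy1, toy_env, "T_c", units)
        b = fp.screen(toy1, toy_env, "T_c", units)
        assert a.candidate_units == b.candidate_units
        assert [
            [(e.unit_ids, e.score) for e in gen] for gen in a.generations
        ] == [[(e.unit_ids, e.score) for e in gen] for gen in b.generations]

    def test_beam_monotonicity_along_lineages(self, toy1, toy_env):
        """Along any surviving lineage the score strictly increases."""
        units = fp.default_toy_units(toy1)
        result = fp.screen(toy1, toy_env, "T_c", units)
        for g in range(1, len(result.generations)):
            previous = {e.unit_ids: e.score for e in result.generations[g - 1]}
            for entry in result.generations[g]:
                assert entry.parent in previous
                assert entry.score > previous[entry.parent]

    def test_no_knockable_units_raises(self, toy1, toy_env):
        units = [u for u in fp.default_toy_units(toy1) if not u.knockable]
        with pytest.raises(ValueError, match="no knockable"):
            fp.screen(toy1, toy_env, "T_c", units)

    def test_score_cache_bounds_lp_evaluations(self, toy1, toy_env):
        units = fp.default_toy_units(toy1)
        result = fp.screen(toy1, toy_env, "T_c", units)
        n = len([u for u in units if u.knockable])
        # unique sets of size 1 and 2 bound the solves with start_depth 1
        assert result.evaluations <= n + n * (n - 1) // 2


class TestScreeningConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            fp.ScreeningConfig(max_knockouts=0, start_depth=1)
        with pytest.raises(ValueError):
            fp.ScreeningConfig(start_depth=3)
        with pytest.raises(ValueError):
            fp.ScreeningConfig(parents_p=0)

    def test_start_depth_two_finds_pair_seeded_candidates(self, toy1, toy_env):
        units = fp.default_toy_units(toy1)
        cfg = fp.ScreeningConfig(start_depth=2)
        result = fp.screen(toy1, toy_env, "T_c", units, cfg)
        # every candidate now has >= 2 knockouts and contains the vent
        assert result.min_knockouts == 2
        assert all("R2" in s for s in result.candidate_units)

    def test_narrow_beam_still_deterministic(self, toy1, toy_env):
        units = fp.default_toy_units(toy1)
        cfg = fp.ScreeningConfig(parents_p=1)
        a = fp.screen(toy1, toy_env, "T_c", units, cfg)
        b = fp.screen(toy1, toy_env, "T_c", units, cfg)
        assert a.candidate_units == b.candidate_units


class TestHistogram:
    def test_counts_by_minimum_size(self, toy1, toy_env):
        units = fp.default_toy_units(toy1)
        res = fp.screen(toy1, toy_env, "T_c", units)
        hist, missing = fp.min_knockout_histogram({"T_c": res, "T2": res})
        assert hist == {1: 2}
        assert missing == []

    def test_targets_without_candidates_reported_separately(self, toy1, toy_env):
        res = fp.ScreeningResult(target="empty")
        ok = fp.screen(toy1, toy_env, "T_c", fp.default_toy_units(toy1))
        hist, missing = fp.min_knockout_histogram({"T_c": ok, "empty": res})
        assert hist == {1: 1}
        assert missing == ["empty"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fp.min_knockout_histogram({})


class TestOracleEquivalence:
    def test_screen_recovers_all_minimal_sets_on_certified_toys(
        self, random_toys_20
    ):
        """On certified random fixtures, the beam search finds every
        minimal producing set of size <= 3 known to the exhaustive
        oracle, and every stored candidate is producing."""
        env, models = random_toys_20
        for model in models[:6]:
            units = fp.default_toy_units(model)
            by_id = {u.unit_id: u for u in units}
            oracle = fp.brute_force_screen(model, env, "T_c", units, max_k=3)
            result = fp.screen(model, env, "T_c", units)
            found = set(result.candidate_units)
            for minimal in oracle.minimal:
                assert minimal in found
            for rec in result.candidates:
                if rec.classification == "positive":
                    reactions = frozenset(
                        r for uid in rec.knockouts
                        for r in by_id[uid].member_reactions
                    )
                    _, flux = fp.lexicographic_target_max(
                        model, env, "T_c", reactions, enforce_min_growth=True
                    )
                    assert flux > 1e-9
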