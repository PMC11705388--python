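"""Optimizer: penalties, objectives, dominance machinery, evolutionary search."""

import numpy as np
import pandas as pd
import pytest

from cropswitch import build_default_cfts, gen_region, gen_suitability
from cropswitch.cfts import DEMAND_CATEGORIES
from cropswitch.demand import DemandSet
from cropswitch.optimize import (
    CountyWeights,
    ObjectiveVector,
    OptimizationProblem,
    OptimizerConfig,
    PenaltyConfig,
    compute_weights,
    crop_production,
    evaluate_objectives,
    evolve,
    nondominated_sort,
    reference_points,
    repair_allocation,
    self_sufficiency_factor,
    supply_chain_penalty,
)
from cropswitch.synthetic import Allocation, Region

from conftest import naive_front_peel


def _demand(values):
    return DemandSet(
        year=0,
        by_category=dict(zip(DEMAND_CATEGORIES, values)),
        per_capita={},
    )


class TestSelfSufficiency:
    def test_minimum_capped_ratio(self):
        p = self_sufficiency_factor(
            np.array([90.0, 10.0, 5.0, 8.0, 6.0]),
            _demand([100.0, 50.0, 5.0, 8.0, 6.0]),
        )
        assert p == pytest.approx(0.2)

    def test_full_sufficiency(self):
        d = _demand([10.0, 20.0, 30.0, 40.0, 50.0])
        assert self_sufficiency_factor(np.array([10.0, 20.0, 30.0, 40.0, 50.0]), d) == 1.0

    def test_zero_production_absorbs(self):
        d = _demand([1.0] * 5)
        assert self_sufficiency_factor(np.array([0.0, 5.0, 5.0, 5.0, 5.0]), d) == 0.0

    def test_oversupply_not_rewarded(self):
        d = _demand([1.0] * 5)
        assert self_sufficiency_factor(np.array([100.0] * 5), d) == 1.0

    def test_zero_demand_rejected(self):
        with pytest.raises(ValueError):
            self_sufficiency_factor(np.ones(5), _demand([1.0, 0.0, 1.0, 1.0, 1.0]))


class TestSupplyChainPenalty:
    def test_single_loss(self):
        base = np.array([10.0, 8.0, 1, 1, 1, 1, 1])
        cur = np.array([9.0, 9.0, 1, 1, 1, 1, 1])
        assert supply_chain_penalty(cur, base) == pytest.approx(1.0)

    def test_no_loss(self):
        base = np.full(7, 5.0)
        assert supply_chain_penalty(base + 1.0, base) == 0.0

    def test_two_losses(self):
        base = np.array([10.0, 8.0, 0, 0, 0, 0, 0])
        cur = np.array([8.0, 6.0, 0, 0, 0, 0, 0])
        assert supply_chain_penalty(cur, base) == pytest.approx(8.0)

    def test_deepening_loss_never_decreases(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(1, 10, 7)
        cur = rng.uniform(1, 10, 7)
        p0 = supply_chain_penalty(cur, base)
        cur2 = cur.copy()
        cur2[3] -= 0.5
        assert supply_chain_penalty(cur2, base) >= p0


class TestWeights:
    def test_minmax_ln(self):
        region = gen_region(3, 1, seed=1)
        region.counties["n_surplus"] = [0.0, 5.0, 10.0]
        w = compute_weights(region)
        np.testing.assert_allclose(w.ln, [0.0, 0.5, 1.0])

    def test_tws_inversion(self):
        region = gen_region(2, 1, seed=1)
        region.counties["tws"] = [0.0, 10.0]
        w = compute_weights(region)
        np.testing.assert_allclose(w.iwu, [1.0, 0.0])

    def test_wettest_county_smallest_weight(self, region10):
        w = compute_weights(region10)
        wettest = int(region10.counties["tws"].idxmax())
        assert w.iwu[wettest] == w.iwu.min()

    def test_identical_scores_uniform_half(self):
        region = gen_region(3, 1, seed=1)
        region.counties["n_surplus"] = 4.0
        region.counties["tws"] = 2.0
        w = compute_weights(region)
        np.testing.assert_allclose(w.ln, 0.5)
        np.testing.assert_allclose(w.iwu, 0.5)


class TestEvaluateObjectives:
    def _one_cell_problem(self):
        region = gen_region(1, 1, seed=1)
        region.counties.loc[0, "area_ha"] = 100.0
        region.cells["area_ha"] = [100.0]
        cfts = build_default_cfts().iloc[[0]].reset_index(drop=True)
        cfts.loc[0, "calories_kcal_t"] = 1e6
        from cropswitch.synthetic import SuitabilitySurface

        suit = SuitabilitySurface(
            yield_t_ha=np.array([[5.0]]),
            leach_kg_ha=np.array([[2.0]]),
            irrigation_mm=np.array([[30.0]]),
            fert_rate=np.array([305.0]),
        )
        alloc = Allocation(areas_ha=np.array([[100.0]]))
        return region, cfts, suit, alloc

    def test_hand_computed_cp(self):
        region, cfts, suit, alloc = self._one_cell_problem()
        w = CountyWeights(ln=np.zeros(1), iwu=np.zeros(1))
        obj = evaluate_objectives(
            alloc, suit, w, cfts, _demand([1.0] * 5), np.zeros(7),
            penalties=PenaltyConfig(use_sf=False, use_cp=False),
        )
        assert obj.raw_cp == pytest.approx(5e8)  # 100 ha × 5 t/ha × 1e6 kcal/t
        assert obj.f_cp == pytest.approx(5e8)

    def test_zero_weights_annihilate_environmental_objectives(self):
        region, cfts, suit, alloc = self._one_cell_problem()
        w = CountyWeights(ln=np.zeros(1), iwu=np.zeros(1))
        obj = evaluate_objectives(
            alloc, suit, w, cfts, _demand([1.0] * 5), np.zeros(7)
        )
        assert obj.f_ln == 0.0
        assert obj.f_iwu == 0.0

    def test_bilinearity_under_doubling(self, region10, cfts, baseline_alloc):
        suit = gen_suitability(region10, cfts, 305.0, seed=4)
        w = compute_weights(region10)
        demand = _demand([1e15, 1e14, 1e13, 1e13, 1e13])
        base_cp = crop_production(baseline_alloc, suit, cfts)
        obj1 = evaluate_objectives(
            baseline_alloc, suit, w, cfts, demand, base_cp
        )
        doubled = Allocation(areas_ha=2.0 * baseline_alloc.areas_ha)
        obj2 = evaluate_objectives(doubled, suit, w, cfts, demand, base_cp)
        assert obj2.raw_cp == pytest.approx(2.0 * obj1.raw_cp, rel=1e-12)
        assert obj2.f_ln == pytest.approx(2.0 * obj1.f_ln, rel=1e-12)
        assert obj2.f_iwu == pytest.approx(2.0 * obj1.f_iwu, rel=1e-12)

    def test_mismatched_indices_rejected(self, region10, cfts, baseline_alloc):
        suit = gen_suitability(region10, cfts, 305.0, seed=4)
        w = compute_weights(region10)
        bad = Allocation(areas_ha=baseline_alloc.areas_ha[:5])
        with pytest.raises(ValueError):
            evaluate_objectives(bad, suit, w, cfts, _demand([1.0] * 5), np.zeros(7))


class TestNondominatedSort:
    def test_three_point_example(self):
        F = np.array([[1, 1, 1], [2, 2, 2], [1, 2, 0]], dtype=float)
        fronts = nondominated_sort(F)
        assert sorted(fronts[0].tolist()) == [0, 2]
        assert fronts[1].tolist() == [1]

    def test_single_point(self):
        fronts = nondominated_sort(np.array([[3.0, 1.0, 2.0]]))
        assert fronts[0].tolist() == [0]

    def test_duplicates_share_front(self):
        F = np.array([[1.0, 1.0], [1.0, 1.0], [2.0, 2.0]])
        fronts = nondominated_sort(F)
        assert sorted(fronts[0].tolist()) == [0, 1]

    def test_empty_input(self):
        assert nondominated_sort([]) == []

    def test_objective_vectors_negate_cp(self):
        # higher F_CP is better: it must land in the first front
        a = ObjectiveVector(f_cp=10.0, f_ln=1.0, f_iwu=1.0, p_sf=1, p_cp=0)
        b = ObjectiveVector(f_cp=5.0, f_ln=1.0, f_iwu=1.0, p_sf=1, p_cp=0)
        fronts = nondominated_sort([a, b])
        assert fronts[0].tolist() == [0]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 200))
        F = rng.random((n, 3))
        fast = nondominated_sort(F)
        slow = naive_front_peel(F)
        assert len(fast) == len(slow)
        for f, s in zip(fast, slow):
            assert sorted(f.tolist()) == sorted(s.tolist())


class TestReferencePoints:
    def test_simplex_vertices(self):
        pts = reference_points(3, 1)
        expect = {(1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0)}
        assert {tuple(p) for p in pts} == expect

    def test_cardinality(self):
        assert len(reference_points(3, 2)) == 6
        assert len(reference_points(3, 4)) == 15

    def test_points_sum_to_one(self):
        pts = reference_points(3, 7)
        np.testing.assert_allclose(pts.sum(axis=1), 1.0, atol=1e-12)

    def test_invalid_args_rejected(self):
        with pytest.raises(ValueError):
            reference_points(1, 3)
        with pytest.raises(ValueError):
            reference_points(3, 0)


class TestRepair:
    def _region_area(self, s):
        region = gen_region(1, 1, seed=1)
        region.counties.loc[0, "area_ha"] = s
        return region

    def test_clip_and_renormalize(self):
        region = self._region_area(100.0)
        alloc = repair_allocation(np.array([[-0.1, 0.5, 0.6]]), region)
        np.testing.assert_allclose(
            alloc.areas_ha[0], [0.0, 100 * 5 / 11, 100 * 6 / 11]
        )

    def test_idempotent_on_simplex(self):
        region = self._region_area(50.0)
        raw = np.array([[0.2, 0.3, 0.5]])
        alloc = repair_allocation(raw, region)
        np.testing.assert_allclose(alloc.areas_ha[0], [10.0, 15.0, 25.0])

    def test_all_zero_uniform_fallback(self):
        region = self._region_area(110.0)
        alloc = repair_allocation(np.zeros((1, 11)), region)
        np.testing.assert_allclose(alloc.areas_ha[0], 10.0)


def _single_objective_problem(seed=11):
    cfts = build_default_cfts().iloc[[3, 10]].reset_index(drop=True)
    region = gen_region(1, 1, seed=seed)
    suit = gen_suitability(region, cfts, 305.0, sigma_yield=0.0, sigma_water=0.0)
    problem = OptimizationProblem(
        region=region,
        cfts=cfts,
        suit=suit,
        weights=CountyWeights(ln=np.zeros(1), iwu=np.zeros(1)),
        demand=_demand([1.0] * 5),
        baseline_cp_by_crop=np.zeros(7),
    )
    yc = suit.yield_t_ha[0] * cfts["calories_kcal_t"].to_numpy()
    return problem, int(np.argmax(yc))


def _toy_triobjective_problem(seed=21):
    cfts = build_default_cfts().iloc[[2, 4, 7]].reset_index(drop=True)
    region = gen_region(5, 1, seed=seed)
    suit = gen_suitability(region, cfts, 305.0, seed=seed + 1)
    return OptimizationProblem(
        region=region,
        cfts=cfts,
        suit=suit,
        weights=compute_weights(region),
        demand=_demand([1.0] * 5),
        baseline_cp_by_crop=np.zeros(7),
    )


PEN_OFF = PenaltyConfig(use_sf=False, use_cp=False)


class TestEvolve:
    def test_single_objective_optimum_recovered(self):
        problem, best_j = _single_objective_problem()
        cfg = OptimizerConfig(
            pop_size=52, generations=100, seed=5, penalties=PEN_OFF
        )
        sols = evolve(problem, cfg)
        best_frac = max(s[0].fractions()[0, best_j] for s in sols)
        assert best_frac >= 0.99

    def test_elitism_in_single_objective_mode(self):
        problem, _ = _single_objective_problem()
        cfg = OptimizerConfig(pop_size=20, generations=60, seed=6, penalties=PEN_OFF)
        _, log = evolve(problem, cfg, return_log=True)
        assert (np.diff(log.best_f_cp) >= -1e-9 * abs(log.best_f_cp[-1])).all()

    def test_area_constraint_every_evaluation(self):
        problem = _toy_triobjective_problem()
        cfg = OptimizerConfig(pop_size=20, generations=20, seed=7, penalties=PEN_OFF)
        sols, log = evolve(problem, cfg, return_log=True)
        assert log.max_area_violation <= 1e-9
        areas = problem.region.areas
        for alloc, _obj in sols:
            alloc.check_simplex(areas)
            assert np.isclose(
                alloc.areas_ha.sum(), problem.region.total_area, rtol=1e-9
            )

    def test_seeded_reproducibility(self):
        problem = _toy_triobjective_problem()
        cfg = OptimizerConfig(pop_size=20, generations=15, seed=9, penalties=PEN_OFF)
        s1 = evolve(problem, cfg)
        s2 = evolve(problem, cfg)
        assert len(s1) == len(s2)
        for (a1, o1), (a2, o2) in zip(s1, s2):
            np.testing.assert_array_equal(a1.areas_ha, a2.areas_ha)
            assert o1 == o2

    def test_front_survives_random_search_audit(self):
        from cropswitch.optimize import _BatchEvaluator

        problem = _toy_triobjective_problem()
        cfg = OptimizerConfig(pop_size=52, generations=300, seed=23, penalties=PEN_OFF)
        sols = evolve(problem, cfg)
        ev = _BatchEvaluator(problem, PEN_OFF)
        rng = np.random.default_rng(24)
        pool = rng.dirichlet(np.ones(3), size=(2000, 5))
        F_pool, _ = ev(pool)
        for _alloc, obj in sols:
            f = obj.min_space()
            dominated = (
                (F_pool <= f).all(axis=1) & (F_pool < f).any(axis=1)
            ).any()
            assert not dominated

    def test_invalid_config_rejected(self):
        problem = _toy_triobjective_problem()
        with pytest.raises(ValueError):
            evolve(problem, OptimizerConfig(pop_size=5, generations=10))
        with pytest.raises(ValueError):
            evolve(problem, OptimizerConfig(pop_size=20, generations=0))

    def test_penalty_monotonicity_in_demand(self, region10, cfts, baseline_alloc):
        # raising one category's demand never raises p_sf for a fixed allocation
        suit = gen_suitability(region10, cfts, 305.0, seed=4)
        w = compute_weights(region10)
        base_cp = crop_production(baseline_alloc, suit, cfts)
        lo = _demand([1e15, 1e14, 1e13, 1e13, 1e13])
        hi = _demand([5e15, 1e14, 1e13, 1e13, 1e13])
        p_lo = evaluate_objectives(baseline_alloc, suit, w, cfts, lo, base_cp).p_sf
        p_hi = evaluate_objectives(baseline_alloc, suit, w, cfts, hi, base_cp).p_sf
        assert p_hi <= p_lo
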