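import itertools
import math

import numpy as np
import pytest

import palmbreed.annealing as ann
from palmbreed.annealing import (
    MateSelectionProblem,
    SAConfig,
    ThresholdSpec,
    anneal,
    calibrate_T0,
    compute_threshold,
    evaluate_E,
    initial_solution,
    neighbor,
    parallel_restarts,
)
from palmbreed.fixtures import ms_instance, synthetic_ebv_table, synthetic_kinship, tiny_sa_instance


@pytest.fixture(scope="module")
def tiny():
    return tiny_sa_instance(np.random.default_rng(42))


@pytest.fixture(scope="module")
def tiny_optimum(tiny):
    p = tiny.problem
    best = math.inf
    n_valid = 0
    for combo in itertools.combinations(range(p.n_cells), p.n_cross):
        idx = np.asarray(combo)
        if p.feasible(idx):
            n_valid += 1
            best = min(best, p.evaluate_cells(idx))
    return best, n_valid


class TestEvaluationFunction:
    def test_zero_ebvs_give_zero_energy(self):
        n = 6
        p = MateSelectionProblem(
            ids=np.arange(n), g_bn=np.zeros(n), g_bw=np.zeros(n),
            kinship=np.zeros((n, n)), deli_mean_a=0.0, deli_mean_b=0.0,
            deli_mean_ab=0.0, n_cross=4,
        )
        assert p.evaluate_cells(np.arange(4)) == 0.0

    def test_factorized_evaluation_matches_double_loop(self, tiny):
        # incremental factorized E vs the plain definition over all pairs
        from palmbreed.mating import CrossMatrix, conventional_mating

        rng = np.random.default_rng(7)
        p = tiny.problem
        deli = tiny.deli_ebvs
        deli_design = conventional_mating(
            deli["individual_id"].to_numpy(), 4, 4, 2, True, rng
        )
        # rebuild the problem against this specific Deli design
        da, db, dab = ann.deli_design_stats(deli_design, deli)
        p2 = MateSelectionProblem(
            ids=p.ids, g_bn=p.g_bn, g_bw=p.g_bw, kinship=p.kinship,
            deli_mean_a=da, deli_mean_b=db, deli_mean_ab=dab, n_cross=4,
        )
        for _ in range(10):
            cells = rng.choice(p2.n_cells, 4, replace=False)
            X = p2.cross_matrix(cells)
            assert p2.evaluate_cells(cells) == pytest.approx(
                evaluate_E(X, deli_design, deli, tiny.lame_ebvs), rel=1e-10
            )

    def test_better_parents_lower_the_energy(self):
        n = 4
        g = np.array([1.0, 1.0, 5.0, 5.0])
        p = MateSelectionProblem(
            ids=np.arange(n), g_bn=g, g_bw=g, kinship=np.zeros((n, n)),
            deli_mean_a=1.0, deli_mean_b=1.0, deli_mean_ab=1.0, n_cross=1,
        )
        low = p.evaluate_cells(np.array([p.cell_of(0, 1)]))
        high = p.evaluate_cells(np.array([p.cell_of(2, 3)]))
        assert high < low


class TestThreshold:
    def test_formula_and_endpoints(self):
        spec = ThresholdSpec(c_delta_f=0.0, f_n=0.1, f_rand_next=0.15, f_conv_next=0.2)
        assert spec.bound == pytest.approx(0.15)  # c = 0: bound = F_rand
        spec = ThresholdSpec(c_delta_f=1.0, f_n=0.1, f_rand_next=0.15, f_conv_next=0.2)
        assert spec.bound == pytest.approx(0.2)   # c = 1: bound = F_conv
        spec = ThresholdSpec(c_delta_f=0.25, f_n=0.1, f_rand_next=0.15, f_conv_next=0.2)
        assert spec.delta_f == pytest.approx((0.15 - 0.1) + 0.25 * (0.2 - 0.15))

    def test_conventional_anchor_exceeds_random_anchor(self):
        # truncation selection clusters relatives (family-structured EBVs),
        # so F_conv >= F_rand on replicate average
        diffs = []
        for rep in range(8):
            inst = ms_instance(rng=np.random.default_rng(300 + rep))
            diffs.append(inst.threshold.f_conv_next - inst.threshold.f_rand_next)
        assert np.mean(diffs) > 0

    def test_compute_threshold_is_deterministic_given_seed(self):
        ids = np.arange(1, 21)
        kin = synthetic_kinship(20, np.random.default_rng(0))
        t1 = compute_threshold(ids, kin, ids, 0.05, 0.25,
                               np.random.default_rng(9), 8, 16, 4)
        t2 = compute_threshold(ids, kin, ids, 0.05, 0.25,
                               np.random.default_rng(9), 8, 16, 4)
        assert t1 == t2


class TestInitialSolution:
    def test_structure_and_randomization(self, tiny):
        cfg = tiny.config
        seen = set()
        for s in range(5):
            x0 = initial_solution(tiny.problem, cfg, np.random.default_rng(s))
            assert x0.size == cfg.n_cross
            X = tiny.problem.cross_matrix(x0)
            X.validate(n_cross=cfg.n_cross, n_selected=cfg.n_select_init)
            seen.add(tuple(sorted(x0)))
        assert len(seen) > 1  # non-degenerate randomization

    def test_deterministic_given_seed(self, tiny):
        a = initial_solution(tiny.problem, tiny.config, np.random.default_rng(4))
        b = initial_solution(tiny.problem, tiny.config, np.random.default_rng(4))
        assert np.array_equal(a, b)


class TestNeighbor:
    def test_single_swap_changes_exactly_two_cells(self, tiny):
        # start from a feasible design (found by enumeration; random X0s on
        # this instance violate the kinship bound by construction)
        p = tiny.problem
        x = next(
            np.asarray(c)
            for c in itertools.combinations(range(p.n_cells), p.n_cross)
            if p.feasible(np.asarray(c))
        )
        rng = np.random.default_rng(1)
        for _ in range(5):
            alt = neighbor(x, 1, p, tiny.config, rng)
            assert alt is not None
            assert len(set(x) ^ set(alt)) == 2
            x = alt

    def test_neighbors_satisfy_count_and_kinship_bound(self, tiny):
        rng = np.random.default_rng(2)
        x = initial_solution(tiny.problem, tiny.config, rng)
        for _ in range(30):
            alt = neighbor(x, 2, tiny.problem, tiny.config, rng)
            if alt is None:
                continue
            assert alt.size == tiny.config.n_cross
            assert tiny.problem.mean_kinship(alt) < tiny.problem.bound
            x = alt

    def test_impossible_bound_signals_failure(self, tiny):
        from dataclasses import replace

        p = tiny.problem
        hard = MateSelectionProblem(
            ids=p.ids, g_bn=p.g_bn, g_bw=p.g_bw, kinship=p.kinship,
            deli_mean_a=p.deli_mean_a, deli_mean_b=p.deli_mean_b,
            deli_mean_ab=p.deli_mean_ab, bound=-1.0, n_cross=p.n_cross,
        )
        cfg = replace(tiny.config, neighbor_attempt_cap=200)
        rng = np.random.default_rng(3)
        x = initial_solution(hard, cfg, rng)
        assert neighbor(x, 1, hard, cfg, rng) is None


class TestT0Calibration:
    def test_mean_positive_delta_over_ln2(self, tiny, monkeypatch):
        # with probes of known energy difference d, T0 solves exp(-d/T0)=1/2
        p = tiny.problem
        cfg = tiny.config
        rng = np.random.default_rng(11)
        x0 = initial_solution(p, cfg, rng)
        e0 = p.evaluate_cells(x0)
        target = None
        for combo in itertools.combinations(range(p.n_cells), p.n_cross):
            idx = np.asarray(combo)
            if p.feasible(idx) and p.evaluate_cells(idx) > e0:
                target = idx
                break
        d = p.evaluate_cells(target) - e0
        monkeypatch.setattr(ann, "neighbor", lambda *a, **k: target)
        t0 = calibrate_T0(x0, p, cfg, rng)
        assert t0 == pytest.approx(d / math.log(2))

    def test_all_improving_probes_fall_back_to_floor(self, tiny, monkeypatch):
        p = tiny.problem
        cfg = tiny.config
        rng = np.random.default_rng(12)
        # worst feasible solution: every probe improves
        worst, e_worst = None, -math.inf
        for combo in itertools.combinations(range(p.n_cells), p.n_cross):
            idx = np.asarray(combo)
            if p.feasible(idx):
                e = p.evaluate_cells(idx)
                if e > e_worst:
                    worst, e_worst = idx, e
        t0 = calibrate_T0(worst, p, cfg, rng)
        assert t0 == cfg.t0_floor or t0 > 0

    def test_no_valid_alternative_returns_none(self, tiny, monkeypatch):
        monkeypatch.setattr(ann, "neighbor", lambda *a, **k: None)
        rng = np.random.default_rng(13)
        x0 = initial_solution(tiny.problem, tiny.config, rng)
        assert calibrate_T0(x0, tiny.problem, tiny.config, rng) is None

    def test_deterministic_given_seed(self, tiny):
        x0 = initial_solution(tiny.problem, tiny.config, np.random.default_rng(14))
        a = calibrate_T0(x0, tiny.problem, tiny.config, np.random.default_rng(15))
        b = calibrate_T0(x0, tiny.problem, tiny.config, np.random.default_rng(15))
        assert a == b


class TestAnneal:
    def test_best_energy_never_above_feasible_initial(self, tiny):
        for s in range(5):
            rng = np.random.default_rng(20 + s)
            res = anneal(tiny.problem, tiny.config, rng)
            x_check = res.best_cells
            assert tiny.problem.feasible(x_check)
            assert res.best_e <= res.trace["e_current"].iloc[0] + 1e-12

    def test_cooling_follows_geometric_law(self, tiny):
        res = anneal(tiny.problem, tiny.config, np.random.default_rng(30))
        temps = res.trace["temperature"].to_numpy()
        ratios = temps[1:] / temps[:-1]
        np.testing.assert_allclose(ratios, 0.95, rtol=1e-12)

    def test_nr_schedule_indexed_by_temperature_level(self, tiny):
        res = anneal(tiny.problem, tiny.config, np.random.default_rng(31))
        tr = res.trace
        assert (tr.loc[tr["level"] <= 3, "nr"] == 2).all()
        assert (tr.loc[tr["level"] > 3, "nr"] == 1).all()

    def test_accepted_solutions_all_satisfy_constraints(self, tiny):
        res = anneal(tiny.problem, tiny.config, np.random.default_rng(32))
        for cells in res.acceptance_log:
            assert cells.size == tiny.config.n_cross
            assert tiny.problem.mean_kinship(cells) < tiny.problem.bound

    def test_single_run_finds_tiny_optimum_with_restarts(self, tiny, tiny_optimum):
        opt, n_valid = tiny_optimum
        assert 0 < n_valid <= 2000
        best, _ = parallel_restarts(tiny.problem, tiny.config, 555, k=16)
        assert best.best_e == pytest.approx(opt, abs=1e-9)


class TestParallelRestarts:
    def test_k1_equals_single_anneal_with_spawned_seed(self, tiny):
        best, _ = parallel_restarts(tiny.problem, tiny.config, 77, k=1)
        direct = anneal(
            tiny.problem, tiny.config,
            np.random.default_rng(np.random.SeedSequence(77).spawn(1)[0]),
        )
        assert best.best_e == direct.best_e

    def test_more_restarts_never_worse(self, tiny):
        b1, _ = parallel_restarts(tiny.problem, tiny.config, 78, k=1)
        b8, _ = parallel_restarts(tiny.problem, tiny.config, 78, k=8)
        assert b8.best_e <= b1.best_e

    def test_result_independent_of_parallelism(self, tiny):
        serial, _ = parallel_restarts(tiny.problem, tiny.config, 79, k=4, n_jobs=1)
        parallel, _ = parallel_restarts(tiny.problem, tiny.config, 79, k=4, n_jobs=2)
        assert serial.best_e == parallel.best_e
        assert np.array_equal(np.sort(serial.best_cells), np.sort(parallel.best_cells))

    def test_invalid_restart_count_rejected(self, tiny):
        with pytest.raises(ValueError):
            parallel_restarts(tiny.problem, tiny.config, 1, k=0)


class TestSAConfig:
    def test_table_presets(self):
        c120 = SAConfig.preset_120()
        assert (c120.n_presel, c120.n1, c120.n2, c120.n_m) == (50, 80, 50, 30)
        c330 = SAConfig.preset_330()
        assert (c330.n_presel, c330.n1, c330.n2, c330.n_m) == (60, 100, 100, 60)

    def test_nr_schedule_default(self):
        cfg = SAConfig()
        assert [cfg.nr_at_level(k) for k in (1, 5, 6, 15, 16, 40)] == [3, 3, 2, 2, 1, 1]

    def test_invalid_cooling_rejected(self):
        with pytest.raises(ValueError):
            SAConfig(cooling_factor=1.5)
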