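"""CD statistic, parameter grid, grid-search fit, bootstrap, windows."""

import numpy as np
import pytest

from oculoforage.fitting import (
    DegenerateReferenceError,
    GridSummaries,
    bootstrap_intervals,
    coefficient_of_determination,
    fit,
    load_or_compute_grid,
    normalization_scales,
    parameter_grid,
    parameter_pair_distance,
    sliding_window_fit,
)
from oculoforage.model import ModelParams, simulate_agent
from oculoforage.summaries import summarize
from oculoforage.synth import generate_session


class TestParameterGrid:
    def test_cardinality(self):
        assert len(parameter_grid()) == 6120

    def test_capacity_one_has_51_entries(self):
        assert sum(1 for p in parameter_grid() if p.capacity == 1) == 51

    def test_boundary_members_present(self):
        grid = set(p.astuple() for p in parameter_grid())
        assert (15, 15, 1.0) in grid and (1, 1, 0.0) in grid

    def test_deterministic_order(self):
        a, b = parameter_grid(), parameter_grid()
        assert a == b
        assert a[0].astuple() == (1, 1, 0.0)


class TestCoefficientOfDetermination:
    def test_identity_is_one(self):
        m = np.random.default_rng(0).random(75)
        assert coefficient_of_determination(m, m) == pytest.approx(1.0)

    def test_toy_arithmetic(self):
        # num = 0.125; den = sum((M - mean(S))^2) = 1/6; CD = 1 - 0.75
        M = np.array([0.5, 0.5, 0.0])
        S = np.array([0.25, 0.5, 0.25])
        assert coefficient_of_determination(M, S) == pytest.approx(0.25)

    def test_degenerate_reference_raises(self):
        M = np.full(5, 0.2)
        S = np.full(5, 0.2)
        with pytest.raises(DegenerateReferenceError):
            coefficient_of_determination(M, S)

    def test_conventional_r2_mode_centers_on_observed(self):
        M = np.array([0.5, 0.5, 0.0])
        S = np.array([0.25, 0.5, 0.25])
        den = ((M - M.mean()) ** 2).sum()
        expect = 1 - 0.125 / den
        assert coefficient_of_determination(M, S, center="obs") == pytest.approx(expect)

    def test_self_matched_beats_mismatched(self, grid500):
        obs = summarize(
            simulate_agent(ModelParams(10, 2, 0.9), 3000, np.random.default_rng(14))
        ).concat()
        idx = {p.astuple(): i for i, p in enumerate(grid500.params)}
        cd_self = coefficient_of_determination(obs, grid500.matrix[idx[(10, 2, 0.9)]])
        cd_far = coefficient_of_determination(obs, grid500.matrix[idx[(1, 1, 0.0)]])
        assert cd_self > cd_far


class TestFit:
    def test_recovery_at_known_params(self, grid500):
        obs = summarize(
            simulate_agent(ModelParams(10, 2, 0.9), 5000, np.random.default_rng(15))
        )
        fr = fit(obs, cache=grid500)
        assert abs(fr.best_params.capacity - 10) <= 1
        assert abs(fr.best_params.utility - 0.9) <= 0.04 + 1e-9
        assert fr.best_cd > 0.95
        assert fr.reliable
        assert fr.best_cd == pytest.approx(fr.grid_cds.max())

    def test_zero_revisit_data_identifies_perfect_use(self, grid500):
        obs = summarize(
            simulate_agent(ModelParams(15, 1, 1.0), 5000, np.random.default_rng(16))
        )
        fr = fit(obs, cache=grid500)
        assert fr.best_params.utility == 1.0
        assert fr.best_params.capacity >= 14

    def test_sparse_random_window_flagged_unreliable(self, grid500):
        # ~50 trials of near-random behavior: too noisy for a trustworthy fit
        obs = summarize(
            simulate_agent(ModelParams(1, 1, 0.02), 50, np.random.default_rng(17))
        )
        fr = fit(obs, cache=grid500)
        assert fr.reliable == (fr.best_cd >= 0.7)

    def test_fit_deterministic_and_cache_roundtrip(self, grid500, tmp_path):
        obs = summarize(
            simulate_agent(ModelParams(7, 2, 0.8), 1000, np.random.default_rng(18))
        )
        a = fit(obs, cache=grid500)
        b = fit(obs, cache=grid500)
        assert a.best_params == b.best_params and a.best_cd == b.best_cd
        # disk round trip reproduces the same grid CDs
        grid500.save(tmp_path)
        reloaded = load_or_compute_grid(
            grid500.n_sim_trials, grid500.seed, cache_dir=tmp_path
        )
        c = fit(obs, cache=reloaded)
        assert np.allclose(a.grid_cds, c.grid_cds)


class TestBootstrap:
    def test_single_resample_degenerate_interval(self, grid500):
        trials = simulate_agent(ModelParams(10, 2, 0.9), 300, np.random.default_rng(19))
        br = bootstrap_intervals(trials, n_boot=1, seed=0, cache=grid500)
        assert np.all(br.lower == br.upper)

    def test_interval_contains_point_typically(self, grid500):
        trials = simulate_agent(
            ModelParams(10, 2, 0.9), 1000, np.random.default_rng(20)
        )
        br = bootstrap_intervals(trials, n_boot=100, seed=1, cache=grid500)
        assert np.all(br.lower <= br.upper)
        assert br.samples.shape == (100, 3)

    def test_requires_two_trials(self, grid500):
        trials = simulate_agent(ModelParams(5, 1, 0.5), 1, np.random.default_rng(21))
        with pytest.raises(ValueError):
            bootstrap_intervals(trials, n_boot=5, cache=grid500)


class TestSlidingWindows:
    def test_step_equal_window_partitions_timeline(self, grid500):
        sess = generate_session(
            ModelParams(10, 2, 0.9), 200, rng=np.random.default_rng(22)
        )
        wfs = sliding_window_fit([sess], 10, 10, cache=grid500)
        for a, b in zip(wfs, wfs[1:]):
            assert b.t_start_minutes == pytest.approx(a.t_end_minutes)
        assert sum(w.n_trials for w in wfs) == sess.n_trials

    def test_stationary_sessions_recover_baseline(self, grid500):
        sessions = [
            generate_session(
                ModelParams(10, 2, 0.9), 450, rng=np.random.default_rng(23 + i)
            )
            for i in range(3)
        ]
        wfs = sliding_window_fit(sessions, 10, 5, cache=grid500)
        fitted = [w for w in wfs if w.reliable]
        assert len(fitted) >= 3
        for w in fitted:
            assert abs(w.result.best_params.capacity - 10) <= 2
            assert abs(w.result.best_params.utility - 0.9) <= 0.1

    def test_invalid_window_rejected(self, grid500):
        with pytest.raises(ValueError):
            sliding_window_fit([], window_minutes=0, step_minutes=1, cache=grid500)


class TestParameterPairDistance:
    def test_zero_for_identical(self):
        p = ModelParams(10, 2, 0.9)
        assert parameter_pair_distance(p, p) == 0.0

    def test_unit_scale_arithmetic(self):
        d = parameter_pair_distance(ModelParams(10, 2, 0.9), ModelParams(9, 2, 0.9))
        assert d == pytest.approx(1.0)

    def test_zero_scale_rejected(self):
        with pytest.raises(ValueError):
            parameter_pair_distance(
                ModelParams(10, 2, 0.9), ModelParams(9, 2, 0.9), scales=(0, 1, 1)
            )

    def test_within_group_smaller_than_across(self, grid500):
        """Sessions from two distinct agents separate in parameter space."""
        rng = np.random.default_rng(24)
        fits = {"a": [], "b": []}
        for g, p in (("a", ModelParams(10, 2, 0.9)), ("b", ModelParams(5, 1, 0.6))):
            for _ in range(3):
                obs = summarize(simulate_agent(p, 2000, rng))
                fits[g].append(fit(obs, cache=grid500).best_params)
        scales = normalization_scales(fits["a"] + fits["b"])
        within = [
            parameter_pair_distance(x, y, scales)
            for g in fits
            for i, x in enumerate(fits[g])
            for y in fits[g][i + 1 :]
        ]
        across = [
            parameter_pair_distance(x, y, scales)
            for x in fits["a"]
            for y in fits["b"]
        ]
        assert np.mean(within) < np.mean(across)
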