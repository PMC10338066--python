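"""Sparse weight objective, annealing, C-scan and cross-validation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rdcfit as rf
from rdcfit.errors import EmptySelectionError, UndefinedNormalizationError


def _cfg(c=0.0, **kw):
    return rf.WeightObjectiveConfig((1, 30), c, **kw)


class TestObjective:
    def test_c_zero_equals_regional_q(self, mixture_problem):
        d_members, d_meas, tensor, _, _ = mixture_problem
        w = np.full(10, 0.1)
        f, misfit, penalty = rf.objective_f(w, d_members, d_meas, tensor.da, tensor.rh, _cfg())
        assert penalty == 0.0
        q = rf.q_factor(w @ d_members, d_meas, tensor.da, tensor.rh)
        assert f == pytest.approx(q, abs=1e-12)
        assert misfit == pytest.approx(q, abs=1e-12)

    def test_identical_members_decided_by_penalty_alone(self, truth_tensor):
        # all rows equal -> misfit constant; -C*sum(w+eps)^2 is minimized at a vertex
        d_members = np.tile(np.linspace(-3, 3, 12), (4, 1))
        d_meas = d_members[0] + 0.1
        cfg = _cfg(c=0.05)
        vertex = np.array([1.0, 0.0, 0.0, 0.0])
        uniform = np.full(4, 0.25)
        f_vertex = rf.objective_f(vertex, d_members, d_meas, 10.0, 0.3, cfg)[0]
        f_uniform = rf.objective_f(uniform, d_members, d_meas, 10.0, 0.3, cfg)[0]
        assert f_vertex < f_uniform
        m_vertex = rf.objective_f(vertex, d_members, d_meas, 10.0, 0.3, cfg)[1]
        m_uniform = rf.objective_f(uniform, d_members, d_meas, 10.0, 0.3, cfg)[1]
        assert m_vertex == pytest.approx(m_uniform, abs=1e-12)

    def test_two_member_noiseless_grid_oracle(self, truth_tensor):
        # truth weights (0.3, 0.7); a 0.001-step scan of w1 must bottom at 0.3 with F = 0
        spec = rf.SyntheticSpec(
            n_residues=30, n_members=2, motion={r: rf.Scatter() for r in range(1, 31)}, seed=31
        )
        vs, _ = rf.generate_vector_ensemble(spec)
        w_true = np.array([0.3, 0.7])
        table = rf.generate_rdc_table(vs, truth_tensor, w_true, sigma=0.0, seed=32)
        d_members = rf.predict_members(vs, truth_tensor)
        d_meas = table.df["value_hz"].to_numpy()
        grid = np.arange(0.0, 1.0 + 1e-12, 0.001)
        f_vals = [
            rf.objective_f(np.array([w, 1 - w]), d_members, d_meas,
                           truth_tensor.da, truth_tensor.rh, _cfg())[0]
            for w in grid
        ]
        best = grid[int(np.argmin(f_vals))]
        assert best == pytest.approx(0.3, abs=1e-9)
        assert min(f_vals) == pytest.approx(0.0, abs=1e-9)

    def test_empty_region_and_zero_da_raise(self):
        with pytest.raises(EmptySelectionError):
            rf.objective_f(np.array([1.0]), np.empty((1, 0)), np.empty(0), 10.0, 0.0, _cfg())
        with pytest.raises(UndefinedNormalizationError):
            rf.objective_f(np.array([1.0]), np.ones((1, 3)), np.ones(3), 0.0, 0.0, _cfg())

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            rf.WeightObjectiveConfig((10, 5))
        with pytest.raises(ValueError):
            rf.WeightObjectiveConfig((1, 5), c=-0.1)
        with pytest.raises(ValueError):
            rf.WeightObjectiveConfig((1, 5), epsilon=0.0)


class TestAnneal:
    def test_identical_members_collapse_to_single_weight(self):
        d_members = np.tile(np.linspace(-3, 3, 12), (5, 1))
        d_meas = d_members[0]
        sol = rf.anneal_weights(d_members, d_meas, 10.0, 0.3, _cfg(c=0.05), seed=1)
        assert np.sum(sol.weights > 0.99) == 1

    def test_sparse_weight_recovery(self, mixture_problem):
        d_members, d_meas, tensor, w_true, _ = mixture_problem
        sol = rf.anneal_weights(d_members, d_meas, tensor.da, tensor.rh,
                                _cfg(c=0.005), seed=7)
        assert abs(sol.weights[2] - 0.3) < 0.05
        assert abs(sol.weights[5] - 0.7) < 0.05
        inactive = [sol.weights[i] for i in range(10) if i not in (2, 5)]
        assert max(inactive) < 0.02
        assert sol.selected == [2, 5]

    def test_three_member_matches_grid_oracle(self, mixture_problem):
        d_members, d_meas, tensor, _, _ = mixture_problem
        d3 = d_members[[2, 5, 8]]
        cfg = _cfg(c=0.005)
        sol = rf.anneal_weights(d3, d_meas, tensor.da, tensor.rh, cfg, seed=11)
        oracle = rf.simplex_grid_search(d3, d_meas, tensor.da, tensor.rh, cfg, 0.01)
        assert np.max(np.abs(sol.weights - oracle.weights)) <= 0.01 + 1e-9
        assert sol.f <= oracle.f + 1e-9

    def test_simplex_preserved_and_bitwise_reproducible(self, mixture_problem):
        d_members, d_meas, tensor, _, _ = mixture_problem
        a = rf.anneal_weights(d_members, d_meas, tensor.da, tensor.rh, _cfg(c=0.01), seed=42)
        b = rf.anneal_weights(d_members, d_meas, tensor.da, tensor.rh, _cfg(c=0.01), seed=42)
        assert np.array_equal(a.weights, b.weights)
        assert a.f == b.f
        assert np.min(a.weights) >= 0.0
        assert abs(a.weights.sum() - 1.0) < 1e-12

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=10, deadline=None)
    def test_simplex_invariant_any_seed(self, mixture_problem, seed):
        d_members, d_meas, tensor, _, _ = mixture_problem
        schedule = rf.AnnealSchedule(moves_per_t=20, cooling=0.7)
        sol = rf.anneal_weights(d_members[:4], d_meas, tensor.da, tensor.rh,
                                _cfg(c=0.01), schedule, seed=seed)
        assert np.min(sol.weights) >= 0.0
        assert abs(sol.weights.sum() - 1.0) < 1e-12

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            rf.AnnealSchedule(cooling=1.5)
        with pytest.raises(ValueError):
            rf.AnnealSchedule(moves_per_t=0)


class TestScanSparsity:
    def test_single_member_truth_gives_minimal_ensemble_of_one(self, truth_tensor):
        spec = rf.SyntheticSpec(
            n_residues=20, n_members=6, motion={r: rf.Scatter() for r in range(1, 21)}, seed=41
        )
        vs, _ = rf.generate_vector_ensemble(spec)
        w_true = np.zeros(6)
        w_true[3] = 1.0
        table = rf.generate_rdc_table(vs, truth_tensor, w_true, sigma=0.0, seed=42)
        d_members = rf.predict_members(vs, truth_tensor)
        d_meas = table.df["value_hz"].to_numpy()
        scan = rf.scan_sparsity(d_members, d_meas, truth_tensor.da, truth_tensor.rh,
                                _cfg(), [0.01, 0.05, 0.1], sigma_bar=0.05, seed=5)
        assert scan.feasible
        for sol in scan.solutions:
            assert sol.selected == [3]

    def test_three_state_mixture_recovered(self, truth_tensor):
        spec = rf.SyntheticSpec(
            n_residues=30, n_members=8, motion={r: rf.Scatter() for r in range(1, 31)}, seed=43
        )
        vs, _ = rf.generate_vector_ensemble(spec)
        w_true = np.zeros(8)
        w_true[[1, 4, 6]] = [0.2, 0.16, 0.64]
        sigma = 0.1
        table = rf.generate_rdc_table(vs, truth_tensor, w_true, sigma=sigma, seed=44)
        d_members = rf.predict_members(vs, truth_tensor)
        d_meas = table.df["value_hz"].to_numpy()
        scan = rf.scan_sparsity(d_members, d_meas, truth_tensor.da, truth_tensor.rh,
                                _cfg(), [0.0, 0.002, 0.005, 0.01, 0.02], sigma_bar=sigma, seed=6)
        assert scan.feasible
        sol = scan.minimal_solution
        assert sol.selected == [1, 4, 6]
        np.testing.assert_allclose(sol.weights[[1, 4, 6]], [0.2, 0.16, 0.64], atol=0.05)

    def test_misfit_monotone_as_c_decreases(self, mixture_problem):
        d_members, d_meas, tensor, _, _ = mixture_problem
        d3 = d_members[[2, 5, 8]]
        scan = rf.scan_sparsity(d3, d_meas, tensor.da, tensor.rh, _cfg(),
                                [0.0, 0.01, 0.03, 0.1], sigma_bar=0.2, seed=8)
        misfits = [s.misfit for s in scan.solutions]
        assert all(a <= b + 1e-9 for a, b in zip(misfits, misfits[1:]))

    def test_descending_grid_rejected(self, mixture_problem):
        d_members, d_meas, tensor, _, _ = mixture_problem
        with pytest.raises(ValueError):
            rf.scan_sparsity(d_members, d_meas, tensor.da, tensor.rh, _cfg(),
                             [0.1, 0.0], sigma_bar=0.2)


class TestCrossValidation:
    def test_noiseless_truth_in_span_gives_zero_free_q(self, truth_tensor):
        spec = rf.SyntheticSpec(
            n_residues=24, n_members=4, motion={r: rf.Scatter() for r in range(1, 25)}, seed=51
        )
        vs, _ = rf.generate_vector_ensemble(spec)
        w_true = np.array([0.5, 0.3, 0.2, 0.0])
        table = rf.generate_rdc_table(vs, truth_tensor, w_true, sigma=0.0, seed=52)
        d_members = rf.predict_members(vs, truth_tensor)
        d_meas = table.df["value_hz"].to_numpy()
        cv = rf.cross_validate_weights(d_members, d_meas, truth_tensor.da, truth_tensor.rh,
                                       _cfg(), holdout_fraction=0.2, repeats=4, seed=9)
        # weights recovered to the optimizer's resolution -> free Q negligible
        # relative to realistic Q values (~0.1-0.3)
        assert cv.free_q_mean < 1e-3

    def test_overfit_detected_by_free_q(self, truth_tensor):
        # 50 members, 6 records: training misfit ~0, held-out misfit large
        rng = np.random.default_rng(53)
        d_members = rng.normal(0.0, 10.0, size=(50, 6))
        d_meas = rng.normal(0.0, 10.0, size=6)
        cv = rf.cross_validate_weights(d_members, d_meas, truth_tensor.da, truth_tensor.rh,
                                       rf.WeightObjectiveConfig((1, 6)),
                                       holdout_fraction=0.17, repeats=6, seed=10)
        assert cv.free_q_mean > 1.5 * max(cv.train_q_mean, 1e-12)

    def test_truth_weights_beat_random_on_free_q(self, mixture_problem):
        d_members, d_meas, tensor, w_true, _ = mixture_problem
        norm = np.sqrt(tensor.da**2 * (4 + 3 * tensor.rh**2) / 5)
        rng = np.random.default_rng(54)
        wins = 0
        repeats = 100
        for _ in range(repeats):
            hold = rng.choice(d_meas.size, size=3, replace=False)
            rand_w = rng.exponential(1.0, d_members.shape[0])
            rand_w /= rand_w.sum()
            q_truth = np.sqrt(np.mean((w_true @ d_members[:, hold] - d_meas[hold]) ** 2)) / norm
            q_rand = np.sqrt(np.mean((rand_w @ d_members[:, hold] - d_meas[hold]) ** 2)) / norm
            wins += q_truth < q_rand
        assert wins >= 0.95 * repeats

    def test_bad_holdout_fraction_rejected(self, mixture_problem):
        d_members, d_meas, tensor, _, _ = mixture_problem
        with pytest.raises(ValueError):
            rf.cross_validate_weights(d_members, d_meas, tensor.da, tensor.rh,
                                      _cfg(), holdout_fraction=0.9)


class TestPerResidueRmsd:
    def _table(self):
        return rf.RDCTable.from_records(
            [
                {"medium": "m1", "chain": "A", "resid_i": r, "atom_i": "N",
                 "resid_j": r, "atom_j": "H", "type": "NH",
                 "value_hz": v, "sigma_hz": 0.2}
                for r, v in ((5, 1.0), (6, -2.0))
            ]
        )

    def test_zero_when_predictions_match(self):
        table = self._table()
        pred = table.df["value_hz"].to_numpy()
        assert rf.per_residue_rmsd(pred, table, (5, 6)) == 0.0

    def test_hand_arithmetic(self):
        table = self._table()
        pred = table.df["value_hz"].to_numpy() + np.array([3.0, 4.0])
        assert rf.per_residue_rmsd(pred, table, (5, 6)) == pytest.approx(np.sqrt(12.5))

    def test_mixed_types_match_independent_oracle(self):
        records = [
            {"medium": "m1", "chain": "A", "resid_i": 5, "atom_i": "N",
             "resid_j": 5, "atom_j": "H", "type": "NH", "value_hz": 4.0, "sigma_hz": 0.2},
            {"medium": "m1", "chain": "A", "resid_i": 5, "atom_i": "C",
             "resid_j": 6, "atom_j": "H", "type": "C'H", "value_hz": 1.0, "sigma_hz": 0.2},
        ]
        table = rf.RDCTable.from_records(records)
        pred = np.array([3.0, 1.5])
        got = rf.per_residue_rmsd(pred, table, (1, 99), {"C'H": 3.09})
        # oracle: scale both sides by the per-type factor, then rms
        resid = np.array([(3.0 - 4.0) * 1.0, (1.5 - 1.0) * 3.09])
        assert got == pytest.approx(np.sqrt(np.mean(resid**2)), abs=1e-12)

    def test_empty_region_raises(self):
        with pytest.raises(EmptySelectionError):
            rf.per_residue_rmsd(np.array([0.0, 0.0]), self._table(), (50, 60))
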