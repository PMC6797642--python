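import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sparsesca as ss
from sparsesca.selection import _pstr_rotation

from conftest import make_multiblock


class TestMaxLambdas:
    def test_refit_verification(self, herring):
        lam_L, lam_G = ss.max_lambdas(herring, 3)
        at_max = ss.fit_sparse_sca(
            herring, 3, ss.PenaltyConfig(lam_L, 0), n_starts=1, seed=0
        )
        assert np.all(at_max.model.P_C == 0.0)
        below = ss.fit_sparse_sca(
            herring, 3, ss.PenaltyConfig(0.99 * lam_L, 0), n_starts=1, seed=0
        )
        assert np.any(below.model.P_C != 0.0)

    def test_group_max_verification(self, herring):
        _, lam_G = ss.max_lambdas(herring, 3)
        at_max = ss.fit_sparse_sca(
            herring, 3, ss.PenaltyConfig(0, lam_G), n_starts=1, seed=0
        )
        assert np.all(at_max.model.P_C == 0.0)
        below = ss.fit_sparse_sca(
            herring, 3, ss.PenaltyConfig(0, 0.99 * lam_G), n_starts=1, seed=0
        )
        assert np.any(below.model.P_C != 0.0)

    def test_zero_data(self):
        data = ss.MultiblockData(
            [np.zeros((5, 3))], [f"s{i}" for i in range(5)], ["x"],
            [[f"v{j}" for j in range(3)]],
        )
        assert ss.max_lambdas(data, 2) == (0.0, 0.0)

    def test_single_block_closed_form(self, rng):
        data = make_multiblock(12, (5,), seed=21)
        T = ss.fit_sca(data, 2).T
        lam_L, _ = ss.max_lambdas(data, 2)
        assert lam_L == pytest.approx(2 * np.abs(data.blocks[0].T @ T).max())


class TestCellFolds:
    def test_exact_division(self):
        folds = ss.make_cell_folds(10, 10, 10, seed=0)
        counts = np.bincount(folds.ravel(), minlength=10)
        assert np.all(counts == 10)

    def test_determinism(self):
        f1 = ss.make_cell_folds(21, 20, 10, seed=3)
        f2 = ss.make_cell_folds(21, 20, 10, seed=3)
        np.testing.assert_array_equal(f1, f2)

    def test_balanced(self):
        folds = ss.make_cell_folds(21, 20, 10, seed=1)
        counts = np.bincount(folds.ravel(), minlength=10)
        assert counts.max() - counts.min() <= 1

    def test_min_folds(self):
        with pytest.raises(ValueError):
            ss.make_cell_folds(5, 5, 1, seed=0)


class TestOneSeSelect:
    def test_not_higher_example(self):
        mspe = [1.0, 0.8, 0.85, 1.2]
        se = [0.0, 0.1, 0.0, 0.0]
        idx, sel = ss.one_se_select(mspe, se, ["a", "b", "c", "d"], "not_higher")
        assert sel == "c"

    def test_all_equal_picks_largest_penalty(self):
        mspe = [1.0, 1.0, 1.0]
        se = [0.1, 0.1, 0.1]
        _, sel = ss.one_se_select(mspe, se, [0.1, 0.5, 0.3], "not_higher")
        assert sel == 0.5

    def test_only_minimum_qualifies(self):
        mspe = [0.8, 1.5, 2.0]
        se = [0.1, 0.1, 0.1]
        for mode in ("not_higher", "closest"):
            _, sel = ss.one_se_select(mspe, se, [1, 2, 3], mode)
            assert sel == 1

    def test_not_higher_never_exceeds_threshold(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            mspe = rng.uniform(0.5, 2.0, 12)
            se = rng.uniform(0.01, 0.3, 12)
            b = np.argmin(mspe)
            idx, _ = ss.one_se_select(mspe, se, list(range(12)), "not_higher")
            assert mspe[idx] <= mspe[b] + se[b] + 1e-12

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ss.one_se_select([1.0], [0.1, 0.2], [1, 2])


class TestCvSparse:
    def test_reconstruction_beats_zero_model(self):
        status = ss.TargetStructure(np.ones((2, 2), dtype=int))
        design = ss.SimulationDesign(I=24, J=(5, 4), R=2, structure=status, seed=3)
        data, _, _ = ss.simulate_multiblock(design)
        lam_L, lam_G = ss.max_lambdas(data, 2)
        cv = ss.cv_sparse_sca(
            data, 2,
            lambda_L_grid=[1e-8, lam_L],
            lambda_G_grid=[1e-8, lam_G],
            n_folds=5, seed=0,
        )
        mspe = {g: m for g, m in zip(cv.grid, cv.mspe)}
        assert mspe[(1e-8, 1e-8)] < mspe[(lam_L, lam_G)]

    def test_zero_model_mspe_matches_heldout_mass(self, small_data):
        lam_L, lam_G = ss.max_lambdas(small_data, 2)
        cv = ss.cv_sparse_sca(
            small_data, 2,
            lambda_L_grid=[lam_L * 1.01],
            lambda_G_grid=[lam_G * 1.01],
            n_folds=4, seed=5,
        )
        X_C, _ = ss.concatenate(small_data)
        assert cv.mspe[0] == pytest.approx((X_C**2).mean(), rel=0.05)

    def test_determinism(self, small_data):
        kwargs = dict(
            lambda_L_grid=[0.1, 0.5], lambda_G_grid=[0.1], n_folds=3, seed=9
        )
        cv1 = ss.cv_sparse_sca(small_data, 2, **kwargs)
        cv2 = ss.cv_sparse_sca(small_data, 2, **kwargs)
        np.testing.assert_array_equal(cv1.mspe, cv2.mspe)
        assert cv1.selected == cv2.selected

    def test_empty_grid_raises(self, small_data):
        with pytest.raises(ValueError):
            ss.cv_sparse_sca(small_data, 2, lambda_L_grid=[], lambda_G_grid=[0.1])


class TestCvStructured:
    def test_grid_of_length_one_collapses_region(self, small_data):
        target = ss.TargetStructure(np.ones((2, 2), dtype=int))
        cv = ss.cv_structured_sca(
            small_data, 2, target, lambda_L_grid=[0.3], n_folds=3, seed=0
        )
        assert cv.region == (0.3, 0.3)
        assert cv.selected == 0.3

    def test_monotone_mspe_selects_smallest(self, monkeypatch, small_data):
        # craft monotone-increasing MSPE by evaluating an absurd grid
        target = ss.TargetStructure(np.ones((2, 2), dtype=int))
        lam_max, _ = ss.max_lambdas(small_data, 2)
        grid = list(np.linspace(1e-8, 3 * lam_max, 6))
        cv = ss.cv_structured_sca(
            small_data, 2, target, lambda_L_grid=grid, n_folds=4, seed=2
        )
        if np.all(np.diff(cv.mspe) > 0):
            assert cv.region[0] == grid[0]

    def test_interior_selection_mid_noise(self, recovery_sim):
        design, data, _, _ = recovery_sim
        target = design.structure
        cv = ss.cv_structured_sca(
            data, 3, target, n_folds=5, n_grid=20, seed=4
        )
        grid = cv.grid
        assert grid[0] < cv.selected < grid[-1]


class TestEnumerateStructures:
    def test_k2_r1(self):
        out = ss.enumerate_structures(2, 1)
        assert len(out) == 3

    def test_k2_r2(self):
        assert len(ss.enumerate_structures(2, 2)) == 6

    def test_k3_r1(self):
        assert len(ss.enumerate_structures(3, 1)) == 7

    def test_cap(self):
        with pytest.raises(ValueError, match="cap"):
            ss.enumerate_structures(4, 10, cap=100)

    def test_no_all_zero_columns_and_unique(self):
        out = ss.enumerate_structures(2, 3)
        seen = set()
        for ts in out:
            assert (ts.status.sum(axis=0) > 0).all()
            key = ts.column_multiset()
            assert key not in seen
            seen.add(key)


class TestRotateToTarget:
    def test_already_satisfying_target(self, rng):
        P = rng.standard_normal((7, 2))
        P[4:, 0] = 0.0
        target = ss.TargetStructure(np.array([[1, 1], [0, 1]]))
        B, rotated = ss.rotate_to_target(P, target, (4, 3))
        mask = target.expand((4, 3)) == 0
        assert float((rotated[mask] ** 2).sum()) < 1e-10

    def test_all_ones_target_returns_identity(self, rng):
        P = rng.standard_normal((6, 3))
        target = ss.TargetStructure(np.ones((2, 3), dtype=int))
        B, rotated = ss.rotate_to_target(P, target, (3, 3))
        np.testing.assert_array_equal(B, np.eye(3))
        np.testing.assert_array_equal(rotated, P)

    def test_recovers_known_rotation(self, rng):
        # construct loadings satisfying a distinctive pattern, then rotate 45 deg
        P = rng.standard_normal((8, 2))
        P[5:, 0] = 0.0  # block 2 silent on component 1
        theta = np.pi / 4
        Q = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        target = ss.TargetStructure(np.array([[1, 1], [0, 1]]))
        B, rotated = ss.rotate_to_target(P @ Q, target, (5, 3))
        mask = target.expand((5, 3)) == 0
        assert float((rotated[mask] ** 2).sum()) < 1e-10

    def test_criterion_never_negative_and_sign_invariant(self, rng):
        P = rng.standard_normal((6, 2))
        target = ss.TargetStructure(np.array([[1, 0], [1, 1]]))
        B, rotated = ss.rotate_to_target(P, target, (3, 3))
        mask = target.expand((3, 3)) == 0
        crit = float((rotated[mask] ** 2).sum())
        assert crit >= 0
        # flipping a rotation column leaves the criterion unchanged
        flipped = rotated.copy()
        flipped[:, 0] = -flipped[:, 0]
        assert float((flipped[mask] ** 2).sum()) == pytest.approx(crit)


class TestDisco:
    def test_herring_two_common_two_distinctive(self, herring):
        structure, model, table = ss.disco_sca(herring, 4)
        assert structure.column_multiset() == (
            (1, 1), (1, 1), (1, 0), (0, 1),
        )

    def test_synthetic_recovery(self):
        status = np.array([[1, 1, 1, 0], [1, 1, 0, 1]])
        design = ss.SimulationDesign(
            I=40, J=(8, 7), R=4, structure=ss.TargetStructure(status),
            noise_proportion=0.02, balance_blocks=True, seed=0,
        )
        data, _, _ = ss.simulate_multiblock(design)
        selected, _, _ = ss.disco_sca(data, 4)
        assert selected.column_multiset() == ss.TargetStructure(status).column_multiset()

    def test_asymmetric_toy_zero_loading(self, rng):
        t = rng.standard_normal(30)
        t -= t.mean()
        t /= np.linalg.norm(t)
        X1 = np.outer(t, rng.standard_normal(5))
        X2 = rng.standard_normal((30, 4)) * 1e-3
        raw = ss.MultiblockData(
            [X1, X2], [f"s{i}" for i in range(30)], ["a", "b"],
            [[f"a{j}" for j in range(5)], [f"b{j}" for j in range(4)]],
        )
        data = ss.pre_process(raw, ss.PreprocessConfig(scale_mode="none"))
        selected, _, _ = ss.disco_sca(data, 1, criterion="zero_loading")
        np.testing.assert_array_equal(selected.status.ravel(), [1, 0])

    def test_vaf_balance_rejects_r1(self, small_data):
        with pytest.raises(ValueError, match="R >= 2"):
            ss.disco_sca(small_data, 1)

    def test_rotated_model_consistent(self, herring):
        _, model, _ = ss.disco_sca(herring, 3)
        # rotation preserves the fit: T P' identical to the unrotated SCA fit
        base = ss.fit_sca(herring, 3)
        np.testing.assert_allclose(
            model.reconstruct(), base.reconstruct(), atol=1e-8
        )


class TestPcaGca:
    def test_identical_blocks_share_everything(self, rng):
        X = rng.standard_normal((25, 6))
        raw = ss.MultiblockData(
            [X, X.copy()], [f"s{i}" for i in range(25)], ["a", "b"],
            [[f"a{j}" for j in range(6)], [f"b{j}" for j in range(6)]],
        )
        data = ss.pre_process(raw)
        report = ss.pca_gca(data, [3, 3])
        np.testing.assert_allclose(report.pair_correlations[(0, 1)], 1.0, atol=1e-8)
        assert report.pair_common[(0, 1)] == 3

    def test_independent_blocks_share_nothing(self):
        data = make_multiblock(2000, (4, 4), seed=17)
        report = ss.pca_gca(data, [2, 2])
        assert report.pair_common[(0, 1)] == 0
        assert report.pair_correlations[(0, 1)].max() < 0.2

    def test_herring_two_common(self, herring):
        report = ss.pca_gca(herring, [3, 3], threshold=0.7)
        assert report.pair_common[(0, 1)] == 2
        assert report.implied_R == 4
        assert report.implied_structure.column_multiset() == (
            (1, 1), (1, 1), (1, 0), (0, 1),
        )

    def test_threshold_monotonicity(self, herring):
        counts = [
            ss.pca_gca(herring, [3, 3], threshold=t).pair_common[(0, 1)]
            for t in (0.3, 0.5, 0.7, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_invalid_threshold(self, herring):
        with pytest.raises(ValueError):
            ss.pca_gca(herring, [3, 3], threshold=1.5)

    def test_three_blocks_pairwise_only(self):
        data = make_multiblock(30, (4, 4, 3), seed=23)
        report = ss.pca_gca(data, [2, 2, 2])
        assert set(report.pair_common) == {(0, 1), (0, 2), (1, 2)}
        assert report.implied_structure is None


class TestEigenScreen:
    def test_rank_two_block(self, rng):
        A = rng.standard_normal((15, 2)) @ rng.standard_normal((2, 6))
        raw = ss.MultiblockData(
            [A], [f"s{i}" for i in range(15)], ["x"],
            [[f"v{j}" for j in range(6)]],
        )
        eig, cum = ss.eigen_screen(
            ss.pre_process(raw, ss.PreprocessConfig(scale_mode="none")), 0
        )
        assert (eig[:2] > 1e-10).all()
        np.testing.assert_allclose(eig[2:], 0.0, atol=1e-10)

    def test_trace_identity(self, herring):
        eig, _ = ss.eigen_screen(herring, 0)
        total = (herring.blocks[0] ** 2).sum() / (herring.n_samples - 1)
        assert eig.sum() == pytest.approx(total)

    def test_matches_svd(self, medium_data):
        eig, cum = ss.eigen_screen(medium_data, 1, max_R=4)
        s = np.linalg.svd(medium_data.blocks[1], compute_uv=False)
        np.testing.assert_allclose(eig, s[:4] ** 2 / 19)
        assert cum[-1] <= 1 + 1e-12

    def test_max_r_bound(self, medium_data):
        with pytest.raises(ValueError):
            ss.eigen_screen(medium_data, 0, max_R=99)


@given(st.integers(2, 3), st.integers(1, 3))
@settings(max_examples=20, deadline=None)
def test_enumeration_count_formula(K, R):
    import math

    out = ss.enumerate_structures(K, R)
    assert len(out) == math.comb(2**K - 1 + R - 1, R)
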