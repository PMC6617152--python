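import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ddspls import (
    BlockDataset,
    block_weights,
    cross_covariance,
    fit_ddspls,
    generate_multiblock,
    load_model,
    nipals_first_component,
    predict,
    save_model,
    select_lambda,
    soft_threshold,
    standardize,
    study_preset,
    super_weights,
)
from ddspls.core import CrossCovariance
from ddspls.errors import NoSignalError, ParameterError

from conftest import planted_spec, random_dataset


# ---------------------------------------------------------------- oracles ---


def brute_force_lambda(matrices, L0):
    """Enumerate every candidate threshold (entry values and midpoints) and
    return the smallest with <= L0 surviving columns, with the survivor set.

    Independent of the implementation path: applies the soft-threshold
    operator explicitly and counts non-null columns.
    """

    def survivors(lam):
        out = []
        for M in matrices:
            S = np.sign(M) * np.maximum(np.abs(M) - lam, 0.0)
            out.append(np.abs(S).sum(axis=0) > 0)
        return out

    entries = np.concatenate([np.abs(M).ravel() for M in matrices])
    cands = np.unique(np.concatenate([[0.0], entries]))
    cands = np.unique(np.concatenate([cands, (cands[:-1] + cands[1:]) / 2]))
    feasible = [
        lam for lam in cands if sum(s.sum() for s in survivors(lam)) <= L0
    ]
    lam = min(feasible)
    return lam, survivors(lam)


def _cc_from_rows(rows):
    mats = {f"B{k}": np.asarray(M, float) for k, M in enumerate(rows)}
    return CrossCovariance(
        matrices=mats,
        column_max={k: np.abs(M).max(axis=0) for k, M in mats.items()},
    )


# --------------------------------------------------------- soft threshold ---


class TestSoftThreshold:
    def test_identity_at_zero(self):
        x = np.array([-2.0, -0.1, 0.0, 0.3, 5.0])
        np.testing.assert_array_equal(soft_threshold(x, 0.0), x)

    def test_small_value_zeroed(self):
        assert soft_threshold(0.5, 1.0) == 0.0

    def test_negative_value(self):
        assert soft_threshold(-0.8, 0.3) == pytest.approx(-0.5)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ParameterError):
            soft_threshold(1.0, -0.1)

    @given(
        st.floats(-100, 100, allow_nan=False),
        st.floats(0, 100, allow_nan=False),
    )
    @settings(max_examples=200)
    def test_matches_closed_form(self, x, lam):
        expected = np.sign(x) * max(abs(x) - lam, 0.0)
        assert soft_threshold(x, lam) == expected

    @given(st.floats(0, 10), st.floats(0, 10), st.floats(-5, 5))
    @settings(max_examples=100)
    def test_shrinkage_monotone_in_lambda(self, l1, l2, x):
        lo, hi = sorted([l1, l2])
        assert abs(soft_threshold(x, hi)) <= abs(soft_threshold(x, lo))


# -------------------------------------------------------- cross covariance ---


class TestCrossCovariance:
    def test_identical_column_gives_one(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(10)
        ds = BlockDataset(
            blocks={"X": np.column_stack([x, rng.standard_normal(10)])},
            block_column_names={"X": ["a", "b"]},
            response=x[:, None].copy(),
            response_names=["y"],
            row_ids=[str(i) for i in range(10)],
        )
        std, _ = standardize(ds)
        cc = cross_covariance(std)
        assert cc.matrices["X"][0, 0] == pytest.approx(1.0)

    def test_shapes(self, small_data):
        std, _ = standardize(small_data)
        cc = cross_covariance(std)
        for name, X in small_data.blocks.items():
            assert cc.matrices[name].shape == (small_data.q, X.shape[1])

    def test_independent_noise_near_zero(self):
        ds = random_dataset(seed=3, n=1000, block_sizes=(30,), q=3)
        std, _ = standardize(ds)
        cc = cross_covariance(std)
        frac = np.mean(np.abs(cc.matrices["B1"]) < 0.15)
        assert frac >= 0.99


# ------------------------------------------------------------ lambda rule ---


class TestSelectLambda:
    def test_spec_example(self):
        cc = _cc_from_rows([[[0.9, 0.5, 0.1]]])
        lam = select_lambda(cc, L0=2)
        assert lam == pytest.approx(0.1)
        surviving = cc.all_column_max() > lam
        np.testing.assert_array_equal(surviving, [True, True, False])

    def test_budget_covers_everything(self):
        cc = _cc_from_rows([[[0.9, 0.5, 0.1]]])
        assert select_lambda(cc, L0=3) == 0.0

    def test_tie_case_undershoots(self):
        cc = _cc_from_rows([[[0.6, 0.6, 0.2]]])
        lam = select_lambda(cc, L0=1)
        assert lam == pytest.approx(0.6)
        assert int(np.sum(cc.all_column_max() > lam)) == 0

    def test_all_zero_raises(self):
        with pytest.raises(NoSignalError):
            select_lambda(_cc_from_rows([[[0.0, 0.0]]]), L0=1)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        mats = [
            rng.uniform(-1, 1, (rng.integers(1, 4), rng.integers(1, 6)))
            for _ in range(3)
        ]
        L0 = int(rng.integers(1, 8))
        cc = _cc_from_rows(mats)
        lam = select_lambda(cc, L0)
        lam_oracle, surv_oracle = brute_force_lambda(mats, L0)
        assert lam == pytest.approx(lam_oracle, abs=0)
        for (name, M), s in zip(cc.matrices.items(), surv_oracle):
            np.testing.assert_array_equal(cc.column_max[name] > lam, s)

    def test_surviving_count_monotone_in_lambda(self):
        rng = np.random.default_rng(9)
        M = rng.uniform(-1, 1, (3, 12))
        colmax = np.abs(M).max(axis=0)
        counts = [int(np.sum(colmax > lam)) for lam in np.sort(colmax)]
        assert counts == sorted(counts, reverse=True)


# ----------------------------------------------------------- SVD weights ---


class TestBlockWeights:
    def test_rank_one(self):
        a = np.array([1.0, -2.0])
        b = np.array([3.0, 0.0, 4.0])
        U = block_weights({"X": np.outer(a, b)}, R=2)["X"]
        np.testing.assert_allclose(np.abs(U[:, 0]), b / 5.0, atol=1e-12)
        np.testing.assert_array_equal(U[:, 1], 0.0)
        assert U[np.argmax(np.abs(U[:, 0])), 0] > 0  # sign convention

    def test_all_zero_block(self):
        U = block_weights({"X": np.zeros((2, 4))}, R=2)["X"]
        np.testing.assert_array_equal(U, 0.0)

    def test_orthonormal_columns(self):
        rng = np.random.default_rng(4)
        M = rng.standard_normal((3, 5))
        U = block_weights({"X": M}, R=2)["X"]
        np.testing.assert_allclose(U.T @ U, np.eye(2), atol=1e-10)

    def test_matches_numpy_svd_subspace(self):
        rng = np.random.default_rng(8)
        M = rng.standard_normal((4, 7))
        U = block_weights({"X": M}, R=3)["X"]
        V = np.linalg.svd(M)[2][:3].T
        for j in range(3):
            assert abs(U[:, j] @ V[:, j]) == pytest.approx(1.0, abs=1e-10)


class TestSuperWeights:
    def test_zero_scores(self):
        Y = np.random.default_rng(0).standard_normal((8, 2))
        slices, stacked = super_weights(np.zeros((8, 4)), Y, R=2)
        assert len(slices) == 2
        for b in slices:
            np.testing.assert_array_equal(b, 0.0)

    def test_single_block_aligned_scores(self):
        # scores already maximally covariant with Y: beta ~ identity up to
        # sign/rotation inside the component subspace
        rng = np.random.default_rng(1)
        Y = rng.standard_normal((50, 2))
        Y = (Y - Y.mean(0)) / Y.std(0, ddof=1)
        scores = Y @ np.diag([2.0, 1.0])  # aligned, different strengths
        slices, _ = super_weights(scores, Y, R=2)
        beta = slices[0]
        np.testing.assert_allclose(np.abs(beta), np.eye(2), atol=0.2)

    def test_shape_contract(self):
        rng = np.random.default_rng(2)
        Y = rng.standard_normal((10, 3))
        scores = rng.standard_normal((10, 6))  # T=3, R=2
        slices, stacked = super_weights(scores, Y, R=2)
        assert len(slices) == 3 and stacked.shape == (6, 2)
        super_comp = scores @ stacked
        assert super_comp.shape == (10, 2)


# ------------------------------------------------------------------- fit ---


class TestFit:
    def test_noiseless_recovery(self):
        spec = planted_spec(seed=5, n=20, noise=0.0)
        data, truth = generate_multiblock(spec)
        model = fit_ddspls(data, R=1, L0=3)
        assert model.selected_covariates == truth.active_set
        resid = np.linalg.norm(predict(model, data) - data.response)
        assert resid < 1e-8

    def test_all_tied_at_zero_gives_intercept_only(self):
        ds = random_dataset(seed=6, n=6, block_sizes=(3,), q=2)
        ds.blocks["B1"][:] = 1.0  # constant block: all cross-covariances zero
        model = fit_ddspls(ds, R=1, L0=1)
        assert model.selected_covariates == set()
        preds = predict(model, ds)
        np.testing.assert_allclose(
            preds, np.broadcast_to(ds.response.mean(0), ds.response.shape)
        )

    def test_budget_respected(self):
        for seed in range(10):
            ds = random_dataset(seed=seed, n=10, block_sizes=(6, 5), q=3)
            for L0 in (1, 3, 7):
                model = fit_ddspls(ds, R=2, L0=L0)
                assert len(model.selected_covariates) <= L0

    def test_unselected_rows_exactly_zero(self):
        ds = random_dataset(seed=13, n=12, block_sizes=(8, 8), q=2)
        model = fit_ddspls(ds, R=1, L0=3)
        for name in ds.block_names:
            sel = {c for b, c in model.selected_covariates if b == name}
            for j, col in enumerate(ds.block_column_names[name]):
                row = model.regression[name][j]
                if col not in sel:
                    np.testing.assert_array_equal(row, 0.0)
                else:
                    assert np.abs(row).sum() > 0

    def test_study_preset_blocks(self):
        data, truth = generate_multiblock(study_preset(seed=0))
        model = fit_ddspls(data, R=2, L0=7)
        blocks_selected = {b for b, _ in model.selected_covariates}
        assert blocks_selected == {"GB", "TB"}
        assert "performance" not in blocks_selected
        assert model.selected_responses == {"SM", "VL"}

    def test_r_cannot_exceed_q(self, small_data):
        with pytest.raises(ParameterError):
            fit_ddspls(small_data, R=small_data.q + 1, L0=2)

    def test_weight_columns_bounded_by_rank(self):
        # rank-1 planted signal, R=2: second weight column must be zero
        spec = planted_spec(seed=2, n=30, noise=0.0, q=2)
        data, _ = generate_multiblock(spec)
        model = fit_ddspls(data, R=2, L0=3)
        for name in ("X1", "X2"):
            U = model.block_weights[name]
            assert np.abs(U[:, 1]).max() < 1e-8


class TestPredict:
    def test_intercept_only_predicts_means(self):
        ds = random_dataset(seed=20, n=8, block_sizes=(4,), q=2)
        ds.blocks["B1"][:] = 2.5
        model = fit_ddspls(ds, R=1, L0=2)
        preds = predict(model, ds)
        assert np.ptp(preds, axis=0).max() == 0.0

    def test_noiseless_exact(self):
        spec = planted_spec(seed=8, n=25, noise=0.0)
        data, _ = generate_multiblock(spec)
        model = fit_ddspls(data, R=1, L0=3)
        np.testing.assert_allclose(predict(model, data), data.response, atol=1e-6)

    def test_rescaling_invariance(self):
        ds = random_dataset(seed=30, n=14, block_sizes=(5, 4), q=2)
        base = predict(fit_ddspls(ds, R=1, L0=4), ds)
        scaled = ds.subset_rows(range(ds.n))
        scaled.blocks["B1"][:, 2] *= 1000.0
        other = predict(fit_ddspls(scaled, R=1, L0=4), scaled)
        np.testing.assert_allclose(base, other, atol=1e-8)

    def test_unknown_block_rejected(self, small_data):
        from ddspls.errors import SchemaError

        model = fit_ddspls(small_data, R=1, L0=2)
        with pytest.raises(SchemaError):
            predict(model, {"wrong": np.zeros((2, 3))})


# ----------------------------------------------------------------- NIPALS ---


class TestNipals:
    def test_one_hot_cross_covariance(self):
        # orthogonal columns so Y'X is one-hot
        rng = np.random.default_rng(0)
        A = rng.standard_normal((30, 5))
        X = np.linalg.qr(A - A.mean(0))[0]  # zero-mean orthonormal columns
        y = X[:, 3:4].copy()
        u, v, t, s = nipals_first_component(X, y)
        assert abs(u[3]) == pytest.approx(1.0, abs=1e-6)
        assert abs(v[0]) == pytest.approx(1.0, abs=1e-12)

    def test_unit_norms(self):
        rng = np.random.default_rng(5)
        u, v, t, s = nipals_first_component(
            rng.standard_normal((12, 6)), rng.standard_normal((12, 2))
        )
        assert np.linalg.norm(u) == pytest.approx(1.0, abs=1e-12)
        assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-12)

    def test_zero_cross_covariance_raises(self):
        X = np.eye(4)
        Y = np.zeros((4, 2))
        with pytest.raises(NoSignalError):
            nipals_first_component(X, Y)

    @pytest.mark.parametrize("seed", range(20))
    def test_svd_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((15, 7))
        Y = rng.standard_normal((15, 3))
        u = nipals_first_component(X, Y)[0]
        v1 = np.linalg.svd(Y.T @ X)[2][0]
        assert abs(u @ v1) >= 1 - 1e-8

    def test_equivalence_with_single_block_fit(self):
        # T=1, lambda=0 (budget covers all), R=1: ddsPLS weight == NIPALS u
        ds = random_dataset(seed=41, n=20, block_sizes=(6,), q=3)
        model = fit_ddspls(ds, R=1, L0=6)
        assert model.lambda_ == 0.0
        std, _ = standardize(ds)
        u = nipals_first_component(std.blocks["B1"], std.response)[0]
        w = model.block_weights["B1"][:, 0]
        assert abs(u @ w) >= 1 - 1e-8


# ---------------------------------------------------------- serialization ---


def test_model_json_round_trip(tmp_path):
    ds = random_dataset(seed=50, n=15, block_sizes=(6, 3), q=2)
    model = fit_ddspls(ds, R=2, L0=4)
    path = tmp_path / "model.json"
    save_model(model, path)
    back = load_model(path)
    np.testing.assert_array_equal(predict(model, ds), predict(back, ds))
    assert back.selected_covariates == model.selected_covariates
    assert back.lambda_ == model.lambda_
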