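import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tauconnect import (
    ConnectivityMatrix,
    fisher_z,
    functional_connectivity,
    group_average,
    pet_covariance,
    vectorize_upper,
)
from tauconnect.connectivity import ConnectivityError, R_CLIP

from conftest import make_subject_table


class TestFisherZ:
    def test_fixed_points_and_closed_form(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(np.arctanh(0.5))
        assert fisher_z(0.5) == pytest.approx(0.5493061443340549, abs=1e-12)

    def test_perfect_correlation_is_clipped_finite(self):
        z = fisher_z(1.0)
        assert np.isfinite(z)
        assert z == pytest.approx(np.arctanh(1 - R_CLIP))
        assert 8 < z < 9

    def test_out_of_range_rejected(self):
        with pytest.raises(ConnectivityError):
            fisher_z(1.001)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.floats(-7.9, 7.9))
    def test_inverse_of_tanh_on_interior(self, z):
        assert fisher_z(np.tanh(z)) == pytest.approx(z, abs=1e-9)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.floats(-0.999, 0.999), st.floats(-0.999, 0.999))
    def test_monotone_and_odd(self, r1, r2):
        if r1 < r2:
            assert fisher_z(r1) < fisher_z(r2)
        assert fisher_z(-r1) == pytest.approx(-fisher_z(r1), abs=1e-12)


class TestFunctionalConnectivity:
    def test_matches_hand_computed_pearson(self):
        ts = np.array(
            [[1.0, 2.0, 0.5], [2.0, 1.5, 1.0], [3.0, 4.0, 0.0], [4.0, 3.0, 2.0], [5.0, 6.0, 1.0]]
        )
        fc = functional_connectivity(ts)
        for i in range(3):
            for j in range(i + 1, 3):
                xi, xj = ts[:, i], ts[:, j]
                num = ((xi - xi.mean()) * (xj - xj.mean())).sum()
                den = np.sqrt(((xi - xi.mean()) ** 2).sum() * ((xj - xj.mean()) ** 2).sum())
                assert fc.values[i, j] == pytest.approx(np.arctanh(num / den), abs=1e-10)
        assert np.allclose(np.diag(fc.values), 0)

    def test_proportional_columns_hit_clip_value(self):
        ts = np.column_stack([np.arange(5.0), 2 * np.arange(5.0) + 1])
        fc = functional_connectivity(ts)
        assert fc.values[0, 1] == pytest.approx(np.arctanh(1 - R_CLIP))

    def test_constant_column_error_names_roi(self):
        ts = np.column_stack([np.arange(5.0), np.zeros(5)])
        with pytest.raises(ConnectivityError, match=r"\[2\]"):
            functional_connectivity(ts)

    def test_invariant_to_affine_rescaling(self, rng):
        ts = rng.normal(size=(60, 4))
        fc1 = functional_connectivity(ts)
        ts2 = ts.copy()
        ts2[:, 2] = 5.0 - 3.2 * ts2[:, 2]
        fc2 = functional_connectivity(ts2)
        keep = np.abs(fc1.values)  # sign of row/col 2 flips under negative scale
        assert np.allclose(np.abs(fc2.values), keep, atol=1e-10)


class TestGroupAverage:
    def _mat(self, values):
        return ConnectivityMatrix(values=values, kind="functional")

    def test_idempotent_on_identical_inputs(self, rng):
        v = rng.normal(size=(4, 4))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        avg = group_average([self._mat(v), self._mat(v)], group="NC")
        assert np.allclose(avg.values, v)
        assert avg.n_subjects == 2

    def test_opposite_matrices_cancel(self, rng):
        v = rng.normal(size=(4, 4))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        avg = group_average([self._mat(v), self._mat(-v)], group="AD")
        assert np.allclose(avg.values, 0)

    def test_matches_loop_mean(self, rng):
        mats = []
        for _ in range(5):
            v = rng.normal(size=(3, 3))
            v = (v + v.T) / 2
            np.fill_diagonal(v, 0)
            mats.append(self._mat(v))
        avg = group_average(mats, group="NC")
        expect = sum(m.values for m in mats) / 5
        assert np.allclose(avg.values, expect, atol=1e-15)


class TestPetCovariance:
    def _table(self, tau, groups=None):
        tau = np.asarray(tau, float)
        groups = groups or ["AD"] * tau.shape[0]
        return make_subject_table(tau=tau, fdg=np.ones_like(tau) + 0.5, groups=groups)

    def test_matches_rank_then_pearson_oracle(self, rng):
        tau = rng.uniform(0.8, 2.5, (5, 3))
        cov = pet_covariance(self._table(tau), "AD", "tau")
        for i in range(3):
            for j in range(i + 1, 3):
                ri = stats.rankdata(tau[:, i])
                rj = stats.rankdata(tau[:, j])
                expect = np.corrcoef(ri, rj)[0, 1]
                assert cov.values[i, j] == pytest.approx(np.arctanh(expect), abs=1e-10)

    def test_identical_rank_order_is_clipped_unit(self):
        tau = np.column_stack([np.arange(1, 6.0), np.exp(np.arange(5.0))])
        cov = pet_covariance(self._table(tau), "AD", "tau")
        assert cov.values[0, 1] == pytest.approx(np.arctanh(1 - R_CLIP))

    def test_invariant_to_monotone_transforms(self, rng):
        tau = rng.uniform(0.8, 2.5, (8, 4))
        base = pet_covariance(self._table(tau), "AD", "tau")
        warped = tau.copy()
        warped[:, 0] = np.exp(warped[:, 0])
        warped[:, 2] = warped[:, 2] ** 3
        assert np.allclose(
            pet_covariance(self._table(warped), "AD", "tau").values, base.values, atol=1e-12
        )

    def test_constant_suvr_error_names_roi(self):
        tau = np.column_stack([np.arange(1, 6.0), np.full(5, 1.3)])
        with pytest.raises(ConnectivityError, match=r"\[2\]"):
            pet_covariance(self._table(tau), "AD", "tau")

    def test_too_few_subjects_rejected(self, rng):
        tau = rng.uniform(0.8, 2.5, (3, 3))
        with pytest.raises(ConnectivityError, match=">= 4"):
            pet_covariance(self._table(tau), "AD", "tau")

    def test_covariate_equal_to_ranked_suvr_removes_all_structure(self, rng):
        tau = rng.uniform(0.8, 2.5, (10, 3))
        table = self._table(tau)
        # make age exactly the ranks of ROI 1's SUVR within the AD group
        table.subjects.loc[:, "age"] = stats.rankdata(tau[:, 0])
        cov = pet_covariance(table, "AD", "tau", covariates=("age",))
        assert np.allclose(cov.values[0, 1:], 0.0, atol=1e-8)
        assert cov.adjusted_for == ("age",)

    def test_partial_matches_residualization_oracle(self, rng):
        tau = rng.uniform(0.8, 2.5, (12, 3))
        table = self._table(tau)
        cov = pet_covariance(table, "AD", "tau", covariates=("age", "education"))
        Z = np.column_stack(
            [
                np.ones(12),
                table.subjects["age"].to_numpy(float),
                table.subjects["education"].to_numpy(float),
            ]
        )
        ranks = stats.rankdata(tau, axis=0)
        resid = ranks - Z @ np.linalg.lstsq(Z, ranks, rcond=None)[0]
        expect = np.corrcoef(resid, rowvar=False)
        for i in range(3):
            for j in range(i + 1, 3):
                assert cov.values[i, j] == pytest.approx(np.arctanh(expect[i, j]), abs=1e-10)


class TestVectorizeUpper:
    def test_row_major_order(self):
        m = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]])
        assert np.array_equal(vectorize_upper(m), [1, 2, 3])

    def test_edge_count_at_scale(self):
        m = np.zeros((200, 200))
        assert vectorize_upper(m).size == 19900

    def test_network_mask_combinatorics(self, toy_atlas, rng):
        m = rng.normal(size=(6, 6))
        m = (m + m.T) / 2
        mask = toy_atlas.network_mask("DMN")
        edges = vectorize_upper(m, roi_mask=mask)
        assert edges.size == 1  # 2 DMN ROIs -> 1 edge
        assert edges[0] == m[0, 1]
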