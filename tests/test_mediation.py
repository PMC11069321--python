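import numpy as np
import pytest

from tauconnect import (
    ConnectivityMatrix,
    edge_mediation,
    fdg_zscores,
    hotspot_mediation,
    mediate,
    simulate_mediation_triplet,
)
from tauconnect.mediation import MediationError

from conftest import make_subject_table


def conn(values, kind="functional"):
    values = np.asarray(values, float)
    np.fill_diagonal(values, 0.0)
    return ConnectivityMatrix(values=(values + values.T) / 2, kind=kind)


class TestFdgZscores:
    def test_equal_group_means_give_zero(self):
        fdg = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]] * 2)
        table = make_subject_table(
            tau=np.ones_like(fdg) + 0.1, fdg=fdg, groups=["NC"] * 3 + ["AD"] * 3
        )
        assert np.allclose(fdg_zscores(table), 0.0)

    def test_hand_computed_value(self):
        # NC values {1,2,3} per ROI (mean 2, sd 1); AD constant 1 -> z = -1
        fdg = np.array([[1.0], [2.0], [3.0], [1.0], [1.0]])
        table = make_subject_table(
            tau=np.ones_like(fdg) * 1.5 + np.arange(5)[:, None] * 0.01,
            fdg=fdg,
            groups=["NC"] * 3 + ["AD"] * 2,
        )
        assert fdg_zscores(table)[0] == pytest.approx(-1.0, abs=1e-12)

    def test_missing_group_rejected(self, rng):
        table = make_subject_table(
            tau=rng.uniform(1, 2, (4, 3)), fdg=rng.uniform(1, 2, (4, 3)), groups=["NC"] * 4
        )
        with pytest.raises(MediationError):
            fdg_zscores(table)

    def test_zero_nc_sd_error_names_roi(self, rng):
        fdg = rng.uniform(1, 2, (6, 3))
        fdg[:3, 1] = 1.4  # NC constant at ROI 2
        table = make_subject_table(
            tau=rng.uniform(1, 2, (6, 3)), fdg=fdg, groups=["NC"] * 3 + ["AD"] * 3
        )
        with pytest.raises(MediationError, match=r"\[2\]"):
            fdg_zscores(table)


class TestMediate:
    def test_worked_orthogonal_example_is_exact(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        m = x + np.array([1.0, -1.0, -1.0, 1.0])
        y = x + 2 * m
        res = mediate(x, m, y, n_boot=50, seed=0)
        assert res.a == pytest.approx(1.0, abs=1e-10)
        assert res.b == pytest.approx(2.0, abs=1e-10)
        assert res.c_total == pytest.approx(3.0, abs=1e-10)
        assert res.c_prime == pytest.approx(1.0, abs=1e-10)
        assert res.indirect == pytest.approx(2.0, abs=1e-10)
        assert res.proportion == pytest.approx(2.0 / 3.0, abs=1e-10)

    def test_null_b_path_has_ci_covering_zero(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(300)
        m = 0.8 * x + rng.standard_normal(300)
        y = 0.5 * x + rng.standard_normal(300)  # Y independent of M given X
        res = mediate(x, m, y, n_boot=500, seed=2)
        assert abs(res.indirect) < 0.1
        lo, hi = res.ci_indirect
        assert lo < 0 < hi
        assert not res.criteria["m_associated_with_y"]

    def test_difference_equals_product_identity(self, rng):
        for _ in range(5):
            x = rng.standard_normal(60)
            m = 0.5 * x + rng.standard_normal(60)
            y = 0.3 * x + 0.4 * m + rng.standard_normal(60)
            z = rng.standard_normal((60, 2))
            res = mediate(x, m, y, covariates=z, n_boot=10, seed=0)
            # indirect (difference method) == a*b (product method) for OLS
            assert res.indirect == pytest.approx(res.a * res.b, abs=1e-10)

    def test_generator_triplet_recovery(self):
        x, m, y = simulate_mediation_triplet(0.8, 0.5, 0.4, 5000, seed=5)
        res = mediate(x, m, y, n_boot=200, seed=6)
        assert res.proportion == pytest.approx(0.5, abs=0.05)
        assert all(res.criteria.values())

    def test_bootstrap_deterministic_under_seed(self, rng):
        x, m, y = simulate_mediation_triplet(0.8, 0.5, 0.4, 200, seed=7)
        r1 = mediate(x, m, y, n_boot=100, seed=3)
        r2 = mediate(x, m, y, n_boot=100, seed=3)
        assert r1.ci_indirect == r2.ci_indirect
        assert r1.p_indirect == r2.p_indirect

    def test_ci_width_shrinks_with_sample_size(self):
        widths = []
        for n in (200, 800, 3200):
            x, m, y = simulate_mediation_triplet(0.8, 0.5, 0.4, n, seed=11)
            res = mediate(x, m, y, n_boot=300, seed=0)
            widths.append(res.ci_indirect[1] - res.ci_indirect[0])
        assert widths[0] > widths[1] > widths[2]

    def test_collinear_mediator_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(MediationError, match="collinear"):
            mediate(x, 2 * x, x + 1.0, n_boot=10)

    def test_unstable_proportion_flagged_near_null_total_effect(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(200)
        m = rng.standard_normal(200)
        y = rng.standard_normal(200)
        xc = x - x.mean()
        y = y - xc * (xc @ y) / (xc @ xc)  # total effect exactly zero
        res = mediate(x, m, y, n_boot=20, seed=0)
        assert res.proportion is None
        assert res.proportion_unstable


class TestEdgeMediation:
    def test_no_mediation_channel_when_fc_unrelated(self, rng):
        P = 12
        tau = rng.normal(size=(P, P))
        fdg = 0.8 * tau + 0.01 * rng.normal(size=(P, P))  # y ~ pure function of x
        fc = rng.normal(size=(P, P))
        res = edge_mediation(
            conn(tau, "tau_covariance"), conn(fc), conn(fdg, "fdg_covariance"),
            n_boot=200, seed=0,
        )
        assert abs(res.proportion) < 0.05
        lo, hi = res.ci_indirect
        assert lo < 0 < hi

    def test_full_mediation_construction(self, rng):
        P = 12
        tau = rng.normal(size=(P, P))
        tau = (tau + tau.T) / 2
        fc = 0.9 * tau + 0.05 * ((lambda m: (m + m.T) / 2)(rng.normal(size=(P, P))))
        fdg = 0.7 * fc  # y depends on x only through m
        res = edge_mediation(
            conn(tau, "tau_covariance"), conn(fc), conn(fdg, "fdg_covariance"),
            n_boot=200, seed=1,
        )
        assert res.proportion == pytest.approx(1.0, abs=0.02)

    def test_mismatched_sizes_rejected(self, rng):
        with pytest.raises(MediationError):
            edge_mediation(
                conn(rng.normal(size=(5, 5)), "tau_covariance"),
                conn(rng.normal(size=(6, 6))),
                conn(rng.normal(size=(5, 5)), "fdg_covariance"),
            )


class TestHotspotMediation:
    def test_delegates_to_mediate_on_same_columns(self, rng):
        P = 6
        tau_mean = np.array([2.0, 1.1, 1.3, 1.5, 1.2, 1.4])
        fc = conn(rng.normal(size=(P, P)))
        fdg_z = rng.normal(size=P)
        res = hotspot_mediation(tau_mean, fc, fdg_z, n_boot=50, seed=4)
        targets = np.arange(P) != 0  # hotspot = argmax = ROI 0
        expect = mediate(
            tau_mean[targets], fc.values[0, targets], fdg_z[targets], n_boot=50, seed=4
        )
        assert res.a == expect.a
        assert res.c_prime == expect.c_prime
        assert res.ci_indirect == expect.ci_indirect

    def test_constant_outcome_rejected(self, rng):
        tau_mean = rng.uniform(1, 2, 8)
        fc = conn(rng.normal(size=(8, 8)))
        with pytest.raises(MediationError, match="variance"):
            hotspot_mediation(tau_mean, fc, np.zeros(8), n_boot=10)

    def test_recovers_generator_proportion_on_average(self):
        # mean recovered proportion over replicates close to a*b/(a*b+c') = 0.5;
        # single-cohort estimates are noisy (39 target ROIs), the mean is not
        from tauconnect import CohortConfig, simulate_cohort
        from tauconnect.connectivity import group_functional_connectivity

        props = []
        for rep in range(10):
            cohort = simulate_cohort(CohortConfig(seed=40_000 + rep))
            fc = group_functional_connectivity(cohort.timeseries_ad, "AD")
            tau_mean = cohort.subjects.group_suvr("AD", "tau").mean(axis=0)
            res = hotspot_mediation(
                tau_mean, fc, fdg_zscores(cohort.subjects), n_boot=20, seed=rep
            )
            props.append(res.proportion)
        assert np.mean(props) == pytest.approx(0.5, abs=0.2)
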