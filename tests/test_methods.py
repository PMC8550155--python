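"""The nine unmixing estimators: recovery, reductions, conventions."""

import numpy as np
import pytest

import ctsbss as c
from ctsbss.eval_sim import (
    default_lp_params,
    default_sv_params,
    generate_lp_source,
    generate_ns_source,
    generate_sv_source,
    md_index,
)
from ctsbss.methods import WEIGHT_SCHEMES

from util import match_sources_dev, random_signed_permutation


def lp_data(rng, T=10000, p=4):
    Z = np.column_stack([generate_lp_source(par, T, rng)
                         for par in default_lp_params(p)])
    Om = rng.standard_normal((p, p))
    return Z @ Om.T, Om


def sv_data(rng, T=10000, p=4):
    Z = np.column_stack([generate_sv_source(par, T, rng)
                         for par in default_sv_params(p)])
    Om = rng.standard_normal((p, p))
    return Z @ Om.T, Om


def ns_data(rng, T=10000, p=4, ar=0.0):
    Z = np.column_stack([generate_ns_source(T, rng, ar=ar) for _ in range(p)])
    Om = rng.standard_normal((p, p))
    return Z @ Om.T, Om


def mix_data(rng, T=10000, p=4):
    Z = np.column_stack(
        [generate_lp_source(par, T, rng) for par in default_lp_params(p // 2)]
        + [generate_sv_source(par, T, rng) for par in default_sv_params(p // 2)])
    Om = rng.standard_normal((p, p))
    return Z @ Om.T, Om


class TestAmuse:
    def test_recovers_ar_sources(self, rng):
        Z = np.column_stack([generate_lp_source({"ar": [phi]}, 10000, rng)
                             for phi in (0.9, 0.2)])
        Om = rng.standard_normal((2, 2))
        res = c.amuse(Z @ Om.T, tau=1)
        assert md_index(res.unmixing, Om).value < 0.1

    def test_population_matrices_exact(self, rng):
        # build data whose COV and S_1 are exactly the population matrices
        Om = rng.standard_normal((2, 2))
        res_gevd = c.gevd_two_matrices(Om @ Om.T, Om @ np.diag([0.9, 0.2]) @ Om.T)
        assert md_index(res_gevd.eigenvectors, Om).value < 1e-8

    def test_equal_autocorrelations_warn(self, rng):
        Z = np.column_stack([generate_lp_source({"ar": [0.5]}, 5000, rng)
                             for _ in range(2)])
        res = c.amuse(Z, tau=1)
        assert res.diagnostics["gap_warning"]

    def test_requires_positive_lag(self, rng):
        with pytest.raises(ValueError):
            c.amuse(rng.standard_normal((100, 2)), tau=0)

    def test_gamma_whitens_covariance(self, rng):
        X, _ = lp_data(rng, T=3000)
        res = c.amuse(X, 1)
        _, cov = c.sample_mean_cov(X)
        assert np.abs(res.unmixing @ cov @ res.unmixing.T - np.eye(4)).max() < 1e-8


class TestSobi:
    def test_single_lag_reduces_to_amuse(self, rng):
        X, _ = lp_data(rng, T=5000)
        r_sobi = c.sobi(X, lags=[1])
        r_amuse = c.amuse(X, tau=1)
        assert md_index(r_sobi.unmixing @ np.linalg.inv(r_amuse.unmixing),
                        np.eye(4)).value < 1e-6

    def test_recovers_arma_sources(self, rng):
        X, Om = lp_data(rng)
        res = c.sobi(X)
        assert md_index(res.unmixing, Om).value < 0.2

    def test_rejects_lag_zero(self, rng):
        with pytest.raises(ValueError, match="positive"):
            c.sobi(rng.standard_normal((100, 2)), lags=[0, 1])

    def test_sources_unit_variance(self, rng):
        X, _ = lp_data(rng, T=3000)
        res = c.sobi(X)
        _, cov = c.sample_mean_cov(res.sources)
        assert np.abs(cov - np.eye(4)).max() < 1e-6


class TestGfobi:
    def test_lag0_is_fobi_on_iid_nongaussian(self, rng):
        S = np.column_stack([
            rng.uniform(-np.sqrt(3), np.sqrt(3), 20000),
            rng.laplace(scale=1 / np.sqrt(2), size=20000),
            rng.standard_normal(20000),
        ])
        Om = rng.standard_normal((3, 3))
        res = c.gfobi(S @ Om.T, lags=[0])
        assert md_index(res.unmixing, Om).value < 0.1

    def test_recovers_sv_sources(self, rng):
        X, Om = sv_data(rng)
        res = c.gfobi(X)
        assert md_index(res.unmixing, Om).value < 0.2

    def test_gaussian_iid_is_degenerate(self, rng):
        res = c.gfobi(rng.standard_normal((5000, 3)), lags=[0])
        assert res.diagnostics["gap_warning"]


class TestGjade:
    def test_lag0_is_jade_on_iid_nongaussian(self, rng):
        S = np.column_stack([
            rng.uniform(-np.sqrt(3), np.sqrt(3), 20000),
            rng.laplace(scale=1 / np.sqrt(2), size=20000),
        ])
        Om = rng.standard_normal((2, 2))
        res = c.gjade(S @ Om.T, lags=[0])
        assert md_index(res.unmixing, Om).value < 0.1

    def test_no_worse_than_gfobi_on_sv(self, rng):
        X, Om = sv_data(rng)
        md_jade = md_index(c.gjade(X).unmixing, Om).value
        md_fobi = md_index(c.gfobi(X).unmixing, Om).value
        assert md_jade <= md_fobi + 0.1

    def test_gaussian_iid_criterion_near_zero(self, rng):
        res = c.gjade(rng.standard_normal((20000, 2)), lags=[0])
        assert res.diagnostics["objective"] < 0.05

    def test_warns_for_large_p(self, rng):
        X = rng.standard_normal((400, 13))
        with pytest.warns(UserWarning, match="gJADE"):
            c.gjade(X, lags=[0])


class TestVsobi:
    def test_recovers_sv_sources(self, rng):
        X, Om = sv_data(rng, T=8000)
        res = c.vsobi(X, seed=0)
        assert md_index(res.unmixing, Om).value < 0.25


class TestNssSd:
    def test_two_block_variance_recovery(self, rng):
        # distinct per-component variance ratios across the two halves
        T = 10000
        half = T // 2
        Z = rng.standard_normal((T, 3))
        Z[half:, 0] *= 3.0
        Z[half:, 1] *= 0.5
        Om = rng.standard_normal((3, 3))
        res = c.nss_sd(Z @ Om.T)
        assert md_index(res.unmixing, Om).value < 0.1

    def test_stationary_input_warns(self, rng):
        res = c.nss_sd(rng.standard_normal((4000, 3)))
        assert res.diagnostics["gap_warning"]

    def test_default_halves_recorded(self, rng):
        res = c.nss_sd(rng.standard_normal((100, 2)))
        assert res.params["T1"] == (0, 50) and res.params["T2"] == (50, 100)

    def test_unit_variance_sources(self, rng):
        X, _ = ns_data(rng, T=4000)
        res = c.nss_sd(X)
        assert np.allclose(res.sources.std(axis=0), 1.0, atol=1e-8)


class TestNssJd:
    def test_k2_equals_nss_sd_up_to_jp(self, rng):
        X, _ = ns_data(rng, T=2000)
        r_jd = c.nss_jd(X, K=2)
        r_sd = c.nss_sd(X)
        assert md_index(r_jd.unmixing @ np.linalg.inv(r_sd.unmixing),
                        np.eye(4)).value < 0.01

    def test_variance_modulated_recovery(self, rng):
        X, Om = ns_data(rng)
        res = c.nss_jd(X, K=6)
        assert md_index(res.unmixing, Om).value < 0.2


class TestNssTdJd:
    def test_lag0_only_reduces_to_nss_jd(self, rng):
        X, _ = ns_data(rng, T=3000)
        r1 = c.nss_td_jd(X, K=4, lags=[0])
        r2 = c.nss_jd(X, K=4)
        assert np.allclose(r1.unmixing, r2.unmixing, atol=1e-10)

    def test_beats_nss_jd_on_block_stationary_ar(self, rng):
        mds_td, mds_jd = [], []
        for _ in range(5):
            Z = np.column_stack([generate_ns_source(10000, rng, ar=phi,
                                                    n_blocks=6)
                                 for phi in (0.2, 0.45, 0.7, 0.9)])
            Om = rng.standard_normal((4, 4))
            X = Z @ Om.T
            mds_td.append(md_index(c.nss_td_jd(X, K=6).unmixing, Om).value)
            mds_jd.append(md_index(c.nss_jd(X, K=6).unmixing, Om).value)
        assert np.mean(mds_td) < np.mean(mds_jd)

    def test_k1_approximates_sobi_with_covariance(self, rng):
        X, Om = lp_data(rng, T=8000)
        res = c.nss_td_jd(X, K=1, lags=range(0, 7))
        assert md_index(res.unmixing, Om).value < 0.2


class TestCombined:
    def test_recovers_mixed_sources(self, rng):
        X, Om = mix_data(rng)
        for scheme in WEIGHT_SCHEMES:
            res = c.nss_sobi_gfobi(X, scheme=scheme)
            assert md_index(res.unmixing, Om).value < 0.25, scheme

    def test_equal_weights_worse_than_kurtosis_on_sos_data(self, rng):
        # second-order-only sources: the unweighted B matrices drown the signal
        mds = {"equal": [], "kurtosis": []}
        for _ in range(5):
            X, Om = lp_data(rng, T=2000)
            for scheme in mds:
                res = c.nss_sobi_gfobi(X, scheme=scheme)
                mds[scheme].append(md_index(res.unmixing, Om).value)
        assert np.mean(mds["equal"]) > np.mean(mds["kurtosis"])

    def test_empty_fourth_moment_lags_reduces_to_nss_td_jd(self, rng):
        X, _ = ns_data(rng, T=3000)
        r1 = c.nss_sobi_gfobi(X, K=4, lags1=range(0, 4), lags2=[],
                              scheme="equal")
        r2 = c.nss_td_jd(X, K=4, lags=range(0, 4))
        assert np.allclose(r1.unmixing, r2.unmixing, atol=1e-10)

    def test_interval_shorter_than_lag_errors(self, rng):
        X = rng.standard_normal((120, 3))
        with pytest.raises(ValueError):
            c.nss_sobi_gfobi(X, K=6, lags1=range(0, 25), lags2=range(0, 25))

    def test_unknown_scheme_rejected(self, rng):
        with pytest.raises(ValueError, match="scheme"):
            c.nss_sobi_gfobi(rng.standard_normal((500, 3)), scheme="huber")


class TestCommonConventions:
    """Shared contracts: equivariance, determinism, sign convention."""

    METHODS = [
        ("amuse", lambda X, s: c.amuse(X, 1), 1e-6),
        ("sobi", lambda X, s: c.sobi(X), 1e-6),
        ("gfobi", lambda X, s: c.gfobi(X), 1e-6),
        ("gjade", lambda X, s: c.gjade(X), 1e-6),
        ("vsobi", lambda X, s: c.vsobi(X, seed=s), 1e-3),
        ("nss_sd", lambda X, s: c.nss_sd(X), 1e-6),
        ("nss_jd", lambda X, s: c.nss_jd(X), 1e-6),
        ("nss_td_jd", lambda X, s: c.nss_td_jd(X), 1e-6),
        ("comb_equal", lambda X, s: c.nss_sobi_gfobi(X, scheme="equal"), 1e-6),
        ("comb_kurt", lambda X, s: c.nss_sobi_gfobi(X, scheme="kurtosis"), 1e-6),
    ]

    @pytest.mark.parametrize("name,fn,tol", METHODS,
                             ids=[m[0] for m in METHODS])
    def test_affine_equivariance(self, name, fn, tol):
        rng = np.random.default_rng(99)
        X, _ = mix_data(rng, T=3000)
        A = rng.standard_normal((4, 4))
        Z1 = fn(X, 0).sources
        Z2 = fn(X @ A.T, 0).sources
        assert match_sources_dev(Z1, Z2) < tol

    @pytest.mark.parametrize("name,fn,tol", METHODS,
                             ids=[m[0] for m in METHODS])
    def test_deterministic_and_signed(self, name, fn, tol):
        rng = np.random.default_rng(7)
        X, _ = mix_data(rng, T=2000)
        r1, r2 = fn(X, 3), fn(X, 3)
        assert np.array_equal(r1.unmixing, r2.unmixing)
        for row in r1.unmixing:
            assert row[np.argmax(np.abs(row))] > 0
        assert np.linalg.matrix_rank(r1.unmixing) == 4

    def test_premixing_invariance_of_sobi_sources(self, rng):
        # sources themselves invariant (up to JP) under full-rank premixing
        X, _ = lp_data(rng, T=4000)
        A = random_signed_permutation(rng, 4) @ rng.standard_normal((4, 4))
        assert match_sources_dev(c.sobi(X).sources,
                                 c.sobi(X @ A.T).sources) < 1e-6
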