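"""Weighted-NNLS deconvolution: weights, penalty, recovery, equivalences."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import nnls

from detrem.deconvolve import (
    DeconvolutionConfig,
    common_genes,
    deconvolute,
    deconvolute_sample,
    detrem_penalty,
    music_weights,
    pooled_signature_variance,
)
from detrem.evaluate import ccc
from detrem.reference import SignatureSet
from detrem.simulate import simulate_bulk
from detrem.synthetic import default_ranges_for


def make_signature(rng, n_types=4, n_genes=60, labels=None):
    """Well-conditioned random signature with positive variance terms."""
    labels = labels or [f"t{i}" for i in range(n_types)]
    genes = [f"g{i}" for i in range(n_genes)]
    theta = rng.lognormal(0, 1, size=(n_types, n_genes))
    theta /= theta.sum(axis=1, keepdims=True)
    sigma = rng.uniform(0, 1e-6, size=(n_types, n_genes))
    pooled = pd.DataFrame(
        rng.lognormal(0, 1, size=(n_types, n_genes)), index=labels, columns=genes
    )
    return SignatureSet(
        theta=pd.DataFrame(theta, index=labels, columns=genes),
        sigma=pd.DataFrame(sigma, index=labels, columns=genes),
        cell_size=pd.Series(rng.uniform(500, 3000, n_types), index=labels),
        pooled_profile=pooled,
        pooled_normalized=pooled.div(pooled.sum(axis=1), axis=0),
    )


class TestCommonGenes:
    def test_identity_when_all_shared(self):
        sig = make_signature(np.random.default_rng(0))
        bulk = pd.DataFrame(
            np.ones((60, 2)), index=sig.theta.columns, columns=["s1", "s2"]
        )
        assert list(common_genes(sig, bulk)) == list(sig.theta.columns)

    def test_missing_and_silent_genes_excluded(self):
        sig = make_signature(np.random.default_rng(1), n_genes=10)
        bulk = pd.DataFrame(
            np.ones((9, 1)), index=list(sig.theta.columns[:9]), columns=["s1"]
        )
        bulk.loc["g3"] = 0.0  # present but unexpressed in bulk
        genes = common_genes(sig, bulk)
        assert "g9" not in genes and "g3" not in genes

    def test_invariant_to_bulk_gene_order(self):
        rng = np.random.default_rng(2)
        sig = make_signature(rng)
        bulk = pd.DataFrame(
            rng.poisson(5, size=(60, 3)).astype(float),
            index=sig.theta.columns, columns=["a", "b", "c"],
        ) + 1.0
        shuffled = bulk.sample(frac=1, random_state=0)
        assert list(common_genes(sig, bulk)) == list(common_genes(sig, shuffled))

    def test_empty_intersection_error(self):
        sig = make_signature(np.random.default_rng(3), n_genes=5)
        bulk = pd.DataFrame(np.ones((2, 1)), index=["x1", "x2"], columns=["s"])
        with pytest.raises(ValueError):
            common_genes(sig, bulk)


class TestMusicWeights:
    def test_zero_variance_zero_residual_gives_inverse_nu(self):
        sig = make_signature(np.random.default_rng(0))
        sig.sigma.iloc[:, :] = 0.0
        w = music_weights(np.zeros(60), sig, nu=1e-4)
        assert np.allclose(w, 1e4)

    def test_monotone_decreasing_in_residual(self):
        sig = make_signature(np.random.default_rng(1))
        w0 = music_weights(np.zeros(60), sig)
        w1 = music_weights(np.full(60, 0.5), sig)
        assert np.all(w1 < w0)

    def test_bounded_by_inverse_nu_and_positive(self):
        rng = np.random.default_rng(2)
        sig = make_signature(rng)
        w = music_weights(rng.normal(0, 1, 60), sig, nu=1e-4)
        assert np.all(w > 0) and np.all(w <= 1e4)

    def test_matches_elementwise_loop_oracle(self):
        rng = np.random.default_rng(4)
        sig = make_signature(rng, n_types=3, n_genes=100)
        sig.sigma.iloc[:, :] = rng.uniform(0, 0.5, size=(3, 100))
        r = rng.normal(0, 0.3, 100)
        w = music_weights(r, sig, nu=1e-4)
        theta = sig.theta.to_numpy()
        sigma = sig.sigma.to_numpy()
        s = sig.cell_size.to_numpy()
        for g in range(100):
            sigma_g = sum(
                (s[k] * theta[k, g]) ** 2 * sigma[k, g] for k in range(3)
            )
            assert np.isclose(w[g], 1.0 / (sigma_g + r[g] ** 2 + 1e-4))


class TestDetremPenalty:
    @pytest.mark.parametrize(
        "q,expected",
        [(1.0, 1.0), (2.0, 10.0), (0.5, 10.0), (2**0.05, 1.0), (2**0.2, 2.0)],
    )
    def test_penalty_values(self, q, expected):
        assert np.isclose(detrem_penalty(np.array([q]))[0], expected)

    def test_never_amplifies(self):
        rng = np.random.default_rng(0)
        q = rng.lognormal(0, 1, 500)
        assert np.all(detrem_penalty(q) >= 1.0)

    def test_monotone_in_log_discordance(self):
        q = np.array([1.0, 1.5, 2.0, 4.0])
        d = detrem_penalty(q)
        assert np.all(np.diff(d) >= 0)

    def test_literal_clamp_variant_caps_at_one(self):
        q = np.array([1.0, 2**0.05, 4.0])
        d = detrem_penalty(q, literal_clamp=True)
        assert np.allclose(d, [0.0, 0.5, 1.0])

    def test_nonpositive_quotient_rejected(self):
        with pytest.raises(ValueError):
            detrem_penalty(np.array([1.0, 0.0]))


class TestDeconvoluteSample:
    def test_exact_model_recovery(self):
        rng = np.random.default_rng(0)
        sig = make_signature(rng)
        p_true = np.array([0.4, 0.3, 0.2, 0.1])
        y = sig.theta.to_numpy().T @ p_true
        config = DeconvolutionConfig(eps=1e-6)
        p, _, converged, _, _ = deconvolute_sample(y, sig, config)
        assert converged
        assert np.allclose(p, p_true, atol=1e-6)

    def test_exact_model_is_immediate_fixed_point(self):
        rng = np.random.default_rng(1)
        sig = make_signature(rng)
        p_true = np.array([0.25, 0.25, 0.25, 0.25])
        y = sig.theta.to_numpy().T @ p_true
        _, _, converged, n_iter, _ = deconvolute_sample(y, sig)
        assert converged and n_iter == 2  # second solve confirms the first

    def test_all_zero_bulk_is_an_error(self):
        sig = make_signature(np.random.default_rng(2))
        with pytest.raises(ValueError, match="all-zero"):
            deconvolute_sample(np.zeros(60), sig)

    def test_detrem_with_unit_quotient_equals_music(self):
        rng = np.random.default_rng(3)
        sig = make_signature(rng)
        y = rng.poisson(100, 60).astype(float) + 1
        p_m, q_m, c_m, i_m, w_m = deconvolute_sample(
            y, sig, DeconvolutionConfig(method="music")
        )
        p_d, q_d, c_d, i_d, w_d = deconvolute_sample(
            y, sig, DeconvolutionConfig(method="detrem"), quotient=np.ones(60)
        )
        assert np.array_equal(p_m, p_d)
        assert np.array_equal(q_m, q_d)
        assert np.array_equal(w_m, w_d)
        assert (c_m, i_m) == (c_d, i_d)

    def test_center_normalize_flags_run_and_sum_to_one(self):
        rng = np.random.default_rng(4)
        sig = make_signature(rng)
        y = rng.poisson(200, 60).astype(float) + 1
        for center, normalize in [(True, False), (False, True), (True, True)]:
            p, _, _, _, _ = deconvolute_sample(
                y, sig, DeconvolutionConfig(center=center, normalize=normalize)
            )
            assert np.isclose(np.nansum(p), 1.0)

    def test_matches_straightline_reimplementation(self):
        """Independent straight-line implementation of the same update loop."""
        rng = np.random.default_rng(5)
        sig = make_signature(rng, n_types=3, n_genes=80)
        sig.sigma.iloc[:, :] = rng.uniform(0, 0.2, size=(3, 80))
        nu, eps = 1e-4, 0.01
        A = sig.theta.to_numpy().T
        s = sig.cell_size.to_numpy()
        sigma_g = np.zeros(80)
        for g in range(80):
            for k in range(3):
                sigma_g[g] += (s[k] * A[g, k]) ** 2 * sig.sigma.iloc[k, g]

        for trial in range(5):
            y_raw = rng.poisson(300, 80).astype(float) + 1
            y = y_raw / y_raw.sum()
            w = np.ones(80)
            p_old = None
            for _ in range(1000):
                coef, _ = nnls(A * np.sqrt(w)[:, None], y * np.sqrt(w))
                p = coef / coef.sum()
                resid = y - A @ coef
                w = 1.0 / (sigma_g + resid**2 + nu)
                if p_old is not None and np.max(np.abs(p - p_old)) < eps:
                    break
                p_old = p
            p_pkg, _, _, _, _ = deconvolute_sample(y_raw, sig)
            assert np.allclose(p_pkg, p, atol=1e-12)


@pytest.fixture(scope="module")
def sim_and_sig():
    rng = np.random.default_rng(6)
    labels = ["AST", "GAB", "MIC", "OLI", "GLU"]
    sig = make_signature(rng, n_types=5, n_genes=200, labels=labels)
    # make the signature coherent with the simulation profile so that
    # deconvolution against theta can recover the simulated proportions
    sig.theta = sig.pooled_normalized.copy()
    ranges = default_ranges_for(labels)
    sim = simulate_bulk(
        sig.pooled_normalized, ranges, 30, rng=7, depth_range=(40_000, 60_000)
    )
    return sim, sig


class TestDeconvolute:
    def test_single_sample_equals_sample_path(self, sim_and_sig):
        sim, sig = sim_and_sig
        one = sim.counts.iloc[:, [0]]
        res = deconvolute(one, sig)
        genes = common_genes(sig, one)
        p, *_ = deconvolute_sample(
            one.loc[genes].iloc[:, 0], sig, genes=genes
        )
        assert np.allclose(res.proportions.iloc[0].to_numpy(), p)

    def test_sample_permutation_permutes_rows_only(self, sim_and_sig):
        sim, sig = sim_and_sig
        res = deconvolute(sim.counts, sig)
        perm = sim.counts.sample(frac=1, axis=1, random_state=1)
        res_perm = deconvolute(perm, sig)
        aligned = res_perm.proportions.loc[res.proportions.index]
        assert np.allclose(aligned.to_numpy(), res.proportions.to_numpy())

    def test_proportions_nonnegative_rows_sum_to_one(self, sim_and_sig):
        sim, sig = sim_and_sig
        res = deconvolute(sim.counts, sig)
        props = res.proportions.to_numpy()
        assert np.nanmin(props) >= 0
        assert np.allclose(np.nansum(props, axis=1), 1.0)

    def test_deconvolution_recovers_simulated_proportions(self, sim_and_sig):
        sim, sig = sim_and_sig
        res = deconvolute(sim.counts, sig, DeconvolutionConfig(method="music"))
        truth = sim.true_proportions[res.proportions.columns]
        for label in res.proportions.columns:
            assert ccc(truth[label].to_numpy(), res.proportions[label].to_numpy()) > 0.99

    def test_detrem_full_path_with_unit_quotient_equals_music(self, sim_and_sig):
        sim, sig = sim_and_sig
        genes = common_genes(sig, sim.counts)
        ones = pd.Series(1.0, index=genes)
        res_m = deconvolute(sim.counts, sig, DeconvolutionConfig(method="music"))
        res_d = deconvolute(
            sim.counts, sig, DeconvolutionConfig(method="detrem"), quotient=ones
        )
        assert res_m.proportions.equals(res_d.proportions)
        assert res_m.final_weights.equals(res_d.final_weights)
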