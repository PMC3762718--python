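import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import wpindex as w
from wpindex.model import ParameterSet


def test_annual_detection_frequencies():
    data = np.array([[[1, 0], [-1, -1]], [[0, 1], [-1, 0]]], dtype=np.int8)
    assert list(w.annual_detection_frequencies(data)) == [2, 0]
    # pooled frequencies dominate each component's
    a = np.array([[[1, 0]]], dtype=np.int8)
    b = np.array([[[0, 1]]], dtype=np.int8)
    pooled = np.maximum(a, b)
    assert (w.annual_detection_frequencies(pooled) >= w.annual_detection_frequencies(a)).all()


def test_chi2_discrepancy_values():
    assert w.chi2_discrepancy([3, 4], [3, 4]) == 0.0
    assert w.chi2_discrepancy([10], [5]) == pytest.approx(25 / 5.5)
    # denominator uses the expected count, so the statistic is asymmetric
    assert w.chi2_discrepancy([5], [10]) == pytest.approx(25 / 10.5)
    with pytest.raises(ValueError):
        w.chi2_discrepancy([-1], [1])


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    st.lists(st.integers(min_value=0, max_value=500), min_size=1, max_size=6),
    st.lists(st.floats(min_value=0, max_value=500), min_size=1, max_size=6),
)
def test_chi2_nonnegative_and_zero_iff_equal(obs, exp):
    n = min(len(obs), len(exp))
    obs, exp = obs[:n], exp[:n]
    v = w.chi2_discrepancy(obs, exp)
    assert v >= 0
    if v == 0:
        assert np.allclose(obs, exp)


@pytest.fixture(scope="module")
def fitted():
    params = w.SpeciesSimParams("sp", beta_psi=[0.4], phi=[0.8] * 3, gamma=[0.1] * 3, p=[0.4] * 4)
    cov = w.simulate_site_covariates(60, seed=1)
    _, y = w.simulate_species(params, cov, 4, 10, seed=2)
    y = w.apply_missingness(y, 0.1, seed=3)
    spec = w.ModelSpec((), "constant", "constant", "constant", 4, 10)
    X = np.ones((60, 1))
    post = w.fit_mcmc(y, X, spec, w.MCMCConfig(2, 1200, 400, 2, seed=4))
    return y, X, spec, post


def test_bppc_well_specified_data(fitted):
    y, X, spec, post = fitted
    res = w.bppc(post, y, seed=0)
    assert res.chi2_obs.shape == res.chi2_new.shape == (post.n_draws,)
    assert (res.chi2_obs >= 0).all() and (res.chi2_new >= 0).all()
    assert 0.05 < res.bayesian_p < 0.95
    assert res.bayesian_p == pytest.approx((res.chi2_new > res.chi2_obs).mean())


def test_bppc_invariant_to_site_order(fitted):
    y, X, spec, post = fitted
    perm = np.random.default_rng(0).permutation(y.shape[0])
    y2 = y[perm]
    post2 = w.PosteriorSamples(
        spec=post.spec, config=post.config, draws=post.draws,
        z=post.z[:, :, perm, :], rhat=post.rhat,
    )
    assert w.bppc(post2, y2, seed=0).bayesian_p == w.bppc(post, y, seed=0).bayesian_p


def test_bppc_detects_corrupted_data(fitted):
    y, X, spec, post = fitted
    bad = y.copy()
    bad[:, 2, :] = np.where(bad[:, 2, :] == -1, -1, 1)  # force year-3 detections
    post_bad = w.fit_mcmc(bad, X, spec, w.MCMCConfig(2, 1200, 400, 2, seed=5))
    p = w.bppc(post_bad, bad, seed=0).bayesian_p
    assert p < 0.05 or p > 0.95


def test_dic_degenerate_posterior_has_zero_pd(fitted):
    y, X, spec, post = fitted
    theta = ParameterSet(beta_psi=[0.4], phi=[0.8], gamma=[0.1], p=[0.4])
    one = {
        "beta": np.full((2, 50, 1), 0.4),
        "phi": np.full((2, 50, 1), 0.8),
        "gamma": np.full((2, 50, 1), 0.1),
        "p": np.full((2, 50, 1), 0.4),
        "psi_fs": np.full((2, 50, 4), 0.5),
        "psi_exp": np.full((2, 50, 4), 0.5),
    }
    degen = w.PosteriorSamples(spec=spec, config=post.config, draws=one, z=None)
    d = w.dic(degen, y, X, spec)
    assert d == pytest.approx(2 * w.neg_log_likelihood(y, X, spec, theta), rel=1e-10)


def test_dic_stable_across_sampler_seeds(fitted):
    y, X, spec, post = fitted
    post2 = w.fit_mcmc(y, X, spec, w.MCMCConfig(2, 1200, 400, 2, seed=99))
    assert abs(w.dic(post, y, X, spec) - w.dic(post2, y, X, spec)) < 2


def test_select_model():
    fits = [("m1", 100.0, 3), ("m2", 102.0, 4)]
    best, table = w.select_model(fits)
    assert best[0] == "m1"
    assert list(table["delta_aic"]) == [0.0, 2.0]
    # tie -> fewer parameters
    best, _ = w.select_model([("big", 100.0, 9), ("small", 100.0, 2)])
    assert best[0] == "small"
    best, _ = w.select_model([("only", 5.0, 1)])
    assert best[0] == "only"
    with pytest.raises(ValueError):
        w.select_model([])
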