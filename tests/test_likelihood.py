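import numpy as np
import pytest

import wpindex as w
from wpindex.model import ParameterSet

from _oracles import enum_dataset_loglik, enum_site_likelihood

NA = -1


@pytest.mark.parametrize(
    "row,p,z,expected",
    [
        ([1, 0], 0.5, 1, 0.25),
        ([1, 0], 0.5, 0, 0.0),
        ([NA, NA], 0.7, 1, 1.0),
        ([NA, NA], 0.7, 0, 1.0),
        ([1, 1, 0, NA], 0.3, 1, 0.3 * 0.3 * 0.7),
    ],
)
def test_within_year_prob(row, p, z, expected):
    assert w.within_year_prob(row, p, z) == pytest.approx(expected, abs=1e-12)


def test_within_year_prob_rejects_bad_entries():
    with pytest.raises(ValueError):
        w.within_year_prob([2, 0], 0.5, 1)


def test_site_likelihood_closed_forms():
    assert w.site_likelihood([[1, 0]], 0.5, 0.8, 0.2, 0.5) == pytest.approx(0.125)
    assert w.site_likelihood([[0, 0]], 0.4, 0.8, 0.2, 0.5) == pytest.approx(0.7)
    # 2 years x 1 period: enumeration over (Z1, Z2) gives 0.5*0.5*(0.8*0.5+0.2)
    assert w.site_likelihood([[1], [0]], 0.5, 0.8, 0.2, [0.5, 0.5]) == pytest.approx(0.15)


def test_site_likelihood_matches_enumeration():
    """Forward recursion equals brute-force latent-state enumeration."""
    rng = np.random.default_rng(7)
    for _ in range(50):
        T = rng.integers(1, 4)
        K = rng.integers(1, 4)
        psi1 = rng.uniform(0.05, 0.95)
        phi = rng.uniform(0.05, 0.95, size=max(T - 1, 1))
        gamma = rng.uniform(0.05, 0.95, size=max(T - 1, 1))
        p = rng.uniform(0.05, 0.95, size=T)
        hist = rng.choice([0, 1, NA], size=(T, K), p=[0.5, 0.3, 0.2])
        got = w.site_likelihood(list(hist), psi1, phi, gamma, p)
        want = enum_site_likelihood(list(hist), psi1, phi, gamma, p)
        assert got == pytest.approx(want, abs=1e-10)


def test_total_probability_sums_to_one():
    """Summed over every possible complete detection history of one site."""
    T, K = 2, 2
    psi1, phi, gamma, p = 0.37, 0.66, 0.21, 0.44
    total = 0.0
    for bits in range(2 ** (T * K)):
        hist = [[(bits >> (t * K + k)) & 1 for k in range(K)] for t in range(T)]
        total += w.site_likelihood(hist, psi1, phi, gamma, [p, p])
    assert total == pytest.approx(1.0, abs=1e-8)


def test_neg_log_likelihood_examples():
    spec = w.ModelSpec((), "constant", "constant", "constant", n_years=1, n_periods=2)
    theta = ParameterSet(beta_psi=[0.0], phi=[0.5], gamma=[0.5], p=[0.5])
    data = np.array([[[1, 0]]], dtype=np.int8)
    X = np.ones((1, 1))
    nll = w.neg_log_likelihood(data, X, spec, theta)
    assert nll == pytest.approx(-np.log(0.125), rel=1e-12)
    # independence: duplicating every site doubles the value
    data2 = np.repeat(data, 2, axis=0)
    assert w.neg_log_likelihood(data2, np.ones((2, 1)), spec, theta) == pytest.approx(2 * nll)


def test_neg_log_likelihood_matches_enumeration_oracle():
    rng = np.random.default_rng(3)
    data = rng.choice([0, 1, NA], size=(3, 3, 3), p=[0.5, 0.3, 0.2]).astype(np.int8)
    spec = w.ModelSpec((), "by_year", "by_year", "by_year", n_years=3, n_periods=3)
    theta = ParameterSet(
        beta_psi=[0.3], phi=[0.8, 0.6], gamma=[0.1, 0.3], p=[0.5, 0.4, 0.6]
    )
    X = np.ones((3, 1))
    got = w.neg_log_likelihood(data, X, spec, theta)
    from scipy.special import expit

    want = -enum_dataset_loglik(data, expit(np.full(3, 0.3)), theta.phi, theta.gamma, theta.p)
    assert got == pytest.approx(want, abs=1e-10)


def test_perfect_data_has_zero_nll_at_truth():
    """psi1=1 and p=1: the observed all-ones history is certain."""
    spec = w.ModelSpec((), "constant", "constant", "constant", n_years=2, n_periods=3)
    theta = ParameterSet(beta_psi=[30.0], phi=[1.0], gamma=[0.0], p=[1.0])
    data = np.ones((4, 2, 3), dtype=np.int8)
    assert w.neg_log_likelihood(data, np.ones((4, 1)), spec, theta) == pytest.approx(0.0, abs=1e-8)


@pytest.mark.parametrize(
    "args,expected",
    [((0.6, 0.8, 0.1), 0.52), ((0.33, 1.0, 0.0), 0.33), ((0.0, 0.7, 0.25), 0.25)],
)
def test_occupancy_recursion(args, expected):
    assert w.occupancy_recursion(*args) == pytest.approx(expected)


def test_occupancy_recursion_rejects_out_of_range():
    with pytest.raises(ValueError):
        w.occupancy_recursion(1.2, 0.5, 0.5)
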