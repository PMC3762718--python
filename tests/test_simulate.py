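import numpy as np
import pytest

import wpindex as w


def test_covariates_reproducible_and_sized():
    a = w.simulate_site_covariates(60, seed=5)
    b = w.simulate_site_covariates(60, seed=5)
    assert a.equals(b)
    assert len(a) == 60
    assert a["elevation"].between(30, 3000).all()


def test_covariate_correlation_config():
    cov = w.simulate_site_covariates(200, seed=1, canopy_corr=0.0, edge_corr=0.0)
    r1 = np.corrcoef(cov["elevation"], cov["canopy_height"])[0, 1]
    r2 = np.corrcoef(cov["elevation"], cov["edge_distance"])[0, 1]
    assert abs(r1) < 0.3 and abs(r2) < 0.3
    cov = w.simulate_site_covariates(200, seed=1, canopy_corr=-0.8)
    assert np.corrcoef(cov["elevation"], cov["canopy_height"])[0, 1] < -0.5


def _params(**kw):
    d = dict(species_id="sp", beta_psi=[0.0], phi=[0.8] * 4, gamma=[0.1] * 4, p=[0.4] * 5)
    d.update(kw)
    return w.SpeciesSimParams(**d)


def test_perfect_detection_reveals_latent_state():
    cov = w.simulate_site_covariates(50, seed=2)
    Z, y = w.simulate_species(_params(p=[1.0] * 5), cov, 5, 15, seed=3)
    assert np.array_equal((y == 1).any(axis=2), Z == 1)
    # every occupied site-year detected in every period
    assert np.array_equal(y.min(axis=2) == 1, Z == 1)


def test_frozen_dynamics():
    cov = w.simulate_site_covariates(80, seed=2)
    Z, _ = w.simulate_species(_params(phi=[1.0] * 4, gamma=[0.0] * 4), cov, 5, 5, seed=4)
    assert (Z == Z[:, :1]).all()


def test_year1_occupancy_matches_logistic_intercept():
    cov = w.simulate_site_covariates(10000, seed=6)
    Z, _ = w.simulate_species(_params(), cov, 1, 1, seed=7)
    # beta=(0,) -> psi1 = 0.5; binomial 3 SE = 3*sqrt(0.25/10000)
    assert Z[:, 0].mean() == pytest.approx(0.5, abs=0.015)


def test_occupancy_trajectory_matches_recursion():
    """Empirical occupancy follows psi_{t+1} = psi_t phi + (1-psi_t) gamma."""
    cov = w.simulate_site_covariates(5000, seed=8)
    psi1, phi, gamma = 0.6, 0.8, 0.1
    Z, _ = w.simulate_species(
        _params(beta_psi=[np.log(psi1 / (1 - psi1))], phi=[phi] * 4, gamma=[gamma] * 4),
        cov, 5, 1, seed=9,
    )
    expected = [psi1]
    for _ in range(4):
        expected.append(w.occupancy_recursion(expected[-1], phi, gamma))
    for t in range(5):
        se = np.sqrt(expected[t] * (1 - expected[t]) / 5000)
        assert Z[:, t].mean() == pytest.approx(expected[t], abs=3 * se)


def test_conditional_detection_frequency():
    cov = w.simulate_site_covariates(2000, seed=10)
    Z, y = w.simulate_species(_params(), cov, 5, 15, seed=11)
    occ = Z[:, :, None].astype(bool) & np.ones_like(y, bool)
    n = occ.sum()
    freq = (y[occ] == 1).mean()
    assert freq == pytest.approx(0.4, abs=3 * np.sqrt(0.24 / n))
    assert (y[~occ] == 0).all()


def test_missingness_modes():
    rng = np.random.default_rng(0)
    arr = rng.choice([0, 1], size=(100, 1, 100)).astype(np.int8)
    assert np.array_equal(w.apply_missingness(arr, 0.0, seed=1), arr)
    out = w.apply_missingness(arr, 0.2, seed=1)
    assert (out == -1).mean() == pytest.approx(0.2, abs=0.012)
    # NA never replaces a detection with a new one; union restores original
    restored = np.where(out == -1, arr, out)
    assert np.array_equal(restored, arr)
    # tail mode: once NA, NA until the end of the year
    tail = w.apply_missingness(arr, 0.5, seed=2, mode="tail")
    na = tail == -1
    assert (na[:, :, :-1] <= na[:, :, 1:]).all()


def test_community_reproducible_and_truth():
    scen = w.stable_scenario(seed=3)
    b1 = w.simulate_community(scen)
    b2 = w.simulate_community(w.stable_scenario(seed=3))
    assert all(np.array_equal(b1.detections[s], b2.detections[s]) for s in b1.detections)
    assert len(b1.detections) == 13
    assert np.allclose(b1.true_wpi(), 1.0)

    decl = w.simulate_community(w.hunted_decline_scenario(seed=3))
    occ = decl.true_expected_occupancy()
    for sp in ("paca", "agouti"):
        assert occ.loc[sp, 3] <= 0.6 * occ.loc[sp, 0]


def test_scenario_yaml_round_trip(tmp_path):
    scen = w.hunted_decline_scenario(seed=9)
    path = tmp_path / "scen.yaml"
    scen.to_yaml(path)
    back = w.CommunityScenario.from_yaml(path)
    assert back.n_sites == scen.n_sites and back.name == scen.name
    assert len(back.species) == len(scen.species)
    b1 = w.simulate_community(scen)
    b2 = w.simulate_community(back)
    assert all(np.array_equal(b1.detections[s], b2.detections[s]) for s in b1.detections)
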