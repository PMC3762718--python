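import numpy as np
import pandas as pd
import pytest

import wpindex as w
from wpindex.metrics import DECLINE, INCREASE, NO_CHANGE

from _oracles import scan_hpdi


def test_hpdi_uniform_grid_and_edge_cases():
    lo, hi = w.hpdi(np.arange(1, 101), 0.95)
    assert hi - lo == 94  # shortest 95-point window on the grid
    lo, hi = w.hpdi(np.full(50, 3.25))
    assert (lo, hi) == (3.25, 3.25)
    with pytest.raises(ValueError):
        w.hpdi(np.arange(10))


def test_hpdi_matches_exhaustive_scan():
    draws = np.random.default_rng(0).beta(2, 5, size=100_000)
    assert w.hpdi(draws) == scan_hpdi(draws)


def test_posterior_mode_behaviour():
    rng = np.random.default_rng(1)
    x = rng.normal(size=100_000)
    # HSM sampling noise at this n has sd ~0.08 (simulated); 0.15 is ~2 sd
    assert abs(w.posterior_mode(x) - np.median(x)) < 0.15
    assert w.posterior_mode(np.full(200, 2.5)) == 2.5
    skewed = rng.exponential(size=100_000)
    assert w.posterior_mode(skewed) < np.median(skewed)
    with pytest.raises(ValueError):
        w.posterior_mode(np.arange(50))


def _occ(arrs, species=None):
    arrs = np.asarray(arrs, dtype=float)
    species = species or [f"sp{i}" for i in range(arrs.shape[0])]
    return w.OccupancyPosterior(occ=arrs, species=species)


def test_relative_occupancy():
    occ = _occ(np.tile([[0.4], [0.4]], (1, 3))[None, :, :].repeat(2, axis=0))
    rel = w.relative_occupancy(occ)
    assert np.allclose(rel.occ, 1.0)
    occ = _occ(np.array([[[0.4], [0.2]]]))
    rel = w.relative_occupancy(occ)
    assert np.allclose(rel.occ[0, :, 0], [1.0, 0.5])
    # idempotent
    again = w.relative_occupancy(rel)
    assert np.allclose(again.occ, rel.occ)
    # zero baseline flags the species
    occ = _occ(np.array([[[0.0], [0.3]]]), species=["bad"])
    assert w.relative_occupancy(occ).flagged_species == ["bad"]


def test_wpi_geometric_mean_examples():
    n = 200
    # two species at relative occupancies 0.5 and 2.0 -> WPI 1
    occ = _occ(np.stack([
        np.tile([[0.4], [0.2]], (1, n)),
        np.tile([[0.3], [0.6]], (1, n)),
    ]))
    s = w.wpi_series(occ)
    assert np.allclose(s.draws[1], 1.0)
    assert np.allclose(s.draws[0], 1.0)  # baseline is exactly 1 in every draw
    # three species all at relative occupancy 0.25 -> WPI 0.25
    occ = _occ(np.stack([np.tile([[0.8], [0.2]], (1, n))] * 3))
    assert np.allclose(w.wpi_series(occ).draws[1], 0.25)
    # stable community: WPI identically 1, zero-width HPDI
    occ = _occ(np.tile([[0.5], [0.5], [0.5]], (1, n))[None].repeat(4, axis=0))
    s = w.wpi_series(occ)
    assert np.allclose(s.point, 1.0) and np.allclose(s.hpdi_lo, 1.0) and np.allclose(s.hpdi_hi, 1.0)


def test_wpi_permutation_invariance_and_am_gm():
    rng = np.random.default_rng(2)
    arrs = rng.uniform(0.05, 0.95, size=(5, 4, 300))
    occ = _occ(arrs)
    s1 = w.wpi_series(occ)
    perm = [3, 0, 4, 1, 2]
    s2 = w.wpi_series(_occ(arrs[perm], species=[occ.species[i] for i in perm]))
    assert np.allclose(s1.draws, s2.draws)
    rel = w.relative_occupancy(occ).occ
    assert (s1.draws <= rel.mean(axis=0) + 1e-12).all()


def test_wpi_empty_subset_rejected():
    occ = _occ(np.full((2, 3, 100), 0.5))
    with pytest.raises(ValueError):
        w.wpi_series(occ, subset=[])


def test_group_wpi_partition_and_constant_attribute():
    rng = np.random.default_rng(3)
    occ = _occ(rng.uniform(0.1, 0.9, size=(4, 3, 200)))
    attrs = pd.DataFrame(
        {
            "guild": ["carnivore", "omnivore", "carnivore", "small_herbivore"],
            "hunted": [False, False, False, False],
            "iucn_status": ["LC", "LC", "NT", "LC"],
        },
        index=pd.Index(occ.species, name="species_id"),
    )
    groups = w.group_wpi(occ, attrs, "guild")
    members = [sp for g in groups.values() for sp in g.species]
    assert sorted(members) == sorted(occ.species)  # a partition
    # constant attribute -> single group equal to the full-community WPI
    hunted = w.group_wpi(occ, attrs, "hunted")
    assert list(hunted) == ["not_hunted"]
    assert np.allclose(hunted["not_hunted"].draws, w.wpi_series(occ).draws)
    with pytest.raises(ValueError):
        w.group_wpi(occ, attrs, "elevation")


def test_lambda_classification_rules():
    n = 1000
    draws = np.vstack([np.ones(n), np.full(n, 0.8)])
    lam = w.lambda_matrix(draws)
    assert lam.classify(0, 1) == DECLINE
    draws = np.vstack([np.ones(n), np.linspace(0.8, 1.2, n)])
    assert w.lambda_matrix(draws).classify(0, 1) == NO_CHANGE
    draws = np.vstack([np.ones(n), np.linspace(1.05, 1.4, n)])
    assert w.lambda_matrix(draws).classify(0, 1) == INCREASE


def test_lambda_consistency_with_single_species_wpi():
    rng = np.random.default_rng(4)
    arrs = rng.uniform(0.1, 0.9, size=(1, 4, 300))
    occ = _occ(arrs, species=["solo"])
    s = w.wpi_series(occ)
    lam_wpi = w.lambda_matrix(s.draws)
    rel = arrs[0] / arrs[0][:1]
    lam_sp = w.lambda_matrix(rel)
    for key, d in lam_sp.draws.items():
        assert np.allclose(lam_wpi.draws[key], d)


def test_naive_occupancy():
    m = np.array([[1, 0], [0, 0]], dtype=float)
    assert w.naive_occupancy(m) == 0.5
    m = np.array([[1, 0], [np.nan, np.nan], [0, 0]])
    assert w.naive_occupancy(m) == 0.5  # all-NA site excluded
    with pytest.raises(ValueError):
        w.naive_occupancy(np.full((2, 2), np.nan))
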