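import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import wpindex as w
from wpindex.ingest import PeriodDetectionMatrix


def test_daily_matrix_marks_detection_zero_and_na(small_events):
    events, deployments = small_events
    m = w.build_daily_matrix(events, deployments, "paca", 2008)
    # site A active all 3 days, one detection on day 2 (duplicates collapse)
    assert list(m.values.loc["A"]) == [0.0, 1.0, 0.0]
    # site B active only days 1-2 of the 3-day window
    b = m.values.loc["B"]
    assert list(b[:2]) == [0.0, 0.0] and np.isnan(b.iloc[2])
    # site C starts day 2
    assert np.isnan(m.values.loc["C"].iloc[0])


def test_daily_matrix_sampled_cells_equal_deployment_effort(small_events):
    events, deployments = small_events
    m = w.build_daily_matrix(events, deployments, "paca", 2008)
    effort = int((deployments["end_date"] - deployments["start_date"]).dt.days.sum()) + len(
        deployments
    )
    assert m.n_sampled() == effort


@pytest.mark.parametrize(
    "site,date,err",
    [
        ("Z", "2008-02-02", "unknown site"),
        ("C", "2008-02-01", "outside any active deployment"),
    ],
)
def test_daily_matrix_rejects_bad_events(small_events, site, date, err):
    events, deployments = small_events
    bad = pd.concat(
        [events, pd.DataFrame({"species_id": ["paca"], "site_id": [site],
                               "date": [pd.Timestamp(date)]})]
    )
    with pytest.raises(ValueError, match=err):
        w.build_daily_matrix(bad, deployments, "paca", 2008)


def _daily(rows, species="sp", year=2008):
    vals = pd.DataFrame(np.asarray(rows, dtype=float),
                        index=[f"s{i}" for i in range(len(rows))])
    vals.columns = [f"d{j}" for j in range(vals.shape[1])]
    return w.DailyDetectionMatrix(species_id=species, year=year, values=vals)


def test_collapse_examples():
    m = w.collapse_to_periods(_daily([[1, 0, 0, 0]]), 2)
    assert list(m.values.iloc[0]) == [1.0, 0.0]
    m = w.collapse_to_periods(_daily([[np.nan, np.nan, 0, 1]]), 2)
    row = m.values.iloc[0]
    assert np.isnan(row.iloc[0]) and row.iloc[1] == 1.0
    # 30 days into 15 periods: blocks of exactly 2
    m = w.collapse_to_periods(_daily([list(range(2)) * 15]), 15)
    assert m.n_periods == 15
    # remainder days are front-loaded: 7 days into 3 periods -> 3,2,2
    m = w.collapse_to_periods(_daily([[0, 0, 1, 0, 0, 0, 0]]), 3)
    assert list(m.values.iloc[0]) == [1.0, 0.0, 0.0]


def test_collapse_rejects_more_periods_than_days():
    with pytest.raises(ValueError):
        w.collapse_to_periods(_daily([[0, 1]]), 3)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(
        st.lists(st.sampled_from([0.0, 1.0, np.nan]), min_size=6, max_size=20),
        min_size=1,
        max_size=4,
    ).filter(lambda rows: len({len(r) for r in rows}) == 1),
    st.integers(min_value=1, max_value=6),
)
def test_collapse_preserves_information(rows, n_periods):
    """Collapsing never invents detections and never hides sampled effort."""
    daily = _daily(rows)
    n_days = daily.values.shape[1]
    per = w.collapse_to_periods(daily, n_periods)
    d = daily.values.to_numpy(float)
    p = per.values.to_numpy(float)
    assert np.nansum(p == 1.0) <= np.nansum(d == 1.0) or np.nansum(d == 1.0) > 0
    # total detections preserved as "some period is 1 iff some day is 1" per site
    for i in range(d.shape[0]):
        assert ((d[i] == 1.0).any()) == ((p[i] == 1.0).any())
        # a site with any sampled day keeps at least one sampled period
        assert (~np.isnan(d[i])).any() == (~np.isnan(p[i])).any()


def test_pool_species_union_and_algebra():
    a = _daily([[1, 0], [np.nan, 0]])
    b = _daily([[0, 0], [np.nan, 1]], species="b")
    ab = w.pool_species([a, b])
    assert list(ab.values.iloc[0]) == [1.0, 0.0]
    row = ab.values.iloc[1]
    assert np.isnan(row.iloc[0]) and row.iloc[1] == 1.0
    # commutative, associative, idempotent
    ba = w.pool_species([b, a])
    assert ab == ba
    c = _daily([[0, 1], [0, np.nan]], species="c")
    assert w.pool_species([w.pool_species([a, b]), c]) == w.pool_species(
        [a, w.pool_species([b, c])]
    )
    assert w.pool_species([a, a]) == w.pool_species([a])


def test_pool_species_rejects_mismatched_shapes():
    with pytest.raises(ValueError):
        w.pool_species([_daily([[1, 0]]), _daily([[1, 0, 0]])])


def test_standardize_covariates():
    cov = pd.DataFrame(
        {"elevation": [100.0, 300.0], "forest_type": ["b_type", "a_type"]},
        index=pd.Index(["s1", "s2"], name="site_id"),
    )
    std = w.standardize_covariates(cov)
    assert np.allclose(std.values["elevation"], [-0.70710678, 0.70710678])
    assert std.reference_levels["forest_type"] == "a_type"
    assert list(std.values["forest_type_b_type"]) == [1.0, 0.0]
    # idempotence: standardizing a standardized column leaves it unchanged
    again = w.standardize_covariates(std.values[["elevation"]])
    assert np.allclose(again.values["elevation"], std.values["elevation"], atol=1e-12)


def test_standardize_rejects_constant_column():
    cov = pd.DataFrame({"elevation": [5.0, 5.0, 5.0]})
    with pytest.raises(ValueError, match="elevation"):
        w.standardize_covariates(cov)


def test_matrix_csv_round_trip(tmp_path):
    m = _daily([[1, 0, np.nan], [np.nan, np.nan, 0]])
    path = tmp_path / "m.csv"
    m.to_csv(path)
    back = w.DailyDetectionMatrix.from_csv(path, "sp", 2008)
    assert back == m
    assert "NA" in path.read_text()


def test_events_round_trip(small_events):
    events, deployments = small_events
    mats = [w.build_daily_matrix(events, deployments, sp, 2008) for sp in ("paca", "agouti")]
    ev2, dep2 = w.events_from_daily(mats)
    again = w.build_daily_matrix(ev2, dep2, "paca", 2008)
    assert again == mats[0]
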