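"""Direct standardisation and the regional inequality statistics."""

import numpy as np
import pandas as pd
import pytest

import canmorb as cm
from canmorb.rates_metrics import ESP2013_WEIGHTS, StandardisationWeights


def test_esp_weights_published_subtotals():
    """The embedded standard population reproduces its published totals."""
    assert sum(ESP2013_WEIGHTS.values()) == 100_000
    adult_bands = [b for b in ESP2013_WEIGHTS if cm.band_midpoint(b) >= 17]
    assert cm.ESP2013.subtotal(adult_bands) == 84_000
    over45 = [b for b in ESP2013_WEIGHTS if cm.band_midpoint(b) >= 47]
    assert cm.ESP2013.subtotal(over45) == 46_000


def test_restricted_weights_renormalise():
    w = cm.ESP2013.restricted(["60-64", "65-69"])
    assert w.sum() == pytest.approx(1.0)
    assert w[0] == pytest.approx(6000 / 11500)


def test_missing_band_listed_in_error():
    with pytest.raises(KeyError, match="95-99"):
        cm.ESP2013.restricted(["60-64", "95-99"])
    with pytest.raises(ValueError):
        StandardisationWeights({"60-64": -1.0})


def test_standardise_constant_rate_is_identity():
    rates = {b: 100.0 for b in ("45-49", "60-64", "85+")}
    assert cm.age_standardise(rates) == pytest.approx(100.0)


def test_standardise_two_band_arithmetic():
    w = StandardisationWeights({"a": 0.6, "b": 0.4})
    assert cm.age_standardise({"a": 50.0, "b": 150.0}, w) == pytest.approx(90.0)


def test_standardisation_is_linear():
    rng = np.random.default_rng(0)
    bands = ["45-49", "50-54", "60-64", "85+"]
    r = rng.uniform(10, 300, 4)
    s = rng.uniform(10, 300, 4)
    lhs = cm.age_standardise(dict(zip(bands, 2 * r + 3 * s)))
    rhs = 2 * cm.age_standardise(dict(zip(bands, r))) + 3 * cm.age_standardise(
        dict(zip(bands, s))
    )
    assert lhs == pytest.approx(rhs)


def point_series(rates_by_region, year=2016, gender="male"):
    return cm.StandardisedRateSeries.from_point_rates(
        pd.DataFrame(
            {
                "region": list(rates_by_region),
                "year": year,
                "gender": gender,
                "rate": list(rates_by_region.values()),
            }
        )
    )


def test_absolute_difference_point_rates():
    s = point_series({"A": 916.8, "B": 801.3, "C": 850.0})
    ad = cm.absolute_difference(s, 2016, "male")
    assert ad.point == pytest.approx(115.5)
    assert cm.round_half_away(ad.point) == 116


def test_identical_rates_give_zero_gap():
    s = point_series({"A": 100.0, "B": 100.0})
    assert cm.absolute_difference(s, 2016, "male").point == 0.0
    assert cm.relative_difference(s, 2016, "male").point == 0.0


def test_single_region_errors():
    s = point_series({"A": 100.0})
    with pytest.raises(ValueError):
        cm.absolute_difference(s, 2016, "male")


def test_relative_change_arithmetic():
    frame = pd.DataFrame(
        {
            "region": ["A", "A"],
            "year": [1981, 2016],
            "gender": "male",
            "rate": [100.0, 150.0],
        }
    )
    s = cm.StandardisedRateSeries.from_point_rates(frame)
    assert cm.relative_change(s, "A", "male").point == pytest.approx(50.0)
    frame.loc[1, "rate"] = 100.0
    s2 = cm.StandardisedRateSeries.from_point_rates(frame)
    assert cm.relative_change(s2, "A", "male").point == pytest.approx(0.0)
    with pytest.raises(ValueError):
        cm.relative_change(s, "A", "male", year0=1990)


def test_interval_from_draws_matches_direct_simulation():
    """RC interval under lognormal draws vs quantiles of the simulated
    ratio distribution (simulation oracle)."""
    rng = np.random.default_rng(4)
    n = 40_000
    r0 = 100.0 * np.exp(rng.normal(0, 0.05, n))
    r1 = 150.0 * np.exp(rng.normal(0, 0.05, n))
    frame = pd.DataFrame(
        {
            "region": ["A", "A"],
            "gender": "male",
            "year": [1981, 2016],
            "point": [r0.mean(), r1.mean()],
            "lower": [np.percentile(r0, 2.5), np.percentile(r1, 2.5)],
            "upper": [np.percentile(r0, 97.5), np.percentile(r1, 97.5)],
        }
    )
    series = cm.StandardisedRateSeries(frame, np.column_stack([r0, r1]))
    rc = cm.relative_change(series, "A", "male")
    direct = 100.0 * (r1 - r0) / r0
    assert rc.point == pytest.approx(direct.mean(), rel=1e-12)
    assert rc.lower == pytest.approx(np.percentile(direct, 2.5), rel=1e-9)
    assert rc.upper == pytest.approx(np.percentile(direct, 97.5), rel=1e-9)


def test_per_draw_gap_exceeds_gap_of_summaries():
    """E[max-min] >= max(E)-min(E): the per-draw statistic is the canonical
    one and is never smaller than the difference of point summaries."""
    rng = np.random.default_rng(11)
    draws = rng.normal(loc=[100.0, 104.0, 99.0], scale=3.0, size=(5000, 3))
    frame = pd.DataFrame(
        {
            "region": ["A", "B", "C"],
            "gender": "male",
            "year": 2016,
            "point": draws.mean(axis=0),
            "lower": np.percentile(draws, 2.5, axis=0),
            "upper": np.percentile(draws, 97.5, axis=0),
        }
    )
    series = cm.StandardisedRateSeries(frame, draws)
    per_draw = cm.absolute_difference(series, 2016, "male")
    of_points = frame["point"].max() - frame["point"].min()
    assert per_draw.point >= of_points
    assert per_draw.lower <= per_draw.point <= per_draw.upper


def test_standardised_series_from_fitted_draws(lung_fit):
    truth, table, design, draws = lung_fit
    series = cm.StandardisedRateSeries.from_draws(draws, table)
    f = series.frame
    assert set(f["gender"]) == {"male", "female"}
    assert len(f) == 9 * 2 * 36
    assert ((f["lower"] <= f["point"]) & (f["point"] <= f["upper"])).all()
    # rates in a plausible per-100k range for the default truth
    assert f["point"].between(10, 2000).all()
    ad = cm.absolute_difference(series, 2016, "male")
    assert ad.lower < ad.point < ad.upper and ad.point > 0


def test_regional_differential_sum_to_zero_and_recovery(lung_fit):
    truth, table, design, draws = lung_fit
    diff = cm.regional_differential(draws, table, age_mid=67, year=2010, gender="male")
    assert len(diff) == 9
    # per-draw identity: sum over regions of log(1 + d) is exactly zero
    sel = table.df[
        (table.df["age_mid"] == 67)
        & (table.df["year"] == 2010)
        & (table.df["gender"] == "male")
    ]
    u = draws.log_theta[:, sel.index.to_numpy()]
    logs = u - u.mean(axis=1, keepdims=True)
    np.testing.assert_allclose(logs.sum(axis=1), 0.0, atol=1e-9)
    # the North East truth effect (+0.18 log scale => ~+20%) is recovered
    ne = diff[diff["region"] == "North East"].iloc[0]
    assert ne["lower"] < np.exp(0.18) - 1 < ne["upper"]


def test_regional_differential_needs_matching_cells(lung_fit):
    _, table, _, draws = lung_fit
    with pytest.raises(ValueError):
        cm.regional_differential(draws, table, age_mid=12, year=2010, gender="male")


def test_inequality_summary_tables(lung_fit):
    _, table, _, draws = lung_fit
    series = cm.StandardisedRateSeries.from_draws(draws, table)
    out = cm.inequality_summary(series, gender="female")
    by_year, by_region = out["by_year"], out["by_region"]
    assert len(by_year) == 36 and len(by_region) == 9
    assert (by_year["AD"] >= 0).all()
    assert ((by_year["AD_lower"] <= by_year["AD"]) & (by_year["AD"] <= by_year["AD_upper"])).all()


@pytest.mark.parametrize(
    "x,nd,expected",
    [(115.5, 0, 116), (26.5, 0, 27), (-26.5, 0, -27), (0.545, 2, 0.55), (0.1249, 2, 0.12)],
)
def test_round_half_away(x, nd, expected):
    assert cm.round_half_away(x, nd) == expected


def test_published_rates_table_shape():
    pub = cm.published_rates_2016()
    assert len(pub) == 9 * 8
    assert set(pub["cancer_type"]) == {"all", "lung", "bowel", "prostate", "breast"}
    assert pub["rate"].between(100, 1000).all()
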