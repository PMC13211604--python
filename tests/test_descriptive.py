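"""Composition, detection filtering, diurnal, correlation, regression and
background-enhancement statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vhhrisk.descriptive import (
    ConcentrationMatrix,
    background_enhancement,
    composition_summary,
    correlation_matrix,
    detection_filter,
    diurnal_profile,
    enhancement_table,
    tracer_regression,
)
from vhhrisk.registry import REGULATED, UNREGULATED


def _matrix(values: np.ndarray, species, windows=None, mdls=None):
    n = len(values)
    values = pd.DataFrame(values, columns=species)
    if windows is None:
        windows = ["08:00"] * n
    ts = pd.DataFrame({"date": ["d1"] * n, "window": windows})
    if mdls is None:
        flags = pd.DataFrame(False, index=range(n), columns=species)
    else:
        flags = values.lt(pd.Series(mdls))
    return ConcentrationMatrix(values=values, timestamps=ts, below_mdl=flags)


class TestDetectionFilter:
    def test_toy_detection_fractions(self):
        # detection fractions 1.0 / 0.61 / 0.30 against a 0.60 threshold
        n = 100
        vals = np.ones((n, 3))
        vals[61:, 1] = 0.0
        vals[30:, 2] = 0.0
        m = _matrix(vals, ["a", "b", "c"], mdls={"a": 0.5, "b": 0.5, "c": 0.5})
        kept, dropped = detection_filter(m, 0.60)
        assert kept.species == ["a", "b"]
        assert dropped == ["c"]

    def test_strict_inequality_at_the_boundary(self):
        # 29/49 detected = 59.2% <= 60% -> dropped; 49/49 -> retained
        vals = np.ones((49, 2))
        vals[29:, 1] = 0.0
        m = _matrix(vals, ["full", "part"], mdls={"full": 0.5, "part": 0.5})
        kept, dropped = detection_filter(m)
        assert kept.species == ["full"] and dropped == ["part"]

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.5, 2.0])
    def test_threshold_domain(self, bad, campaign):
        with pytest.raises(ValueError):
            detection_filter(campaign.concentrations, bad)

    def test_missing_counts_as_nondetect(self):
        vals = np.ones((10, 1))
        m = _matrix(vals, ["a"])
        m.values.iloc[:5, 0] = np.nan
        m.below_mdl.iloc[:, 0] = False
        kept, dropped = detection_filter(m, 0.60)
        assert dropped == ["a"]


class TestComposition:
    def test_single_species_share_is_100(self, registry):
        m = _matrix(np.full((5, 1), 3.0), ["Freon-12"])
        s = composition_summary(m, registry)
        assert s.table["share_pct"].iloc[0] == pytest.approx(100.0)

    def test_shares_sum_to_100(self, campaign, registry):
        s = composition_summary(campaign.concentrations, registry)
        assert s.table["share_pct"].sum() == pytest.approx(100.0, abs=0.1)
        assert sum(s.group_totals.values()) == pytest.approx(s.grand_total, rel=1e-12)

    def test_empty_matrix_rejected(self, registry):
        m = _matrix(np.zeros((0, 1)).reshape(0, 1), ["Freon-12"])
        with pytest.raises(ValueError):
            composition_summary(m, registry)


class TestDiurnal:
    def test_constant_series_flat_profile(self):
        windows = ["08:00", "10:00"] * 5
        m = _matrix(np.full((10, 1), 7.0), ["a"], windows=windows)
        p = diurnal_profile(m)
        assert p.sd_of_window_means["a"] == pytest.approx(0.0)

    def test_sd_of_window_means_matches_direct_formula(self):
        # one sample per window; window means equal the planted series
        planted = [270.0, 265.0, 260.0, 255.0, 260.0, 265.0, 270.0]
        windows = ["08:00", "10:00", "12:00", "14:00", "16:00", "18:00", "20:00"]
        m = _matrix(np.array(planted).reshape(-1, 1), ["a"], windows=windows)
        p = diurnal_profile(m)
        assert np.allclose(p.window_means["a"].values, planted)
        assert p.sd_of_window_means["a"] == pytest.approx(np.std(planted, ddof=1), rel=1e-12)

    def test_planted_u_shape_recovered_from_clean_signal(self, registry):
        from vhhrisk.synthetic import default_campaign_config, generate_campaign

        cfg = default_campaign_config(registry, seed=4, noise_fraction=0.0)
        cfg.source_scales[:, 1] = 0.0  # freeze activity: pure diurnal signal
        camp = generate_campaign(cfg)
        p = diurnal_profile(camp.concentrations)
        assert p.window_means["Trichloroethylene"].idxmin() == "16:00"
        assert p.sd_of_window_means["Freon-12"] == pytest.approx(0.0, abs=1e-9)


class TestCorrelation:
    def test_perfect_and_anti_correlation(self):
        x = np.arange(10.0)
        m = _matrix(np.column_stack([x, 2 * x, 10 - x]), ["a", "b", "c"])
        r, p = correlation_matrix(m)
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert r.loc["a", "c"] == pytest.approx(-1.0)
        assert p.loc["a", "b"] < 1e-10
        assert np.allclose(np.diag(r), 1.0)

    def test_independent_columns_near_zero(self, rng):
        m = _matrix(rng.standard_normal((10_000, 2)) + 10, ["a", "b"])
        r, _ = correlation_matrix(m)
        assert abs(r.loc["a", "b"]) < 0.05

    def test_matches_bruteforce_pearson_on_toys(self, rng):
        for _ in range(5):
            vals = rng.uniform(1, 10, size=(5, 3))
            m = _matrix(vals, ["a", "b", "c"])
            r, _ = correlation_matrix(m)
            for i, ci in enumerate("abc"):
                for j, cj in enumerate("abc"):
                    xi, xj = vals[:, i], vals[:, j]
                    num = np.sum((xi - xi.mean()) * (xj - xj.mean()))
                    den = np.sqrt(np.sum((xi - xi.mean()) ** 2) * np.sum((xj - xj.mean()) ** 2))
                    assert r.loc[ci, cj] == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_column_reported_undefined(self):
        m = _matrix(np.column_stack([np.arange(5.0), np.full(5, 2.0)]), ["a", "b"])
        r, p = correlation_matrix(m)
        assert np.isnan(r.loc["a", "b"]) and np.isnan(p.loc["a", "b"])
        assert r.loc["a", "a"] == 1.0

    def test_tracer_appended(self, campaign):
        r, _ = correlation_matrix(campaign.concentrations, campaign.tracer)
        assert "CO" in r.columns
        assert r.loc["Chloromethane", "CO"] > 0.5


class TestTracerRegression:
    def test_exact_line_slope_and_zero_se(self):
        x = np.arange(10.0)
        res = tracer_regression(2 * x + 1, x)
        assert res.slope == pytest.approx(2.0)
        assert res.slope_se == pytest.approx(0.0, abs=1e-12)
        assert res.r == pytest.approx(1.0)

    def test_constant_response_zero_slope(self):
        res = tracer_regression(np.full(10, 3.0), np.arange(10.0))
        assert res.slope == pytest.approx(0.0)

    def test_recovers_planted_emission_ratio(self, rng):
        # planted slope 1.4 (the chloromethane/CO emission-ratio scale)
        x = rng.uniform(100, 400, 49)
        y = 1.4 * x + rng.normal(0, 40, 49)
        res = tracer_regression(y, x)
        assert abs(res.slope - 1.4) < 2 * res.slope_se

    def test_shift_invariance_and_response_scaling(self, rng):
        x = rng.uniform(0, 10, 30)
        y = 3 * x + rng.normal(0, 1, 30)
        base = tracer_regression(y, x).slope
        assert tracer_regression(y + 100, x).slope == pytest.approx(base, rel=1e-9)
        assert tracer_regression(y, x + 100).slope == pytest.approx(base, rel=1e-9)
        assert tracer_regression(5 * y, x).slope == pytest.approx(5 * base, rel=1e-9)

    def test_degenerate_tracer_rejected(self):
        with pytest.raises(ValueError):
            tracer_regression(np.arange(5.0), np.full(5, 1.0))


class TestEnhancement:
    def test_freon12_worked_numbers(self):
        e = background_enhancement("Freon-12", 563.0, 501.0)
        assert e.absolute_enhancement == pytest.approx(62.0)
        assert e.percent_enhancement == pytest.approx(12.4, abs=0.05)

    def test_equal_values_zero_enhancement(self):
        e = background_enhancement("x", 50.0, 50.0)
        assert e.absolute_enhancement == 0.0 and e.percent_enhancement == 0.0

    def test_freon113_worked_numbers(self):
        e = background_enhancement("Freon-113", 81.0, 71.0)
        assert e.absolute_enhancement == pytest.approx(10.0)

    def test_nonpositive_background_rejected(self):
        with pytest.raises(ValueError):
            background_enhancement("x", 10.0, 0.0)

    def test_table_covers_species_with_backgrounds(self, registry):
        means = pd.Series({r.name: r.campaign_mean for r in registry})
        table = enhancement_table(registry, means)
        assert len(table) == sum(r.background is not None for r in registry) == 11
        row = table.set_index("species").loc["Methylene chloride"]
        assert row["pct_enhancement"] > 1000  # order-of-magnitude industrial excess


@settings(derandomize=True, max_examples=30)
@given(
    st.lists(st.floats(1.0, 1e4), min_size=2, max_size=8),
)
def test_shares_always_sum_to_100(values):
    from vhhrisk.registry import SpeciesRecord, SpeciesRegistry

    names = [f"s{i}" for i in range(len(values))]
    reg = SpeciesRegistry(
        SpeciesRecord(name=n, category=UNREGULATED, molecular_weight=100.0, mdl=1.0)
        for n in names
    )
    m = _matrix(np.array(values).reshape(1, -1), names)
    s = composition_summary(m, reg)
    assert s.table["share_pct"].sum() == pytest.approx(100.0, abs=0.1)
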