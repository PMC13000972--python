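import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from windfleck import (
    allometry,
    bin_series,
    cultivar_indices,
    frequency_by_class,
    natural_frequency,
    qom_class_edges,
    variance_decomposition,
    wind_class_edges,
)
from windfleck.stats import event_mean_value, time_in_class


class TestTraitFormulas:
    @pytest.mark.parametrize("t, expected", [(3.0, 1.0), (1.5, 2.0), (6.0, 0.5)])
    def test_natural_frequency(self, t, expected):
        assert natural_frequency(t) == expected

    def test_natural_frequency_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            natural_frequency(0.0)

    def test_allometry_hand_values(self):
        a = allometry(height_cm=80, total_mass_g=10, leaf_mass_g=2,
                      leaf_area_cm2=100)
        assert a.lma == pytest.approx(0.02)
        assert a.hm == pytest.approx(8.0)
        b = allometry(height_cm=80, total_mass_g=12.5, leaf_mass_g=2.5,
                      leaf_area_cm2=100)
        assert b.ltm == pytest.approx(0.25)

    def test_ltm_nan_when_no_stem_mass(self):
        a = allometry(height_cm=80, total_mass_g=2.0, leaf_mass_g=2.0,
                      leaf_area_cm2=100)
        assert np.isnan(a.ltm)
        assert a.lma == pytest.approx(0.02)


class TestBinning:
    def test_qom_edges_are_exponential(self):
        e = qom_class_edges()
        assert e.size == 16
        assert e[0] == pytest.approx(np.exp(-11))
        assert e[-1] == pytest.approx(np.exp(-2))
        ratios = e[1:] / e[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-12)

    def test_wind_class_assignment(self):
        edges = wind_class_edges(2.4)
        labels = bin_series(np.array([0.45]), edges)
        lo, hi = edges[labels[0]], edges[labels[0] + 1]
        assert lo == pytest.approx(0.3) and hi == pytest.approx(0.6)

    def test_zero_qom_is_outside(self):
        assert bin_series(np.array([0.0]), qom_class_edges())[0] == -1

    def test_uniform_series_time_in_one_class(self):
        values = np.full(1000, 1.0)
        edges = wind_class_edges(2.4)
        labels = bin_series(values, edges)
        tic = time_in_class(labels, rate=100.0, n_classes=len(edges) - 1)
        assert tic.sum() == pytest.approx(10.0)
        assert (tic > 0).sum() == 1

    def test_half_open_edges(self):
        edges = np.array([0.0, 1.0, 2.0])
        assert list(bin_series(np.array([0.0, 1.0, 2.0]), edges)) == [0, 1, -1]


class TestFrequencyByClass:
    def test_hand_computed(self):
        freq, counts = frequency_by_class(
            np.zeros(10, dtype=int), np.array([5.0, 1.0])
        )
        assert freq[0] == pytest.approx(2.0)
        assert counts[0] == 10

    def test_single_event_class_missing(self):
        freq, _ = frequency_by_class(np.array([0]), np.array([5.0]))
        assert np.isnan(freq[0])

    def test_count_conservation(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(-1, 4, 200)
        tic = np.full(4, 10.0)
        _, counts = frequency_by_class(labels, tic)
        assert counts.sum() == (labels >= 0).sum()

    def test_zero_time_with_events_raises(self):
        with pytest.raises(ValueError):
            frequency_by_class(np.array([0, 0]), np.array([0.0]))

    def test_zero_time_as_missing(self):
        freq, _ = frequency_by_class(
            np.array([0, 0]), np.array([0.0]), on_zero_time="missing"
        )
        assert np.isnan(freq[0])


class TestCultivarIndices:
    def frame(self, sens):
        return pd.DataFrame(
            {
                "cultivar": [f"c{i}" for i in range(len(sens))],
                "mean_qom": sens,
                "mean_wind": np.ones(len(sens)),
                "fleck_frequency": np.ones(len(sens)),
            }
        )

    def test_z_scores_closed_form(self):
        out = cultivar_indices(self.frame([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out["motion_sensitivity_z"], [-1, 0, 1])

    def test_degenerate_axis_reports_zero(self):
        out = cultivar_indices(self.frame([2.0, 2.0]))
        np.testing.assert_allclose(out["motion_sensitivity_z"], 0.0)

    def test_larger_gain_larger_z(self):
        out = cultivar_indices(self.frame([0.5, 1.0]))
        z = out.set_index("cultivar")["motion_sensitivity_z"]
        assert z["c1"] > z["c0"]

    def test_zero_mean_wind_rejected(self):
        df = self.frame([1.0, 2.0])
        df.loc[0, "mean_wind"] = 0.0
        with pytest.raises(ValueError):
            cultivar_indices(df)


def trait_frame(cell_means, jitter=None):
    """cell_means: (n_varieties, n_blocks) array of variety × block means."""
    cell_means = np.asarray(cell_means, dtype=float)
    rows = []
    for i in range(cell_means.shape[0]):
        for j in range(cell_means.shape[1]):
            rows.append(
                {"cultivar": f"v{i}", "block": f"b{j}", "value": cell_means[i, j]}
            )
    return pd.DataFrame(rows)


class TestVarianceDecomposition:
    def test_no_residual_gives_h2_one(self):
        y = np.array([[10.0, 10], [12, 12], [14, 14]])
        vd = variance_decomposition(trait_frame(y))
        assert vd.sigma2_r == 0.0
        assert vd.h2 == 1.0

    def test_equal_variety_means_gives_h2_zero(self):
        y = np.array([[10.0, 12], [12, 10], [11, 11]])  # all variety means = 11
        vd = variance_decomposition(trait_frame(y))
        assert vd.h2 == 0.0
        vd0 = variance_decomposition(trait_frame(np.array([[10.0, 10]] * 4)))
        assert vd0.h2 == 0.0

    def test_literal_formula_plug(self):
        # variety means 10/12/14 (σ²=4), pooled within-variety variance 1.0:
        # the uncorrected plug gives 4/(4+1/3); the ANOVA-corrected default
        # subtracts σ̂²_r/n from the among-means variance
        d = np.sqrt(0.5)
        y = np.array([[10 - d, 10 + d], [12 - d, 12 + d], [14 - d, 14 + d]])
        n = 2
        vd_raw = variance_decomposition(trait_frame(y), correct_bias=False)
        assert vd_raw.sigma2_V == pytest.approx(4.0)
        assert vd_raw.sigma2_r == pytest.approx(1.0)
        assert vd_raw.h2 == pytest.approx(4 / (4 + 1 / n))
        vd = variance_decomposition(trait_frame(y))
        assert vd.sigma2_V == pytest.approx(4.0 - 1.0 / n)
        assert vd.h2 == pytest.approx(3.5 / (3.5 + 0.5))

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(2)
        y = rng.normal(50, 3, (8, 3))
        h0 = variance_decomposition(trait_frame(y)).h2
        assert variance_decomposition(trait_frame(y + 100)).h2 == pytest.approx(h0)
        assert variance_decomposition(trait_frame(y * 7)).h2 == pytest.approx(h0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_h2_always_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(0, rng.uniform(0.1, 10), (5, 3))
        vd = variance_decomposition(trait_frame(y))
        assert 0.0 <= vd.h2 <= 1.0
        assert 0.0 <= vd.repeatability <= 1.0
        assert vd.sigma2_V >= 0 and vd.sigma2_r >= 0

    def test_technical_replicates_preaveraged(self):
        df = trait_frame(np.array([[10.0, 12], [14, 16]]))
        df2 = pd.concat([df, df], ignore_index=True)  # duplicate replicate rows
        a = variance_decomposition(df)
        b = variance_decomposition(df2)
        assert a.h2 == pytest.approx(b.h2)

    def test_single_block_rejected(self):
        df = trait_frame(np.array([[10.0], [12.0]]))
        with pytest.raises(ValueError):
            variance_decomposition(df)


def test_event_mean_value_windows():
    class Ev:
        def __init__(self, s, e):
            self.start_time, self.end_time = s, e

    t = np.arange(100) / 100.0
    v = t.copy()
    out = event_mean_value([Ev(0.10, 0.20)], t, v)
    assert out[0] == pytest.approx(np.mean(v[10:21]), abs=0.01)
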