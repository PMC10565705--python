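import numpy as np
import pandas as pd
import pytest

import serialdep as sd
from serialdep.dogmodel import (
    DEFAULT_WIDTH_GRID,
    ModelSpec,
    bic,
    dog_basis,
    peak_bias,
    smooth_curve,
)

from conftest import make_trials


class TestDogBasis:
    def test_odd_and_zero(self):
        assert dog_basis(0.0, 30.0) == 0.0
        d = np.linspace(-90, 90, 181)
        np.testing.assert_allclose(dog_basis(-d, 22.0), -dog_basis(d, 22.0))

    def test_maximum_location_and_value(self):
        grid = np.linspace(0, 90, 900001)
        vals = dog_basis(grid, 30.0)
        k = np.argmax(vals)
        assert grid[k] == pytest.approx(30.0, abs=1e-3)
        assert vals[k] == pytest.approx(30.0 * np.exp(-0.5), abs=1e-7)
        assert 30.0 * np.exp(-0.5) == pytest.approx(18.196, abs=1e-3)

    def test_invalid_width(self):
        with pytest.raises(ValueError):
            dog_basis(10.0, -1.0)


class TestPeakBias:
    def test_zero_coefficient(self):
        assert peak_bias(0.0, 30.0)[0] == 0.0

    def test_closed_form_unit_peak(self):
        b = 1.0 / (30.0 * np.exp(-0.5))
        value, at = peak_bias(b, 30.0)
        assert value == pytest.approx(1.0)
        assert at == 30.0

    def test_matches_grid_maximum(self):
        rng = np.random.default_rng(0)
        grid = np.linspace(0, 90, 2000001)
        for _ in range(5):
            b, w = rng.uniform(0.01, 0.2), rng.uniform(12, 70)
            value, at = peak_bias(b, w)
            curve = b * dog_basis(grid, w)
            assert np.max(curve) == pytest.approx(value, abs=1e-9)
            assert grid[np.argmax(curve)] == pytest.approx(at, abs=1e-3)


class TestBIC:
    def test_extra_parameter_costs_log_n(self):
        assert bic(10.0, 500, 3) - bic(10.0, 500, 2) == pytest.approx(np.log(500))

    def test_doubling_rss(self):
        assert bic(20.0, 400, 2) - bic(10.0, 400, 2) == pytest.approx(400 * np.log(2))

    def test_guards(self):
        with pytest.raises(ValueError):
            bic(0.0, 100, 2)
        with pytest.raises(ValueError):
            bic(1.0, 3, 5)


class TestFit:
    def test_constant_zero_errors(self):
        rng = np.random.default_rng(1)
        d = rng.uniform(-90, 90, 500)
        fit = sd.fit_dog_model(d, np.zeros_like(d) + 0.0 * d, spec="d1",
                               width_grid=[20.0, 40.0])
        assert fit.params["delta1"] == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_single_kernel_recovery(self):
        d, e, _ = sd.simulate_dog_dataset(
            50000, seed=2, attract_peak=2.0, attract_width=30.0, noise_sd=8.0
        )
        fit = sd.fit_dog_model(d, e, spec="d1")
        value, at = peak_bias(fit.params["delta1"], fit.widths[0])
        assert value == pytest.approx(2.0, abs=0.3)
        assert at == pytest.approx(30.0, abs=3.0)

    def test_null_data_small_coefficient(self):
        d, e, _ = sd.simulate_dog_dataset(20000, seed=3, noise_sd=8.0)
        fit = sd.fit_dog_model(d, e, spec="d1")
        z = fit.params["delta1"] / fit.bse["delta1"]
        assert abs(z) < 3.5
        assert abs(peak_bias(fit.params["delta1"], fit.widths[0])[0]) < 0.3

    def test_width_search_matches_exhaustive_enumeration(self):
        """The Gram-matrix search must agree with brute-force OLS over the
        same candidate set (small grid, both one- and two-component)."""
        d, e, loc = sd.simulate_dog_dataset(
            4000, seed=4, attract_peak=1.5, attract_width=25.0,
            repulse_peak=0.8, repulse_width=60.0,
        )
        grid = np.arange(10.0, 81.0, 5.0)

        def rss_at(widths, with_loc=False):
            cols = [np.ones_like(d)] + [dog_basis(d, w) for w in widths]
            if with_loc:
                cols += [dog_basis(d, w) * loc for w in widths]
            X = np.column_stack(cols)
            beta, *_ = np.linalg.lstsq(X, e, rcond=None)
            r = e - X @ beta
            return r @ r

        fit1 = sd.fit_dog_model(d, e, spec="d1", width_grid=grid)
        best1 = min(grid, key=lambda w: rss_at([w]))
        assert fit1.widths == (best1,)

        fit2 = sd.fit_dog_model(d, e, loc, spec="d2xloc", width_grid=grid)
        pairs = [(w1, w2) for w1 in grid for w2 in grid if w2 >= 2 * w1]
        best2 = min(pairs, key=lambda p: rss_at(p, with_loc=True))
        assert fit2.widths == best2

    def test_direction_recovery(self):
        hits = 0
        for s in range(20):
            d, e, _ = sd.simulate_dog_dataset(
                8000, seed=100 + s, attract_peak=1.0, attract_width=25.0, noise_sd=8.0
            )
            hits += sd.fit_dog_model(d, e, spec="d1").params["delta1"] > 0
            d, e, _ = sd.simulate_dog_dataset(
                8000, seed=200 + s, attract_peak=-1.0, attract_width=25.0, noise_sd=8.0
            )
            hits += sd.fit_dog_model(d, e, spec="d1").params["delta1"] < 0
        assert hits >= 38  # ≥95% correct sign over 40 fits

    def test_nesting_r_squared(self):
        for s in range(3):
            d, e, loc = sd.simulate_dog_dataset(
                5000, seed=300 + s, attract_peak=1.0, attract_width=30.0, noise_sd=8.0
            )
            fits = sd.fit_model_family(d, e, loc)
            assert fits["d2"].r_squared >= fits["d1"].r_squared - 1e-12
            assert fits["d1"].r_squared >= fits["d0"].r_squared - 1e-12
            assert fits["d1xloc"].r_squared >= fits["d1"].r_squared - 1e-12
            assert fits["d2xloc"].r_squared >= fits["d2"].r_squared - 1e-12

    def test_fixed_widths_skip_search(self):
        d, e, _ = sd.simulate_dog_dataset(2000, seed=5, attract_peak=1.0)
        fit = sd.fit_dog_model(d, e, spec="d2", fixed_widths=(20.0, 55.0))
        assert fit.widths == (20.0, 55.0)

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="observations"):
            sd.fit_dog_model([1.0, 2.0], [0.1, 0.2], spec="d1", width_grid=[30.0])

    def test_interaction_needs_both_levels(self):
        d, e, _ = sd.simulate_dog_dataset(500, seed=6)
        with pytest.raises(ValueError, match="location"):
            sd.fit_dog_model(d, e, loc=np.zeros(500), spec="d1xloc")

    def test_bic_consistent_with_refit(self):
        d, e, _ = sd.simulate_dog_dataset(3000, seed=7, attract_peak=1.0)
        fit = sd.fit_dog_model(d, e, spec="d1", width_grid=[25.0, 40.0])
        assert fit.bic == pytest.approx(bic(fit.rss, fit.n_obs, fit.n_params))
        assert fit.n_params == 2


class TestCompareModels:
    def _fit_like(self, bic_value, name="d1", n=1000):
        return sd.FitResult(
            spec=ModelSpec.from_name(name), widths=(30.0,), params={}, bse={},
            r_squared=0.1, rss=1.0, n_obs=n, n_params=2, bic=bic_value,
        )

    def test_delta_bic_scale_and_labels(self):
        fits = [self._fit_like(100.0, "d0"), self._fit_like(98.0, "d1"),
                self._fit_like(104.0, "d2")]
        cmp = sd.compare_models(fits)
        table = cmp.table.set_index("model")
        assert table.loc["d0", "delta_bic"] == pytest.approx(4.0)
        assert table.loc["d1", "delta_bic"] == pytest.approx(6.0)
        assert table.loc["d2", "delta_bic"] == pytest.approx(0.0)
        assert cmp.best_model == "d1"
        assert table.loc["d1", "evidence"] == "strong"
        assert table.loc["d0", "evidence"] == "positive"
        assert table.loc["d2", "evidence"] == "worst"

    def test_delta_bic_invariant_to_shared_constant(self):
        fits_a = [self._fit_like(50.0, "d0"), self._fit_like(47.0, "d1")]
        fits_b = [self._fit_like(50.0 + 123.4, "d0"), self._fit_like(47.0 + 123.4, "d1")]
        da = sd.compare_models(fits_a).table["delta_bic"].to_numpy()
        db = sd.compare_models(fits_b).table["delta_bic"].to_numpy()
        np.testing.assert_allclose(da, db)

    def test_differing_n_obs_rejected(self):
        with pytest.raises(ValueError, match="n_obs"):
            sd.compare_models([self._fit_like(10.0, n=100), self._fit_like(9.0, n=200)])

    def test_needs_two_fits(self):
        with pytest.raises(ValueError):
            sd.compare_models([self._fit_like(10.0)])


class TestCompareCoefficients:
    def _fit_with(self, b, se):
        return sd.FitResult(
            spec=ModelSpec.from_name("d1"), widths=(30.0,),
            params={"intercept": 0.0, "delta1": b},
            bse={"intercept": 0.1, "delta1": se},
            r_squared=0.1, rss=1.0, n_obs=100, n_params=2, bic=0.0,
        )

    def test_equal_coefficients(self):
        z, p = sd.compare_coefficients(self._fit_with(0.5, 0.1), self._fit_with(0.5, 0.2), "delta1")
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_normal_quantile(self):
        se_a, se_b = 0.1, 0.2
        diff = 1.96 * np.hypot(se_a, se_b)
        z, p = sd.compare_coefficients(
            self._fit_with(0.5 + diff, se_a), self._fit_with(0.5, se_b), "delta1"
        )
        assert z == pytest.approx(1.96)
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_missing_term(self):
        with pytest.raises(KeyError):
            sd.compare_coefficients(self._fit_with(0.5, 0.1), self._fit_with(0.5, 0.1), "delta2")

    def test_type_one_error_on_split_halves(self):
        rej = 0
        R = 60
        for s in range(R):
            d, e, _ = sd.simulate_dog_dataset(
                6000, seed=400 + s, attract_peak=1.4, attract_width=25.0,
                repulse_peak=0.5, repulse_width=60.0, noise_sd=8.0,
            )
            half = 3000
            fa = sd.fit_dog_model(d[:half], e[:half], spec="d2", fixed_widths=(25.0, 60.0))
            fb = sd.fit_dog_model(d[half:], e[half:], spec="d2", fixed_widths=(25.0, 60.0))
            _, p = sd.compare_coefficients(fa, fb, "delta2")
            rej += p < 0.05
        assert rej / R < 0.15  # nominal 5% false-rejection rate


class TestSplit:
    def test_partition(self, annotated_experiment):
        similar, dissimilar = sd.split_by_similarity(annotated_experiment)
        eligible = annotated_experiment[
            annotated_experiment["distractor_present"]
            & annotated_experiment["prev_probe_distractor_delta"].notna()
        ]
        assert len(similar) + len(dissimilar) == len(eligible)
        assert (similar["prev_probe_distractor_delta"].abs() < 45).all()
        assert (dissimilar["prev_probe_distractor_delta"].abs() >= 45).all()

    def test_threshold_cases(self):
        t = make_trials(
            n=3,
            distractor_present=True,
            distractor_orientation=[90.0, 90.0, 90.0],
            distractor_location=1.0,
            probe_orientation=[80.0, 100.0, 60.0],
        )
        ann = sd.annotate_trials(t)
        ann.loc[:, "prev_probe_distractor_delta"] = [10.0, 80.0, 45.0]
        similar, dissimilar = sd.split_by_similarity(ann)
        assert list(similar["trial_index"]) == [1]
        assert list(dissimilar["trial_index"]) == [2, 3]


class TestSmoothCurve:
    def test_constant_errors_flat(self):
        rng = np.random.default_rng(8)
        d = rng.uniform(-90, 90, 2000)
        curve = smooth_curve(d, np.full(2000, 1.5))
        assert np.allclose(curve["mean"], 1.5)
        assert np.allclose(curve["sd"], 0.0)

    def test_window_one_is_per_degree_bins(self):
        d = np.array([10.2, 10.4, 30.0, 29.8])
        e = np.array([1.0, 3.0, 5.0, 7.0])
        curve = smooth_curve(d, e, window=1).set_index("delta")
        assert curve.loc[10.0, "mean"] == pytest.approx(2.0)
        assert curve.loc[30.0, "mean"] == pytest.approx(6.0)

    def test_linearity_on_balanced_grid(self):
        # smoothing each replicate then averaging equals averaging first:
        # both are the same linear functional of the pooled samples
        d = np.tile(np.arange(-89.0, 91.0), 2)
        e1 = np.sin(np.deg2rad(d))
        e2 = np.cos(np.deg2rad(d))
        joint = smooth_curve(d, np.r_[e1[:180], e2[180:]])
        s1 = smooth_curve(d[:180], e1[:180])
        s2 = smooth_curve(d[180:], e2[180:])
        np.testing.assert_allclose(
            joint["mean"], (s1["mean"] + s2["mean"]) / 2.0, atol=1e-12
        )

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_curve([0.0], [0.0], window=20)
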