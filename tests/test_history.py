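"""LOESS smoothing, Δpyrite series, bootstrap bands and the inversion."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from pyritize.history import (
    bootstrap_band,
    delta_series,
    invert_permissible_region,
    loess_smooth,
    synthetic_isotope_records,
)


class TestLoess:
    def test_constant_series_unchanged(self):
        x = np.linspace(0, 10, 30)
        np.testing.assert_allclose(
            loess_smooth(x, np.full(30, 7.0), span=0.4), 7.0, atol=1e-10
        )

    def test_full_span_on_linear_data_is_the_line(self):
        x = np.linspace(0, 10, 40)
        y = 2.0 * x - 1.0
        np.testing.assert_allclose(loess_smooth(x, y, span=1.0), y, atol=1e-8)

    def test_span_controls_oscillation_retention(self):
        rng = np.random.default_rng(0)
        x = np.sort(rng.uniform(0, 20, 200))
        signal = np.sin(x)
        y = signal + rng.normal(0, 0.2, 200)
        tight = loess_smooth(x, y, span=0.2)
        wide = loess_smooth(x, y, span=0.9)
        assert np.std(tight) > 0.55  # oscillation retained
        assert np.std(wide) < 0.3  # flattened

    def test_insufficient_data(self):
        with pytest.raises(ValueError, match="insufficient"):
            loess_smooth([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], span=0.5)

    def test_matches_reference_r_implementation(self, tmp_path):
        """Cross-check against R's loess (tricube local quadratic,
        surface='direct') as an independent oracle."""
        rng = np.random.default_rng(11)
        x = np.sort(rng.uniform(0, 10, 60))
        y = np.sin(x) + rng.normal(0, 0.3, 60)
        csv = tmp_path / "lo.csv"
        pd.DataFrame({"x": x, "y": y}).to_csv(csv, index=False)
        script = (
            f'd<-read.csv("{csv}");'
            'f<-loess(y~x,d,span=0.5,degree=2,surface="direct");'
            'cat(predict(f,d$x),sep="\\n")'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        reference = np.array([float(v) for v in out.stdout.split()])
        mine = loess_smooth(x, y, span=0.5, degree=2)
        np.testing.assert_allclose(mine, reference, atol=1e-5)

    def test_unsorted_input_stays_aligned(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10, 80)
        y = 3.0 * x + rng.normal(0, 0.1, 80)
        sm = loess_smooth(x, y, span=0.6)
        # smoothing a near-line must stay close to y in the INPUT order
        assert np.max(np.abs(sm - 3.0 * x)) < 0.5


class TestDeltaSeries:
    def test_arithmetic(self):
        pyrite = pd.DataFrame({"age_Ma": [100.0], "d34s_permil": [3.0]})
        sulfate = pd.DataFrame(
            {"age_Ma": [0.0, 200.0], "d34s_permil": [28.0, 28.0]}
        )
        out = delta_series(pyrite, sulfate)
        assert out["delta_pyrite"].iloc[0] == pytest.approx(25.0)

    def test_identical_records_zero(self):
        ages = np.linspace(0, 500, 20)
        frame = pd.DataFrame({"age_Ma": ages, "d34s_permil": np.sin(ages / 50)})
        out = delta_series(frame, frame)
        np.testing.assert_allclose(out["delta_pyrite"], 0.0, atol=1e-12)

    def test_extrapolation_excluded_and_counted(self):
        pyrite = pd.DataFrame(
            {"age_Ma": [50.0, 150.0, 700.0], "d34s_permil": [0.0, 0.0, 0.0]}
        )
        sulfate = pd.DataFrame(
            {"age_Ma": [0.0, 541.0], "d34s_permil": [20.0, 30.0]}
        )
        out = delta_series(pyrite, sulfate)
        assert len(out) == 2
        assert out.attrs["n_excluded"] == 1

    def test_no_overlap(self):
        pyrite = pd.DataFrame({"age_Ma": [900.0], "d34s_permil": [0.0]})
        sulfate = pd.DataFrame({"age_Ma": [0.0, 541.0], "d34s_permil": [20.0, 30.0]})
        with pytest.raises(ValueError, match="overlap"):
            delta_series(pyrite, sulfate)


@pytest.fixture(scope="module")
def records():
    return synthetic_isotope_records(seed=3, n_pyrite=250, n_sulfate=100)


class TestBootstrapBand:
    def test_seed_reproducibility(self, records):
        pyrite, sulfate, _ = records
        b1 = bootstrap_band(pyrite, sulfate, n_boot=40, seed=9)
        b2 = bootstrap_band(pyrite, sulfate, n_boot=40, seed=9)
        np.testing.assert_array_equal(b1.lower, b2.lower)
        np.testing.assert_array_equal(b1.upper, b2.upper)

    def test_band_ordered_and_contains_central(self, records):
        pyrite, sulfate, _ = records
        band = bootstrap_band(pyrite, sulfate, n_boot=120, seed=1)
        ok = np.isfinite(band.lower) & np.isfinite(band.smoothed)
        assert np.all(band.lower[ok] <= band.upper[ok])
        contained = (band.smoothed[ok] >= band.lower[ok]) & (
            band.smoothed[ok] <= band.upper[ok]
        )
        assert contained.mean() >= 0.9

    def test_band_narrows_with_less_noise(self):
        noisy = synthetic_isotope_records(seed=5, pyrite_sd=10.0, n_pyrite=250)
        quiet = synthetic_isotope_records(seed=5, pyrite_sd=0.5, sulfate_sd=0.1,
                                          n_pyrite=250)
        bn = bootstrap_band(noisy[0], noisy[1], n_boot=60, seed=2)
        bq = bootstrap_band(quiet[0], quiet[1], n_boot=60, seed=2)
        assert np.nanmedian(bq.upper - bq.lower) < 0.35 * np.nanmedian(
            bn.upper - bn.lower
        )

    def test_wider_coverage_widens_band(self, records):
        pyrite, sulfate, _ = records
        b90 = bootstrap_band(pyrite, sulfate, n_boot=60, seed=3)
        b50 = bootstrap_band(
            pyrite, sulfate, n_boot=60, seed=3, percentiles=(25.0, 75.0)
        )
        ok = np.isfinite(b90.lower) & np.isfinite(b50.lower)
        assert np.nanmedian((b90.upper - b90.lower)[ok]) > np.nanmedian(
            (b50.upper - b50.lower)[ok]
        )

    def test_period_range(self, records):
        pyrite, sulfate, _ = records
        band = bootstrap_band(pyrite, sulfate, n_boot=40, seed=4)
        lo, hi = band.period_range(100.0, 200.0)
        assert lo < hi


@pytest.fixture(scope="module")
def hm():
    from pyritize.grid import heatmap
    from pyritize.solver import SolverOptions

    return heatmap(
        np.geomspace(0.5, 50, 6), np.geomspace(0.3, 20, 6), psi0=10.0,
        options=SolverOptions(tol=1e-6),
    )


class TestInversion:
    def test_full_range_selects_everything(self, hm):
        region = invert_permissible_region((-50.0, 200.0), hm)
        assert region.mask.all()

    def test_disjoint_range_is_empty(self, hm):
        region = invert_permissible_region((-500.0, -400.0), hm)
        assert region.empty and not region.mask.any()

    def test_band_topology(self, hm):
        """A 0-10 permil offset selects the high-Γ0/low-Da* (closed)
        corner; a >=40 permil band sits at lower Γ0 and higher Da*."""
        closed = invert_permissible_region((0.0, 10.0), hm)
        open_band = invert_permissible_region((40.0, 55.0), hm)
        assert not closed.empty and not open_band.empty
        assert closed.centroid[0] > open_band.centroid[0]  # Γ0 ordering
        assert closed.centroid[1] < open_band.centroid[1]  # Da* ordering

    def test_region_reports_minimum_content_range(self, hm):
        region = invert_permissible_region((0.0, 30.0), hm)
        lo, hi = region.pi_integral_range
        assert 0.0 <= lo <= hi

    def test_invalid_range(self, hm):
        with pytest.raises(ValueError):
            invert_permissible_region((10.0, 0.0), hm)


def test_synthetic_records_structure():
    pyrite, sulfate, truth = synthetic_isotope_records(seed=0)
    assert set(pyrite.columns) >= {"age_Ma", "d34s_permil", "species"}
    assert (pyrite["species"] == "pyrite").all()
    assert (sulfate["species"] == "sulfate").all()
    # pyrite is isotopically lighter than coeval sulfate on average
    assert pyrite["d34s_permil"].mean() < sulfate["d34s_permil"].mean()
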