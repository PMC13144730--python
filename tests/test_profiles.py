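"""Contact-matrix loading, 4C-like profile extraction, controls and ratios."""

import numpy as np
import pytest

from stripefit import minicool
from stripefit.fitting import model_ratio
from stripefit.model import ExtrusionParams, RoadblockSet
from stripefit.profiles import (
    ContactMatrix,
    ContactProfile,
    RatioProfile,
    Viewpoint,
    average_controls,
    detrend,
    extract_profile,
    load_matrix,
    ratio,
)
from stripefit.synthetic import SyntheticSpec, synth_matrix


def _background_matrix(n=200, gamma=1.5, bin_width=1.0):
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :]) * bin_width
    m = np.maximum(sep, bin_width) ** -gamma
    return ContactMatrix("chrT", bin_width, m)


class TestLoadMatrix:
    def test_dense_tsv_roundtrip(self, tmp_path):
        m = np.array([[1.0, 0.5, 0.1], [0.5, 2.0, 0.4], [0.1, 0.4, 1.5]])
        path = tmp_path / "toy.tsv"
        np.savetxt(path, m, delimiter="\t")
        loaded = load_matrix(path, "chrT")
        np.testing.assert_allclose(loaded.matrix, m)
        assert loaded.chromosome == "chrT"

    def test_asymmetric_tsv_rejected(self, tmp_path):
        m = np.array([[1.0, 0.5], [0.6, 2.0]])
        path = tmp_path / "bad.tsv"
        np.savetxt(path, m, delimiter="\t")
        with pytest.raises(ValueError, match="symmetric"):
            load_matrix(path, "chrT")

    def test_cool_balancing_is_outer_product_of_weights(self, tmp_path):
        rng = np.random.default_rng(0)
        counts = rng.poisson(20.0, (6, 6)).astype(float)
        counts = np.triu(counts) + np.triu(counts, 1).T
        weights = rng.uniform(0.5, 1.5, 6)
        path = tmp_path / "toy.cool"
        minicool.write_cool(path, "chrT", counts, bin_bp=1000, weights=weights)

        raw = load_matrix(path, "chrT", apply_weights=False)
        np.testing.assert_allclose(raw.matrix, counts)
        balanced = load_matrix(path, "chrT", apply_weights=True)
        np.testing.assert_allclose(balanced.matrix, counts * np.outer(weights, weights))

    def test_cool_without_weights_rejected(self, tmp_path):
        counts = np.full((4, 4), 3.0)
        path = tmp_path / "noweights.cool"
        minicool.write_cool(path, "chrT", counts, bin_bp=1000)
        with pytest.raises(ValueError, match="weights"):
            load_matrix(path, "chrT", apply_weights=True)


class TestExtractProfile:
    def test_constant_rows_give_constant_profile(self):
        n = 120
        m = ContactMatrix("chrT", 1.0, np.ones((n, n)))
        vp = Viewpoint("chrT", 20_500, 3.0, "W")
        prof = extract_profile(m, vp, smooth_kernel=39, smooth_order=2)
        # Savitzky-Golay reproduces polynomials up to its order exactly
        np.testing.assert_allclose(prof.values, prof.values[0], rtol=1e-9)
        assert np.sum(prof.values) == pytest.approx(1.0, abs=1e-9)

    def test_profile_normalized_after_smoothing(self):
        m = _background_matrix()
        prof = extract_profile(m, Viewpoint("chrT", 50_500, 3.0, "W"), 39, 2)
        assert np.nansum(prof.values) == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(prof.distances) > 0)

    def test_orientation_mirrors(self):
        m = _background_matrix(n=150)
        mirrored = ContactMatrix("chrT", 1.0, m.matrix[::-1, ::-1].copy())
        right = extract_profile(m, Viewpoint("chrT", 40_500, 3.0, "W"), 9, 1)
        left = extract_profile(
            mirrored, Viewpoint("chrT", (150 - 41) * 1000 + 500, 3.0, "C"), 9, 1
        )
        np.testing.assert_allclose(right.values, left.values, rtol=1e-9)

    def test_nan_bins_masked_back_after_smoothing(self):
        m = _background_matrix()
        mat = m.matrix.copy()
        mat[:, 80] = np.nan
        mat[80, :] = np.nan
        m2 = ContactMatrix("chrT", 1.0, mat)
        prof = extract_profile(m2, Viewpoint("chrT", 20_500, 3.0, "W"), 9, 1)
        bad = np.where(~np.isfinite(prof.values))[0]
        assert list(prof.distances[bad]) == [59.0]  # bin 80, 59 kb right of window
        assert np.isfinite(np.delete(prof.values, bad)).all()

    def test_viewpoint_chromosome_mismatch(self):
        m = _background_matrix()
        with pytest.raises(ValueError, match="chromosome"):
            extract_profile(m, Viewpoint("chrX", 20_500, 3.0, "W"), 9, 1)

    def test_kernel_must_exceed_order(self):
        m = _background_matrix()
        with pytest.raises(ValueError, match="order"):
            extract_profile(m, Viewpoint("chrT", 20_500, 3.0, "W"), 1, 2)

    def test_extracted_stripe_matches_generator(self):
        """Round trip: stripe matrix -> extraction reproduces the generating
        enrichment (measurement-matched) within a few percent."""
        spec = SyntheticSpec(
            ExtrusionParams(150.0, 0.1), arm_length=500.0, loading_site_kb=100.0, seed=8
        )
        m = synth_matrix(spec)
        prof = extract_profile(m, Viewpoint("synthetic", 100_500, 3.0, "W"), 39, 2)
        ctrls = [
            extract_profile(m, Viewpoint("synthetic", c * 1000 + 500, 3.0, "W"), 39, 2)
            for c in (40, 50, 60, 70, 80, 90)
        ]
        observed = ratio(prof, average_controls(ctrls))
        predicted = model_ratio(
            150.0, 0.1, observed.distances, RoadblockSet((), 500.0),
            measurement=(3, 39, 2),
        )
        sel = (observed.distances >= 10) & (observed.distances <= 300)
        rel = np.abs(observed.values[sel] / predicted[sel] - 1.0)
        assert np.nanmedian(rel) < 0.05


class TestControlsAndRatios:
    def test_identical_controls_average_to_same(self):
        s = np.arange(1.0, 101.0)
        p = ContactProfile(s, 1.0 / s)
        avg = average_controls([p, p, p])
        np.testing.assert_allclose(avg.values, p.values)

    def test_two_controls_average_pointwise(self):
        s = np.arange(1.0, 51.0)
        a = ContactProfile(s, np.full(50, 2.0))
        b = ContactProfile(s, np.full(50, 4.0))
        np.testing.assert_allclose(average_controls([a, b]).values, 3.0)

    def test_controls_variance_reduction(self):
        rng = np.random.default_rng(4)
        s = np.arange(1.0, 201.0)
        base = s**-1.5
        profiles = [
            ContactProfile(s, base * rng.normal(1.0, 0.1, s.size)) for _ in range(6)
        ]
        avg = average_controls(profiles)
        resid_single = np.std(profiles[0].values / base - 1.0)
        resid_avg = np.std(avg.values / base - 1.0)
        assert resid_avg < resid_single / 1.8  # ~sqrt(6) in expectation

    def test_empty_and_mixed_bin_width_controls_rejected(self):
        with pytest.raises(ValueError):
            average_controls([])
        a = ContactProfile(np.arange(1.0, 51.0), np.ones(50))
        b = ContactProfile(5.0 * np.arange(1.0, 51.0), np.ones(50))
        with pytest.raises(ValueError, match="bin width"):
            average_controls([a, b])

    def test_ratio_of_equal_profiles_is_one(self):
        s = np.arange(1.0, 101.0)
        p = ContactProfile(s, 1.0 / s)
        np.testing.assert_allclose(ratio(p, p).values, 1.0)

    def test_ratio_scales(self):
        s = np.arange(1.0, 101.0)
        p = ContactProfile(s, 2.0 / s)
        c = ContactProfile(s, 1.0 / s)
        np.testing.assert_allclose(ratio(p, c).values, 2.0)

    def test_zero_control_bins_become_nan_with_warning(self):
        s = np.arange(1.0, 11.0)
        p = ContactProfile(s, np.ones(10))
        c_vals = np.ones(10)
        c_vals[4] = 0.0
        with pytest.warns(UserWarning, match="zero"):
            r = ratio(p, ContactProfile(s, c_vals))
        assert np.isnan(r.values[4]) and np.isfinite(np.delete(r.values, 4)).all()

    def test_profile_tsv_roundtrip(self, tmp_path):
        s = np.arange(1.0, 41.0)
        p = ContactProfile(s, 1.0 / s, sem=0.01 / s)
        path = tmp_path / "p.tsv"
        p.to_tsv(path)
        back = ContactProfile.from_tsv(path)
        np.testing.assert_allclose(back.values, p.values)
        np.testing.assert_allclose(back.sem, p.sem)


class TestDetrend:
    def test_constant_input_gives_one(self):
        s = np.arange(1.0, 101.0)
        r = RatioProfile(s, np.full(100, 3.3))
        np.testing.assert_allclose(detrend(r).values, 1.0, atol=1e-9)

    def test_smooth_trend_removed(self):
        s = np.arange(1.0, 201.0)
        r = RatioProfile(s, 2.0 * np.exp(-s / 300.0))
        out = detrend(r, lowess_fraction=0.3)
        assert np.all(np.abs(out.values[5:-5] - 1.0) < 0.02)

    def test_injected_peak_survives_detrending(self):
        s = np.arange(1.0, 301.0)
        trend = 1.5 * np.exp(-s / 400.0)
        peak = 0.2 * trend * np.exp(-((s - 150.0) ** 2) / (2 * 2.5**2))
        out = detrend(RatioProfile(s, trend + peak), lowess_fraction=0.3)
        apex = s[np.nanargmax(out.values)]
        assert abs(apex - 150.0) <= 1.0
        assert np.nanmax(out.values) == pytest.approx(1.2, abs=0.05)

    def test_too_few_points_rejected(self):
        r = RatioProfile(np.arange(1.0, 11.0), np.ones(10))
        with pytest.raises(ValueError, match="20"):
            detrend(r)
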