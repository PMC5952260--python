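"""Segmented initialization, bounded fits, and voxel-wise maps."""

import numpy as np
import pytest

from t2ivim import (
    FitConfig,
    FitError,
    IVIMParams,
    SignalSeries,
    T2IVIMParams,
    apparent_fraction,
    fit_ivim,
    fit_t2ivim,
    fit_voxelwise,
    init_t2t,
    ivim_signal,
    protocol2,
    read_roi_csv,
    segmented_init_ivim,
    simulate_series,
    write_roi_csv,
)
from t2ivim.acquisition import AcquisitionScheme, SchemeEntry
from t2ivim.phantom import PhantomSpec, VesselRegion, simulate_phantom


def single_te_scheme(bs, te=62.0):
    return AcquisitionScheme([SchemeEntry(b=float(b), TE=te) for b in bs])


B8 = (0, 10, 50, 100, 150, 200, 250, 400, 800)


class TestSegmentedInit:
    def test_mono_exponential_exact(self):
        # f = 0: log-linear high-b fit recovers D exactly, f hits the floor
        scheme = single_te_scheme(B8)
        s = 100.0 * np.exp(-scheme.b * 1e-3)
        init = segmented_init_ivim(SignalSeries(scheme, s))
        assert init.D == pytest.approx(1e-3, abs=1e-9)
        assert init.f == 0.01

    def test_biexponential_seed_quality(self):
        # pseudo-diffusion term is < e^-22 at b > 150, so bias is negligible
        truth = IVIMParams(100.0, 0.2, 1e-3, 0.15)
        scheme = single_te_scheme(B8)
        init = segmented_init_ivim(
            SignalSeries(scheme, ivim_signal(truth, scheme.b))
        )
        assert init.f == pytest.approx(0.2, abs=0.02)
        assert init.D == pytest.approx(1e-3, rel=0.02)
        assert init.Dstar == pytest.approx(10 * init.D)

    def test_threshold_above_max_b_errors(self):
        scheme = single_te_scheme((0, 50, 100))
        series = SignalSeries(scheme, np.ones(3))
        with pytest.raises(FitError):
            segmented_init_ivim(series, b_threshold=150.0)


class TestInitT2t:
    def test_exact_on_monoexponential_decay(self):
        scheme = AcquisitionScheme(
            [SchemeEntry(b=50.0, TE=te) for te in (62.0, 80.0, 100.0)]
        )
        s = 100.0 * np.exp(-scheme.TE / 42.1)
        assert init_t2t(SignalSeries(scheme, s)) == pytest.approx(
            42.1, abs=1e-6
        )

    def test_biased_estimate_within_15pct(self, liver_params, p2):
        # residual pseudo-diffusion signal at b=50 biases the seed upward
        series = simulate_series(liver_params, p2, SNR=np.inf)
        est = init_t2t(series)
        assert est == pytest.approx(liver_params.T2t, rel=0.15)

    def test_single_te_errors(self):
        scheme = single_te_scheme(B8)
        series = SignalSeries(scheme, np.ones(len(scheme)))
        with pytest.raises(FitError, match="b_ref"):
            init_t2t(series)


class TestFitIvim:
    def test_noiseless_recovery(self):
        truth = IVIMParams(100.0, 0.2, 1e-3, 0.15)
        scheme = single_te_scheme(B8)
        series = SignalSeries(scheme, ivim_signal(truth, scheme.b))
        res = fit_ivim(series)
        assert res.converged
        np.testing.assert_allclose(
            res.params.as_array(), truth.as_array(), rtol=1e-4
        )
        assert res.fDstar == res.params.f * res.params.Dstar
        assert len(res.residuals) == len(scheme)

    def test_single_te_reduction_oracle(self, liver_params):
        # a single-TE IVIM fit of two-compartment-T2 data returns f_app
        scheme = single_te_scheme(B8, te=62.0)
        series = simulate_series(liver_params, scheme, SNR=np.inf)
        res = fit_ivim(series)
        expected = apparent_fraction(
            liver_params.f, liver_params.T2p, liver_params.T2t, 62.0
        )
        assert res.params.f == pytest.approx(expected, abs=1e-3)

    def test_multiple_tes_rejected(self, noiseless_p2_series):
        with pytest.raises(FitError, match="single-TE"):
            fit_ivim(noiseless_p2_series)

    def test_constant_signal_never_crashes(self):
        scheme = single_te_scheme(B8)
        series = SignalSeries(scheme, np.full(len(scheme), 50.0))
        res = fit_ivim(series)  # must not raise
        assert res.params.f <= 0.05 or not res.converged


class TestFitT2Ivim:
    def test_noiseless_recovery_p2(self, p2):
        truth = T2IVIMParams(100.0, 0.18, 1.07e-3, 0.15, 77.6, 42.1)
        series = simulate_series(truth, p2, SNR=np.inf)
        res = fit_t2ivim(series)
        assert res.converged
        np.testing.assert_allclose(
            res.params.as_array(), truth.as_array(), rtol=1e-3
        )

    def test_equal_t2s_match_single_te_ivim(self, p2):
        truth = T2IVIMParams(100.0, 0.2, 1e-3, 0.1, 50.0, 50.0)
        series = simulate_series(truth, p2, SNR=np.inf)
        f_t2 = fit_t2ivim(series).params.f
        f_ivim = fit_ivim(series.at_TE(62.0)).params.f
        assert f_t2 == pytest.approx(f_ivim, abs=1e-3)

    def test_protocol1_residuals_flat(self, noiseless_p1_series, liver_params):
        res = fit_t2ivim(noiseless_p1_series)
        assert np.all(np.abs(res.residuals) < 1e-8 * liver_params.S0)

    def test_single_te_rejected(self, noiseless_p2_series):
        with pytest.raises(FitError, match=">= 2 distinct TEs"):
            fit_t2ivim(noiseless_p2_series.at_TE(62.0))

    def test_std_errors_reported(self, liver_params, p2):
        series = simulate_series(liver_params, p2, SNR=50.0, seed=3)
        res = fit_t2ivim(series)
        assert set(res.std_errors) == set(T2IVIMParams.param_names())
        assert all(np.isfinite(v) for v in res.std_errors.values())
        lo, hi = res.ci95["f"]
        assert lo < res.params.f < hi


class TestBiasDirection:
    def test_apparent_f_increases_with_te(self, noiseless_p1_series):
        # single-TE IVIM fits of T2p > T2t data inflate f at longer TE
        fs = [
            fit_ivim(noiseless_p1_series.at_TE(te)).params.f
            for te in (62.0, 72.0, 82.0, 92.0, 102.0)
        ]
        assert np.all(np.diff(fs) > 0)


class TestVoxelwise:
    def test_homogeneous_matches_roi_fit(self, liver_params, p2):
        series = simulate_series(liver_params, p2, SNR=np.inf)
        vol = np.tile(series.signal, (4, 4, 1, 1))
        maps = fit_voxelwise(vol, p2, model="t2ivim")
        roi = fit_t2ivim(series)
        for name in T2IVIMParams.param_names():
            np.testing.assert_allclose(
                maps.maps[name], getattr(roi.params, name), rtol=1e-6
            )
        assert maps.n_failed == 0
        # apparent-f map evaluated at the minimum TE exceeds the true f
        assert np.all(maps.maps["f_apparent"] > maps.maps["f"])

    def test_vessel_stripe_has_higher_f(self, p2):
        spec = PhantomSpec(
            dims=(8, 8, 1),
            SNR=200.0,
            seed=11,
            vessels=[VesselRegion(kind="box", extent=(3, 5, 0, 8, 0, 1))],
        )
        result = simulate_phantom(spec, p2)
        maps = fit_voxelwise(result.volume, p2, model="t2ivim")
        vessel = result.truth["f"] > 0.5
        assert (
            np.nanmedian(maps.maps["f"][vessel])
            > np.nanmedian(maps.maps["f"][~vessel])
        )

    def test_empty_mask(self, p2):
        vol = np.zeros((2, 2, 1, len(p2)))
        maps = fit_voxelwise(vol, p2, mask=np.zeros((2, 2, 1), bool))
        assert maps.n_fitted == 0
        assert np.all(np.isnan(maps.maps["f"]))

    def test_frame_count_mismatch(self, p2):
        with pytest.raises(ValueError, match="frames"):
            fit_voxelwise(np.zeros((2, 2, 1, 7)), p2)


class TestRoiCsv:
    def test_round_trip(self, noiseless_p2_series, tmp_path):
        path = tmp_path / "roi.csv"
        write_roi_csv(noiseless_p2_series, path)
        back = read_roi_csv(path)
        np.testing.assert_allclose(back.signal, noiseless_p2_series.signal)
        np.testing.assert_allclose(back.scheme.b, noiseless_p2_series.scheme.b)
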