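"""Reconstruction chain: closed-form stage checks and a direct-DFT oracle."""

import math

import numpy as np
import pytest

from panc13c import (
    AcquisitionParams,
    CSIDataset,
    ReconConfig,
    apodize_spatial,
    baseline_correct,
    integrate_peaks,
    line_broaden,
    phase_correct,
    reconstruct,
    transform,
    zero_fill,
)
from panc13c.acquisition import k_indices


def direct_dft(fids: np.ndarray) -> np.ndarray:
    """Direct evaluation of the spatial-spectral transform definition.

    Spectrum at frequency bin q (frequency (q - Nt/2) / (Nt dwell)) and
    image position j (offset (j - N/2)/N of the FOV):

        img[jy, jx, q] = sum_{a,b,n} fids[a,b,n]
            * exp(-2 pi i (a - Ny/2)(jy - Ny/2) / Ny)
            * exp(-2 pi i (b - Nx/2)(jx - Nx/2) / Nx)
            * exp(-2 pi i (q - Nt/2) n / Nt)

    Built from explicit phase matrices; independent of any FFT routine.
    """
    ny, nx, nt = fids.shape
    jy = np.arange(ny)
    ey = np.exp(-2j * np.pi * np.outer(jy - ny // 2, k_indices(ny)) / ny)
    jx = np.arange(nx)
    ex = np.exp(-2j * np.pi * np.outer(jx - nx // 2, k_indices(nx)) / nx)
    q = np.arange(nt)
    et = np.exp(-2j * np.pi * np.outer(q - nt // 2, np.arange(nt)) / nt)
    return np.einsum("abn,ja,kb,qn->jkq", fids, ey, ex, et, optimize=True)


def dataset(acq: AcquisitionParams, fids: np.ndarray) -> CSIDataset:
    return CSIDataset(fids=fids.astype(complex), acq=acq)


class TestApodization:
    def test_dc_only_dataset_unchanged(self, small_acq):
        ny, nx = small_acq.matrix
        fids = np.zeros((ny, nx, small_acq.n_fid_points), dtype=complex)
        fids[ny // 2, nx // 2, :] = 1.0 + 2.0j
        out = apodize_spatial(dataset(small_acq, fids))
        np.testing.assert_array_equal(out.fids, fids)

    def test_edge_sample_killed(self, small_acq, rng):
        ny, nx = small_acq.matrix
        fids = rng.standard_normal((ny, nx, small_acq.n_fid_points)) + 0j
        out = apodize_spatial(dataset(small_acq, fids))
        # row 0 / column 0 sit at k = -k_max where the window is cos(pi/2) = 0
        assert np.allclose(out.fids[0, :, :], 0.0, atol=1e-12)
        assert np.allclose(out.fids[:, 0, :], 0.0, atol=1e-12)

    def test_energy_never_increases(self, small_acq, rng):
        fids = rng.standard_normal(
            (small_acq.matrix[0], small_acq.matrix[1], small_acq.n_fid_points)
        ) + 1j * rng.standard_normal(
            (small_acq.matrix[0], small_acq.matrix[1], small_acq.n_fid_points)
        )
        out = apodize_spatial(dataset(small_acq, fids))
        assert np.sum(np.abs(out.fids) ** 2) <= np.sum(np.abs(fids) ** 2)


class TestLineBroadening:
    def test_zero_is_identity(self, small_acq, rng):
        fids = rng.standard_normal((8, 8, 64)) + 0j
        ds = dataset(small_acq, fids)
        assert line_broaden(ds, 0.0) is ds

    def test_negative_rejected(self, small_acq):
        with pytest.raises(ValueError):
            line_broaden(dataset(small_acq, np.zeros((8, 8, 64))), -5.0)

    def test_exponential_decay_rate_adds(self, small_acq):
        t = np.arange(small_acq.n_fid_points) * small_acq.dwell
        r = 200.0  # s^-1
        fids = np.zeros((8, 8, 64), dtype=complex)
        fids[4, 4] = np.exp(-r * t)
        lb = 20.0
        out = line_broaden(dataset(small_acq, fids), lb)
        expected = np.exp(-(r + math.pi * lb) * t)
        np.testing.assert_allclose(out.fids[4, 4], expected, rtol=1e-12)

    def test_lorentzian_linewidth_increases_by_lb(self, small_acq):
        """FWHM of the absorption line grows from 1/(pi T2) to
        1/(pi T2) + lb, measured by half-maximum interpolation.  The first
        FID point is halved (trapezoidal quadrature of the continuous
        transform) so the line sits on a flat baseline."""
        nt = 1024
        acq = AcquisitionParams(matrix=(8, 8), n_fid_points=nt, tr=0.2)
        t = np.arange(nt) * acq.dwell
        t2 = 0.004  # 79.6 Hz natural linewidth; decayed to e^-42 at readout end
        fid = np.exp(-t / t2)
        fid[0] *= 0.5
        fids = np.zeros((8, 8, nt), dtype=complex)
        fids[4, 4] = fid
        lb = 40.0

        def fwhm(ds):
            img = transform(zero_fill(ds, 8, 8192))
            spec = img.cube[4, 4].real
            peak = spec.max()
            above = spec >= peak / 2.0
            idx = np.nonzero(above)[0]
            # linear interpolation at the half-maximum crossings
            f = img.freq_axis
            lo_i, hi_i = idx[0], idx[-1]
            lo = np.interp(peak / 2.0, [spec[lo_i - 1], spec[lo_i]], [f[lo_i - 1], f[lo_i]])
            hi = np.interp(
                peak / 2.0, [spec[hi_i + 1], spec[hi_i]], [f[hi_i + 1], f[hi_i]]
            )
            return hi - lo

        base = fwhm(dataset(acq, fids))
        broadened = fwhm(line_broaden(dataset(acq, fids), lb))
        assert broadened - base == pytest.approx(lb, rel=0.02)


class TestZeroFill:
    def test_identity_when_targets_equal_dims(self, small_acq, rng):
        fids = rng.standard_normal((8, 8, 64)) + 0j
        out = zero_fill(dataset(small_acq, fids), 8, 64)
        np.testing.assert_array_equal(out.fids, fids)

    def test_paper_target_dims(self):
        acq = AcquisitionParams()
        fids = np.zeros((32, 32, 128), dtype=complex)
        out = zero_fill(CSIDataset(fids=fids, acq=acq), 128, 1024)
        assert out.fids.shape == (128, 128, 1024)
        assert out.acq.matrix == (128, 128)
        assert out.acq.n_fid_points == 1024

    def test_original_samples_preserved_at_their_coordinates(self, small_acq, rng):
        fids = rng.standard_normal((8, 8, 64)) + 1j * rng.standard_normal((8, 8, 64))
        out = zero_fill(dataset(small_acq, fids), 32, 256)
        # DC was at index 4, moves to index 16
        np.testing.assert_array_equal(out.fids[12:20, 12:20, :64], fids)

    def test_energy_unchanged(self, small_acq, rng):
        fids = rng.standard_normal((8, 8, 64)) + 0j
        out = zero_fill(dataset(small_acq, fids), 64, 512)
        assert np.sum(np.abs(out.fids) ** 2) == pytest.approx(
            np.sum(np.abs(fids) ** 2), rel=1e-14
        )

    def test_shrinking_rejected(self, small_acq):
        with pytest.raises(ValueError):
            zero_fill(dataset(small_acq, np.zeros((8, 8, 64))), 4, 64)


class TestTransform:
    def test_matches_direct_dft(self, small_acq, rng):
        fids = rng.standard_normal((8, 8, 64)) + 1j * rng.standard_normal((8, 8, 64))
        img = transform(dataset(small_acq, fids))
        oracle = direct_dft(fids)
        err = np.max(np.abs(img.cube - oracle)) / np.max(np.abs(oracle))
        assert err < 1e-8

    def test_single_exponential_peaks_at_nearest_bin(self, small_acq):
        f0 = 952.0
        t = np.arange(64) * small_acq.dwell
        fids = np.zeros((8, 8, 64), dtype=complex)
        fids[4, 4] = np.exp(2j * np.pi * f0 * t)
        img = transform(dataset(small_acq, fids))
        q = np.argmax(np.abs(img.cube[4, 4]))
        assert abs(img.freq_axis[q] - f0) <= img.df / 2

    def test_two_point_sources_localized(self, small_acq):
        """Constructed k-space of two point voxels focuses back onto them."""
        ny, nx = 8, 8
        voxels = [(2, 3), (6, 5)]
        ky, kx = np.meshgrid(k_indices(ny), k_indices(nx), indexing="ij")
        fids = np.zeros((ny, nx, 64), dtype=complex)
        for iy, ix in voxels:
            uy, ux = (iy - ny // 2) / ny, (ix - nx // 2) / nx
            fids += np.exp(2j * np.pi * (ky * uy + kx * ux))[:, :, None] * np.ones(64)
        img = transform(dataset(small_acq, fids))
        intensity = np.abs(img.cube).sum(axis=2)
        top2 = np.argsort(intensity.ravel())[-2:]
        found = {tuple(np.unravel_index(i, intensity.shape)) for i in top2}
        assert found == set(voxels)


class TestPhaseAndBaseline:
    def _real_spectrum_image(self, small_acq):
        t = np.arange(64) * small_acq.dwell
        fids = np.zeros((8, 8, 64), dtype=complex)
        fids[4, 4] = np.exp(2j * np.pi * 440.0 * t - t / 0.003)
        return transform(dataset(small_acq, fids))

    def test_rotated_spectrum_recovered(self, small_acq):
        img = self._real_spectrum_image(small_acq)
        ref = phase_correct(img, "auto_zero_order")
        for phi_deg in (30.0, 117.0, -64.0):
            rotated = img.cube * np.exp(1j * math.radians(phi_deg))
            out = phase_correct(
                type(img)(rotated, img.freq_axis, img.spatial_axes), "auto_zero_order"
            )
            peak = np.argmax(np.abs(out.cube[4, 4]))
            residual = np.angle(out.cube[4, 4, peak] / ref.cube[4, 4, peak])
            assert abs(math.degrees(residual)) < 0.1

    def test_already_real_spectrum_unchanged(self, small_acq):
        img = self._real_spectrum_image(small_acq)
        phased = phase_correct(img, "auto_zero_order")
        twice = phase_correct(phased, "auto_zero_order")
        np.testing.assert_allclose(twice.cube, phased.cube, rtol=1e-9, atol=1e-12)

    def test_magnitude_mode_non_negative(self, small_acq, rng):
        img = self._real_spectrum_image(small_acq)
        out = phase_correct(img, "magnitude")
        assert np.all(out.cube.real >= 0)
        assert out.is_magnitude

    def test_constant_offset_removed_by_median(self, small_acq):
        img = self._real_spectrum_image(small_acq)
        img = phase_correct(img, "auto_zero_order")
        offset = 3.7
        shifted = type(img)(img.cube + offset, img.freq_axis, img.spatial_axes)
        windows = {"alanine": (340.0, 540.0)}
        out = baseline_correct(shifted, "offset_median", peak_windows=windows)
        ref = baseline_correct(img, "offset_median", peak_windows=windows)
        np.testing.assert_allclose(out.cube.real, ref.cube.real, atol=1e-10)

    def test_zero_spectrum_stays_zero(self, small_acq):
        img = transform(dataset(small_acq, np.zeros((8, 8, 64), dtype=complex)))
        out = baseline_correct(img, "offset_median", peak_windows={"p": (0.0, 100.0)})
        assert np.all(out.cube == 0)

    def test_linear_ramp_removed_by_polynomial(self, small_acq):
        img = self._real_spectrum_image(small_acq)
        img = phase_correct(img, "auto_zero_order")
        ramp = 0.01 * (img.freq_axis - img.freq_axis[0])
        shifted = type(img)(img.cube + ramp, img.freq_axis, img.spatial_axes)
        windows = {"alanine": (340.0, 540.0)}
        out = baseline_correct(shifted, "polynomial", peak_windows=windows)
        ref = baseline_correct(img, "polynomial", peak_windows=windows)
        scale = np.abs(ref.cube.real).max()
        assert np.max(np.abs(out.cube.real - ref.cube.real)) < 0.01 * scale

    def test_windows_covering_axis_rejected(self, small_acq):
        img = self._real_spectrum_image(small_acq)
        with pytest.raises(ValueError, match="baseline"):
            baseline_correct(
                img, "offset_median", peak_windows={"all": (-4000.0, 4000.0)}
            )


class TestIntegratePeaks:
    def test_lorentzian_partial_area_analytic(self):
        """Windowed integral of a unit-area Lorentzian matches the analytic
        partial area (2/pi) atan(2W / FWHM) for a +-10 FWHM window.

        A one-sided decay e^{-t/T2} transforms to an absorption line of area
        x(0+)/2 (the inversion midpoint at the jump), so the unit-area FID is
        2 dwell e^{-t/T2} with the first point halved (trapezoid rule)."""
        acq = AcquisitionParams(matrix=(8, 8), n_fid_points=128, tr=0.03)
        t2 = 0.003
        fwhm = 1.0 / (math.pi * t2)
        t = np.arange(128) * acq.dwell
        fid = 2.0 * acq.dwell * np.exp(-t / t2)
        fid[0] *= 0.5
        fids = np.zeros((8, 8, 128), dtype=complex)
        fids[4, 4] = fid
        ds = zero_fill(CSIDataset(fids=fids, acq=acq), 8, 2048)
        img = phase_correct(transform(ds), "auto_zero_order")
        width = 10.0 * fwhm
        windows = {"pyruvate": (-width, width)}
        img = baseline_correct(img, "offset_median", peak_windows=windows)
        maps = integrate_peaks(img, windows)
        expected = (2.0 / math.pi) * math.atan(2.0 * width / fwhm)
        assert maps.maps["pyruvate"][4, 4] == pytest.approx(expected, rel=0.02)

    def test_empty_spectrum_integrates_to_zero(self, small_acq):
        img = transform(dataset(small_acq, np.zeros((8, 8, 64), dtype=complex)))
        maps = integrate_peaks(img, {"alanine": (340.0, 540.0)})
        assert np.all(maps.maps["alanine"] == 0)

    def test_linearity_in_input(self, small_acq, rng):
        fids = rng.standard_normal((8, 8, 64)) + 1j * rng.standard_normal((8, 8, 64))
        img1 = transform(dataset(small_acq, fids))
        img2 = transform(dataset(small_acq, 2.0 * fids))
        w = {"lactate": (860.0, 1040.0)}
        m1 = integrate_peaks(img1, w).maps["lactate"]
        m2 = integrate_peaks(img2, w).maps["lactate"]
        np.testing.assert_allclose(m2, 2.0 * m1, rtol=1e-12)

    def test_window_outside_axis_rejected(self, small_acq):
        img = transform(dataset(small_acq, np.zeros((8, 8, 64), dtype=complex)))
        with pytest.raises(ValueError, match="outside"):
            integrate_peaks(img, {"x": (2900.0, 3100.0)})


class TestReconstructChain:
    def test_default_dims_from_paper_matrix(self):
        acq = AcquisitionParams()
        fids = np.zeros((32, 32, 128), dtype=complex)
        fids[16, 16, :] = 1.0
        _, maps = reconstruct(CSIDataset(fids=fids, acq=acq))
        assert all(m.shape == (128, 128) for m in maps.maps.values())
        assert set(maps.maps) == {"pyruvate", "lactate", "alanine", "pyruvate_hydrate"}

    def test_disabled_processing_equals_bare_transform_integration(self, small_acq, rng):
        fids = rng.standard_normal((8, 8, 64)) + 1j * rng.standard_normal((8, 8, 64))
        ds = dataset(small_acq, fids)
        windows = {"lactate": (860.0, 1040.0)}
        cfg = ReconConfig(
            spatial_apodization="none",
            line_broadening=0.0,
            spatial_zero_fill=8,
            spectral_zero_fill=64,
            phase_mode="magnitude",
            baseline_mode="none",
            peak_windows=windows,
        )
        _, maps = reconstruct(ds, cfg)
        bare = integrate_peaks(phase_correct(transform(ds), "magnitude"), windows)
        np.testing.assert_allclose(
            maps.maps["lactate"], bare.maps["lactate"], rtol=1e-12
        )

    def test_chain_scales_linearly(self, small_acq, rng):
        fids = 0.1 * (
            rng.standard_normal((8, 8, 64)) + 1j * rng.standard_normal((8, 8, 64))
        )
        t = np.arange(64) * small_acq.dwell
        fids[4, 4] += 5.0 * np.exp(2j * np.pi * 440.0 * t - t / 0.004)
        cfg = ReconConfig(spatial_zero_fill=16, spectral_zero_fill=128)
        _, m1 = reconstruct(dataset(small_acq, fids), cfg)
        _, m2 = reconstruct(dataset(small_acq, 3.0 * fids), cfg)
        for name in m1.maps:
            scale = np.abs(m1.maps[name]).max()
            np.testing.assert_allclose(
                m2.maps[name], 3.0 * m1.maps[name], atol=1e-10 * max(scale, 1.0) * 3
            )

    def test_provenance_records_config(self, small_acq):
        fids = np.zeros((8, 8, 64), dtype=complex)
        cfg = ReconConfig(spatial_zero_fill=16, spectral_zero_fill=128, line_broadening=11.0)
        _, maps = reconstruct(dataset(small_acq, fids), cfg)
        assert maps.provenance.line_broadening == 11.0
        assert maps.provenance.peak_windows is not None


class TestConfigValidation:
    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            ReconConfig(peak_windows={"a": (0.0, 100.0), "b": (50.0, 150.0)})

    def test_negative_line_broadening_rejected(self):
        with pytest.raises(ValueError):
            ReconConfig(line_broadening=-1.0)
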