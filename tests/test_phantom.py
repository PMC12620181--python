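"""Digital phantom, respiratory surrogate and forward k-space simulation."""

import numpy as np
import pytest

from aquamap.phantom import (
    make_motion_trace,
    make_vial_phantom,
    simulate_kspace,
)
from aquamap.sequence import bloch_simulate
from aquamap.subspace import project, reconstruct
from aquamap.trajectory import generate_sampling
from aquamap.waterfat import fat_model


@pytest.fixture(scope="module")
def spectrum():
    return fat_model("single_peak_test")


@pytest.fixture(scope="module")
def phantom16():
    return make_vial_phantom((16, 16, 8), n_vials=4, seed=1)


@pytest.fixture(scope="module")
def sampling16(timing):
    return generate_sampling(16, 8, timing, r=7.5, n_repetitions=1)


class TestVialPhantom:
    def test_fat_fraction_value_present(self, phantom16):
        assert 0.25 in phantom16.tissue_table["fat_fraction"]

    def test_seeded_reproducibility(self):
        a = make_vial_phantom((16, 16, 8), n_vials=4, seed=7)
        b = make_vial_phantom((16, 16, 8), n_vials=4, seed=7)
        np.testing.assert_array_equal(a.label_map, b.label_map)
        np.testing.assert_array_equal(a.tissue_table, b.tissue_table)
        np.testing.assert_array_equal(a.coil_maps, b.coil_maps)

    def test_zero_b0_profile(self, phantom16):
        assert np.all(phantom16.b0_map == 0)

    def test_per_vial_b0_within_range(self):
        p = make_vial_phantom((16, 16, 8), n_vials=4, b0_profile="per_vial",
                              b0_max=100.0, seed=2)
        assert np.any(p.tissue_table["b0"] != 0)
        assert np.all(np.abs(p.tissue_table["b0"]) <= 100.0)

    def test_labels_disjoint_and_ground_truth_maps(self, phantom16):
        labs = np.unique(phantom16.label_map)
        assert labs[0] == 0
        t1 = phantom16.map_of("t1")
        assert np.all(t1[phantom16.label_map == 0] == 0)

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            make_vial_phantom((6, 6, 4), n_vials=8)

    def test_invalid_fat_fraction_rejected(self):
        with pytest.raises(ValueError):
            make_vial_phantom((16, 16, 8), n_vials=3, ff_values=(1.5,))


class TestMotionTrace:
    def test_zero_amplitude_constant(self):
        tr = make_motion_trace(10.0, amplitude=0.0, seed=0)
        assert np.all(tr.amplitude == 0)

    def test_plateau_is_histogram_mode(self):
        tr = make_motion_trace(120.0, period=3.7, amplitude=1.0, seed=1)
        hist, edges = np.histogram(tr.amplitude, bins=20)
        mode_bin = np.argmax(hist)
        # end-expiration level (0) is the most occupied amplitude
        assert edges[mode_bin] <= 0.05

    def test_seed_reproducible(self):
        a = make_motion_trace(30.0, noise_sd=0.1, seed=9)
        b = make_motion_trace(30.0, noise_sd=0.1, seed=9)
        np.testing.assert_array_equal(a.amplitude, b.amplitude)

    def test_bad_period_rejected(self):
        with pytest.raises(ValueError):
            make_motion_trace(10.0, period=0.0)

    def test_interpolation(self):
        tr = make_motion_trace(10.0, seed=0)
        mid = tr.at(tr.sample_times[:5].mean())
        assert np.isfinite(mid)


class TestSimulateKSpace:
    def test_matches_bruteforce_dft(self, phantom16, timing, sampling16, spectrum):
        """Fourier encoding verified against a direct DFT oracle."""
        kd = simulate_kspace(phantom16, timing, sampling16, spectrum,
                             noise_sd=0.0)
        nx, ny, nz = phantom16.shape
        nxo = 2 * nx
        tt = phantom16.tissue_table
        cyc = sampling16.cycle_profile_index()
        coords = sampling16.profile_coords
        tls = {}
        for lab in range(1, tt.shape[0]):
            tls[lab] = bloch_simulate(
                timing, tt["t1"][lab], tt["t2"][lab], tt["b0"][lab]
            ).values.real
        ftl = bloch_simulate(timing, 350.0, 50.0, 0.0).values.real
        c1 = spectrum.dephasing(timing.te[0])
        xs = np.arange(nxo) - nxo // 2
        ys = np.arange(ny) - ny // 2
        zs = np.arange(nz) - nz // 2
        for n in (0, 17, 333):
            j = cyc[n]
            ky, kz = coords[n]
            vol = np.zeros((nxo, ny, nz), complex)
            for lab in range(1, tt.shape[0]):
                amp = tt["proton_density"][lab] * (
                    (1 - tt["fat_fraction"][lab]) * tls[lab][j]
                    + tt["fat_fraction"][lab] * c1 * ftl[j]
                ) * np.exp(2j * np.pi * tt["b0"][lab] * 1e-3 * timing.te[0])
                ind = phantom16.label_map == lab
                vol[(nxo - nx) // 2:(nxo + nx) // 2][ind] += (
                    amp * phantom16.coil_maps[0][ind])
            line = np.array([
                np.sum(vol * np.exp(-2j * np.pi * (
                    kx * xs[:, None, None] / nxo
                    + ky * ys[None, :, None] / ny
                    + kz * zs[None, None, :] / nz)))
                for kx in xs
            ])
            err = np.abs(line - kd.data[n, 0, 0]) / np.abs(line).max()
            assert err.max() < 1e-5

    def test_rigid_shift_is_linear_phase(self, phantom16, timing, sampling16,
                                         spectrum):
        """Fourier shift theorem: motion multiplies k-lines by a phase ramp."""
        from aquamap.phantom import MotionTrace

        static = simulate_kspace(phantom16, timing, sampling16, spectrum)
        shift_units = 0.7
        tr = MotionTrace(amplitude=np.array([shift_units, shift_units]),
                         sample_times=np.array([0.0, 1e9]))
        moved = simulate_kspace(phantom16, timing, sampling16, spectrum,
                                motion=tr, motion_gain=5.0)
        nxo = static.n_readout
        kx = np.arange(nxo) - nxo // 2
        fov = nxo * phantom16.voxel_size
        ramp = np.exp(-2j * np.pi * kx * shift_units * 5.0 / fov)
        np.testing.assert_allclose(
            moved.data[10, 0, 0], static.data[10, 0, 0] * ramp, atol=1e-3
        )

    def test_noiseless_deterministic_and_parseval(self, phantom16, timing,
                                                  sampling16, spectrum):
        a = simulate_kspace(phantom16, timing, sampling16, spectrum, seed=1)
        b = simulate_kspace(phantom16, timing, sampling16, spectrum, seed=2)
        np.testing.assert_array_equal(a.data, b.data)
        # unitarity along the readout: k-line energy = N * image-line energy
        line = a.data[5, 0, 0].astype(np.complex128)
        img = np.fft.ifft(np.fft.ifftshift(line))
        assert np.sum(np.abs(line) ** 2) == pytest.approx(
            line.size * np.sum(np.abs(img) ** 2), rel=1e-9)

    def test_pd_linearity(self, phantom16, timing, sampling16, spectrum):
        doubled = make_vial_phantom((16, 16, 8), n_vials=4, seed=1)
        doubled.tissue_table["proton_density"][:] *= 2.0
        a = simulate_kspace(phantom16, timing, sampling16, spectrum)
        b = simulate_kspace(doubled, timing, sampling16, spectrum)
        np.testing.assert_allclose(b.data, 2 * a.data, atol=1e-4)

    def test_water_only_signals_lie_in_dictionary_span(
            self, timing, small_dictionary, small_grid):
        """FF = 0 on-grid voxel timelines ARE water dictionary timelines."""
        p = make_vial_phantom((16, 16, 8), n_vials=3, ff_values=(0.0,), seed=3)
        tt = p.tissue_table
        for lab in range(1, tt.shape[0]):
            # snap the tissue onto the dictionary grid
            t1 = small_grid.t1_values[np.argmin(np.abs(
                small_grid.t1_values - tt["t1"][lab]))]
            t2 = small_grid.t2_values[np.argmin(np.abs(
                small_grid.t2_values - tt["t2"][lab]))]
            tl = bloch_simulate(timing, t1, t2, 0.0).values.real
            atom = small_dictionary.atoms[small_dictionary.atom_index(t1, t2, 0.0)]
            resid = np.linalg.norm(tl - atom) / np.linalg.norm(tl)
            assert resid < 1e-5

    def test_noise_covariance_respected(self, phantom16, timing, sampling16,
                                        spectrum):
        cov = 0.01 * np.array([[2.0, 0.5, 0, 0], [0.5, 1.0, 0, 0],
                               [0, 0, 1.0, 0], [0, 0, 0, 1.0]])
        kd = simulate_kspace(phantom16, timing, sampling16, spectrum,
                             noise_sd=0.1, noise_covariance=cov, seed=4)
        clean = simulate_kspace(phantom16, timing, sampling16, spectrum)
        noise = (kd.data - clean.data).reshape(-1, 4, kd.n_readout)
        noise = np.moveaxis(noise, 1, 0).reshape(4, -1)
        est = np.cov(noise.real) + np.cov(noise.imag)
        np.testing.assert_allclose(est / 2.0, cov, rtol=0.1, atol=5e-4)
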