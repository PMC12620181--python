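"""B0-specific dictionary matching, masking and the B1 sensitivity study."""

import numpy as np
import pytest

from aquamap.matching import (
    b1_sensitivity_analysis,
    mask_maps,
    match_parameters,
    select_b0_subdictionary,
)
from aquamap.sequence import bloch_simulate
from aquamap.subspace import CompressedDictionary


def _coeff_volume(cdict, indices, scale=1.0):
    """Stack compressed atoms as a (k, n, 1, 1) coefficient volume."""
    X = cdict.coeffs[indices].astype(complex).T * scale
    return X.reshape(cdict.coeffs.shape[1], -1, 1, 1)


class TestSelectSubdictionary:
    def test_nearest_grid_value(self, small_cdict):
        sub = select_b0_subdictionary(small_cdict, 205.0)
        assert np.all(small_cdict.params[sub, 2] == 180.0)  # 60 Hz steps here
        sub = select_b0_subdictionary(small_cdict, 130.0)
        assert np.all(small_cdict.params[sub, 2] == 120.0)

    def test_zero_field_subset_size(self, small_cdict, small_grid):
        sub = select_b0_subdictionary(small_cdict, 0.0)
        assert sub.size == small_grid.t1_values.size * small_grid.t2_values.size
        assert np.all(small_cdict.params[sub, 2] == 0.0)

    def test_out_of_range_clamped(self, small_cdict):
        sub = select_b0_subdictionary(small_cdict, -999.0)
        assert np.all(small_cdict.params[sub, 2] == -300.0)

    def test_tie_breaks_toward_zero(self, small_cdict):
        # 30 Hz is equidistant between 0 and 60 on the 60-Hz test grid
        sub = select_b0_subdictionary(small_cdict, 30.0)
        assert np.all(small_cdict.params[sub, 2] == 0.0)


class TestMatchParameters:
    def test_identity_match(self, small_dictionary, small_cdict):
        idx = small_dictionary.atom_index(825.0, 36.0, 0.0)
        vol = _coeff_volume(small_cdict, [idx])
        maps = match_parameters(vol, small_cdict, np.zeros((1, 1, 1)))
        assert maps.wt1[0, 0, 0] == 825.0
        assert maps.wt2[0, 0, 0] == 36.0

    def test_scale_invariance_and_pd(self, small_dictionary, small_cdict):
        idx = small_dictionary.atom_index(465.0, 18.0, 0.0)
        scale = 2.0 * np.exp(1j * 0.9)
        vol = _coeff_volume(small_cdict, [idx], scale=scale)
        maps = match_parameters(vol, small_cdict, np.zeros((1, 1, 1)))
        assert maps.wt1[0, 0, 0] == 465.0
        # PD is the optimal complex scale of the matched atom
        np.testing.assert_allclose(maps.pd_water[0, 0, 0], scale, rtol=1e-6)
        assert maps.match_residual[0, 0, 0] < 1e-6 * abs(scale)

    def test_corner_sweep_exact(self, small_dictionary, small_cdict, small_grid):
        corners = [
            small_dictionary.atom_index(t1, t2, 0.0)
            for t1 in (small_grid.t1_values[0], small_grid.t1_values[-1])
            for t2 in (small_grid.t2_values[0], small_grid.t2_values[-1])
        ]
        vol = _coeff_volume(small_cdict, corners)
        psi = np.zeros(vol.shape[1:])
        maps = match_parameters(vol, small_cdict, psi)
        expect = small_dictionary.params[corners]
        np.testing.assert_array_equal(maps.wt1.ravel(), expect[:, 0])
        np.testing.assert_array_equal(maps.wt2.ravel(), expect[:, 1])

    def test_random_atoms_exact_after_compression(self, small_dictionary,
                                                  small_cdict):
        rng = np.random.default_rng(0)
        idx = rng.choice(small_dictionary.n_atoms, 100, replace=False)
        vol = _coeff_volume(small_cdict, idx, scale=1.7j)
        psi = small_dictionary.params[idx, 2].reshape(-1, 1, 1)
        maps = match_parameters(vol, small_cdict, psi)
        np.testing.assert_array_equal(maps.wt1.ravel(),
                                      small_dictionary.params[idx, 0])
        np.testing.assert_array_equal(maps.wt2.ravel(),
                                      small_dictionary.params[idx, 1])

    def test_compression_preserves_uncompressed_matching(
            self, small_dictionary, small_basis, small_cdict):
        """k = 5 compressed matching agrees with full-timeline matching."""
        rng = np.random.default_rng(1)
        idx = rng.choice(small_dictionary.n_atoms, 200, replace=False)
        sub0 = select_b0_subdictionary(small_cdict, 0.0)
        at_b0 = small_dictionary.params[idx, 2]
        agree = 0
        atoms = small_dictionary.atoms
        for i, b0 in zip(idx, at_b0):
            sub = select_b0_subdictionary(small_cdict, b0)
            tl = atoms[i].astype(np.float64)
            # full-timeline normalized match
            D = atoms[sub].astype(np.float64)
            scores = np.abs(D @ tl) / np.linalg.norm(D, axis=1)
            best_full = sub[np.argmax(scores)]
            # compressed match
            c = small_basis.phi.T @ tl
            Dc = small_cdict.coeffs[sub]
            sc = np.abs(Dc @ c) / small_cdict.norms[sub]
            best_comp = sub[np.argmax(sc)]
            agree += best_full == best_comp
        assert agree / idx.size >= 0.99

    def test_b0_specific_vs_forced_zero_bias(self, timing, small_dictionary,
                                             small_cdict):
        """At psi = 240 Hz, the B0-specific rule recovers the parameters while
        the forced B0 = 0 subdictionary underestimates wT1."""
        t1, t2 = 825.0, 36.0
        tl = bloch_simulate(timing, t1, t2, 240.0).values.real
        c = (tl @ small_cdict.basis.phi).astype(complex).reshape(-1, 1, 1, 1)
        good = match_parameters(c, small_cdict, np.full((1, 1, 1), 240.0))
        # within one (coarse test) grid step
        t1_step = np.max(np.diff(small_dictionary.grid.t1_values))
        t2_step = np.max(np.diff(small_dictionary.grid.t2_values))
        assert abs(good.wt1[0, 0, 0] - t1) <= t1_step
        assert abs(good.wt2[0, 0, 0] - t2) <= t2_step
        sub0 = select_b0_subdictionary(small_cdict, 0.0)
        cd0 = CompressedDictionary(
            coeffs=small_cdict.coeffs[sub0], norms=small_cdict.norms[sub0],
            params=small_cdict.params[sub0], basis=small_cdict.basis)
        bad = match_parameters(c, cd0, np.zeros((1, 1, 1)))
        # systematic underestimate by more than the local grid spacing
        local_step = 90.0  # T1 spacing of the coarse test grid below 1500 ms
        assert bad.wt1[0, 0, 0] - t1 < -local_step

    def test_shape_mismatch_rejected(self, small_cdict):
        with pytest.raises(ValueError):
            match_parameters(np.zeros((2, 4, 4, 1), complex), small_cdict,
                             np.zeros((4, 4, 1)))


class TestMask:
    def test_constant_volume_all_true(self):
        assert mask_maps(np.full((4, 4, 2), 3.0)).all()

    def test_zeros_masked_out(self):
        v = np.zeros((10, 10, 1))
        v[:5] = 1.0
        m = mask_maps(v)
        assert m[:5].all() and not m[5:].any()

    def test_threshold_boundary_inclusive(self):
        v = np.linspace(0, 1, 100).reshape(10, 10, 1)
        m = mask_maps(v)
        thresh = 0.1 * np.percentile(v, 95)
        assert m[v >= thresh].all()
        assert not m[v < thresh].any()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mask_maps(np.zeros((0,)))


@pytest.fixture(scope="module")
def surfaces(timing, small_basis, small_cdict):
    return b1_sensitivity_analysis(
        timing,
        t1_values=[555.0, 825.0, 1095.0, 1455.0],
        t2_values=[18.0, 36.0, 45.0, 63.0],
        b1_values=[0.6, 0.8, 1.0, 1.2],
        basis=small_basis,
        cdict=small_cdict,
    )


class TestB1Sensitivity:
    def test_nominal_b1_errors_within_grid_step(self, surfaces, small_grid):
        ib1 = list(surfaces.b1_values).index(1.0)
        t1_step = np.max(np.diff(small_grid.t1_values))
        t2_step = np.max(np.diff(small_grid.t2_values))
        assert np.all(np.abs(surfaces.dt1[:, :, ib1]) <= t1_step / 2 + 1e-9)
        assert np.all(np.abs(surfaces.dt2[:, :, ib1]) <= t2_step / 2 + 1e-9)

    def test_liver_like_errors_small(self, surfaces):
        i1 = list(surfaces.t1_values).index(825.0)
        i2 = list(surfaces.t2_values).index(36.0)
        for ib1, b1 in enumerate(surfaces.b1_values):
            if 0.8 <= b1 <= 1.2:
                assert abs(surfaces.dt1[i1, i2, ib1]) / 825.0 < 0.10
                assert abs(surfaces.dt2[i1, i2, ib1]) / 36.0 < 0.10


class TestMatchingVariants:
    def test_joint_two_echo_matching_identity(self, small_dictionary,
                                              small_cdict):
        idx = small_dictionary.atom_index(1095.0, 63.0, 0.0)
        vol = _coeff_volume(small_cdict, [idx])
        maps = match_parameters(vol, small_cdict, np.zeros((1, 1, 1)),
                                echo2_coeffs=vol * np.exp(0.4j))
        assert maps.wt1[0, 0, 0] == 1095.0
        assert maps.wt2[0, 0, 0] == 63.0
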