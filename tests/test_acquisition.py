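import logging

import nibabel as nib
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drmm import (
    AcquisitionGrid,
    NoiseEstimate,
    SignalVolume,
    correct_rician_bias,
    estimate_sigma_background,
    load_volume,
    normalize_signal,
    write_map,
    write_volume,
)
from drmm.acquisition import GridError


class TestAcquisitionGrid:
    def test_exemplar_protocol_has_16_points(self, grid16):
        assert grid16.n_points == 16
        assert grid16.te_values == (57.0, 70.0, 150.0, 200.0)
        assert grid16.b_values == (0.0, 150.0, 750.0, 1500.0)
        assert grid16.points[grid16.reference_index] == (57.0, 0.0)

    def test_points_sorted_lexicographically(self):
        grid = AcquisitionGrid(((150.0, 0.0), (57.0, 750.0), (57.0, 0.0)))
        assert grid.points == ((57.0, 0.0), (57.0, 750.0), (150.0, 0.0))

    @pytest.mark.parametrize(
        "points",
        [
            (),  # empty
            ((57.0, 0.0), (57.0, 0.0)),  # duplicate
            ((0.0, 0.0),),  # TE must be positive
            ((57.0, -5.0),),  # negative b
            ((70.0, 0.0), (57.0, 150.0)),  # no (min TE, min b) point
        ],
    )
    def test_invalid_grids_rejected(self, points):
        with pytest.raises(GridError):
            AcquisitionGrid(points)

    def test_csv_round_trip(self, grid16, tmp_path):
        path = tmp_path / "grid.csv"
        grid16.to_csv(path)
        assert AcquisitionGrid.from_csv(path) == grid16

    def test_csv_rejects_non_canonical_order(self, tmp_path):
        table = AcquisitionGrid.from_product().to_table()
        table.loc[0, "volume_index"] = 99  # moves the reference volume last
        path = tmp_path / "grid.csv"
        table.to_csv(path, index=False)
        with pytest.raises(GridError, match="order"):
            AcquisitionGrid.from_csv(path)


class TestLoadVolume:
    def _write(self, tmp_path, shape):
        data = np.random.default_rng(0).uniform(10, 100, shape)
        img = nib.Nifti1Image(data, np.eye(4))
        path = tmp_path / "vol.nii"
        nib.save(img, str(path))
        return path, data

    def test_load_matches_grid(self, grid16, tmp_path):
        path, data = self._write(tmp_path, (3, 3, 2, 16))
        vol = load_volume(path, grid16)
        assert vol.shape == (3, 3, 2, 16)
        np.testing.assert_allclose(vol.data, data)

    def test_point_count_mismatch(self, grid16, tmp_path):
        path, _ = self._write(tmp_path, (3, 3, 2, 15))
        with pytest.raises(GridError, match="expected 16 points"):
            load_volume(path, grid16)

    def test_single_voxel_volume(self, grid16, tmp_path):
        path, _ = self._write(tmp_path, (1, 1, 1, 16))
        vol = load_volume(path, grid16)
        assert vol.shape == (1, 1, 1, 16)

    def test_non_finite_voxels_reported_with_coordinates(self, grid16, tmp_path):
        data = np.ones((2, 2, 1, 16))
        data[1, 0, 0, 3] = np.nan
        nib.save(nib.Nifti1Image(data, np.eye(4)), str(tmp_path / "bad.nii"))
        with pytest.raises(ValueError, match=r"non-finite.*\(1, 0, 0, 3\)"):
            load_volume(tmp_path / "bad.nii", grid16)

    def test_missing_file(self, grid16, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_volume(tmp_path / "nope.nii", grid16)

    def test_directory_of_3d_volumes(self, grid16, tmp_path):
        rng = np.random.default_rng(1)
        stack = rng.uniform(10, 100, (2, 2, 1, 16))
        d = tmp_path / "vols"
        d.mkdir()
        for i in range(16):
            nib.save(
                nib.Nifti1Image(stack[..., i], np.eye(4)), str(d / f"vol_{i:02d}.nii")
            )
        vol = load_volume(d, grid16)
        np.testing.assert_allclose(vol.data, stack)


class TestRicianCorrection:
    def test_pythagorean_case(self):
        vol = SignalVolume(np.full((1, 1, 1, 1), 13.0))
        out = correct_rician_bias(vol, NoiseEstimate(sigma=5.0))
        assert out.data[0, 0, 0, 0] == pytest.approx(12.0, abs=1e-12)

    def test_below_floor_clamps_to_zero(self):
        vol = SignalVolume(np.zeros((1, 1, 1, 2)))
        out = correct_rician_bias(vol, NoiseEstimate(sigma=5.0))
        assert (out.data == 0).all()

    def test_zero_sigma_is_identity(self, rng):
        vol = SignalVolume(rng.uniform(0, 50, (2, 2, 1, 4)))
        out = correct_rician_bias(vol, NoiseEstimate(sigma=0.0))
        np.testing.assert_array_equal(out.data, vol.data)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            NoiseEstimate(sigma=-1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        m=st.floats(0, 1e4, allow_nan=False),
        dm=st.floats(0, 100, allow_nan=False),
        sigma=st.floats(0, 100, allow_nan=False),
    )
    def test_monotone_and_never_increases(self, m, dm, sigma):
        vol = SignalVolume(np.array(m).reshape(1, 1, 1, 1))
        vol2 = SignalVolume(np.array(m + dm).reshape(1, 1, 1, 1))
        noise = NoiseEstimate(sigma=sigma)
        a = correct_rician_bias(vol, noise).data.item()
        b = correct_rician_bias(vol2, noise).data.item()
        assert a <= b  # monotone in M
        assert a <= m  # never exceeds the input


class TestNormalization:
    def test_reference_entry_becomes_exactly_one(self, grid16, rng):
        vol = SignalVolume(rng.uniform(50, 500, (3, 3, 1, 16)))
        out = normalize_signal(vol, grid16)
        ref = out.data[..., grid16.reference_index]
        np.testing.assert_array_equal(ref[out.get_mask()], 1.0)

    def test_known_scale(self, grid16):
        data = np.full((1, 1, 1, 16), 50.0)
        data[0, 0, 0, grid16.reference_index] = 200.0
        out = normalize_signal(SignalVolume(data), grid16)
        assert out.data[0, 0, 0, 1] == pytest.approx(0.25)
        assert out.data[0, 0, 0, grid16.reference_index] == 1.0

    def test_zero_voxel_dropped_from_mask_and_logged(self, grid16, caplog):
        data = np.full((2, 1, 1, 16), 100.0)
        data[1, 0, 0, :] = 0.0
        with caplog.at_level(logging.WARNING):
            out = normalize_signal(SignalVolume(data), grid16)
        assert out.get_mask()[0, 0, 0] and not out.get_mask()[1, 0, 0]
        assert np.isnan(out.data[1, 0, 0, :]).all()
        assert "dropping 1 voxel" in caplog.text

    def test_idempotent_on_normalized_input(self, grid16, rng):
        vol = SignalVolume(rng.uniform(50, 500, (2, 2, 1, 16)))
        once = normalize_signal(vol, grid16)
        twice = normalize_signal(once, grid16)
        np.testing.assert_array_equal(
            once.data[once.get_mask()], twice.data[twice.get_mask()]
        )


class TestMapIO:
    def test_round_trip_bit_identical(self, grid16, tmp_path, rng):
        template = SignalVolume(rng.uniform(0, 1, (4, 4, 2, 16)))
        m = rng.uniform(0, 1, (4, 4, 2))
        m[0, 0, 0] = np.nan  # out-of-mask convention
        path = write_map(m, template, tmp_path / "map.nii")
        back = np.asarray(nib.load(str(path)).dataobj)
        np.testing.assert_array_equal(back, m)

    def test_shape_mismatch(self, tmp_path, rng):
        template = SignalVolume(rng.uniform(0, 1, (4, 4, 2, 16)))
        with pytest.raises(ValueError, match="does not match"):
            write_map(np.zeros((2, 2, 2)), template, tmp_path / "map.nii")

    def test_volume_round_trip(self, grid16, tmp_path, rng):
        vol = SignalVolume(rng.uniform(0, 1, (2, 2, 1, 16)))
        path = write_volume(vol, tmp_path / "vol.nii")
        np.testing.assert_array_equal(load_volume(path, grid16).data, vol.data)


def test_background_sigma_estimate_recovers_rayleigh_noise(rng):
    sigma_true = 7.0
    noise = np.sqrt(
        rng.normal(0, sigma_true, (6, 6, 2, 16)) ** 2
        + rng.normal(0, sigma_true, (6, 6, 2, 16)) ** 2
    )
    est = estimate_sigma_background(SignalVolume(noise), corner=(6, 6, 2))
    assert est.source == "background_roi"
    assert est.sigma == pytest.approx(sigma_true, rel=0.1)
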