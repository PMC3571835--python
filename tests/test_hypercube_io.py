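"""ENVI I/O round-trips, reflectance calibration, cropping and ROI extraction."""

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from hyperseed.errors import (
    CapacityError,
    DimensionError,
    EnviFormatError,
    EnviIntegrityError,
    ParameterError,
    SpectralRangeError,
)
from hyperseed.hypercube_io import (
    Hypercube,
    ReferencePair,
    calibrate_reflectance,
    crop_spectral,
    extract_rois,
    read_envi,
    write_envi,
)

from conftest import make_cube


class TestEnviRoundTrip:
    @pytest.mark.parametrize("interleave", ["bil", "bip", "bsq"])
    @pytest.mark.parametrize("dtype", [np.float32, np.uint16])
    def test_round_trip_identity(self, rng, tmp_path, interleave, dtype):
        cube = make_cube(rng, 3, 4, 5, dtype=np.float32)
        if dtype is np.uint16:
            cube = Hypercube((cube.data * 1000).astype(np.uint16), cube.wavelengths)
        path = write_envi(cube, tmp_path / "c.hdr", interleave)
        back = read_envi(path)
        assert np.array_equal(back.data, cube.data)
        assert np.array_equal(back.wavelengths, cube.wavelengths)

    def test_interleave_invariance(self, rng, tmp_path):
        cube = make_cube(rng, 3, 4, 5)
        cubes = [
            read_envi(write_envi(cube, tmp_path / f"c_{il}.hdr", il))
            for il in ("bil", "bip", "bsq")
        ]
        for other in cubes[1:]:
            assert np.array_equal(cubes[0].data, other.data)

    @settings(
        deadline=None,
        max_examples=20,
        derandomize=True,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    @given(
        rows=st.integers(1, 6),
        cols=st.integers(1, 6),
        bands=st.integers(1, 8),
        interleave=st.sampled_from(["bil", "bip", "bsq"]),
        seed=st.integers(0, 1000),
    )
    def test_round_trip_property(self, tmp_path, rows, cols, bands, interleave, seed):
        rng = np.random.default_rng(seed)
        cube = make_cube(rng, rows, cols, bands)
        back = read_envi(write_envi(cube, tmp_path / f"p{seed}.hdr", interleave))
        assert np.array_equal(back.data, cube.data)

    def test_header_declares_geometry(self, rng, tmp_path):
        # a 672-column image is recorded as `samples = 672`-style header keys
        cube = make_cube(rng, 2, 7, 3)
        text = write_envi(cube, tmp_path / "c.hdr", "bsq").read_text()
        assert "samples = 7" in text
        assert "lines = 2" in text
        assert "interleave = bsq" in text

    def test_512_band_wavelength_vector(self, tmp_path):
        wl = np.linspace(380.0, 1030.0, 512)
        cube = Hypercube(np.zeros((2, 2, 512), dtype=np.float32), wl)
        back = read_envi(write_envi(cube, tmp_path / "c.hdr"))
        assert len(back.wavelengths) == 512
        assert back.wavelengths[0] == pytest.approx(380.0)
        assert back.wavelengths[-1] == pytest.approx(1030.0)

    def test_missing_key_is_named(self, rng, tmp_path):
        path = write_envi(make_cube(rng), tmp_path / "c.hdr")
        text = "\n".join(
            l for l in path.read_text().splitlines() if not l.startswith("interleave")
        )
        path.write_text(text)
        with pytest.raises(EnviFormatError, match="interleave"):
            read_envi(path)

    def test_size_mismatch_detected(self, rng, tmp_path):
        path = write_envi(make_cube(rng), tmp_path / "c.hdr")
        binary = path.with_suffix(".img")
        binary.write_bytes(binary.read_bytes()[:-8])
        with pytest.raises(EnviIntegrityError):
            read_envi(path)

    def test_unsupported_dtype_rejected(self, rng, tmp_path):
        path = write_envi(make_cube(rng), tmp_path / "c.hdr")
        path.write_text(path.read_text().replace("data type = 4", "data type = 5"))
        with pytest.raises(EnviFormatError, match="data type"):
            read_envi(path)


class TestCalibration:
    def _refs(self, shape, wl, white=1.0, black=0.2):
        return ReferencePair(
            Hypercube(np.full(shape, white), wl),
            Hypercube(np.full(shape, black), wl),
        )

    def test_raw_equals_white_gives_ones(self):
        wl = np.arange(3.0)
        refs = self._refs((2, 2, 3), wl)
        raw = Hypercube(np.full((2, 2, 3), 1.0), wl)
        out = calibrate_reflectance(raw, refs)
        assert np.allclose(out.data, 1.0)
        assert out.kind == "reflectance"

    def test_raw_equals_black_gives_zeros(self):
        wl = np.arange(3.0)
        refs = self._refs((2, 2, 3), wl)
        raw = Hypercube(np.full((2, 2, 3), 0.2), wl)
        assert np.allclose(calibrate_reflectance(raw, refs).data, 0.0)

    def test_midpoint_value(self):
        wl = np.arange(1.0)
        refs = self._refs((1, 1, 1), wl)
        raw = Hypercube(np.full((1, 1, 1), 0.6), wl)
        assert calibrate_reflectance(raw, refs).data[0, 0, 0] == pytest.approx(0.5)

    def test_degenerate_denominator_flagged(self):
        wl = np.arange(2.0)
        refs = ReferencePair(
            Hypercube(np.array([[[1.0, 0.3]]]), wl),
            Hypercube(np.array([[[0.0, 0.3]]]), wl),  # band 1: W == B
        )
        raw = Hypercube(np.array([[[0.5, 0.7]]]), wl)
        out = calibrate_reflectance(raw, refs)
        assert out.data[0, 0, 1] == 0.0
        assert out.meta["degenerate_mask"][0, 0, 1]
        assert not out.meta["degenerate_mask"][0, 0, 0]
        assert out.meta["qc"]["n_degenerate"] == 1

    def test_negative_eps_rejected(self):
        wl = np.arange(1.0)
        refs = self._refs((1, 1, 1), wl)
        raw = Hypercube(np.ones((1, 1, 1)), wl)
        with pytest.raises(ParameterError):
            calibrate_reflectance(raw, refs, eps=-1.0)

    def test_shape_mismatch_rejected(self, rng):
        wl = np.arange(3.0)
        refs = self._refs((2, 2, 3), wl)
        raw = Hypercube(np.ones((3, 3, 3)), np.arange(3.0))
        with pytest.raises(DimensionError):
            calibrate_reflectance(raw, refs)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(scale=st.floats(0.1, 100.0), seed=st.integers(0, 100))
    def test_affine_invariance(self, scale, seed):
        # scaling I0, W, B by a common positive constant leaves I unchanged
        rng = np.random.default_rng(seed)
        wl = np.arange(4.0)
        w = 1.0 + rng.random((2, 3, 4))
        b = 0.1 * rng.random((2, 3, 4))
        i0 = b + (w - b) * rng.random((2, 3, 4))
        base = calibrate_reflectance(
            Hypercube(i0, wl), ReferencePair(Hypercube(w, wl), Hypercube(b, wl))
        )
        scaled = calibrate_reflectance(
            Hypercube(i0 * scale, wl),
            ReferencePair(Hypercube(w * scale, wl), Hypercube(b * scale, wl)),
        )
        assert np.allclose(base.data, scaled.data, atol=1e-10)


class TestCropSpectral:
    def _cube(self, wavelengths):
        wl = np.asarray(wavelengths, dtype=float)
        data = np.arange(2 * 2 * len(wl), dtype=float).reshape(2, 2, len(wl))
        return Hypercube(data, wl, kind="reflectance")

    def test_full_range_is_identity(self):
        cube = self._cube([400, 500, 600])
        out = crop_spectral(cube, 400, 600)
        assert np.array_equal(out.data, cube.data)
        assert np.array_equal(out.wavelengths, cube.wavelengths)

    def test_closed_interval_endpoints_kept(self):
        cube = self._cube([400, 500, 600, 900, 950])
        out = crop_spectral(cube, 500, 900)
        assert list(out.wavelengths) == [500, 600, 900]
        assert out.data.shape[2] == 3

    def test_idempotent(self):
        cube = self._cube([400, 500, 600, 900, 950])
        once = crop_spectral(cube, 500, 900)
        twice = crop_spectral(once, 500, 900)
        assert np.array_equal(once.data, twice.data)

    def test_empty_result_raises(self):
        with pytest.raises(SpectralRangeError):
            crop_spectral(self._cube([400, 500]), 600, 700)

    def test_inverted_bounds_raise(self):
        with pytest.raises(ParameterError):
            crop_spectral(self._cube([400, 500]), 700, 600)


class TestExtractRois:
    def test_whole_image_single_roi(self, rng):
        cube = make_cube(rng, 8, 8, 3)
        (roi,) = extract_rois(cube, side=8, n=1, seed=0)
        assert roi.origin == (0, 0)
        assert np.array_equal(roi.cube.data, cube.data)

    def test_deterministic_for_seed(self, rng):
        cube = make_cube(rng, 40, 40, 2)
        a = extract_rois(cube, 8, 5, seed=3)
        b = extract_rois(cube, 8, 5, seed=3)
        assert [r.origin for r in a] == [r.origin for r in b]

    def test_ten_disjoint_100px_rois_in_1000px_image(self):
        cube = Hypercube(
            np.zeros((1000, 1000, 1), dtype=np.float32), np.array([500.0])
        )
        rois = extract_rois(cube, side=100, n=10, seed=1)
        assert len(rois) == 10
        mask = np.zeros((1000, 1000), dtype=int)
        for r in rois:
            r0, c0 = r.origin
            mask[r0 : r0 + 100, c0 : c0 + 100] += 1
        assert mask.max() == 1  # pairwise disjoint
        assert mask.sum() == 10 * 100 * 100

    def test_rois_are_subsets_of_parent(self, rng):
        cube = make_cube(rng, 30, 30, 2)
        for roi in extract_rois(cube, 7, 4, seed=5):
            r0, c0 = roi.origin
            assert np.array_equal(
                roi.cube.data, cube.data[r0 : r0 + 7, c0 : c0 + 7]
            )

    def test_capacity_error_states_maximum(self, rng):
        cube = make_cube(rng, 20, 20, 2)
        with pytest.raises(CapacityError, match="4"):
            extract_rois(cube, 10, 5, seed=0)

    def test_fallback_fills_dense_requests(self, rng):
        # asking for every grid tile forces the deterministic fallback
        cube = make_cube(rng, 20, 20, 2)
        rois = extract_rois(cube, 10, 4, seed=0)
        origins = {r.origin for r in rois}
        assert origins == {(0, 0), (0, 10), (10, 0), (10, 10)}
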