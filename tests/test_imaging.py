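"""Stack I/O, preconditioning, raster <-> mesh conversion, synthesis."""

import numpy as np
import pytest

from flipdg.dg import DGSpace
from flipdg.errors import FieldMismatchError, FormatError, NormalizationError
from flipdg.geometry import NUCLEUS, build_synthetic_geometry, triangulate
from flipdg.imaging import (
    ImageStack,
    image_to_mesh_function,
    masked_gaussian,
    precondition,
    rasterize,
    raster_mask,
    read_stack,
    synthesize_flip_stack,
    write_stack,
)
from flipdg.model import BleachSchedule, ModelParameters


def _stack(frames, pixel_size=0.1, mask=None):
    return ImageStack(
        frames=frames,
        times=np.arange(len(frames), dtype=float),
        pixel_size=pixel_size,
        cell_mask=mask,
    )


class TestStackIO:
    def test_float32_round_trip_bitwise(self, tmp_path, rng):
        frames = rng.random((50, 64, 64)).astype(np.float32)
        stack = _stack(frames)
        path = tmp_path / "stack.tif"
        write_stack(stack, path)
        back = read_stack(path)
        assert np.array_equal(back.frames.astype(np.float32), frames)
        assert np.array_equal(back.times, stack.times)
        assert back.pixel_size == stack.pixel_size

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(Exception):
            read_stack(tmp_path / "nope.tif")

    def test_integer_input_scaled_by_dtype_max(self, tmp_path):
        import tifffile

        frames = np.full((3, 8, 8), 255, dtype=np.uint8)
        path = tmp_path / "int.tif"
        tifffile.imwrite(path, frames, photometric="minisblack")
        back = read_stack(path)
        assert back.frames.max() == 1.0
        assert back.metadata["integer_scale"] == 255

    def test_rgb_input_rejected(self, tmp_path):
        import tifffile

        path = tmp_path / "rgb.tif"
        tifffile.imwrite(path, np.zeros((4, 8, 8, 3), dtype=np.uint8))
        with pytest.raises(FormatError):
            read_stack(path)

    def test_nonincreasing_times_rejected(self):
        with pytest.raises(FormatError):
            ImageStack(np.zeros((2, 4, 4)), times=[1.0, 1.0], pixel_size=0.1)


class TestPrecondition:
    def test_constant_frame_normalizes_to_one(self):
        mask = np.ones((16, 16), dtype=bool)
        stack = _stack(np.full((3, 16, 16), 0.25), mask=mask)
        pre = precondition(stack)
        assert np.allclose(pre.frames[0][mask], 1.0)
        assert pre.frames[0][mask].max() == pytest.approx(1.0)

    def test_masked_blur_conserves_mass(self, rng):
        mask = np.zeros((32, 32), dtype=bool)
        mask[4:28, 6:26] = True
        frame = rng.random((32, 32)) * mask
        out = masked_gaussian(frame, mask, sigma_px=1.0)
        assert out[mask].sum() == pytest.approx(frame[mask].sum(), rel=1e-10)
        assert np.all(out[~mask] == 0)

    def test_impulse_spreads_within_mask(self):
        mask = np.ones((33, 33), dtype=bool)
        frame = np.zeros((33, 33))
        frame[16, 16] = 1.0
        out = masked_gaussian(frame, mask, sigma_px=1.0)
        assert out[16, 16] < 1.0
        assert out[15, 16] > 0
        assert out.sum() == pytest.approx(1.0, rel=1e-10)

    def test_normalization_idempotent(self, rng):
        mask = np.ones((16, 16), dtype=bool)
        frames = 0.5 + 0.3 * rng.random((4, 16, 16))
        pre1 = precondition(_stack(frames, mask=mask), blur_radius_px=1.0)
        pre2 = precondition(pre1, blur_radius_px=1e-9)  # re-normalize only
        assert np.allclose(pre2.frames, pre1.frames, atol=1e-9)

    def test_empty_mask_rejected(self):
        stack = _stack(np.ones((3, 8, 8)), mask=np.zeros((8, 8), dtype=bool))
        with pytest.raises(NormalizationError):
            precondition(stack)


@pytest.fixture(scope="module")
def small_geometry():
    """Coarse-pixel geometry producing ~60x60 images (fast raster tests)."""
    return build_synthetic_geometry(
        ((7.5, 7.5), (6.0, 5.0)), ((7.5, 7.5), (2.5, 2.0)), (11.5, 7.5),
        pixel_size=0.25,
    )


@pytest.fixture(scope="module")
def small_mesh(small_geometry):
    return triangulate(small_geometry, 0.8)


class TestRasterMeshConversion:
    def test_constant_image_to_constant_coefficients(self, small_mesh):
        space = DGSpace(small_mesh)
        frame = np.full((60, 60), 0.7)
        coeffs = image_to_mesh_function(frame, small_mesh, space, 0.25)
        assert np.allclose(coeffs, 0.7)

    def test_linear_ramp_reproduced(self, small_mesh):
        space = DGSpace(small_mesh)
        n = 60
        cols = np.arange(n)
        frame = np.tile((cols + 0.5) * 0.25, (n, 1))  # ramp in physical x
        coeffs = image_to_mesh_function(frame, small_mesh, space, 0.25)
        assert np.allclose(coeffs, space.node_coords[:, 0], atol=1e-9)

    def test_node_outside_image_rejected(self, small_mesh):
        space = DGSpace(small_mesh)
        with pytest.raises(FieldMismatchError):
            image_to_mesh_function(np.ones((20, 20)), small_mesh, space, 0.25)

    def test_rasterize_constant_field(self, small_mesh):
        coeffs = np.full(3 * small_mesh.n_elements, 0.4)
        img = rasterize(coeffs, small_mesh, (60, 60), 0.25, background=-1.0)
        mask = raster_mask(small_mesh, (60, 60), 0.25)
        assert np.allclose(img[mask], 0.4)
        assert np.all(img[~mask] == -1.0)

    def test_membrane_jump_visible_in_raster(self, small_mesh):
        """A field with a jump across the nucleus outline shows an abrupt
        intensity step between adjacent pixels at the membrane."""
        region = np.repeat(small_mesh.element_region, 3)
        coeffs = np.where(region == NUCLEUS, 1.0, 0.0).astype(float)
        img = rasterize(coeffs, small_mesh, (60, 60), 0.25, background=0.0)
        dx = np.abs(np.diff(img, axis=1))
        assert dx.max() > 0.9  # full jump within one pixel pair

    def test_round_trip_error_decreases_with_pixel_size(self, small_mesh):
        space = DGSpace(small_mesh)
        smooth = space.interpolate(lambda x, y: np.sin(0.4 * x) * np.cos(0.3 * y))
        errs = []
        for px, n in ((0.25, 60), (0.125, 120)):
            img = rasterize(smooth, small_mesh, (n, n), px)
            back = image_to_mesh_function(img, small_mesh, space, px)
            errs.append(np.abs(back - smooth).mean())
        assert errs[1] < errs[0]


@pytest.fixture(scope="module")
def synth_args(small_geometry, small_mesh):
    return dict(
        params=ModelParameters(16.1, 35.6, 0.319, 0.111),
        geometry=small_geometry,
        schedule=BleachSchedule(n_frames=5),
        mesh=small_mesh,
    )


class TestSynthesis:
    def test_seed_determinism(self, synth_args):
        s1, _ = synthesize_flip_stack(noise_sd=0.02, seed=7, **synth_args)
        s2, _ = synthesize_flip_stack(noise_sd=0.02, seed=7, **synth_args)
        s3, _ = synthesize_flip_stack(noise_sd=0.02, seed=8, **synth_args)
        assert np.array_equal(s1.frames, s2.frames)
        assert not np.array_equal(s1.frames, s3.frames)

    def test_frame_times_follow_protocol(self, synth_args):
        stack, _ = synthesize_flip_stack(**synth_args)
        assert stack.times[0] == 0.0
        assert np.allclose(np.diff(stack.times[1:]), 2.6)
        assert stack.times[1] == pytest.approx(2.0)

    def test_nucleus_decays_slower_for_small_permeability(self, synth_args):
        """The sealed-ish nucleus loses fluorescence more slowly than the
        cytoplasm that hosts the bleach spot."""
        stack, mesh = synthesize_flip_stack(**synth_args)
        labels_nuc = raster_mask(mesh, stack.shape, stack.pixel_size)
        from flipdg.imaging import rasterize as rast

        region = np.repeat(mesh.element_region, 3).astype(float)
        nuc_img = rast(region, mesh, stack.shape, stack.pixel_size) == NUCLEUS
        cyt_img = labels_nuc & ~nuc_img
        nuc_loss = stack.frames[-1][nuc_img].mean() / stack.frames[0][nuc_img].mean()
        cyt_loss = stack.frames[-1][cyt_img].mean() / stack.frames[0][cyt_img].mean()
        assert nuc_loss > cyt_loss
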