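"""Image stacks: I/O, preconditioning and raster <-> mesh conversion.

Raster convention: image row 0 is the top of the field; mesh coordinates
are y-up with the origin at the lower-left corner.  A pixel (row, col)
has its center at

    x = (col + 0.5) * pixel_size,
    y = (n_rows - row - 0.5) * pixel_size.

Preconditioning mirrors the experimental pipeline: Gaussian smoothing
restricted to the cell domain (mask-normalized so background does not
bleed in, then rescaled to conserve total masked intensity) followed by
normalization of the whole stack with the maximum of the first blurred
frame, so the initial intensity lies in [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .dg import DGSpace, assemble, run_flip
from .errors import FieldMismatchError, FormatError, GeometryError, NormalizationError
from .geometry import CellGeometry, TriMesh, triangulate
from .model import (
    BleachSchedule,
    ModelParameters,
    build_rate_maps,
    init_fields_from_frame,
)

#: Gaussian blur radius (standard deviation) of the preconditioning, pixels.
DEFAULT_BLUR_RADIUS_PX = 1.0


@dataclass
class ImageStack:
    """Time-lapse single-channel image stack with pixel geometry."""

    frames: np.ndarray            # (T, H, W) float
    times: np.ndarray             # (T,) seconds
    pixel_size: float             # micrometres per pixel
    cell_mask: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3:
            raise FormatError("frames must be a (T, H, W) array")
        if len(self.times) != len(self.frames):
            raise FormatError("one timestamp per frame required")
        if np.any(np.diff(self.times) <= 0):
            raise FormatError("times must be strictly increasing")
        if not np.all(np.isfinite(self.frames)):
            raise FormatError("frame intensities must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as multi-page float32 TIFF plus a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32), photometric="minisblack")
    sidecar = {
        "times": stack.times.tolist(),
        "pixel_size": stack.pixel_size,
        "metadata": stack.metadata,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
    if stack.cell_mask is not None:
        tifffile.imwrite(
            path.with_name(path.stem + "_mask" + path.suffix),
            stack.cell_mask.astype(np.uint8),
        )


def read_stack(path, pixel_size: float | None = None, times=None) -> ImageStack:
    """Read a single-channel multi-page TIFF stack.

    Integer data are scaled to [0, 1] by the dtype maximum (recorded in
    metadata); a JSON sidecar written by :func:`write_stack` supplies
    times and pixel size when present.
    """
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise FormatError(
            f"expected a single-channel multi-page TIFF, got shape {frames.shape}"
        )
    metadata = {}
    if np.issubdtype(frames.dtype, np.integer):
        scale = float(np.iinfo(frames.dtype).max)
        metadata["integer_scale"] = scale
        frames = frames.astype(np.float64) / scale
    else:
        frames = frames.astype(np.float64)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        times = sidecar.get("times", times)
        pixel_size = sidecar.get("pixel_size", pixel_size)
        metadata.update(sidecar.get("metadata", {}))
    if times is None:
        times = np.arange(len(frames), dtype=float)
    if pixel_size is None:
        pixel_size = 1.0
    mask = None
    mask_path = path.with_name(path.stem + "_mask" + path.suffix)
    if mask_path.exists():
        mask = tifffile.imread(mask_path).astype(bool)
    return ImageStack(
        frames=frames, times=np.asarray(times, float), pixel_size=float(pixel_size),
        cell_mask=mask, metadata=metadata,
    )


def masked_gaussian(frame: np.ndarray, mask: np.ndarray, sigma_px: float) -> np.ndarray:
    """Gaussian blur restricted to a mask, conserving total masked intensity.

    Normalized convolution (blur of frame*mask divided by blur of mask)
    prevents background bleed-in; the result is rescaled so the summed
    intensity inside the mask is unchanged.
    """
    mask = mask.astype(bool)
    if not mask.any():
        raise NormalizationError("cell mask is empty")
    m = mask.astype(float)
    num = ndimage.gaussian_filter(frame * m, sigma_px)
    den = ndimage.gaussian_filter(m, sigma_px)
    out = np.zeros_like(frame, dtype=float)
    out[mask] = num[mask] / den[mask]
    total_before = frame[mask].sum()
    total_after = out[mask].sum()
    if total_after > 0:
        out[mask] *= total_before / total_after
    return out


def precondition(stack: ImageStack, blur_radius_px: float = DEFAULT_BLUR_RADIUS_PX) -> ImageStack:
    """Blur each frame inside the cell mask and normalize the stack.

    The whole stack is divided by the maximum of the first blurred frame
    inside the mask, so the first frame lies in [0, 1].  Normalization is
    idempotent; pixels outside the mask are set to zero.
    """
    if stack.cell_mask is None:
        raise NormalizationError("precondition requires a cell mask")
    mask = stack.cell_mask.astype(bool)
    blurred = np.stack([masked_gaussian(f, mask, blur_radius_px) for f in stack.frames])
    peak = blurred[0][mask].max()
    if peak <= 0:
        raise NormalizationError("first frame has no positive intensity inside the mask")
    blurred /= peak
    meta = dict(stack.metadata)
    meta.update({"blur_radius_px": blur_radius_px, "normalization_peak": float(peak)})
    return ImageStack(
        frames=blurred, times=stack.times.copy(), pixel_size=stack.pixel_size,
        cell_mask=mask.copy(), metadata=meta,
    )


# ---------------------------------------------------------------------------
# Raster <-> mesh conversion
# ---------------------------------------------------------------------------

def image_to_mesh_function(frame: np.ndarray, mesh: TriMesh, space: DGSpace,
                           pixel_size: float, mask: np.ndarray | None = None) -> np.ndarray:
    """Sample an image at the DG node positions (bilinear interpolation).

    With ``mask`` given, pixels outside the mask are first replaced by
    their nearest inside value, so nodes on the cell outline do not
    interpolate against zeroed background pixels.
    """
    frame = np.asarray(frame, dtype=float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.all():
            idx = ndimage.distance_transform_edt(~mask, return_indices=True)[1]
            frame = frame[idx[0], idx[1]]
    n_rows, n_cols = frame.shape
    xy = space.node_coords
    col = xy[:, 0] / pixel_size - 0.5
    row = n_rows - 0.5 - xy[:, 1] / pixel_size
    if (col.min() < -0.5 or col.max() > n_cols - 0.5
            or row.min() < -0.5 or row.max() > n_rows - 0.5):
        raise FieldMismatchError("mesh node outside the image field")
    return ndimage.map_coordinates(
        frame, np.vstack([row, col]), order=1, mode="nearest"
    )


def rasterize(
    coefficients: np.ndarray,
    mesh: TriMesh,
    shape: tuple[int, int],
    pixel_size: float,
    background: float = 0.0,
) -> np.ndarray:
    """Evaluate a DG field at pixel centers; outside the mesh -> background.

    Each pixel center is evaluated in its containing element, so jumps
    across the membrane remain visible in the raster.
    """
    from matplotlib.tri import Triangulation

    n_rows, n_cols = shape
    cols, rows = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    x = (cols.ravel() + 0.5) * pixel_size
    y = (n_rows - rows.ravel() - 0.5) * pixel_size
    tri = Triangulation(mesh.vertices[:, 0], mesh.vertices[:, 1], mesh.triangles)
    finder = tri.get_trifinder()
    elem = finder(x, y)
    out = np.full(n_rows * n_cols, float(background))
    inside = elem >= 0
    if inside.any():
        coeffs = np.asarray(coefficients)[np.arange(len(coefficients)).reshape(-1, 3)]
        idx = elem[inside]
        coords = mesh.element_coords[idx]  # (n, 3, 2)
        # barycentric coordinates of each point in its element
        v0 = coords[:, 0]
        d1 = coords[:, 1] - v0
        d2 = coords[:, 2] - v0
        dp = np.column_stack([x[inside], y[inside]]) - v0
        det = d1[:, 0] * d2[:, 1] - d2[:, 0] * d1[:, 1]
        l1 = (dp[:, 0] * d2[:, 1] - dp[:, 1] * d2[:, 0]) / det
        l2 = (d1[:, 0] * dp[:, 1] - d1[:, 1] * dp[:, 0]) / det
        l0 = 1.0 - l1 - l2
        vals = coeffs[idx]
        out[inside] = l0 * vals[:, 0] + l1 * vals[:, 1] + l2 * vals[:, 2]
    return out.reshape(n_rows, n_cols)


def raster_mask(mesh: TriMesh, shape: tuple[int, int], pixel_size: float) -> np.ndarray:
    """Boolean image of pixel centers covered by the mesh."""
    from matplotlib.tri import Triangulation

    n_rows, n_cols = shape
    cols, rows = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    x = (cols.ravel() + 0.5) * pixel_size
    y = (n_rows - rows.ravel() - 0.5) * pixel_size
    tri = Triangulation(mesh.vertices[:, 0], mesh.vertices[:, 1], mesh.triangles)
    return (tri.get_trifinder()(x, y) >= 0).reshape(shape)


# ---------------------------------------------------------------------------
# Synthetic FLIP stacks
# ---------------------------------------------------------------------------

@dataclass
class GoalSeries:
    """Per-frame goal functions c_g(t_i) as DG coefficient vectors."""

    coefficients: list[np.ndarray]
    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.coefficients) != len(self.times):
            raise FieldMismatchError("one goal function per calibration frame required")


def goals_from_stack(
    stack: ImageStack, mesh: TriMesh, space: DGSpace, times=None
) -> GoalSeries:
    """Build goal functions by nodal interpolation of preconditioned frames.

    The first frame (t = 0, pre-bleach) initializes the model; frames at
    the snapshot times t_i become the calibration goals.
    """
    if times is None:
        sel = slice(1, None)
        times = stack.times[1:]
    else:
        sel = np.isin(stack.times, times)
    frames = stack.frames[sel]
    coeffs = [
        image_to_mesh_function(f, mesh, space, stack.pixel_size, mask=stack.cell_mask)
        for f in frames
    ]
    return GoalSeries(coefficients=coeffs, times=np.asarray(times, float))


def synthesize_flip_stack(
    params: ModelParameters,
    geometry: CellGeometry,
    schedule: BleachSchedule,
    base_pattern=None,
    noise_sd: float = 0.0,
    seed: int = 0,
    target_edge_length: float = 0.5,
    mesh: TriMesh | None = None,
    shape: tuple[int, int] | None = None,
) -> tuple[ImageStack, TriMesh]:
    """Forward-simulate a FLIP experiment and rasterize it to an image stack.

    ``base_pattern`` is a callable ``f(x, y)`` giving the initial total
    intensity c0 in (0, 1] (default: 0.4 in the cytoplasm, 0.9 in the
    nucleus, emulating nuclear accumulation of the probe).  The first
    output frame is the pre-bleach state at t = 0; subsequent frames are
    the snapshots at t_i with seeded additive Gaussian noise (clipped at
    zero).  The ground-truth parameters are recorded in the metadata.
    """
    if noise_sd < 0:
        raise GeometryError("noise_sd must be nonnegative")
    if mesh is None:
        mesh = triangulate(geometry, target_edge_length)
    space = DGSpace(mesh)
    if base_pattern is None:
        region = np.repeat(mesh.element_region, 3)
        c0 = np.where(region == 2, 0.9, 0.4)
    else:
        c0 = np.clip(space.interpolate(base_pattern), 0.0, 1.0)
    state = init_fields_from_frame(c0)
    rates = build_rate_maps(c0, params.gamma) if params.gamma > 0 else None
    system = assemble(space, params, rates)
    traj = run_flip(state, system, schedule)

    px = geometry.pixel_size
    if shape is None:
        w, h = geometry.field_extent
        shape = (int(round(h / px)), int(round(w / px)))
    mask = raster_mask(mesh, shape, px)
    frames = [rasterize(state.c, mesh, shape, px)]
    for snap in traj.snapshots:
        frames.append(rasterize(snap.c, mesh, shape, px))
    frames = np.stack(frames)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=frames.shape)
        frames = np.clip(frames + noise * mask, 0.0, None)
    times = np.concatenate([[0.0], schedule.snapshot_times])
    stack = ImageStack(
        frames=frames,
        times=times,
        pixel_size=px,
        cell_mask=mask,
        metadata={
            "ground_truth": {
                "alpha": params.alpha, "beta": params.beta,
                "gamma": params.gamma, "p": params.p,
            },
            "noise_sd": noise_sd,
            "seed": seed,
            "schedule": {
                "t_bleach": schedule.t_bleach, "t_recover": schedule.t_recover,
                "n_frames": schedule.n_frames, "dt": schedule.dt,
                "t_offset": schedule.t_offset,
            },
        },
    )
    return stack, mesh
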