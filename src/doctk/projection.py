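"""Tissue-surface segmentation and surface-following slab projections.

The surface is found per (x, y) column of the frame-averaged dB intensity
volume as the first depth where the signal stays above
``noise_floor_db + margin_db`` for at least ``min_run`` consecutive pixels,
then median-smoothed laterally. Columns with no qualifying crossing are
marked invalid, and invalidity propagates into every downstream projection
(invalid columns render as background, never as silently filled values).

Slab projections extract a fixed-thickness depth band below the surface
(default 100 px = 724 um at the 7.24 um axial pitch) and reduce it axially
by an arithmetic mean over in-bounds voxels; columns truncated by the volume
bottom are averaged over the available depth only, so shallow samples do not
bias the mean toward zero-padding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .contrast import OctVolume

__all__ = [
    "SurfaceMap",
    "SlabProjection",
    "segment_surface",
    "extract_slab",
    "slab_average_projection",
    "en_face_slice",
]


@dataclass
class SurfaceMap:
    height: np.ndarray  # (nx, ny) first-tissue z index, undefined where invalid
    valid: np.ndarray  # (nx, ny) bool


@dataclass
class SlabProjection:
    image: np.ndarray  # (nx, ny); NaN where invalid
    valid: np.ndarray
    slab_pixels: int
    slab_um: float
    reducer: str = "mean"


def _volume_data(volume: OctVolume | np.ndarray) -> np.ndarray:
    return volume.data if isinstance(volume, OctVolume) else np.asarray(volume)


def segment_surface(
    mean_db_volume: OctVolume | np.ndarray,
    noise_floor_db: float,
    margin_db: float = 10.0,
    min_run: int = 3,
    smooth_window: int = 5,
) -> SurfaceMap:
    """Segment the first tissue depth per column of an averaged dB volume."""
    vol = _volume_data(mean_db_volume)
    if vol.size == 0:
        raise ValueError("empty volume")
    nz, nx, ny = vol.shape
    above = vol > (noise_floor_db + margin_db)
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    run_ok = above.copy()
    for k in range(1, min_run):
        shifted = np.zeros_like(above)
        shifted[: nz - k] = above[k:]
        run_ok &= shifted
    valid = run_ok.any(axis=0)
    height = np.argmax(run_ok, axis=0).astype(np.int64)
    if smooth_window and smooth_window > 1 and valid.any():
        # fill invalid columns with the median height so the filter does not
        # drag borders toward zero, then re-apply validity
        fill = int(np.median(height[valid]))
        h = np.where(valid, height, fill)
        height = median_filter(h, size=smooth_window, mode="nearest")
        height = np.clip(height, 0, nz - 1)
    return SurfaceMap(height=height, valid=valid)


def extract_slab(
    volume: OctVolume | np.ndarray,
    surface: SurfaceMap,
    slab_pixels: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Surface-aligned slab sub-volume.

    Returns ``(slab, in_bounds)`` of shape (slab_pixels, nx, ny): per valid
    column the voxels ``[height, height + slab_pixels)``; entries beyond the
    volume bottom or in invalid columns are zero with ``in_bounds`` False.
    """
    if slab_pixels < 1:
        raise ValueError("slab_pixels must be >= 1")
    vol = _volume_data(volume)
    nz, nx, ny = vol.shape
    if not surface.valid.any():
        raise ValueError("surface is invalid everywhere")
    z_idx = surface.height[None, :, :] + np.arange(slab_pixels)[:, None, None]
    in_bounds = (z_idx < nz) & surface.valid[None, :, :]
    z_clip = np.clip(z_idx, 0, nz - 1)
    slab = np.take_along_axis(vol, z_clip, axis=0)
    slab = np.where(in_bounds, slab, 0.0)
    return slab, in_bounds


def slab_average_projection(
    volume: OctVolume | np.ndarray,
    surface: SurfaceMap,
    slab_pixels: int = 100,
    reducer: str = "mean",
    axial_pitch_um: float | None = None,
) -> SlabProjection:
    """En face slab projection: mean (or max) over the surface-aligned slab.

    The mean is taken over in-bounds voxels only; invalid columns are NaN in
    the image and False in ``valid`` (rendered black downstream).
    """
    vol = _volume_data(volume)
    if axial_pitch_um is None:
        axial_pitch_um = volume.pixel_pitch_um[0] if isinstance(volume, OctVolume) else 7.24
    slab, in_bounds = extract_slab(vol, surface, slab_pixels)
    counts = in_bounds.sum(axis=0)
    valid = counts > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        if reducer == "mean":
            image = slab.sum(axis=0) / counts
        elif reducer == "max":
            image = np.where(in_bounds, slab, -np.inf).max(axis=0)
        else:
            raise ValueError(f"unknown reducer {reducer!r}")
    image = np.where(valid, image, np.nan)
    return SlabProjection(
        image=image,
        valid=valid,
        slab_pixels=slab_pixels,
        slab_um=slab_pixels * axial_pitch_um,
        reducer=reducer,
    )


def en_face_slice(
    volume: OctVolume | np.ndarray,
    depth_index: int | None = None,
    depth_um: float | None = None,
    axial_pitch_um: float | None = None,
) -> np.ndarray:
    """Fixed-depth (not surface-following) en face slice.

    Address the slice either by z index or by physical depth in micrometres
    (converted with the axial pitch, nearest index).
    """
    vol = _volume_data(volume)
    if (depth_index is None) == (depth_um is None):
        raise ValueError("give exactly one of depth_index or depth_um")
    if depth_um is not None:
        if axial_pitch_um is None:
            if isinstance(volume, OctVolume):
                axial_pitch_um = volume.pixel_pitch_um[0]
            else:
                raise ValueError("axial_pitch_um required for depth_um addressing")
        depth_index = int(round(depth_um / axial_pitch_um))
    if not 0 <= depth_index < vol.shape[0]:
        raise IndexError(f"depth index {depth_index} out of range [0, {vol.shape[0]})")
    return vol[depth_index]
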