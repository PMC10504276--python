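"""File I/O: TIFF volumes, HDF5 phantoms and frame stacks, PNG previews.

Volumes go to multi-page TIFF (page = z slice) with a JSON description tag
carrying ``{"axes": "zxy", "pitch_um": [...], "contrast": ..., "window_s": ...}``.
Phantoms and raw frame stacks go to HDF5 with the same axis-order metadata.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .contrast import OctVolume
from .phantom import ComplexFrameStack, PhantomSpec
from .projection import SurfaceMap

__all__ = [
    "save_volume",
    "load_volume",
    "save_surface",
    "load_surface",
    "save_projection_tiff",
    "save_png",
    "save_phantom",
    "load_phantom",
    "save_frame_stacks",
    "load_frame_stacks",
    "save_yaml",
    "load_yaml",
    "sha256_of",
]


def save_volume(path: str | Path, volume: OctVolume) -> Path:
    path = Path(path)
    meta = {
        "axes": "zxy",
        "pitch_um": list(volume.pixel_pitch_um),
        "contrast": volume.kind,
        "window_s": volume.window_seconds,
    }
    tifffile.imwrite(path, volume.data.astype(np.float32), description=json.dumps(meta))
    return path


def load_volume(path: str | Path) -> OctVolume:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    return OctVolume(
        data=np.asarray(data),
        pixel_pitch_um=tuple(meta.get("pitch_um", (7.24, 1.0, 1.0))),
        kind=meta.get("contrast", "unknown"),
        window_seconds=meta.get("window_s"),
    )


def save_surface(path: str | Path, surface: SurfaceMap) -> tuple[Path, Path]:
    path = Path(path)
    tifffile.imwrite(path, surface.height.astype(np.uint16))
    valid_path = path.with_name(path.stem + "_valid" + path.suffix)
    tifffile.imwrite(valid_path, surface.valid.astype(np.uint8) * 255)
    return path, valid_path


def load_surface(path: str | Path) -> SurfaceMap:
    path = Path(path)
    height = tifffile.imread(path).astype(np.int64)
    valid_path = path.with_name(path.stem + "_valid" + path.suffix)
    valid = tifffile.imread(valid_path) > 0
    return SurfaceMap(height=height, valid=valid)


def save_projection_tiff(path: str | Path, image: np.ndarray) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    return path


def save_png(path: str | Path, image_uint8: np.ndarray) -> Path:
    path = Path(path)
    iio.imwrite(path, image_uint8)
    return path


def save_phantom(path: str | Path, phantom: PhantomSpec) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["axes"] = "zxy"
        f.attrs["grid_shape"] = phantom.grid_shape
        f.attrs["pixel_pitch_um"] = phantom.pixel_pitch_um
        f.attrs["noise_variance"] = phantom.noise_variance
        f.attrs["seed"] = phantom.seed
        f.attrs["psf_fwhm_px"] = phantom.psf_fwhm_px
        f.attrs["meta"] = yaml.safe_dump(phantom.meta)
        f.create_dataset("surface_height", data=phantom.surface_height)
        f.create_dataset("tau_map", data=phantom.tau_map)
        f.create_dataset("static_fraction_map", data=phantom.static_fraction_map)
        f.create_dataset("backscatter_map", data=phantom.backscatter_map)
        g = f.create_group("masks")
        for name, mask in phantom.structure_masks.items():
            g.create_dataset(name, data=mask.astype(np.uint8))
    return path


def load_phantom(path: str | Path) -> PhantomSpec:
    with h5py.File(path, "r") as f:
        masks = {name: f["masks"][name][...].astype(bool) for name in f["masks"]}
        return PhantomSpec(
            grid_shape=tuple(int(v) for v in f.attrs["grid_shape"]),
            pixel_pitch_um=tuple(float(v) for v in f.attrs["pixel_pitch_um"]),
            surface_height=f["surface_height"][...],
            structure_masks=masks,
            tau_map=f["tau_map"][...],
            static_fraction_map=f["static_fraction_map"][...],
            backscatter_map=f["backscatter_map"][...],
            noise_variance=float(f.attrs["noise_variance"]),
            seed=int(f.attrs["seed"]),
            psf_fwhm_px=float(f.attrs["psf_fwhm_px"]),
            meta=yaml.safe_load(f.attrs["meta"]),
        )


def save_frame_stacks(path: str | Path, stacks: list[ComplexFrameStack]) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        for st in stacks:
            g = f.create_group(f"location_{st.location_index:04d}")
            g.create_dataset("frames", data=st.frames)
            g.create_dataset("timestamps", data=st.timestamps)
            g.attrs["location_index"] = st.location_index
            g.attrs["noise_variance"] = st.noise_variance
    return path


def load_frame_stacks(path: str | Path) -> list[ComplexFrameStack]:
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f):
            g = f[name]
            out.append(
                ComplexFrameStack(
                    frames=g["frames"][...],
                    timestamps=g["timestamps"][...],
                    location_index=int(g.attrs["location_index"]),
                    noise_variance=float(g.attrs["noise_variance"]),
                )
            )
    return out


def save_yaml(path: str | Path, obj) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(obj, sort_keys=False))
    return path


def load_yaml(path: str | Path):
    return yaml.safe_load(Path(path).read_text())


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
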