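"""Image and medical-volume I/O: PNG handling, NIfTI axial slicing, resizing.

Slicing mirrors the standard preprocessing of multimodal brain-MRI volumes:
a 3D (H, W, D) or 4D (H, W, D, M) NIfTI volume is cut along its third array
axis into per-slice 8-bit grayscale PNGs, with intensities min-max scaled
per volume (not per slice) so inter-slice contrast is preserved.
"""

from __future__ import annotations

import dataclasses
import os

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = ["SliceRecord", "read_image", "write_image_u8", "slice_volume",
           "resize_image", "to_rgb"]


@dataclasses.dataclass(frozen=True)
class SliceRecord:
    volume_id: str
    slice_index: int
    modality_index: int
    path: str


def read_image(path) -> np.ndarray:
    """Read an 8/16-bit image as float64 scaled to [0, 1]; (H,W) or (H,W,C)."""
    arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    return arr.astype(np.float64)


def write_image_u8(path, array: np.ndarray) -> None:
    """Write a uint8 array ((H,W) grayscale or (H,W,3) RGB) as PNG."""
    arr = np.asarray(array)
    if arr.dtype != np.uint8:
        raise ValueError("write_image_u8 expects a uint8 array")
    iio.imwrite(path, arr)


def slice_volume(volume_path, modality_index: int, output_dir,
                 axis: int = 2) -> list[SliceRecord]:
    """Cut a NIfTI volume into per-slice PNGs.

    4D volumes select ``modality_index`` along the 4th axis; 3D volumes
    force it to 0.  Filenames follow ``<id>_slice_<k>_modality_<m>.png``.
    A constant-valued volume degenerates to all-zero slices.
    """
    import nibabel as nib

    img = nib.load(os.fspath(volume_path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim == 4:
        if not 0 <= modality_index < data.shape[3]:
            raise ValueError(
                f"modality_index {modality_index} out of range "
                f"for {data.shape[3]} modalities")
        data = data[..., modality_index]
    elif data.ndim == 3:
        modality_index = 0
    else:
        raise ValueError(f"expected a 3D or 4D volume, got shape {data.shape}")

    lo, hi = data.min(), data.max()
    scaled = (np.zeros_like(data) if hi == lo
              else (data - lo) / (hi - lo))
    scaled = np.round(scaled * 255).astype(np.uint8)

    vol_id = os.path.basename(os.fspath(volume_path))
    for ext in (".nii.gz", ".nii"):
        if vol_id.endswith(ext):
            vol_id = vol_id[:-len(ext)]
    os.makedirs(output_dir, exist_ok=True)
    records = []
    for k in range(data.shape[axis]):
        sl = np.take(scaled, k, axis=axis)
        name = f"{vol_id}_slice_{k}_modality_{modality_index}.png"
        path = os.path.join(output_dir, name)
        write_image_u8(path, sl)
        records.append(SliceRecord(vol_id, k, modality_index, path))
    return records


def slice_manifest(records: list[SliceRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def resize_image(image: np.ndarray, target, kind: str = "bilinear"):
    """Resize to ``target`` (H, W); ``nearest`` preserves binary masks."""
    from skimage.transform import resize

    th, tw = target
    if th <= 0 or tw <= 0:
        raise ValueError("target size must be positive")
    image = np.asarray(image)
    if image.shape[:2] == (th, tw):
        return image.copy()
    out_shape = (th, tw) + image.shape[2:]
    if kind == "nearest":
        return resize(image, out_shape, order=0, preserve_range=True,
                      anti_aliasing=False).astype(image.dtype)
    if kind == "bilinear":
        return resize(image, out_shape, order=1, preserve_range=True,
                      anti_aliasing=False)
    raise ValueError(f"unknown resize kind {kind!r}")


def to_rgb(image: np.ndarray) -> np.ndarray:
    """Replicate a single-channel image to 3 channels; pass RGB through."""
    image = np.asarray(image)
    if image.ndim == 2:
        return np.stack([image] * 3, axis=-1)
    if image.ndim == 3 and image.shape[2] == 3:
        return image
    raise ValueError("expected (H,W) or (H,W,3) image")
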