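"""Synthetic 2D tumour phantoms with ground-truth masks.

Each phantom emulates one axial slice of the kind a brain-tumour
classification pipeline consumes: an elliptical "head" region with smooth
low-frequency texture on a dark background, and — for the tumour class — a
compact, brighter blob lying entirely inside the head, whose pixel support
is the ground-truth segmentation mask.  The tumour is an ellipse of random
orientation with a low-amplitude radial boundary perturbation, so the
convex-hull step of the postprocessing pipeline does visible work.

Intensities are scaled so that the tumour/head contrast dominates texture
and noise by construction, which makes the two-class task learnable by a
small classifier in a handful of epochs.
"""

from __future__ import annotations

import dataclasses
import os

import numpy as np
import pandas as pd

from .io_formats import write_image_u8

__all__ = ["Phantom", "PhantomConfig", "generate_phantom", "generate_dataset",
           "tumour_head_contrast"]

_BACKGROUND = 0.02
_HEAD_BASE = 0.40
_TEXTURE_AMP = 0.10


@dataclasses.dataclass(frozen=True)
class PhantomConfig:
    """Geometry and intensity parameters of the phantom generator.

    size is (H, W) in pixels; the 240x240 default matches the axial slice
    resolution of the multimodal brain-tumour benchmarks this generator
    stands in for.  tumour_contrast is the added intensity of the blob over
    the local head texture; noise_sd is the additive Gaussian noise scale.
    """

    size: tuple = (240, 240)
    head_axes_range: tuple = (70, 100)
    tumour_radius_range: tuple = (15, 30)
    tumour_contrast: float = 0.5
    noise_sd: float = 0.02

    def validate(self):
        if self.tumour_radius_range[1] >= self.head_axes_range[0]:
            raise ValueError(
                "tumour_radius_range max must be < head_axes_range min "
                "(the tumour has to fit inside the head)")
        if self.noise_sd < 0 or self.tumour_contrast <= 0:
            raise ValueError("noise_sd must be >= 0 and tumour_contrast > 0")
        if min(self.size) < 16:
            raise ValueError("phantom size too small")


@dataclasses.dataclass(frozen=True)
class Phantom:
    image: np.ndarray   # (H, W) float in [0, 1]
    mask: np.ndarray    # (H, W) uint8 in {0, 1}
    label: int          # 1 iff the mask has foreground
    seed: int


def _smooth_field(rng, shape, cells=8):
    """Low-frequency texture: coarse Gaussian grid, bilinearly upsampled."""
    from skimage.transform import resize
    coarse = rng.normal(0.0, 1.0, (cells, cells))
    field = resize(coarse, shape, order=1, mode="edge", anti_aliasing=False)
    m = np.abs(field).max()
    return field / m if m > 0 else field


def _ellipse_mask(shape, center, axes, theta):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - center[0], xx - center[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / axes[1]) ** 2 + (v / axes[0]) ** 2 <= 1.0


def _blob_mask(shape, center, r, stretch, theta, pert_coeffs):
    """Perturbed ellipse of area ~ pi r^2: axes (r*stretch, r/stretch) plus a
    zero-mean radial Fourier perturbation of relative amplitude <= ~0.1."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = (yy - center[0]).astype(float), (xx - center[1]).astype(float)
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st        # along axis r*stretch
    v = -dx * st + dy * ct       # along axis r/stretch
    rho = np.sqrt((u / (r * stretch)) ** 2 + (v / (r / stretch)) ** 2)
    phi = np.arctan2(v, u)
    pert = np.zeros_like(phi)
    for k, (a, b) in enumerate(pert_coeffs, start=2):
        pert += a * np.cos(k * phi) + b * np.sin(k * phi)
    return rho <= 1.0 + pert


def generate_phantom(config: PhantomConfig, with_tumour: bool,
                     seed: int) -> Phantom:
    """Deterministically generate one phantom slice.

    The head is a filled, textured ellipse near the image centre; if
    ``with_tumour``, a brighter perturbed-ellipse blob is placed fully
    inside the head and its exact pixel support becomes the mask.
    """
    phantom, _ = generate_phantom_with_head(config, with_tumour, seed)
    return phantom


def generate_phantom_with_head(config: PhantomConfig, with_tumour: bool,
                               seed: int):
    """As ``generate_phantom`` but also returns the head-region mask,
    for checking the blob-inside-head invariant."""
    config.validate()
    rng = np.random.default_rng(seed)
    h, w = config.size
    cy, cx = h / 2.0, w / 2.0

    a = rng.uniform(*config.head_axes_range)
    b = rng.uniform(*config.head_axes_range)
    a = min(a, h / 2.0 - 2)
    b = min(b, w / 2.0 - 2)
    head_theta = rng.uniform(0, np.pi)
    jitter = rng.uniform(-4, 4, size=2)
    head_center = (cy + jitter[0], cx + jitter[1])
    head = _ellipse_mask((h, w), head_center, (a, b), head_theta)

    image = np.full((h, w), _BACKGROUND)
    texture = _smooth_field(rng, (h, w))
    image[head] = _HEAD_BASE + _TEXTURE_AMP * texture[head]

    mask = np.zeros((h, w), dtype=np.uint8)
    label = 0
    if with_tumour:
        r = rng.uniform(*config.tumour_radius_range)
        stretch = rng.uniform(1.0, 1.15)
        theta = rng.uniform(0, np.pi)
        pert = rng.uniform(-0.04, 0.04, size=(3, 2))
        # place the blob centre so that the blob (max radius ~1.25 r) stays
        # strictly inside the head ellipse
        margin = 1.3 * r
        off_u = off_v = 0.0
        if a - margin > 2 and b - margin > 2:
            for _ in range(200):
                ou = rng.uniform(-1, 1) * (a - margin)
                ov = rng.uniform(-1, 1) * (b - margin)
                if (ou / (a - margin)) ** 2 + (ov / (b - margin)) ** 2 <= 1.0:
                    off_u, off_v = ou, ov
                    break
        ct, st = np.cos(head_theta), np.sin(head_theta)
        center = (head_center[0] + off_u * ct + off_v * st,
                  head_center[1] + off_v * ct - off_u * st)
        blob = _blob_mask((h, w), center, r, stretch, theta, pert)
        blob &= head  # safety net; placement already keeps it inside
        mask[blob] = 1
        image[blob] += config.tumour_contrast
        label = 1

    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, (h, w))
    image = np.clip(image, 0.0, 1.0)
    return Phantom(image=image, mask=mask, label=label, seed=seed), head


def tumour_head_contrast(phantom: Phantom, annulus_width: int = 5) -> float:
    """Mean tumour intensity minus mean intensity of the surrounding head
    annulus — the separability margin the classifier exploits."""
    from scipy import ndimage
    if phantom.label == 0:
        raise ValueError("phantom has no tumour")
    fg = phantom.mask.astype(bool)
    ring = ndimage.binary_dilation(fg, iterations=annulus_width) & ~fg
    return float(phantom.image[fg].mean() - phantom.image[ring].mean())


def _item_seed(base_seed: int, index: int) -> int:
    return int((base_seed * 1000003 + 7919 * index + 1) % (2 ** 31))


def generate_dataset(config: PhantomConfig, n: int, tumour_fraction: float,
                     seed: int, out_dir: str | None = None):
    """Generate ``n`` phantoms, ``floor(n * tumour_fraction)`` with tumour.

    Returns (phantoms, manifest).  With ``out_dir``, images and masks are
    written as 8-bit grayscale PNGs named
    ``PHANTOM_<id>_slice_<k>_modality_0.png`` and the manifest as
    ``manifest.csv`` (columns: path, label, seed, mask_path).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= tumour_fraction <= 1.0:
        raise ValueError("tumour_fraction must be in [0, 1]")
    config.validate()
    n_tumour = int(np.floor(n * tumour_fraction))
    labels = np.zeros(n, dtype=int)
    labels[:n_tumour] = 1
    np.random.default_rng(seed).shuffle(labels)

    phantoms, rows = [], []
    for i, lab in enumerate(labels):
        s = _item_seed(seed, i)
        ph = generate_phantom(config, with_tumour=bool(lab), seed=s)
        phantoms.append(ph)
        img_name = f"PHANTOM_{i:03d}_slice_{i}_modality_0.png"
        mask_name = f"PHANTOM_{i:03d}_slice_{i}_modality_0_mask.png"
        if out_dir is not None:
            os.makedirs(out_dir, exist_ok=True)
            write_image_u8(os.path.join(out_dir, img_name),
                           np.round(ph.image * 255).astype(np.uint8))
            write_image_u8(os.path.join(out_dir, mask_name),
                           ph.mask * 255)
        rows.append({"path": img_name, "label": int(ph.label),
                     "seed": s, "mask_path": mask_name})
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return phantoms, manifest
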