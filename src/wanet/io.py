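"""Readers and writers for images, masks and probability maps."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG fundus image as float in [0, 1] (RGB kept)."""
    a = np.asarray(iio.imread(path))
    if a.ndim == 3 and a.shape[2] == 4:  # drop alpha
        a = a[:, :, :3]
    a = a.astype(float)
    if a.max() > 1.0:
        a = a / (65535.0 if a.max() > 255 else 255.0)
    return a


def read_mask(path) -> np.ndarray:
    """Read a PNG/GIF binary mask as a 0/1 uint8 grid."""
    a = np.asarray(iio.imread(path))
    if a.ndim == 3:
        a = a[..., :3].mean(axis=2)
    return (a > (a.max() / 2 if a.max() > 0 else 0)).astype(np.uint8)


def save_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask) > 0).astype(np.uint8) * 255)


def save_image(path, img: np.ndarray) -> None:
    """Write a [0, 1] image as 8-bit PNG."""
    a = np.clip(np.asarray(img), 0.0, 1.0)
    iio.imwrite(path, np.round(a * 255).astype(np.uint8))


def save_prob_map(path, prob: np.ndarray) -> None:
    """Write a [0, 1] probability map as 16-bit PNG."""
    a = np.clip(np.asarray(prob), 0.0, 1.0)
    iio.imwrite(path, np.round(a * 65535).astype(np.uint16))


def load_prob_map(path) -> np.ndarray:
    a = np.asarray(iio.imread(path)).astype(float)
    return a / 65535.0 if a.max() > 255 else a / 255.0


def save_array(path, arr: np.ndarray) -> None:
    np.save(path, np.asarray(arr))


def load_array(path) -> np.ndarray:
    return np.load(path)


def load_map_or_array(path) -> np.ndarray:
    path = Path(path)
    return load_array(path) if path.suffix == ".npy" else load_prob_map(path)
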