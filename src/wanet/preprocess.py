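"""Fundus preprocessing and patch plumbing.

The pipeline mirrors the standard retinal-vessel recipe: RGB to
grayscale, per-image standardization, contrast-limited adaptive
histogram equalization (CLAHE), then gamma correction (gamma = 1.2).
Images are cut into small overlapping square patches (48 x 48, stride 5
at test time; uniformly sampled positions for training) and per-patch
predictions are reassembled into a full-resolution probability map by
averaging overlapping windows.

All images are float grids in [0, 1]; masks are 0/1 integer grids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import exposure

#: ITU-R BT.601 luminance weights for R, G, B.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass
class PreprocessConfig:
    gamma: float = 1.2
    clahe_clip: float = 2.0
    clahe_tiles: tuple[int, int] = (8, 8)
    standardize_mode: str = "per_image"

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.clahe_clip <= 0:
            raise ValueError("clahe_clip must be > 0")
        if any(t < 1 for t in self.clahe_tiles):
            raise ValueError("clahe_tiles must each be >= 1")
        if self.standardize_mode not in ("per_image", "per_dataset"):
            raise ValueError("standardize_mode must be per_image or per_dataset")


@dataclass
class PatchGrid:
    """Patches plus their 0-based (row, col) top-left coordinates.

    Every patch lies fully inside ``source_shape``; image and mask grids
    extracted together share the same coordinates, so a grid-mode
    PatchGrid can be reassembled exactly by overlap averaging.
    """

    patches: np.ndarray  # (N, S, S)
    coords: np.ndarray  # (N, 2) int
    source_shape: tuple[int, int]
    patch_size: int
    stride: int | None = None

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches)
        self.coords = np.asarray(self.coords, dtype=int)
        if len(self.patches) != len(self.coords):
            raise ValueError("patches and coords must have equal length")

    def __len__(self) -> int:
        return len(self.patches)


def _as_image(img) -> np.ndarray:
    a = np.asarray(img, dtype=float)
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("image contains non-finite values")
    return a


def rgb_to_gray(rgb) -> np.ndarray:
    """Weighted luminance combination of an H x W x 3 image, in [0, 1].

    Inputs on a [0, 255] scale are rescaled automatically.
    """
    a = np.asarray(rgb, dtype=float)
    if a.ndim != 3 or a.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB image, got shape {a.shape}")
    if a.max() > 1.0:
        a = a / 255.0
    return a @ LUMA_WEIGHTS


def standardize(img, mode: str = "per_image",
                stats: tuple[float, float] | None = None) -> np.ndarray:
    """Z-score then min-max rescale back to [0, 1].

    The z-score uses the image's own mean/std (``per_image``) or supplied
    dataset-level ``stats`` (``per_dataset``); the min-max step restores
    the bounded range CLAHE and gamma correction need. A constant image
    has no scale and maps to all 0.5 with a warning.
    """
    a = _as_image(img)
    if mode == "per_dataset":
        if stats is None:
            raise ValueError("per_dataset standardization requires stats=(mean, std)")
        mean, std = stats
    elif mode == "per_image":
        mean, std = a.mean(), a.std()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if std == 0 or a.max() == a.min():
        warnings.warn("constant image: standardization is degenerate, returning 0.5")
        return np.full_like(a, 0.5)
    z = (a - mean) / std
    return (z - z.min()) / (z.max() - z.min())


def clahe(img, clip: float = 2.0, tiles: tuple[int, int] = (8, 8)) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on a [0, 1] image.

    ``clip`` follows the familiar OpenCV-style convention (a multiple of
    the uniform histogram height, typically 2-4); it is mapped onto
    scikit-image's normalized clip limit over 256 bins. A constant image
    is returned unchanged.
    """
    a = _as_image(img)
    if a.min() < 0 or a.max() > 1:
        raise ValueError("clahe expects an image in [0, 1]")
    h, w = a.shape
    th, tw = tiles
    if th > h or tw > w:
        raise ValueError(f"tile grid {tiles} exceeds image shape {a.shape}")
    if a.max() == a.min():
        return a.copy()
    kernel = (max(1, h // th), max(1, w // tw))
    return exposure.equalize_adapthist(a, kernel_size=kernel,
                                       clip_limit=clip / 256.0, nbins=256)


def gamma_correct(img, gamma: float = 1.2) -> np.ndarray:
    """Power-law mapping v -> v**gamma on a [0, 1] image."""
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    a = _as_image(img)
    if a.min() < 0 or a.max() > 1:
        raise ValueError("gamma correction expects an image in [0, 1]")
    return a ** gamma


def preprocess_pipeline(rgb, cfg: PreprocessConfig | None = None,
                        stats: tuple[float, float] | None = None) -> np.ndarray:
    """Grayscale -> standardize -> CLAHE -> gamma, in that order.

    Accepts RGB (H x W x 3) or an already-gray 2-D image.
    """
    cfg = cfg or PreprocessConfig()
    a = np.asarray(rgb, dtype=float)
    gray = rgb_to_gray(a) if a.ndim == 3 else _as_image(a)
    if gray.max() > 1.0:
        gray = gray / 255.0
    out = standardize(gray, cfg.standardize_mode, stats)
    out = clahe(out, cfg.clahe_clip, cfg.clahe_tiles)
    return gamma_correct(out, cfg.gamma)


def _axis_positions(dim: int, size: int, stride: int) -> list[int]:
    """Sliding-window starts: floor((dim-size)/stride)+1 interior positions,
    plus one final edge-aligned window when the stride does not divide
    (dim - size), so every pixel is covered."""
    last = dim - size
    pos = list(range(0, last + 1, stride))
    if last % stride != 0:
        pos.append(last)
    return pos


def grid_coords(shape: tuple[int, int], size: int, stride: int) -> np.ndarray:
    """Row-major top-left coordinates of the deterministic sliding grid."""
    rows = _axis_positions(shape[0], size, stride)
    cols = _axis_positions(shape[1], size, stride)
    return np.array([(r, c) for r in rows for c in cols], dtype=int)


def extract_patches(
    img,
    mask=None,
    size: int = 48,
    stride: int = 5,
    mode: str = "grid",
    n: int | None = None,
    seed: int | None = None,
    fov=None,
) -> PatchGrid | tuple[PatchGrid, PatchGrid]:
    """Cut an image (and optionally its mask) into S x S patches.

    ``grid`` mode enumerates sliding-window positions row-major with one
    extra edge-aligned window per axis when the stride does not divide
    evenly. ``random`` mode draws ``n`` uniformly distributed fully-inside
    positions with the given seed (with replacement); an optional FOV mask
    restricts patch centers to the field of view.
    """
    a = _as_image(img)
    h, w = a.shape
    if size > h or size > w:
        raise ValueError(f"patch size {size} exceeds image shape {a.shape}")
    if mask is not None:
        m = np.asarray(mask)
        if m.shape != a.shape:
            raise ValueError(f"mask shape {m.shape} != image shape {a.shape}")

    if mode == "grid":
        coords = grid_coords((h, w), size, stride)
    elif mode == "random":
        if n is None or seed is None:
            raise ValueError("random mode requires n and seed")
        rng = np.random.default_rng(seed)
        if fov is not None:
            f = np.asarray(fov).astype(bool)
            ok = np.zeros((h - size + 1, w - size + 1), dtype=bool)
            rr, cc = np.nonzero(f)
            ctr_r, ctr_c = rr - size // 2, cc - size // 2
            keep = ((ctr_r >= 0) & (ctr_r <= h - size)
                    & (ctr_c >= 0) & (ctr_c <= w - size))
            ok[ctr_r[keep], ctr_c[keep]] = True
            valid = np.flatnonzero(ok.ravel())
            if valid.size == 0:
                raise ValueError("no valid patch positions inside the FOV")
            picks = rng.choice(valid, size=n, replace=True)
            coords = np.column_stack(np.unravel_index(picks, ok.shape))
        else:
            coords = np.column_stack([
                rng.integers(0, h - size + 1, size=n),
                rng.integers(0, w - size + 1, size=n),
            ])
    else:
        raise ValueError(f"unknown mode {mode!r}")

    patches = np.stack([a[r:r + size, c:c + size] for r, c in coords]) \
        if len(coords) else np.empty((0, size, size))
    grid = PatchGrid(patches, coords, (h, w), size,
                     stride if mode == "grid" else None)
    if mask is None:
        return grid
    mpatches = np.stack([m[r:r + size, c:c + size] for r, c in coords]) \
        if len(coords) else np.empty((0, size, size))
    return grid, PatchGrid(mpatches, coords, (h, w), size,
                           stride if mode == "grid" else None)


def reconstruct_map(grid: PatchGrid) -> np.ndarray:
    """Average overlapping patch predictions back into a full-size map.

    Every pixel of ``source_shape`` must be covered by at least one
    patch; an uncovered pixel raises an error naming its location.
    """
    h, w = grid.source_shape
    s = grid.patch_size
    acc = np.zeros((h, w), dtype=float)
    cnt = np.zeros((h, w), dtype=float)
    for patch, (r, c) in zip(grid.patches, grid.coords):
        acc[r:r + s, c:c + s] += patch
        cnt[r:r + s, c:c + s] += 1.0
    if np.any(cnt == 0):
        r, c = np.argwhere(cnt == 0)[0]
        raise ValueError(f"pixel ({r}, {c}) not covered by any patch")
    return acc / cnt
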