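"""Synthetic fundus phantoms: branching dark vessels on a bright disc.

The generator emulates the statistical structure that makes retinal
vessel segmentation hard — a tree of dark, low-contrast vessels of mixed
calibre (thick trunks tapering to one-pixel terminals) on a vignetted
bright background inside a circular camera field of view, with additive
sensor noise. It is a geometric phantom, not a hemodynamic model: no
tortuosity statistics, lesions, exudates, or optic disc.

Each image comes with its exact binary vessel mask and FOV disc, so the
whole train/predict/evaluate pipeline can run end-to-end without any
external dataset.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class SynthConfig:
    image_shape: tuple[int, int] = (160, 160)
    n_trees: int = 4
    branch_depth: int = 4
    root_width: float = 4.0
    terminal_width: float = 1.0
    branch_angle_spread: float = 40.0  # degrees
    segment_length: float = 26.0  # root segment length, px
    length_decay: float = 0.82  # child length = parent length * decay
    vessel_darkness: float = 0.35  # contrast fraction of background_base
    background_base: float = 0.65
    vignette_strength: float = 0.25
    noise_sd: float = 0.03
    blur_sigma: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_shape
        if h < 16 or w < 16:
            raise ValueError(f"degenerate image shape {self.image_shape}")
        if self.terminal_width > self.root_width or self.terminal_width < 1:
            raise ValueError("need 1 <= terminal_width <= root_width")
        if not (0 < self.vessel_darkness < 1):
            raise ValueError("vessel_darkness must lie in (0, 1)")


def fov_disc(shape: tuple[int, int], radius_frac: float = 0.48) -> np.ndarray:
    """Binary circular field-of-view mask centred in the frame."""
    h, w = shape
    r = radius_frac * min(h, w)
    yy, xx = np.mgrid[0:h, 0:w]
    return (((yy - h / 2) ** 2 + (xx - w / 2) ** 2) <= r * r).astype(np.uint8)


def _stamp_segment(mask: np.ndarray, p0: np.ndarray, p1: np.ndarray,
                   width: float) -> None:
    """Rasterize a straight stroke by stamping discs along the centreline."""
    h, w = mask.shape
    length = max(1, int(np.ceil(np.linalg.norm(p1 - p0))))
    rad = max(0.5, width / 2.0)
    ri = int(np.ceil(rad))
    yy, xx = np.mgrid[-ri:ri + 1, -ri:ri + 1]
    disc = (yy * yy + xx * xx) <= rad * rad
    for t in np.linspace(0.0, 1.0, length + 1):
        cy, cx = np.round(p0 + t * (p1 - p0)).astype(int)
        y0, y1 = cy - ri, cy + ri + 1
        x0, x1 = cx - ri, cx + ri + 1
        sy0, sx0 = max(0, -y0), max(0, -x0)
        sy1 = disc.shape[0] - max(0, y1 - h)
        sx1 = disc.shape[1] - max(0, x1 - w)
        if sy0 >= sy1 or sx0 >= sx1:
            continue
        mask[max(0, y0):min(h, y1), max(0, x0):min(w, x1)] |= \
            disc[sy0:sy1, sx0:sx1]


def _grow(mask: np.ndarray, rng: np.random.Generator, cfg: SynthConfig,
          origin: np.ndarray, angle: float, depth: int) -> None:
    frac = depth / max(1, cfg.branch_depth)
    width = cfg.root_width - (cfg.root_width - cfg.terminal_width) * frac
    length = cfg.segment_length * cfg.length_decay ** depth \
        * rng.uniform(0.8, 1.2)
    end = origin + length * np.array([np.sin(angle), np.cos(angle)])
    _stamp_segment(mask, origin, end, width)
    if depth >= cfg.branch_depth:
        return
    spread = np.deg2rad(cfg.branch_angle_spread)
    for sign in (-1.0, 1.0):
        child = angle + sign * spread * rng.uniform(0.4, 1.0)
        _grow(mask, rng, cfg, end, child, depth + 1)


def generate_vessel_mask(cfg: SynthConfig, seed: int | None = None) -> np.ndarray:
    """Binary branching vessel trees, clipped to the FOV disc.

    Trees are seeded on the FOV margin heading inward and bifurcate
    recursively; stroke width tapers linearly from root_width to
    terminal_width with depth. Deterministic given the seed.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    h, w = cfg.image_shape
    mask = np.zeros((h, w), dtype=bool)
    fov = fov_disc(cfg.image_shape).astype(bool)
    centre = np.array([h / 2, w / 2])
    radius = 0.44 * min(h, w)
    for _ in range(cfg.n_trees):
        phi = rng.uniform(0, 2 * np.pi)
        origin = centre + radius * np.array([np.sin(phi), np.cos(phi)])
        inward = phi + np.pi + rng.uniform(-0.5, 0.5)
        _grow(mask, rng, cfg, origin, inward, depth=0)
    return (mask & fov).astype(np.uint8)


def render_fundus(mask: np.ndarray, cfg: SynthConfig,
                  seed: int | None = None,
                  rgb: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Render a grayscale fundus-like image from a vessel mask.

    Background is ``background_base`` with a radial vignette inside the
    FOV disc (near-black outside); vessel pixels are darkened by
    ``vessel_darkness * background_base``, edges softened by a Gaussian
    blur, and seeded Gaussian noise added. Returns (image, fov); with
    ``rgb=True`` the image is replicated into three identical channels.
    """
    mask = np.asarray(mask)
    if mask.shape != tuple(cfg.image_shape):
        raise ValueError(f"mask shape {mask.shape} != {cfg.image_shape}")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    h, w = cfg.image_shape
    fov = fov_disc(cfg.image_shape)
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = ((yy - h / 2) ** 2 + (xx - w / 2) ** 2) / (0.5 * min(h, w)) ** 2
    base = cfg.background_base * (1.0 - cfg.vignette_strength * r2)
    img = np.where(fov > 0, base, 0.05)
    dark = cfg.vessel_darkness * cfg.background_base * mask.astype(float)
    if cfg.blur_sigma > 0:
        dark = ndimage.gaussian_filter(dark, cfg.blur_sigma)
    img = img - dark
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    if rgb:
        img = np.repeat(img[:, :, None], 3, axis=2)
    return img, fov


def generate_image(cfg: SynthConfig, seed: int | None = None):
    """One (image, mask, fov) triple from a single seed."""
    s = cfg.seed if seed is None else seed
    mask = generate_vessel_mask(cfg, seed=s)
    img, fov = render_fundus(mask, cfg, seed=s + 1)
    return img, mask, fov


def generate_dataset(n_images: int, cfg: SynthConfig | None = None,
                     seed: int | None = None):
    """Independent seeded draws; per-image seeds derive from the master seed.

    Returns a list of (image, mask, fov) triples.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    cfg = cfg or SynthConfig()
    master = cfg.seed if seed is None else seed
    child_seeds = np.random.SeedSequence(master).generate_state(n_images)
    return [generate_image(cfg, seed=int(s) % (2 ** 31)) for s in child_seeds]


def vessel_fraction(mask: np.ndarray, fov: np.ndarray | None = None) -> float:
    """Fraction of (FOV) pixels that are vessel — the class imbalance."""
    m = np.asarray(mask).astype(bool)
    if fov is None:
        return float(m.mean())
    f = np.asarray(fov).astype(bool)
    return float(m[f].mean())
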