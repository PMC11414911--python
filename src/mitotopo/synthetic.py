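"""Synthetic fixtures and phantoms: every pipeline stage is testable offline.

Three generators:

* :func:`worked_example_image` — the 3x3 grayscale image whose sublevel
  filtration has persistence diagrams P0 = {(1, inf), (2, 3)} and
  P1 = {(3, 10)}; the package's canonical exact fixture.
* :func:`make_known_betti_image` — binary images with prescribed Betti
  numbers by construction (disjoint rectangles, some carrying enclosed
  holes), the oracle for the labeling code.
* :func:`make_network_phantom` / :func:`make_fragmented_phantom` —
  grayscale phantoms emulating the two mitochondrial morphology classes:
  an interconnected tubular network (smooth random-walk filaments) versus
  scattered punctate fragments (small disks).  Structure is rendered DARK
  on a light background so thresholding applies without inversion, then
  blurred and corrupted with Gaussian noise.  Both return the image and
  its ground-truth structure mask, and are bit-deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .raster import BinaryImage, GrayscaleImage

__all__ = [
    "PhantomParams",
    "worked_example_image",
    "make_known_betti_image",
    "make_network_phantom",
    "make_fragmented_phantom",
]


def worked_example_image() -> GrayscaleImage:
    """The 3x3 demonstration image [[1,3,2],[1,10,2],[1,3,2]].

    Thresholding at t = 1 gives the left column; at t = 3 an 8-pixel ring
    enclosing the centre pixel; at t = 10 the full square.
    """
    return GrayscaleImage(np.array([[1, 3, 2], [1, 10, 2], [1, 3, 2]], dtype=np.uint8))


# ---------------------------------------------------------------------------
# known-Betti binary images
# ---------------------------------------------------------------------------

_COMP_H = 7  # rectangle height; holes are 3x3 with a >=2 px black rim
_SEP = 3
_MARGIN = 2


def make_known_betti_image(
    beta0: int, beta1: int, seed: int = 0, size: int | None = None
) -> BinaryImage:
    """A binary image with exactly the requested Betti numbers.

    ``beta0`` disjoint black rectangles are laid out on a white canvas with
    >= 2 px separation and a white border; ``beta1`` 3x3 white holes are
    distributed round-robin among them.  Positions are jittered by the
    seeded generator.  Raises if the shapes cannot fit a requested canvas.
    """
    if beta0 < 0 or beta1 < 0:
        raise ValueError("Betti numbers must be non-negative")
    if beta1 > 0 and beta0 == 0:
        raise ValueError("holes require at least one component")
    rng = np.random.default_rng(seed)
    if beta0 == 0:
        side = size or 8
        return BinaryImage(np.ones((side, side), dtype=np.uint8))

    holes = [beta1 // beta0 + (1 if k < beta1 % beta0 else 0) for k in range(beta0)]
    widths = [max(_COMP_H, 4 * h + 3) for h in holes]
    cell_w = max(widths) + _SEP
    cell_h = _COMP_H + _SEP
    n_cols = max(1, int(np.ceil(np.sqrt(beta0))))
    n_rows = int(np.ceil(beta0 / n_cols))
    height = 2 * _MARGIN + n_rows * cell_h - _SEP
    width = 2 * _MARGIN + n_cols * cell_w - _SEP
    side = max(height, width)
    if size is not None:
        if size < side:
            raise ValueError(f"{beta0} components do not fit a {size}x{size} canvas")
        side = size
    values = np.ones((side, side), dtype=np.uint8)
    for k in range(beta0):
        r = _MARGIN + (k // n_cols) * cell_h + rng.integers(0, 2)
        c = _MARGIN + (k % n_cols) * cell_w + rng.integers(0, 2)
        w = widths[k]
        values[r : r + _COMP_H, c : c + w] = 0
        for j in range(holes[k]):
            values[r + 2 : r + 5, c + 2 + 4 * j : c + 5 + 4 * j] = 1
    return BinaryImage(values)


# ---------------------------------------------------------------------------
# grayscale phantoms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomParams:
    """Rendering parameters shared by both phantom classes.

    Intensities follow the dark-structure convention, so
    ``foreground_level < background_level``.  Defaults give 256 px images
    whose structure intensity sits inside the 100-150 threshold band used
    by the feature summaries, with mild blur and noise as in moderately
    clean fluorescence data (after inversion).
    """

    size: int = 256
    n_filaments: int = 12
    filament_thickness: int = 3
    n_spots: int = 150
    spot_radius_px: int = 2
    background_level: int = 200
    foreground_level: int = 110
    noise_sd: float = 20.0
    blur_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.foreground_level < self.background_level <= 255:
            raise ValueError("need 0 <= foreground_level < background_level <= 255")
        if self.size < 32:
            raise ValueError("size must be >= 32")


def _render(mask: np.ndarray, p: PhantomParams, rng: np.random.Generator) -> GrayscaleImage:
    img = np.full(mask.shape, float(p.background_level))
    img[mask] = float(p.foreground_level)
    if p.blur_sd > 0:
        img = ndimage.gaussian_filter(img, p.blur_sd)
    if p.noise_sd > 0:
        img = img + rng.normal(0.0, p.noise_sd, size=img.shape)
    return GrayscaleImage(np.clip(np.rint(img), 0, 255).astype(np.uint8))


def _disk(radius: int) -> np.ndarray:
    r = max(int(radius), 0)
    y, x = np.mgrid[-r : r + 1, -r : r + 1]
    return (x * x + y * y) <= r * r


def make_network_phantom(p: PhantomParams) -> tuple[GrayscaleImage, BinaryImage]:
    """Connected tubular network: bounded-curvature random-walk filaments.

    Each filament is a unit-step walk whose heading diffuses slowly (so the
    curve is tubular, not space-filling) and reflects off the frame; all
    walks are stamped at ``filament_thickness`` and rendered dark.
    Returns (grayscale image, ground-truth structure mask: 0 = structure).
    """
    rng = np.random.default_rng(p.seed)
    s = p.size
    mask = np.zeros((s, s), dtype=bool)
    n_steps = int(2.2 * s)
    for _ in range(p.n_filaments):
        pos = rng.uniform(0.1 * s, 0.9 * s, size=2)
        heading = rng.uniform(0, 2 * np.pi)
        turns = rng.normal(0.0, 0.15, size=n_steps)
        for dt in turns:
            heading += dt
            pos = pos + np.array([np.sin(heading), np.cos(heading)])
            for ax in (0, 1):
                if pos[ax] < 1 or pos[ax] > s - 2:
                    pos[ax] = np.clip(pos[ax], 1, s - 2)
                    heading = -heading if ax == 0 else np.pi - heading
            mask[int(round(pos[0])), int(round(pos[1]))] = True
    mask = ndimage.binary_dilation(mask, structure=_disk(p.filament_thickness // 2))
    img = _render(mask, p, rng)
    return img, BinaryImage(np.where(mask, 0, 1).astype(np.uint8))


def make_fragmented_phantom(p: PhantomParams) -> tuple[GrayscaleImage, BinaryImage]:
    """Fragmented punctate morphology: ``n_spots`` small disks, rendered dark.

    Returns (grayscale image, ground-truth structure mask: 0 = structure).
    """
    rng = np.random.default_rng(p.seed)
    s = p.size
    mask = np.zeros((s, s), dtype=bool)
    r = p.spot_radius_px
    disk = _disk(r)
    centers = rng.integers(r + 1, s - r - 1, size=(p.n_spots, 2))
    for cy, cx in centers:
        mask[cy - r : cy + r + 1, cx - r : cx + r + 1] |= disk
    img = _render(mask, p, rng)
    return img, BinaryImage(np.where(mask, 0, 1).astype(np.uint8))
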