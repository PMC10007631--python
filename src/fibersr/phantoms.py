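"""Synthetic ground-truth targets: H&E-like tissue phantoms and test patterns.

The phantom generator emulates grayscale H&E histology as seen in brightfield
endomicroscopy: a bright stroma-like background with smooth and fine texture,
and dark elliptical cell nuclei whose positions and diameters are recorded as
ground truth.  Intensities are chosen so a grey-level threshold of 100/255
cleanly separates nuclei from background, which is what downstream
nuclei-diameter measurement relies on.

Also provided: horizontal sinewave targets for modulation-transfer-function
probing and 1951 USAF three-bar patterns for pixel-size calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "Nucleus",
    "PhantomTile",
    "PatternSpec",
    "PackingError",
    "generate_phantom",
    "generate_sinewave",
    "generate_usaf_bars",
]

NUCLEUS_THRESHOLD = 100.0 / 255.0  # grey level separating nuclei from stroma

# Intensity bands (fractions of full scale).  Nuclei sit well below the
# 100/255 threshold and the background well above it, so thresholding is
# unambiguous on ground truth.
_NUCLEUS_BAND = (0.08, 0.30)
_BACKGROUND_BAND = (0.65, 0.90)


class PackingError(RuntimeError):
    """Requested nuclei could not be placed without overlap."""


@dataclass(frozen=True)
class Nucleus:
    """Recorded ground truth for one elliptical nucleus."""

    center_px: tuple[float, float]  # (x, y) pixel coordinates
    major_um: float
    minor_um: float
    orientation_deg: float


@dataclass(frozen=True)
class PhantomTile:
    """A synthetic tissue tile with its nuclei ground truth."""

    image: np.ndarray  # float in [0, 1]
    nuclei: tuple[Nucleus, ...]
    pixel_size: float  # um/px
    seed: int | None = None


@dataclass(frozen=True)
class PatternSpec:
    """Specification of a resolution test pattern.

    ``period`` is pixels per cycle for sinewaves and line width in
    micrometres for bar patterns; ``contrast`` is Michelson contrast.
    """

    kind: str  # "sinewave" | "bars"
    period: float
    contrast: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("sinewave", "bars"):
            raise ValueError("kind must be 'sinewave' or 'bars'")
        if self.period <= 0:
            raise ValueError("period/line width must be positive")
        if not (0.0 < self.contrast <= 1.0):
            raise ValueError("contrast must lie in (0, 1]")


def _background(size: int, rng: np.random.Generator) -> np.ndarray:
    """Bright stroma-like background with multi-scale texture.

    Smooth low-frequency variation mimics stromal density changes; a mild
    fine-scale component (a few pixels) mimics fibrous texture, which also
    keeps the phantom spectrum from being purely low-frequency.
    """
    lo, hi = _BACKGROUND_BAND
    base = rng.uniform(lo + 0.05, hi - 0.05)
    tex = np.zeros((size, size))
    for sigma, amp in ((size / 6.0, 1.0), (4.0, 0.5), (1.5, 0.3)):
        noise = rng.standard_normal((size, size))
        smooth = gaussian_filter(noise, sigma, mode="reflect")
        sd = smooth.std()
        if sd > 0:
            tex += amp * smooth / sd
    tex /= np.abs(tex).max() + 1e-12
    img = base + tex * (hi - lo) / 2.0
    return np.clip(img, lo, hi)


def generate_phantom(
    size: int = 256,
    nucleus_count: int = 12,
    diameter_range: tuple[float, float] = (4.5, 9.6),
    pixel_size: float = 0.316,
    seed: int | None = None,
    max_attempts: int = 1000,
) -> PhantomTile:
    """Generate one H&E-like tile with non-overlapping dark elliptical nuclei.

    Nucleus axis lengths (micrometres) are drawn uniformly from
    ``diameter_range`` — the larger becomes the major axis — matching the
    5-12 um scale of prostate cell nuclei.  Placement uses rejection
    sampling; a :class:`PackingError` is raised if ``nucleus_count`` ellipses
    cannot be placed in ``max_attempts`` draws.
    """
    d_lo, d_hi = float(diameter_range[0]), float(diameter_range[1])
    if not (0 < d_lo <= d_hi < size * pixel_size):
        raise ValueError("diameter range must lie within (0, field size)")
    rng = np.random.default_rng(seed)
    img = _background(size, rng)

    placed: list[Nucleus] = []
    attempts = 0
    while len(placed) < nucleus_count:
        if attempts >= max_attempts:
            raise PackingError(
                f"placed {len(placed)}/{nucleus_count} nuclei in {max_attempts} attempts"
            )
        attempts += 1
        d1 = rng.uniform(d_lo, d_hi)
        d2 = rng.uniform(d_lo, d_hi)
        major, minor = max(d1, d2), min(d1, d2)
        theta = rng.uniform(0.0, 180.0)
        r_px = major / 2.0 / pixel_size
        cx = rng.uniform(r_px + 1, size - r_px - 1)
        cy = rng.uniform(r_px + 1, size - r_px - 1)
        ok = True
        for other in placed:
            sep = np.hypot(cx - other.center_px[0], cy - other.center_px[1])
            min_sep = (major + other.major_um) / 2.0 / pixel_size + 2.0
            if sep < min_sep:
                ok = False
                break
        if not ok:
            continue
        nuc = Nucleus((cx, cy), major, minor, theta)
        _paint_nucleus(img, nuc, pixel_size, rng)
        placed.append(nuc)

    return PhantomTile(
        image=img.astype(np.float32),
        nuclei=tuple(placed),
        pixel_size=pixel_size,
        seed=seed,
    )


def _paint_nucleus(
    img: np.ndarray, nuc: Nucleus, pixel_size: float, rng: np.random.Generator
) -> None:
    """Fill one ellipse with dark chromatin-like intensity, in place."""
    lo, hi = _NUCLEUS_BAND
    a = nuc.major_um / 2.0 / pixel_size  # semi-axes in px
    b = nuc.minor_um / 2.0 / pixel_size
    cx, cy = nuc.center_px
    theta = np.deg2rad(nuc.orientation_deg)

    size = img.shape[0]
    x0 = max(int(np.floor(cx - a - 2)), 0)
    x1 = min(int(np.ceil(cx + a + 2)), size)
    y0 = max(int(np.floor(cy - a - 2)), 0)
    y1 = min(int(np.ceil(cy + a + 2)), size)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    rho2 = (u / a) ** 2 + (v / b) ** 2
    inside = rho2 <= 1.0

    base = rng.uniform(lo + 0.03, hi - 0.05)
    # slightly darker center, mimicking condensed chromatin
    shade = base + 0.04 * rho2 - 0.02
    patch = img[y0:y1, x0:x1]
    patch[inside] = np.clip(shade[inside], lo, hi)


def generate_sinewave(size: int, period: float) -> np.ndarray:
    """Horizontal sinewave target: intensity varies along columns only.

    Mean 0.5, Michelson contrast 1.0.  Periods below 2 px would alias the
    raster and are rejected.
    """
    if period < 2:
        raise ValueError("period must be at least 2 px to avoid aliasing")
    x = np.arange(size, dtype=float)
    row = 0.5 + 0.5 * np.sin(2.0 * np.pi * x / period)
    return np.tile(row, (size, 1)).astype(np.float32)


def usaf_resolution_lp_mm(group: int, element: int) -> float:
    """1951 USAF chart resolution in line pairs per mm: 2^(g + (e-1)/6)."""
    if not 1 <= element <= 6:
        raise ValueError("element must be in 1..6")
    return float(2.0 ** (group + (element - 1) / 6.0))


def generate_usaf_bars(
    group: int,
    element: int,
    pixel_size: float,
    size: int | None = None,
) -> tuple[np.ndarray, float]:
    """Render a 1951 USAF-style three-bar target and return its line width.

    Resolution is ``2^(group + (element-1)/6)`` line pairs/mm so the line
    width is ``500 / resolution`` micrometres.  Three dark vertical bars of
    that width, separated by equal bright gaps, are drawn at full contrast
    on a bright ground.  Returns ``(image, line_width_um)``.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    res = usaf_resolution_lp_mm(group, element)
    line_width_um = 500.0 / res
    lw_px = line_width_um / pixel_size

    if size is None:
        size = int(np.ceil(lw_px * 9))
    img = np.ones((size, size), dtype=np.float32)

    bar_len = min(size, int(round(5 * lw_px)))
    y0 = (size - bar_len) // 2
    total_w = 5 * lw_px  # 3 bars + 2 gaps
    x_start = (size - total_w) / 2.0
    xx = np.arange(size) + 0.5
    for k in range(3):
        left = x_start + 2 * k * lw_px
        in_bar = (xx >= left) & (xx < left + lw_px)
        img[y0 : y0 + bar_len, in_bar] = 0.0
    return img, line_width_um
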