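"""Downstream analyses: pixel-size calibration, nuclei-diameter measurement,
and the sinewave modulation-transfer-function (MTF) resolution probe.

Calibration follows the USAF-target procedure: a bar of known physical width
is measured in pixels and the quotient gives micrometres per pixel (31.25 um
over 99 px gives the 0.316 um/px used throughout).  Nuclei diameters are read
off a line profile as the longest run of pixels strictly below a grey-level
threshold (default 100 on the 0-255 scale).  The MTF probe pushes sinewave
targets of decreasing period through the honeycomb simulator and a chosen
reconstructor, fits a sinusoid of the known period, and records the Michelson
modulation per period; the resolution limit is the smallest period whose
modulation still reaches the criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .bundle import (
    DEFAULT_ANGLES,
    CoreMask,
    FiberBundleLayout,
    RotationStack,
    build_stack,
    precompute_masks,
)
from .phantoms import generate_sinewave

__all__ = [
    "CalibrationResult",
    "NucleusMeasurement",
    "MTFResult",
    "calibrate_pixel_size",
    "measure_nucleus",
    "fit_sinusoid_modulation",
    "mtf_probe",
]

#: Michelson modulation a fitted sinewave must reach to count as resolved.
DEFAULT_MTF_CRITERION = 0.1


@dataclass(frozen=True)
class CalibrationResult:
    """Pixel-size calibration from a feature of known physical width."""

    pixel_size: float  # um/px, full precision
    line_width: float  # um
    measured_px: float  # px

    @property
    def display(self) -> str:
        """Pixel size rounded to 3 decimals for reporting."""
        return f"{self.pixel_size:.3f}"


@dataclass(frozen=True)
class NucleusMeasurement:
    """One line-profile diameter measurement."""

    line: tuple[tuple[float, float], tuple[float, float]]  # ((x0,y0),(x1,y1)) px
    below_threshold_px: int
    diameter: float  # um
    threshold: float  # grey level, 0-255 scale


@dataclass(frozen=True)
class MTFResult:
    """Modulation per tested period and the resolution limit.

    Periods are scanned descending (frequency increasing) until the fitted
    Michelson modulation first drops below the criterion; ``limit_period`` is
    the smallest period of that initial passing run (px/cycle), or ``None``
    when even the largest period fails.  Stopping at the first failure keeps
    spurious aliased modulation at much smaller periods from being mistaken
    for resolution.  ``limit_frequency`` converts the limit to cycles/mm via
    the pixel size.
    """

    periods: tuple[float, ...]
    modulation: tuple[float, ...]
    criterion: float
    limit_period: float | None
    limit_frequency: float | None  # cycles/mm


def calibrate_pixel_size(line_width: float, measured_px: float) -> CalibrationResult:
    """Micrometres per pixel from a known line width measured in pixels."""
    if line_width <= 0 or measured_px <= 0:
        raise ValueError("line width and pixel count must be positive")
    return CalibrationResult(
        pixel_size=line_width / measured_px,
        line_width=float(line_width),
        measured_px=float(measured_px),
    )


def _longest_true_run(mask: np.ndarray) -> int:
    best = run = 0
    for v in mask:
        run = run + 1 if v else 0
        best = max(best, run)
    return best


def measure_nucleus(
    image: np.ndarray,
    line: tuple[tuple[float, float], tuple[float, float]],
    threshold: float = 100.0,
    pixel_size: float = 0.316,
) -> NucleusMeasurement:
    """Measure a nucleus diameter along a line profile.

    ``image`` is on the 0-255 grey scale.  The profile is sampled at
    unit-pixel steps with bilinear interpolation; the diameter is the longest
    run of samples strictly below ``threshold`` (equality counts as
    background), times ``pixel_size``.  Using the longest run rather than the
    total count keeps isolated dark specks on the line from inflating the
    measurement.
    """
    image = np.asarray(image, dtype=float)
    (x0, y0), (x1, y1) = line
    h, w = image.shape
    for x, y in ((x0, y0), (x1, y1)):
        if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
            raise ValueError("line endpoints must lie inside the image")

    length = float(np.hypot(x1 - x0, y1 - y0))
    n = max(int(np.ceil(length)) + 1, 2)
    xs = np.linspace(x0, x1, n)
    ys = np.linspace(y0, y1, n)
    profile = map_coordinates(image, [ys, xs], order=1, mode="nearest")
    run = _longest_true_run(profile < threshold)
    return NucleusMeasurement(
        line=((float(x0), float(y0)), (float(x1), float(y1))),
        below_threshold_px=int(run),
        diameter=run * pixel_size,
        threshold=float(threshold),
    )


def fit_sinusoid_modulation(
    image: np.ndarray, period: float, row_band: slice | None = None
) -> float:
    """Fit ``a*sin + b*cos + offset`` of a known period along columns and
    return the Michelson modulation amplitude/offset of the fit.

    The fit is linear least squares over a horizontal band of rows (default:
    the central quarter of the image), so a DC shift or additive noise in the
    reconstruction does not bias the modulation estimate.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    if row_band is None:
        row_band = slice(int(h * 3 / 8), int(h * 5 / 8) or 1)
    band = image[row_band]
    x = np.arange(w, dtype=float)
    basis = np.column_stack(
        [np.sin(2 * np.pi * x / period), np.cos(2 * np.pi * x / period), np.ones(w)]
    )
    big_basis = np.tile(basis, (band.shape[0], 1))
    coef, *_ = np.linalg.lstsq(big_basis, band.ravel(), rcond=None)
    amplitude = float(np.hypot(coef[0], coef[1]))
    offset = float(coef[2])
    if offset <= 1e-9:
        return 0.0
    return amplitude / offset


def mtf_probe(
    reconstructor: Callable[[RotationStack], np.ndarray],
    layout: FiberBundleLayout,
    periods: Sequence[float],
    criterion: float = DEFAULT_MTF_CRITERION,
    angles: Sequence[float] = DEFAULT_ANGLES,
    masks: Sequence[CoreMask] | None = None,
) -> MTFResult:
    """Probe a reconstructor's resolution with sinewave targets.

    For each period (descending, px/cycle) a full-contrast sinewave the size
    of the layout field is forward-simulated into a rotation stack,
    reconstructed, and its Michelson modulation fitted.  The resolution limit
    is the smallest period the reconstructor resolves before it first fails
    the criterion; if the very first period fails, the limit is flagged
    unresolved (``None``).
    """
    periods = [float(p) for p in periods]
    if any(b >= a for a, b in zip(periods, periods[1:])):
        raise ValueError("periods must be sorted descending")
    if not (0.0 < criterion < 1.0):
        raise ValueError("criterion must lie in (0, 1)")
    h, w = layout.field_shape
    if h != w:
        raise ValueError("MTF probe expects a square field")
    if masks is None:
        masks = precompute_masks(layout, angles)

    modulation = []
    for period in periods:
        target = generate_sinewave(h, period)
        stack = build_stack(target, layout, angles, masks=masks)
        recon = reconstructor(stack)
        modulation.append(fit_sinusoid_modulation(recon, period))

    limit = None
    for p, m in zip(periods, modulation):
        if m >= criterion:
            limit = p
        else:
            break
    freq = None
    if limit is not None:
        freq = 1000.0 / (limit * layout.pixel_size)
    return MTFResult(
        periods=tuple(periods),
        modulation=tuple(modulation),
        criterion=criterion,
        limit_period=limit,
        limit_frequency=freq,
    )
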