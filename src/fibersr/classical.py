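"""Classical honeycomb-removal baselines: Gaussian blurring and core-center
linear interpolation.

Both operate on a single honeycomb frame.  Gaussian blurring simply smears
the core mosaic over the cladding.  Linear interpolation measures one
intensity per core, triangulates the core centers (Delaunay), and fills the
image by barycentric interpolation; pixels outside the convex hull of the
centers are left at 0, which reproduces the dark seams seen when interpolated
tiles are stitched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.ndimage import gaussian_filter
from scipy.spatial import QhullError

from .bundle import CoreMask, InvalidParameterError

__all__ = [
    "CoreSamples",
    "DegenerateGeometryError",
    "gaussian_reconstruct",
    "extract_core_samples",
    "interp_reconstruct",
]


class DegenerateGeometryError(ValueError):
    """Too few or collinear core centers for triangulation."""


@dataclass(frozen=True)
class CoreSamples:
    """Per-core point samples: centers (pixel coords) and mean intensities."""

    points: np.ndarray  # (n, 2) float, (x, y) in px
    values: np.ndarray  # (n,) float in [0, 1]

    def __post_init__(self) -> None:
        points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        values = np.asarray(self.values, dtype=float).reshape(-1)
        if points.shape[0] != values.shape[0]:
            raise InvalidParameterError("points and values must pair one-to-one")
        if values.size and (values.min() < -1e-9 or values.max() > 1 + 1e-9):
            raise InvalidParameterError("sample values must lie in [0, 1]")
        object.__setattr__(self, "points", points)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return int(self.values.shape[0])


def gaussian_reconstruct(frame: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-blur a honeycomb frame to wash out the cladding lattice."""
    if sigma <= 0:
        raise InvalidParameterError("sigma must be positive")
    out = gaussian_filter(np.asarray(frame, dtype=np.float64), sigma, mode="reflect")
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def extract_core_samples(frame: np.ndarray, mask: CoreMask) -> CoreSamples:
    """Measure one (center, mean intensity) sample per labelled core.

    Centers are the centroids of each core's footprint in pixel coordinates
    (x = column, y = row); values are footprint means of the frame.  The mask
    plays the role of the lookup table used for real-time interpolation on
    real bundles.
    """
    frame = np.asarray(frame, dtype=np.float64)
    labels = mask.label_raster
    if frame.shape != labels.shape:
        raise InvalidParameterError("frame and mask must share a shape")
    labs = mask.labels_present
    if labs.size == 0:
        raise InvalidParameterError("mask contains no cores")

    flat = labels.ravel()
    n_lab = int(flat.max()) + 1
    counts = np.bincount(flat, minlength=n_lab).astype(float)
    sums = np.bincount(flat, weights=frame.ravel(), minlength=n_lab)
    yy, xx = np.mgrid[0 : labels.shape[0], 0 : labels.shape[1]]
    sx = np.bincount(flat, weights=xx.ravel().astype(float), minlength=n_lab)
    sy = np.bincount(flat, weights=yy.ravel().astype(float), minlength=n_lab)

    safe = np.maximum(counts, 1.0)
    values = (sums / safe)[labs]
    centers = np.column_stack([(sx / safe)[labs], (sy / safe)[labs]])
    return CoreSamples(points=centers, values=np.clip(values, 0.0, 1.0))


def interp_reconstruct(samples: CoreSamples, shape: tuple[int, int]) -> np.ndarray:
    """Linearly interpolate core samples over a raster.

    Core centers are Delaunay-triangulated and each pixel inside the convex
    hull gets the barycentric linear interpolant of its triangle's vertex
    values (exact on affine intensity fields).  Pixels outside the hull are
    set to 0.
    """
    if len(samples) < 3:
        raise DegenerateGeometryError("need at least 3 core samples")
    try:
        interp = LinearNDInterpolator(samples.points, samples.values, fill_value=0.0)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate core geometry: {exc}") from exc
    h, w = int(shape[0]), int(shape[1])
    yy, xx = np.mgrid[0:h, 0:w]
    out = interp(np.column_stack([xx.ravel().astype(float), yy.ravel().astype(float)]))
    return np.nan_to_num(out.reshape(h, w), nan=0.0).astype(np.float32)
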