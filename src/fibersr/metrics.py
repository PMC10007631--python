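"""Image-quality metrics (MAE, MSE, PSNR, SSIM) and summary tables.

PSNR follows the standard definition ``10*log10(peak^2 / MSE)`` with images on
the 0-255 scale (a ``literal_formula`` flag evaluates the non-standard
``20*log10(255 / MSE)`` variant for comparison).  SSIM defaults to the
windowed form — 11x11 Gaussian window (sigma 1.5), K1=0.01, K2=0.03 — with a
single-window ("global") option that evaluates the SSIM formula once over the
whole image; the global form is also what the training loss differentiates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

__all__ = [
    "QualityReport",
    "SummaryRow",
    "ImprovementFactor",
    "mae",
    "mse",
    "psnr",
    "ssim",
    "global_ssim",
    "summarize",
    "summary_table",
    "improvement_factor",
]

SSIM_K1 = 0.01
SSIM_K2 = 0.03
SSIM_WIN = 11
SSIM_SIGMA = 1.5


@dataclass(frozen=True)
class QualityReport:
    """Per-image quality scores for one restoration method."""

    method: str
    image_id: str
    psnr_db: float  # math.inf flags identical images
    ssim: float


@dataclass(frozen=True)
class SummaryRow:
    """Mean/max/min/population-SD summary of PSNR and SSIM for one method."""

    method: str
    psnr_mean: float
    psnr_max: float
    psnr_min: float
    psnr_sd: float
    ssim_mean: float
    ssim_max: float
    ssim_min: float
    ssim_sd: float


@dataclass(frozen=True)
class ImprovementFactor:
    """SSIM ratio between two methods, with the 2-decimal truncation used
    for headline reporting alongside the full-precision value."""

    value: float
    truncated: float


def _check_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("images must share a shape")
    return x, y


def mae(x: np.ndarray, y: np.ndarray) -> float:
    x, y = _check_pair(x, y)
    return float(np.mean(np.abs(x - y)))


def mse(x: np.ndarray, y: np.ndarray) -> float:
    x, y = _check_pair(x, y)
    return float(np.mean((x - y) ** 2))


def psnr(
    x: np.ndarray, y: np.ndarray, peak: float = 255.0, literal_formula: bool = False
) -> float:
    """Peak signal-to-noise ratio in dB between images given in [0, 1].

    Intensities are rescaled to [0, peak] before computing the MSE.  Returns
    ``math.inf`` for identical images.  ``literal_formula=True`` evaluates
    ``20*log10(peak/MSE)`` instead of the standard ``10*log10(peak^2/MSE)``.
    """
    x, y = _check_pair(x, y)
    err = mse(x * peak, y * peak)
    if err == 0.0:
        return math.inf
    if literal_formula:
        return 20.0 * math.log10(peak / err)
    return 10.0 * math.log10(peak**2 / err)


def ssim(x: np.ndarray, y: np.ndarray, global_window: bool = False) -> float:
    """Structural similarity index between images given in [0, 1].

    Windowed by default (11x11 Gaussian window, sigma 1.5, K1=0.01, K2=0.03,
    population statistics), averaged over windows.  ``global_window=True``
    evaluates the SSIM formula once with whole-image statistics.
    """
    x, y = _check_pair(x, y)
    if global_window:
        return global_ssim(x, y)
    return float(
        structural_similarity(
            x,
            y,
            data_range=1.0,
            gaussian_weights=True,
            sigma=SSIM_SIGMA,
            win_size=SSIM_WIN,
            use_sample_covariance=False,
            K1=SSIM_K1,
            K2=SSIM_K2,
        )
    )


def global_ssim(x: np.ndarray, y: np.ndarray) -> float:
    """Single-window SSIM: luminance/contrast/structure terms from
    whole-image population statistics."""
    x, y = _check_pair(x, y)
    c1 = (SSIM_K1 * 1.0) ** 2
    c2 = (SSIM_K2 * 1.0) ** 2
    mu_x, mu_y = x.mean(), y.mean()
    var_x, var_y = x.var(), y.var()
    cov = ((x - mu_x) * (y - mu_y)).mean()
    num = (2 * mu_x * mu_y + c1) * (2 * cov + c2)
    den = (mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2)
    return float(num / den)


def evaluate_pair(method: str, image_id: str, pred: np.ndarray, truth: np.ndarray) -> QualityReport:
    """Convenience: build a QualityReport for one prediction/truth pair."""
    return QualityReport(method, image_id, psnr(pred, truth), ssim(pred, truth))


def summarize(reports: Sequence[QualityReport]) -> list[SummaryRow]:
    """Summarize per-image reports into one row per method.

    Statistics use the population standard deviation.  Infinite PSNR values
    (identical images) are excluded from PSNR statistics.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("report list must be non-empty")
    rows: list[SummaryRow] = []
    for method in dict.fromkeys(r.method for r in reports):  # first-seen order
        group = [r for r in reports if r.method == method]
        ps = np.array([r.psnr_db for r in group], dtype=float)
        ps = ps[np.isfinite(ps)]
        if ps.size == 0:
            ps = np.array([math.inf])
        ss = np.array([r.ssim for r in group], dtype=float)
        rows.append(
            SummaryRow(
                method=method,
                psnr_mean=float(ps.mean()),
                psnr_max=float(ps.max()),
                psnr_min=float(ps.min()),
                psnr_sd=float(ps.std()),
                ssim_mean=float(ss.mean()),
                ssim_max=float(ss.max()),
                ssim_min=float(ss.min()),
                ssim_sd=float(ss.std()),
            )
        )
    return rows


def summary_table(rows: Iterable[SummaryRow]) -> pd.DataFrame:
    """Arrange summary rows as a table with PSNR then SSIM blocks, each with
    Mean / Max / Min / Std div columns."""
    data = [
        {
            "Method": r.method,
            "PSNR Mean": r.psnr_mean,
            "PSNR Max": r.psnr_max,
            "PSNR Min": r.psnr_min,
            "PSNR Std div": r.psnr_sd,
            "SSIM Mean": r.ssim_mean,
            "SSIM Max": r.ssim_max,
            "SSIM Min": r.ssim_min,
            "SSIM Std div": r.ssim_sd,
        }
        for r in rows
    ]
    return pd.DataFrame(data)


def improvement_factor(summary_a: SummaryRow, summary_b: SummaryRow) -> ImprovementFactor:
    """Ratio of mean SSIM of method A over method B.

    The headline number is truncated (not rounded) to two decimals, so e.g.
    0.83 / 0.42 = 1.976... reports as 1.97.
    """
    if summary_a.ssim_mean <= 0 or summary_b.ssim_mean <= 0:
        raise ValueError("both summaries must carry positive mean SSIM")
    value = summary_a.ssim_mean / summary_b.ssim_mean
    truncated = math.floor(value * 100.0) / 100.0
    return ImprovementFactor(value=value, truncated=truncated)
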