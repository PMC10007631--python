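"""Canonical end-to-end study at a CPU-friendly scale.

This module wires the whole method together — phantom tiles, honeycomb
simulation, autoencoder training, classical baselines, quality metrics and
the MTF probe — at the package's default scaled-down study size: 250 H&E-like
tiles of 128x128 px at 0.316 um/px over the default bundle (pitch 3.3 um,
core radii 1.5-2.0 um, 0.3 um center jitter), eleven rotation angles, a
0.64/0.16/0.20 split, Adam at 1e-4 with patience-5 early stopping.  The same
entry point backs the test suite and the reproduction script, so every
reported number is recomputed from scratch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .analysis import MTFResult, measure_nucleus, mtf_probe
from .bundle import (
    DEFAULT_ANGLES,
    CoreMask,
    FiberBundleLayout,
    RotationStack,
    StackDataset,
    build_dataset,
    build_stack,
    generate_layout,
    precompute_masks,
)
from .classical import extract_core_samples, gaussian_reconstruct, interp_reconstruct
from .metrics import QualityReport, SummaryRow, evaluate_pair, summarize
from .model import (
    Autoencoder,
    ModelSpec,
    TrainingConfig,
    TrainingHistory,
    build_model,
    restore,
    train,
)
from .phantoms import PhantomTile, generate_phantom

__all__ = [
    "StudyConfig",
    "StudyResult",
    "default_layout",
    "make_phantom_tiles",
    "run_study",
    "mfae_reconstructor",
    "interp_reconstructor",
    "gaussian_reconstructor",
    "raw_reconstructor",
]

#: Bundle geometry emulating a 30k-core, 3-4 um core bundle at 0.316 um/px.
DEFAULT_PITCH_UM = 3.3
DEFAULT_RADIUS_RANGE_UM = (1.5, 2.0)
DEFAULT_JITTER_UM = 0.3
DEFAULT_PIXEL_SIZE = 0.316


@dataclass(frozen=True)
class StudyConfig:
    """Study sizes and training budget for the scaled-down experiment."""

    n_tiles: int = 250
    tile_size: int = 128
    nucleus_count: int = 5
    diameter_range: tuple[float, float] = (4.5, 9.6)
    pixel_size: float = DEFAULT_PIXEL_SIZE
    angles: tuple[float, ...] = DEFAULT_ANGLES
    split_fractions: tuple[float, float, float] = (0.64, 0.16, 0.20)
    encoder_widths: tuple[int, ...] = (8, 16, 32, 64)
    max_epochs: int = 30
    batch_size: int = 1
    learning_rate: float = 1e-4
    seed: int = 0

    def training_config(self) -> TrainingConfig:
        return TrainingConfig(
            learning_rate=self.learning_rate,
            max_epochs=self.max_epochs,
            batch_size=self.batch_size,
            seed=self.seed,
        )


@dataclass
class StudyResult:
    """Everything the scaled-down study produces."""

    config: StudyConfig
    layout: FiberBundleLayout
    masks: list[CoreMask]
    splits: dict[str, StackDataset]
    model: Autoencoder
    history: TrainingHistory
    reports: list[QualityReport] = field(default_factory=list)
    summaries: dict[str, SummaryRow] = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        from .metrics import summary_table

        return summary_table(self.summaries.values())


def default_layout(
    field_size: int = 64,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    seed: int = 0,
) -> FiberBundleLayout:
    """The package's default synthetic bundle over a square field."""
    return generate_layout(
        pitch=DEFAULT_PITCH_UM,
        jitter_sd=DEFAULT_JITTER_UM,
        core_radius_range=DEFAULT_RADIUS_RANGE_UM,
        field_shape=(field_size, field_size),
        pixel_size=pixel_size,
        seed=seed,
    )


def make_phantom_tiles(
    n_tiles: int,
    tile_size: int = 64,
    nucleus_count: int = 3,
    diameter_range: tuple[float, float] = (4.5, 9.6),
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    seed: int = 0,
) -> list[PhantomTile]:
    """Generate a reproducible batch of phantom tiles (one sub-seed each)."""
    root = np.random.default_rng(seed)
    sub_seeds = root.integers(0, 2**31 - 1, size=n_tiles)
    return [
        generate_phantom(
            size=tile_size,
            nucleus_count=nucleus_count,
            diameter_range=diameter_range,
            pixel_size=pixel_size,
            seed=int(s),
        )
        for s in sub_seeds
    ]


def mfae_reconstructor(model: Autoencoder) -> Callable[[RotationStack], np.ndarray]:
    """Reconstructor handle applying a trained multi-frame model."""
    return lambda stack: restore(model, stack)


def raw_reconstructor() -> Callable[[RotationStack], np.ndarray]:
    """The un-restored 0-degree honeycomb frame (lower baseline)."""
    return lambda stack: stack.frame_at(0.0)


def interp_reconstructor(mask0: CoreMask) -> Callable[[RotationStack], np.ndarray]:
    """Single-frame Delaunay linear interpolation over core centers."""

    def _run(stack: RotationStack) -> np.ndarray:
        frame = stack.frame_at(0.0)
        samples = extract_core_samples(frame, mask0)
        return interp_reconstruct(samples, frame.shape)

    return _run


def gaussian_reconstructor(
    sigma_px: float | None = None,
    pitch_um: float = DEFAULT_PITCH_UM,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
) -> Callable[[RotationStack], np.ndarray]:
    """Single-frame Gaussian blurring (sigma defaults to half the core pitch)."""
    if sigma_px is None:
        sigma_px = pitch_um / 2.0 / pixel_size

    def _run(stack: RotationStack) -> np.ndarray:
        return gaussian_reconstruct(stack.frame_at(0.0), sigma_px)

    return _run


def evaluate_methods(
    splits: dict[str, StackDataset],
    model: Autoencoder,
    mask0: CoreMask,
    methods: Sequence[str] = ("raw", "gaussian", "interp", "mfae"),
) -> tuple[list[QualityReport], dict[str, SummaryRow]]:
    """Score reconstruction methods on the held-out test split."""
    recons: dict[str, Callable[[RotationStack], np.ndarray]] = {
        "raw": raw_reconstructor(),
        "gaussian": gaussian_reconstructor(),
        "interp": interp_reconstructor(mask0),
        "mfae": mfae_reconstructor(model),
    }
    test = splits["test"]
    reports: list[QualityReport] = []
    for name in methods:
        recon = recons[name]
        for i in range(len(test)):
            stack = test.stack(i)
            reports.append(
                evaluate_pair(name, f"test_{i:03d}", recon(stack), stack.ground_truth)
            )
    summaries = {row.method: row for row in summarize(reports)}
    return reports, summaries


def run_study(
    config: StudyConfig | None = None,
    seed: int | None = None,
    evaluate: bool = True,
) -> StudyResult:
    """Run the scaled-down study end to end.

    Generates phantom tiles, simulates 11-angle rotation stacks over the
    default bundle, trains the multi-frame autoencoder with early stopping,
    and (optionally) scores MFAE against the raw frame, Gaussian blurring
    and linear interpolation on the held-out test split.
    """
    config = config or StudyConfig()
    if seed is not None:
        config = StudyConfig(**{**config.__dict__, "seed": int(seed)})
    rng = np.random.default_rng(config.seed)
    layout_seed, tile_seed, split_seed, model_seed = (
        int(s) for s in rng.integers(0, 2**31 - 1, size=4)
    )

    layout = default_layout(config.tile_size, config.pixel_size, seed=layout_seed)
    masks = precompute_masks(layout, config.angles)
    tiles = make_phantom_tiles(
        config.n_tiles,
        config.tile_size,
        config.nucleus_count,
        config.diameter_range,
        config.pixel_size,
        seed=tile_seed,
    )
    splits = build_dataset(
        [t.image for t in tiles],
        layout,
        config.angles,
        config.split_fractions,
        seed=split_seed,
        masks=masks,
    )

    spec = ModelSpec(
        input_channels=len(config.angles), encoder_widths=config.encoder_widths
    )
    model = build_model(spec, seed=model_seed)
    model, history = train(model, splits, config.training_config())

    result = StudyResult(
        config=config,
        layout=layout,
        masks=masks,
        splits=splits,
        model=model,
        history=history,
    )
    if evaluate:
        zero_idx = config.angles.index(0.0)
        result.reports, result.summaries = evaluate_methods(
            splits, model, masks[zero_idx]
        )
    return result


def run_mtf_comparison(
    result: StudyResult,
    periods: Sequence[float] | None = None,
    criterion: float = 0.1,
    probe_field: int | None = None,
    probe_seed: int = 12345,
) -> dict[str, MTFResult]:
    """MTF-probe the trained model and the interpolation baseline.

    A fresh default bundle of ``probe_field`` pixels (default: the training
    tile size) carries the sinewave targets; both reconstructors see the
    identical stacks.
    """
    if periods is None:
        periods = list(range(30, 4, -1))
    size = probe_field or result.config.tile_size
    layout = default_layout(size, result.config.pixel_size, seed=probe_seed)
    masks = precompute_masks(layout, result.config.angles)
    zero_idx = result.config.angles.index(0.0)
    out = {}
    for name, recon in (
        ("mfae", mfae_reconstructor(result.model)),
        ("interp", interp_reconstructor(masks[zero_idx])),
    ):
        out[name] = mtf_probe(
            recon,
            layout,
            periods,
            criterion=criterion,
            angles=result.config.angles,
            masks=masks,
        )
    return out


def run_nuclei_comparison(
    result: StudyResult,
    tiles: Sequence[PhantomTile],
    threshold: float = 100.0,
) -> pd.DataFrame:
    """Measure phantom nuclei on ground truth, MFAE and interpolation images.

    For each recorded nucleus the measurement line crosses the nucleus center
    along its major axis (padded past both tips); the diameter is read from
    the thresholded line profile on each image.  Returns one row per nucleus
    with the three measured diameters and the generator's ground truth.
    """
    zero_idx = result.config.angles.index(0.0)
    mask0 = result.masks[zero_idx]
    recon_i = interp_reconstructor(mask0)
    recon_m = mfae_reconstructor(result.model)
    rows = []
    for t_idx, tile in enumerate(tiles):
        stack = build_stack(tile.image, result.layout, result.config.angles, masks=result.masks)
        images = {
            "ground_truth": tile.image,
            "interp": recon_i(stack),
            "mfae": recon_m(stack),
        }
        size = tile.image.shape[0]
        for n_idx, nuc in enumerate(tile.nuclei):
            cx, cy = nuc.center_px
            half = nuc.major_um / 2.0 / tile.pixel_size + 3.0
            theta = np.deg2rad(nuc.orientation_deg)
            dx, dy = np.cos(theta), np.sin(theta)
            x0, y0 = cx - half * dx, cy - half * dy
            x1, y1 = cx + half * dx, cy + half * dy
            clip = lambda v: float(np.clip(v, 0, size - 1))
            line = ((clip(x0), clip(y0)), (clip(x1), clip(y1)))
            row = {
                "tile": t_idx,
                "nucleus": n_idx,
                "true_major_um": nuc.major_um,
            }
            for name, img in images.items():
                m = measure_nucleus(
                    img * 255.0, line, threshold=threshold, pixel_size=tile.pixel_size
                )
                row[f"{name}_um"] = m.diameter
            rows.append(row)
    return pd.DataFrame(rows)
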