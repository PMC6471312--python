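"""Synthetic en-face OCT phantoms with known reflectivity structure.

Every study group's averaged graph can be rendered as an 8-bit image
whose column means follow the group's analytic model, with three texture
ingredients layered on top:

* grain texture — bright discs (resolved granulation clusters and
  distinctive bright spots; the leucite grains themselves, 1-5 um, are
  below the 10 um lateral resolution), placed without overlap so they
  remain countable, and column-mean-neutral so the averaged profile
  still follows the generating graph;
* multiplicative speckle (unit-mean gamma) or additive Gaussian noise;
* 8-bit quantization, applied last.

The generating model, its parameter set and the planted grain count are
returned as ground truth, so every downstream stage of the pipeline can
be tested for recovery without instrument data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .groups import get_group
from .model import AnchorSet, PiecewiseModel, build_model, model_to_dict
from .params import ParameterSet, graph_extremes, parameters_from_model
from .profile import EnFaceImage

__all__ = [
    "SceneConfig",
    "GroundTruth",
    "scene_from_group",
    "render_enface",
    "true_parameters",
    "write_ground_truth",
]

NOISE_MODELS = ("none", "gaussian", "speckle")


@dataclass(frozen=True)
class SceneConfig:
    """Full description of one phantom scene (deterministic given seed)."""

    archetype: str
    anchors: AnchorSet
    seed: int
    width_px: int = 500
    height_px: int = 500
    lateral_extent_mm: float = 3.25
    grain_density: float = 2.0        #: grains per mm^2
    grain_radius_px: tuple[int, int] = (1, 3)
    grain_brightness: float = 120.0   #: additive gray levels inside a disc
    band_axis: str = "y"              #: axis the bands run parallel to
    noise_model: str = "speckle"
    noise_scale: float = 0.1
    non_overlapping_grains: bool = True

    def __post_init__(self) -> None:
        if self.width_px < 16 or self.height_px < 16:
            raise ValueError("phantom must be at least 16x16 px")
        if self.lateral_extent_mm <= 0:
            raise ValueError("lateral extent must be positive")
        if self.band_axis not in ("x", "y"):
            raise ValueError("band_axis must be 'x' or 'y'")
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(f"noise_model must be one of {NOISE_MODELS}")
        if (self.noise_scale == 0) != (self.noise_model == "none"):
            raise ValueError("noise_scale must be 0 exactly when noise_model='none'")
        if self.noise_scale < 0 or self.grain_density < 0:
            raise ValueError("noise_scale and grain_density must be nonnegative")
        r0, r1 = self.grain_radius_px
        if r0 < 1 or r1 < r0:
            raise ValueError("grain_radius_px must be a positive (lo, hi) range")


@dataclass(frozen=True)
class GroundTruth:
    model: PiecewiseModel
    parameters: ParameterSet
    grain_count: int


def scene_from_group(
    group_label: str,
    seed: int,
    *,
    width_px: int = 500,
    height_px: int = 500,
    noise_model: str = "speckle",
    noise_scale: float = 0.1,
    grain_density: float = 2.0,
    band_axis: str = "y",
) -> SceneConfig:
    """Scene reproducing one study group's averaged reflectivity graph."""
    group = get_group(group_label)
    if noise_scale == 0:
        noise_model = "none"
    return SceneConfig(
        archetype=group.archetype,
        anchors=group.anchors,
        seed=int(seed),
        width_px=width_px,
        height_px=height_px,
        lateral_extent_mm=group.anchors.x_max,
        noise_model=noise_model,
        noise_scale=noise_scale,
        grain_density=grain_density,
        band_axis=band_axis,
    )


def _place_grains(
    rng: np.random.Generator, config: SceneConfig
) -> list[tuple[int, int, int]]:
    area = config.lateral_extent_mm * (
        config.lateral_extent_mm * config.height_px / config.width_px
    )
    target = int(round(config.grain_density * area))
    placed: list[tuple[int, int, int]] = []
    r_lo, r_hi = config.grain_radius_px
    attempts = 0
    max_attempts = 200 * max(target, 1)
    while len(placed) < target and attempts < max_attempts:
        attempts += 1
        r = int(rng.integers(r_lo, r_hi + 1))
        row = int(rng.integers(r, config.height_px - r))
        col = int(rng.integers(r, config.width_px - r))
        if config.non_overlapping_grains:
            # gap of >= 2 px keeps discs 8-disconnected after thresholding
            if any(
                (row - r2) ** 2 + (col - c2) ** 2 < (r + rr + 2) ** 2
                for rr, r2, c2 in placed
            ):
                continue
        placed.append((r, row, col))
    return placed


def render_enface(config: SceneConfig) -> tuple[EnFaceImage, GroundTruth]:
    """Render a phantom; identical configs give bit-identical images."""
    model = build_model(config.archetype, config.anchors)
    lo, hi = graph_extremes(model)
    if lo < 0 or hi > 255:
        raise ValueError(
            f"anchors produce reflectivities outside [0, 255]: ({lo:g}, {hi:g})"
        )
    pitch = config.lateral_extent_mm / config.width_px
    x = (np.arange(config.width_px) + 0.5) * pitch
    mu = np.asarray(model.evaluate(x), dtype=float)
    field = np.tile(mu, (config.height_px, 1))

    rng = np.random.default_rng(config.seed)
    grains = _place_grains(rng, config)
    if grains:
        rows = np.arange(config.height_px)[:, None]
        cols = np.arange(config.width_px)[None, :]
        grain_field = np.zeros_like(field)
        for r, row, col in grains:
            disc = (rows - row) ** 2 + (cols - col) ** 2 <= r * r
            grain_field[disc] += config.grain_brightness
        # granulation redistributes backscatter locally (a bright grain
        # sits in a darker matrix): double-center the texture so both
        # column and row means stay on the generating graph
        field += (
            grain_field
            - grain_field.mean(axis=0, keepdims=True)
            - grain_field.mean(axis=1, keepdims=True)
            + grain_field.mean()
        )

    if config.noise_model == "gaussian":
        field = field + rng.normal(0.0, config.noise_scale, field.shape)
    elif config.noise_model == "speckle":
        s2 = config.noise_scale**2
        eta = rng.gamma(shape=1.0 / s2, scale=s2, size=field.shape)
        field = field * eta

    if config.band_axis == "x":
        field = field.T

    pixels = np.clip(np.rint(field), 0, 255).astype(np.uint8)
    extent_y = config.lateral_extent_mm * config.height_px / config.width_px
    if config.band_axis == "x":
        image = EnFaceImage(pixels, extent_y, config.lateral_extent_mm)
    else:
        image = EnFaceImage(pixels, config.lateral_extent_mm, extent_y)
    truth = GroundTruth(
        model=model,
        parameters=parameters_from_model(model),
        grain_count=len(grains),
    )
    return image, truth


def true_parameters(truth: GroundTruth) -> ParameterSet:
    """Parameter set of the generating model, for recovery tests."""
    return truth.parameters


def write_ground_truth(truth: GroundTruth, config: SceneConfig, path) -> None:
    """JSON sidecar: model segments, anchors, parameters, grain count, seed."""
    payload = {
        "model": model_to_dict(truth.model, config.anchors),
        "parameters": truth.parameters.as_dict(),
        "grain_count": truth.grain_count,
        "seed": config.seed,
        "noise_model": config.noise_model,
        "noise_scale": config.noise_scale,
    }
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")
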