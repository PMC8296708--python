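"""Histopathology quantification: fibrosis fraction, centralized nuclei,
and the weighted myodystrophy severity score.

Fibrosis is the percentage of a Sirius-Red-stained section classified as
red (collagen) relative to the total tissue area, averaged over up to three
fields per muscle.  Centralized nuclei are counted per 100 manually
annotated fibers.  The severity score combines five lesion parameters, each
graded by severity (mild=1..severe=3) and extension (focal=1..diffuse=3);
the per-animal score is the sum of severity x extension over the recorded
findings and the group mean total score (MTS) averages the animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.color import rgb2hsv

__all__ = [
    "LESION_PARAMETERS",
    "RedPixelConfig",
    "SeverityFinding",
    "SeverityCard",
    "FiberAnnotation",
    "EmptyInputError",
    "InvalidPercentError",
    "DuplicateFindingError",
    "fibrosis_fraction",
    "muscle_fibrosis",
    "centralized_nuclei_pct",
    "severity_score",
    "group_mts",
]

LESION_PARAMETERS = (
    "degeneration_necrosis",
    "regeneration",
    "inflammatory_infiltrate",
    "interstitial_reaction",
    "adipose_deposition",
)


class EmptyInputError(ValueError):
    """Empty image or annotation set."""


class InvalidPercentError(ValueError):
    """Percentage outside [0, 100]."""


class DuplicateFindingError(ValueError):
    """More than one finding for the same lesion parameter."""


@dataclass(frozen=True)
class RedPixelConfig:
    """HSV thresholds classifying a pixel as fibrosis red.

    Red sits at the hue wrap-around, so the window is hue >= hue_low OR
    hue <= hue_high (hue in [0, 1]).  Low-saturation (pale eosin / white
    background) pixels are excluded by min_saturation.  The defaults bracket
    the exact triplet emitted by the synthetic histology generator.
    """

    hue_low: float = 0.92
    hue_high: float = 0.08
    min_saturation: float = 0.30
    tissue_luminance_max: float | None = None  # optional background mask

    def __post_init__(self) -> None:
        for v in (self.hue_low, self.hue_high, self.min_saturation):
            if not 0.0 <= v <= 1.0:
                raise ValueError("HSV thresholds must lie in [0, 1]")


def fibrosis_fraction(
    image: np.ndarray, red_config: RedPixelConfig | None = None
) -> float:
    """Percent of tissue area classified as fibrosis red.

    ``image`` is an RGB array (H, W, 3), uint8 or float in [0, 1].  By
    default the total area is the full image; setting
    ``tissue_luminance_max`` masks out brighter background pixels first.
    """
    cfg = red_config or RedPixelConfig()
    img = np.asarray(image)
    if img.size == 0:
        raise EmptyInputError("empty image")
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    rgb = img[..., :3]
    if rgb.dtype != np.float64 and rgb.dtype != np.float32:
        rgb = rgb.astype(float) / 255.0
    hsv = rgb2hsv(rgb)
    hue, sat, val = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    red = ((hue >= cfg.hue_low) | (hue <= cfg.hue_high)) & (sat >= cfg.min_saturation)
    if cfg.tissue_luminance_max is not None:
        tissue = val <= cfg.tissue_luminance_max
        red &= tissue
        total = int(tissue.sum())
        if total == 0:
            raise EmptyInputError("tissue mask removed every pixel")
    else:
        total = red.size
    return 100.0 * float(red.sum()) / total


def muscle_fibrosis(field_percents: list[float] | np.ndarray) -> float:
    """Per-muscle fibrosis: arithmetic mean of 1-3 field percentages."""
    vals = np.asarray(field_percents, dtype=float)
    if vals.ndim != 1 or not 1 <= vals.size <= 3:
        raise ValueError("expected 1 to 3 field percentages")
    if np.any((vals < 0) | (vals > 100)):
        raise InvalidPercentError("field percentages must lie in [0, 100]")
    return float(vals.mean())


@dataclass(frozen=True)
class FiberAnnotation:
    """One manually measured fiber: area and nuclear position."""

    fiber_id: int
    area_um2: float
    nucleus_centralized: bool
    mouse_id: str = ""

    def __post_init__(self) -> None:
        if self.area_um2 <= 0:
            raise ValueError("fiber area must be positive")


def centralized_nuclei_pct(
    annotations: list[FiberAnnotation] | pd.DataFrame,
) -> float:
    """Percentage of annotated fibers with a centrally located nucleus."""
    if isinstance(annotations, pd.DataFrame):
        flags = annotations["centralized"].to_numpy(dtype=bool)
    else:
        flags = np.array([a.nucleus_centralized for a in annotations], dtype=bool)
    if flags.size == 0:
        raise EmptyInputError("no fiber annotations")
    return 100.0 * float(flags.sum()) / flags.size


@dataclass(frozen=True)
class SeverityFinding:
    """One graded lesion: parameter, severity 1-3, extension 1-3."""

    parameter: str
    severity: int
    extension: int

    def __post_init__(self) -> None:
        if self.parameter not in LESION_PARAMETERS:
            raise ValueError(f"unknown lesion parameter {self.parameter!r}")
        if self.severity not in (1, 2, 3):
            raise ValueError("severity must be 1, 2 or 3")
        if self.extension not in (1, 2, 3):
            raise ValueError("extension must be 1, 2 or 3")

    @property
    def score(self) -> int:
        return self.severity * self.extension


@dataclass(frozen=True)
class SeverityCard:
    """Per-animal set of graded findings (at most one per parameter)."""

    animal_id: str
    findings: tuple[SeverityFinding, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "findings", tuple(self.findings))
        params = [f.parameter for f in self.findings]
        if len(params) != len(set(params)):
            raise DuplicateFindingError(
                f"duplicate lesion parameter on animal {self.animal_id!r}"
            )

    @property
    def total_score(self) -> int:
        return severity_score(self)


def severity_score(card: SeverityCard) -> int:
    """Animal score: sum of severity x extension over recorded findings.

    A parameter with no finding contributes 0; the maximum over the five
    parameters at severe + diffuse grading is 5 x 9 = 45.
    """
    return sum(f.score for f in card.findings)


def group_mts(cards: list[SeverityCard]) -> float:
    """Group mean total score: average of per-animal severity scores."""
    if not cards:
        raise EmptyInputError("no severity cards")
    return float(np.mean([severity_score(c) for c in cards]))
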