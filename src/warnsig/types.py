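"""Shared domain types: the raw image unit and the per-frog phenotype record."""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

from .errors import ValidationError

#: Region labels used throughout (mask values 1, 2, 3 in indexed-PNG masks).
REGIONS = ("head", "dorsum", "limb")

#: The four qualitative patterning classes.
PATTERN_CLASSES = ("striped", "spotted", "lined", "diffuse")

#: Colour-characteristic name -> region label.
COLOUR_REGIONS = {"colour.head": "head", "colour.back": "dorsum", "colour.limb": "limb"}


def wrap_hue(h):
    """Wrap hue(s) into [0, 360)."""
    return np.mod(h, 360.0)


def circular_mean_deg(hues) -> float:
    """Circular mean of angles in degrees, result in [0, 360)."""
    rad = np.deg2rad(np.asarray(hues, dtype=float))
    return float(wrap_hue(np.rad2deg(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean()))))


def circular_diff_deg(a, b):
    """Signed smallest rotation from ``a`` to ``b`` in degrees, in (-180, 180]."""
    d = np.mod(np.asarray(b, dtype=float) - np.asarray(a, dtype=float), 360.0)
    return np.where(d > 180.0, d - 360.0, d)


@dataclass(frozen=True)
class Patch:
    """An axis-aligned colour-reference patch with its known true RGB."""

    row0: int
    row1: int
    col0: int
    col1: int
    true_rgb: tuple[float, float, float]


@dataclass
class FrogImage:
    """A standardized dorsal photograph plus its annotations.

    Attributes
    ----------
    raster : (H, W, 3) float array, RGB in [0, 1].
    landmarks : mapping of landmark name -> (x, y) pixel coordinates
        (0-based, x right / y down, pixel centres).
    masks : mapping of region label -> (H, W) boolean raster; regions are
        mutually disjoint.
    patches : reference patches with observed location and true RGB.
    """

    raster: np.ndarray
    landmarks: dict[str, tuple[float, float]]
    masks: dict[str, np.ndarray]
    patches: list[Patch] = field(default_factory=list)

    def validate(self) -> "FrogImage":
        r = np.asarray(self.raster, dtype=float)
        if r.ndim != 3 or r.shape[2] != 3:
            raise ValidationError("raster must be H x W x 3")
        if r.min() < 0.0 or r.max() > 1.0:
            raise ValidationError("raster values must lie in [0, 1]")
        h, w = r.shape[:2]
        for name, (x, y) in self.landmarks.items():
            if not (0 <= x < w and 0 <= y < h):
                raise ValidationError(f"landmark {name!r} outside image bounds")
        total = np.zeros((h, w), dtype=int)
        for region, m in self.masks.items():
            if m.shape != (h, w):
                raise ValidationError(f"mask {region!r} shape mismatch")
            total += m.astype(int)
        if (total > 1).any():
            raise ValidationError("region masks overlap")
        return self

    def copy_with(self, raster: np.ndarray) -> "FrogImage":
        return FrogImage(raster=raster, landmarks=dict(self.landmarks),
                         masks={k: v.copy() for k, v in self.masks.items()},
                         patches=list(self.patches))


@dataclass
class PhenotypeRecord:
    """One frog's 6 quantitative characteristics plus its qualitative class.

    Colour is stored as hue (degrees, [0, 360)) and saturation ([0, 1]) per
    region; brightness is deliberately not stored. Pattern is stored as
    transect transition counts (two dorsal transects plus one hindlimb
    transect); front limbs are never measured.
    """

    individual_id: str
    species: str
    locality: str
    hue_head: float
    sat_head: float
    hue_back: float
    sat_back: float
    hue_limb: float
    sat_limb: float
    dorsal_transitions_left: int
    dorsal_transitions_right: int
    limb_transitions: int
    pattern_class: str
    jitter_seed: int = 0

    def __post_init__(self):
        if self.pattern_class not in PATTERN_CLASSES:
            raise ValidationError(f"unknown pattern class {self.pattern_class!r}")
        for name in ("sat_head", "sat_back", "sat_limb"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} outside [0, 1]")
        for name in ("dorsal_transitions_left", "dorsal_transitions_right",
                     "limb_transitions"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")

    @classmethod
    def columns(cls) -> list[str]:
        return [f.name for f in fields(cls)]
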