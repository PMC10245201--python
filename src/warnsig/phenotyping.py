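"""Extraction of warning-signal characteristics from annotated images.

Implements the four measurement primitives — reference-patch colour
correction, region HSB colour (brightness dropped), landmark-aligned head
pattern rasters, and transect transition counts ("adjacent method") — plus
the composite that turns one image into a phenotype record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv
from skimage.draw import line as bresenham_line
from skimage.transform import estimate_transform

from .errors import (AlignmentError, CalibrationError, DegeneratePatchError,
                     GeometryError, NoPatternPixelsError, ValidationError)
from .types import FrogImage, PhenotypeRecord, circular_mean_deg

__all__ = [
    "RegionColor", "Transect", "CorrectionReport", "color_correct",
    "extract_region_color", "align_head_pattern", "count_transitions",
    "default_transects", "phenotype_image", "BLACKNESS_THRESHOLD",
]

#: A pixel counts as non-black pattern when its HSB brightness exceeds this.
BLACKNESS_THRESHOLD = 0.2

#: Transect role -> region mask it must stay inside.
TRANSECT_REGION = {"dorsal_left": "dorsum", "dorsal_right": "dorsum",
                   "limb": "limb"}


@dataclass(frozen=True)
class RegionColor:
    """Mean colour of a body region; brightness is dropped by design."""

    hue: float          # degrees in [0, 360)
    saturation: float   # fraction in [0, 1]


@dataclass
class Transect:
    """An ordered polyline sampled for colour-class transitions."""

    points: np.ndarray  # (N, 2) float, (x, y) pixel coordinates
    role: str

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[0] < 2 or self.points.shape[1] != 2:
            raise ValidationError("transect needs at least 2 (x, y) points")
        if self.role not in TRANSECT_REGION:
            raise ValidationError(f"unknown transect role {self.role!r}")

    @property
    def region(self) -> str:
        return TRANSECT_REGION[self.role]


@dataclass
class CorrectionReport:
    """Fitted 3x4 affine colour correction and its per-patch residuals."""

    matrix: np.ndarray       # (3, 3)
    offset: np.ndarray       # (3,)
    residuals: np.ndarray    # (n_patches,) RGB residual norm per patch
    n_patches: int


def brightness(raster: np.ndarray) -> np.ndarray:
    """Hexcone HSB brightness: per-pixel max over RGB."""
    return np.asarray(raster, dtype=float).max(axis=-1)


def _observed_patch_means(image: FrogImage) -> np.ndarray:
    return np.array([image.raster[p.row0:p.row1, p.col0:p.col1].reshape(-1, 3).mean(axis=0)
                     for p in image.patches])


def color_correct(image: FrogImage) -> tuple[FrogImage, CorrectionReport]:
    """Fit and apply a 3x4 affine RGB correction from the reference patches.

    Least squares maps observed patch mean RGB to the patches' known true
    RGB; the fitted transform is applied to the whole raster (clipped to
    [0, 1]).

    Raises
    ------
    CalibrationError
        Fewer than 4 reference patches.
    DegeneratePatchError
        Patch colours do not span RGB space (singular design).
    """
    if len(image.patches) < 4:
        raise CalibrationError(
            f"colour correction needs >= 4 patches, got {len(image.patches)}")
    observed = _observed_patch_means(image)
    true = np.array([p.true_rgb for p in image.patches], dtype=float)
    design = np.hstack([observed, np.ones((len(observed), 1))])
    if np.linalg.matrix_rank(design, tol=1e-8) < 4:
        raise DegeneratePatchError("reference patches do not span colour space")
    coef, *_ = np.linalg.lstsq(design, true, rcond=None)
    matrix, offset = coef[:3].T, coef[3]
    residuals = np.linalg.norm(design @ coef - true, axis=1)
    corrected = np.clip(image.raster @ matrix.T + offset, 0.0, 1.0)
    return image.copy_with(corrected), CorrectionReport(
        matrix=matrix, offset=offset, residuals=residuals,
        n_patches=len(image.patches))


def extract_region_color(image: FrogImage, region: str,
                         threshold: float = BLACKNESS_THRESHOLD,
                         hue_mode: str = "circular") -> RegionColor:
    """Mean hue/saturation of a region's non-black pattern pixels.

    Pixels inside the region mask with brightness above ``threshold`` are
    converted RGB -> HSB (hexcone); hue is averaged on the circle (or
    arithmetically with ``hue_mode='arithmetic'`` for literal replication)
    and saturation arithmetically. Brightness is discarded.
    """
    if region not in image.masks:
        raise ValidationError(f"no mask for region {region!r}")
    sel = image.masks[region] & (brightness(image.raster) > threshold)
    if not sel.any():
        raise NoPatternPixelsError(f"region {region!r} has no non-black pixels")
    hsv = rgb2hsv(image.raster[sel].reshape(-1, 1, 3)).reshape(-1, 3)
    hues = hsv[:, 0] * 360.0
    if hue_mode == "circular":
        hue = circular_mean_deg(hues)
    elif hue_mode == "arithmetic":
        hue = float(np.mod(hues.mean(), 360.0))
    else:
        raise ValidationError(f"unknown hue_mode {hue_mode!r}")
    return RegionColor(hue=hue, saturation=float(hsv[:, 1].mean()))


def _head_bbox(landmarks: dict[str, tuple[float, float]]) -> tuple[float, float, float, float]:
    """(x0, x1, y0, y1) of the head window in a landmark frame."""
    names = ("snout", "neck", "head_left", "head_right")
    if all(n in landmarks for n in names):
        x0, x1 = landmarks["head_left"][0], landmarks["head_right"][0]
        y0, y1 = landmarks["snout"][1], landmarks["neck"][1]
    else:
        pts = np.array(list(landmarks.values()))
        (x0, y0), (x1, y1) = pts.min(axis=0), pts.max(axis=0)
    return float(x0), float(x1), float(y0), float(y1)


def align_head_pattern(image: FrogImage, template: dict[str, tuple[float, float]],
                       grid_size: int = 64,
                       threshold: float = BLACKNESS_THRESHOLD) -> np.ndarray:
    """Warp the binary head pattern onto a common G x G landmark frame.

    A least-squares affine transform is fitted from the image landmarks to
    the template landmarks; each cell of a G x G grid spanning the
    template's head window is mapped back into the image and marked 1 when
    it lands on a non-black head-region pixel.
    """
    common = sorted(set(image.landmarks) & set(template))
    if len(common) < 3:
        raise AlignmentError("need at least 3 shared landmarks")
    src = np.array([image.landmarks[n] for n in common], dtype=float)
    dst = np.array([template[n] for n in common], dtype=float)
    sv = np.linalg.svd(src - src.mean(axis=0), compute_uv=False)
    if sv[-1] < 1e-6 * max(sv[0], 1.0):
        raise AlignmentError("landmark configuration is collinear/degenerate")
    tform = estimate_transform("affine", src, dst)
    if not np.all(np.isfinite(tform.params)):
        raise AlignmentError("affine fit failed")

    pattern = image.masks["head"] & (brightness(image.raster) > threshold)
    x0, x1, y0, y1 = _head_bbox(template)
    g = grid_size
    xs = x0 + (np.arange(g) + 0.5) * (x1 - x0) / g
    ys = y0 + (np.arange(g) + 0.5) * (y1 - y0) / g
    gx, gy = np.meshgrid(xs, ys)
    back = tform.inverse(np.column_stack([gx.ravel(), gy.ravel()]))
    cols = np.rint(back[:, 0]).astype(int)
    rows = np.rint(back[:, 1]).astype(int)
    h, w = pattern.shape
    inside = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    out = np.zeros(g * g, dtype=bool)
    out[inside] = pattern[rows[inside], cols[inside]]
    return out.reshape(g, g)


def _polyline_pixels(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Bresenham pixel chain along an ordered polyline; joints deduplicated."""
    rows, cols = [], []
    pts = np.rint(points).astype(int)
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        rr, cc = bresenham_line(y0, x0, y1, x1)
        if rows and len(rr) and rr[0] == rows[-1][-1] and cc[0] == cols[-1][-1]:
            rr, cc = rr[1:], cc[1:]
        rows.append(rr)
        cols.append(cc)
    return np.concatenate(rows), np.concatenate(cols)


def count_transitions(image: FrogImage, transect: Transect,
                      threshold: float = BLACKNESS_THRESHOLD) -> int:
    """Number of black/non-black label changes along a transect.

    The "adjacent method" reticulation score: pixels along the polyline are
    labelled by the blackness threshold and changes of label are counted, so
    a transect crossing b isolated bands scores 2b.
    """
    rows, cols = _polyline_pixels(transect.points)
    mask = image.masks[transect.region]
    h, w = mask.shape
    if ((rows < 0) | (rows >= h) | (cols < 0) | (cols >= w)).any() or \
            not mask[rows, cols].all():
        raise GeometryError(f"transect {transect.role!r} leaves its region mask")
    labels = brightness(image.raster)[rows, cols] > threshold
    return int(np.count_nonzero(labels[1:] != labels[:-1]))


def default_transects(landmarks: dict[str, tuple[float, float]],
                      offset_frac: float = 0.15,
                      inset_frac: float = 0.02) -> dict[str, Transect]:
    """Transect layout from anatomy: dorsal lines offset from the spine axis.

    Dorsal transects run neck -> groin, displaced perpendicular to the spine
    axis by ``offset_frac`` of the flank-to-flank body width on either side;
    the limb transect runs hip -> knee. Endpoints are inset slightly along
    each axis so the polylines stay inside their region masks.
    """
    lm = {k: np.asarray(v, dtype=float) for k, v in landmarks.items()}
    for name in ("neck", "groin", "flank_left", "flank_right", "hip", "knee"):
        if name not in lm:
            raise ValidationError(f"transect layout needs landmark {name!r}")
    axis = lm["groin"] - lm["neck"]
    u = axis / np.linalg.norm(axis)
    perp = np.array([u[1], -u[0]])            # unit vector toward the right flank
    if np.dot(perp, lm["flank_right"] - lm["flank_left"]) < 0:
        perp = -perp
    width = np.linalg.norm(lm["flank_right"] - lm["flank_left"])
    off = offset_frac * width * perp
    inset = inset_frac * axis
    out = {
        "dorsal_left": Transect(np.array([lm["neck"] + inset - off,
                                          lm["groin"] - inset - off]), "dorsal_left"),
        "dorsal_right": Transect(np.array([lm["neck"] + inset + off,
                                           lm["groin"] - inset + off]), "dorsal_right"),
    }
    limb_axis = lm["knee"] - lm["hip"]
    out["limb"] = Transect(np.array([lm["hip"] + inset_frac * limb_axis,
                                     lm["knee"] - inset_frac * limb_axis]), "limb")
    return out


REGION_FIELDS = {"head": "head", "dorsum": "back", "limb": "limb"}


def phenotype_image(image: FrogImage, template: dict[str, tuple[float, float]],
                    pattern_class: str, individual_id: str = "",
                    species: str = "", locality: str = "", *,
                    transects: dict[str, Transect] | None = None,
                    grid_size: int = 64,
                    threshold: float = BLACKNESS_THRESHOLD,
                    offset_frac: float = 0.15,
                    hue_mode: str = "circular") -> tuple[PhenotypeRecord, np.ndarray]:
    """Measure all six quantitative characteristics of one image.

    Assumes colour correction has already been applied (or an identity cast).
    The qualitative ``pattern_class`` is an annotation input, never computed.
    Returns the phenotype record and the aligned head-pattern raster.
    """
    fields: dict = {"individual_id": individual_id, "species": species,
                    "locality": locality, "pattern_class": pattern_class}
    for region, suffix in REGION_FIELDS.items():
        rc = extract_region_color(image, region, threshold, hue_mode)
        fields[f"hue_{suffix}"] = rc.hue
        fields[f"sat_{suffix}"] = rc.saturation
    transects = transects or default_transects(image.landmarks, offset_frac)
    fields["dorsal_transitions_left"] = count_transitions(
        image, transects["dorsal_left"], threshold)
    fields["dorsal_transitions_right"] = count_transitions(
        image, transects["dorsal_right"], threshold)
    fields["limb_transitions"] = count_transitions(image, transects["limb"], threshold)
    raster = align_head_pattern(image, template, grid_size, threshold)
    return PhenotypeRecord(**fields), raster
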