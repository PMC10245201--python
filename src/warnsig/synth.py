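"""Synthetic frog studies with known ground truth.

Generates phenotype tables (colour / band-count / class draws from population
specs with a mimicry-convergence dial) and renders cartoon frog images whose
pattern geometry is exactly controllable: the dorsal region is crossed by a
known number of transversal bands so a neck-to-groin transect sees exactly two
colour transitions per band, and reference patches with known true RGB allow a
global linear colour cast to be fitted back out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.color import hsv2rgb
from skimage.transform import SimilarityTransform, warp

from ._rng import substream
from .errors import ConfigurationError, RenderError, ValidationError
from .types import (PATTERN_CLASSES, Patch, FrogImage, PhenotypeRecord,
                    circular_diff_deg, wrap_hue)

__all__ = [
    "RegionColorSpec", "PopulationSpec", "StudySpec", "RenderSpec",
    "default_render_spec", "effective_means", "generate_phenotypes",
    "render_frog", "head_pattern_grid", "predation_gradient_study",
]

#: Colour regions as named in phenotype records.
COLOR_KEYS = ("head", "back", "limb")


@dataclass
class RegionColorSpec:
    """Generative colour distribution for one body region."""

    hue_mean: float
    hue_sd: float
    sat_mean: float
    sat_sd: float

    def validate(self, where: str) -> None:
        if self.hue_sd < 0 or self.sat_sd < 0:
            raise ConfigurationError(f"{where}: negative sd")
        if not (0.0 <= self.sat_mean <= 1.0):
            raise ConfigurationError(f"{where}: sat_mean outside [0, 1]")


@dataclass
class PopulationSpec:
    """Generative parameters for one (species, locality) population."""

    species: str
    locality: str
    n_individuals: int
    colors: dict[str, RegionColorSpec]
    dorsal_band_count_mean: float
    dorsal_band_count_sd: float
    limb_band_count_mean: float
    limb_band_count_sd: float
    pattern_class: str
    convergence: float = 0.0
    partner_species: str | None = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.species, self.locality)

    def validate(self) -> None:
        where = f"population {self.key}"
        if self.n_individuals < 2:
            raise ConfigurationError(f"{where}: n_individuals must be >= 2")
        if set(self.colors) != set(COLOR_KEYS):
            raise ConfigurationError(f"{where}: colors must have keys {COLOR_KEYS}")
        for k, c in self.colors.items():
            c.validate(f"{where}.{k}")
        for name in ("dorsal_band_count_mean", "dorsal_band_count_sd",
                     "limb_band_count_mean", "limb_band_count_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{where}: {name} must be >= 0")
        if self.pattern_class not in PATTERN_CLASSES:
            raise ConfigurationError(f"{where}: unknown pattern class "
                                     f"{self.pattern_class!r}")
        if not (0.0 <= self.convergence <= 1.0):
            raise ConfigurationError(f"{where}: convergence outside [0, 1]")


@dataclass
class StudySpec:
    """A full synthetic study: populations, the sympatry map, and the seed."""

    populations: list[PopulationSpec]
    sympatry: dict[str, list[str]]
    seed: int = 0

    def validate(self) -> "StudySpec":
        keys = [p.key for p in self.populations]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ConfigurationError(f"duplicate population keys: {dupes}")
        for p in self.populations:
            p.validate()
            present = self.sympatry.get(p.locality)
            if present is None or p.species not in present:
                raise ConfigurationError(
                    f"sympatry map inconsistent with population {p.key}")
        return self

    def population(self, species: str, locality: str) -> PopulationSpec:
        for p in self.populations:
            if p.key == (species, locality):
                return p
        raise ConfigurationError(f"no population {(species, locality)}")


# ---------------------------------------------------------------------------
# Convergence pull


def _partner_of(spec: StudySpec, pop: PopulationSpec) -> PopulationSpec | None:
    """The designated convergence attractor: one sympatric heterospecific."""
    if pop.partner_species is not None:
        return spec.population(pop.partner_species, pop.locality)
    for sp in spec.sympatry.get(pop.locality, []):
        if sp != pop.species:
            try:
                return spec.population(sp, pop.locality)
            except ConfigurationError:
                continue
    return None


def effective_means(spec: StudySpec, pop: PopulationSpec) -> dict:
    """Generative means after the convergence pull.

    With convergence c the focal mean moves a fraction c of the way toward
    the midpoint between its own and its partner's raw means, so two fully
    converged partners (c = 1) share identical generative means. Hue moves
    along the shorter arc.
    """
    partner = _partner_of(spec, pop)
    if partner is None:
        if pop.convergence > 0:
            raise ConfigurationError(
                f"population {pop.key} has convergence > 0 but no sympatric partner")
        partner = pop
    c = pop.convergence
    out = {}
    for k in COLOR_KEYS:
        own, oth = pop.colors[k], partner.colors[k]
        out[f"hue_{k}"] = wrap_hue(
            own.hue_mean + 0.5 * c * float(circular_diff_deg(own.hue_mean, oth.hue_mean)))
        out[f"sat_{k}"] = own.sat_mean + 0.5 * c * (oth.sat_mean - own.sat_mean)
    for name in ("dorsal_band_count_mean", "limb_band_count_mean"):
        out[name] = getattr(pop, name) + 0.5 * c * (getattr(partner, name)
                                                    - getattr(pop, name))
    return out


# ---------------------------------------------------------------------------
# Phenotype generation


def _draw_count(rng: np.random.Generator, mean: float, sd: float) -> int:
    return int(max(0, round(rng.normal(mean, sd))))


def generate_phenotypes(spec: StudySpec) -> pd.DataFrame:
    """Draw one phenotype record per individual; reproducible given the seed.

    Hue is drawn on the circle (wrapped normal), saturation as a clipped
    normal, band counts as ``max(0, round(Normal))``; the two dorsal
    transects are exchangeable draws. Transition counts are twice the band
    counts (each band is entered and left once).
    """
    spec.validate()
    rows = []
    for pop in spec.populations:
        eff = effective_means(spec, pop)
        rng = substream(spec.seed, "phenotypes", pop.species, pop.locality)
        for i in range(pop.n_individuals):
            rec = {"individual_id": f"{pop.species}_{pop.locality}_{i:03d}",
                   "species": pop.species, "locality": pop.locality}
            for k in COLOR_KEYS:
                c = pop.colors[k]
                rec[f"hue_{k}"] = float(wrap_hue(rng.normal(eff[f"hue_{k}"], c.hue_sd)))
                rec[f"sat_{k}"] = float(np.clip(rng.normal(eff[f"sat_{k}"], c.sat_sd),
                                                0.0, 1.0))
            rec["dorsal_transitions_left"] = 2 * _draw_count(
                rng, eff["dorsal_band_count_mean"], pop.dorsal_band_count_sd)
            rec["dorsal_transitions_right"] = 2 * _draw_count(
                rng, eff["dorsal_band_count_mean"], pop.dorsal_band_count_sd)
            rec["limb_transitions"] = 2 * _draw_count(
                rng, eff["limb_band_count_mean"], pop.limb_band_count_sd)
            rec["pattern_class"] = pop.pattern_class
            rec["jitter_seed"] = int(rng.integers(0, 2**31 - 1))
            rows.append(rec)
    return pd.DataFrame(rows, columns=PhenotypeRecord.columns())


def head_rasters_from_table(table: pd.DataFrame, grid_size: int = 32,
                            dot_jitter: int = 2) -> dict[str, np.ndarray]:
    """Head-pattern rasters synthesized directly from table records.

    Draws the same class+jitter head layout the renderer paints, in template
    pose, without rendering full images — the table-only stand-in for the
    landmark-aligned raster extraction.
    """
    out = {}
    for _, row in table.iterrows():
        rng = np.random.default_rng(int(row["jitter_seed"]))
        out[row["individual_id"]] = head_pattern_grid(
            row["pattern_class"], (grid_size, grid_size), rng, dot_jitter)
    return out


def records_from_table(table: pd.DataFrame) -> list[PhenotypeRecord]:
    return [PhenotypeRecord(**{k: row[k] for k in PhenotypeRecord.columns()})
            for _, row in table.iterrows()]


# ---------------------------------------------------------------------------
# Rendering


@dataclass
class RenderSpec:
    """Geometry and imaging conditions for the cartoon frog renderer.

    ``pose`` is a similarity transform (rotation about the image centre,
    isotropic scale, then translation) applied to the body and landmarks but
    not to the reference patches, which stay fixed in the camera frame like a
    colour chart. ``cast_matrix``/``cast_offset`` form a global linear colour
    cast applied to the whole frame last.
    """

    size: int = 256
    head_rect: tuple[int, int, int, int] = (24, 72, 92, 164)     # r0, r1, c0, c1
    dorsum_rect: tuple[int, int, int, int] = (80, 200, 80, 176)
    limb_rect: tuple[int, int, int, int] = (208, 244, 100, 156)
    spine_col: int = 128
    landmarks: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "snout": (128.0, 24.0),
        "head_left": (92.0, 48.0),
        "head_right": (163.0, 48.0),
        "neck": (128.0, 80.0),
        "flank_left": (80.0, 140.0),
        "flank_right": (175.0, 140.0),
        "spine_mid": (128.0, 140.0),
        "groin": (128.0, 199.0),
        "hip": (128.0, 208.0),
        "knee": (128.0, 243.0),
    })
    patches: list[Patch] = field(default_factory=lambda: [
        Patch(2, 14, 8, 20, (1.0, 1.0, 1.0)),
        Patch(2, 14, 44, 56, (0.55, 0.55, 0.55)),
        Patch(2, 14, 80, 92, (0.25, 0.25, 0.25)),
        Patch(2, 14, 116, 128, (0.80, 0.15, 0.10)),
        Patch(2, 14, 188, 200, (0.10, 0.70, 0.20)),
        Patch(2, 14, 224, 236, (0.12, 0.20, 0.85)),
    ])
    cast_matrix: np.ndarray = field(default_factory=lambda: np.eye(3))
    cast_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation_deg: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)
    scale: float = 1.0
    dot_jitter: int = 2
    min_strip_px: int = 3

    def band_capacity(self, rect: tuple[int, int, int, int]) -> int:
        """Largest band count whose 2b+1 strips are all >= min_strip_px."""
        height = rect[1] - rect[0]
        return (height // self.min_strip_px - 1) // 2


def default_render_spec(**overrides) -> RenderSpec:
    return RenderSpec(**overrides)


def _strip_parity(height: int, bands: int, shift: int = 0) -> np.ndarray:
    """Boolean per-pixel array: True on the ``bands`` odd strips of 2b+1."""
    n = 2 * bands + 1
    idx = ((np.arange(height) + shift) % height) * n // height
    return (idx % 2) == 1


def head_pattern_grid(pattern_class: str, shape: tuple[int, int],
                      rng: np.random.Generator, dot_jitter: int = 2) -> np.ndarray:
    """Binary head-pattern layout in the head rectangle's local frame.

    ``striped`` draws anteroposterior (vertical) lines, ``lined`` transversal
    bars, ``spotted`` a jittered grid of dots, ``diffuse`` a solid field.
    Stripe/bar phase and dot positions take small per-individual jitter.
    """
    h, w = shape
    if pattern_class == "diffuse":
        return np.ones((h, w), dtype=bool)
    if pattern_class == "lined":
        shift = int(rng.integers(0, 4))
        return np.repeat(_strip_parity(h, 4, shift)[:, None], w, axis=1)
    if pattern_class == "striped":
        shift = int(rng.integers(0, 4))
        return np.repeat(_strip_parity(w, 4, shift)[None, :], h, axis=0)
    if pattern_class == "spotted":
        grid = np.zeros((h, w), dtype=bool)
        rr, cc = np.mgrid[0:h, 0:w]
        for r0 in range(6, h, 12):
            for c0 in range(6, w, 12):
                jr, jc = rng.integers(-dot_jitter, dot_jitter + 1, size=2)
                grid |= (rr - (r0 + jr)) ** 2 + (cc - (c0 + jc)) ** 2 <= 16
        return grid
    raise ValidationError(f"unknown pattern class {pattern_class!r}")


def _region_rgb(hue: float, sat: float) -> np.ndarray:
    return hsv2rgb(np.array([[[hue / 360.0, sat, 1.0]]], dtype=float))[0, 0]


def _bands_from_transitions(transitions: int, what: str) -> int:
    if transitions % 2 != 0:
        raise RenderError(f"{what}: transition count {transitions} is odd; "
                          "rendered bands contribute two transitions each")
    return transitions // 2


def render_frog(record: PhenotypeRecord, render: RenderSpec | None = None,
                jitter_seed: int | None = None) -> FrogImage:
    """Render one phenotype record to a FrogImage with annotations.

    The dorsal region carries exactly ``dorsal_transitions/2`` transversal
    bands on each side of the spine and the hindlimb region exactly
    ``limb_transitions/2`` bands, painted in the record's region colours at
    full brightness on a black body; region geometry otherwise follows the
    qualitative pattern class (head decoration only).
    """
    render = render or default_render_spec()
    H = W = render.size
    img = np.zeros((H, W, 3), dtype=float)

    b_left = _bands_from_transitions(record.dorsal_transitions_left, "dorsal left")
    b_right = _bands_from_transitions(record.dorsal_transitions_right, "dorsal right")
    b_limb = _bands_from_transitions(record.limb_transitions, "limb")
    if max(b_left, b_right) > render.band_capacity(render.dorsum_rect):
        raise RenderError(f"dorsal band count {max(b_left, b_right)} exceeds "
                          f"capacity {render.band_capacity(render.dorsum_rect)}")
    if b_limb > render.band_capacity(render.limb_rect):
        raise RenderError(f"limb band count {b_limb} exceeds capacity "
                          f"{render.band_capacity(render.limb_rect)}")

    # head decoration by qualitative class
    hr0, hr1, hc0, hc1 = render.head_rect
    rng = np.random.default_rng(record.jitter_seed if jitter_seed is None
                                else jitter_seed)
    head_bin = head_pattern_grid(record.pattern_class, (hr1 - hr0, hc1 - hc0),
                                 rng, render.dot_jitter)
    img[hr0:hr1, hc0:hc1][head_bin] = _region_rgb(record.hue_head, record.sat_head)

    # dorsal transversal bands, split at the spine
    dr0, dr1, dc0, dc1 = render.dorsum_rect
    back_rgb = _region_rgb(record.hue_back, record.sat_back)
    if b_left:
        rows = _strip_parity(dr1 - dr0, b_left)
        img[dr0:dr1, dc0:render.spine_col][rows, :] = back_rgb
    if b_right:
        rows = _strip_parity(dr1 - dr0, b_right)
        img[dr0:dr1, render.spine_col + 1:dc1][rows, :] = back_rgb
    # limb bands
    lr0, lr1, lc0, lc1 = render.limb_rect
    if b_limb:
        rows = _strip_parity(lr1 - lr0, b_limb)
        img[lr0:lr1, lc0:lc1][rows, :] = _region_rgb(record.hue_limb,
                                                     record.sat_limb)

    masks = {}
    for region, rect in (("head", render.head_rect), ("dorsum", render.dorsum_rect),
                         ("limb", render.limb_rect)):
        m = np.zeros((H, W), dtype=bool)
        m[rect[0]:rect[1], rect[2]:rect[3]] = True
        masks[region] = m

    landmarks = {k: (float(x), float(y)) for k, (x, y) in render.landmarks.items()}

    if (render.rotation_deg, render.translation, render.scale) != (0.0, (0.0, 0.0), 1.0):
        centre = np.array([W / 2.0, H / 2.0])
        tform = (SimilarityTransform(translation=-centre)
                 + SimilarityTransform(scale=render.scale,
                                       rotation=math.radians(render.rotation_deg))
                 + SimilarityTransform(translation=centre
                                       + np.asarray(render.translation, dtype=float)))
        img = warp(img, tform.inverse, order=0, preserve_range=True)
        masks = {k: warp(m.astype(float), tform.inverse, order=0,
                         preserve_range=True) > 0.5 for k, m in masks.items()}
        pts = tform(np.array([landmarks[k] for k in landmarks]))
        landmarks = {k: (float(x), float(y))
                     for k, (x, y) in zip(landmarks, pts)}
        for name, (x, y) in landmarks.items():
            if not (0 <= x < W and 0 <= y < H):
                raise RenderError(f"pose moves landmark {name!r} out of frame")

    body = np.zeros((H, W), dtype=bool)
    for m in masks.values():
        body |= m
    for p in render.patches:
        if body[p.row0:p.row1, p.col0:p.col1].any():
            raise RenderError("pose moves the body over a reference patch")
        img[p.row0:p.row1, p.col0:p.col1] = p.true_rgb

    img = np.clip(img @ np.asarray(render.cast_matrix, dtype=float).T
                  + np.asarray(render.cast_offset, dtype=float), 0.0, 1.0)
    return FrogImage(raster=img, landmarks=landmarks, masks=masks,
                     patches=list(render.patches)).validate()


# ---------------------------------------------------------------------------
# A ready-made study where one dial drives both uniformity and convergence


def predation_gradient_study(seed: int = 0, n_per_population: int = 8,
                             strength: np.ndarray | None = None,
                             effect: float = 0.85) -> StudySpec:
    """A 9-locality, 15-sympatric-population study driven by one parameter.

    Per-locality "predation strength" jointly shrinks within-population sds
    (factor ``1 - effect * strength``) and raises the convergence pull
    between sympatric partners, so stronger predation should yield lower Var
    and higher mimicry similarity.
    """
    localities = [f"L{j+1}" for j in range(9)]
    # the three-species locality (two sympatric partners, so summed Im) gets
    # the weakest predation so its structurally lower ms follows the trend
    strength = (np.array([0.20, 0.35, 0.50, 0.65, 0.80, 0.95, 0.05, 0.5, 0.5])
                if strength is None else np.asarray(strength, dtype=float))
    base_hue = {"A": 20.0, "B": 140.0, "C": 260.0}
    species_at = {loc: ["A", "B"] for loc in localities[:6]}
    species_at[localities[6]] = ["A", "B", "C"]
    species_at[localities[7]] = ["C"]
    species_at[localities[8]] = ["C"]

    pops = []
    for j, loc in enumerate(localities):
        gamma = float(strength[j])
        shrink = max(1.0 - effect * gamma, 0.02)
        conv = min(0.95 * gamma, 1.0) if len(species_at[loc]) > 1 else 0.0
        for sp in species_at[loc]:
            colors = {k: RegionColorSpec(
                hue_mean=wrap_hue(base_hue[sp] + 40.0 * j + 7.0 * ki),
                hue_sd=0.5 + 14.0 * shrink,
                sat_mean=0.75, sat_sd=0.005 + 0.08 * shrink)
                for ki, k in enumerate(COLOR_KEYS)}
            pops.append(PopulationSpec(
                species=sp, locality=loc, n_individuals=n_per_population,
                colors=colors,
                dorsal_band_count_mean=2.0 + (j % 3) + (0.5 if sp == "B" else 0.0),
                dorsal_band_count_sd=0.05 + 1.2 * shrink,
                limb_band_count_mean=1.0 + (j % 2),
                limb_band_count_sd=0.05 + 0.8 * shrink,
                # one class study-wide: class-specific head-pattern jitter
                # would add a locality effect uncorrelated with strength
                pattern_class="diffuse",
                convergence=conv))
    return StudySpec(populations=pops, sympatry=species_at, seed=seed).validate()
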