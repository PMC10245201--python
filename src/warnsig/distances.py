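"""Per-characteristic distance matrices and their fusion into a global matrix.

Seven characteristics enter the fusion with identical weight: three region
colours (hue/saturation pairs), three pattern measures (aligned head raster,
dorsal transect count pair, limb transect count) and the qualitative pattern
class. Each pairwise matrix is min-max normalized over its full set of
entries and the normalized matrices are squared, summed and square-rooted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import (ArityError, LabelMismatchError, MembershipError,
                     MissingDataError, ValidationError)
from .types import PATTERN_CLASSES

__all__ = [
    "CHARACTERISTICS", "CharacteristicMatrix", "GlobalMatrix",
    "euclidean_matrix", "dice_matrix", "minmax_normalize", "combine",
    "characteristic_vectors", "characteristic_matrices", "global_from_table",
]

#: Canonical characteristic order for the fusion.
CHARACTERISTICS = ("colour.head", "colour.back", "colour.limb",
                   "pattern.head", "pattern.back", "pattern.limb",
                   "classif.pattern")

_COLOUR = {"colour.head", "colour.back", "colour.limb"}


@dataclass
class CharacteristicMatrix:
    """Symmetric nonnegative pairwise distance matrix for one characteristic."""

    labels: list[str]
    values: np.ndarray
    characteristic: str
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("matrix must be symmetric")
        if (self.values < -1e-12).any():
            raise ValidationError("matrix must be nonnegative")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValidationError("matrix diagonal must be zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class GlobalMatrix:
    """The fused global phenotypic distance; entries lie in [0, sqrt(7)]."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    def submatrix(self, ids) -> np.ndarray:
        idx = self.index_of(ids)
        return self.values[np.ix_(idx, idx)]

    def index_of(self, ids) -> np.ndarray:
        pos = {lab: i for i, lab in enumerate(self.labels)}
        try:
            return np.array([pos[i] for i in ids], dtype=int)
        except KeyError as e:
            raise MembershipError(f"unknown individual {e.args[0]!r}") from e

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def _circular_colour_pdist(vectors: np.ndarray) -> np.ndarray:
    hue = vectors[:, 0][:, None]
    sat = vectors[:, 1][:, None]
    dh = np.abs(hue - hue.T)
    dh = np.minimum(dh, 360.0 - dh) / 180.0
    ds = np.abs(sat - sat.T)
    return np.sqrt(dh ** 2 + ds ** 2)


def euclidean_matrix(labels, vectors, characteristic: str,
                     hue_mode: str = "circular") -> CharacteristicMatrix:
    """Pairwise Euclidean distance matrix for one quantitative characteristic.

    Colour characteristics take (hue, saturation) vectors; in circular mode
    the hue difference is the shorter arc scaled by 1/180 so one full hue
    reversal weighs like one full saturation swing. Linear mode applies the
    same 1/180 scaling to the raw arithmetic hue difference.
    """
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    if vectors.shape[0] == 1 and len(labels) != 1:
        vectors = vectors.T
    if np.isnan(vectors).any():
        bad = [labels[i] for i in np.unique(np.nonzero(np.isnan(vectors))[0])]
        raise MissingDataError(f"missing values for {bad} in {characteristic}")
    if characteristic in _COLOUR:
        if hue_mode == "circular":
            d = _circular_colour_pdist(vectors)
        elif hue_mode == "linear":
            scaled = vectors.copy()
            scaled[:, 0] /= 180.0
            d = squareform(pdist(scaled))
        else:
            raise ValidationError(f"unknown hue_mode {hue_mode!r}")
    else:
        d = squareform(pdist(vectors))
    np.fill_diagonal(d, 0.0)
    return CharacteristicMatrix(list(labels), d, characteristic)


def dice_matrix(labels, classes) -> CharacteristicMatrix:
    """Dice distance between single-label class sets: 0 if equal, 1 otherwise."""
    classes = list(classes)
    for c in classes:
        if c not in PATTERN_CLASSES:
            raise ValidationError(f"unknown pattern class {c!r}")
    arr = np.asarray(classes, dtype=object)
    d = (arr[:, None] != arr[None, :]).astype(float)
    return CharacteristicMatrix(list(labels), d, "classif.pattern")


def minmax_normalize(mat: CharacteristicMatrix) -> CharacteristicMatrix:
    """(mat - min) / (max - min) with min/max over the full matrix.

    The zero diagonal is included, so for matrices with positive off-diagonal
    entries this reduces to division by the maximum. A constant matrix maps
    to all zeros.
    """
    lo, hi = float(mat.values.min()), float(mat.values.max())
    if hi == lo:
        values = np.zeros_like(mat.values)
    else:
        values = (mat.values - lo) / (hi - lo)
    return replace(mat, values=values, normalized=True)


def combine(matrices) -> GlobalMatrix:
    """Fuse exactly 7 normalized matrices: entrywise sqrt of sum of squares."""
    matrices = list(matrices)
    if len(matrices) != 7:
        raise ArityError(f"fusion needs exactly 7 matrices, got {len(matrices)}")
    labels = matrices[0].labels
    for m in matrices[1:]:
        if m.labels != labels:
            raise LabelMismatchError("characteristic matrices have different labels")
    total = np.zeros_like(matrices[0].values)
    for m in matrices:
        total += m.values ** 2
    return GlobalMatrix(list(labels), np.sqrt(total))


# ---------------------------------------------------------------------------
# From a phenotype table to the global matrix


def characteristic_vectors(table: pd.DataFrame,
                           head_rasters: dict[str, np.ndarray] | None = None,
                           back_mode: str = "pair") -> dict[str, np.ndarray]:
    """Per-characteristic value vectors keyed by characteristic name.

    ``head_rasters`` maps individual_id -> aligned binary head raster; if
    given, the head-pattern characteristic is the flattened raster. The
    dorsal pattern enters as the (left, right) transition pair by default, or
    their sum with ``back_mode='sum'``.
    """
    out = {}
    for ch, suffix in (("colour.head", "head"), ("colour.back", "back"),
                       ("colour.limb", "limb")):
        out[ch] = table[[f"hue_{suffix}", f"sat_{suffix}"]].to_numpy(dtype=float)
    if back_mode == "pair":
        out["pattern.back"] = table[["dorsal_transitions_left",
                                     "dorsal_transitions_right"]].to_numpy(dtype=float)
    elif back_mode == "sum":
        out["pattern.back"] = (table["dorsal_transitions_left"]
                               + table["dorsal_transitions_right"]
                               ).to_numpy(dtype=float)[:, None]
    else:
        raise ValidationError(f"unknown back_mode {back_mode!r}")
    out["pattern.limb"] = table["limb_transitions"].to_numpy(dtype=float)[:, None]
    if head_rasters is not None:
        try:
            out["pattern.head"] = np.stack(
                [np.asarray(head_rasters[i], dtype=float).ravel()
                 for i in table["individual_id"]])
        except KeyError as e:
            raise MissingDataError(f"no head raster for {e.args[0]!r}") from e
    return out


def characteristic_matrices(table: pd.DataFrame,
                            head_rasters: dict[str, np.ndarray],
                            hue_mode: str = "circular",
                            back_mode: str = "pair") -> dict[str, CharacteristicMatrix]:
    """All 7 raw characteristic matrices from a phenotype table + head rasters."""
    labels = list(table["individual_id"])
    vecs = characteristic_vectors(table, head_rasters, back_mode)
    mats = {ch: euclidean_matrix(labels, v, ch, hue_mode)
            for ch, v in vecs.items()}
    mats["classif.pattern"] = dice_matrix(labels, table["pattern_class"])
    return {ch: mats[ch] for ch in CHARACTERISTICS}


def global_from_table(table: pd.DataFrame, head_rasters: dict[str, np.ndarray],
                      hue_mode: str = "circular",
                      back_mode: str = "pair") -> GlobalMatrix:
    """Convenience: build, normalize and fuse all 7 characteristic matrices."""
    mats = characteristic_matrices(table, head_rasters, hue_mode, back_mode)
    return combine([minmax_normalize(mats[ch]) for ch in CHARACTERISTICS])
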