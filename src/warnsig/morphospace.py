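"""Morphospace construction: MDS embedding, density peaks, outlier fractions."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .distances import GlobalMatrix
from .errors import UndefinedFractionError, ValidationError

__all__ = ["Embedding", "DensityMap", "classical_mds", "nonmetric_mds",
           "density_map", "outlier_fraction"]


@dataclass
class Embedding:
    """Low-dimensional coordinates of all individuals.

    ``retained_variance`` is the share of positive eigenvalue mass captured
    by the kept axes; ``negative_mass`` the share of total absolute
    eigenvalue mass sitting in negative eigenvalues (non-Euclidean part of
    the input, reported as a diagnostic).
    """

    coordinates: np.ndarray   # (n, k)
    eigenvalues: np.ndarray   # (k,), non-increasing
    retained_variance: float
    negative_mass: float
    labels: list[str] | None = None


@dataclass
class DensityMap:
    """Per-population 2-D frequency surfaces on a common grid."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    surfaces: dict          # population key -> (bins, bins) counts
    levels: dict            # population key -> 10 contour level thresholds


def _as_matrix(D) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(D, GlobalMatrix):
        return D.values, list(D.labels)
    return np.asarray(D, dtype=float), None


def classical_mds(D, k: int = 2, strict_k: bool = True) -> Embedding:
    """Torgerson metric MDS: double-centre squared distances, eigendecompose.

    Keeps the top-k positive-eigenvalue axes, scaled by sqrt(eigenvalue).
    Sign convention: the first nonzero loading of each axis is positive. If
    fewer than k positive eigenvalues exist a warning is issued and the
    available axes are returned.
    """
    dm, labels = _as_matrix(D)
    n = dm.shape[0]
    if k < 1:
        raise ValidationError("k must be >= 1")
    if strict_k and n < k + 1:
        raise ValidationError(f"need at least k+1={k+1} points, got {n}")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm ** 2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(abs(evals[0]), 1.0) * 1e-12
    positive = evals > tol
    n_pos = int(positive.sum())
    if n_pos < k:
        warnings.warn(f"only {n_pos} positive eigenvalues; returning {n_pos} "
                      f"axes instead of {k}")
    kept = min(k, max(n_pos, 1))
    lam = np.clip(evals[:kept], 0.0, None)
    coords = evecs[:, :kept] * np.sqrt(lam)
    for c in range(coords.shape[1]):
        col = coords[:, c]
        nz = np.nonzero(np.abs(col) > tol)[0]
        if len(nz) and col[nz[0]] < 0:
            coords[:, c] = -col
    pos_mass = float(evals[positive].sum()) if n_pos else 0.0
    neg_mass = float(-evals[evals < -tol].sum())
    total_abs = float(np.abs(evals).sum())
    return Embedding(
        coordinates=coords, eigenvalues=evals[:kept],
        retained_variance=(lam.sum() / pos_mass if pos_mass > 0 else 0.0),
        negative_mass=(neg_mass / total_abs if total_abs > 0 else 0.0),
        labels=labels)


def nonmetric_mds(D, k: int = 2, seed: int = 0, tol: float = 1e-6,
                  max_iter: int = 500) -> Embedding:
    """Stress-minimizing (non-metric) MDS behind the same interface."""
    from sklearn.manifold import MDS

    dm, labels = _as_matrix(D)
    model = MDS(n_components=k, metric=False, dissimilarity="precomputed",
                random_state=seed, eps=tol, max_iter=max_iter,
                normalized_stress="auto")
    coords = model.fit_transform(dm)
    spread = coords.var(axis=0)
    order = np.argsort(spread)[::-1]
    coords = coords[:, order]
    return Embedding(coordinates=coords, eigenvalues=spread[order],
                     retained_variance=float("nan"), negative_mass=float("nan"),
                     labels=labels)


def density_map(embedding: Embedding, assignments, bins: int = 50,
                n_levels: int = 10, pad: float = 0.05) -> DensityMap:
    """Per-population 2-D histograms on a shared padded grid.

    ``assignments`` maps each row of the embedding to a population key (a
    sequence aligned with the coordinate rows). Contour levels are
    ``n_levels`` thresholds equally spaced between 0 and each population's
    peak frequency.
    """
    coords = embedding.coordinates
    if coords.shape[1] < 2:
        raise ValidationError("density map needs a 2-D embedding")
    xy = coords[:, :2]
    lo, hi = xy.min(axis=0), xy.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    lo, hi = lo - pad * span, hi + pad * span
    x_edges = np.linspace(lo[0], hi[0], bins + 1)
    y_edges = np.linspace(lo[1], hi[1], bins + 1)
    keys = list(assignments)
    surfaces, levels = {}, {}
    for key in dict.fromkeys(keys):          # preserve first-seen order
        sel = np.array([k == key for k in keys], dtype=bool)
        if not sel.any():
            warnings.warn(f"population {key} empty; skipped")
            continue
        h, _, _ = np.histogram2d(xy[sel, 0], xy[sel, 1],
                                 bins=[x_edges, y_edges])
        surfaces[key] = h
        levels[key] = np.linspace(0.0, h.max(), n_levels + 1)[1:]
    return DensityMap(x_edges=x_edges, y_edges=y_edges, surfaces=surfaces,
                      levels=levels)


def outlier_fraction(coordinates: np.ndarray, focal_idx,
                     conspecific_idx: dict) -> float:
    """Share of focal individuals nearer another conspecific centroid.

    For each focal individual, its own population centroid is recomputed
    without that individual (leave-self-out); the individual is an outlier
    when some other conspecific population's centroid is strictly closer.
    Ties are not outliers.
    """
    coordinates = np.asarray(coordinates, dtype=float)
    focal_idx = np.asarray(list(focal_idx), dtype=int)
    others = {k: np.asarray(list(v), dtype=int)
              for k, v in conspecific_idx.items() if len(v)}
    if not others:
        raise UndefinedFractionError("no conspecific alternative population")
    if len(focal_idx) < 2:
        raise UndefinedFractionError("focal population needs >= 2 members "
                                     "for leave-self-out centroids")
    other_centroids = np.stack([coordinates[v].mean(axis=0)
                                for v in others.values()])
    total = coordinates[focal_idx].sum(axis=0)
    n = len(focal_idx)
    outliers = 0
    for i in focal_idx:
        own = (total - coordinates[i]) / (n - 1)
        d_own = np.linalg.norm(coordinates[i] - own)
        d_other = np.linalg.norm(other_centroids - coordinates[i], axis=1).min()
        if d_other < d_own:
            outliers += 1
    return outliers / n
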