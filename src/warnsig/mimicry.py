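"""Within-population variability, mimicry convergence metrics, and their link.

Var is the mean pairwise global distance within a population. The mimetic
distance Im of a focal population is its centroid distance to a sympatric
heterospecific population divided by its mean centroid distance to allopatric
conspecific populations; mimicry similarity ms is the reciprocal of the
aggregated Im (values below 1 mean no detected convergence). The predicted
negative Var-ms relationship is tested with a Pearson correlation after a
Shapiro-Wilk normality check on each margin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .distances import GlobalMatrix
from .errors import (DegenerateDataError, DegenerateDenominatorError,
                     InsufficientMembersError, InsufficientPointsError,
                     MembershipError, ValidationError)

__all__ = [
    "PopulationKey", "VarResult", "MimicryResult", "CorrelationResult",
    "population_members", "within_population_var", "centroid_distance",
    "mimetic_distance", "classify_mimicry", "var_ms_correlation",
    "mimicry_table",
]

#: (species, locality)
PopulationKey = tuple[str, str]


@dataclass(frozen=True)
class VarResult:
    population: PopulationKey
    var: float
    n: int


@dataclass
class MimicryResult:
    population: PopulationKey
    im: dict[PopulationKey, float]
    ms: float
    aggregate: str = "sum"


@dataclass
class CorrelationResult:
    r: float
    df: int
    p: float                     # two-sided
    p_one_sided: float           # H1: r < 0
    shapiro: dict[str, tuple[float, float]]  # margin -> (W, p)
    warnings: list[str] = field(default_factory=list)


def population_members(table: pd.DataFrame) -> dict[PopulationKey, list[str]]:
    """individual ids per (species, locality), in table order."""
    out: dict[PopulationKey, list[str]] = {}
    for _, row in table.iterrows():
        out.setdefault((row["species"], row["locality"]), []).append(
            row["individual_id"])
    return out


def within_population_var(D: GlobalMatrix, members,
                          population: PopulationKey = ("", "")) -> VarResult:
    """Mean global distance over all unordered within-population pairs."""
    members = list(members)
    n = len(members)
    if n < 2:
        raise InsufficientMembersError(
            f"population {population} has {n} member(s); Var needs >= 2")
    sub = D.submatrix(members)
    iu = np.triu_indices(n, k=1)
    return VarResult(population=population, var=float(sub[iu].mean()), n=n)


def centroid_distance(D: GlobalMatrix, group_a, group_b,
                      method: str = "gram") -> float:
    """Distance between two group centroids implied by the distance matrix.

    ``gram`` (default) evaluates the centroid distance in closed form from
    mean squared distances:

        ||cA - cB||^2 = mean_{a,b} d_ab^2 - mean_{a,a'} d_aa'^2 / 2
                                         - mean_{b,b'} d_bb'^2 / 2

    which is exact for Euclidean-embeddable matrices (and exact for
    singleton groups in general); a negative value, possible only for
    non-Euclidean input, is clamped to zero. ``embedding`` computes centroids
    in the positive-eigenvalue classical-MDS embedding instead.
    """
    a = D.index_of(list(group_a))
    b = D.index_of(list(group_b))
    if len(a) == 0 or len(b) == 0:
        raise MembershipError("centroid distance needs non-empty groups")
    if method == "gram":
        s = D.values ** 2
        d2 = (s[np.ix_(a, b)].mean() - s[np.ix_(a, a)].mean() / 2.0
              - s[np.ix_(b, b)].mean() / 2.0)
        return float(np.sqrt(max(d2, 0.0)))
    if method == "embedding":
        from .morphospace import classical_mds
        emb = classical_mds(D, k=len(D.labels) - 1, strict_k=False)
        ca = emb.coordinates[a].mean(axis=0)
        cb = emb.coordinates[b].mean(axis=0)
        return float(np.linalg.norm(ca - cb))
    raise ValidationError(f"unknown centroid method {method!r}")


def mimetic_distance(D: GlobalMatrix, members: dict[PopulationKey, list[str]],
                     focal: PopulationKey, partners,
                     allopatric_conspecifics=None,
                     aggregate: str = "sum",
                     method: str = "gram") -> MimicryResult:
    """Im per sympatric partner and the mimicry similarity ms of a population.

    ``allopatric_conspecifics`` defaults to all conspecific populations at
    other localities present in ``members``. ms = 1 / sum(Im) by default;
    ``aggregate='mean'`` divides by the mean instead (identical for a single
    partner).
    """
    if focal not in members:
        raise MembershipError(f"unknown population {focal}")
    partners = list(partners)
    if not partners:
        raise MembershipError(f"population {focal} has no sympatric partner")
    species, locality = focal
    if allopatric_conspecifics is None:
        allopatric_conspecifics = [k for k in members
                                   if k[0] == species and k[1] != locality]
    allopatric_conspecifics = list(allopatric_conspecifics)
    if not allopatric_conspecifics:
        raise MembershipError(
            f"population {focal} has no allopatric conspecific population")
    allo = float(np.mean([centroid_distance(D, members[focal], members[k], method)
                          for k in allopatric_conspecifics]))
    if allo == 0.0:
        raise DegenerateDenominatorError(
            f"mean allopatric centroid distance is zero for {focal}")
    im = {}
    for k in partners:
        if k not in members:
            raise MembershipError(f"unknown partner population {k}")
        im[k] = centroid_distance(D, members[focal], members[k], method) / allo
    if aggregate == "sum":
        total = sum(im.values())
    elif aggregate == "mean":
        total = float(np.mean(list(im.values())))
    else:
        raise ValidationError(f"unknown aggregate {aggregate!r}")
    ms = float("inf") if total == 0.0 else 1.0 / total
    return MimicryResult(population=focal, im=im, ms=ms, aggregate=aggregate)


def classify_mimicry(ms: float) -> str:
    """'non_mimetic' below the neutral point 1, 'mimetic' at or above it."""
    if ms < 0:
        raise ValidationError(f"ms must be nonnegative, got {ms}")
    return "non_mimetic" if ms < 1.0 else "mimetic"


def var_ms_correlation(var_values, ms_values) -> CorrelationResult:
    """Pearson correlation between Var and ms across populations.

    Two-sided p from the t distribution with n - 2 degrees of freedom; a
    one-sided p for the directional (negative) hypothesis is also reported.
    Shapiro-Wilk is run on each margin first; non-normality produces a
    warning entry, never an error.
    """
    var_values = np.asarray(var_values, dtype=float)
    ms_values = np.asarray(ms_values, dtype=float)
    n = len(var_values)
    if n != len(ms_values):
        raise ValidationError("Var and ms vectors differ in length")
    if n < 3:
        raise InsufficientPointsError(f"correlation needs >= 3 points, got {n}")
    if np.std(var_values) == 0.0 or np.std(ms_values) == 0.0:
        raise DegenerateDataError("zero variance in a correlation margin")
    shapiro, warn = {}, []
    for name, vals in (("var", var_values), ("ms", ms_values)):
        w, p = stats.shapiro(vals)
        shapiro[name] = (float(w), float(p))
        if p < 0.05:
            warn.append(f"Shapiro-Wilk rejects normality of {name} (p={p:.3g})")
    res = stats.pearsonr(var_values, ms_values)
    r = float(res.statistic)
    p_two = float(res.pvalue)
    p_one = p_two / 2.0 if r < 0 else 1.0 - p_two / 2.0
    return CorrelationResult(r=r, df=n - 2, p=p_two, p_one_sided=p_one,
                             shapiro=shapiro, warnings=warn)


def mimicry_table(D: GlobalMatrix, table: pd.DataFrame,
                  sympatry: dict[str, list[str]],
                  aggregate: str = "sum",
                  method: str = "gram") -> pd.DataFrame:
    """Tidy per-population results: n, Var, per-partner Im, ms, classification.

    Populations without a sympatric heterospecific partner (or without any
    allopatric conspecific population) are skipped with a warning: no mimicry
    metric is defined for them.
    """
    members = population_members(table)
    rows = []
    for key, ids in members.items():
        species, locality = key
        vr = within_population_var(D, ids, key)
        partners = [(sp, locality) for sp in sympatry.get(locality, [])
                    if sp != species and (sp, locality) in members]
        has_allo = any(k[0] == species and k[1] != locality for k in members)
        if not partners or not has_allo:
            warnings.warn(f"population {key} skipped: no sympatric partner "
                          "or no allopatric conspecifics")
            continue
        mr = mimetic_distance(D, members, key, partners, aggregate=aggregate,
                              method=method)
        for pk, im in mr.im.items():
            rows.append({"species": species, "locality": locality, "n": vr.n,
                         "var": vr.var, "partner_species": pk[0],
                         "im": im, "ms": mr.ms,
                         "classification": classify_mimicry(mr.ms)})
    return pd.DataFrame(rows)
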