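"""Variability anatomy: which characteristics of the signal vary most.

Per-population, per-characteristic variability is the mean normalized
pairwise distance among members. Characteristics are compared with a
Kruskal-Wallis test followed by pairwise Wilcoxon rank-sum tests under
Bonferroni correction. Note the within-population pair distances share
individuals and are therefore not independent; the procedure replicates
standard practice rather than correcting for it (recorded in output
metadata).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .distances import CHARACTERISTICS, CharacteristicMatrix, GlobalMatrix
from .errors import InsufficientMembersError, ValidationError
from .mimicry import PopulationKey, population_members

__all__ = ["CharacteristicVar", "KWResult", "characteristic_var",
           "characteristic_var_table", "variance_sum",
           "compare_characteristics", "rank_characteristics",
           "within_pair_distances"]


@dataclass(frozen=True)
class CharacteristicVar:
    population: PopulationKey
    characteristic: str
    var: float
    n_pairs: int


@dataclass
class KWResult:
    h: float
    df: int
    p: float
    groups: list[str]
    pairwise: pd.DataFrame      # Bonferroni-adjusted Wilcoxon p-values
    note: str = ("within-population pair distances share individuals; "
                 "groups are not independent samples")


def _pair_values(mat: CharacteristicMatrix | GlobalMatrix, members) -> np.ndarray:
    members = list(members)
    if len(members) < 2:
        raise InsufficientMembersError(
            f"population needs >= 2 members, got {len(members)}")
    if isinstance(mat, GlobalMatrix):
        sub = mat.submatrix(members)
    else:
        idx = {lab: i for i, lab in enumerate(mat.labels)}
        pos = np.array([idx[m] for m in members])
        sub = mat.values[np.ix_(pos, pos)]
    return sub[np.triu_indices(len(members), k=1)]


def characteristic_var(nm: CharacteristicMatrix, members,
                       population: PopulationKey = ("", "")) -> CharacteristicVar:
    """Mean normalized pairwise distance within one population."""
    vals = _pair_values(nm, members)
    return CharacteristicVar(population=population,
                             characteristic=nm.characteristic,
                             var=float(vals.mean()), n_pairs=len(vals))


def within_pair_distances(norm_mats: dict[str, CharacteristicMatrix],
                          members: dict[PopulationKey, list[str]]
                          ) -> dict[str, np.ndarray]:
    """All within-population pair distances pooled per characteristic."""
    return {ch: np.concatenate([_pair_values(nm, ids)
                                for ids in members.values()])
            for ch, nm in norm_mats.items()}


def characteristic_var_table(norm_mats: dict[str, CharacteristicMatrix],
                             table: pd.DataFrame) -> pd.DataFrame:
    """Tidy (species, locality, characteristic, var, n_pairs) table."""
    members = population_members(table)
    rows = []
    for key, ids in members.items():
        for ch, nm in norm_mats.items():
            cv = characteristic_var(nm, ids, key)
            rows.append({"species": key[0], "locality": key[1],
                         "characteristic": ch, "var": cv.var,
                         "n_pairs": cv.n_pairs})
    return pd.DataFrame(rows)


def variance_sum(var_table: pd.DataFrame,
                 norm_mats: dict[str, CharacteristicMatrix] | None = None,
                 table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-characteristic totals across populations, both readings.

    ``sum_mean_pairwise`` sums each population's mean pairwise distance;
    ``sum_pair_variance`` sums each population's variance of its pairwise
    distances (requires ``norm_mats`` and ``table``; NaN otherwise). Both are
    reported because "sum of the variance" is ambiguous.
    """
    out = (var_table.groupby("characteristic")["var"].sum()
           .rename("sum_mean_pairwise").to_frame())
    if norm_mats is not None and table is not None:
        members = population_members(table)
        pv = {}
        for ch, nm in norm_mats.items():
            pv[ch] = float(np.sum([_pair_values(nm, ids).var(ddof=0)
                                   for ids in members.values()]))
        out["sum_pair_variance"] = pd.Series(pv)
    else:
        out["sum_pair_variance"] = np.nan
    return out.reset_index()


def compare_characteristics(groups: dict[str, np.ndarray],
                            pairwise_mode: str = "ranksum") -> KWResult:
    """Kruskal-Wallis across characteristic groups + pairwise Wilcoxon.

    Pairwise tests are two-sided rank-sum tests by default (``'signed_rank'``
    pairs matched values instead); p-values are multiplied by the number of
    comparisons and capped at 1.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValidationError("need at least 2 groups")
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    for n, a in zip(names, arrays):
        if len(a) < 2:
            raise ValidationError(f"group {n!r} has fewer than 2 values")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied across all groups; H undefined, p = 1")
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*arrays)
    df = len(names) - 1
    n_comp = df * (df + 1) // 2          # = C(len(names), 2)
    pw = pd.DataFrame(np.ones((len(names), len(names))), index=names,
                      columns=names)
    for a, b in itertools.combinations(range(len(names)), 2):
        x, y = arrays[a], arrays[b]
        if np.all(np.concatenate([x, y]) == x[0]):
            raw = 1.0
        elif pairwise_mode == "ranksum":
            raw = stats.ranksums(x, y).pvalue
        elif pairwise_mode == "signed_rank":
            m = min(len(x), len(y))
            d = x[:m] - y[:m]
            raw = 1.0 if np.all(d == 0) else stats.wilcoxon(x[:m], y[:m]).pvalue
        else:
            raise ValidationError(f"unknown pairwise_mode {pairwise_mode!r}")
        adj = min(raw * n_comp, 1.0)
        pw.iloc[a, b] = pw.iloc[b, a] = adj
    np.fill_diagonal(pw.values, np.nan)
    return KWResult(h=float(h), df=df, p=float(p), groups=names, pairwise=pw)


def rank_characteristics(var_table: pd.DataFrame) -> pd.DataFrame:
    """Characteristics ordered by mean variability across populations.

    Ties share a rank (dense ranking); stable order by characteristic name
    within ties. The least and most variable characteristics are flagged.
    """
    means = (var_table.groupby("characteristic")["var"].mean()
             .rename("mean_var").reset_index()
             .sort_values(["mean_var", "characteristic"],
                          kind="stable", ignore_index=True))
    means["rank"] = means["mean_var"].rank(method="dense").astype(int)
    means["flag"] = ""
    means.loc[means["rank"] == means["rank"].min(), "flag"] = "least_variable"
    means.loc[means["rank"] == means["rank"].max(), "flag"] = "most_variable"
    return means
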