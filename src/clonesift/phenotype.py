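"""Morphometric and colony-assay computations.

Cross-species morphometric comparisons rescale each trait within each
species linearly to [0, 1] before a covariance-based PCA, so that caste
separation (queen-like versus worker-like trait combinations) rather
than absolute size drives the leading components. Size matching removes
extreme individuals iteratively until group means no longer differ,
allowing caste-morphology contrasts at matched body size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


def normalize_traits(
    table: pd.DataFrame,
    trait_cols: Sequence[str],
    species_col: str = "species",
) -> pd.DataFrame:
    """Linearly scale each trait within each species to range [0, 1].

    The species minimum maps to 0 and the maximum to 1. A trait constant
    within a species is set to 0 with a warning.
    """
    out = table.copy()
    for _, idx in out.groupby(species_col).groups.items():
        for trait in trait_cols:
            vals = out.loc[idx, trait].astype(float)
            lo, hi = vals.min(), vals.max()
            if hi == lo:
                warnings.warn(
                    f"trait {trait!r} constant within a species; set to 0",
                    stacklevel=2,
                )
                out.loc[idx, trait] = 0.0
            else:
                out.loc[idx, trait] = (vals - lo) / (hi - lo)
    return out


@dataclass
class SizeMatchResult:
    excluded_a: list[int]  # positional indices into the input arrays
    excluded_b: list[int]
    matched_a: np.ndarray
    matched_b: np.ndarray
    p_value: float
    n_steps: int


def _mean_test(a: np.ndarray, b: np.ndarray, test: str) -> float:
    if test == "welch":
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    if test == "wilcoxon":
        return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    raise ValueError("test must be 'welch' or 'wilcoxon'")


def size_match(
    lengths_a: Sequence[float],
    lengths_b: Sequence[float],
    alpha: float = 0.05,
    test: str = "welch",
) -> SizeMatchResult:
    """Iteratively exclude extremes until group means are not different.

    One individual is removed per step: the group whose mean deviates
    more from the pooled mean loses its extreme (its largest value if
    its mean is above the pooled mean, its smallest otherwise). Ties
    alternate, starting with the larger-mean group. Stops as soon as the
    two-sample test p-value reaches ``alpha``.
    """
    a = np.asarray(lengths_a, dtype=float)
    b = np.asarray(lengths_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 individuals")
    keep_a = list(range(len(a)))
    keep_b = list(range(len(b)))
    excluded_a: list[int] = []
    excluded_b: list[int] = []
    steps = 0
    tie_to_a = None  # resolved at first tie: larger-mean group goes first
    while True:
        va, vb = a[keep_a], b[keep_b]
        p = _mean_test(va, vb, test)
        if p >= alpha:
            return SizeMatchResult(excluded_a, excluded_b, va, vb, p, steps)
        if len(keep_a) <= 3 or len(keep_b) <= 3:
            raise ValueError(
                "groups exhausted before means matched "
                f"(p={p:.3g} with {len(keep_a)} vs {len(keep_b)} left)"
            )
        pooled = np.concatenate([va, vb]).mean()
        dev_a, dev_b = abs(va.mean() - pooled), abs(vb.mean() - pooled)
        if np.isclose(dev_a, dev_b):
            if tie_to_a is None:
                tie_to_a = va.mean() >= vb.mean()
            target_a = tie_to_a
            tie_to_a = not tie_to_a
        else:
            target_a = dev_a > dev_b
        if target_a:
            vals, keep, excl = va, keep_a, excluded_a
        else:
            vals, keep, excl = vb, keep_b, excluded_b
        extreme = int(np.argmax(vals)) if vals.mean() >= pooled else int(np.argmin(vals))
        excl.append(keep.pop(extreme))
        steps += 1


def percent_mean_difference(
    group_a: Sequence[float], group_b: Sequence[float], decimals: int = 1
) -> float:
    """Percent by which group_a's mean exceeds group_b's: 100 (ma/mb - 1)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if b.mean() == 0:
        raise ValueError("reference group mean is zero")
    return round(100.0 * (a.mean() / b.mean() - 1.0), decimals)


@dataclass
class PCAResult:
    scores: np.ndarray  # individuals x components
    loadings: np.ndarray  # traits x components
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    mean: np.ndarray


def pca_project(
    table: pd.DataFrame, trait_cols: Sequence[str], n_components: int | None = None
) -> PCAResult:
    """Covariance-based PCA of (already normalized) trait columns.

    No re-standardization is applied: the [0, 1] normalization already
    equalizes trait ranges, so components reflect covariance structure.
    """
    X = table[list(trait_cols)].to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 individuals")
    if np.isnan(X).any():
        raise ValueError("missing values in trait columns")
    from sklearn.decomposition import PCA

    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return PCAResult(
        scores=scores,
        loadings=pca.components_.T,
        explained_variance=pca.explained_variance_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        mean=pca.mean_,
    )


def raid_summary(table: pd.DataFrame, n_colonies: int | None = None) -> pd.DataFrame:
    """Per-scout-genotype raid summaries across colonies.

    Expects columns ``colony``, ``scout_genotype``, ``n_participants``
    (one row per raid). ``n_colonies`` defaults to the number of
    distinct colonies in the table; pass it explicitly when some
    colonies initiated no raids. Returns, per scout genotype: total
    raids, mean raids initiated per colony, and mean participants per
    raid.
    """
    if n_colonies is None:
        n_colonies = table["colony"].nunique()
    if n_colonies < 1:
        raise ValueError("need at least one colony")
    raids = table.dropna(subset=["scout_genotype"])
    rows = []
    for genotype, grp in raids.groupby("scout_genotype", sort=False):
        rows.append({
            "scout_genotype": genotype,
            "n_raids": len(grp),
            "raids_per_colony": len(grp) / n_colonies,
            "mean_participants": float(grp["n_participants"].mean())
            if "n_participants" in grp else float("nan"),
        })
    return pd.DataFrame(rows, columns=["scout_genotype", "n_raids",
                                       "raids_per_colony", "mean_participants"])


def participant_fraction(
    table: pd.DataFrame, genotype: str, count_col: str, total_col: str
) -> float:
    """Mean per-raid fraction of participants of one genotype."""
    frac = table[count_col] / table[total_col]
    if ((frac < 0) | (frac > 1)).any():
        raise ValueError("participant fractions outside [0, 1]")
    return float(frac.mean())
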