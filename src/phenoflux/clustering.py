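"""Genotype grouping by similarity of the diurnal transpiration pattern.

Per-plant medians of the 23 transpiration variables are averaged per
genotype and z-scaled per variable; genotypes are then agglomerated
(average linkage) on the mean absolute difference of scaled variables and
the tree is cut into two transpiration phenotype groups.  Group A is, by
convention, the water-saving group: the cluster with the lower mean 24-h
transpiration per unit mass (relTransp_dayNight).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import pdist, squareform
from scipy import stats

from .transpiration import TRAITS


@dataclass
class GenotypeVariableMatrix:
    """Genotype × variable matrix of means, with its z-scaling parameters."""

    scaled: pd.DataFrame    # z-scaled genotype means
    means: pd.Series        # per-variable scaling mean
    sds: pd.Series          # per-variable scaling sd

    @property
    def genotypes(self) -> list[str]:
        return list(self.scaled.index)


@dataclass
class SimilarityTree:
    linkage_matrix: np.ndarray
    genotypes: list[str]
    metric: str
    group_labels: dict[str, str]  # genotype -> "A" | "B"

    def to_newick(self) -> str:
        """Newick serialization with merge-height branch lengths."""
        root = to_tree(self.linkage_matrix)

        def walk(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.genotypes[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(root, root.dist) + ";"


def build_matrix(
    plant_summaries: pd.DataFrame,
    variables: list[str] | None = None,
    reference_genotype: str | None = None,
    reference_sub_experiment: str | None = None,
) -> GenotypeVariableMatrix:
    """Genotype means of per-plant variable medians, column z-scaled.

    To avoid flooding the analysis with reference-cultivar replicates from
    every batch, the reference genotype can be restricted to a single
    designated sub-experiment (default: its first, in sorted order) when the
    table carries a ``sub_experiment`` column.
    """
    df = plant_summaries.copy()
    if variables is None:
        variables = [c for c in TRAITS if c in df.columns]
    if not variables:
        raise ValueError("no transpiration variables found in plant summaries")
    if reference_genotype is not None and "sub_experiment" in df.columns:
        is_ref = df["genotype"] == reference_genotype
        if is_ref.any():
            subs = sorted(df.loc[is_ref, "sub_experiment"].unique())
            keep_sub = reference_sub_experiment or subs[0]
            df = df[~is_ref | (df["sub_experiment"] == keep_sub)]
    counts = df.groupby("genotype").size()
    for geno, n in counts.items():
        if n < 2:
            import warnings

            warnings.warn(f"genotype {geno!r} has only {n} plant(s)", stacklevel=2)
    means = df.groupby("genotype")[variables].mean()
    mu = means.mean(axis=0)
    sd = means.std(axis=0, ddof=1)
    nonzero = sd.replace(0.0, np.nan)
    scaled = (means - mu) / nonzero
    scaled = scaled.dropna(axis=1, how="all")
    return GenotypeVariableMatrix(scaled=scaled, means=mu, sds=sd)


def similarity_tree(
    matrix: GenotypeVariableMatrix,
    metric: str = "mean_abs",
    daily_total_variable: str = "relTransp_dayNight",
) -> SimilarityTree:
    """Average-linkage tree on genotype phenotypic distances, cut at 2 groups.

    ``metric`` is ``mean_abs`` (mean absolute difference of scaled variables)
    or ``euclidean``.  Ties in merge order are broken deterministically by
    the sorted genotype order of the input.
    """
    X = matrix.scaled.sort_index()
    genotypes = list(X.index)
    if len(genotypes) < 3:
        raise ValueError("need at least 3 genotypes")
    if X.shape[1] == 0:
        raise ValueError("all genotypes identical: two-group cut is undefined")
    if metric == "mean_abs":
        dist = pdist(X.to_numpy(), metric="cityblock") / X.shape[1]
    elif metric == "euclidean":
        dist = pdist(X.to_numpy(), metric="euclidean")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    if np.all(dist == 0):
        raise ValueError("all genotypes identical: two-group cut is undefined")
    Z = linkage(dist, method="average")
    cut = fcluster(Z, t=2, criterion="maxclust")
    if len(set(cut)) < 2:
        raise ValueError("tree cut did not produce two non-empty groups")
    # name the water-saving (lower daily total) cluster "A"
    if daily_total_variable in X.columns:
        key = X[daily_total_variable].to_numpy()
    else:
        key = X.mean(axis=1).to_numpy()
    mean1 = key[cut == 1].mean()
    mean2 = key[cut == 2].mean()
    a_cluster = 1 if mean1 <= mean2 else 2
    labels = {g: ("A" if c == a_cluster else "B") for g, c in zip(genotypes, cut)}
    return SimilarityTree(
        linkage_matrix=Z, genotypes=genotypes, metric=metric, group_labels=labels
    )


def pairwise_distance_frame(matrix: GenotypeVariableMatrix, metric: str = "mean_abs") -> pd.DataFrame:
    X = matrix.scaled.sort_index()
    if metric == "mean_abs":
        d = pdist(X.to_numpy(), metric="cityblock") / X.shape[1]
    else:
        d = pdist(X.to_numpy(), metric=metric)
    return pd.DataFrame(squareform(d), index=X.index, columns=X.index)


def _tier(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.05:
        return "*"
    return "nS"


def test_variable_separation(
    plant_level_vars: pd.DataFrame,
    group_labels: dict[str, str],
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Plant-level two-sample tests of each variable between the two groups.

    Every plant inherits its genotype's group; Welch t-tests per variable
    with tiers *** (p < 0.001), * (p < 0.05), nS otherwise.
    """
    df = plant_level_vars.copy()
    df["group"] = df["genotype"].map(group_labels)
    if df["group"].isna().any():
        missing = sorted(df.loc[df["group"].isna(), "genotype"].unique())
        raise ValueError(f"genotypes without a group label: {missing}")
    if variables is None:
        variables = [c for c in TRAITS if c in df.columns]
    rows = []
    for grp in ("A", "B"):
        if (df["group"] == grp).sum() < 2:
            raise ValueError(f"group {grp} has fewer than 2 plants")
    a = df[df["group"] == "A"]
    b = df[df["group"] == "B"]
    for var in variables:
        x = a[var].dropna().to_numpy()
        y = b[var].dropna().to_numpy()
        if x.size < 2 or y.size < 2:
            p, delta = np.nan, np.nan
        else:
            p = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
            delta = float(np.mean(y) - np.mean(x))  # group B minus group A
        rows.append(
            {"variable": var, "p_value": p,
             "tier": _tier(p) if np.isfinite(p) else "nS",
             "delta_B_minus_A": delta}
        )
    return pd.DataFrame(rows)
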