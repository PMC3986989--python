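"""Between-zone comparison statistics and metal clustering.

Two tools support the spatial analysis: a one-way ANOVA comparing a
quantity (concentration, index value, per-sample RI) across the transect
zones, and agglomerative hierarchical clustering of the metals to group
probable sources.  Clustering uses correlation distance (1 - Pearson r
between metal columns) with average linkage by default, so metals that
co-vary across samples — the signature of a shared source — merge at low
height.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .datamodel import METALS, ParameterError, ValidationError


@dataclass
class AnovaResult:
    metal: str
    F: float
    p: float
    significant_at_0_05: bool
    degenerate: bool = False


@dataclass
class Dendrogram:
    """Merge sequence of an agglomerative clustering.

    ``merges`` lists (cluster_a, cluster_b, height, size) rows in scipy
    linkage convention: leaves are 0..n-1 in ``labels`` order, merge i
    creates cluster n+i.
    """

    labels: list[str]
    merges: list[tuple[int, int, float, int]]
    method: str = "average"
    metric: str = "correlation"

    @property
    def linkage_matrix(self) -> np.ndarray:
        return np.array(self.merges, dtype=float)

    def cut(self, k: int) -> dict[str, int]:
        """Assign each leaf to one of ``k`` flat clusters (1..k)."""
        assign = hierarchy.fcluster(self.linkage_matrix, k,
                                    criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assign)))

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage_matrix)

        def rec(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            length = node.dist
            kids = ",".join(
                f"{rec(ch)}:{max(length - ch.dist, 0.0):.6g}"
                for ch in (node.left, node.right))
            return f"({kids})"

        return rec(tree) + ";"


def oneway_anova(groups: list[np.ndarray | list[float]],
                 metal: str = "") -> AnovaResult:
    """Classical one-way ANOVA across groups.

    F = MSB/MSW with (k-1, N-k) degrees of freedom.  Zero within-group
    variance with a nonzero between-group component yields an infinite-F
    sentinel with p = 0; completely constant data is undefined and
    returned flagged with NaN statistics.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValidationError("ANOVA needs at least two groups")
    for g in arrays:
        if g.size < 2:
            raise ValidationError("each ANOVA group needs >= 2 observations")
        if not np.isfinite(g).all():
            raise ValidationError("non-finite observation in ANOVA group")

    allv = np.concatenate(arrays)
    means = np.array([g.mean() for g in arrays])
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in arrays))
    ssb = float(sum(g.size * (m - allv.mean()) ** 2
                    for g, m in zip(arrays, means)))
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(metal, float("nan"), float("nan"), False,
                               degenerate=True)
        return AnovaResult(metal, float("inf"), 0.0, True)

    F, p = stats.f_oneway(*arrays)
    return AnovaResult(metal, float(F), float(p), bool(p < 0.05))


def anova_by_zone(samples: pd.DataFrame, value_columns: list[str]
                  | None = None, contrast: str = "omnibus") -> pd.DataFrame:
    """Per-site, per-metal one-way ANOVA of concentrations across zones.

    ``contrast="omnibus"`` compares all zones; ``"row_vs_far"`` pools the
    right-of-way zones (trench, working, piling) against the 50 m plots.

    Returns columns ``site, metal, F, p, significant_at_0_05, degenerate``.
    """
    cols = value_columns or list(METALS)
    rows = []
    for site, df in samples.groupby("site", sort=True):
        for col in cols:
            if contrast == "omnibus":
                groups = [g[col].to_numpy() for _, g in df.groupby("zone")
                          if len(g) >= 2]
            elif contrast == "row_vs_far":
                row_zones = df[df["zone"].isin(["trench", "working",
                                                "piling"])]
                far = df[df["zone"].isin(["d50_side1", "d50_side2"])]
                groups = [row_zones[col].to_numpy(), far[col].to_numpy()]
            else:
                raise ParameterError(
                    f"unknown contrast {contrast!r}; "
                    "expected 'omnibus' or 'row_vs_far'")
            res = oneway_anova(groups, metal=col)
            rows.append({"site": site, "metal": col, "F": res.F, "p": res.p,
                         "significant_at_0_05": res.significant_at_0_05,
                         "degenerate": res.degenerate})
    return pd.DataFrame(rows)


def metal_clustering(matrix: pd.DataFrame, metric: str = "correlation",
                     method: str = "average") -> Dendrogram:
    """Hierarchically cluster metal columns of a samples x metals matrix.

    metric ``"correlation"`` (default) uses 1 - Pearson r between
    columns; ``"sqeuclidean_z"`` uses squared Euclidean distance on
    z-scored columns.  Columns are processed in canonical metal order for
    deterministic tie-breaking.
    """
    cols = [m for m in METALS if m in matrix.columns]
    cols += [c for c in matrix.columns if c not in cols]
    X = matrix[cols].to_numpy(dtype=float)
    n_samples, n_vars = X.shape
    if n_vars < 2:
        raise ValidationError("clustering needs at least two metals")
    if n_samples < 3:
        raise ValidationError("clustering needs at least three samples")
    sd = X.std(axis=0)
    for j, s in enumerate(sd):
        if s == 0:
            raise ValidationError(
                f"metal {cols[j]} is constant across samples")

    if metric == "correlation":
        corr = np.corrcoef(X, rowvar=False)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
        condensed = squareform(dist, checks=False)
    elif metric == "sqeuclidean_z":
        Z = (X - X.mean(axis=0)) / sd
        from scipy.spatial.distance import pdist
        condensed = pdist(Z.T, metric="sqeuclidean")
    else:
        raise ParameterError(
            f"unknown clustering metric {metric!r}; "
            "expected 'correlation' or 'sqeuclidean_z'")

    if method not in ("average", "complete", "ward"):
        raise ParameterError(
            f"unknown linkage method {method!r}; "
            "expected 'average', 'complete' or 'ward'")
    Zl = hierarchy.linkage(condensed, method=method)
    merges = [(int(a), int(b), float(h), int(s)) for a, b, h, s in Zl]
    return Dendrogram(labels=list(cols), merges=merges, method=method,
                      metric=metric)
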