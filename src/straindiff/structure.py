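"""Sample-structure QC: PCA variance decomposition and strain dendrograms.

PCA is covariance-matrix PCA of samples over gene-centered log2-CPM
(prcomp-style).  Each leading component is associated with the design
factors (region, strain, sex, batch) by one-way ANOVA with an eta-squared
effect size and Bonferroni-corrected flags; a variance-share summary
weights eta-squared by each component's explained-variance fraction, so
"~40% of variance associated with region" style statements are
computable.

Strain relatedness is summarised by the Manhattan distance of absolute
log2 fold changes between each strain pair (equal weight to every gene,
unlike Euclidean distance which would further up-weight large changes),
followed by agglomerative clustering into a dendrogram serialisable to
newick.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, TransformerMixin


@dataclass
class PCAResult:
    scores: pd.DataFrame                # samples x components
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame | None = None  # genes x components

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


class ExpressionPCA(BaseEstimator, TransformerMixin):
    """prcomp-style PCA of samples over genes.

    ``fit`` takes a genes x samples log2-CPM DataFrame, centers each
    gene, and decomposes the sample covariance by SVD.  Scores are
    sample projections; explained-variance ratios use the 1/(n-1)
    covariance convention.
    """

    def __init__(self, n_components: int | None = None, center: bool = True):
        self.n_components = n_components
        self.center = center

    def fit(self, logcpm: pd.DataFrame, y=None):
        if logcpm.shape[1] < 2:
            raise ValueError("PCA needs at least 2 samples")
        x = logcpm.to_numpy(dtype=float).T  # samples x genes
        self.mean_ = x.mean(axis=0) if self.center else np.zeros(x.shape[1])
        xc = x - self.mean_
        u, s, vt = np.linalg.svd(xc, full_matrices=False)
        n = x.shape[0]
        var = s**2 / (n - 1)
        total = var.sum()
        k = self.n_components or len(s)
        k = min(k, len(s))
        self.singular_values_ = s[:k]
        self.components_ = vt[:k]
        self.explained_variance_ = var[:k]
        self.explained_variance_ratio_ = var[:k] / total if total > 0 else var[:k]
        self._scores = u[:, :k] * s[:k]
        self._sample_ids = logcpm.columns
        self._gene_ids = logcpm.index
        return self

    def transform(self, logcpm: pd.DataFrame) -> pd.DataFrame:
        x = logcpm.to_numpy(dtype=float).T - self.mean_
        scores = x @ self.components_.T
        return pd.DataFrame(
            scores, index=logcpm.columns,
            columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
        )

    def result(self) -> PCAResult:
        k = len(self.singular_values_)
        cols = [f"PC{i + 1}" for i in range(k)]
        return PCAResult(
            scores=pd.DataFrame(self._scores, index=self._sample_ids, columns=cols),
            explained_variance_ratio=self.explained_variance_ratio_,
            loadings=pd.DataFrame(self.components_.T, index=self._gene_ids, columns=cols),
        )


def run_pca(
    logcpm: pd.DataFrame, center: bool = True, n_components: int | None = None,
) -> PCAResult:
    """Functional wrapper over :class:`ExpressionPCA`."""
    return ExpressionPCA(n_components=n_components, center=center).fit(logcpm).result()


def associate_factors(
    pca: PCAResult,
    samples: pd.DataFrame,
    factors: tuple[str, ...] = ("region", "strain", "sex", "batch"),
    n_components: int = 10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-way ANOVA of component scores on each categorical factor.

    For every (component, factor) cell: an F-test of score differences
    across factor levels, eta-squared (between-group share of score
    variance), and a significance flag Bonferroni-corrected across all
    cells.  Factors with a single level raise.
    """
    k = min(n_components, pca.n_components)
    cells = []
    scores = pca.scores
    meta = samples.loc[scores.index]
    factors = tuple(f for f in factors if f in meta.columns)
    n_cells = k * len(factors)
    for ci in range(k):
        comp = scores.iloc[:, ci]
        for f in factors:
            levels = meta[f].unique()
            if len(levels) < 2:
                raise ValueError(f"factor {f!r} has a single level")
            groups = [comp[meta[f] == lv].to_numpy() for lv in levels]
            fstat, p = stats.f_oneway(*groups)
            grand = comp.mean()
            ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
            ss_total = ((comp - grand) ** 2).sum()
            eta2 = ss_between / ss_total if ss_total > 0 else 0.0
            cells.append({
                "component": scores.columns[ci],
                "component_index": ci,
                "factor": f,
                "F": float(fstat),
                "p": float(p),
                "eta_squared": float(eta2),
                "explained_variance_ratio": float(pca.explained_variance_ratio[ci]),
                "significant": bool(p < alpha / n_cells),
            })
    return pd.DataFrame(cells)


def factor_variance_share(association: pd.DataFrame) -> pd.Series:
    """Total explained-variance share attributable to each factor:
    sum over components of (explained-variance ratio x eta-squared)."""
    assoc = association.copy()
    assoc["share"] = assoc["explained_variance_ratio"] * assoc["eta_squared"]
    return assoc.groupby("factor")["share"].sum()


# ---------------------------------------------------------------------------
# strain distances and dendrogram
# ---------------------------------------------------------------------------

@dataclass
class StrainDistanceMatrix:
    values: pd.DataFrame        # strains x strains
    region: str
    gene_universe: str          # 'all' or 'deg'

    @property
    def strains(self) -> list[str]:
        return list(self.values.index)

    def check_metric(self, atol: float = 1e-8) -> None:
        d = self.values.to_numpy()
        if not np.allclose(d, d.T, atol=atol):
            raise AssertionError("distance matrix not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=atol):
            raise AssertionError("nonzero diagonal")
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    if d[i, j] > d[i, k] + d[k, j] + atol:
                        raise AssertionError(
                            f"triangle inequality violated at ({i},{j},{k})"
                        )


def strain_distance_matrix(
    deg_table: pd.DataFrame,
    region: str | None = None,
    gene_universe: str = "all",
    strains: list[str] | None = None,
) -> StrainDistanceMatrix:
    """Manhattan distance of absolute log2 fold change per strain pair.

    d(i, j) = sum over the gene universe of |log2FC(i vs j)|; with
    ``gene_universe='deg'`` the sum runs only over genes called DE in
    that pair's contrast.
    """
    tab = deg_table
    if region is not None and "region" in tab.columns:
        tab = tab[tab["region"] == region]
    if strains is None:
        from .consensus import _strains_from_contrasts
        strains = _strains_from_contrasts(tab)
    n = len(strains)
    d = np.zeros((n, n))
    for i, a in enumerate(strains):
        for j in range(i + 1, n):
            b = strains[j]
            sub = tab[tab["contrast"].isin([f"{a}_vs_{b}", f"{b}_vs_{a}"])]
            if not len(sub):
                raise KeyError(f"missing contrast between {a!r} and {b!r}")
            if gene_universe == "deg":
                sub = sub[sub["is_deg"]]
            val = float(sub["log2FC"].abs().sum())
            d[i, j] = d[j, i] = val
    return StrainDistanceMatrix(
        values=pd.DataFrame(d, index=strains, columns=strains),
        region=region or "all",
        gene_universe=gene_universe,
    )


@dataclass
class Dendrogram:
    linkage_matrix: np.ndarray
    labels: list[str]

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def cophenetic(self) -> pd.DataFrame:
        coph = squareform(hierarchy.cophenet(self.linkage_matrix))
        return pd.DataFrame(coph, index=self.labels, columns=self.labels)

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage_matrix)

        def recurse(node, parent_height: float) -> str:
            length = parent_height - (node.dist if not node.is_leaf() else 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = recurse(node.left, node.dist)
            right = recurse(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return recurse(tree, tree.dist).rsplit(":", 1)[0] + ";"


def hierarchical_cluster(
    dist: StrainDistanceMatrix, linkage: str = "average",
) -> Dendrogram:
    """Agglomerative clustering of the strain distance matrix."""
    d = dist.values.to_numpy()
    if not np.isfinite(d).all():
        raise ValueError("non-finite distances")
    condensed = squareform(d, checks=False)
    z = hierarchy.linkage(condensed, method=linkage)
    return Dendrogram(linkage_matrix=z, labels=dist.strains)
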