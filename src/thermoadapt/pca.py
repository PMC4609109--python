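"""Principal component analysis of expression profiles.

Arrays (or replicate-averaged profiles) are the observations and genes the
variables, so the components capture expression-level variance *between
culturing conditions*.  Covariance PCA (gene-wise centering, no unit-variance
scaling) is used: it preserves the magnitude structure that makes the leading
component track growth rate.

The sign of each component is fixed so that the largest-magnitude loading is
positive, which makes results reproducible across linear-algebra backends.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, floor

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA as _SKPCA

__all__ = ["PCAResult", "ExpressionPCA", "run_pca", "top_loaded_genes",
           "pc_growth_correlation"]


@dataclass
class PCAResult:
    """Scores, loadings and variance fractions of a fitted PCA."""

    scores: pd.DataFrame            # observations x components
    loadings: pd.DataFrame          # genes x components
    variance_fraction: pd.Series    # per component, sums to <= 1


class ExpressionPCA(BaseEstimator, TransformerMixin):
    """PCA over expression columns with a deterministic sign convention.

    Parameters
    ----------
    n_components : int or None
        Number of components to keep; ``None`` keeps the full decomposition.
    center : bool
        Gene-wise centering (default).  Disabling it decomposes raw
        second moments instead of the covariance.

    Attributes (after :meth:`fit`)
    ------------------------------
    loadings_ : genes x components DataFrame with orthonormal columns
    scores_ : observations x components DataFrame
    variance_fraction_ : per-component fraction of total variance
    result_ : :class:`PCAResult` bundling the three
    """

    def __init__(self, n_components: int | None = None, center: bool = True):
        self.n_components = n_components
        self.center = center

    def fit(self, matrix: pd.DataFrame) -> "ExpressionPCA":
        """Fit on a genes x observations DataFrame (matrix or profile set)."""
        if matrix.shape[1] < 2:
            raise ValueError("need at least 2 columns (observations) for PCA")
        n_obs, n_genes = matrix.shape[1], matrix.shape[0]
        max_k = min(n_obs, n_genes)
        k = self.n_components if self.n_components is not None else max_k
        if k > max_k:
            raise ValueError(f"n_components={k} exceeds min(genes, columns)={max_k}")
        X = matrix.to_numpy().T  # observations x genes
        if self.center:
            self._mean = X.mean(axis=0)
            pca = _SKPCA(n_components=k, svd_solver="full")
            scores = pca.fit_transform(X)
            components = pca.components_          # k x genes
            frac = pca.explained_variance_ratio_
        else:
            self._mean = np.zeros(X.shape[1])
            u, s, vt = np.linalg.svd(X, full_matrices=False)
            u, s, vt = u[:, :k], s[:k], vt[:k]
            scores = u * s
            components = vt
            total = float(np.sum(X**2))
            frac = (s**2) / total if total > 0 else np.zeros(k)
        # sign convention: largest-|loading| entry positive per component
        flip = np.sign(components[np.arange(components.shape[0]),
                                  np.argmax(np.abs(components), axis=1)])
        flip[flip == 0] = 1.0
        components = components * flip[:, None]
        scores = scores * flip[None, :]
        names = [f"PC{i + 1}" for i in range(components.shape[0])]
        self.loadings_ = pd.DataFrame(components.T, index=matrix.index, columns=names)
        self.scores_ = pd.DataFrame(scores, index=matrix.columns, columns=names)
        self.variance_fraction_ = pd.Series(frac, index=names, name="variance_fraction")
        self.result_ = PCAResult(self.scores_, self.loadings_, self.variance_fraction_)
        return self

    def transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        """Project new genes x observations columns onto the fitted components."""
        if not hasattr(self, "loadings_"):
            raise ValueError("ExpressionPCA is not fitted yet")
        X = matrix.to_numpy().T - self._mean
        scores = X @ self.loadings_.to_numpy()
        return pd.DataFrame(scores, index=matrix.columns, columns=self.loadings_.columns)


def run_pca(matrix: pd.DataFrame, n_components: int | None = None,
            center: bool = True) -> PCAResult:
    """Fit :class:`ExpressionPCA` and return its :class:`PCAResult`."""
    return ExpressionPCA(n_components=n_components, center=center).fit(matrix).result_


def top_loaded_genes(pca: PCAResult, component: str,
                     tail_fraction: float = 0.05) -> list[str]:
    """Genes with the most extreme loadings on one component.

    Takes the union of the ceil(alpha*N) most positively and the
    floor(alpha*N) most negatively loaded genes.  For N = 4383 genes at
    alpha = 0.05 this is 220 + 219 = 439 genes per component.  Ties are
    broken by gene-id order, so the selection is deterministic.
    """
    if not (0.0 < tail_fraction < 0.5):
        raise ValueError("tail_fraction must be in (0, 0.5)")
    if component not in pca.loadings.columns:
        raise KeyError(f"unknown component {component!r}")
    load = pca.loadings[component]
    n = len(load)
    n_pos = ceil(tail_fraction * n)
    n_neg = floor(tail_fraction * n)
    order = pd.DataFrame({"loading": load, "gene": load.index.astype(str)})
    descending = order.sort_values(["loading", "gene"], ascending=[False, True])
    ascending = order.sort_values(["loading", "gene"], ascending=[True, True])
    top = list(descending.index[:n_pos])
    bottom = list(ascending.index[:n_neg])
    selected = top + [g for g in bottom if g not in set(top)]
    return selected


def pc_growth_correlation(pca: PCAResult, meta: pd.DataFrame,
                          component: str = "PC1") -> float:
    """Pearson correlation between component scores and growth rates.

    ``meta`` must provide a growth rate for every scored observation
    (matched on ``sample_id``); missing rates raise an error listing the
    offending samples.
    """
    if component not in pca.scores.columns:
        raise KeyError(f"unknown component {component!r}")
    rates = meta.set_index("sample_id")["growth_rate"] if "sample_id" in meta.columns \
        else meta["growth_rate"]
    missing = [s for s in pca.scores.index
               if s not in rates.index or pd.isna(rates.loc[s])]
    if missing:
        raise ValueError(f"samples without growth rates: {missing}")
    aligned = rates.loc[pca.scores.index].astype(float)
    if aligned.std() == 0 or pca.scores[component].std() == 0:
        raise ValueError("zero variance in scores or growth rates; correlation undefined")
    return float(pearsonr(pca.scores[component].to_numpy(), aligned.to_numpy()).statistic)
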