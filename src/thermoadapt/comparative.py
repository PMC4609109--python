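"""Profile-level comparisons: correlations, condition dendrogram, contrasts.

Profiles are replicate-averaged log-expression columns labeled
``<strain>_<condition>`` (see :func:`thermoadapt.core.average_replicates`).
The standard contrasts of the analysis are expressed as differences between
profiles:

* ``dG(s)``   = s_r - Anc_r          (genotype-mediated change)
* ``dHS_A``   = Anc_hs - Anc_r       (heat-shock-induced change, ancestor)
* ``dT(s)``   = s_e - s_r            (growth-temperature-mediated change)
* ``dGHS(s)`` = s_hs - Anc_r         (simultaneous change)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr, spearmanr
from sklearn.base import BaseEstimator

__all__ = [
    "DeltaProfile",
    "profile_correlation",
    "correlation_matrix",
    "ProfileDendrogram",
    "cluster_profiles",
    "make_delta",
    "standard_contrasts",
    "geneset_delta_summary",
]


@dataclass
class DeltaProfile:
    """A per-gene expression-change vector between two profiles."""

    values: pd.Series
    label: str
    minuend: str
    subtrahend: str

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def __len__(self) -> int:
        return len(self.values)


def _delta_values(delta) -> pd.Series:
    return delta.values if isinstance(delta, DeltaProfile) else pd.Series(delta)


def _check_label(profiles: pd.DataFrame, label: str) -> None:
    if label not in profiles.columns:
        raise KeyError(f"unknown profile label {label!r}; have {list(profiles.columns)}")


def profile_correlation(profiles: pd.DataFrame, a: str, b: str,
                        method: str = "pearson") -> float:
    """Correlation between two profile columns (Pearson by default)."""
    _check_label(profiles, a)
    _check_label(profiles, b)
    if len(profiles) < 3:
        raise ValueError("need at least 3 genes for a correlation")
    x = profiles[a].to_numpy()
    y = profiles[b].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError(f"zero-variance profile among ({a!r}, {b!r}); correlation undefined")
    if method == "pearson":
        return float(pearsonr(x, y).statistic)
    if method == "spearman":
        return float(spearmanr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def correlation_matrix(profiles: pd.DataFrame, method: str = "pearson") -> pd.DataFrame:
    """Symmetric profile-profile correlation matrix with unit diagonal."""
    if profiles.shape[1] < 2:
        raise ValueError("need at least 2 profiles")
    if (profiles.std(axis=0) == 0).any():
        bad = list(profiles.columns[profiles.std(axis=0) == 0])
        raise ValueError(f"zero-variance profiles: {bad}")
    corr = profiles.corr(method=method)
    np.fill_diagonal(corr.values, 1.0)
    return corr


class ProfileDendrogram(BaseEstimator):
    """Agglomerative clustering of expression profiles.

    Parameters
    ----------
    distance : {"pearson", "spearman", "euclidean"}
        ``"pearson"`` (default) uses 1 - Pearson correlation between
        profiles, matching log-scale expression comparisons.
    linkage : str
        Any scipy linkage method; ``"average"`` by default.

    Attributes (after :meth:`fit`)
    ------------------------------
    labels_ : list of profile labels (leaf names)
    linkage_ : scipy linkage matrix
    tree_ : scipy ClusterNode root of the merge tree
    """

    def __init__(self, distance: str = "pearson", linkage: str = "average"):
        self.distance = distance
        self.linkage = linkage

    def fit(self, profiles: pd.DataFrame) -> "ProfileDendrogram":
        if profiles.shape[1] < 2:
            raise ValueError("need at least 2 profiles to cluster")
        if self.distance in ("pearson", "spearman"):
            corr = correlation_matrix(profiles, method=self.distance)
            dist = 1.0 - corr.to_numpy()
            np.fill_diagonal(dist, 0.0)
            dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
            condensed = squareform(dist, checks=False)
        elif self.distance == "euclidean":
            from scipy.spatial.distance import pdist

            condensed = pdist(profiles.to_numpy().T)
        else:
            raise ValueError(f"unknown distance {self.distance!r}")
        valid = [m for m in ("single", "complete", "average", "weighted",
                             "centroid", "median", "ward")]
        if self.linkage not in valid:
            raise ValueError(f"unknown linkage {self.linkage!r}; choose from {valid}")
        self.labels_ = list(profiles.columns)
        self.linkage_ = hierarchy.linkage(condensed, method=self.linkage)
        self.tree_ = hierarchy.to_tree(self.linkage_)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "tree_"):
            raise ValueError("ProfileDendrogram is not fitted yet")

    def to_newick(self) -> str:
        """Newick export with branch lengths from merge heights."""
        self._check_fitted()
        labels = self.labels_

        def walk(node) -> str:
            if node.is_leaf():
                return labels[node.id]
            left = walk(node.get_left())
            right = walk(node.get_right())
            bl_left = node.dist - node.get_left().dist
            bl_right = node.dist - node.get_right().dist
            return f"({left}:{bl_left:.10g},{right}:{bl_right:.10g})"

        return walk(self.tree_) + ";"

    def first_split(self) -> tuple[set[str], set[str]]:
        """The two clades separated by the root (the 'first split')."""
        self._check_fitted()

        def leaves(node) -> set[str]:
            return {self.labels_[i] for i in node.pre_order(lambda n: n.id)}

        return leaves(self.tree_.get_left()), leaves(self.tree_.get_right())


def cluster_profiles(profiles: pd.DataFrame, distance: str = "pearson",
                     linkage: str = "average") -> ProfileDendrogram:
    """Fit a :class:`ProfileDendrogram` on a profile set."""
    return ProfileDendrogram(distance=distance, linkage=linkage).fit(profiles)


def make_delta(profiles: pd.DataFrame, minuend: str, subtrahend: str,
               name: str | None = None) -> DeltaProfile:
    """Element-wise difference between two profiles, labeled by contrast."""
    _check_label(profiles, minuend)
    _check_label(profiles, subtrahend)
    label = name or f"{minuend}-{subtrahend}"
    return DeltaProfile(
        values=profiles[minuend] - profiles[subtrahend],
        label=label,
        minuend=minuend,
        subtrahend=subtrahend,
    )


def standard_contrasts(profiles: pd.DataFrame, strain: str,
                       ancestor: str = "Anc") -> dict[str, DeltaProfile]:
    """The named contrasts for one strain: dG, dHS_A, dT, dGHS.

    ``dT`` requires the strain's e-profile and is omitted if absent.
    """
    out = {
        "dG": make_delta(profiles, f"{strain}_r", f"{ancestor}_r", name=f"dG_{strain}"),
        "dHS_A": make_delta(profiles, f"{ancestor}_hs", f"{ancestor}_r", name="dHS_A"),
        "dGHS": make_delta(profiles, f"{strain}_hs", f"{ancestor}_r", name=f"dGHS_{strain}"),
    }
    if f"{strain}_e" in profiles.columns:
        out["dT"] = make_delta(profiles, f"{strain}_e", f"{strain}_r", name=f"dT_{strain}")
    return out


def geneset_delta_summary(delta, geneset) -> dict[str, float]:
    """Summary statistics of a delta profile restricted to a gene set.

    Used to check that e.g. the major heat-shock genes show equivalent
    induction across strains (hs contrasts) and return toward steady levels
    at evolved growth temperatures (dT contrasts).
    """
    values = _delta_values(delta)
    members = [g for g in geneset if g in values.index]
    if not members:
        raise ValueError("gene set has empty intersection with the delta profile")
    sub = values.loc[members]
    return {"mean": float(sub.mean()), "median": float(sub.median()), "n": len(members)}
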