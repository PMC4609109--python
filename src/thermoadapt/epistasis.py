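"""Negative-epistasis decomposition of transcriptional change.

For an evolved strain, the change under simultaneous genotype + heat-shock
perturbation (``dGHS = s_hs - Anc_r``) is regressed on the additive
prediction (``dG + dHS_A``).  An OLS slope below 1 means the simultaneous
change is systematically smaller than the sum of the parts; the magnitude of
this negative epistasis is reported as ``1 - slope``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress, pearsonr
from sklearn.base import BaseEstimator

from .comparative import DeltaProfile, make_delta

__all__ = [
    "EpistasisResult",
    "epistasis_contrasts",
    "delta_association",
    "EpistasisRegression",
    "epistasis_regression",
    "responsiveness_alignment",
]


@dataclass
class EpistasisResult:
    """Per-strain epistasis regression summary.

    ``magnitude`` is exactly ``1 - slope``; positive values indicate
    negative epistasis (mutual cancellation of the two perturbations).
    In results from :func:`strain_epistasis`, ``pearson_r``/``r_pvalue``
    describe the association between the two perturbation contrasts
    (dHS_A vs dG); from a bare :func:`epistasis_regression` they describe
    the regression fit itself.
    """

    strain: str
    n_genes: int
    pearson_r: float
    r_pvalue: float
    slope: float
    intercept: float
    magnitude: float
    subset: str = "all"


def _values(delta) -> pd.Series:
    return delta.values if isinstance(delta, DeltaProfile) else pd.Series(delta)


def epistasis_contrasts(profiles: pd.DataFrame, strain: str,
                        ancestor: str = "Anc") -> dict[str, DeltaProfile]:
    """The four vectors of the epistasis analysis for one strain.

    Returns ``dG`` (genotype-mediated), ``dHS_A`` (heat-shock-induced in the
    ancestor), ``additive`` (their sum) and ``simultaneous``
    (strain_hs - ancestor_r).
    """
    for label in (f"{ancestor}_r", f"{ancestor}_hs", f"{strain}_r", f"{strain}_hs"):
        if label not in profiles.columns:
            raise KeyError(f"missing profile {label!r} for epistasis contrasts")
    dg = make_delta(profiles, f"{strain}_r", f"{ancestor}_r", name=f"dG_{strain}")
    dhs = make_delta(profiles, f"{ancestor}_hs", f"{ancestor}_r", name="dHS_A")
    additive = DeltaProfile(values=dg.values + dhs.values,
                            label=f"additive_{strain}",
                            minuend=f"{strain}_r+{ancestor}_hs",
                            subtrahend=f"2x{ancestor}_r")
    simultaneous = make_delta(profiles, f"{strain}_hs", f"{ancestor}_r",
                              name=f"dGHS_{strain}")
    return {"dG": dg, "dHS_A": dhs, "additive": additive,
            "simultaneous": simultaneous}


def delta_association(x, y) -> dict[str, float]:
    """Pearson correlation between two delta profiles with a two-sided p.

    The p-value comes from the t-distribution with n - 2 degrees of freedom.
    """
    xv, yv = _values(x), _values(y)
    if len(xv) != len(yv) or not xv.index.equals(yv.index):
        raise ValueError("delta profiles must cover the same genes")
    if len(xv) < 3:
        raise ValueError("need at least 3 genes")
    if xv.std() == 0 or yv.std() == 0:
        raise ValueError("zero-variance delta; correlation undefined")
    res = pearsonr(xv.to_numpy(), yv.to_numpy())
    return {"r": float(res.statistic), "p": float(res.pvalue)}


class EpistasisRegression(BaseEstimator):
    """OLS of the simultaneous change on the additive change.

    Parameters
    ----------
    fit_intercept : bool
        Free intercept by default; ``False`` forces the fit through the
        origin.
    genes : sequence or None
        Optional gene subset (e.g. the union of top-loaded PC genes).

    Attributes (after :meth:`fit`)
    ------------------------------
    slope_, intercept_, magnitude_ (= 1 - slope), r_, p_, n_genes_, result_
    """

    def __init__(self, fit_intercept: bool = True, genes=None):
        self.fit_intercept = fit_intercept
        self.genes = genes

    def fit(self, additive, simultaneous, strain: str = "",
            subset_label: str | None = None) -> "EpistasisRegression":
        x, y = _values(additive), _values(simultaneous)
        if not x.index.equals(y.index):
            raise ValueError("additive and simultaneous must cover the same genes")
        label = subset_label or ("all" if self.genes is None else "custom")
        if self.genes is not None:
            keep = [g for g in self.genes if g in x.index]
            x, y = x.loc[keep], y.loc[keep]
        if len(x) < 3:
            raise ValueError("need at least 3 genes after subsetting")
        if x.std() == 0:
            raise ValueError("zero variance in the additive change; slope undefined")
        xv, yv = x.to_numpy(), y.to_numpy()
        if self.fit_intercept:
            fit = linregress(xv, yv)
            slope, intercept = float(fit.slope), float(fit.intercept)
            r, p = float(fit.rvalue), float(fit.pvalue)
        else:
            slope = float(np.dot(xv, yv) / np.dot(xv, xv))
            intercept = 0.0
            rr = pearsonr(xv, yv)
            r, p = float(rr.statistic), float(rr.pvalue)
        self.slope_ = slope
        self.intercept_ = intercept
        self.magnitude_ = 1.0 - slope
        self.r_ = r
        self.p_ = p
        self.n_genes_ = len(x)
        self.result_ = EpistasisResult(
            strain=strain, n_genes=len(x), pearson_r=r, r_pvalue=p,
            slope=slope, intercept=intercept, magnitude=1.0 - slope,
            subset=label,
        )
        return self


def epistasis_regression(additive, simultaneous, genes=None, strain: str = "",
                         fit_intercept: bool = True,
                         subset_label: str | None = None) -> EpistasisResult:
    """OLS slope of simultaneous vs additive change; magnitude = 1 - slope."""
    est = EpistasisRegression(fit_intercept=fit_intercept, genes=genes)
    return est.fit(additive, simultaneous, strain=strain,
                   subset_label=subset_label).result_


def strain_epistasis(profiles: pd.DataFrame, strain: str, ancestor: str = "Anc",
                     genes=None, fit_intercept: bool = True) -> EpistasisResult:
    """Contrasts + regression for one evolved strain.

    ``pearson_r``/``r_pvalue`` in the returned result report the
    association between the heat-shock-induced and genotype-mediated
    contrasts (how independent the two perturbations are), while
    slope/magnitude come from the simultaneous-vs-additive regression.
    """
    import dataclasses

    c = epistasis_contrasts(profiles, strain, ancestor=ancestor)
    result = epistasis_regression(c["additive"], c["simultaneous"], genes=genes,
                                  strain=strain, fit_intercept=fit_intercept)
    assoc = delta_association(c["dHS_A"], c["dG"])
    return dataclasses.replace(result, pearson_r=assoc["r"], r_pvalue=assoc["p"])


def responsiveness_alignment(profiles: pd.DataFrame, strain: str,
                             ancestor: str = "Anc") -> float:
    """Correlation between heat-shock-induced and temperature-mediated change.

    Pearson r between ``dHS_A`` (ancestor heat-shock response) and
    ``dT = strain_e - strain_r``.  An increasing value along the lineage
    means the adapted steady state aligns progressively with the heat-shock
    direction.
    """
    for label in (f"{ancestor}_r", f"{ancestor}_hs", f"{strain}_r", f"{strain}_e"):
        if label not in profiles.columns:
            raise KeyError(f"missing profile {label!r} for responsiveness alignment")
    dhs = make_delta(profiles, f"{ancestor}_hs", f"{ancestor}_r", name="dHS_A")
    dt = make_delta(profiles, f"{strain}_e", f"{strain}_r", name=f"dT_{strain}")
    return delta_association(dhs, dt)["r"]
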