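"""Allometric and environmental covariation tests: OLS and PGLS.

Single-predictor regressions with intercept, reported in the standard
table layout (multiple R^2, adjusted R^2, degrees of freedom, F, p,
slope).  PGLS is generalized least squares whose residual covariance is
the Brownian-motion matrix C from the phylogeny; with a star tree of
equal depths C is proportional to identity and PGLS reduces exactly to
OLS.  Statistics for PGLS (R^2, F) are computed on the whitened model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from wingmorph.phylo import phylo_vcv

__all__ = ["RegressionResult", "ols", "pgls", "regression_table"]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    multiple_r2: float
    adjusted_r2: float
    F: float
    df: tuple[int, int]
    p_value: float
    n: int

    def as_row(self) -> dict:
        return {
            "multiple_r2": self.multiple_r2,
            "adjusted_r2": self.adjusted_r2,
            "df": f"{self.df[0]}, {self.df[1]}",
            "F": self.F,
            "p": self.p_value,
            "slope": self.slope,
        }


def _prepare(response, predictor, log_predictor: bool):
    y = np.asarray(response, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("response and predictor must be matched 1-D vectors")
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    if len(y) < 3:
        raise ValueError("need >= 3 complete observations")
    if log_predictor:
        if np.any(x <= 0):
            raise ValueError("log transform requires positive predictor values")
        x = np.log(x)
    if np.var(x) == 0:
        raise ValueError("zero predictor variance")
    return y, x, ok


def ols(response, predictor, log_predictor: bool = False) -> RegressionResult:
    """Simple least-squares fit of response on predictor (with intercept).

    ``log_predictor`` applies a natural-log transform first (used for
    centroid size as the allometric predictor).
    """
    y, x, _ = _prepare(response, predictor, log_predictor)
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        multiple_r2=float(fit.rsquared),
        adjusted_r2=float(fit.rsquared_adj),
        F=float(fit.fvalue),
        df=(int(fit.df_model), int(fit.df_resid)),
        p_value=float(fit.f_pvalue),
        n=len(y),
    )


def pgls(
    response, predictor, tree, labels=None, log_predictor: bool = False
) -> RegressionResult:
    """Phylogenetic GLS under Brownian motion.

    ``response`` and ``predictor`` may be pandas Series indexed by taxon
    label (then ``labels`` is optional) or plain vectors ordered like
    ``labels``.  Taxa missing from the tree are dropped; the BM matrix C
    from the tree supplies the residual covariance:
    beta = (X' C^-1 X)^-1 X' C^-1 y.
    """
    if isinstance(response, pd.Series) and isinstance(predictor, pd.Series):
        common = response.index.intersection(predictor.index)
        response = response.loc[common]
        predictor = predictor.loc[common]
        labels = list(common)
    if labels is None:
        raise ValueError("labels required for non-Series inputs")
    y, x, ok = _prepare(response, predictor, log_predictor)
    labels = [lab for lab, keep in zip(labels, ok) if keep]

    tree_tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
    in_tree = np.array([lab in tree_tips for lab in labels])
    if not in_tree.all():
        import warnings

        warnings.warn(f"dropping {np.sum(~in_tree)} taxa absent from the tree")
    y, x = y[in_tree], x[in_tree]
    labels = [lab for lab, keep in zip(labels, in_tree) if keep]
    if len(y) < 3:
        raise ValueError("need >= 3 taxa matched to the tree")

    # prune the covariance to the matched taxa
    C = phylo_vcv(tree, labels)
    X = sm.add_constant(x)
    fit = sm.GLS(y, X, sigma=C).fit()
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        multiple_r2=float(fit.rsquared),
        adjusted_r2=float(fit.rsquared_adj),
        F=float(fit.fvalue),
        df=(int(fit.df_model), int(fit.df_resid)),
        p_value=float(fit.f_pvalue),
        n=len(y),
    )


_PAIRINGS = [
    # (name, predictor column, response column, log predictor?)
    ("wing centroid size, wing shape", "centroid_size", "pc1", True),
    ("temperature, wing size", "mat", "log_centroid_size", False),
    ("temperature, wing shape", "mat", "pc1", False),
    ("rainfall, wing shape", "mar", "pc1", False),
    ("rainfall, PC2", "mar", "pc2", False),
]


def regression_table(data: pd.DataFrame, tree=None, holm: bool = False) -> pd.DataFrame:
    """The five standard covariation tests as one results table.

    ``data`` columns: pc1, pc2, centroid_size, mat, mar (rows = taxa,
    index = taxon labels; missing covariates are dropped per test).
    With a tree the fits are PGLS, otherwise OLS.  ``holm`` optionally
    appends Holm-adjusted p-values.
    """
    if "log_centroid_size" not in data:
        data = data.assign(log_centroid_size=np.log(data["centroid_size"]))
    rows = []
    for name, xcol, ycol, logx in _PAIRINGS:
        sub = data[[xcol, ycol]].dropna()
        if tree is None:
            res = ols(sub[ycol], sub[xcol], log_predictor=logx)
        else:
            res = pgls(sub[ycol], sub[xcol], tree, log_predictor=logx)
        row = {"test": name, "n": res.n}
        row.update(res.as_row())
        rows.append(row)
    table = pd.DataFrame(rows)
    if holm:
        from statsmodels.stats.multitest import multipletests

        table["p_holm"] = multipletests(table["p"], method="holm")[1]
    return table
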