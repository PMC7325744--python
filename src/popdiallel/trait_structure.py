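"""Phenotypic correlation/covariance structure and simplified path models.

Correlations are computed on hybrid entry means (one value per hybrid per
trait, pooled over locations) with pairwise-complete handling; path models
are standardized multiple regressions solved from the correlation-matrix
normal equations, which is the quantity the simplified causal diagrams
report (with a single predictor the coefficient is the Pearson r).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel_io import PlotObservation, fieldbook_frame
from .errors import CollinearityError, EmptyDesignError


def significance_stars(p: float) -> str:
    """Figure-style star mapping: <0.0001 '***', <0.001 '**', <0.05 '*'."""
    if np.isnan(p):
        return "NA"
    if p < 1e-4:
        return "***"
    if p < 1e-3:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


def entry_means(
    plots: Iterable[PlotObservation], hybrids_only: bool = True
) -> pd.DataFrame:
    """Hybrid x trait matrix of entry means pooled over locations."""
    df = fieldbook_frame(plots)
    if hybrids_only:
        df = df.dropna(subset=["maternal", "paternal"])
    if df.empty:
        raise EmptyDesignError("no observations to summarize")
    return df.pivot_table(
        index="genotype", columns="trait", values="value", aggfunc="mean"
    )


@dataclass
class TraitMatrix:
    """Pairwise Pearson structure with p-values, stars, and covariances."""

    traits: list[str]
    correlation: pd.DataFrame
    p_values: pd.DataFrame
    stars: pd.DataFrame
    covariance: pd.DataFrame
    variances: pd.Series
    undefined: list[str]  # constant traits with no defined correlation


def correlation_matrix(means: pd.DataFrame) -> TraitMatrix:
    """Pairwise-complete Pearson correlations across entry means.

    Covariances and correlations for each pair come from the same
    pairwise-complete subset, so corr = cov / (sd_i * sd_j) holds exactly
    per pair. Constant traits are flagged, their pairs left NaN.
    """
    traits = list(means.columns)
    n_t = len(traits)
    corr = pd.DataFrame(np.eye(n_t), index=traits, columns=traits)
    pval = pd.DataFrame(np.nan, index=traits, columns=traits)
    cov = pd.DataFrame(np.nan, index=traits, columns=traits)
    undefined = [
        t for t in traits if means[t].dropna().nunique() <= 1
    ]
    for i, ti in enumerate(traits):
        cov.loc[ti, ti] = float(means[ti].var(ddof=1))
        for tj in traits[i + 1 :]:
            pair = means[[ti, tj]].dropna()
            if len(pair) < 3 or ti in undefined or tj in undefined:
                corr.loc[ti, tj] = corr.loc[tj, ti] = np.nan
                continue
            x, y = pair[ti].to_numpy(), pair[tj].to_numpy()
            r, p = stats.pearsonr(x, y)
            c = float(np.cov(x, y, ddof=1)[0, 1])
            corr.loc[ti, tj] = corr.loc[tj, ti] = float(r)
            pval.loc[ti, tj] = pval.loc[tj, ti] = float(p)
            cov.loc[ti, tj] = cov.loc[tj, ti] = c
    stars = pval.map(significance_stars)
    return TraitMatrix(
        traits=traits,
        correlation=corr,
        p_values=pval,
        stars=stars,
        covariance=cov,
        variances=pd.Series(np.diag(cov), index=traits),
        undefined=undefined,
    )


@dataclass
class PathResult:
    """Standardized regression ("path") coefficients for one outcome."""

    outcome: str
    predictors: list[str]
    coefficients: pd.Series
    marginal_correlations: pd.Series
    residual_variance: float


def path_coefficients(
    outcome: str,
    predictors: Sequence[str],
    means: pd.DataFrame,
) -> PathResult:
    """Solve the correlation-matrix normal equations R_xx b = r_xy.

    Satisfies the classical path identity: each predictor's marginal
    correlation equals its own coefficient plus the correlation-weighted
    sum of the other coefficients.
    """
    cols = [outcome, *predictors]
    data = means[cols].dropna()
    z = (data - data.mean()) / data.std(ddof=1)
    rxx = z[list(predictors)].corr().to_numpy()
    rxy = np.array([z[outcome].corr(z[p]) for p in predictors])
    if np.linalg.cond(rxx) > 1e10:
        raise CollinearityError(
            "predictor correlation matrix is singular or near-singular"
        )
    beta = np.linalg.solve(rxx, rxy)
    resid = 1.0 - float(beta @ rxy)
    return PathResult(
        outcome=outcome,
        predictors=list(predictors),
        coefficients=pd.Series(beta, index=list(predictors)),
        marginal_correlations=pd.Series(rxy, index=list(predictors)),
        residual_variance=resid,
    )
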