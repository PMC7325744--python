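"""Maternal/paternal general and specific combining ability from hybrid
cell means, with contrast-based standard errors.

Estimators follow the factorial (maternal x paternal, selfs excluded,
reciprocals distinct) layout: effects are deviations of unweighted marginal
means of available cell means from the grand cell mean, so that

    mu_hat + g_maternal + g_paternal + s_cross  ==  cell mean   (exactly)

and all effect vectors sum to zero on balanced data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .anova_varcomp import (
    fit_gcbd_anova,
    heritability,
    variance_components,
)
from .datamodel_io import PlotObservation, fieldbook_frame
from .errors import EmptyDesignError

ROLES = ("maternal", "paternal")


@dataclass
class CellMeans:
    """Per-cross means with counts and role marginals."""

    trait: str
    means: pd.DataFrame  # maternal x paternal, NaN where no plots
    counts: pd.DataFrame
    grand_mean: float  # unweighted mean of available cell means
    maternal_marginals: pd.Series
    paternal_marginals: pd.Series

    @property
    def missing_cells(self) -> list[tuple[str, str]]:
        out = []
        for m in self.means.index:
            for p in self.means.columns:
                if pd.isna(self.means.loc[m, p]):
                    out.append((m, p))
        return out


@dataclass
class GcaTable:
    """Per-parent general combining ability for one role."""

    role: str
    trait: str
    effects: pd.Series
    standard_errors: Optional[pd.Series] = None
    heritability: Optional[float] = None


@dataclass
class ScaMatrix:
    """Cross-specific combining ability (maternal x paternal)."""

    trait: str
    values: pd.DataFrame
    standard_errors: Optional[pd.DataFrame] = None
    repeatability: Optional[float] = None


def hybrid_cell_means(
    plots: Iterable[PlotObservation], trait: str
) -> CellMeans:
    """Per-cross plot means; marginals are unweighted means of available
    cell means (missing cells flagged and excluded)."""
    df = fieldbook_frame(plots)
    df = df[(df["trait"] == trait)].dropna(subset=["maternal", "paternal"])
    if df.empty:
        raise EmptyDesignError(f"no hybrid observations for trait {trait!r}")
    means = df.pivot_table(
        index="maternal", columns="paternal", values="value", aggfunc="mean"
    )
    counts = (
        df.pivot_table(
            index="maternal",
            columns="paternal",
            values="value",
            aggfunc="count",
        )
        .fillna(0)
        .astype(int)
    )
    # selfs never exist; they appear as NaN and are simply absent cells
    grand = float(np.nanmean(means.to_numpy()))
    return CellMeans(
        trait=trait,
        means=means,
        counts=counts,
        grand_mean=grand,
        maternal_marginals=means.mean(axis=1, skipna=True),
        paternal_marginals=means.mean(axis=0, skipna=True),
    )


def estimate_gca(cells: CellMeans, role: str) -> GcaTable:
    """GCA effect per parent: marginal mean minus grand mean.

    Positive = above-average parent. (The deviation is taken as
    marginal - grand so that parents with better-than-average offspring
    carry positive effects.)
    """
    if role not in ROLES:
        raise ValueError(f"role must be one of {ROLES}")
    marg = (
        cells.maternal_marginals
        if role == "maternal"
        else cells.paternal_marginals
    )
    if len(marg) < 2:
        raise EmptyDesignError(f"need >=2 {role} parents")
    return GcaTable(role=role, trait=cells.trait, effects=marg - cells.grand_mean)


def estimate_sca(
    cells: CellMeans, mgca: GcaTable, pgca: GcaTable
) -> ScaMatrix:
    """SCA per cross: cell mean minus grand mean and both GCA effects.

    Satisfies the exact reconstruction identity
    ``grand + g_m + g_p + s == cell mean`` for every observed cell.
    """
    if not mgca.effects.index.equals(cells.means.index) or not (
        pgca.effects.index.equals(cells.means.columns)
    ):
        raise ValueError("GCA tables do not match the cell-mean layout")
    sca = (
        cells.means
        - cells.grand_mean
        - mgca.effects.to_numpy()[:, None]
        - pgca.effects.to_numpy()[None, :]
    )
    return ScaMatrix(trait=cells.trait, values=sca)


# ---------------------------------------------------------------------------
# Standard errors via contrast algebra
# ---------------------------------------------------------------------------


def _cell_weight_frames(cells: CellMeans) -> tuple[np.ndarray, np.ndarray]:
    """(availability mask, plot counts) aligned to the cell-mean layout."""
    avail = ~np.isnan(cells.means.to_numpy())
    counts = cells.counts.reindex(
        index=cells.means.index, columns=cells.means.columns
    ).fillna(0).to_numpy(dtype=float)
    return avail, counts


def gca_standard_errors(
    cells: CellMeans, residual_variance: float, role: str
) -> pd.Series:
    """SE of each GCA effect as a linear contrast of cell means.

    Effect = (1/C_role) sum(row or column cells) - (1/C) sum(all cells);
    Var = sigma2_e * sum(coef^2 / n_cell) over contributing cells.
    """
    avail, counts = _cell_weight_frames(cells)
    total_cells = avail.sum()
    labels = (
        cells.means.index if role == "maternal" else cells.means.columns
    )
    ses = {}
    for i, label in enumerate(labels):
        in_group = np.zeros_like(avail, dtype=bool)
        if role == "maternal":
            in_group[i, :] = True
        else:
            in_group[:, i] = True
        in_group &= avail
        n_group = in_group.sum()
        if n_group == 0 or counts[in_group].min() < 1:
            ses[label] = np.nan
            continue
        coef = np.where(in_group, 1.0 / n_group, 0.0) - np.where(
            avail, 1.0 / total_cells, 0.0
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            var = residual_variance * np.nansum(
                np.where(avail, coef**2 / np.where(counts > 0, counts, np.nan), 0.0)
            )
        ses[label] = float(np.sqrt(var))
    return pd.Series(ses, name=f"{role}_gca_se")


def sca_standard_errors(
    cells: CellMeans, residual_variance: float
) -> pd.DataFrame:
    """SE of each SCA effect as a linear contrast of cell means."""
    avail, counts = _cell_weight_frames(cells)
    total_cells = avail.sum()
    m_labels, p_labels = cells.means.index, cells.means.columns
    out = pd.DataFrame(
        np.nan, index=m_labels, columns=p_labels, dtype=float
    )
    for i in range(len(m_labels)):
        row_mask = np.zeros_like(avail, dtype=bool)
        row_mask[i, :] = True
        row_mask &= avail
        n_row = row_mask.sum()
        for j in range(len(p_labels)):
            if not avail[i, j]:
                continue
            col_mask = np.zeros_like(avail, dtype=bool)
            col_mask[:, j] = True
            col_mask &= avail
            n_col = col_mask.sum()
            coef = (
                -np.where(row_mask, 1.0 / n_row, 0.0)
                - np.where(col_mask, 1.0 / n_col, 0.0)
                + np.where(avail, 1.0 / total_cells, 0.0)
            )
            coef[i, j] += 1.0
            with np.errstate(divide="ignore", invalid="ignore"):
                var = residual_variance * np.nansum(
                    np.where(
                        avail,
                        coef**2 / np.where(counts > 0, counts, np.nan),
                        0.0,
                    )
                )
            out.iloc[i, j] = float(np.sqrt(var))
    return out


def combining_se(
    plots: Iterable[PlotObservation],
    cells: CellMeans,
    target: str | tuple[str, str],
) -> pd.Series | float:
    """Standard errors for a GCA role ("maternal"/"paternal") or one cross.

    The residual variance comes from the full two-way fit with hybrid
    identity as the treatment factor.
    """
    fit = fit_gcbd_anova(plots, treatment_factor="hybrid", trait=cells.trait)
    sigma2 = fit.residual_variance
    if isinstance(target, str):
        return gca_standard_errors(cells, sigma2, target)
    se = sca_standard_errors(cells, sigma2)
    return float(se.loc[target[0], target[1]])


# ---------------------------------------------------------------------------
# Full per-trait diallel report
# ---------------------------------------------------------------------------


@dataclass
class DiallelEstimates:
    """Everything the per-trait combining-ability report carries."""

    trait: str
    grand_mean: float
    mgca: GcaTable
    pgca: GcaTable
    sca: ScaMatrix
    hybrid_repeatability: Optional[float]


def diallel_analysis(
    plots: Iterable[PlotObservation], trait: str
) -> DiallelEstimates:
    """One-call pipeline: cell means -> GCA/SCA -> SEs -> heritabilities."""
    cells = hybrid_cell_means(plots, trait)
    mgca = estimate_gca(cells, "maternal")
    pgca = estimate_gca(cells, "paternal")
    sca = estimate_sca(cells, mgca, pgca)

    fit_h = fit_gcbd_anova(plots, treatment_factor="hybrid", trait=trait)
    sigma2 = fit_h.residual_variance
    mgca.standard_errors = gca_standard_errors(cells, sigma2, "maternal")
    pgca.standard_errors = gca_standard_errors(cells, sigma2, "paternal")
    sca.standard_errors = sca_standard_errors(cells, sigma2)

    repeatability = None
    try:
        repeatability = heritability(
            variance_components(fit_h)
        ).ratio
    except Exception:
        pass
    sca.repeatability = repeatability
    for role, table in (("maternal", mgca), ("paternal", pgca)):
        try:
            fit_r = fit_gcbd_anova(plots, treatment_factor=role, trait=trait)
            table.heritability = heritability(
                variance_components(fit_r)
            ).ratio
        except Exception:
            table.heritability = None
    return DiallelEstimates(
        trait=trait,
        grand_mean=cells.grand_mean,
        mgca=mgca,
        pgca=pgca,
        sca=sca,
        hybrid_repeatability=repeatability,
    )
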