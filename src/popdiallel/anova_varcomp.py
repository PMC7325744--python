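"""Two-location GCBD ANOVA with Type II sums of squares, expected-mean-square
variance components, and heritability/repeatability ratios.

The linear model is ``y = mu + location + treatment + location:treatment +
error`` with the treatment factor chosen as hybrid identity, maternal parent,
or paternal parent. Type II sums of squares are computed by model comparison
(residual-SS difference between nested least-squares fits), which reduces to
the textbook two-way decomposition on balanced data and keeps proper degrees
of freedom when plots or whole hybrids are missing. Replicate rows within a
location are absorbed into the plot error rather than modelled as a block
stratum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel_io import PlotObservation, fieldbook_frame
from .errors import (
    DegenerateDesignError,
    EmptyDesignError,
    UndefinedRatioError,
)

TREATMENT_FACTORS = ("hybrid", "maternal", "paternal")


@dataclass
class AnovaFit:
    """Least-squares fit of the two-way location x treatment model."""

    trait: str
    treatment_factor: str
    grand_mean: float
    location_effects: pd.Series
    treatment_effects: pd.Series
    interaction_effects: pd.Series  # index: (location, treatment)
    table: pd.DataFrame  # rows: location, treatment, interaction, error
    n_locations: int
    n_treatments: int
    n_obs: int

    @property
    def residual_variance(self) -> float:
        return float(self.table.loc["error", "ms"])

    def shrunken_treatment_effects(
        self, sigma2_treatment: float, sigma2_error: float
    ) -> pd.Series:
        """BLUP-style shrinkage of raw treatment deviations (optional path)."""
        counts = self._treatment_counts
        if sigma2_treatment <= 0:
            return self.treatment_effects * 0.0
        lam = sigma2_treatment / (
            sigma2_treatment + sigma2_error / counts.reindex(
                self.treatment_effects.index
            )
        )
        return self.treatment_effects * lam

    _treatment_counts: pd.Series = None  # set by fit_gcbd_anova


def _rss(y: np.ndarray, x: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and column-space rank of a design matrix."""
    coef, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    return float(resid @ resid), int(rank)


def _dummies(values: pd.Series) -> np.ndarray:
    return pd.get_dummies(values, dtype=float).to_numpy()


def fit_gcbd_anova(
    plots: Iterable[PlotObservation],
    treatment_factor: str = "hybrid",
    trait: Optional[str] = None,
) -> AnovaFit:
    """Fit the two-way model for one trait with Type II sums of squares.

    ``treatment_factor`` selects what the tau term indexes: full hybrid
    identity, or the maternal / paternal parent of each plot's cross.
    """
    if treatment_factor not in TREATMENT_FACTORS:
        raise ValueError(f"unknown treatment factor {treatment_factor!r}")
    df = fieldbook_frame(plots)
    if trait is not None:
        df = df[df["trait"] == trait]
    elif df["trait"].nunique() > 1:
        raise ValueError("multiple traits present; pass trait=...")
    else:
        trait = df["trait"].iloc[0] if len(df) else None
    col = "genotype" if treatment_factor == "hybrid" else treatment_factor
    df = df.dropna(subset=[col])
    if df.empty:
        raise EmptyDesignError("no observations for requested trait/factor")
    if df["location"].nunique() < 2:
        raise DegenerateDesignError("need at least 2 locations")
    if df[col].nunique() < 2:
        raise DegenerateDesignError("need at least 2 treatment levels")

    y = df["value"].to_numpy(dtype=float)
    n = len(y)
    ones = np.ones((n, 1))
    d_loc = _dummies(df["location"])
    d_trt = _dummies(df[col])
    # interaction = observed location x treatment cells
    cell = df["location"].astype(str) + "\x1f" + df[col].astype(str)
    d_cell = _dummies(cell)

    rss_loc, r_loc = _rss(y, np.hstack([ones, d_loc]))
    rss_trt, r_trt = _rss(y, np.hstack([ones, d_trt]))
    rss_add, r_add = _rss(y, np.hstack([ones, d_loc, d_trt]))
    rss_full, r_full = _rss(y, d_cell)

    df_loc = r_add - r_trt
    df_trt = r_add - r_loc
    df_int = r_full - r_add
    df_err = n - r_full
    if df_trt == 0 or df_loc == 0:
        raise DegenerateDesignError(
            "treatment and location are confounded (singular comparison)"
        )

    ss_loc = max(rss_trt - rss_add, 0.0)
    ss_trt = max(rss_loc - rss_add, 0.0)
    ss_int = max(rss_add - rss_full, 0.0)
    ss_err = rss_full
    if df_err == 0:
        ms_err = np.nan
    else:
        ms_err = ss_err / df_err

    rows = {}
    for name, ss, dfree in (
        ("location", ss_loc, df_loc),
        ("treatment", ss_trt, df_trt),
        ("interaction", ss_int, df_int),
    ):
        ms = ss / dfree if dfree > 0 else np.nan
        if dfree > 0 and df_err > 0 and ms_err > 0:
            f = ms / ms_err
            p = float(stats.f.sf(f, dfree, df_err))
        else:
            f, p = np.nan, np.nan
        rows[name] = {"ss": ss, "df": dfree, "ms": ms, "F": f, "p": p}
    rows["error"] = {
        "ss": ss_err,
        "df": df_err,
        "ms": ms_err,
        "F": np.nan,
        "p": np.nan,
    }
    table = pd.DataFrame(rows).T[["ss", "df", "ms", "F", "p"]]

    grand = float(y.mean())
    loc_eff = df.groupby("location")["value"].mean() - grand
    trt_eff = df.groupby(col)["value"].mean() - grand
    cell_mean = df.groupby(["location", col])["value"].mean()
    inter = cell_mean - grand
    for (loc, t), _ in inter.items():
        inter.loc[(loc, t)] = (
            cell_mean.loc[(loc, t)]
            - (grand + loc_eff.loc[loc])
            - trt_eff.loc[t]
            + 0.0
        )

    fit = AnovaFit(
        trait=trait,
        treatment_factor=treatment_factor,
        grand_mean=grand,
        location_effects=loc_eff,
        treatment_effects=trt_eff,
        interaction_effects=inter,
        table=table,
        n_locations=int(df["location"].nunique()),
        n_treatments=int(df[col].nunique()),
        n_obs=n,
    )
    fit._treatment_counts = df.groupby(col)["value"].count()
    return fit


def type1_anova(
    plots: Iterable[PlotObservation],
    treatment_factor: str = "hybrid",
    trait: Optional[str] = None,
) -> pd.DataFrame:
    """Sequential (Type I) sums of squares, location entered first.

    Kept as an independent route for the balanced-data equality check
    against the Type II table.
    """
    df = fieldbook_frame(plots)
    if trait is not None:
        df = df[df["trait"] == trait]
    col = "genotype" if treatment_factor == "hybrid" else treatment_factor
    df = df.dropna(subset=[col])
    y = df["value"].to_numpy(dtype=float)
    n = len(y)
    ones = np.ones((n, 1))
    d_loc = _dummies(df["location"])
    d_trt = _dummies(df[col])
    cell = df["location"].astype(str) + "\x1f" + df[col].astype(str)
    d_cell = _dummies(cell)

    rss0, _ = _rss(y, ones)
    rss1, _ = _rss(y, np.hstack([ones, d_loc]))
    rss2, _ = _rss(y, np.hstack([ones, d_loc, d_trt]))
    rss3, _ = _rss(y, d_cell)
    return pd.DataFrame(
        {
            "ss": [rss0 - rss1, rss1 - rss2, rss2 - rss3, rss3],
        },
        index=["location", "treatment", "interaction", "error"],
    )


# ---------------------------------------------------------------------------
# Variance components and heritability
# ---------------------------------------------------------------------------


@dataclass
class VarianceComponents:
    """EMS solutions for the random two-way model (clipped at zero)."""

    sigma2_treatment: float
    sigma2_interaction: float
    sigma2_error: float
    preclip_treatment: float
    preclip_interaction: float
    clipped: bool
    treatment_factor: str = "hybrid"


def variance_components_from_ms(
    ms_treatment: float,
    ms_interaction: float,
    ms_error: float,
    n_locations: int,
    reps_per_cell: float,
    clip: bool = True,
    treatment_factor: str = "hybrid",
) -> VarianceComponents:
    """Invert the expected mean squares of the random two-way model.

    E[MS_error] = s2_e; E[MS_int] = s2_e + r s2_int;
    E[MS_trt] = s2_e + r s2_int + r L s2_trt.
    """
    r = float(reps_per_cell)
    sig_e = float(ms_error)
    pre_int = (ms_interaction - ms_error) / r
    pre_trt = (ms_treatment - ms_interaction) / (r * n_locations)
    sig_int = max(pre_int, 0.0) if clip else pre_int
    sig_trt = max(pre_trt, 0.0) if clip else pre_trt
    return VarianceComponents(
        sigma2_treatment=sig_trt,
        sigma2_interaction=sig_int,
        sigma2_error=sig_e,
        preclip_treatment=pre_trt,
        preclip_interaction=pre_int,
        clipped=bool(clip and (pre_trt < 0 or pre_int < 0)),
        treatment_factor=treatment_factor,
    )


def variance_components(
    fit: AnovaFit, clip: bool = True
) -> VarianceComponents:
    """Henderson-III-style EMS inversion using the Type II mean squares.

    The replication coefficient is the average plot count per observed
    location x treatment cell; exact on balanced data, a documented
    approximation under mild unbalance.
    """
    if fit.table.loc["error", "df"] == 0:
        raise DegenerateDesignError("zero residual degrees of freedom")
    n_cells = fit.n_locations * fit.n_treatments
    reps = fit.n_obs / n_cells
    return variance_components_from_ms(
        ms_treatment=fit.table.loc["treatment", "ms"],
        ms_interaction=fit.table.loc["interaction", "ms"],
        ms_error=fit.table.loc["error", "ms"],
        n_locations=fit.n_locations,
        reps_per_cell=reps,
        clip=clip,
        treatment_factor=fit.treatment_factor,
    )


@dataclass(frozen=True)
class HeritabilityEstimate:
    """Plot-basis variance ratio in [0, 1]."""

    ratio: float
    role: str  # maternal | paternal | hybrid
    basis: str = "plot"


_FACTOR_TO_ROLE = {"hybrid": "hybrid", "maternal": "maternal", "paternal": "paternal"}


def heritability(components: VarianceComponents) -> HeritabilityEstimate:
    """Broad-sense heritability (parent roles) or repeatability (hybrid).

    ratio = s2_treatment / (s2_treatment + s2_interaction + s2_error),
    the plot-basis phenotypic denominator.
    """
    total = (
        components.sigma2_treatment
        + components.sigma2_interaction
        + components.sigma2_error
    )
    if total <= 0:
        raise UndefinedRatioError("all variance components are zero")
    ratio = components.sigma2_treatment / total
    return HeritabilityEstimate(
        ratio=float(min(max(ratio, 0.0), 1.0)),
        role=_FACTOR_TO_ROLE[components.treatment_factor],
    )
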