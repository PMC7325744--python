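"""Weighted rank-summation selection index for hybrid prescreening.

Each hybrid's continuous rank value is

    X_h = sum_i (y_ih / y_i,max - 1)^2 * I_i * (sd_ih / sd_i,max)

summed over the weighted traits after orientation (traits where small is
good are complemented first), where y_i,max and sd_i,max are the best
oriented mean and the largest replicate-row standard deviation across the
ranked hybrids. Smaller X_h is better; a hybrid at the oriented maximum of
every weighted trait scores exactly zero. The variability term multiplies
by default (penalizing heterogeneous hybrids); a divisive variant is
selectable for sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel_io import (
    AnalysisConfig,
    PlotObservation,
    TraitSpec,
    fieldbook_frame,
)
from .errors import DegenerateTraitError, EmptyDesignError, IntegrityError


@dataclass(frozen=True)
class TraitSummary:
    """Per-hybrid, per-trait mean and replicate-row standard deviation."""

    hybrid: str
    trait: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise IntegrityError("negative standard deviation")
        if self.n < 1:
            raise IntegrityError("summary with n < 1")


@dataclass
class RankResult:
    """Total index value with its per-trait decomposition."""

    hybrid: str
    total: float
    contributions: dict[str, float]
    rank: int = 0
    imputed_traits: list[str] = field(default_factory=list)


def summarize_traits(
    plots: Iterable[PlotObservation],
    hybrids: Optional[Sequence[str]] = None,
) -> list[TraitSummary]:
    """Mean and sd per hybrid per trait over replicate rows pooled across
    locations (sd = 0 when only one row is available)."""
    df = fieldbook_frame(plots)
    if hybrids is not None:
        df = df[df["genotype"].isin(hybrids)]
    grouped = df.groupby(["genotype", "trait"])["value"]
    out = []
    for (hybrid, trait), values in grouped:
        arr = values.to_numpy(dtype=float)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        out.append(
            TraitSummary(
                hybrid=hybrid,
                trait=trait,
                mean=float(arr.mean()),
                sd=sd,
                n=len(arr),
            )
        )
    return out


def orient_traits(
    summaries: Iterable[TraitSummary], specs: Sequence[TraitSpec]
) -> list[TraitSummary]:
    """Apply trait orientations: complemented traits map mean -> 1 - mean
    (sds unchanged), excluded / zero-weight traits are dropped."""
    spec_map = {s.name: s for s in specs}
    out = []
    for s in summaries:
        spec = spec_map.get(s.trait)
        if spec is None or spec.orientation == "excluded" or spec.weight == 0:
            continue
        if spec.orientation == "complement_then_maximize":
            if not (0.0 <= s.mean <= 1.0):
                raise IntegrityError(
                    f"complement orientation needs a proportion; trait "
                    f"{s.trait!r} has mean {s.mean}"
                )
            s = TraitSummary(
                hybrid=s.hybrid,
                trait=s.trait,
                mean=1.0 - s.mean,
                sd=s.sd,
                n=s.n,
            )
        out.append(s)
    return out


def trait_term(
    y: float,
    y_max: float,
    sd: float,
    sd_max: float,
    weight: float,
    variant: str = "multiplicative",
) -> float:
    """One trait's nonnegative contribution to a hybrid's index value."""
    if y_max == 0:
        raise DegenerateTraitError("best trait value is zero")
    base = (y / y_max - 1.0) ** 2 * weight
    if sd_max <= 0:
        ratio = 1.0  # no variability information -> neutral penalty
    elif variant == "multiplicative":
        ratio = sd / sd_max
    elif variant == "divisive":
        ratio = sd_max / sd if sd > 0 else 1.0
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return base * ratio


def rank_hybrids(
    summaries: Iterable[TraitSummary],
    specs: Sequence[TraitSpec],
    variant: str = "multiplicative",
) -> list[RankResult]:
    """Index totals for every hybrid, ascending (best first).

    y_max and sd_max are taken per trait over the ranked hybrids after
    orientation. A hybrid missing a weighted trait receives that trait's
    worst observed contribution (pessimistic imputation) and is flagged.
    Ties share a rank position; display order among ties puts the higher
    oriented expansion-volume mean first when available.
    """
    oriented = orient_traits(summaries, specs)
    if not oriented:
        raise EmptyDesignError("no oriented trait summaries to rank")
    spec_map = {s.name: s for s in specs}
    by_trait: dict[str, list[TraitSummary]] = {}
    hybrids: list[str] = []
    for s in oriented:
        by_trait.setdefault(s.trait, []).append(s)
        if s.hybrid not in hybrids:
            hybrids.append(s.hybrid)
    if not hybrids:
        raise EmptyDesignError("zero hybrids")

    contrib: dict[str, dict[str, float]] = {h: {} for h in hybrids}
    imputed: dict[str, list[str]] = {h: [] for h in hybrids}
    ev_mean: dict[str, float] = {}

    for trait, rows in by_trait.items():
        y_max = max(r.mean for r in rows)
        sd_max = max(r.sd for r in rows)
        weight = spec_map[trait].weight
        try:
            terms = {
                r.hybrid: trait_term(
                    r.mean, y_max, r.sd, sd_max, weight, variant
                )
                for r in rows
            }
        except DegenerateTraitError:
            warnings.warn(
                f"trait {trait!r} skipped: best oriented value is zero",
                stacklevel=2,
            )
            continue
        worst = max(terms.values())
        for h in hybrids:
            if h in terms:
                contrib[h][trait] = terms[h]
            else:
                contrib[h][trait] = worst
                imputed[h].append(trait)
        if trait == "ev":
            for r in rows:
                ev_mean[r.hybrid] = r.mean

    results = [
        RankResult(
            hybrid=h,
            total=float(sum(contrib[h].values())),
            contributions=contrib[h],
            imputed_traits=imputed[h],
        )
        for h in hybrids
    ]
    results.sort(key=lambda r: (r.total, -ev_mean.get(r.hybrid, -np.inf)))
    totals = sorted(r.total for r in results)
    for r in results:
        r.rank = 1 + sum(1 for t in totals if t < r.total - 1e-15)
    return results


def rank_table(results: Sequence[RankResult]) -> pd.DataFrame:
    """Wide report: hybrid, total, rank, one contribution column per trait."""
    traits = sorted({t for r in results for t in r.contributions})
    rows = []
    for r in results:
        row = {"hybrid": r.hybrid, "total": r.total, "rank": r.rank}
        row.update({t: r.contributions.get(t, np.nan) for t in traits})
        rows.append(row)
    return pd.DataFrame(rows, columns=["hybrid", "total", "rank", *traits])


def rank_from_fieldbook(
    plots: Iterable[PlotObservation],
    config: Optional[AnalysisConfig] = None,
) -> list[RankResult]:
    """Field book -> summaries -> ranked hybrids, using config trait specs."""
    config = config or AnalysisConfig()
    hybrid_plots = [p for p in plots if p.maternal and p.paternal]
    summaries = summarize_traits(hybrid_plots)
    variant = (
        "multiplicative"
        if config.sigma_ratio == "multiplicative"
        else "divisive"
    )
    return rank_hybrids(summaries, config.traits, variant=variant)
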