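"""Pedigree-based heterosis categories and the category trend test.

Crosses are assigned to five ordered genetic-diversity levels from the
ancestry of their two inbred parents, then a trait can be tested for the
stepwise-improvement trend across categories (two-way ANOVA with category
as the treatment, Tukey-Kramer HSD pairwise comparisons, and a monotone
flag over the category order).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import studentized_range

from .anova_varcomp import fit_gcbd_anova
from .datamodel_io import PedigreeRecord, PlotObservation
from .errors import DegenerateDesignError, IntegrityError


class HeterosisCategory(IntEnum):
    """Ordered by increasing genetic diversity of the cross."""

    PSEUDO_SELF = 0
    SAME_POPCORN = 1
    SAME_QPM = 2
    SAME_POOL_HYBRID = 3
    COMPLETE_HYBRID = 4

    @property
    def label(self) -> str:
        return self.name.lower()


CATEGORY_ORDER = tuple(HeterosisCategory)


def categorize_cross(
    a: PedigreeRecord, b: PedigreeRecord
) -> HeterosisCategory:
    """Five-level pedigree-distance category of the cross a x b.

    Same QPM and same popcorn ancestor -> pseudo-self; same popcorn only ->
    same-popcorn (popcorn similarity dominates because lines were twice
    back-crossed to the popcorn parent); same QPM only -> same-QPM; all
    ancestors distinct but popcorn parents share a heterotic pool ->
    same-pool hybrid; otherwise complete hybrid.
    """
    same_pop = a.popcorn_parent == b.popcorn_parent
    same_qpm = a.qpm_parent == b.qpm_parent
    if same_pop and same_qpm:
        return HeterosisCategory.PSEUDO_SELF
    if same_pop:
        return HeterosisCategory.SAME_POPCORN
    if same_qpm:
        return HeterosisCategory.SAME_QPM
    if a.heterotic_pool == b.heterotic_pool:
        return HeterosisCategory.SAME_POOL_HYBRID
    return HeterosisCategory.COMPLETE_HYBRID


def categorize_crosses(
    pedigree: Iterable[PedigreeRecord],
    crosses: Iterable[tuple[str, str]],
) -> dict[tuple[str, str], HeterosisCategory]:
    """Categorize many crosses against a pedigree lookup."""
    lookup = {r.inbred: r for r in pedigree}
    out = {}
    for m, p in crosses:
        if m not in lookup or p not in lookup:
            raise IntegrityError(f"unknown inbred in cross {m} x {p}")
        out[(m, p)] = categorize_cross(lookup[m], lookup[p])
    return out


# ---------------------------------------------------------------------------
# Tukey HSD
# ---------------------------------------------------------------------------


def tukey_hsd(
    means: Mapping[str, float],
    ns: Mapping[str, int],
    mse: float,
    df_error: int,
) -> pd.DataFrame:
    """Tukey-Kramer pairwise comparisons from group summaries.

    q = |m_i - m_j| / sqrt(mse/2 * (1/n_i + 1/n_j)); p from the
    studentized-range distribution with k groups and the residual df.
    Stars: p < 0.001 '***', < 0.01 '**', < 0.05 '*', else 'NS'.
    """
    groups = list(means)
    k = len(groups)
    if k < 2:
        raise DegenerateDesignError("need at least 2 groups")
    if df_error < 1:
        raise DegenerateDesignError("residual df must be >= 1")
    rows = []
    for g1, g2 in combinations(groups, 2):
        diff = means[g1] - means[g2]
        se2 = mse / 2.0 * (1.0 / ns[g1] + 1.0 / ns[g2])
        if se2 <= 0:
            q = np.inf if diff != 0 else 0.0
            p = 0.0 if diff != 0 else 1.0
        else:
            q = abs(diff) / np.sqrt(se2)
            p = float(studentized_range.sf(q, k, df_error))
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "diff": diff,
                "q": q,
                "p": p,
                "stars": significance_stars(p),
            }
        )
    return pd.DataFrame(rows)


def significance_stars(p: float) -> str:
    if np.isnan(p):
        return "NA"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


# ---------------------------------------------------------------------------
# Category trend
# ---------------------------------------------------------------------------


@dataclass
class TrendReport:
    """Per-category summaries with ANOVA, Tukey pairs, and monotone flag."""

    trait: str
    category_means: pd.Series  # indexed by category label, in fixed order
    category_ns: pd.Series
    anova_p: float
    tukey: pd.DataFrame
    monotone: bool
    violations: list[tuple[str, str]]


def category_trend(
    plots: Iterable[PlotObservation],
    categories: Mapping[str, HeterosisCategory],
    trait: str,
    monotone_tolerance_se: float = 0.25,
) -> TrendReport:
    """Test the trait trend across heterosis categories.

    Each plot is relabelled by its cross's category and the two-way
    location x category model is fitted; pairwise Tukey-Kramer follows.
    The monotone flag clears when category means are non-decreasing along
    the diversity order, allowing adjacent dips smaller than
    ``monotone_tolerance_se`` times the SE of the adjacent difference.
    """
    relabelled = []
    for p in plots:
        if p.trait != trait or p.genotype not in categories:
            continue
        relabelled.append(
            PlotObservation(
                location=p.location,
                block=p.block,
                genotype=categories[p.genotype].label,
                trait=p.trait,
                value=p.value,
            )
        )
    if not relabelled:
        raise DegenerateDesignError("no plots matched the categorized crosses")
    present = {p.genotype for p in relabelled}
    if len(present) < 2:
        raise DegenerateDesignError("need >=2 populated categories")

    fit = fit_gcbd_anova(relabelled, treatment_factor="hybrid", trait=trait)
    mse = fit.residual_variance
    df_err = int(fit.table.loc["error", "df"])

    values = pd.DataFrame(
        {
            "category": [p.genotype for p in relabelled],
            "value": [p.value for p in relabelled],
        }
    )
    order = [c.label for c in CATEGORY_ORDER if c.label in present]
    means = values.groupby("category")["value"].mean().reindex(order)
    ns = values.groupby("category")["value"].count().reindex(order)

    pairs = tukey_hsd(means.to_dict(), ns.to_dict(), mse, df_err)

    monotone = True
    violations: list[tuple[str, str]] = []
    for lo, hi in zip(order[:-1], order[1:]):
        drop = means[lo] - means[hi]  # positive = decrease along the order
        se_diff = np.sqrt(mse * (1.0 / ns[lo] + 1.0 / ns[hi]))
        if drop > monotone_tolerance_se * se_diff:
            monotone = False
            violations.append((lo, hi))

    return TrendReport(
        trait=trait,
        category_means=means,
        category_ns=ns,
        anova_p=float(fit.table.loc["treatment", "p"]),
        tukey=pairs,
        monotone=monotone,
        violations=violations,
    )
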