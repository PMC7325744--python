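"""Amino-acid protein-quality analytics.

Group fold changes with delta-method SEs, lysine as a percentage of total
protein, popping loss/retention, cross-method correlation screening with a
0.700 flag threshold, additive/dominant/over-dominant inheritance
classification from replicate profiles, and dietary-requirement fractions.
Inputs are already-quantified g/100 g tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel_io import AminoAcidRecord, amino_frame
from .errors import PopdiallelError

LOW_CORRELATION_FLAG = 0.700


def _mean_se(values: Sequence[float]) -> tuple[float, float, int]:
    arr = np.asarray(values, dtype=float)
    n = len(arr)
    se = float(arr.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return float(arr.mean()), se, n


@dataclass(frozen=True)
class GroupComparison:
    """Target-vs-reference group means with the fold change between them."""

    target_mean: float
    target_se: float
    reference_mean: float
    reference_se: float
    fold: float
    fold_se: float
    n_target: int
    n_reference: int


def fold_change(
    target: Sequence[float], reference: Sequence[float]
) -> GroupComparison:
    """fold = mean(target) / mean(reference); SE by the delta method."""
    t_mean, t_se, t_n = _mean_se(target)
    r_mean, r_se, r_n = _mean_se(reference)
    if r_mean <= 0:
        raise PopdiallelError("reference mean must be positive")
    fold = t_mean / r_mean
    if t_mean == 0:
        fold_se = t_se / r_mean
    else:
        fold_se = abs(fold) * np.sqrt(
            (t_se / t_mean) ** 2 + (r_se / r_mean) ** 2
        )
    return GroupComparison(
        target_mean=t_mean,
        target_se=t_se,
        reference_mean=r_mean,
        reference_se=r_se,
        fold=float(fold),
        fold_se=float(fold_se),
        n_target=t_n,
        n_reference=r_n,
    )


def lysine_percent_of_protein(
    lysine_g_per_100g: float, protein_g_per_100g: float
) -> float:
    """Lysine as a percentage of total protein."""
    if protein_g_per_100g <= 0:
        raise PopdiallelError("total protein must be positive")
    return 100.0 * lysine_g_per_100g / protein_g_per_100g


@dataclass(frozen=True)
class PoppingRetention:
    """Raw-to-popped change for one residue level."""

    loss: float  # raw - popped, g/100 g (negative = gain)
    retention_pct: float  # 100 * popped / raw
    gained: bool  # some residues rise after popping


def popping_retention(raw: float, popped: float) -> PoppingRetention:
    if raw <= 0:
        raise PopdiallelError("raw level must be positive")
    loss = raw - popped
    return PoppingRetention(
        loss=float(loss),
        retention_pct=float(100.0 * popped / raw),
        gained=popped > raw,
    )


def method_correlations(
    records: Iterable[AminoAcidRecord],
    flag_threshold: float = LOW_CORRELATION_FLAG,
) -> pd.DataFrame:
    """Pearson r across genotypes per residue/fraction per treatment pair.

    Genotype means are correlated between each pair of treatments; pairs
    with fewer than three paired genotypes are skipped with a warning.
    Rows with r below the threshold carry ``low_correlation = True``.
    """
    df = amino_frame(records)
    rows = []
    for (residue, fraction), sub in df.groupby(["residue", "fraction"]):
        wide = sub.pivot_table(
            index="genotype", columns="treatment", values="value",
            aggfunc="mean",
        )
        for t1, t2 in combinations(sorted(wide.columns), 2):
            pair = wide[[t1, t2]].dropna()
            if len(pair) < 3:
                warnings.warn(
                    f"{residue}/{fraction}: <3 genotypes for {t1}-{t2}; "
                    "pair skipped",
                    stacklevel=2,
                )
                continue
            r, p = stats.pearsonr(pair[t1], pair[t2])
            rows.append(
                {
                    "residue": residue,
                    "fraction": fraction,
                    "treatment_1": t1,
                    "treatment_2": t2,
                    "r": float(r),
                    "p": float(p),
                    "n": len(pair),
                    "low_correlation": bool(r < flag_threshold),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "residue",
            "fraction",
            "treatment_1",
            "treatment_2",
            "r",
            "p",
            "n",
            "low_correlation",
        ],
    )


@dataclass(frozen=True)
class InheritanceCall:
    """Mid-parent / high-parent classification for one residue."""

    residue: str
    hybrid_mean: float
    maternal_mean: float
    paternal_mean: float
    mid_parent: float
    call: str  # additive | dominant | over_dominant | ambiguous
    p_vs_mid: float
    p_vs_high: float


def _welch_above(
    hybrid: np.ndarray, other_mean: float, other_var: float, other_df: float,
    alpha: float,
) -> tuple[bool, float]:
    """Two-sided Welch test of hybrid mean vs a reference mean; 'above'
    requires both significance and a positive difference."""
    n = len(hybrid)
    v_h = hybrid.var(ddof=1) / n if n > 1 else 0.0
    se2 = v_h + other_var
    diff = hybrid.mean() - other_mean
    if se2 <= 0:
        if diff == 0:
            return False, 1.0
        return diff > 0, 0.0
    t = diff / np.sqrt(se2)
    if v_h > 0 and other_var > 0:
        dof = se2**2 / (v_h**2 / (n - 1) + other_var**2 / other_df)
    else:
        dof = max(n - 1, 1) if v_h > 0 else other_df
    p = float(2.0 * stats.t.sf(abs(t), dof))
    return (p < alpha) and (diff > 0), p


def classify_inheritance(
    hybrid: Sequence[float],
    maternal: Sequence[float],
    paternal: Sequence[float],
    alpha: float = 0.05,
    residue: str = "",
) -> InheritanceCall:
    """Classify hybrid inheritance against mid-parent and high-parent levels.

    Two Welch tests: hybrid vs the mid-parent value (mid-parent SE is half
    the root-sum-square of the parent SEs) and hybrid vs the high-parent
    group. Not above mid -> additive; above mid but not above high ->
    dominant; above high and above mid -> over-dominant; above high without
    above mid (or degenerate exact ties) -> ambiguous.
    """
    h = np.asarray(hybrid, dtype=float)
    m = np.asarray(maternal, dtype=float)
    p = np.asarray(paternal, dtype=float)
    if min(len(h), len(m), len(p)) < 2:
        raise PopdiallelError("need >=2 replicates per group")

    m_mean, p_mean = m.mean(), p.mean()
    mid = (m_mean + p_mean) / 2.0
    high = m if m_mean >= p_mean else p

    # mid-parent variance by the delta method: Var(mid) = (Var_m/n + Var_p/n)/4
    v_mid = (m.var(ddof=1) / len(m) + p.var(ddof=1) / len(p)) / 4.0
    df_mid = len(m) + len(p) - 2
    above_mid, p_mid = _welch_above(h, mid, v_mid, df_mid, alpha)

    v_high = high.var(ddof=1) / len(high)
    above_high, p_high = _welch_above(
        h, high.mean(), v_high, len(high) - 1, alpha
    )

    if (
        h.var(ddof=1) == 0
        and m.var(ddof=1) == 0
        and p.var(ddof=1) == 0
        and h.mean() == mid == high.mean()
    ):
        call = "ambiguous"
    elif above_high and above_mid:
        call = "over_dominant"
    elif above_mid:
        call = "dominant"
    elif above_high:
        call = "ambiguous"
    else:
        call = "additive"
    return InheritanceCall(
        residue=residue,
        hybrid_mean=float(h.mean()),
        maternal_mean=float(m_mean),
        paternal_mean=float(p_mean),
        mid_parent=float(mid),
        call=call,
        p_vs_mid=p_mid,
        p_vs_high=p_high,
    )


def classify_profiles(
    records: Iterable[AminoAcidRecord],
    hybrid: str,
    maternal: str,
    paternal: str,
    fraction: str = "protein_bound",
    treatment: str = "raw",
    alpha: float = 0.05,
    fdr: bool = False,
) -> list[InheritanceCall]:
    """Per-residue inheritance calls from a profile table.

    ``fdr=True`` applies Benjamini-Hochberg across residues to both test
    families before calling (off by default; per-residue trends otherwise).
    """
    df = amino_frame(records)
    df = df[(df["fraction"] == fraction) & (df["treatment"] == treatment)]
    calls = []
    for residue, sub in df.groupby("residue"):
        groups = {
            g: sub[sub["genotype"] == g]["value"].to_numpy()
            for g in (hybrid, maternal, paternal)
        }
        if any(len(v) < 2 for v in groups.values()):
            continue
        calls.append(
            classify_inheritance(
                groups[hybrid],
                groups[maternal],
                groups[paternal],
                alpha=alpha,
                residue=residue,
            )
        )
    if fdr and calls:
        calls = _apply_fdr(calls, alpha)
    return calls


def _apply_fdr(calls: list[InheritanceCall], alpha: float) -> list[InheritanceCall]:
    from scipy.stats import false_discovery_control

    p_mid = false_discovery_control([c.p_vs_mid for c in calls])
    p_high = false_discovery_control([c.p_vs_high for c in calls])
    adjusted = []
    for c, pm, ph in zip(calls, p_mid, p_high):
        above_mid = pm < alpha and c.hybrid_mean > c.mid_parent
        high_mean = max(c.maternal_mean, c.paternal_mean)
        above_high = ph < alpha and c.hybrid_mean > high_mean
        if above_high and above_mid:
            call = "over_dominant"
        elif above_mid:
            call = "dominant"
        elif above_high:
            call = "ambiguous"
        else:
            call = "additive"
        adjusted.append(
            InheritanceCall(
                residue=c.residue,
                hybrid_mean=c.hybrid_mean,
                maternal_mean=c.maternal_mean,
                paternal_mean=c.paternal_mean,
                mid_parent=c.mid_parent,
                call=call,
                p_vs_mid=float(pm),
                p_vs_high=float(ph),
            )
        )
    return adjusted


def daily_requirement_fraction(
    lysine_g_per_100g: float,
    serving_g: float,
    requirement_g_per_day: float,
) -> float:
    """Percent of the daily lysine requirement covered by one serving.

    The requirement is always a user input (published per-kg guidance and
    absolute figures are not mutually consistent), e.g. 30 mg/kg/day x
    body mass.
    """
    if requirement_g_per_day <= 0:
        raise PopdiallelError("requirement must be positive")
    grams = lysine_g_per_100g / 100.0 * serving_g
    return 100.0 * grams / requirement_g_per_day
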