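"""Synthetic diallel field trials, pedigrees, and amino-acid profiles.

Generates field-book / pedigree / amino-acid fixtures with the statistical
structure the downstream estimators assume: a 4-maternal x 12-paternal
factorial (selfs excluded, 44 crosses) grown in a generalized complete block
design at 2 locations x 6 replicate rows, with maternal/paternal GCA, SCA,
location, location-by-genotype, and plot-error variance components and a
factor-structured multi-trait genetic correlation (agronomic yield traits
positively intercorrelated and negatively related to expansion volume).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .datamodel_io import (
    AminoAcidRecord,
    PedigreeRecord,
    PlotObservation,
    PROPORTION_TRAITS,
)
from .errors import ConfigError

# ---------------------------------------------------------------------------
# Default design and parameter tables
# ---------------------------------------------------------------------------

DEFAULT_MATERNAL_IDS = ("I05", "I06", "I09", "I10")
DEFAULT_PATERNAL_IDS = tuple(f"I{i:02d}" for i in range(1, 13))
DEFAULT_LOCATIONS = ("NE", "KS")
DEFAULT_BLOCKS_PER_LOCATION = 6

#: trait -> grand mean (internal units: proportions in [0,1])
DEFAULT_TRAIT_MEANS: dict[str, float] = {
    "germination": 0.88,
    "dap": 62.0,
    "rot": 0.08,
    "neh": 11.0,
    "el": 15.0,
    "rpe": 14.0,
    "weg": 46.6,
    "ks": 68.0,
    "hgw": 13.0,
    "vit": 5.5,
    "pa": 0.93,
    "ev": 750.0,
}

#: trait -> (sigma2_mGCA, sigma2_pGCA, sigma2_SCA, sigma2_loc, sigma2_GxE,
#: sigma2_error); magnitudes chosen so plot-basis heritabilities fall in the
#: ~0.02-0.45 range typical of replicated popcorn trials.
DEFAULT_VARIANCE_COMPONENTS: dict[str, tuple[float, ...]] = {
    "germination": (0.0008, 0.0008, 0.0010, 0.0004, 0.0006, 0.006),
    "dap": (1.0, 1.0, 1.2, 2.0, 0.8, 8.0),
    "rot": (0.0003, 0.0003, 0.0004, 0.0002, 0.0004, 0.003),
    "neh": (0.4, 0.4, 0.5, 0.3, 0.6, 4.0),
    "el": (2.2, 0.6, 1.0, 0.5, 0.5, 4.5),
    "rpe": (0.5, 0.4, 0.5, 0.2, 0.3, 2.5),
    "weg": (60.0, 25.0, 40.0, 15.0, 25.0, 160.0),
    "ks": (35.0, 12.0, 18.0, 6.0, 10.0, 60.0),
    "hgw": (0.8, 0.3, 0.4, 0.2, 0.3, 1.4),
    "vit": (0.02, 0.25, 0.15, 0.05, 0.08, 0.5),
    "pa": (0.0002, 0.0008, 0.0006, 0.0002, 0.0003, 0.0025),
    "ev": (900.0, 1800.0, 1500.0, 500.0, 800.0, 6000.0),
}

#: Two-factor loading structure (agronomic, popping) used to build a valid
#: (PSD by construction) genetic correlation matrix across traits.
DEFAULT_FACTOR_LOADINGS: dict[str, tuple[float, float]] = {
    "germination": (0.30, 0.10),
    "dap": (0.10, 0.00),
    "rot": (-0.20, 0.00),
    "neh": (0.40, 0.10),
    "el": (0.70, 0.00),
    "rpe": (0.50, -0.10),
    "weg": (0.80, -0.20),
    "ks": (0.50, -0.30),
    "hgw": (0.70, -0.30),
    "vit": (0.00, 0.50),
    "pa": (-0.10, 0.70),
    "ev": (-0.40, 0.70),
}

_BOUNDED = {
    "germination": (0.0, 1.0),
    "rot": (0.0, 1.0),
    "pa": (0.0, 1.0),
    "vit": (1.0, 7.0),
}


def default_genetic_correlation(traits: Sequence[str]) -> np.ndarray:
    """Correlation matrix from the two-factor loading table (PSD)."""
    lam = np.array([DEFAULT_FACTOR_LOADINGS[t] for t in traits])
    corr = lam @ lam.T
    np.fill_diagonal(corr, 1.0)
    return corr


# ---------------------------------------------------------------------------
# Parameter / truth containers
# ---------------------------------------------------------------------------


@dataclass
class SimulationParams:
    """Full specification of one simulated multi-trait diallel trial."""

    maternal_ids: tuple[str, ...] = DEFAULT_MATERNAL_IDS
    paternal_ids: tuple[str, ...] = DEFAULT_PATERNAL_IDS
    locations: tuple[str, ...] = DEFAULT_LOCATIONS
    blocks_per_location: int = DEFAULT_BLOCKS_PER_LOCATION
    traits: tuple[str, ...] = tuple(DEFAULT_TRAIT_MEANS)
    means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_MEANS)
    )
    #: trait -> (m_gca, p_gca, sca, location, gxe, error) variances
    components: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_VARIANCE_COMPONENTS)
    )
    genetic_corr: Optional[np.ndarray] = None
    missing_prob: float = 0.0
    clip_bounded_traits: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genetic_corr is None:
            self.genetic_corr = default_genetic_correlation(self.traits)
        self.validate()

    def validate(self) -> None:
        corr = np.asarray(self.genetic_corr, dtype=float)
        t = len(self.traits)
        if corr.shape != (t, t):
            raise ConfigError("genetic correlation shape mismatch")
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise ConfigError("genetic correlation not symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
            raise ConfigError("genetic correlation diagonal not unit")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ConfigError("genetic correlation not positive semidefinite")
        for trait in self.traits:
            comps = self.components[trait]
            if len(comps) != 6 or any(c < 0 for c in comps):
                raise ConfigError(f"invalid variance components for {trait}")
        if not (0.0 <= self.missing_prob < 1.0):
            raise ConfigError("missing_prob outside [0,1)")

    @property
    def crosses(self) -> list[tuple[str, str]]:
        """All maternal x paternal combinations, selfs excluded."""
        return [
            (m, p)
            for m in self.maternal_ids
            for p in self.paternal_ids
            if m != p
        ]


@dataclass
class TrueEffects:
    """Ground-truth effect draws per trait, for recovery testing.

    Every effect vector is exactly centered (sum zero).
    """

    m_gca: dict[str, dict[str, float]]
    p_gca: dict[str, dict[str, float]]
    sca: dict[str, dict[tuple[str, str], float]]
    location: dict[str, dict[str, float]]
    gxe: dict[str, dict[tuple[str, str], float]]

    def to_jsonable(self) -> dict:
        return {
            "m_gca": self.m_gca,
            "p_gca": self.p_gca,
            "sca": {
                t: {f"{m}x{p}": v for (m, p), v in d.items()}
                for t, d in self.sca.items()
            },
            "location": self.location,
            "gxe": {
                t: {f"{loc}|{g}": v for (loc, g), v in d.items()}
                for t, d in self.gxe.items()
            },
        }


# ---------------------------------------------------------------------------
# Diallel trial simulation
# ---------------------------------------------------------------------------


def _correlated_effects(
    rng: np.random.Generator,
    n: int,
    sds: np.ndarray,
    chol: np.ndarray,
) -> np.ndarray:
    """n x T matrix with cross-trait correlation, exact zero column sums."""
    z = rng.standard_normal((n, chol.shape[0])) @ chol.T
    z *= sds
    z -= z.mean(axis=0)
    return z


def simulate_diallel_trial(
    params: SimulationParams,
) -> tuple[list[PlotObservation], TrueEffects]:
    """Simulate one multi-trait trial; returns plots and ground truth.

    Plot value = mu + g_maternal + g_paternal + s_cross + beta_location
    + (beta*tau)_location,cross + error, with GCA/SCA effects sharing the
    configured cross-trait correlation and independent per-trait errors.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    traits = list(params.traits)
    n_t = len(traits)
    corr = np.asarray(params.genetic_corr, dtype=float)
    # PSD-safe Cholesky: tiny jitter only if exactly singular
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(corr + 1e-10 * np.eye(n_t))

    comps = np.array([params.components[t] for t in traits])  # T x 6
    crosses = params.crosses
    n_m, n_p, n_c = (
        len(params.maternal_ids),
        len(params.paternal_ids),
        len(crosses),
    )
    n_loc = len(params.locations)

    mg = _correlated_effects(rng, n_m, np.sqrt(comps[:, 0]), chol)
    pg = _correlated_effects(rng, n_p, np.sqrt(comps[:, 1]), chol)
    sc = _correlated_effects(rng, n_c, np.sqrt(comps[:, 2]), chol)

    loc_eff = rng.standard_normal((n_loc, n_t)) * np.sqrt(comps[:, 3])
    loc_eff -= loc_eff.mean(axis=0)

    # grand-centered only: keeps the classical EMS coefficients exact so the
    # downstream expected-mean-square inversion stays unbiased
    gxe = rng.standard_normal((n_loc, n_c, n_t)) * np.sqrt(comps[:, 4])
    gxe -= gxe.mean(axis=(0, 1), keepdims=True)

    m_index = {m: i for i, m in enumerate(params.maternal_ids)}
    p_index = {p: i for i, p in enumerate(params.paternal_ids)}

    plots: list[PlotObservation] = []
    for li, loc in enumerate(params.locations):
        for block in range(1, params.blocks_per_location + 1):
            for ci, (m, p) in enumerate(crosses):
                if params.missing_prob and (
                    rng.random() < params.missing_prob
                ):
                    continue
                noise = rng.standard_normal(n_t) * np.sqrt(comps[:, 5])
                for ti, trait in enumerate(traits):
                    value = (
                        params.means[trait]
                        + mg[m_index[m], ti]
                        + pg[p_index[p], ti]
                        + sc[ci, ti]
                        + loc_eff[li, ti]
                        + gxe[li, ci, ti]
                        + noise[ti]
                    )
                    if params.clip_bounded_traits and trait in _BOUNDED:
                        lo, hi = _BOUNDED[trait]
                        value = min(max(value, lo), hi)
                    plots.append(
                        PlotObservation(
                            location=loc,
                            block=f"B{block}",
                            genotype=f"{m}x{p}",
                            trait=trait,
                            value=float(value),
                            maternal=m,
                            paternal=p,
                        )
                    )

    truth = TrueEffects(
        m_gca={
            t: {
                m: float(mg[m_index[m], ti])
                for m in params.maternal_ids
            }
            for ti, t in enumerate(traits)
        },
        p_gca={
            t: {
                p: float(pg[p_index[p], ti])
                for p in params.paternal_ids
            }
            for ti, t in enumerate(traits)
        },
        sca={
            t: {cross: float(sc[ci, ti]) for ci, cross in enumerate(crosses)}
            for ti, t in enumerate(traits)
        },
        location={
            t: {
                loc: float(loc_eff[li, ti])
                for li, loc in enumerate(params.locations)
            }
            for ti, t in enumerate(traits)
        },
        gxe={
            t: {
                (loc, f"{m}x{p}"): float(gxe[li, ci, ti])
                for li, loc in enumerate(params.locations)
                for ci, (m, p) in enumerate(crosses)
            }
            for ti, t in enumerate(traits)
        },
    )
    return plots, truth


# ---------------------------------------------------------------------------
# Amino-acid profile simulation
# ---------------------------------------------------------------------------

INHERITANCE_MODES = ("additive", "dominant", "over_dominant")

#: per-method multiplicative retention of the raw-kernel level
DEFAULT_RETENTION = {"air": 0.90, "microwave": 0.85, "oil": 0.75}


def simulate_amino_profiles(
    mode_map: Mapping[str, str],
    parent_levels: Mapping[str, tuple[float, float]],
    noise_cv: float = 0.05,
    replicates: int = 6,
    seed: int = 0,
    over_dominance_delta: float = 0.2,
    retention: Optional[Mapping[str, float]] = None,
    fraction: str = "protein_bound",
) -> list[AminoAcidRecord]:
    """Simulate hybrid + parent amino-acid profiles under known inheritance.

    Hybrid expected level per residue: mid-parent (additive), high parent
    (dominant), or high parent x (1 + delta) (over-dominant). Popped
    treatments scale the raw expectation by a per-method retention factor.
    Noise is normal with sd = noise_cv x expected level, floored at zero.
    """
    if retention is None:
        retention = DEFAULT_RETENTION
    rng = np.random.default_rng(seed)
    records: list[AminoAcidRecord] = []
    for residue, mode in mode_map.items():
        if mode not in INHERITANCE_MODES:
            raise ConfigError(f"unknown inheritance mode {mode!r}")
        mat, pat = parent_levels[residue]
        if mat < 0 or pat < 0:
            raise ConfigError("parent levels must be nonnegative")
        mid, high = (mat + pat) / 2.0, max(mat, pat)
        if mode == "additive":
            hyb = mid
        elif mode == "dominant":
            hyb = high
        else:
            hyb = high * (1.0 + over_dominance_delta)
        levels = {"maternal": mat, "paternal": pat, "hybrid": hyb}
        classes = {
            "maternal": "QPP_inbred",
            "paternal": "QPP_inbred",
            "hybrid": "QPP_hybrid",
        }
        treatments = {"raw": 1.0, **retention}
        for genotype, level in levels.items():
            for treatment, factor in treatments.items():
                if genotype != "hybrid" and treatment != "raw":
                    continue  # only hybrids are popped in the default design
                expected = level * factor
                draws = expected + rng.standard_normal(replicates) * (
                    noise_cv * expected
                )
                for rep, v in enumerate(draws, start=1):
                    records.append(
                        AminoAcidRecord(
                            genotype=genotype,
                            germplasm_class=classes[genotype],
                            residue=residue,
                            fraction=fraction,
                            treatment=treatment,
                            replicate=rep,
                            value=float(max(v, 0.0)),
                        )
                    )
    return records


# ---------------------------------------------------------------------------
# Default pedigree
# ---------------------------------------------------------------------------

#: Sister-line pairs share one QPM x popcorn origin; popcorn parents P2 and
#: P3 belong to one heterotic pool, so crosses between lines carrying P2 and
#: P3 (all other ancestors distinct) are same-pool hybrids.
_PEDIGREE_TABLE: tuple[tuple[str, str, str], ...] = (
    ("I01", "Tx807", "P2"),
    ("I02", "Tx807", "P2"),
    ("I03", "CML154Q", "P3"),
    ("I04", "CML154Q", "P3"),
    ("I05", "K0326Y", "P2"),
    ("I06", "K0326Y", "P2"),
    ("I07", "Tx807", "P4"),
    ("I08", "Tx807", "P4"),
    ("I09", "CML154Q", "P1"),
    ("I10", "CML154Q", "P1"),
    ("I11", "Tx807", "P3"),
    ("I12", "Tx807", "P3"),
)

POPCORN_POOLS = {"P1": "pool_A", "P2": "pool_B", "P3": "pool_B", "P4": "pool_C"}


def make_default_pedigree() -> list[PedigreeRecord]:
    """Twelve-inbred pedigree whose 44 default crosses populate all five
    heterosis categories (4 pseudo-self, 8 same-pool)."""
    return [
        PedigreeRecord(
            inbred=i,
            qpm_parent=q,
            popcorn_parent=p,
            heterotic_pool=POPCORN_POOLS[p],
        )
        for i, q, p in _PEDIGREE_TABLE
    ]


def default_crosses() -> list[tuple[str, str]]:
    """The default 44 maternal x paternal crosses (selfs excluded)."""
    return SimulationParams().crosses
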