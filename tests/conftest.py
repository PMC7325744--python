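"""Shared fixtures: small simulated trials and toy cell-mean layouts."""

import numpy as np
import pytest

from popdiallel.datamodel_io import PlotObservation
from popdiallel.synthetic_data import (
    SimulationParams,
    simulate_diallel_trial,
)


def single_trait_params(
    trait: str = "el",
    mean: float = 15.0,
    components: tuple[float, ...] = (2.2, 0.6, 1.0, 0.5, 0.5, 4.5),
    **kwargs,
) -> SimulationParams:
    """Params for a one-trait trial (fast path for estimator tests)."""
    return SimulationParams(
        traits=(trait,),
        means={trait: mean},
        components={trait: components},
        genetic_corr=np.eye(1),
        **kwargs,
    )


def complete_grid_params(**kwargs) -> SimulationParams:
    """Disjoint maternal/paternal ids: a full 4 x 12 grid with no structural
    holes, for exact zero-sum / reconstruction checks."""
    defaults = dict(
        maternal_ids=("M1", "M2", "M3", "M4"),
        paternal_ids=tuple(f"P{i:02d}" for i in range(1, 13)),
    )
    defaults.update(kwargs)
    return single_trait_params(**defaults)


@pytest.fixture(scope="session")
def default_trial():
    """One default multi-trait trial (44 crosses, 2 locations, 6 blocks)."""
    return simulate_diallel_trial(SimulationParams(seed=7))


@pytest.fixture(scope="session")
def complete_grid_trial():
    """Balanced complete-grid single-trait trial with its ground truth."""
    return simulate_diallel_trial(complete_grid_params(seed=11))


def make_plots(cell_values, trait="el", reps=1, noise=None, seed=0):
    """Plots from an explicit {(maternal, paternal): value} mapping.

    One location pair is synthesized so two-way fits are possible when
    reps >= 1; values are replicated across blocks (plus optional noise).
    """
    rng = np.random.default_rng(seed)
    plots = []
    for loc in ("L1", "L2"):
        for block in range(1, reps + 1):
            for (m, p), value in cell_values.items():
                v = value
                if noise is not None:
                    v += rng.normal(0.0, noise)
                plots.append(
                    PlotObservation(
                        location=loc,
                        block=f"B{block}",
                        genotype=f"{m}x{p}",
                        trait=trait,
                        value=float(v),
                        maternal=m,
                        paternal=p,
                    )
                )
    return plots
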