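import numpy as np
import pandas as pd
import pytest

from popdiallel.combining_ability import (
    combining_se,
    diallel_analysis,
    estimate_gca,
    estimate_sca,
    gca_standard_errors,
    hybrid_cell_means,
    sca_standard_errors,
)
from popdiallel.datamodel_io import PlotObservation
from popdiallel.errors import EmptyDesignError
from popdiallel.synthetic_data import simulate_diallel_trial

from conftest import complete_grid_params, make_plots

TOY = {("A", "C"): 10.0, ("A", "D"): 12.0, ("B", "C"): 14.0, ("B", "D"): 16.0}


class TestHybridCellMeans:
    def test_single_plot_cell_mean_is_value(self):
        plots = [
            PlotObservation(
                location="L1", block="B1", genotype="AxC",
                trait="el", value=10.0, maternal="A", paternal="C",
            )
        ]
        with pytest.raises(EmptyDesignError):
            hybrid_cell_means(plots, "ev")
        cells = hybrid_cell_means(plots, "el")
        assert cells.means.loc["A", "C"] == 10.0
        assert cells.counts.loc["A", "C"] == 1

    def test_toy_marginals(self):
        cells = hybrid_cell_means(make_plots(TOY), "el")
        assert cells.grand_mean == pytest.approx(13.0)
        assert cells.maternal_marginals.tolist() == pytest.approx([11.0, 15.0])
        assert cells.paternal_marginals.tolist() == pytest.approx([12.0, 14.0])

    def test_missing_cell_flagged_and_excluded(self):
        toy = dict(TOY)
        del toy[("B", "D")]
        cells = hybrid_cell_means(make_plots(toy), "el")
        assert cells.missing_cells == [("B", "D")]
        assert cells.maternal_marginals.loc["B"] == pytest.approx(14.0)
        assert cells.paternal_marginals.loc["D"] == pytest.approx(12.0)


class TestEstimateGca:
    def test_toy_effects(self):
        cells = hybrid_cell_means(make_plots(TOY), "el")
        mg = estimate_gca(cells, "maternal")
        pg = estimate_gca(cells, "paternal")
        assert mg.effects.tolist() == pytest.approx([-2.0, 2.0])
        assert pg.effects.tolist() == pytest.approx([-1.0, 1.0])

    def test_equal_cells_give_zero_effects(self):
        cells = hybrid_cell_means(
            make_plots({k: 5.0 for k in TOY}), "el"
        )
        assert estimate_gca(cells, "maternal").effects.abs().max() == 0.0

    def test_zero_sum_on_balanced_grid(self, complete_grid_trial):
        plots, _ = complete_grid_trial
        cells = hybrid_cell_means(plots, "el")
        for role in ("maternal", "paternal"):
            assert abs(estimate_gca(cells, role).effects.sum()) < 1e-10

    def test_single_parent_rejected(self):
        toy = {("A", "C"): 10.0, ("A", "D"): 12.0}
        cells = hybrid_cell_means(make_plots(toy), "el")
        with pytest.raises(EmptyDesignError):
            estimate_gca(cells, "maternal")


class TestEstimateSca:
    def test_additive_table_gives_zero_sca(self):
        cells = hybrid_cell_means(make_plots(TOY), "el")
        sca = estimate_sca(
            cells,
            estimate_gca(cells, "maternal"),
            estimate_gca(cells, "paternal"),
        )
        assert np.abs(sca.values.to_numpy()).max() < 1e-12

    def test_non_additive_toy(self):
        toy = {
            ("A", "C"): 10.0, ("A", "D"): 13.0,
            ("B", "C"): 14.0, ("B", "D"): 15.0,
        }
        cells = hybrid_cell_means(make_plots(toy), "el")
        sca = estimate_sca(
            cells,
            estimate_gca(cells, "maternal"),
            estimate_gca(cells, "paternal"),
        )
        expected = np.array([[-0.5, 0.5], [0.5, -0.5]])
        np.testing.assert_allclose(sca.values.to_numpy(), expected, atol=1e-12)

    def test_reconstruction_identity(self, complete_grid_trial):
        plots, _ = complete_grid_trial
        cells = hybrid_cell_means(plots, "el")
        mg = estimate_gca(cells, "maternal")
        pg = estimate_gca(cells, "paternal")
        sca = estimate_sca(cells, mg, pg)
        recon = (
            cells.grand_mean
            + mg.effects.to_numpy()[:, None]
            + pg.effects.to_numpy()[None, :]
            + sca.values
        )
        np.testing.assert_allclose(
            recon.to_numpy(), cells.means.to_numpy(), atol=1e-10
        )

    def test_row_and_column_sums_zero_on_balanced_grid(
        self, complete_grid_trial
    ):
        plots, _ = complete_grid_trial
        cells = hybrid_cell_means(plots, "el")
        sca = estimate_sca(
            cells,
            estimate_gca(cells, "maternal"),
            estimate_gca(cells, "paternal"),
        )
        assert sca.values.sum(axis=1).abs().max() < 1e-10
        assert sca.values.sum(axis=0).abs().max() < 1e-10

    def test_units_carried_through(self):
        # effects remain in trait units: scaling data scales SCA linearly
        cells = hybrid_cell_means(make_plots(TOY), "el")
        toy10 = {k: 10 * v for k, v in TOY.items()}
        cells10 = hybrid_cell_means(make_plots(toy10), "el")
        sca = estimate_sca(
            cells,
            estimate_gca(cells, "maternal"),
            estimate_gca(cells, "paternal"),
        )
        sca10 = estimate_sca(
            cells10,
            estimate_gca(cells10, "maternal"),
            estimate_gca(cells10, "paternal"),
        )
        np.testing.assert_allclose(
            sca10.values.to_numpy(), 10 * sca.values.to_numpy(), atol=1e-10
        )


class TestTranslationEquivariance:
    def test_adding_constant_shifts_only_grand_mean(self):
        cells = hybrid_cell_means(make_plots(TOY), "el")
        shifted = hybrid_cell_means(
            make_plots({k: v + 7.5 for k, v in TOY.items()}), "el"
        )
        assert shifted.grand_mean == pytest.approx(cells.grand_mean + 7.5)
        for role in ("maternal", "paternal"):
            pd.testing.assert_series_equal(
                estimate_gca(cells, role).effects,
                estimate_gca(shifted, role).effects,
                atol=1e-12,
            )


class TestStandardErrors:
    def test_zero_residual_variance_gives_zero_se(self):
        cells = hybrid_cell_means(make_plots(TOY, reps=2), "el")
        se = gca_standard_errors(cells, 0.0, "maternal")
        assert (se == 0).all()

    def test_doubled_replication_halves_squared_se(self):
        cells1 = hybrid_cell_means(make_plots(TOY, reps=2), "el")
        cells2 = hybrid_cell_means(make_plots(TOY, reps=4), "el")
        se1 = gca_standard_errors(cells1, 1.0, "maternal")
        se2 = gca_standard_errors(cells2, 1.0, "maternal")
        np.testing.assert_allclose(se2**2, se1**2 / 2.0, rtol=1e-12)

    def test_gca_se_matches_plot_weight_oracle(self):
        # independent route: per-plot contrast weights for g_A
        cells = hybrid_cell_means(make_plots(TOY, reps=3), "el")
        sigma2 = 2.5
        se = gca_standard_errors(cells, sigma2, "maternal")
        n_plots_per_cell = 6  # 2 locations x 3 blocks
        n_row_cells, n_cells = 2, 4
        weights = []
        for (m, _p) in TOY:
            w_cell = (1.0 / n_row_cells if m == "A" else 0.0) - 1.0 / n_cells
            weights.extend([w_cell / n_plots_per_cell] * n_plots_per_cell)
        oracle = np.sqrt(sigma2 * sum(w**2 for w in weights))
        assert se.loc["A"] == pytest.approx(oracle, rel=1e-10)

    def test_sca_se_matches_plot_weight_oracle(self):
        cells = hybrid_cell_means(make_plots(TOY, reps=3), "el")
        sigma2 = 1.8
        se = sca_standard_errors(cells, sigma2)
        n = 6
        # coefficient on each cell mean for s_{A,C}
        coefs = {}
        for (m, p) in TOY:
            c = 0.0
            if (m, p) == ("A", "C"):
                c += 1.0
            if m == "A":
                c -= 1.0 / 2
            if p == "C":
                c -= 1.0 / 2
            c += 1.0 / 4
            coefs[(m, p)] = c
        oracle = np.sqrt(sigma2 * sum(c**2 / n for c in coefs.values()))
        assert se.loc["A", "C"] == pytest.approx(oracle, rel=1e-10)

    def test_combining_se_dispatch(self):
        plots = make_plots(TOY, reps=3, noise=0.5, seed=1)
        cells = hybrid_cell_means(plots, "el")
        role_se = combining_se(plots, cells, "maternal")
        assert set(role_se.index) == {"A", "B"}
        assert (role_se > 0).all()
        cross_se = combining_se(plots, cells, ("A", "C"))
        assert cross_se > 0


class TestParameterRecovery:
    def test_gca_correlation_high_when_signal_dominates(self):
        # sigma2_pGCA / sigma2_error = 1 with 48 plots per paternal marginal
        rs = []
        for seed in range(5):
            params = complete_grid_params(
                components=(0.5, 1.0, 0.2, 0.1, 0.1, 1.0), seed=seed
            )
            plots, truth = simulate_diallel_trial(params)
            cells = hybrid_cell_means(plots, "el")
            est = estimate_gca(cells, "paternal").effects
            true = pd.Series(truth.p_gca["el"]).reindex(est.index)
            rs.append(np.corrcoef(est, true)[0, 1])
        assert np.mean(rs) >= 0.9


class TestDiallelAnalysis:
    def test_full_report(self, default_trial):
        plots, _ = default_trial
        est = diallel_analysis(plots, "el")
        assert est.mgca.effects.shape == (4,)
        assert est.pgca.effects.shape == (12,)
        assert est.sca.values.shape == (4, 12)
        assert est.mgca.standard_errors.notna().all()
        assert 0 <= est.mgca.heritability <= 1
        assert 0 <= est.hybrid_repeatability <= 1
        # selfs are structurally absent
        for m in ("I05", "I06", "I09", "I10"):
            assert pd.isna(est.sca.values.loc[m, m])
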