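"""Trajectory generation, time re-inference, and likelihood tables."""

import numpy as np
import pytest

from snow.data_model import TimeMap
from snow.flow_map import (
    GeneratedSeries,
    generate_timeseries,
    per_cell_loglik_over_time,
    reinfer_time,
)
from snow.networks import ModelConfig, SnowModel, TrainedModel
from snow.toy_sim import ToyDesign, simulate_toy


@pytest.fixture(scope="module")
def toy_and_model():
    design = ToyDesign(n_cells=80, n_types=2, n_rhythmic=6, n_flat=4)
    data, truth = simulate_toy(design, seed=5)
    model = SnowModel(ModelConfig(n_genes=data.n_genes, hidden_width=24, latent_dim=4), rng=1)
    trained = TrainedModel(
        model=model,
        time_map=TimeMap(0.0, 48.0),
        l_ref=float(np.median(data.library_sizes)),
        gene_names=data.gene_names,
    )
    return data, trained


class TestGenerate:
    def test_default_grid_is_100_points(self, toy_and_model):
        data, trained = toy_and_model
        series = generate_timeseries(trained, data=data)
        assert series.pseudo_times.size == 100
        assert series.values.shape == (80, 100, 10)

    def test_values_sum_to_library_size(self, toy_and_model):
        data, trained = toy_and_model
        series = generate_timeseries(trained, data=data, grid=np.array([8.0]))
        sums = series.values.sum(axis=2)
        np.testing.assert_allclose(sums, series.library_sizes[:, None], rtol=1e-3)

    def test_scalar_library_override(self, toy_and_model):
        data, trained = toy_and_model
        series = generate_timeseries(trained, data=data, grid=np.array([0.0, 24.0]), l=500.0)
        np.testing.assert_allclose(series.values.sum(axis=2), 500.0, rtol=1e-3)

    def test_cycling_style_grid(self, toy_and_model):
        data, trained = toy_and_model
        series = generate_timeseries(trained, data=data, grid=np.linspace(0, 48, 24))
        assert series.pseudo_times.size == 24
        assert series.pseudo_times[-1] == 48.0

    def test_deterministic_given_checkpoint(self, toy_and_model):
        data, trained = toy_and_model
        s1 = generate_timeseries(trained, data=data, grid=np.array([4.0, 12.0]))
        s2 = generate_timeseries(trained, data=data, grid=np.array([4.0, 12.0]))
        np.testing.assert_array_equal(s1.values, s2.values)

    def test_latent_input_route(self, toy_and_model):
        _, trained = toy_and_model
        z = np.zeros((3, 4))
        series = generate_timeseries(trained, z=z, grid=np.array([0.0, 24.0]))
        assert series.values.shape == (3, 2, 10)

    def test_sampled_counts_are_integers(self, toy_and_model):
        data, trained = toy_and_model
        series = generate_timeseries(
            trained, data=data, grid=np.array([6.0]), sample=True,
            rng=np.random.default_rng(0),
        )
        assert np.all(series.values == np.round(series.values))

    def test_empty_grid_rejected(self, toy_and_model):
        data, trained = toy_and_model
        with pytest.raises(ValueError):
            generate_timeseries(trained, data=data, grid=np.array([]))

    def test_decreasing_grid_rejected(self):
        with pytest.raises(ValueError):
            GeneratedSeries(
                pseudo_times=np.array([1.0, 0.0]),
                values=np.zeros((1, 2, 1)),
                cell_ids=np.array(["c"]),
                library_sizes=np.array([1.0]),
            )


class TestReinference:
    def test_mae_zero_iff_exact(self, toy_and_model):
        data, trained = toy_and_model
        series = generate_timeseries(trained, data=data, grid=np.linspace(0, 48, 5))
        ri = reinfer_time(trained, series)
        assert ri.mae >= 0.0
        assert ri.t_hat.shape == (80, 5)
        assert ri.mae == pytest.approx(np.abs(ri.t_hat - series.pseudo_times).mean())

    def test_best_constant_predictor_mae_is_quarter_span(self):
        """If the predictor outputs a constant, the best achievable MAE on a
        uniform grid of span S is S/4 (constant at the midpoint)."""
        S = 48.0
        grid = np.linspace(0.0, S, 1001)
        mae_mid = np.abs(grid - S / 2).mean()
        assert mae_mid == pytest.approx(S / 4, rel=1e-3)

    def test_gene_mismatch_rejected(self, toy_and_model):
        _, trained = toy_and_model
        bad = GeneratedSeries(
            pseudo_times=np.array([0.0, 1.0]),
            values=np.ones((2, 2, 7)),
            cell_ids=np.array(["a", "b"]),
            library_sizes=np.ones(2),
        )
        with pytest.raises(ValueError):
            reinfer_time(trained, bad)


class TestLikelihoodTable:
    def test_total_equals_per_gene_sum(self, toy_and_model):
        data, trained = toy_and_model
        table = per_cell_loglik_over_time(trained, data)
        np.testing.assert_allclose(
            table.per_cell["log_likelihood"].to_numpy(),
            table.per_gene.sum(axis=1),
            rtol=1e-10,
        )

    def test_grouping_by_constant_key(self, toy_and_model):
        data, trained = toy_and_model
        table = per_cell_loglik_over_time(trained, data, group_keys=("everything",))
        med = table.per_cell.groupby("everything")["log_likelihood"].median()
        assert len(med) == 1

    def test_grouped_by_time_covers_levels(self, toy_and_model):
        data, trained = toy_and_model
        table = per_cell_loglik_over_time(trained, data)
        med = table.grouped_median("time")
        assert set(med.index) == set(data.time_levels)

    def test_spiked_timepoint_has_depressed_likelihood(self):
        """A 10-fold batch spike at one timepoint drops that timepoint's
        median per-cell log-likelihood under a model fit to the clean data."""
        from snow.loss_train import LossWeights, TrainConfig, train
        from snow.networks import ModelConfig
        from snow.toy_sim import inject_batch_spike

        design = ToyDesign(n_cells=160, n_types=2, n_rhythmic=4, n_flat=8)
        data, _ = simulate_toy(design, seed=9)
        trained = train(
            data,
            ModelConfig(n_genes=data.n_genes, hidden_width=32, latent_dim=4),
            TrainConfig(
                batch_size=80, n_steps=400, n_synthetic=16, smooth_n_cells=8,
                n_projections=16, seed=0, log_every=100,
            ),
        )
        spike_t = data.time_levels[3]
        spiked = inject_batch_spike(data, gene=0, timepoint=spike_t, fold=10.0)
        med_clean = per_cell_loglik_over_time(trained, data).grouped_median("time")
        med_spiked = per_cell_loglik_over_time(trained, spiked).grouped_median("time")
        # the likelihood drop attributable to the spike, per timepoint
        drop = med_spiked - med_clean
        assert drop.loc[spike_t] < drop.drop(index=spike_t).min() - 1.0
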