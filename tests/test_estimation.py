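"""Losses, interpolation, and the two fitting procedures."""

import numpy as np
import pandas as pd
import pytest

from blanchsim import (
    ArrheniusRate,
    Dataset,
    FitSpec,
    FreeParameter,
    MonophasicInactivation,
    cyclic_coordinate_fit,
    fit_parameters,
    rmse,
    weighted_l2,
)
from blanchsim.errors import ExtrapolationError, FitError, ValidationError
from blanchsim.estimation import interpolate_prediction
from blanchsim.synthetic import NoiseModel, gen_isothermal_activity
from blanchsim.workflows import isothermal_activity_forward, monophasic_from_params

T_REF = 353.15


def make_dataset(rows):
    return Dataset(
        records=pd.DataFrame(rows, columns=["experiment_id", "observable", "time_s", "value"])
    )


class TestLosses:
    def test_perfect_prediction_gives_zero_rmse(self):
        t = np.linspace(0, 10, 11)
        y = np.exp(-0.3 * t)
        assert rmse(t, y, t, y) == 0.0

    def test_constant_offset_gives_the_offset(self):
        t = np.linspace(0, 10, 11)
        y = np.exp(-0.3 * t)
        assert rmse(t, y + 0.07, t, y) == pytest.approx(0.07)

    def test_interpolated_residual_by_hand(self):
        # knots (0, 1.0) and (10, 0.0); observation 0.4 at t=5 -> residual 0.1
        value = rmse([5.0], [0.4], [0.0, 10.0], [1.0, 0.0])
        assert value == pytest.approx(0.1)

    def test_observation_outside_prediction_range_rejected(self):
        with pytest.raises(ExtrapolationError):
            interpolate_prediction([0.0, 10.0], [1.0, 0.0], [12.0])

    def test_single_experiment_weighted_l2_is_mse(self):
        obs = {"a": (np.array([0.0, 5.0, 10.0]), np.array([1.0, 0.5, 0.2]))}
        pred = {"a": (np.array([0.0, 10.0]), np.array([1.0, 0.0]))}
        resid = np.array([0.0, 0.0, 0.2])
        assert weighted_l2(obs, pred) == pytest.approx(np.mean(resid**2))

    def test_experiments_weigh_equally_regardless_of_density(self):
        # 2-point and 10-point experiments, every residual 0.1 -> 0.01+0.01
        obs = {
            "small": (np.linspace(1, 2, 2), np.full(2, 0.1)),
            "big": (np.linspace(1, 2, 10), np.full(10, 0.1)),
        }
        pred = {k: (np.array([0.0, 3.0]), np.array([0.0, 0.0])) for k in obs}
        assert weighted_l2(obs, pred) == pytest.approx(0.02)
        assert weighted_l2(obs, pred, mode="sum") == pytest.approx(0.02 + 0.08 + 0.02)

    def test_empty_experiment_rejected(self):
        obs = {"a": (np.array([]), np.array([]))}
        pred = {"a": (np.array([0.0, 1.0]), np.array([0.0, 0.0]))}
        with pytest.raises(ValidationError):
            weighted_l2(obs, pred)


@pytest.fixture(scope="module")
def mono_truth():
    return MonophasicInactivation(ArrheniusRate(0.05, T_REF, 200e3))


@pytest.fixture(scope="module")
def mono_dataset(mono_truth):
    return gen_isothermal_activity(
        mono_truth, (70.0, 75.0, 80.0, 85.0), (30.0, 60.0, 120.0, 300.0, 600.0),
        observable="activity_pme",
    )


def mono_forward(dataset):
    times = np.unique(dataset.records["time_s"].to_numpy(float))
    return isothermal_activity_forward(
        lambda p: monophasic_from_params(p, T_REF), dataset.conditions, times
    )


def mono_spec(k0, e0, **kwargs):
    return FitSpec(
        free=[
            FreeParameter("k_ref", k0, 1e-4, 1.0, log_scale=True),
            FreeParameter("ea", e0, 50e3, 500e3),
        ],
        **kwargs,
    )


class TestQuasiNewtonFit:
    def test_starting_at_truth_converges_immediately(self, mono_dataset):
        fwd = mono_forward(mono_dataset)
        fit = fit_parameters(mono_spec(0.05, 200e3), mono_dataset, fwd, "activity_pme")
        assert fit.loss < 1e-10
        assert fit.n_iterations <= 2

    def test_perturbed_start_recovers_parameters(self, mono_dataset):
        fwd = mono_forward(mono_dataset)
        fit = fit_parameters(mono_spec(0.05 * 1.5, 200e3 * 1.5), mono_dataset, fwd, "activity_pme")
        assert fit.params["k_ref"] == pytest.approx(0.05, rel=1e-2)
        assert fit.params["ea"] == pytest.approx(200e3, rel=1e-2)
        assert fit.converged

    def test_agrees_with_dense_grid_search_on_one_parameter(self, mono_dataset):
        fwd = mono_forward(mono_dataset)
        spec = FitSpec(
            free=[FreeParameter("k_ref", 0.02, 1e-3, 0.5, log_scale=True)],
            fixed={"ea": 200e3},
        )
        fit = fit_parameters(spec, mono_dataset, fwd, "activity_pme")
        grid = np.geomspace(1e-3, 0.5, 4001)
        obs = mono_dataset.observations("activity_pme")
        losses = [
            weighted_l2(obs, fwd({"k_ref": k, "ea": 200e3})) for k in grid
        ]
        k_grid = grid[int(np.argmin(losses))]
        assert fit.params["k_ref"] == pytest.approx(k_grid, rel=2e-3)

    def test_row_order_never_changes_the_fit(self, mono_dataset, mono_truth):
        fwd = mono_forward(mono_dataset)
        shuffled = Dataset(
            records=mono_dataset.records.sample(frac=1.0, random_state=5).reset_index(drop=True),
            conditions=mono_dataset.conditions,
        )
        f1 = fit_parameters(mono_spec(0.08, 260e3), mono_dataset, fwd, "activity_pme")
        f2 = fit_parameters(mono_spec(0.08, 260e3), shuffled, fwd, "activity_pme")
        assert f1.params == f2.params

    def test_multistart_never_worse_than_initial_points(self, mono_dataset):
        fwd = mono_forward(mono_dataset)
        fit = fit_parameters(
            mono_spec(0.3, 450e3, multistart=4, seed=11), mono_dataset, fwd, "activity_pme"
        )
        assert len(fit.multistart) == 4
        assert all(fit.loss <= row["start_loss"] + 1e-15 for row in fit.multistart)

    def test_noisy_replicates_are_unbiased(self, mono_truth):
        """Multiplicative 5 % noise: mean recovered k_ref over 50 seeded
        replicates lies within 2 standard errors of the truth."""
        recovered = []
        for seed in range(50):
            ds = gen_isothermal_activity(
                mono_truth, (70.0, 75.0, 80.0, 85.0), (30.0, 60.0, 120.0, 300.0, 600.0),
                noise=NoiseModel(sigma=0.05, seed=seed), observable="activity_pme",
            )
            fwd = mono_forward(ds)
            fit = fit_parameters(mono_spec(0.08, 250e3), ds, fwd, "activity_pme")
            recovered.append(fit.params["k_ref"])
        recovered = np.array(recovered)
        se = recovered.std(ddof=1) / np.sqrt(recovered.size)
        assert abs(recovered.mean() - 0.05) < 2 * se


class TestCyclicCoordinateFit:
    @staticmethod
    def quadratic_problem():
        """Separable quadratic: loss = (a-2)^2 + (b+1)^2 via a linear model."""
        records = pd.DataFrame(
            [("e1", "temperature", 0.0, 2.0), ("e2", "temperature", 0.0, -1.0)],
            columns=["experiment_id", "observable", "time_s", "value"],
        )
        ds = Dataset(records=records)

        def forward(p):
            return {
                "e1": (np.array([0.0, 1.0]), np.full(2, p["a"])),
                "e2": (np.array([0.0, 1.0]), np.full(2, p["b"])),
            }

        spec = FitSpec(
            free=[FreeParameter("a", 0.0, -5.0, 5.0), FreeParameter("b", 0.0, -5.0, 5.0)],
            method="cyclic_coordinate",
        )
        return spec, ds, forward

    def test_separable_quadratic_solved_in_one_cycle(self):
        spec, ds, forward = self.quadratic_problem()
        fit = cyclic_coordinate_fit(spec, ds, forward, "temperature")
        assert fit.params["a"] == pytest.approx(2.0, abs=1e-3)
        assert fit.params["b"] == pytest.approx(-1.0, abs=1e-3)
        assert fit.n_iterations <= 2

    def test_stops_after_mandatory_first_cycle_when_already_optimal(self):
        spec, ds, forward = self.quadratic_problem()
        spec.free = [FreeParameter("a", 2.0, -5.0, 5.0), FreeParameter("b", -1.0, -5.0, 5.0)]
        fit = cyclic_coordinate_fit(spec, ds, forward, "temperature")
        assert fit.n_iterations == 1
        assert fit.loss < 1e-6


class TestValidation:
    def test_initial_value_outside_bounds_rejected(self):
        with pytest.raises(ValidationError):
            FreeParameter("k", 2.0, 0.0, 1.0)

    def test_log_scale_needs_positive_bounds(self):
        with pytest.raises(ValidationError):
            FreeParameter("k", 0.5, -1.0, 1.0, log_scale=True)

    def test_dataset_requires_known_observables(self):
        with pytest.raises(ValidationError):
            make_dataset([("e", "colour", 0.0, 1.0)])

    def test_dataset_activity_range_enforced(self):
        with pytest.raises(ValidationError):
            make_dataset([("e", "activity_pod", 0.0, 1.5)])

    def test_non_finite_initial_loss_raises(self, mono_dataset):
        def bad_forward(params):
            return {
                eid: (np.array([0.0, 1e4]), np.array([np.nan, np.nan]))
                for eid in mono_dataset.conditions
            }

        with pytest.raises(FitError):
            fit_parameters(mono_spec(0.05, 200e3), mono_dataset, bad_forward, "activity_pme")
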