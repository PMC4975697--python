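"""Synthetic data generation and parameter estimation."""

import numpy as np
import pytest

from cyanopbr import (
    CultureState,
    EstimationSpec,
    HeterotrophicParams,
    ObservationSet,
    ParameterSpec,
    fit,
    generate_synthetic,
    objective,
    simulate_collocation,
    simulate_heterotrophic,
)
from cyanopbr.estimation import _PENALTY

DESIGN = np.linspace(0.0, 150.0, 31)[1:]


@pytest.fixture(scope="module")
def noiseless_obs(het_params, optics, lab_light, replete_state):
    return generate_synthetic(
        het_params, replete_state, DESIGN, optics, lab_light, noise_scale=0.0, seed=0
    )


class TestSyntheticData:
    def test_noiseless_samples_equal_model_trajectory(
        self, noiseless_obs, het_params, optics, lab_light, replete_state
    ):
        t_full = np.concatenate([[0.0], DESIGN])
        traj = simulate_heterotrophic(replete_state, t_full, het_params, optics, lab_light)
        for v in noiseless_obs.variables:
            np.testing.assert_allclose(noiseless_obs.data[v].to_numpy(), traj[v][1:])

    def test_seed_determinism(self, het_params, optics, lab_light, replete_state):
        a = generate_synthetic(het_params, replete_state, DESIGN, optics, lab_light,
                               noise_scale=0.05, seed=7)
        b = generate_synthetic(het_params, replete_state, DESIGN, optics, lab_light,
                               noise_scale=0.05, seed=7)
        c = generate_synthetic(het_params, replete_state, DESIGN, optics, lab_light,
                               noise_scale=0.05, seed=8)
        for v in a.variables:
            np.testing.assert_array_equal(a.data[v], b.data[v])
        assert not np.array_equal(a.data["X"], c.data["X"])

    def test_relative_noise_scale_is_calibrated(
        self, noiseless_obs, het_params, optics, lab_light, replete_state
    ):
        # Pool relative residuals across seeds: their spread should match
        # the requested 5% multiplicative scale.
        truth = noiseless_obs.data["X"].to_numpy()
        resid = []
        for seed in range(10):
            noisy = generate_synthetic(het_params, replete_state, DESIGN, optics,
                                       lab_light, observed=("X",), noise_scale=0.05,
                                       seed=seed)
            resid.append(noisy.data["X"].to_numpy() / truth - 1.0)
        cv = np.std(np.concatenate(resid))
        assert 0.04 < cv < 0.06

    def test_csv_round_trip(self, noiseless_obs, tmp_path):
        path = tmp_path / "obs.csv"
        noiseless_obs.to_csv(path)
        back = ObservationSet.from_csv(path)
        np.testing.assert_allclose(back.times, noiseless_obs.times)
        for v in noiseless_obs.variables:
            np.testing.assert_allclose(back.data[v], noiseless_obs.data[v])

    def test_unsorted_times_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            ObservationSet(np.array([0.0, 2.0, 1.0]), pd.DataFrame({"X": [1, 2, 3]}))


TWO_FREE = {
    "mu_max_h": ParameterSpec(0.1, 0.6, 0.25),
    "kq": ParameterSpec(0.05, 0.4, 0.25),
}


class TestObjective:
    def test_zero_at_truth(self, noiseless_obs, optics, lab_light, replete_state):
        spec = EstimationSpec(free=TWO_FREE)
        loss = objective([0.332, 0.165], spec, noiseless_obs, replete_state, optics, lab_light)
        assert loss == pytest.approx(0.0, abs=1e-10)

    def test_positive_off_truth(self, noiseless_obs, optics, lab_light, replete_state):
        spec = EstimationSpec(free=TWO_FREE)
        loss = objective([0.332 * 1.1, 0.165], spec, noiseless_obs, replete_state,
                         optics, lab_light)
        assert loss > 1e-3

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_simulation_failure_gives_finite_penalty(
        self, noiseless_obs, optics, lab_light
    ):
        # KN=0 with N0=0 makes the nitrate Monod term 0/0; the failed
        # simulation must surface as a large finite loss, not an exception.
        spec = EstimationSpec(free=TWO_FREE, fixed={"KN": 0.0})
        bad_state = CultureState(X=0.2, N=0.0, q=1.0, C=50.0, O2=0.0)
        loss = objective([0.332, 0.165], spec, noiseless_obs, bad_state, optics, lab_light)
        assert np.isfinite(loss)
        assert loss >= _PENALTY**2

    def test_free_and_fixed_must_be_disjoint(self):
        with pytest.raises(ValueError):
            EstimationSpec(free=TWO_FREE, fixed={"kq": 0.2})

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError):
            EstimationSpec(free={"not_a_param": ParameterSpec(0, 1, 0.5)})


class TestCollocationBackend:
    def test_matches_stiff_integrator(self, het_params, optics, lab_light, replete_state):
        t = np.linspace(0.0, 100.0, 21)
        shoot = simulate_heterotrophic(replete_state, t, het_params, optics, lab_light)
        colloc = simulate_collocation(replete_state, t, het_params, optics, lab_light)
        for v in ("X", "N", "q", "C", "O2", "H2"):
            scale = max(np.max(np.abs(shoot[v])), 1e-12)
            assert np.max(np.abs(shoot[v] - colloc[v])) / scale < 1e-5

    def test_loss_agreement_between_backends(
        self, noiseless_obs, optics, lab_light, replete_state
    ):
        spec = EstimationSpec(free=TWO_FREE)
        x = [0.30, 0.20]  # deliberately off-truth: both losses are nonzero
        a = objective(x, spec, noiseless_obs, replete_state, optics, lab_light,
                      backend="shooting")
        b = objective(x, spec, noiseless_obs, replete_state, optics, lab_light,
                      backend="collocation")
        assert abs(a - b) / a < 1e-4


class TestFit:
    def test_noiseless_recovery_two_parameters(
        self, noiseless_obs, optics, lab_light, replete_state
    ):
        spec = EstimationSpec(free=TWO_FREE)
        res = fit(spec, noiseless_obs, replete_state, optics, lab_light,
                  n_restarts=1, seed=0)
        assert res.estimates["mu_max_h"] == pytest.approx(0.332, rel=1e-2)
        assert res.estimates["kq"] == pytest.approx(0.165, rel=1e-2)
        assert res.loss < 1e-9

    def test_recovery_error_shrinks_with_noise(
        self, het_params, optics, lab_light, replete_state
    ):
        spec = EstimationSpec(free={"mu_max_h": ParameterSpec(0.1, 0.6, 0.2)})
        errors = []
        for scale in (0.10, 0.0):
            obs = generate_synthetic(het_params, replete_state, DESIGN, optics,
                                     lab_light, noise_scale=scale, seed=5)
            res = fit(spec, obs, replete_state, optics, lab_light, n_restarts=1, seed=0)
            errors.append(abs(res.estimates["mu_max_h"] - 0.332) / 0.332)
        assert errors[1] < errors[0]
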