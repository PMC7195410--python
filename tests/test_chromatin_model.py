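import numpy as np
import pytest

from flcseason import (
    ChromatinParams,
    ChromatinState,
    LogisticResponse,
    TemperatureModel,
    apply_variant,
    gen_temperature,
    logistic_rate,
    ode_rhs,
    predict_mrna,
    scale_states_to_levels,
    simulate,
    simulate_stochastic,
)
from flcseason.chromatin_model import (
    _rhs_compiled,
    _rhs_unchecked,
    find_fixed_point,
    initial_state_from_levels,
)
from flcseason.synthetic_data import DEFAULT_INIT, default_params


def random_state(rng):
    k27 = rng.dirichlet(np.ones(4))
    return np.concatenate([k27, rng.uniform(0, 1, 2)])


def random_params(rng, variant=1):
    d = dict(zip(
        ("zeta", "alpha", "eta", "beta", "iota", "gamma", "rho_amp",
         "epsilon", "kappa", "lambda", "phi", "psi"),
        np.maximum(rng.uniform(0, 10, 12), 1e-3),
    ))
    d["variant"] = variant
    return ChromatinParams.from_dict(d)


class TestLogisticRate:
    def test_midpoint_is_half_amplitude(self):
        for direction in ("cold-activated", "warm-activated"):
            f = LogisticResponse(2.0, 1.3, 5.0, direction)
            assert logistic_rate(5.0, f) == pytest.approx(1.0)

    def test_cold_activated_saturation(self):
        f = LogisticResponse(3.0, 1.0, 5.0, "cold-activated")
        assert logistic_rate(1e4, f) == pytest.approx(0.0, abs=1e-12)
        assert logistic_rate(-1e4, f) == pytest.approx(3.0)

    def test_unit_example(self):
        f = LogisticResponse(1.0, 1.0, 5.0, "cold-activated")
        assert logistic_rate(7.0, f) == pytest.approx(
            1.0 / (1.0 + np.e**2)
        )

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            LogisticResponse(-1.0, 1.0, 5.0, "cold-activated")
        with pytest.raises(ValueError):
            LogisticResponse(1.0, 0.0, 5.0, "cold-activated")


class TestOdeRhs:
    def test_worked_symmetric_state(self):
        """Equal K27 proportions, half-occupied K4, all rates 1: the only
        imbalance is the half-strength removal step."""
        params = ChromatinParams(
            mu=LogisticResponse(2.0, 1.0, 5.0, "cold-activated"),
            nu=LogisticResponse(2.0, 1.0, 5.0, "warm-activated"),
            xi=LogisticResponse(2.0, 1.0, 5.0, "warm-activated"),
            tau_fn=LogisticResponse(2.0, 1.0, 5.0, "cold-activated"),
            kappa=1.0, lam=1.0, phi=1.0, psi=1.0,
        )
        state = ChromatinState(0.25, 0.25, 0.25, 0.25, aN=0.5, aD=0.5)
        deriv = ode_rhs(state, T=5.0, params=params)  # all sensors -> 1
        np.testing.assert_array_equal(deriv[:4], [0.0, 0.0, 0.125, -0.125])

    def test_k4_gain_vanishes_at_full_occupancy(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            vec = random_state(rng)
            vec[4] = 1.0  # aN = 1
            p = random_params(rng)
            assert ode_rhs(vec, rng.uniform(-10, 30), p)[4] <= 1e-12

    def test_k27_cycle_conserves_mass(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            vec = random_state(rng)
            p = random_params(rng, variant=rng.integers(1, 5))
            deriv = ode_rhs(vec, rng.uniform(-10, 30), p)
            assert abs(deriv[:4].sum()) < 1e-12

    def test_state_outside_simplex_rejected(self):
        p = random_params(np.random.default_rng(2))
        with pytest.raises(ValueError, match="simplex"):
            ode_rhs(np.array([0.5, 0.5, 0.5, 0.5, 0.5, 0.5]), 10.0, p)

    def test_compiled_rhs_matches_reference(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            vec = random_state(rng)
            variant = int(rng.integers(1, 5))
            p = random_params(rng, variant)
            T = rng.uniform(-10, 30)
            d = p.to_dict()
            pv = np.array([
                d["zeta"], d["alpha"], d["theta1"],
                d["eta"], d["beta"], d["theta2"],
                d["iota"], d["gamma"], d["theta3"],
                d["rho_amp"], d["epsilon"], d["theta4"],
                d["kappa"], d["lambda"], d["phi"], d["psi"],
                float(variant),
            ])
            np.testing.assert_allclose(
                _rhs_compiled(vec, T, pv), _rhs_unchecked(vec, T, p),
                atol=1e-14,
            )


class TestApplyVariant:
    def test_variant2_equals_full_model_at_full_k4(self):
        rng = np.random.default_rng(4)
        p1 = random_params(rng, 1)
        p2 = p1.with_variant(2)
        vec = random_state(rng)
        vec[4] = 1.0
        np.testing.assert_allclose(
            _rhs_unchecked(vec, 8.0, p1), _rhs_unchecked(vec, 8.0, p2)
        )

    def test_variant3_equals_full_model_when_nr_fully_covered(self):
        rng = np.random.default_rng(5)
        p1 = random_params(rng, 1)
        p3 = p1.with_variant(3)
        vec = np.array([0.0, 0.6, 0.4, 0.0, 0.5, 0.5])  # mNuD+mNmD = 1
        np.testing.assert_allclose(
            _rhs_unchecked(vec, 8.0, p1), _rhs_unchecked(vec, 8.0, p3)
        )

    def test_variant2_removes_winter_k27_faster(self, temp_smooth):
        # without the aN gate, the removal step runs through winter when
        # K4 at the NR is repressed
        p1 = default_params()
        p2 = p1.with_variant(2)
        t_grid = np.arange(183.0, 500.0)
        tr1 = simulate(p1, temp_smooth, t_grid, DEFAULT_INIT)
        tr2 = simulate(p2, temp_smooth, t_grid, DEFAULT_INIT)
        winter = slice(90, 180)
        assert tr2[winter, 2].max() < tr1[winter, 2].max()

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            default_params().with_variant(5)


class TestSimulate:
    def test_conservation_and_bounds_over_two_years(self, params, temp):
        t_grid = np.arange(0.0, 731.0)
        traj = simulate(params, temp, t_grid, DEFAULT_INIT)
        assert np.abs(traj[:, :4].sum(axis=1) - 1).max() < 1e-6
        assert traj.min() >= 0 and traj.max() <= 1

    def test_refinement_stability(self, params, temp):
        t_grid = np.arange(0.0, 731.0, 7.0)
        a = simulate(params, temp, t_grid, DEFAULT_INIT,
                     rtol=1e-8, atol=1e-10)
        b = simulate(params, temp, t_grid, DEFAULT_INIT,
                     rtol=5e-9, atol=5e-11)
        assert np.abs(a - b).max() < 1e-5

    def test_constant_temperature_reaches_fixed_point(self, params):
        # 8 °C keeps every transition rate well away from 0, so the
        # slowest relaxation mode settles within the horizon
        const = gen_temperature(
            TemperatureModel(annual_mean=8.0, amplitude=0.0, noise_sd=0.0),
            n_years=9,
        )
        fp = find_fixed_point(params, 8.0).as_array()
        traj = simulate(params, const, np.array([0.0, 3000.0]),
                        DEFAULT_INIT)
        np.testing.assert_allclose(traj[-1], fp, atol=1e-4)

    def test_grid_outside_coverage_rejected(self, params, temp):
        with pytest.raises(ValueError, match="coverage"):
            simulate(params, temp, np.array([0.0, 5000.0]), DEFAULT_INIT)

    def test_sustained_cold_accumulates_nucleation_state(self, params):
        """Deep cold from the bare state: nucleation fires (mu active),
        spreading stalls (nu is warm-activated), so MU dominates."""
        cold = gen_temperature(
            TemperatureModel(annual_mean=-2.0, amplitude=0.0,
                             noise_sd=0.0), 3)
        init = ChromatinState(1.0, 0.0, 0.0, 0.0, aN=1.0, aD=0.0)
        traj = simulate(params, cold, np.array([0.0, 400.0]), init)
        assert traj[-1, 1] > 0.9

    def test_warmth_after_full_coverage_clears_without_um_peak(
        self, params
    ):
        """From MM dominance in sustained warmth, mass exits through UM to
        UU without UM ever accumulating."""
        warm = gen_temperature(
            TemperatureModel(annual_mean=22.0, amplitude=0.0,
                             noise_sd=0.0), 3)
        init = ChromatinState(0.0, 0.0, 1.0, 0.0, aN=0.1, aD=0.9)
        t_grid = np.arange(0.0, 400.0)
        traj = simulate(params, warm, t_grid, init)
        assert traj[-1, 0] > 0.9          # cleared to UU
        assert traj[:, 3].max() < 0.5     # UM stays transient


class TestSimulateStochastic:
    def test_single_locus_is_jump_path_on_valid_states(self, params,
                                                       temp_smooth):
        t_grid = np.arange(183.0, 400.0)
        traj = simulate_stochastic(params, temp_smooth, t_grid,
                                   DEFAULT_INIT, n_cells=1, seed=0)
        assert set(np.unique(traj[:, :4])) <= {0.0, 1.0}
        assert np.all(traj[:, :4].sum(axis=1) == 1.0)
        assert set(np.unique(traj[:, 4:])) <= {0.0, 1.0}

    def test_fixed_seed_reproducible(self, params, temp_smooth):
        t_grid = np.arange(183.0, 300.0)
        a = simulate_stochastic(params, temp_smooth, t_grid, DEFAULT_INIT,
                                n_cells=100, seed=7)
        b = simulate_stochastic(params, temp_smooth, t_grid, DEFAULT_INIT,
                                n_cells=100, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_ensemble_mean_tracks_ode_at_moderate_size(self, params,
                                                       temp_smooth):
        t_grid = np.arange(183.0, 500.0, 14.0)
        ode = simulate(params, temp_smooth, t_grid, DEFAULT_INIT)
        sto = simulate_stochastic(params, temp_smooth, t_grid,
                                  DEFAULT_INIT, n_cells=2000, seed=1)
        assert np.abs(sto - ode).max() < 0.06

    def test_per_cell_coupling_supported(self, params, temp_smooth):
        t_grid = np.arange(183.0, 300.0, 14.0)
        traj = simulate_stochastic(params, temp_smooth, t_grid,
                                   DEFAULT_INIT, n_cells=500, seed=2,
                                   coupling="per-cell")
        assert traj.shape == (len(t_grid), 6)
        assert traj.min() >= 0 and traj.max() <= 1


class TestObservables:
    def test_scale_states_examples(self):
        traj = np.array([[0.1, 0.6, 0.2, 0.1, 0.5, 0.25]])
        levels = scale_states_to_levels(
            traj, {"K27_NR": 2.0, "K27_DNR": 1.0, "K4_NR": 4.0,
                   "K4_DNR": 1.0},
        )
        assert levels["K27_NR"][0] == pytest.approx(1.6)
        assert levels["K27_DNR"][0] == pytest.approx(0.3)
        assert levels["K4_NR"][0] == pytest.approx(2.0)
        assert levels["K4_DNR"][0] == pytest.approx(0.25)

    def test_unit_maxima_identity(self):
        traj = np.array([[0.25, 0.25, 0.25, 0.25, 0.4, 0.7]])
        levels = scale_states_to_levels(
            traj, {k: 1.0 for k in ("K27_NR", "K27_DNR", "K4_NR",
                                    "K4_DNR")},
        )
        assert levels["K27_NR"][0] == pytest.approx(0.5)
        assert levels["K4_DNR"][0] == pytest.approx(0.7)

    @pytest.mark.parametrize(
        "sigma,omega,level,expected",
        [(1.0, 0.0, 10.0, 1.0), (0.0, 2.5, 7.0, 2.5),
         (2.0, -1.0, 100.0, 3.0)],
    )
    def test_mrna_link_examples(self, sigma, omega, level, expected):
        assert predict_mrna(np.array([level]), sigma, omega)[0] == \
            pytest.approx(expected)

    def test_mrna_nonpositive_level_rejected(self):
        with pytest.raises(ValueError):
            predict_mrna(np.array([0.0]), 1.0, 0.0)

    def test_initial_state_independence_product(self):
        maxima = {"K27_NR": 2.0, "K27_DNR": 1.0, "K4_NR": 4.0,
                  "K4_DNR": 2.0}
        st = initial_state_from_levels(1.0, 0.25, 2.0, 0.5, maxima)
        assert st.mNuD == pytest.approx(0.5 * 0.75)
        assert st.mNmD == pytest.approx(0.5 * 0.25)
        assert st.uNmD == pytest.approx(0.5 * 0.25)
        assert st.aN == pytest.approx(0.5)
        assert st.aD == pytest.approx(0.25)

    def test_state_invariants_enforced(self):
        with pytest.raises(ValueError):
            ChromatinState(0.5, 0.5, 0.5, 0.5, 0.5, 0.5)
        with pytest.raises(ValueError):
            ChromatinState(1.2, -0.2, 0.0, 0.0, 0.5, 0.5)
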