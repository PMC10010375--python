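"""Diffusion-limited growth law: constraint solver, phase switching, invariants."""

import numpy as np
import pytest

from dlgrowth.core import (
    DLParams,
    TumorState,
    critical_volume,
    dl_rhs,
    growth_fraction,
    growth_fraction_vec,
    necrotic_area_fraction,
    radius_from_volume,
    simulate_dl,
    solve_necrotic_radius,
)
from dlgrowth.pk import weekly_protocol


def scan_necrotic_radius(R, R_c, n=2_000_001):
    """Independent oracle: dense sign-scan of the diffusion constraint."""
    u = np.linspace(0.0, 1.0 - 1e-12, n)
    Rn = u * R
    f = R**2 - 3 * Rn**2 + 2 * Rn**3 / R - R_c**2
    i = np.nonzero(np.diff(np.sign(f)))[0][0]
    # linear interpolation inside the bracketing cell
    return Rn[i] + (Rn[i + 1] - Rn[i]) * f[i] / (f[i] - f[i + 1])


class TestGeometry:
    def test_critical_volume_closed_form(self):
        assert critical_volume(0.41) == pytest.approx(4.0 * np.pi / 3.0 * 0.41**3)
        assert critical_volume(0.41) == pytest.approx(0.2887, abs=1e-4)

    def test_critical_volume_degenerates_to_zero(self):
        assert critical_volume(1e-12) < 1e-30
        with pytest.raises(ValueError):
            critical_volume(0.0)
        with pytest.raises(ValueError):
            critical_volume(-1.0)

    @pytest.mark.parametrize("r", [0.1, 0.41, 1.0])
    def test_radius_volume_round_trip(self, r):
        assert radius_from_volume(critical_volume(r)) == pytest.approx(r, rel=1e-12)


class TestNecroticRadiusConstraint:
    def test_onset_has_no_core(self):
        assert solve_necrotic_radius(0.41, 0.41) == 0.0

    def test_matches_dense_scan_oracle(self):
        R, R_c = 2 * 0.41, 0.41
        assert solve_necrotic_radius(R, R_c) == pytest.approx(scan_necrotic_radius(R, R_c), abs=1e-6)

    def test_large_tumor_rim_thickness_asymptote(self):
        # rim thickness R - R_n -> R_c/sqrt(3) as R -> infinity
        R_c = 0.41
        R = 100 * R_c
        rim = R - solve_necrotic_radius(R, R_c)
        assert rim == pytest.approx(R_c / np.sqrt(3.0), rel=1e-2)
        assert rim == pytest.approx(0.2367, abs=1e-3)

    def test_fully_proliferating_phase_is_an_error(self):
        with pytest.raises(ValueError, match="fully proliferating"):
            solve_necrotic_radius(0.2, 0.41)


class TestGrowthFraction:
    def test_below_critical_volume_everything_proliferates(self):
        assert growth_fraction(0.1, 0.41) == 1.0

    def test_continuous_at_onset(self):
        V_c = critical_volume(0.41)
        assert growth_fraction(V_c, 0.41) == 1.0
        assert growth_fraction(V_c * (1 + 1e-6), 0.41) == pytest.approx(1.0, abs=1e-3)

    def test_matches_scan_oracle_above_onset(self):
        V, R_c = 1.0, 0.41
        R = radius_from_volume(V)
        G_oracle = 1.0 - (scan_necrotic_radius(R, R_c) / R) ** 3
        assert growth_fraction(V, R_c) == pytest.approx(G_oracle, abs=1e-6)

    def test_strictly_decreasing_in_volume(self):
        V = np.linspace(0.3, 3.0, 50)
        G = [growth_fraction(v, 0.41) for v in V]
        assert np.all(np.diff(G) < 0.0)

    def test_vectorized_path_agrees_with_scalar_solver(self):
        # fast tabulated-inverse route vs bracketed Brent route
        V = np.geomspace(0.05, 20.0, 200)
        G_fast = growth_fraction_vec(V, 0.41)
        G_ref = np.array([growth_fraction(v, 0.41) for v in V])
        assert np.max(np.abs(G_fast - G_ref)) < 1e-9

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            growth_fraction(0.0, 0.41)
        with pytest.raises(ValueError):
            growth_fraction(-1.0, 0.41)


class TestNecroticAreaFraction:
    def test_fully_proliferating_has_no_necrotic_area(self):
        assert necrotic_area_fraction(1.0) == 0.0

    def test_central_section_geometry(self):
        # R_n/R = 0.8 -> G = 1 - 0.8^3 = 0.488, area fraction 0.8^2 = 0.64
        assert necrotic_area_fraction(1.0 - 0.8**3) == pytest.approx(0.64, rel=1e-12)

    def test_strictly_decreasing_in_growth_fraction(self):
        G = np.linspace(0.05, 1.0, 40)
        area = [necrotic_area_fraction(g) for g in G]
        assert np.all(np.diff(area) < 0.0)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.1])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            necrotic_area_fraction(bad)


class TestRhs:
    def test_fully_proliferating_no_drug_is_exponential(self, dl_params):
        state = TumorState.from_volume(0.1, dl_params.R_c)
        dV, dRn = dl_rhs(state, dl_params, c=0.0)
        assert dV == pytest.approx(dl_params.lambda_net * 0.1)
        assert dRn == 0.0

    def test_strong_drug_shrinks_a_proliferating_tumor(self, dl_params):
        state = TumorState.from_volume(0.1, dl_params.R_c)
        c = 2.0 * dl_params.lambda_net / dl_params.k_drug
        dV, _ = dl_rhs(state, dl_params, c=c)
        assert dV < 0.0

    def test_necrotic_radius_rate_matches_finite_difference(self, dl_params):
        # dR_n/dt from the differentiated constraint vs a finite difference
        # of the algebraic solve along the volume trajectory
        state = TumorState.from_volume(1.2, dl_params.R_c)
        dV, dRn = dl_rhs(state, dl_params, c=0.0)
        h = 1e-6
        V2 = state.V + dV * h
        Rn2 = solve_necrotic_radius(radius_from_volume(V2), dl_params.R_c)
        assert dRn == pytest.approx((Rn2 - state.R_n) / h, rel=1e-4)


class TestSimulateDL:
    def test_exponential_phase_closed_form(self):
        # large critical radius: no necrosis over the horizon
        p = DLParams(lambda_net=0.12, lambda_nec=0.05, k_drug=5.7e-3, R_c=1.0, V0=0.25)
        traj = simulate_dl(p, None, np.array([0.0, 2.0]))
        assert traj.V[-1] == pytest.approx(0.25 * np.exp(0.24), rel=1e-6)
        assert traj.V[-1] == pytest.approx(0.3178, abs=2e-4)

    def test_exponential_limit_no_necrosis(self):
        p = DLParams(lambda_net=0.12, lambda_nec=0.05, k_drug=5.7e-3, R_c=1e3, V0=0.25)
        t = np.linspace(0.0, 30.0, 31)
        traj = simulate_dl(p, None, t)
        assert np.max(np.abs(traj.V - 0.25 * np.exp(0.12 * t)) / (0.25 * np.exp(0.12 * t))) < 1e-6
        assert np.all(traj.G == 1.0)

    def test_dae_and_differentiated_constraint_agree(self, dl_params, protocol1, day_grid):
        a = simulate_dl(dl_params, protocol1, day_grid, method="ode")
        b = simulate_dl(dl_params, protocol1, day_grid, method="dae")
        assert np.max(np.abs(a.V - b.V) / b.V) < 1e-5
        assert np.max(np.abs(a.G - b.G)) < 1e-5

    def test_dae_ode_equivalence_on_random_parameter_draws(self):
        rng = np.random.default_rng(7)
        t = np.linspace(0.0, 25.0, 26)
        sch = weekly_protocol(1)
        for _ in range(20):
            p = DLParams(
                lambda_net=rng.uniform(0.05, 0.25),
                lambda_nec=rng.uniform(0.01, 0.15),
                k_drug=rng.uniform(1e-3, 1e-2),
                R_c=rng.uniform(0.2, 0.7),
                V0=rng.uniform(0.1, 0.6),
            )
            a = simulate_dl(p, sch, t, method="ode")
            b = simulate_dl(p, sch, t, method="dae")
            assert np.max(np.abs(a.V - b.V) / np.maximum(b.V, 1e-6)) < 1e-4

    def test_constraint_residual_along_trajectory(self, dl_params, day_grid):
        traj = simulate_dl(dl_params, None, day_grid)
        R = radius_from_volume(traj.V)
        limited = traj.R_n > 0.0
        resid = R[limited] ** 2 - 3 * traj.R_n[limited] ** 2 + 2 * traj.R_n[limited] ** 3 / R[limited] - dl_params.R_c**2
        assert np.max(np.abs(resid)) < 1e-6
        assert np.max(np.abs(traj.G - (1.0 - (traj.R_n / R) ** 3))) < 1e-9

    def test_growth_fraction_continuous_through_onset(self, dl_params):
        # V0 below V_c; the tumor grows through the onset during the run
        t = np.linspace(0.0, 10.0, 401)
        p = DLParams(lambda_net=0.12, lambda_nec=0.05, k_drug=5.7e-3, R_c=0.41, V0=0.25)
        traj = simulate_dl(p, None, t)
        assert traj.G[0] == 1.0
        assert traj.G[-1] < 1.0
        assert np.max(np.abs(np.diff(traj.G))) < 5e-3  # no jump at the crossing

    def test_growth_fraction_rebounds_under_treatment(self):
        # a large tumor (deep in the diffusion-limited phase) shrinks under
        # a strong dose; the interior regains nutrient access and G rises
        p = DLParams(lambda_net=0.12, lambda_nec=0.05, k_drug=5.7e-3, R_c=0.41, V0=1.0)
        t = np.linspace(0.0, 20.0, 201)
        sch = weekly_protocol(1, dose=100.0)
        traj = simulate_dl(p, sch, t)
        after_first_dose = (t > 1.0) & (t < 8.0)
        dV = np.diff(traj.V[after_first_dose])
        dG = np.diff(traj.G[after_first_dose])
        assert dV.min() < 0.0  # shrinkage happens
        assert dG.max() > 0.0  # G rises while the tumor shrinks

    def test_dose_events_reduce_growth(self, dl_params, protocol1, day_grid):
        control = simulate_dl(dl_params, None, day_grid)
        treated = simulate_dl(dl_params, protocol1, day_grid)
        assert treated.V[-1] < control.V[-1]

    def test_bad_grid_rejected(self, dl_params):
        with pytest.raises(ValueError):
            simulate_dl(dl_params, None, np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            simulate_dl(dl_params, None, np.array([0.0, 2.0, 1.0]))


class TestParamValidation:
    @pytest.mark.parametrize("name", ["lambda_net", "lambda_nec", "k_drug", "R_c", "V0"])
    def test_strict_positivity(self, name):
        base = dict(lambda_net=0.12, lambda_nec=0.05, k_drug=5.7e-3, R_c=0.41, V0=0.25)
        base[name] = 0.0
        with pytest.raises(ValueError, match=name):
            DLParams(**base)

    def test_state_invariants(self):
        s = TumorState.from_volume(1.0, 0.41)
        assert s.V == pytest.approx(4 * np.pi / 3 * s.R**3, rel=1e-9)
        assert 0.0 <= s.R_n < s.R
        assert s.G == pytest.approx(1.0 - (s.R_n / s.R) ** 3, rel=1e-9)
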