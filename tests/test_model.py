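"""Core model: right-hand side, Jacobian, residual, non-dimensionalization."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp

from colontme.estimation import derive_parameters
from colontme.model import (
    PARAM_NAMES,
    STATE_NAMES,
    ParameterSet,
    as_state,
    dfdtheta,
    finite_difference_jacobian,
    jacobian,
    nondimensionalize,
    rhs,
    steady_state_residual,
)
from colontme.reference import CLUSTERS, initial_condition, steady_state

IDX = {n: i for i, n in enumerate(STATE_NAMES)}


class TestRhs:
    def test_all_zero_state_leaves_only_influxes(self, cluster_params):
        """Every interaction term carries a state factor, so at the origin
        only the two constant influxes remain."""
        p = cluster_params[1]
        f = rhs(np.zeros(14), p)
        expected = np.zeros(14)
        expected[IDX["TN"]] = p["A_TN"]
        expected[IDX["DN"]] = p["A_DN"]
        np.testing.assert_allclose(f, expected, rtol=0, atol=0)

    @pytest.mark.parametrize("cluster", CLUSTERS)
    def test_derived_parameters_zero_the_rhs_at_the_steady_state(
            self, cluster, cluster_params):
        ss = steady_state(cluster)
        _, norm = steady_state_residual(ss.as_state(), cluster_params[cluster])
        assert norm < 1e-10

    def test_tgfbeta_equation_matches_linear_closed_form(self, cluster_params):
        """With macrophages and T-regs frozen, TGF-beta relaxes to its
        production/decay balance along (1 - exp(-delta t))."""
        p = cluster_params[2]
        ss = steady_state(2)
        M, Tr = ss["M"], ss["Tr"]
        frozen = np.zeros(14)
        frozen[IDX["M"]], frozen[IDX["Tr"]] = M, Tr

        def dGb(t, y):
            state = frozen.copy()
            state[IDX["Gb"]] = y[0]
            return [rhs(state, p)[IDX["Gb"]]]

        delta = p["delta_Gb"]
        t_star = 1.0 / delta
        sol = solve_ivp(dGb, (0.0, t_star), [0.0], rtol=1e-10, atol=1e-12)
        plateau = (p["lam_GbM"] * M + p["lam_GbTr"] * Tr) / delta
        exact = plateau * (1.0 - np.exp(-delta * t_star))
        assert sol.y[0, -1] == pytest.approx(exact, rel=1e-8)

    def test_nonfinite_state_is_rejected_with_symbol_named(self, cluster_params):
        bad = np.ones(14)
        bad[IDX["mu2"]] = np.nan
        with pytest.raises(ValueError, match="mu2"):
            rhs(bad, cluster_params[1])

    def test_invalid_parameter_is_rejected_with_symbol_named(self):
        with pytest.raises(ValueError, match="delta_H"):
            ParameterSet({"delta_H": -1.0})


class TestJacobian:
    def test_hmgb1_decay_is_linear(self, cluster_params):
        p = cluster_params[3]
        state = np.abs(np.sin(np.arange(14) + 1.0)) * 100.0
        J = jacobian(state, p)
        assert J[IDX["H"], IDX["H"]] == -p["delta_H"]

    def test_matches_central_finite_differences_at_cluster2_steady_state(
            self, cluster_params):
        x = steady_state(2).as_state()
        J = jacobian(x, cluster_params[2])
        Jfd = finite_difference_jacobian(x, cluster_params[2], rel_step=1e-6)
        scale = np.abs(Jfd).max()
        assert np.abs(J - Jfd).max() / scale < 1e-5

    def test_logistic_diagonal_at_capacity(self):
        """At C = C0 with everything else zero the cancer diagonal entry is
        lam_C (1 - 2 C/C0) - delta_C = -lam_C - delta_C."""
        from conftest import make_decoupled_params
        p = make_decoupled_params(lam_C=0.7, delta_C=0.3, C0=5.0)
        x = np.zeros(14)
        x[IDX["C"]] = p["C0"]
        J = jacobian(x, p)
        assert J[IDX["C"], IDX["C"]] == pytest.approx(-p["lam_C"] - p["delta_C"])

    @pytest.mark.parametrize("cluster", (1, 4))
    def test_parameter_gradient_matches_finite_differences(self, cluster,
                                                           cluster_params):
        p = cluster_params[cluster]
        x = steady_state(cluster).as_state() * 0.7  # off equilibrium
        G = dfdtheta(x, p)
        theta = p.to_array()
        Gfd = np.zeros_like(G)
        for j, name in enumerate(PARAM_NAMES):
            h = 1e-6 * max(theta[j], 1e-3)
            Gfd[:, j] = (rhs(x, p.replace(**{name: theta[j] + h}))
                         - rhs(x, p.replace(**{name: max(theta[j] - h, 0.0)}))
                         ) / (h + min(h, theta[j]))
        scale = np.abs(Gfd).max()
        assert np.abs(G - Gfd).max() / scale < 1e-5


class TestResidual:
    def test_all_ones_of_dimensionless_system(self, cluster_params):
        dsys = nondimensionalize(cluster_params[1], steady_state(1).as_state())
        _, norm = dsys.residual(np.ones(14))
        assert norm < 1e-10

    def test_uniform_inflation_breaks_the_cancer_balance(self, cluster_params):
        x = steady_state(1).as_state() * 1.1
        r, norm = steady_state_residual(x, cluster_params[1])
        assert norm > 0
        assert abs(r[IDX["C"]]) > 0

    def test_perturbing_delta_M_touches_only_the_macrophage_cell_equation(
            self, cluster_params):
        p = cluster_params[4]
        x = steady_state(4).as_state()
        pert = p.replace(delta_M=p["delta_M"] * 1.1)
        r, _ = steady_state_residual(x, pert)
        cells = [IDX[n] for n in ("TN", "Th", "TC", "Tr", "DN", "D", "C", "N")]
        assert abs(r[IDX["M"]]) > 1e-3
        assert np.abs(r[cells]).max() < 1e-12

    def test_nonpositive_scale_rejected(self, cluster_params):
        with pytest.raises(ValueError):
            steady_state_residual(np.ones(14), cluster_params[1],
                                  scale=np.zeros(14))


class TestNondimensionalize:
    def test_dimensional_and_dimensionless_trajectories_are_scale_related(
            self, cluster_params):
        p = cluster_params[1]
        x_inf = steady_state(1).as_state()
        dsys = nondimensionalize(p, x_inf)
        x0_bar = initial_condition(1)
        kw = dict(method="LSODA", rtol=1e-10, atol=1e-12,
                  t_eval=np.linspace(0.0, 500.0, 21))
        dim = solve_ivp(lambda t, y: rhs(y, p), (0, 500), x0_bar * x_inf,
                        jac=lambda t, y: jacobian(y, p), **kw)
        bar = solve_ivp(lambda t, y: dsys.rhs(y), (0, 500), x0_bar,
                        jac=lambda t, y: dsys.jacobian(y), **kw)
        np.testing.assert_allclose(dim.y, bar.y * x_inf[:, None],
                                   rtol=1e-6, atol=1e-8 * x_inf.max())

    def test_pure_decay_rates_are_scale_invariant(self, cluster_params):
        dsys = nondimensionalize(cluster_params[2], steady_state(2).as_state())
        coeffs = dsys.term_coefficients()
        assert coeffs["H:delta_H"] == cluster_params[2]["delta_H"]
        assert coeffs["C:lam_C"] == cluster_params[2]["lam_C"]

    def test_hmgb1_production_coefficient_rescales_by_source_over_target(
            self, cluster_params):
        p = cluster_params[5]
        ss = steady_state(5)
        coeffs = nondimensionalize(p, ss.as_state()).term_coefficients()
        assert coeffs["H:lam_HN"] == pytest.approx(
            p["lam_HN"] * ss["N"] / ss["H"])

    def test_zero_reference_rejected(self, cluster_params):
        bad = steady_state(3).as_state()
        bad[IDX["DN"]] = 0.0
        with pytest.raises(ValueError, match="DN"):
            nondimensionalize(cluster_params[3], bad)


class TestInvariantProperties:
    @given(st.floats(min_value=0.1, max_value=10.0),
           st.integers(min_value=0, max_value=13))
    def test_rhs_terms_vanish_with_their_state_factors(self, value, index):
        """A state with a single nonzero component only drives equations in
        which that variable appears as a source (plus the influxes)."""
        from conftest import make_decoupled_params
        p = make_decoupled_params()
        x = np.zeros(14)
        x[index] = value
        f = rhs(x, p)
        # decoupled: every equation is influx minus own decay
        expected = np.zeros(14)
        expected[IDX["TN"]] = p["A_TN"]
        expected[index] -= _own_decay(p, index) * value
        if STATE_NAMES[index] == "C":
            # necrotic production captures a fraction of the cancer death flux
            expected[IDX["N"]] += p["alpha_NC"] * p["delta_C"] * value
        np.testing.assert_allclose(f, expected, rtol=1e-12, atol=1e-12)

    @pytest.mark.parametrize("cluster", CLUSTERS)
    def test_macrophages_never_exceed_capacity(self, cluster, cluster_params):
        p = cluster_params[cluster]
        x_inf = steady_state(cluster).as_state()
        x0 = initial_condition(cluster) * x_inf
        sol = solve_ivp(lambda t, y: rhs(y, p), (0.0, 2000.0), x0,
                        method="LSODA", rtol=1e-8,
                        atol=1e-10 * np.maximum(x_inf, 1.0),
                        jac=lambda t, y: jacobian(y, p))
        assert sol.y[IDX["M"]].max() <= p["M0"] * (1.0 + 1e-9)


def _own_decay(p, index):
    name = STATE_NAMES[index]
    return {
        "TN": p["delta_TN"], "Th": p["delta_Th"], "TC": p["delta_TC"],
        "Tr": p["delta_Tr"], "DN": p["delta_D"], "D": p["delta_D"],
        "M": p["delta_M"], "C": p["delta_C"] - p["lam_C"],
        "N": p["delta_N"], "H": p["delta_H"], "mu1": p["delta_mu1"],
        "mu2": p["delta_mu2"], "Ig": p["delta_Ig"], "Gb": p["delta_Gb"],
    }[name]


def test_state_roundtrip_between_mapping_and_vector():
    x = as_state({n: float(i + 1) for i, n in enumerate(STATE_NAMES)})
    np.testing.assert_array_equal(x, np.arange(1.0, 15.0))
    with pytest.raises(KeyError):
        as_state({n: 1.0 for n in STATE_NAMES[:-1]})
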