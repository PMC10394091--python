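"""Steady states, Routh-Hurwitz verdicts, Lyapunov traces, R0/Rc."""

import numpy as np
import pytest

from caplung import equilibria_stability as eqs
from caplung.fde_engine import FDEProblem, SolutionGrid, solve_fde
from caplung.models import base_rhs, make_base_fde_rhs


class TestFindEquilibria:
    def test_tumor_free_state_present_with_printed_immune_level(self, preset):
        found = eqs.find_equilibria(preset.base, n_starts=20, seed=7)
        tf = [e for e in found if e.kind == "tumor-free-with-immunity"]
        assert tf, "tumor-free equilibrium not found"
        # I* = phi1*I0/phi3 = 0.03*90/0.01 = 270
        np.testing.assert_allclose(tf[0].state, [0.0, 270.0, 0.0], atol=1e-8)

    def test_constructed_root_has_zero_residual(self, preset):
        b = preset.base
        state = np.array([0.0, b.phi1 * b.I_baseline / b.phi3, 0.0])
        assert np.max(np.abs(base_rhs(state, b))) <= 1e-12

    def test_every_accepted_equilibrium_reverifies(self, preset):
        for e in eqs.find_equilibria(preset.base, n_starts=30, seed=11):
            assert e.residual <= 1e-8
            assert np.max(np.abs(base_rhs(e.state, preset.base))) <= 1e-8

    def test_positive_equilibrium_found_when_it_exists(self, mild_therapy):
        # the mild scenario sustains metastasis: gamma*N - delta - beta3*I
        # admits a root with all components positive
        found = eqs.find_equilibria(mild_therapy.base, n_starts=30, seed=3)
        pos = [e for e in found if e.kind == "positive"]
        assert pos
        assert all(c > 0 for c in pos[0].state)
        assert pos[0].residual <= 1e-8

    def test_deterministic_given_seed(self, preset):
        a = eqs.find_equilibria(preset.base, n_starts=15, seed=5)
        b = eqs.find_equilibria(preset.base, n_starts=15, seed=5)
        assert len(a) == len(b)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.state, y.state)


class TestJacobian:
    def test_carrying_capacity_corner_entry(self, preset):
        J = eqs.jacobian_base(preset.base, (preset.base.K, 0.0, 0.0))
        assert J[0, 0] == pytest.approx(-preset.base.lam)

    def test_origin_diagonal(self, preset):
        b = preset.base
        J = eqs.jacobian_base(b, (0.0, 0.0, 0.0))
        np.testing.assert_allclose(np.diag(J), [b.lam, -b.phi3, -b.delta])

    @pytest.mark.parametrize("state", [(3000.0, 90.0, 20.0), (12.3, 456.0, 7.8), (0.5, 0.1, 0.9)])
    def test_matches_central_finite_differences(self, preset, state):
        b = preset.base
        J = eqs.jacobian_base(b, state)
        for j in range(3):
            # relative step keeps roundoff below 1e-5 at cell-count scale;
            # truncation is zero (rhs is at most quadratic per direction)
            step = 1e-6 * max(1.0, abs(state[j]))
            plus = np.array(state, dtype=float)
            minus = plus.copy()
            plus[j] += step
            minus[j] -= step
            fd = (base_rhs(plus, b) - base_rhs(minus, b)) / (2 * step)
            np.testing.assert_allclose(J[:, j], fd, atol=1e-5)


class TestRouthHurwitz:
    def test_triple_negative_real_root_is_stable(self):
        rep = eqs.routh_hurwitz_cubic((3.0, 3.0, 1.0))
        assert rep.verdict == "stable"

    def test_root_at_origin_is_not_stable(self):
        rep = eqs.routh_hurwitz_cubic((0.0, -1.0, 0.0))  # x^3 - x
        assert rep.verdict != "stable"

    def test_pure_imaginary_pair_is_marginal(self):
        rep = eqs.routh_hurwitz_cubic((1.0, 1.0, 1.0))  # roots -1, +/-i
        assert rep.verdict == "marginal"

    def test_T_convention_normalisation_and_minors(self):
        rep = eqs.routh_hurwitz_cubic((-3.0, -3.0, -1.0), convention="T")
        assert rep.monic_coeffs == (3.0, 3.0, 1.0)
        T1, T2, T3 = rep.char_coeffs
        assert rep.minors[0] == 1.0
        assert rep.minors[1] == pytest.approx(T3 - T1 * T2)
        assert rep.minors[2] == pytest.approx((T2 * T3 - T1 ** 2 * T3) / T1)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            eqs.routh_hurwitz_cubic((1.0, 2.0))

    def test_agrees_with_companion_eigenvalues_on_random_cubics(self):
        rng = np.random.default_rng(20230801)
        checked = 0
        for _ in range(1000):
            a = rng.uniform(-5.0, 5.0, size=3)
            roots = np.roots([1.0, *a])
            max_re = roots.real.max()
            if abs(max_re) < 1e-9:
                continue  # marginal band excluded
            rep = eqs.routh_hurwitz_cubic(tuple(a))
            assert rep.verdict == ("stable" if max_re < 0 else "unstable")
            checked += 1
        assert checked > 900

    def test_stability_report_eigenvalues_satisfy_characteristic_polynomial(self, preset):
        rep = eqs.stability_report(preset.base, (0.0, 270.0, 0.0))
        a1, a2, a3 = rep.monic_coeffs
        for lam in rep.eigenvalues:
            val = lam ** 3 + a1 * lam ** 2 + a2 * lam + a3
            assert abs(val) <= 1e-8 * max(1.0, abs(a3))
        assert rep.verdict == "stable"


class TestLyapunov:
    def _eq(self, state):
        return eqs.Equilibrium(state=np.asarray(state, dtype=float), residual=0.0, kind="other")

    def test_constant_trajectory_at_equilibrium(self):
        times = np.linspace(0, 1, 11)
        grid = SolutionGrid(times=times, states=np.tile([2.0, 3.0], (11, 1)))
        tr = eqs.lyapunov_trace(grid, self._eq([2.0, 3.0]))
        assert np.all(tr.V == 0.0)
        assert tr.monotone_fraction == 1.0

    def test_exponential_decay_is_monotone_every_step(self):
        prob = FDEProblem(order=1.0, rhs=lambda t, y, u: -y, initial_state=[5.0],
                          t0=0.0, t_final=3.0, step=2.0 ** -6)
        grid = solve_fde(prob)
        tr = eqs.lyapunov_trace(grid, self._eq([0.0]))
        assert tr.monotone_fraction == 1.0
        assert tr.settle_index == 0

    def test_V_nonnegative_for_arbitrary_trajectory(self):
        rng = np.random.default_rng(0)
        grid = SolutionGrid(times=np.arange(20.0), states=rng.normal(size=(20, 3)))
        tr = eqs.lyapunov_trace(grid, self._eq([0.3, -1.0, 2.0]))
        assert (tr.V >= 0.0).all()

    def test_dimension_mismatch_raises(self):
        grid = SolutionGrid(times=np.arange(3.0), states=np.zeros((3, 2)))
        with pytest.raises(ValueError):
            eqs.lyapunov_trace(grid, self._eq([0.0, 0.0, 0.0]))

    def test_fractional_preset_run_settles_monotonically(self, preset):
        """A small-tumour start under printed rates decays toward the stable
        tumour-free state with an eventually monotone Lyapunov trace."""
        prob = FDEProblem(order=0.9, rhs=make_base_fde_rhs(preset.base),
                          initial_state=[5.0, 350.0, 1.0], t0=0.0, t_final=100.0,
                          step=2.0 ** -5)
        grid = solve_fde(prob)
        tr = eqs.lyapunov_trace(grid, self._eq([0.0, 270.0, 0.0]))
        assert tr.monotone_fraction >= 0.99
        assert tr.settle_index is not None


class TestReproductionNumbers:
    def test_forced_unit_eigenvalue_substitutions(self, preset):
        # R0 = beta1*phi1/mu = 0.01*0.03/0.01 ; Rc = beta2*gamma*phi2/(mu*phi3)
        R0, Rc = eqs.reproduction_from_lambda1(preset.base, 1.0)
        assert R0 == pytest.approx(0.03)
        assert Rc == pytest.approx(0.28)

    def test_zero_eigenvalue_is_undefined(self, preset):
        with pytest.raises(ZeroDivisionError):
            eqs.reproduction_from_lambda1(preset.base, 1e-13)

    def test_scale_consistency_quadratic_in_coupled_rates(self, preset):
        c = 1.7
        rep = eqs.reproduction_numbers(preset.base)
        scaled = eqs.reproduction_numbers(
            preset.base.replace(beta1=preset.base.beta1 * c, phi1=preset.base.phi1 * c))
        assert scaled.R0 == pytest.approx(c * c * rep.R0, rel=1e-12)

    def test_printed_jacobian_structure(self, preset):
        b = preset.base
        rep = eqs.reproduction_numbers(b, jacobian_mode="paper-literal")
        expected = np.array([[-b.lam, 0.0, -b.mu * b.K],
                             [0.0, -b.phi3, 0.0],
                             [b.gamma * b.K, 0.0, -b.delta]])
        np.testing.assert_array_equal(rep.jacobian_dfe, expected)
        np.testing.assert_array_equal(rep.dfe, [b.K, 0.0, 0.0])

    def test_jacobian_modes_disagree_at_dfe(self, preset):
        lit = eqs.dfe_jacobian(preset.base, "paper-literal")
        der = eqs.dfe_jacobian(preset.base, "derived")
        assert lit[2, 2] != der[2, 2]  # -delta vs gamma*K - delta
        assert lit[0, 1] == 0.0 and der[0, 1] != 0.0

    def test_interpretation_table_covers_phi_sets_and_dominance_rules(self, preset):
        tab = eqs.interpretation_table(preset.base, preset.control_phis[:3])
        assert len(tab) == 4
        assert set(tab["phi_set"]) == {"set1", "set2"}
        assert set(tab["dominance"]) == {"max-real-part", "max-modulus"}
        assert np.isfinite(tab[["R0", "Rc"]].to_numpy()).all()

    def test_dominance_rules_select_documented_eigenvalues(self, preset):
        mrp = eqs.reproduction_numbers(preset.base, dominance="max-real-part")
        mmod = eqs.reproduction_numbers(preset.base, dominance="max-modulus")
        assert mrp.lambda1.real == pytest.approx(-preset.base.phi3)
        assert abs(mmod.lambda1) > abs(mrp.lambda1)
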