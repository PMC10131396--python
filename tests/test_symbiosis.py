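"""Symbiosis ODE model: vector field, equilibria, closed forms, regimes."""

import numpy as np
import pytest
import sympy
from hypothesis import given, settings
from hypothesis import strategies as st

from coralmeta import (
    ConfigError,
    EXAMPLE_PARAMS,
    SymbiosisParams,
    boundary_lambda,
    classify_regime,
    derivatives,
    find_equilibria,
    isoclines,
    jacobian,
    simulate_model,
)


def _random_params(rng, **overrides):
    base = dict(
        r=rng.uniform(0.5, 2.0),
        K=rng.uniform(0.5, 2.0),
        gamma1=rng.uniform(0.0, 2.0),
        gamma2=rng.uniform(0.0, 0.5),
        a1=rng.uniform(0.0, 0.3),
        a2=rng.uniform(0.0, 0.3),
        g1=rng.uniform(0.5, 2.0),
        g2=rng.uniform(0.5, 2.0),
        b1=rng.uniform(0.0, 0.3),
        b2=rng.uniform(0.0, 0.3),
        d1=rng.uniform(0.2, 1.0),
        d2=rng.uniform(0.2, 1.0),
        e1=rng.uniform(0.3, 2.0),
        e2=rng.uniform(0.3, 2.0),
        c1=rng.uniform(0.0, 0.5),
        c2=rng.uniform(0.0, 0.5),
    )
    base.update(overrides)
    return SymbiosisParams(**base)


@pytest.fixture(scope="module")
def symbolic_field():
    """Independent symbolic evaluation of the three rate equations."""
    H, S, B = sympy.symbols("H S B", nonnegative=True)
    syms = sympy.symbols(
        "r K gamma1 gamma2 a1 a2 g1 g2 b1 b2 d1 d2 e1 e2 c1 c2", positive=True
    )
    r, K, g1_, g2_, a1, a2, gr1, gr2, b1, b2, d1, d2, e1, e2, c1, c2 = syms
    fH = r * H * (1 - H / (K + g1_ * S + g2_ * S * B)) - a1 * S * H - a2 * B * H
    fS = gr1 * H * S * (1 + b1 * B) - d1 * S * (1 + e1 * S + c1 * B)
    fB = gr2 * H * B * (1 + b2 * S) - d2 * B * (1 + e2 * B + c2 * S)
    return sympy.lambdify((H, S, B) + syms, (fH, fS, fB), "numpy")


class TestDerivatives:
    def test_symbiont_free_reduces_to_logistic(self):
        p = SymbiosisParams(r=1.3, K=2.0)
        dH, dS, dB = derivatives((0.5, 0.0, 0.0), p)
        assert dH == pytest.approx(1.3 * 0.5 * (1 - 0.5 / 2.0))
        assert dS == 0.0 and dB == 0.0

    def test_carrying_capacity_is_a_fixed_point(self):
        p = SymbiosisParams(r=1.0, K=1.7)
        assert derivatives((1.7, 0.0, 0.0), p) == pytest.approx([0.0, 0.0, 0.0])

    def test_matches_symbolic_oracle(self, rng, symbolic_field):
        for _ in range(20):
            p = _random_params(rng)
            st_ = rng.uniform(0.0, 3.0, 3)
            expected = symbolic_field(
                *st_, p.r, p.K, p.gamma1, p.gamma2, p.a1, p.a2,
                p.g1, p.g2, p.b1, p.b2, p.d1, p.d2, p.e1, p.e2, p.c1, p.c2,
            )
            assert derivatives(st_, p) == pytest.approx(np.array(expected))

    @given(
        H=st.floats(0, 5, allow_nan=False),
        S=st.floats(0, 5, allow_nan=False),
        B=st.floats(0, 5, allow_nan=False),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_coordinate_planes_are_invariant(self, H, S, B):
        p = EXAMPLE_PARAMS["coexistence"]
        assert derivatives((0.0, S, B), p)[0] == 0.0
        assert derivatives((H, 0.0, B), p)[1] == 0.0
        assert derivatives((H, S, 0.0), p)[2] == 0.0

    def test_jacobian_matches_finite_differences(self, rng):
        for _ in range(10):
            p = _random_params(rng)
            st_ = rng.uniform(0.1, 2.0, 3)
            J = jacobian(st_, p)
            h = 1e-6
            for j in range(3):
                e = np.zeros(3)
                e[j] = h
                col = (derivatives(st_ + e, p) - derivatives(st_ - e, p)) / (2 * h)
                assert J[:, j] == pytest.approx(col, rel=1e-4, abs=1e-6)


class TestSimulate:
    def test_logistic_limit(self):
        p = SymbiosisParams(r=1.0, K=1.7)
        _, states = simulate_model(p, (0.05, 0.0, 0.0), 200.0)
        assert states[-1, 0] == pytest.approx(1.7, rel=1e-3)

    def test_stays_at_stable_equilibrium(self):
        p = EXAMPLE_PARAMS["parasitism"]
        eq = [e for e in find_equilibria(p) if e.stability == "stable"][0]
        _, states = simulate_model(p, eq.state, 50.0)
        assert states[-1] == pytest.approx(eq.state, abs=1e-6)

    def test_tolerance_refinement_converges(self):
        p = EXAMPLE_PARAMS["coexistence"]
        _, s1 = simulate_model(p, (0.2, 0.2, 0.2), 30.0, rtol=1e-8, atol=1e-10)
        _, s2 = simulate_model(p, (0.2, 0.2, 0.2), 30.0, rtol=5e-9, atol=5e-11)
        assert np.abs(s1[-1] - s2[-1]).max() / np.abs(s1[-1]).max() < 1e-6

    def test_nonnegativity_preserved(self, rng):
        for _ in range(5):
            p = _random_params(rng)
            init = rng.uniform(0.0, 1.5, 3)
            _, states = simulate_model(p, init, 20.0)
            assert (states >= 0).all()

    def test_negative_initial_state_rejected(self):
        with pytest.raises(ConfigError):
            simulate_model(EXAMPLE_PARAMS["mutualism"], (-0.1, 0.0, 0.0), 1.0)


class TestBoundaryForms:
    def test_invasion_threshold(self):
        p = SymbiosisParams(g1=1.0, d1=0.5, e1=1.0)
        assert boundary_lambda(p, 1, 0.5) == pytest.approx(0.0)

    def test_direct_substitution(self):
        p = SymbiosisParams(g1=1.0, d1=0.5, e1=0.5)
        assert boundary_lambda(p, 2, 1.0) == pytest.approx(
            (1.0 / p.e2) * ((p.g2 / p.d2) * 1.0 - 1.0)
        )
        assert boundary_lambda(p, 1, 1.0) == pytest.approx(2.0)

    def test_solver_matches_closed_form_on_boundary(self, rng):
        # numerically solved coral-algal equilibrium vs the lambda formula
        found = 0
        while found < 5:
            p = _random_params(rng, g2=0.01, b1=0.0, c1=0.0)
            for e in find_equilibria(p):
                if e.kind == "coral-algal":
                    lam = boundary_lambda(p, 1, e.H)
                    assert e.S == pytest.approx(lam, rel=1e-6)
                    found += 1

    def test_invalid_partner_index(self):
        with pytest.raises(ConfigError):
            boundary_lambda(SymbiosisParams(), 3, 1.0)


class TestEquilibria:
    def test_origin_and_carrying_capacity_always_found(self, rng):
        p = _random_params(rng)
        eqs = find_equilibria(p)
        kinds = {e.kind for e in eqs}
        assert "trivial" in kinds and "coral-only" in kinds
        co = [e for e in eqs if e.kind == "coral-only"][0]
        assert co.H == pytest.approx(p.K, rel=1e-9)

    def test_residuals_below_tolerance(self, rng):
        p = _random_params(rng)
        for e in find_equilibria(p):
            assert e.residual < 1e-7

    def test_stability_agrees_with_simulation(self):
        p = EXAMPLE_PARAMS["coexistence"]
        stable = [e for e in find_equilibria(p) if e.stability == "stable"]
        assert stable
        eq = stable[0]
        start = eq.state * 1.05 + 1e-3
        _, states = simulate_model(p, start, 300.0)
        assert states[-1] == pytest.approx(eq.state, rel=1e-4, abs=1e-6)

    def test_boundary_record_carries_lambdas(self):
        p = EXAMPLE_PARAMS["parasitism"]
        ca = [e for e in find_equilibria(p) if e.kind == "coral-algal"][0]
        assert ca.boundary["lambda1_B"] == pytest.approx(ca.S, rel=1e-9)
        assert ca.boundary["H_bar_B"] == pytest.approx(ca.H, rel=1e-9)


class TestIsoclines:
    def test_partner_nullcline_is_the_lambda_line(self):
        p = EXAMPLE_PARAMS["parasitism"]
        curves = isoclines(p, plane=("B", 0.0), bounds=(0.01, 2.0, 0.01, 2.0), n=120)
        pts = curves["S"]
        assert len(pts)
        expected = (p.g1 * pts[:, 0] / p.d1 - 1.0) / p.e1
        mask = expected > 0.02  # away from the S=0 branch
        assert pts[mask, 1] == pytest.approx(expected[mask], abs=0.03)

    def test_nullclines_pass_through_boundary_equilibrium(self):
        p = EXAMPLE_PARAMS["parasitism"]
        eq = [e for e in find_equilibria(p) if e.kind == "coral-algal"][0]
        curves = isoclines(p, plane=("B", 0.0), bounds=(0.01, 2.0, 0.01, 2.0), n=200)
        for name in ("H", "S"):
            d = np.abs(curves[name] - eq.state[:2]).sum(axis=1).min()
            assert d < 0.05

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ConfigError):
            isoclines(EXAMPLE_PARAMS["mutualism"], bounds=(1.0, 0.5, 0.0, 1.0))


class TestRegimes:
    def test_example_parameter_sets_realize_their_regimes(self):
        rep = classify_regime(EXAMPLE_PARAMS["mutualism"])
        assert rep.coral_algal == "mutualism"
        rep = classify_regime(EXAMPLE_PARAMS["parasitism"])
        assert rep.coral_algal == "parasitism"
        rep = classify_regime(EXAMPLE_PARAMS["coexistence"])
        assert rep.partners == "coexistence"
        rep = classify_regime(EXAMPLE_PARAMS["exclusion"])
        assert rep.partners != "coexistence"
        assert rep.bistable

    def test_pure_cost_symbiont_is_parasitic(self):
        # no benefit (gamma = 0), positive cost, symbiont persists
        p = SymbiosisParams(
            r=1.0, K=1.0, gamma1=0.0, a1=0.2, g1=1.0, d1=0.5, e1=1.0,
            g2=0.1, d2=1.0, e2=1.0,
        )
        rep = classify_regime(p)
        assert rep.coral_algal == "parasitism"
        best = max((e for e in rep.equilibria if e.stability == "stable"), key=lambda e: e.H)
        assert best.H < p.K

    def test_strong_competition_excludes_a_partner(self):
        rep = classify_regime(EXAMPLE_PARAMS["exclusion"])
        stable = [e for e in rep.equilibria if e.stability == "stable"]
        assert all(min(e.S, e.B) < 1e-7 for e in stable)


def test_params_validation():
    with pytest.raises(ConfigError):
        SymbiosisParams(e1=0.0)
    with pytest.raises(ConfigError):
        SymbiosisParams(r=-1.0)
    with pytest.raises(ConfigError):
        SymbiosisParams.from_dict({"r": 1.0, "bogus": 2.0})
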