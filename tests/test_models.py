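"""Model-family structure: canonical forms, simulation, constraints, asymptotics."""

import numpy as np
import pytest

import strideadapt as sa
from strideadapt.models import PARAM_NAMES, STATE_DIM


def mk(family, **params):
    return sa.ModelSpec(family, params)


class TestCanonicalForm:
    def test_single_state_native_conversion_collapses_when_c_is_one(self):
        spec = mk("single_state", a=0.9, b=0.2, c=1.0, d=0.5)
        can = sa.single_state_to_canonical(spec)
        assert can.params["a_prime"] == pytest.approx(0.9)
        assert can.params["b_prime"] == pytest.approx(0.1)
        assert can.params["c"] == 1.0 and can.params["d"] == 0.5

    def test_fast_slow_matrices(self):
        real = sa.canonical_form(mk("fast_slow", af=0.5, bf=0.3, **{"as": 0.9}, bs=0.1, d=2.0))
        np.testing.assert_allclose(real.A, np.diag([0.5, 0.9]))
        np.testing.assert_allclose(real.B, [0.6, 0.2])
        np.testing.assert_allclose(real.C, [1.0, 1.0])
        assert real.D == 2.0

    def test_modified_udl_matrices(self):
        real = sa.canonical_form(mk("modified_udl", amu=0.6, bmu=0.2, cmu=0.9, dmu=1.0))
        np.testing.assert_allclose(real.A, [[0.9, 0.1], [0.2, 0.8]])
        np.testing.assert_allclose(real.B, [0.1, 0.2])
        np.testing.assert_allclose(real.C, [0.0, 1.0])
        assert real.D == 1.0

    def test_udl_matrices(self):
        real = sa.canonical_form(mk("udl", au=0.5, bu=0.2, du=1.0))
        assert real.A[0, 0] == pytest.approx(0.7)
        assert real.B[0] == pytest.approx(0.2)
        assert real.C[0] == 1.0 and real.D == 1.0

    def test_wrong_parameter_names_rejected(self):
        with pytest.raises(ValueError):
            sa.ModelSpec("udl", {"au": 0.5, "bu": 0.2})
        with pytest.raises(ValueError):
            sa.ModelSpec("no_such_family", {"a": 1.0})

    @pytest.mark.parametrize(
        "family,count", [("single_state", 4), ("udl", 3), ("fast_slow", 5), ("modified_udl", 4), ("two_state", 9)]
    )
    def test_parameter_counts(self, family, count):
        assert len(PARAM_NAMES[family]) == count


class TestSimulate:
    def test_zero_input_zero_state_stays_zero(self, rng):
        spec = sa.sample_spec("two_state", rng)
        y = sa.simulate(sa.canonical_form(spec), np.zeros(50))
        np.testing.assert_array_equal(y, np.zeros(50))

    def test_modified_udl_three_step_hand_recursion(self):
        real = sa.canonical_form(mk("modified_udl", amu=0.6, bmu=0.2, cmu=0.9, dmu=1.0))
        y = sa.simulate(real, np.array([0.0, 1.0, 1.0]))
        np.testing.assert_allclose(y, [1.0, 1.2, 1.38])

    def test_udl_two_step_hand_recursion(self):
        real = sa.canonical_form(mk("udl", au=0.5, bu=0.2, du=1.0))
        # u(0)=0, u(1)=1; the final feedthrough input u(2) is held at 1
        y, states = sa.simulate(real, np.array([0.0, 1.0]), return_states=True)
        assert y[0] == pytest.approx(1.0)
        assert states[1, 0] == pytest.approx(0.2)
        assert y[1] == pytest.approx(1.2)

    def test_udl_without_learning_is_pure_feedthrough_from_zero(self):
        # bu = 0 removes the use-dependent update; from x=0 the state stays 0
        spec = mk("udl", au=0.5, bu=0.0, du=2.0)
        u = np.r_[np.zeros(3), np.ones(5)]
        y = sa.simulate_native(spec, u)
        u_next = np.r_[u[1:], u[-1]]
        np.testing.assert_allclose(y, 2.0 * u_next)

    def test_output_length_matches_schedule(self, rng):
        spec = sa.sample_spec("fast_slow", rng)
        y = sa.simulate(sa.canonical_form(spec), np.ones(37))
        assert y.shape == (37,)


class TestOracleEquivalence:
    @pytest.mark.parametrize("family", sa.FAMILIES)
    def test_native_recursion_matches_canonical_state_space(self, family, schedule):
        # agreement to 1e-10 relative to trajectory scale: marginally stable
        # draws ramp to magnitudes where an absolute band would sit below the
        # float64 accumulation floor of two independent 400-step recursions
        rng = np.random.default_rng(sum(map(ord, family)))
        for _ in range(20):
            spec = sa.sample_spec(family, rng)
            y_can = sa.simulate(sa.canonical_form(spec), schedule)
            y_nat = sa.simulate_native(spec, schedule)
            scale = max(1.0, float(np.max(np.abs(y_nat))))
            assert np.max(np.abs(y_can - y_nat)) / scale < 1e-10

    def test_single_state_native_params_match_canonical(self, step_schedule):
        native = mk("single_state", a=0.9, b=0.2, c=1.0, d=0.5)
        can = sa.single_state_to_canonical(native)
        y_nat = sa.simulate_native(native, step_schedule)
        y_can = sa.simulate(sa.canonical_form(can), step_schedule)
        np.testing.assert_allclose(y_nat, y_can, atol=1e-12)


class TestConstraints:
    def test_valid_fast_slow_ordering(self):
        rep = sa.check_constraints(mk("fast_slow", af=0.5, bf=0.3, **{"as": 0.9}, bs=0.1, d=1.0))
        assert rep.valid and rep.violations == []

    def test_reversed_fast_slow_ordering_flagged(self):
        rep = sa.check_constraints(mk("fast_slow", af=0.9, bf=0.3, **{"as": 0.5}, bs=0.1, d=1.0))
        assert not rep.valid
        assert any(name == "as>af" for name, _ in rep.violations)

    def test_unstable_single_state_flagged(self):
        rep = sa.check_constraints(mk("single_state", a_prime=1.05, b_prime=0.1, c=1.0, d=0.0))
        assert not rep.valid
        assert any(name == "stability" for name, _ in rep.violations)

    def test_cmu_out_of_range_flagged(self):
        rep = sa.check_constraints(mk("modified_udl", amu=0.2, bmu=0.1, cmu=1.2, dmu=1.0))
        assert any("cmu" in name for name, _ in rep.violations)

    def test_marginal_unit_eigenvalue_admitted(self):
        # the modified-UDL A always has an eigenvalue of exactly 1
        rep = sa.check_constraints(mk("modified_udl", amu=0.6, bmu=0.2, cmu=0.9, dmu=1.0))
        assert rep.valid


class TestEigenAnalysis:
    def test_modified_udl_spectrum_is_one_and_trace_minus_one(self):
        real = sa.canonical_form(mk("modified_udl", amu=0.6, bmu=0.2, cmu=0.9, dmu=1.0))
        rep = sa.eigen_analysis(real)
        np.testing.assert_allclose(sorted(np.real(rep.eigenvalues)), [0.7, 1.0], atol=1e-12)
        assert rep.stable

    def test_diagonal_fast_slow_radius(self):
        real = sa.canonical_form(mk("fast_slow", af=0.5, bf=0.3, **{"as": 0.9}, bs=0.1, d=1.0))
        assert sa.eigen_analysis(real).spectral_radius == pytest.approx(0.9)

    def test_marginal_scalar_pole_is_stable(self):
        real = sa.canonical_form(mk("single_state", a_prime=1.0, b_prime=0.1, c=1.0, d=0.0))
        rep = sa.eigen_analysis(real)
        assert rep.spectral_radius == pytest.approx(1.0) and rep.stable


class TestAfterEffects:
    def test_modified_udl_asymptote_matches_long_washout_iteration(self):
        spec = mk("modified_udl", amu=0.6, bmu=0.2, cmu=0.9, dmu=1.0)
        state = np.array([0.21, 0.38])
        target = sa.after_effect_asymptote(spec, state)
        assert target == pytest.approx(0.26667, abs=5e-6)
        # oracle: iterate the u=0 dynamics 500 steps from the same state
        y = sa.simulate(sa.canonical_form(spec, x_init=state), np.zeros(500))
        assert y[-1] == pytest.approx(target, abs=1e-9)
        # left-eigenvector weighted average of the washout state
        assert target == pytest.approx((2 / 3) * 0.21 + (1 / 3) * 0.38)

    def test_consensus_state_is_a_fixed_point(self, rng):
        spec = sa.sample_spec("modified_udl", rng)
        q = 0.73
        assert sa.after_effect_asymptote(spec, [q, q]) == pytest.approx(q)

    def test_stable_udl_always_washes_out_to_zero(self):
        spec = mk("udl", au=0.5, bu=0.2, du=1.0)
        assert sa.after_effect_asymptote(spec, [3.0]) == 0.0

    def test_marginal_second_mode_rejected(self):
        spec = mk("modified_udl", amu=0.9, bmu=0.4, cmu=0.7, dmu=1.0)  # amu+bmu+cmu = 2
        with pytest.raises(ValueError):
            sa.after_effect_asymptote(spec, [0.1, 0.2])


class TestStructuralProperties:
    def test_modified_udl_with_frozen_reference_reproduces_udl(self, step_schedule):
        mu = mk("modified_udl", amu=0.55, bmu=0.25, cmu=1.0, dmu=1.3)
        ud = mk("udl", au=0.55, bu=0.25, du=1.3)
        y_mu = sa.simulate(sa.canonical_form(mu), step_schedule)
        y_ud = sa.simulate(sa.canonical_form(ud), step_schedule)
        np.testing.assert_allclose(y_mu, y_ud, atol=1e-12)

    @pytest.mark.parametrize("family", ["fast_slow", "modified_udl"])
    def test_two_state_embedding(self, family, step_schedule, rng):
        spec = sa.sample_spec(family, rng)
        real = sa.canonical_form(spec)
        emb = sa.ModelSpec(
            "two_state",
            {
                "a11": real.A[0, 0], "a12": real.A[0, 1], "a21": real.A[1, 0], "a22": real.A[1, 1],
                "b1": real.B[0], "b2": real.B[1], "c1": real.C[0], "c2": real.C[1], "d": real.D,
            },
        )
        np.testing.assert_allclose(
            sa.simulate(sa.canonical_form(spec), step_schedule),
            sa.simulate(sa.canonical_form(emb), step_schedule),
            atol=1e-12,
        )

    def test_modified_udl_conserved_quantity_under_washout(self, rng):
        for _ in range(10):
            spec = sa.sample_spec("modified_udl", rng)
            p = spec.params
            state = rng.normal(size=2)
            _, states = sa.simulate(
                sa.canonical_form(spec, x_init=state), np.zeros(100), return_states=True
            )
            w = np.array([1.0 - p["amu"] - p["bmu"], 1.0 - p["cmu"]])
            q = np.r_[[w @ state], states @ w]
            assert np.max(np.abs(q - q[0])) < 1e-9 * max(1.0, abs(q[0]))

    def test_modified_udl_ramps_under_sustained_input(self):
        # B outside the range of (I - A): output grows linearly, not exponentially
        spec = mk("modified_udl", amu=0.6, bmu=0.2, cmu=0.9, dmu=1.0)
        y = sa.simulate(sa.canonical_form(spec), np.ones(3000))
        late = np.diff(y[-500:])
        assert np.max(np.abs(late - late[0])) < 1e-9
        assert abs(late[0]) > 1e-3

    def test_amu_cmu_swap_is_observationally_invisible(self, schedule, rng):
        for _ in range(10):
            spec = sa.sample_spec("modified_udl", rng)
            twin = sa.modified_udl_conjugate(spec)
            np.testing.assert_allclose(
                sa.simulate(sa.canonical_form(spec), schedule),
                sa.simulate(sa.canonical_form(twin), schedule),
                atol=1e-9,
            )

    def test_canonicalize_orders_retentions(self):
        spec = mk("modified_udl", amu=0.9, bmu=0.2, cmu=0.6, dmu=1.0)
        can = sa.canonicalize_modified_udl(spec)
        assert can.params["cmu"] >= can.params["amu"]
        assert can.params == {"amu": 0.6, "bmu": 0.2, "cmu": 0.9, "dmu": 1.0}


class TestSerialization:
    @pytest.mark.parametrize("family", sa.FAMILIES)
    def test_json_round_trip_is_exact(self, family, rng, tmp_path):
        from strideadapt.io import read_model_spec, write_model_spec

        spec = sa.sample_spec(family, rng)
        path = tmp_path / "spec.json"
        write_model_spec(spec, path)
        back = read_model_spec(path)
        assert back.family == spec.family
        assert back.params == spec.params

    def test_state_dims(self):
        assert STATE_DIM["single_state"] == 1 and STATE_DIM["udl"] == 1
        assert all(STATE_DIM[f] == 2 for f in ("fast_slow", "modified_udl", "two_state"))
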