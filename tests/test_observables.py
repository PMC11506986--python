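"""Marginals, entropy, order-parameter clouds and no-outbreak mass."""

import math

import numpy as np
import pytest

import epime as e
from conftest import make_system
from epime.observables import no_outbreak_mass, order_parameter_cloud


def uniform_state(space):
    return e.ProbabilityVector(p=np.full(space.size, 1.0 / space.size))


class TestMarginals:
    def test_delta_state_marginalizes_to_delta(self):
        _, space, _ = make_system(0.6, 0.1, 2, e.Model.SIR)
        pv = e.delta_state(space, (1, 1))
        marg = e.marginal_infected(pv, space)
        np.testing.assert_array_equal(marg.probabilities, [0, 1, 0])

    def test_uniform_infected_marginal_counts_states(self):
        """Uniform over the 6 states of N=2: three states have I=0, two
        have I=1, one has I=2."""
        _, space, _ = make_system(0.6, 0.1, 2, e.Model.SIR)
        marg = e.marginal_infected(uniform_state(space), space)
        np.testing.assert_allclose(marg.probabilities,
                                   [3 / 6, 2 / 6, 1 / 6], atol=1e-15)

    def test_uniform_recovered_marginal_counts_states(self):
        """R=0 requires S+I=2 (three states), R=1 requires S+I=1 (two),
        R=2 only (0,0): counting gives P(R) = (3, 2, 1)/6."""
        _, space, _ = make_system(0.6, 0.1, 2, e.Model.SIR)
        marg = e.marginal_recovered(uniform_state(space), space)
        np.testing.assert_allclose(marg.probabilities,
                                   [3 / 6, 2 / 6, 1 / 6], atol=1e-15)

    def test_recovered_delta_at_origin(self):
        _, space, _ = make_system(0.6, 0.1, 2, e.Model.SIR)
        marg = e.marginal_recovered(e.delta_state(space, (0, 0)), space)
        np.testing.assert_array_equal(marg.probabilities, [0, 0, 1])

    def test_sis_vector_passes_through(self):
        _, space, _ = make_system(0.6, 0.1, 4, e.Model.SIS)
        pv = e.delta_state(space, 3)
        np.testing.assert_array_equal(
            e.marginal_infected(pv, space).probabilities, pv.p)

    def test_marginals_conserve_mass(self):
        _, space, gen = make_system(0.6, 0.1, 6, e.Model.SIR)
        pv = e.step(gen, e.delta_state(space, (5, 1)), 3.0)
        assert e.marginal_infected(pv, space).probabilities.sum() == \
            pytest.approx(1.0, abs=1e-9)
        assert e.marginal_recovered(pv, space).probabilities.sum() == \
            pytest.approx(1.0, abs=1e-9)

    def test_mismatched_vector_rejected(self):
        _, space, _ = make_system(0.6, 0.1, 2, e.Model.SIR)
        with pytest.raises(ValueError):
            e.marginal_infected(e.ProbabilityVector(p=np.ones(4) / 4), space)

    def test_marginalization_commutes_with_propagation_when_beta_zero(self):
        """With beta=0 the infected marginal of the propagated SIR state is
        the closed-form binomial, independent of the susceptible split."""
        _, space, gen = make_system(0.0, 0.2, 5, e.Model.SIR)
        pv = e.step(gen, e.delta_state(space, (2, 3)), 4.0)
        p = math.exp(-0.2 * 4.0)
        binom = [math.comb(3, k) * p ** k * (1 - p) ** (3 - k)
                 for k in range(4)] + [0.0, 0.0]
        np.testing.assert_allclose(
            e.marginal_infected(pv, space).probabilities, binom, atol=1e-10)


class TestEntropy:
    def test_delta_has_zero_entropy(self):
        m = e.MarginalDistribution("I", [0.0, 1.0, 0.0])
        assert e.entropy(m) == 0.0

    def test_uniform_has_log_m(self):
        m = e.MarginalDistribution("I", np.full(7, 1 / 7))
        assert e.entropy(m) == pytest.approx(math.log(7), abs=1e-12)
        assert e.entropy(m, log_base=2) == pytest.approx(math.log2(7),
                                                         abs=1e-12)

    def test_bounds_hold_along_a_propagation(self):
        _, space, gen = make_system(0.6, 0.1, 12, e.Model.SIS)
        series = e.evolve(gen, e.delta_state(space, 1),
                          e.PropagationConfig(dt=0.1, t_max=30,
                                              record_stride=10))
        for pv in series:
            h = e.entropy(e.marginal_infected(pv, space))
            assert 0.0 <= h <= math.log(space.N + 1) + 1e-12


class TestExpectedFraction:
    def test_delta(self):
        m = e.MarginalDistribution("I", [0, 0, 0, 1.0])
        assert e.expected_fraction(m) == pytest.approx(1.0)

    def test_uniform_is_half(self):
        m = e.MarginalDistribution("I", np.full(11, 1 / 11))
        assert e.expected_fraction(m) == pytest.approx(0.5)

    def test_binomial_mean(self):
        p = 0.3
        probs = [math.comb(4, k) * p ** k * (1 - p) ** (4 - k)
                 for k in range(5)]
        m = e.MarginalDistribution("I", probs)
        assert e.expected_fraction(m) == pytest.approx(p, abs=1e-12)


class TestNoOutbreakMass:
    def test_full_bound_captures_everything(self):
        m = e.MarginalDistribution("R", np.full(5, 0.2))
        assert no_outbreak_mass(m, 4) == pytest.approx(1.0)

    def test_delta_at_zero(self):
        m = e.MarginalDistribution("R", [1.0, 0, 0])
        assert no_outbreak_mass(m, 0) == 1.0

    def test_negative_bound_rejected(self):
        m = e.MarginalDistribution("R", [1.0, 0, 0])
        with pytest.raises(ValueError):
            no_outbreak_mass(m, -1)

    def test_fractional_bound_floors(self):
        m = e.MarginalDistribution("R", [0.5, 0.3, 0.2])
        assert no_outbreak_mass(m, 1.7) == pytest.approx(0.8)


class TestOrderParameterCloud:
    def test_sis_metastable_mode_near_deterministic_prevalence(self):
        """At R0 well above 1 the infected marginal at t=1000 concentrates
        (outside the absorbing spike) around (1 - 1/R0) * N."""
        res = order_parameter_cloud([6.0], N=20, i0=1, model=e.Model.SIS,
                                    measure_time=1000.0)
        probs = res.cloud["probability"].to_numpy()
        mode = 1 + int(np.argmax(probs[1:]))
        assert abs(mode - (1 - 1 / 6) * 20) <= 1.5

    def test_sir_entropy_non_monotonic_in_r0(self):
        res = order_parameter_cloud([0.8, 1.2, 2.0, 4.0], N=40, i0=1,
                                    model=e.Model.SIR, measure_time=600.0)
        h = res.entropies["entropy"].to_numpy()
        k = int(np.argmax(h))
        assert 0 < k < len(h) - 1          # rises then falls

    def test_sir_no_outbreak_mass_approaches_one_below_threshold(self):
        res = order_parameter_cloud([0.2], N=30, i0=1, model=e.Model.SIR,
                                    measure_time=600.0)
        sub = res.cloud[res.cloud["r0"] == 0.2]
        probs = sub["probability"].to_numpy()
        m = e.MarginalDistribution("R", probs)
        assert no_outbreak_mass(m, 0.2 * 30 + 1) > 0.97

    def test_sir_steady_recovered_marginal_is_bimodal(self):
        """For R0 well above 1 the stationary recovered marginal carries
        mass both in the minor-outbreak window and around the deterministic
        attack rate."""
        r0, n = 4.0, 100
        res = order_parameter_cloud([r0], N=n, i0=1, model=e.Model.SIR,
                                    measure_time=1000.0)
        probs = res.cloud["probability"].to_numpy()
        m = e.MarginalDistribution("R", probs)
        rho_inf = e.sir_final_size(r0, s0=(n - 1) / n)
        minor_bound = 0.2 * rho_inf * n + 1
        minor_mass = no_outbreak_mass(m, minor_bound)
        lo, hi = int(0.8 * rho_inf * n), int(np.ceil(1.2 * rho_inf * n))
        major_mass = probs[lo:hi + 1].sum()
        assert minor_mass >= 0.5 * (1 / r0)
        assert major_mass >= 0.5 * (1 - 1 / r0)
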