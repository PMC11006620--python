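"""ATN dynamics: rate functions, functional response, ODE right-hand side,
integration with extinction clamping, and foraging policies."""

import numpy as np
import pytest

from conftest import random_community
from flexforage.atn_simulator import (ATNParameters, BOLTZMANN_EV, Community,
                                      ForagingPolicy, arrhenius, derivatives,
                                      foraging_weights, functional_response,
                                      metabolic_rate, ricker_niche, simulate)


class TestRickerNiche:
    def test_maximum_at_optimal_ratio_is_exactly_one(self):
        assert ricker_niche(71.68, 1.0) == 1.0

    def test_far_tail_thresholded_to_zero(self):
        assert ricker_niche(1e9, 1.0) == 0.0
        assert ricker_niche(1.0, 1e9) == 0.0

    def test_formula_oracle_at_ratio_ropt_e(self):
        # u = m_i/(m_j R_opt) = e: L = (e * e^{1-e})^gamma
        got = ricker_niche(71.68 * np.e, 1.0, gamma_R=2.0)
        expected = (np.e * np.exp(1.0 - np.e)) ** 2.0
        assert abs(got - expected) < 1e-12

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            ricker_niche(-1.0, 1.0)


class TestArrhenius:
    @pytest.mark.parametrize("E", [-0.69, -0.65, -0.38, 0.25, 0.26])
    def test_identity_at_reference_temperature(self, E):
        assert arrhenius(E, 293.15, 293.15) == 1.0

    def test_negative_activation_energy_rises_with_warming(self):
        assert arrhenius(-0.69, 303.15) > 1.0

    def test_positive_activation_energy_falls_with_warming(self):
        assert arrhenius(0.26, 303.15) < 1.0

    def test_matches_direct_formula(self):
        T, T0, E = 283.15, 293.15, -0.38
        expected = np.exp(E * (T0 - T) / (BOLTZMANN_EV * T0 * T))
        assert arrhenius(E, T, T0) == pytest.approx(expected, rel=1e-14)


class TestMetabolicRate:
    def test_normalization_constant_at_unit_mass(self):
        assert metabolic_rate(1.0, 293.15, ATNParameters()) == 0.314

    def test_quarter_power_scaling(self):
        assert metabolic_rate(16.0, 293.15, ATNParameters()) == pytest.approx(
            0.314 * 16 ** -0.25)

    def test_monotone_decreasing_in_mass(self):
        m = np.array([1.0, 10.0, 100.0, 1000.0])
        x = metabolic_rate(m, 293.15, ATNParameters())
        assert np.all(np.diff(x) < 0)


class TestFunctionalResponse:
    def test_single_prey_reduces_to_holling_type_two(self,
                                                     two_species_community):
        com = two_species_community
        com.c0_i = np.zeros(2)
        params = ATNParameters(q=0.0)
        B = np.array([0.7, 0.3])
        _, b, h, _ = com.rate_matrices(params)
        F = functional_response(B, com, params)
        expected = (b[1, 0] * B[0] / (1.0 + h[1, 0] * b[1, 0] * B[0])
                    / com.masses[1])
        assert abs(F[1, 0] - expected) < 1e-12

    def test_zero_prey_biomass_gives_zero_feeding(self,
                                                  two_species_community):
        F = functional_response(np.array([0.0, 0.5]), two_species_community,
                                ATNParameters())
        assert np.all(F == 0)

    def test_negative_biomass_rejected(self, two_species_community):
        with pytest.raises(ValueError):
            functional_response(np.array([-0.1, 0.5]),
                                two_species_community, ATNParameters())

    def test_scalar_loop_oracle(self):
        """Element-by-element re-implementation of the response on random
        small communities and states."""
        rng = np.random.default_rng(10)
        params = ATNParameters(T=288.15)
        for _ in range(20):
            com = random_community(rng)
            S = com.n_species
            B = rng.uniform(0.0, 2.0, S)
            w = foraging_weights(com, ForagingPolicy("static"))
            _, b, h, c = com.rate_matrices(params)
            F = functional_response(B, com, params, w=w)
            for i in range(S):
                half = sum(w[i, k] * h[i, k] * b[i, k]
                           * B[k] ** (1 + params.q) for k in range(S))
                for j in range(S):
                    expected = (w[i, j] * b[i, j] * B[j] ** (1 + params.q)
                                / (1 + c[i] * B[i] + half) / com.masses[i])
                    assert abs(F[i, j] - expected) < 1e-12


class TestForagingWeights:
    def test_static_uniform_over_prey(self):
        rng = np.random.default_rng(3)
        com = random_community(rng)
        w = foraging_weights(com, ForagingPolicy("static"))
        for i in np.flatnonzero(~com.is_basal):
            n = com.link[i].sum()
            assert np.allclose(w[i, com.link[i]], 1.0 / n)

    def test_rows_sum_to_one(self):
        from flexforage.experiment import default_predictor

        rng = np.random.default_rng(4)
        com = random_community(rng, n_species_max=5)
        pol = ForagingPolicy("flexible", predictor=default_predictor())
        w = foraging_weights(com, pol, biomasses=rng.uniform(0.1, 1,
                                                             com.n_species),
                             temp_C=10.0)
        rows = com.link.any(axis=1)
        np.testing.assert_allclose(w[rows].sum(axis=1), 1.0, atol=1e-12)

    def test_tiny_scale_concentrates_on_one_prey(self, two_species_community):
        com = two_species_community
        com.L = np.array([[0.0, 0.0], [1.0, 1.0]])  # give consumer 2 prey
        com.link = com.L > 0

        def predictor(log_m, temp, log_res):
            from scipy.stats import skewnorm
            return lambda x: skewnorm.pdf(x, 0.0, loc=0.0, scale=1e-3)

        pol = ForagingPolicy("flexible", predictor=predictor)
        w = foraging_weights(com, pol, biomasses=np.array([1.0, 1.0]),
                             temp_C=10.0)
        # prey 0 sits at log mass 0 = the preference location
        assert w[1, 0] > 0.999

    def test_vanishing_density_falls_back_to_uniform(self,
                                                     two_species_community):
        def predictor(log_m, temp, log_res):
            return lambda x: np.zeros_like(x)

        pol = ForagingPolicy("flexible", predictor=predictor)
        w = foraging_weights(two_species_community, pol,
                             biomasses=np.array([1.0, 1.0]), temp_C=10.0)
        assert w[1, 0] == 1.0


class TestDerivatives:
    def test_nutrient_only_closed_form(self):
        """No uptake (v = 0): dN_l/dt = D(S_l - N_l), a linear relaxation."""
        rng = np.random.default_rng(5)
        com = random_community(rng)
        params = ATNParameters(v=(0.0, 0.0))
        state = np.concatenate([rng.uniform(0.1, 1, com.n_species),
                                [1.0, 4.0]])
        d = derivatives(state, com, params)
        assert abs(d[-2] - params.D * (params.S[0] - 1.0)) < 1e-12
        assert abs(d[-1] - params.D * (params.S[1] - 4.0)) < 1e-12

    def test_all_biomass_zero(self):
        rng = np.random.default_rng(6)
        com = random_community(rng)
        params = ATNParameters()
        state = np.concatenate([np.zeros(com.n_species), [2.0, 3.0]])
        d = derivatives(state, com, params)
        assert np.all(d[:com.n_species] == 0)
        assert d[-2] == pytest.approx(params.D * (params.S[0] - 2.0))

    def test_nan_state_rejected(self):
        rng = np.random.default_rng(7)
        com = random_community(rng)
        state = np.full(com.n_species + 2, np.nan)
        with pytest.raises(ValueError):
            derivatives(state, com, ATNParameters())

    def test_term_by_term_oracle(self):
        """Scalar re-derivation of every consumer, basal and nutrient
        term on random small communities."""
        rng = np.random.default_rng(8)
        params = ATNParameters(T=287.15)
        for _ in range(20):
            com = random_community(rng)
            S = com.n_species
            B = rng.uniform(0.0, 2.0, S)
            N = rng.uniform(0.5, 5.0, 2)
            state = np.concatenate([B, N])
            w = foraging_weights(com, ForagingPolicy("static"))
            F = functional_response(B, com, params, w=w)
            d = derivatives(state, com, params, w=w)
            arrE = lambda E: np.exp(E * (params.T0 - params.T)
                                    / (BOLTZMANN_EV * params.T0 * params.T))
            for i in range(S):
                x_i = params.x0 * com.masses[i] ** -0.25 * arrE(params.E_x)
                loss = sum(B[j] * F[j, i] for j in range(S)) + x_i * B[i]
                if com.is_basal[i]:
                    bi = list(com.basal_indices).index(i)
                    r_i = com.masses[i] ** -0.25 * arrE(params.E_r)
                    G = min(N[0] / (com.K[bi, 0] + N[0]),
                            N[1] / (com.K[bi, 1] + N[1]))
                    expected = r_i * G * B[i] - loss
                else:
                    gain = sum(
                        (params.e_P if com.is_basal[j] else params.e_A)
                        * F[i, j] for j in range(S)) * B[i]
                    expected = gain - loss
                assert abs(d[i] - expected) < 1e-10
            for l in range(2):
                uptake = 0.0
                for bi, i in enumerate(com.basal_indices):
                    r_i = com.masses[i] ** -0.25 * arrE(params.E_r)
                    G = min(N[0] / (com.K[bi, 0] + N[0]),
                            N[1] / (com.K[bi, 1] + N[1]))
                    uptake += r_i * G * B[i]
                expected = (params.D * (params.S[l] - N[l])
                            - params.v[l] * uptake)
                assert abs(d[S + l] - expected) < 1e-10


class TestSimulate:
    def test_basal_only_community_persists(self):
        com = Community(
            masses=np.array([2.0, 20.0, 200.0]),
            is_basal=np.ones(3, bool),
            beta_cons=np.full(3, 0.47), beta_res=np.full(3, 0.15),
            eta_cons=np.full(3, -0.48), eta_res=np.full(3, -0.66),
            c0_i=np.full(3, 0.8), L=np.zeros((3, 3)),
            link=np.zeros((3, 3), bool),
            K=np.full((3, 2), 0.15))
        res = simulate(com, ATNParameters(), B0=np.array([0.5, 0.5, 0.5]),
                       t_end=500.0)
        assert res.extinct == {}
        assert np.all(res.final_biomasses > 0)
        assert np.all(res.biomasses < 1e6)

    def test_preyless_consumer_decays_at_metabolic_rate(self):
        """A consumer without prey decays as exp(-x t); its extinction
        time equals log(B0/theta)/x."""
        com = Community(
            masses=np.array([1.0, 100.0]),
            is_basal=np.array([True, False]),
            beta_cons=np.full(2, 0.47), beta_res=np.full(2, 0.15),
            eta_cons=np.full(2, -0.48), eta_res=np.full(2, -0.66),
            c0_i=np.zeros(2), L=np.zeros((2, 2)),
            link=np.zeros((2, 2), bool), K=np.full((1, 2), 0.15))
        params = ATNParameters()
        B0 = np.array([0.5, 0.8])
        res = simulate(com, params, B0=B0, t_end=3000.0)
        x = metabolic_rate(100.0, params.T, params)
        expected_t = np.log(B0[1] / params.extinction_threshold) / x
        assert 1 in res.extinct
        assert res.extinct[1] == pytest.approx(expected_t, rel=1e-5)

    def test_determinism(self):
        rng = np.random.default_rng(9)
        com = random_community(rng)
        B0 = rng.uniform(0.1, 1, com.n_species)
        params = ATNParameters().with_temperature_C(15.0)
        r1 = simulate(com, params, B0=B0, t_end=300.0)
        r2 = simulate(com, params, B0=B0, t_end=300.0)
        assert r1.extinct == r2.extinct
        np.testing.assert_array_equal(r1.biomasses, r2.biomasses)

    def test_nonnegativity_and_no_resurrection(self):
        from flexforage.synthetic_data import generate_community

        params = ATNParameters().with_temperature_C(18.0)
        com = generate_community(10, 6, params, seed=12)
        rng = np.random.default_rng(13)
        res = simulate(com, params, B0=rng.uniform(0.1, 1, com.n_species),
                       t_end=1000.0)
        assert res.biomasses.min() > -1e-10
        for sp, t_ext in res.extinct.items():
            after = res.t > t_ext + 1e-9
            assert np.all(res.biomasses[after, sp] == 0.0)

    def test_constant_pdf_flexible_matches_static_bitwise(self):
        from flexforage.synthetic_data import generate_community

        params = ATNParameters().with_temperature_C(12.0)
        com = generate_community(6, 4, params, seed=21)
        rng = np.random.default_rng(22)
        B0 = rng.uniform(0.1, 1, com.n_species)

        def constant_pdf(log_m, temp, log_res):
            return lambda x: np.ones_like(np.asarray(x, dtype=float))

        r_static = simulate(com, params, ForagingPolicy("static"),
                            B0=B0, t_end=500.0)
        r_flex = simulate(com, params,
                          ForagingPolicy("flexible", predictor=constant_pdf),
                          B0=B0, t_end=500.0)
        np.testing.assert_array_equal(r_static.biomasses, r_flex.biomasses)
        assert r_static.extinct == r_flex.extinct

    def test_invalid_t_end(self):
        rng = np.random.default_rng(1)
        com = random_community(rng)
        with pytest.raises(ValueError):
            simulate(com, ATNParameters(), B0=np.ones(com.n_species),
                     t_end=-1.0)


class TestTemperatureSigns:
    def test_warming_raises_metabolism_and_lowers_handling(self):
        rng = np.random.default_rng(30)
        com = random_community(rng)
        cold = ATNParameters().with_temperature_C(10.0)
        warm = ATNParameters().with_temperature_C(20.5)
        x_cold = metabolic_rate(com.masses, cold.T, cold)
        x_warm = metabolic_rate(com.masses, warm.T, warm)
        assert np.all(x_warm > x_cold)
        _, _, h_cold, _ = com.rate_matrices(cold)
        _, _, h_warm, _ = com.rate_matrices(warm)
        assert np.all(h_warm < h_cold)


def test_energy_bookkeeping_without_metabolism():
    """With both assimilation efficiencies at 1 and metabolism off, the
    net biomass change equals basal production: predation only moves
    biomass around."""
    rng = np.random.default_rng(31)
    com = random_community(rng)
    params = ATNParameters(e_P=1.0, e_A=1.0, x0=0.0)
    S = com.n_species
    B = rng.uniform(0.1, 1.5, S)
    N = np.array([3.0, 3.0])
    w = foraging_weights(com, ForagingPolicy("static"))
    F = functional_response(B, com, params, w=w)
    gains = sum(B[i] * F[i, j] for i in range(S) for j in range(S))
    losses = sum(B[j] * F[j, i] for i in range(S) for j in range(S))
    assert gains == pytest.approx(losses, abs=1e-8)
    d = derivatives(np.concatenate([B, N]), com, params, w=w)
    r = com.masses ** -0.25
    bi = com.basal_indices
    G = np.minimum(N[0] / (com.K[:, 0] + N[0]), N[1] / (com.K[:, 1] + N[1]))
    production = float((r[bi] * G * B[bi]).sum())
    assert d[:S].sum() == pytest.approx(production, abs=1e-8)
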