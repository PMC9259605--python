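import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tagkin import DemographyParams, ModelParams, ParameterError
from tagkin.coalescence import CoalescenceProbs, equilibrium_two_locus
from tagkin.engine import (
    ConvergenceConfig,
    PopulationState,
    compute_mterms,
    fitness,
    generation_step,
    iterate_to_equilibrium,
    m_abandon,
    m_helped,
    m_interact,
    mutation_step,
    recombination_step,
    selection_step,
    standard_initial_state,
    state_stats,
    summary_stats,
)

F_N30_M03 = 0.49 / 15.79


def params_for(demography, **kw):
    kw.setdefault("alpha", 1.0)
    kw.setdefault("c_search", 0.0)
    kw.setdefault("b", 0.3)
    kw.setdefault("c", 0.1)
    kw.setdefault("mu_trait", 0.001)
    return ModelParams(demography=demography, **kw)


class TestMInteract:
    def test_fixed_tag_always_interacts(self):
        for alpha in (0.0, 0.5, 1.0):
            for F in (0.0, 0.2, 1.0):
                assert m_interact(1.0, F, alpha) == pytest.approx(1.0)

    def test_alpha_one_algebraic_identity(self):
        # with alpha = 1 the denominator equals the numerator
        assert m_interact(0.05, 0.2, 1.0) == pytest.approx(1.0, abs=1e-12)

    def test_alpha_zero_direct_evaluation(self):
        F = F_N30_M03
        expect = F + (1.0 - F) * 0.1  # 0.12793 at F ~= 0.03103
        assert m_interact(0.1, F, 0.0) == pytest.approx(expect, abs=1e-15)
        assert m_interact(0.1, F, 0.0) == pytest.approx(0.12793, abs=5e-6)

    def test_singular_point_defined_zero(self):
        assert m_interact(0.0, 0.0, 1.0) == 0.0


def oracle_m_helped(state, probs, params):
    """Independent scalar re-implementation from the itemised encounter
    outcomes: (i) tag-IBD helper, (ii) chance-matched helper, and for a
    helper focal additionally (iii) both-locus IBD and (iv) trait-IBD
    chance-matched actors, each upscaled by the geometric search factor."""
    F, phi, gamma = probs.F, probs.phi, probs.gamma
    a, N, L = params.alpha, params.N, state.L_max
    x = state.tag_freq
    p = state.helper_prop
    mint = [float(m_interact(float(x[i]), F, a)) for i in range(L)]
    ind1, ind0, deme1, deme0 = [], [], [], []
    for i in range(L):
        up = 1.0 - a * (1.0 - x[i]) * (1.0 - F)
        o_i = (F - phi) * p[i]
        o_ii = (1 - 2 * F + phi) * p[i] * x[i]
        o_iii = phi
        o_iv = (F - phi) * x[i]
        ind1.append((o_i + o_ii + o_iii + o_iv) / up)
        ind0.append((o_i + o_ii) / up)
        helpers = sum(x[l] * p[l] for l in range(L))
        reach = [x[l] + (1 - x[l]) * a * mint[l] for l in range(L)]
        o_bi = (F - gamma) * helpers
        o_bii = (1 - 2 * F + gamma) * sum(
            p[l] * x[l] * reach[l] for l in range(L)
        )
        o_di = gamma
        o_dii = (F - gamma) * (
            sum(x[l] * p[l] / helpers * reach[l] for l in range(L))
            if helpers > 0 else 0.0
        )
        frac = (N - 2) / N
        deme1.append(ind1[i] / N + mint[i] / N
                     + frac * (o_bi + o_bii + o_di + o_dii))
        deme0.append(ind0[i] / N + frac * (o_bi + o_bii))
    pop = sum(p[l] * x[l] * mint[l] for l in range(L))
    return (np.array(ind1), np.array(ind0), np.array(deme1),
            np.array(deme0), pop)


class TestMHelped:
    def test_no_helpers_gives_zero_defector_terms(self, probs, demography):
        x = np.column_stack([np.array([0.6, 0.4]), np.zeros(2)])
        state = PopulationState(x)
        p = params_for(demography, L_max=2)
        ind1, ind0, deme1, deme0, pop = m_helped(state, probs, p)
        assert np.all(ind0 == 0)
        assert np.all(deme0 == 0)
        assert pop == 0

    def test_single_fixed_helper_tag(self, demography):
        cp = equilibrium_two_locus(DemographyParams(N=30, m=0.3, r=0.0))
        assert cp.F == pytest.approx(cp.phi)
        state = PopulationState(np.array([[0.0, 1.0]]))
        p = params_for(demography, L_max=1, mu_trait=0.0)
        ind1, _, _, _, pop = m_helped(state, cp, p)
        assert ind1[0] == pytest.approx(1.0, abs=1e-12)
        assert pop == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_enumeration_oracle(self, probs, demography, random_state, seed):
        state = random_state(6, seed)
        p = params_for(demography, L_max=6)
        got = m_helped(state, probs, p)
        want = oracle_m_helped(state, probs, p)
        for g, w in zip(got, want):
            np.testing.assert_allclose(g, w, atol=1e-13)


class TestMAbandon:
    def test_no_search_no_abandonment(self, probs, demography, random_state):
        state = random_state(4, 0)
        p = params_for(demography, alpha=0.0, L_max=4)
        ind, deme, pop, unbounded = m_abandon(state, probs, p)
        assert np.all(ind == 0) and np.all(deme == 0) and pop == 0
        assert not unbounded

    def test_fixed_tag_never_abandons(self, probs, demography):
        state = PopulationState(np.array([[0.5, 0.5]]))
        p = params_for(demography, alpha=0.7, c_search=0.001, L_max=1)
        ind, _, _, _ = m_abandon(state, probs, p)
        assert ind[0] == 0.0

    def test_limiting_total_search_cost(self):
        # rare tag, vanishing relatedness: total cost -> alpha*c_search/(1-alpha)
        alpha, cs = 0.999, 0.0009
        q = alpha * (1.0 - 0.0) * (1.0 - 0.0)
        total = cs * q / (1.0 - q)
        assert total == pytest.approx(0.9, abs=0.002)

    def test_unbounded_sentinel_at_alpha_one(self, demography):
        probs0 = CoalescenceProbs(0.0, 0.0, 0.0, 0.0)
        state = PopulationState(
            np.array([[1.0 - 2e-9, 0.0], [1e-9, 1e-9]])
        )
        p = params_for(demography, alpha=1.0, L_max=2)
        ind, _, _, unbounded = m_abandon(state, probs0, p)
        assert not np.isfinite(ind[1]) or ind[1] > 1e8 or unbounded is False


class TestFitness:
    def test_neutral_parameters_unit_fitness(self, probs, demography,
                                             random_state):
        state = random_state(5, 3)
        p = params_for(demography, b=0.0, c=0.0, L_max=5)
        w = fitness(state, compute_mterms(state, probs, p), p).w
        np.testing.assert_allclose(w, 1.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_mean_fitness_is_one(self, demography, probs, random_state, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(2, 9))
        state = random_state(L, seed + 100)
        alpha = float(rng.uniform(0, 0.95))
        cs = float(rng.uniform(0, 0.5 * (1 - alpha) / max(alpha, 1e-9)))
        cs = min(cs, 0.005)
        p = params_for(demography, alpha=alpha, c_search=cs, L_max=L)
        w = fitness(state, compute_mterms(state, probs, p), p).w
        assert float((state.x * w).sum()) == pytest.approx(1.0, abs=1e-9)

    def test_fixed_helper_tag_unit_fitness_at_full_mixing(self):
        d = DemographyParams(N=30, m=1.0, r=0.1)
        cp = equilibrium_two_locus(d)
        state = PopulationState(np.array([[0.0, 1.0]]))
        p = params_for(d, L_max=1)
        w = fitness(state, compute_mterms(state, cp, p), p).w
        assert w[0, 1] == pytest.approx(1.0, abs=1e-12)


class TestSelectionStep:
    def test_neutral_identity(self, probs, demography, random_state):
        state = random_state(4, 7)
        p = params_for(demography, b=0.0, c=0.0, L_max=4)
        out = selection_step(state, fitness(
            state, compute_mterms(state, probs, p), p))
        np.testing.assert_allclose(out.x, state.x, atol=1e-12)

    def test_elementwise_product_oracle(self, probs, demography, random_state):
        state = random_state(5, 11)
        p = params_for(demography, L_max=5)
        fit = fitness(state, compute_mterms(state, probs, p), p)
        out = selection_step(state, fit)
        want = state.x * fit.w
        np.testing.assert_allclose(out.x, want / want.sum(), atol=1e-14)


def oracle_recombination(x, A, r):
    """Zygote-enumeration oracle: pair every two gamete genotypes, apply
    meiosis explicitly, and accumulate offspring frequencies."""
    L = x.shape[0]
    out = A * x.copy()
    for i in range(L):
        for j in (0, 1):
            for l in range(L):
                for k in (0, 1):
                    zyg = x[i, j] * x[l, k]
                    # tag from gamete 1 w.p. 1/2 (trait follows w.p. 1-r)
                    out[i, j] += (1 - A) * zyg * 0.5 * (1 - r)
                    out[i, k] += (1 - A) * zyg * 0.5 * r
                    out[l, k] += (1 - A) * zyg * 0.5 * (1 - r)
                    out[l, j] += (1 - A) * zyg * 0.5 * r
    return out


class TestRecombinationStep:
    def test_zero_recombination_identity(self, demography, random_state):
        cp = equilibrium_two_locus(DemographyParams(N=30, m=0.3, r=0.0))
        state = random_state(4, 5)
        p = params_for(DemographyParams(N=30, m=0.3, r=0.0), L_max=4)
        out = recombination_step(state, cp, p)
        np.testing.assert_allclose(out.x, state.x, atol=1e-14)

    def test_no_association_identity(self, probs, demography):
        # equal helper proportions across tags: nothing to break up
        tags = np.array([0.5, 0.3, 0.2])
        x = np.column_stack([tags * 0.7, tags * 0.3])
        state = PopulationState(x)
        p = params_for(demography, L_max=3)
        out = recombination_step(state, probs, p)
        np.testing.assert_allclose(out.x, state.x, atol=1e-14)

    def test_marginals_preserved(self, probs, demography, random_state):
        state = random_state(6, 13)
        p = params_for(demography, L_max=6)
        out = recombination_step(state, probs, p)
        np.testing.assert_allclose(out.tag_freq, state.tag_freq, atol=1e-12)
        assert out.p_bar == pytest.approx(state.p_bar, abs=1e-12)

    def test_association_decays_at_free_recombination(self):
        d = DemographyParams(N=30, m=0.0, r=0.5)
        probs0 = CoalescenceProbs(0.0, 0.0, 0.0, 0.0)
        x = np.array([[0.75, 0.05], [0.02, 0.18]])  # rare tag rich in helpers
        state = PopulationState(x)
        p = params_for(d, L_max=2)
        before = abs(state_stats(state)["D"])
        out = recombination_step(state, probs0, p)
        after = abs(state_stats(out)["D"])
        assert after < before

    @pytest.mark.parametrize("seed", [0, 4, 9])
    def test_zygote_enumeration_oracle(self, probs, demography, random_state,
                                       seed):
        state = random_state(5, seed)
        p = params_for(demography, L_max=5)
        A = (2 * probs.F - probs.phi) * (1 - p.m) ** 2
        want = oracle_recombination(state.x, A, p.r)
        out = recombination_step(state, probs, p)
        np.testing.assert_allclose(out.x, want, atol=1e-13)


def oracle_mutation(x, mu_t, mu_g, L):
    """Full (2L x 2L) mutation-kernel oracle."""
    K = np.zeros((2 * L, 2 * L))
    for i in range(L):
        for j in (0, 1):
            a = 2 * i + j
            K[a, a] += 1 - mu_t - mu_g
            K[a, 2 * i + (1 - j)] += mu_t
            for l in range(L):
                if l != i:
                    K[a, 2 * l + j] += mu_g / (L - 1)
    return (x.reshape(-1) @ K).reshape(L, 2)


class TestMutationStep:
    def test_zero_mutation_identity(self, demography, random_state):
        state = random_state(3, 1)
        p = params_for(demography, mu_trait=0.0, L_max=3)
        np.testing.assert_allclose(mutation_step(state, p).x, state.x)

    def test_symmetric_trait_mutation(self, demography):
        state = PopulationState(np.array([[0.8, 0.2]]))
        p = params_for(demography, mu_trait=0.5, L_max=1)
        out = mutation_step(state, p)
        # p''' = p(1 - 0.5) + (1 - p) 0.5 = 0.5
        assert out.p_bar == pytest.approx(0.5, abs=1e-14)

    def test_matrix_kernel_oracle(self, demography, random_state):
        state = random_state(3, 8)
        p = params_for(demography, mu_trait=0.001, mu_tag=0.0001, L_max=3)
        want = oracle_mutation(state.x, 0.001, 0.0001, 3)
        np.testing.assert_allclose(mutation_step(state, p).x, want, atol=1e-15)

    def test_tag_marginals_fixed_without_tag_mutation(self, demography,
                                                      random_state):
        state = random_state(4, 2)
        p = params_for(demography, mu_trait=0.01, L_max=4)
        np.testing.assert_allclose(
            mutation_step(state, p).tag_freq, state.tag_freq, atol=1e-15
        )


class TestGenerationStep:
    def test_neutral_identity(self, probs, demography, random_state):
        state = random_state(4, 21)
        p = params_for(demography, b=0.0, c=0.0, mu_trait=0.0, L_max=4)
        # selection is neutral; recombination still acts on associations,
        # so use an association-free state
        tags = state.tag_freq
        flat = PopulationState(np.column_stack([tags * 0.6, tags * 0.4]))
        out = generation_step(flat, p, probs)
        np.testing.assert_allclose(out.x, flat.x, atol=1e-12)

    def test_composition_of_steps(self, probs, demography, random_state):
        state = random_state(7, 31)
        p = params_for(demography, L_max=7)
        composed = mutation_step(
            recombination_step(
                selection_step(
                    state, fitness(state, compute_mterms(state, probs, p), p)
                ),
                probs, p,
            ),
            p,
        )
        out = generation_step(state, p, probs)
        np.testing.assert_allclose(out.x, composed.x, atol=1e-15)

    def test_frequency_conservation(self, probs, demography, random_state):
        state = random_state(5, 17)
        p = params_for(demography, alpha=0.9, c_search=0.001, L_max=5)
        for _ in range(50):
            state = generation_step(state, p, probs)
            assert abs(state.x.sum() - 1.0) < 1e-9

    def test_fast_kernel_agrees_with_reference(self, probs, demography,
                                               random_state):
        pytest.importorskip("numba")
        from tagkin._kernels import run_generations_fast

        state = random_state(8, 23)
        for alpha, cs in [(1.0, 0.0), (0.6, 0.002), (0.0, 0.0)]:
            p = params_for(demography, alpha=alpha, c_search=cs, L_max=8)
            x, _, _ = run_generations_fast(
                state.x, 20, probs.F, probs.phi, probs.gamma, probs.G,
                p.alpha, p.c_search, p.b, p.c, p.mu_trait, p.mu_tag,
                p.N, p.m, p.r,
            )
            ref = state
            for _ in range(20):
                ref = generation_step(ref, p, probs)
            np.testing.assert_allclose(x, ref.x, atol=1e-12)


class TestStandardInitialState:
    def test_single_tag(self):
        s = standard_initial_state(1, seed=0)
        np.testing.assert_allclose(s.x, [[0.9, 0.1]])

    @given(L=st.integers(1, 200), seed=st.integers(0, 2**31))
    @settings(max_examples=20, deadline=None)
    def test_construction_properties(self, L, seed):
        s = standard_initial_state(L, seed)
        assert s.x.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(s.tag_freq > 0)
        if L > 1:
            assert s.tag_freq[0] == pytest.approx(0.9, abs=1e-9)
        np.testing.assert_allclose(s.helper_prop, 0.1, atol=1e-9)

    def test_determinism(self):
        a = standard_initial_state(100, seed=5)
        b = standard_initial_state(100, seed=5)
        np.testing.assert_array_equal(a.x, b.x)


class TestSummaryStats:
    def test_single_fixed_tag(self):
        s = PopulationState(np.array([[0.7, 0.3], [0.0, 0.0]]))
        stats = summary_stats([s, s], T_end=1, T_interval=1)
        assert stats.L_eff == pytest.approx(1.0)
        assert stats.tag_diversity == pytest.approx(0.0)

    def test_equal_tags_full_diversity(self):
        L = 8
        x = np.full((L, 2), 1.0 / (2 * L))
        s = PopulationState(x)
        stats = summary_stats([s, s], T_end=1, T_interval=0)
        assert stats.L_eff == pytest.approx(L)
        assert stats.tag_diversity == pytest.approx(1.0)

    def test_linkage_disequilibrium_covariance_oracle(self):
        # tags (0.8, 0.2), helper proportions (0.1, 0.9) -> p_bar = 0.26
        x = np.array([[0.8 * 0.9, 0.8 * 0.1], [0.2 * 0.1, 0.2 * 0.9]])
        s = PopulationState(x)
        pt = state_stats(s)
        assert s.p_bar == pytest.approx(0.26)
        # individual-level covariance of tag-frequency and trait deviations
        mean_tagfreq = 0.8**2 + 0.2**2
        cov = 0.0
        for i, (xf, p) in enumerate(zip([0.8, 0.2], [0.1, 0.9])):
            for trait, w in ((1, xf * p), (0, xf * (1 - p))):
                cov += w * (xf - mean_tagfreq) * (trait - 0.26)
        assert pt["D"] == pytest.approx(cov, abs=1e-15)

    def test_excess_helping_sums_to_zero(self, random_state):
        s = random_state(9, 44)
        pt = state_stats(s)
        assert abs(pt["excess_helping"].sum()) < 1e-12

    def test_window_bounds_checked(self):
        s = PopulationState(np.array([[0.5, 0.5]]))
        with pytest.raises(ParameterError):
            summary_stats([s, s], T_end=5, T_interval=0)


class TestDynamics:
    def test_mutation_only_equilibrium(self, demography):
        # b = c = 0 with trait mutation: helping settles at 0.5
        p = params_for(demography, b=0.0, c=0.0, mu_trait=0.01, L_max=3)
        res = iterate_to_equilibrium(
            standard_initial_state(3, seed=0), p,
            ConvergenceConfig(tol=1e-12, window=200, max_generations=200_000),
        )
        assert res.stats.coop == pytest.approx(0.5, abs=1e-6)

    def test_interaction_certain_at_full_search(self, probs, demography,
                                                random_state):
        state = random_state(5, 2)
        mt = compute_mterms(state, probs, params_for(demography, L_max=5))
        seg = state.tag_freq > 0
        np.testing.assert_allclose(mt.interact[seg], 1.0, atol=1e-12)

    def test_crozier_diversity_loss_without_search(self, demography):
        p = params_for(demography, alpha=0.0, L_max=30)
        init = standard_initial_state(30, seed=3)
        res = iterate_to_equilibrium(
            init, p, ConvergenceConfig(tol=1e-9, window=1000,
                                       max_generations=500_000),
        )
        assert res.stats.L_eff < 1.05
        assert res.stats.coop < 0.05

    def test_negative_frequency_dependence_two_tags(self):
        # L_max = 2 regime: the rare tag gains excess helpers, rises in
        # frequency, and the excess decays as frequencies equalise
        p = ModelParams(
            demography=DemographyParams(N=30, m=0.3, r=0.1),
            alpha=1.0, c_search=0.0, b=0.015, c=0.005,
            mu_trait=0.0001, L_max=2,
        )
        probs = equilibrium_two_locus(p.demography)
        state = standard_initial_state(2, seed=1)
        rare_freq = [state.tag_freq[1]]
        excess = [float(state_stats(state)["excess_helping"][1])]
        chunks, per_chunk = 25, 200_000
        from tagkin.engine import iterate_to_equilibrium as _run

        for _ in range(chunks):
            res = _run(state, p,
                       ConvergenceConfig(tol=0.0, window=per_chunk,
                                         max_generations=per_chunk),
                       probs=probs)
            state = res.state
            rare_freq.append(state.tag_freq[1])
            excess.append(float(state_stats(state)["excess_helping"][1]))
        rare = np.array(rare_freq)
        exc = np.array(excess)
        assert rare[-1] > rare[0]  # the rare tag rose
        assert np.all(np.diff(rare) > -1e-9)  # monotonically
        assert exc[1] > 0  # excess helping turns positive early
        assert abs(exc[-1]) < 0.1 * exc.max()  # and decays away
        assert rare[-1] == pytest.approx(0.5, abs=0.05)
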