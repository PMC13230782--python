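import numpy as np
import pytest
from scipy import stats

from cosref import (BlockModel, ContagionConfig, RegulationMatrix,
                    ensemble_rho_inf, make_distribution, seeded_rho0,
                    tl_contained, tl_fixed_point, tl_update_general,
                    tl_update_two, TLModel)
from cosref.errors import ComplexityError, ParameterError


def literal_update_two(y, model, omega, theta, rho0):
    """Quadruple-loop reference for the two-community cavity recursion.

    Enumerates every (k_intra, k_inter, m_intra, m_inter) combination with
    explicit binomials and the strict gate m.omega > theta*k, splitting the
    arriving link's channel; independent of the package's reduced inner sums.
    """
    wi, we = omega
    out = []
    for I in (0, 1):
        o = 1 - I
        pi = model.dists[I][I].dense_pmf()
        pe = model.dists[I][o].dense_pmf()
        z = model.z_community(I)
        tot = 0.0
        for ki in range(len(pi)):
            for ke in range(len(pe)):
                p = pi[ki] * pe[ke]
                if p == 0.0 or ki + ke == 0:
                    continue
                gate = theta * (ki + ke)
                term = 0.0
                if ki > 0:
                    Bi = stats.binom.pmf(np.arange(ki), ki - 1, y[I])
                    Be = stats.binom.pmf(np.arange(ke + 1), ke, y[o])
                    term += ki * sum(Bi[a] * Be[b]
                                     for a in range(ki) for b in range(ke + 1)
                                     if wi * a + we * b > gate)
                if ke > 0:
                    Bi = stats.binom.pmf(np.arange(ki + 1), ki, y[I])
                    Be = stats.binom.pmf(np.arange(ke), ke - 1, y[o])
                    term += ke * sum(Bi[a] * Be[b]
                                     for a in range(ki + 1) for b in range(ke)
                                     if wi * a + we * b > gate)
                tot += p * term
        out.append(rho0[I] + (1 - rho0[I]) * tot / z)
    return np.asarray(out)


@pytest.fixture(scope="module")
def small_model():
    # small Poisson supports keep the literal oracle affordable
    intra = make_distribution("poisson", {"z": 2.0}, truncation_mass=1e-8)
    inter = make_distribution("poisson", {"z": 1.5}, truncation_mass=1e-8)
    return TLModel.two_community(intra, inter)


class TestUpdateTwo:
    @pytest.mark.parametrize("y,omega,theta", [
        ((0.2, 0.0), (1.0, 1.0), 0.25),
        ((0.3, 0.1), (0.7, 1.0), 0.25),
        ((0.5, 0.4), (0.6, 0.3), 0.4),
        ((0.9, 0.8), (1.0, 0.0), 0.1),
        ((0.1, 0.2), (0.0, 0.5), 0.3),
    ])
    def test_matches_literal_nested_sum(self, small_model, y, omega, theta):
        rho0 = np.array([0.1, 0.0])
        got = tl_update_two(y, small_model, omega, theta=theta, rho0=rho0)
        want = literal_update_two(y, small_model, omega, theta, rho0)
        assert np.allclose(got, want, atol=1e-10, rtol=0)

    def test_omega_zero_returns_rho0(self, small_model):
        rho0 = np.array([0.15, 0.02])
        got = tl_update_two((0.7, 0.7), small_model, (0.0, 0.0), theta=0.25, rho0=rho0)
        assert np.allclose(got, rho0, atol=0)

    def test_all_adopted_corner(self):
        # y = (1, 1): every cavity neighbour adopted, so a degree-k node
        # passes iff (k - 1) > theta k; closed form via the joint pmf.
        model = TLModel.two_community_poisson(15.0, 0.5)
        theta, rho0 = 0.25, np.array([0.1, 0.0])
        got = tl_update_two((1.0, 1.0), model, (1.0, 1.0), theta=theta, rho0=rho0)
        pi = model.dists[0][0].dense_pmf()
        pe = model.dists[0][1].dense_pmf()
        joint = np.convolve(pi, pe)
        ks = np.arange(len(joint))
        ok = (ks - 1) > theta * ks
        expected = 0.1 + 0.9 * (ks[ok] * joint[ok]).sum() / model.z_community(0)
        assert got[0] == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_y(self, small_model):
        rho0 = np.array([0.1, 0.0])
        lo = tl_update_two((0.2, 0.2), small_model, (0.8, 0.9), theta=0.3, rho0=rho0)
        hi = tl_update_two((0.3, 0.3), small_model, (0.8, 0.9), theta=0.3, rho0=rho0)
        assert np.all(hi >= lo)

    def test_rule_args_validation(self, small_model):
        with pytest.raises(ParameterError):
            tl_update_two((0.1, 0.1), small_model, (1, 1), rho0=np.zeros(2))
        with pytest.raises(ParameterError):
            tl_update_two((0.1, 0.1), small_model, (1, 1), theta=0.2, C=1.0,
                          rho0=np.zeros(2))


class TestUpdateGeneral:
    def test_n2_specialisation_matches_fast_path(self, small_model):
        rho0 = np.array([0.12, 0.03])
        for y, om, theta in [((0.2, 0.05), (0.9, 0.7), 0.25),
                             ((0.4, 0.3), (0.5, 1.0), 0.15),
                             ((0.8, 0.6), (1.0, 0.0), 0.35)]:
            two = tl_update_two(y, small_model, om, theta=theta, rho0=rho0)
            gen = tl_update_general(y, small_model, RegulationMatrix.from_pair(*om),
                                    theta=theta, rho0=rho0)
            assert np.allclose(two, gen, atol=1e-12, rtol=0)

    def test_omega_zero_returns_rho0(self, small_model):
        rho0 = np.array([0.2, 0.05])
        got = tl_update_general((0.5, 0.5), small_model, np.zeros((2, 2)),
                                theta=0.25, rho0=rho0)
        assert np.allclose(got, rho0, atol=0)

    def test_three_module_symmetry(self):
        intra = make_distribution("poisson", {"z": 3.0}, truncation_mass=1e-7)
        inter = make_distribution("poisson", {"z": 1.0}, truncation_mass=1e-7)
        model = TLModel.symmetric(3, intra, inter)
        rho0 = np.array([0.3, 0.0, 0.0])
        y = tl_update_general(rho0, model, RegulationMatrix.from_pair(1.0, 0.8, n=3),
                              theta=0.2, rho0=rho0)
        assert y[1] == pytest.approx(y[2], abs=1e-14)
        assert y[0] > y[1]

    def test_complexity_guard(self):
        intra = make_distribution("poisson", {"z": 20.0})
        model = TLModel.symmetric(4, intra, intra)
        with pytest.raises(ComplexityError):
            tl_update_general(np.zeros(4), model, np.ones((4, 4)), theta=0.2,
                              rho0=np.zeros(4), op_budget=1e6)


class TestFixedPoint:
    def test_omega_zero_exact(self, small_model):
        rho0 = np.array([0.2, 0.0])
        res = tl_fixed_point(small_model, (0.0, 0.0), theta=0.25, rho0=rho0)
        assert res.converged
        assert np.allclose(res.y_inf, rho0, atol=0)
        assert np.allclose(res.rho_inf, rho0, atol=0)
        assert res.rho_global == pytest.approx(0.1, abs=1e-15)

    def test_iterates_monotone_nondecreasing(self, small_model):
        rho0 = np.array([0.2, 0.0])
        y = rho0.copy()
        for _ in range(40):
            y_next = tl_update_two(y, small_model, (0.9, 0.9), theta=0.25, rho0=rho0)
            assert np.all(y_next >= y - 1e-15)
            y = y_next
        assert np.all(y <= 1.0)

    def test_rho_monotone_in_parameters(self, small_model):
        rho0 = np.array([0.2, 0.0])
        rhos_w = [tl_fixed_point(small_model, (w, w), theta=0.25, rho0=rho0).rho_global
                  for w in (0.2, 0.5, 0.8, 1.0)]
        assert np.all(np.diff(rhos_w) >= -1e-12)
        rhos_t = [tl_fixed_point(small_model, (1, 1), theta=t, rho0=rho0).rho_global
                  for t in (0.1, 0.3, 0.5)]
        assert np.all(np.diff(rhos_t) <= 1e-12)
        rhos_r = [tl_fixed_point(small_model, (0.5, 0.5), theta=0.3,
                                 rho0=np.array([r, 0.0])).rho_global
                  for r in (0.1, 0.2, 0.4)]
        assert np.all(np.diff(rhos_r) >= -1e-12)

    def test_constant_rule_matches_equivalent_proportional_gate(self):
        # regular(4) intra + regular(3) inter: every node has k = 7, so
        # theta = 0.2 gates at 1.4 and C = 1.5 gates at 1.5 -- with omega =
        # (1, 1) and integer influence both mean "at least 2 adopted
        # neighbours", in the recursion and in the steady state alike.
        model = TLModel.two_community(make_distribution("regular", {"degree": 4}),
                                      make_distribution("regular", {"degree": 3}))
        rho0 = np.array([0.2, 0.0])
        a = tl_fixed_point(model, (1.0, 1.0), theta=0.2, rho0=rho0)
        b = tl_fixed_point(model, (1.0, 1.0), C=1.5, rho0=rho0)
        assert np.allclose(a.y_inf, b.y_inf, atol=1e-12)
        assert np.allclose(a.rho_inf, b.rho_inf, atol=1e-12)

    def test_seeded_rho0_helper(self):
        model = TLModel.two_community_poisson(10.0, 0.5)
        assert np.allclose(seeded_rho0(model, 0.1), [0.2, 0.0])
        with pytest.raises(ParameterError):
            seeded_rho0(model, 0.6)

    def test_containment_indicator(self):
        model = TLModel.two_community_poisson(15.0, 0.5)
        rho0 = seeded_rho0(model, 0.1)
        assert tl_contained(model, (0.0, 0.0), theta=0.25, rho0=rho0)
        assert not tl_contained(model, (1.0, 1.0), theta=0.25, rho0=rho0)


class TestAgainstSimulation:
    def test_three_module_fixed_point_vs_monte_carlo(self):
        intra = make_distribution("poisson", {"z": 4.0}, truncation_mass=1e-7)
        inter = make_distribution("poisson", {"z": 1.0}, truncation_mass=1e-7)
        model = TLModel.symmetric(3, intra, inter)
        rho0 = np.array([0.3, 0.0, 0.0])
        Omega = RegulationMatrix.from_pair(1.0, 1.0, n=3)
        tl = tl_fixed_point(model, Omega, theta=0.2, rho0=rho0, tol=1e-8)
        assert tl.converged
        cfg = ContagionConfig(rho0=0.1, theta=0.2, seed=21)
        sim = ensemble_rho_inf(model.block_model(9000), Omega, cfg, 4)
        assert abs(tl.rho_global - sim.mean) < 0.03
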