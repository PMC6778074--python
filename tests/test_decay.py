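"""Decay data model, chain activity math and emission sampling."""

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from nanodose.constants import LN2
from nanodose.decay import (
    DecayChain,
    DegenerateChainError,
    Radionuclide,
    UnknownNuclideError,
    _beta_density,
    available_nuclides,
    bateman_activities,
    build_chain,
    chain_cumulative_disintegrations,
    cumulative_activity,
    decay_constant,
    load_nuclide,
    sample_beta_energy,
    sample_emissions,
)


@pytest.mark.parametrize("half_life, expected, tol", [
    (LN2, 1.0, 1e-12),
    (11.43 * 86400, 7.018e-7, 1e-3),   # Ra-223
    (78.41 * 3600, 2.456e-6, 1e-3),    # Zr-89
])
def test_decay_constant_values(half_life, expected, tol):
    assert decay_constant(half_life) == pytest.approx(expected, rel=tol)


def test_decay_constant_rejects_nonpositive():
    with pytest.raises(ValueError):
        decay_constant(0.0)


def test_all_packaged_nuclides_validate():
    symbols = available_nuclides()
    assert len(symbols) >= 20
    for sym in symbols:
        nuc = load_nuclide(sym)
        nuc.validate()
        if not nuc.stable:
            assert nuc.decay_constant == pytest.approx(
                LN2 / nuc.half_life_s, rel=1e-12)
            assert sum(b for _, b in nuc.modes) == pytest.approx(1.0, abs=1e-9)


def test_unknown_nuclide_raises():
    with pytest.raises(UnknownNuclideError):
        load_nuclide("Xx-999")


class TestCumulativeActivity:
    def test_zero_activity(self):
        assert cumulative_activity(0.0, "Ra-223") == 0.0

    def test_ra223_total_disintegrations(self):
        # 1 kBq of Ra-223: ~1.4e9 disintegrations of the parent
        atilde = cumulative_activity(1000.0, "Ra-223")
        assert round(atilde / 1e9, 1) == 1.4

    def test_y90_closed_form(self):
        # A0 * t_half / ln2
        expected = 1000.0 * 64.05 * 3600 / LN2
        assert cumulative_activity(1000.0, "Y-90") == pytest.approx(expected)

    def test_parent_entry_closed_form_every_isotope(self):
        for sym in ("Ra-223", "Bi-213", "Y-90", "Lu-177", "Cu-67",
                    "Cu-64", "Zr-89"):
            chain = build_chain(sym, 1000.0)
            cum = chain_cumulative_disintegrations(chain)
            nuc = load_nuclide(sym)
            assert cum.per_nuclide[sym] == pytest.approx(
                1000.0 / nuc.decay_constant, rel=1e-12)


def _ode_activities(lambdas, branchings, a0, t_eval):
    """Stiff-ODE oracle for a linear chain: dN1/dt = -l1 N1;
    dNi/dt = b_{i-1} l_{i-1} N_{i-1} - l_i N_i."""
    n = len(lambdas)
    n0 = np.zeros(n)
    n0[0] = a0 / lambdas[0]

    def rhs(t, y):
        dy = -lambdas * y
        dy[1:] += branchings * lambdas[:-1] * y[:-1]
        return dy

    sol = solve_ivp(rhs, (0.0, t_eval.max()), n0, t_eval=t_eval,
                    method="LSODA", rtol=1e-12, atol=1e-20)
    return lambdas[:, None] * sol.y


def _linear_chain(lambdas, branchings, a0=1000.0):
    """Assemble a DecayChain directly from decay constants (test helper)."""
    members = tuple(
        Radionuclide(symbol=f"T-{i}", half_life_s=LN2 / lam,
                     modes=(((f"T-{i+1}" if i < len(lambdas) - 1 else "end"),
                             1.0),))
        for i, lam in enumerate(lambdas))
    cum = np.concatenate([[1.0], np.cumprod(branchings)])
    paths = tuple(
        (tuple(f"T-{j}" for j in range(i + 1)), float(cum[i]))
        for i in range(len(lambdas)))
    return DecayChain(parent="T-0", a0_bq=a0, members=members,
                      cumulative_branching=tuple(cum),
                      paths=paths)


class TestBateman:
    def test_single_member_is_pure_exponential(self):
        chain = _linear_chain(np.array([1e-3]), np.array([]))
        t = np.array([0.0, 100.0, 5000.0])
        act = bateman_activities(chain, t)["T-0"]
        np.testing.assert_allclose(act, 1000.0 * np.exp(-1e-3 * t), rtol=1e-13)

    def test_daughter_activity_zero_at_t0(self):
        chain = _linear_chain(np.array([1e-3, 5e-3]), np.array([1.0]))
        act = bateman_activities(chain, 0.0)
        assert act["T-1"] == pytest.approx(0.0, abs=1e-9)

    def test_two_member_matches_ode(self):
        chain = _linear_chain(np.array([1e-3, 5e-3]), np.array([1.0]))
        t = np.array([600.0])
        act = bateman_activities(chain, t)
        oracle = _ode_activities(np.array([1e-3, 5e-3]), np.array([1.0]),
                                 1000.0, t)
        assert act["T-1"][0] == pytest.approx(oracle[1, 0], rel=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_random_chains_match_ode(self, seed):
        """2-4 member chains with lambda ratios in [1.1, 1e4], 20 times."""
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 5)
        lam0 = 10.0 ** rng.uniform(-6, -3)
        ratios = 10.0 ** rng.uniform(np.log10(1.1), 4, n - 1)
        lambdas = lam0 * np.concatenate([[1.0], np.cumprod(ratios)])
        rng.shuffle(lambdas)
        branchings = rng.uniform(0.2, 1.0, n - 1)
        chain = _linear_chain(lambdas, branchings)
        t = np.linspace(0.01, 3.0, 20) / lambdas.min()
        act = bateman_activities(chain, t)
        oracle = _ode_activities(lambdas, branchings, 1000.0, t)
        for i in range(n):
            np.testing.assert_allclose(act[f"T-{i}"], oracle[i],
                                       rtol=1e-8, atol=1e-12)

    def test_degenerate_lambdas_raise(self):
        chain = _linear_chain(np.array([1e-3, 1e-3]), np.array([1.0]))
        with pytest.raises(DegenerateChainError):
            bateman_activities(chain, 10.0)


class TestChainCumulative:
    def test_single_nuclide_special_case(self):
        chain = _linear_chain(np.array([1e-6]), np.array([]))
        cum = chain_cumulative_disintegrations(chain)
        assert cum.per_nuclide["T-0"] == pytest.approx(1e9)

    @pytest.mark.parametrize("branching", [1.0, 0.5])
    def test_daughter_budget_vs_time_integration(self, branching):
        lambdas = np.array([1e-3, 7e-3])
        chain = _linear_chain(lambdas, np.array([branching]))
        cum = chain_cumulative_disintegrations(chain)
        # oracle: numerically integrate the daughter activity to ~infinity
        integral, _ = quad(
            lambda t: bateman_activities(chain, t)["T-1"][()],
            0, 60.0 / lambdas.min(), limit=400)
        assert cum.per_nuclide["T-1"] == pytest.approx(integral, rel=1e-6)
        assert cum.per_nuclide["T-1"] == pytest.approx(
            branching * cum.per_nuclide["T-0"], rel=1e-12)

    def test_ra223_chain_members_near_parent_budget(self):
        cum = chain_cumulative_disintegrations(build_chain("Ra-223", 1000.0))
        parent = cum.per_nuclide["Ra-223"]
        # main path branching is ~1, so every major daughter matches ~A0/lam
        for sym in ("Rn-219", "Po-215", "Pb-211", "Bi-211"):
            assert cum.per_nuclide[sym] == pytest.approx(parent, rel=1e-9)
        assert cum.per_nuclide["Po-211"] == pytest.approx(
            0.00276 * parent, rel=1e-6)


class TestBetaSampling:
    def test_support_bounds(self, rng):
        e = sample_beta_energy(500.0, 30, -1, rng, 5000)
        assert np.all(e > 0) and np.all(e < 500.0)

    def test_y90_mean_matches_quadrature(self):
        rng = np.random.default_rng(9)
        draws = sample_beta_energy(2280.1, 40, -1, rng, 100_000)
        num = quad(lambda e: e * _beta_density(np.array([e]), 2280.1, 40, -1)[0],
                   0, 2280.1, limit=200)[0]
        den = quad(lambda e: _beta_density(np.array([e]), 2280.1, 40, -1)[0],
                   0, 2280.1, limit=200)[0]
        assert draws.mean() == pytest.approx(num / den, rel=5e-3)

    def test_small_endpoint_limit(self, rng):
        e = sample_beta_energy(0.05, 30, -1, rng, 100)
        assert np.all(e < 0.05)

    def test_positron_spectrum_suppressed_at_low_energy(self):
        """The Coulomb factor suppresses slow positrons but boosts slow
        electrons, so the beta+ mean exceeds the beta- mean."""
        rng = np.random.default_rng(4)
        em = sample_beta_energy(653.1, 28, -1, rng, 30_000).mean()
        ep = sample_beta_energy(653.1, 28, +1, rng, 30_000).mean()
        assert ep > em


class TestSampleEmissions:
    def test_deterministic_single_gamma_line(self):
        toy = Radionuclide(symbol="Toy-1", half_life_s=1.0,
                           modes=(("Pb-207", 1.0),),
                           gamma_lines=((100.0, 1.0),))
        ev = sample_emissions(toy, 1, np.random.default_rng(0))
        assert len(ev) == 1
        assert ev.energy_kev[0] == 100.0
        assert ev.ptype[0] == 2

    def test_ra223_alpha_intensities_within_3sigma(self):
        n = 30_000
        ev = sample_emissions("Ra-223", n, np.random.default_rng(1),
                              follow_chain=False)
        nuc = load_nuclide("Ra-223")
        alphas = ev.energy_kev[ev.ptype == 3]
        for energy, intensity in nuc.alpha_lines:
            count = int((np.abs(alphas - energy) < 0.1).sum())
            sigma = np.sqrt(n * intensity * (1 - intensity))
            assert abs(count - n * intensity) < 3 * sigma + 1

    def test_ra223_parent_max_alpha_energy(self):
        ev = sample_emissions("Ra-223", 20_000, np.random.default_rng(2),
                              follow_chain=False)
        emax = ev.energy_kev[ev.ptype == 3].max()
        assert emax == pytest.approx(5871.3, abs=1.0)  # ~5.9 MeV

    def test_chain_walk_emits_daughter_alphas(self):
        ev = sample_emissions("Ra-223", 2000, np.random.default_rng(3))
        # Po-215's 7.386 MeV line only exists two generations down
        assert (np.abs(ev.energy_kev - 7386.1) < 0.5).any()
        assert "Po-215" in ev.nuclide_names

    def test_mean_alphas_per_decay_matches_branching(self):
        """Ra-223 chain: ~3 alpha decays of intensity ~1 each plus the
        parent's; binomial 3-sigma band around the packaged expectation."""
        n = 5000
        ev = sample_emissions("Ra-223", n, np.random.default_rng(4))
        expected = 0.0
        chain = build_chain("Ra-223", 1000.0)
        for m, b in zip(chain.members, chain.cumulative_branching):
            expected += b * sum(i for _, i in m.alpha_lines)
        count = int((ev.ptype == 3).sum())
        assert abs(count - n * expected) < 4 * np.sqrt(n * expected)

    def test_bitwise_reproducible(self):
        a = sample_emissions("Bi-213", 500, np.random.default_rng(7))
        b = sample_emissions("Bi-213", 500, np.random.default_rng(7))
        np.testing.assert_array_equal(a.energy_kev, b.energy_kev)
        np.testing.assert_array_equal(a.direction, b.direction)
        np.testing.assert_array_equal(a.history, b.history)

    def test_directions_are_unit_and_isotropic(self):
        ev = sample_emissions("Y-90", 4000, np.random.default_rng(8))
        norms = np.linalg.norm(ev.direction, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)
        assert abs(ev.direction[:, 2].mean()) < 0.05

    def test_cut_suppresses_subthreshold_lines(self):
        toy = Radionuclide(symbol="Toy-2", half_life_s=1.0,
                           modes=(("Pb-207", 1.0),),
                           gamma_lines=((0.005, 1.0), (50.0, 1.0)))
        ev = sample_emissions(toy, 100, np.random.default_rng(0))
        assert len(ev) == 100  # the 5 eV line is below the 10 eV cut
        assert np.all(ev.energy_kev == 50.0)
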