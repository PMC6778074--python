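"""Transport engine: sampling primitives, stepping, energy bookkeeping."""

import numpy as np
import pytest
from scipy.stats import kstest

from nanodose.decay import EmissionBatch
from nanodose.fixtures import FixtureSpec, generate_fixture
from nanodose.geometry import generate_cluster
from nanodose.transport import (
    ParticleState,
    TransportConfig,
    TransportGeometry,
    _CollectingScorer,
    _sample_delta_energies,
    atomic_deexcitation,
    photon_interaction,
    sample_ionization,
    step_particle,
    transport_history,
)


class TestSampleIonization:
    def test_support(self, rng):
        for _ in range(200):
            eps = sample_ionization(5.0, "water", rng)
            assert 0.01 <= eps <= 2.5

    def test_below_threshold_returns_none(self, rng):
        assert sample_ionization(0.015, "water", rng) is None

    def test_boundary_energy_near_cut(self, rng):
        eps = [sample_ionization(0.025, "water", rng) for _ in range(100)]
        assert np.all(np.asarray(eps) <= 0.0125 + 1e-12)

    def test_inverse_square_spectrum(self):
        """CDF transform of the 1/eps^2 density must be uniform."""
        rng = np.random.default_rng(3)
        a, b = 0.01, 5.0
        eps = _sample_delta_energies(np.full(200_000, b), a, rng)
        u = (1.0 / a - 1.0 / eps) / (1.0 / a - 1.0 / b)
        assert kstest(u, "uniform").pvalue > 0.01


class TestAtomicDeexcitation:
    def test_fluorescence_fraction_matches_omega_k(self):
        rng = np.random.default_rng(5)
        n = 20_000
        fluor = sum(1 for _ in range(n)
                    if atomic_deexcitation("K", rng)[0][0] == "gamma")
        sigma = np.sqrt(n * 0.34 * 0.66)
        assert abs(fluor - 0.34 * n) < 3 * sigma

    def test_omega_one_gives_no_auger(self, rng):
        for _ in range(50):
            (kind, e, sub), = atomic_deexcitation("K", rng, omega_k=1.0)
            assert kind == "gamma" and sub == "fluorescence"

    def test_omega_zero_gives_kll_auger(self, rng):
        for _ in range(50):
            (kind, e, sub), = atomic_deexcitation("K", rng, omega_k=0.0)
            assert kind == "e-" and e == pytest.approx(5.67)

    def test_unknown_shell_raises(self, rng):
        with pytest.raises(ValueError):
            atomic_deexcitation("M", rng)


class TestPhotonInteraction:
    def test_products_conserve_energy(self, rng):
        for _ in range(100):
            kind, prods = photon_interaction(80.0, "water", rng)
            total = sum(e for _, e in prods)
            if kind == "photoelectric":
                assert total == pytest.approx(80.0 - 0.543)
            else:
                assert total == pytest.approx(80.0)

    def test_low_energy_is_photoelectric_dominated(self, rng):
        kinds = [photon_interaction(2.0, "water", rng)[0] for _ in range(200)]
        assert kinds.count("photoelectric") > 190

    def test_mean_free_path_matches_attenuation_table(self):
        """First-interaction distances of low-energy (photoelectric-
        dominated) photons are exponential with mean 1/mu from the table."""
        from nanodose.physics_tables import attenuation_table
        e_kev = 2.0
        mu = float(attenuation_table("water").mu_total(e_kev)[0])
        n = 3000
        spec = FixtureSpec(n_events=n, energy=("delta", e_kev), ptype="gamma",
                           seed=2)
        ev = generate_fixture(spec)
        geom = TransportGeometry.water_only(30.0 / mu)  # ~15 mfp half-box
        collector = _CollectingScorer()
        transport_history(ev, geom, TransportConfig(), scorers=(collector,),
                          rng=4)
        # photons are transported before the photoelectrons they liberate,
        # so the first interaction per history is the photon absorption
        first = {}
        for pos_b, _, hist_b in collector.interactions:
            for p, h in zip(pos_b, hist_b):
                first.setdefault(int(h), np.linalg.norm(p))
        paths = np.array(list(first.values()))
        assert len(paths) > 0.99 * n
        assert paths.mean() == pytest.approx(1.0 / mu, rel=0.05)
        assert kstest(paths * mu, "expon").pvalue > 0.01


class TestStepParticle:
    def test_kill_below_cut_deposits_locally(self, rng):
        geom = TransportGeometry.water_only(1000.0)
        st = ParticleState("e-", 0.008, np.zeros(3), np.array([0.0, 0.0, 1.0]))
        new, records = step_particle(st, geom, TransportConfig(), rng)
        assert not new.alive
        assert sum(r.energy_kev for r in records) == pytest.approx(0.008)

    def test_step_respects_boundary_distance(self, rng):
        cl = generate_cluster(n=1, box_nm=1000.0, seed=0)
        geom = TransportGeometry(cl, 1000.0)
        # electron 30 nm from the NP surface, aimed straight at it
        st = ParticleState("e-", 50.0, np.array([0.0, 0.0, -38.5]),
                           np.array([0.0, 0.0, 1.0]))
        new, _ = step_particle(st, geom, TransportConfig(), rng)
        travelled = np.linalg.norm(new.position_nm - st.position_nm)
        assert travelled <= 30.0 + 0.01  # cannot step past the surface

    def test_gamma_rejected(self, rng):
        geom = TransportGeometry.water_only(1000.0)
        st = ParticleState("gamma", 100.0, np.zeros(3),
                           np.array([0.0, 0.0, 1.0]))
        with pytest.raises(ValueError):
            step_particle(st, geom, TransportConfig(), rng)


class TestEnergyLedger:
    def test_contained_electron_fully_deposited(self):
        spec = FixtureSpec(n_events=300, energy=("delta", 1.0), ptype="e-",
                           seed=1)
        led = transport_history(generate_fixture(spec),
                                TransportGeometry.water_only(3500.0),
                                TransportConfig(), rng=5)
        assert led.totals()["deposited_water"] == pytest.approx(300.0,
                                                                rel=1e-9)
        assert np.abs(led.imbalance()).max() < 1e-6

    def test_thin_target_gamma_mostly_escapes(self):
        spec = FixtureSpec(n_events=500, energy=("delta", 10_000.0),
                           ptype="gamma", seed=2)
        led = transport_history(generate_fixture(spec),
                                TransportGeometry.water_only(3500.0),
                                TransportConfig(), rng=6)
        t = led.totals()
        assert t["escaped"] > 0.999 * t["emitted"]

    def test_positron_annihilation_bookkeeping(self):
        spec = FixtureSpec(n_events=50, energy=("delta", 5.0), ptype="e+",
                           seed=3)
        led = transport_history(generate_fixture(spec),
                                TransportGeometry.water_only(3500.0),
                                TransportConfig(), rng=7)
        t = led.totals()
        # each positron stops in the box and adds 1022 keV of photons
        assert t["emitted"] == pytest.approx(50 * (5.0 + 1022.0))
        assert np.abs(led.imbalance()).max() < 1e-6

    def test_mixed_history_conservation_with_cluster(self, small_cluster):
        parts = []
        for i, (ptype, e) in enumerate([("e-", 30.0), ("alpha", 800.0),
                                        ("gamma", 150.0), ("e+", 20.0)]):
            spec = FixtureSpec(n_events=60, energy=("delta", e), ptype=ptype,
                               spatial=("annulus", (0.0, 0.0, 0.0), 3.0, 4.0),
                               seed=10 + i)
            parts.append(generate_fixture(spec))
        ev = EmissionBatch.concatenate(parts)
        geom = TransportGeometry(small_cluster, small_cluster.box_nm)
        led = transport_history(ev, geom, TransportConfig(), rng=8,
                                n_histories=60)
        assert np.abs(led.imbalance()).max() < 1e-6

    def test_bitwise_deterministic(self, small_cluster):
        spec = FixtureSpec(n_events=100, energy=("uniform", 5.0, 50.0),
                           ptype="e-",
                           spatial=("uniform_box", 500.0), seed=4)
        ev = generate_fixture(spec)
        geom = TransportGeometry(small_cluster, small_cluster.box_nm)
        a = transport_history(ev, geom, TransportConfig(), rng=9)
        b = transport_history(ev, geom, TransportConfig(), rng=9)
        np.testing.assert_array_equal(a.deposited_water, b.deposited_water)
        np.testing.assert_array_equal(a.deposited_np, b.deposited_np)
        np.testing.assert_array_equal(a.escaped, b.escaped)


class TestMaterialSymmetry:
    def test_water_override_arms_identical(self, small_cluster):
        """Replacing NP materials with water in both arms with the same
        seed must give bitwise-identical water deposits (null experiment)."""
        spec = FixtureSpec(n_events=80, energy=("delta", 20.0), ptype="e-",
                           spatial=("uniform_box", 400.0), seed=5)
        ev = generate_fixture(spec)
        g1 = TransportGeometry(small_cluster, small_cluster.box_nm,
                               water_override=True)
        g2 = g1.as_water()
        a = transport_history(ev, g1, TransportConfig(), rng=11)
        b = transport_history(ev, g2, TransportConfig(), rng=11)
        np.testing.assert_array_equal(a.deposited_water, b.deposited_water)

    def test_np_materials_absorb_more_than_water(self, small_cluster):
        """With real NP materials some energy lodges in the cores."""
        spec = FixtureSpec(n_events=200, energy=("delta", 10.0), ptype="e-",
                           spatial=("annulus", (0.0, 0.0, 0.0), 3.0, 4.0),
                           seed=6)
        ev = generate_fixture(spec)
        geom = TransportGeometry(small_cluster, small_cluster.box_nm)
        led = transport_history(ev, geom, TransportConfig(), rng=12)
        assert led.totals()["deposited_np"] > 0
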