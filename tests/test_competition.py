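"""Monod growth and serial-transfer competition: closed-form oracles and
conservation laws."""

import math

import numpy as np
import pytest

from dropgrow.competition import (
    BatchState,
    DropletEnsemble,
    StrainKinetics,
    TransferProtocol,
    closed_form_droplet_update,
    monod_rate,
    serial_batch_transfers,
    serial_droplet_transfers,
    simulate_batch,
    simulate_droplet_transfer,
)
from dropgrow.synthetic import generate_kinetics

RATE, YIELD = generate_kinetics("rate-vs-yield")
YIELD_RATIO = YIELD.yield_Y / RATE.yield_Y


def tiny_founder_ensemble(freq_yield, n=1000, sampling="expected", seed=0):
    """Exact-single ensemble in the negligible-founder-biomass limit."""
    return DropletEnsemble(
        n_droplets=n,
        core_substrate=50.0,
        founder_frequencies=[1 - freq_yield, freq_yield],
        founder_biomass=1e-9 * RATE.yield_Y * 50.0,
        sampling=sampling,
        rng_seed=seed,
    )


class TestMonodRate:
    def test_zero_substrate(self):
        assert monod_rate(RATE, 0.0) == 0.0

    def test_half_saturation(self):
        assert monod_rate(RATE, RATE.K_s) == pytest.approx(RATE.mu_max / 2)

    def test_saturation_limit(self):
        assert monod_rate(RATE, 1e6 * RATE.K_s) == pytest.approx(RATE.mu_max, rel=1e-5)

    def test_negative_substrate_rejected(self):
        with pytest.raises(ValueError):
            monod_rate(RATE, -1.0)


class TestSimulateBatch:
    def test_no_substrate_no_growth(self):
        st = BatchState(substrate_S=0.0, populations_N=[0.05])
        traj = simulate_batch([RATE], st, 10.0)
        assert traj.populations[0] == pytest.approx(0.05, rel=1e-9)
        assert traj.substrate == pytest.approx(0.0, abs=1e-12)

    def test_exponential_growth_in_saturated_limit(self):
        """With S >> K_s throughout, N(t) = N0 exp(mu_max t) within 1%."""
        st = BatchState(substrate_S=1e6, populations_N=[0.01])
        traj = simulate_batch([RATE], st, 5.0)
        expected = 0.01 * math.exp(RATE.mu_max * 5.0)
        assert traj.populations[0, -1] == pytest.approx(expected, rel=0.01)

    def test_exponential_competition_log_ratio(self):
        """ln(N1/N2) grows at rate mu_max1 - mu_max2 when S >> K_s."""
        a = StrainKinetics("a", 0.9, 0.5, 0.02)
        b = StrainKinetics("b", 0.6, 0.5, 0.02)
        st = BatchState(substrate_S=1e6, populations_N=[0.01, 0.01])
        traj = simulate_batch([a, b], st, 6.0)
        logratio = np.log(traj.populations[0] / traj.populations[1])
        slope = (logratio[-1] - logratio[0]) / (traj.times[-1] - traj.times[0])
        assert slope == pytest.approx(0.3, rel=1e-3)

    def test_substrate_monotone_and_nonnegative(self):
        st = BatchState(substrate_S=50.0, populations_N=[0.01, 0.02])
        traj = simulate_batch([RATE, YIELD], st, 48.0)
        assert np.all(np.diff(traj.substrate) <= 1e-9)
        assert np.all(traj.substrate >= 0)

    def test_mass_balance_random_sweep(self):
        """Substrate consumed equals biomass formed over yield, 20 random draws."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            strains = [
                StrainKinetics(f"s{i}", rng.uniform(0.2, 1.2), rng.uniform(0.1, 5.0),
                               rng.uniform(0.005, 0.05))
                for i in range(rng.integers(1, 4))
            ]
            S0 = rng.uniform(10, 100)
            feed = float(rng.choice([0.0, rng.uniform(0, 1.0)]))
            st = BatchState(substrate_S=S0, populations_N=rng.uniform(1e-4, 0.1, len(strains)))
            traj = simulate_batch(strains, st, 48.0, feed_rate=feed)
            Y = np.array([s.yield_Y for s in strains])
            tol = 10 * 1e-8 * (S0 + feed * 48.0)
            assert abs(traj.mass_balance_residual(Y)) <= tol

    def test_fed_batch_accumulates_without_cells(self):
        st = BatchState(substrate_S=0.0, populations_N=[0.0])
        traj = simulate_batch([RATE], st, 10.0, feed_rate=2.0)
        assert traj.substrate[-1] == pytest.approx(20.0, rel=1e-6)


class TestSerialBatch:
    def test_identical_strains_stay_balanced(self):
        strains = generate_kinetics("neutral")
        proto = TransferProtocol(n_transfers=5)
        traj = serial_batch_transfers(strains, proto, [0.5, 0.5])
        assert traj.frequencies == pytest.approx(0.5, abs=1e-9)

    def test_rate_specialist_takes_shared_pool(self):
        """Shared nutrients select for rate: the yield specialist declines
        monotonically and is effectively lost."""
        proto = TransferProtocol(n_transfers=15)
        traj = serial_batch_transfers([RATE, YIELD], proto, [0.2, 0.8])
        f_yield = traj.frequencies[:, 1]
        assert np.all(np.diff(f_yield) < 0)
        assert f_yield[-1] < 1e-4
        assert not traj.extinct

    def test_frequencies_sum_to_one(self):
        proto = TransferProtocol(n_transfers=6)
        traj = serial_batch_transfers([RATE, YIELD], proto, [0.2, 0.8])
        assert traj.frequencies.sum(axis=1) == pytest.approx(1.0, abs=1e-9)

    def test_bad_frequencies_rejected(self):
        with pytest.raises(ValueError):
            serial_batch_transfers([RATE, YIELD], TransferProtocol(), [0.5, 0.6])


class TestClosedFormUpdate:
    @pytest.mark.parametrize(
        "f, r, expected",
        [(0.0, 1.5, 0.0), (1.0, 1.5, 1.0), (0.8, 1.5, 0.85714), (0.5, 1.0, 0.5)],
    )
    def test_values(self, f, r, expected):
        assert closed_form_droplet_update(f, r) == pytest.approx(expected, abs=1e-5)

    def test_strictly_increasing_iteration(self):
        f = 0.1
        for _ in range(20):
            nxt = closed_form_droplet_update(f, 1.5)
            assert nxt > f
            f = nxt

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            closed_form_droplet_update(1.2, 1.5)
        with pytest.raises(ValueError):
            closed_form_droplet_update(0.5, 0.0)


class TestDropletTransfer:
    def test_single_strain_pooled_frequency_one(self):
        ens = DropletEnsemble(
            n_droplets=100, core_substrate=50.0, founder_frequencies=[1.0],
            rng_seed=3,
        )
        _, freqs = simulate_droplet_transfer([RATE], ens, 48.0)
        assert freqs[0] == pytest.approx(1.0)

    def test_matches_closed_form_in_deterministic_limit(self):
        """Full consumption + single founders + negligible founder biomass
        reduce the ODE ensemble to the analytic yield-ratio update."""
        for f in (0.2, 0.5, 0.8):
            _, freqs = simulate_droplet_transfer(
                [RATE, YIELD], tiny_founder_ensemble(f), 48.0
            )
            assert abs(freqs[1] - closed_form_droplet_update(f, YIELD_RATIO)) < 1e-6

    def test_equal_yields_leave_frequencies_unchanged(self):
        a = StrainKinetics("fast", 0.9, 0.5, 0.02)
        b = StrainKinetics("slow", 0.5, 0.5, 0.02)
        ens = DropletEnsemble(
            n_droplets=1000, core_substrate=50.0, founder_frequencies=[0.3, 0.7],
            founder_biomass=1e-9 * 0.02 * 50.0, sampling="expected",
        )
        _, freqs = simulate_droplet_transfer([a, b], ens, 48.0)
        assert freqs == pytest.approx([0.3, 0.7], abs=1e-6)

    def test_stochastic_ensemble_within_binomial_error(self):
        """A finite multinomial ensemble agrees with the analytic update to
        3 binomial standard errors."""
        n = 100_000
        f0 = 0.8
        _, freqs = simulate_droplet_transfer(
            [RATE, YIELD], tiny_founder_ensemble(f0, n=n, sampling="multinomial", seed=11),
            48.0,
        )
        expected = closed_form_droplet_update(f0, YIELD_RATIO)
        se = math.sqrt(f0 * (1 - f0) / n)  # founder-sampling noise dominates
        assert abs(freqs[1] - expected) <= 3 * se

    def test_zero_occupied_droplets_is_an_error(self):
        ens = DropletEnsemble(
            n_droplets=10, core_substrate=50.0, founder_frequencies=[0.5, 0.5],
            founder_mode="poisson", mean_occupancy=0.0,
        )
        with pytest.raises(ValueError, match="occupied"):
            simulate_droplet_transfer([RATE, YIELD], ens, 48.0)

    def test_poisson_mode_multiplets_compete_within_droplets(self):
        ens = DropletEnsemble(
            n_droplets=5000, core_substrate=50.0, founder_frequencies=[0.5, 0.5],
            founder_mode="poisson", mean_occupancy=0.5, rng_seed=5,
        )
        pooled, freqs = simulate_droplet_transfer([RATE, YIELD], ens, 48.0)
        assert freqs.sum() == pytest.approx(1.0)
        assert np.all(pooled > 0)


class TestSerialDroplet:
    def test_four_transfers_match_iterated_closed_form(self):
        """Starting at 80% yield specialist with yield ratio 1.5, four
        privatized transfers land at ~0.9529 (the iterated analytic map)."""
        ens = tiny_founder_ensemble(0.8)
        proto = TransferProtocol(n_transfers=4)
        traj = serial_droplet_transfers([RATE, YIELD], ens, proto)
        f = 0.8
        for _ in range(4):
            f = closed_form_droplet_update(f, YIELD_RATIO)
        assert f == pytest.approx(0.952941, abs=1e-6)
        assert traj.frequencies[-1, 1] == pytest.approx(f, abs=1e-5)

    def test_neutral_yield_ratio_gives_flat_trajectory(self):
        a = StrainKinetics("fast", 0.9, 0.5, 0.02)
        b = StrainKinetics("slow", 0.5, 0.5, 0.02)
        ens = DropletEnsemble(
            n_droplets=500, core_substrate=50.0, founder_frequencies=[0.4, 0.6],
            founder_biomass=1e-9 * 0.02 * 50.0, sampling="expected",
        )
        traj = serial_droplet_transfers([a, b], ens, TransferProtocol(n_transfers=3))
        assert traj.frequencies[:, 1] == pytest.approx(0.6, abs=1e-5)

    def test_privatization_enriches_yield_specialist(self):
        """The same strains that lose the shared pool rise monotonically above
        0.99 under nutrient privatization."""
        ens = DropletEnsemble(
            n_droplets=1000, core_substrate=50.0, founder_frequencies=[0.2, 0.8],
            sampling="expected",
        )
        traj = serial_droplet_transfers([RATE, YIELD], ens, TransferProtocol(n_transfers=12))
        f_yield = traj.frequencies[:, 1]
        assert np.all(np.diff(f_yield) > 0)
        assert f_yield[-1] > 0.99

    def test_fixed_seed_is_bit_identical(self):
        ens = tiny_founder_ensemble(0.7, n=2000, sampling="multinomial", seed=21)
        proto = TransferProtocol(n_transfers=3)
        t1 = serial_droplet_transfers([RATE, YIELD], ens, proto)
        t2 = serial_droplet_transfers([RATE, YIELD], ens, proto)
        assert np.array_equal(t1.frequencies, t2.frequencies)
        assert np.array_equal(t1.abundances, t2.abundances)
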