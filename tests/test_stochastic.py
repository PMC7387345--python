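import numpy as np
import pytest
from scipy import stats

from p53combo.network import CAS_COMMIT, NORMAL
from p53combo.protocols import make_protocol
from p53combo.stochastic import apoptotic_fraction, spawn_seed, ssa_run


@pytest.fixture(scope="module")
def quiet_protocol():
    return make_protocol(24, 2, 0.0)


class TestExactSsa:
    def test_birth_death_stationary_poisson(self, birth_death_network,
                                            quiet_protocol):
        """Analytic oracle: stationary law of X is Poisson(b/d) = Poisson(100).

        Checks mean and variance against Monte-Carlo error from the
        integrated autocorrelation (relaxation time 1/d)."""
        run = ssa_run(birth_death_network, quiet_protocol, horizon_h=48.0,
                      seed=42, mode="exact", sample_every_h=0.05)
        x = run.species("X")[100:]  # discard the transient
        lam = 2.0 / 0.02
        # effective sample size: samples every 180 s, tau_relax = 50 s
        n_eff = len(x)
        se_mean = np.sqrt(lam / n_eff)
        assert abs(x.mean() - lam) < 4 * se_mean
        assert abs(x.var() - lam) / lam < 0.15

    def test_same_seed_identical_runs(self, birth_death_network,
                                      quiet_protocol):
        a = ssa_run(birth_death_network, quiet_protocol, 24.0, seed=7,
                    mode="exact", sample_every_h=0.1)
        b = ssa_run(birth_death_network, quiet_protocol, 24.0, seed=7,
                    mode="exact", sample_every_h=0.1)
        assert np.array_equal(a.states, b.states)

    def test_different_seeds_differ(self, birth_death_network, quiet_protocol):
        a = ssa_run(birth_death_network, quiet_protocol, 24.0, seed=7,
                    mode="exact", sample_every_h=0.1)
        b = ssa_run(birth_death_network, quiet_protocol, 24.0, seed=8,
                    mode="exact", sample_every_h=0.1)
        assert not np.array_equal(a.states, b.states)


class TestScalingFidelity:
    def test_commitment_time_distributions_agree(self, burst_commit_network,
                                                 quiet_protocol):
        """Scaled (hybrid) and exact runs of the burst-commitment fixture
        must give the same commitment-time distribution: two-sample KS test
        not rejecting at alpha = 0.01 over >= 200 runs per arm."""
        n = 220
        horizon = 72.0

        def commit_times(mode, offset):
            times, committed = [], 0
            for i in range(n):
                run = ssa_run(burst_commit_network, quiet_protocol, horizon,
                              seed=spawn_seed(offset, i), mode=mode)
                if run.committed:
                    committed += 1
                    times.append(run.commit_time_h)
            return np.array(times), committed

        t_exact, k_exact = commit_times("exact", 1)
        t_scaled, k_scaled = commit_times("scaled", 2)
        # both arms commit at comparable rates
        p_frac = stats.fisher_exact([[k_exact, n - k_exact],
                                     [k_scaled, n - k_scaled]])[1]
        assert p_frac > 0.01
        assert min(k_exact, k_scaled) > 20
        ks = stats.ks_2samp(t_exact, t_scaled)
        assert ks.pvalue > 0.01


class TestApoptoticFraction:
    def test_zero_treatment_no_apoptosis(self, network, quiet_protocol):
        net = network.apply_phenotype(NORMAL)
        af = apoptotic_fraction(net, quiet_protocol, 30, seed0=5)
        assert af.n_apoptotic == 0
        assert af.ci95[0] == 0.0

    def test_single_cell_fraction_binary(self, network):
        net = network.apply_phenotype(NORMAL)
        prot = make_protocol(24, 3, 5.0)
        af = apoptotic_fraction(net, prot, 1, seed0=3)
        assert af.fraction in (0.0, 1.0)

    def test_fraction_monotone_in_horizon(self, network):
        net = network.apply_phenotype(NORMAL)
        prot = make_protocol(24, 6, 1.0, (6.0, 18.0), 10.0, "oral")
        af = apoptotic_fraction(net, prot, 40, seed0=9)
        fracs = [af.fraction_at(t) for t in (24, 48, 72, 96, 120, 144)]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))
        assert af.fraction == pytest.approx(af.fraction_at(af.horizon_h))

    def test_reproducible_from_seed(self, network):
        net = network.apply_phenotype(NORMAL)
        prot = make_protocol(24, 3, 1.5, (6.0, 18.0), 10.0, "oral")
        a = apoptotic_fraction(net, prot, 15, seed0=21)
        b = apoptotic_fraction(net, prot, 15, seed0=21)
        assert a.commit_times_h == b.commit_times_h

    def test_counter_based_streams_stable_under_growth(self, network):
        """Growing n_cells must not reshuffle earlier cells' outcomes."""
        net = network.apply_phenotype(NORMAL)
        prot = make_protocol(24, 3, 2.0)
        small = [ssa_run(net, prot, seed=spawn_seed(4, i)).commit_time_h
                 for i in range(5)]
        large = [ssa_run(net, prot, seed=spawn_seed(4, i)).commit_time_h
                 for i in range(8)]
        assert small == large[:5]

    def test_invalid_n_cells(self, network, quiet_protocol):
        with pytest.raises(ValueError):
            apoptotic_fraction(network, quiet_protocol, 0)

    def test_ci_is_exact_binomial(self, network):
        from scipy.stats import beta
        from p53combo.stochastic import ApoptoticFraction

        af = ApoptoticFraction(n_cells=100, n_apoptotic=97,
                               commit_times_h=(), horizon_h=144.0)
        lo, hi = af.ci95
        assert lo == pytest.approx(beta.ppf(0.025, 97, 4))
        assert hi == pytest.approx(beta.ppf(0.975, 98, 3))


class TestSpawnSeed:
    def test_31_bit_range(self):
        seeds = [spawn_seed(s, i) for s in (0, 1, 2**31) for i in range(50)]
        assert all(0 <= s < 2**31 for s in seeds)

    def test_distinct_across_cells(self):
        seeds = {spawn_seed(1, i) for i in range(1000)}
        assert len(seeds) == 1000
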