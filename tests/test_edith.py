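"""Transport model, likelihoods, inference and detection maps."""

import numpy as np
import pandas as pd
import pytest

from ednascape.edith import (DetectionMap, EDITHParams, EDNASampleTable,
                             MCMCConfig, PriorConfig, TransportSolver,
                             apply_presence_threshold, detection_probability,
                             expected_reads, fit_edith, forward_concentration,
                             log_likelihood, read_count_logpmf,
                             threshold_sweep)
from ednascape.ibch import default_config
from ednascape.network import generate_synthetic_network, travel_time, upstream_set
from .conftest import chain_network


def brute_force_concentration(net, p, tau):
    """Independent oracle: direct enumeration over upstream paths."""
    out = np.zeros(net.n_reaches)
    for j, jid in enumerate(net.ids):
        for iid in upstream_set(net, str(jid)):
            i = net.index[iid]
            t = travel_time(net, iid, str(jid))
            out[j] += p[i] * net.source_area[i] * np.exp(-t / tau)
        out[j] /= net.discharge[j]
    return out


class TestForwardConcentration:
    def test_zero_production_gives_zero(self, chain3):
        C = forward_concentration(chain3, np.zeros(3), tau=100.0)
        assert (C == 0).all()

    def test_single_reach_closed_form(self):
        net = chain_network([100.0], [1.0])  # A_S = 100 m², Q = 1
        C = forward_concentration(net, np.ones(1), tau=np.inf)
        assert C[0] == pytest.approx(100.0)

    def test_two_reach_decay_hand_value(self):
        # chain a->b, A_S = 100 each, travel 100 s, tau 100 s, Q_b = 1
        net = chain_network([100.0, 100.0], [1.0, 1.0],
                            discharge=np.array([1.0, 1.0]))
        C = forward_concentration(net, np.ones(2), tau=100.0)
        assert C[1] == pytest.approx(100 * np.exp(-1) + 100, rel=1e-12)

    def test_matches_bruteforce_oracle_small_networks(self):
        rng = np.random.default_rng(0)
        for trial in range(30):
            n = int(rng.integers(1, 11))
            net = generate_synthetic_network(n, seed=trial)
            p = rng.uniform(0.1, 2.0, n)
            tau = float(rng.uniform(50, 5000))
            C = forward_concentration(net, p, tau)
            np.testing.assert_allclose(
                C, brute_force_concentration(net, p, tau), rtol=1e-10)

    def test_mass_balance_no_decay(self):
        net = generate_synthetic_network(500, seed=9)
        p = np.random.default_rng(1).uniform(0.0, 1.0, 500)
        C = forward_concentration(net, p, tau=np.inf)
        k = net.outlet_index
        flux = net.discharge[k] * C[k]
        assert flux == pytest.approx((p * net.source_area).sum(), rel=1e-9)

    def test_monotone_in_tau(self):
        net = generate_synthetic_network(200, seed=4)
        p = np.random.default_rng(2).uniform(0, 1, 200)
        taus = np.logspace(1, 6, 10)
        prev = forward_concentration(net, p, taus[0])
        for tau in taus[1:]:
            cur = forward_concentration(net, p, tau)
            assert (cur >= prev - 1e-15).all()
            prev = cur

    def test_shape_mismatch_rejected(self, chain3):
        with pytest.raises(ValueError, match="reaches"):
            forward_concentration(chain3, np.ones(5), tau=1.0)

    def test_batched_solver_matches_single(self, net200):
        solver = TransportSolver(net200, [str(net200.ids[5]), net200.outlet_id])
        rng = np.random.default_rng(3)
        P = rng.uniform(0, 1, (4, 200))
        taus = rng.uniform(100, 1e5, 4)
        batch = solver.concentration(P, taus)
        for b in range(4):
            np.testing.assert_allclose(batch[b],
                                       solver.concentration(P[b], taus[b]))


class TestExpectedReads:
    def test_linear_link(self):
        assert expected_reads(np.array([0.0]), np.array([1000]))[0] == 0
        assert expected_reads(np.array([0.01]), np.array([1000]))[0] == pytest.approx(10)
        one = expected_reads(np.array([0.3]), np.array([500]))
        two = expected_reads(np.array([0.3]), np.array([1000]))
        assert two[0] == pytest.approx(2 * one[0])

    def test_negative_calibration_rejected(self):
        with pytest.raises(ValueError):
            expected_reads(np.array([1.0]), np.array([10]), calibration=-1)


class TestLikelihood:
    def test_geometric_closed_form(self):
        for mean, n in [(3.0, 0), (3.0, 7), (0.5, 2)]:
            q = 1 / (1 + mean)
            expect = np.log(q) + n * np.log(1 - q)
            got = read_count_logpmf(np.array([n]), np.array([mean]),
                                    "geometric")[0]
            assert got == pytest.approx(expect, rel=1e-12)

    def test_zero_mean_is_point_mass(self):
        lp = read_count_logpmf(np.array([0, 3]), np.array([0.0, 0.0]),
                               "geometric")
        assert lp[0] == 0.0 and lp[1] == -np.inf

    def test_negbin_limits_to_poisson(self):
        from scipy import stats
        grid_n = np.arange(0, 20)
        for mean in [0.5, 3.0, 12.0]:
            nb = read_count_logpmf(grid_n, np.full_like(grid_n, mean, float),
                                   "negative_binomial", dispersion=1e8)
            po = stats.poisson.logpmf(grid_n, mean)
            np.testing.assert_allclose(nb, po, atol=1e-6)

    def test_all_zero_reads_low_production_limit(self, chain3):
        data = EDNASampleTable(sites=["a", "b", "c"], taxa=["T"],
                               reads=np.zeros((3, 1), int),
                               site_depth=np.full(3, 1000))
        chain3.covariates["x"] = [0.0, 0.0, 0.0]
        ll = log_likelihood(
            EDITHParams(beta0=-30.0, beta=np.zeros(1), tau=1e4),
            data, "T", chain3)
        assert -1e-6 < ll <= 0  # probability -> 1 per site

    def test_unknown_site_rejected(self, chain3):
        data = EDNASampleTable(sites=["zz"], taxa=["T"],
                               reads=np.zeros((1, 1), int),
                               site_depth=np.array([10]))
        chain3.covariates["x"] = [0.0, 0.0, 0.0]
        with pytest.raises(KeyError, match="zz"):
            log_likelihood(EDITHParams(-6, np.zeros(1), 100.0), data, "T",
                           chain3)

    def test_grid_argmax_at_generating_parameters(self):
        """Noise-free data: coarse-grid likelihood peaks at the truth's cell."""
        net = generate_synthetic_network(60, seed=21)
        net.covariates = net.covariates[[]].assign(x=np.linspace(-1, 1, 60))
        true = EDITHParams(beta0=-6.0, beta=np.array([1.0]), tau=10_000.0)
        C = forward_concentration(net, true.production(net), true.tau)
        sites = [str(r) for r in net.ids[::3]]
        pos = net.positions(sites)
        depth = np.full(len(sites), 50_000)
        calib = 0.01
        counts = np.rint(expected_reads(C[pos], depth, calib)).astype(int)
        data = EDNASampleTable(sites=sites, taxa=["T"], reads=counts[:, None],
                               site_depth=depth)
        b0_grid = np.arange(-7.0, -4.9, 0.5)
        b_grid = np.arange(0.0, 2.1, 0.5)
        tau_grid = 10.0 ** np.arange(3.0, 5.1, 0.5)
        best, arg = -np.inf, None
        for b0 in b0_grid:
            for b in b_grid:
                for tau in tau_grid:
                    ll = log_likelihood(
                        EDITHParams(b0, np.array([b]), float(tau)),
                        data, "T", net, calibration=calib)
                    if ll > best:
                        best, arg = ll, (b0, b, tau)
        assert arg == (-6.0, 1.0, pytest.approx(10_000.0))


class TestFit:
    def _strong_signal_data(self, n_reaches=200, n_sites=40, seed=13):
        net = generate_synthetic_network(n_reaches, seed=seed)
        rng = np.random.default_rng(seed)
        true = EDITHParams(beta0=-6.0, beta=np.array([0.8]), tau=14_400.0)
        C = forward_concentration(net, true.production(net), true.tau)
        sites = sorted(rng.choice([str(r) for r in net.ids], n_sites,
                                  replace=False))
        pos = net.positions(sites)
        depth = np.full(n_sites, 50_000)
        mean = expected_reads(C[pos], depth, self.CALIB)
        counts = np.minimum((rng.geometric(1 / (1 + mean)) - 1), depth)
        data = EDNASampleTable(sites=sites, taxa=["T"],
                               reads=counts[:, None].astype(int),
                               site_depth=depth)
        return net, data, true

    CALIB = 0.01

    def test_tau_recovery_within_factor_three(self):
        net, data, true = self._strong_signal_data()
        post = fit_edith(data, "T", net, calibration=self.CALIB,
                         mcmc=MCMCConfig(n_chains=3, n_iter=3000), seed=5)
        tau_med = np.exp(np.median(
            post.samples[:, post.param_names.index("log_tau")]))
        assert true.tau / 3 < tau_med < true.tau * 3

    def test_seed_determinism(self):
        net, data, _ = self._strong_signal_data(n_reaches=60, n_sites=15)
        mc = MCMCConfig(n_chains=2, n_iter=400)
        a = fit_edith(data, "T", net, mcmc=mc, seed=9)
        b = fit_edith(data, "T", net, mcmc=mc, seed=9)
        np.testing.assert_array_equal(a.samples, b.samples)
        assert a.acceptance_rate == b.acceptance_rate

    def test_prior_only_run_reproduces_prior_quantiles(self):
        net, data, _ = self._strong_signal_data(n_reaches=30, n_sites=8)
        priors = PriorConfig(beta0_mean=-6, beta0_sd=2)
        post = fit_edith(
            data, "T", net, priors=priors, seed=3,
            mcmc=MCMCConfig(n_chains=4, n_iter=6000, likelihood_weight=0.0,
                            map_init=False, init_jitter=1.0))
        b0 = post.samples[:, 0]
        # prior is Normal(-6, 2): check median and quartiles within MC error
        assert np.median(b0) == pytest.approx(-6.0, abs=0.25)
        assert np.quantile(b0, 0.75) == pytest.approx(-6 + 2 * 0.6745, abs=0.35)
        u = post.samples[:, post.param_names.index("log_tau")]
        lo, hi = np.log(priors.tau_bounds)
        assert np.median(u) == pytest.approx((lo + hi) / 2, abs=0.35)

    def test_all_zero_reads_flagged_not_fatal(self):
        net, data, _ = self._strong_signal_data(n_reaches=30, n_sites=8)
        zero = EDNASampleTable(sites=data.sites, taxa=["T"],
                               reads=np.zeros_like(data.reads),
                               site_depth=data.site_depth)
        post = fit_edith(zero, "T", net,
                         mcmc=MCMCConfig(n_chains=2, n_iter=600), seed=2)
        assert "all_zero_reads" in post.warnings
        # posterior production concentrated low
        p = post.production_draws(net).mean()
        assert p < 1e-6


class TestDetectionMaps:
    def _toy_posterior(self, net, draws):
        from ednascape.edith import EDITHPosterior
        return EDITHPosterior(taxon="T", samples=np.asarray(draws),
                              param_names=["beta0", "beta_0", "log_tau"],
                              acceptance_rate=0.3, seed=0, rhat=1.0)

    def test_counting_oracle(self, chain3):
        chain3.covariates["x"] = [0.0, 0.0, 0.0]
        # 10 draws; 7 with beta0 above log10(p_star)
        draws = [[-5.0, 0.0, 5.0]] * 7 + [[-9.0, 0.0, 5.0]] * 3
        post = self._toy_posterior(chain3, draws)
        dmap = detection_probability(post, chain3, p_star=1e-6)
        assert (dmap.detection_prob == 0.7).all()

    def test_extremes(self, chain3):
        chain3.covariates["x"] = [0.0, 0.0, 0.0]
        post = self._toy_posterior(chain3, [[-20.0, 0.0, 5.0]] * 5)
        assert (detection_probability(post, chain3, 1e-6).detection_prob == 0).all()
        post = self._toy_posterior(chain3, [[-2.0, 0.0, 5.0]] * 5)
        assert (detection_probability(post, chain3, 1e-6).detection_prob == 1).all()

    def test_boundary_inclusive_at_half(self):
        s = pd.Series([0.5, 0.49, 0.51], index=["a", "b", "c"])
        m = apply_presence_threshold(DetectionMap("T", s), 0.5)
        assert m.presence.tolist() == [True, False, True]

    def test_threshold_monotone_subset(self):
        rng = np.random.default_rng(0)
        s = pd.Series(rng.uniform(0, 1, 50))
        lo = apply_presence_threshold(DetectionMap("T", s), 0.3).presence
        hi = apply_presence_threshold(DetectionMap("T", s), 0.7).presence
        assert (hi <= lo).all()  # presence set at 0.7 ⊆ presence set at 0.3


class TestThresholdSweep:
    def _maps(self, net, seed=0):
        rng = np.random.default_rng(seed)
        taxa = ["Perlidae", "Baetidae", "Gammaridae"]
        idx = pd.Index([str(r) for r in net.ids], name="reach_id")
        return {t: DetectionMap(t, pd.Series(rng.uniform(0, 1, net.n_reaches),
                                             index=idx)) for t in taxa}

    def test_single_value_matches_default_pipeline(self, net200):
        from ednascape.ibch import ibch_map
        maps = self._maps(net200)
        cfg = default_config()
        per_reach, _ = threshold_sweep(maps, [0.5], net200, cfg)
        direct = ibch_map({t: apply_presence_threshold(m, 0.5)
                           for t, m in maps.items()}, net200, cfg)
        pd.testing.assert_frame_equal(
            per_reach.drop(columns="threshold"), direct)

    def test_richness_non_increasing_in_threshold(self, net200):
        per_reach, _ = threshold_sweep(
            self._maps(net200), [0.3, 0.5, 0.7], net200, default_config())
        piv = per_reach.pivot(index="reach_id", columns="threshold",
                              values="richness")
        assert (piv[0.5] <= piv[0.3]).all() and (piv[0.7] <= piv[0.5]).all()

    def test_matches_independent_runs(self, net200):
        from ednascape.ibch import ibch_map
        maps = self._maps(net200, seed=5)
        cfg = default_config()
        per_reach, summary = threshold_sweep(maps, [0.3, 0.5, 0.7], net200, cfg)
        assert len(summary) == 3
        for thr in [0.3, 0.5, 0.7]:
            direct = ibch_map({t: apply_presence_threshold(m, thr)
                               for t, m in maps.items()}, net200, cfg)
            sub = per_reach[per_reach.threshold == thr].drop(
                columns="threshold").reset_index(drop=True)
            pd.testing.assert_frame_equal(sub, direct)

    def test_empty_grid_rejected(self, net200):
        with pytest.raises(ValueError, match="empty"):
            threshold_sweep(self._maps(net200), [], net200, default_config())
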