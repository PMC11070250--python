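"""Scenario generators: determinism, statistical structure, degenerate inputs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ednascape.network import generate_synthetic_network
from ednascape.synthetic import (OccupancyConfig, ScenarioConfig,
                                 attach_quality_field, make_scenario,
                                 simulate_edna_reads, simulate_habitat,
                                 simulate_kicknet, simulate_taxa)


def small_truth(n_reaches=120, n_taxa=8, seed=0, **occ):
    net = generate_synthetic_network(n_reaches, seed=seed)
    attach_quality_field(net, 0.7, seed + 1)
    presence, params, warns = simulate_taxa(
        net, n_taxa, OccupancyConfig(**occ), seed + 2)
    from ednascape.synthetic import ScenarioTruth
    return ScenarioTruth(network=net, true_presence=presence,
                         true_params=params,
                         latent_quality=net.covariates["quality"],
                         warnings=warns)


class TestSimulateTaxa:
    def test_saturating_intercept_all_present(self):
        t = small_truth(intercept_mean=40.0, intercept_sd=0.0)
        assert t.true_presence.all().all()

    def test_sinking_intercept_empty_with_warning(self):
        with pytest.warns(RuntimeWarning, match="empty truth"):
            t = small_truth(intercept_mean=-40.0, intercept_sd=0.0,
                            quality_slope=0.0, logA_min_slope=0.0,
                            logA_slope_sd=1e-9)
        assert not t.true_presence.any().any()
        assert any("empty_truth" in w for w in t.warnings)

    def test_occupancy_matches_logistic_expectation(self):
        net = generate_synthetic_network(500, seed=10)
        attach_quality_field(net, 0.7, 11)
        presence, params, _ = simulate_taxa(net, 20, OccupancyConfig(),
                                            seed=12)
        q = net.covariates["quality"].to_numpy()
        lA = net.covariates["logA"].to_numpy()
        for t in params:
            prob = 1 / (1 + np.exp(-(t.intercept + t.quality_slope * q
                                     + t.logA_slope * lA)))
            expect = prob.mean()
            se = np.sqrt((prob * (1 - prob)).sum()) / len(prob)
            got = presence[t.name].mean()
            assert abs(got - expect) <= 3 * se + 1e-12

    def test_production_positive_exactly_where_present(self):
        t = small_truth()
        for p in t.true_params:
            prod = t.production(p.name)
            present = t.true_presence[p.name].to_numpy()
            assert (prod[present] > 0).all()
            assert (prod[~present] == 0).all()


class TestSimulateReads:
    def test_all_absent_truth_gives_zero_reads(self):
        with pytest.warns(RuntimeWarning):
            t = small_truth(intercept_mean=-40.0, intercept_sd=0.0,
                            quality_slope=0.0, logA_min_slope=0.0,
                            logA_slope_sd=1e-9)
        sites = [str(r) for r in t.network.ids[:10]]
        table = simulate_edna_reads(t, sites, depth=1000, seed=0)
        assert (table.reads == 0).all()

    def test_noise_free_mode_returns_rounded_means(self):
        t = small_truth()
        sites = [str(r) for r in t.network.ids[:10]]
        a = simulate_edna_reads(t, sites, depth=1000, seed=0,
                                noise_model="none")
        b = simulate_edna_reads(t, sites, depth=1000, seed=999,
                                noise_model="none")
        np.testing.assert_array_equal(a.reads, b.reads)  # deterministic

    def test_empirical_mean_matches_expectation(self):
        """Site means over replicates within 3 SE of the forward model."""
        from ednascape.edith import TransportSolver, expected_reads
        t = small_truth(n_reaches=60, n_taxa=3)
        sites = [str(r) for r in t.network.ids[:6]]
        solver = TransportSolver(t.network, sites)
        taxon = t.true_params[0].name
        mean = expected_reads(
            solver.concentration(t.production(taxon), t.true_params[0].tau),
            np.full(len(sites), 1000))
        reps = np.stack([
            simulate_edna_reads(t, sites, depth=1000, seed=s).reads[:, 0]
            for s in range(400)])
        emp = reps.mean(axis=0)
        # geometric variance = m(1+m)
        se = np.sqrt(mean * (1 + mean) / 400)
        assert (np.abs(emp - mean) <= 3 * se + 1.0).all()

    def test_bad_depth_rejected(self):
        t = small_truth()
        with pytest.raises(ValueError):
            simulate_edna_reads(t, [str(t.network.ids[0])], depth=0, seed=0)


class TestSimulateKicknet:
    def test_perfect_detection_equals_truth(self):
        t = small_truth()
        sites = [str(r) for r in t.network.ids[:15]]
        obs = simulate_kicknet(t, sites, detect_prob=1.0, seed=0)
        pd.testing.assert_frame_equal(obs, t.true_presence.loc[sites])

    def test_zero_detection_all_absent(self):
        t = small_truth()
        sites = [str(r) for r in t.network.ids[:15]]
        obs = simulate_kicknet(t, sites, detect_prob=0.0, seed=0)
        assert not obs.any().any()

    def test_detection_ratio_binomial(self):
        t = small_truth(n_reaches=300, n_taxa=10)
        sites = [str(r) for r in t.network.ids]
        n_true = t.true_presence.to_numpy().sum()
        hits = sum(simulate_kicknet(t, sites, 0.7, seed=s).to_numpy().sum()
                   for s in range(30))
        p_hat = hits / (30 * n_true)
        se = np.sqrt(0.7 * 0.3 / (30 * n_true))
        assert abs(p_hat - 0.7) <= 3 * se

    def test_no_false_positives_by_default(self):
        t = small_truth()
        sites = [str(r) for r in t.network.ids[:20]]
        obs = simulate_kicknet(t, sites, 0.8, seed=1)
        assert not (obs & ~t.true_presence.loc[sites]).any().any()


class TestSimulateHabitat:
    def test_noise_free_is_monotone_in_quality(self):
        t = small_truth()
        hab = simulate_habitat(t, n_classes=5, noise_sd=0.0, seed=0)
        df = pd.DataFrame({"q": t.latent_quality, "h": hab})
        med = df.groupby("h")["q"].median()
        assert (med.diff().dropna() > 0).all()

    def test_huge_noise_decouples_from_quality(self):
        t = small_truth(n_reaches=4000, n_taxa=1)
        hab = simulate_habitat(t, n_classes=5, noise_sd=1e6, seed=0)
        from ednascape.validate import habitat_association
        # stand-in index tied to quality
        scores = pd.Series(t.latent_quality.to_numpy() * 3 + 10,
                           index=hab.index)
        out = habitat_association(scores.clip(0, 20).round(), hab,
                                  max_score=20)
        assert out.r2 < 0.05

    def test_quantile_bins_balanced(self):
        t = small_truth(n_reaches=250)
        hab = simulate_habitat(t, n_classes=5, noise_sd=0.5, seed=0)
        counts = hab.value_counts()
        assert counts.max() - counts.min() <= 1


class TestMakeScenario:
    def test_seed_determinism_bit_identical_bundle(self, tmp_path):
        import hashlib
        h = []
        for d in ["one", "two"]:
            out = tmp_path / d
            make_scenario(ScenarioConfig(n_reaches=80, n_taxa=6,
                                         n_edna_sites=15, n_kicknet_sites=8),
                          seed=1, outdir=out)
            digest = {f.name: hashlib.sha256(f.read_bytes()).hexdigest()
                      for f in sorted(out.iterdir())}
            h.append(digest)
        assert h[0] == h[1]

    def test_bundle_round_trips_through_readers(self, tmp_path):
        from ednascape import io
        cfg = ScenarioConfig(n_reaches=60, n_taxa=5, n_edna_sites=12,
                             n_kicknet_sites=6)
        scen = make_scenario(cfg, seed=3, outdir=tmp_path)
        net, reads, kick, hab = io.read_scenario_inputs(tmp_path)
        assert net.n_reaches == 60
        np.testing.assert_array_equal(reads.reads, scen.edna.reads)
        pd.testing.assert_frame_equal(kick, scen.kicknet)
        pd.testing.assert_series_equal(hab, scen.habitat.astype(int),
                                       check_names=False)
        np.testing.assert_allclose(net.discharge,
                                   scen.truth.network.discharge)

    def test_quality_structures_index_vs_habitat(self, default_scenario):
        """High-GI taxa concentrate in good reaches: true IBCH correlates
        positively with habitat class (the study's qualitative structure)."""
        from ednascape.ibch import default_config, score_sites
        scen = default_scenario
        truth_scores = score_sites(scen.truth.true_presence,
                                   default_config())["ibch"]
        rho = stats.spearmanr(truth_scores.to_numpy(),
                              scen.habitat.to_numpy()).statistic
        assert rho > 0.3
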