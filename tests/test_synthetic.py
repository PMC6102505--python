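"""Simulator correctness: determinism, injected-DNM statistics, read model."""

import numpy as np
import pytest
from scipy.stats import binom, chisquare

from dnmkit.synthetic import (
    FeatureTrack,
    SimulationConfig,
    default_feature_tracks,
    find_reversible_indel_sites,
    inject_reversible_indel,
    remove_reversible_indel,
    simulate_trio_dataset,
)


class TestDeterminism:
    def test_identical_seed_identical_files(self, tmp_path):
        config = SimulationConfig(n_trios=2, n_sites=2000, mu=1e-3, seed=1)
        a = tmp_path / "a"
        b = tmp_path / "b"
        simulate_trio_dataset(config, a)
        simulate_trio_dataset(config, b)
        files_a = sorted(p.name for p in a.iterdir())
        assert files_a == sorted(p.name for p in b.iterdir())
        for name in files_a:
            assert (a / name).read_bytes() == (b / name).read_bytes(), name

    def test_different_seed_different_data(self):
        c1 = SimulationConfig(n_trios=1, n_sites=1000, mu=1e-3, seed=1)
        c2 = SimulationConfig(n_trios=1, n_sites=1000, mu=1e-3, seed=2)
        d1 = simulate_trio_dataset(c1)
        d2 = simulate_trio_dataset(c2)
        assert not d1.evidence["trio01"].equals(d2.evidence["trio01"])


class TestGroundTruth:
    def test_mu_zero_injects_nothing(self):
        ds = simulate_trio_dataset(
            SimulationConfig(n_trios=3, n_sites=2000, mu=0.0, seed=4)
        )
        assert len(ds.ground_truth) == 0

    def test_total_count_matches_binomial_expectation(self):
        """Injected DNMs per cohort ~ Binomial(2 * n_sites * n_trios, mu)."""
        n_trios, n_sites, mu = 20, 100_000, 1e-4
        ds = simulate_trio_dataset(
            SimulationConfig(
                n_trios=n_trios, n_sites=n_sites, mu=mu,
                perfect_calls=True, seed=9,
            )
        )
        n = 2 * n_sites * n_trios
        expected = n * mu
        sd = np.sqrt(n * mu * (1 - mu))
        assert abs(len(ds.ground_truth) - expected) < 4 * sd

    def test_injections_lie_on_simulated_sites(self, small_dataset):
        ds = small_dataset
        site_keys = set(zip(ds.sites["chrom"], ds.sites["pos"]))
        for _, row in ds.ground_truth.iterrows():
            assert (row["chrom"], row["pos"]) in site_keys

    def test_uniform_over_sites_without_multipliers(self):
        """With neutral feature multipliers the injected DNMs are uniform
        over sites: chi-square GOF over 20 site bins, median p over 10
        seeds, not rejected at alpha = 0.01."""
        pvals = []
        for seed in range(10):
            ds = simulate_trio_dataset(
                SimulationConfig(
                    n_trios=4, n_sites=20_000, mu=2e-3,
                    perfect_calls=True, seed=100 + seed,
                )
            )
            pos_index = {
                (c, p): i
                for i, (c, p) in enumerate(zip(ds.sites["chrom"], ds.sites["pos"]))
            }
            idx = np.array(
                [pos_index[(r["chrom"], r["pos"])] for _, r in ds.ground_truth.iterrows()]
            )
            counts, _ = np.histogram(idx, bins=20, range=(0, len(ds.sites)))
            pvals.append(chisquare(counts).pvalue)
        assert np.median(pvals) > 0.01


class TestReadModel:
    def test_mean_depth_law_of_large_numbers(self):
        ds = simulate_trio_dataset(
            SimulationConfig(n_trios=1, n_sites=100_000, mu=0.0, seed=2)
        )
        observed = ds.evidence["trio01"].depth.mean()
        assert observed == pytest.approx(38.5, rel=0.01)

    def test_het_allele_balance_matches_binomial_tail(self):
        """Among truly het child sites with depth > 20, the fraction with
        allele balance in [0.3, 0.7] matches the Binomial(d, 1/2)
        computation within Monte-Carlo error."""
        ds = simulate_trio_dataset(
            SimulationConfig(n_trios=1, n_sites=100_000, mu=0.0, seed=8)
        )
        arr = ds.evidence["trio01"]
        het = (arr.true_gt[:, 0] == 1) & (arr.depth[:, 0] > 20)
        d = arr.depth[het, 0]
        ab = arr.alt_reads[het, 0] / d
        observed = np.mean((ab >= 0.3) & (ab <= 0.7))
        # exact expectation weighted by the observed depth distribution
        uniq, counts = np.unique(d, return_counts=True)
        per_depth = [
            binom.cdf(np.floor(0.7 * di), di, 0.5)
            - binom.cdf(np.ceil(0.3 * di) - 1, di, 0.5)
            for di in uniq
        ]
        expected = float(np.average(per_depth, weights=counts))
        mc_sd = np.sqrt(expected * (1 - expected) / len(d))
        assert abs(observed - expected) < 5 * mc_sd

    def test_perfect_calls_reproduce_truth(self, perfect_dataset):
        for trio in perfect_dataset.trios:
            arr = perfect_dataset.evidence[trio.trio_id]
            assert np.array_equal(arr.called_gt, arr.true_gt)
            assert (arr.gq == 99).all()


class TestSpectrumWeight:
    def test_ts_tv_weight_controls_site_alleles(self):
        from dnmkit.detection import classify_substitution

        ds = simulate_trio_dataset(
            SimulationConfig(n_trios=1, n_sites=50_000, mu=0.0,
                             ts_tv_weight=1.5, seed=6)
        )
        snv = ds.sites[ds.sites["is_snv"]]
        kinds = [classify_substitution(r, a) for r, a in zip(snv["ref"], snv["alt"])]
        ts = kinds.count("transition")
        tv = kinds.count("transversion")
        assert ts / tv == pytest.approx(1.5, abs=0.1)


class TestFeatureTracks:
    def test_coverage_fraction_approximated(self):
        tracks = default_feature_tracks()
        tracks["dhs"] = FeatureTrack(0.3)
        ds = simulate_trio_dataset(
            SimulationConfig(n_trios=1, n_sites=50_000, mu=0.0, seed=5,
                             feature_tracks=tracks)
        )
        frac = ds.sites["dhs"].mean()
        assert frac == pytest.approx(0.3, abs=0.05)

    def test_conserved_flag_consistent_with_score(self, small_dataset):
        sites = small_dataset.sites
        assert (
            (sites["gerp"] > 12).astype(int) == sites["conserved"]
        ).all()

    def test_multiplier_enriches_injections(self):
        tracks = default_feature_tracks()
        tracks["cpg"] = FeatureTrack(0.2, 5.0)
        ds = simulate_trio_dataset(
            SimulationConfig(n_trios=10, n_sites=20_000, mu=1e-3,
                             perfect_calls=True, seed=12, feature_tracks=tracks)
        )
        flag = {
            (c, p): f for c, p, f in zip(ds.sites["chrom"], ds.sites["pos"], ds.sites["cpg"])
        }
        truth = ds.ground_truth
        in_cpg = sum(flag[(r["chrom"], r["pos"])] for _, r in truth.iterrows())
        frac_sites = ds.sites["cpg"].mean()
        # odds of landing in-feature are multiplier-fold the site odds
        odds_obs = (in_cpg / len(truth)) / (1 - in_cpg / len(truth))
        odds_null = frac_sites / (1 - frac_sites)
        assert odds_obs / odds_null == pytest.approx(5.0, rel=0.35)


class TestReversibleIndel:
    def test_inject_then_detect(self, perfect_dataset):
        from dnmkit.detection import detect_and_filter_arrays

        ds = perfect_dataset
        for trio in ds.trios:
            sites = find_reversible_indel_sites(ds, trio.trio_id)
            if len(sites):
                break
        else:
            pytest.skip("no eligible site in fixture")
        token = inject_reversible_indel(ds, trio.trio_id, int(sites[0]))
        try:
            arr = ds.evidence[trio.trio_id]
            cands = detect_and_filter_arrays(
                arr.called_gt, arr.depth, arr.ref_reads, arr.alt_reads, arr.gq,
                ds.sites, trio.trio_id,
            )
            hit = [c for c in cands if c.config == "reversible_indel"]
            assert len(hit) == 1 and hit[0].passed
            assert (ds.ground_truth["config"] == "reversible_indel").sum() == 1
        finally:
            remove_reversible_indel(ds, token)

    def test_inject_requires_homalt_parents(self, perfect_dataset):
        ds = perfect_dataset
        trio = ds.trios[0]
        arr = ds.evidence[trio.trio_id]
        not_ok = np.flatnonzero(
            ~ds.sites["is_snv"].to_numpy() & (arr.true_gt[:, 1] != 2)
        )
        with pytest.raises(ValueError, match="homozygous-alternative"):
            inject_reversible_indel(ds, trio.trio_id, int(not_ok[0]))

    def test_inject_on_snv_site_rejected(self, perfect_dataset):
        ds = perfect_dataset
        snv_idx = int(np.flatnonzero(ds.sites["is_snv"].to_numpy())[0])
        with pytest.raises(ValueError, match="indel site"):
            inject_reversible_indel(ds, ds.trios[0].trio_id, snv_idx)

    def test_inject_remove_is_identity(self, perfect_dataset):
        ds = perfect_dataset
        trio_id = None
        for trio in ds.trios:
            sites = find_reversible_indel_sites(ds, trio.trio_id)
            if len(sites):
                trio_id = trio.trio_id
                break
        if trio_id is None:
            pytest.skip("no eligible site in fixture")
        before = ds.evidence[trio_id].copy()
        truth_len = len(ds.ground_truth)
        token = inject_reversible_indel(ds, trio_id, int(sites[0]))
        assert not ds.evidence[trio_id].equals(before)
        remove_reversible_indel(ds, token)
        assert ds.evidence[trio_id].equals(before)
        assert len(ds.ground_truth) == truth_len


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mu": -0.1},
            {"mu": 1.5},
            {"mean_depth": 0},
            {"error_rate": 0.6},
            {"indel_fraction": 1.2},
            {"n_trios": 0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs).validate()

    def test_invalid_feature_track_rejected(self):
        with pytest.raises(ValueError):
            FeatureTrack(coverage=1.5)
        with pytest.raises(ValueError):
            FeatureTrack(coverage=0.5, multiplier=0)
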