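"""Seeded simulation experiments that characterise the estimator.

These are the package's built-in reproducibility experiments: parameter
recovery of the mutation rate (bias and Wilson-CI coverage over many
simulated cohorts) and recovery of a known context-feature enrichment as
a stratified-rate ratio. Both run on error-free evidence so they measure
the estimator itself rather than genotyping noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detection import FilterThresholds, detect_and_filter_arrays
from .rate import callable_sums_from_arrays, estimate_rate
from .synthetic import FeatureTrack, SimulationConfig, default_feature_tracks, simulate_trio_dataset


def _simulated_estimate(config: SimulationConfig, thresholds: FilterThresholds):
    """Simulate one cohort and run detection + rate estimation on it."""
    ds = simulate_trio_dataset(config)
    counts = []
    sums = []
    is_snv = ds.sites["is_snv"].to_numpy()
    for trio in ds.trios:
        arr = ds.evidence[trio.trio_id]
        cands = detect_and_filter_arrays(
            arr.called_gt, arr.depth, arr.ref_reads, arr.alt_reads, arr.gq,
            ds.sites, trio.trio_id, thresholds,
        )
        counts.append(
            sum(
                1
                for c in cands
                if c.passed and c.config != "reversible_indel" and c.variant_class == "SNV"
            )
        )
        s_snv, _ = callable_sums_from_arrays(
            arr.ref_reads, arr.alt_reads, arr.depth, is_snv,
            config.error_rate if config.error_rate > 0 else 0.01,
            thresholds,
        )
        sums.append(s_snv)
    return estimate_rate(counts, sums), ds


@dataclass(frozen=True)
class RecoveryResult:
    mu: float
    mean_rate: float
    relative_bias: float
    ci_coverage: float
    n_replicates: int


def rate_recovery(
    n_replicates: int = 100,
    n_trios: int = 20,
    n_sites: int = 100_000,
    mu: float = 1e-4,
    seed: int = 0,
) -> RecoveryResult:
    """Repeatedly simulate cohorts with known ``mu`` under error-free
    evidence, estimate the rate each time, and summarise the relative
    bias of the mean estimate and the empirical Wilson-CI coverage."""
    thresholds = FilterThresholds()
    rng = np.random.default_rng(seed)
    rates = []
    covered = 0
    for _ in range(n_replicates):
        config = SimulationConfig(
            n_trios=n_trios,
            n_sites=n_sites,
            mu=mu,
            indel_fraction=0.0,
            perfect_calls=True,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        est, _ = _simulated_estimate(config, thresholds)
        rates.append(est.rate)
        if est.ci_low <= mu <= est.ci_high:
            covered += 1
    mean_rate = float(np.mean(rates))
    return RecoveryResult(
        mu=mu,
        mean_rate=mean_rate,
        relative_bias=(mean_rate - mu) / mu,
        ci_coverage=covered / n_replicates,
        n_replicates=n_replicates,
    )


def enrichment_recovery(
    multiplier: float = 3.0,
    coverage: float = 0.2,
    n_seeds: int = 50,
    n_trios: int = 10,
    n_sites: int = 20_000,
    mu: float = 1e-3,
    seed: int = 0,
) -> float:
    """Simulate cohorts where one feature (open chromatin) multiplies the
    local DNM rate, and return the median (over seeds) ratio of the
    in-feature to out-of-feature pooled stratified rate. An unbiased
    pipeline recovers the configured multiplier."""
    thresholds = FilterThresholds()
    rng = np.random.default_rng(seed)
    ratios = []
    for _ in range(n_seeds):
        tracks = default_feature_tracks()
        tracks["dhs"] = FeatureTrack(coverage, multiplier)
        config = SimulationConfig(
            n_trios=n_trios,
            n_sites=n_sites,
            mu=mu,
            indel_fraction=0.0,
            perfect_calls=True,
            seed=int(rng.integers(0, 2**31 - 1)),
            feature_tracks=tracks,
        )
        ds = simulate_trio_dataset(config)
        in_dhs = ds.sites["dhs"].to_numpy() == 1
        is_snv = ds.sites["is_snv"].to_numpy()
        site_flag = {
            (c, p): f
            for c, p, f in zip(ds.sites["chrom"], ds.sites["pos"], ds.sites["dhs"])
        }
        n_in = n_out = 0
        p_in = p_out = 0.0
        for trio in ds.trios:
            arr = ds.evidence[trio.trio_id]
            cands = detect_and_filter_arrays(
                arr.called_gt, arr.depth, arr.ref_reads, arr.alt_reads, arr.gq,
                ds.sites, trio.trio_id, thresholds,
            )
            for c in cands:
                if not c.passed or c.variant_class != "SNV":
                    continue
                if site_flag[(c.chrom, c.pos)] == 1:
                    n_in += 1
                else:
                    n_out += 1
            s_in, _ = callable_sums_from_arrays(
                arr.ref_reads[in_dhs], arr.alt_reads[in_dhs], arr.depth[in_dhs],
                is_snv[in_dhs], 0.01, thresholds,
            )
            s_out, _ = callable_sums_from_arrays(
                arr.ref_reads[~in_dhs], arr.alt_reads[~in_dhs], arr.depth[~in_dhs],
                is_snv[~in_dhs], 0.01, thresholds,
            )
            p_in += s_in
            p_out += s_out
        if p_in > 0 and p_out > 0 and n_out > 0:
            ratios.append((n_in / (2 * p_in)) / (n_out / (2 * p_out)))
    return float(np.median(ratios))
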