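"""Callable-site probability model and the per-position-per-generation
(PPPG) de novo mutation rate estimator.

The rate estimator is

    rate_PPPG = sum_i n_i / (2 * sum_i sum_j P_ji)

where ``n_i`` is the number of de novo mutations (DNMs) identified in trio
``i``, ``N`` the number of callable sites of that trio, and ``P_ji`` the
probability that a DNM arising at site ``j`` in trio ``i`` would have been
observed given the trio's read evidence. The factor 2 converts positions
to transmitted haplotype-positions, so the estimate is per position pair
per generation.

For a single-nucleotide site,

    P_ji = P(M=HomR) * P(F=HomR) * d_het(child)
         + P(M=HomA) * P(F=HomA) * d_het(child)

— the two parental configurations under which a new heterozygous child
allele is a detectable Mendelian violation — and for an indel site

    P_ji = P(M=HomA) * P(F=HomA) * d_homref(child)

(the "reversible" configuration). Parental genotype probabilities are
posteriors under a binomial read model with per-read error ``eps`` and a
uniform genotype prior; ``d_het``/``d_homref`` are the probabilities that
the child's reads at its observed depth would yield the required genotype
call *and* survive the depth/GQ/allele-balance filters. Sites failing the
depth filter in any member contribute P_ji = 0, so low-coverage sites add
nothing to the callable denominator.

Confidence intervals are Wilson score intervals for a binomial proportion
with x = total DNMs and N = the rounded haplotype-position denominator;
Wilson behaves well for the very rare events involved here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import binom, norm

from .detection import FilterThresholds
from .variant_io import Genotype, SampleEvidence, TrioSiteRecord

DEFAULT_ERROR_RATE = 0.01

_HOMR, _HET, _HOMA = 0, 1, 2


@dataclass(frozen=True)
class CallableProbability:
    """Per-site, per-trio probability that a DNM there would be observed."""

    trio_id: str
    chrom: str
    pos: int
    p_snv: float
    p_indel: float

    def __post_init__(self) -> None:
        for p in (self.p_snv, self.p_indel):
            if not (0.0 <= p <= 1.0) or not math.isfinite(p):
                raise ValueError(f"probability {p} outside [0, 1]")


@dataclass(frozen=True)
class RateEstimate:
    """A PPPG rate with its Wilson 95% CI and the quantities behind it."""

    n_mutations: int
    denominator: float  # 2 * sum_i sum_j P_ji, haplotype-position units
    rate: float
    ci_low: float
    ci_high: float
    n_trios: int


# ---------------------------------------------------------------------------
# Genotype posteriors


def genotype_posteriors(
    evidence: SampleEvidence | tuple[int, int],
    error_rate: float = DEFAULT_ERROR_RATE,
) -> np.ndarray:
    """Posterior probabilities over (HomR, Het, HomA) for one sample.

    Uses binomial read likelihoods L(HomR) = (1-eps)^r * eps^a,
    L(Het) = 0.5^(r+a), L(HomA) = eps^r * (1-eps)^a (the binomial
    coefficient cancels) and a uniform genotype prior.
    """
    if isinstance(evidence, SampleEvidence):
        r, a = evidence.ref_reads, evidence.alt_reads
    else:
        r, a = evidence
    if r + a <= 0:
        raise ValueError("genotype posterior requires informative reads")
    if not (0 < error_rate < 0.5):
        raise ValueError("error_rate must be in (0, 0.5)")
    ll = _log10_likelihoods(np.array([r]), np.array([a]), error_rate)[0]
    post = 10.0 ** (ll - ll.max())
    return post / post.sum()


def _log10_likelihoods(r: np.ndarray, a: np.ndarray, eps: float) -> np.ndarray:
    """log10 genotype likelihoods, shape (n, 3) for columns HomR/Het/HomA."""
    l_eps = math.log10(eps)
    l_1me = math.log10(1.0 - eps)
    l_half = math.log10(0.5)
    out = np.empty((len(r), 3))
    out[:, _HOMR] = r * l_1me + a * l_eps
    out[:, _HET] = (r + a) * l_half
    out[:, _HOMA] = r * l_eps + a * l_1me
    return out


def _posterior_array(r: np.ndarray, a: np.ndarray, eps: float) -> np.ndarray:
    """Vectorised genotype posteriors, shape (n, 3). Rows with r+a == 0
    get uniform 1/3 (no information)."""
    ll = _log10_likelihoods(r, a, eps)
    ll -= ll.max(axis=1, keepdims=True)
    post = 10.0**ll
    post /= post.sum(axis=1, keepdims=True)
    return post


def genotype_quality(r: int, a: int, eps: float) -> float:
    """Phred-scaled gap between the best and second-best genotype
    likelihood (uniform prior), the GQ the read model implies."""
    ll = np.sort(_log10_likelihoods(np.array([r]), np.array([a]), eps)[0])
    return 10.0 * (ll[2] - ll[1])


# ---------------------------------------------------------------------------
# Child detection probabilities


def _call_and_gq(depth: int, eps: float) -> tuple[np.ndarray, np.ndarray]:
    """For every alt-read outcome k = 0..depth: the max-likelihood genotype
    call and its GQ."""
    k = np.arange(depth + 1)
    ll = _log10_likelihoods(depth - k, k, eps)
    order = np.argsort(ll, axis=1)
    call = order[:, 2]
    gq = 10.0 * (
        ll[np.arange(depth + 1), order[:, 2]] - ll[np.arange(depth + 1), order[:, 1]]
    )
    return call, gq


def het_detection_probability(
    depth: int,
    thresholds: FilterThresholds = FilterThresholds(),
    error_rate: float = DEFAULT_ERROR_RATE,
) -> float:
    """Probability that a truly heterozygous child site at this depth is
    called Het and survives the depth/GQ/allele-balance filters.

    Alt reads are Binomial(depth, 1/2); an outcome k counts iff the
    max-likelihood call is Het, its GQ >= min_gq, and k/depth lies in
    [ab_low, ab_high]. Zero when depth fails the strict depth filter.
    """
    if depth < 0:
        raise ValueError("depth must be nonnegative")
    if depth <= thresholds.min_depth_exclusive:
        return 0.0
    call, gq = _call_and_gq(depth, error_rate)
    k = np.arange(depth + 1)
    ab = k / depth
    ok = (
        (call == _HET)
        & (gq >= thresholds.min_gq)
        & (ab >= thresholds.ab_low)
        & (ab <= thresholds.ab_high)
    )
    return float(binom.pmf(k[ok], depth, 0.5).sum())


def homref_detection_probability(
    depth: int,
    thresholds: FilterThresholds = FilterThresholds(),
    error_rate: float = DEFAULT_ERROR_RATE,
) -> float:
    """Probability that a truly homozygous-reference child site at this
    depth is called HomR and survives the filters (alt reads are error
    reads, Binomial(depth, eps); allele balance must fall below ab_low)."""
    if depth < 0:
        raise ValueError("depth must be nonnegative")
    if depth <= thresholds.min_depth_exclusive:
        return 0.0
    call, gq = _call_and_gq(depth, error_rate)
    k = np.arange(depth + 1)
    ab = k / depth
    ok = (call == _HOMR) & (gq >= thresholds.min_gq) & (ab < thresholds.ab_low)
    return float(binom.pmf(k[ok], depth, error_rate).sum())


class _DetectionCache:
    """Memoised d_het/d_homref by depth for one (thresholds, eps) pair."""

    def __init__(self, thresholds: FilterThresholds, error_rate: float) -> None:
        self.thresholds = thresholds
        self.error_rate = error_rate
        self._het: dict[int, float] = {}
        self._homref: dict[int, float] = {}

    def het(self, depth: int) -> float:
        if depth not in self._het:
            self._het[depth] = het_detection_probability(
                depth, self.thresholds, self.error_rate
            )
        return self._het[depth]

    def homref(self, depth: int) -> float:
        if depth not in self._homref:
            self._homref[depth] = homref_detection_probability(
                depth, self.thresholds, self.error_rate
            )
        return self._homref[depth]


def site_callable_probability(
    record: TrioSiteRecord,
    error_rate: float = DEFAULT_ERROR_RATE,
    thresholds: FilterThresholds = FilterThresholds(),
    _cache: _DetectionCache | None = None,
) -> CallableProbability:
    """P_ji for one site: the probability a DNM arising there in this trio
    would have been observed, for the SNV and the indel configuration."""
    for member in record.members:
        if member.ref_reads + member.alt_reads <= 0:
            raise ValueError("all trio members need informative reads")
    cache = _cache or _DetectionCache(thresholds, error_rate)

    if any(m.depth <= thresholds.min_depth_exclusive for m in record.members):
        return CallableProbability(record.trio_id, record.chrom, record.pos, 0.0, 0.0)

    post_m = genotype_posteriors(record.mother, error_rate)
    post_f = genotype_posteriors(record.father, error_rate)
    d_het = cache.het(record.child.depth)
    d_homref = cache.homref(record.child.depth)

    p_snv = (
        post_m[_HOMR] * post_f[_HOMR] + post_m[_HOMA] * post_f[_HOMA]
    ) * d_het
    p_indel = post_m[_HOMA] * post_f[_HOMA] * d_homref
    return CallableProbability(
        record.trio_id,
        record.chrom,
        record.pos,
        float(min(p_snv, 1.0)),
        float(min(p_indel, 1.0)),
    )


def callable_probability_sums(
    records: Iterable[TrioSiteRecord],
    error_rate: float = DEFAULT_ERROR_RATE,
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[float, float]:
    """Stream records of one trio and return (sum of p_snv over SNV sites,
    sum of p_indel over indel sites). Sites with a Missing member or
    without informative reads in every member contribute zero."""
    cache = _DetectionCache(thresholds, error_rate)
    sum_snv = 0.0
    sum_indel = 0.0
    for record in records:
        if record.has_missing():
            continue
        if any(m.ref_reads + m.alt_reads <= 0 for m in record.members):
            continue
        cp = site_callable_probability(record, error_rate, thresholds, cache)
        if record.is_snv:
            sum_snv += cp.p_snv
        else:
            sum_indel += cp.p_indel
    return sum_snv, sum_indel


def callable_sums_from_arrays(
    ref_reads: np.ndarray,
    alt_reads: np.ndarray,
    depths: np.ndarray,
    is_snv: np.ndarray,
    error_rate: float = DEFAULT_ERROR_RATE,
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[float, float]:
    """Vectorised equivalent of :func:`callable_probability_sums` for one
    trio. Arrays are shaped (n_sites, 3) with columns child/mother/father
    (``is_snv`` is (n_sites,) boolean)."""
    informative = (ref_reads + alt_reads) > 0
    deep = depths > thresholds.min_depth_exclusive
    usable = informative.all(axis=1) & deep.all(axis=1)

    post_m = _posterior_array(ref_reads[:, 1], alt_reads[:, 1], error_rate)
    post_f = _posterior_array(ref_reads[:, 2], alt_reads[:, 2], error_rate)

    cache = _DetectionCache(thresholds, error_rate)
    child_depth = depths[:, 0]
    d_het = np.zeros(len(child_depth))
    d_homref = np.zeros(len(child_depth))
    for depth in np.unique(child_depth[usable]):
        mask = usable & (child_depth == depth)
        d_het[mask] = cache.het(int(depth))
        d_homref[mask] = cache.homref(int(depth))

    both_homr = post_m[:, _HOMR] * post_f[:, _HOMR]
    both_homa = post_m[:, _HOMA] * post_f[:, _HOMA]
    p_snv = np.where(usable, (both_homr + both_homa) * d_het, 0.0)
    p_indel = np.where(usable, both_homa * d_homref, 0.0)
    return float(p_snv[is_snv].sum()), float(p_indel[~is_snv].sum())


# ---------------------------------------------------------------------------
# Rate estimation


def wilson_interval(
    x: int, n_trials: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion.

    bounds = (x + z^2/2 -+ z * sqrt(x * (1 - x/N) + z^2/4)) / (N + z^2)

    with z the two-sided standard-normal quantile. Well behaved for the
    very small proportions a mutation-rate estimate involves, where the
    Wald interval collapses.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if not (0 <= x <= n_trials):
        raise ValueError("need 0 <= x <= n_trials")
    z = norm.ppf(0.5 + confidence / 2.0)
    half = z * math.sqrt(x * (1.0 - x / n_trials) + z * z / 4.0)
    centre = x + z * z / 2.0
    denom = n_trials + z * z
    low = max((centre - half) / denom, 0.0)
    high = min((centre + half) / denom, 1.0)
    return (low, high)


def estimate_rate(
    per_trio_counts: Sequence[int],
    per_trio_prob_sums: Sequence[float],
    confidence: float = 0.95,
) -> RateEstimate:
    """PPPG rate from per-trio DNM counts n_i and per-trio callable-
    probability sums sum_j P_ji; CI from the Wilson interval with the
    haplotype-position denominator rounded to integer trials."""
    if len(per_trio_counts) != len(per_trio_prob_sums):
        raise ValueError("counts and probability sums must align per trio")
    n_mut = int(sum(per_trio_counts))
    if any(c < 0 for c in per_trio_counts):
        raise ValueError("counts must be nonnegative")
    denominator = 2.0 * float(sum(per_trio_prob_sums))
    if denominator <= 0:
        raise ValueError("callable denominator is zero")
    rate = n_mut / denominator
    ci_low, ci_high = wilson_interval(n_mut, round(denominator), confidence)
    return RateEstimate(
        n_mutations=n_mut,
        denominator=denominator,
        rate=rate,
        ci_low=ci_low,
        ci_high=ci_high,
        n_trios=len(per_trio_counts),
    )
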