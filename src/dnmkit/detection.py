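"""Mendelian-violation candidate detection and quality filtering.

A candidate de novo mutation (DNM) is a trio genotype configuration that
cannot arise by inheritance: a heterozygous child with two homozygous-
reference parents, a heterozygous child with two homozygous-alternative
parents (a back-mutation of the population allele), or — for indels only —
a homozygous-reference child with two homozygous-alternative parents (the
"reversible" indel configuration, where the parents carry a non-reference
indel and the child reverts to the reference).

Candidates then pass three conservative filters before being counted:
genotype quality >= 50 for every trio member, read depth strictly > 20 at
the site in every member, and allele balance (alt-read fraction) within
[0.3, 0.7] for heterozygous members. Homozygous members must show allele
balance *outside* that band on the matching side (< 0.3 for hom-ref,
> 0.7 for hom-alt): a nominally homozygous parent with 40% alt reads is
evidence of a missed heterozygote, exactly the somatic/artifact signal
the balance filter exists to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import poisson

from .variant_io import Genotype, SampleEvidence, TrioSiteRecord

PASS = "PASS"

#: Candidate trio genotype configurations, keyed by
#: (child, mother, father) genotype.
CONFIG_HET_HOMREF = "het_child_homref_parents"
CONFIG_HET_HOMALT = "het_child_homalt_parents"
CONFIG_REVERSIBLE = "reversible_indel"

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass(frozen=True)
class FilterThresholds:
    """Quality thresholds applied to candidate DNMs.

    Defaults follow the conservative trio-filter set: GQ >= 50 (inclusive),
    depth > 20 (strict), allele balance in [0.3, 0.7] (inclusive ends).
    """

    min_gq: float = 50.0
    min_depth_exclusive: int = 20
    ab_low: float = 0.3
    ab_high: float = 0.7

    def __post_init__(self) -> None:
        if not (0 <= self.ab_low < self.ab_high <= 1):
            raise ValueError("need 0 <= ab_low < ab_high <= 1")
        if self.min_gq < 0 or self.min_depth_exclusive < 0:
            raise ValueError("thresholds must be nonnegative")


@dataclass(frozen=True)
class CandidateDNM:
    """A Mendelian-violation call with class and substitution labels."""

    trio_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str  # "SNV" | "indel"
    config: str
    substitution: str | None  # e.g. "A>G" for SNVs, None for indels
    ts_tv: str  # "transition" | "transversion" | "NA"
    filter_status: str = PASS

    @property
    def passed(self) -> bool:
        return self.filter_status == PASS

    @property
    def key(self) -> tuple[str, str, int, str, str]:
        return (self.trio_id, self.chrom, self.pos, self.ref, self.alt)


def classify_substitution(ref: str, alt: str) -> str:
    """Classify a ref/alt pair as transition, transversion, or NA (indel).

    Transitions are purine<->purine ({A,G}) or pyrimidine<->pyrimidine
    ({C,T}); all other single-base changes are transversions.
    """
    if len(ref) != 1 or len(alt) != 1:
        return "NA"
    r, a = ref.upper(), alt.upper()
    for b in (r, a):
        if b not in "ACGT":
            raise ValueError(f"non-ACGT base {b!r}")
    if {r, a} <= _PURINES or {r, a} <= _PYRIMIDINES:
        return "transition"
    return "transversion"


def detect_candidates(record: TrioSiteRecord) -> CandidateDNM | None:
    """Return a candidate DNM if the trio genotypes are a Mendelian
    violation of one of the three recognised configurations, else None.

    All three genotypes must be non-Missing (pre-filter upstream).
    """
    c, m, f = (
        record.child.genotype,
        record.mother.genotype,
        record.father.genotype,
    )
    if Genotype.MISSING in (c, m, f):
        raise ValueError("detect_candidates requires non-Missing genotypes")

    is_snv = record.is_snv
    if c is Genotype.HET and m is Genotype.HOM_REF and f is Genotype.HOM_REF:
        config = CONFIG_HET_HOMREF
    elif c is Genotype.HET and m is Genotype.HOM_ALT and f is Genotype.HOM_ALT:
        config = CONFIG_HET_HOMALT
    elif (
        c is Genotype.HOM_REF
        and m is Genotype.HOM_ALT
        and f is Genotype.HOM_ALT
        and not is_snv
    ):
        config = CONFIG_REVERSIBLE
    else:
        return None

    ts_tv = classify_substitution(record.ref, record.alt)
    return CandidateDNM(
        trio_id=record.trio_id,
        chrom=record.chrom,
        pos=record.pos,
        ref=record.ref,
        alt=record.alt,
        variant_class="SNV" if is_snv else "indel",
        config=config,
        substitution=f"{record.ref}>{record.alt}" if is_snv else None,
        ts_tv=ts_tv,
    )


def _allele_balance_rule(evidence: SampleEvidence, thresholds: FilterThresholds) -> bool:
    """Allele-balance consistency for one member, by its called genotype.

    Het: AB within [ab_low, ab_high]. Hom-ref: AB < ab_low. Hom-alt:
    AB > ab_high. Members without allele-specific reads are not judged.
    """
    ab = evidence.allele_balance
    if ab is None:
        return True
    gt = evidence.genotype
    if gt is Genotype.HET:
        return thresholds.ab_low <= ab <= thresholds.ab_high
    if gt is Genotype.HOM_REF:
        return ab < thresholds.ab_low
    if gt is Genotype.HOM_ALT:
        return ab > thresholds.ab_high
    return True


def apply_filters(
    candidate: CandidateDNM,
    record: TrioSiteRecord,
    thresholds: FilterThresholds = FilterThresholds(),
) -> CandidateDNM:
    """Return the candidate with filter_status set to PASS or the first
    failing rule (``min_gq``, ``min_depth``, ``allele_balance``)."""
    for member in record.members:
        if member.gq < thresholds.min_gq:
            return replace(candidate, filter_status="min_gq")
    for member in record.members:
        if member.depth <= thresholds.min_depth_exclusive:
            return replace(candidate, filter_status="min_depth")
    for member in record.members:
        if not _allele_balance_rule(member, thresholds):
            return replace(candidate, filter_status="allele_balance")
    return replace(candidate, filter_status=PASS)


def detect_and_filter(
    records: Iterable[TrioSiteRecord],
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[CandidateDNM]:
    """Run detection + filtering over a record stream; sites with any
    Missing trio genotype are excluded."""
    out: list[CandidateDNM] = []
    for record in records:
        if record.has_missing():
            continue
        candidate = detect_candidates(record)
        if candidate is not None:
            out.append(apply_filters(candidate, record, thresholds))
    return out


def detect_and_filter_arrays(
    called_gt: np.ndarray,
    depth: np.ndarray,
    ref_reads: np.ndarray,
    alt_reads: np.ndarray,
    gq: np.ndarray,
    sites,
    trio_id: str,
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[CandidateDNM]:
    """Vectorised detection over (n_sites, 3) evidence matrices (columns
    child/mother/father); Mendelian violations are located with array
    masks, then each hit goes through the same scalar detect/filter path
    so the two routes cannot disagree. ``sites`` is a DataFrame with
    chrom/pos/ref/alt/is_snv columns."""
    c, m, f = called_gt[:, 0], called_gt[:, 1], called_gt[:, 2]
    is_snv = sites["is_snv"].to_numpy()
    complete = (called_gt >= 0).all(axis=1) & (depth > 0).all(axis=1)
    violation = complete & (
        ((c == 1) & (m == 0) & (f == 0))
        | ((c == 1) & (m == 2) & (f == 2))
        | ((c == 0) & (m == 2) & (f == 2) & ~is_snv)
    )
    gt_map = {0: Genotype.HOM_REF, 1: Genotype.HET, 2: Genotype.HOM_ALT}
    chroms = sites["chrom"].to_numpy()
    poss = sites["pos"].to_numpy()
    refs = sites["ref"].to_numpy()
    alts = sites["alt"].to_numpy()
    out: list[CandidateDNM] = []
    for j in np.flatnonzero(violation):
        members = [
            SampleEvidence(
                gt_map[int(called_gt[j, col])],
                int(depth[j, col]),
                int(ref_reads[j, col]),
                int(alt_reads[j, col]),
                float(gq[j, col]),
            )
            for col in range(3)
        ]
        record = TrioSiteRecord(
            chrom=str(chroms[j]),
            pos=int(poss[j]),
            ref=str(refs[j]),
            alt=str(alts[j]),
            child=members[0],
            mother=members[1],
            father=members[2],
            trio_id=trio_id,
        )
        candidate = detect_candidates(record)
        if candidate is not None:
            out.append(apply_filters(candidate, record, thresholds))
    return out


def flag_outlier_trios(
    per_trio_counts: Mapping[str, int] | Sequence[int],
    expected_mean: float,
    alpha: float = 1e-6,
) -> list[str]:
    """Flag trios whose DNM count is in the extreme Poisson upper tail.

    A trio with count ``k`` is flagged when P(X >= k | Poisson(mean))
    < alpha. An excess of apparent DNMs in one trio is the signature of
    sample mix-up or non-paternity, so flagged trios should be reviewed
    (e.g. by independent paternity testing), not silently dropped.
    """
    if expected_mean <= 0:
        raise ValueError("expected_mean must be positive")
    if isinstance(per_trio_counts, Mapping):
        items = list(per_trio_counts.items())
    else:
        items = [(str(i), c) for i, c in enumerate(per_trio_counts)]
    flagged = []
    for trio_id, count in items:
        if count < 0:
            raise ValueError("counts must be nonnegative")
        # P(X >= count) = sf(count - 1)
        if count > 0 and poisson.sf(count - 1, expected_mean) < alpha:
            flagged.append(trio_id)
    return flagged
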