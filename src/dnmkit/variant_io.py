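"""Readers and writers for the standard formats the pipeline touches.

Multi-sample VCF (via :mod:`cyvcf2`), pedigree TSV, BED3 annotation
intervals, per-position score tables, and the pipeline's own TSV reports.

Coordinate conventions: VCF positions are 1-based; BED intervals are
0-based half-open. Conversion happens at the read boundary only — every
in-memory position in this package is 1-based.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterator, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)


class Genotype(Enum):
    """Diploid genotype of one sample relative to a single ref/alt pair."""

    HOM_REF = "HomR"
    HET = "Het"
    HOM_ALT = "HomA"
    MISSING = "Missing"


@dataclass(frozen=True)
class Trio:
    """A father-mother-child sample triple.

    Parental ages are years at the child's birth and may be absent.
    """

    trio_id: str
    child_id: str
    mother_id: str
    father_id: str
    mother_age: float | None = None
    father_age: float | None = None

    def __post_init__(self) -> None:
        ids = {self.child_id, self.mother_id, self.father_id}
        if len(ids) != 3:
            raise ValueError(
                f"trio {self.trio_id!r}: child/mother/father ids must be distinct"
            )
        for label, age in (("mother", self.mother_age), ("father", self.father_age)):
            if age is not None and not (10 <= age <= 100):
                raise ValueError(
                    f"trio {self.trio_id!r}: {label} age {age} outside [10, 100]"
                )

    @property
    def sample_ids(self) -> tuple[str, str, str]:
        return (self.child_id, self.mother_id, self.father_id)


@dataclass(frozen=True)
class SampleEvidence:
    """Read-level evidence for one sample at one site.

    ``gq`` is phred-scaled genotype quality; ``depth`` the total read
    count (DP); ``ref_reads``/``alt_reads`` the allele-specific counts
    (AD) for the ref and the one alt allele this record describes.
    """

    genotype: Genotype
    depth: int = 0
    ref_reads: int = 0
    alt_reads: int = 0
    gq: float = 0.0

    def __post_init__(self) -> None:
        if self.depth < 0 or self.ref_reads < 0 or self.alt_reads < 0:
            raise ValueError("read counts must be nonnegative")
        if self.ref_reads + self.alt_reads > self.depth:
            raise ValueError("ref_reads + alt_reads must not exceed depth")
        if self.genotype is not Genotype.MISSING and self.depth == 0:
            raise ValueError("non-missing genotype requires depth > 0")

    @property
    def allele_balance(self) -> float | None:
        """Fraction of informative reads supporting the alt allele.

        Undefined (None) when no allele-specific reads were observed.
        """
        informative = self.ref_reads + self.alt_reads
        if informative == 0:
            return None
        return self.alt_reads / informative


@dataclass(frozen=True)
class TrioSiteRecord:
    """One genomic site with genotype evidence for child/mother/father."""

    chrom: str
    pos: int
    ref: str
    alt: str
    child: SampleEvidence
    mother: SampleEvidence
    father: SampleEvidence
    trio_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be 1-based (>= 1)")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def members(self) -> tuple[SampleEvidence, SampleEvidence, SampleEvidence]:
        return (self.child, self.mother, self.father)

    def has_missing(self) -> bool:
        return any(m.genotype is Genotype.MISSING for m in self.members)


# ---------------------------------------------------------------------------
# Pedigree


def read_pedigree(path: str | Path) -> list[Trio]:
    """Read a tab-separated pedigree file into a list of :class:`Trio`.

    Columns: trio_id, child, mother, father, and optionally mother_age,
    father_age. Lines starting with ``#`` are ignored. Order preserved.
    """
    trios: list[Trio] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >= 4 columns")
            trio_id, child, mother, father = fields[:4]
            if trio_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate trio_id {trio_id!r}")
            seen.add(trio_id)
            mother_age = float(fields[4]) if len(fields) > 4 and fields[4] != "." else None
            father_age = float(fields[5]) if len(fields) > 5 and fields[5] != "." else None
            trios.append(
                Trio(trio_id, child, mother, father, mother_age, father_age)
            )
    return trios


def write_pedigree(trios: Sequence[Trio], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#trio_id\tchild\tmother\tfather\tmother_age\tfather_age\n")
        for t in trios:
            ma = "." if t.mother_age is None else f"{t.mother_age:g}"
            fa = "." if t.father_age is None else f"{t.father_age:g}"
            fh.write(
                f"{t.trio_id}\t{t.child_id}\t{t.mother_id}\t{t.father_id}\t{ma}\t{fa}\n"
            )


# ---------------------------------------------------------------------------
# VCF


def _genotype_for_alt(alleles: Sequence[int], alt_index: int) -> Genotype:
    """Genotype of a sample relative to alt allele ``alt_index`` (1-based
    within the VCF ALT list). Any missing allele makes the whole call
    Missing; alleles that are neither ref nor this alt count as ref-like."""
    if any(a < 0 for a in alleles):
        return Genotype.MISSING
    n_alt = sum(1 for a in alleles if a == alt_index)
    if n_alt == 0:
        return Genotype.HOM_REF
    if n_alt == 1:
        return Genotype.HET
    return Genotype.HOM_ALT


def read_trio_vcf(path: str | Path, trio: Trio) -> Iterator[TrioSiteRecord]:
    """Stream :class:`TrioSiteRecord` from a multi-sample VCF.

    Multiallelic records are decomposed into one record per alt allele.
    A sample whose GT/DP/AD/GQ is absent or malformed at a record gets a
    Missing genotype for that record (with a logged warning), never a
    hard error; a trio sample absent from the header is a hard error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    try:
        sample_index: dict[str, int] = {}
        for sid in trio.sample_ids:
            if sid not in vcf.samples:
                raise ValueError(f"sample {sid!r} not in VCF header of {path}")
            sample_index[sid] = vcf.samples.index(sid)

        idx = [sample_index[s] for s in trio.sample_ids]  # child, mother, father
        warned_fields: set[str] = set()

        for variant in vcf:
            genotypes = variant.genotypes  # [[a, b, phased], ...]
            dp = variant.format("DP")
            ad = variant.format("AD")
            gq = variant.format("GQ")
            for missing_name, arr in (("DP", dp), ("AD", ad), ("GQ", gq)):
                if arr is None and missing_name not in warned_fields:
                    warned_fields.add(missing_name)
                    logger.warning(
                        "%s: FORMAT/%s absent at %s:%d; affected genotypes set Missing",
                        path, missing_name, variant.CHROM, variant.POS,
                    )
            for alt_k, alt in enumerate(variant.ALT, start=1):
                evidence = []
                for i in idx:
                    gt = _genotype_for_alt(genotypes[i][:-1], alt_k)
                    if dp is None or ad is None or gq is None:
                        evidence.append(SampleEvidence(Genotype.MISSING))
                        continue
                    depth = int(dp[i][0]) if dp[i][0] >= 0 else -1
                    ref_reads = int(ad[i][0]) if ad[i][0] >= 0 else -1
                    alt_reads = int(ad[i][alt_k]) if ad[i][alt_k] >= 0 else -1
                    gq_val = float(gq[i][0]) if gq[i][0] >= 0 else -1.0
                    if depth < 0 or ref_reads < 0 or alt_reads < 0 or gq_val < 0:
                        evidence.append(SampleEvidence(Genotype.MISSING))
                        continue
                    if gt is not Genotype.MISSING and depth == 0:
                        gt = Genotype.MISSING
                    if ref_reads + alt_reads > depth:
                        # AD occasionally exceeds DP in real callers; trust AD
                        depth = ref_reads + alt_reads
                    evidence.append(
                        SampleEvidence(gt, depth, ref_reads, alt_reads, gq_val)
                    )
                yield TrioSiteRecord(
                    chrom=variant.CHROM,
                    pos=variant.POS,
                    ref=variant.REF,
                    alt=alt,
                    child=evidence[0],
                    mother=evidence[1],
                    father=evidence[2],
                    trio_id=trio.trio_id,
                )
    finally:
        vcf.close()


# ---------------------------------------------------------------------------
# BED interval tracks


class GenomeIntervals:
    """Point-membership queries against a set of genomic intervals.

    Built from BED (0-based half-open) intervals; queried with 1-based
    positions. A 1-based position ``pos`` is inside BED interval
    ``[start, end)`` iff ``start < pos <= end``.
    """

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}

    def add(self, chrom: str, start: int, end: int) -> None:
        """Add a 0-based half-open interval."""
        if start >= end:
            raise ValueError(f"empty interval [{start}, {end})")
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end)

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position."""
        tree = self._trees.get(chrom)
        if tree is None:
            return False
        return bool(tree.overlaps(pos - 1))

    def chroms(self) -> list[str]:
        return sorted(self._trees)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return self.contains(*key)


def read_interval_track(path: str | Path) -> GenomeIntervals:
    """Read a BED3+ file into a :class:`GenomeIntervals` query structure.

    Intervals with start >= end are skipped with a warning; unsorted
    input is allowed.
    """
    track = GenomeIntervals()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                warnings.warn(f"{path}:{lineno}: empty interval skipped", stacklevel=2)
                continue
            track.add(chrom, start, end)
    return track


def read_position_scores(path: str | Path) -> dict[tuple[str, int], float]:
    """Read a per-position score table (chrom, 1-based pos, score) TSV."""
    scores: dict[tuple[str, int], float] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            chrom, pos, score = line.split("\t")[:3]
            scores[(chrom, int(pos))] = float(score)
    return scores


def read_position_flags(path: str | Path) -> dict[tuple[str, int], int]:
    """Read a per-position binary flag table (chrom, pos, 0/1) TSV."""
    flags: dict[tuple[str, int], int] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            chrom, pos, flag = line.split("\t")[:3]
            flags[(chrom, int(pos))] = int(flag)
    return flags


# ---------------------------------------------------------------------------
# Candidate DNM report

DNM_REPORT_COLUMNS = (
    "trio_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "variant_class",
    "config",
    "substitution",
    "ts_tv",
    "filter_status",
)


def write_dnm_report(candidates: Sequence["CandidateDNM"], path: str | Path) -> None:
    """Write candidate DNMs as TSV, ordered by (trio_id, chrom, pos)."""
    ordered = sorted(candidates, key=lambda c: (c.trio_id, c.chrom, c.pos, c.alt))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(DNM_REPORT_COLUMNS)
        for c in ordered:
            writer.writerow(
                [
                    c.trio_id,
                    c.chrom,
                    c.pos,
                    c.ref,
                    c.alt,
                    c.variant_class,
                    c.config,
                    c.substitution or ".",
                    c.ts_tv,
                    c.filter_status,
                ]
            )


def read_dnm_report(path: str | Path) -> list["CandidateDNM"]:
    """Read a TSV written by :func:`write_dnm_report` back into candidates."""
    from .detection import CandidateDNM

    out: list[CandidateDNM] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(
                CandidateDNM(
                    trio_id=row["trio_id"],
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    variant_class=row["variant_class"],
                    config=row["config"],
                    substitution=None if row["substitution"] == "." else row["substitution"],
                    ts_tv=row["ts_tv"],
                    filter_status=row["filter_status"],
                )
            )
    return out
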