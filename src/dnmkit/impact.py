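"""Aggregation of categorical deleteriousness predictions per DNM.

Ten widely used tools provide categorical calls per variant (PolyPhen-2
HDIV/HVAR, LRT, PROVEAN, CADD, FATHMM, MutationTaster, MutationAssessor,
SIFT, FATHMM-MKL coding). Two selection rules define "likely pathogenic":
at least six damaging/probably-damaging calls, or damaging by at least
half of the informative tools. A conservation score (GERP++) can
optionally join the vote as an eleventh binary input (score > 2 counts as
damaging-equivalent), off by default since it is a constraint score, not
a damaging/tolerated classifier.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

PREDICTORS = (
    "Polyphen_HDIV",
    "Polyphen_HVAR",
    "LRT",
    "PROVEAN",
    "CADD",
    "FATHMM",
    "MutationTaster",
    "MutationAssessor",
    "SIFT",
    "FathmmMKL_coding",
)

DAMAGING_CALLS = frozenset({"damaging", "probably_damaging"})
VALID_CALLS = frozenset({"damaging", "probably_damaging", "tolerated", "unknown"})

#: ANNOVAR-style single-letter (and word) codes normalised to our vocabulary.
DEFAULT_CALL_VOCABULARY: dict[str, str] = {
    "D": "damaging",
    "A": "damaging",  # MutationTaster "disease causing automatic"
    "H": "damaging",  # MutationAssessor "high"
    "M": "damaging",  # MutationAssessor "medium"
    "P": "probably_damaging",
    "T": "tolerated",
    "N": "tolerated",
    "L": "tolerated",
    "B": "tolerated",
    ".": "unknown",
    "": "unknown",
    "NA": "unknown",
    "U": "unknown",
    "damaging": "damaging",
    "probably_damaging": "probably_damaging",
    "tolerated": "tolerated",
    "unknown": "unknown",
}

GERP_DAMAGING_THRESHOLD = 2.0


@dataclass(frozen=True)
class ImpactProfile:
    """Predictor calls for one DNM, keyed by its report key."""

    dnm_key: tuple
    calls: Mapping[str, str] = field(default_factory=dict)
    gerp_score: float | None = None

    def __post_init__(self) -> None:
        for name, call in self.calls.items():
            if call not in VALID_CALLS:
                raise ValueError(f"{name}: invalid call {call!r}")


def normalize_call(raw: str, vocabulary: Mapping[str, str] | None = None) -> str:
    """Map a raw predictor code to damaging/probably_damaging/tolerated/
    unknown; unrecognised codes are unknown."""
    vocab = DEFAULT_CALL_VOCABULARY if vocabulary is None else vocabulary
    return vocab.get(raw.strip(), "unknown")


def count_damaging(profile: ImpactProfile, include_gerp: bool = False) -> int:
    """Number of predictors calling the variant damaging or probably
    damaging; unknown calls never count. With ``include_gerp``, a
    conservation score > 2 adds one vote."""
    n = sum(1 for call in profile.calls.values() if call in DAMAGING_CALLS)
    if include_gerp and profile.gerp_score is not None:
        if profile.gerp_score > GERP_DAMAGING_THRESHOLD:
            n += 1
    return n


def n_informative(profile: ImpactProfile, include_gerp: bool = False) -> int:
    n = sum(1 for call in profile.calls.values() if call != "unknown")
    if include_gerp and profile.gerp_score is not None:
        n += 1
    return n


def select_likely_pathogenic(
    profiles: Iterable[ImpactProfile],
    rule: str,
    include_gerp: bool = False,
) -> list[ImpactProfile]:
    """Apply one of the two selection rules.

    ``at_least_6``: >= 6 damaging/probably-damaging votes.
    ``at_least_half``: votes >= ceil(informative/2), with informative the
    predictors that produced a call (unknown excluded).
    """
    if rule not in ("at_least_6", "at_least_half"):
        raise ValueError(f"unknown rule {rule!r}")
    selected = []
    for profile in profiles:
        votes = count_damaging(profile, include_gerp)
        if rule == "at_least_6":
            keep = votes >= 6
        else:
            informative = n_informative(profile, include_gerp)
            keep = informative > 0 and votes >= math.ceil(informative / 2)
        if keep:
            selected.append(profile)
    return selected


def read_predictor_table(
    path: str | Path,
    vocabulary: Mapping[str, str] | None = None,
    predictors: Sequence[str] = PREDICTORS,
) -> list[ImpactProfile]:
    """Read an annotation TSV with one column per predictor plus
    trio_id/chrom/pos/ref/alt key columns (ANNOVAR-style); an optional
    ``GERP`` column supplies the conservation score."""
    profiles: list[ImpactProfile] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            key = (
                row.get("trio_id", ""),
                row["chrom"],
                int(row["pos"]),
                row["ref"],
                row["alt"],
            )
            calls = {
                name: normalize_call(row.get(name, ""), vocabulary)
                for name in predictors
            }
            gerp_raw = row.get("GERP", "").strip()
            gerp = float(gerp_raw) if gerp_raw not in ("", ".") else None
            profiles.append(ImpactProfile(key, calls, gerp))
    return profiles


def write_selection(
    profiles: Sequence[ImpactProfile],
    path: str | Path,
    include_gerp: bool = False,
) -> None:
    """Write selected DNMs with their damaging-vote counts as TSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["trio_id", "chrom", "pos", "ref", "alt", "n_damaging", "n_informative"]
        )
        for p in profiles:
            writer.writerow(
                list(p.dnm_key)
                + [count_damaging(p, include_gerp), n_informative(p, include_gerp)]
            )
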