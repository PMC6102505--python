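"""Descriptive summaries of a passing DNM call set.

Transition/transversion ratio, substitution composition, per-chromosome
distribution with Pearson correlations against gene density and
chromosome size, per-person means, and concordance between two call sets
(e.g. the outputs of two different trio callers).
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .detection import CandidateDNM

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _passing(candidates: Iterable[CandidateDNM]) -> list[CandidateDNM]:
    return [c for c in candidates if c.passed]


def tstv_ratio(candidates: Iterable[CandidateDNM]) -> float:
    """Transitions / transversions among passing SNV candidates.

    Returns ``inf`` when transversions are absent; raises if no passing
    SNV exists at all.
    """
    snvs = [c for c in _passing(candidates) if c.variant_class == "SNV"]
    if not snvs:
        raise ValueError("no passing SNV candidates")
    ts = sum(1 for c in snvs if c.ts_tv == "transition")
    tv = len(snvs) - ts
    if tv == 0:
        return math.inf
    return ts / tv


def substitution_composition(candidates: Iterable[CandidateDNM]) -> pd.Series:
    """Counts of each ref>alt substitution among passing SNVs."""
    subs = [c.substitution for c in _passing(candidates) if c.substitution]
    return pd.Series(subs, dtype=object).value_counts().sort_index()


def per_chromosome_summary(
    candidates: Iterable[CandidateDNM],
    chrom_lengths: Mapping[str, int],
    gene_density: Mapping[str, float],
    n_trios: int | None = None,
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Per-chromosome DNM counts with the standard error of the per-trio
    mean, plus Pearson correlations (R, two-sided p) of counts against
    gene density and chromosome length.

    Every chromosome in ``chrom_lengths`` appears in the table (zero
    counts included); a candidate chromosome missing from the table is an
    error.
    """
    passing = _passing(candidates)
    if not passing:
        raise ValueError("no passing candidates")
    for c in passing:
        if c.chrom not in chrom_lengths:
            raise ValueError(f"chromosome {c.chrom!r} absent from length table")

    chroms = list(chrom_lengths)
    counts = {ch: 0 for ch in chroms}
    per_trio: dict[str, dict[str, int]] = {ch: {} for ch in chroms}
    for c in passing:
        counts[c.chrom] += 1
        per_trio[c.chrom][c.trio_id] = per_trio[c.chrom].get(c.trio_id, 0) + 1

    trio_ids = sorted({c.trio_id for c in passing})
    denom = n_trios if n_trios is not None else len(trio_ids)
    sems = []
    for ch in chroms:
        per = np.array(
            [per_trio[ch].get(t, 0) for t in trio_ids]
            + [0] * max(denom - len(trio_ids), 0),
            dtype=float,
        )
        sems.append(per.std(ddof=1) / math.sqrt(len(per)) if len(per) > 1 else 0.0)

    table = pd.DataFrame(
        {
            "chrom": chroms,
            "count": [counts[ch] for ch in chroms],
            "sem": sems,
            "length": [chrom_lengths[ch] for ch in chroms],
            "gene_density": [gene_density.get(ch, np.nan) for ch in chroms],
        }
    )

    correlations: dict[str, tuple[float, float]] = {}
    y = table["count"].to_numpy(dtype=float)
    for name in ("gene_density", "length"):
        x = table[name].to_numpy(dtype=float)
        ok = ~np.isnan(x)
        if ok.sum() < 3 or np.std(x[ok]) == 0:
            correlations[name] = (math.nan, math.nan)
        elif np.std(y[ok]) == 0:
            # counts constant: no linear association with any predictor
            correlations[name] = (0.0, 1.0)
        else:
            r, p = pearsonr(y[ok], x[ok])
            correlations[name] = (float(r), float(p))
    return table, correlations


def per_person_mean(n_dnms: int, n_trios: int) -> float:
    """Mean passing DNMs per offspring: total / number of trios."""
    if n_trios <= 0:
        raise ValueError("n_trios must be positive")
    if n_dnms < 0:
        raise ValueError("n_dnms must be nonnegative")
    return n_dnms / n_trios


def _left_align_key(c: CandidateDNM) -> tuple[str, str, int, str, str]:
    """Concordance key with a minimal indel normalisation: shared trailing
    bases of ref/alt are trimmed so representation differences between
    callers do not hide a match."""
    ref, alt = c.ref, c.alt
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    return (c.trio_id, c.chrom, c.pos, ref, alt)


def concordance(
    set_a: Iterable[CandidateDNM], set_b: Iterable[CandidateDNM]
) -> dict[str, float]:
    """Overlap of two call sets keyed by (trio, chrom, pos, alleles).

    Returns the shared count, the Jaccard index |A∩B|/|A∪B|, the shared
    count as a percentage of the union, and — because published overlap
    percentages rarely state their denominator — also as percentages of
    each input set.
    """
    keys_a = {_left_align_key(c) for c in set_a}
    keys_b = {_left_align_key(c) for c in set_b}
    inter = keys_a & keys_b
    union = keys_a | keys_b
    n_union = len(union)
    return {
        "n_shared": len(inter),
        "n_a": len(keys_a),
        "n_b": len(keys_b),
        "n_union": n_union,
        "jaccard": len(inter) / n_union if n_union else 0.0,
        "pct_of_union": 100.0 * len(inter) / n_union if n_union else 0.0,
        "pct_of_a": 100.0 * len(inter) / len(keys_a) if keys_a else 0.0,
        "pct_of_b": 100.0 * len(inter) / len(keys_b) if keys_b else 0.0,
    }


def per_trio_counts(
    candidates: Iterable[CandidateDNM], trio_ids: Sequence[str]
) -> dict[str, int]:
    """Passing-DNM count per trio, zero-filled over ``trio_ids``."""
    counts = {t: 0 for t in trio_ids}
    for c in _passing(candidates):
        if c.trio_id in counts:
            counts[c.trio_id] += 1
    return counts
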