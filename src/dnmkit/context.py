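"""Genomic-context annotation of DNMs and context-stratified rate models.

Each site is annotated with binary context flags — open chromatin (DHS),
CpG island, three histone marks (H3K27ac, H3K4me1, H3K4me3) — plus an
evolutionary-constraint score binarised at > 12 ("conserved") and an
expression-specificity flag. Per-trio DNM rates are stratified by a
feature, and single-predictor ordinary-least-squares regressions relate
per-trio feature counts to per-trio rates; parental-age association is a
Pearson correlation of per-trio DNM counts against each parent's age.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import pearsonr

from .detection import CandidateDNM
from .variant_io import GenomeIntervals, Trio

CONSERVATION_THRESHOLD = 12.0

INTERVAL_FEATURES = ("dhs", "cpg", "h3k27ac", "h3k4me1", "h3k4me3")


@dataclass(frozen=True)
class ContextAnnotation:
    """Binary genomic-context flags for one site.

    ``conserved`` is derived from the constraint score: 1 iff the score
    is strictly greater than 12 (a score of exactly 12 is non-conserved;
    None when the score is unavailable, excluding the site from
    conservation strata).
    """

    dhs: int
    cpg: int
    h3k27ac: int
    h3k4me1: int
    h3k4me3: int
    gerp_score: float | None
    conserved: int | None
    expression_nonspecific: int | None

    def __post_init__(self) -> None:
        for name in ("dhs", "cpg", "h3k27ac", "h3k4me1", "h3k4me3"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name} flag must be 0 or 1")
        if self.gerp_score is None:
            if self.conserved is not None:
                raise ValueError("conserved must be unset without a score")
        elif self.conserved != int(self.gerp_score > CONSERVATION_THRESHOLD):
            raise ValueError("conserved must equal (gerp_score > 12)")

    def flag(self, feature: str) -> int | None:
        if feature == "conserved":
            return self.conserved
        if feature == "nonspecific_expression":
            return self.expression_nonspecific
        return getattr(self, feature)


@dataclass(frozen=True)
class RegressionResult:
    """Slope, its standard error, two-sided p, R^2 and n for one OLS fit."""

    beta: float
    se: float
    p_value: float
    r_squared: float
    n_obs: int


def annotate_context(
    chrom: str,
    pos: int,
    tracks: Mapping[str, GenomeIntervals],
    gerp_scores: Mapping[tuple[str, int], float] | None = None,
    expression_flags: Mapping[tuple[str, int], int] | None = None,
) -> ContextAnnotation:
    """Annotate a 1-based position with interval-membership flags, the
    conservation binarisation, and the expression-specificity flag."""
    flags = {}
    for feature in INTERVAL_FEATURES:
        track = tracks.get(feature)
        flags[feature] = int(track.contains(chrom, pos)) if track is not None else 0
    score = None if gerp_scores is None else gerp_scores.get((chrom, pos))
    conserved = None if score is None else int(score > CONSERVATION_THRESHOLD)
    expr = None if expression_flags is None else expression_flags.get((chrom, pos))
    return ContextAnnotation(
        dhs=flags["dhs"],
        cpg=flags["cpg"],
        h3k27ac=flags["h3k27ac"],
        h3k4me1=flags["h3k4me1"],
        h3k4me3=flags["h3k4me3"],
        gerp_score=score,
        conserved=conserved,
        expression_nonspecific=expr,
    )


def stratified_rate(
    candidates: Iterable[CandidateDNM],
    callable_table: pd.DataFrame,
    feature: str,
    level: int,
    trio_ids: Sequence[str] | None = None,
) -> pd.Series:
    """Per-trio DNM rates restricted to sites where ``feature`` equals
    ``level``.

    ``callable_table`` has one row per (trio_id, site) with columns
    ``trio_id``, ``p_snv`` and one 0/1 column per feature; alternatively
    a single shared site table (no trio_id column) used for every trio.
    The per-trio rate is (passing DNMs in-stratum) / (2 * sum of p_snv
    over in-stratum sites); trios with a zero stratum denominator are
    excluded (NaN dropped).
    """
    if feature not in callable_table.columns:
        raise ValueError(f"unknown feature {feature!r}")
    passing = [c for c in candidates if c.passed]
    if trio_ids is None:
        trio_ids = sorted({c.trio_id for c in passing})

    # candidate stratum membership by site lookup
    site_flags = {
        (ch, p): fl
        for ch, p, fl in zip(
            callable_table["chrom"], callable_table["pos"], callable_table[feature]
        )
    }

    shared = "trio_id" not in callable_table.columns
    rates = {}
    for trio_id in trio_ids:
        if shared:
            sub = callable_table
        else:
            sub = callable_table[callable_table["trio_id"] == trio_id]
        stratum = sub[sub[feature] == level]
        denom = 2.0 * float(stratum["p_snv"].sum())
        n = sum(
            1
            for c in passing
            if c.trio_id == trio_id and site_flags.get((c.chrom, c.pos)) == level
        )
        rates[trio_id] = n / denom if denom > 0 else np.nan
    return pd.Series(rates).dropna()


def fit_rate_regression(
    x: Sequence[float], y: Sequence[float]
) -> RegressionResult:
    """Ordinary least squares y = a + b*x for one predictor.

    Returns the slope b, its standard error, the two-sided t-test p-value
    on the slope, and R^2. Requires >= 3 observations and predictor
    variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance")
    if np.ptp(y) == 0:
        # constant response: flat fit, no explainable variance
        return RegressionResult(0.0, 0.0, 1.0, 0.0, len(x))
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        beta=float(model.params[1]),
        se=float(model.bse[1]),
        p_value=float(model.pvalues[1]),
        r_squared=float(model.rsquared),
        n_obs=int(model.nobs),
    )


def regression_table(
    per_trio_feature_counts: Mapping[str, Mapping[str, float]],
    per_trio_rates: Mapping[str, float],
) -> pd.DataFrame:
    """One OLS row per feature: per-trio counts of DNM positions carrying
    the feature, regressed against that trio's DNM rate."""
    rows = []
    trios = sorted(per_trio_rates)
    y = [per_trio_rates[t] for t in trios]
    for feature, counts in per_trio_feature_counts.items():
        x = [counts.get(t, 0) for t in trios]
        try:
            res = fit_rate_regression(x, y)
        except ValueError:
            continue
        rows.append(
            {
                "feature": feature,
                "beta": res.beta,
                "se": res.se,
                "p_value": res.p_value,
                "r_squared": res.r_squared,
                "n_obs": res.n_obs,
            }
        )
    return pd.DataFrame(rows)


def parental_age_correlation(
    trios: Sequence[Trio], per_trio_counts: Mapping[str, int]
) -> dict[str, tuple[float, float]]:
    """Pearson R and two-sided p of per-trio DNM counts against maternal
    and paternal age (trios with missing ages are dropped per parent)."""
    out: dict[str, tuple[float, float]] = {}
    for parent in ("mother", "father"):
        ages, counts = [], []
        for trio in trios:
            age = trio.mother_age if parent == "mother" else trio.father_age
            if age is not None and trio.trio_id in per_trio_counts:
                ages.append(age)
                counts.append(per_trio_counts[trio.trio_id])
        if len(ages) < 3:
            raise ValueError(f"fewer than 3 trios with known {parent} age")
        if np.std(counts) == 0 or np.std(ages) == 0:
            out[parent] = (0.0, 1.0)
        else:
            r, p = pearsonr(ages, counts)
            out[parent] = (float(r), float(p))
    return out
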