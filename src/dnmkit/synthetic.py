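"""Synthetic trio-exome generator with known ground-truth de novo mutations.

Emulates a cohort of father-mother-child exome trios genotyped jointly:

* population alternative-allele frequencies drawn from a Beta distribution,
  parental genotypes in Hardy-Weinberg proportions;
* Mendelian transmission of one allele per parent, with a de novo mutation
  flipping each transmitted allele independently with probability ``mu``
  per position per haplotype (so genome-wide counts are
  Binomial(2 * n_sites, mu) per trio, and the rate estimator's factor 2
  recovers ``mu`` directly);
* read evidence per sample: depth ~ Poisson(mean_depth), alt reads ~
  Binomial(depth, p) with p = eps, 1/2, 1-eps for the three true
  genotypes; genotypes re-called by maximum likelihood under the same
  read model, GQ the phred gap between best and second-best likelihood
  (capped at 99);
* annotation tracks (open chromatin, CpG islands, three histone marks)
  as random interval unions with configurable genome coverage, a
  per-position conservation score, a per-position expression-specificity
  flag, and per-feature DNM-rate multipliers so context-enrichment
  recovery can be tested against a known truth.

Everything is deterministic under a fixed seed. ``perfect_calls`` replaces
the read model with error-free, fixed-depth evidence; useful when a test
needs the estimator isolated from genotyping noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .variant_io import Genotype, SampleEvidence, Trio, TrioSiteRecord, write_pedigree

_GT_CODE = {0: Genotype.HOM_REF, 1: Genotype.HET, 2: Genotype.HOM_ALT, -1: Genotype.MISSING}
_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

INTERVAL_FEATURES = ("dhs", "cpg", "h3k27ac", "h3k4me1", "h3k4me3")
SCORE_FEATURES = ("conserved", "nonspecific_expression")
ALL_FEATURES = INTERVAL_FEATURES + SCORE_FEATURES

PERFECT_DEPTH = 60


@dataclass(frozen=True)
class FeatureTrack:
    """One genomic-context feature: what fraction of the simulated exome it
    covers and how it scales the local DNM rate (1.0 = neutral)."""

    coverage: float
    multiplier: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.coverage <= 1.0):
            raise ValueError("coverage must be in [0, 1]")
        if self.multiplier <= 0:
            raise ValueError("multiplier must be positive")


def default_feature_tracks() -> dict[str, FeatureTrack]:
    """Exome-scale coverage fractions for the context features; all rate
    multipliers neutral by default."""
    return {
        "dhs": FeatureTrack(0.15),
        "cpg": FeatureTrack(0.05),
        "h3k27ac": FeatureTrack(0.10),
        "h3k4me1": FeatureTrack(0.10),
        "h3k4me3": FeatureTrack(0.05),
        "conserved": FeatureTrack(0.20),
        "nonspecific_expression": FeatureTrack(0.50),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for one synthetic cohort.

    Defaults mirror a 48-trio exome design with mean depth 38.5x and a
    ~1.5:1 transition:transversion weight among new mutations; ``mu`` and
    ``n_sites`` are set to a desk-scale regime (1e-4 over 5e4 sites) so a
    default run yields a few hundred events rather than the near-zero
    expectation a whole-exome rate would give at this site count.
    """

    n_trios: int = 48
    n_sites: int = 50_000
    mu: float = 1e-4
    mean_depth: float = 38.5
    error_rate: float = 0.01
    maf_alpha: float = 0.5
    maf_beta: float = 2.0
    indel_fraction: float = 0.03
    ts_tv_weight: float = 1.5
    mosaic_rate: float = 0.0
    paternal_age_slope: float = 0.0
    perfect_calls: bool = False
    seed: int = 0
    n_chromosomes: int = 22
    feature_tracks: dict[str, FeatureTrack] = field(default_factory=default_feature_tracks)

    def validate(self) -> None:
        if not (0.0 <= self.mu < 1.0):
            raise ValueError("mu must be in [0, 1)")
        if self.n_trios < 1 or self.n_sites < 1:
            raise ValueError("n_trios and n_sites must be positive")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not (0.0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        if not (0.0 <= self.indel_fraction <= 1.0):
            raise ValueError("indel_fraction must be in [0, 1]")
        if self.ts_tv_weight <= 0:
            raise ValueError("ts_tv_weight must be positive")
        if not (0.0 <= self.mosaic_rate < 1.0):
            raise ValueError("mosaic_rate must be in [0, 1)")
        if self.maf_alpha <= 0 or self.maf_beta <= 0:
            raise ValueError("Beta shape parameters must be positive")
        for name, track in self.feature_tracks.items():
            if name not in ALL_FEATURES:
                raise ValueError(f"unknown feature {name!r}")
            # FeatureTrack validates its own fields on construction
            _ = track


@dataclass
class TrioArrays:
    """Per-trio evidence matrices, shape (n_sites, 3); columns are
    child, mother, father."""

    true_gt: np.ndarray  # int8, alt-allele counts 0/1/2
    called_gt: np.ndarray  # int8, -1 = missing
    depth: np.ndarray  # int32
    ref_reads: np.ndarray  # int32
    alt_reads: np.ndarray  # int32
    gq: np.ndarray  # int16

    def copy(self) -> "TrioArrays":
        return TrioArrays(*(a.copy() for a in (
            self.true_gt, self.called_gt, self.depth,
            self.ref_reads, self.alt_reads, self.gq,
        )))

    def equals(self, other: "TrioArrays") -> bool:
        return all(
            np.array_equal(a, b)
            for a, b in (
                (self.true_gt, other.true_gt),
                (self.called_gt, other.called_gt),
                (self.depth, other.depth),
                (self.ref_reads, other.ref_reads),
                (self.alt_reads, other.alt_reads),
                (self.gq, other.gq),
            )
        )


@dataclass
class TrioDataset:
    """A simulated cohort: site manifest, per-trio evidence, truth table."""

    config: SimulationConfig
    sites: pd.DataFrame  # chrom,pos,ref,alt,is_snv,maf,gerp,<flags>,mu_mult
    chrom_table: pd.DataFrame  # chrom,length,n_genes
    trios: list[Trio]
    evidence: dict[str, TrioArrays]
    ground_truth: pd.DataFrame
    intervals: dict[str, list[tuple[str, int, int]]]  # feature -> BED rows

    # -- access ------------------------------------------------------------

    def records(self, trio_id: str) -> Iterator[TrioSiteRecord]:
        """Yield TrioSiteRecord objects for one trio, in site order."""
        arr = self.evidence[trio_id]
        sites = self.sites
        chroms = sites["chrom"].to_numpy()
        poss = sites["pos"].to_numpy()
        refs = sites["ref"].to_numpy()
        alts = sites["alt"].to_numpy()
        for j in range(len(sites)):
            members = []
            for col in range(3):
                gt = _GT_CODE[int(arr.called_gt[j, col])]
                depth = int(arr.depth[j, col])
                if gt is Genotype.MISSING or depth == 0:
                    members.append(SampleEvidence(Genotype.MISSING))
                else:
                    members.append(
                        SampleEvidence(
                            gt,
                            depth,
                            int(arr.ref_reads[j, col]),
                            int(arr.alt_reads[j, col]),
                            float(arr.gq[j, col]),
                        )
                    )
            yield TrioSiteRecord(
                chrom=str(chroms[j]),
                pos=int(poss[j]),
                ref=str(refs[j]),
                alt=str(alts[j]),
                child=members[0],
                mother=members[1],
                father=members[2],
                trio_id=trio_id,
            )

    # -- serialisation -----------------------------------------------------

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write VCFs (one per trio), pedigree, BED tracks, score tables,
        the chromosome table and the ground truth; return the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        ped = out / "pedigree.tsv"
        write_pedigree(self.trios, ped)
        paths["pedigree"] = ped

        for trio in self.trios:
            vcf_path = out / f"{trio.trio_id}.vcf"
            self._write_trio_vcf(trio, vcf_path)
            paths[f"vcf:{trio.trio_id}"] = vcf_path

        for feature in INTERVAL_FEATURES:
            bed = out / f"{feature}.bed"
            with open(bed, "w") as fh:
                for chrom, start, end in self.intervals[feature]:
                    fh.write(f"{chrom}\t{start}\t{end}\n")
            paths[f"track:{feature}"] = bed

        gerp = out / "gerp_scores.tsv"
        with open(gerp, "w") as fh:
            fh.write("#chrom\tpos\tgerp\n")
            for chrom, pos, score in zip(
                self.sites["chrom"], self.sites["pos"], self.sites["gerp"]
            ):
                fh.write(f"{chrom}\t{pos}\t{score:.3f}\n")
        paths["gerp"] = gerp

        expr = out / "expression_flags.tsv"
        with open(expr, "w") as fh:
            fh.write("#chrom\tpos\tnonspecific_expression\n")
            for chrom, pos, flag in zip(
                self.sites["chrom"], self.sites["pos"],
                self.sites["nonspecific_expression"],
            ):
                fh.write(f"{chrom}\t{pos}\t{int(flag)}\n")
        paths["expression"] = expr

        chrom_path = out / "chromosomes.tsv"
        self.chrom_table.to_csv(chrom_path, sep="\t", index=False)
        paths["chromosomes"] = chrom_path

        truth = out / "ground_truth.tsv"
        self.ground_truth.to_csv(truth, sep="\t", index=False)
        paths["ground_truth"] = truth
        return paths

    def _write_trio_vcf(self, trio: Trio, path: Path) -> None:
        arr = self.evidence[trio.trio_id]
        sites = self.sites
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=dnmkit-synthetic\n")
            for _, row in self.chrom_table.iterrows():
                fh.write(f"##contig=<ID={row['chrom']},length={row['length']}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
            fh.write(
                '##FORMAT=<ID=AD,Number=R,Type=Integer,'
                'Description="Allelic depths for the ref and alt alleles">\n'
            )
            fh.write(
                '##FORMAT=<ID=GQ,Number=1,Type=Integer,'
                'Description="Genotype quality">\n'
            )
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                f"{trio.child_id}\t{trio.mother_id}\t{trio.father_id}\n"
            )
            gt_str = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
            chroms = sites["chrom"].to_numpy()
            poss = sites["pos"].to_numpy()
            refs = sites["ref"].to_numpy()
            alts = sites["alt"].to_numpy()
            for j in range(len(sites)):
                cols = []
                for col in range(3):
                    g = int(arr.called_gt[j, col])
                    d = int(arr.depth[j, col])
                    if g < 0 or d == 0:
                        cols.append("./.:.:.:.")
                    else:
                        cols.append(
                            f"{gt_str[g]}:{d}:{int(arr.ref_reads[j, col])},"
                            f"{int(arr.alt_reads[j, col])}:{int(arr.gq[j, col])}"
                        )
                fh.write(
                    f"{chroms[j]}\t{poss[j]}\t.\t{refs[j]}\t{alts[j]}\t.\t.\t.\t"
                    "GT:DP:AD:GQ\t" + "\t".join(cols) + "\n"
                )


# ---------------------------------------------------------------------------
# Generation


def _chromosome_layout(config: SimulationConfig, rng: np.random.Generator):
    """Chromosome names, lengths (~20x the site count spread over
    decreasing lengths) and per-chromosome site allocations."""
    n_chrom = config.n_chromosomes
    weights = np.arange(n_chrom, 0, -1, dtype=float)
    weights /= weights.sum()
    genome = 20 * config.n_sites
    lengths = np.maximum((weights * genome).astype(int), config.n_sites // n_chrom + 10)
    alloc = np.floor(weights * config.n_sites).astype(int)
    alloc[0] += config.n_sites - alloc.sum()
    names = [f"chr{i + 1}" for i in range(n_chrom)]
    n_genes = rng.poisson(lengths * 0.01) + 1
    return names, lengths, alloc, n_genes


def _interval_union(
    chrom_names: list[str],
    lengths: np.ndarray,
    fraction: float,
    rng: np.random.Generator,
    mean_len: float = 400.0,
) -> list[tuple[str, int, int]]:
    """Random non-overlapping interval union covering ~``fraction`` of the
    genome: alternating exponential gaps and interval lengths."""
    if fraction <= 0:
        return []
    intervals: list[tuple[str, int, int]] = []
    mean_gap = mean_len * (1.0 - fraction) / max(fraction, 1e-9)
    for chrom, length in zip(chrom_names, lengths):
        cursor = 0
        while cursor < length:
            gap = int(rng.exponential(mean_gap)) + 1
            start = cursor + gap
            if start >= length:
                break
            size = int(rng.exponential(mean_len)) + 1
            end = min(start + size, int(length))
            intervals.append((chrom, start, end))
            cursor = end
    return intervals


def _flags_from_intervals(
    chrom: np.ndarray, pos: np.ndarray, intervals: list[tuple[str, int, int]]
) -> np.ndarray:
    """Membership flags of 1-based positions in BED intervals (vectorised
    per chromosome with searchsorted over non-overlapping intervals)."""
    flags = np.zeros(len(pos), dtype=np.int8)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in intervals:
        by_chrom.setdefault(c, []).append((s, e))
    for c, ivs in by_chrom.items():
        ivs.sort()
        starts = np.array([s for s, _ in ivs])
        ends = np.array([e for _, e in ivs])
        mask = chrom == c
        p0 = pos[mask] - 1  # 0-based point
        idx = np.searchsorted(starts, p0, side="right") - 1
        inside = (idx >= 0) & (p0 < ends[np.clip(idx, 0, None)])
        flags[np.where(mask)[0][inside]] = 1
    return flags


def _draw_alleles(
    n_snv: int, n_indel: int, ts_tv_weight: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Ref/alt allele pairs: SNVs with the configured transition:
    transversion weight, indels as short insertions/deletions."""
    refs: list[str] = []
    alts: list[str] = []
    ref_snv = rng.choice(_BASES, n_snv)
    is_ts = rng.random(n_snv) < ts_tv_weight / (ts_tv_weight + 1.0)
    tv_pick = rng.integers(0, 2, n_snv)
    for r, ts, tv in zip(ref_snv, is_ts, tv_pick):
        refs.append(r)
        alts.append(_TRANSITION[r] if ts else _TRANSVERSIONS[r][tv])
    anchor = rng.choice(_BASES, n_indel)
    ins = rng.random(n_indel) < 0.5
    tail_len = rng.integers(1, 4, n_indel)
    tails = ["".join(rng.choice(_BASES, int(t))) for t in tail_len]
    for b, i, tail in zip(anchor, ins, tails):
        if i:
            refs.append(b)
            alts.append(b + tail)
        else:
            refs.append(b + tail)
            alts.append(b)
    return np.array(refs, dtype=object), np.array(alts, dtype=object)


def _simulate_reads(
    true_gt: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> TrioArrays:
    """Read evidence + re-called genotypes for one trio's (n, 3) truth."""
    n = true_gt.shape[0]
    if config.perfect_calls:
        depth = np.full((n, 3), PERFECT_DEPTH, dtype=np.int32)
        alt = np.where(true_gt == 1, PERFECT_DEPTH // 2, 0).astype(np.int32)
        alt[true_gt == 2] = PERFECT_DEPTH
        ref = depth - alt
        called = true_gt.astype(np.int8)
        gq = np.full((n, 3), 99, dtype=np.int16)
        return TrioArrays(true_gt.astype(np.int8), called, depth, ref, alt, gq)

    eps = config.error_rate
    depth = rng.poisson(config.mean_depth, size=(n, 3)).astype(np.int32)
    p_alt = np.choose(true_gt, [eps, 0.5, 1.0 - eps])
    alt = rng.binomial(depth, p_alt).astype(np.int32)
    ref = depth - alt

    # genotype re-calling under the same read model, uniform prior
    l_eps, l_1me, l_half = (
        math.log10(max(eps, 1e-12)),
        math.log10(1.0 - eps),
        math.log10(0.5),
    )
    ll = np.stack(
        [
            ref * l_1me + alt * l_eps,
            (ref + alt) * l_half,
            ref * l_eps + alt * l_1me,
        ],
        axis=-1,
    )
    order = np.argsort(ll, axis=-1)
    called = order[..., 2].astype(np.int8)
    best = np.take_along_axis(ll, order[..., 2:3], axis=-1)[..., 0]
    second = np.take_along_axis(ll, order[..., 1:2], axis=-1)[..., 0]
    gq = np.minimum(np.rint(10.0 * (best - second)), 99).astype(np.int16)
    called[depth == 0] = -1
    gq[depth == 0] = 0
    return TrioArrays(true_gt.astype(np.int8), called, depth, ref, alt, gq)


def simulate_trio_dataset(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> TrioDataset:
    """Simulate a trio cohort; optionally write all files to ``out_dir``.

    Deterministic for a fixed config (seed included): running twice
    produces identical in-memory arrays and byte-identical files.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    chrom_names, lengths, alloc, n_genes = _chromosome_layout(config, rng)
    chrom_col: list[str] = []
    pos_col: list[np.ndarray] = []
    for name, length, n_c in zip(chrom_names, lengths, alloc):
        pos = np.sort(rng.choice(int(length), size=int(n_c), replace=False)) + 1
        chrom_col.extend([name] * int(n_c))
        pos_col.append(pos)
    chrom = np.array(chrom_col)
    pos = np.concatenate(pos_col)
    n_sites = len(pos)

    n_indel = int(round(config.indel_fraction * n_sites))
    is_snv = np.ones(n_sites, dtype=bool)
    if n_indel:
        is_snv[rng.choice(n_sites, size=n_indel, replace=False)] = False
    refs = np.empty(n_sites, dtype=object)
    alts = np.empty(n_sites, dtype=object)
    n_snv = int(is_snv.sum())
    all_refs, all_alts = _draw_alleles(n_snv, n_indel, config.ts_tv_weight, rng)
    refs[is_snv] = all_refs[:n_snv]
    alts[is_snv] = all_alts[:n_snv]
    refs[~is_snv] = all_refs[n_snv:]
    alts[~is_snv] = all_alts[n_snv:]

    maf = rng.beta(config.maf_alpha, config.maf_beta, n_sites)

    # context features
    intervals: dict[str, list[tuple[str, int, int]]] = {}
    flags: dict[str, np.ndarray] = {}
    for feature in INTERVAL_FEATURES:
        track = config.feature_tracks.get(feature, FeatureTrack(0.0))
        intervals[feature] = _interval_union(chrom_names, lengths, track.coverage, rng)
        flags[feature] = _flags_from_intervals(chrom, pos, intervals[feature])
    cons_frac = config.feature_tracks.get("conserved", FeatureTrack(0.0)).coverage
    conserved = (rng.random(n_sites) < cons_frac).astype(np.int8)
    gerp = np.where(
        conserved == 1,
        rng.uniform(12.01, 25.0, n_sites),
        rng.uniform(-12.0, 11.99, n_sites),
    )
    flags["conserved"] = conserved
    expr_frac = config.feature_tracks.get(
        "nonspecific_expression", FeatureTrack(0.0)
    ).coverage
    flags["nonspecific_expression"] = (rng.random(n_sites) < expr_frac).astype(np.int8)

    mu_mult = np.ones(n_sites)
    for feature in ALL_FEATURES:
        track = config.feature_tracks.get(feature)
        if track is not None and track.multiplier != 1.0:
            mu_mult *= np.where(flags[feature] == 1, track.multiplier, 1.0)

    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "ref": refs,
            "alt": alts,
            "is_snv": is_snv,
            "maf": maf,
            "gerp": gerp,
            "mu_mult": mu_mult,
            **{f: flags[f] for f in ALL_FEATURES},
        }
    )
    chrom_table = pd.DataFrame(
        {"chrom": chrom_names, "length": lengths, "n_genes": n_genes}
    )

    # trios + ages
    trios: list[Trio] = []
    width = max(2, len(str(config.n_trios)))
    mother_ages = np.clip(rng.normal(29.0, 4.0, config.n_trios), 18, 45).round(1)
    father_ages = np.clip(rng.normal(32.0, 5.0, config.n_trios), 18, 55).round(1)
    for i in range(config.n_trios):
        tid = f"trio{i + 1:0{width}d}"
        trios.append(
            Trio(
                tid,
                f"{tid}_c",
                f"{tid}_m",
                f"{tid}_f",
                float(mother_ages[i]),
                float(father_ages[i]),
            )
        )

    evidence: dict[str, TrioArrays] = {}
    truth_rows: list[dict] = []
    config_names = {
        (0, 0): "het_child_homref_parents",
        (2, 2): "het_child_homalt_parents",
    }

    for i, trio in enumerate(trios):
        g_mother = rng.binomial(2, maf)
        g_father = rng.binomial(2, maf)
        t_mother = (rng.random(n_sites) < g_mother / 2.0).astype(np.int8)
        t_father = (rng.random(n_sites) < g_father / 2.0).astype(np.int8)

        age_mult = (
            math.exp(config.paternal_age_slope * (float(father_ages[i]) - 32.0))
            if config.paternal_age_slope
            else 1.0
        )
        mu_site = np.minimum(config.mu * mu_mult * age_mult, 0.5)
        flip_m = rng.random(n_sites) < mu_site
        flip_f = rng.random(n_sites) < mu_site
        t_mother = np.where(flip_m, 1 - t_mother, t_mother).astype(np.int8)
        t_father = np.where(flip_f, 1 - t_father, t_father).astype(np.int8)
        child = (t_mother + t_father).astype(np.int8)

        for hap, flip in (("maternal", flip_m), ("paternal", flip_f)):
            for j in np.flatnonzero(flip):
                cfg = config_names.get(
                    (int(g_mother[j]), int(g_father[j])), "undetectable"
                )
                truth_rows.append(
                    {
                        "trio_id": trio.trio_id,
                        "chrom": chrom[j],
                        "pos": int(pos[j]),
                        "ref": refs[j],
                        "alt": alts[j],
                        "variant_class": "SNV" if is_snv[j] else "indel",
                        "config": cfg,
                        "haplotype": hap,
                    }
                )

        true_gt = np.stack([child, g_mother.astype(np.int8), g_father.astype(np.int8)], axis=1)
        arrays = _simulate_reads(true_gt, config, rng)

        if config.mosaic_rate > 0 and not config.perfect_calls:
            # low-allele-balance artifacts: child truly HomR, miscalled Het
            eligible = np.flatnonzero(
                (true_gt[:, 0] == 0) & (g_mother == 0) & (g_father == 0)
            )
            chosen = eligible[rng.random(len(eligible)) < config.mosaic_rate]
            d = arrays.depth[chosen, 0]
            mosaic_alt = rng.binomial(d, 0.15).astype(np.int32)
            arrays.alt_reads[chosen, 0] = mosaic_alt
            arrays.ref_reads[chosen, 0] = d - mosaic_alt
            arrays.called_gt[chosen, 0] = 1
            arrays.gq[chosen, 0] = 99

        evidence[trio.trio_id] = arrays

    ground_truth = pd.DataFrame(
        truth_rows,
        columns=[
            "trio_id", "chrom", "pos", "ref", "alt",
            "variant_class", "config", "haplotype",
        ],
    )

    dataset = TrioDataset(
        config=config,
        sites=sites,
        chrom_table=chrom_table,
        trios=trios,
        evidence=evidence,
        ground_truth=ground_truth,
        intervals=intervals,
    )
    if out_dir is not None:
        dataset.write(out_dir)
    return dataset


def synthesize_predictor_calls(
    candidates,
    rng: np.random.Generator,
    pathogenic_fraction: float = 0.1,
    out_path: str | Path | None = None,
) -> pd.DataFrame:
    """Categorical deleteriousness calls from ten in-silico predictors for
    a set of candidate DNMs.

    A ``pathogenic_fraction`` of variants are drawn as truly deleterious
    (each tool then votes damaging with probability 0.8), the rest as
    benign (damaging with probability 0.1); each call is independently
    unknown with probability 0.05. A conservation score is emitted in a
    ``GERP`` column.
    """
    from .impact import PREDICTORS

    rows = []
    for c in candidates:
        pathogenic = rng.random() < pathogenic_fraction
        p_dmg = 0.8 if pathogenic else 0.1
        row = {
            "trio_id": c.trio_id,
            "chrom": c.chrom,
            "pos": c.pos,
            "ref": c.ref,
            "alt": c.alt,
        }
        for name in PREDICTORS:
            u = rng.random()
            if u < 0.05:
                row[name] = "."
            elif rng.random() < p_dmg:
                row[name] = "D" if rng.random() < 0.7 else "P"
            else:
                row[name] = "T"
        row["GERP"] = round(float(rng.uniform(2.0, 6.0) if pathogenic else rng.uniform(-3.0, 3.0)), 2)
        rows.append(row)
    columns = ["trio_id", "chrom", "pos", "ref", "alt", *PREDICTORS, "GERP"]
    table = pd.DataFrame(rows, columns=columns)
    if out_path is not None:
        table.to_csv(out_path, sep="\t", index=False)
    return table


# ---------------------------------------------------------------------------
# Reversible indels


@dataclass(frozen=True)
class _ReversalToken:
    trio_id: str
    site_index: int
    previous: tuple  # saved evidence row + truth length


def find_reversible_indel_sites(dataset: TrioDataset, trio_id: str) -> np.ndarray:
    """Indices of indel sites where both parents are truly homozygous for
    the alternative (indel) allele in the given trio."""
    arr = dataset.evidence[trio_id]
    is_indel = ~dataset.sites["is_snv"].to_numpy()
    return np.flatnonzero(is_indel & (arr.true_gt[:, 1] == 2) & (arr.true_gt[:, 2] == 2))


def inject_reversible_indel(
    dataset: TrioDataset, trio_id: str, site_index: int
) -> _ReversalToken:
    """Force the child homozygous-reference at an indel site where both
    parents are homozygous-alternative: the child reverts to the
    reference, which is a de novo event relative to the parents.

    Returns a token that :func:`remove_reversible_indel` uses to restore
    the dataset exactly.
    """
    arr = dataset.evidence[trio_id]
    sites = dataset.sites
    if bool(sites["is_snv"].iloc[site_index]):
        raise ValueError("reversible-indel injection requires an indel site")
    if arr.true_gt[site_index, 1] != 2 or arr.true_gt[site_index, 2] != 2:
        raise ValueError("both parents must be homozygous-alternative at the site")

    token = _ReversalToken(
        trio_id,
        site_index,
        (
            arr.true_gt[site_index].copy(),
            arr.called_gt[site_index].copy(),
            arr.depth[site_index].copy(),
            arr.ref_reads[site_index].copy(),
            arr.alt_reads[site_index].copy(),
            arr.gq[site_index].copy(),
            len(dataset.ground_truth),
        ),
    )
    depth = max(int(round(dataset.config.mean_depth)), 21)
    arr.true_gt[site_index, 0] = 0
    arr.called_gt[site_index, 0] = 0
    arr.depth[site_index, 0] = depth
    arr.ref_reads[site_index, 0] = depth
    arr.alt_reads[site_index, 0] = 0
    arr.gq[site_index, 0] = 99
    dataset.ground_truth.loc[len(dataset.ground_truth)] = {
        "trio_id": trio_id,
        "chrom": sites["chrom"].iloc[site_index],
        "pos": int(sites["pos"].iloc[site_index]),
        "ref": sites["ref"].iloc[site_index],
        "alt": sites["alt"].iloc[site_index],
        "variant_class": "indel",
        "config": "reversible_indel",
        "haplotype": "both",
    }
    return token


def remove_reversible_indel(dataset: TrioDataset, token: _ReversalToken) -> None:
    """Undo :func:`inject_reversible_indel`, restoring the dataset."""
    arr = dataset.evidence[token.trio_id]
    (true_gt, called, depth, ref, alt, gq, truth_len) = token.previous
    arr.true_gt[token.site_index] = true_gt
    arr.called_gt[token.site_index] = called
    arr.depth[token.site_index] = depth
    arr.ref_reads[token.site_index] = ref
    arr.alt_reads[token.site_index] = alt
    arr.gq[token.site_index] = gq
    dataset.ground_truth.drop(
        dataset.ground_truth.index[truth_len:], inplace=True
    )
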