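"""Format I/O: pedigree, VCF decomposition, BED membership, report round-trip."""

import pytest

from dnmkit.detection import CandidateDNM
from dnmkit.variant_io import (
    GenomeIntervals,
    Genotype,
    SampleEvidence,
    Trio,
    TrioSiteRecord,
    read_dnm_report,
    read_interval_track,
    read_pedigree,
    read_trio_vcf,
    write_dnm_report,
    write_pedigree,
)

TRIO = Trio("t1", "c1", "m1", "f1", 28, 31)


class TestPedigree:
    def test_parse_line_with_ages(self, tmp_path):
        ped = tmp_path / "ped.tsv"
        ped.write_text("t1\tc1\tm1\tf1\t28\t31\n")
        (trio,) = read_pedigree(ped)
        assert trio == Trio("t1", "c1", "m1", "f1", 28.0, 31.0)

    def test_ages_optional(self, tmp_path):
        ped = tmp_path / "ped.tsv"
        ped.write_text("t1\tc1\tm1\tf1\n")
        (trio,) = read_pedigree(ped)
        assert trio.mother_age is None and trio.father_age is None

    def test_child_as_own_parent_rejected(self, tmp_path):
        ped = tmp_path / "ped.tsv"
        ped.write_text("t1\tc1\tc1\tf1\n")
        with pytest.raises(ValueError, match="distinct"):
            read_pedigree(ped)

    def test_duplicate_trio_id_rejected(self, tmp_path):
        ped = tmp_path / "ped.tsv"
        ped.write_text("t1\tc1\tm1\tf1\nt1\tc2\tm2\tf2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_pedigree(ped)

    def test_count_and_order_preserved(self, tmp_path):
        ped = tmp_path / "ped.tsv"
        lines = [f"t{i}\tc{i}\tm{i}\tf{i}\t25\t30" for i in range(48)]
        ped.write_text("\n".join(lines) + "\n")
        trios = read_pedigree(ped)
        assert len(trios) == 48
        assert [t.trio_id for t in trios] == [f"t{i}" for i in range(48)]

    def test_write_read_round_trip(self, tmp_path):
        trios = [TRIO, Trio("t2", "c2", "m2", "f2")]
        path = tmp_path / "out.tsv"
        write_pedigree(trios, path)
        assert read_pedigree(path) == trios

    def test_age_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="age"):
            Trio("t1", "c1", "m1", "f1", mother_age=5)


def _write_vcf(path, body, samples=("c1", "m1", "f1")):
    header = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr1,length=100000>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">\n'
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="q">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
        + "\n"
    )
    path.write_text(header + body)
    return path


class TestTrioVCF:
    def test_basic_genotype_mapping(self, tmp_path):
        vcf = _write_vcf(
            tmp_path / "a.vcf",
            "chr1\t100\t.\tA\tG\t.\t.\t.\tGT:DP:AD:GQ\t"
            "0/1:40:20,20:99\t0/0:38:38,0:99\t0/0:35:35,0:99\n",
        )
        (rec,) = list(read_trio_vcf(vcf, TRIO))
        assert (rec.child.genotype, rec.mother.genotype, rec.father.genotype) == (
            Genotype.HET,
            Genotype.HOM_REF,
            Genotype.HOM_REF,
        )
        assert rec.child.allele_balance == pytest.approx(0.5)
        assert rec.pos == 100 and rec.ref == "A" and rec.alt == "G"

    def test_multiallelic_decomposition(self, tmp_path):
        vcf = _write_vcf(
            tmp_path / "m.vcf",
            "chr1\t200\t.\tA\tC,T\t.\t.\t.\tGT:DP:AD:GQ\t"
            "1/2:40:0,20,20:99\t0/1:38:19,19,0:99\t0/2:35:18,0,17:99\n",
        )
        recs = list(read_trio_vcf(vcf, TRIO))
        assert len(recs) == 2
        assert [r.alt for r in recs] == ["C", "T"]
        # child 1/2 relative to alt C: one C allele -> Het; other alt counts ref-like
        assert recs[0].child.genotype is Genotype.HET
        assert recs[1].child.genotype is Genotype.HET
        # mother 0/1: Het for C, HomR for T
        assert recs[0].mother.genotype is Genotype.HET
        assert recs[1].mother.genotype is Genotype.HOM_REF

    def test_decomposition_conserves_alt_count(self, tmp_path, small_dataset):
        ds = small_dataset
        out = tmp_path / "sim"
        paths = ds.write(out)
        trio = ds.trios[0]
        recs = list(read_trio_vcf(paths[f"vcf:{trio.trio_id}"], trio))
        # generator emits biallelic sites: one record per manifest site
        assert len(recs) == len(ds.sites)

    def test_round_trip_against_generator(self, tmp_path, small_dataset):
        """Records read back from a written VCF match the in-memory ones."""
        ds = small_dataset
        paths = ds.write(tmp_path / "sim")
        trio = ds.trios[1]
        from_file = list(read_trio_vcf(paths[f"vcf:{trio.trio_id}"], trio))
        in_memory = list(ds.records(trio.trio_id))
        assert len(from_file) == len(in_memory)
        for a, b in zip(from_file, in_memory):
            assert (a.chrom, a.pos, a.ref, a.alt) == (b.chrom, b.pos, b.ref, b.alt)
            assert a.child == b.child and a.mother == b.mother and a.father == b.father

    def test_missing_sample_is_hard_error(self, tmp_path):
        vcf = _write_vcf(
            tmp_path / "s.vcf",
            "chr1\t100\t.\tA\tG\t.\t.\t.\tGT:DP:AD:GQ\t0/0:30:30,0:99\t0/0:30:30,0:99\n",
            samples=("c1", "m1"),
        )
        with pytest.raises(ValueError, match="f1"):
            list(read_trio_vcf(vcf, TRIO))

    def test_missing_format_field_gives_missing_genotype(self, tmp_path):
        vcf = _write_vcf(
            tmp_path / "g.vcf",
            "chr1\t100\t.\tA\tG\t.\t.\t.\tGT:DP\t0/1:40\t0/0:38\t0/0:35\n",
        )
        (rec,) = list(read_trio_vcf(vcf, TRIO))
        assert rec.has_missing()


class TestIntervalTrack:
    def test_half_open_boundaries(self, tmp_path):
        bed = tmp_path / "t.bed"
        bed.write_text("chr1\t99\t200\n")
        track = read_interval_track(bed)
        assert track.contains("chr1", 100)  # first base of the interval
        assert not track.contains("chr1", 99)  # before it
        assert track.contains("chr1", 200)  # last base
        assert not track.contains("chr1", 201)

    def test_unknown_chromosome_outside(self, tmp_path):
        bed = tmp_path / "t.bed"
        bed.write_text("chr1\t0\t10\n")
        assert not read_interval_track(bed).contains("chr2", 5)

    def test_empty_interval_skipped_with_warning(self, tmp_path):
        bed = tmp_path / "t.bed"
        bed.write_text("chr1\t50\t50\nchr1\t10\t20\n")
        with pytest.warns(UserWarning):
            track = read_interval_track(bed)
        assert track.contains("chr1", 15)
        assert not track.contains("chr1", 50)

    def test_membership_matches_linear_scan(self, rng):
        """10,000 random intervals / queries vs a brute-force oracle."""
        intervals = []
        track = GenomeIntervals()
        for _ in range(10_000):
            chrom = f"chr{rng.integers(1, 4)}"
            start = int(rng.integers(0, 100_000))
            end = start + int(rng.integers(1, 500))
            intervals.append((chrom, start, end))
            track.add(chrom, start, end)
        for _ in range(10_000):
            chrom = f"chr{rng.integers(1, 4)}"
            pos = int(rng.integers(1, 100_500))
            brute = any(
                c == chrom and s < pos <= e for c, s, e in intervals
            )
            assert track.contains(chrom, pos) == brute


class TestDnmReport:
    CANDS = [
        CandidateDNM("t2", "chr1", 500, "A", "G", "SNV",
                     "het_child_homref_parents", "A>G", "transition", "PASS"),
        CandidateDNM("t1", "chr2", 100, "AC", "A", "indel",
                     "reversible_indel", None, "NA", "PASS"),
        CandidateDNM("t1", "chr1", 900, "C", "A", "SNV",
                     "het_child_homalt_parents", "C>A", "transversion", "min_gq"),
    ]

    def test_empty_list_writes_header_only(self, tmp_path):
        path = tmp_path / "r.tsv"
        write_dnm_report([], path)
        assert path.read_text().count("\n") == 1

    def test_row_count_and_ordering(self, tmp_path):
        path = tmp_path / "r.tsv"
        write_dnm_report(self.CANDS, path)
        lines = path.read_text().strip().split("\n")
        assert len(lines) == 4
        first = lines[1].split("\t")
        assert (first[0], first[1]) == ("t1", "chr1")

    def test_round_trip_identity(self, tmp_path):
        path = tmp_path / "r.tsv"
        write_dnm_report(self.CANDS, path)
        back = read_dnm_report(path)
        assert sorted(back, key=lambda c: c.key) == sorted(
            self.CANDS, key=lambda c: c.key
        )


class TestEvidenceInvariants:
    def test_reads_cannot_exceed_depth(self):
        with pytest.raises(ValueError):
            SampleEvidence(Genotype.HET, depth=10, ref_reads=8, alt_reads=5)

    def test_called_genotype_requires_depth(self):
        with pytest.raises(ValueError):
            SampleEvidence(Genotype.HET, depth=0)

    def test_record_requires_distinct_alleles(self):
        ev = SampleEvidence(Genotype.HOM_REF, 30, 30, 0, 99)
        with pytest.raises(ValueError):
            TrioSiteRecord("chr1", 10, "A", "A", ev, ev, ev)
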