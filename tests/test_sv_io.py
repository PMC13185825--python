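"""I/O, merging, missingness, novelty and saturation behaviour."""

import numpy as np
import pytest

from repsv import sv_io
from repsv.sv_io import (
    SVCallSet,
    SVRecord,
    filter_missingness,
    merge_callsets,
    novelty_filter,
    read_repeat_annotation,
    read_sv_vcf,
    saturation_curve,
    write_repeat_annotation,
    write_sv_vcf,
)

VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=1000000>
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="l">
##INFO=<ID=END,Number=1,Type=Integer,Description="e">
##FORMAT=<ID=GT,Number=1,Type=String,Description="g">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2
1\t5000\tdel1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;SVLEN=-120;END=5119\tGT\t0/1\t./.
1\t6000\tins1\tN\t<INS>\t.\tPASS\tSVTYPE=INS;SVLEN=300\tGT\t1/1\t0/0
1\t7000\tdel2\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=7099\tGT\t0/1\t0/1
1\t8000\tbnd1\tN\t<BND>\t.\tPASS\tSVTYPE=BND\tGT\t0/1\t0/1
1\t9000\tdel3\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL\tGT\t0/1\t0/1
"""


def _rec(chrom="1", pos=1000, end=None, svtype="DEL", svlen=100, id=".",
         gt=None, source="a"):
    if end is None:
        end = pos if svtype == "INS" else pos + svlen - 1
    return SVRecord(chrom, pos, end, svtype, svlen, id,
                    None if gt is None else np.array(gt, dtype=np.int8),
                    frozenset({source}), source)


class TestReadVCF:
    def test_parsing_and_conventions(self, tmp_path):
        p = tmp_path / "t.vcf"
        p.write_text(VCF_TEXT)
        cs = read_sv_vcf(p)
        # BND skipped, del3 lacks SVLEN and END -> skipped
        assert [r.id for r in cs.records] == ["del1", "ins1", "del2"]
        assert cs.n_skipped == 2
        del1 = cs.records[0]
        assert del1.svlen == 120 and del1.pos == 5000 and del1.end == 5119
        ins1 = cs.records[1]
        assert ins1.svlen == 300 and ins1.pos == 6000 and ins1.end == 6000
        del2 = cs.records[2]  # END-only record
        assert del2.svlen == 100
        # genotypes: 0/1 -> 1, ./. -> -1, 1/1 -> 2, 0/0 -> 0
        assert list(del1.genotypes) == [1, -1]
        assert list(ins1.genotypes) == [2, 0]

    def test_round_trip_preserves_records(self, tmp_path, small_cohort):
        p1 = tmp_path / "a.vcf"
        p2 = tmp_path / "b.vcf"
        write_sv_vcf(small_cohort.cohort, p1, contigs=list(small_cohort.genome.chromosomes))
        back = read_sv_vcf(p1)
        assert back.samples == small_cohort.cohort.samples
        for r0, r1 in zip(small_cohort.cohort.records, back.records):
            assert (r0.chrom, r0.pos, r0.end, r0.svtype, r0.svlen) == \
                   (r1.chrom, r1.pos, r1.end, r1.svtype, r1.svlen)
            assert np.array_equal(r0.genotypes, r1.genotypes)
        write_sv_vcf(back, p2, contigs=list(small_cohort.genome.chromosomes))
        assert p1.read_bytes() == p2.read_bytes()


class TestRepeatAndGeneIO:
    def test_rmout_coordinate_convention(self, tmp_path, small_cohort):
        p = tmp_path / "r.out"
        write_repeat_annotation(small_cohort.repeats, p, "rmout")
        back = read_repeat_annotation(p, "rmout")
        assert [(f.chrom, f.start, f.end, f.rep_type) for f in back.features] == \
               [(f.chrom, f.start, f.end, f.rep_type) for f in small_cohort.repeats.features]

    def test_bed_round_trip(self, tmp_path, small_cohort):
        p = tmp_path / "r.bed"
        write_repeat_annotation(small_cohort.repeats, p, "bed")
        back = read_repeat_annotation(p, "bed")
        assert [(f.chrom, f.start, f.end, f.rep_type) for f in back.features] == \
               [(f.chrom, f.start, f.end, f.rep_type) for f in small_cohort.repeats.features]

    def test_bed_line_convention(self, tmp_path):
        p = tmp_path / "one.bed"
        p.write_text("chr1\t99\t200\tBov-A2\n")
        t = read_repeat_annotation(p, "bed")
        f = t.features[0]
        assert (f.start, f.end, f.rep_type) == (99, 200, "Bov-A2")

    def test_rmout_line_convention(self, tmp_path):
        p = tmp_path / "one.out"
        p.write_text("  463  1.3  0.6  1.7  chr1  101  200  (0)  +  L1  LINE/L1  1  100  (0)  1\n")
        f = read_repeat_annotation(p, "rmout").features[0]
        assert (f.start, f.end, f.rep_type) == (100, 200, "LINE/L1")

    def test_inverted_interval_raises(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t300\t200\tx\n")
        with pytest.raises(ValueError):
            read_repeat_annotation(p, "bed")

    def test_gff_round_trip(self, tmp_path, small_cohort):
        p = tmp_path / "g.gff3"
        sv_io.write_gene_annotation(small_cohort.genes, p)
        back = sv_io.read_gene_annotation(p)
        assert [(f.chrom, f.start, f.end, f.kind, f.gene_id) for f in back.features] == \
               [(f.chrom, f.start, f.end, f.kind, f.gene_id) for f in small_cohort.genes.features]


class TestMerge:
    def test_distance_clustering(self):
        # starts 10,000/10,500 and ends 10,300/10,800 are both within 1000 bp
        a = SVCallSet(["sA"], [_rec(pos=10_000, end=10_300, svlen=301, source="a")], "a")
        b = SVCallSet(["sB"], [_rec(pos=10_500, end=10_800, svlen=301, source="b")], "b")
        m = merge_callsets([a, b])
        assert len(m) == 1
        assert m.records[0].pos == 10_000  # smallest-tuple representative

    def test_distance_exceeded_not_merged(self):
        a = SVCallSet([], [_rec(pos=10_000, svlen=100, source="a")], "a")
        b = SVCallSet([], [_rec(pos=11_200, svlen=100, source="b")], "b")
        m = merge_callsets([a, b], min_support=1)
        assert len(m) == 2

    def test_types_must_match(self):
        a = SVCallSet([], [_rec(pos=10_000, svtype="DEL", source="a")], "a")
        b = SVCallSet([], [_rec(pos=10_000, end=10_000, svtype="INS", svlen=100, source="b")], "b")
        m = merge_callsets([a, b], min_support=1)
        assert len(m) == 2

    def test_min_length_and_cap(self):
        short = [_rec(pos=1000, svlen=49, source=s) for s in "abc"]
        big = [_rec(pos=50_000, svlen=100_001, end=150_000, source=s) for s in "abc"]
        sets = [SVCallSet([], [s, b], src) for s, b, src in zip(short, big, "abc")]
        assert len(merge_callsets(sets)) == 0

    def test_min_support(self):
        a = SVCallSet([], [_rec(pos=1000, source="a")], "a")
        m1 = merge_callsets([a], min_support=1)
        m2 = merge_callsets([a], min_support=2)
        assert len(m1) == 1 and len(m2) == 0

    def test_lower_median_length(self):
        sets = [
            SVCallSet([], [_rec(pos=1000, svlen=l, end=1000 + l - 1, source=s)], s)
            for l, s in [(100, "a"), (110, "b"), (130, "c")]
        ]
        m = merge_callsets(sets, min_support=3)
        assert m.records[0].svlen == 110
        # even member count -> lower median
        m = merge_callsets(sets[:2], min_support=2)
        assert m.records[0].svlen == 100

    def test_idempotent_and_order_invariant(self, small_cohort):
        sets = small_cohort.callsets[:6]
        m1 = merge_callsets(sets, min_support=1)
        m2 = merge_callsets(list(reversed(sets)), min_support=1)
        assert len(m1) == len(m2)
        assert [(r.chrom, r.pos, r.svtype) for r in m1.records] == \
               [(r.chrom, r.pos, r.svtype) for r in m2.records]
        again = merge_callsets([m1], min_support=1)
        assert len(again) == len(m1)


class TestFilters:
    def test_missingness_boundary(self):
        recs = [
            _rec(pos=1000, id="hi", gt=[-1, -1, -1, 1]),   # 0.75 missing
            _rec(pos=3000, id="edge", gt=[-1, -1, 1, 0]),  # 0.50 missing, kept
            _rec(pos=5000, id="ok", gt=[1, 0, 1, 0]),
        ]
        cs = SVCallSet(["a", "b", "c", "d"], recs, "x")
        out = filter_missingness(cs, max_missing=0.5)
        assert sorted(r.id for r in out.records) == ["edge", "ok"]

    def test_all_absent_dropped(self):
        recs = [_rec(pos=1000, id="gone", gt=[0, 0]), _rec(pos=3000, id="kept", gt=[1, 0])]
        cs = SVCallSet(["a", "b"], recs, "x")
        out = filter_missingness(cs, drop_all_absent=True)
        assert [r.id for r in out.records] == ["kept"]

    def test_novelty_reciprocal_boundary(self):
        q = SVCallSet([], [_rec(pos=101, end=200, svlen=100, id="q")], "q")
        pub_hit = SVCallSet([], [_rec(pos=151, end=250, svlen=100)], "p")
        pub_miss = SVCallSet([], [_rec(pos=181, end=280, svlen=100)], "p")
        novel, known = novelty_filter(q, pub_hit)
        assert [r.id for r in known.records] == ["q"]  # 50 of 100 -> exactly 0.5
        novel, known = novelty_filter(q, pub_miss)
        assert [r.id for r in novel.records] == ["q"]

    def test_novelty_ins_effective_interval(self):
        q = SVCallSet([], [_rec(pos=101, svtype="INS", svlen=100, id="q")], "q")
        pub = SVCallSet([], [_rec(pos=151, svtype="INS", svlen=100)], "p")
        novel, known = novelty_filter(q, pub)
        assert [r.id for r in known.records] == ["q"]


class TestSaturation:
    def test_identical_sets_flat(self):
        base = [_rec(pos=p, id=f"s{p}") for p in (1000, 3000, 5000)]
        sets = [SVCallSet([], list(base), s) for s in "abcd"]
        t = saturation_curve(sets, n_reps=5, seed=1)
        assert np.allclose(t["pan_mean"], 3) and np.allclose(t["core_mean"], 3)

    def test_disjoint_sets_linear_union_zero_core(self):
        sets = [
            SVCallSet([], [_rec(pos=1000 * (10 * i + j), id=f"s{i}_{j}") for j in range(4)], str(i))
            for i in range(3)
        ]
        t = saturation_curve(sets, n_reps=3, seed=1)
        assert list(t["pan_mean"]) == [4, 8, 12]
        assert list(t["core_mean"])[1:] == [0, 0]

    def test_deterministic_and_validated(self, small_cohort):
        sets = small_cohort.callsets[:5]
        t1 = saturation_curve(sets, n_reps=4, seed=9)
        t2 = saturation_curve(sets, n_reps=4, seed=9)
        assert t1.equals(t2)
        with pytest.raises(ValueError):
            saturation_curve(sets, n_reps=0, seed=1)
        with pytest.raises(ValueError):
            saturation_curve(sets[:1], n_reps=1, seed=1)
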