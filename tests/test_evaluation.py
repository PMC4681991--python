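import itertools
import random

import pysam
import pytest

from rnfkit.evaluation import (
    AlignmentObservation,
    CATEGORY_ORDER,
    EvalConfig,
    ReadCategory,
    ReadRecord,
    build_curve,
    classify,
    evaluate_alignments,
    read_alignments,
    read_curve_tsv,
    write_curve_tsv,
)
from rnfkit.model import Read, ReadTuple, RnfError, Segment, encode_lrn

CONFIG = EvalConfig(ref_genome_id=1, tolerance=5, require_strand=True,
                    chrom_ids={"chr1": 1, "chr2": 2})


def _truth(*segments):
    return ReadTuple(1, [Read(list(segments))], prefix="t")


def _obs(chrom="chr2", pos=100, reverse=False, mapq=60, mapped=True):
    return AlignmentObservation(name="x", is_mapped=mapped, chrom=chrom,
                                pos=pos, is_reverse=reverse, mapq=mapq)


class TestClassify:
    def test_exact_position_correct(self):
        truth = _truth(Segment(1, 2, "F", 100, 199))
        assert classify(_obs(), truth, CONFIG, 0) is ReadCategory.CORRECT

    def test_within_tolerance_correct(self):
        truth = _truth(Segment(1, 2, "F", 100, 199))
        assert classify(_obs(pos=105), truth, CONFIG, 0) is \
            ReadCategory.CORRECT
        assert classify(_obs(pos=106), truth, CONFIG, 0) is \
            ReadCategory.WRONG_POSITION

    def test_contaminant_mapped_anywhere(self):
        truth = _truth(Segment(2, 0, "N", 0, 0))
        assert classify(_obs(pos=12345), truth, CONFIG, 0) is \
            ReadCategory.CONTAMINANT_MAPPED

    def test_distant_position_wrong(self):
        truth = _truth(Segment(1, 2, "F", 100, 199))
        assert classify(_obs(pos=350), truth, CONFIG, 0) is \
            ReadCategory.WRONG_POSITION

    def test_wrong_strand_wrong(self):
        truth = _truth(Segment(1, 2, "F", 100, 199))
        assert classify(_obs(reverse=True), truth, CONFIG, 0) is \
            ReadCategory.WRONG_POSITION
        relaxed = EvalConfig(ref_genome_id=1, tolerance=5,
                             require_strand=False,
                             chrom_ids=CONFIG.chrom_ids)
        assert classify(_obs(reverse=True), truth, relaxed, 0) is \
            ReadCategory.CORRECT

    def test_under_threshold(self):
        truth = _truth(Segment(1, 2, "F", 100, 199))
        assert classify(_obs(mapq=10), truth, CONFIG, 30) is \
            ReadCategory.UNDER_THRESHOLD

    def test_unmapped_host_read(self):
        truth = _truth(Segment(1, 2, "F", 100, 199))
        assert classify(_obs(mapped=False), truth, CONFIG, 0) is \
            ReadCategory.SHOULD_MAP_UNMAPPED

    def test_unmapped_contaminant(self):
        truth = _truth(Segment(2, 0, "N", 0, 0))
        assert classify(_obs(mapped=False), truth, CONFIG, 0) is \
            ReadCategory.CONTAMINANT_UNMAPPED

    def test_chimeric_matches_any_segment(self):
        truth = _truth(Segment(1, 1, "F", 900, 949),
                       Segment(1, 2, "F", 100, 149))
        assert classify(_obs(chrom="chr2", pos=100), truth, CONFIG, 0) is \
            ReadCategory.CORRECT
        assert classify(_obs(chrom="chr1", pos=900), truth, CONFIG, 0) is \
            ReadCategory.CORRECT


def _record(truth, obs, name="r"):
    return ReadRecord(name=name, end=1, truth=truth, observation=obs)


class TestBuildCurve:
    def test_four_read_example(self):
        truth = _truth(Segment(1, 2, "F", 100, 199))
        records = [
            _record(truth, _obs(mapq=60), "a"),
            _record(truth, _obs(mapq=10), "b"),
            _record(truth, _obs(pos=900, mapq=60), "c"),
            _record(truth, _obs(mapped=False, mapq=0), "d"),
        ]
        curve = build_curve(records, CONFIG)
        by_q = {p.q: p for p in curve}
        assert sorted(by_q) == [0, 10, 60]
        assert by_q[0].sensitivity == pytest.approx(0.5)
        assert by_q[0].precision == pytest.approx(2 / 3)
        assert by_q[60].sensitivity == pytest.approx(0.25)
        assert by_q[60].precision == pytest.approx(0.5)

    def test_perfect_mapper(self):
        truth = [_truth(Segment(1, 2, "F", 100 + i, 199 + i))
                 for i in range(10)]
        records = [_record(t, _obs(pos=100 + i, mapq=60), f"r{i}")
                   for i, t in enumerate(truth)]
        for point in build_curve(records, CONFIG):
            assert point.sensitivity == 1.0
            assert point.fdr == 0.0

    def test_all_contaminant_unmapped(self):
        truth = _truth(Segment(2, 0, "N", 0, 0))
        records = [_record(truth, _obs(mapped=False), f"r{i}")
                   for i in range(5)]
        for point in build_curve(records, CONFIG):
            assert point.precision == 1.0 and point.fdr == 0.0

    def test_counts_conserved_and_sensitivity_monotone(self):
        rng = random.Random(17)
        records = []
        for i in range(50):
            contaminant = rng.random() < 0.3
            truth = (_truth(Segment(2, 0, "N", 0, 0)) if contaminant
                     else _truth(Segment(1, 1, "F", 100, 199)))
            if rng.random() < 0.2:
                obs = _obs(mapped=False, mapq=0)
            else:
                obs = _obs(chrom="chr1",
                           pos=rng.choice([100, 500]),
                           mapq=rng.choice([0, 10, 30, 60]))
            records.append(_record(truth, obs, f"r{i}"))
        curve = build_curve(records, CONFIG)
        sensitivities = [p.sensitivity for p in curve]
        for point in curve:
            assert sum(point.counts.values()) == 50
            assert point.fdr == pytest.approx(1.0 - point.precision)
        assert sensitivities == sorted(sensitivities, reverse=True)

    def test_matches_exhaustive_oracle(self):
        # independent re-derivation: re-classify every read at every
        # threshold with first-principles logic, no shared helpers
        rng = random.Random(23)
        for trial in range(20):
            records = []
            for i in range(rng.randint(1, 20)):
                contaminant = rng.random() < 0.4
                truth = (_truth(Segment(2, 0, "N", 0, 0)) if contaminant
                         else _truth(Segment(1, 1, "F", 100, 199)))
                mapped = rng.random() < 0.8
                obs = _obs(chrom="chr1", pos=rng.choice([100, 104, 700]),
                           reverse=rng.random() < 0.5,
                           mapq=rng.choice([0, 20, 60]),
                           mapped=mapped)
                records.append(_record(truth, obs, f"r{i}"))
            curve = build_curve(records, CONFIG)
            thresholds = sorted({r.obs.mapq for r in records
                                 if r.obs.is_mapped} | {0})
            assert [p.q for p in curve] == thresholds
            n_true = sum(
                1 for r in records
                if any(s.genome_id == 1 for s in r.truth.segments))
            for point in curve:
                correct = wrong = contam_mapped = 0
                for r in records:
                    o = r.obs
                    is_contam = not any(s.genome_id == 1
                                        for s in r.truth.segments)
                    if o.is_mapped and o.mapq >= point.q:
                        if is_contam:
                            contam_mapped += 1
                        else:
                            seg = r.truth.segments[0]
                            good = (o.chrom == "chr1"
                                    and seg.chromosome_id == 1
                                    and abs(o.pos - seg.left) <= 5
                                    and (seg.direction == "R") == o.is_reverse)
                            if good:
                                correct += 1
                            else:
                                wrong += 1
                assert point.counts[ReadCategory.CORRECT] == correct
                assert point.counts[ReadCategory.WRONG_POSITION] == wrong
                assert point.counts[ReadCategory.CONTAMINANT_MAPPED] == \
                    contam_mapped
                denom = correct + wrong + contam_mapped
                assert point.precision == pytest.approx(
                    correct / denom if denom else 1.0)
                assert point.sensitivity == pytest.approx(
                    correct / n_true if n_true else 0.0)


def _write_sam(path, rows, srn=False):
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": "chr1", "LN": 100000}, {"SN": "chr2", "LN": 100000}],
    })
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for qname, chrom, pos, mapq, flag in rows:
            a = pysam.AlignedSegment(header)
            a.query_name = qname
            a.flag = flag
            if not flag & 4:
                a.reference_id = header.get_tid(chrom)
                a.reference_start = pos - 1
                a.cigarstring = "10M"
            a.mapping_quality = mapq
            a.query_sequence = "A" * 10
            a.query_qualities = pysam.qualitystring_to_array("I" * 10)
            out.write(a)


class TestReadAlignments:
    def test_loads_primary_records(self, tmp_path):
        names = [encode_lrn(ReadTuple(i, [Read([Segment(1, 1, "F", 100, 109)])],
                                      prefix="t"))
                 for i in range(1, 4)]
        sam = tmp_path / "a.sam"
        _write_sam(sam, [(n, "chr1", 100, 60, 0) for n in names])
        records, warnings = read_alignments(str(sam))
        assert len(records) == 3 and warnings == []

    def test_secondary_ignored_duplicate_primary_warns(self, tmp_path):
        name = encode_lrn(ReadTuple(1, [Read([Segment(1, 1, "F", 100, 109)])],
                                    prefix="t"))
        sam = tmp_path / "a.sam"
        _write_sam(sam, [(name, "chr1", 100, 60, 0),
                         (name, "chr1", 500, 0, 256),   # secondary
                         (name, "chr2", 900, 60, 0)])   # duplicate primary
        records, warnings = read_alignments(str(sam))
        assert len(records) == 1
        assert records[0].observation.pos == 100
        assert len(warnings) == 1

    def test_non_rnf_qname_rejected(self, tmp_path):
        sam = tmp_path / "a.sam"
        _write_sam(sam, [("read1", "chr1", 100, 60, 0)])
        with pytest.raises(RnfError, match="read1"):
            read_alignments(str(sam))

    def test_srn_resolved_through_correspondence(self, tmp_path):
        lrn = encode_lrn(ReadTuple(1, [Read([Segment(1, 1, "F", 100, 109)])],
                                   prefix="t"))
        sam_lrn = tmp_path / "lrn.sam"
        sam_srn = tmp_path / "srn.sam"
        _write_sam(sam_lrn, [(lrn, "chr1", 100, 60, 0)])
        _write_sam(sam_srn, [("#1", "chr1", 100, 60, 0)])
        _, curve_lrn, _ = evaluate_alignments(str(sam_lrn), CONFIG)
        _, curve_srn, _ = evaluate_alignments(str(sam_srn), CONFIG,
                                              correspondence={"#1": lrn})
        assert curve_lrn == curve_srn

    def test_srn_without_correspondence_rejected(self, tmp_path):
        sam = tmp_path / "a.sam"
        _write_sam(sam, [("#1", "chr1", 100, 60, 0)])
        with pytest.raises(RnfError, match="correspondence"):
            read_alignments(str(sam))

    def test_paired_ends_scored_independently(self, tmp_path):
        name = encode_lrn(ReadTuple(
            1, [Read([Segment(1, 1, "F", 100, 109)]),
                Read([Segment(1, 1, "R", 300, 309)])], prefix="t"))
        sam = tmp_path / "a.sam"
        _write_sam(sam, [(name, "chr1", 100, 60, 64 | 1),
                         (name, "chr1", 300, 60, 128 | 16 | 1)])
        records, _ = read_alignments(str(sam))
        assert {(r.name, r.end) for r in records} == {(name, 1), (name, 2)}


class TestCurveTsv:
    def test_round_trip(self, tmp_path):
        truth = _truth(Segment(1, 2, "F", 100, 199))
        records = [_record(truth, _obs(mapq=q), f"r{q}")
                   for q in (0, 10, 60)]
        curve = build_curve(records, CONFIG)
        path = tmp_path / "c.curve.tsv"
        write_curve_tsv(curve, str(path))
        back = read_curve_tsv(str(path))
        assert [p.q for p in back] == [p.q for p in curve]
        for a, b in zip(back, curve):
            assert a.counts == b.counts
            assert a.sensitivity == pytest.approx(b.sensitivity)
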