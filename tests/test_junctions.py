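"""Junction parsing, overlap rates and six-category classification."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from splicemark.junctions import (
    AnnotatedEvent,
    CATEGORIES,
    JunctionObservation,
    classify_junction,
    filter_min_support,
    merge_observations,
    overlap_rate,
    parse_junction_bed,
    parse_region_tsv,
    summarize_categories,
)
from splicemark.model import GenomicInterval, TranscriptIndex

from .conftest import make_transcript


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def obs(blocks, sample="s1", count=10):
    return JunctionObservation(
        sample_id=sample, chrom=blocks[0].chrom, blocks=tuple(blocks),
        read_count=count,
    )


class TestParsing:
    def test_bed12_block_arithmetic_and_score(self, tmp_path):
        line = (
            "chr1\t100\t360\tJ1\t7\t+\t100\t360\t0\t2\t50,60\t0,200\n"
        )
        p = tmp_path / "s.bed"
        p.write_text(line)
        (o,) = parse_junction_bed(p, "s1")
        assert [(b.start, b.end) for b in o.blocks] == [(100, 150), (300, 360)]
        assert o.read_count == 7

    def test_blockcount_three_skipped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "s.bed"
        p.write_text(
            "chr1\t0\t300\tJ1\t5\t+\t0\t300\t0\t3\t10,10,10\t0,100,290\n"
        )
        with caplog.at_level("WARNING"):
            assert parse_junction_bed(p, "s1") == []
        assert "blockCount" in caplog.text

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "s.bed"
        p.write_text("chr1\t100\n")
        with pytest.raises(ValueError, match=":1"):
            parse_junction_bed(p, "s1")

    def test_region_tsv_with_header_and_counts(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text("chrom\tstart\tend\tread_count\nchr1\t100\t200\t9\n")
        (o,) = parse_region_tsv(p, "s1")
        assert (o.blocks[0].start, o.blocks[0].end, o.read_count) == (100, 200, 9)

    def test_region_tsv_empty_and_negative(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text("")
        assert parse_region_tsv(p, "s1") == []
        p.write_text("chr1\t0\t10\t-1\n")
        with pytest.raises(ValueError, match="negative"):
            parse_region_tsv(p, "s1")


class TestOverlapRate:
    @pytest.mark.parametrize(
        "block,region,expected",
        [
            (iv(100, 200), iv(100, 200), 1.0),
            (iv(100, 200), iv(150, 300), 0.5),
            (iv(100, 200), iv(110, 200), 0.9),
            (iv(0, 50), iv(100, 200), 0.0),
            (iv(100, 200), iv(100, 200, chrom="chr2"), 0.0),
        ],
    )
    def test_examples(self, block, region, expected):
        assert overlap_rate(block, region) == pytest.approx(expected)

    @given(
        st.integers(0, 500), st.integers(1, 100),
        st.integers(0, 500), st.integers(1, 100),
        st.integers(-50, 50),
    )
    def test_bounded_translation_invariant_and_containment(
        self, bs, bw, rs, rw, shift
    ):
        block, region = iv(bs, bs + bw), iv(rs, rs + rw)
        rate = overlap_rate(block, region)
        assert 0.0 <= rate <= 1.0
        contained = region.start <= block.start and block.end <= region.end
        assert (rate == 1.0) == contained
        if min(bs, rs) + shift >= 0:
            shifted = overlap_rate(
                iv(bs + shift, bs + bw + shift), iv(rs + shift, rs + rw + shift)
            )
            assert rate == pytest.approx(shifted)

    @given(st.integers(0, 300), st.integers(1, 80), st.integers(0, 300),
           st.integers(1, 80))
    def test_matches_position_enumeration_oracle(self, bs, bw, rs, rw):
        block, region = iv(bs, bs + bw), iv(rs, rs + rw)
        brute = sum(
            1 for x in range(block.start, block.end)
            if region.start <= x < region.end
        ) / block.width
        assert overlap_rate(block, region) == pytest.approx(brute)


@pytest.fixture
def three_exon_index():
    # exons [0,100) [200,300) [400,500); introns [100,200) [300,400)
    tx = make_transcript([(0, 100), (200, 300), (400, 500)])
    return TranscriptIndex([tx])


class TestClassify:
    def test_neighboring_exon_exon_is_normal_splicing(self, three_exon_index):
        (ev,) = classify_junction(
            obs([iv(60, 100), iv(200, 240)]), three_exon_index
        )
        assert ev.category == "E_E_NM"
        assert (ev.left_label, ev.right_label) == ("EXON1", "EXON2")

    def test_skipping_junction_is_E_E_AS(self, three_exon_index):
        (ev,) = classify_junction(
            obs([iv(60, 100), iv(400, 440)]), three_exon_index
        )
        assert ev.category == "E_E_AS"
        assert (ev.left_label, ev.right_label) == ("EXON1", "EXON3")

    def test_single_block_in_intron_is_intron_retention(self, three_exon_index):
        (ev,) = classify_junction(obs([iv(110, 190)]), three_exon_index)
        assert ev.category == "INTRON_AS"
        assert (ev.left_label, ev.right_label) == ("INTRON1", None)

    @pytest.mark.parametrize(
        "blocks,category,labels",
        [
            ([iv(160, 200), iv(200, 240)], "I_E_AS", ("INTRON1", "EXON2")),
            ([iv(60, 100), iv(100, 140)], "E_I_AS", ("EXON1", "INTRON1")),
            ([iv(50, 90)], "EXON_NM", ("EXON1", None)),
        ],
    )
    def test_intron_flank_and_single_exon_categories(
        self, three_exon_index, blocks, category, labels
    ):
        (ev,) = classify_junction(obs(blocks), three_exon_index)
        assert ev.category == category
        assert (ev.left_label, ev.right_label) == labels

    def test_block_below_threshold_is_unannotated(self, three_exon_index):
        # best overlap 85/100 = 0.85 < 0.9
        assert classify_junction(obs([iv(85, 185)]), three_exon_index) == []

    def test_both_blocks_must_pass_individually(self, three_exon_index):
        assert classify_junction(
            obs([iv(60, 100), iv(150, 250)]), three_exon_index
        ) == []

    def test_minus_strand_labels_follow_transcription_order(self):
        tx = make_transcript([(0, 100), (200, 300), (400, 500)], strand="-")
        index = TranscriptIndex([tx])
        # genomic left exon is EXON3; junction joins EXON2 (5') to EXON3 (3')
        (ev,) = classify_junction(obs([iv(60, 100), iv(200, 240)]), index)
        assert ev.category == "E_E_NM"
        assert (ev.left_label, ev.right_label) == ("EXON2", "EXON3")

    def test_adjacency_on_another_transcript_flips_category(self):
        """Category depends only on the exon-index difference per transcript."""
        skipping = make_transcript(
            [(0, 100), (200, 300), (400, 500)], transcript_id="T_long"
        )
        # same outer exons, middle exon absent -> the pair is adjacent here
        short = make_transcript(
            [(0, 100), (400, 500)], transcript_id="T_short"
        )
        events = classify_junction(
            obs([iv(60, 100), iv(400, 440)]),
            TranscriptIndex([skipping, short]),
        )
        by_tx = {ev.transcript_id: ev.category for ev in events}
        assert by_tx == {"T_long": "E_E_AS", "T_short": "E_E_NM"}

    def test_junction_annotating_two_transcripts_yields_two_events(self):
        a = make_transcript([(0, 100), (200, 300)], transcript_id="TA")
        b = make_transcript([(0, 100), (200, 300)], transcript_id="TB")
        events = classify_junction(
            obs([iv(60, 100), iv(200, 240)]), TranscriptIndex([a, b])
        )
        assert sorted(ev.transcript_id for ev in events) == ["TA", "TB"]


def _brute_force_classify(o, transcripts, min_overlap=0.9):
    """Enumerate all (block, region) pairs; same contract, no index."""
    out = []
    for tx in transcripts:
        if tx.chrom != o.chrom:
            continue
        picks = []
        for block in o.blocks:
            scored = []
            for region in tx.regions:
                inter = max(
                    0,
                    min(block.end, region.interval.end)
                    - max(block.start, region.interval.start),
                )
                rate = inter / block.width
                scored.append(
                    (rate, region.kind == "exon", -region.index, region)
                )
            scored.sort(key=lambda t: (t[0], t[1], t[2]), reverse=True)
            rate, _, _, best = scored[0]
            if rate < min_overlap:
                picks = None
                break
            picks.append(best)
        if picks is None:
            continue
        if len(picks) == 2 and tx.strand == "-":
            picks = picks[::-1]
        left, right = picks[0], picks[1] if len(picks) == 2 else None
        if right is None:
            cat = "EXON_NM" if left.kind == "exon" else "INTRON_AS"
        elif left.kind == "exon" and right.kind == "exon":
            cat = "E_E_NM" if abs(left.index - right.index) == 1 else "E_E_AS"
        elif left.kind == "intron" and right.kind == "exon":
            cat = "I_E_AS"
        elif left.kind == "exon" and right.kind == "intron":
            cat = "E_I_AS"
        else:
            continue
        out.append((tx.transcript_id, cat, left.label,
                    right.label if right else None))
    return sorted(out)


def _random_fixture(rng):
    n_exons = int(rng.integers(2, 5))
    coords, pos = [], int(rng.integers(0, 50))
    for _ in range(n_exons):
        width = int(rng.integers(30, 200))
        coords.append((pos, pos + width))
        pos += width + int(rng.integers(30, 150))
    strand = "+" if rng.random() < 0.5 else "-"
    tx = make_transcript(coords, strand=strand)
    span = coords[-1][1]
    if rng.random() < 0.5:
        s = int(rng.integers(0, span - 20))
        blocks = [iv(s, s + int(rng.integers(10, 80)))]
    else:
        s1 = int(rng.integers(0, span // 2))
        e1 = s1 + int(rng.integers(10, 60))
        s2 = e1 + int(rng.integers(0, span // 2))
        blocks = [iv(s1, e1), iv(s2, s2 + int(rng.integers(10, 60)))]
    return tx, obs(blocks)


def test_classification_agrees_with_brute_force_on_random_fixtures(rng):
    for _ in range(300):
        tx, o = _random_fixture(rng)
        got = sorted(
            (e.transcript_id, e.category, e.left_label, e.right_label)
            for e in classify_junction(o, TranscriptIndex([tx]))
        )
        assert got == _brute_force_classify(o, [tx])


class TestMergeAndFilter:
    def _events(self):
        return [
            AnnotatedEvent("E_E_NM|T|EXON1|EXON2", "E_E_NM", "G", "T",
                           "EXON1", "EXON2", {s: c})
            for s, c in [("s1", 2), ("s2", 3), ("s3", 1)]
        ]

    def test_same_junction_in_three_samples_merges_to_one_event(self):
        (merged,) = merge_observations(self._events(), samples=["s1", "s2", "s3", "s4"])
        assert merged.counts == {"s1": 2, "s2": 3, "s3": 1, "s4": 0}

    def test_disjoint_events_stay_separate(self):
        evs = self._events()
        evs.append(
            AnnotatedEvent("EXON_NM|T|EXON1|-", "EXON_NM", "G", "T",
                           "EXON1", None, {"s1": 5})
        )
        assert len(merge_observations(evs)) == 2

    def test_category_conflict_is_a_key_collision(self):
        evs = self._events()
        evs.append(
            AnnotatedEvent("E_E_NM|T|EXON1|EXON2", "E_E_AS", "G", "T",
                           "EXON1", "EXON2", {"s1": 5})
        )
        with pytest.raises(ValueError, match="collision"):
            merge_observations(evs)

    @pytest.mark.parametrize(
        "totals,min_reads,kept", [((5, 6, 7), 6, [6, 7]), ((5, 6, 7), 1, [5, 6, 7])]
    )
    def test_pooled_support_boundary(self, totals, min_reads, kept):
        events = [
            AnnotatedEvent(f"EXON_NM|T{t}|EXON1|-", "EXON_NM", "G", f"T{t}",
                           "EXON1", None, {"s1": t})
            for t in totals
        ]
        out = filter_min_support(events, min_reads=min_reads)
        assert [ev.total_reads for ev in out] == kept

    def test_empty_input_passes_through(self):
        assert filter_min_support([]) == []

    def test_per_sample_scope_requires_one_sample_at_threshold(self):
        ev = AnnotatedEvent("EXON_NM|T|EXON1|-", "EXON_NM", "G", "T",
                            "EXON1", None, {"s1": 5, "s2": 5})
        assert filter_min_support([ev], scope="per-sample") == []
        assert filter_min_support([ev], scope="pooled") == [ev]


def test_category_summary_is_exhaustive_and_sums_to_total(rng):
    """Every retained event has exactly one category; counts sum to Total."""
    events = []
    for i in range(40):
        cat = CATEGORIES[int(rng.integers(0, len(CATEGORIES)))]
        right = None if cat in ("EXON_NM", "INTRON_AS") else "EXON2"
        events.append(
            AnnotatedEvent(f"{cat}|T{i}|EXON1|{right or '-'}", cat, "G",
                           f"T{i}", "EXON1", right, {"s1": 8})
        )
    summary = summarize_categories(events)
    assert sum(summary[c] for c in CATEGORIES) == summary["Total"] == 40
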