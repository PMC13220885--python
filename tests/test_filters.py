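"""Filter cascade: score, homology, M/M, aggregation, recurrence, accounting."""

import numpy as np
import pytest

from chimscreen.annotation import TranscriptSequenceSet
from chimscreen.cohort_io import CohortCallTable, SampleMetadata
from chimscreen.filters import (
    FilterConfig,
    aggregate_calls,
    homology_filter,
    recurrence_filter,
    run_screen,
    score_filter,
)
from chimscreen.junctions import annotate_call
from .conftest import make_call

RNG = np.random.default_rng(42)
BASES = np.array(list("ACGT"))


def random_seq(n, rng=RNG):
    return "".join(rng.choice(BASES, size=n))


class TestScoreFilter:
    def test_paper_threshold_boundary(self):
        kept = score_filter([make_call(score=0.59), make_call(score=0.60)], 0.6)
        assert [c.score for c in kept] == [0.60]

    def test_identity_on_perfect_scores(self):
        calls = [make_call(score=1.0) for _ in range(3)]
        assert score_filter(calls, 0.6) == calls

    def test_empty_input(self):
        assert score_filter([], 0.6) == []


class TestHomologyFilter:
    @pytest.fixture
    def transcripts(self):
        return TranscriptSequenceSet({"T1": random_seq(60), "T2": random_seq(60)})

    def test_near_copy_removed(self, transcripts):
        probe = list(transcripts["T1"][10:30])
        probe[5] = {"A": "C", "C": "G", "G": "T", "T": "A"}[probe[5]]  # 19/20 = 0.95
        artifact = make_call(junction_seq="".join(probe))
        genuine = make_call(junction_seq=random_seq(20))
        kept = homology_filter([artifact, genuine], transcripts, 0.90)
        assert kept == [genuine]

    def test_exact_threshold_kept(self):
        # 18 of 20 positions identical: identity exactly 0.90 is NOT "more than 90%"
        target = random_seq(40)
        probe = list(target[10:30])
        for i in (3, 11):
            probe[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[probe[i]]
        call = make_call(junction_seq="".join(probe))
        transcripts = TranscriptSequenceSet({"T1": target})
        # guard: the mutated probe really aligns at 18/20 to T1
        from chimscreen.alignment import local_align

        assert local_align("".join(probe), target).identity == pytest.approx(0.90)
        assert homology_filter([call], transcripts, 0.90) == [call]

    def test_empty_transcript_set_noop(self, caplog):
        calls = [make_call()]
        with caplog.at_level("WARNING"):
            kept = homology_filter(calls, TranscriptSequenceSet({}), 0.90)
        assert kept == calls

    def test_threshold_monotonicity(self, transcripts):
        """Raising the identity threshold never removes a previously kept call."""
        calls = [make_call(junction_seq=random_seq(20)) for _ in range(10)]
        calls.append(make_call(junction_seq=transcripts["T1"][5:25]))
        previous: set | None = None
        for threshold in (0.3, 0.5, 0.7, 0.9, 1.0):
            kept = {id(c) for c in homology_filter(calls, transcripts, threshold)}
            if previous is not None:
                assert previous <= kept
            previous = kept

    def test_seed_prefilter_matches_full_scan(self, small_world):
        _, _, transcripts, cohort, _ = small_world
        calls = cohort.calls[:300]
        fast = homology_filter(calls, transcripts, config=FilterConfig(seed_prefilter=True))
        full = homology_filter(calls, transcripts, config=FilterConfig(seed_prefilter=False))
        assert fast == full

    def test_score_and_homology_commute(self, transcripts):
        rng = np.random.default_rng(9)
        calls = [
            make_call(
                score=float(rng.uniform(0, 1)),
                junction_seq=(
                    transcripts["T2"][10:30] if rng.random() < 0.3 else random_seq(20, rng)
                ),
            )
            for _ in range(40)
        ]
        ab = homology_filter(score_filter(calls, 0.6), transcripts, 0.90)
        ba = score_filter(homology_filter(calls, transcripts, 0.90), 0.6)
        assert ab == ba


class TestAggregation:
    METADATA = [
        SampleMetadata("S1", "F"),
        SampleMetadata("S2", "F"),
        SampleMetadata("S3", "F"),
        SampleMetadata("S4", "M"),
        SampleMetadata("S5", "M"),
    ]

    def _annotate(self, calls, annotation):
        return [annotate_call(c, annotation) for c in calls]

    def test_same_sample_counts_once(self, two_gene_annotation):
        calls = self._annotate(
            [make_call(sample_id="S1"), make_call(sample_id="S1")], two_gene_annotation
        )
        aggs = aggregate_calls(calls, self.METADATA)
        assert len(aggs) == 1
        assert len(aggs[0].detected_samples) == 1

    def test_sex_counts(self, two_gene_annotation):
        calls = self._annotate(
            [make_call(sample_id=s) for s in ("S1", "S2", "S3", "S4", "S5")],
            two_gene_annotation,
        )
        (agg,) = aggregate_calls(calls, self.METADATA)
        assert (agg.n_female_detected, agg.n_male_detected) == (3, 2)
        assert agg.n_female_detected + agg.n_male_detected == len(agg.detected_samples)

    def test_one_bp_shift_is_distinct_key(self, two_gene_annotation):
        calls = self._annotate(
            [make_call(sample_id="S1"), make_call(sample_id="S2", pos3=1399)],
            two_gene_annotation,
        )
        assert len(aggregate_calls(calls, self.METADATA)) == 2

    def test_merge_window_collapses_near_keys(self, two_gene_annotation):
        calls = self._annotate(
            [make_call(sample_id="S1"), make_call(sample_id="S2", pos3=1399)],
            two_gene_annotation,
        )
        assert len(aggregate_calls(calls, self.METADATA, merge_window_bp=2)) == 1

    def test_unknown_sample_errors(self, two_gene_annotation):
        calls = self._annotate([make_call(sample_id="S9")], two_gene_annotation)
        with pytest.raises(KeyError, match="S9"):
            aggregate_calls(calls, self.METADATA)


class TestRecurrence:
    def _aggs(self, sizes, two_gene_annotation):
        meta = [SampleMetadata(f"S{i}", "F") for i in range(10)]
        out = []
        for k, size in enumerate(sizes):
            calls = [
                annotate_call(make_call(sample_id=f"S{i}", pos3=1400 - k), two_gene_annotation)
                for i in range(size)
            ]
            out.extend(aggregate_calls(calls, meta))
        return out

    def test_at_threshold_kept(self, two_gene_annotation):
        aggs = self._aggs([5, 4], two_gene_annotation)
        kept = recurrence_filter(aggs, 5)
        assert len(kept) == 1 and len(kept[0].detected_samples) == 5

    def test_min_one_is_identity(self, two_gene_annotation):
        aggs = self._aggs([3, 1], two_gene_annotation)
        assert recurrence_filter(aggs, 1) == aggs


class TestRunScreen:
    @pytest.fixture
    def hand_fixture(self, two_gene_annotation):
        """10 calls: 2 low-score, 1 homology artifact, 1 M/M, and two genuine
        chimeras detected in 4 and 2 individuals."""
        transcripts = TranscriptSequenceSet({"T1": random_seq(60)})
        probe = list(transcripts["T1"][20:40])
        probe[7] = {"A": "C", "C": "G", "G": "T", "T": "A"}[probe[7]]  # identity 0.95
        seq_a, seq_b = random_seq(20), random_seq(20)
        calls = [
            make_call(sample_id="S1", score=0.30),  # low score
            make_call(sample_id="S2", score=0.59),  # low score
            make_call(sample_id="S3", junction_seq="".join(probe)),  # homology artifact
            make_call(sample_id="S4", pos5=150, pos3=1350),  # M/M
        ]
        # chimera A (exon1 donor -> minus-strand exon1 acceptor) in 4 samples
        calls += [make_call(sample_id=f"S{i}", junction_seq=seq_a) for i in (1, 2, 3, 4)]
        # chimera B at different boundaries in 2 samples
        calls += [
            make_call(sample_id=f"S{i}", pos5=400, pos3=1100, junction_seq=seq_b)
            for i in (5, 6)
        ]
        samples = [SampleMetadata(f"S{i}", "F" if i % 2 else "M") for i in range(1, 7)]
        return CohortCallTable(calls=calls, samples=samples), transcripts

    def test_hand_enumerated_stage_counts(self, two_gene_annotation, hand_fixture):
        cohort, transcripts = hand_fixture
        config = FilterConfig(min_recurrence=2)
        result = run_screen(cohort, two_gene_annotation, transcripts, config)
        kept = [s.kept_n for s in result.stage_counts.stages]
        assert kept == [8, 7, 7, 6, 2, 2]
        assert len(result.aggregates) == 2
        assert sorted(len(a.detected_samples) for a in result.aggregates) == [2, 4]

    def test_min_recurrence_five_removes_all(self, two_gene_annotation, hand_fixture):
        cohort, transcripts = hand_fixture
        result = run_screen(cohort, two_gene_annotation, transcripts, FilterConfig())
        assert result.aggregates == []

    def test_drop_mm_false_keeps_mm_call(self, two_gene_annotation, hand_fixture):
        cohort, transcripts = hand_fixture
        config = FilterConfig(min_recurrence=1, drop_MM=False)
        result = run_screen(cohort, two_gene_annotation, transcripts, config)
        assert result.stage_counts["mm_filter"].removed_n == 0
        mm_keys = {a.chimera_key for a in result.aggregates}
        assert ("G1", "G2", 150, 1350) in mm_keys

    def test_conservation_and_chaining(self, small_world):
        """input = kept + removed at every stage, and stages chain end-to-end."""
        config, annotation, transcripts, cohort, _ = small_world
        result = run_screen(cohort, annotation, transcripts, FilterConfig())
        result.stage_counts.validate()
        assert result.stage_counts.stages[0].input_n == len(cohort.calls)
        n_rejected_calls = sum(
            s.removed_n for s in result.stage_counts.stages if s.unit == "calls"
        )
        surviving_calls = result.stage_counts["mm_filter"].kept_n
        assert n_rejected_calls + surviving_calls == len(cohort.calls)

    def test_unannotated_gene_routed_not_dropped(self, two_gene_annotation, hand_fixture):
        cohort, transcripts = hand_fixture
        rogue = make_call(sample_id="S1", gene5="GHOST", score=0.99)
        cohort.calls.append(rogue)
        result = run_screen(cohort, two_gene_annotation, transcripts, FilterConfig())
        assert rogue in result.unannotated
        assert any(r.stage == "classify" for r in result.rejects)
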