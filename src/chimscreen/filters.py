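"""The false-positive filter cascade and recurrence aggregation.

Stages, in order: caller-score filter (drop score < 0.6), junction-homology
filter (drop probes with > 90% identity to any annotated transcript),
junction classification, M/M removal (both breakpoints mid-exon), aggregation
of calls into per-chimera detection sets, and the recurrence filter (keep
chimeras seen in >= 5 individuals).  Every stage keeps conservation books:
input = kept + removed, and consecutive stages chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

from .alignment import (
    DEFAULT_GAP,
    DEFAULT_MATCH,
    DEFAULT_MISMATCH,
    AlignmentResult,
    local_align,
    seed_kmer_size,
    shares_kmer,
)
from .annotation import GenomeAnnotation, TranscriptSequenceSet
from .cohort_io import CohortCallTable, FusionCall, SampleMetadata
from .junctions import (
    DEFAULT_PROXIMAL_CUTOFF_BP,
    DEFAULT_TOLERANCE_BP,
    AnnotatedFusion,
    ClassificationError,
    annotate_call,
)

logger = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """Thresholds and parameters of the screen.

    Defaults follow the published screen: callers' score cutoff 0.6 (events
    scoring strictly less are removed), homology removal strictly above 90%
    identity, recurrence >= 5 individuals, M/M junctions dropped, E tolerance
    2 bp, proximal/distal cut at 100 kb.
    """

    min_score: float = 0.6
    identity_threshold: float = 0.90
    min_recurrence: int = 5
    drop_MM: bool = True
    match_score: int = DEFAULT_MATCH
    mismatch_penalty: int = DEFAULT_MISMATCH
    gap_penalty: int = DEFAULT_GAP
    proximal_cutoff_bp: int = DEFAULT_PROXIMAL_CUTOFF_BP
    tolerance_bp: int = DEFAULT_TOLERANCE_BP
    merge_window_bp: int = 0
    seed_prefilter: bool = True

    def validate(self) -> None:
        if not 0.0 <= self.min_score <= 1.0:
            raise ValueError("min_score must be in [0, 1]")
        if not 0.0 < self.identity_threshold <= 1.0:
            raise ValueError("identity_threshold must be in (0, 1]")
        if self.min_recurrence < 1:
            raise ValueError("min_recurrence must be >= 1")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class ChimeraAggregate:
    """Cross-cohort detection record for one chimera (exact junction key)."""

    chimera_key: tuple[str, str, int, int]
    detected_samples: set[str]
    n_female_detected: int
    n_male_detected: int
    representative: AnnotatedFusion


@dataclass(frozen=True)
class StageCount:
    name: str
    input_n: int
    kept_n: int
    removed_n: int
    unit: str = "calls"


@dataclass
class StageCounts:
    stages: list[StageCount] = field(default_factory=list)

    def add(self, name: str, input_n: int, kept_n: int, unit: str = "calls") -> None:
        self.stages.append(StageCount(name, input_n, kept_n, input_n - kept_n, unit))

    def validate(self) -> None:
        for s in self.stages:
            if s.input_n != s.kept_n + s.removed_n:
                raise AssertionError(f"stage {s.name}: {s.input_n} != {s.kept_n} + {s.removed_n}")
            if min(s.input_n, s.kept_n, s.removed_n) < 0:
                raise AssertionError(f"stage {s.name}: negative count")
        for prev, cur in zip(self.stages, self.stages[1:]):
            if prev.kept_n != cur.input_n:
                raise AssertionError(
                    f"stages {prev.name} -> {cur.name} do not chain "
                    f"({prev.kept_n} != {cur.input_n})"
                )

    def __getitem__(self, name: str) -> StageCount:
        for s in self.stages:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass(frozen=True)
class RejectRecord:
    call: FusionCall
    stage: str
    reason: str


@dataclass
class ScreenResult:
    aggregates: list[ChimeraAggregate]
    stage_counts: StageCounts
    rejects: list[RejectRecord]
    unannotated: list[FusionCall]


def score_filter(calls: list[FusionCall], min_score: float = 0.6) -> list[FusionCall]:
    """Keep calls whose score is >= *min_score* (events scoring strictly less are removed)."""
    return [c for c in calls if c.score >= min_score]


def _best_hit(
    probe: str,
    transcripts: TranscriptSequenceSet,
    config: FilterConfig,
) -> AlignmentResult | None:
    """Best alignment of a junction probe over all transcripts.

    With the seed prefilter enabled, targets sharing no pigeonhole k-mer with
    the probe are skipped: such targets cannot yield identity above the
    threshold, so the keep/remove decision is unchanged (the reported best
    identity for kept probes is then a lower bound over seeded targets).
    """
    k = seed_kmer_size(config.identity_threshold, len(probe))
    best: AlignmentResult | None = None
    for tx_id in sorted(transcripts.sequences):
        target = transcripts.sequences[tx_id]
        if config.seed_prefilter and not shares_kmer(probe, target, k):
            continue
        res = local_align(
            probe,
            target,
            match=config.match_score,
            mismatch=config.mismatch_penalty,
            gap=config.gap_penalty,
            target_id=tx_id,
        )
        if best is None or (res.identity, res.matches) > (best.identity, best.matches):
            best = res
    return best


def homology_filter(
    calls: list[FusionCall],
    transcripts: TranscriptSequenceSet,
    identity_threshold: float = 0.90,
    config: FilterConfig | None = None,
    hits_out: dict[str, AlignmentResult] | None = None,
) -> list[FusionCall]:
    """Drop calls whose junction probe aligns > *identity_threshold* to any transcript.

    The comparison is strict ("more than 90%"): identity exactly at the
    threshold is kept.  Probes are deduplicated before alignment.  When
    *hits_out* is given it receives the best hit per probe sequence (for
    removed probes, the offending transcript id).
    """
    if config is None:
        config = FilterConfig(identity_threshold=identity_threshold)
    else:
        config = FilterConfig(**{**config.as_dict(), "identity_threshold": identity_threshold})
    if len(transcripts) == 0:
        logger.warning("homology filter skipped: empty transcript set")
        return list(calls)
    cache: dict[str, AlignmentResult | None] = {}
    kept = []
    for call in calls:
        probe = call.junction_seq
        if probe not in cache:
            cache[probe] = _best_hit(probe, transcripts, config)
        hit = cache[probe]
        if hits_out is not None and hit is not None:
            hits_out[probe] = hit
        if hit is not None and hit.identity > identity_threshold:
            continue
        kept.append(call)
    return kept


def aggregate_calls(
    annotated: list[AnnotatedFusion],
    metadata: list[SampleMetadata],
    merge_window_bp: int = 0,
) -> list[ChimeraAggregate]:
    """Group annotated calls by chimera key, counting each individual once.

    Detection is binary per (sample, chimera).  With ``merge_window_bp > 0``,
    calls of the same gene pair whose breakpoints each differ by at most the
    window are merged under the smallest participating key.
    """
    sex_of = {s.sample_id: s.sex for s in metadata}
    for fusion in annotated:
        if fusion.call.sample_id not in sex_of:
            raise KeyError(f"sample {fusion.call.sample_id} absent from metadata")

    key_of = {f.call.chimera_key: f.call.chimera_key for f in annotated}
    if merge_window_bp > 0:
        by_pair: dict[tuple[str, str], list[tuple[str, str, int, int]]] = {}
        for key in key_of:
            by_pair.setdefault(key[:2], []).append(key)
        for keys in by_pair.values():
            keys.sort()
            cluster_rep = keys[0]
            for prev, cur in zip(keys, keys[1:]):
                if (
                    abs(cur[2] - prev[2]) <= merge_window_bp
                    and abs(cur[3] - prev[3]) <= merge_window_bp
                ):
                    key_of[cur] = key_of[prev]
                else:
                    cluster_rep = cur
                    key_of[cur] = cluster_rep

    groups: dict[tuple[str, str, int, int], ChimeraAggregate] = {}
    for fusion in annotated:
        key = key_of[fusion.call.chimera_key]
        agg = groups.get(key)
        if agg is None:
            agg = ChimeraAggregate(
                chimera_key=key,
                detected_samples=set(),
                n_female_detected=0,
                n_male_detected=0,
                representative=fusion,
            )
            groups[key] = agg
        sample = fusion.call.sample_id
        if sample in agg.detected_samples:
            continue
        agg.detected_samples.add(sample)
        if sex_of[sample] == "F":
            agg.n_female_detected += 1
        else:
            agg.n_male_detected += 1
    return [groups[key] for key in sorted(groups)]


def recurrence_filter(
    aggregates: list[ChimeraAggregate], min_recurrence: int = 5
) -> list[ChimeraAggregate]:
    """Keep chimeras detected in at least *min_recurrence* individuals."""
    return [a for a in aggregates if len(a.detected_samples) >= min_recurrence]


def run_screen(
    cohort: CohortCallTable,
    annotation: GenomeAnnotation,
    transcripts: TranscriptSequenceSet,
    config: FilterConfig | None = None,
) -> ScreenResult:
    """Apply the full filter cascade with per-stage accounting.

    Order: score -> homology -> classification -> M/M removal -> aggregation
    -> recurrence.  Calls whose parental genes are unannotated are routed to
    a separate bin (``result.unannotated``), not silently dropped.  The
    aggregation stage changes units from calls to chimeras; its ``removed_n``
    counts calls collapsed into an already-seen (sample, chimera) pair.
    """
    config = config or FilterConfig()
    config.validate()
    cohort.validate()
    counts = StageCounts()
    rejects: list[RejectRecord] = []

    calls = list(cohort.calls)
    kept = score_filter(calls, config.min_score)
    removed_set = set(map(id, kept))
    rejects += [
        RejectRecord(c, "score", f"score {c.score} < {config.min_score}")
        for c in calls
        if id(c) not in removed_set
    ]
    counts.add("score", len(calls), len(kept))
    calls = kept

    hits: dict[str, AlignmentResult] = {}
    kept = homology_filter(
        calls, transcripts, config.identity_threshold, config=config, hits_out=hits
    )
    kept_ids = set(map(id, kept))
    for c in calls:
        if id(c) not in kept_ids:
            hit = hits.get(c.junction_seq)
            reason = (
                f"identity {hit.identity:.3f} to {hit.target_id}"
                if hit
                else "homologous to an annotated transcript"
            )
            rejects.append(RejectRecord(c, "homology", reason))
    counts.add("homology", len(calls), len(kept))
    calls = kept

    annotated: list[AnnotatedFusion] = []
    unannotated: list[FusionCall] = []
    for call in calls:
        try:
            annotated.append(
                annotate_call(
                    call,
                    annotation,
                    tolerance_bp=config.tolerance_bp,
                    proximal_cutoff_bp=config.proximal_cutoff_bp,
                )
            )
        except ClassificationError as exc:
            unannotated.append(call)
            rejects.append(RejectRecord(call, "classify", f"gene {exc.gene_id} unannotated"))
    counts.add("classify", len(calls), len(annotated))

    if config.drop_MM:
        kept_annotated = [f for f in annotated if f.junction_class.value != "MM"]
        rejects += [
            RejectRecord(f.call, "mm_filter", "both breakpoints mid-exon (M/M)")
            for f in annotated
            if f.junction_class.value == "MM"
        ]
    else:
        kept_annotated = annotated
    counts.add("mm_filter", len(annotated), len(kept_annotated))

    aggregates = aggregate_calls(kept_annotated, cohort.samples, config.merge_window_bp)
    counts.add("aggregate", len(kept_annotated), len(aggregates), unit="calls->chimeras")

    surviving = recurrence_filter(aggregates, config.min_recurrence)
    rejects += [
        RejectRecord(
            a.representative.call,
            "recurrence",
            f"detected in {len(a.detected_samples)} < {config.min_recurrence} individuals",
        )
        for a in aggregates
        if len(a.detected_samples) < config.min_recurrence
    ]
    counts.add("recurrence", len(aggregates), len(surviving), unit="chimeras")

    counts.validate()
    for stage in counts.stages:
        logger.info(
            "stage %s: %d in, %d kept, %d removed (%s)",
            stage.name,
            stage.input_n,
            stage.kept_n,
            stage.removed_n,
            stage.unit,
        )
    return ScreenResult(
        aggregates=surviving, stage_counts=counts, rejects=rejects, unannotated=unannotated
    )
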