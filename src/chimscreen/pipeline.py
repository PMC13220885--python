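"""End-to-end orchestration: read inputs, screen, test, write reports."""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import read_gtf, read_transcript_fasta
from .cohort_io import (
    CohortCallTable,
    read_call_table,
    read_metadata,
    write_results,
)
from .filters import FilterConfig, RejectRecord, StageCounts, run_screen
from .junctions import ClassificationError, annotate_call
from .stats import (
    DEFAULT_ALPHA,
    BubbleRow,
    SexAssociationResult,
    bubble_table,
    sex_association,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage-labelled fatal error; the message names the failing stage."""


@dataclass
class PipelineConfig:
    calls: Path
    metadata: Path
    gtf: Path
    fasta: Path
    out_dir: Path
    filter: FilterConfig = field(default_factory=FilterConfig)
    alpha: float = DEFAULT_ALPHA
    plot: bool = False
    seed: int | None = None


@dataclass
class ScreenBundle:
    """Everything write_results needs, in one place."""

    association_results: list[SexAssociationResult]
    stage_counts: StageCounts
    bubble_rows: list[BubbleRow]
    cutoff_line: float
    rejects: list[RejectRecord]
    params: dict
    seed: int | None
    timestamp: str | None = None


@dataclass
class SummaryReport:
    stage_counts: StageCounts
    n_tested: int
    n_significant: int
    cutoff_line: float
    n_female: int
    n_male: int
    parameters: dict
    seed: int | None
    version: str = __version__

    def __post_init__(self):
        if self.n_significant > self.n_tested:
            raise AssertionError("n_significant exceeds n_tested")


def run_pipeline(config: PipelineConfig) -> SummaryReport:
    """simulate-independent screen run: inputs -> filters -> stats -> files."""
    for stage, path in (
        ("calls", config.calls),
        ("metadata", config.metadata),
        ("gtf", config.gtf),
        ("fasta", config.fasta),
    ):
        if not Path(path).exists():
            raise PipelineError(f"input ({stage}): file not found: {path}")

    try:
        samples = read_metadata(config.metadata)
        calls = read_call_table(config.calls)
    except Exception as exc:
        raise PipelineError(f"input parsing: {exc}") from exc
    try:
        annotation = read_gtf(config.gtf)
        transcripts = read_transcript_fasta(config.fasta)
    except Exception as exc:
        raise PipelineError(f"annotation: {exc}") from exc

    cohort = CohortCallTable(calls=list(calls), samples=samples)
    try:
        screen = run_screen(cohort, annotation, transcripts, config.filter)
    except Exception as exc:
        raise PipelineError(f"screen: {exc}") from exc

    n_female, n_male = cohort.n_female, cohort.n_male
    try:
        results = sex_association(screen.aggregates, n_female, n_male, alpha=config.alpha)
        bubble_rows, cutoff = bubble_table(results, alpha=config.alpha)
    except Exception as exc:
        raise PipelineError(f"stats: {exc}") from exc

    params = {
        "filter": config.filter.as_dict(),
        "alpha": config.alpha,
        "n_female": n_female,
        "n_male": n_male,
    }
    bundle = ScreenBundle(
        association_results=results,
        stage_counts=screen.stage_counts,
        bubble_rows=bubble_rows,
        cutoff_line=cutoff,
        rejects=screen.rejects,
        params=params,
        seed=config.seed,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    try:
        paths = write_results(bundle, config.out_dir)
    except Exception as exc:
        raise PipelineError(f"report: {exc}") from exc

    if config.plot:
        from .stats import plot_bubble

        plot_bubble(bubble_rows, cutoff, Path(config.out_dir) / "bubble.png")

    logger.info(
        "screen complete: %d chimeras tested, %d significant (cutoff %.2f); results in %s",
        sum(1 for r in results if not r.untestable),
        sum(1 for r in results if r.significant),
        cutoff,
        paths["summary"].parent,
    )
    return SummaryReport(
        stage_counts=screen.stage_counts,
        n_tested=sum(1 for r in results if not r.untestable),
        n_significant=sum(1 for r in results if r.significant),
        cutoff_line=cutoff,
        n_female=n_female,
        n_male=n_male,
        parameters=params,
        seed=config.seed,
    )


def annotate_table(calls_path: Path, gtf_path: Path, out_path: Path, config: FilterConfig | None = None) -> int:
    """Annotate a call table without filtering; returns the number of rows written."""
    config = config or FilterConfig()
    calls = read_call_table(calls_path)
    annotation = read_gtf(gtf_path)
    rows = []
    for call in calls:
        base = dict(call.__dict__)
        try:
            fused = annotate_call(
                call,
                annotation,
                tolerance_bp=config.tolerance_bp,
                proximal_cutoff_bp=config.proximal_cutoff_bp,
            )
        except ClassificationError as exc:
            base.update(junction_class="unannotated", offset5="", offset3="",
                        category="", distance_bp="", isoform_label="",
                        canonical_readthrough="", note=f"gene {exc.gene_id} unannotated")
            rows.append(base)
            continue
        arch = fused.architecture
        base.update(
            junction_class=fused.junction_class.value,
            offset5=fused.junction_class.offset5,
            offset3=fused.junction_class.offset3,
            category=fused.category.value,
            distance_bp=fused.category.distance_bp,
            isoform_label=arch.isoform_label if arch else "",
            canonical_readthrough=arch.canonical_readthrough if arch else "",
            note="",
        )
        rows.append(base)
    pd.DataFrame(rows).to_csv(out_path, sep="\t", index=False)
    return len(rows)
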