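"""Cohort-level tables: fusion calls, sample metadata, screen results.

The call-table dialect is a single TSV concatenating per-sample fusion-caller
outputs with an added ``sample_id`` column.  Columns are matched by header
name, order free; a mapping for common EricScript header names is applied
when the canonical names are absent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

CALL_COLUMNS = [
    "sample_id",
    "gene5",
    "gene3",
    "chrom5",
    "chrom3",
    "pos5",
    "pos3",
    "strand5",
    "strand3",
    "score",
    "junction_seq",
    "reads_spanning",
]

#: Best-effort mapping from EricScript's own per-sample headers to this dialect.
ERICSCRIPT_COLUMN_MAP = {
    "GeneName1": "gene5",
    "GeneName2": "gene3",
    "chr1": "chrom5",
    "chr2": "chrom3",
    "Breakpoint1": "pos5",
    "Breakpoint2": "pos3",
    "strand1": "strand5",
    "strand2": "strand3",
    "EricScore": "score",
    "JunctionSequence": "junction_seq",
    "crossingreads": "reads_spanning",
}

MIN_JUNCTION_SEQ_LEN = 10


class CohortIOError(ValueError):
    pass


@dataclass(frozen=True)
class FusionCall:
    """One candidate chimeric RNA call in one sample.

    ``pos5`` is the 1-based genomic coordinate of the last base of the 5'
    segment; ``pos3`` the first base of the 3' segment.  ``score`` is the
    caller's confidence in [0, 1].
    """

    sample_id: str
    gene5: str
    gene3: str
    chrom5: str
    chrom3: str
    pos5: int
    pos3: int
    strand5: str
    strand3: str
    score: float
    junction_seq: str
    reads_spanning: int

    def validate(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise CohortIOError(f"score {self.score} outside [0, 1]")
        if len(self.junction_seq) < MIN_JUNCTION_SEQ_LEN:
            raise CohortIOError(
                f"junction_seq shorter than {MIN_JUNCTION_SEQ_LEN} bases"
            )
        if self.gene5 == self.gene3:
            raise CohortIOError(f"gene5 == gene3 ({self.gene5})")
        if self.strand5 not in {"+", "-"} or self.strand3 not in {"+", "-"}:
            raise CohortIOError("strands must be + or -")
        if self.pos5 < 1 or self.pos3 < 1:
            raise CohortIOError("positions must be 1-based positive")
        if self.reads_spanning < 0:
            raise CohortIOError("reads_spanning must be non-negative")

    @property
    def chimera_key(self) -> tuple[str, str, int, int]:
        return (self.gene5, self.gene3, self.pos5, self.pos3)


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    sex: str  # "F" or "M"
    age: float | None = None
    bmi: float | None = None
    population: str | None = None
    karyotype: str | None = None


@dataclass
class CohortCallTable:
    calls: list[FusionCall]
    samples: list[SampleMetadata]

    def validate(self) -> None:
        known = {s.sample_id for s in self.samples}
        for call in self.calls:
            if call.sample_id not in known:
                raise CohortIOError(
                    f"call sample {call.sample_id} absent from metadata"
                )

    @property
    def n_female(self) -> int:
        return sum(1 for s in self.samples if s.sex == "F")

    @property
    def n_male(self) -> int:
        return sum(1 for s in self.samples if s.sex == "M")


class ParsedCalls(list):
    """List of FusionCall that also carries per-row rejection records."""

    def __init__(self, calls=(), rejects=None):
        super().__init__(calls)
        self.rejects: list[tuple[int, str]] = list(rejects or [])


def read_call_table(path: str | Path) -> ParsedCalls:
    """Read a cohort call TSV; rows violating invariants are rejected.

    Returns a list of :class:`FusionCall`; the returned object additionally
    exposes ``.rejects`` as (row_number, reason) pairs so that
    accepted + rejected always equals the number of data rows.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = df.rename(columns=ERICSCRIPT_COLUMN_MAP)
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise CohortIOError(f"{path}: missing required columns: {', '.join(missing)}")
    calls = ParsedCalls()
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # row 1 = header
        try:
            call = FusionCall(
                sample_id=str(getattr(row, "sample_id")),
                gene5=str(getattr(row, "gene5")),
                gene3=str(getattr(row, "gene3")),
                chrom5=str(getattr(row, "chrom5")),
                chrom3=str(getattr(row, "chrom3")),
                pos5=_parse_int(getattr(row, "pos5"), "pos5"),
                pos3=_parse_int(getattr(row, "pos3"), "pos3"),
                strand5=str(getattr(row, "strand5")),
                strand3=str(getattr(row, "strand3")),
                score=_parse_float(getattr(row, "score"), "score"),
                junction_seq=str(getattr(row, "junction_seq")).upper(),
                reads_spanning=_parse_int(getattr(row, "reads_spanning"), "reads_spanning"),
            )
            call.validate()
        except (CohortIOError, ValueError) as exc:
            logger.warning("%s: row %d rejected: %s", path, idx, exc)
            calls.rejects.append((idx, str(exc)))
            continue
        calls.append(call)
    return calls


def _parse_int(value, name: str) -> int:
    try:
        return int(str(value))
    except (TypeError, ValueError) as exc:
        raise CohortIOError(f"unparseable {name}: {value!r}") from exc


def _parse_float(value, name: str) -> float:
    try:
        return float(str(value))
    except (TypeError, ValueError) as exc:
        raise CohortIOError(f"unparseable {name}: {value!r}") from exc


_SEX_CODES = {"f": "F", "female": "F", "m": "M", "male": "M"}


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read the sample metadata TSV (sample_id, sex, optional covariates)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns or "sex" not in df.columns:
        raise CohortIOError(f"{path}: metadata requires sample_id and sex columns")
    samples: list[SampleMetadata] = []
    seen: set[str] = set()
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        sample_id = str(getattr(row, "sample_id"))
        if sample_id in seen:
            raise CohortIOError(f"{path}: row {idx}: duplicate sample id {sample_id}")
        seen.add(sample_id)
        raw_sex = str(getattr(row, "sex")).strip().lower()
        if raw_sex not in _SEX_CODES:
            raise CohortIOError(f"{path}: row {idx}: unknown sex code {raw_sex!r}")
        samples.append(
            SampleMetadata(
                sample_id=sample_id,
                sex=_SEX_CODES[raw_sex],
                age=_optional_float(row, "age"),
                bmi=_optional_float(row, "bmi"),
                population=_optional_str(row, "population"),
                karyotype=_optional_str(row, "karyotype"),
            )
        )
    return samples


def _optional_float(row, name: str) -> float | None:
    value = getattr(row, name, None)
    if value is None or pd.isna(value) or str(value) == "":
        return None
    return float(value)


def _optional_str(row, name: str) -> str | None:
    value = getattr(row, name, None)
    if value is None or pd.isna(value) or str(value) == "":
        return None
    return str(value)


def write_call_table(calls: list[FusionCall], path: str | Path) -> None:
    df = pd.DataFrame([c.__dict__ for c in calls], columns=CALL_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def write_metadata(samples: list[SampleMetadata], path: str | Path) -> None:
    df = pd.DataFrame([s.__dict__ for s in samples])
    df.to_csv(path, sep="\t", index=False)


RESULT_COLUMNS = [
    "gene5",
    "gene3",
    "chrom5",
    "pos5",
    "chrom3",
    "pos3",
    "junction_class",
    "offset5",
    "offset3",
    "category",
    "distance_bp",
    "isoform_label",
    "canonical_readthrough",
    "n_detected",
    "n_female_detected",
    "n_male_detected",
    "pct_female",
    "chi2",
    "p",
    "neg_log10_p",
    "p_adjusted",
    "fisher_p",
    "significant",
]


def write_results(bundle, out_dir: str | Path) -> dict[str, Path]:
    """Write screen_results.tsv, bubble.tsv, rejects.tsv and summary.json.

    *bundle* is duck-typed: it must expose ``association_results`` (each with
    an ``aggregate`` whose representative carries the annotated call),
    ``stage_counts``, ``bubble_rows``, ``cutoff_line``, ``rejects``,
    ``params`` and ``seed``.  Row order is deterministic (chrom5, pos5, gene
    pair).
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_test"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise CohortIOError(f"cannot write to {out_dir}: {exc}") from exc

    rows = []
    for res in bundle.association_results:
        agg = res.aggregate
        rep = agg.representative
        call = rep.call
        arch = rep.architecture
        rows.append(
            {
                "gene5": call.gene5,
                "gene3": call.gene3,
                "chrom5": call.chrom5,
                "pos5": call.pos5,
                "chrom3": call.chrom3,
                "pos3": call.pos3,
                "junction_class": rep.junction_class.value,
                "offset5": rep.junction_class.offset5,
                "offset3": rep.junction_class.offset3,
                "category": rep.category.value,
                "distance_bp": rep.category.distance_bp,
                "isoform_label": arch.isoform_label if arch else "",
                "canonical_readthrough": arch.canonical_readthrough if arch else "",
                "n_detected": res.total_detected,
                "n_female_detected": agg.n_female_detected,
                "n_male_detected": agg.n_male_detected,
                "pct_female": res.pct_female,
                "chi2": res.chi2,
                "p": res.p,
                "neg_log10_p": res.neg_log10_p,
                "p_adjusted": res.p_adjusted,
                "fisher_p": res.fisher_p,
                "significant": res.significant,
            }
        )
    results_df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if not results_df.empty:
        results_df = results_df.sort_values(
            ["chrom5", "pos5", "gene5", "gene3"], kind="mergesort"
        )
    results_path = out_dir / "screen_results.tsv"
    results_df.to_csv(results_path, sep="\t", index=False)

    bubble_df = pd.DataFrame(
        [
            {"x": r.x, "y": r.y, "size": r.size, "color": r.color, "label": r.label}
            for r in bundle.bubble_rows
        ],
        columns=["x", "y", "size", "color", "label"],
    )
    bubble_path = out_dir / "bubble.tsv"
    bubble_df.to_csv(bubble_path, sep="\t", index=False)

    rejects_df = pd.DataFrame(
        [
            {
                "sample_id": rej.call.sample_id,
                "gene5": rej.call.gene5,
                "gene3": rej.call.gene3,
                "pos5": rej.call.pos5,
                "pos3": rej.call.pos3,
                "stage": rej.stage,
                "reason": rej.reason,
            }
            for rej in bundle.rejects
        ],
        columns=["sample_id", "gene5", "gene3", "pos5", "pos3", "stage", "reason"],
    )
    if not rejects_df.empty:
        rejects_df = rejects_df.sort_values(
            ["stage", "sample_id", "gene5", "gene3", "pos5"], kind="mergesort"
        )
    rejects_path = out_dir / "rejects.tsv"
    rejects_df.to_csv(rejects_path, sep="\t", index=False)

    summary = {
        "stages": [
            {
                "name": s.name,
                "unit": s.unit,
                "input_n": s.input_n,
                "kept_n": s.kept_n,
                "removed_n": s.removed_n,
            }
            for s in bundle.stage_counts.stages
        ],
        "n_tested": sum(1 for r in bundle.association_results if not r.untestable),
        "n_significant": sum(1 for r in bundle.association_results if r.significant),
        "cutoff_line": bundle.cutoff_line,
        "parameters": bundle.params,
        "seed": bundle.seed,
        "version": _version(),
    }
    timestamp = getattr(bundle, "timestamp", None)
    if timestamp is not None:
        summary["timestamp"] = timestamp
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")

    return {
        "screen_results": results_path,
        "bubble": bubble_path,
        "rejects": rejects_path,
        "summary": summary_path,
    }


def _version() -> str:
    from chimscreen import __version__

    return __version__
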