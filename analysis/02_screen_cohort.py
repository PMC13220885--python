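#!/usr/bin/env python
"""Run the false-positive filter cascade on the simulated cohort.

Stages: caller score >= 0.6, junction homology <= 90% identity to annotated
transcripts, junction classification (E/E..M/M), M/M removal, aggregation to
per-chimera detection sets, recurrence >= 5 individuals.  Prints the
per-stage accounting and writes screen outputs under results/screen/.
"""

import json
from pathlib import Path

from chimscreen.annotation import read_gtf, read_transcript_fasta
from chimscreen.cohort_io import CohortCallTable, read_call_table, read_metadata, write_results
from chimscreen.filters import FilterConfig, run_screen
from chimscreen.pipeline import ScreenBundle
from chimscreen.stats import bubble_table, sex_association

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 20_260_918 % 2**31


def main() -> None:
    cohort_dir = BASE / "cohort"
    annotation = read_gtf(cohort_dir / "annotation.gtf")
    transcripts = read_transcript_fasta(cohort_dir / "transcripts.fa")
    calls = read_call_table(cohort_dir / "calls.tsv")
    samples = read_metadata(cohort_dir / "metadata.tsv")
    cohort = CohortCallTable(calls=list(calls), samples=samples)

    config = FilterConfig()
    screen = run_screen(cohort, annotation, transcripts, config)
    print("stage accounting (input -> kept / removed):")
    for s in screen.stage_counts.stages:
        print(f"  {s.name:<11} {s.input_n:>6} -> {s.kept_n:>5} / {s.removed_n:<5} ({s.unit})")
    print(f"surviving chimeras: {len(screen.aggregates)}")

    results = sex_association(screen.aggregates, cohort.n_female, cohort.n_male)
    rows, cutoff = bubble_table(results)
    bundle = ScreenBundle(
        association_results=results,
        stage_counts=screen.stage_counts,
        bubble_rows=rows,
        cutoff_line=cutoff,
        rejects=screen.rejects,
        params={"filter": config.as_dict(), "alpha": 0.05,
                "n_female": cohort.n_female, "n_male": cohort.n_male},
        seed=SEED,
    )
    paths = write_results(bundle, BASE / "screen")
    print(json.dumps({k: str(v) for k, v in paths.items()}, indent=2))


if __name__ == "__main__":
    main()
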