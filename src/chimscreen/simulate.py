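"""Synthetic cohort generator for end-to-end verification of the screen.

Emulates a blood RNA-seq cohort at the detection level: each chimera is
observed in each sample as an independent Bernoulli draw with a sex-specific
penetrance.  The generated world contains

* same-strand adjacent gene pairs (read-through geometry) in a fake genome,
* planted sex-specific chimeras (default: one with female penetrance 0.15
  and male penetrance 0, mirroring a 24/157-vs-0/268 detection pattern),
* sex-independent background chimeras, and
* three artifact classes the filter cascade must remove: low-score calls,
  M/M junctions (both breakpoints mid-exon), and junction probes copied from
  a single transcript with at most one mutation (homology > 90%).

Genuine chimera probes are one arm from each parent around true exon
boundaries, so they classify E/E and align to either parent at ~50%
identity.  All randomness flows from a single seed through fixed, named
substreams, so adding an artifact class never perturbs the background draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import (
    GeneModel,
    GenomeAnnotation,
    TranscriptModel,
    TranscriptSequenceSet,
    write_gtf,
    write_transcript_fasta,
)
from .cohort_io import (
    CohortCallTable,
    FusionCall,
    SampleMetadata,
    write_call_table,
    write_metadata,
)

ROLE_PLANTED = "planted_sex_specific"
ROLE_BACKGROUND = "background"
ROLE_LOW_SCORE = "low_score_artifact"
ROLE_MM = "mm_artifact"
ROLE_HOMOLOGY = "homology_artifact"

# fixed substream indices; never renumber (determinism contract)
_STREAM_ANNOTATION = 101
_STREAM_SAMPLES = 201
_STREAM_DESIGN = 301
_STREAM_EMISSION = {
    ROLE_PLANTED: 510,
    ROLE_BACKGROUND: 520,
    ROLE_LOW_SCORE: 530,
    ROLE_MM: 540,
    ROLE_HOMOLOGY: 550,
}

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Stated world of the synthetic cohort (defaults mirror the discovery cohort)."""

    n_female: int = 157
    n_male: int = 268
    n_background_chimeras: int = 50
    background_detect_prob: float = 0.1
    planted: list[tuple[str, float, float]] = field(
        default_factory=lambda: [("planted_1", 0.15, 0.0)]
    )
    n_low_score_artifacts: int = 5
    n_mm_artifacts: int = 5
    n_homology_artifacts: int = 5
    score_real_range: tuple[float, float] = (0.6, 1.0)
    score_artifact_range: tuple[float, float] = (0.05, 0.59)
    junction_arm_length: int = 25
    gene_pair_spacing_bp: int = 9_124
    exons_per_gene: int = 6
    exon_length_range: tuple[int, int] = (60, 120)
    intron_length_range: tuple[int, int] = (200, 800)
    seed: int = 0

    def validate(self) -> None:
        if self.n_female < 0 or self.n_male < 0:
            raise ValueError("cohort sizes must be non-negative")
        if not 0.0 <= self.background_detect_prob <= 1.0:
            raise ValueError("background_detect_prob must be in [0, 1]")
        for label, pf, pm in self.planted:
            if not (0.0 <= pf <= 1.0 and 0.0 <= pm <= 1.0):
                raise ValueError(f"planted {label}: penetrances must be in [0, 1]")
        lo, hi = self.score_real_range
        if not (0.6 <= lo <= hi <= 1.0):
            raise ValueError("score_real_range must lie within [0.6, 1]")
        lo, hi = self.score_artifact_range
        if not (0.0 <= lo <= hi < 0.6):
            raise ValueError("score_artifact_range must lie within [0, 0.6)")
        if self.exons_per_gene < 4:
            raise ValueError("exons_per_gene must be >= 4")
        if self.gene_pair_spacing_bp < 1:
            raise ValueError("gene_pair_spacing_bp must be >= 1")
        if self.junction_arm_length * 2 > self.exon_length_range[0] + self.exon_length_range[0]:
            raise ValueError("junction arms longer than the shortest possible exon pair")

    @property
    def n_gene_pairs(self) -> int:
        return (
            len(self.planted)
            + self.n_background_chimeras
            + self.n_low_score_artifacts
            + self.n_mm_artifacts
            + self.n_homology_artifacts
        )

    def as_dict(self) -> dict:
        d = asdict(self)
        d["planted"] = [list(p) for p in self.planted]
        return d


def preset_gtex_blood(**overrides) -> SimulationConfig:
    """The discovery-cohort preset: 157 female and 268 male samples."""
    return SimulationConfig(**{"n_female": 157, "n_male": 268, **overrides})


@dataclass(frozen=True)
class TruthRecord:
    chimera_key: tuple[str, str, int, int]
    label: str
    role: str
    penetrance_female: float
    penetrance_male: float
    samples: tuple[str, ...]


@dataclass
class TruthManifest:
    records: list[TruthRecord]

    def by_role(self, role: str) -> list[TruthRecord]:
        return [r for r in self.records if r.role == role]

    def validate_against(self, cohort: CohortCallTable) -> None:
        """Emitted samples in the manifest must match the call table exactly."""
        observed: dict[tuple, set[str]] = {}
        for call in cohort.calls:
            observed.setdefault(call.chimera_key, set()).add(call.sample_id)
        expected = {r.chimera_key: set(r.samples) for r in self.records if r.samples}
        if observed != expected:
            raise AssertionError("truth manifest inconsistent with call table")


def generate_annotation(
    n_gene_pairs: int,
    exons_per_gene: int = 6,
    gene_pair_spacing_bp: int = 9_124,
    seed: int = 0,
    exon_length_range: tuple[int, int] = (60, 120),
    intron_length_range: tuple[int, int] = (200, 800),
) -> tuple[GenomeAnnotation, TranscriptSequenceSet]:
    """Build a fake genome of adjacent same-strand gene pairs.

    Each pair sits on one chromosome, upstream gene then *gene_pair_spacing_bp*
    of intergenic space, then the downstream gene, both on the same strand
    (alternating between pairs so minus-strand logic is exercised).  One
    transcript per gene; transcript sequences are uniform-random ACGT.
    Deterministic given *seed*.
    """
    if n_gene_pairs < 1:
        raise ValueError("n_gene_pairs must be >= 1")
    if exons_per_gene < 3:
        raise ValueError("exons_per_gene must be >= 3")
    if gene_pair_spacing_bp < 1:
        raise ValueError("gene_pair_spacing_bp must be >= 1")
    rng = np.random.default_rng([seed, _STREAM_ANNOTATION])
    annotation = GenomeAnnotation()
    seqs: dict[str, str] = {}
    pairs_per_chrom = 8
    for i in range(n_gene_pairs):
        chrom = f"chr{i // pairs_per_chrom + 1}"
        strand = "+" if i % 2 == 0 else "-"
        base = 100_000 + (i % pairs_per_chrom) * 1_000_000

        def gene_block(start: int):
            lens = rng.integers(
                exon_length_range[0], exon_length_range[1] + 1, size=exons_per_gene
            )
            introns = rng.integers(
                intron_length_range[0], intron_length_range[1] + 1, size=exons_per_gene - 1
            )
            exons = []
            pos = start
            for k in range(exons_per_gene):
                exons.append((pos, pos + int(lens[k]) - 1))
                pos = exons[-1][1] + 1 + (int(introns[k]) if k < exons_per_gene - 1 else 0)
            return exons, exons[-1][1]

        # upstream gene (A) precedes downstream (B) in transcript orientation;
        # genomically that means A first on '+', B first on '-'
        first_exons, first_end = gene_block(base)
        second_exons, _ = gene_block(first_end + 1 + gene_pair_spacing_bp)
        if strand == "+":
            exons_a, exons_b = first_exons, second_exons
        else:
            exons_b, exons_a = first_exons, second_exons
        for suffix, exons in (("A", exons_a), ("B", exons_b)):
            gene_id = f"GP{i:03d}{suffix}"
            tx_exons = sorted(exons, reverse=(strand == "-"))
            tx = TranscriptModel(transcript_id=f"{gene_id}.T1", exons=tx_exons)
            gene = GeneModel(
                gene_id=gene_id, symbol=gene_id, chrom=chrom, strand=strand, transcripts=[tx]
            )
            gene.validate()
            annotation.genes[gene_id] = gene
            seqs[tx.transcript_id] = "".join(
                rng.choice(_BASES, size=tx.length, p=[0.25, 0.25, 0.25, 0.25])
            )
    return annotation, TranscriptSequenceSet(seqs)


def _cumulative_lengths(tx: TranscriptModel) -> list[int]:
    out = [0]
    for lo, hi in tx.exons:
        out.append(out[-1] + hi - lo + 1)
    return out


@dataclass
class _ChimeraDesign:
    label: str
    role: str
    gene5: str
    gene3: str
    chrom: str
    strand: str
    pos5: int
    pos3: int
    junction_seq: str
    pen_female: float
    pen_male: float

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.gene5, self.gene3, self.pos5, self.pos3)


def _design_chimera(
    label: str,
    role: str,
    gene_a: GeneModel,
    gene_b: GeneModel,
    seq_a: str,
    seq_b: str,
    arm: int,
    rng: np.random.Generator,
    pen_female: float,
    pen_male: float,
    exons_per_gene: int,
    donor_ordinal: int | None = None,
    acceptor_ordinal: int | None = None,
) -> _ChimeraDesign:
    tx_a = gene_a.transcripts[0]
    tx_b = gene_b.transcripts[0]
    if donor_ordinal is None:
        donor_ordinal = int(rng.integers(2, exons_per_gene))  # 2 .. second-to-last
    if acceptor_ordinal is None:
        acceptor_ordinal = int(rng.integers(2, 4))  # exon 2 or 3
    sign = 1 if gene_a.strand == "+" else -1

    cum_a = _cumulative_lengths(tx_a)
    cum_b = _cumulative_lengths(tx_b)
    donor_t = cum_a[donor_ordinal]  # mRNA coordinate of the donor exon's last base
    acceptor_t = cum_b[acceptor_ordinal - 1]  # 0-based mRNA offset of acceptor exon start

    if role == ROLE_MM:
        shift = int(rng.integers(3, 11))  # both breakpoints >= 3 bp inside their exons
        pos5 = tx_a.donor_end(donor_ordinal) - shift * sign
        pos3 = tx_b.acceptor_start(acceptor_ordinal) + shift * sign
        donor_t -= shift
        acceptor_t += shift
    else:
        pos5 = tx_a.donor_end(donor_ordinal)
        pos3 = tx_b.acceptor_start(acceptor_ordinal)

    if role == ROLE_HOMOLOGY:
        # probe copied from the donor transcript across the exon boundary,
        # with at most one substitution: near-perfect identity to one transcript
        window = list(seq_a[donor_t - arm : donor_t + arm])
        if rng.random() < 0.9:
            idx = int(rng.integers(0, len(window)))
            window[idx] = {"A": "C", "C": "G", "G": "T", "T": "A"}[window[idx]]
        probe = "".join(window)
    else:
        donor_arm = seq_a[donor_t - arm : donor_t]
        acceptor_arm = seq_b[acceptor_t : acceptor_t + arm]
        probe = donor_arm + acceptor_arm

    return _ChimeraDesign(
        label=label,
        role=role,
        gene5=gene_a.gene_id,
        gene3=gene_b.gene_id,
        chrom=gene_a.chrom,
        strand=gene_a.strand,
        pos5=int(pos5),
        pos3=int(pos3),
        junction_seq=probe,
        pen_female=pen_female,
        pen_male=pen_male,
    )


def simulate_cohort(
    config: SimulationConfig,
    annotation: GenomeAnnotation,
    transcripts: TranscriptSequenceSet,
) -> tuple[CohortCallTable, TruthManifest]:
    """Draw a full cohort call table plus its ground-truth manifest.

    Every (sample, chimera) detection is an independent Bernoulli draw with
    the sex-appropriate penetrance.  Artifact chimeras are guaranteed at
    least one emission so filter-stage recovery checks are never vacuous.
    """
    config.validate()
    pairs = _discover_pairs(annotation)
    if len(pairs) < config.n_gene_pairs:
        raise ValueError(
            f"annotation has {len(pairs)} gene pairs; {config.n_gene_pairs} required"
        )

    rng_samples = np.random.default_rng([config.seed, _STREAM_SAMPLES])
    samples = _draw_samples(config, rng_samples)

    rng_design = np.random.default_rng([config.seed, _STREAM_DESIGN])
    designs: list[_ChimeraDesign] = []
    pair_iter = iter(pairs)

    def next_pair():
        gene_a, gene_b = next(pair_iter)
        return (
            gene_a,
            gene_b,
            transcripts[gene_a.transcripts[0].transcript_id],
            transcripts[gene_b.transcripts[0].transcript_id],
        )

    for label, pf, pm in config.planted:
        gene_a, gene_b, seq_a, seq_b = next_pair()
        designs.append(
            _design_chimera(
                label,
                ROLE_PLANTED,
                gene_a,
                gene_b,
                seq_a,
                seq_b,
                config.junction_arm_length,
                rng_design,
                pf,
                pm,
                config.exons_per_gene,
                donor_ordinal=config.exons_per_gene - 2,  # third from last
                acceptor_ordinal=2,
            )
        )
    role_counts = [
        (ROLE_BACKGROUND, config.n_background_chimeras),
        (ROLE_LOW_SCORE, config.n_low_score_artifacts),
        (ROLE_MM, config.n_mm_artifacts),
        (ROLE_HOMOLOGY, config.n_homology_artifacts),
    ]
    for role, count in role_counts:
        for j in range(count):
            gene_a, gene_b, seq_a, seq_b = next_pair()
            designs.append(
                _design_chimera(
                    f"{role}_{j + 1}",
                    role,
                    gene_a,
                    gene_b,
                    seq_a,
                    seq_b,
                    config.junction_arm_length,
                    rng_design,
                    config.background_detect_prob,
                    config.background_detect_prob,
                    config.exons_per_gene,
                )
            )

    emission_rngs = {
        role: np.random.default_rng([config.seed, stream])
        for role, stream in _STREAM_EMISSION.items()
    }
    calls: list[FusionCall] = []
    records: list[TruthRecord] = []
    sample_ids = [s.sample_id for s in samples]
    is_female = np.array([s.sex == "F" for s in samples])
    for design in designs:
        rng = emission_rngs[design.role]
        pen = np.where(is_female, design.pen_female, design.pen_male)
        detected = rng.random(len(samples)) < pen
        guaranteed = design.role in {ROLE_LOW_SCORE, ROLE_MM, ROLE_HOMOLOGY}
        if guaranteed and not detected.any():
            detected[int(rng.integers(len(samples)))] = True
        emitted = [sid for sid, hit in zip(sample_ids, detected) if hit]
        low, high = (
            config.score_artifact_range
            if design.role == ROLE_LOW_SCORE
            else config.score_real_range
        )
        scores = rng.uniform(low, high, size=len(emitted))
        reads = rng.integers(2, 41, size=len(emitted))
        for sid, score, n_reads in zip(emitted, scores, reads):
            calls.append(
                FusionCall(
                    sample_id=sid,
                    gene5=design.gene5,
                    gene3=design.gene3,
                    chrom5=design.chrom,
                    chrom3=design.chrom,
                    pos5=design.pos5,
                    pos3=design.pos3,
                    strand5=design.strand,
                    strand3=design.strand,
                    score=round(float(score), 4),
                    junction_seq=design.junction_seq,
                    reads_spanning=int(n_reads),
                )
            )
        records.append(
            TruthRecord(
                chimera_key=design.key,
                label=design.label,
                role=design.role,
                penetrance_female=design.pen_female,
                penetrance_male=design.pen_male,
                samples=tuple(emitted),
            )
        )

    cohort = CohortCallTable(calls=calls, samples=samples)
    manifest = TruthManifest(records=records)
    cohort.validate()
    manifest.validate_against(cohort)
    return cohort, manifest


def _draw_samples(config: SimulationConfig, rng: np.random.Generator) -> list[SampleMetadata]:
    samples = []
    populations = ["EUR", "AFR", "EAS", "SAS", "AMR"]
    for sex, count, prefix in (("F", config.n_female, "F"), ("M", config.n_male, "M")):
        for i in range(1, count + 1):
            samples.append(
                SampleMetadata(
                    sample_id=f"{prefix}{i:04d}",
                    sex=sex,
                    age=float(rng.integers(21, 71)),
                    bmi=round(float(rng.uniform(18.0, 35.0)), 1),
                    population=populations[int(rng.integers(len(populations)))],
                    karyotype="XX" if sex == "F" else "XY",
                )
            )
    return samples


def _discover_pairs(annotation: GenomeAnnotation) -> list[tuple[GeneModel, GeneModel]]:
    """Pair up genes named ``<stem>A`` / ``<stem>B`` (generate_annotation convention)."""
    pairs = []
    for gene_id in sorted(annotation.genes):
        if gene_id.endswith("A") and gene_id[:-1] + "B" in annotation.genes:
            pairs.append((annotation.genes[gene_id], annotation.genes[gene_id[:-1] + "B"]))
    return pairs


#: filter stage expected to remove each artifact class
INTENDED_STAGE = {
    ROLE_LOW_SCORE: "score",
    ROLE_MM: "mm_filter",
    ROLE_HOMOLOGY: "homology",
}


def evaluate_against_truth(manifest: TruthManifest, screen_result, assoc_results) -> dict:
    """Score one screen run against the planted ground truth.

    Returns ``planted_flagged`` (label -> was the planted chimera significant)
    and ``artifacts_removed`` (True when every emitted artifact call was
    rejected at its intended stage and no artifact chimera survived).
    """
    rejected: dict[tuple, list[str]] = {}
    for rej in screen_result.rejects:
        rejected.setdefault(rej.call.chimera_key, []).append(rej.stage)
    surviving = {a.chimera_key for a in screen_result.aggregates}
    significant = {r.chimera_key for r in assoc_results if r.significant}
    planted_flagged: dict[str, bool] = {}
    artifacts_removed = True
    for rec in manifest.records:
        if rec.role == ROLE_PLANTED:
            planted_flagged[rec.label] = rec.chimera_key in significant
        elif rec.role in INTENDED_STAGE and rec.samples:
            stages = rejected.get(rec.chimera_key, [])
            want = INTENDED_STAGE[rec.role]
            if (
                rec.chimera_key in surviving
                or len(stages) != len(rec.samples)
                or any(stage != want for stage in stages)
            ):
                artifacts_removed = False
    return {"planted_flagged": planted_flagged, "artifacts_removed": artifacts_removed}


def simulate_to_dir(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate a cohort and write every file the pipeline consumes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    annotation, transcripts = generate_annotation(
        config.n_gene_pairs,
        exons_per_gene=config.exons_per_gene,
        gene_pair_spacing_bp=config.gene_pair_spacing_bp,
        seed=config.seed,
        exon_length_range=config.exon_length_range,
        intron_length_range=config.intron_length_range,
    )
    cohort, manifest = simulate_cohort(config, annotation, transcripts)
    paths = {
        "gtf": out_dir / "annotation.gtf",
        "fasta": out_dir / "transcripts.fa",
        "calls": out_dir / "calls.tsv",
        "metadata": out_dir / "metadata.tsv",
        "truth": out_dir / "truth.tsv",
    }
    write_gtf(annotation, paths["gtf"])
    write_transcript_fasta(transcripts, paths["fasta"])
    write_call_table(cohort.calls, paths["calls"])
    write_metadata(cohort.samples, paths["metadata"])
    write_truth(manifest, paths["truth"])
    return paths


def write_truth(manifest: TruthManifest, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "gene5": r.chimera_key[0],
                "gene3": r.chimera_key[1],
                "pos5": r.chimera_key[2],
                "pos3": r.chimera_key[3],
                "label": r.label,
                "role": r.role,
                "penetrance_female": r.penetrance_female,
                "penetrance_male": r.penetrance_male,
                "samples": ",".join(r.samples),
            }
            for r in manifest.records
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> TruthManifest:
    df = pd.read_csv(path, sep="\t", dtype=str)
    records = [
        TruthRecord(
            chimera_key=(row.gene5, row.gene3, int(row.pos5), int(row.pos3)),
            label=row.label,
            role=row.role,
            penetrance_female=float(row.penetrance_female),
            penetrance_male=float(row.penetrance_male),
            samples=tuple(row.samples.split(",")) if isinstance(row.samples, str) and row.samples else (),
        )
        for row in df.itertuples(index=False)
    ]
    return TruthManifest(records)
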