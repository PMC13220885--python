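"""Synthetic cohort generator: determinism, geometry, planted statistics."""

import numpy as np
import pytest

from chimscreen.alignment import local_align
from chimscreen.annotation import ACCEPTOR_START, DONOR_END, boundary_offset
from chimscreen.filters import FilterConfig, run_screen
from chimscreen.junctions import chromosomal_category
from chimscreen.simulate import (
    ROLE_BACKGROUND,
    ROLE_HOMOLOGY,
    ROLE_LOW_SCORE,
    ROLE_MM,
    ROLE_PLANTED,
    SimulationConfig,
    generate_annotation,
    preset_gtex_blood,
    read_truth,
    simulate_cohort,
    simulate_to_dir,
)
from chimscreen.stats import sex_association
from .conftest import SMALL_CONFIG


class TestGenerateAnnotation:
    def test_seeded_runs_byte_identical(self, tmp_path):
        from chimscreen.annotation import write_gtf, write_transcript_fasta

        files = []
        for name in ("a", "b"):
            ann, seqs = generate_annotation(4, seed=1)
            gtf, fasta = tmp_path / f"{name}.gtf", tmp_path / f"{name}.fa"
            write_gtf(ann, gtf)
            write_transcript_fasta(seqs, fasta)
            files.append((gtf.read_bytes(), fasta.read_bytes()))
        assert files[0] == files[1]

    def test_gene_and_exon_counts(self, tmp_path):
        from chimscreen.annotation import write_gtf

        ann, _ = generate_annotation(3, exons_per_gene=5, seed=2)
        assert len(ann.genes) == 6
        gtf = tmp_path / "c.gtf"
        write_gtf(ann, gtf)
        exon_lines = [l for l in gtf.read_text().splitlines() if "\texon\t" in l]
        assert len(exon_lines) == 30

    def test_pair_spacing_gives_proximal_geometry(self):
        """Pairs spaced like the X-linked locus fall inside the 100-kb cut."""
        ann, seqs = generate_annotation(2, gene_pair_spacing_bp=9_124, seed=3)
        config = SimulationConfig(
            n_female=4, n_male=4, n_background_chimeras=2, background_detect_prob=1.0,
            planted=[], n_low_score_artifacts=0, n_mm_artifacts=0, n_homology_artifacts=0,
            gene_pair_spacing_bp=9_124, seed=3,
        )
        cohort, _ = simulate_cohort(config, ann, seqs)
        for call in cohort.calls:
            assert chromosomal_category(call).value == "intrachromosomal_proximal"

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_annotation(0)
        with pytest.raises(ValueError):
            generate_annotation(1, exons_per_gene=2)
        with pytest.raises(ValueError):
            generate_annotation(1, gene_pair_spacing_bp=0)


class TestSimulateCohort:
    def test_seeded_call_table_identical(self, small_world):
        config, annotation, transcripts, cohort, _ = small_world
        again, _ = simulate_cohort(config, annotation, transcripts)
        assert again.calls == cohort.calls

    def test_planted_female_counts_match_binomial(self):
        """pi_F = 0.15 over 157 women: mean detection near 23.55, no male hits."""
        ann, seqs = generate_annotation(1, seed=0)
        mean = 157 * 0.15
        sigma = np.sqrt(157 * 0.15 * 0.85)
        counts = []
        for seed in range(20):
            config = SimulationConfig(
                n_background_chimeras=0, planted=[("p", 0.15, 0.0)],
                n_low_score_artifacts=0, n_mm_artifacts=0, n_homology_artifacts=0,
                seed=seed,
            )
            cohort, truth = simulate_cohort(config, ann, seqs)
            rec = truth.by_role(ROLE_PLANTED)[0]
            assert not any(s.startswith("M") for s in rec.samples)
            counts.append(len(rec.samples))
        assert abs(np.mean(counts) - mean) < 3 * sigma / np.sqrt(len(counts))

    def test_null_penetrance_pct_female_calibrated(self):
        """Equal penetrance in both sexes gives %female near the cohort share."""
        ann, seqs = generate_annotation(1, seed=0)
        fractions = []
        for seed in range(40):
            config = SimulationConfig(
                n_background_chimeras=1, background_detect_prob=0.3, planted=[],
                n_low_score_artifacts=0, n_mm_artifacts=0, n_homology_artifacts=0,
                seed=seed,
            )
            _, truth = simulate_cohort(config, ann, seqs)
            rec = truth.by_role(ROLE_BACKGROUND)[0]
            if rec.samples:
                f = sum(1 for s in rec.samples if s.startswith("F"))
                fractions.append(100 * f / len(rec.samples))
        expected = 100 * 157 / 425
        assert abs(np.mean(fractions) - expected) < 5.0

    def test_truth_manifest_consistent_with_calls(self, small_world):
        _, _, _, cohort, truth = small_world
        truth.validate_against(cohort)  # raises on inconsistency
        roles = {r.role for r in truth.records}
        assert roles == {ROLE_PLANTED, ROLE_BACKGROUND, ROLE_LOW_SCORE, ROLE_MM, ROLE_HOMOLOGY}

    def test_genuine_junctions_are_exonic_edges(self, small_world):
        """Planted and background breakpoints sit exactly on exon boundaries."""
        _, annotation, _, _, truth = small_world
        for rec in truth.by_role(ROLE_PLANTED) + truth.by_role(ROLE_BACKGROUND):
            gene5, gene3, pos5, pos3 = rec.chimera_key
            assert boundary_offset(annotation.gene(gene5), pos5, DONOR_END).offset_bp == 0
            assert boundary_offset(annotation.gene(gene3), pos3, ACCEPTOR_START).offset_bp == 0

    def test_mm_artifacts_are_mid_exon(self, small_world):
        _, annotation, _, _, truth = small_world
        for rec in truth.by_role(ROLE_MM):
            gene5, gene3, pos5, pos3 = rec.chimera_key
            assert abs(boundary_offset(annotation.gene(gene5), pos5, DONOR_END).offset_bp) >= 3
            assert (
                abs(boundary_offset(annotation.gene(gene3), pos3, ACCEPTOR_START).offset_bp) >= 3
            )

    def test_probe_identity_structure(self, small_world):
        """Genuine probes align ~50% to each parent; homology artifacts > 90%."""
        _, annotation, transcripts, cohort, truth = small_world
        probes = {c.chimera_key: c.junction_seq for c in cohort.calls}
        for rec in truth.by_role(ROLE_BACKGROUND)[:3]:
            if rec.chimera_key not in probes:
                continue
            probe = probes[rec.chimera_key]
            best = max(
                local_align(probe, seq).identity for _, seq in transcripts.items()
            )
            assert best <= 0.75
        for rec in truth.by_role(ROLE_HOMOLOGY):
            probe = probes[rec.chimera_key]
            best = max(
                local_align(probe, seq).identity for _, seq in transcripts.items()
            )
            assert best > 0.90

    def test_insufficient_pairs_error_before_output(self):
        ann, seqs = generate_annotation(2, seed=0)
        with pytest.raises(ValueError, match="gene pairs"):
            simulate_cohort(SMALL_CONFIG, ann, seqs)


class TestEndToEndRecovery:
    def test_planted_recovered_and_artifacts_staged(self, small_world):
        from chimscreen.simulate import evaluate_against_truth

        config, annotation, transcripts, cohort, truth = small_world
        screen = run_screen(cohort, annotation, transcripts, FilterConfig())
        results = sex_association(screen.aggregates, cohort.n_female, cohort.n_male)
        verdict = evaluate_against_truth(truth, screen, results)
        assert verdict["planted_flagged"] == {"planted_1": True}
        assert verdict["artifacts_removed"]

    def test_simulate_to_dir_roundtrip(self, tmp_path):
        config = SimulationConfig(
            n_female=6, n_male=8, n_background_chimeras=2, planted=[("p", 0.9, 0.0)],
            n_low_score_artifacts=1, n_mm_artifacts=1, n_homology_artifacts=1, seed=4,
        )
        paths = simulate_to_dir(config, tmp_path / "cohort")
        for path in paths.values():
            assert path.exists()
        from chimscreen.annotation import read_gtf, read_transcript_fasta
        from chimscreen.cohort_io import read_call_table, read_metadata

        ann = read_gtf(paths["gtf"])
        assert len(ann.genes) == 2 * config.n_gene_pairs
        seqs = read_transcript_fasta(paths["fasta"])
        assert len(seqs) == 2 * config.n_gene_pairs
        calls = read_call_table(paths["calls"])
        assert calls.rejects == []
        meta = read_metadata(paths["metadata"])
        assert len(meta) == 14
        truth = read_truth(paths["truth"])
        assert len(truth.records) == config.n_gene_pairs
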