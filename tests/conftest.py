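import pytest

from chimscreen.annotation import (
    GeneModel,
    GenomeAnnotation,
    TranscriptModel,
)
from chimscreen.cohort_io import FusionCall
from chimscreen.simulate import SimulationConfig, generate_annotation, simulate_cohort


def make_gene(gene_id, chrom, strand, exons, symbol=None, tx_id=None):
    """Build a single-transcript gene; exons given genomically ascending."""
    ordered = sorted(exons, reverse=(strand == "-"))
    gene = GeneModel(
        gene_id=gene_id,
        symbol=symbol or gene_id,
        chrom=chrom,
        strand=strand,
        transcripts=[TranscriptModel(transcript_id=tx_id or f"{gene_id}.T1", exons=ordered)],
    )
    gene.validate()
    return gene


def make_call(**overrides):
    defaults = dict(
        sample_id="S1",
        gene5="G1",
        gene3="G2",
        chrom5="chr1",
        chrom3="chr1",
        pos5=200,
        pos3=1400,
        strand5="+",
        strand3="-",
        score=0.9,
        junction_seq="ACGTACGTACGTACGTACGT",
        reads_spanning=5,
    )
    defaults.update(overrides)
    call = FusionCall(**defaults)
    call.validate()
    return call


@pytest.fixture
def two_gene_annotation():
    """G1: plus strand, 3 exons; G2: minus strand, 2 exons (exon 1 genomically last)."""
    ann = GenomeAnnotation()
    ann.genes["G1"] = make_gene("G1", "chr1", "+", [(100, 200), (300, 400), (500, 600)])
    ann.genes["G2"] = make_gene("G2", "chr1", "-", [(1000, 1100), (1300, 1400)])
    return ann


# Donor gene shaped like the X-linked ubiquitin-activating enzyme locus: 26
# exons with exon 24 (third from last) ending at chrX:47,214,428; acceptor
# neighbour with exon 2 starting at chrX:47,223,552.  100-bp exons, 100-bp
# introns, plus strand.
DONOR_EXON24_END = 47_214_428
ACCEPTOR_EXON2_START = 47_223_552


@pytest.fixture
def xlinked_pair_annotation():
    donor_start = DONOR_EXON24_END - (23 * 200 + 99)
    donor_exons = [(donor_start + i * 200, donor_start + i * 200 + 99) for i in range(26)]
    acceptor_start = ACCEPTOR_EXON2_START - 200
    acceptor_exons = [
        (acceptor_start + i * 200, acceptor_start + i * 200 + 99) for i in range(15)
    ]
    ann = GenomeAnnotation()
    ann.genes["DONOR_X"] = make_gene("DONOR_X", "chrX", "+", donor_exons)
    ann.genes["ACCEPTOR_X"] = make_gene("ACCEPTOR_X", "chrX", "+", acceptor_exons)
    return ann


@pytest.fixture
def xlinked_call():
    return make_call(
        gene5="DONOR_X",
        gene3="ACCEPTOR_X",
        chrom5="chrX",
        chrom3="chrX",
        pos5=DONOR_EXON24_END,
        pos3=ACCEPTOR_EXON2_START,
        strand5="+",
        strand3="+",
    )


SMALL_CONFIG = SimulationConfig(
    n_female=25,
    n_male=30,
    n_background_chimeras=8,
    background_detect_prob=0.25,
    planted=[("planted_1", 0.5, 0.0)],
    n_low_score_artifacts=2,
    n_mm_artifacts=2,
    n_homology_artifacts=2,
    seed=7,
)


@pytest.fixture(scope="session")
def small_world():
    """A small but complete synthetic cohort shared across tests."""
    config = SMALL_CONFIG
    annotation, transcripts = generate_annotation(
        config.n_gene_pairs,
        exons_per_gene=config.exons_per_gene,
        gene_pair_spacing_bp=config.gene_pair_spacing_bp,
        seed=config.seed,
    )
    cohort, truth = simulate_cohort(config, annotation, transcripts)
    return config, annotation, transcripts, cohort, truth
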