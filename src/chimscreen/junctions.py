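"""Junction classification against the annotation.

Each side of a fusion junction is labelled "E" (edge of exon) when the
breakpoint lies within a tolerance (default 2 bp, inclusive) of a canonical
exon boundary of its parental gene, and "M" (middle of exon) otherwise.  The
5' side is compared only against splice-donor ends and the 3' side only
against splice-acceptor starts, since a spliced junction joins a donor to an
acceptor.  "Canonical" boundaries are the union over all annotated
transcripts of the gene; the nearest one wins.

The module also assigns the chromosomal category (100-kb cut between proximal
and distal intrachromosomal chimeras) and the read-through architecture: the
classic cis-SAGe (read-through) motif joins the second-to-last exon of the
upstream gene to exon 2 of its downstream neighbour, labelled e.g. "e25e2".
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotation import (
    ACCEPTOR_START,
    DONOR_END,
    GeneModel,
    GenomeAnnotation,
    boundary_offset,
)
from .cohort_io import FusionCall

DEFAULT_TOLERANCE_BP = 2
DEFAULT_PROXIMAL_CUTOFF_BP = 100_000

INTERCHROMOSOMAL = "interchromosomal"
INTRACHROMOSOMAL_PROXIMAL = "intrachromosomal_proximal"
INTRACHROMOSOMAL_DISTAL = "intrachromosomal_distal"


class ClassificationError(KeyError):
    """A parental gene id is absent from the annotation."""

    def __init__(self, gene_id: str):
        super().__init__(gene_id)
        self.gene_id = gene_id


@dataclass(frozen=True)
class JunctionClass:
    value: str  # EE | EM | ME | MM
    offset5: int
    offset3: int


@dataclass(frozen=True)
class ChromosomalCategory:
    value: str
    distance_bp: int | None = None


@dataclass(frozen=True)
class ReadThroughArchitecture:
    donor_exon_from_start: int
    donor_exon_from_end: int
    acceptor_exon_from_start: int
    same_strand: bool
    donor_upstream: bool
    canonical_readthrough: bool
    isoform_label: str


@dataclass(frozen=True)
class AnnotatedFusion:
    call: FusionCall
    junction_class: JunctionClass
    category: ChromosomalCategory
    architecture: ReadThroughArchitecture | None = None


def _lookup(annotation: GenomeAnnotation, gene_id: str) -> GeneModel:
    try:
        return annotation.gene(gene_id)
    except KeyError:
        raise ClassificationError(gene_id) from None


def classify_junction(
    call: FusionCall,
    annotation: GenomeAnnotation,
    tolerance_bp: int = DEFAULT_TOLERANCE_BP,
) -> JunctionClass:
    """Label both junction sides E/M against the parental genes' boundaries.

    A side is E iff the breakpoint's nearest matching boundary (donor ends for
    the 5' side, acceptor starts for the 3' side) is within ``tolerance_bp``
    inclusive.  Raises :class:`ClassificationError` carrying the gene id when
    a parent is unannotated.
    """
    gene5 = _lookup(annotation, call.gene5)
    gene3 = _lookup(annotation, call.gene3)
    res5 = boundary_offset(gene5, call.pos5, DONOR_END)
    res3 = boundary_offset(gene3, call.pos3, ACCEPTOR_START)
    side5 = "E" if abs(res5.offset_bp) <= tolerance_bp else "M"
    side3 = "E" if abs(res3.offset_bp) <= tolerance_bp else "M"
    return JunctionClass(value=side5 + side3, offset5=res5.offset_bp, offset3=res3.offset_bp)


def chromosomal_category(
    call: FusionCall, cutoff_bp: int = DEFAULT_PROXIMAL_CUTOFF_BP
) -> ChromosomalCategory:
    """Inter- vs intrachromosomal, the latter split at *cutoff_bp* (default 100 kb)."""
    if call.chrom5 != call.chrom3:
        return ChromosomalCategory(INTERCHROMOSOMAL)
    distance = abs(call.pos3 - call.pos5)
    value = INTRACHROMOSOMAL_PROXIMAL if distance <= cutoff_bp else INTRACHROMOSOMAL_DISTAL
    return ChromosomalCategory(value, distance_bp=distance)


def _ordinal_for_side(gene: GeneModel, pos: int, side: str) -> tuple[int, int]:
    """(ordinal_from_start, ordinal_from_end) of the exon the breakpoint belongs to.

    Uses the nearest-boundary transcript; when the breakpoint sits inside an
    exon rather than at an edge, the containing exon's ordinals are reported.
    """
    res = boundary_offset(gene, pos, side)
    tx = next(t for t in gene.transcripts if t.transcript_id == res.transcript_id)
    containing = tx.containing_exon(pos)
    if containing is not None and res.offset_bp != 0:
        return containing, tx.exon_count - containing + 1
    return res.exon_ordinal_from_start, res.exon_ordinal_from_end


def annotate_architecture(
    call: FusionCall, annotation: GenomeAnnotation
) -> ReadThroughArchitecture:
    """Describe the junction in read-through (cis-SAGe) terms.

    Exon ordinals come from the boundary-matched transcript of each gene.
    ``canonical_readthrough`` is true only for the classic motif: same-strand
    neighbours with the donor gene upstream, junction joining the donor's
    second-to-last exon to the acceptor's exon 2.
    """
    gene5 = _lookup(annotation, call.gene5)
    gene3 = _lookup(annotation, call.gene3)
    donor_start, donor_end = _ordinal_for_side(gene5, call.pos5, DONOR_END)
    acceptor_start, _ = _ordinal_for_side(gene3, call.pos3, ACCEPTOR_START)
    same_strand = gene5.strand == gene3.strand and gene5.chrom == gene3.chrom
    if same_strand:
        # donor upstream: its transcription end precedes the acceptor's start
        # when both are read in transcript orientation
        if gene5.strand == "+":
            donor_upstream = gene5.tx_end < gene3.tx_start
        else:
            donor_upstream = gene5.tx_end > gene3.tx_start
    else:
        donor_upstream = False
    canonical = same_strand and donor_upstream and donor_end == 2 and acceptor_start == 2
    return ReadThroughArchitecture(
        donor_exon_from_start=donor_start,
        donor_exon_from_end=donor_end,
        acceptor_exon_from_start=acceptor_start,
        same_strand=same_strand,
        donor_upstream=donor_upstream,
        canonical_readthrough=canonical,
        isoform_label=f"e{donor_start}e{acceptor_start}",
    )


def annotate_call(
    call: FusionCall,
    annotation: GenomeAnnotation,
    tolerance_bp: int = DEFAULT_TOLERANCE_BP,
    proximal_cutoff_bp: int = DEFAULT_PROXIMAL_CUTOFF_BP,
) -> AnnotatedFusion:
    """Full annotation of one call: junction class, category, architecture."""
    jclass = classify_junction(call, annotation, tolerance_bp)
    category = chromosomal_category(call, proximal_cutoff_bp)
    architecture = annotate_architecture(call, annotation)
    return AnnotatedFusion(
        call=call, junction_class=jclass, category=category, architecture=architecture
    )
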