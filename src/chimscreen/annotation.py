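"""Gene-annotation model with exon-boundary queries.

The screen classifies fusion junctions by their distance to annotated exon
boundaries, so the central query here is: given a genomic position inside a
gene, how far is it from the nearest splice-donor end (or splice-acceptor
start) over all transcripts of that gene, and which exon ordinal does that
boundary belong to?

Coordinates are 1-based inclusive throughout (GTF convention).  Exons of a
transcript are stored in *transcript orientation* (5'->3' of the mRNA), so on
the minus strand exon 1 is the genomically last interval.  A "donor end" is
the transcript-orientation 3' edge of an exon; an "acceptor start" is its 5'
edge.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

DONOR_END = "donor_end"
ACCEPTOR_START = "acceptor_start"


class AnnotationError(ValueError):
    """Raised for malformed annotation input or invalid boundary queries."""


@dataclass
class TranscriptModel:
    """One transcript: ordered exons as 1-based inclusive genomic intervals.

    ``exons`` are sorted in transcript orientation: genomic starts strictly
    increasing on the plus strand, strictly decreasing on the minus strand.
    """

    transcript_id: str
    exons: list[tuple[int, int]]

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def length(self) -> int:
        return sum(hi - lo + 1 for lo, hi in self.exons)

    def validate(self, strand: str) -> None:
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id} has no exons")
        for lo, hi in self.exons:
            if lo > hi:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exon start {lo} > end {hi}"
                )
        starts = [lo for lo, _ in self.exons]
        ordered = sorted(starts, reverse=(strand == "-"))
        if starts != ordered or len(set(starts)) != len(starts):
            raise AnnotationError(
                f"transcript {self.transcript_id}: exons not ordered for strand {strand}"
            )
        genomic = sorted(self.exons)
        for (lo1, hi1), (lo2, hi2) in zip(genomic, genomic[1:]):
            if lo2 <= hi1:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exons {lo1}-{hi1} and "
                    f"{lo2}-{hi2} overlap"
                )

    def donor_end(self, ordinal: int) -> int:
        """Genomic coordinate of the transcript-orientation 3' edge of exon *ordinal* (1-based)."""
        lo, hi = self.exons[ordinal - 1]
        return hi if self._ascending() else lo

    def acceptor_start(self, ordinal: int) -> int:
        """Genomic coordinate of the transcript-orientation 5' edge of exon *ordinal* (1-based)."""
        lo, hi = self.exons[ordinal - 1]
        return lo if self._ascending() else hi

    def _ascending(self) -> bool:
        if len(self.exons) == 1:
            return True
        return self.exons[0][0] < self.exons[1][0]

    def containing_exon(self, pos: int) -> int | None:
        """1-based ordinal of the exon containing *pos*, or None if intronic/outside."""
        for i, (lo, hi) in enumerate(self.exons, start=1):
            if lo <= pos <= hi:
                return i
        return None

    def transcript_coord(self, pos: int, strand: str) -> int | None:
        """Map a genomic position inside an exon to a 1-based mRNA coordinate."""
        offset = 0
        for lo, hi in self.exons:
            if lo <= pos <= hi:
                within = (pos - lo) if strand == "+" else (hi - pos)
                return offset + within + 1
            offset += hi - lo + 1
        return None


@dataclass
class GeneModel:
    gene_id: str
    symbol: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def validate(self) -> None:
        if not self.symbol:
            raise AnnotationError(f"gene {self.gene_id}: empty symbol")
        if self.strand not in {"+", "-"}:
            raise AnnotationError(f"gene {self.gene_id}: strand must be + or -")
        for tx in self.transcripts:
            tx.validate(self.strand)

    @property
    def span(self) -> tuple[int, int]:
        los = [lo for tx in self.transcripts for lo, _ in tx.exons]
        his = [hi for tx in self.transcripts for _, hi in tx.exons]
        return min(los), max(his)

    @property
    def tx_start(self) -> int:
        """Transcription start in genomic coordinates (strand-aware)."""
        lo, hi = self.span
        return lo if self.strand == "+" else hi

    @property
    def tx_end(self) -> int:
        """Transcription end in genomic coordinates (strand-aware)."""
        lo, hi = self.span
        return hi if self.strand == "+" else lo


@dataclass
class BoundaryQueryResult:
    transcript_id: str
    exon_ordinal_from_start: int
    exon_ordinal_from_end: int
    offset_bp: int


@dataclass
class GenomeAnnotation:
    genes: dict[str, GeneModel] = field(default_factory=dict)

    @property
    def contig_names(self) -> set[str]:
        return {g.chrom for g in self.genes.values()}

    def gene(self, gene_id: str) -> GeneModel:
        """Look up a gene by id, falling back to symbol."""
        if gene_id in self.genes:
            return self.genes[gene_id]
        for g in self.genes.values():
            if g.symbol == gene_id:
                return g
        raise KeyError(gene_id)

    def __contains__(self, gene_id: str) -> bool:
        try:
            self.gene(gene_id)
            return True
        except KeyError:
            return False


@dataclass
class TranscriptSequenceSet:
    """Transcript id -> mRNA sequence over {A,C,G,T,N}."""

    sequences: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, tx_id: str) -> str:
        return self.sequences[tx_id]

    def items(self):
        return self.sequences.items()


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _first(attrs, *keys) -> str | None:
    for key in keys:
        if key in attrs and attrs[key]:
            return attrs[key][0]
    return None


def read_gtf(path: str | Path) -> GenomeAnnotation:
    """Parse exon features from a GTF (or GFF3-attribute-style) file.

    Only ``exon`` features are consumed; each must carry ``gene_id`` and
    ``transcript_id`` attributes (``gene_name`` is used as the symbol when
    present).  Transcripts with no exon lines are absent from the model.
    Minus-strand exons come out ordered 5'->3' of the mRNA.
    """
    exon_map: dict[tuple[str, str], list[tuple[int, int]]] = {}
    gene_meta: dict[str, tuple[str, str, str]] = {}  # id -> (symbol, chrom, strand)
    tx_gene: dict[str, str] = {}

    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # noqa: BLE001 - re-raise with location
                raise AnnotationError(f"{path}:{lineno}: unparseable line: {exc}") from exc
            if feat.featuretype != "exon":
                continue
            gene_id = _first(feat.attributes, "gene_id")
            tx_id = _first(feat.attributes, "transcript_id")
            if gene_id is None or tx_id is None:
                raise AnnotationError(
                    f"{path}:{lineno}: exon feature missing gene_id/transcript_id"
                )
            symbol = _first(feat.attributes, "gene_name") or gene_id
            if gene_id not in gene_meta:
                gene_meta[gene_id] = (symbol, feat.seqid, feat.strand)
            else:
                prev_symbol, chrom, strand = gene_meta[gene_id]
                if (chrom, strand) != (feat.seqid, feat.strand):
                    raise AnnotationError(
                        f"{path}:{lineno}: gene {gene_id} spans multiple "
                        "chromosomes or strands"
                    )
            prior_gene = tx_gene.setdefault(tx_id, gene_id)
            if prior_gene != gene_id:
                raise AnnotationError(
                    f"{path}:{lineno}: transcript {tx_id} assigned to two genes"
                )
            exon_map.setdefault((gene_id, tx_id), []).append((feat.start, feat.end))

    annotation = GenomeAnnotation()
    for (gene_id, tx_id), exons in exon_map.items():
        symbol, chrom, strand = gene_meta[gene_id]
        gene = annotation.genes.setdefault(
            gene_id, GeneModel(gene_id=gene_id, symbol=symbol, chrom=chrom, strand=strand)
        )
        exons = sorted(exons, reverse=(strand == "-"))
        gene.transcripts.append(TranscriptModel(transcript_id=tx_id, exons=exons))
    for gene in annotation.genes.values():
        gene.transcripts.sort(key=lambda tx: tx.transcript_id)
        gene.validate()
    return annotation


def write_gtf(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write exon features back out; ``read_gtf(write_gtf(x)) == x``."""
    with open(path, "wt") as fh:
        for gene_id in sorted(annotation.genes):
            gene = annotation.genes[gene_id]
            for tx in gene.transcripts:
                for lo, hi in sorted(tx.exons):
                    attrs = (
                        f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}"; '
                        f'gene_name "{gene.symbol}";'
                    )
                    fh.write(
                        f"{gene.chrom}\tchimscreen\texon\t{lo}\t{hi}\t.\t"
                        f"{gene.strand}\t.\t{attrs}\n"
                    )


def read_transcript_fasta(path: str | Path) -> TranscriptSequenceSet:
    """Load transcript sequences; ids are the first whitespace token of headers.

    Soft-masked (lowercase) bases are uppercased.  Duplicate ids and empty
    sequences are errors; an empty file yields an empty set with a warning.
    """
    sequences: dict[str, str] = {}
    with _open_text(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            seq = str(record.seq).upper()
            if record.id in sequences:
                raise AnnotationError(f"duplicate transcript id {record.id}")
            if not seq:
                raise AnnotationError(f"empty sequence for transcript {record.id}")
            sequences[record.id] = seq
    if not sequences:
        logger.warning("no FASTA records found in %s", path)
    return TranscriptSequenceSet(sequences)


def write_transcript_fasta(seqs: TranscriptSequenceSet, path: str | Path, width: int = 70) -> None:
    with open(path, "wt") as fh:
        for tx_id in sorted(seqs.sequences):
            fh.write(f">{tx_id}\n")
            seq = seqs.sequences[tx_id]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _orientation_sign(strand: str) -> int:
    return 1 if strand == "+" else -1


def iter_boundaries(gene: GeneModel, side: str) -> Iterator[tuple[TranscriptModel, int, int]]:
    """Yield (transcript, ordinal, genomic boundary coordinate) for one side kind."""
    for tx in gene.transcripts:
        for ordinal in range(1, tx.exon_count + 1):
            if side == DONOR_END:
                yield tx, ordinal, tx.donor_end(ordinal)
            elif side == ACCEPTOR_START:
                yield tx, ordinal, tx.acceptor_start(ordinal)
            else:
                raise AnnotationError(f"unknown boundary side {side!r}")


def boundary_offset(gene: GeneModel, genomic_pos: int, side: str) -> BoundaryQueryResult:
    """Nearest-boundary query over all transcripts of *gene*.

    The offset is signed in transcript orientation (query minus boundary), so
    a position 2 bp inside an exon measured from its donor end gives -2 on
    either strand.  Ties on |offset| go to the lexicographically smallest
    transcript id, then the smallest exon ordinal.
    """
    if not gene.transcripts:
        raise AnnotationError(f"gene {gene.gene_id} has no transcripts")
    sign = _orientation_sign(gene.strand)
    best: tuple[int, str, int] | None = None
    best_result: BoundaryQueryResult | None = None
    for tx, ordinal, boundary in iter_boundaries(gene, side):
        offset = (genomic_pos - boundary) * sign
        key = (abs(offset), tx.transcript_id, ordinal)
        if best is None or key < best:
            best = key
            best_result = BoundaryQueryResult(
                transcript_id=tx.transcript_id,
                exon_ordinal_from_start=ordinal,
                exon_ordinal_from_end=tx.exon_count - ordinal + 1,
                offset_bp=offset,
            )
    assert best_result is not None
    return best_result
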