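"""Genome and annotation I/O: gene models, CDS extraction, intron inference.

Coordinate conventions
----------------------
Annotation input follows the GFF3/GTF convention (1-based, inclusive).
Everything in memory is 0-based, half-open, on the forward strand of the
chromosome. Serialized marker tables report 1-based inclusive positions;
BED output is 0-based half-open, per the BED standard.

CDS granularity is one segment per annotated CDS feature line (the coding
piece of one exon, UTRs excluded). For genes with several transcripts the
transcript with the largest total CDS length is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

if TYPE_CHECKING:  # avoid a runtime cycle: marker_discovery imports genome_io
    from .marker_discovery import MarkerRecord

logger = logging.getLogger("epicminer")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: characters accepted verbatim in genome sequences; everything else maps to N
_VALID = frozenset("ACGTN")


def sanitize_sequence(seq: str) -> str:
    """Uppercase a nucleotide string and map non-ACGTN characters to N."""
    seq = seq.upper()
    if set(seq) <= _VALID:
        return seq
    return "".join(c if c in _VALID else "N" for c in seq)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeRecord:
    """A genome: a label plus its chromosome sequences (uppercase ACGTN)."""

    genome_id: str
    chromosomes: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.chromosomes.items():
            if not seq:
                raise ValueError(f"empty sequence for chromosome {name!r}")
        self.chromosomes = {
            name: sanitize_sequence(seq) for name, seq in self.chromosomes.items()
        }

    def slice(self, chromosome: str, start: int, end: int, strand: str = "+") -> str:
        """Extract ``[start, end)`` of a chromosome, reverse-complemented on '-'."""
        seq = self.chromosomes[chromosome][start:end]
        return reverse_complement(seq) if strand == "-" else seq


@dataclass
class CDSSegment:
    """One annotated coding segment of a gene.

    ``start``/``end`` are 0-based half-open chromosomal coordinates;
    ``sequence`` is in transcription orientation (reverse complement of the
    chromosomal slice for minus-strand genes).
    """

    segment_id: str
    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.segment_id}: end must exceed start")
        if len(self.sequence) != self.length:
            raise ValueError(f"{self.segment_id}: sequence/coordinate length mismatch")


@dataclass
class GeneModel:
    """A gene as an ordered run of CDS segments on one chromosome and strand.

    Segments are stored in ascending chromosomal order regardless of strand.
    """

    gene_id: str
    chromosome: str
    strand: str
    description: str
    cds_segments: list[CDSSegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cds_segments.sort(key=lambda s: s.start)
        prev_end = -1
        for seg in self.cds_segments:
            if seg.chromosome != self.chromosome or seg.strand != self.strand:
                raise ValueError(f"{self.gene_id}: segment off gene chromosome/strand")
            if seg.start < prev_end:
                raise ValueError(f"{self.gene_id}: overlapping CDS segments")
            prev_end = seg.end

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_segments[0].start, self.cds_segments[-1].end


@dataclass
class IntronSpan:
    """The gap between two consecutive CDS segments of one gene.

    ``upstream_segment_index`` is the 0-based index (in chromosomal order) of
    the segment immediately left of the intron.
    """

    gene_id: str
    upstream_segment_index: int
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_genome(
    fasta_path: str | Path,
    annotation_path: str | Path | None = None,
    genome_id: str | None = None,
) -> tuple[GenomeRecord, list[GeneModel]]:
    """Load a genome FASTA and, optionally, its gene annotation.

    References may be given without annotation, in which case the gene list
    is empty. Genes with no CDS feature are dropped (with a logged count);
    genes whose CDS reference an unknown chromosome are skipped with a
    warning.
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise FileNotFoundError(fasta_path)
    chromosomes: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in chromosomes:
            raise ValueError(f"duplicate chromosome id {rec.id!r} in {fasta_path}")
        chromosomes[rec.id] = str(rec.seq)
    genome = GenomeRecord(genome_id or fasta_path.stem, chromosomes)
    genes: list[GeneModel] = []
    if annotation_path is not None:
        annotation_path = Path(annotation_path)
        if not annotation_path.exists():
            raise FileNotFoundError(annotation_path)
        genes = _read_gene_models(annotation_path, genome)
    return genome, genes


def _read_gene_models(annotation_path: Path, genome: GenomeRecord) -> list[GeneModel]:
    is_gtf = annotation_path.suffix.lower() == ".gtf"
    db = gffutils.create_db(
        str(annotation_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=is_gtf,
        disable_infer_transcripts=is_gtf,
    )

    # map transcript id -> gene id so CDS Parent chains resolve either way
    tx_to_gene: dict[str, str] = {}
    gene_meta: dict[str, tuple[str, str]] = {}  # gene -> (description, strand)
    n_genes_seen = 0
    for ftype in ("gene",):
        for g in db.features_of_type(ftype):
            n_genes_seen += 1
            desc = ""
            for key in ("description", "Note", "product", "gene_name"):
                if key in g.attributes:
                    desc = g.attributes[key][0]
                    break
            gene_meta[g.id] = (desc, g.strand)
    for ftype in ("mRNA", "transcript"):
        try:
            for t in db.features_of_type(ftype):
                parents = t.attributes.get("Parent", [t.id])
                tx_to_gene[t.id] = parents[0]
        except Exception:  # pragma: no cover - feature type absent
            continue

    # group CDS features by (gene, transcript)
    by_tx: dict[tuple[str, str], list[gffutils.Feature]] = {}
    for cds in db.features_of_type("CDS"):
        if is_gtf or ("gene_id" in cds.attributes and "transcript_id" in cds.attributes):
            gene_id = cds.attributes["gene_id"][0]
            tx_id = cds.attributes.get("transcript_id", [gene_id])[0]
        else:
            parent = cds.attributes.get("Parent", [None])[0]
            if parent is None:
                logger.warning("CDS %s has no Parent; skipped", cds.id)
                continue
            gene_id = tx_to_gene.get(parent, parent)
            tx_id = parent
        by_tx.setdefault((gene_id, tx_id), []).append(cds)

    # per gene: longest-total-CDS transcript
    by_gene: dict[str, list[gffutils.Feature]] = {}
    for (gene_id, _tx), feats in sorted(by_tx.items()):
        total = sum(f.end - f.start + 1 for f in feats)
        if gene_id not in by_gene or total > sum(
            f.end - f.start + 1 for f in by_gene[gene_id]
        ):
            by_gene[gene_id] = feats

    genes: list[GeneModel] = []
    n_dropped = max(0, n_genes_seen - len(by_gene))
    for gene_id, feats in by_gene.items():
        chrom = feats[0].seqid
        if chrom not in genome.chromosomes:
            logger.warning(
                "gene %s references unknown chromosome %s; skipped", gene_id, chrom
            )
            continue
        strand = feats[0].strand
        desc, meta_strand = gene_meta.get(gene_id, ("", strand))
        if strand not in "+-":
            strand = meta_strand if meta_strand in "+-" else "+"
        feats = sorted(feats, key=lambda f: f.start)
        segments = []
        for i, f in enumerate(feats):
            start, end = f.start - 1, f.end  # GFF 1-based inclusive -> half-open
            seq = genome.slice(chrom, start, end, strand)
            segments.append(
                CDSSegment(
                    segment_id=f"{gene_id}.cds{i + 1}",
                    gene_id=gene_id,
                    chromosome=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    sequence=seq,
                )
            )
        genes.append(GeneModel(gene_id, chrom, strand, desc, segments))
    if n_dropped:
        logger.info("dropped %d annotated genes lacking CDS features", n_dropped)
    return genes


def infer_introns(gene: GeneModel) -> list[IntronSpan]:
    """Derive intron coordinates as the gaps between consecutive CDS segments.

    A gene with a single segment has no introns. Abutting segments (zero gap)
    produce no intron and log a warning.
    """
    if not gene.cds_segments:
        raise ValueError(f"{gene.gene_id}: gene has no CDS segments")
    introns: list[IntronSpan] = []
    for i in range(len(gene.cds_segments) - 1):
        left, right = gene.cds_segments[i], gene.cds_segments[i + 1]
        if right.start == left.end:
            logger.warning(
                "%s: segments %d/%d abut; no intron emitted", gene.gene_id, i, i + 1
            )
            continue
        introns.append(IntronSpan(gene.gene_id, i, left.end, right.start))
    return introns


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_genome_fasta(genome: GenomeRecord, out_path: str | Path, width: int = 80) -> None:
    with open(out_path, "w") as fh:
        for name, seq in genome.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(genes: Iterable[GeneModel], out_path: str | Path, source: str = "epicminer") -> None:
    """Write gene models as GFF3 (gene -> mRNA -> CDS, 1-based inclusive)."""
    with open(out_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            start, end = gene.span
            attrs = f"ID={gene.gene_id}"
            if gene.description:
                attrs += f";description={gene.description}"
            fh.write(
                f"{gene.chromosome}\t{source}\tgene\t{start + 1}\t{end}\t.\t"
                f"{gene.strand}\t.\t{attrs}\n"
            )
            tx = f"{gene.gene_id}.t1"
            fh.write(
                f"{gene.chromosome}\t{source}\tmRNA\t{start + 1}\t{end}\t.\t"
                f"{gene.strand}\t.\tID={tx};Parent={gene.gene_id}\n"
            )
            for seg in gene.cds_segments:
                fh.write(
                    f"{gene.chromosome}\t{source}\tCDS\t{seg.start + 1}\t{seg.end}\t.\t"
                    f"{gene.strand}\t0\tID={seg.segment_id};Parent={tx}\n"
                )


def _species_columns(markers: Iterable["MarkerRecord"]) -> list[str]:
    species: list[str] = []
    for m in markers:
        for sp in m.species_intron_lengths:
            if sp not in species:
                species.append(sp)
    return species


def write_marker_table(markers: list["MarkerRecord"], out_path: str | Path) -> None:
    """Serialize the marker catalogue as TSV.

    Columns: Locus, Chromosome, Marker start (bp) [1-based], Gene description,
    Mean exon identity, then one per-species intron-length column. Rows are
    ordered by chromosome then start.
    """
    markers = sorted(markers, key=lambda m: (m.chromosome, m.marker_start))
    species = _species_columns(markers)
    with open(out_path, "w") as fh:
        header = ["Locus", "Chromosome", "Marker start (bp)", "Gene description",
                  "Mean exon identity"] + [f"Intron len {sp} (bp)" for sp in species]
        fh.write("\t".join(header) + "\n")
        for m in markers:
            row = [
                m.locus_name,
                m.chromosome,
                str(m.marker_start + 1),
                m.gene_description,
                f"{m.mean_identity:.2f}",
            ]
            row += [
                str(m.species_intron_lengths[sp]) if sp in m.species_intron_lengths else "NA"
                for sp in species
            ]
            fh.write("\t".join(row) + "\n")


def write_marker_fasta(
    markers: list["MarkerRecord"],
    genomes: Mapping[str, GenomeRecord] | GenomeRecord,
    out_path: str | Path,
) -> None:
    """Write one FASTA record per marker per species with a known span.

    Each record covers the upstream flanking exon through the downstream
    flanking exon, introns included. Headers encode locus, species and the
    1-based chromosomal span. Out-of-bounds spans are skipped with a warning.
    """
    if isinstance(genomes, GenomeRecord):
        genomes = {genomes.genome_id: genomes}
    with open(out_path, "w") as fh:
        for m in sorted(markers, key=lambda x: (x.chromosome, x.marker_start)):
            for sp, (chrom, start, end, strand) in m.species_spans.items():
                if sp not in genomes:
                    continue
                genome = genomes[sp]
                if chrom not in genome.chromosomes or start < 0 or end > len(
                    genome.chromosomes[chrom]
                ):
                    logger.warning(
                        "marker %s span out of bounds in %s; skipped", m.locus_name, sp
                    )
                    continue
                seq = genome.slice(chrom, start, end, strand)
                fh.write(f">{m.locus_name}|{sp}|{chrom}:{start + 1}-{end}({strand})\n")
                fh.write(str(Seq(seq)) + "\n")


def write_marker_bed(markers: list["MarkerRecord"], out_path: str | Path) -> None:
    """BED6 of marker intervals on the query genome (0-based half-open)."""
    with open(out_path, "w") as fh:
        for m in sorted(markers, key=lambda x: (x.chromosome, x.marker_start)):
            start, end = m.query_span
            score = min(1000, int(round(m.mean_identity * 1000)))
            fh.write(
                f"{m.chromosome}\t{start}\t{end}\t{m.locus_name}\t{score}\t{m.query_strand}\n"
            )
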