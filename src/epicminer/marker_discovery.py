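"""The EPIC marker pipeline: single-copy CDS detection, conservation mapping,
intron-size and identity screening, nearby-marker merging, and naming.

The procedure mirrors a whole-genome comparison strategy for finding short
introns flanked by single-copy, conserved coding exons:

1. collect all annotated CDS segments of the query genome and keep the
   large ones (>= 100 bp by default);
2. compare them all-vs-all and discard any segment with another sequence
   covering more than 20% of it at more than 40% identity (not single-copy);
3. map each surviving segment onto every reference genome by local
   alignment (annotation-free), infer each reference's intron length from
   the gap between the two flanking-exon hits;
4. keep exon junctions whose intron is <= 1,000 bp in at least one species
   and whose mean flanking-exon identity across references reaches the
   chosen tier (65 / 80 / 85%);
5. report qualifying junctions within 1,000 bp of each other as one marker.

Markers are named from the last five digits of the gene identifier plus
"E" and an ordinal distinguishing markers within the gene.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from statistics import fmean
from typing import Iterable, Sequence

from .alignment import (
    EPIC_SCORING,
    HomologyHit,
    ScoringScheme,
    hit_metrics,
    local_align,
    score_only,
    search_all,
)
from .genome_io import (
    CDSSegment,
    GeneModel,
    GenomeRecord,
    infer_introns,
    read_genome,
    reverse_complement,
    write_marker_bed,
    write_marker_fasta,
    write_marker_table,
)

logger = logging.getLogger("epicminer")

__all__ = [
    "PipelineParams",
    "EpicCandidate",
    "MarkerRecord",
    "ReferenceHit",
    "RunReport",
    "filter_large_cds",
    "single_copy_filter",
    "map_to_reference",
    "find_epic_candidates",
    "mean_exon_identity",
    "merge_nearby",
    "count_markers_by_tier",
    "locus_name_for",
    "run_pipeline",
]


@dataclass(frozen=True)
class PipelineParams:
    """Tunable thresholds of the marker pipeline.

    The defaults are the published operating point: CDS >= 100 bp,
    single-copy means no other sequence with coverage > 0.20 and identity
    > 0.40 (strict inequalities), intron <= 1,000 bp in at least one
    species, mean flanking-exon identity tier 0.85 (0.65 and 0.80 are the
    permissive tiers), and qualifying junctions within 1,000 bp reported as
    one marker.
    """

    min_cds_len: int = 100
    copy_coverage_thresh: float = 0.20
    copy_identity_thresh: float = 0.40
    max_intron_len: int = 1000
    min_mean_identity: float = 0.85
    merge_window: int = 1000
    require_all_references: bool = True
    # mapping floors: a reference hit below this identity, or covering less
    # than this fraction of the exon, counts as unmapped (a short spurious
    # local hit can reach high identity, so identity alone cannot reject it)
    map_identity_floor: float = 0.50
    map_coverage_floor: float = 0.50
    # minimum local-alignment score for the all-vs-all self-comparison
    min_hit_score: float = 20.0
    # "upstream_exon" reports the upstream flanking exon start as the marker
    # start; "intron" reports the intron start instead
    marker_start_convention: str = "upstream_exon"

    def __post_init__(self) -> None:
        for name in (
            "copy_coverage_thresh",
            "copy_identity_thresh",
            "min_mean_identity",
            "map_identity_floor",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.min_cds_len <= 0 or self.max_intron_len <= 0 or self.merge_window < 0:
            raise ValueError("lengths must be positive")
        if self.marker_start_convention not in ("upstream_exon", "intron"):
            raise ValueError("marker_start_convention must be 'upstream_exon' or 'intron'")


@dataclass
class ReferenceHit:
    """Best hit of a query CDS segment on a reference genome.

    ``start``/``end`` are forward-strand chromosomal coordinates (0-based,
    half-open) regardless of the hit strand.
    """

    hit: HomologyHit
    chromosome: str
    strand: str
    start: int
    end: int

    @property
    def identity(self) -> float:
        return self.hit.identity


@dataclass
class EpicCandidate:
    """A qualifying exon junction: an intron with conserved flanking exons."""

    gene_id: str
    chromosome: str
    marker_start: int
    upstream_segment_id: str
    downstream_segment_id: str
    species_intron_lengths: dict[str, int]
    reference_identities: dict[str, float]
    mean_identity: float
    query_span: tuple[int, int]  # upstream exon start .. downstream exon end
    query_strand: str
    species_spans: dict[str, tuple[str, int, int, str]]
    gene_description: str = ""
    flank_lengths: tuple[int, int] = (0, 0)


@dataclass
class MarkerRecord:
    """A reported marker: one or more merged qualifying junctions."""

    locus_name: str
    gene_id: str
    chromosome: str
    marker_start: int
    gene_description: str
    mean_identity: float
    n_introns_merged: int
    species_intron_lengths: dict[str, int]
    query_span: tuple[int, int]
    query_strand: str
    species_spans: dict[str, tuple[str, int, int, str]]
    candidates: list[EpicCandidate] = field(default_factory=list, repr=False)


def locus_name_for(gene_id: str, ordinal: int) -> str:
    """Marker name: last five digits of the gene identifier + 'E' + ordinal.

    Gene ids with fewer than five digits are left-padded with zeros, so a
    gene ...59107 yields '59107E2' for its second marker.
    """
    digits = re.sub(r"\D", "", gene_id)
    if not digits:
        digits = "00000"
    return f"{digits[-5:].zfill(5)}E{ordinal}"


# ---------------------------------------------------------------------------
# Stage 1-2: size and copy-number screens
# ---------------------------------------------------------------------------

def filter_large_cds(segments: Sequence[CDSSegment], min_len: int = 100) -> list[CDSSegment]:
    """Keep CDS segments of length >= ``min_len`` (order preserved)."""
    return [s for s in segments if s.length >= min_len]


def single_copy_filter(
    segments: Sequence[CDSSegment],
    self_hits: Iterable[HomologyHit],
    params: PipelineParams = PipelineParams(),
) -> list[CDSSegment]:
    """Remove segments that have a same-genome homolog above both thresholds.

    A segment is discarded iff some non-self hit covers more than
    ``copy_coverage_thresh`` of it at identity above
    ``copy_identity_thresh`` (both strict).
    """
    known = {s.segment_id for s in segments}
    removed: set[str] = set()
    for h in self_hits:
        if h.query_id not in known or h.subject_id not in known:
            raise ValueError(f"hit references unknown segment: {h.query_id}/{h.subject_id}")
        if h.query_id == h.subject_id:
            continue
        if h.coverage > params.copy_coverage_thresh and h.identity > params.copy_identity_thresh:
            removed.add(h.query_id)
    return [s for s in segments if s.segment_id not in removed]


# ---------------------------------------------------------------------------
# Stage 3: annotation-free mapping onto references
# ---------------------------------------------------------------------------

def map_to_reference(
    query_segment: CDSSegment,
    reference: GenomeRecord,
    scoring: ScoringScheme = EPIC_SCORING,
    min_identity_floor: float = 0.50,
    min_coverage_floor: float = 0.50,
) -> ReferenceHit | None:
    """Best local hit of a CDS segment on a reference genome, both strands.

    Returns ``None`` when no positive-scoring hit exists, or when the best
    hit's identity falls below ``min_identity_floor``, or when it covers
    less than ``min_coverage_floor`` of the segment (short spurious local
    hits have high identity, so both floors are needed to call a segment
    absent). Coordinates are reported on the forward strand of the
    reference chromosome.
    """
    best: tuple[float, str, str] | None = None  # (score, chrom, strand)
    for chrom, seq in reference.chromosomes.items():
        for strand, subject in (("+", seq), ("-", reverse_complement(seq))):
            s = score_only(query_segment.sequence, subject, scoring)
            if best is None or s > best[0]:
                best = (s, chrom, strand)
    if best is None or best[0] <= 0:
        return None
    _, chrom, strand = best
    seq = reference.chromosomes[chrom]
    subject = seq if strand == "+" else reverse_complement(seq)
    aln = local_align(
        query_segment.sequence,
        subject,
        scoring,
        query_id=query_segment.segment_id,
        subject_id=f"{reference.genome_id}:{chrom}",
    )
    hit = hit_metrics(aln, query_segment.length)
    if aln.is_empty or hit.identity < min_identity_floor or hit.coverage < min_coverage_floor:
        return None
    if strand == "+":
        start, end = aln.subject_start, aln.subject_end
    else:
        start, end = len(seq) - aln.subject_end, len(seq) - aln.subject_start
    return ReferenceHit(hit, chrom, strand, start, end)


# ---------------------------------------------------------------------------
# Stage 4: candidate discovery
# ---------------------------------------------------------------------------

def _reference_intron_gap(up: ReferenceHit, down: ReferenceHit) -> int | None:
    """Distance between the flanking hits on the reference, or None.

    The two hits must lie on the same chromosome and strand; which comes
    first on the forward strand depends on the relative orientation of the
    query gene and the reference copy, so the gap is taken between the two
    hits in coordinate order. Overlapping hits make the reference unmapped
    for this junction.
    """
    if up.chromosome != down.chromosome or up.strand != down.strand:
        return None
    first, second = sorted((up, down), key=lambda h: h.start)
    gap = second.start - first.end
    return gap if gap >= 0 else None


def mean_exon_identity(candidate: EpicCandidate) -> float:
    """Mean, over mapped references, of the two flanking-exon identities."""
    if not candidate.reference_identities:
        raise ValueError("candidate has no mapped references")
    return fmean(candidate.reference_identities.values())


def find_epic_candidates(
    query: GenomeRecord,
    genes: Sequence[GeneModel],
    references: Sequence[GenomeRecord],
    params: PipelineParams = PipelineParams(),
    scoring: ScoringScheme = EPIC_SCORING,
    surviving_ids: set[str] | None = None,
    _hit_cache: dict[tuple[str, str], ReferenceHit | None] | None = None,
) -> list[EpicCandidate]:
    """Screen every consecutive pair of surviving CDS segments.

    A junction qualifies when (a) both flanking segments map to every
    required reference, (b) the intron is <= ``max_intron_len`` in at least
    one species (query included; a reference's intron length is the gap
    between its two flanking hits), and (c) the mean flanking-exon identity
    over mapped references reaches ``min_mean_identity`` (after rounding to
    two decimals, matching the published tier convention).

    ``surviving_ids`` is the output of the copy-number screen; ``None``
    means all segments survived.
    """
    cache: dict[tuple[str, str], ReferenceHit | None] = (
        _hit_cache if _hit_cache is not None else {}
    )

    def mapped(seg: CDSSegment, ref: GenomeRecord) -> ReferenceHit | None:
        key = (seg.segment_id, ref.genome_id)
        if key not in cache:
            cache[key] = map_to_reference(
                seg, ref, scoring, params.map_identity_floor, params.map_coverage_floor
            )
        return cache[key]

    candidates: list[EpicCandidate] = []
    for gene in genes:
        introns = infer_introns(gene) if len(gene.cds_segments) > 1 else []
        for intron in introns:
            i = intron.upstream_segment_index
            up, down = gene.cds_segments[i], gene.cds_segments[i + 1]
            if surviving_ids is not None and (
                up.segment_id not in surviving_ids or down.segment_id not in surviving_ids
            ):
                continue
            if up.length < params.min_cds_len or down.length < params.min_cds_len:
                continue
            lengths: dict[str, int] = {query.genome_id: intron.length}
            identities: dict[str, float] = {}
            spans: dict[str, tuple[str, int, int, str]] = {
                query.genome_id: (gene.chromosome, up.start, down.end, gene.strand)
            }
            for ref in references:
                up_hit, down_hit = mapped(up, ref), mapped(down, ref)
                if up_hit is None or down_hit is None:
                    continue
                gap = _reference_intron_gap(up_hit, down_hit)
                if gap is None:
                    logger.debug(
                        "%s junction %d: discordant flank hits in %s",
                        gene.gene_id, i, ref.genome_id,
                    )
                    continue
                lengths[ref.genome_id] = gap
                identities[ref.genome_id] = (up_hit.identity + down_hit.identity) / 2
                spans[ref.genome_id] = (
                    up_hit.chromosome,
                    min(up_hit.start, down_hit.start),
                    max(up_hit.end, down_hit.end),
                    up_hit.strand,
                )
            if not identities:
                continue
            if params.require_all_references and len(identities) < len(references):
                continue
            if min(lengths.values()) > params.max_intron_len:
                continue
            mean_id = fmean(identities.values())
            if round(mean_id, 2) < params.min_mean_identity:
                continue
            marker_start = (
                up.start if params.marker_start_convention == "upstream_exon"
                else intron.start
            )
            candidates.append(
                EpicCandidate(
                    gene_id=gene.gene_id,
                    chromosome=gene.chromosome,
                    marker_start=marker_start,
                    upstream_segment_id=up.segment_id,
                    downstream_segment_id=down.segment_id,
                    species_intron_lengths=lengths,
                    reference_identities=identities,
                    mean_identity=mean_id,
                    query_span=(up.start, down.end),
                    query_strand=gene.strand,
                    species_spans=spans,
                    gene_description=gene.description,
                    flank_lengths=(up.length, down.length),
                )
            )
    return candidates


# ---------------------------------------------------------------------------
# Stage 5: merging and naming
# ---------------------------------------------------------------------------

def merge_nearby(
    candidates: Sequence[EpicCandidate], merge_window: int = 1000
) -> list[MarkerRecord]:
    """Report qualifying junctions of a gene within ``merge_window`` bp of
    each other as a single marker covering the union span.

    Proximity is measured between query-genome spans and chained
    transitively. The merged record's mean identity is the mean over its
    constituent junctions; per-species intron lengths are summed over
    constituents for species mapped in all of them. Output is sorted by
    chromosome then start; ordinals are assigned within each gene by
    ascending start.
    """
    by_gene: dict[str, list[EpicCandidate]] = {}
    for c in candidates:
        by_gene.setdefault(c.gene_id, []).append(c)

    records: list[MarkerRecord] = []
    for gene_id, cands in by_gene.items():
        cands = sorted(cands, key=lambda c: c.query_span[0])
        clusters: list[list[EpicCandidate]] = []
        for c in cands:
            if clusters and c.query_span[0] - max(
                x.query_span[1] for x in clusters[-1]
            ) <= merge_window:
                clusters[-1].append(c)
            else:
                clusters.append([c])
        for ordinal, cluster in enumerate(
            sorted(clusters, key=lambda cl: min(c.query_span[0] for c in cl)), start=1
        ):
            span = (
                min(c.query_span[0] for c in cluster),
                max(c.query_span[1] for c in cluster),
            )
            common_species = set.intersection(
                *(set(c.species_intron_lengths) for c in cluster)
            )
            lengths = {
                sp: sum(c.species_intron_lengths[sp] for c in cluster)
                for sp in sorted(common_species)
            }
            span_species = set.intersection(*(set(c.species_spans) for c in cluster))
            spans = {}
            for sp in sorted(span_species):
                chroms = {c.species_spans[sp][0] for c in cluster}
                strands = {c.species_spans[sp][3] for c in cluster}
                if len(chroms) > 1 or len(strands) > 1:
                    continue
                spans[sp] = (
                    chroms.pop(),
                    min(c.species_spans[sp][1] for c in cluster),
                    max(c.species_spans[sp][2] for c in cluster),
                    strands.pop(),
                )
            first = min(cluster, key=lambda c: c.query_span[0])
            records.append(
                MarkerRecord(
                    locus_name=locus_name_for(gene_id, ordinal),
                    gene_id=gene_id,
                    chromosome=first.chromosome,
                    marker_start=min(c.marker_start for c in cluster),
                    gene_description=first.gene_description,
                    mean_identity=fmean(c.mean_identity for c in cluster),
                    n_introns_merged=len(cluster),
                    species_intron_lengths=lengths,
                    query_span=span,
                    query_strand=first.query_strand,
                    species_spans=spans,
                    candidates=list(cluster),
                )
            )
    records.sort(key=lambda m: (m.chromosome, m.marker_start))
    return records


def count_markers_by_tier(
    candidates: Sequence[EpicCandidate],
    tiers: Sequence[float] = (0.65, 0.80, 0.85),
    merge_window: int = 1000,
) -> dict[float, int]:
    """Marker counts after re-screening one candidate set at several
    identity tiers (the 65/80/85% reporting convention).

    Candidates should be discovered with ``min_mean_identity`` at or below
    the lowest tier; each tier keeps candidates whose rounded mean identity
    reaches it, then merges and counts.
    """
    counts: dict[float, int] = {}
    for tier in tiers:
        kept = [c for c in candidates if round(c.mean_identity, 2) >= tier]
        counts[tier] = len(merge_nearby(kept, merge_window))
    return counts


# ---------------------------------------------------------------------------
# End-to-end
# ---------------------------------------------------------------------------

@dataclass
class RunReport:
    """Per-stage counts and provenance of a pipeline run."""

    n_cds_total: int = 0
    n_cds_large: int = 0
    n_cds_single_copy: int = 0
    n_candidates: int = 0
    n_markers: int = 0
    params: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    wall_clock_s: float = 0.0

    def to_json(self, out_path: str | Path) -> None:
        with open(out_path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    query_fasta: str | Path,
    query_annotation: str | Path,
    reference_fastas: Sequence[str | Path],
    params: PipelineParams = PipelineParams(),
    scoring: ScoringScheme = EPIC_SCORING,
    out_prefix: str | Path | None = None,
) -> tuple[list[MarkerRecord], RunReport]:
    """Run the whole marker pipeline from files to catalogue.

    Deterministic given inputs and parameters. When ``out_prefix`` is set,
    writes ``<prefix>.markers.tsv``, ``.markers.fasta``, ``.markers.bed``
    and ``.report.json``. An empty catalogue is a successful outcome.
    """
    t0 = time.monotonic()
    query, genes = read_genome(query_fasta, query_annotation, genome_id="query")
    references = []
    for i, path in enumerate(reference_fastas, start=1):
        ref, _ = read_genome(path, None, genome_id=Path(path).stem)
        references.append(ref)

    all_segments = [seg for g in genes for seg in g.cds_segments]
    large = filter_large_cds(all_segments, params.min_cds_len)
    self_hits = search_all(large, large, scoring, params.min_hit_score)
    single = single_copy_filter(large, self_hits, params)
    surviving = {s.segment_id for s in single}
    candidates = find_epic_candidates(
        query, genes, references, params, scoring, surviving_ids=surviving
    )
    markers = merge_nearby(candidates, params.merge_window)

    report = RunReport(
        n_cds_total=len(all_segments),
        n_cds_large=len(large),
        n_cds_single_copy=len(single),
        n_candidates=len(candidates),
        n_markers=len(markers),
        params=asdict(params),
        inputs={
            "query_fasta": {"path": str(query_fasta), "sha256": _sha256(query_fasta)},
            "query_annotation": {
                "path": str(query_annotation),
                "sha256": _sha256(query_annotation),
            },
            "references": [
                {"path": str(p), "sha256": _sha256(p)} for p in reference_fastas
            ],
        },
        wall_clock_s=round(time.monotonic() - t0, 3),
    )
    logger.info(
        "pipeline: %d CDS -> %d large -> %d single-copy -> %d candidates -> %d markers",
        report.n_cds_total,
        report.n_cds_large,
        report.n_cds_single_copy,
        report.n_candidates,
        report.n_markers,
    )
    if out_prefix is not None:
        prefix = Path(out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        write_marker_table(markers, f"{prefix}.markers.tsv")
        genomes = {query.genome_id: query, **{r.genome_id: r for r in references}}
        write_marker_fasta(markers, genomes, f"{prefix}.markers.fasta")
        write_marker_bed(markers, f"{prefix}.markers.bed")
        report.to_json(f"{prefix}.report.json")
    return markers, report
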