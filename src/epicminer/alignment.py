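"""Affine-gap local alignment with identity/coverage metrics.

The homology-search step of the marker pipeline, with a scoring choice that
makes exon comparison tolerant of short low-matching stretches between
distant species: the mismatch penalty is relaxed from the stock nucleotide-
search default of -3 to -1 (match reward +1 in both cases). The engine is
an exact affine-gap Smith-Waterman (Bio.Align.PairwiseAligner); identity
counts identical columns over all aligned columns, gap columns included,
and coverage is the fraction of the full query covered by aligned query
bases — the conventions of BLAST-style nucleotide search.

Gap model: a gap of length L scores ``gap_open + L * gap_extend`` (both
values are non-positive scores, so the classic "cost 5 to open, 2 to
extend" convention is ``gap_open=-5, gap_extend=-2``).

N is never a match: any column involving N (including N/N) scores the
mismatch penalty and does not count as identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import CDSSegment, sanitize_sequence

__all__ = [
    "ScoringScheme",
    "LocalAlignment",
    "HomologyHit",
    "BLASTN_SCORING",
    "EPIC_SCORING",
    "local_align",
    "hit_metrics",
    "search_all",
    "score_only",
    "write_hit_table",
]


@dataclass(frozen=True)
class ScoringScheme:
    """Scoring parameters for nucleotide local alignment.

    Defaults are the relaxed-mismatch scheme used throughout the marker
    pipeline; ``BLASTN_SCORING`` keeps the stock -3 mismatch for comparison.
    """

    match_reward: int = 1
    mismatch_penalty: int = -1
    gap_open: int = -5
    gap_extend: int = -2

    def __post_init__(self) -> None:
        if self.match_reward <= 0:
            raise ValueError("match_reward must be positive")
        if self.mismatch_penalty > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be non-positive")


EPIC_SCORING = ScoringScheme()
BLASTN_SCORING = ScoringScheme(mismatch_penalty=-3)


@lru_cache(maxsize=8)
def _aligner(scoring: ScoringScheme) -> Align.PairwiseAligner:
    matrix = substitution_matrices.Array("ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            if a == b and a != "N":
                matrix[a, b] = float(scoring.match_reward)
            else:
                matrix[a, b] = float(scoring.mismatch_penalty)
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    # PairwiseAligner charges open on the first gapped position, extend on
    # the rest; our convention charges open once plus extend per position.
    aligner.open_gap_score = float(scoring.gap_open + scoring.gap_extend)
    aligner.extend_gap_score = float(scoring.gap_extend)
    return aligner


@dataclass
class LocalAlignment:
    """An optimal local alignment between two sequences.

    Intervals are 0-based half-open in the respective sequences; an empty
    alignment (no positive-scoring pair) has score 0 and zero columns.
    """

    query_id: str
    subject_id: str
    query_start: int = 0
    query_end: int = 0
    subject_start: int = 0
    subject_end: int = 0
    n_columns: int = 0
    n_matches: int = 0
    n_gap_columns: int = 0
    score: float = 0.0

    @property
    def query_span(self) -> int:
        """Aligned (non-gap) query bases."""
        return self.query_end - self.query_start

    @property
    def subject_span(self) -> int:
        return self.subject_end - self.subject_start

    @property
    def is_empty(self) -> bool:
        return self.n_columns == 0


@dataclass
class HomologyHit:
    """A scored homology relationship: alignment plus identity and coverage."""

    query_id: str
    subject_id: str
    identity: float
    coverage: float
    score: float
    alignment: LocalAlignment = field(repr=False)


def score_only(query_seq: str, subject_seq: str, scoring: ScoringScheme = EPIC_SCORING) -> float:
    """Optimal local-alignment score without traceback (fast path)."""
    if not query_seq or not subject_seq:
        raise ValueError("sequences must be non-empty")
    return float(
        _aligner(scoring).score(sanitize_sequence(query_seq), sanitize_sequence(subject_seq))
    )


def local_align(
    query_seq: str,
    subject_seq: str,
    scoring: ScoringScheme = EPIC_SCORING,
    query_id: str = "query",
    subject_id: str = "subject",
) -> LocalAlignment:
    """Optimal affine-gap local alignment of two nucleotide sequences.

    Returns an empty ``LocalAlignment`` (score 0) when no positive-scoring
    pairing exists. Tie-breaking among co-optimal alignments is the engine's
    deterministic traceback order.
    """
    if not query_seq or not subject_seq:
        raise ValueError("sequences must be non-empty")
    q = sanitize_sequence(query_seq)
    s = sanitize_sequence(subject_seq)
    aligner = _aligner(scoring)
    score = float(aligner.score(q, s))
    if score <= 0:
        return LocalAlignment(query_id, subject_id, score=0.0)
    aln = aligner.align(q, s)[0]
    gapped_q, gapped_s = str(aln[0]), str(aln[1])
    n_columns = len(gapped_q)
    n_matches = sum(
        1 for a, b in zip(gapped_q, gapped_s) if a == b and a != "-" and a != "N"
    )
    n_gap_columns = sum(1 for a, b in zip(gapped_q, gapped_s) if a == "-" or b == "-")
    q_blocks, s_blocks = aln.aligned
    return LocalAlignment(
        query_id=query_id,
        subject_id=subject_id,
        query_start=int(q_blocks[0][0]),
        query_end=int(q_blocks[-1][1]),
        subject_start=int(s_blocks[0][0]),
        subject_end=int(s_blocks[-1][1]),
        n_columns=n_columns,
        n_matches=n_matches,
        n_gap_columns=n_gap_columns,
        score=score,
    )


def hit_metrics(aln: LocalAlignment, query_len: int) -> HomologyHit:
    """Derive identity and query coverage from an alignment.

    identity = identical columns / aligned columns (gap columns included);
    coverage = aligned non-gap query bases / full query length. An empty
    alignment yields identity 0 and coverage 0.
    """
    if query_len < aln.query_span:
        raise ValueError("query_len smaller than the aligned query span")
    if aln.is_empty:
        return HomologyHit(aln.query_id, aln.subject_id, 0.0, 0.0, aln.score, aln)
    identity = aln.n_matches / aln.n_columns
    coverage = aln.query_span / query_len
    return HomologyHit(aln.query_id, aln.subject_id, identity, coverage, aln.score, aln)


def search_all(
    query_set: Sequence[CDSSegment],
    subject_set: Sequence[CDSSegment],
    scoring: ScoringScheme = EPIC_SCORING,
    min_score: float = 20.0,
) -> list[HomologyHit]:
    """All-vs-all local alignment of two CDS collections.

    Returns every hit with score >= ``min_score``. Pairs with identical
    segment ids (self-pairs, when a set is searched against itself) are
    excluded. Hits are grouped per query in input order; within a query they
    are sorted by descending score, ties broken by subject id.
    """
    for name, s in (("query", query_set), ("subject", subject_set)):
        ids = [seg.segment_id for seg in s]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate segment ids in {name} set")
    hits: list[HomologyHit] = []
    for q in query_set:
        per_query: list[HomologyHit] = []
        for s in subject_set:
            if q.segment_id == s.segment_id:
                continue
            if score_only(q.sequence, s.sequence, scoring) < min_score:
                continue
            aln = local_align(
                q.sequence, s.sequence, scoring, q.segment_id, s.segment_id
            )
            per_query.append(hit_metrics(aln, q.length))
        per_query.sort(key=lambda h: (-h.score, h.subject_id))
        hits.extend(per_query)
    return hits


def write_hit_table(hits: Iterable[HomologyHit], out_path: str | Path) -> None:
    """Tab-separated hit table (stable column order for downstream scripts)."""
    with open(out_path, "w") as fh:
        fh.write(
            "query\tsubject\tidentity\tcoverage\tscore\t"
            "query_start\tquery_end\tsubject_start\tsubject_end\n"
        )
        for h in hits:
            a = h.alignment
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.identity:.4f}\t{h.coverage:.4f}\t"
                f"{h.score:g}\t{a.query_start + 1}\t{a.query_end}\t"
                f"{a.subject_start + 1}\t{a.subject_end}\n"
            )
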