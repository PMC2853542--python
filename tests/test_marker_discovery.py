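"""Screens, reference mapping, candidate discovery, merging, pipeline."""

import numpy as np
import pytest

import epicminer as em
from epicminer.alignment import HomologyHit, LocalAlignment
from epicminer.genome_io import CDSSegment, GeneModel, reverse_complement
from epicminer.marker_discovery import (
    EpicCandidate,
    PipelineParams,
    count_markers_by_tier,
    single_copy_filter,
)

from conftest import random_seq


def _seg(seg_id, length, seq=None, start=0):
    seq = seq or "A" * length
    return CDSSegment(seg_id, seg_id.split(".")[0], "c1", "+", start, start + length, seq)


def _hit(q, s, identity, coverage):
    aln = LocalAlignment(q, s, score=10.0, n_columns=10, n_matches=int(10 * identity))
    return HomologyHit(q, s, identity, coverage, 10.0, aln)


class TestSizeAndCopyScreens:
    def test_large_cds_boundary_is_inclusive(self):
        segs = [_seg("a.cds1", 99), _seg("b.cds1", 100), _seg("c.cds1", 101)]
        kept = em.filter_large_cds(segs, 100)
        assert [s.segment_id for s in kept] == ["b.cds1", "c.cds1"]
        assert em.filter_large_cds([], 100) == []

    def test_copy_thresholds_are_strict(self):
        segs = [_seg("a.cds1", 100), _seg("b.cds1", 100)]
        # identity not above 0.40 -> kept
        kept = single_copy_filter(segs, [_hit("a.cds1", "b.cds1", 0.35, 0.25)])
        assert [s.segment_id for s in kept] == ["a.cds1", "b.cds1"]
        # both thresholds exceeded -> removed
        kept = single_copy_filter(segs, [_hit("a.cds1", "b.cds1", 0.45, 0.25)])
        assert [s.segment_id for s in kept] == ["b.cds1"]
        # exactly at a threshold is not "more than"
        kept = single_copy_filter(segs, [_hit("a.cds1", "b.cds1", 0.40, 0.50)])
        assert len(kept) == 2

    def test_unknown_segment_in_hits_is_an_error(self):
        with pytest.raises(ValueError):
            single_copy_filter([_seg("a.cds1", 100)], [_hit("a.cds1", "ghost", 0.9, 0.9)])

    def test_planted_duplicates_are_removed_from_simulated_genome(self, noise_free_run):
        sim = noise_free_run["sim"]
        report = noise_free_run["report"]
        dup_genes = {
            g.gene_id for g in sim.truth.genes.values()
            if g.role in ("duplicated", "duplicate_copy")
        }
        n_dup_segments = sum(
            len(g.cds_segments) for g in noise_free_run["sim"].genes
            if g.gene_id in dup_genes
        )
        assert report.n_cds_single_copy == report.n_cds_large - n_dup_segments

    def test_removing_planted_duplicate_restores_partner(self, noise_free_run):
        """Perturbation: without its paralog, a duplicated gene is single-copy."""
        sim = noise_free_run["sim"]
        segs = [s for g in sim.genes for s in g.cds_segments]
        large = em.filter_large_cds(segs, 100)
        hits = em.search_all(large, large, min_score=20)
        params = PipelineParams()
        removed_ids = {s.segment_id for s in large} - {
            s.segment_id for s in single_copy_filter(large, hits, params)
        }
        dup_gene = next(
            g.gene_id for g in sim.truth.genes.values() if g.role == "duplicated"
        )
        assert any(i.startswith(dup_gene + ".") for i in removed_ids)
        # drop the paralog copy's segments and the hits that involve them
        copy_prefix = dup_gene + "D."
        pruned = [s for s in large if not s.segment_id.startswith(copy_prefix)]
        pruned_hits = [
            h for h in hits
            if not h.query_id.startswith(copy_prefix)
            and not h.subject_id.startswith(copy_prefix)
        ]
        survivors = {
            s.segment_id for s in single_copy_filter(pruned, pruned_hits, params)
        }
        assert all(
            s.segment_id in survivors
            for s in pruned
            if s.segment_id.startswith(dup_gene + ".")
        )


class TestReferenceMapping:
    def test_exact_planted_exon_maps_at_unit_identity(self, rng):
        exon = random_seq(rng, 150)
        chrom = random_seq(rng, 2000) + exon + random_seq(rng, 1500)
        ref = em.GenomeRecord("r", {"cA": chrom})
        seg = _seg("g.cds1", 150, exon)
        hit = em.map_to_reference(seg, ref)
        assert hit is not None
        assert hit.identity == 1.0
        assert (hit.chromosome, hit.start, hit.end, hit.strand) == ("cA", 2000, 2150, "+")

    def test_planted_exon_on_reverse_strand_is_found(self, rng):
        exon = random_seq(rng, 150)
        chrom = random_seq(rng, 800) + reverse_complement(exon) + random_seq(rng, 600)
        ref = em.GenomeRecord("r", {"cA": chrom})
        hit = em.map_to_reference(_seg("g.cds1", 150, exon), ref)
        assert hit is not None and hit.strand == "-"
        assert (hit.start, hit.end) == (800, 950)

    def test_mutated_exon_maps_near_planted_identity(self, rng):
        exon = random_seq(rng, 200)
        mutated = "".join(
            c if rng.random() > 0.1 else "ACGT"[("ACGT".index(c) + 1) % 4] for c in exon
        )
        chrom = random_seq(rng, 1000) + mutated + random_seq(rng, 1000)
        ref = em.GenomeRecord("r", {"cA": chrom})
        hit = em.map_to_reference(_seg("g.cds1", 200, exon), ref)
        assert hit is not None
        assert 0.85 <= hit.identity <= 0.98
        assert abs(hit.start - 1000) < 30 and abs(hit.end - 1200) < 30

    def test_absent_query_returns_none_under_floor(self, rng):
        ref = em.GenomeRecord("r", {"cA": random_seq(rng, 3000)})
        hit = em.map_to_reference(
            _seg("g.cds1", 200, random_seq(rng, 200)), ref, min_identity_floor=0.5
        )
        assert hit is None


def _two_exon_query_and_refs(rng, intron_lengths, mutate_refs=0.0):
    """Query gene e1-intron-e2 plus references with chosen intron lengths."""
    e1, e2 = random_seq(rng, 150), random_seq(rng, 150)
    q_intron = intron_lengths["query"]
    chrom = random_seq(rng, 300) + e1 + random_seq(rng, q_intron) + e2 + random_seq(rng, 300)
    query = em.GenomeRecord("query", {"c1": chrom})
    gene = GeneModel(
        "SIMG00042", "c1", "+", "test gene",
        [
            CDSSegment("SIMG00042.cds1", "SIMG00042", "c1", "+", 300, 450, e1),
            CDSSegment("SIMG00042.cds2", "SIMG00042", "c1", "+", 450 + q_intron,
                       600 + q_intron, e2),
        ],
    )
    refs = []
    for name, ilen in intron_lengths.items():
        if name == "query":
            continue
        r1 = e1 if mutate_refs == 0 else "".join(
            c if rng.random() > mutate_refs else "ACGT"[("ACGT".index(c) + 1) % 4]
            for c in e1
        )
        r2 = e2 if mutate_refs == 0 else "".join(
            c if rng.random() > mutate_refs else "ACGT"[("ACGT".index(c) + 1) % 4]
            for c in e2
        )
        rchrom = random_seq(rng, 200) + r1 + random_seq(rng, ilen) + r2 + random_seq(rng, 200)
        refs.append(em.GenomeRecord(name, {"cr": rchrom}))
    return query, [gene], refs


class TestCandidateDiscovery:
    def test_intron_short_in_one_species_qualifies(self, rng):
        lengths = {"query": 300, "r1": 500, "r2": 1200, "r3": 800, "r4": 900}
        query, genes, refs = _two_exon_query_and_refs(rng, lengths)
        cands = em.find_epic_candidates(query, genes, refs)
        assert len(cands) == 1
        assert cands[0].species_intron_lengths == lengths
        assert cands[0].mean_identity == 1.0

    def test_all_introns_long_disqualifies(self, rng):
        lengths = {"query": 1400, "r1": 1100, "r2": 1200, "r3": 1300, "r4": 1500}
        query, genes, refs = _two_exon_query_and_refs(rng, lengths)
        assert em.find_epic_candidates(query, genes, refs) == []

    def test_identity_tier_screens_out_diverged_exons(self, rng):
        lengths = {"query": 300, "r1": 400}
        query, genes, refs = _two_exon_query_and_refs(rng, lengths, mutate_refs=0.25)
        params = PipelineParams(min_mean_identity=0.85)
        assert em.find_epic_candidates(query, genes, refs, params) == []
        permissive = PipelineParams(min_mean_identity=0.65)
        assert len(em.find_epic_candidates(query, genes, refs, permissive)) == 1

    def test_mean_exon_identity_arithmetic(self):
        cand = EpicCandidate(
            gene_id="g", chromosome="c", marker_start=0,
            upstream_segment_id="g.cds1", downstream_segment_id="g.cds2",
            species_intron_lengths={"query": 100},
            reference_identities={"r1": 0.9, "r2": 0.8, "r3": 0.9, "r4": 0.8},
            mean_identity=0.85, query_span=(0, 100), query_strand="+",
            species_spans={},
        )
        assert em.mean_exon_identity(cand) == pytest.approx(0.85)
        cand.reference_identities = {}
        with pytest.raises(ValueError):
            em.mean_exon_identity(cand)


def _cand(gene, span, identity=0.9):
    return EpicCandidate(
        gene_id=gene, chromosome="c1", marker_start=span[0],
        upstream_segment_id=f"{gene}.u", downstream_segment_id=f"{gene}.d",
        species_intron_lengths={"query": span[1] - span[0]},
        reference_identities={"r1": identity}, mean_identity=identity,
        query_span=span, query_strand="+",
        species_spans={"query": ("c1", span[0], span[1], "+")},
    )


class TestMerging:
    def test_nearby_candidates_merge_to_union_span(self):
        recs = em.merge_nearby([_cand("SIMG1", (300, 400)), _cand("SIMG1", (700, 800))])
        assert len(recs) == 1
        assert recs[0].query_span == (300, 800)
        assert recs[0].n_introns_merged == 2

    def test_distant_candidates_stay_separate(self):
        recs = em.merge_nearby([_cand("SIMG1", (300, 400)), _cand("SIMG1", (5400, 5500))])
        assert len(recs) == 2
        assert [r.locus_name for r in recs] == ["00001E1", "00001E2"]

    def test_different_genes_never_merge(self):
        recs = em.merge_nearby([_cand("SIMG1", (300, 400)), _cand("SIMG2", (450, 550))])
        assert len(recs) == 2

    def test_merge_is_idempotent_on_random_candidate_sets(self, rng):
        for _ in range(50):
            cands = []
            for g in range(int(rng.integers(1, 4))):
                pos = 0
                for _ in range(int(rng.integers(1, 6))):
                    pos += int(rng.integers(50, 3000))
                    width = int(rng.integers(50, 400))
                    cands.append(_cand(f"SIMG{g}", (pos, pos + width)))
                    pos += width
            once = em.merge_nearby(cands)
            # feed the merged regions back in: a second merge must not change them
            again = em.merge_nearby([_cand(r.gene_id, r.query_span) for r in once])
            assert [(r.gene_id, r.query_span) for r in once] == [
                (r.gene_id, r.query_span) for r in again
            ]

    def test_merged_records_cover_all_candidates_without_overlap(self, rng):
        cands = []
        pos = 0
        for _ in range(8):
            pos += int(rng.integers(100, 2500))
            cands.append(_cand("SIMG9", (pos, pos + 200)))
            pos += 200
        recs = em.merge_nearby(cands)
        spans = sorted(r.query_span for r in recs)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2
        assert sum(r.n_introns_merged for r in recs) == len(cands)
        for c in cands:
            assert sum(
                1 for r in recs
                if r.query_span[0] <= c.query_span[0] and c.query_span[1] <= r.query_span[1]
            ) == 1


class TestPipeline:
    def test_stage_counts_and_exact_recovery(self, noise_free_run):
        report = noise_free_run["report"]
        assert report.n_cds_total >= report.n_cds_large >= report.n_cds_single_copy
        assert report.n_candidates >= report.n_markers
        found = {m.gene_id for m in noise_free_run["markers"]}
        truth = noise_free_run["sim"].truth.qualifying_genes()
        assert found == truth

    def test_reported_intron_lengths_match_truth(self, noise_free_run):
        sim = noise_free_run["sim"]
        for m in noise_free_run["markers"]:
            jt = sim.truth.genes[m.gene_id].junctions[0]
            assert m.species_intron_lengths == jt.species_intron_lengths

    def test_identity_tiers_are_monotone_on_fixed_input(self, noise_free_run):
        sim = noise_free_run["sim"]
        segs = [s for g in sim.genes for s in g.cds_segments]
        large = em.filter_large_cds(segs, 100)
        hits = em.search_all(large, large, min_score=20)
        surviving = {s.segment_id for s in single_copy_filter(large, hits)}
        params = PipelineParams(min_mean_identity=0.0)
        cands = em.find_epic_candidates(
            sim.query, sim.genes, sim.references, params, surviving_ids=surviving
        )
        counts = count_markers_by_tier(cands, (0.65, 0.80, 0.85))
        assert counts[0.65] >= counts[0.80] >= counts[0.85]

    def test_single_reference_run_completes(self, noise_free_run, tmp_path):
        markers, report = em.run_pipeline(
            noise_free_run["paths"]["query_fasta"],
            noise_free_run["paths"]["query_gff3"],
            [noise_free_run["refs"][0]],
            out_prefix=tmp_path / "single",
        )
        assert report.n_markers == len(markers)
        assert (tmp_path / "single.report.json").exists()
        assert (tmp_path / "single.markers.tsv").exists()

    def test_catalogue_outputs_are_deterministic(self, noise_free_run, tmp_path):
        args = (
            noise_free_run["paths"]["query_fasta"],
            noise_free_run["paths"]["query_gff3"],
            [noise_free_run["refs"][0]],
        )
        em.run_pipeline(*args, out_prefix=tmp_path / "a")
        em.run_pipeline(*args, out_prefix=tmp_path / "b")
        assert (tmp_path / "a.markers.tsv").read_text() == (
            tmp_path / "b.markers.tsv"
        ).read_text()
        assert (tmp_path / "a.markers.bed").read_text() == (
            tmp_path / "b.markers.bed"
        ).read_text()
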