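"""Synthetic multi-species genome sets with planted ground truth.

The generator emulates the statistical structure the marker pipeline
assumes: genes with exon/intron structure placed on chromosomes with
intergenic spacers, lineage-specific substitution divergence with exons
evolving slower than introns (the premise that makes exon-primed
intron-crossing markers possible), intron length variation through indels,
and planted paralog duplications in the query genome.

Each gene descends from a random ancestor; every species' copy is mutated
independently, so the expected identity between the query and a reference
exon under per-lineage substitution rate r is

    E[identity] = (1 - r)^2 + r^2 / 3

(a substitution always changes the base; two independent substitutions
agree with probability 1/3). Exons accumulate substitutions only — their
lengths are invariant — so realized identities in the truth set are exact
column-wise fractions, not alignment artifacts.

Genes are planted in four roles: ordinary single-copy genes (which should
be recovered as markers when their intron is short enough), long-intron
genes (intron > the screening limit in every species), low-identity genes
(exons diverged past the identity tier), and duplicated genes (a paralog
copy inserted into the query, so the copy-number screen must discard
both). The truth set records realized intron lengths and exon identities
and the derived qualifies-as-marker flag per exon junction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from statistics import fmean
from typing import Sequence

import numpy as np

from .genome_io import (
    CDSSegment,
    GeneModel,
    GenomeRecord,
    reverse_complement,
    write_genome_fasta,
    write_gff3,
)
from .marker_discovery import PipelineParams

__all__ = [
    "SimulationConfig",
    "JunctionTruth",
    "GeneTruth",
    "TruthSet",
    "SimulatedGenomeSet",
    "expected_pairwise_identity",
    "mutate_sequence",
    "simulate_genome_set",
    "noise_free_config",
    "write_simulation",
]

_BASES = np.array(list("ACGT"))


def expected_pairwise_identity(rate: float) -> float:
    """Expected identity of two lineages mutated at per-site rate ``rate``."""
    return (1.0 - rate) ** 2 + rate**2 / 3.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated genome set.

    ``n_species`` counts the query plus the references. Substitution rates
    are per-site, per-lineage probabilities; introns must evolve at least
    as fast as exons. Lengths in bp. The seed is mandatory: every run is a
    pure function of its config.
    """

    seed: int
    n_species: int = 5
    n_genes: int = 18
    exons_per_gene: tuple[int, int] = (2, 3)
    exon_len: tuple[int, int] = (150, 300)
    intron_len: tuple[int, int] = (200, 900)
    exon_substitution_rate: float = 0.02
    intron_substitution_rate: float = 0.08
    intron_indel_rate: float = 0.01
    mean_indel_size: float = 5.0
    n_duplicated_genes: int = 2
    duplicate_identity: float = 0.95
    n_long_intron_genes: int = 2
    long_intron_len: tuple[int, int] = (1200, 1600)
    n_low_identity_genes: int = 2
    low_identity_rate: float = 0.15
    intergenic_len: tuple[int, int] = (200, 400)
    duplicate_placement: str = "dispersed"

    def __post_init__(self) -> None:
        for name in (
            "exons_per_gene",
            "exon_len",
            "intron_len",
            "long_intron_len",
            "intergenic_len",
        ):
            lo, hi = getattr(self, name)
            if lo > hi or lo <= 0:
                raise ValueError(f"infeasible range for {name}: ({lo}, {hi})")
        for name in (
            "exon_substitution_rate",
            "intron_substitution_rate",
            "intron_indel_rate",
            "duplicate_identity",
            "low_identity_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.intron_substitution_rate < self.exon_substitution_rate:
            raise ValueError("introns must evolve at least as fast as exons")
        if self.n_species < 2:
            raise ValueError("need at least a query and one reference")
        n_special = (
            self.n_duplicated_genes + self.n_long_intron_genes + self.n_low_identity_genes
        )
        if n_special > self.n_genes:
            raise ValueError("more special-role genes than genes")
        if self.duplicate_placement not in ("dispersed", "tandem"):
            raise ValueError("duplicate_placement must be 'dispersed' or 'tandem'")


def noise_free_config(seed: int, n_genes: int = 18, n_species: int = 5) -> SimulationConfig:
    """The noise-free preset: exact exon copies for ordinary genes.

    Substitution and indel noise are off, every gene has a single intron,
    and the planted disqualifiers (long introns, strongly diverged exons,
    duplicates) remain, so pipeline recovery against the truth set is
    exact-match testable.
    """
    return SimulationConfig(
        seed=seed,
        n_species=n_species,
        n_genes=n_genes,
        exons_per_gene=(2, 2),
        exon_substitution_rate=0.0,
        intron_substitution_rate=0.0,
        intron_indel_rate=0.0,
        low_identity_rate=0.20,
    )


# ---------------------------------------------------------------------------
# Mutation model
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _substitute(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Independent per-site substitution to a uniformly chosen other base."""
    if rate <= 0.0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hit:
        current = arr[i].decode()
        options = [b for b in "ACGT" if b != current]
        arr[i] = rng.choice(options).encode()
    return arr.tobytes().decode()


def mutate_sequence(
    seq: str,
    substitution_rate: float,
    indel_rate: float = 0.0,
    mean_indel: float = 5.0,
    seed: int | np.random.Generator = 0,
) -> str:
    """Mutate a sequence with per-site substitutions and geometric indels.

    Each site is substituted independently with probability
    ``substitution_rate`` to a uniformly chosen *different* base. Indel
    events occur per site at ``indel_rate``; each is an insertion or a
    deletion (equal odds) of geometric length with mean ``mean_indel``.
    """
    if not 0.0 <= substitution_rate <= 1.0 or not 0.0 <= indel_rate <= 1.0:
        raise ValueError("rates must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = _substitute(seq, substitution_rate, rng)
    if indel_rate <= 0.0 or not out:
        return out
    n_events = rng.binomial(len(out), indel_rate)
    if n_events == 0:
        return out
    positions = sorted(rng.integers(0, len(out), size=n_events), reverse=True)
    for pos in positions:
        length = int(rng.geometric(1.0 / max(mean_indel, 1.0)))
        if rng.random() < 0.5:
            out = out[:pos] + _random_seq(rng, length) + out[pos:]
        else:
            out = out[:pos] + out[pos + length :]
    return out


# ---------------------------------------------------------------------------
# Truth set
# ---------------------------------------------------------------------------

@dataclass
class JunctionTruth:
    """Realized properties of one exon junction (one potential marker)."""

    gene_id: str
    junction_index: int  # 1-based, transcription order
    species_intron_lengths: dict[str, int]
    reference_exon_identities: dict[str, float]
    flank_lengths: tuple[int, int]
    qualifies: bool = False


@dataclass
class GeneTruth:
    gene_id: str
    role: str  # single | long_intron | low_identity | duplicated | duplicate_copy
    single_copy: bool
    junctions: list[JunctionTruth] = field(default_factory=list)
    exon_lengths: list[int] = field(default_factory=list)
    # reference -> per-exon realized identity vs the query copy
    exon_identities: dict[str, list[float]] = field(default_factory=dict)


def _junction_qualifies(
    gene: GeneTruth, junction: JunctionTruth, params: PipelineParams, n_references: int
) -> bool:
    """Recompute the qualifies-as-marker flag from realized truth fields."""
    if not gene.single_copy:
        return False
    if min(junction.flank_lengths) < params.min_cds_len:
        return False
    mapped = {
        ref: ident
        for ref, ident in junction.reference_exon_identities.items()
        if ident >= params.map_identity_floor
    }
    if not mapped:
        return False
    if params.require_all_references and len(mapped) < n_references:
        return False
    lengths = dict(junction.species_intron_lengths)
    lengths = {sp: l for sp, l in lengths.items() if sp == "query" or sp in mapped}
    if min(lengths.values()) > params.max_intron_len:
        return False
    return round(fmean(mapped.values()), 2) >= params.min_mean_identity


@dataclass
class TruthSet:
    """Planted ground truth for one simulated genome set."""

    params: PipelineParams
    n_references: int
    genes: dict[str, GeneTruth] = field(default_factory=dict)

    def qualifying_junctions(self) -> list[tuple[str, int]]:
        return [
            (g.gene_id, j.junction_index)
            for g in self.genes.values()
            for j in g.junctions
            if j.qualifies
        ]

    def qualifying_genes(self) -> set[str]:
        return {gene_id for gene_id, _ in self.qualifying_junctions()}

    def recompute_qualifies(self, params: PipelineParams | None = None) -> dict[tuple[str, int], bool]:
        """Re-derive every qualifies flag from the stored truth fields."""
        params = params or self.params
        return {
            (g.gene_id, j.junction_index): _junction_qualifies(
                g, j, params, self.n_references
            )
            for g in self.genes.values()
            for j in g.junctions
        }

    def is_consistent(self) -> bool:
        stored = {
            (g.gene_id, j.junction_index): j.qualifies
            for g in self.genes.values()
            for j in g.junctions
        }
        return stored == self.recompute_qualifies()

    def to_json(self, out_path: str | Path) -> None:
        payload = {
            "params": asdict(self.params),
            "n_references": self.n_references,
            "genes": {gid: asdict(g) for gid, g in self.genes.items()},
        }
        with open(out_path, "w") as fh:
            json.dump(payload, fh, indent=2, default=list)
            fh.write("\n")


@dataclass
class SimulatedGenomeSet:
    """A query genome with annotation, reference genomes, and the truth."""

    config: SimulationConfig
    query: GenomeRecord
    genes: list[GeneModel]
    references: list[GenomeRecord]
    truth: TruthSet


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------

def _gene_roles(config: SimulationConfig, rng: np.random.Generator) -> list[str]:
    roles = (
        ["long_intron"] * config.n_long_intron_genes
        + ["low_identity"] * config.n_low_identity_genes
        + ["duplicated"] * config.n_duplicated_genes
    )
    roles += ["single"] * (config.n_genes - len(roles))
    rng.shuffle(roles)
    return roles


def simulate_genome_set(
    config: SimulationConfig, params: PipelineParams = PipelineParams()
) -> SimulatedGenomeSet:
    """Generate a query genome (annotated), references, and the truth set.

    Deterministic for a fixed config. Species are named ``query`` and
    ``ref1..refN``; all genomes are single-chromosome (``chr1``). References
    carry no annotation, exercising the annotation-free mapping path.
    ``params`` states the pipeline operating point the truth's
    qualifies-as-marker flags refer to.
    """
    rng = np.random.default_rng(config.seed)
    species = ["query"] + [f"ref{i}" for i in range(1, config.n_species)]
    roles = _gene_roles(config, rng)

    # --- ancestors -------------------------------------------------------
    ancestors = []  # per gene: dict(exons=[...], introns=[...])
    for gi in range(config.n_genes):
        k = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exons = [
            _random_seq(rng, int(rng.integers(config.exon_len[0], config.exon_len[1] + 1)))
            for _ in range(k)
        ]
        intron_range = (
            config.long_intron_len if roles[gi] == "long_intron" else config.intron_len
        )
        introns = [
            _random_seq(rng, int(rng.integers(intron_range[0], intron_range[1] + 1)))
            for _ in range(k - 1)
        ]
        ancestors.append({"exons": exons, "introns": introns})

    # --- per-species realizations ---------------------------------------
    # realized[sp][gi] = {"exons": [...], "introns": [...]}
    realized: dict[str, list[dict]] = {sp: [] for sp in species}
    for gi, anc in enumerate(ancestors):
        exon_rate = (
            config.low_identity_rate
            if roles[gi] == "low_identity"
            else config.exon_substitution_rate
        )
        for sp in species:
            exons = [_substitute(e, exon_rate, rng) for e in anc["exons"]]
            introns = [
                mutate_sequence(
                    i,
                    config.intron_substitution_rate,
                    config.intron_indel_rate,
                    config.mean_indel_size,
                    rng,
                )
                for i in anc["introns"]
            ]
            realized[sp].append({"exons": exons, "introns": introns})

    # --- duplicate copies in the query -----------------------------------
    dup_rate = 1.0 - config.duplicate_identity
    duplicates: dict[int, dict] = {}
    for gi in range(config.n_genes):
        if roles[gi] == "duplicated":
            src = realized["query"][gi]
            duplicates[gi] = {
                "exons": [_substitute(e, dup_rate, rng) for e in src["exons"]],
                "introns": [_substitute(i, dup_rate, rng) for i in src["introns"]],
            }

    gene_ids = [f"SIMG{gi + 1:05d}" for gi in range(config.n_genes)]

    # --- assembly ---------------------------------------------------------
    def gene_sequence(parts: dict) -> str:
        chunks = []
        for j, exon in enumerate(parts["exons"]):
            chunks.append(exon)
            if j < len(parts["introns"]):
                chunks.append(parts["introns"][j])
        return "".join(chunks)

    chromosomes: dict[str, str] = {}
    query_placements: list[tuple[str, str, int, dict, str]] = []
    for sp in species:
        pieces: list[str] = []
        pos = 0
        order: list[tuple[str, dict, str]] = []  # (gene_id, parts, role_tag)
        for gi in range(config.n_genes):
            order.append((gene_ids[gi], realized[sp][gi], roles[gi]))
            if (
                sp == "query"
                and gi in duplicates
                and config.duplicate_placement == "tandem"
            ):
                order.append((gene_ids[gi] + "D", duplicates[gi], "duplicate_copy"))
        if sp == "query" and config.duplicate_placement == "dispersed":
            for gi in sorted(duplicates):
                order.append((gene_ids[gi] + "D", duplicates[gi], "duplicate_copy"))
        for gene_id, parts, role in order:
            spacer = _random_seq(
                rng, int(rng.integers(config.intergenic_len[0], config.intergenic_len[1] + 1))
            )
            pieces.append(spacer)
            pos += len(spacer)
            seq = gene_sequence(parts)
            strand = "+" if rng.random() < 0.5 else "-"
            pieces.append(seq if strand == "+" else reverse_complement(seq))
            if sp == "query":
                query_placements.append((gene_id, strand, pos, parts, role))
            pos += len(seq)
        pieces.append(
            _random_seq(
                rng, int(rng.integers(config.intergenic_len[0], config.intergenic_len[1] + 1))
            )
        )
        chromosomes[sp] = "".join(pieces)

    query = GenomeRecord("query", {"chr1": chromosomes["query"]})
    references = [
        GenomeRecord(sp, {"chr1": chromosomes[sp]}) for sp in species[1:]
    ]

    # --- query annotation -------------------------------------------------
    role_desc = {
        "single": "simulated single-copy protein-coding gene",
        "long_intron": "simulated gene with long introns",
        "low_identity": "simulated fast-evolving gene",
        "duplicated": "simulated duplicated gene",
        "duplicate_copy": "simulated paralogous copy",
    }
    genes: list[GeneModel] = []
    for gene_id, strand, offset, parts, role in query_placements:
        seq = gene_sequence(parts)
        total = len(seq)
        # transcription-order coordinates of each exon within the gene
        segments = []
        cursor = 0
        for j, exon in enumerate(parts["exons"]):
            a, b = cursor, cursor + len(exon)
            if strand == "+":
                start, end = offset + a, offset + b
            else:
                start, end = offset + total - b, offset + total - a
            segments.append((j, start, end, exon))
            cursor = b
            if j < len(parts["introns"]):
                cursor += len(parts["introns"][j])
        segments.sort(key=lambda s: s[1])  # chromosomal order
        cds = [
            CDSSegment(
                segment_id=f"{gene_id}.cds{k + 1}",
                gene_id=gene_id,
                chromosome="chr1",
                strand=strand,
                start=start,
                end=end,
                sequence=exon,
            )
            for k, (_, start, end, exon) in enumerate(segments)
        ]
        genes.append(GeneModel(gene_id, "chr1", strand, role_desc[role], cds))

    # --- truth ------------------------------------------------------------
    truth = TruthSet(params=params, n_references=len(references))
    for gi in range(config.n_genes):
        gene_id = gene_ids[gi]
        role = roles[gi]
        single_copy = role != "duplicated"
        q_parts = realized["query"][gi]
        exon_identities = {
            ref: [
                _hamming_identity(qe, realized[ref][gi]["exons"][j])
                for j, qe in enumerate(q_parts["exons"])
            ]
            for ref in species[1:]
        }
        gt = GeneTruth(
            gene_id=gene_id,
            role=role,
            single_copy=single_copy,
            exon_lengths=[len(e) for e in q_parts["exons"]],
            exon_identities=exon_identities,
        )
        for j in range(len(q_parts["introns"])):
            lengths = {
                sp: len(realized[sp][gi]["introns"][j]) for sp in species
            }
            ref_ident = {
                ref: (exon_identities[ref][j] + exon_identities[ref][j + 1]) / 2
                for ref in species[1:]
            }
            jt = JunctionTruth(
                gene_id=gene_id,
                junction_index=j + 1,
                species_intron_lengths=lengths,
                reference_exon_identities=ref_ident,
                flank_lengths=(len(q_parts["exons"][j]), len(q_parts["exons"][j + 1])),
            )
            jt.qualifies = _junction_qualifies(gt, jt, params, len(references))
            gt.junctions.append(jt)
        truth.genes[gene_id] = gt
    for gi in sorted(duplicates):
        dup_id = gene_ids[gi] + "D"
        d_parts = duplicates[gi]
        gt = GeneTruth(
            gene_id=dup_id,
            role="duplicate_copy",
            single_copy=False,
            exon_lengths=[len(e) for e in d_parts["exons"]],
        )
        for j in range(len(d_parts["introns"])):
            jt = JunctionTruth(
                gene_id=dup_id,
                junction_index=j + 1,
                species_intron_lengths={"query": len(d_parts["introns"][j])},
                reference_exon_identities={},
                flank_lengths=(len(d_parts["exons"][j]), len(d_parts["exons"][j + 1])),
                qualifies=False,
            )
            gt.junctions.append(jt)
        truth.genes[dup_id] = gt

    return SimulatedGenomeSet(config, query, genes, references, truth)


def _hamming_identity(a: str, b: str) -> float:
    if len(a) != len(b):
        raise ValueError("exon copies must have equal length")
    return sum(1 for x, y in zip(a, b) if x == y) / len(a)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_simulation(simset: SimulatedGenomeSet, out_dir: str | Path) -> dict[str, Path]:
    """Write per-species FASTA, the query GFF3, and the truth (JSON + TSV).

    Returns a name -> path map of everything written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    qpath = out_dir / "query.fasta"
    write_genome_fasta(simset.query, qpath)
    written["query_fasta"] = qpath
    gpath = out_dir / "query.gff3"
    write_gff3(simset.genes, gpath)
    written["query_gff3"] = gpath
    for ref in simset.references:
        rpath = out_dir / f"{ref.genome_id}.fasta"
        write_genome_fasta(ref, rpath)
        written[f"{ref.genome_id}_fasta"] = rpath
    jpath = out_dir / "truth.json"
    simset.truth.to_json(jpath)
    written["truth_json"] = jpath
    tpath = out_dir / "truth.tsv"
    with open(tpath, "w") as fh:
        fh.write(
            "gene_id\tjunction\trole\tsingle_copy\tqualifies\t"
            "min_intron_len\tmean_ref_identity\n"
        )
        for g in simset.truth.genes.values():
            for j in g.junctions:
                mean_id = (
                    f"{fmean(j.reference_exon_identities.values()):.4f}"
                    if j.reference_exon_identities
                    else "NA"
                )
                fh.write(
                    f"{g.gene_id}\t{j.junction_index}\t{g.role}\t"
                    f"{int(g.single_copy)}\t{int(j.qualifies)}\t"
                    f"{min(j.species_intron_lengths.values())}\t{mean_id}\n"
                )
    written["truth_tsv"] = tpath
    return written
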