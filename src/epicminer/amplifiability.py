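"""Amplification-success statistics for a tested marker panel.

Given a taxa x loci presence/absence matrix of PCR amplification (and
sequencing) outcomes, this module computes per-locus success rates, the
pairwise shared-amplification statistic

    DA_ij = |amplified in both i and j| / |amplified in either i or j|,

which ranges from 0 (no shared markers) to 1 (all markers shared),
pairwise p-distances from aligned exon sequences (pairwise deletion of
gapped or ambiguous sites), intron-size differences between taxa, and the
Pearson correlations relating marker transferability to genetic distance.

Note on naming: DA was introduced as a "difference of amplifiability", but
its range makes it a similarity; it is exposed here as
``amplifiability_similarity`` with ``da_ij`` as an alias.

A transcription of the published 9-taxa x 12-loci validation panel ships
with the package (``load_validation_panel``): a cell is 1 iff a sequence
accession was obtained for that taxon and locus; genome-database retrievals
for the four model-species rows are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PresenceMatrix",
    "PDistanceMatrix",
    "CorrelationResult",
    "load_validation_panel",
    "success_rate",
    "taxa_amplified",
    "amplifiability_similarity",
    "da_ij",
    "da_matrix",
    "p_distance",
    "p_distance_matrix",
    "intron_size_difference",
    "pearson",
    "locus_stats_table",
    "da_vs_distance_table",
    "intron_vs_distance_table",
]


class PresenceMatrix:
    """Taxa x loci amplification outcomes with a tested mask.

    Backed by a float DataFrame: 1.0 amplified, 0.0 tested-but-failed,
    NaN untested.
    """

    def __init__(self, df: pd.DataFrame):
        values = df.astype(float)
        if not values.isin([0.0, 1.0]).where(values.notna(), True).all().all():
            raise ValueError("presence matrix cells must be 1, 0 or NA")
        values.index.name = "taxon"
        self._df = values

    @property
    def taxa(self) -> list[str]:
        return list(self._df.index)

    @property
    def loci(self) -> list[str]:
        return list(self._df.columns)

    @property
    def frame(self) -> pd.DataFrame:
        return self._df.copy()

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PresenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", "na", ""])
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        out = self._df.copy()
        out.index.name = "taxon"
        out.to_csv(path, sep="\t", na_rep="NA", float_format="%g")

    def tested(self, taxon: str, locus: str) -> bool:
        return not pd.isna(self._df.at[taxon, locus])

    def amplified_loci(self, taxon: str) -> set[str]:
        row = self._df.loc[taxon]
        return set(row.index[row == 1.0])

    def __repr__(self) -> str:  # pragma: no cover
        return f"PresenceMatrix({len(self.taxa)} taxa x {len(self.loci)} loci)"


def load_validation_panel() -> PresenceMatrix:
    """The packaged 9-taxa x 12-loci marker validation matrix."""
    ref = resources.files("epicminer").joinpath("data/validation_panel_presence.tsv")
    with resources.as_file(ref) as path:
        return PresenceMatrix.from_tsv(path)


def success_rate(matrix: PresenceMatrix, locus: str) -> float:
    """Amplified count / tested count for one locus (unrounded)."""
    col = matrix.frame[locus].dropna()
    if col.empty:
        raise ValueError(f"locus {locus!r} was tested in no taxon")
    return float(col.sum() / len(col))


def taxa_amplified(matrix: PresenceMatrix, locus: str) -> int:
    """Number of tested taxa in which the locus amplified."""
    return int(matrix.frame[locus].dropna().sum())


def amplifiability_similarity(matrix: PresenceMatrix, taxon_i: str, taxon_j: str) -> float:
    """DA_ij: loci amplified in both taxa over loci amplified in either.

    Only loci tested in both taxa are considered. Raises ``ValueError``
    when the union is empty (the statistic is undefined, not 0).
    """
    df = matrix.frame
    ri, rj = df.loc[taxon_i], df.loc[taxon_j]
    both_tested = ri.notna() & rj.notna()
    if not both_tested.any():
        raise ValueError(f"no locus tested in both {taxon_i!r} and {taxon_j!r}")
    ai, aj = (ri == 1.0) & both_tested, (rj == 1.0) & both_tested
    union = int((ai | aj).sum())
    if union == 0:
        raise ValueError(
            f"DA undefined: no locus amplified in either {taxon_i!r} or {taxon_j!r}"
        )
    return float((ai & aj).sum() / union)


#: DA_ij under its published name
da_ij = amplifiability_similarity


def da_matrix(matrix: PresenceMatrix) -> pd.DataFrame:
    """Square symmetric DataFrame of DA over all taxon pairs (diagonal 1)."""
    taxa = matrix.taxa
    out = pd.DataFrame(np.nan, index=taxa, columns=taxa, dtype=float)
    for i, ti in enumerate(taxa):
        for tj in taxa[i:]:
            try:
                v = amplifiability_similarity(matrix, ti, tj)
            except ValueError:
                v = np.nan
            out.at[ti, tj] = out.at[tj, ti] = v
    return out


# ---------------------------------------------------------------------------
# p-distance
# ---------------------------------------------------------------------------

_UNAMBIGUOUS = frozenset("ACGT")


def p_distance(aligned_i: str, aligned_j: str) -> float:
    """Proportion of differing sites over comparable sites.

    Sites with a gap or an ambiguous base in either sequence are excluded
    (pairwise deletion). Raises ``ValueError`` with zero comparable sites.
    """
    if len(aligned_i) != len(aligned_j):
        raise ValueError("aligned sequences must have equal length")
    ai, aj = aligned_i.upper(), aligned_j.upper()
    compared = differing = 0
    for a, b in zip(ai, aj):
        if a in _UNAMBIGUOUS and b in _UNAMBIGUOUS:
            compared += 1
            if a != b:
                differing += 1
    if compared == 0:
        raise ValueError("no comparable sites between the two sequences")
    return differing / compared


@dataclass
class PDistanceMatrix:
    """Pairwise p-distances plus the site count used for each pair."""

    distances: pd.DataFrame
    site_counts: pd.DataFrame

    @property
    def taxa(self) -> list[str]:
        return list(self.distances.index)

    def to_tsv(self, path: str | Path) -> None:
        out = self.distances.copy()
        out.index.name = "taxon"
        out.to_csv(path, sep="\t", float_format="%.6f")


def p_distance_matrix(
    alignment: Mapping[str, str], deletion: str = "pairwise"
) -> PDistanceMatrix:
    """All-pairs p-distances from a taxon -> gapped-sequence alignment.

    ``deletion='pairwise'`` excludes gapped/ambiguous sites per pair;
    ``'complete'`` first drops every column with a gap or ambiguity in any
    sequence.
    """
    taxa = list(alignment)
    seqs = {t: alignment[t].upper() for t in taxa}
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("all aligned sequences must have equal length")
    if deletion == "complete":
        keep = [
            i
            for i in range(lengths.pop())
            if all(seqs[t][i] in _UNAMBIGUOUS for t in taxa)
        ]
        seqs = {t: "".join(s[i] for i in keep) for t, s in seqs.items()}
        if not keep:
            raise ValueError("complete deletion removed every site")
    elif deletion != "pairwise":
        raise ValueError("deletion must be 'pairwise' or 'complete'")
    d = pd.DataFrame(0.0, index=taxa, columns=taxa, dtype=float)
    n = pd.DataFrame(0, index=taxa, columns=taxa, dtype=int)
    for i, ti in enumerate(taxa):
        si = seqs[ti]
        n.at[ti, ti] = sum(1 for c in si if c in _UNAMBIGUOUS)
        for tj in taxa[i + 1 :]:
            sj = seqs[tj]
            compared = differing = 0
            for a, b in zip(si, sj):
                if a in _UNAMBIGUOUS and b in _UNAMBIGUOUS:
                    compared += 1
                    if a != b:
                        differing += 1
            if compared == 0:
                raise ValueError(f"no comparable sites between {ti!r} and {tj!r}")
            d.at[ti, tj] = d.at[tj, ti] = differing / compared
            n.at[ti, tj] = n.at[tj, ti] = compared
    return PDistanceMatrix(d, n)


def intron_size_difference(
    sizes: Mapping[str, Mapping[str, int]], taxon_i: str, taxon_j: str, locus: str
) -> int:
    """Absolute intron-length difference between two taxa at one locus.

    ``sizes`` maps taxon -> (locus -> intron length in bp).
    """
    return abs(int(sizes[taxon_i][locus]) - int(sizes[taxon_j][locus]))


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    """Pearson r with its two-sided p-value from the exact t transform."""

    r: float
    n: int
    p_value: float


def pearson(x, y) -> CorrelationResult:
    """Pearson correlation with a two-sided p-value.

    Requires equal-length inputs of at least 3 values; zero variance in
    either input makes r undefined and raises ``ValueError``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if len(x) < 3:
        raise ValueError("at least 3 pairs are required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("r undefined: zero variance in x or y")
    res = stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), len(x), float(res.pvalue))


# ---------------------------------------------------------------------------
# Report tables (the scatter data behind the transferability analyses)
# ---------------------------------------------------------------------------

def locus_stats_table(matrix: PresenceMatrix) -> pd.DataFrame:
    """Per-locus amplification statistics (success rate to 2 decimals)."""
    rows = []
    for locus in matrix.loci:
        rows.append(
            {
                "locus": locus,
                "n_tested": int(matrix.frame[locus].notna().sum()),
                "n_amplified": taxa_amplified(matrix, locus),
                "success_rate": round(success_rate(matrix, locus), 2),
            }
        )
    return pd.DataFrame(rows)


def da_vs_distance_table(
    matrix: PresenceMatrix, pdist: PDistanceMatrix
) -> pd.DataFrame:
    """One row per unordered taxon pair: DA_ij and p-distance.

    Pairs must be present in both inputs; the diagonal is excluded.
    """
    taxa = [t for t in matrix.taxa if t in pdist.taxa]
    rows = []
    for i, ti in enumerate(taxa):
        for tj in taxa[i + 1 :]:
            try:
                da = amplifiability_similarity(matrix, ti, tj)
            except ValueError:
                continue
            rows.append(
                {
                    "taxon_i": ti,
                    "taxon_j": tj,
                    "da": da,
                    "p_distance": float(pdist.distances.at[ti, tj]),
                }
            )
    return pd.DataFrame(rows)


def intron_vs_distance_table(
    sizes: Mapping[str, Mapping[str, int]], pdist: PDistanceMatrix
) -> pd.DataFrame:
    """One row per taxon pair per shared locus: size difference vs distance."""
    taxa = [t for t in sizes if t in pdist.taxa]
    rows = []
    for i, ti in enumerate(taxa):
        for tj in taxa[i + 1 :]:
            shared = sorted(set(sizes[ti]) & set(sizes[tj]))
            for locus in shared:
                rows.append(
                    {
                        "taxon_i": ti,
                        "taxon_j": tj,
                        "locus": locus,
                        "intron_size_difference": intron_size_difference(
                            sizes, ti, tj, locus
                        ),
                        "p_distance": float(pdist.distances.at[ti, tj]),
                    }
                )
    return pd.DataFrame(rows)
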