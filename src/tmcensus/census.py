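"""Per-genome and cross-genome census statistics for TM-protein complements.

The census counts, for each genome: proteins, TM proteins (>=1 predicted
segment), the TM-segment-count histogram, and a 2x2 cross-tabulation of TM
status against conservation in orthogroups.  Cross-genome operations pool
histograms, stratify proteins by length, and thin redundant genomes down to
representatives.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import GenomeMetadata, OrthogroupTable, ProteinRecord
from .tm_predictor import TopologyPrediction

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenomeCensusRow:
    """Aggregate TM statistics of one genome.

    ``histogram`` maps the raw TM-segment count per protein to the number of
    such proteins (uncapped; see :meth:`capped_histogram` for plotting).
    ``cross_tab`` is ((tm & conserved, tm & not), (non-tm & conserved,
    non-tm & not)).
    """

    genome_id: str
    n_proteins: int
    n_tm: int
    histogram: Mapping[int, int]
    n_in_orthogroups: int
    cross_tab: tuple[tuple[int, int], tuple[int, int]]

    def __post_init__(self) -> None:
        if sum(self.histogram.values()) != self.n_proteins:
            raise ValueError("histogram must sum to n_proteins")
        if sum(v for k, v in self.histogram.items() if k >= 1) != self.n_tm:
            raise ValueError("n_tm must equal histogram mass at k >= 1")
        (a, b), (c, d) = self.cross_tab
        if a + b != self.n_tm or a + c != self.n_in_orthogroups:
            raise ValueError("cross_tab margins must match n_tm / n_in_orthogroups")
        if a + b + c + d != self.n_proteins:
            raise ValueError("cross_tab must sum to n_proteins")

    @property
    def tm_fraction(self) -> float:
        return self.n_tm / self.n_proteins if self.n_proteins else 0.0

    def capped_histogram(self, cap: int = 15) -> dict[str, int]:
        """Histogram with exact bins ``0..cap-1`` and a ``"{cap}+"`` overflow
        bin pooling all counts >= cap."""
        out: dict[str, int] = {}
        overflow = 0
        for k, v in sorted(self.histogram.items()):
            if k >= cap:
                overflow += v
            else:
                out[str(k)] = v
        if overflow:
            out[f"{cap}+"] = overflow
        return out


def genome_census(
    proteins: Sequence[ProteinRecord],
    predictions: Mapping[str, TopologyPrediction],
    orthogroups: OrthogroupTable | None = None,
) -> GenomeCensusRow:
    """Build the census row for one genome's proteins.

    Every protein must have exactly one prediction; missing ids raise a
    ``ValueError`` listing them.
    """
    if not proteins:
        raise ValueError("genome has no proteins")
    genome_id = proteins[0].genome_id
    missing = [p.protein_id for p in proteins if p.protein_id not in predictions]
    if missing:
        raise ValueError(f"predictions missing for proteins: {missing}")
    hist: Counter[int] = Counter()
    tab = [[0, 0], [0, 0]]
    for p in proteins:
        pred = predictions[p.protein_id]
        hist[pred.tm_count] += 1
        conserved = bool(orthogroups and orthogroups.group_of(p.protein_id) is not None)
        tab[0 if pred.is_tm_protein else 1][0 if conserved else 1] += 1
    return GenomeCensusRow(
        genome_id=genome_id,
        n_proteins=len(proteins),
        n_tm=tab[0][0] + tab[0][1],
        histogram=dict(hist),
        n_in_orthogroups=tab[0][0] + tab[1][0],
        cross_tab=((tab[0][0], tab[0][1]), (tab[1][0], tab[1][1])),
    )


def census_all(
    proteomes: Mapping[str, Sequence[ProteinRecord]],
    predictions: Mapping[str, TopologyPrediction],
    orthogroups: OrthogroupTable | None = None,
) -> list[GenomeCensusRow]:
    return [
        genome_census(proteomes[g], predictions, orthogroups)
        for g in sorted(proteomes)
    ]


def aggregate_histogram(
    rows: Sequence[GenomeCensusRow], normalize: bool = False
) -> dict[int, float]:
    """Pool per-genome TM-count histograms over proteins.

    With ``normalize`` the pooled counts become proportions summing to 1.
    """
    if not rows:
        raise ValueError("no census rows")
    pooled: Counter[int] = Counter()
    for r in rows:
        pooled.update(r.histogram)
    if not normalize:
        return dict(sorted(pooled.items()))
    total = sum(pooled.values())
    return {k: v / total for k, v in sorted(pooled.items())}


@dataclass(frozen=True)
class LengthStratification:
    """Protein counts per length bin, stratified by TM-segment class.

    ``bins`` are half-open ``[lo, lo + bin_width)`` keyed by ``lo``;
    classes are ``"0" "1" "2" "3" "4+"``.
    """

    bin_width: int
    counts: Mapping[int, Mapping[str, int]]

    CLASSES = ("0", "1", "2", "3", "4+")

    def totals(self) -> dict[int, int]:
        return {lo: sum(c.values()) for lo, c in self.counts.items()}

    def proportions(self) -> dict[int, dict[str, float]]:
        out = {}
        for lo, c in self.counts.items():
            total = sum(c.values())
            out[lo] = {k: v / total for k, v in c.items()}
        return out


def stratify_by_length(
    proteins: Sequence[ProteinRecord],
    predictions: Mapping[str, TopologyPrediction],
    bin_width: int = 100,
) -> LengthStratification:
    """Assign each protein to a length bin and a TM-count class (0,1,2,3,4+)."""
    if bin_width < 10:
        raise ValueError("bin_width must be >= 10 aa")
    counts: dict[int, Counter[str]] = {}
    for p in proteins:
        k = predictions[p.protein_id].tm_count
        cls = str(k) if k < 4 else "4+"
        lo = (p.length // bin_width) * bin_width
        counts.setdefault(lo, Counter())[cls] += 1
    return LengthStratification(
        bin_width=bin_width,
        counts={lo: dict(c) for lo, c in sorted(counts.items())},
    )


# ---------------------------------------------------------------------------
# representative selection
# ---------------------------------------------------------------------------

def shared_gene_fraction(
    groups_a: set[str], groups_b: set[str], mode: str = "min"
) -> float:
    """Fraction of genes two genomes share, judged by common orthogroups.

    ``mode="min"`` divides the shared-group count by the smaller genome's
    orthogroup-assigned gene count; ``mode="jaccard"`` divides by the union.
    """
    if not groups_a or not groups_b:
        return 0.0
    shared = len(groups_a & groups_b)
    if mode == "min":
        return shared / min(len(groups_a), len(groups_b))
    if mode == "jaccard":
        return shared / len(groups_a | groups_b)
    raise ValueError(f"unknown sharing mode {mode!r}")


def select_representatives(
    genome_groups: Mapping[str, set[str]],
    threshold: float = 0.9,
    seed: int = 0,
    mode: str = "min",
) -> set[str]:
    """Thin redundant virus genomes to one representative per lineage.

    Genome pairs sharing at least ``threshold`` of their genes (shared
    orthogroups over the smaller genome's gene count by default) are linked;
    connected components under single linkage each retain one seeded-random
    representative.  Genomes with no orthogroup-assigned genes are kept
    unconditionally with a warning.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    ids = sorted(genome_groups)
    kept: set[str] = set()
    linked_ids = []
    for g in ids:
        if not genome_groups[g]:
            logger.warning("genome %s has no orthogroup-assigned genes; kept", g)
            kept.add(g)
        else:
            linked_ids.append(g)
    # union-find over >= threshold pairs (single linkage)
    parent = {g: g for g in linked_ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(linked_ids):
        for b in linked_ids[i + 1:]:
            f = shared_gene_fraction(genome_groups[a], genome_groups[b], mode)
            if f >= threshold - 1e-12:
                parent[find(a)] = find(b)

    components: dict[str, list[str]] = {}
    for g in linked_ids:
        components.setdefault(find(g), []).append(g)
    rng = np.random.default_rng(seed)
    for members in sorted(components.values()):
        members = sorted(members)
        kept.add(members[int(rng.integers(len(members)))])
    return kept


def select_cellular_representatives(
    metadata: Mapping[str, GenomeMetadata],
    protein_counts: Mapping[str, int],
) -> set[str]:
    """Keep the largest genome (most proteins) per genus among cellular
    genomes; ties go to the lexicographically smallest genome id.  Genomes
    without a genus are kept with a warning."""
    kept: set[str] = set()
    by_genus: dict[str, list[str]] = {}
    for g, md in sorted(metadata.items()):
        if md.is_virus:
            continue
        if md.genus is None:
            logger.warning("cellular genome %s has no genus; kept", g)
            kept.add(g)
        else:
            by_genus.setdefault(md.genus, []).append(g)
    for genus, members in sorted(by_genus.items()):
        best = max(sorted(members), key=lambda g: (protein_counts[g], ))
        # max with sorted input returns the first maximum = smallest id on ties
        kept.add(best)
    return kept
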