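"""Statistical comparisons between genome categories.

Wraps the three procedures the census relies on — Pearson/point-biserial
correlation, the Mann-Whitney-Wilcoxon rank-sum test, and the Pearson
chi-squared test — plus the orthogroup prediction-consistency report.

The MWW test is exact wherever feasible: the full permutation distribution
is enumerated whenever C(n+m, n) <= 100 000 (this handles ties via
midranks), the tie-free exact distribution is used up to n*m <= 400, and a
normal approximation with midrank tie correction covers the rest.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .census import GenomeCensusRow
from .io_formats import GenomeMetadata, OrthogroupTable
from .tm_predictor import TopologyPrediction

ENUMERATION_CAP = 100_000
EXACT_NM_CAP = 400


def build_labeling(metadata: Mapping[str, GenomeMetadata]) -> dict[str, dict]:
    """Per-genome grouping labels.

    ``lipid_binary`` is 1 for lipid_associated and tentative_lipid families
    (tentative labels inherit their class), else 0.  ``host_domain_binary``
    encodes Archaea = 1, Bacteria = 0 so that archaeal TM enrichment comes
    out with a positive sign.
    """
    out = {}
    for g, md in metadata.items():
        out[g] = {
            "family": md.virus_family,
            "host_domain": md.host_domain,
            "lipid_binary": md.lipid_binary,
            "host_domain_binary": 1 if md.host_domain == "Archaea" else 0,
        }
    return out


def correlate(
    rows: Sequence[GenomeCensusRow],
    labeling: Mapping[str, Mapping],
    covariate: str = "lipid_binary",
) -> float:
    """Pearson correlation of per-genome TM fraction with a covariate.

    ``covariate`` is ``lipid_binary``, ``host_domain_binary`` (both giving
    point-biserial values) or ``n_proteins``.  Requires >= 3 genomes and
    nonzero variance on both sides.
    """
    if len(rows) < 3:
        raise ValueError("correlation needs at least 3 genomes")
    y = np.array([r.tm_fraction for r in rows], dtype=float)
    if covariate == "n_proteins":
        x = np.array([r.n_proteins for r in rows], dtype=float)
    else:
        x = np.array([labeling[r.genome_id][covariate] for r in rows], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: a variable has zero variance")
    return float(stats.pearsonr(y, x).statistic)


# ---------------------------------------------------------------------------
# Mann-Whitney-Wilcoxon
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MWWResult:
    u: float          # U statistic of the first sample
    p_value: float    # two-sided
    method: str       # enumeration | exact | asymptotic

    def p_display(self, floor: float = 2e-16) -> str:
        """Exact p where computable, a floor notation otherwise."""
        return f"< {floor:g}" if self.p_value < floor else f"{self.p_value:.4g}"


def _u_statistic(pooled_ranks: np.ndarray, idx_a: Sequence[int], n: int) -> float:
    return float(pooled_ranks[list(idx_a)].sum() - n * (n + 1) / 2)


def mww_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> MWWResult:
    """Two-sided Mann-Whitney-Wilcoxon rank-sum test.

    The enumeration path computes the permutation distribution of U over all
    C(n+m, n) relabelings with midranks, and the two-sided p as the
    probability of a U at least as far from nm/2 as observed — the
    convention the small-sample oracle in the test suite also uses.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_obs = _u_statistic(ranks, range(n), n)
    center = n * m / 2
    if math.comb(n + m, n) <= ENUMERATION_CAP:
        dev = abs(u_obs - center)
        hits = total = 0
        for idx in itertools.combinations(range(n + m), n):
            u = _u_statistic(ranks, idx, n)
            total += 1
            if abs(u - center) >= dev - 1e-9:
                hits += 1
        return MWWResult(u=u_obs, p_value=hits / total, method="enumeration")
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and n * m <= EXACT_NM_CAP:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return MWWResult(u=float(res.statistic), p_value=float(res.pvalue), method="exact")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return MWWResult(u=float(res.statistic), p_value=float(res.pvalue), method="asymptotic")


# ---------------------------------------------------------------------------
# chi-squared
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChiSquaredResult:
    statistic: float
    dof: int
    p_value: float
    n_bins: int  # columns used after merging


def _align_histograms(h1: Mapping[int, float], h2: Mapping[int, float]) -> np.ndarray:
    keys = sorted(set(h1) | set(h2))
    return np.array([[h1.get(k, 0) for k in keys], [h2.get(k, 0) for k in keys]],
                    dtype=float)


def chisq_test(
    observed: np.ndarray | Sequence[Sequence[float]] | None = None,
    hist_a: Mapping[int, float] | None = None,
    hist_b: Mapping[int, float] | None = None,
    min_expected: float = 5.0,
) -> ChiSquaredResult:
    """Pearson chi-squared test on a contingency table or two histograms.

    Histogram comparisons align the two count maps on the union of their
    keys.  Columns whose smallest expected count falls below ``min_expected``
    are merged rightward (the leftmost deficient column absorbs its right
    neighbour; a deficient last column folds left) until all expectations
    are adequate or only two columns remain.  No continuity correction.
    """
    if observed is None:
        if hist_a is None or hist_b is None:
            raise ValueError("provide a table or two histograms")
        table = _align_histograms(hist_a, hist_b)
    else:
        table = np.asarray(observed, dtype=float)
    if table.ndim != 2:
        raise ValueError("observed must be a 2-D table")
    table = table[:, table.sum(axis=0) > 0]

    def expected(t: np.ndarray) -> np.ndarray:
        return np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()

    while table.shape[1] > 2:
        exp = expected(table)
        deficient = np.nonzero(exp.min(axis=0) < min_expected)[0]
        if deficient.size == 0:
            break
        j = int(deficient[0])
        if j == table.shape[1] - 1:
            j -= 1
        table[:, j] += table[:, j + 1]
        table = np.delete(table, j + 1, axis=1)
    if table.shape[1] < 2 or table.shape[0] < 2:
        raise ValueError("fewer than 2 usable bins after merging")
    res = stats.chi2_contingency(table, correction=False)
    return ChiSquaredResult(
        statistic=float(res.statistic),
        dof=int(res.dof),
        p_value=float(res.pvalue),
        n_bins=table.shape[1],
    )


# ---------------------------------------------------------------------------
# orthogroup consistency
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupConsistency:
    group_id: str
    tm_counts: tuple[int, ...]  # sorted member TM counts
    is_uniform: bool
    max_difference: int


@dataclass(frozen=True)
class ConsistencyReport:
    """Agreement of TM-count predictions among orthologs.

    Aggregates are computed over groups with >= 2 predicted members;
    discordance magnitude is max minus min member TM count.
    """

    groups: tuple[GroupConsistency, ...]
    fraction_uniform: float
    discordant_by_one: float   # fraction of discordant groups
    discordant_by_two: float

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def orthogroup_consistency(
    predictions: Mapping[str, TopologyPrediction],
    orthogroups: OrthogroupTable,
) -> ConsistencyReport:
    """Judge per-orthogroup uniformity of predicted TM counts."""
    groups = []
    for gid in sorted(orthogroups.group_members):
        counts = sorted(
            predictions[p].tm_count
            for p in orthogroups.group_members[gid]
            if p in predictions
        )
        if len(counts) < 2:
            continue
        diff = counts[-1] - counts[0]
        groups.append(GroupConsistency(
            group_id=gid, tm_counts=tuple(counts),
            is_uniform=diff == 0, max_difference=diff,
        ))
    if not groups:
        raise ValueError("no orthogroup has >= 2 predicted members")
    n_uniform = sum(g.is_uniform for g in groups)
    discordant = [g for g in groups if not g.is_uniform]
    nd = len(discordant)
    return ConsistencyReport(
        groups=tuple(groups),
        fraction_uniform=n_uniform / len(groups),
        discordant_by_one=(sum(g.max_difference == 1 for g in discordant) / nd) if nd else 0.0,
        discordant_by_two=(sum(g.max_difference == 2 for g in discordant) / nd) if nd else 0.0,
    )
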