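"""Built-in α-helical transmembrane topology predictor.

A hydropathy sliding-window segment caller with positive-inside-rule
orientation and an N-terminal signal-peptide guard.  The calling rules are,
in order:

1. every length-``window`` stretch whose mean hydropathy is at least
   ``threshold`` marks all residues it covers as seed;
2. maximal seed runs separated by fewer than ``merge_gap`` residues are
   merged;
3. run boundaries are trimmed back while the terminal residue's hydropathy
   is below ``trim_threshold`` (boundary refinement — the union of
   qualifying windows systematically overshoots into flanking loops);
4. runs longer than ``max_len`` are split at the lowest-hydropathy interior
   residue (recursively) and re-trimmed;
5. runs shorter than ``min_len`` are discarded;
6. if a signal peptide is detected, segments lying wholly within the signal
   region are removed;
7. the N-terminal side is oriented by the positive-inside rule.

Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from statistics import median
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import ProteinRecord

#: Kyte-Doolittle hydropathy values (dimensionless, positive = hydrophobic).
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class HydropathyScale:
    """A residue -> hydropathy mapping; all 20 standard residues required."""

    values: Mapping[str, float]
    name: str = "kyte-doolittle"

    def __post_init__(self) -> None:
        missing = set(KYTE_DOOLITTLE) - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues {sorted(missing)}")

    def profile(self, sequence: str) -> np.ndarray:
        return np.array([self.values[c] for c in sequence], dtype=float)


DEFAULT_SCALE = HydropathyScale(KYTE_DOOLITTLE)


@dataclass(frozen=True)
class PredictorConfig:
    """Tunable parameters of the segment caller.

    Defaults: a 19-residue window (the classic hydropathy-plot width, close
    to the ~20 aa a membrane-spanning helix needs), mean-hydropathy seed
    threshold 1.6 Kyte-Doolittle units, segment length bounds 15-35 aa,
    merge gap 3, boundary trim at hydropathy 0, signal guard on.
    """

    window: int = 19
    threshold: float = 1.6
    min_len: int = 15
    max_len: int = 35
    merge_gap: int = 3
    trim_threshold: float = 0.0
    signal_guard: bool = True
    # signal-peptide heuristic parameters
    sp_scan_len: int = 30
    sp_n_region: int = 5
    sp_h_min: int = 7
    sp_h_max: int = 15
    sp_h_kd_min: float = 1.5
    sp_h_start_max: int = 10
    sp_c_search: int = 6
    sp_small_residues: str = "AGSCT"
    scale: HydropathyScale = DEFAULT_SCALE

    def __post_init__(self) -> None:
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("need 0 < min_len <= max_len")
        if self.window < 1 or self.merge_gap < 0:
            raise ValueError("window >= 1 and merge_gap >= 0 required")


DEFAULT_CONFIG = PredictorConfig()


@dataclass(frozen=True, order=True)
class TMSegment:
    """One predicted membrane-spanning helix, 1-based inclusive."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad segment bounds {self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TopologyPrediction:
    """Predicted topology of one protein.

    ``n_terminal_side`` is informational when ``segments`` is empty.
    """

    protein_id: str
    segments: tuple[TMSegment, ...]
    n_terminal_side: str  # "in" | "out"
    signal_peptide: bool = False
    source: str = "builtin"

    def __post_init__(self) -> None:
        if self.n_terminal_side not in ("in", "out"):
            raise ValueError(f"bad n_terminal_side {self.n_terminal_side!r}")
        prev_end = 0
        for seg in self.segments:
            if seg.start <= prev_end + 1 and prev_end:
                raise ValueError("segments must be disjoint with >=1 residue between")
            if seg.start <= prev_end:
                raise ValueError("segments must be ascending")
            prev_end = seg.end

    @property
    def tm_count(self) -> int:
        return len(self.segments)

    @property
    def is_tm_protein(self) -> bool:
        """A protein counts as TM when it has at least one TM segment,
        regardless of signal peptide."""
        return bool(self.segments)


# ---------------------------------------------------------------------------
# segment calling
# ---------------------------------------------------------------------------

def _seed_coverage(profile: np.ndarray, config: PredictorConfig) -> np.ndarray:
    """Boolean per-residue array marking residues covered by any window whose
    mean hydropathy is at least the threshold."""
    n = len(profile)
    covered = np.zeros(n, dtype=bool)
    w = config.window
    if n < w:
        return covered
    sums = np.convolve(profile, np.ones(w), mode="valid")
    # tolerance guards against float accumulation at the threshold boundary
    hits = np.nonzero(sums >= config.threshold * w - 1e-9)[0]
    for i in hits:
        covered[i : i + w] = True
    return covered


def _runs(mask: np.ndarray) -> list[list[int]]:
    """Maximal runs of True as [start, end] 0-based inclusive pairs."""
    runs: list[list[int]] = []
    idx = np.nonzero(mask)[0]
    for i in idx:
        if runs and i == runs[-1][1] + 1:
            runs[-1][1] = i
        else:
            runs.append([i, i])
    return runs


def _trim(run: list[int], profile: np.ndarray, config: PredictorConfig) -> list[int] | None:
    a, b = run
    while a <= b and profile[a] < config.trim_threshold:
        a += 1
    while b >= a and profile[b] < config.trim_threshold:
        b -= 1
    return [a, b] if a <= b else None


def _refine(run: list[int], profile: np.ndarray, config: PredictorConfig) -> list[list[int]]:
    """Trim a run, split it at the lowest-hydropathy interior residue while it
    exceeds max_len, and drop pieces shorter than min_len."""
    trimmed = _trim(run, profile, config)
    if trimmed is None:
        return []
    a, b = trimmed
    if b - a + 1 > config.max_len and b - a >= 2:
        interior = profile[a + 1 : b]
        j = a + 1 + int(np.argmin(interior))
        return _refine([a, j - 1], profile, config) + _refine([j + 1, b], profile, config)
    if b - a + 1 < config.min_len:
        return []
    return [[a, b]]


def call_segments(sequence: str, config: PredictorConfig = DEFAULT_CONFIG) -> list[TMSegment]:
    """Run the sliding-window caller on a sanitized sequence."""
    profile = config.scale.profile(sequence)
    covered = _seed_coverage(profile, config)
    raw = _runs(covered)
    # merge runs separated by fewer than merge_gap residues
    merged: list[list[int]] = []
    for run in raw:
        if merged and run[0] - merged[-1][1] - 1 < config.merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(list(run))
    segments: list[TMSegment] = []
    for run in merged:
        for a, b in _refine(run, profile, config):
            segments.append(TMSegment(int(a) + 1, int(b) + 1))
    return segments


def detect_signal_peptide(
    sequence: str, config: PredictorConfig = DEFAULT_CONFIG
) -> tuple[bool, int]:
    """Detect an N-terminal signal peptide by its tripartite n/h/c pattern.

    Requires: at least one Lys/Arg within the first ``sp_n_region`` residues
    (n-region); a hydrophobic run of ``sp_h_min``..``sp_h_max`` residues
    (each with hydropathy >= ``sp_h_kd_min``) starting no later than
    ``sp_h_start_max``; and a small-residue A-X-A-style motif (positions p
    and p+2 both small) within ``sp_c_search`` residues after the run.

    Returns ``(detected, cleavage_region_end)``; the end is the 1-based
    position of the last signal residue, 0 when not detected.  Sequences
    shorter than 25 residues never carry a signal.
    """
    if len(sequence) < 25:
        return False, 0
    head = sequence[: config.sp_scan_len]
    if not any(c in "KR" for c in head[: config.sp_n_region]):
        return False, 0
    profile = config.scale.profile(head)
    hydro = profile >= config.sp_h_kd_min
    for a, b in _runs(hydro):
        length = b - a + 1
        start_1 = a + 1
        if start_1 > config.sp_h_start_max:
            break
        if not (config.sp_h_min <= length <= config.sp_h_max):
            continue
        # c-region: small residues at p and p+2, p within sp_c_search of the
        # run end (starting just before it: Ala at the run tail is itself
        # hydrophobic, so the motif may straddle the boundary)
        small = set(config.sp_small_residues)
        for p in range(max(a + 1, b - 2), min(b + 1 + config.sp_c_search, len(head) - 2)):
            if head[p] in small and head[p + 2] in small:
                return True, p + 3  # 1-based index of the second small residue
    return False, 0


def decide_orientation(
    segments: Sequence[TMSegment], sequence: str
) -> str:
    """Orient the N-terminal side by the positive-inside rule.

    Lys+Arg are counted in the alternating inter-segment loops under both
    orientations; the orientation placing more on the 'in' side wins, with
    ties broken to 'in' (the N_in-C_in topology dominant in nearly all
    organisms).
    """
    if not segments:
        raise ValueError("orientation needs at least one segment")
    bounds = [0] + [s for seg in segments for s in (seg.start - 1, seg.end)] + [len(sequence)]
    loops = [sequence[bounds[2 * i] : bounds[2 * i + 1]] for i in range(len(segments) + 1)]
    kr = [sum(c in "KR" for c in loop) for loop in loops]
    n_in = sum(kr[0::2])   # loops that are inside if the N terminus is inside
    n_out = sum(kr[1::2])
    return "in" if n_in >= n_out else "out"


def predict_topology(
    protein: ProteinRecord, config: PredictorConfig = DEFAULT_CONFIG
) -> TopologyPrediction:
    """Predict the full TM topology of one protein.

    Sequences shorter than the window give a zero-segment prediction.  When
    the signal guard is on and a signal peptide is detected, segments that
    start inside the signal region are removed (their hydrophobic core is an
    export signal, not a membrane anchor, even when the called segment leaks
    past the cleavage site); segments further downstream still count.
    """
    segments = call_segments(protein.sequence, config)
    signal, signal_end = (False, 0)
    if config.signal_guard:
        signal, signal_end = detect_signal_peptide(protein.sequence, config)
        if signal:
            segments = [s for s in segments if s.start > signal_end]
    side = decide_orientation(segments, protein.sequence) if segments else "in"
    return TopologyPrediction(
        protein_id=protein.protein_id,
        segments=tuple(segments),
        n_terminal_side=side,
        signal_peptide=signal,
        source="builtin",
    )


def predict_proteomes(
    proteomes: Mapping[str, Sequence[ProteinRecord]],
    config: PredictorConfig = DEFAULT_CONFIG,
) -> dict[str, TopologyPrediction]:
    """Predict every protein in a proteome collection, keyed by protein id."""
    out: dict[str, TopologyPrediction] = {}
    for genome_id in sorted(proteomes):
        for rec in proteomes[genome_id]:
            out[rec.protein_id] = predict_topology(rec, config)
    return out


# ---------------------------------------------------------------------------
# concordance and length statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConcordanceSummary:
    """Cross-predictor agreement on per-protein TM-segment counts."""

    n_shared: int
    identical_fraction: float
    discordant_by_one: float  # fraction of discordant proteins, NaN-free: 0 when none
    discordant_by_two: float
    discordant_by_more: float


def compare_predictions(
    a: Mapping[str, TopologyPrediction], b: Mapping[str, TopologyPrediction]
) -> ConcordanceSummary:
    """Compare two prediction sets on their shared protein-id universe.

    Reports the fraction of proteins with identical TM-segment counts and,
    among the discordant ones, the fractions differing by exactly one, two,
    and more than two segments.
    """
    shared = sorted(set(a) & set(b))
    if not shared:
        raise ValueError("prediction sets share no protein ids")
    diffs = [abs(a[p].tm_count - b[p].tm_count) for p in shared]
    n = len(diffs)
    n_discord = sum(d > 0 for d in diffs)
    def frac(k):
        if n_discord == 0:
            return 0.0
        return sum(1 for d in diffs if d == k) / n_discord
    return ConcordanceSummary(
        n_shared=n,
        identical_fraction=sum(d == 0 for d in diffs) / n,
        discordant_by_one=frac(1),
        discordant_by_two=frac(2),
        discordant_by_more=(sum(1 for d in diffs if d > 2) / n_discord) if n_discord else 0.0,
    )


@dataclass(frozen=True)
class SegmentLengthStats:
    mean: float
    median: float
    histogram: dict[int, int]  # length (aa) -> segment count
    n_segments: int


def segment_length_stats(
    predictions: Iterable[TopologyPrediction],
) -> SegmentLengthStats:
    """Mean, median, and per-residue histogram of TM segment lengths."""
    lengths = [seg.length for p in predictions for seg in p.segments]
    if not lengths:
        raise ValueError("no TM segments in input")
    return SegmentLengthStats(
        mean=float(np.mean(lengths)),
        median=float(median(lengths)),
        histogram=dict(sorted(Counter(lengths).items())),
        n_segments=len(lengths),
    )
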