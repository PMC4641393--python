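"""Readers and writers for the external formats the census pipeline touches.

Canonical in-memory containers are plain dataclasses plus pandas DataFrames
for tabular data.  All TM-segment coordinates are 1-based inclusive, the
convention used by Phobius short-format output; every table writer records
this in its provenance header.

Protein sequences are sanitized on input: ambiguity codes and stop symbols
(``B J O U X Z * -``, anything outside the 20 standard residues) are deleted,
not substituted.  Sequences that are empty after sanitization are dropped
with a logged warning.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: classes a lipid-association label may take
LIPID_CLASSES = (
    "lipid_associated",
    "non_lipid",
    "tentative_lipid",
    "tentative_non_lipid",
    "unknown",
)


class ParseError(ValueError):
    """Raised when an input file violates its documented grammar."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence tied to its genome of origin."""

    protein_id: str
    genome_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for protein {self.protein_id!r}")
        bad = set(self.sequence) - STANDARD_AA
        if bad:
            raise ValueError(
                f"protein {self.protein_id!r} contains nonstandard residues {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomeMetadata:
    """Per-genome annotation used for grouping and labelling."""

    genome_id: str
    name: str
    entity_class: str  # virus | bacterium | archaeon
    virus_family: str | None = None
    host_domain: str | None = None  # Bacteria | Archaea | None
    lipid_class: str = "unknown"
    genus: str | None = None

    def __post_init__(self) -> None:
        if self.entity_class not in ("virus", "bacterium", "archaeon"):
            raise ValueError(f"bad entity_class {self.entity_class!r}")
        if self.lipid_class not in LIPID_CLASSES:
            raise ValueError(f"bad lipid_class {self.lipid_class!r}")
        if self.entity_class == "virus" and self.host_domain not in ("Bacteria", "Archaea"):
            raise ValueError(f"virus {self.genome_id!r} must have a host domain")
        if self.entity_class != "virus" and self.virus_family is not None:
            raise ValueError(f"cellular genome {self.genome_id!r} cannot have a virus family")

    @property
    def is_virus(self) -> bool:
        return self.entity_class == "virus"

    @property
    def lipid_binary(self) -> int:
        """1 for (tentatively) lipid-associated virions, else 0."""
        return int(self.lipid_class in ("lipid_associated", "tentative_lipid"))


class OrthogroupTable:
    """Membership table mapping proteins to orthologous groups.

    Each protein belongs to at most one group.  Member ids that do not
    resolve to a loaded protein are not an error here; resolution happens
    where proteomes are available.
    """

    def __init__(self, protein_to_group: Mapping[str, str]):
        self.protein_to_group: dict[str, str] = dict(protein_to_group)
        members: dict[str, set[str]] = {}
        for pid, gid in self.protein_to_group.items():
            members.setdefault(gid, set()).add(pid)
        self.group_members: dict[str, set[str]] = members

    def __len__(self) -> int:
        return len(self.group_members)

    def group_of(self, protein_id: str) -> str | None:
        return self.protein_to_group.get(protein_id)

    def dangling_members(self, known_proteins: Iterable[str]) -> set[str]:
        known = set(known_proteins)
        return {p for p in self.protein_to_group if p not in known}


@dataclass(frozen=True)
class ProphageRegion:
    """A prophage integrated in a cellular genome, as a set of its proteins."""

    genome_id: str
    region_id: str
    protein_ids: frozenset[str]


def sanitize_sequence(seq: str) -> str:
    """Delete every character that is not one of the 20 standard residues.

    Idempotent; uppercases first so lowercase records survive.
    """
    return "".join(c for c in seq.upper() if c in STANDARD_AA)


def read_proteomes(
    paths: Sequence[str | Path],
    genome_of: Mapping[str, str] | None = None,
) -> dict[str, list[ProteinRecord]]:
    """Read protein FASTA files into records grouped by genome.

    Genome assignment uses the explicit ``genome_of`` sidecar mapping
    (protein id -> genome id) when given; otherwise headers are split on the
    first ``|`` as ``genome_id|protein_id``.  Headers without a ``|`` fall
    back to one genome per file, named after the file stem.

    Raises
    ------
    ParseError
        If a protein id repeats within a genome.
    OSError
        If a file cannot be read (the message names the file).
    """
    proteomes: dict[str, list[ProteinRecord]] = {}
    seen: dict[str, set[str]] = {}
    for path in paths:
        path = Path(path)
        try:
            records = list(SeqIO.parse(str(path), "fasta"))
        except OSError as exc:
            raise OSError(f"cannot read proteome file {path}: {exc}") from exc
        for rec in records:
            header = rec.id
            if genome_of is not None and header in genome_of:
                genome_id, protein_id = genome_of[header], header
            elif "|" in header:
                genome_id, protein_id = header.split("|", 1)
            else:
                genome_id, protein_id = path.stem, header
            seq = sanitize_sequence(str(rec.seq))
            if not seq:
                logger.warning(
                    "dropping protein %s (genome %s): empty after sanitization",
                    protein_id, genome_id,
                )
                continue
            if protein_id in seen.setdefault(genome_id, set()):
                raise ParseError(
                    f"duplicate protein id {protein_id!r} in genome {genome_id!r} ({path})"
                )
            seen[genome_id].add(protein_id)
            proteomes.setdefault(genome_id, []).append(
                ProteinRecord(protein_id=protein_id, genome_id=genome_id, sequence=seq)
            )
        if not records:
            logger.warning("proteome file %s contained no records", path)
    return proteomes


def write_proteomes(
    proteomes: Mapping[str, Sequence[ProteinRecord]], path: str | Path
) -> None:
    """Write all proteomes to one FASTA file with ``genome|protein`` headers."""
    path = Path(path)
    with open(path, "w") as fh:
        for genome_id in sorted(proteomes):
            for rec in proteomes[genome_id]:
                fh.write(f">{rec.genome_id}|{rec.protein_id}\n")
                for i in range(0, rec.length, 60):
                    fh.write(rec.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Phobius short format
# ---------------------------------------------------------------------------

_TOPO_SEGMENT = re.compile(r"(\d+)-(\d+)")


def _parse_topology_string(topo: str, line_no: int) -> tuple[list[tuple[int, int]], str, int]:
    """Decode a Phobius-style topology string.

    Returns (segments, n_terminal_side, signal_end).  Grammar: an optional
    signal-peptide prefix ``n<a>-<b>c<x>/<y>`` followed by alternating side
    letters (``i``/``o``) and ``start-end`` TM segments, e.g.
    ``i12-33o45-66i``.  ``signal_end`` is 0 when no signal prefix is present.
    """
    signal_end = 0
    rest = topo
    if rest.startswith("n"):
        m = re.match(r"n(\d+)-(\d+)c(\d+)/(\d+)", rest)
        if not m:
            raise ParseError(f"line {line_no}: malformed signal prefix in {topo!r}")
        signal_end = int(m.group(3))
        rest = rest[m.end():]
    if not rest or rest[0] not in "io":
        raise ParseError(f"line {line_no}: topology {topo!r} must start with i or o")
    if rest[-1] not in "io":
        raise ParseError(f"line {line_no}: topology {topo!r} must end on a side letter")
    n_side = "in" if rest[0] == "i" else "out"
    segments: list[tuple[int, int]] = []
    pos = 0
    expected_side = rest[0]
    while pos < len(rest):
        if rest[pos] != expected_side:
            raise ParseError(f"line {line_no}: sides must alternate in {topo!r}")
        pos += 1
        if pos == len(rest):
            break
        m = _TOPO_SEGMENT.match(rest, pos)
        if not m:
            raise ParseError(f"line {line_no}: expected start-end at col {pos} of {topo!r}")
        start, end = int(m.group(1)), int(m.group(2))
        if start > end or (segments and start <= segments[-1][1]):
            raise ParseError(f"line {line_no}: segment {start}-{end} out of order in {topo!r}")
        segments.append((start, end))
        pos = m.end()
        expected_side = "o" if expected_side == "i" else "i"
    return segments, n_side, signal_end


def parse_phobius(path: str | Path):
    """Parse Phobius short-format output into topology predictions.

    Expected columns per row: sequence id, TM segment count, signal-peptide
    flag (``Y``/``N`` or ``1``/``0``), topology string.  A header line
    beginning with ``SEQENCE``/``SEQUENCE`` (Phobius misspells it) or ``#``
    is skipped.  Coordinates are kept 1-based inclusive as printed.

    Returns a dict protein_id -> :class:`tmcensus.tm_predictor.TopologyPrediction`
    with ``source="phobius"``.
    """
    from .tm_predictor import TMSegment, TopologyPrediction

    predictions = {}
    path = Path(path)
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.upper().startswith("SEQ"):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"line {line_no}: expected 4 columns, got {len(fields)}")
            pid, tm_count_s, sp_flag, topo = fields[0], fields[1], fields[2], fields[3]
            try:
                tm_count = int(tm_count_s)
            except ValueError as exc:
                raise ParseError(f"line {line_no}: bad TM count {tm_count_s!r}") from exc
            signal = sp_flag.upper() in ("Y", "1")
            if tm_count == 0 and topo in ("-", "."):
                segments, n_side = [], "in"
            else:
                segments, n_side, _ = _parse_topology_string(topo, line_no)
            if len(segments) != tm_count:
                raise ParseError(
                    f"line {line_no}: TM count {tm_count} disagrees with "
                    f"{len(segments)} segments in topology {topo!r}"
                )
            predictions[pid] = TopologyPrediction(
                protein_id=pid,
                segments=tuple(TMSegment(s, e) for s, e in segments),
                n_terminal_side=n_side,
                signal_peptide=signal,
                source="phobius",
            )
    return predictions


def write_phobius_like(predictions, path: str | Path) -> None:
    """Write predictions in the 4-column Phobius short format."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("SEQUENCE_ID\tTM\tSP\tPREDICTION\n")
        for pid in sorted(predictions):
            pred = predictions[pid]
            side = "i" if pred.n_terminal_side == "in" else "o"
            if not pred.segments:
                topo = side
            else:
                parts = []
                cur = side
                for seg in pred.segments:
                    parts.append(f"{cur}{seg.start}-{seg.end}")
                    cur = "o" if cur == "i" else "i"
                parts.append(cur)
                topo = "".join(parts)
            sp = "Y" if pred.signal_peptide else "N"
            fh.write(f"{pid}\t{len(pred.segments)}\t{sp}\t{topo}\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

METADATA_COLUMNS = [
    "genome_id", "name", "entity_class", "virus_family",
    "host_domain", "lipid_class", "genus",
]


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df


def read_metadata(path: str | Path) -> dict[str, GenomeMetadata]:
    """Read the genome metadata TSV. Unknown columns are ignored but preserved
    by :func:`write_metadata` round-trips at the DataFrame level."""
    df = _read_tsv(path, METADATA_COLUMNS)
    out: dict[str, GenomeMetadata] = {}
    for row in df.itertuples(index=False):
        md = GenomeMetadata(
            genome_id=row.genome_id,
            name=row.name,
            entity_class=row.entity_class,
            virus_family=row.virus_family or None,
            host_domain=row.host_domain or None,
            lipid_class=row.lipid_class or "unknown",
            genus=row.genus or None,
        )
        if md.genome_id in out:
            raise ParseError(f"duplicate genome_id {md.genome_id!r} in metadata")
        out[md.genome_id] = md
    return out


def write_metadata(metadata: Mapping[str, GenomeMetadata], path: str | Path,
                   provenance: str | None = None) -> None:
    rows = [
        {
            "genome_id": m.genome_id, "name": m.name, "entity_class": m.entity_class,
            "virus_family": m.virus_family or "", "host_domain": m.host_domain or "",
            "lipid_class": m.lipid_class, "genus": m.genus or "",
        }
        for m in (metadata[g] for g in sorted(metadata))
    ]
    _write_tsv(pd.DataFrame(rows, columns=METADATA_COLUMNS), path, provenance)


def read_orthogroups(path: str | Path) -> OrthogroupTable:
    df = _read_tsv(path, ["protein_id", "group_id"])
    mapping: dict[str, str] = {}
    for row in df.itertuples(index=False):
        if row.protein_id in mapping and mapping[row.protein_id] != row.group_id:
            raise ParseError(
                f"protein {row.protein_id!r} assigned to more than one orthogroup"
            )
        mapping[row.protein_id] = row.group_id
    return OrthogroupTable(mapping)


def write_orthogroups(table: OrthogroupTable, path: str | Path,
                      provenance: str | None = None) -> None:
    rows = sorted(table.protein_to_group.items())
    df = pd.DataFrame(rows, columns=["protein_id", "group_id"])
    _write_tsv(df, path, provenance)


def read_prophages(path: str | Path) -> list[ProphageRegion]:
    df = _read_tsv(path, ["genome_id", "region_id", "protein_ids"])
    return [
        ProphageRegion(
            genome_id=row.genome_id,
            region_id=row.region_id,
            protein_ids=frozenset(p for p in row.protein_ids.split(",") if p),
        )
        for row in df.itertuples(index=False)
    ]


def write_prophages(regions: Iterable[ProphageRegion], path: str | Path,
                    provenance: str | None = None) -> None:
    rows = [
        {
            "genome_id": r.genome_id,
            "region_id": r.region_id,
            "protein_ids": ",".join(sorted(r.protein_ids)),
        }
        for r in sorted(regions, key=lambda r: (r.genome_id, r.region_id))
    ]
    _write_tsv(pd.DataFrame(rows, columns=["genome_id", "region_id", "protein_ids"]),
               path, provenance)


def _write_tsv(df: pd.DataFrame, path: str | Path, provenance: str | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# coordinates: 1-based inclusive\n")
        if provenance:
            fh.write(f"# provenance: {provenance}\n")
        df.to_csv(fh, sep="\t", index=False)


# --- census table serialization --------------------------------------------

CENSUS_COLUMNS = [
    "genome_id", "n_proteins", "n_tm", "tm_fraction", "histogram",
    "n_in_orthogroups", "tm_cons", "tm_not_cons", "nontm_cons", "nontm_not_cons",
]


def _encode_histogram(hist: Mapping[int, int]) -> str:
    return ";".join(f"{k}:{hist[k]}" for k in sorted(hist) if hist[k] > 0) or "-"


def _decode_histogram(text: str) -> dict[int, int]:
    if text in ("-", ""):
        return {}
    out: dict[int, int] = {}
    for part in text.split(";"):
        k, v = part.split(":")
        out[int(k)] = int(v)
    return out


def write_census_tables(rows, path: str | Path, provenance: str | None = None) -> None:
    """Write per-genome census rows as TSV (fractions at 4 decimal places)."""
    rows = list(rows)
    if not rows:
        raise ValueError("no census rows to write")
    data = []
    for r in rows:
        data.append({
            "genome_id": r.genome_id,
            "n_proteins": r.n_proteins,
            "n_tm": r.n_tm,
            "tm_fraction": f"{r.tm_fraction:.4f}",
            "histogram": _encode_histogram(r.histogram),
            "n_in_orthogroups": r.n_in_orthogroups,
            "tm_cons": r.cross_tab[0][0], "tm_not_cons": r.cross_tab[0][1],
            "nontm_cons": r.cross_tab[1][0], "nontm_not_cons": r.cross_tab[1][1],
        })
    _write_tsv(pd.DataFrame(data, columns=CENSUS_COLUMNS), path, provenance)


def read_census_tables(path: str | Path):
    """Read a census TSV back into :class:`tmcensus.census.GenomeCensusRow`."""
    from .census import GenomeCensusRow

    df = _read_tsv(path, CENSUS_COLUMNS)
    rows = []
    for r in df.itertuples(index=False):
        rows.append(GenomeCensusRow(
            genome_id=r.genome_id,
            n_proteins=int(r.n_proteins),
            n_tm=int(r.n_tm),
            histogram=_decode_histogram(r.histogram),
            n_in_orthogroups=int(r.n_in_orthogroups),
            cross_tab=((int(r.tm_cons), int(r.tm_not_cons)),
                       (int(r.nontm_cons), int(r.nontm_not_cons))),
        ))
    return rows
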