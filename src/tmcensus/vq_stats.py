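"""Viral Quotient: how virus-specific an orthologous gene family is.

For an orthogroup, let f_viral be the fraction of the lytic-virus genome
universe containing at least one member, f_cellular the fraction of the
cellular genome universe containing at least one member anywhere, and
f_prophage the fraction of cellular genomes whose matches include at least
one protein inside a detected prophage region.  Prophage-located homologs
are credited to the viral side:

    VQ = (f_viral + f_prophage) / (f_viral + f_prophage + f_cellular)

so a family found only in lytic viruses scores 1.0, one found only outside
prophages in cellular genomes scores 0.0, and one found only inside
prophages scores exactly 0.5 (its prophage credit equals its cellular
presence).  VQ > 0.5 therefore marks predominantly phage- and
prophage-related families, VQ < 0.5 predominantly cellular ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import GenomeMetadata, OrthogroupTable, ProphageRegion


@dataclass(frozen=True)
class VQRecord:
    """Genome-frequencies of an orthogroup's matches and its Viral Quotient."""

    group_id: str
    f_viral: float
    f_cellular: float
    f_prophage: float
    vq: float

    def __post_init__(self) -> None:
        for name in ("f_viral", "f_cellular", "f_prophage", "vq"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} = {v} outside [0, 1]")


def compute_vq(
    group_id: str,
    member_genomes: Iterable[str],
    metadata: Mapping[str, GenomeMetadata],
    prophage_genomes: Iterable[str] = (),
    n_virus: int | None = None,
    n_cellular: int | None = None,
    prophage_mode: str = "credit",
) -> VQRecord:
    """Compute the Viral Quotient of one orthogroup.

    Parameters
    ----------
    member_genomes
        Genomes (virus or cellular) containing at least one group member.
    prophage_genomes
        Cellular genomes where at least one member lies inside a prophage
        region (must be a subset of the cellular members).
    n_virus, n_cellular
        Universe sizes; default to the counts in ``metadata``.
    prophage_mode
        ``"credit"`` (default) adds the prophage frequency to the viral
        numerator only; ``"double"`` additionally counts it a second time in
        the denominator (an alternative algebraic reading, not default).
    """
    if n_virus is None:
        n_virus = sum(1 for m in metadata.values() if m.is_virus)
    if n_cellular is None:
        n_cellular = sum(1 for m in metadata.values() if not m.is_virus)
    member_genomes = set(member_genomes)
    if not member_genomes:
        raise ValueError(f"orthogroup {group_id!r} has no resolvable members")
    unknown = member_genomes - set(metadata)
    if unknown:
        raise ValueError(f"orthogroup {group_id!r}: genomes not in metadata: {sorted(unknown)}")
    viral = {g for g in member_genomes if metadata[g].is_virus}
    cellular = member_genomes - viral
    prophage = set(prophage_genomes) & cellular
    f_viral = len(viral) / n_virus if n_virus else 0.0
    f_cellular = len(cellular) / n_cellular if n_cellular else 0.0
    f_prophage = len(prophage) / n_cellular if n_cellular else 0.0
    numerator = f_viral + f_prophage
    if prophage_mode == "credit":
        denominator = f_viral + f_prophage + f_cellular
    elif prophage_mode == "double":
        denominator = f_viral + f_prophage + f_cellular + f_prophage
    else:
        raise ValueError(f"unknown prophage_mode {prophage_mode!r}")
    vq = numerator / denominator if denominator else 0.0
    return VQRecord(group_id=group_id, f_viral=f_viral, f_cellular=f_cellular,
                    f_prophage=f_prophage, vq=vq)


def classify_vq(record: VQRecord) -> str:
    """Classify a family as viral_only (VQ = 1), predominantly_viral
    (0.5 <= VQ < 1; the 0.5 boundary is assigned to the viral side because a
    prophage-only family scores exactly 0.5), or predominantly_cellular."""
    if record.vq == 1.0:
        return "viral_only"
    if record.vq >= 0.5:
        return "predominantly_viral"
    return "predominantly_cellular"


def vq_table(
    orthogroups: OrthogroupTable,
    protein_to_genome: Mapping[str, str],
    metadata: Mapping[str, GenomeMetadata],
    prophages: Sequence[ProphageRegion] = (),
    prophage_mode: str = "credit",
) -> list[VQRecord]:
    """Compute VQ for every orthogroup from a membership table.

    ``protein_to_genome`` resolves member proteins; members that do not
    resolve are skipped (a group with none resolvable raises).
    """
    prophage_proteins: dict[str, str] = {}
    for region in prophages:
        for pid in region.protein_ids:
            prophage_proteins[pid] = region.genome_id
    records = []
    for gid in sorted(orthogroups.group_members):
        members = orthogroups.group_members[gid]
        genomes = {protein_to_genome[p] for p in members if p in protein_to_genome}
        pro = {prophage_proteins[p] for p in members if p in prophage_proteins}
        records.append(compute_vq(gid, genomes, metadata, pro,
                                  prophage_mode=prophage_mode))
    return records
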