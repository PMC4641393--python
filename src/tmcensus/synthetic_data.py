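"""Seeded generator of synthetic proteomes with planted TM ground truth.

The generator emulates the statistical structure the census assumes for
dsDNA prokaryotic viruses and their bacterial/archaeal hosts: virus-like
genomes carry few TM proteins (target fraction 0.08 on average, almost all
with 1-3 segments) while cell-like genomes carry 20-25 % TM proteins with
secondary abundance peaks at 6 and 12 segments; planted helices are ~21 aa
of hydrophobic-enriched composition separated by charged loops carrying a
Lys/Arg excess on the cytoplasmic side; a small minority of proteins get an
N-terminal signal peptide; virion lipid association boosts a virus genome's
TM target; orthogroups are built from perturbed copies of per-group
prototype proteins; some cellular genomes carry a prophage block whose
genes come from the viral orthogroup pool.

All randomness flows from a single integer seed through fixed-purpose
substreams (``default_rng([seed, stream, index, ...])``), so generating a
genome never disturbs the others and group prototypes do not depend on
which genome first uses them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import (
    GenomeMetadata,
    OrthogroupTable,
    ProphageRegion,
    ProteinRecord,
)
from .tm_predictor import TMSegment, TopologyPrediction

# rng stream codes
_VIRUS, _CELL, _PROTO = 1, 2, 3

#: residue frequencies inside planted membrane helices (hydrophobic-enriched)
TM_COMPOSITION = {
    "L": 0.24, "I": 0.15, "V": 0.15, "F": 0.11, "A": 0.16, "M": 0.07,
    "W": 0.02, "C": 0.02, "G": 0.04, "S": 0.02, "T": 0.02,
}

#: loop residues outside the planted Lys/Arg positions (hydrophilic, K/R-free)
LOOP_COMPOSITION = {
    "D": 0.14, "E": 0.14, "S": 0.14, "T": 0.11, "P": 0.09, "G": 0.12,
    "N": 0.09, "Q": 0.09, "H": 0.04, "Y": 0.04,
}

#: whole-protein composition for soluble (0-TM) proteins; surface-biased
#: (charged/polar-enriched) so hydrophobic windows stay rare, as they do in
#: real soluble proteins scanned by TM predictors
NONTM_COMPOSITION = {
    "A": 0.05, "R": 0.05, "N": 0.06, "D": 0.08, "C": 0.005, "Q": 0.04,
    "E": 0.10, "G": 0.10, "H": 0.02, "I": 0.03, "L": 0.06, "K": 0.08,
    "M": 0.015, "F": 0.02, "P": 0.05, "S": 0.10, "T": 0.06, "W": 0.01,
    "Y": 0.03, "V": 0.04,
}

#: virus family -> (host domain, lipid class); weights give realistic mixes
VIRUS_FAMILIES: dict[str, tuple[str, str]] = {
    "Myoviridae": ("Bacteria", "non_lipid"),
    "Podoviridae": ("Bacteria", "non_lipid"),
    "Siphoviridae": ("Bacteria", "non_lipid"),
    "Rudiviridae": ("Archaea", "non_lipid"),
    "Bicaudaviridae": ("Archaea", "tentative_non_lipid"),
    "Tectiviridae": ("Bacteria", "lipid_associated"),
    "Corticoviridae": ("Bacteria", "lipid_associated"),
    "Plasmaviridae": ("Bacteria", "lipid_associated"),
    "Fuselloviridae": ("Archaea", "lipid_associated"),
    "Ampullaviridae": ("Archaea", "lipid_associated"),
    "Lipothrixviridae": ("Archaea", "lipid_associated"),
    "Globuloviridae": ("Archaea", "tentative_lipid"),
}
_NON_LIPID_FAMILIES = (
    ("Myoviridae", 0.40), ("Podoviridae", 0.25), ("Siphoviridae", 0.25),
    ("Rudiviridae", 0.07), ("Bicaudaviridae", 0.03),
)
_LIPID_FAMILIES = (
    ("Tectiviridae", 0.20), ("Corticoviridae", 0.05), ("Plasmaviridae", 0.05),
    ("Fuselloviridae", 0.30), ("Ampullaviridae", 0.15),
    ("Lipothrixviridae", 0.15), ("Globuloviridae", 0.10),
)


def _default_virus_counts() -> dict[int, float]:
    return {1: 0.60, 2: 0.25, 3: 0.15}


def _default_cell_counts() -> dict[int, float]:
    # heavy multi-TM tail with secondary abundance peaks at 6 and 12 segments
    return {
        1: 0.385, 2: 0.17, 3: 0.09, 4: 0.05, 5: 0.03, 6: 0.09, 7: 0.03,
        8: 0.02, 9: 0.015, 10: 0.015, 11: 0.02, 12: 0.06, 13: 0.015, 14: 0.01,
    }


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of the synthetic proteome generator.

    Defaults encode the study conditions the census targets: 0.08 mean TM
    fraction for virus-like genomes (lipid-associated families boosted by a
    mean-preserving multiplier), 0.22 for cell-like genomes, helix lengths
    ~N(21, 1.5) truncated to [19, 25] aa, loops of >=10 aa with a planted
    excess of 3 Lys/Arg on the 'in' side, <5 % signal peptides.
    """

    seed: int = 0
    n_virus_genomes: int = 40
    n_cellular_genomes: int = 12
    genes_per_virus_mean: float = 80.0
    genes_per_cell_mean: float = 300.0
    genes_dispersion: float = 10.0
    tm_fraction_virus: float = 0.08
    tm_fraction_cell: float = 0.22
    lipid_family_fraction: float = 0.15
    lipid_tm_multiplier: float = 7.0
    tm_target_jitter: float = 0.015
    tm_count_dist_virus: Mapping[int, float] = field(default_factory=_default_virus_counts)
    tm_count_dist_cell: Mapping[int, float] = field(default_factory=_default_cell_counts)
    helix_len_mean: float = 21.0
    helix_len_sd: float = 1.5
    helix_len_min: int = 19
    helix_len_max: int = 25
    loop_len_mean: float = 16.0
    loop_len_sd: float = 3.0
    loop_len_min: int = 10
    loop_kr_rate: float = 0.15
    loop_kr_bias: int = 3
    p_n_in: float = 0.7
    signal_rate: float = 0.04
    conservation_rate: float = 0.6
    n_orthogroups: int = 400
    ortho_substitution_rate: float = 0.02
    ortho_indel_rate: float = 0.01
    cross_pool_rate: float = 0.05
    duplicate_genome_rate: float = 0.0
    prophage_rate: float = 0.5
    prophage_size: int = 20
    prophage_conservation: float = 0.8
    nontm_len_median: float = 220.0
    nontm_len_sigma: float = 0.45
    length_confounding: bool = True
    p_archaeon_cell: float = 0.3

    def validate(self) -> None:
        rates = [
            self.tm_fraction_virus, self.tm_fraction_cell, self.signal_rate,
            self.conservation_rate, self.cross_pool_rate, self.prophage_rate,
            self.prophage_conservation, self.lipid_family_fraction, self.p_n_in,
            self.duplicate_genome_rate, self.p_archaeon_cell, self.loop_kr_rate,
        ]
        if any(not (0.0 <= r <= 1.0) for r in rates):
            raise ValueError("all rate parameters must lie in [0, 1]")
        if not (0.0 <= self.ortho_indel_rate <= 0.05):
            raise ValueError("ortho_indel_rate must lie in [0, 0.05]")
        if not (1 <= self.helix_len_min <= self.helix_len_max):
            raise ValueError("bad helix length bounds")
        if not (self.helix_len_min <= self.helix_len_mean <= self.helix_len_max):
            raise ValueError("helix_len_mean outside its bounds")
        if self.loop_len_min < 1:
            raise ValueError("loop_len_min must be >= 1")
        if self.helix_len_max + 2 * self.loop_len_min > 5000:
            raise ValueError("helix length infeasible for any protein")
        for dist in (self.tm_count_dist_virus, self.tm_count_dist_cell):
            if not dist or any(k < 1 for k in dist):
                raise ValueError("TM-count distributions need keys >= 1")
            if abs(sum(dist.values()) - 1.0) > 1e-6:
                raise ValueError("TM-count distributions must sum to 1")
        if self.n_orthogroups < 1 or self.genes_dispersion <= 0:
            raise ValueError("n_orthogroups >= 1 and genes_dispersion > 0 required")


@dataclass(frozen=True)
class ProteinTruth:
    """Planted topology of one synthetic protein."""

    protein_id: str
    genome_id: str
    segments: tuple[TMSegment, ...]
    n_terminal_side: str
    signal_peptide: bool

    @property
    def tm_count(self) -> int:
        return len(self.segments)


@dataclass
class GroundTruth:
    """Everything the generator planted, for oracle-style checks."""

    proteins: dict[str, ProteinTruth]
    genome_tm_fraction: dict[str, float]
    group_members: dict[str, set[str]]

    def as_predictions(self) -> dict[str, TopologyPrediction]:
        """Planted topologies in prediction form, for feeding the census
        directly (bypassing the predictor)."""
        return {
            pid: TopologyPrediction(
                protein_id=pid,
                segments=t.segments,
                n_terminal_side=t.n_terminal_side,
                signal_peptide=t.signal_peptide,
                source="truth",
            )
            for pid, t in self.proteins.items()
        }


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    proteomes: dict[str, list[ProteinRecord]]
    metadata: dict[str, GenomeMetadata]
    orthogroups: OrthogroupTable
    prophages: list[ProphageRegion]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# sequence building blocks
# ---------------------------------------------------------------------------

def _sample(rng: np.random.Generator, composition: Mapping[str, float], n: int) -> list[str]:
    residues = list(composition)
    probs = np.array([composition[r] for r in residues])
    probs = probs / probs.sum()
    return list(rng.choice(residues, size=n, p=probs))


def _draw_count(rng: np.random.Generator, dist: Mapping[int, float]) -> int:
    keys = sorted(dist)
    probs = np.array([dist[k] for k in keys])
    return int(rng.choice(keys, p=probs / probs.sum()))


def _helix_length(rng: np.random.Generator, spec: SyntheticSpec) -> int:
    while True:
        v = int(round(rng.normal(spec.helix_len_mean, spec.helix_len_sd)))
        if spec.helix_len_min <= v <= spec.helix_len_max:
            return v


def _loop(rng: np.random.Generator, spec: SyntheticSpec, is_in_side: bool) -> str:
    length = max(spec.loop_len_min,
                 int(round(rng.normal(spec.loop_len_mean, spec.loop_len_sd))))
    kr = int(round(spec.loop_kr_rate * length))
    if is_in_side:
        kr += spec.loop_kr_bias
    kr = min(kr, length)
    residues = _sample(rng, LOOP_COMPOSITION, length)
    positions = rng.choice(length, size=kr, replace=False)
    for pos in positions:
        residues[int(pos)] = "K" if rng.random() < 0.5 else "R"
    return "".join(residues)


def _signal_peptide(rng: np.random.Generator) -> str:
    """n-region (Met + 2 basic), 8-12 aa hydrophobic h-region, A-X-A c-motif."""
    n_region = "M" + "".join("K" if rng.random() < 0.5 else "R" for _ in range(2))
    h_len = int(rng.integers(8, 13))
    h_region = "".join(_sample(rng, {"L": 0.5, "A": 0.2, "V": 0.2, "F": 0.1}, h_len))
    x = _sample(rng, LOOP_COMPOSITION, 1)[0]
    return n_region + h_region + "A" + x + "A"


@dataclass(frozen=True)
class _Built:
    sequence: str
    segments: tuple[TMSegment, ...]
    side: str
    signal: bool


def _build_tm_protein(rng: np.random.Generator, k: int, spec: SyntheticSpec) -> _Built:
    side = "in" if rng.random() < spec.p_n_in else "out"
    signal = rng.random() < spec.signal_rate
    parts: list[str] = []
    segments: list[TMSegment] = []
    pos = 0
    if signal:
        sp = _signal_peptide(rng)
        parts.append(sp)
        pos += len(sp)
    for j in range(k + 1):
        in_side = (j % 2 == 0) == (side == "in")
        loop = _loop(rng, spec, in_side)
        parts.append(loop)
        pos += len(loop)
        if j < k:
            h = _helix_length(rng, spec)
            parts.append("".join(_sample(rng, TM_COMPOSITION, h)))
            segments.append(TMSegment(pos + 1, pos + h))
            pos += h
    return _Built("".join(parts), tuple(segments), side, signal)


def _build_soluble_protein(rng: np.random.Generator, spec: SyntheticSpec,
                           count_dist: Mapping[int, float]) -> _Built:
    if spec.length_confounding:
        length = int(np.clip(
            rng.lognormal(math.log(spec.nontm_len_median), spec.nontm_len_sigma),
            60, 1500,
        ))
    else:
        # match the length a TM protein of a random class would have, so that
        # length no longer separates the TM classes
        k = _draw_count(rng, count_dist)
        length = sum(_helix_length(rng, spec) for _ in range(k)) + (k + 1) * max(
            spec.loop_len_min, int(round(spec.loop_len_mean)))
    seq = "".join(_sample(rng, NONTM_COMPOSITION, length))
    signal = rng.random() < spec.signal_rate
    if signal:
        seq = _signal_peptide(rng) + seq
    return _Built(seq, (), "in", signal)


# ---------------------------------------------------------------------------
# orthogroup prototypes and perturbation
# ---------------------------------------------------------------------------

_POOL_CODE = {"viral": 1, "cellular": 2}


def _prototype(spec: SyntheticSpec, pool: str, k: int, j: int) -> _Built:
    rng = np.random.default_rng([spec.seed % (2**31), _PROTO, _POOL_CODE[pool], k, j])
    if k == 0:
        dist = spec.tm_count_dist_virus if pool == "viral" else spec.tm_count_dist_cell
        return _build_soluble_protein(rng, spec, dist)
    return _build_tm_protein(rng, k, spec)


def _loop_positions(built: _Built) -> list[int]:
    """0-based positions outside planted helices (and outside the signal)."""
    helix = np.zeros(len(built.sequence), dtype=bool)
    for seg in built.segments:
        helix[seg.start - 1 : seg.end] = True
    return [i for i in range(len(built.sequence)) if not helix[i]]


def _perturb_once(built: _Built, rng: np.random.Generator,
                  substitution_rate: float, indel_rate: float) -> _Built:
    """One homolog: loop-only point substitutions at non-K/R positions plus
    rare single-residue loop indels; the planted TM count never changes."""
    seq = list(built.sequence)
    loop_pos = [i for i in _loop_positions(built) if seq[i] not in "KR"]
    loop_residues = list(LOOP_COMPOSITION)
    for i in loop_pos:
        if rng.random() < substitution_rate:
            seq[i] = loop_residues[int(rng.integers(len(loop_residues)))]
    segments = list(built.segments)
    if indel_rate > 0:
        shift_at: list[tuple[int, int]] = []  # (0-based position, +1 insert / -1 delete)
        for i in loop_pos:
            r = rng.random()
            if r < indel_rate / 2:
                shift_at.append((i, 1))
            elif r < indel_rate:
                shift_at.append((i, -1))
        for i, delta in sorted(shift_at, reverse=True):
            if delta > 0:
                seq.insert(i, loop_residues[int(rng.integers(len(loop_residues)))])
            else:
                if seq[i] in "KR":
                    continue  # keep the planted charge bias intact
                del seq[i]
            segments = [
                TMSegment(s.start + (delta if s.start > i else 0),
                          s.end + (delta if s.start > i else 0))
                for s in segments
            ]
    return _Built("".join(seq), tuple(segments), built.side, built.signal)


def perturb_orthogroup(
    record: ProteinRecord,
    truth: ProteinTruth,
    n_copies: int,
    indel_rate: float = 0.0,
    substitution_rate: float = 0.02,
    seed: int = 0,
) -> list[tuple[ProteinRecord, ProteinTruth]]:
    """Spawn homologous copies of one protein for orthogroup testing.

    Copies differ from the original by loop-only substitutions and (at
    ``indel_rate`` per loop residue) single-residue loop indels; helices are
    untouched, so every copy retains the planted TM count.
    """
    if not (0.0 <= indel_rate <= 0.05):
        raise ValueError("indel_rate must lie in [0, 0.05]")
    built = _Built(record.sequence, truth.segments, truth.n_terminal_side,
                   truth.signal_peptide)
    out = []
    for i in range(n_copies):
        rng = np.random.default_rng([seed % (2**31), 17, i])
        pb = _perturb_once(built, rng, substitution_rate, indel_rate)
        pid = f"{record.protein_id}_h{i}"
        out.append((
            ProteinRecord(protein_id=pid, genome_id=record.genome_id, sequence=pb.sequence),
            ProteinTruth(protein_id=pid, genome_id=record.genome_id,
                         segments=pb.segments, n_terminal_side=pb.side,
                         signal_peptide=pb.signal),
        ))
    return out


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

def _stride_flags(n: int, p: float) -> list[bool]:
    """Deterministic assignment of ~p*n True flags, stable under appending."""
    return [math.floor((i + 1) * p) > math.floor(i * p) for i in range(n)]


@dataclass
class _GenePlan:
    tm_count: int
    group: tuple[str, int, int] | None  # (pool, k, j) or None for singleton
    in_prophage: bool = False


def _plan_genes(rng: np.random.Generator, n_genes: int, tm_target: float,
                count_dist: Mapping[int, float], pool: str,
                spec: SyntheticSpec, conservation: float | None = None,
                prophage_slots: set[int] = frozenset()) -> list[_GenePlan]:
    plans = []
    for i in range(n_genes):
        in_pro = i in prophage_slots
        if in_pro:
            conserved = rng.random() < spec.prophage_conservation
            gene_pool = "viral"
            k = _draw_count(rng, spec.tm_count_dist_virus) \
                if rng.random() < spec.tm_fraction_virus else 0
        else:
            conserved = rng.random() < (conservation if conservation is not None
                                        else spec.conservation_rate)
            gene_pool = pool
            if pool == "cellular" and conserved and rng.random() < spec.cross_pool_rate:
                gene_pool = "viral"
            k = _draw_count(rng, count_dist) if rng.random() < tm_target else 0
        group = None
        if conserved:
            j = int(rng.integers(spec.n_orthogroups))
            group = (gene_pool, k, j)
        plans.append(_GenePlan(tm_count=k, group=group, in_prophage=in_pro))
    return plans


def _virus_tm_target(spec: SyntheticSpec, lipid: bool, rng: np.random.Generator) -> float:
    base = spec.tm_fraction_virus
    if base == 0.0:
        return 0.0
    p, m = spec.lipid_family_fraction, spec.lipid_tm_multiplier
    non_lipid_target = base / (1.0 + p * (m - 1.0))
    target = non_lipid_target * (m if lipid else 1.0)
    return float(np.clip(rng.normal(target, spec.tm_target_jitter), 0.005, 0.9))


def _cell_tm_target(spec: SyntheticSpec, rng: np.random.Generator) -> float:
    if spec.tm_fraction_cell == 0.0:
        return 0.0
    return float(np.clip(rng.normal(spec.tm_fraction_cell, spec.tm_target_jitter),
                         0.005, 0.9))


def _pick_family(rng: np.random.Generator, lipid: bool) -> str:
    table = _LIPID_FAMILIES if lipid else _NON_LIPID_FAMILIES
    names = [t[0] for t in table]
    probs = np.array([t[1] for t in table])
    return str(rng.choice(names, p=probs / probs.sum()))


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate the full synthetic dataset: proteomes, metadata, orthogroups,
    prophage regions and planted ground truth.  Byte-identical for a given
    spec (dataclass fields) and seed."""
    spec.validate()
    proteomes: dict[str, list[ProteinRecord]] = {}
    metadata: dict[str, GenomeMetadata] = {}
    protein_to_group: dict[str, str] = {}
    prophages: list[ProphageRegion] = []
    truth = GroundTruth(proteins={}, genome_tm_fraction={}, group_members={})
    proto_cache: dict[tuple[str, int, int], _Built] = {}

    def realize(genome_id: str, plans: list[_GenePlan],
                rng: np.random.Generator, count_dist: Mapping[int, float]) -> None:
        records: list[ProteinRecord] = []
        n_tm = 0
        for i, plan in enumerate(plans):
            pid = f"{genome_id}_p{i:04d}"
            if plan.group is not None:
                key = plan.group
                if key not in proto_cache:
                    proto_cache[key] = _prototype(spec, key[0], key[1], key[2])
                built = _perturb_once(proto_cache[key], rng,
                                      spec.ortho_substitution_rate,
                                      spec.ortho_indel_rate)
                gid = f"{key[0]}.k{key[1]}.g{key[2]:04d}"
                protein_to_group[pid] = gid
                truth.group_members.setdefault(gid, set()).add(pid)
            elif plan.tm_count > 0:
                built = _build_tm_protein(rng, plan.tm_count, spec)
            else:
                built = _build_soluble_protein(rng, spec, count_dist)
            records.append(ProteinRecord(protein_id=pid, genome_id=genome_id,
                                         sequence=built.sequence))
            truth.proteins[pid] = ProteinTruth(
                protein_id=pid, genome_id=genome_id, segments=built.segments,
                n_terminal_side=built.side, signal_peptide=built.signal,
            )
            if built.segments:
                n_tm += 1
        proteomes[genome_id] = records
        truth.genome_tm_fraction[genome_id] = n_tm / len(records) if records else 0.0

    # --- virus genomes ---
    lipid_flags = _stride_flags(spec.n_virus_genomes, spec.lipid_family_fraction)
    prev_plan: list[_GenePlan] | None = None
    for i in range(spec.n_virus_genomes):
        rng = np.random.default_rng([spec.seed % (2**31), _VIRUS, i])
        genome_id = f"vg{i:03d}"
        lipid = lipid_flags[i]
        family = _pick_family(rng, lipid)
        host, lipid_class = VIRUS_FAMILIES[family]
        n_genes = max(5, int(rng.negative_binomial(
            spec.genes_dispersion,
            spec.genes_dispersion / (spec.genes_dispersion + spec.genes_per_virus_mean))))
        target = _virus_tm_target(spec, lipid, rng)
        duplicate = prev_plan is not None and rng.random() < spec.duplicate_genome_rate
        if duplicate:
            plans = prev_plan
        else:
            plans = _plan_genes(rng, n_genes, target, spec.tm_count_dist_virus,
                                "viral", spec)
        realize(genome_id, plans, rng, spec.tm_count_dist_virus)
        prev_plan = plans
        metadata[genome_id] = GenomeMetadata(
            genome_id=genome_id, name=f"Synthetic {family} virus {i}",
            entity_class="virus", virus_family=family, host_domain=host,
            lipid_class=lipid_class, genus=None,
        )

    # --- cellular genomes ---
    archaeon_flags = _stride_flags(spec.n_cellular_genomes, spec.p_archaeon_cell)
    prophage_flags = _stride_flags(spec.n_cellular_genomes, spec.prophage_rate)
    n_genera = max(1, int(round(spec.n_cellular_genomes * 0.7)))
    for i in range(spec.n_cellular_genomes):
        rng = np.random.default_rng([spec.seed % (2**31), _CELL, i])
        genome_id = f"cg{i:03d}"
        n_genes = max(30, int(rng.negative_binomial(
            spec.genes_dispersion,
            spec.genes_dispersion / (spec.genes_dispersion + spec.genes_per_cell_mean))))
        target = _cell_tm_target(spec, rng)
        prophage_slots: set[int] = set()
        if prophage_flags[i] and n_genes > spec.prophage_size + 10:
            start = int(rng.integers(0, n_genes - spec.prophage_size))
            prophage_slots = set(range(start, start + spec.prophage_size))
        plans = _plan_genes(rng, n_genes, target, spec.tm_count_dist_cell,
                            "cellular", spec, prophage_slots=prophage_slots)
        realize(genome_id, plans, rng, spec.tm_count_dist_cell)
        if prophage_slots:
            prophages.append(ProphageRegion(
                genome_id=genome_id,
                region_id=f"{genome_id}_pro0",
                protein_ids=frozenset(
                    f"{genome_id}_p{j:04d}" for j in sorted(prophage_slots)),
            ))
        entity = "archaeon" if archaeon_flags[i] else "bacterium"
        genus = f"Genus{i % n_genera:02d}"
        metadata[genome_id] = GenomeMetadata(
            genome_id=genome_id, name=f"Synthetic {genus} organism {i}",
            entity_class=entity, virus_family=None, host_domain=None,
            lipid_class="unknown", genus=genus,
        )

    return SyntheticDataset(
        spec=spec,
        proteomes=proteomes,
        metadata=metadata,
        orthogroups=OrthogroupTable(protein_to_group),
        prophages=prophages,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# ground-truth TSV round-trip (for the CLI)
# ---------------------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write("# coordinates: 1-based inclusive\n")
        fh.write("protein_id\tgenome_id\ttm_count\tsegments\tn_terminal_side\tsignal_peptide\n")
        for pid in sorted(truth.proteins):
            t = truth.proteins[pid]
            segs = ";".join(f"{s.start}-{s.end}" for s in t.segments) or "-"
            fh.write(f"{pid}\t{t.genome_id}\t{t.tm_count}\t{segs}\t"
                     f"{t.n_terminal_side}\t{int(t.signal_peptide)}\n")


def read_ground_truth(path) -> dict[str, ProteinTruth]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    out = {}
    for row in df.itertuples(index=False):
        segs = tuple(
            TMSegment(*(int(x) for x in part.split("-")))
            for part in (row.segments.split(";") if row.segments != "-" else [])
        )
        out[row.protein_id] = ProteinTruth(
            protein_id=row.protein_id, genome_id=row.genome_id, segments=segs,
            n_terminal_side=row.n_terminal_side,
            signal_peptide=bool(int(row.signal_peptide)),
        )
    return out
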