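"""Pipeline wiring: simulate -> predict -> census -> vq -> compare.

A :class:`RunConfig` holds one parameter block per stage plus global
settings; :func:`run_pipeline` executes the stages in dependency order into
an output directory.  Every table carries a provenance header (package
version, seed, config hash) and no timestamps, so a rerun with the same
config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .census import census_all, select_representatives
from .group_compare import (
    build_labeling,
    chisq_test,
    correlate,
    mww_test,
    orthogroup_consistency,
)
from .io_formats import (
    write_census_tables,
    write_metadata,
    write_orthogroups,
    write_phobius_like,
    write_proteomes,
    write_prophages,
)
from .census import aggregate_histogram
from .synthetic_data import SyntheticSpec, generate, write_ground_truth
from .tm_predictor import PredictorConfig, predict_proteomes
from .vq_stats import classify_vq, vq_table

logger = logging.getLogger(__name__)

_SECTIONS = ("simulate", "predictor", "census", "vq", "compare")


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``simulate`` keys override :class:`SyntheticSpec` fields, ``predictor``
    keys override :class:`PredictorConfig` fields; ``census`` accepts
    ``threshold``/``bin_width``/``sharing_mode``/``histogram_cap``; ``vq``
    accepts ``prophage_mode``.  Unknown sections or keys are rejected.
    """

    seed: int = 0
    log_level: str = "INFO"
    out_dir: str = "tmcensus_run"
    simulate: dict = field(default_factory=dict)
    predictor: dict = field(default_factory=dict)
    census: dict = field(default_factory=dict)
    vq: dict = field(default_factory=dict)
    compare: dict = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any]) -> "RunConfig":
        known_global = {"seed", "log_level", "out_dir"}
        unknown = set(raw) - known_global - set(_SECTIONS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: raw[k] for k in raw})
        spec_fields = {f.name for f in dataclasses.fields(SyntheticSpec)}
        bad = set(cfg.simulate) - spec_fields
        if bad:
            raise ValueError(f"unknown simulate keys: {sorted(bad)}")
        pred_fields = {f.name for f in dataclasses.fields(PredictorConfig)}
        bad = set(cfg.predictor) - pred_fields
        if bad:
            raise ValueError(f"unknown predictor keys: {sorted(bad)}")
        bad = set(cfg.census) - {"threshold", "bin_width", "sharing_mode", "histogram_cap"}
        if bad:
            raise ValueError(f"unknown census keys: {sorted(bad)}")
        bad = set(cfg.vq) - {"prophage_mode"}
        if bad:
            raise ValueError(f"unknown vq keys: {sorted(bad)}")
        bad = set(cfg.compare) - {"alpha"}
        if bad:
            raise ValueError(f"unknown compare keys: {sorted(bad)}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_mapping(raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    def provenance(self) -> str:
        return f"tmcensus={__version__} seed={self.seed} config={self.config_hash()}"


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Execute the full pipeline into ``out_dir``; returns the directory.

    A failure in any stage raises with the stage name in the message.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = config.provenance()

    def stage(name: str):
        logger.info("stage: %s", name)
        return name

    try:
        stage("simulate")
        spec = SyntheticSpec(**{"seed": config.seed, **config.simulate})
        data = generate(spec)
        write_proteomes(data.proteomes, out / "proteomes.fasta")
        write_metadata(data.metadata, out / "metadata.tsv", prov)
        write_orthogroups(data.orthogroups, out / "orthogroups.tsv", prov)
        write_prophages(data.prophages, out / "prophages.tsv", prov)
        write_ground_truth(data.truth, out / "ground_truth.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage simulate failed: {exc}") from exc

    try:
        stage("predict")
        pconfig = PredictorConfig(**config.predictor)
        predictions = predict_proteomes(data.proteomes, pconfig)
        write_phobius_like(predictions, out / "predictions.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage predict failed: {exc}") from exc

    try:
        stage("census")
        threshold = config.census.get("threshold", 0.9)
        mode = config.census.get("sharing_mode", "min")
        virus_groups = {
            g: {data.orthogroups.group_of(p.protein_id)
                for p in data.proteomes[g]
                if data.orthogroups.group_of(p.protein_id)}
            for g in data.proteomes if data.metadata[g].is_virus
        }
        representatives = select_representatives(
            virus_groups, threshold=threshold, seed=config.seed, mode=mode)
        rows = census_all(data.proteomes, predictions, data.orthogroups)
        write_census_tables(rows, out / "census.tsv", prov)
        pooled = aggregate_histogram(
            [r for r in rows if data.metadata[r.genome_id].is_virus], normalize=True)
        with open(out / "pooled_histogram_virus.tsv", "w") as fh:
            fh.write(f"# provenance: {prov}\ntm_count\tproportion\n")
            for k, v in pooled.items():
                fh.write(f"{k}\t{v:.6f}\n")
        with open(out / "representatives.tsv", "w") as fh:
            fh.write(f"# provenance: {prov}\n# seed={config.seed} threshold={threshold}\n")
            fh.write("genome_id\n")
            for g in sorted(representatives):
                fh.write(g + "\n")
    except Exception as exc:
        raise RuntimeError(f"stage census failed: {exc}") from exc

    try:
        stage("vq")
        protein_to_genome = {
            p.protein_id: g for g, recs in data.proteomes.items() for p in recs
        }
        vq_records = vq_table(data.orthogroups, protein_to_genome, data.metadata,
                              data.prophages,
                              prophage_mode=config.vq.get("prophage_mode", "credit"))
        with open(out / "vq.tsv", "w") as fh:
            fh.write(f"# provenance: {prov}\n")
            fh.write("group_id\tf_viral\tf_cellular\tf_prophage\tvq\tclass\n")
            for r in vq_records:
                fh.write(f"{r.group_id}\t{r.f_viral:.4f}\t{r.f_cellular:.4f}\t"
                         f"{r.f_prophage:.4f}\t{r.vq:.4f}\t{classify_vq(r)}\n")
    except Exception as exc:
        raise RuntimeError(f"stage vq failed: {exc}") from exc

    try:
        stage("compare")
        labeling = build_labeling(data.metadata)
        virus_rows = [r for r in rows if data.metadata[r.genome_id].is_virus]
        cell_rows = [r for r in rows if not data.metadata[r.genome_id].is_virus]
        lines = [f"# provenance: {prov}", "comparison\tstatistic\tvalue"]
        if virus_rows and cell_rows:
            hv = aggregate_histogram(virus_rows)
            hc = aggregate_histogram(cell_rows)
            chi = chisq_test(hist_a=hv, hist_b=hc)
            mww = mww_test([r.tm_fraction for r in virus_rows],
                           [r.tm_fraction for r in cell_rows])
            lines += [
                f"virus_vs_cell_histogram\tchi2\t{chi.statistic:.4f}",
                f"virus_vs_cell_histogram\tp\t{chi.p_value:.3e}",
                f"virus_vs_cell_tm_fraction\tmww_p\t{mww.p_display()}",
            ]
        try:
            r_lipid = correlate(virus_rows, labeling, "lipid_binary")
            lines.append(f"tm_fraction_vs_lipid\tpearson\t{r_lipid:.4f}")
        except ValueError as exc:
            lines.append(f"tm_fraction_vs_lipid\terror\t{exc}")
        classes = [classify_vq(r) for r in vq_records]
        for cls in ("viral_only", "predominantly_viral", "predominantly_cellular"):
            lines.append(f"vq_distribution\t{cls}\t{classes.count(cls)}")
        try:
            consistency = orthogroup_consistency(predictions, data.orthogroups)
            lines.append(f"orthogroup_consistency\tfraction_uniform\t"
                         f"{consistency.fraction_uniform:.4f}")
        except ValueError as exc:
            lines.append(f"orthogroup_consistency\terror\t{exc}")
        (out / "report.tsv").write_text("\n".join(lines) + "\n")
    except Exception as exc:
        raise RuntimeError(f"stage compare failed: {exc}") from exc

    return out
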