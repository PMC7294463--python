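"""Config-driven end-to-end runs.

A run either simulates a DGE matrix (seeded) or loads one, then walks
the full chain: per-cell-type detection fractions, 2%-rule expressed
sets, highest-cell-type assignment, receptor calls from a bulk profile
anchored by a (simulated or supplied) proteome, interaction prediction
against the ligand-receptor database, and network comparison.  All stage
outputs are written as TSV/JSON with a manifest of parameters, seed and
output checksums; identical configs reproduce identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

from . import fixtures
from .abundance import (DEFAULT_THRESHOLD, assign_highest,
                        detection_fractions, expressed_sets)
from .io import (GeneSet, read_annotation, read_dge, write_network)
from .lrdb import default_db, load_db
from .network import mark_protein_evidence, predict_interactions
from .simulate import (nerve_sim_config, simulate_bulk, simulate_dge,
                       simulate_proteome)


@dataclass
class RunConfig:
    """Validated configuration for :func:`run_pipeline`."""

    out_dir: str
    seed: int = 0
    # input mode: "simulate" (nerve-like defaults) or "load"
    mode: str = "simulate"
    dge_path: str | None = None
    dge_format: str = "dense-tsv"
    annotation_path: str | None = None
    ligand_panel_path: str | None = None   # default: bundled injured panel
    db_path: str | None = None             # default: bundled database
    detection_threshold: float = DEFAULT_THRESHOLD
    enrichment_factor: float = 4.0
    n_cells_scale: float = 0.1
    proteome_sensitivity: float = 0.5
    receptor_percentile: float = 87.0

    def __post_init__(self) -> None:
        if not 0 < self.detection_threshold < 100:
            raise ValueError("detection threshold must be in (0, 100)")
        if self.enrichment_factor < 1:
            raise ValueError("enrichment factor must be >= 1")
        if self.mode not in ("simulate", "load"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "load" and not (self.dge_path and self.annotation_path):
            raise ValueError("load mode needs dge_path and annotation_path")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to
    ``manifest.json`` in the output directory)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []

    def stage(name):
        stages.append(name)

    try:
        stage("input")
        if config.mode == "simulate":
            sim = nerve_sim_config(config.seed,
                                   n_cells_scale=config.n_cells_scale)
            matrix, annot, truth = simulate_dge(sim)
            truth.fraction.to_csv(out / "truth_detection.tsv", sep="\t")
        else:
            matrix = read_dge(config.dge_path, config.dge_format)
            annot = read_annotation(config.annotation_path)

        if config.ligand_panel_path:
            from .io import read_gene_list

            panel = read_gene_list(config.ligand_panel_path, "ligand_panel")
        else:
            panel = fixtures.injured_ligand_panel()
        db = load_db(config.db_path) if config.db_path else default_db()

        stage("abundance")
        table = detection_fractions(matrix, annot, panel)
        table.fraction.to_csv(out / "detection_fractions.tsv", sep="\t")
        sets = expressed_sets(table, config.detection_threshold)
        with open(out / "expressed_sets.json", "w") as fh:
            json.dump({k: v.sorted() for k, v in sets.items()}, fh, indent=1,
                      sort_keys=True)
        highest = assign_highest(table)
        highest.assign(assigned=highest["assigned"].map(
            lambda t: ",".join(t))).to_csv(out / "highest_type.tsv", sep="\t")

        stage("receptors")
        receptor_panel = GeneSet("receptor_panel", db.receptors)
        bulk = simulate_bulk(sorted(receptor_panel.members), 8000, "NTRK1",
                             0.9, seed=config.seed + 1)
        proteome = simulate_proteome(
            receptor_panel, config.proteome_sensitivity,
            GeneSet("decoys", frozenset(f"DECOY{i}" for i in range(200))),
            0.02, seed=config.seed + 2)
        from .receptors import anchor_receptor_call

        call = anchor_receptor_call(bulk, "target_neurons", proteome,
                                    receptor_panel)
        (out / "receptor_call.json").write_text(json.dumps({
            "population": call.population, "mode": call.mode,
            "cutoff_gene": call.cutoff_gene,
            "cutoff_value": call.cutoff_value,
            "receptors": call.receptors.sorted()}, indent=1))

        stage("interactions")
        expressed_any = sets["any"]
        network = predict_interactions(expressed_any, call, db)
        network = mark_protein_evidence(network, proteome)
        write_network(network, out / "network.tsv", "tsv")

        stage("manifest")
        manifest = {
            "config": asdict(config),
            "stages": stages,
            "n_cells": matrix.n_cells,
            "n_genes": matrix.n_genes,
            "n_expressed_any": len(expressed_any),
            "n_receptors_called": len(call.receptors),
            "n_edges": len(network),
            "n_ligand_nodes": len(network.ligand_nodes),
            "outputs": {p.name: _sha256(p)
                        for p in sorted(out.glob("*.tsv"))},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))
        return manifest
    except Exception as err:  # re-raise with the failing stage named
        raise RuntimeError(f"pipeline failed at stage "
                           f"{stages[-1] if stages else 'setup'}: {err}") from err
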