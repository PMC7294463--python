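"""Prediction of unidirectional ligand -> receptor paracrine interactions.

An interaction is predicted between an injured-nerve ligand and a target
neuron population whenever the ligand-receptor database pairs the ligand
with a receptor in that population's receptor repertoire.  The headline
size of a model is its number of ligand nodes (ligands with at least one
cognate expressed receptor); the edge count is reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Mapping, NamedTuple, Sequence

from .abundance import DetectionTable, assign_highest, enrichment_flags
from .io import GeneSet
from .lrdb import LigandReceptorDB
from .receptors import ReceptorCall


class Edge(NamedTuple):
    source: str      # source cell type, or "Injured nerve" for the whole organ
    ligand: str
    receptor: str
    target: str      # target neuron population


@dataclass(frozen=True)
class InteractionNetwork:
    edges: frozenset[Edge]
    ligand_sources: Mapping[str, dict] = field(default_factory=dict)
    receptor_evidence: Mapping[str, str] = field(default_factory=dict)

    @property
    def ligand_nodes(self) -> frozenset[str]:
        return frozenset(e.ligand for e in self.edges)

    @property
    def receptor_nodes(self) -> frozenset[str]:
        return frozenset(e.receptor for e in self.edges)

    @property
    def pairs(self) -> frozenset[tuple[str, str]]:
        return frozenset((e.ligand, e.receptor) for e in self.edges)

    def sorted_edges(self) -> list[Edge]:
        return sorted(self.edges)

    def __len__(self) -> int:
        return len(self.edges)


def predict_interactions(ligands: GeneSet, receptor_call: ReceptorCall | GeneSet,
                         db: LigandReceptorDB,
                         source: str = "Injured nerve") -> InteractionNetwork:
    """Cross the ligand panel with a population's receptor repertoire
    through the database: an edge per database pair whose ligand is in
    the panel and whose receptor is in the repertoire."""
    if isinstance(receptor_call, ReceptorCall):
        receptors = receptor_call.receptors.members
        target = receptor_call.population
    else:
        receptors = receptor_call.members
        target = receptor_call.name
    if not db.pairs:
        warnings.warn("empty ligand-receptor database: no interactions")
    edges = frozenset(
        Edge(source, lig, rec, target)
        for lig, rec in db.pairs
        if lig in ligands.members and rec in receptors)
    return InteractionNetwork(edges)


def annotate_ligand_sources(network: InteractionNetwork,
                            detection: DetectionTable,
                            compare_types: Sequence[str] | None = None,
                            enrichment_factor: float = 4.0,
                            tie_resolution: Mapping[str, str] | None = None,
                            ) -> InteractionNetwork:
    """Annotate each ligand node with the nerve cell type expressing it
    in the highest proportion of cells, and flag ligands enriched
    ``enrichment_factor``-fold over every other cell type."""
    missing = network.ligand_nodes - set(detection.fraction.index)
    if missing:
        raise ValueError(f"ligands missing from detection table: "
                         f"{sorted(missing)[:5]}")
    assigned = assign_highest(detection, compare_types,
                              tie_resolution=tie_resolution)
    types = list(compare_types) if compare_types else detection.cell_types
    enriched_by_type = {
        t: enrichment_flags(detection, t, enrichment_factor, types).members
        for t in types}
    annots = {}
    for lig in sorted(network.ligand_nodes):
        row = assigned.loc[lig]
        annots[lig] = {
            "source": row["assigned"],
            "tie": bool(row["tie"]),
            "enriched": any(lig in enriched_by_type[t]
                            for t in row["assigned"]),
        }
    return replace(network, ligand_sources=annots)


def mark_protein_evidence(network: InteractionNetwork,
                          proteome_receptors: GeneSet) -> InteractionNetwork:
    """Label each receptor transcript+protein when it was detected by
    cell-surface proteomics, transcript-only otherwise."""
    evidence = {rec: ("transcript+protein" if rec in proteome_receptors.members
                      else "transcript-only")
                for rec in sorted(network.receptor_nodes)}
    return replace(network, receptor_evidence=evidence)


def compare_networks(networks: Mapping[str, InteractionNetwork],
                     level: str = "ligand") -> dict:
    """Exclusive-region counts and shared / unique membership lists over
    2-4 networks, at the ligand-node or (ligand, receptor)-pair level."""
    if level == "ligand":
        sets = {name: set(net.ligand_nodes) for name, net in networks.items()}
    elif level == "pair":
        sets = {name: set(net.pairs) for name, net in networks.items()}
    else:
        raise ValueError(f"unknown comparison level {level!r}")
    if not 2 <= len(sets) <= 4:
        raise ValueError("compare_networks supports 2-4 networks")
    names = sorted(sets)
    regions: dict[tuple[str, ...], int] = {}
    for k in range(len(names), 0, -1):
        for combo in combinations(names, k):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(set(), *(sets[n] for n in names
                                         if n not in combo))
            regions[combo] = len(inside - outside)
    shared = set.intersection(*sets.values())
    unique = {name: sets[name] - set.union(
        *(sets[o] for o in names if o != name)) for name in names}
    return {"regions": regions, "shared": sorted(shared),
            "unique": {k: sorted(v) for k, v in unique.items()}}
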