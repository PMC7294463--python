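"""The curated ligand-receptor pair database driving interaction
prediction.

The bundled default database is reconstructed from the published
interaction tables (the union of all printed ligand-receptor pairs over
the four target neuron populations).  Any user TSV with ``ligand`` and
``receptor`` columns can be loaded instead.

Receptor complexes are annotation only: a ligand-receptor interaction is
predicted when ANY cognate receptor of a complex is expressed (OR
semantics), matching databases that list each complex component as its
own pair row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .io import GeneSet, canonical_symbol, read_pair_table


@dataclass(frozen=True)
class LigandReceptorDB:
    pairs: frozenset[tuple[str, str]]
    complex_groups: Mapping[str, str] = field(default_factory=dict)
    provenance: Mapping[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for lig, rec in self.pairs:
            if not lig or not rec:
                raise ValueError("empty gene symbol in pair")
            if lig == rec:
                raise ValueError(f"self-pair {lig}->{rec} not allowed")
        if self.complex_groups:
            from collections import Counter
            counts = Counter(self.complex_groups.values())
            bad = [label for label, n in counts.items() if n < 2]
            if bad:
                raise ValueError(
                    f"complex labels with fewer than 2 receptors: {bad}")

    @property
    def ligands(self) -> frozenset[str]:
        return frozenset(l for l, _ in self.pairs)

    @property
    def receptors(self) -> frozenset[str]:
        return frozenset(r for _, r in self.pairs)

    def sorted_pairs(self) -> list[tuple[str, str]]:
        return sorted(self.pairs)


def make_db(pairs: Iterable[tuple[str, str]],
            complex_groups: Mapping[str, str] | None = None,
            provenance: Mapping[tuple[str, str], str] | None = None,
            ) -> LigandReceptorDB:
    norm = frozenset((canonical_symbol(l), canonical_symbol(r))
                     for l, r in pairs)
    return LigandReceptorDB(norm, complex_groups or {}, provenance or {})


def load_db(path: str | Path) -> LigandReceptorDB:
    """Load and validate a ligand-receptor pair TSV."""
    return make_db(read_pair_table(path))


def default_db() -> LigandReceptorDB:
    """The bundled database: union of all published ligand-receptor pairs
    across the four neuron-population interaction models, each pair
    tagged with the population block(s) it was printed in."""
    from .fixtures import fixture_path

    import pandas as pd

    df = pd.read_csv(fixture_path("table9.tsv"), sep="\t")
    prov: dict[tuple[str, str], str] = {}
    for row in df.itertuples():
        pair = (canonical_symbol(row.ligand), canonical_symbol(row.receptor))
        tag = prov.get(pair)
        prov[pair] = f"{tag},{row.target}" if tag else row.target
    return LigandReceptorDB(frozenset(prov), {}, prov)


def receptors_of(db: LigandReceptorDB, ligand: str) -> set[str]:
    """Cognate receptors of a ligand (empty set when unknown)."""
    lig = canonical_symbol(ligand)
    return {r for l, r in db.pairs if l == lig}


def ligands_of(db: LigandReceptorDB, receptor: str) -> set[str]:
    rec = canonical_symbol(receptor)
    return {l for l, r in db.pairs if r == rec}


def subset_db(db: LigandReceptorDB, ligands: GeneSet,
              receptors: GeneSet) -> LigandReceptorDB:
    """Restrict the database to pairs whose ligand and receptor both lie
    in the given sets."""
    keep = frozenset((l, r) for l, r in db.pairs
                     if l in ligands.members and r in receptors.members)
    prov = {p: db.provenance[p] for p in keep if p in db.provenance}
    return LigandReceptorDB(keep, {}, prov)
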