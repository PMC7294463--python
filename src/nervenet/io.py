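"""Readers, writers and core containers for nerve interactome data.

Gene-symbol matching across rodent tables (``Ccl11``) and the
ligand-receptor database (``CCL11``) is case-insensitive; the canonical
form used for all set operations is uppercase, with the original
capitalisation retained for display.  Alias symbols joined with a slash
(``Ngfr/p75NTR``) are matched on their first token.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


def canonical_symbol(symbol: str) -> str:
    """Canonicalise a gene symbol: first alias token, uppercased."""
    return str(symbol).strip().split("/")[0].upper()


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for s in labels:
        if s in seen:
            dups.append(s)
        seen[s] = seen.get(s, 0) + 1
    if dups:
        raise ValueError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass
class ExpressionMatrix:
    """Sparse genes x cells UMI count matrix (a digital gene expression
    matrix) with gene symbols and cell barcodes.

    ``gene_ids`` keep their original capitalisation; matching is done on
    ``genes_upper``.  Counts are non-negative integers.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if len(self.cell_ids) == 0:
            raise ValueError("no cells")
        if len(self.gene_ids) == 0:
            raise ValueError("no genes")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        _check_unique([canonical_symbol(g) for g in self.gene_ids], "gene identifiers")
        _check_unique(list(self.cell_ids), "cell identifiers")
        data = self.counts.data
        if data.size and data.min() < 0:
            raise ValueError("negative counts")
        if not np.allclose(data, np.round(data)):
            raise ValueError("non-integer counts")

    @property
    def genes_upper(self) -> list[str]:
        return [canonical_symbol(g) for g in self.gene_ids]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes_upper)}

    def subset_cells(self, cell_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        idx = [pos[c] for c in cell_ids]
        return ExpressionMatrix(list(self.gene_ids), list(cell_ids),
                                self.counts[:, idx])

    def to_anndata(self):
        """Optional convenience export (cells x genes AnnData)."""
        import anndata

        return anndata.AnnData(
            X=self.counts.T.tocsr(),
            obs=pd.DataFrame(index=self.cell_ids),
            var=pd.DataFrame(index=self.gene_ids),
        )


@dataclass
class CellTypeAnnotation:
    """Per-cell cluster/cell-type labels with dataset of origin."""

    table: pd.DataFrame  # columns: cell_id, cell_type, dataset[, group]

    def __post_init__(self) -> None:
        required = {"cell_id", "cell_type"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        if "dataset" not in self.table.columns:
            self.table = self.table.assign(dataset="default")
        _check_unique(list(self.table["cell_id"]), "annotated cell identifiers")
        if (self.table["cell_type"].astype(str).str.len() == 0).any():
            raise ValueError("empty cell_type label")

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.table["cell_type"].unique())

    @property
    def datasets(self) -> list[str]:
        return sorted(self.table["dataset"].unique())

    def cells_of(self, cell_type: str | None = None,
                 dataset: str | None = None) -> list[str]:
        t = self.table
        if cell_type is not None:
            t = t[t["cell_type"] == cell_type]
        if dataset is not None:
            t = t[t["dataset"] == dataset]
        return list(t["cell_id"])


@dataclass(frozen=True)
class GeneSet:
    """A named set of canonical gene symbols."""

    name: str
    members: frozenset[str] = field(default_factory=frozenset)

    @classmethod
    def from_iterable(cls, name: str, genes: Iterable[str]) -> "GeneSet":
        return cls(name, frozenset(canonical_symbol(g) for g in genes))

    def __contains__(self, gene: str) -> bool:
        return canonical_symbol(gene) in self.members

    def __len__(self) -> int:
        return len(self.members)

    def sorted(self) -> list[str]:
        return sorted(self.members)


@dataclass
class BulkProfileSet:
    """Bulk expression values (genes x conditions), e.g. RMA-summarised
    microarray intensities or FPKM; the unit is declared, not inferred."""

    values: pd.DataFrame  # index: canonical gene symbols, columns: conditions
    units: str = "log2-intensity"

    def __post_init__(self) -> None:
        self.values = self.values.copy()
        self.values.index = [canonical_symbol(g) for g in self.values.index]
        _check_unique(list(self.values.index), "genes")
        _check_unique(list(self.values.columns), "conditions")
        if (self.values.values < 0).any():
            raise ValueError("negative expression values")

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)

    def condition(self, name: str) -> pd.Series:
        if name not in self.values.columns:
            raise KeyError(f"unknown condition {name!r}")
        return self.values[name]


# ---------------------------------------------------------------------------
# DGE matrix I/O
# ---------------------------------------------------------------------------

def read_dge(path: str | Path, format: str = "dense-tsv") -> ExpressionMatrix:
    """Read a digital gene expression matrix.

    ``dense-tsv``: genes as rows, cells as columns, first column gene
    symbols.  ``mtx-triplet``: MatrixMarket coordinate file (1-based
    indices) with companion ``genes.tsv`` and ``barcodes.tsv`` in the same
    directory.
    """
    path = Path(path)
    if format == "dense-tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.shape[1] == 0:
            raise ValueError("no cells")
        if df.shape[0] == 0:
            raise ValueError("no genes")
        vals = df.to_numpy()
        return ExpressionMatrix(list(df.index.astype(str)),
                                list(df.columns.astype(str)),
                                sp.csr_matrix(vals))
    if format == "mtx-triplet":
        mtx_path = path / "matrix.mtx" if path.is_dir() else path
        folder = mtx_path.parent
        counts = sp.csr_matrix(scipy.io.mmread(mtx_path))
        genes = [ln.split("\t")[0].strip()
                 for ln in (folder / "genes.tsv").read_text().splitlines() if ln.strip()]
        cells = [ln.strip()
                 for ln in (folder / "barcodes.tsv").read_text().splitlines() if ln.strip()]
        return ExpressionMatrix(genes, cells, counts)
    raise ValueError(f"unknown DGE format {format!r}")


def write_dge(matrix: ExpressionMatrix, path: str | Path,
              format: str = "dense-tsv") -> None:
    path = Path(path)
    if format == "dense-tsv":
        df = pd.DataFrame(matrix.counts.toarray(), index=matrix.gene_ids,
                          columns=matrix.cell_ids)
        df.to_csv(path, sep="\t")
        return
    if format == "mtx-triplet":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(path / "matrix.mtx"), sp.coo_matrix(matrix.counts))
        (path / "genes.tsv").write_text("\n".join(matrix.gene_ids) + "\n")
        (path / "barcodes.tsv").write_text("\n".join(matrix.cell_ids) + "\n")
        return
    raise ValueError(f"unknown DGE format {format!r}")


def read_annotation(path: str | Path) -> CellTypeAnnotation:
    return CellTypeAnnotation(pd.read_csv(path, sep="\t", dtype=str))


def write_annotation(annot: CellTypeAnnotation, path: str | Path) -> None:
    annot.table.to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path, name: str | None = None) -> GeneSet:
    """One symbol per line (header-less) or a TSV with a ``gene`` column."""
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if lines and "\t" in lines[0]:
        df = pd.read_csv(path, sep="\t")
        if "gene" not in df.columns:
            raise ValueError("gene list TSV needs a 'gene' column")
        genes = df["gene"].astype(str)
    else:
        genes = [ln for ln in lines if ln.lower() != "gene"]
    return GeneSet.from_iterable(name or path.stem, genes)


def read_bulk_table(path: str | Path, units: str = "log2-intensity") -> BulkProfileSet:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return BulkProfileSet(df, units=units)


def read_pair_table(path: str | Path) -> list[tuple[str, str]]:
    """Read ligand-receptor pairs from a TSV with ``ligand`` and
    ``receptor`` columns; de-duplicated and case-normalised, input order
    of first occurrence preserved."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "ligand" not in cols or "receptor" not in cols:
        raise ValueError("pair table needs 'ligand' and 'receptor' columns")
    pairs: list[tuple[str, str]] = []
    seen = set()
    for lig, rec in zip(df[cols["ligand"]], df[cols["receptor"]]):
        pair = (canonical_symbol(lig), canonical_symbol(rec))
        if pair not in seen:
            seen.add(pair)
            pairs.append(pair)
    return pairs


# ---------------------------------------------------------------------------
# Network I/O
# ---------------------------------------------------------------------------

def write_network(network, path: str | Path, format: str = "tsv") -> None:
    """Serialise an :class:`~nervenet.network.InteractionNetwork`.

    ``tsv`` and ``graphml`` round-trip the full (source, ligand, receptor,
    target) edge tuples; ``sif`` keeps only the ligand-receptor pairs.
    Edges are written in deterministic lexicographic order.
    """
    path = Path(path)
    edges = sorted(network.edges)
    if format == "tsv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["source", "ligand", "target", "receptor"])
            for src, lig, rec, tgt in edges:
                w.writerow([src, lig, tgt, rec])
        return
    if format == "sif":
        with open(path, "w") as fh:
            for src, lig, rec, tgt in edges:
                fh.write(f"{lig}\tlr\t{rec}\n")
        return
    if format == "graphml":
        import networkx as nx

        g = nx.MultiDiGraph()
        for src, lig, rec, tgt in edges:
            g.add_node(lig, kind="ligand")
            g.add_node(rec, kind="receptor")
            g.add_edge(lig, rec, source=src, target=tgt)
        nx.write_graphml(g, path)
        return
    raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: str = "tsv"):
    from .network import Edge, InteractionNetwork

    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t")
        edges = [Edge(r.source, r.ligand, r.receptor, r.target)
                 for r in df.itertuples()]
        return InteractionNetwork(frozenset(edges))
    if format == "sif":
        edges = []
        for ln in path.read_text().splitlines():
            if not ln.strip():
                continue
            lig, _, rec = ln.split("\t")
            edges.append(Edge("", lig, rec, ""))
        return InteractionNetwork(frozenset(edges))
    if format == "graphml":
        import networkx as nx

        g = nx.read_graphml(path)
        edges = [Edge(d.get("source", ""), u, v, d.get("target", ""))
                 for u, v, d in g.edges(data=True)]
        return InteractionNetwork(frozenset(edges))
    raise ValueError(f"unknown network format {format!r}")
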