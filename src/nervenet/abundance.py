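"""Per-cell-type gene detection fractions and the 2% expression rule.

The central statistic is the *detection fraction*: the percentage of
cells of a given cell type with at least one UMI for a gene.  A gene is
called expressed in a cell type when this fraction is at or above a
threshold, 2% by default; below-threshold entries in published tables
("BT") are carried as an explicit mask, never silently as zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CellTypeAnnotation, ExpressionMatrix, GeneSet, canonical_symbol

DEFAULT_THRESHOLD = 2.0


@dataclass
class DetectionTable:
    """Ligand x cell-type detection fractions in percent.

    ``fraction`` holds the numeric values (0-100); ``bt`` flags entries
    reported below the detection threshold, where the stored number is
    either the raw sub-threshold value (when known) or 0.  ``n_cells``
    gives per-cell-type totals when the table was computed from a count
    matrix (``None`` for transcribed published tables).
    """

    fraction: pd.DataFrame
    n_cells: pd.Series | None = None
    bt: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = self.fraction.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0) < 0 or np.nanmax(vals, initial=0) > 100:
            raise ValueError("detection fractions must lie in [0, 100]")
        if self.bt is None:
            self.bt = self.fraction < DEFAULT_THRESHOLD

    @property
    def ligands(self) -> list[str]:
        return list(self.fraction.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.fraction.columns)


def detection_fractions(matrix: ExpressionMatrix, annot: CellTypeAnnotation,
                        genes: GeneSet | Iterable[str],
                        by: str = "cell_type") -> DetectionTable:
    """Percentage of cells per group (cell type or dataset) with >= 1 UMI.

    Genes absent from the matrix get fraction 0 in every group, with a
    warning.  Cells present in the matrix but not annotated are ignored;
    annotated cells missing from the matrix raise.
    """
    gene_list = genes.sorted() if isinstance(genes, GeneSet) else [
        canonical_symbol(g) for g in genes]
    gidx = matrix.gene_index()
    missing = [g for g in gene_list if g not in gidx]
    if missing:
        warnings.warn(f"{len(missing)} gene(s) absent from matrix, "
                      f"reported as 0%: {missing[:5]}...")
    cell_pos = {c: j for j, c in enumerate(matrix.cell_ids)}
    unknown = set(annot.table["cell_id"]) - set(cell_pos)
    if unknown:
        raise ValueError(f"annotated cells missing from matrix: "
                         f"{sorted(unknown)[:5]}")

    groups = sorted(annot.table[by].unique())
    detected = (matrix.counts >= 1)
    frac = pd.DataFrame(0.0, index=gene_list, columns=groups)
    n_cells = pd.Series(0, index=groups, dtype=int)
    rows = [gidx[g] for g in gene_list if g in gidx]
    present = [g for g in gene_list if g in gidx]
    for grp in groups:
        cells = annot.table.loc[annot.table[by] == grp, "cell_id"]
        cols = [cell_pos[c] for c in cells]
        n_cells[grp] = len(cols)
        if not cols or not rows:
            continue
        sub = detected[rows][:, cols]
        frac.loc[present, grp] = 100.0 * np.asarray(
            sub.sum(axis=1)).ravel() / len(cols)
    return DetectionTable(frac, n_cells=n_cells)


def expressed_sets(table: DetectionTable,
                   threshold: float = DEFAULT_THRESHOLD,
                   ) -> dict[str, GeneSet]:
    """Per-cell-type expressed gene sets (fraction >= threshold,
    inclusive) plus the any-type union under key ``"any"``."""
    if not 0 < threshold < 100:
        raise ValueError("threshold must be in (0, 100)")
    out: dict[str, GeneSet] = {}
    union: set[str] = set()
    for ct in table.cell_types:
        members = set(table.fraction.index[table.fraction[ct] >= threshold])
        out[ct] = GeneSet(ct, frozenset(members))
        union |= members
    out["any"] = GeneSet("any", frozenset(union))
    return out


def assign_highest(table: DetectionTable,
                   compare_types: Sequence[str] | None = None,
                   mesenchymal_members: Sequence[str] | None = None,
                   tie_resolution: Mapping[str, str] | None = None,
                   ) -> pd.DataFrame:
    """Assign each ligand to the cell type(s) with the greatest detection
    fraction.

    The comparison uses the strict maximum; exact ties are surfaced (all
    tied types listed, ``tie`` True) rather than silently broken.
    ``tie_resolution`` may name a winning type per ligand for ties whose
    true order is known from elsewhere (e.g. a published table's own
    annotation of values that tie only at printed precision).

    When ``mesenchymal_members`` is given, ``mesenchymal_highest`` marks
    ligands whose maximum over those member types reaches the overall
    maximum (i.e. no non-member type is strictly higher); aggregate
    "combined" columns should be excluded from ``compare_types``.
    """
    types = list(compare_types) if compare_types else table.cell_types
    sub = table.fraction[types]
    out = []
    for lig, row in sub.iterrows():
        top = row.max()
        winners = tuple(t for t in types if row[t] == top)
        tie = len(winners) > 1
        if tie and tie_resolution and lig in tie_resolution:
            winners = (tie_resolution[lig],)
            tie = False
        rec = {"ligand": lig, "assigned": winners, "tie": tie, "max": top}
        if mesenchymal_members is not None:
            rec["mesenchymal_highest"] = any(
                t in mesenchymal_members for t in winners)
        out.append(rec)
    return pd.DataFrame(out).set_index("ligand")


def combined_fraction(fractions: Sequence[float],
                      n_cells: Sequence[int]) -> float:
    """Detection fraction over the pooled cells of several cell types
    (cell-count weighted), not the mean of per-type fractions."""
    n = np.asarray(n_cells, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if n.sum() == 0:
        raise ValueError("no cells to pool")
    return float((f * n).sum() / n.sum())


def pooled_fraction(table: DetectionTable, member_types: Sequence[str]) -> pd.Series:
    """Per-ligand pooled detection fraction over member cell types."""
    if table.n_cells is None:
        raise ValueError("pooling requires per-type cell counts")
    n = table.n_cells[list(member_types)]
    return (table.fraction[list(member_types)] * n).sum(axis=1) / n.sum()


@dataclass
class FoldChangeTable:
    """Fold changes of detection fractions between two conditions.

    ``ratio`` is numerator/denominator on raw (sub-threshold included)
    fractions; when the denominator is 0 and the numerator positive, the
    ratio is a lower bound (``lower_bound`` True, ratio = numerator,
    displayed ``">x"``); both zero yields NaN.
    """

    table: pd.DataFrame  # columns: numerator, denominator, ratio, lower_bound

    def display(self) -> pd.Series:
        def fmt(row):
            if np.isnan(row.ratio):
                return "-"
            if row.lower_bound:
                return f">{row.ratio:g}"
            return f"{row.ratio:.1f}"
        return self.table.apply(fmt, axis=1)


def fold_changes(numerator: pd.Series, denominator: pd.Series) -> FoldChangeTable:
    """Fold change of raw detection fractions (numerator / denominator).

    Sub-threshold denominators are used at their raw value, matching how
    published fold changes are computed from the unrounded fractions.
    """
    num, den = numerator.align(denominator, join="inner")
    ratio = np.where(den > 0, num / np.where(den > 0, den, 1.0),
                     np.where(num > 0, num, np.nan))
    lower = (den == 0) & (num > 0)
    return FoldChangeTable(pd.DataFrame({
        "numerator": num, "denominator": den,
        "ratio": ratio, "lower_bound": lower}, index=num.index))


def enrichment_flags(table: DetectionTable, focal_type: str,
                     factor: float = 4.0,
                     compare_types: Sequence[str] | None = None) -> GeneSet:
    """Ligands whose focal-type detection fraction is at least ``factor``
    times the maximum over every other compared cell type."""
    types = list(compare_types) if compare_types else table.cell_types
    if focal_type not in types:
        raise ValueError(f"{focal_type!r} not among compared cell types")
    others = [t for t in types if t != focal_type]
    other_max = table.fraction[others].max(axis=1)
    flagged = table.fraction.index[
        table.fraction[focal_type] >= factor * other_max]
    return GeneSet(f"{focal_type}_enriched_{factor:g}x", frozenset(flagged))


def cross_dataset_sets(expressed_unions: Mapping[str, GeneSet | Iterable[str]],
                       ) -> dict:
    """Venn regions and shared / per-dataset-exclusive membership lists
    over 2-3 per-dataset expressed-ligand unions."""
    from .bulk import venn_counts

    named = {name: set(gs.members if isinstance(gs, GeneSet) else
                       (canonical_symbol(g) for g in gs))
             for name, gs in expressed_unions.items()}
    regions = venn_counts(named)
    names = sorted(named)
    shared = set.intersection(*named.values())
    exclusive = {name: named[name] - set.union(
        *(named[o] for o in names if o != name)) for name in names}
    return {"regions": regions, "shared": sorted(shared),
            "exclusive": {k: sorted(v) for k, v in exclusive.items()}}
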