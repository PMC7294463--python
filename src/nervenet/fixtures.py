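"""Loaders for the bundled fixtures transcribed from the published
working tables of the peripheral-nerve interactome study.

The tables cover: microarray ligand calls in uninjured / 3 DPI / 7 DPI
nerve (table 1); single-cell detection fractions of the 143 injured-nerve
ligands in the injured, uninjured and neonatal nerves (tables 2-4) and in
the combined Schwann-cell and mesenchymal-cell datasets (tables 5-6);
cell-surface proteomics protein and receptor lists for sensory (DRG) and
sympathetic (SCG) neurons (tables 7-8); the predicted ligand-receptor
interaction blocks for SCG, DRG, motor neuron (MN) and retinal ganglion
cell (RGC) targets (table 9); and the MN / RGC receptor lists (table 10).

Below-threshold entries print as "BT" (optionally with the raw value in
parentheses); they are loaded as an explicit mask, with the raw value
where the source table provides one and 0 otherwise.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .abundance import DetectionTable
from .io import GeneSet, canonical_symbol

MESENCHYMAL_TYPES = ("epineurial_perineurial", "endoneurial")
INJURED_COMPARE_TYPES = ("epineurial_perineurial", "endoneurial",
                         "vsm_pericytes", "endothelial", "schwann", "immune")


def fixture_path(name: str) -> Path:
    return Path(resources.files("nervenet") / "data" / name)


def _read(name: str) -> pd.DataFrame:
    return pd.read_csv(fixture_path(name), sep="\t", keep_default_na=False)


def _parse_bt(value: str) -> tuple[float, bool]:
    """'12.3' -> (12.3, False); 'BT' -> (0.0, True); 'BT(0.4)' -> (0.4, True)."""
    v = value.strip()
    if v.startswith("BT"):
        if "(" in v:
            return float(v[v.index("(") + 1:v.index(")")]), True
        return 0.0, True
    return float(v), False


def _detection_from_wide(df: pd.DataFrame, value_cols: list[str]) -> DetectionTable:
    genes = [canonical_symbol(g) for g in df["gene"]]
    frac = pd.DataFrame(index=genes, columns=value_cols, dtype=float)
    bt = pd.DataFrame(False, index=genes, columns=value_cols)
    for col in value_cols:
        parsed = [_parse_bt(v) for v in df[col]]
        frac[col] = [p[0] for p in parsed]
        bt[col] = [p[1] for p in parsed]
    return DetectionTable(frac, n_cells=None, bt=bt)


# -- table 1: microarray ligand calls ---------------------------------------

def microarray_ligand_sets() -> dict[str, GeneSet]:
    """Expressed-ligand sets per bulk condition, plus the printed triple
    intersection under key ``"intersect"``."""
    df = _read("table1.tsv")
    return {cond: GeneSet.from_iterable(cond, sub["gene"])
            for cond, sub in df.groupby("condition")}


# -- tables 2-4: nerve detection tables --------------------------------------

_LIGAND_TABLES = {"injured": "table2.tsv", "uninjured": "table3.tsv",
                  "neonatal": "table4.tsv"}


def load_ligand_detection(which: str) -> DetectionTable:
    """Detection-fraction table for ``"injured"`` (combined 3+9 DPI),
    ``"uninjured"`` or ``"neonatal"`` nerve."""
    if which not in _LIGAND_TABLES:
        raise KeyError(f"unknown dataset {which!r}")
    df = _read(_LIGAND_TABLES[which])
    cols = [c for c in df.columns if c not in ("gene", "mark")]
    return _detection_from_wide(df, cols)


def injured_ligand_panel() -> GeneSet:
    """The 143 injured-nerve ligands (the panel all downstream single-cell
    and interaction analyses use)."""
    df = _read("table2.tsv")
    return GeneSet.from_iterable("injured_nerve_ligands", df["gene"])


def mesenchymal_annotation() -> pd.Series:
    """Per-ligand footnote mark from the injured-nerve table: ``"*"`` =
    expressed in >=2% mesenchymal cells, ``"**"`` = additionally highest
    in a mesenchymal compartment, ``""`` = neither.  Records the source
    table's own resolution of comparisons that tie at printed precision."""
    df = _read("table2.tsv")
    return pd.Series(list(df["mark"]),
                     index=[canonical_symbol(g) for g in df["gene"]])


def printed_tie_resolution(table: DetectionTable | None = None,
                           ) -> dict[str, str]:
    """Resolution of highest-cell-type ties that exist only at the
    table's printed precision (fractions are rounded to 0.1%).

    The table's own footnote marks record whether each ligand's highest
    expression was in a mesenchymal compartment on the unrounded data;
    for ligands whose rounded fractions tie across the mesenchymal /
    non-mesenchymal boundary, that annotation decides the winner.
    """
    from .abundance import assign_highest

    if table is None:
        table = load_ligand_detection("injured")
    marks = mesenchymal_annotation()
    assigned = assign_highest(table, list(INJURED_COMPARE_TYPES))
    resolution: dict[str, str] = {}
    for lig, row in assigned[assigned["tie"]].iterrows():
        winners = row["assigned"]
        mes = [t for t in winners if t in MESENCHYMAL_TYPES]
        non = [t for t in winners if t not in MESENCHYMAL_TYPES]
        if not (mes and non):
            continue  # tie within one side: the marks cannot resolve it
        if marks.get(lig) == "**":
            resolution[lig] = mes[0]
        else:
            resolution[lig] = non[0]
    return resolution


# -- tables 5-6: combined Schwann / mesenchymal datasets ----------------------

def load_schwann_detection() -> tuple[DetectionTable, pd.DataFrame]:
    """Combined Schwann-cell dataset: detection table over the four
    Schwann populations plus the printed injured:uninjured fold-change
    column (``fold_change``: float, ``lower_bound``, ``injured_highest``)."""
    df = _read("table5.tsv")
    cols = ["neonatal", "uninjured_myelinating", "uninjured_nonmyelinating",
            "injured"]
    table = _detection_from_wide(df, cols)
    extra = _fold_column(df)
    extra["injured_highest"] = df["injured_highest"].astype(int).astype(bool).values
    return table, extra


def load_mesenchymal_detection() -> tuple[DetectionTable, pd.DataFrame]:
    """Combined mesenchymal-cell dataset: detection table over the eight
    mesenchymal populations plus the printed injured:uninjured
    endoneurial fold-change column."""
    df = _read("table6.tsv")
    cols = [c for c in df.columns if c not in ("gene", "fold_change")]
    return _detection_from_wide(df, cols), _fold_column(df)


def _fold_column(df: pd.DataFrame) -> pd.DataFrame:
    genes = [canonical_symbol(g) for g in df["gene"]]
    fold, lower = [], []
    for v in df["fold_change"]:
        v = str(v).strip()
        if v in ("NA", "", "-"):
            fold.append(np.nan)
            lower.append(False)
        elif v.startswith(">"):
            fold.append(float(v[1:]))
            lower.append(True)
        else:
            fold.append(float(v))
            lower.append(False)
    return pd.DataFrame({"fold_change": fold, "lower_bound": lower}, index=genes)


# -- tables 7-8: proteomics and receptor calls --------------------------------

def surface_protein_sets() -> dict[str, GeneSet]:
    """Cell-surface capture mass-spectrometry protein lists: ``drg``,
    ``scg`` and the printed ``intersect``."""
    df = _read("table7.tsv")
    return {name: GeneSet.from_iterable(name, sub["gene"])
            for name, sub in df.groupby("list")}


def ms_receptor_sets() -> dict[str, GeneSet]:
    """Mass-spectrometry receptor lists (``drg_only``, ``scg_only``,
    ``both``) plus per-population unions ``drg`` and ``scg``."""
    df = _read("table8.tsv")
    ms = df[df["section"] == "ms"]
    out = {name: GeneSet.from_iterable(name, sub["gene"])
           for name, sub in ms.groupby("list")}
    both = out["both"].members
    out["drg"] = GeneSet("drg", out["drg_only"].members | both)
    out["scg"] = GeneSet("scg", out["scg_only"].members | both)
    return out


def receptor_call_sets() -> dict[str, GeneSet]:
    """Published receptor repertoires per neuron population: ``drg`` and
    ``scg`` (microarray, anchor-thresholded), ``mn`` (microarray,
    percentile), ``rgc`` (RNA-seq, FPKM > 1), and the printed intersect
    columns ``drg_scg_mn`` and ``all_four``."""
    t8 = _read("table8.tsv")
    arr = t8[t8["section"] == "microarray"]
    out = {name: GeneSet.from_iterable(name, sub["gene"])
           for name, sub in arr.groupby("list")}
    t10 = _read("table10.tsv")
    for name, sub in t10.groupby("list"):
        out[name] = GeneSet.from_iterable(name, sub["gene"])
    return out


# -- table 9: interaction blocks ----------------------------------------------

def interaction_blocks() -> dict[str, "InteractionNetwork"]:
    """Published predicted interaction networks keyed by target
    population (``SCGs``, ``DRGs``, ``MNs``, ``RGCs``)."""
    from .network import Edge, InteractionNetwork

    df = _read("table9.tsv")
    out = {}
    for target, sub in df.groupby("target"):
        edges = frozenset(
            Edge(r.source, canonical_symbol(r.ligand),
                 canonical_symbol(r.receptor), r.target)
            for r in sub.itertuples())
        out[target] = InteractionNetwork(edges)
    return out
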