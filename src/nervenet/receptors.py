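"""Receptor-repertoire calling for target neuron populations.

Three thresholding modes mirror how receptor expression is anchored in
practice:

* **anchor** -- the cell-surface proteomics hit with the lowest mRNA
  expression sets the cutoff (receptors are at least as reliably
  expressed as something independently seen at the protein level);
* **percentile** -- a fixed expression percentile borrowed from an
  anchored population, for populations without proteomics;
* **fpkm** -- an absolute FPKM cutoff for RNA-seq profiles
  (strictly greater than, conventionally FPKM > 1).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .io import BulkProfileSet, GeneSet, canonical_symbol


@dataclass
class ReceptorCall:
    population: str
    mode: str                      # anchor | percentile | fpkm
    receptors: GeneSet
    cutoff_gene: str | None = None
    cutoff_value: float | None = None
    anchor_percentile: float | None = None  # % of genes at or below cutoff
    proteome_receptors: GeneSet | None = None

    def __post_init__(self) -> None:
        if self.mode == "anchor" and self.cutoff_gene is not None:
            if self.cutoff_gene not in self.receptors.members:
                raise ValueError("anchor gene must be in its own call")


def summarize_probe_level(probes: pd.DataFrame) -> BulkProfileSet:
    """Collapse a probe-level table to one value per gene: mean over
    replicate columns per probe, then max over a gene's probes (the
    averaging precedes the max).  Expects columns ``probe``, ``gene`` and
    one or more replicate value columns; probes without gene annotation
    are dropped with a warning."""
    value_cols = [c for c in probes.columns if c not in ("probe", "gene")]
    if not value_cols:
        raise ValueError("no replicate value columns")
    anno = probes["gene"].astype(str).str.strip()
    bad = (anno == "") | (anno.str.lower().isin(("nan", "none")))
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} probe(s) without gene "
                      "annotation")
    kept = probes[~bad].copy()
    kept["__mean"] = kept[value_cols].mean(axis=1)
    kept["__gene"] = [canonical_symbol(g) for g in kept["gene"]]
    per_gene = kept.groupby("__gene")["__mean"].max()
    return BulkProfileSet(per_gene.to_frame("expression"),
                          units="probe-summarised")


def _single_condition(expr: BulkProfileSet, condition: str | None) -> pd.Series:
    if condition is None:
        if len(expr.conditions) != 1:
            raise ValueError("profile has several conditions; name one")
        condition = expr.conditions[0]
    return expr.condition(condition)


def anchor_receptor_call(expr: BulkProfileSet, population: str,
                         detected_proteins: GeneSet,
                         receptor_panel: GeneSet,
                         condition: str | None = None) -> ReceptorCall:
    """Anchor mode: the proteomics-detected receptor with the minimum
    mRNA expression defines the cutoff; panel genes at or above it
    (ties included) are called."""
    col = _single_condition(expr, condition)
    candidates = [g for g in detected_proteins.members
                  if g in receptor_panel.members and g in col.index]
    if not candidates:
        raise ValueError("no proteomics-detected receptor found in the "
                         "expression profile")
    cutoff_gene = min(candidates, key=lambda g: (col[g], g))
    cutoff = float(col[cutoff_gene])
    members = frozenset(g for g in receptor_panel.members
                        if g in col.index and col[g] >= cutoff)
    return ReceptorCall(
        population=population, mode="anchor",
        receptors=GeneSet(f"{population}_receptors", members),
        cutoff_gene=cutoff_gene, cutoff_value=cutoff,
        anchor_percentile=100.0 * float((col <= cutoff).mean()),
        proteome_receptors=detected_proteins)


def percentile_receptor_call(expr: BulkProfileSet, population: str,
                             percentile: float, receptor_panel: GeneSet,
                             condition: str | None = None) -> ReceptorCall:
    """Percentile mode: panel genes within the top ``percentile`` percent
    of all profiled genes by expression (cutoff at the
    ``100 - percentile`` quantile from the bottom, ties included)."""
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    col = _single_condition(expr, condition)
    cutoff = float(col.quantile((100.0 - percentile) / 100.0,
                                interpolation="higher"))
    members = frozenset(g for g in receptor_panel.members
                        if g in col.index and col[g] >= cutoff)
    return ReceptorCall(
        population=population, mode="percentile",
        receptors=GeneSet(f"{population}_receptors", members),
        cutoff_value=cutoff,
        anchor_percentile=100.0 - percentile)


def fpkm_receptor_call(expr: BulkProfileSet, population: str,
                       receptor_panel: GeneSet, min_fpkm: float = 1.0,
                       condition: str | None = None) -> ReceptorCall:
    """FPKM mode: panel genes strictly above ``min_fpkm``."""
    if "fpkm" not in expr.units.lower():
        raise ValueError("fpkm mode requires a profile declared as FPKM")
    col = _single_condition(expr, condition)
    members = frozenset(g for g in receptor_panel.members
                        if g in col.index and col[g] > min_fpkm)
    return ReceptorCall(
        population=population, mode="fpkm",
        receptors=GeneSet(f"{population}_receptors", members),
        cutoff_value=min_fpkm)


def classify_receptors(receptors: GeneSet,
                       class_map: Mapping[str, str]) -> dict[str, int]:
    """Histogram of receptor classes from a user-supplied gene -> class
    map (e.g. GPCR, RTK/RTP, cytokine receptor); unmapped genes are
    counted under ``"unclassified"``."""
    norm = {canonical_symbol(g): c for g, c in class_map.items()}
    counts: Counter[str] = Counter()
    for g in receptors.members:
        counts[norm.get(g, "unclassified")] += 1
    return dict(counts)
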