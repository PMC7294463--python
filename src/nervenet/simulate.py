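"""Synthetic data with the statistical structure the pipeline assumes.

The detection rule downstream is binary (UMI count >= 1), so the
generator is built around per-gene, per-cell-type *detection
probabilities*; counts given detection follow a zero-truncated negative
binomial, which gives realistic overdispersed tails without affecting
the zero/non-zero structure.  Batches act as sequencing-depth
multipliers only.  Every generator takes an explicit seed; there is no
global random state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats as st

from .abundance import DetectionTable
from .io import (BulkProfileSet, CellTypeAnnotation, ExpressionMatrix,
                 GeneSet, canonical_symbol)


@dataclass
class SimConfig:
    """Generating parameters for a synthetic DGE matrix.

    ``detect_prob`` is a genes x cell-types table of probabilities that a
    cell of that type has at least one UMI for the gene.  ``mean_expr``
    and ``dispersion`` parameterise the count magnitude given detection
    (negative binomial mean and overdispersion alpha, var = mu + alpha
    mu^2).  ``batches`` are (name, fraction of cells, depth multiplier).
    """

    cell_types: list[tuple[str, int]]
    genes: list[str]
    detect_prob: pd.DataFrame
    mean_expr: np.ndarray | float = 2.0
    dispersion: np.ndarray | float = 0.8
    batches: list[tuple[str, float, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.genes = [canonical_symbol(g) for g in self.genes]
        p = self.detect_prob.to_numpy(dtype=float)
        if p.min() < 0 or p.max() > 1:
            raise ValueError("detection probabilities must lie in [0, 1]")
        if list(self.detect_prob.index) != self.genes:
            self.detect_prob = self.detect_prob.loc[self.genes]
        for name, n in self.cell_types:
            if n < 1:
                raise ValueError(f"cell type {name!r} needs >= 1 cell")
        if self.batches is not None:
            total = sum(f for _, f, _ in self.batches)
            if abs(total - 1.0) > 1e-9:
                raise ValueError("batch fractions must sum to 1")


def _ztnb(rng: np.random.Generator, mu: np.ndarray,
          alpha: float) -> np.ndarray:
    """Zero-truncated negative binomial draws via inverse CDF above the
    zero mass (Poisson limit when alpha == 0)."""
    mu = np.asarray(mu, dtype=float)
    if mu.size == 0:
        return np.zeros(0, dtype=np.int64)
    if alpha <= 0:
        p0 = np.exp(-mu)
        u = p0 + (1 - p0) * rng.random(mu.shape)
        return st.poisson.ppf(np.clip(u, None, 1 - 1e-12), mu).astype(np.int64)
    r = 1.0 / alpha
    p = r / (r + mu)
    p0 = st.nbinom.pmf(0, r, p)
    u = p0 + (1 - p0) * rng.random(mu.shape)
    return st.nbinom.ppf(np.clip(u, None, 1 - 1e-12), r, p).astype(np.int64)


def simulate_dge(config: SimConfig,
                 ) -> tuple[ExpressionMatrix, CellTypeAnnotation, DetectionTable]:
    """Draw a sparse UMI matrix: each cell expresses each gene with its
    type's detection probability; expressed counts are zero-truncated
    negative binomial with the configured mean scaled by batch depth.

    Returns the matrix, per-cell annotations (cell type and batch as
    dataset) and the generating truth as a DetectionTable (probability x
    100)."""
    rng = np.random.default_rng(config.seed)
    type_names = [t for t, _ in config.cell_types]
    n_cells = sum(n for _, n in config.cell_types)
    disp = np.broadcast_to(np.asarray(config.dispersion, dtype=float),
                           (len(config.genes),))
    mean = np.broadcast_to(np.asarray(config.mean_expr, dtype=float),
                           (len(config.genes),))

    cell_ids, cell_type_col, batch_col, depth = [], [], [], []
    for tname, n in config.cell_types:
        for _ in range(n):
            cell_ids.append(f"{tname}_{len(cell_ids):05d}")
            cell_type_col.append(tname)
    if config.batches:
        names = [b for b, _, _ in config.batches]
        fracs = [f for _, f, _ in config.batches]
        depths = {b: d for b, _, d in config.batches}
        assignment = rng.choice(names, size=n_cells, p=fracs)
        batch_col = list(assignment)
        depth = np.array([depths[b] for b in assignment])
    else:
        batch_col = ["batch0"] * n_cells
        depth = np.ones(n_cells)

    rows, cols, data = [], [], []
    offset = 0
    for tname, n in config.cell_types:
        probs = config.detect_prob[tname].to_numpy()
        cell_depth = depth[offset:offset + n]
        for gi, p in enumerate(probs):
            if p <= 0:
                continue
            hit = np.nonzero(rng.random(n) < p)[0]
            if hit.size:
                counts = _ztnb(rng, mean[gi] * cell_depth[hit], float(disp[gi]))
                rows.extend([gi] * hit.size)
                cols.extend(offset + hit)
                data.extend(counts)
        offset += n

    counts = sp.csr_matrix(
        (np.asarray(data, dtype=np.int64), (rows, cols)),
        shape=(len(config.genes), n_cells))
    matrix = ExpressionMatrix(list(config.genes), cell_ids, counts)
    annot = CellTypeAnnotation(pd.DataFrame({
        "cell_id": cell_ids, "cell_type": cell_type_col,
        "dataset": batch_col}))
    truth = DetectionTable(100.0 * config.detect_prob[type_names],
                           n_cells=pd.Series(dict(config.cell_types)))
    return matrix, annot, truth


def simulate_bulk(genes: Sequence[str], n_genes_total: int, anchor: str,
                  anchor_quantile: float, seed: int,
                  conditions: Sequence[str] = ("bulk",)) -> BulkProfileSet:
    """Rank-structured bulk profiles containing an anchor gene.

    All genes (the named panel plus synthetic background genes up to
    ``n_genes_total``) draw log-normal expression; the anchor's value is
    then replaced so that the fraction of genes at or below it equals
    ``anchor_quantile`` to within 1/``n_genes_total``."""
    genes = [canonical_symbol(g) for g in genes]
    anchor = canonical_symbol(anchor)
    if anchor not in genes:
        raise ValueError(f"anchor {anchor!r} not in gene list")
    if not 0 < anchor_quantile <= 1:
        raise ValueError("anchor_quantile must be in (0, 1]")
    if n_genes_total < len(genes):
        raise ValueError("n_genes_total smaller than the named gene list")
    rng = np.random.default_rng(seed)
    all_genes = genes + [f"BG{i:05d}" for i in range(n_genes_total - len(genes))]
    n = len(all_genes)
    k = max(1, int(round(anchor_quantile * n)))  # genes at or below anchor
    values = {}
    for cond in conditions:
        v = rng.lognormal(mean=3.0, sigma=1.0, size=n)
        others = np.sort(np.delete(v, all_genes.index(anchor)))
        if k - 1 == 0:
            anchor_val = others[0] / 2.0
        elif k - 1 >= n - 1:
            anchor_val = others[-1] * 1.01
        else:
            anchor_val = 0.5 * (others[k - 2] + others[k - 1])
        v[all_genes.index(anchor)] = anchor_val
        values[cond] = v
    return BulkProfileSet(pd.DataFrame(values, index=all_genes),
                          units="simulated-intensity")


def simulate_proteome(true_receptors: GeneSet, sensitivity: float,
                      decoys: GeneSet, fdr_like: float, seed: int) -> GeneSet:
    """Partially sensitive protein detection: each true receptor is
    detected with probability ``sensitivity`` and each decoy with
    probability ``fdr_like``."""
    if true_receptors.members & decoys.members:
        raise ValueError("true receptors and decoys must be disjoint")
    if not (0 <= sensitivity <= 1 and 0 <= fdr_like <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    detected = [g for g in sorted(true_receptors.members)
                if rng.random() < sensitivity]
    detected += [g for g in sorted(decoys.members) if rng.random() < fdr_like]
    return GeneSet("detected_proteins", frozenset(detected))


def nerve_sim_config(seed: int, n_cells_scale: float = 1.0) -> SimConfig:
    """A nerve-like simulation: generating detection probabilities are
    the transcribed injured-nerve detection fractions, over six cell
    types whose sizes sum to the study's combined injured dataset (5395
    cells; the per-type split is not published, so a split consistent
    with the table's pooled mesenchymal fractions is used)."""
    from .fixtures import INJURED_COMPARE_TYPES, load_ligand_detection

    table = load_ligand_detection("injured")
    probs = table.fraction[list(INJURED_COMPARE_TYPES)] / 100.0
    sizes = {"epineurial_perineurial": 1450, "endoneurial": 500,
             "vsm_pericytes": 550, "endothelial": 700, "schwann": 900,
             "immune": 1295}
    cell_types = [(t, max(1, int(round(n * n_cells_scale))))
                  for t, n in sizes.items()]
    return SimConfig(cell_types=cell_types, genes=list(probs.index),
                     detect_prob=probs, seed=seed)
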