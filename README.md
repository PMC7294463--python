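# nervenet

Ligand-receptor interactome analysis of peripheral nerve.

Injured peripheral nerves are a famously pro-regenerative environment:
severed axons of sensory, sympathetic and motor neurons regrow through
them, and even CNS neurons extend axons into nerve grafts. Which
nerve-resident cells supply the growth-promoting ligands, and which
receptors on the target neurons could receive them? `nervenet`
implements the computational half of that question as a reusable,
tested pipeline:

* **Anchor-gene thresholding of bulk profiles** — a ligand is called
  expressed in a bulk transcriptome when its level is at or above that
  of a reference gene with known nerve expression (classically *Ntf3*):
  `expressed = {g : x_g >= x_anchor}`, with the anchor's percentile rank
  documenting the cutoff's permissiveness.
* **Per-cell-type detection fractions** — the core single-cell
  statistic. For gene *g* and cell type *t* with *n_t* cells,
  `f_gt = 100 * |{cells of t with UMI count >= 1 for g}| / n_t`,
  and *g* is expressed in *t* when `f_gt >= 2%` (the "2% rule").
  On top of this sit highest-cell-type assignment, pooled (cell-count
  weighted) fractions for aggregate compartments, injured:uninjured
  fold changes on raw fractions, and 4-fold enrichment flags.
* **Proteomics-anchored receptor calling** — a neuron population's
  receptor repertoire is the set of receptor mRNAs expressed at or
  above the *lowest-expressed receptor that cell-surface mass
  spectrometry detected at the protein level* (or a percentile / FPKM
  cutoff for populations without proteomics).
* **Interaction prediction** — a directed edge
  `(nerve, ligand) -> (receptor, neuron population)` is predicted
  whenever a curated ligand-receptor database pairs an expressed nerve
  ligand with a receptor in the population's repertoire. The headline
  size of a model is its ligand-node count (ligands with >= 1 cognate
  expressed receptor). Receptor complexes use OR semantics: any
  expressed component supports the edge.
* **Differential-correlation mapping** — each single cell is Pearson-
  correlated against mock-bulk (pseudobulk) profiles of reference
  states; coordinate `x = r(cell, A) - r(cell, B)` places the cell
  between states A and B.
* **A synthetic-data generator** — sparse UMI matrices with per-gene,
  per-cell-type detection probabilities (zero-truncated negative
  binomial counts, batch depth multipliers), rank-structured bulk
  profiles with a pinned anchor quantile, and partially sensitive
  proteome detection — so the whole pipeline is testable without any
  download.

The package bundles, as plain TSV fixtures, the source study's printed
working tables: microarray ligand calls for uninjured / 3 / 7 days
post-injury (DPI) nerve, single-cell detection tables for the 143
injured-nerve ligands across nerve states and cell types, cell-surface
proteomics lists for sensory (DRG) and sympathetic (SCG) neurons,
receptor repertoires for four neuron populations, and the four
predicted interaction blocks, from which the default ligand-receptor
database is reconstructed.

## Worked example

```python
import nervenet as nn
from nervenet import fixtures

# the 143-ligand injured-nerve panel and its detection fractions
table = fixtures.load_ligand_detection("injured")
sets = nn.expressed_sets(table, threshold=2.0)
print(len(sets["any"]), len(sets["schwann"]))     # 143 74

# predict the injured-nerve -> sympathetic-neuron interaction model
net = nn.predict_interactions(
    fixtures.injured_ligand_panel(),
    nn.GeneSet("SCGs", fixtures.receptor_call_sets()["scg"].members),
    nn.default_db())
net = nn.mark_protein_evidence(net, fixtures.ms_receptor_sets()["scg"])
net = nn.annotate_ligand_sources(net, table, fixtures.INJURED_COMPARE_TYPES)
print(len(net.ligand_nodes), len(net))            # 122 287
print(net.ligand_sources["BTC"]["source"])        # ('schwann',)
```

The first two numbers say: of the 143 ligands detectably expressed in
the injured nerve, 74 are expressed by Schwann cells (>= 2% of Schwann
cells have at least one transcript). The model predicts 122 nerve
ligands with at least one cognate receptor on sympathetic neurons, via
287 ligand-receptor edges; betacellulin (BTC), for example, reaches
EGFR/ERBB2 and is made predominantly by Schwann cells. Of the 146
receptors in the model, 22 also carry cell-surface protein evidence.

The same operations are available from a CLI
(`nervenet simulate | abundance | call-ligands-bulk | call-receptors |
predict-interactions | compare-networks | diffcorr | venn | run`); see
`nervenet --help`.

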