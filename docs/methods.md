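# Methods

This note documents the models and conventions `nervenet` implements,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the numerical choices made where the underlying
procedure was ambiguous.

## Detection fractions and the 2% rule

The single-cell statistic everything downstream consumes is the
*detection fraction*: the percentage of cells of a cell type with at
least one UMI for a gene, computed on the raw filtered count matrix.
Detection is `count >= 1` — droplet UMI data are too sparse for a
higher per-cell cutoff to be meaningful, and normalised values are
deliberately not used for detection (normalisation rescales magnitudes,
not the zero/non-zero structure). A gene is *expressed* in a cell type
when its fraction is at or above a threshold, default 2% (inclusive:
published tables define below-threshold as strictly `< 2%`).

Pooled compartments (e.g. all mesenchymal cells) use the cell-count
weighted fraction over member types — identical to recomputing on the
merged cells — never the mean of member fractions.

Fold changes between conditions divide raw (unrounded, sub-threshold
included) fractions. A zero denominator with a positive numerator
yields a lower bound, displayed `">x"`; both zero is undefined.
Regression tests against the published fold-change columns use a
rounding-interval oracle: printed tables carry fractions rounded to
0.1, so a printed ratio is accepted when it lies in the interval of
ratios attainable from fractions within +/-0.05 of the stored values.
A fixed absolute tolerance would be wrong for small denominators, where
rounding alone moves the ratio by far more than it does elsewhere.

### Highest-cell-type assignment and ties

A ligand's source cell type is the one with the strictly greatest
detection fraction among the compared types (aggregate "combined"
columns are excluded from the comparison). Exact ties are surfaced —
the ligand is assigned to all tied types and flagged — rather than
silently broken; spot checks of the transcribed tables (Bmp1, Mif,
Rtn4) are consistent with a strict maximum.

Two ligands in the injured-nerve table tie only at the table's printed
precision (Pomc: endoneurial 3.3 vs endothelial 3.3; Cxcl2:
endoneurial 22.9 vs immune 22.9). The table's own per-row compartment
annotation records how the unrounded data resolved each of them, and
`fixtures.printed_tie_resolution()` turns that annotation into an
explicit tie-resolution map. With it, the mesenchymal-highest and
endoneurial-highest counts recompute to 71 and 39; without it, a strict
maximum yields 70/38 and a ties-inclusive count 72/40. This is the only
place the footnote annotation feeds a computation, and it is opt-in.

## Anchor-gene thresholding of bulk profiles

Bulk ligand calling uses an anchor gene whose expression defines the
threshold; panel genes at or above it are expressed (inclusive, so the
anchor calls itself expressed). The anchor's percentile is reported as
the fraction of all profiled genes at or below its value; because
"expressed in the top X%" phrasing is ambiguous about ties, a
strictly-below convention is exposed as an option. How ties at the
anchor value were handled in the original microarray analysis is not
documented; with continuous intensities they are unlikely, and the
inclusive rule is used throughout.

## Receptor calling

Three modes:

* **anchor** (primary): among proteomics-detected receptors present in
  the expression profile, the minimum-expressed one sets the cutoff;
  panel genes `>= cutoff` are called, ties included, and the anchor is
  always a member of its own call. Exact ties between candidate
  anchors break lexicographically (deterministic; with continuous
  expression values this is a measure-zero event).
* **percentile**: panel genes within the top `p`% of all profiled
  genes; the cutoff is the `(100 - p)`-quantile taken at an observed
  value from above (`interpolation="higher"`), so exactly the top
  share of genes passes and ties at the cutoff are included. Whether a
  published "top 87%" meant at-or-above or strictly-above its quantile
  is not stated; at-or-above is adopted.
* **fpkm**: strictly greater than an absolute FPKM cutoff (default 1),
  per the convention for RNA-seq profiles.

Proteomics false-discovery handling is a property of the input protein
lists, not recomputed here: detected-protein lists are consumed as
gene-symbol sets.

## The ligand-receptor database and interaction prediction

The bundled default database is reconstructed as the union of all
ligand-receptor pairs across the four published target-population
interaction blocks, each pair tagged with the block(s) it appeared in.
The original curated database is not public; any user TSV with
`ligand`/`receptor` columns can be substituted, and counts will then
reflect that database's curation.

Prediction is a filtered cross join: edge `(ligand, receptor)` exists
iff the pair is in the database, the ligand is in the nerve panel, and
the receptor is in the target's call. Receptor complexes are
annotation only (OR semantics): the published blocks list each complex
component as its own row (e.g. CLCF1 -> CNTFR, IL6ST and LIFR
separately), so requiring all components (AND) would contradict the
printed models. A model's headline count is its number of ligand
nodes, not edges — the published node counts (122 sympathetic, 125
sensory) are ligand counts, and exports order edges lexicographically
so outputs are diffable.

Gene symbols are matched case-insensitively with uppercase canonical
form (rodent `Ccl11` vs database `CCL11`); slash-joined aliases
(`Ngfr/p75NTR`) match on their first token.

## Differential correlation

Mock-bulk (pseudobulk) profiles are per-gene arithmetic means over a
dataset's cells, computed on library-size-normalised (scaled to the
median library size), log1p-transformed expression by default; the
normalisation can be disabled, and a gene-subset option exists because
variable-gene subsetting is common in neighbouring analyses. The
"differential correlation" coordinate is the *difference* of two
Pearson coefficients, `x = r(cell, A) - r(cell, B)` — a ratio is the
conceivable alternative, but difference gives axes symmetric about 0,
matching how such maps are drawn, and is bounded in [-2, 2]. Cells
with zero variance over the gene scope have undefined r and are
excluded and reported, not imputed. Which gene set and transformation
the original map used is not stated; all shared genes with the default
normalisation is the package's choice.

## Synthetic data

`simulate_dge` draws, independently per cell, a Bernoulli detection
event with the configured per-gene, per-cell-type probability, then a
zero-truncated negative binomial count (mean `mu` scaled by the cell's
batch depth multiplier, overdispersion `alpha`, variance
`mu + alpha mu^2`) for detected entries. Because the pipeline's
detection rule is binary, only the zero/non-zero structure must be
faithful; the NB tail exists to exercise I/O and normalisation
realistically. Defaults: `mu = 2`, `alpha = 0.8`, one batch. The
nerve-like configuration (`nerve_sim_config`) uses the transcribed
injured-nerve detection fractions as generating probabilities over six
cell types totalling 5395 cells, the published size of the combined
injured dataset; the per-type split is not published, so a split
consistent with the table's pooled mesenchymal fractions
(epineurial:endoneurial near 2.9:1) is used.

`simulate_bulk` draws log-normal expression (log-mean 3, log-sd 1) for
the named genes plus synthetic background genes, then pins the anchor
gene so its at-or-below quantile equals the requested value to within
1/n. `simulate_proteome` detects each true receptor with probability
`sensitivity` and each decoy with probability `fdr_like`.

The generator does **not** emulate ambient RNA, doublets, myelin-debris
contamination, gene-gene correlation, or batch effects beyond depth
scaling. Passing tests on simulated data therefore demonstrate
estimator correctness (detection fractions converge to generating
probabilities; anchor percentiles are recovered; population identity is
recoverable by differential correlation), not robustness to those
artefacts — the transcribed-table regressions carry the realism.

## Fixtures and their quirks

The bundled tables are programmatic transcriptions of the source
study's printed working tables. Below-threshold cells are stored as an
explicit `BT` token (with the raw parenthetical value where the source
prints one) and load as a mask, never as silent zeros. Two published
internal inconsistencies are preserved as printed rather than patched:
the motor-neuron receptor column disagrees with the motor-neuron
interaction block and with the printed intersect columns, and one
population's receptor list omits its own anchor gene while the other
includes it. Consequently the recomputed motor-neuron ligand-node
count (121) and receptor intersections (274 / 256) differ slightly
from the printed 123 / 272 / 258; the sympathetic, sensory and retinal
models recompute exactly.

## Problem sizes

The test suite and the acceptance script run entirely at desk scale:
fixture set algebra is instantaneous; simulation checks use 5,000 to
10,000 cells for binomial parameter recovery, 10,000 genes for anchor
quantile recovery, and 450 cells x 2,000 genes for the
differential-correlation recovery check. These sizes give binomial
99%-interval widths well inside the asserted tolerances (e.g. at
n = 10,000 and p = 0.5 the 99% interval spans about +/-1.3 percentage
points, inside the 1.5-point recovery bound).

## Known limitations

* The default database inherits the published models' manual curation;
  ligand-node counts under a different database are expected to differ.
* Receptor-complex OR semantics may over-predict for obligate
  coreceptors; the complex annotation field exists for stricter
  user-side filtering.
* Detection fractions ignore sequencing-depth differences between cell
  types; with very shallow types the 2% rule undercalls. The
  batch-depth multiplier in the simulator exists to probe exactly this.
* Bulk anchor thresholding depends on the anchor's biological
  stability across conditions; the percentile report is the guard rail.
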