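# plaspace

Spatial interaction mapping of PD-1/PD-L1 *in situ* proximity-ligation
(isPLA) signals in multiplexed tissue images.

PD-1 (on T cells) and PD-L1 (on tumour and myeloid cells) suppress
anti-tumour immunity when they engage; immunotherapy aims to block that
engagement. Conventional staining shows where the two molecules are
*expressed* — an isPLA signal is produced only when they sit within
~40 nm, i.e. where they are plausibly *interacting*. `plaspace` is an
analysis pipeline for per-cell tables exported from segmented multiplexed
images (centroids, nuclear area, median marker and isPLA intensities): it
phenotypes cells, reconstructs tumour/stroma geometry, and quantifies how
PD-1/PD-L1 interactions organise around the tumour boundary in patients
with different therapy responses (RECIST groups CR/PR/SD/PD). It is aimed
at spatial-biology analysts working with PhenoCycler/Opal-style panels
plus an isPLA channel.

Because patient imaging data of this kind is rarely depositable, the
package ships a fully ground-truthed synthetic-tissue generator
(`plaspace.synthetic`) that emulates the geometry the analysis assumes —
tumour nests, boundary-concentrated isPLA positivity, a peritumoural
macrophage *barrier* band in non-responder-like tissue and B/T-cell
aggregates (TLS-like) in responder-like tissue — so every stage is
testable end to end.

## Methods at a glance

- **QC + phenotyping.** Nuclei outside 10–220 µm² or with dim DAPI are
  dropped. Six markers (PanCK, CD20, CD3e, CD8, CD68, isPLA) plus nuclear
  area are transformed `x ↦ asinh(x/150)`, z-scored within columns then
  across rows, clustered by Leiden (resolution 2) on a 30-NN graph, and
  clusters are annotated into five types by their dominant canonical
  marker (PanCK→Tumour, CD20→B, CD68→Macrophage, CD8→CD8 T, CD3e→CD3 T).
- **Tumour mask + signed distances.** Tumour-cell point density is
  rastered (20 µm pitch), smoothed, thresholded and contoured into nest
  polygons; nests ≤ 100 µm² are discarded. Each cell gets a signed
  Euclidean distance *d* to the nearest nest boundary (negative inside).
- **isPLA calling.** One global intensity threshold for the whole cohort
  (fixed, or Otsu on pooled log-intensities); positivity fractions are
  tabulated per sample × region × cell type.
- **Proximity density.** For a cell-type pair within one sample,
  `pairs within 20 µm / cells in the pair`.
- **Cellular neighbourhoods (CN).** Each cell's window (itself + 10
  nearest neighbours) becomes a cell-type frequency vector; pooled windows
  are KMeans-clustered, with K chosen by the Kneedle elbow of the inertia
  curve over K = 3…15. Two variants: plain cell types, and cell types ×
  isPLA state.
- **Spatial contexts (SC).** Over 100-neighbour windows, the minimal
  abundance-ordered CN combination exceeding 90% defines each cell's SC;
  per response group, SC maps are directed graphs over combinations above
  0.001% of cells, with edges to one-larger supersets. Interfaces between
  three chosen CNs are shown by projecting windows with ≥ 99.95% mass on
  the triple into barycentric coordinates.
- **Group statistics.** Cell-type percentages, Kruskal–Wallis tests of
  positivity fractions across response groups (Benjamini–Hochberg over the
  region × cell-type family; SD excluded from headline contrasts), and a
  *barrier coverage* score: the fraction of tumour-boundary arc length
  with ≥ m isPLA⁺ macrophages within d µm.

## Worked example

Run the numbered analysis scripts in order (or call
`plaspace.run_pipeline` for the same thing in one step):

```bash
python analysis/01_simulate_cohort.py        # 14 samples: CR=2 PR=4 SD=2 PD=6
python analysis/02_phenotype_cells.py
python analysis/03_tumour_regions.py
python analysis/04_ispla_scoring.py
python analysis/05_cellular_neighbourhoods.py
python analysis/06_spatial_contexts.py
python analysis/07_response_group_stats.py
```

With the default seed the chain prints, among other things:

```
simulated 14 samples, 67236 cells (seed 0) -> results/cohort
mean agreement with ground-truth types: 0.999
cohort-wide isPLA threshold (Otsu): 25.68
plain: selected K = 7
  CN4: Macrophage 79%
  CN3: Tumour 55% / Macrophage 24%
Kruskal-Wallis across response groups: 10 features, 0 significant after correction
mean barrier coverage by group:
CR    0.017
PD    0.518
PR    0.019
SD    0.566
tumour-macrophage SC interface fraction by group:
CR 0.031   PR 0.022   SD 0.119   PD 0.157
```

Reading this: phenotyping recovers the planted cell types almost
perfectly; the CN step finds a macrophage-dominated neighbourhood and a
mixed macrophage–tumour neighbourhood; non-responder-like samples (SD/PD,
simulated with a macrophage barrier band) show ~30× higher barrier
coverage and ~5× higher tumour–macrophage SC interface prevalence than
responder-like samples (CR/PR, simulated with TLS-like aggregates), while
no single positivity fraction is significant after multiple-testing
correction at n = 14 — the group contrast lives in the spatial
organisation, not in any one marginal fraction.

## Layout

```
src/plaspace/        library: one module per pipeline stage
analysis/            numbered narrative drivers over the library
tests/               pytest suite (unit, property and acceptance tests)
scripts/acceptance.py
docs/methods.md      model, parameters, design choices, limitations
```
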