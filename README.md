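# topotag

Linking tissue architecture to gene expression in spatial transcriptomics.

Spatial transcriptomics (ST) assays such as 10x Visium measure gene
expression at thousands of barcoded spots across a tissue section, each
paired with a patch of the H&E histology image. The cells in a patch form a
2-D point pattern whose *topology* — how they clump into clusters and
arrange into rings — carries biological information that plain cell counts
miss. `topotag` quantifies that topology with persistent homology and asks,
gene by gene, whether expression tracks it:

1. **Image topology features (ITFs).** For each spot, the cell centroids in
   its 350×350 px patch are filtered through a Vietoris–Rips complex. H0
   bars (connected components, i.e. cell clusters) and H1 bars (loops, i.e.
   cell rings) are vectorized as persistence images on a 35×20
   birth×persistence grid: 700 features per homology dimension, 1400 per
   spot.
2. **Topology-associated genes (TAGs).** Genes with ≤ 25% zero reads are
   ranked by log1p-count variance and the top 150 retained. The genes×ITFs
   Pearson matrix `r[g,f] = corr(log(1+x_g), log(1+itf_f))` across spots is
   clustered on both axes (k-means, elbow-selected k, baseline 10), and each
   ITF cluster is matched to its most-similar TAG cluster by block-mean
   correlation.
3. **Enrichment.** Each TAG cluster is tested against GMT gene sets with the
   upper-tail hypergeometric probability P(X ≥ k), Holm-adjusted within
   cluster, significant at α = 0.05.
4. **Prediction.** Per-gene regressors (gradient-boosted trees) predict
   expression of selected genes from selected ITFs under leave-one-out
   cross-validation over spots, scored by the Pearson correlation between
   held-out predictions and truth.

Because public slides carry no topological ground truth, the package ships a
synthetic-slide generator: each spot draws a point pattern from a mixture
(uniform, clustered, 1–3 planted rings), and a chosen subset of genes draws
negative-binomial counts whose log-mean is coupled to the spot's ring count
or nearest-neighbor spacing. Every downstream stage is validated by how well
it recovers that planted structure.

The package is aimed at computational-biology researchers prototyping
topology–expression analyses and at anyone needing a compact, dependency-
light persistent-homology implementation for 2-D point clouds with an exact
reference oracle.

## Worked example

Run the numbered analysis scripts in order (or equivalently
`topotag run-all --seed 1 --out results/run`):

```bash
python analysis/01_simulate_slide.py
python analysis/02_compute_itfs.py
python analysis/03_tag_correlation.py
python analysis/04_enrichment.py
python analysis/05_prediction.py
```

Script 01 simulates the study slide (400 spots, 300 genes, 30 ring-coupled
at β = 1.5) and prints the realized mixture:

```
slide: 400 spots, 300 genes (30 ring-coupled)
pattern mixture realized:
             poisson: 129 spots
              ring:1: 81 spots
      matern_cluster: 81 spots
              ring:2: 62 spots
              ring:3: 47 spots
```

Script 02 reports `400 spots x 1400 ITFs (623 with nonzero variance) in
7.5s (19 ms/spot)` — empty persistence-image cells are constant zero and are
dropped before correlation. Script 03 then selects the genes and clusters
the correlation matrix:

```
selected 150 genes; correlation matrix 150 genes x 623 ITFs (777 constant ITFs dropped)
elbow chose 3 TAG clusters and 4 ITF clusters
  ITF cluster 1 is most similar to TAG cluster 1 (mean PCC +0.193)
```

and script 04 shows the planted gene set surfacing in exactly the TAG
cluster that captured the ring-coupled genes:

```
TAG cluster 1 (13 genes): top term PLANTED:coupled (k=13/13, Holm p=3.58e-19, significant)
TAG cluster 2 (73 genes): top term DECOY:019 (Holm p=0.633)
```

Holm p ≈ 4e-19 says a 13/13 overlap between that cluster and the planted
term is essentially impossible under random gene assignment; the decoy terms
stay non-significant. Script 05 predicts the 19 most ITF-correlated genes
from the 12 most informative ITFs under LOOCV (150 spots) and compares two
boosting learners:

```
held-out PCC (lightgbm): min -0.105, median 0.728, max 0.793
mean PCC difference lightgbm - xgboost: +0.0027 (paired t-test p = 0.774)
```

Strongly ring-coupled genes predict well from topology alone; the gene at
−0.105 is one whose ITF correlation was spurious, and the two learners are
statistically indistinguishable. Per-gene values land in
`results/prediction.tsv`.

As a library:

```python
import numpy as np
from topotag.persistence import FiltrationSpec, h0_diagram, h1_diagram

square = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], float)
print(h0_diagram(square).deaths)                      # [1. 1. 1.]
print(h1_diagram(square, FiltrationSpec(2.0)).bars)   # [[1. 1.41421356]]
```

The four corners merge along three MST edges of length 1, and the square's
loop is born when the last side appears (scale 1) and filled by the
diagonal triangles (scale √2).

## Layout

- `src/topotag/` — the library: `stio` (formats), `synthetic` (slide
  generator), `imaging` (patches, nucleus detection), `persistence`
  (Rips H0/H1 from scratch plus the naive oracle), `vectorize`
  (persistence images), `tag_analysis`, `enrichment`, `prediction`,
  `pipeline`/`cli` (orchestration, manifest, `topotag` command).
- `analysis/` — the numbered narrative drivers shown above.
- `docs/methods.md` — models, parameter choices, and limitations.
- `tests/` — unit, property, and acceptance suites.
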