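# panprobio

Comparative genomics and gut-microbiome association for traditional
probiotic species — *Lactobacillus*, *Lactococcus*, *Streptococcus*,
*Bifidobacterium*, *Bacillus* and relatives — built for studies that ask two
linked questions: **how diverse and complementary are the genomes of these
species**, and **what role do the species play in case/control human gut
cohorts**?

The package implements the full computational arc as a reusable, tested
library, exercisable end-to-end on seeded synthetic data with planted ground
truth (no downloads required):

* **Genome QC** (`panprobio.genome_qc`) — the HMP five high-quality draft
  criteria (≥98% of the assembly in contigs >500 bp; scaffold and contig
  N50 >20 kb; mean contig length >10 kb; >90% of a reference core-gene set),
  a CheckM-style gate (completeness >95%, contamination <5%) and an
  iterative intra-species purity filter requiring pairwise ANI >93%.
* **ANI / AAI** (`panprobio.identity`) — fragment-based one-way identity
  (k-mer seeding, ungapped placement, fragments accepted at ≥30% identity
  over ≥70% coverage), averaged over both directions:
  `ANI(a,b) = (id(a→b) + id(b→a)) / 2`. Species-level AAI via
  reciprocal-best-hit core proteins, intra-species AAI dispersion, and
  single-linkage clustering at an AAI cutoff.
* **Pan-genome** (`panprobio.pangenome`) — greedy protein-family clustering
  (95% identity over 90% of the shorter sequence), core / accessory /
  strain-specific partition, rarefaction curves, and the **pan-genome
  index**: `PI = pan-genome family count / mean per-genome family count`,
  with openness levels A (PI ≤ 1.5), B (1.5 < PI ≤ 3) and C (PI > 3), plus
  OLS regression of PI on its candidate drivers.
* **Annotation filtering** (`panprobio.function_filter`) — database-specific
  hit acceptance (KEGG: query coverage ≥50%; ARDB: both coverages ≥40% and
  identity above the per-gene recommended cutoff; VFDB/CAZy: coverage ≥50%
  and identity ≥60%), species-pairwise feature-enrichment counts
  (FDR-controlled rank-sum tests) and the friendly/unfriendly risk-gene
  burden comparison.
* **Module complementarity** (`panprobio.complementarity`) — KEGG-module
  integrity `|KOs ∩ required| / |required|`, and for every cross-species
  strain pair the improvement ratio
  `(T(A∪B) − max(T(A),T(B))) / max(T(A),T(B))` where `T` sums integrity
  over modules; species-pair means, ranks, terciles and the
  complementarity–ANI correlation.
* **Microbiome association** (`panprobio.microbiome`) — MetaPhlAn2-style
  profile parsing, case/control enrichment (two-sided Wilcoxon rank-sum,
  Benjamini–Hochberg q < 0.05), co-abundance networks over the enriched
  species (Pearson over all samples pooled; edge iff p < 0.05 and cc > 0.4
  or cc < −0.1; width/abundance-decade binning, top-10 degree/abundance
  flags, GraphML export) and mapping-ratio group comparisons.
* **Synthetic data** (`panprobio.simulate`) — seeded generators for every
  input above, each returning a `SimTruth` record of what was planted.

Shared statistical primitives (exact small-sample rank-sum, BH-FDR, Pearson
with t-test p) live in `panprobio.stats`.

## Worked example

`examples/` contains one narrative script per capability. For instance
`python examples/02_ani_pangenome.py` prints:

```
planted identity 95.010% | fragment ANI 95.010%  (bidirectional mean; +-0.5 expected)
114 gene families from 410 genes: 40 core, 59 accessory, 15 specific
PI = pan / mean-per-genome = 114 / 68.3 = 1.668 (openness level B; planted PI 1.668)
rarefaction (k, mean pan, mean core):
  k=1: pan 68.7, core 68.7
  k=3: pan 99.2, core 43.6
  k=6: pan 114.0, core 40.0
```

The first line shows the fragment-ANI engine recovering a planted 5%
nucleotide divergence exactly; the rest shows 95%/90% clustering of a
6-genome synthetic species recovering the planted family structure, the
resulting core/accessory/specific partition, and a pan-genome index of
1.668 — a "half-open" (level B) repertoire — identical to the closed-form
PI of the planted gene sets. `examples/04_enrichment_network.py` runs the
case/control arm: 20 planted 4-fold differential species and a 5-species
correlated block are recovered as 21 q<0.05 calls and a network whose 10
planted edges are all found.

A thin CLI mirrors the library (`panprobio qc|identity|pangenome|
annotate-filter|complement|mwas|simulate ...`); run `panprobio --help`.

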