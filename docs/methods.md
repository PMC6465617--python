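# Methods

This note documents the models, procedures, parameter choices and known
limitations of panprobio, in the order a study would apply them.

## Genome quality control

Three gates are applied in sequence; all inequalities are implemented
exactly as worded, so boundary behaviour is deliberate and tested.

1. **HMP five draft criteria**: fraction of the assembly in contigs >500 bp
   ≥ 0.98 (inclusive, "98% … must be present"); scaffold N50 > 20,000 bp,
   contig N50 > 20,000 bp, mean contig length > 10,000 bp and reference
   core-gene recovery > 0.90 (all strict, "more than"). N50 is the smallest
   length L such that contigs of length ≥ L cover at least half the total.
   The contig-fraction denominator is the total assembly length. The
   core-gene reference set is a configurable input; the package does not
   ship a core-gene catalogue.
2. **Completeness/contamination gate**: completeness > 95% and
   contamination < 5%, both strict. The values are consumed as numbers
   (CheckM output); CheckM itself is out of scope.
3. **Intra-species ANI purity**: every within-species genome pair must have
   ANI strictly above 93%. When pairs fail, removal is iterative: at each
   step the genome with the lowest mean intra-species ANI (ties broken by
   name) is dropped and the rule is re-checked. This order removes the most
   "mis-distributed" genome first; the retained set is a fixed point
   (re-filtering removes nothing). The removal order is a design choice —
   any rule satisfying the pairwise constraint would be admissible — and
   the log records each removal with its failing pairs.

Isolation sources map to a friendliness class through a configurable
keyword table (foods and the healthy human gut → friendly; clinical
specimens, soil, blood, saliva, silage → unfriendly; unmatched → unknown).
Unfriendly keywords take precedence on conflict, the conservative reading
for a safety screen.

## Fragment-based ANI and AAI

Identity between two sequence sets is computed without external aligners.
The query is cut into consecutive fragments (defaults: 1,020 bp nucleotide,
300 aa protein — the conventional ANI fragment recipe); each fragment is
placed on the reference by k-mer seed voting (k = 11 nt / 4 aa, seeds
sampled every 4 / 2 positions) for the best-supported (sequence, diagonal)
pair, ties broken by smallest index for determinism, then scored by
ungapped comparison over the aligned columns. Fragments are accepted at
≥30% identity over ≥70% of the fragment; the one-way identity is the mean
identity of accepted fragments, and **no accepted fragment yields a
no-alignment flag, never 0**. The pairwise value is the mean of the two
one-way values (symmetric by construction); if only one direction aligns
that value is used.

The ungapped placement assumes substitution-dominated divergence, which the
divergence generator produces by default; indel-rich pairs would fragment
the diagonals and bias identity downward. On substitution-only pairs the
estimator recovers the realized identity to well under ±0.5 over
divergences 1–7%.

Species-level AAI between two species is the mean identity over
reciprocal-best-hit pairs of their core proteins. Hits require the local
alignment to cover ≥50% of the shorter protein — unrelated proteins
otherwise produce spuriously perfect micro-alignments — and best hits
maximise matched residues. Intra-species AAI dispersion is the population
standard deviation of all within-species strain-pair AAI values (0 for a
single pair). Species clusters at an AAI cutoff are single-linkage
connected components of the ≥-cutoff graph; cluster count is non-increasing
as the cutoff drops.

## Pan-genome and the pan-genome index

Gene families are built by greedy incremental clustering, longest sequence
first (ties broken lexicographically): a sequence joins the first existing
family, in founding order, whose representative it matches at ≥95% identity
over ≥90% of the shorter sequence, else founds a new family. Identity is
matches over aligned columns of a Smith–Waterman local alignment (match +1,
mismatch −1, gap open −3, extend −1); coverage is aligned residues of the
shorter sequence over its length. A shared-5-mer prefilter skips
representatives that cannot match; the result is provably identical to the
unfiltered greedy loop on the tested regimes, and the prefilter can be
disabled.

Families present in all genomes are core, in exactly one strain-specific,
otherwise accessory. Rarefaction curves average the running union (pan) and
intersection (core) over random genome orderings (default 100 permutations,
seeded).

The pan-genome index is

    PI = pan-genome family count / mean per-genome family count,

with openness levels A (PI ≤ 1.5), B (1.5 < PI ≤ 3) and C (PI > 3). The
orientation matters: the ratio is ≥1 for non-empty genomes and grows with
the accessory repertoire, which is what the published per-species values
and the "open pan-genome" semantics require; the inverse ratio (mean/pan,
≤1) is sometimes stated verbally but contradicts those values, so this
package fixes the pan/mean orientation and documents it here. The
per-genome denominator counts distinct families by default; a `genes` mode
counts raw genes (in-paralogs separately) for comparison.

PI correlates (isolation-source count, genome count, intra-species AAI SD)
are assessed by per-factor Pearson correlation/R² and a combined ordinary
least squares fit with the overall F-test p-value; constant factors are
flagged and excluded.

## Annotation filtering and functional comparisons

Hit tables are BLAST-outfmt-6-like with a database column. Acceptance
rules: KEGG — query coverage (align/query length) ≥50%; ARDB — query and
subject coverage ≥40% and identity strictly above the per-gene recommended
threshold (records lacking the threshold are rejected with a warning);
VFDB and CAZy — query coverage ≥50% and identity ≥60%. One best hit is
kept per query per database (highest identity, ties by subject id) to
avoid double-counting features. Acceptance is monotone in identity and
coverage.

Feature enrichment compares, for each feature and species pair, the two
species' per-strain counts with an unpaired rank-sum test; q-values are
BH-corrected jointly across all tests of the analysis (one figure panel),
with a per-feature option. A cell counts how many other species are
significantly weaker (q < 0.05 with the focal species holding the higher
mean rank), so cells are bounded by the species count minus one and two
species can never count each other for the same feature.

Risk burden sums accepted virulence (VFDB) and resistance (ARDB) genes per
genome and compares friendly- vs unfriendly-source strains with a two-sided
rank-sum test, starred at p < 0.05 / p < 0.01.

## Module integrity and complementarity

Module integrity of genome G for module m is |KOs(G) ∩ required(m)| /
|required(m)|; required KO sets come from the module-definition input as
flat sets — KEGG's boolean module logic (AND/OR complexes) is deliberately
not parsed. The genome total T(G) sums integrity over modules. For a pair,
the merged total is computed on the KO-set union, and

    improvement ratio = (T(A∪B) − max(T(A), T(B))) / max(T(A), T(B)).

Integrity is monotone under union, so the numerator is never negative. The
max baseline (gain over the better single genome) is the default because it
is conservative; a mean-of-both baseline is available as an option. Under
the max baseline a zero denominator implies a zero numerator, so the
infinite-ratio flag exists only for other baselines; pairs flagged infinite
are excluded from species-pair means and reported separately.

Ratios are computed for all unordered cross-species strain pairs
(C(N,2) − Σ C(n_s,2) pairs) and summarised per species pair: mean ratio,
descending rank (ties broken by pair name) and rank terciles
(top/middle/bottom thirds, upper thirds rounded up). The
complementarity–ANI relation is a Pearson correlation of species-pair mean
ratios against species-pair ANI.

## Case/control enrichment and co-abundance networks

Species rows of a MetaPhlAn2-merged table (names containing `s__` without a
strain-level `t__` suffix) form a samples × species relative-abundance
table with case/control labels. Each species present in any sample gets a
two-sided unpaired rank-sum test between groups (all-zero species are
skipped); q-values are BH across tested species and a species is called
enriched in the group with the **higher mean rank** when q < 0.05 — mean
rank rather than mean abundance, for robustness to outliers.

The co-abundance network takes only the enriched species as nodes and
computes Pearson correlations over **all samples pooled** (health status
ignored, as the analysis defines). An edge requires p < 0.05 (raw — edge
p-values are intentionally not multiplicity-corrected; only node selection
uses q-values) and cc > 0.4 or cc < −0.1. Edge widths bin |cc| (thick
≥0.7, medium [0.4, 0.7), thin (0.1, 0.4) — reachable only by negative
edges given the positive cutoff); node sizes bin mean relative abundance by
decade (1/10 … 1/10^6, then <1/10^6). Degree and abundance top-10 flags use
stable sorts with lexicographic tie-breaks. Constant species produce no
edges and are noted. Pearson on relative abundances is methodologically
fragile on compositional data (no CLR or similar transform is applied);
the package reproduces the stated procedure and leaves compositional
corrections to the caller.

Mapping ratios (mapped/total reads per sample) are compared between groups
per target with rank-sum tests, BH-corrected across targets.

### Statistical primitives

The rank-sum test enumerates the exact null when both samples have ≤12
observations and the pooled data are tie-free (the regime where the normal
approximation is weakest and enumeration is cheap), otherwise uses the
tie- and continuity-corrected normal approximation; with all observations
identical it returns p = 1. BH-FDR is the standard step-up with enforced
monotonicity (q ≥ p elementwise). Pearson p-values use the t transform with
n−2 degrees of freedom; constant inputs return NaN rather than raising.
All tests are two-sided, with direction (higher mean rank) extracted
separately.

## Synthetic data generators

All generators are pure functions of (parameters, seed) — the same seed
reproduces byte-identical output — and return a `SimTruth` record; tests
and the acceptance script validate against the recorded plant, never by
re-deriving truth from the generated files.

* **Pan-genome** (`sim_pangenome`): every genome carries all core families;
  each accessory family is carried independently with the accessory rate.
  Family representatives are random proteins (80–160 aa) screened to share
  essentially no 6-mers, so between-family identity sits far below the 95%
  clustering threshold; per-genome copies substitute ≤1% of sites (0.5%
  rate, capped), staying far above it. Clustering at 95%/90% therefore
  recovers the planted partition exactly, and the planted PI equals the
  closed-form pan/mean of the planted sets. Not modelled: phylogenetic
  gain/loss structure, paralogy, partial genes.
* **Divergence pairs** (`sim_divergence_pair`): substitutions at a per-site
  rate on a random nucleotide sequence, no indels, with the realized
  substitution count recorded — the oracle for ANI recovery.
* **Module systems and KO pairs** (`sim_modules`, `sim_ko_pair`): module
  definitions with even, KO-disjoint required sets. With b modules fully
  present in both genomes and c modules split into disjoint halves, the
  improvement ratio is exactly c/(2b+c); the generator picks the achievable
  (b, c) closest to the target and records the realized ratio, so recovery
  checks are exact.
* **Abundance tables** (`sim_abundance`): log-normal abundances (natural-log
  scale σ = 1.5, spanning the orders of magnitude real species profiles
  do), renormalized per sample to 100% so all effects are compositional.
  Planted differential species (half case-, half control-enriched) are
  raised `effect_fold` (default 4) in their group, and draw their log-means
  from the sub-dominant range (N(−2, 1)): real MWAS markers are typically
  low-abundance, and a planted fold-change on a dominant taxon would shift
  per-sample totals and compositionally flip null species — a property of
  closure, not of the analysis under test. The correlated block shares a
  latent log factor among case-enriched species; its loading is set by
  inverting the lognormal correlation attenuation formula
  `cc = (e^{ρσ²} − 1)/(e^{σ²} − 1)` at the target cc, so the *linear-scale*
  Pearson target (default 0.8) is met despite the log-normal tails. With
  200 samples the planted directions and block edges are recovered with
  ≥95% sensitivity and ≲1% spurious edges; the σ = 1.5 choice also keeps
  the group effect itself from inducing above-cutoff correlation between
  co-enriched species. Not modelled: cohort batch effects, zero inflation,
  sequencing-depth variation — so passing tests demonstrate correctness of
  the statistics and thresholds, not robustness to those real-data
  features.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: identity checks use
30 kb sequences with 500 bp fragments, pan-genomes use 5–12 genomes with
tens to low hundreds of families, cohorts use 150 species × 200 samples,
and oracle-equivalence sweeps use ≤30 sequences or ≤12 observations where
brute-force enumeration is exact. These sizes make every expected value
computable by an independent oracle while exercising the same code paths a
full-scale study would use. Deterministic tie-breaks (lexicographic, or
first-encountered in a fixed order) are applied wherever a sort or argmax
could tie, so all outputs are order-independent and reproducible.

Published study counts (per-species retained genomes, per-cohort sample
sizes, per-species PI values) are shipped as input tables in
`panprobio.datasets`; derived quantities (90,543 cross-species pairs, 105
species pairs, 444 genomes, 1,815 samples) are always recomputed from them.

## Known limitations

* The fragment identity engine is ungapped within fragments; heavy indel
  divergence is out of its design envelope (and of the default generator).
* The greedy clustering is representative-based single-assignment, like the
  classic incremental clusterers it emulates; it does not split paralogs or
  build orthology graphs.
* Module logic is flat required-KO sets; modules defined with alternative
  complexes are approximated by whichever KO list the input provides.
* Network inference reproduces thresholded raw Pearson on relative
  abundances, with its known compositional caveats.
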