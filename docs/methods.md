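# Methods

## Overview

`predfit` analyses saturating transposon screens in predatory bacteria.
The measured objects are read-count tables: insertion sites (or mutants) ×
samples, where samples are paired input/output populations of a
competitive expansion, or binary sorted pools (attached/unattached;
input/bdelloplast).  The package estimates per-gene fitness, pool
enrichment scores, phenotype classes and image-based rounding fractions,
and ships a generator that produces all of these inputs with known ground
truth.

## Expansion fitness

For a mutant at input frequency `f1` and output frequency `f2` after the
population expanded `d`-fold,

    W = ln(f2·d/f1) / ln((1−f2)·d/(1−f1)).

Interpretation: the numerator is the mutant's realised log fold-change,
the denominator the rest of the population's; their ratio is the mutant's
relative (per-generation) fitness.  `W = 1` when `f2 = f1`; `W = 0` when
`f2 = 0` (dead-mutant convention, no pseudocount by default — an optional
flag substitutes one read for zero output counts instead).  The formula
can go slightly negative for mutants depleted beyond a `d`-fold absolute
decline; such values are floored at 0, consistent with the convention and
the `W ≥ 0` invariant.

Assumptions worth stating:

- **`d` is supplied, not estimated.**  It is the fold-expansion an
  output/input CFU ratio would measure.  `simulate.realized_expansion`
  makes the distinction explicit: when non-neutral lineages carry mass,
  the realised population expansion differs from the nominal per-neutral
  `d`.
- **W is relative to the bulk.**  The estimator is only the exact inverse
  of the generative growth model when the bulk is dominated by neutral
  lineages.  With ≥ 90 % of library mass neutral the residual bias is
  `ln(Σ f_j d^{W_j−1})/ln d` ≈ 0.01 at `d = 100`; a library where
  improved mutants hold appreciable mass biases every other estimate
  downward.  The default synthetic landscape is chosen to respect this
  regime (below).

Gene aggregation: within each biological replicate, the gene's W is the
input-read-weighted mean over its insertions (weights reflect measurement
precision; an unweighted mode is available); across replicates the
reported W is the unweighted mean and `sd` the sample standard deviation.
Essential calling: zero observed insertions in every replicate →
`essential_zero`; mean insertions per replicate < 1 → `putative_lt1`;
both the per-replicate mean and the pooled (union) insertion count are
reported because the two conventions disagree for sparsely covered genes.
Threshold bins use the screen's published cuts (defective < 0.1,
borderline 0.1–0.5, high > 2.0, improved > 3.0; the first four are a
partition, `high_total` reports the high/improved overlap).  Condition
concordance is Spearman's rho with average ranks, requiring ≥ 3 shared
genes.

## Pool enrichment scores

Both sorting assays reduce to `score = freq(selected)/freq(reference)`:
attached vs. unattached pools for attachment, bdelloplast band vs.
unsorted input for rounding.  Defective mutants score low; a mutant that
partitions like the bulk scores ≈ 1.  (The alternative orientation —
unattached over attached — would invert this reading and is inconsistent
with control values near 1; we use the value-consistent orientation.)
Zero reference frequencies are floored at half a read in the reference
pool and flagged; double zeros are NaN flagged `undefined`.  Replicates
are averaged (mean ± sample SD).  The *collective* control score is
computed on the summed counts of the intergenic-control mutants — pooling
before the ratio, not averaging per-control scores — and is reported
alongside the mutant scores; normalisation by it is optional and off by
default (published rounding controls sit near 1.2, implying unnormalised
reporting).  Classification uses cuts 0.5/0.3 (attachment) and 0.4/0.2
(rounding).

## Phenotyping

Survival `S = 100·CFU(infected)/CFU(uninfected)` (can exceed 100 if prey
grew).  Killing categories use strict boundaries: `S > 50` no_kill,
`S < 1` kills, otherwise intermediate — `S = 50` and `S = 1` are both
intermediate.  Class assignment walks the ordered stages attach → kill →
round → exit and returns the first deficient stage (I–IV).  `ND` at or
before the first determinable failure yields `unclassified`; `ND` after
the deciding stage is harmless (classes are routinely assigned with exit
untested).  A `+` downstream of a `−` is biologically inconsistent and is
flagged while still classifying at the first `−`.

Many-to-one comparisons: ordinary one-way ANOVA, then each group against
the control with family-wise error control.  The parametric path computes
exact Dunnett adjusted p-values as equicoordinate box probabilities of a
central multivariate *t* (correlation `λ_iλ_j`,
`λ_i = sqrt(n_i/(n_i+n_0))`, pooled-variance degrees of freedom); the
`scipy.stats.dunnett` implementation serves as an independent cross-check
in the tests, never as the implementation.  A max-|t| permutation test is
the distribution-free fallback.  Zero pooled variance (exact ties) gives
t = 0 and adjusted p = 1 by convention.  Null calibration (4 groups,
n = 4, 10,000 simulations) gives a family-wise error of ≈ 0.05.

## Imaging

Single-channel images are thresholded globally (Otsu), labelled with
8-connectivity, and filtered by minimum area (default 20 px; an optional
maximum area flags merged cells as `oversized`).  Eccentricity comes from
the eigenvalues of the region's second-central-moment matrix,
`e = sqrt(1 − λ_minor/λ_major)`: 0 for a circle, → 1 for a line
(collinear regions are pinned to 1 and flagged `degenerate`).  A cell is
"rounded" when `e < 0.75`; no published cutoff exists, so the threshold
is an exposed parameter and the published absolute rounded-percentages
(18 % infected vs 3 % uninfected) are treated as context, not as
reproduction targets.  Discretisation error shrinks with raster
resolution; rotation changes a region's measured e by ≤ 0.01.

## Synthetic-data generator

The generator states a world and keeps it fixed:

- **Genome**: uniform-base background with TA dinucleotides planted at
  per-position probability 0.04 (so TA density comfortably exceeds the
  1-per-50-bp floor and raising the enrichment at a fixed seed only adds
  planted sites).  Genes are non-overlapping, strand-annotated, 1-based
  inclusive.
- **Library**: insertions strictly at TA dinucleotides (mariner-family
  site preference), never inside essential genes, none within 60 bp of
  the genome ends (so junction reads never truncate); input frequencies
  are symmetric Dirichlet(α = 1) over insertions — maximally
  uninformative dispersion for a complex library.
- **Landscape** (for 200 genes): 10 essential, 174 neutral `W = 1`,
  8 defective `W ~ U[0, 0.5]`, 4 dead `W = 0`, 4 improved
  `W ~ U[1.2, 1.5]`.  This keeps ~94 % of library mass neutral — the
  regime in which the relative-fitness estimator is well calibrated (see
  above).  Improved mutants are kept mild because `W = 3` at `d = 100`
  implies a 10⁴-fold frequency gain, which a bounded frequency simplex
  cannot sustain for mutants with appreciable starting mass.
- **Expansion**: deterministic growth `d^{W}` per lineage, then exactly
  `depth` reads per sample drawn multinomially; replicates are
  independent draws.  Defaults mirror the screen's stated scale (three
  biological replicates; a saturating library of 90,000 insertions over
  3,584 genes at full scale; low-MOI expansion to ~99 % prey killing —
  the realised `d` per condition is unpublished, so `d` is a config
  input, 100 in the desk-scale world).
- **Sorting**: each cell of mutant *i* enters the attached pool with
  probability `p_i`; bdelloplast entry is `r_i(1−c) + c` with
  contamination `c` defaulting to 0.02 (density separation is imperfect;
  the background term carries non-rounding cells into the band
  uniformly).  Six biological replicates by default.  Intergenic controls
  receive the library mass-weighted mean probability — "controls behave
  like the bulk" — which is what anchors the collective control score
  near 1.
- **Reads**: transposon tag + genomic sequence starting at the
  insertion's TA on the recorded strand, with multiplicities exactly
  equal to the count table (TA is its own reverse complement, so both
  orientations collapse to one site).
- **Images**: ellipses rendered with Gaussian blur and additive Gaussian
  noise; truth records the analytic `e = sqrt(1 − (b/a)²)` and flags
  overlaps.

What a green test does and does not establish: the generator draws
multinomial reads from exact lineage frequencies, so recovery tests
validate the estimators' algebra, conventions and noise behaviour — not
robustness to real-data pathologies (PCR jackpots, mapping bias,
bottlenecks between replicates, Illumina error profiles), which are
explicit non-goals.

## Numerical and design choices

- Exact-match mapping only, minimum mappable fragment 16 bp, default tag
  mismatch tolerance 1; ambiguous and unmapped reads are counted, and
  mapped + rejected + ambiguous + unmapped = total always.
- Coordinates are 1-based inclusive externally (GFF convention), 0-based
  half-open internally.
- Gene assignment trims the 3′-terminal 10 % of each gene by default
  (insertions there often leave function intact); exposed as a flag.
- Sites are keyed by the 1-based position of the TA's first base,
  regardless of read orientation.
- Seeds: one integer per entry point, threaded to all stochastic draws
  through `numpy.random.SeedSequence` spawns per stage.
- Supplementary-style tables are ingested header-driven from .xlsx/.tsv/
  .csv; thresholds are always re-derived from values, never from cell
  formatting; legacy binary .xls is not supported (export first).

## Known limitations

- No bottleneck or multi-timepoint modelling; a single expansion step.
- Exact-match mapping is a stated simplification — real screens should
  supply pre-tallied count tables.
- The collective control score from a score-only table (no counts) falls
  back to the mean of control scores, which differs from pooled-count
  ratio when control abundances are unequal.
- Attachment scoring from two-channel images is out of scope (done
  manually in practice); the imaging module quantifies rounding only.
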