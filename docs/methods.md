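# Methods

## The model class

A demographic model is a rooted binary tree of **ecodemes** — named
population units placed on a one-dimensional lattice — each internally
structured as a chain of **topodemes** (local demes) exchanging migrants
with nearest neighbours at a constant per-generation rate.  This is the
simplest isolation-by-distance layout: all demes the same size, zero
distance between neighbouring ecodemes, adjacency alone gating gene
flow.  The tree is expressed as a list of events in generations before
present:

- **Soft splits.**  Backward in time, two ecodemes merge into their
  parent at time *T*.  Forward in time, migration between the daughters
  does not stop at the split but decays exponentially,

      m(t) = m_min + (m_max − m_min) · exp(−λ (T − t) / E),

  with *t* in generations before present, *m_max* the rate at the split,
  *m_min* the asymptote, and the exponent expressed in migration-update
  epochs of *E* = 200 generations.  λ defaults to 1; the exponent's time
  unit is a modelling choice, and epochs of 200 generations were chosen
  so that one decay constant spans the same interval at which the
  migration matrix is updated.
- **Admixture pulses** (instantaneous transfer of a stated ancestry
  proportion), **Ne changes**, **topodeme-count changes** and **pairwise
  migration-rate overrides**, all with backward semantics: an event at
  time *T* sets the value applying to every *t ≥ T*.

Validation checks the partial order (a child's own split is younger than
the split that created it; pulses only between coexisting ecodemes) and
parameter ranges; every operation in the package refuses invalid models.

## Discretization and simulation

The continuous decay is discretized into piecewise-constant **epochs**:
boundaries at every multiple of 200 generations plus every event time,
rates evaluated at each epoch's younger edge.  The epoch schedule is the
single source of truth for the simulator: it is translated into an
msprime demography with one population per topodeme slot, migration-rate
changes at epoch boundaries, and mass migrations for splits,
deme-count reductions and pulses.  Genomic blocks are independent
replicates (free recombination between blocks, none within by default)
under an infinite-sites binary mutation model, so every simulated site
is biallelic and polarized by construction.  Defaults: mutation rate
1.61e−8 /bp/generation, generation time 29 y, 2 sampled chromosomes per
population taken from the lattice-central topodeme.

## Summary statistic and fitness

Each population contributes a derived-allele count on 2 chromosomes
(states 0/1/2).  For every quadruple of populations the joint spectrum
has 3⁴ = 81 cells; the all-ancestral and all-derived cells are removed
per quadruple, and the 79-cell segments are concatenated over all C(n,4)
quadruples in lexicographic order — 79 cells for n = 4, 5530 for n = 8,
versus 3ⁿ − 2 for the full spectrum.  Cells are indexed by the base-3
code 27c₁+9c₂+3c₃+c₄ minus one.  With fewer than 4 populations the
package falls back to the full 3-state spectrum (3ⁿ − 2 cells); the
4-wise construction needs at least 4 populations, and the fallback keeps
small validation studies runnable.

Per-cell standard errors come from a block bootstrap: genomic blocks are
resampled with replacement to the original count (1000 replicates by
default) and the per-cell standard deviation is floored at ε = 1
count-equivalent (scaled alongside any normalization), so standardizing
never divides by zero.  Fitness of a simulated dataset is

    f = Σ_s ((SS_sim − SS_obs) / σ_obs)²,

zero iff the vectors agree everywhere.  Because simulated and observed
genome sizes can differ, both vectors are normalized to per-quadruple
proportions before comparison (each 79-cell segment sums to 1).

## The evolutionary engine

A population of candidate models (default 20) evolves by reproduction,
mutation and truncation:

- **Reproduction** is linear and decreasing in error: the best candidate
  leaves S_max = 8 offspring, the worst S_min = 2, intermediate errors
  interpolate with round-half-to-even; a degenerate all-equal population
  reproduces at S_max.
- **Mutation** never alters the split topology.  Event times move
  strictly inside the bracket set by neighbouring events, using a 70/30
  mixture of a local log-normal jitter (sd 0.35 on the log scale) around
  the current time and a global log-uniform draw over the bracket.  The
  pure log-uniform proposal concentrates most of its mass near the young
  edge of a wide bracket (its median is the geometric mean of the
  bounds), which in practice dragged split times toward zero; the local
  component restores refinement behaviour while the global component
  retains exploration.  Sizes and rates are jittered log-normally;
  non-split events can be added or removed.  Invalid mutants are
  resampled (20 tries) before falling back to an unchanged copy.
- **Selection** pools parents with children and truncates to the
  original size (elitism), so the best-error trace is monotone
  non-increasing — asserted on every run.

Every candidate in a run is evaluated on one shared simulation seed
(common random numbers).  At the genome sizes used for desk-scale
validation a single stochastic evaluation has a standard deviation
comparable to the truth model's mean fitness; with independent seeds
selection rewards seed luck rather than model quality.  Pairing removes
that axis of noise at no simulation cost.  The residual caveat is that a
run can adapt to its shared realization; validation scenarios therefore
use enough data that this overfitting does not move parameters outside
the tolerances checked (and the recovery study additionally restricts
mutation to the parameters under study, see below).

Runs stop at the iteration budget (default 200), at error zero, or —
optionally — after a plateau window without improvement.  Replicated
runs (default 40) start from initial populations cycling through all
candidate topology variants, so topologies compete both within and
across runs; the support table counts the winning topology per run.

## Goodness of fit

A fitted model is checked by simulating many replicate datasets
(default 1000), fitting principal components to the simulated summary
matrix only, and projecting block-bootstrap replicates of the observed
summary (default 40).  The observed score combines the Mahalanobis
distance in the components covering ≥ 90% of the simulated variance
with the reconstruction residual standardized by its simulated mean;
the residual term matters because a systematic model–data discrepancy
can lie largely outside the top noise components, where a pure
in-subspace distance is blind.  The model is flagged a poor fit when
the observed score exceeds the 99th percentile of the simulated scores.
Scores are computed on counts-scale summaries at matched genome size;
with proportion-normalized inputs the score is invariant to common
rescaling.  Under the null (observed generated by the fitted model) the
flag rate is calibrated at or below the nominal 1–5%.

## Observed-data pipeline

Site-level filters, applied in order with per-criterion drop counts:
minimum depth 5 reads, QUAL ≥ 20, PASS only, exclusion of sites within
6 bp of an indel's affected span, exclusion of multiallelic records.
Mask BEDs (repeats, CNVs, genes, CpG islands) then remove sites, genes
with a strand-agnostic ±20 kb flank (a site exactly at flank distance
is masked; one base further is kept).  "SNP density" windows — 10 kb
windows sliding every 2.5 kb, retained above 90% density — are
interpreted as *callable-site* density, since a window where >90% of
bases are SNPs is impossible; retained windows merge into maximal
intervals that double as the default bootstrap blocks (fixed-width
tiling is available).  Polarization takes the ancestral allele from the
VCF's AA field or an ancestral FASTA; sites whose ancestral allele
matches neither observed allele are dropped and counted.  Coordinates
are 1-based in VCFs, 0-based half-open everywhere internally.

## Synthetic data and what it does not emulate

The fixture factory produces competing topologies as caterpillar joins
over rotated leaf orders (each base topology in a with-migration and a
decay-only variant; 6 bases × 2 variants = the 12-topology competition
design at 8 populations), split times geometric between 400 and 4000
generations, Ne 5000 per topodeme, decay m_max 5e−3.  The toy VCF
fixture hand-places one record per filter class, including the exact
±6 bp indel-flank and 20 kb gene-flank boundaries; its construction is
the oracle for the pipeline tests.

The parameter-recovery scenario is 3 populations with hard splits
(m_max = 0) at 1500 and 4500 generations, Ne 800, 40 blocks × 20 kb.
Hard splits and divergences deep relative to 2N are used because with
shallower splits, or with the fixture's default decay active, the young
split time is not separately identifiable to within a factor of 2 at
this genome size (decay rate, sizes and time trade off).  The study
restricts mutation to event times within a bounded search range (the
analogue of a bounded prior) and stops on a 10-iteration plateau: its
question is time recovery under a known structure, and leaving sizes
and structural events free lets the search fit the single observed
realization better than the truth process does, pulling times off by
more than the factor-2 tolerance.  What passing these tests shows is
that the machinery is correct and that the search recovers identifiable
parameters at small scale; it does not show power on real genomes,
where callable lengths are a thousandfold larger, populations are
samples of individuals rather than single diploids, and real data
violates neutrality, panmixia within demes and the infinite-sites
assumption in ways the generator does not emulate.

## Problem sizes and numerical choices

Validation studies use: 4-population runs with 20 blocks × 10 kb,
population 10, 20 iterations; the recovery study above with population
10, 30 iterations, 10 seeds; goodness-of-fit calibration with 40
simulations per cloud and 20 repeats.  These sizes were chosen so each
study completes in minutes on a single CPU while leaving the measured
properties (monotone elitism, factor-2 recovery, null calibration)
clearly resolved.  Ties in ranking break by candidate creation order;
round-half-to-even is used for offspring counts; sigma floors, epoch
boundaries and bracket endpoints are as stated above.  All randomness
flows from numpy SeedSequence spawning, so every result in the test
suite and the acceptance script is reproducible from a single integer
seed.

## Known limitations

- The demes export requires a time-invariant topodeme count per ecodeme
  (the exchange format has no per-deme cardinality changes).
- The engine's IWO variant keeps mutation magnitudes constant over a
  run; no dispersal-shrinking schedule is implemented.
- Haplotype-based summaries are out of scope; the spectrum's
  multimodality limits fine-scale migration/admixture discrimination.
- Within-block recombination is supported but defaults to zero;
  between-block independence is a simplification of real linkage
  structure.
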