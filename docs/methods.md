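# Methods

## Within-cell model

A cell is a multiset of plasmid copies over a small set of species. Three
species cover the biology studied here:

| species    | autonomous | marker | per-copy cost | meaning                          |
|------------|-----------:|-------:|--------------:|----------------------------------|
| ancestral  | yes        | yes    | 0.0306        | full-length plasmid              |
| satellite  | no         | no     | 0             | *oriV*-only deletion derivative  |
| deletion   | yes        | yes    | 0.0050        | accessory-gene deletion plasmid  |

Fitness is additive: `w = max(floor, 1 − Σ_s n_s c_s)`, floor 0. The
deletion-plasmid cost makes the pure 18-copy carrier match its measured
competitive fitness exactly (`1 − 18·0.0050 = 0.910`). The full-length cost
0.0306 gives `1 − 18·0.0306 = 0.449` for the pure ancestral carrier,
slightly above the measured 0.431; the 0.0306 figure is kept as the model's
calibration constant and the residual is noted rather than re-fitted (the
additive model cannot match both carriers and the mixed-carrier
observations simultaneously). The nominal copy number is 18 per newborn
cell.

**Replication.** At division the plasmid pool is exactly doubled. The
default scheme copies every plasmid exactly once — deterministic doubling,
i.e. equal replication chances with initiation rate-limiting. Two
stochastic urn schemes are available as switches: `polya` (n sequential
template draws from the growing pool; the extra-copy vector is
Dirichlet-multinomial) and `frozen` (n draws from the starting pool,
multinomial). Both urns preserve expected species fractions (the
replication martingale) but add compositional variance; under either, the
satellite-carrier equilibrium settles at a *lower* fitness and *fewer*
satellites than observed (19-state eigenanalysis: Pólya gives 0.719 and
6.2 full-length copies vs 0.770 and 5.1 for deterministic doubling), which
is why deterministic doubling is the default. Replication requires at least
one autonomous plasmid in the cell; Rep proteins act in trans, so one
autonomous copy licenses every plasmid present.

**Segregation.** The doubled pool is assorted randomly but evenly: daughter
one draws exactly half the pool uniformly without replacement (multivariate
hypergeometric); daughter two takes the complement.

**Viability.** Under selection a cell needs at least one marker-bearing
plasmid; daughters that inherit none are removed at birth. Cells with no
autonomous plasmid never divide.

## Population model

The focal cells compete against an implicit background of fixed relative
fitness `w_b`; one generation is one background doubling. For relative
fitness to equal the ratio of Malthusian parameters (the quantity measured
in competition assays), a lineage of fitness `w` must multiply by
`2^(w/w_b)` per generation in expectation. Because mutant cells can be
fitter than the ancestral-carrier background (ratios up to ~2.2), a single
Bernoulli division per generation cannot express the required growth; each
generation is therefore divided into `S` sub-steps with per-sub-step
division probability `q = 2^((w/w_b)/S) − 1`, exact in expectation for any
`S ≥ w/w_b`. The default `S = 8` sits close to the continuous-time limit
(tuned satellite-carrier fitness changes by <0.01 between S=4 and S→∞).
A `linear` division rule (`q = w/w_b`, growth `1 + min(w/w_b, 1)`) is
available for comparison.

Serial transfer is binomial thinning: each cell survives with probability
1/dilution-factor.

All protocol populations carry at most two plasmid species per cell, so a
population aggregates exactly into a 19-vector of cell counts indexed by
ancestral copy number. The aggregated sampler draws, per state, the number
of dividing cells (binomial) and then the multinomial split over the
enumerable daughter-pair outcomes — an exact simulation of the per-cell
process at any population size (tested against the per-cell reference
implementation distributionally). Establishment trials run cell-by-cell
while small (≤192 cells) and switch to the aggregated representation above
that.

### Protocol 1 — equilibrium tuning

Seed 10,000 cells of the focal type (satellite carriers start as 1 SP + 17
FL); bisect on `w_b` until the population neither grows nor shrinks over
500 generations with 2-fold serial dilutions (bisection tolerance 0.005,
drift sign averaged over 10 replicate populations, decisive early exit when
a population leaves a 100-fold corridor). The tuned `w_b` is the focal
type's realized equilibrium fitness. Because a single-mutant founder
population is far from its compositional equilibrium — in mean field it
dips from 10,000 to ~60 cells before the satellite amplifies — the first
100 generations are run with the population held at its working size
(multinomial resample after each transfer) and drift is measured over the
remaining 400 generations of free growth; without the hold, the founding
transient and its stochastic extinctions bias the tuned fitness downward
by ~0.015 and the measurement is noisy. The equilibrium composition is the
time-averaged mean per-cell species count over the second half of a
size-held run at the tuned `w_b`.

### Protocol 2 — phenotypic delay

200 replicate populations of 20,000 cells carrying 1 mutant + 17 ancestral
copies are propagated 50 generations with 1.072-fold dilutions against the
ancestral-carrier background (`w_b = 1 − 18·0.0306 = 0.4492`). The
per-generation realized fitness is the focal doubling ratio times `w_b`
(i.e. on the reference-strain scale); the trajectory is the across-replicate
mean with a normal-approximation 95% band. Because growth ratios are
unaffected by the absolute size, each replicate is resampled back to its
working size each generation after the measurement (mutant lineages grow
roughly threefold per generation here and would overflow any integer
bookkeeping within the run). The crossover statistic is the largest g such
that the satellite mean exceeds the deletion mean at every generation ≤ g.

### Protocol 3 — establishment

Each trial seeds one newborn cell (1 mutant + 17 ancestral) at a division
drawn within a growth cycle with probability proportional to the number of
divisions per generation (2^g weighting over g = 0..10); the daily cycle is
`round(log2(2000)) = 11` background doublings with a 2000-fold transfer at
the end. A trial succeeds when the mutant-carrying descendants number at
least 20 × 2000 = 40,000 at a cycle end (checked before the transfer), and
fails on extinction. The establishment probability is successes over
trials; the excess of the satellite over the deletion plasmid is reported
as a percentage. The acceptance script runs 10^7 trials per type (standard
error on the excess ≈ 1.2 percentage points); the bundled desk preset uses
10^5.

## Microhomology scanner

A repeat call is a pair of loci on the circle whose banded alignment (at
most one indel, band ±1) has ≥7 columns, ≤5 total mismatches with indel
columns counted as mismatches, and identity (matches/columns) ≥75%.
Identity's denominator is the full column count, so an indel column counts
as a non-match column. Alignments must begin and end on match columns; `N`
never matches. Calls are *maximal*: a call is suppressed when another
qualifying alignment contains both of its loci. Only direct (same-strand)
repeats are scanned — the deletions modelled here proceed by
single-strand annealing of same-strand homology. The circle is scanned as a
doubled linear string with candidates deduplicated modulo the length;
tandem and even overlapping loci are allowed so long as the two loci are
not identical, while "alignments" of the circle against itself at shift
zero (directly or via one resynchronising indel) are structurally excluded.
Locus spans are capped at one less than the circle length.

Overlap resolution is greedy: sort by (columns descending, mismatches
ascending, position), keep a call only if neither of its loci overlaps any
already-kept locus. The final position tie-break makes the output
independent of input order. Cross-region counting takes the resolved calls
with one locus entirely inside each of two circular region sets — repeat
pairs that could mediate a deletion with endpoints in those regions.
Junction annotation searches ±20 bases (a window chosen to comfortably
cover the observed 7–15 bp junction homologies) around each endpoint of an
observed deletion and returns the best qualifying repeat with one locus
near each endpoint, using the same ordering as overlap resolution.

The scanner is verified, call for call, against an independent oracle that
exhaustively aligns every anchored locus pair on random circles.

## Deletion-endpoint combinatorics

On an annotated circular map (0-based half-open intervals; roles origin /
rep_gene / marker / accessory / other), a deletion arc [start, end) forms a
satellite plasmid iff it contains every accessory and marker feature
entirely, clips at least one base of at least one replication gene, and
spares every origin base ("at least one of the replication genes" is read
as partial overlap sufficing, since observed satellite deletions begin
inside a rep gene, while the accessory genes and marker are removed
entirely). It forms a deletion plasmid iff it clips at least one base of
*every* accessory feature while touching no non-accessory feature at all
(the backbone from the origin through the marker stays intact; intergenic
bases flanking and between the accessory genes are deletable). The two arc
sets are disjoint for any valid map. Start/end combinations are counted at
single-base resolution over ordered (start, end) pairs; the named classes
are counted in closed form from region boundaries after cutting the circle
at the (single) origin, with the rep-gene overlap condition handled as a
union over rep genes on either side of the required block, and arcs that
would wrap through the origin subtracted. The closed forms equal exhaustive
enumeration of all O(L²) arcs on every tested map, including rotations and
reflections. The SP:DP count ratio is the mutational-target bias; on the
published plasmid annotation it is ~4.

## Synthetic data

The generator produces i.i.d. circular sequences at a requested GC content,
plants repeat pairs with exact column/mismatch/indel structure (mismatched
columns interior and evenly spread, so a planted sub-threshold pair leaves
no qualifying sub-alignment), and lays out miniature plasmid maps in the
study plasmid's feature order (origin, rep genes, marker, accessory). All
generators are pure functions of their seed. Synthetic fixtures emulate
the *structure* of the real data — annotated circular maps, planted
homologies — but not its sequence composition biases (the real plasmid is
not i.i.d.; repeat densities on it differ from the random-sequence
expectation), so passing tests demonstrate correctness of the algorithms,
not sequence-level conclusions about any particular replicon, which require
the real annotated record. The bundled presets carry the three protocols at
their published scale plus flagged desk variants.

## Numerical choices and limitations

* Tolerances: bisection 0.005 on `w_b`; stability judged on mean log drift
  across replicates; identity threshold comparisons carry a 1e-12 slack so
  boundary cases (e.g. 9/12) are kept.
* One global seed expands into per-protocol substreams; every stochastic
  path is reproducible bit-for-bit from the CLI `--seed`.
* The aggregated engine supports cells with at most two plasmid species —
  exactly what the study protocols need; the generic per-cell operations
  handle any species set but scale to smaller populations only.
* Conjugative transfer, chromosomal integration (the IS-mediated fate),
  replication-rate advantages for smaller plasmids, and copy-number
  setpoint regulation are out of scope; cells always double from their
  current total, consistent with the observed constancy of total copy
  number in satellite-carrying cells.
* The phenotypic-delay dilution factor (1.072 per generation) is taken as
  an opaque protocol constant; realized fitness is insensitive to it.
* Measured equilibrium values quoted in this note (0.770/0.719, 5.1/6.2,
  crossover ~13) are produced by the test suite and the acceptance script
  at the presets described above.
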