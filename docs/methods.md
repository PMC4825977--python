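# Methods

## Scope and data model

`plastomarker` operates on a rectangular multiple sequence alignment of
plastid genomes over named taxa. Characters are normalized to uppercase with
`U → T`; the stored alphabet is `A C G T`, the IUPAC ambiguity codes,
gap `-` and missing `?`/`N`. Internally all coordinates are 0-based
half-open (BED convention); every user-facing report prints 1-based
inclusive positions, the convention of the plastome literature.

Partition boundaries (LSC/SSC/IR) are **input**, not inferred: placing them
is a judgement call made while inspecting an alignment, and hard-coding a
heuristic would hide that judgement. An automated exact inverted-repeat
finder (`detect_inverted_repeat`) is provided separately for single genome
sequences; it uses exact reverse-complement matching (binary search over the
repeat length with rolling hashes, candidate hits verified by direct
comparison), which suits the near-identical IRs of plastomes and keeps the
operation dependency-free and testable. Alignments are expected to carry a
single IR copy, as whole-plastome alignments usually do.

## Site classification

Each column is classified as:

* **excluded** — fewer than 2 taxa carry a non-missing state;
* **constant** — exactly one distinct non-missing state;
* **parsimony-informative** — ≥ 2 distinct states each present in ≥ 2 taxa;
* **variable-uninformative** — otherwise (e.g. singletons).

Gaps, `?`/`N` and all ambiguity codes count as missing. Treating ambiguity
codes as missing (rather than expanding them to state sets) matches common
parsimony-statistics practice and keeps the classification equivalent to an
exact oracle: a column is parsimony-informative **iff** its Fitch parsimony
length differs across topologies, which the test suite verifies exhaustively
for all 4⁵ five-taxon columns against all 15 unrooted five-leaf topologies.

Percentages in variability tables use the full partition length as
denominator and are rounded half-up to two decimals; total variability is
computed from the summed count, not by adding rounded percentages. The
excluded class is never folded into the constant count.

## Window scan and candidate extraction

Mean pairwise identity in a window is the arithmetic mean, over all
unordered taxon pairs, of matches/comparable positions, where a position is
comparable only when **both** characters are unambiguous bases. Gap-vs-base
is not a mismatch — it is excluded from the denominator. A pair with no
comparable position is skipped; a window where every pair is undefined has
no value and **breaks** candidate runs. This is one defensible convention
among several (alignment viewers differ and rarely document theirs); it is
stated here and enforced by an exact brute-force oracle test.

Defaults: window 10 bp, step 1 (densest profile; the step is configurable).
Candidate extraction automates a traditionally visual step: maximal runs of
windows with identity `< 0.95` are merged across gaps `< 200` columns,
split into chunks of at most 2000 columns, and kept when ≥ 800 columns long
with missing-data fraction ≤ 0.2. The 800–2000 bp band targets regions
amplifiable by standard PCR and sequenceable in one or two Sanger reads.
The 0.95 threshold is calibrated to the scale of congeneric plastome
divergence: with background pairwise distances of order 1–2%, a 10 bp window
only dips below 0.95 when several taxa disagree, so ordinary singleton
variation does not trigger candidates while genuinely fast stretches do.

## Tree machinery

Distance trees are built by neighbor joining on Jukes–Cantor-corrected
p-distances, d = −(3/4)·ln(1 − 4p/3), with p computed over comparable
positions only; a pair with no comparable positions, or p ≥ 0.75
(saturation), is an error rather than a silent fix-up. NJ breaks Q-criterion
ties on the lowest index pair and clamps negative branch-length estimates to
zero, making runs bit-reproducible. Likelihood and Bayesian inference are
deliberately out of scope: the ranking stage needs topological congruence
and support, not branch-length inference, and NJ+bootstrap supplies both at
a cost that allows thousands of replicate trees in seconds.

Fitch parsimony assigns missing/ambiguous leaf characters the full state
set. The implementation is exact on binary trees (including trees read from
trifurcating-root Newick, which describe the same unrooted topology); on
other multifurcations children are folded sequentially, which scores an
arbitrary binary refinement.

Bootstrap replicates resample alignment columns with replacement (original
length preserved) from one seeded NumPy generator. The majority-rule
consensus keeps exactly the splits occurring in **strictly more** than the
threshold fraction (default 0.5) of replicates — a split at exactly 50% is
excluded, a choice that must be fixed one way or the other and is tested.
Robinson–Foulds distance is the size of the symmetric difference of the two
trees' non-trivial bipartition sets. Support thresholds default to the
bootstrap convention of ≥ 70% moderate / ≥ 85% well supported (posterior
analyses conventionally use 90/95; both presets are provided).

## Marker ranking

For each candidate region the pipeline builds a bootstrap consensus from the
region's sub-alignment and computes: RF distance to the reference tree, the
fraction of reference splits recovered with at least moderate support,
monophyly of a designated ingroup, and the region's variability statistics.
The composite score

    score = 0.5 · recovered_split_fraction
          + 0.3 · (1 − RF / RFmax),   RFmax = 2(n − 3)
          + 0.2 · min(pct_total_variability / 10, 1)

formalizes an otherwise visual comparison. Congruence and support dominate
by construction; raw divergence (capped at 10% so that extreme divergence
cannot buy rank) acts as a tie-breaker among equally congruent regions. The
weights and cap are configurable; the defaults reflect the priority of
congruence with the whole-genome tree over raw variability. A region in
which any taxon has no data at all is flagged
`excluded: insufficient data`, reported with NaN score and sorted last —
never silently dropped. The reference tree is, by default, built from the
whole alignment with the same NJ+bootstrap machinery; an externally inferred
topology can be supplied instead.

## Synthetic data generator

The simulator emulates the structure of a congeneric whole-plastome
alignment, with known ground truth for every downstream stage:

* **Tree** — a fixed 16-taxon topology using the study group's species
  names, with the nine sect. *Gireoudia* species forming a clade; uniform
  edge lengths of 0.0006 expected substitutions/site (total tree length
  ≈ 0.018), chosen so that realized whole-alignment variability lands in the
  few-percent range characteristic of congeneric plastome alignments.
* **Partitions** — LSC 10,100 / IR 2,750 / SSC 2,150 columns (15 kb total),
  the quadripartite proportions of a plastome alignment scaled down by
  roughly a factor of ten to keep the full pipeline fast enough for
  many-seed property tests.
* **Rates** — Jukes–Cantor substitution, per-column rate = partition
  multiplier, defaults IR = 1, LSC = 2.5, SSC = 5: the SSC evolves about
  twice as fast as the LSC and about five times as fast as the IR, the
  characteristic plastome contrast. Planted marker blocks override the
  partition rate; the default planting used in tests is 20×, which yields
  in-block pairwise identities around 0.87–0.90, the divergence scale of
  useful species-level markers.
* **Base composition** — root states drawn AT-rich (64.2% AT); under JC the
  substitution process itself is symmetric, so the skew applies only at the
  root.
* **Missing data** — whole blocks of `?` per taxon, overwriting the
  simulated states. Indels are *not* modelled as evolutionary events because
  every statistic under test treats gaps and missing data uniformly.

One global seed drives a single `numpy` generator; identical configs give
byte-identical alignments. `simulate_contigs` fragments a genome length at
uniformly drawn break points, providing distributions for the assembly
summary statistics (N50, contigs ≥ 1 kb, etc.).

What the simulator does **not** emulate: rate variation within partitions
(other than planted blocks), GTR-type exchangeability and base-frequency
effects on substitution, invariant-site/Gamma mixtures, realistic indel
processes, alignment error, or recombination-free-but-linked effects beyond
column independence. Passing recovery tests therefore demonstrates that the
pipeline's stages measure what they claim under a clean generating process —
not that any particular real alignment will yield the same candidate list.

## Numerical and degenerate-input choices

* Percentage rounding is half-up (`2.345 → 2.35`), matching published
  tables, rather than Python's banker's rounding.
* Identity profiles store undefined windows as NaN; NaNs never propagate
  into candidate regions because undefined windows break runs.
* `extract_candidates` output is sorted, disjoint and deterministic; chunk
  splitting of over-long runs proceeds left to right, and a trailing chunk
  shorter than the minimum length is dropped.
* NJ on fewer than 3 taxa, empty alignments, empty contig lists, inverted
  or empty intervals, overlapping partitions, and leaf-set mismatches all
  raise typed exceptions (`plastomarker.errors`) rather than returning
  sentinel values.
* Seeds for per-region bootstrap runs are drawn below 2³¹ from the master
  seed, so every ranking run is reproducible end to end.

## Desk-scale problem sizes

The test-suite and reproduction-script problem sizes are chosen as the
smallest that make the statistical checks decisive: 15 kb × 16 taxa
simulations (50 seeds for the partition-ordering check, 20 for
planted-marker recovery, 10 for ranking contrasts), 100–1000 bootstrap
replicates, exhaustive oracles at ≤ 5–6 leaves, and 200 random additive
matrices at 4–12 leaves for NJ consistency. All of these are the package's
own choices of scale and finish in seconds to a couple of minutes on one
CPU.

## Optional full-data check

Reproducing the published full-alignment statistics (per-region site counts
and the reported region/partition mean identities) requires the study's
deposited whole-plastome alignment and knowledge of the original software's
gap conventions, which were not published; the missing-data convention is
exposed here as explicit, documented rules instead. This check is therefore
documented as optional and is not part of the test suite; the published
counts themselves are used as inputs to verify the package's percentage and
size arithmetic exactly.

## Known limitations

* Single substitution model (JC) for both simulation and distance
  correction; saturated pairs are an error, not an approximation.
* Sequential-fold Fitch on multifurcations is an upper bound, not the
  Hartigan optimum (exact on binary trees, which is what the pipeline
  builds).
* Candidate extraction approximates a visual curation step; with a single
  tree-building method, instabilities that real studies observe between
  MP/ML/BI topologies are out of reach.
* The composite ranking score is a formalization choice, not an estimate of
  any biological quantity; its weights should be treated as analysis
  settings.
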