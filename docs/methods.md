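# Methods

`tetrack` re-implements, as a tested pipeline over simulated ground
truth, the analysis chain used to profile the evolution of a cut-and-paste
DNA-transposon family across many genomes: homology mining and copy
census, TIR/TSD boundary annotation and full/intact classification,
consensus building, genetic-distance estimation, Kimura divergence
landscapes, and a three-filter screen for horizontal transfer (HT)
validated against planted transfers.

## The element model

The synthetic ancestral element mirrors the family's canonical
architecture: terminal inverted repeats (TIRs, default 23 bp, supported
range 8–40 bp), untranslated filler, and a single transposase ORF
(default 492 aa) — about 2.8 kb in total. Insertion occurs only at TA
dinucleotides and duplicates the target, so every planted copy is flanked
by a TA target-site duplication (TSD); TA is its own reverse complement,
which keeps TSD semantics exact on both strands. Copy classes follow the
field's convention: *full* = both TIRs present; *intact* = full plus a
transposase ORF longer than 300 aa (strict, i.e. ≥ 301); anything without
a TIR pair is *truncated*.

Two generator details exist to make the classes *true by construction*
rather than merely intended:

* Copies planted as **intact** are aged with purifying selection on the
  ORF: substitutions creating an in-frame stop (or hitting the start/stop
  codons) are reverted. Without this, a neutral 5% divergence would give
  a premature stop with probability ≈ 1 − e^(−3) and "intact at 5%
  divergence" would be a contradiction. The same veto can be applied
  along a species tree (`preserve_orf`) to model an active family; the
  distance-level HT studies leave it off, since HT distances are computed
  from consensus sequences that mostly reflect neutral copies.
* Copies planted as **full** (dead) carry premature stops spaced through
  the ORF; **truncated** copies lose a uniform 10–40% prefix and/or
  suffix, which always removes at least one TIR. The decay model is a
  stand-in, not an inference target.

Planted insertions are spaced ≥ 2.6 kb apart so that flank extraction
(2 kb) and hit clustering cannot merge neighbouring loci; truth tables
would otherwise be ambiguous at the locus level.

## Mining

The desk-scale translated search is six-frame translation with exact
4-mer amino-acid seeding and ungapped X-drop extension under BLOSUM62.
It substitutes for a full TBLASTN run at simulation scale; significance
is a raw-score threshold (default 60) that an empirical shuffle null
(`empirical_score_threshold`) comfortably clears, not a true E-value.
Broken transposases produce several hit segments per locus; segments on
one strand within 600 bp are merged into locus-level hits before the
top-k non-overlapping selection (greedy by score, ties to the smaller
start, therefore order-independent).

The copy census applies the family's conventional thresholds as strict
inequalities: length > 1000 bp, reference coverage > 40%, identity > 80%.
Coverage is measured on the reference element (the per-family consensus
fixes the reference), identity over gap-free aligned columns.

## Annotation

De-novo boundary discovery restricts TIR-pair candidates to positions
immediately inside a TA dinucleotide — the TSD is treated as part of the
boundary evidence, which is what keeps the search specific; an
unconstrained window search over thousands of candidate pairs would hit
chance 8–10 bp inverted repeats at a rate incompatible with per-copy
classification. Candidate pairs are ranked longest first, then fewest
mismatches, then leftmost/outermost; the default mismatch allowance is
⌈10% of the repeat length⌉. Once a family reference exists, copies are
annotated against it: the copy's extent is the span aligned to the
reference (overlap alignment, flanks stay unaligned), and the TIR pair is
called when the copy covers each terminal reference TIR at ≥ 80% with
identity > 80%. Consensus building is per-column majority over rows
non-gap in ≥ 50% of copies, with ≥ 6 copies required for a consensus and
the longest intact copy returned as a representative otherwise.

## Distances

* **K2P**: d = −½·ln(1 − 2P − Q) − ¼·ln(1 − 2Q) with transition fraction
  P and transversion fraction Q over pairwise-deleted columns. Estimates
  are flagged saturated (not silently dropped) when a log argument is
  non-positive.
* **Composite-likelihood TN93** (`mcl_distance_matrix`): base
  frequencies and the two transition/transversion rate ratios are
  estimated once from site-pattern counts pooled over *all* pairs; each
  pair's divergence is then the 1-D maximum of its multinomial likelihood
  with those shared parameters fixed, solved on the analytic score
  function by bracketing to ~1e-12. With two sequences this reduces
  exactly to the standard TN93 closed form. Residual numeric differences
  from other implementations of the same named method are accepted.
* **Neighbor joining**: textbook agglomeration; Q-criterion ties broken
  by the lowest-index pair; negative branch lengths clamped to zero with
  the deficit moved to the sister branch.

## The horizontal-transfer screen

Candidate species pairs must pass, in order: element identity strictly
above 70%; the distance-ratio rule — read as d_TE × 1.2 ≤ d_host for
*every* host gene (RPL3 and RPL4; the alternative reading
d_TE ≤ d_host − 1.2·d_TE is dimensionally odd and rejected; an any-gene
mode is available) — with saturated, missing, or zero host distances
failing outright; and a significance test at α = 0.01. Passing pairs are
grouped into events as connected components; confirmation re-runs the
ratio and significance steps against RAG1 (vertebrate pairs) or tub3
(pairs involving an invertebrate).

**Replication for the significance test.** The natural unit of
replication — pairwise distances among an event's species — collapses
for small events (a two-species event has a single pair), and pairwise
distances among shared branches are not independent anyway. Each member
pair therefore contributes per-marker distances computed on six
independent alignment blocks, and the one-factor ANOVA runs across the
marker groups (element, RPL3, RPL4) over these block replicates; an
event is called only when p < 0.01 *and* the element group mean is the
smallest. When raw sequences are unavailable the filter falls back to
one point distance per member pair, and single-pair events are then
untestable and never called.

**Permutation decision.** Distances at shallow divergence are built from
a handful of substitutions; block values are then discrete and the
parametric F p-value is anti-conservative. When the parametric p clears
α and enough values exist for the permutation distribution to resolve α
(≥ 12), the decision is taken on a permutation p-value (4999
rearrangements, fixed internal seed, hence deterministic).

No multiple-testing correction is applied by default, matching the
method's standard usage; a stricter α can be set in configuration.

**Known false-positive mode.** Under vertical-only simulation the
screen's residual false calls (≈ 4% of 20-species replicates) come from
genuine locus-level realized-rate fluctuations: on short shared branches
the element locus can accumulate ~20% fewer substitutions than both host
genes by Poisson chance, which no per-locus statistic can distinguish
from a transfer. The 1.2× margin absorbs this in expectation; users
should treat shallow-divergence calls (host distance ≲ 0.05) with
caution.

## Study conditions for the simulation experiments

The standing conditions, fixed after a design-stage pilot and used by
the analysis scripts, tests, and acceptance metrics: Yule trees of 20
species rescaled to root height 0.5 expected substitutions/site (deep,
phylum-scale host divergence, so that the 70% identity filter restricts
the screen to within-clade comparisons, as in real surveys with dense
taxon sampling); equal element and host substitution rates (K2P,
κ = 2); host genes of 10 kb; a ~2.8 kb element; planted transfers at
0.01 substitutions/site before present between the two most divergent
leaves. Under these conditions the pilot measured a 4% null
called-event rate (100 replicates), 100% recovery of the planted pair,
and 98% confirmation retention.

## Divergence landscapes

Each copy contributes its aligned length (kb) to the 1%-wide bin holding
its copy-to-consensus K2P divergence. Plain K2P is used (no CpG
adjustment); copies with undefined or saturated divergence are excluded
and logged. `recent_activity` flags any mass below 2% divergence;
`fossil_dominated` flags > 50% of mass above 10% — the 50% cut is an
artifact choice where the literature is qualitative ("most copies").

## What the simulations do and do not show

Simulated sequences evolve without indels, rearrangement, or
recombination, so "alignment" across species is positional and exact;
real data add alignment error on top of every stage. Host genes evolve
neutrally at the element's rate, whereas real ribosomal-protein CDS are
under strong purifying selection (slower than a neutral element), which
would make the ratio filter *more* conservative than in these tests. TE
decay is a uniform-truncation stand-in; TSDs never degrade. Passing
tests therefore demonstrate the internal correctness and calibration of
the statistics and the joint behaviour of the filters under the stated
model — not performance on real, indel-rich, selection-shaped genomes.

## Numerical conventions

Coordinates are 0-based half-open throughout; minus-strand regions are
reverse-complemented on extraction and mapped back for reporting. All
stochastic routines are pure functions of (parameters, seed); a single
run seed drives every stage through derived sub-seeds, and reruns of the
pipeline produce byte-identical manifests (SHA-256 over every output).
Divergence solving is capped at 40 substitutions/site; anything at the
cap is flagged saturated and fails HT filters automatically.
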