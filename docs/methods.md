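# Methods

This note documents the models and procedures implemented in
`recsweep`, the defaults that matter, the numerical choices, and what
the simulation-based tests do and do not demonstrate.

## The triplet model

All detection is built on the triplet hypothesis: among three aligned
sequences, one (the recombinant) tracks one parent over part of the
alignment and the other parent elsewhere. Every statistic works on a
*gap-stripped view* of the three rows — columns where any of the three
carries a gap or an ambiguous base are removed, and a column map
translates results back to original alignment coordinates. Coordinates
are 0-based half-open internally; every user-facing report is 1-based
inclusive, converted only at the report layer. IUPAC ambiguity codes
are collapsed to N on input (a deliberate simplification: fractional
matching of ambiguity codes adds complexity for negligible power at the
divergences this tool targets).

Two site classes drive the statistics:

* **variable sites** — view columns with at least two distinct residues
  among the three rows;
* **informative sites** (for candidate recombinant r) — columns where
  the two parents differ and r matches exactly one of them; the A/B
  symbol records which. Swapping the parent labels flips every symbol,
  and all statistics are constructed to be invariant under that flip.

## Signal statistics

**rdp.** Pairwise identities in sliding windows (default 30 view
columns, step 1). A window is flagged when the locally most-similar
pair differs (strictly) from the globally most-similar pair; the
longest run of windows flagged for a single pair is the candidate
region. Its raw p-value is the exact binomial upper tail of that
pair's match count in the region given its whole-view identity,
multiplied by the number of windows examined (Bonferroni within the
method). A run covering every window is rejected — the method requires
a *local* rank change, not overall relatedness.

**maxchi / chimaera.** A boundary slides through a frame of 2w sites
(default w = 35); the 2×2 chi-square of (match, mismatch) × (left,
right) simplifies, with equal half-frames, to 2w(a−c)²/((a+c)(2w−a−c)).
No Yates continuity correction is applied. MaxChi uses the
match/mismatch vector of a sequence pair over the triplet's variable
sites; Chimaera uses a candidate recombinant's A/B informative vector.
Peak location ties break leftmost. Significance comes from permuting
site order, with the (k+1)/(N+1) estimator.

**Selection-aware permutation nulls.** At the triplet level the
reported statistic is the *maximum* over the three pairs (maxchi) or the
three candidate recombinants (chimaera, 3seq). The permutation null
therefore applies the permutation to every competing vector and takes
the same maximum. Without this the within-triplet selection triples
the false-positive rate; with it, the measured fraction of
recombination-free alignments yielding any call is ~2–4% at a nominal
5%.

**3seq-style walk.** The informative vector is oriented by its majority
symbol (the background, major-parent state steps +1; the minority steps
−1) and the statistic is the maximum descent of the walk — the most
concentrated run of minor-parent sites. Majority orientation makes the
statistic parent-label invariant and zero on uniform vectors. The
leftmost interval achieving the maximum descent is the candidate
region. The exact 3SEQ Δ(m,n,k) tail tables are out of scope; the
permutation null substitutes.

**siscan.** Per window (default 100 columns, step 20), match counts for
the three pairs are compared with randomizations that permute the three
residues within each column (500 draws). A window signals when the
pair with the highest z is not the globally most-similar pair and
exceeds z = 3; the peak z's normal tail, times the window count, is the
raw p.

**bootscan.** The triplet plus the most distant remaining sequence (as
outgroup) is bootstrapped per window (default 200 columns, step 20, 100
replicates); each replicate picks the quartet split minimizing the
four-point criterion on Jukes–Cantor distances. A region where the
supported parent switches, flanked on both sides by ≥ 0.7 support for
the other parent, is assessed with the binomial identity tail over the
candidate's informative sites — keeping its p-value on the same footing
as the other methods rather than re-using bootstrap counts.

`siscan` and `bootscan` are implemented and tested but not in the
default method list: per triplet they cost orders of magnitude more
than the other four and serve best as confirmatory checks; enabling
them is one config entry.

**Recombinant identification.** Within a triplet, each candidate's
informative A-fraction inside vs outside the region gives an
affinity-flip score (2f_in−1)(2f_out−1); the minimizer is the
recombinant, with near-ties (within 0.05), non-negative best scores or
undefined sides labelled ambiguous. At the event level, when five or
more sequences are available, a profile-correlation check (the
correlation of a sequence's per-neighbour difference fractions inside
vs outside the region, phylpro-style) arbitrates between the nominated
recombinant and its donor — the donor/acceptor roles are intrinsically
mirror-symmetric within one triplet, and this full-alignment check
substantially reduces swapped calls.

## Multiple testing

Raw p-values are Bonferroni-multiplied by the number of triplets only;
window- and selection-level multiplicity is already handled inside each
method, so the corrections compose without double counting. Because
the permutation floor 1/(N+1) must resolve below α/n_triplets for a
permutation method ever to pass, the engine raises permutation counts
to ⌈1.2·n_triplets/α⌉, capped at 12,000 (beyond ~500 triplets the
permutation methods drop out and the exact-tail rdp statistic carries
detection). Escalating batch sizes with early stopping (stop after 10
exceedances) keep null triplets at ~32 draws, so the cap is only paid
on genuinely signal-bearing triplets.

## Breakpoints

The recombinant's informative vector is modelled as a two-state HMM:
hidden state = parent currently tracked, emission error ε (mismatch
probability), switch probability 0.01 per site boundary. A two-pass
fit (Viterbi at ε = 0.05 → re-estimate ε as the add-one-smoothed
disagreement fraction (k+1)/(n+2), clamped below 0.5 → refit) gives the
segmentation. The event region is the segment that overlaps the
detection signal most — window statistics often truncate the true
region, and the segmentation recovers its full extent; if the refined
interval no longer covers the signal region (posterior collapse on
noisy vectors) the signal region itself is reported, with a warning.

Each breakpoint gets an independent single-switch posterior computed on
the neighbourhood spanning the adjacent segment and the chosen one:
likelihood of "left sites under one state, right sites under the other"
(better orientation kept) times a uniform prior over boundaries,
normalized in log space. The 95% HPD is the shortest contiguous
boundary run containing the mode reaching 0.95 mass. Breakpoints live
at boundaries *between* informative sites — the data cannot localize
them more finely — and are reported at the midpoint of the flanking
informative columns (rounded down). Simulated single-breakpoint
triplets show ~95% HPD coverage of the junction's nearest boundary.

## Consolidation and disassembly

Candidates group greedily (best corrected p first) when their regions
overlap with Jaccard ≥ 0.5 and their donors fall in the same
single-linkage cluster at JC distance ≤ 0.05. Each group becomes one
event built from its best triplet. Events whose refined region spans
the whole alignment are discarded: with no internal breakpoint they
describe relatedness, not recombination.

The disassembly loop takes the best event, replaces each recombinant
row by a region-only and a complement-only fragment (gaps elsewhere, so
column coordinates never shift), and rescans. Only triplets touching
changed rows are rescanned; carried candidates have their Bonferroni
factor updated, and candidates stuck at their permutation floor are
re-run at the higher resolution the larger factor demands. Successive
events whose regions overlap a recorded event (intersection over the
shorter region ≥ 0.5) are folded into it — repeated signals of one
ancestral event return with jittered boundaries, and treating them as
new events double-counts. The flip side, inherited knowingly: distinct
events affecting the same region in different sequences are
under-counted, a recognized bias of fully exploratory scanning.
Splits that would be no-ops (the region covers a fragment's entire
support) are refused, and their candidates dropped, so the loop cannot
stall.

## Patterns

All pattern statistics share one null: breakpoints re-placed uniformly
over their permissible positions (whole alignment, or a detectability
mask when given — breakpoints are only detectable where parents differ,
and the hook exists precisely so a caller can supply that mask; the
full detectability correction is a documented limitation). The
hot/cold-spot scan uses non-overlapping windows, a per-window 2.5/97.5%
local envelope, and a global envelope from the permutation distribution
of the per-replicate maximum (and minimum) count, which controls the
family-wise false-call rate at ~5% — measured ≤ 5% over nested
simulations. The breakpoint pair matrix flags cells above their 97.5th
permutation percentile with begins and ends re-placed independently;
the region count matrix re-places each sequence's breakpoints
preserving their number (the two nulls answer different questions: "do
begin/end positions co-occur?" vs "is this site pair co-inherited more
than random recombination predicts?"). The co-inheritance grid
defaults to 100 points, bounding cost at O(100²·sequences) per
permutation.

## Phylogenetics

Neighbor joining is implemented in-package with strictly deterministic
behaviour: Q-criterion ties break at the lowest active index pair,
negative branch lengths clamp to zero, 3-taxon stars use the closed
three-point formulas. It recovers random additive 5–8-taxon trees
exactly. Robinson–Foulds distance is the symmetric difference of
non-trivial bipartition sets. Window compatibility matrices build one
NJ tree per window (JC distances with difference fractions capped at
0.74 so near-saturated windows stay finite); branch lengths are re-fit
per window by ordinary least squares on the window's distance matrix
before likelihood comparison — comparing *topologies*, not stale branch
lengths. Per-site JC log-likelihoods (Felsenstein pruning with
per-site rescaling; branch lengths floored at 1e-6 so zero-length
branches cannot zero a site) feed an SH-style RELL support: the
observed log-likelihood deficit of the other window's topology is
compared with centred multinomial resamples of per-site differences.
Identical topologies score 1; windows straddling a recombination
boundary score near 0. The approximately-unbiased test's multiscale
bootstrap is out of scope, and outputs are labelled SH-like to avoid
overclaiming.

## Simulator

`simulate_tree_alignment` evolves sites independently along a tree
under Jukes–Cantor (substitution probability 3/4·(1−e^(−4t/3)) per
branch of length t). `random_tree` draws a random bisection topology
with exponential branch lengths scaled to a mean root-to-tip depth of
0.12 substitutions/site — typical pairwise divergence 0.1–0.2, the
regime in which window statistics have both variation and signal, and
consistent with the parents-at-0.2 benchmark scenario used throughout.
`implant_recombination` copies the donor's *current* row (so nested
events are expressible, with generation order recorded), and
`simulate_events_dataset` implants each event from the most divergent
unused sequence — recombination between distinct lineages, which is the
detectable regime.

What the simulations do not emulate: rate heterogeneity across sites,
indels, selection, within-lineage recombination gradients, or base
composition bias. Passing tests therefore demonstrate correctness of
the machinery and calibration under the stated model, not performance
on any particular empirical dataset; on real data the detectability
mask and method cross-checks matter more, and divergence far outside
0.05–0.4 will degrade all window statistics.

## Problem sizes in the test suite

The statistical tests run at sizes chosen to finish in a routine CI
run while keeping their thresholds meaningful: 50 triplet-recovery
replicates, 200 coverage replicates, 200 null alignments for the
type-I check, 25 three-event datasets, 100 + 200 hotspot power/size
replicates, and 30 strip-rescan replicates. The acceptance script uses
smaller replicate counts (printed in its output as `n`) since it
recomputes every quantity in a single sequential run.

## Known limitations

* Ancestral-event under-counting (shared-region merging), as discussed.
* The permutation cap mutes maxchi/chimaera/3seq for datasets beyond
  ~500 triplets (≈15 sequences); rdp remains exact at any scale.
* Bootscan requires ≥4 sequences; with exactly 3 it is skipped.
* The detectability-mask correction for pattern nulls is a hook, not a
  default.
* Jukes–Cantor only, for distances, likelihoods and simulation; linear
  genomes only (no wrap-around windows for circular genomes).
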