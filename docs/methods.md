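# Methods

## Motif model

A motif descriptor is a set of *blocks* — ordered runs of elements whose
internal 5′→3′ order never changes — plus a set of *stems*, each with a
base-pair length range, a pairing policy (Watson–Crick, optionally G·U
wobble, a mismatch budget strictly below the minimum stem length), and a
required/optional flag.  Elements are degenerate IUPAC literals, stem
half-sites (no sequence of their own), bounded spacers, and at most one
zero-width cleavage-site marker.  T is normalized to U on input.  Consecutive
blocks in any ordering are separated by a linker whose length range is a
descriptor-level property (default 0–50 nt; permuted hammerhead ribozymes
typically show ~3 nt).

Because antiparallel complementarity is a symmetric relation, the
`first`/`second` labels on stem halves are only identifiers: which half
appears 5′ of the other is decided by the block order, not the descriptor.

The built-in hammerhead descriptor encodes the catalytic core as
C = (stem I half, `CUGANGA`, stem II half), G = (stem II half, `GAAA`,
stem III half), S = (stem III half, `NUH`, cleavage site, stem I half), with
stems I/II at 3–8 bp, stem III at 2–8 bp, wobble allowed everywhere, and the
loop I–loop II tertiary interaction declared as an optional stem.  That
interaction's two sides live in loop regions whose identity depends on the
permutation, so the built-in descriptor declares it without placing its
halves; optional stems participate in topology only when both halves are
placed in blocks and `include_optional` is set.  The built-in twister
descriptor is an explicit approximation (the authoritative block diagram is
graphical): it keeps the conserved cleavage-site UA dinucleotide and
representative stem ranges, and is intended for permutation/topology
arithmetic, not as a faithful consensus.

## Permutations and topology

A descriptor with *n* blocks yields exactly *n*! layouts, named by the
concatenated block labels in 5′→3′ order and enumerated in lexicographic
order.  Each layout linearizes elements (with inter-block linkers) into
ordinal slots; a stem's extent is the slot interval between its two halves.
The pseudoknot count is the number of unordered stem pairs whose extents
interleave (`i < i′ < j < j′`) — a helix-level count, invariant under stem
length and under cyclic rotation of the block order (interleaving is a
property of the cyclic order of the four endpoints).  Zero crossings ⇒
`junction`, otherwise `pseudoknotted`.  For the hammerhead this classifies
CGS/GSC/SCG as junctions and gives all three of SGC/CSG/GCS exactly three
crossing pairs; the count is reported as-is rather than forced to any
particular convention for "number of pseudoknots".

## Scanning

A (descriptor, layout) pair compiles to an ordered plan of matchable units
with length bounds and, per stem, the index pair of its halves.  Scanning is
depth-first backtracking over unit lengths and positions, shortest length
first, with two exact prunings: remaining-minimum-length feasibility, and
window gates that discard start positions unless every selective literal
(information content ≥ 6 bits, e.g. `CUGANGA`, `GAAA`) has a precomputed hit
inside its feasible offset window.  Both prunings are sound, so the search
remains exhaustive; this is validated against an enumerate-everything oracle
on compact descriptors.  Crossing stems cost nothing special: the second
half of a stem is checked against the first wherever the plan places it.

Coordinates are 0-based half-open on the forward strand (BED convention).
Minus-strand scanning runs on the reverse complement and maps spans back.
`N` in the target fails literals and pairing by default.  Matches are
deduplicated by (span, element spans) and sorted by (start, type name, end);
overlapping placements and overlapping permutation types are all reported,
since one permutation's match is not derivable from another's.  Every match
re-verifies against an independent checker (`verify_match`).

Cleavage-site prediction reads the zero-width marker's coordinate; fragment
lengths are reported in transcript orientation, so 5′-fragment = site and
5′ + 3′ = construct length identically.  Sites at a construct boundary are
flagged degenerate.

## Covariation screen

Statistics are computed per consensus pair, over rows ungapped at both
columns (pairwise exclusion, preserving signal in ragged alignments):

* pair-type tallies (Watson–Crick / wobble / non-canonical / gapped);
* compensatory count — row pairs differing at *both* columns with both rows
  still paired (wobble counts as paired, as in comparative RNA analysis);
* `MI` in bits, and `MI_apc = MI − APC` where APC uses column means over the
  **full** column-pair MI matrix (Dunn et al. 2008).  Restricting the APC
  means to the consensus pairs themselves degenerates when each column
  belongs to exactly one consensus pair — the correction then equals
  MI²/mean and inverts the ranking — so the full-matrix form is used;
* a permutation p-value from ≥ 1000 seeded within-column shuffles
  (composition-preserving), `p = (1 + #{MI* ≥ MI})/(1 + N)`.

The curation rules are explicit, configurable stand-ins for qualitative
judgments: a sequence is flagged when its realized stem pairs are C–G/G–C in
a fraction < 0.15; an insertion longer than 12 nt is flagged unless an
exhaustive search finds a hairpin (stem ≥ 3 bp, loop ≥ 3 nt) inside it.  The
verdict is `promising` iff ≥ K (default 3) consensus pairs have compensatory
count ≥ 1 and p < 0.05 and no stem group is entirely invariant; fewer than
two sequences returns `insufficient data`, since covariation cannot be
observed in a single example.  This screen deliberately does **not**
reimplement R-scape's G-test statistic.

## Kinetics

`f = L/(L+S)` is fitted to `f(t) = (y0 − plateau)·e^(−kt) + plateau` by
bounded nonlinear least squares (trust-region reflective, tolerances 1e-14),
initialized from a log-linear regression of `f − min f`.  Bounds are
`k > 0`, `y0, plateau ∈ [0,1]`; both `y0` and `plateau` are free by default
and either can be fixed (e.g. `plateau = 0` for decay to zero) — published
fits do not always state which convention was used, so both are supported.
Constant series and solver failures return `converged=False` with a message,
never a silent fallback; a fitted plateau above `y0` (a rising series) is
also marked non-converged.  R² = 1 − SS_res/SS_tot.  Replicates are averaged
arithmetically with sample SD (absent for n = 1), reported at full precision
and at two significant figures.

Simulated time courses default to 30 points spanning 3.5 half-lives of the
true rate: slow rates (0.004 min⁻¹ has a 173-min half-life) are
unidentifiable on short windows, so the grid scales with 1/k.  Noisy
fractions are clipped into [0,1] with a logged count.

## Synthetic data

Generators are pure functions of (parameters, seed), built directly on the
compiled pattern so truth records share the scanner's element naming.
Instances sample degenerate literal positions uniformly over their IUPAC
sets and emit stems as jointly sampled pairs (wobble probability 0.1 where
allowed); linkers default to 3 nt.  Mutation policies: `compensatory(rate)`
resamples stem positions jointly (pair-preserving — instances must still
match), `breaking(count)` mutates one partner past the mismatch budget
(instances must stop matching at the planted placement).  Backgrounds are
i.i.d. with configurable GC; planted instances go into per-instance hosts at
recorded offsets and random strands, with truth tables in forward-strand
coordinates.  Simulated alignments fix one geometry (so columns align
without gaps) and vary stem pair types around a reference assignment at the
compensatory rate; the attached pair table assigns pseudoknot tiers greedily
so each tier is internally non-crossing.

What the generators do *not* emulate: indels and alignment uncertainty,
phylogenetic correlation between sequences (rows are exchangeable),
Markovian background composition, and gel-quantification error structure.
Passing screens on these inputs therefore demonstrates correctness of the
statistics and search, not performance on real metatranscriptomes.

## Numerical and design choices

* Tie-breaks: matches ordered by (sequence, start, type name, end, element
  spans); backtracking explores shorter lengths first.
* The permutation null shuffles one column of the pair; with few distinct
  values the null can be degenerate (e.g. four distinct states in four rows
  make every shuffle a bijection with MI = 2), which is the statistically
  correct behaviour, not an artifact.
* Test and simulation scales — 200 planted sequences of ≤ 200 nt for recall,
  200 sequences for oracle equality on a compact descriptor, 100 seeds per
  rate for noisy recovery, 100 seeded runs for the ranking check — were
  chosen as the package's own desk-scale defaults; the enumerate-everything
  oracle is run on compact descriptors because its cost is the product of
  all unit length ranges.
* Known limitations: scanning cost grows with linker range (the 0–50 default
  is configurable and is the dominant term); the hairpin filter's exhaustive
  search is cubic in insertion length and intended for the short insertions
  it screens; optional interaction stems without placed halves cannot
  contribute to topology counts.
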