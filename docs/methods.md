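# Methods

This note records the model behind `longtr`, the parameters that matter,
the design decisions taken where the design was genuinely open, and what
the synthetic benchmark does and does not establish.

## Positions, units, similarity

Read positions are inter-base: position *i* lies between the *i*-th and
(*i*+1)-th character, so `R[a, b]` is half-open with length b−a, and all
reported coordinates (TSV, BED) follow this convention.  A repeat *unit*
is defined only up to cyclic rotation; units are reported as their
lexicographically least rotation, and all unit comparisons in the
evaluation are rotation-aware.  Two strings are called τ-similar when
their longest common subsequence divided by their average length is at
least τ; this is the notion behind "approximate tandem repeat" and is
exposed as `lcs_similarity`.

## Boundary detection

`window_similarity_scan` maintains both sliding k-mer count vectors and
their comparison statistics incrementally (four single-bin updates per
base), so one (k, w) pattern costs O(|R|) independent of k.  Both
similarity forms are supported:

* Manhattan: ξ = 1 − ‖f−h‖₁ / 2w.  Normalized by 2w as defined, although
  2(w−k+1) would be tight for k > 1; the bound only affects the scale,
  not the ordering, of similarities at fixed (k, w).
* Pearson: ξ = (ρ+1)/2.  A zero-variance profile (all counts equal) has
  no defined correlation; ξ is set to the no-correlation midpoint 0.5 so
  boundary scores degrade smoothly on low-complexity windows instead of
  raising errors or producing spurious ±1 spikes.

B(i, w) = S(i, i+w) − S(i−w, i) and E(i, w) = −B(i−w, w) are emitted for
their full valid ranges.  Candidate starts are local maxima of B within
distance w (leftmost on ties, for determinism); the paired end is the
*closest* local maximum of E at least w to the right, after which the
scan resumes, so several repeats per read can surface at one pattern.
Because the closest E maximum can sit inside a long repeat, candidate
ranges underestimate long repeats; the alignment stage recovers the full
extent (below).

**Peak floor.** Local maximality alone fires constantly on repeat-free
sequence, so a floor on B is required.  A fixed floor of 0.2 suits small
windows, where B fluctuates by ±0.2 on random sequence, but is too high
for large windows at high error rates: for a 100–200 nt unit at ~20%
error the true boundary peak reaches only 0.1–0.2 while the noise floor
is below 0.05.  The floor is therefore adaptive per pattern:
θ = max(0.05, min(θ_B, 4·σ̂)), with σ̂ the scaled median absolute
deviation of the pattern's B array and θ_B = 0.2 the configurable
ceiling.  The factor 4 keeps the family-wise false-peak rate low (the
number of independent local maxima per pattern is roughly |R|/w) while
admitting the weak-but-clean peaks of long noisy units.

**Detectability.** A repeat of span L with unit u is expected to need
2|u| ≤ w ≤ L/2 and k ≤ |u| < c·4ᵏ (c = 1/4).  Consistently with the
first condition, candidates whose detected range is shorter than 2w, and
final calls spanning less than 2w of their seeding pattern, are dropped.

## Candidate handling

Candidates from the twenty patterns are clustered by reciprocal overlap
(≥ 75%); each cluster is represented by its smallest-w member, whose
boundaries are the tightest.  Representatives are processed widest
first, and a seed already covered (≥ 80%) by accepted calls is skipped —
without this, every mid-repeat seed of a 100 kb array would redo the
same work.  Short candidate ranges (≤ 300 nt) are pre-screened by the
best positional self-match fraction over shift periods up to half the
range: genuine tandems stay well above random (~0.25 expected, 0.52
required), which removes most chance window-similarity peaks before the
expensive unit sweep.

## Unit assembly

For each k in the sweep (default 2–15, clipped per range so that 4ᵏ is
at least on the order of the squared maximal unit length — expected
k-mer self-collisions below ~1 — and at least 3), k-mer counts of the
padded range form an implicit de Bruijn graph.  From each maximally
frequent k-mer (up to 4, in code order) the frontier next(V) — the
maximum-frequency successors of V — is expanded until it is empty
(failure), a singleton, or contains the start vertex (the cycle
closes).  The traversed path is recovered by parent pointers, choosing
at each backtrack step the predecessor of maximal frequency (ties:
smallest code).  If the forward search fails, the graph is searched
backward over reversed edges and the spelled unit reversed.  Ties among
start vertices are resolved by total cycle weight (sum of node
frequencies along the walk).  Frontier expansion and cycle length are
capped at half the range length: a "unit" longer than that cannot repeat
within the range, and the cap guarantees termination on pathological
graphs.  Candidate units from different k are ranked by wraparound σ
against a common evaluation window (the central ≤ 3000 nt of the range;
units too long for the window are scored on the full range), with ties
to the shorter unit — this resolves the (ACGACG)² ambiguity toward the
primitive unit without an explicit primitivity test.

## Consensus refinement

**Transition repair.** The k-mer frequencies along the cyclic unit dip
over a window of ~k positions at an embedded error and rise sharply
beyond it.  A position is suspect at the boundary of a maximal
low-frequency run (below half the median frequency along the unit);
both run boundaries are used because a deletion leaves only k−1 low
k-mers.  At each suspect position the nine operations (no-op, 3
substitutions, deletion, 4 insertions) are scored by the summed
frequency of the k-mers covering the edited window, and the best
strictly-improving edit is applied, at most one per pass, up to five
passes.  The stage is skipped when the median frequency is below 10:
in a low-copy repeat a rare k-mer may simply be correct.

**Column polish.** The wraparound alignment of the interval against the
unit induces a multiple alignment of the unit copies.  With d the
column depth and ε the average per-column error rate of the alignment,
the count K of a recurring discrepancy is tested against the binomial
upper tail p(K) = Σ_{j≥K} C(d,j)(1−ε/4)^{d−j}(ε/4)^j at the
Bonferroni-corrected level 1%/(8|u|) (8|u| hypotheses: per position 3
substitutions, 1 deletion, 4 insertions).  An edit additionally has to
be the column consensus — the substituting base must be the column
majority, deletions must outnumber aligned bases, insertions must occur
in more than half the rows.  Without this guard a significant minority
(e.g. 15 of 1000 rows) would overwrite a correct base; with it, the
tail test is what protects low-depth columns from coincidence.  The
test-and-edit cycle repeats to a fixpoint, at most five passes, and a
depth below 2 leaves the unit untouched.  Polish runs after chaining,
on the calls that survive, which avoids polishing hundreds of
short-lived candidates.

## Wraparound alignment and boundary refinement

The DP aligns a region against an unbounded tandem concatenation of the
unit at unit edit costs; columns are unit phases 0…L with a free
ε-transition from phase L to phase 0, handled by a second left-to-right
pass per row.  Row 0 is all-zero: the alignment may start at any phase,
making σ exactly rotation-invariant (a cycle has no distinguished
start).  σ = (e−s) − δ; per-row minima give σ(u, R[s, x]) for every
prefix x in the same pass, and the reversed problem gives suffix scores;
both arrays are stored on each call for split-point optimization.
Copies are reported as unit characters traversed divided by |u|
(fractional terminal copies included); identity is matches over
alignment columns, a distinct quantity from the LCS-based τ-similarity,
and both are exposed under distinct names.

Candidate boundaries are only w-accurate, and candidate ends can sit
mid-repeat.  The per-base match profile of the alignment is therefore
reduced to its maximum-scoring segment under scores (1−t) for a match
and −t otherwise, where t lies midway between the estimated in-repeat
identity and 0.55, the empirical match fraction of random DNA against an
unrelated cyclic unit under this DP.  t is seeded from the candidate
core and re-estimated from the found segment (three rounds), so a seed
whose range was mostly flank still converges onto the repeat.  Whenever
the segment touches the aligned region's edge, the region is grown
outward in doubling steps and refinement repeats — this recovers a
100 kb array from a seed anywhere inside it.  Finally, calls reporting
the same unit with a small gap relative to their combined span (< 30%)
are re-called over their union, which reunites fragments of one array
produced by different patterns while keeping genuinely distinct
same-unit repeats (whose separating flank is comparable to the spans)
apart.

## Chaining

Calls are chained by maximum total σ under the pseudo-disjoint relation
(overlap < l = 10 nt counts as disjoint) with the end-sorted
best-predecessor recursion over a prefix-maximum structure, O(n log n).
Calls spanning ≤ l are dropped first; they fit inside a permitted
overlap and would break the order argument the recursion relies on (and
a ≤ 10 nt "repeat" is not a meaningful call).  Calls below σ <
0.2·span are dropped as junk, identical intervals are deduplicated to
the best σ, and a final minimum of 3 estimated copies is required —
fewer copies cannot be distinguished from chance repetition.  Surviving
overlaps are resolved at x* = argmax o(x) (smallest x on ties) from the
stored prefix/suffix arrays, and trimmed calls are realigned, so
reported intervals are strictly disjoint with consistent scores.

## Synthetic benchmark

Each read is flank + unit^copies + flank: the unit is uniform over
{A,C,G,T}^|u| with non-primitive draws rejected, and each flank is a
random string as long as the repeat, so boundary accuracy is tested
against realistic context on both sides.  Flanks that would continue
the tandem phase (a prefix at least one unit long matching the cyclic
continuation at ≥ 75% identity) are resampled; otherwise the planted
boundary would not be the true boundary of the string and
boundary-accuracy assertions would fail on correct calls.  The error
channel is i.i.d. per base — delete with probability *del*, else
substitute (to a different base) with probability *sub*, and insert one
uniform base after with probability *ins* — applied per segment, which
keeps post-error truth boundaries exact.  Presets: `nanopore_like`
(10%/5%/5% sub/ins/del), `accurate` (1%/0.5%/0.5%), and `pacbio_like`
(1.5%/9%/4.5%), the last being this package's own representative
insertion-dominated CLR profile.  The channel has no burst errors, no
junk/chimeric reads, no quality values and no identity distribution
across reads; passing benchmarks therefore demonstrate robustness to
uniform indel/substitution noise at the stated rates, not to
instrument-specific artifacts.

Sensitivity counts a read as recovered when *some* reported call's unit
matches the planted unit at the required rotation-aware identity
(τ = 1.0 for exact recovery; τ = 0.95 tolerates e.g. five errors in a
100 nt unit).  Incidental micro-repeats that random flanks genuinely
contain are reported like any other call and do not affect this metric.

## Problem sizes and numerical choices

The benchmark-backed checks use one read per lattice cell at zero error
(all 35 cells), and 50 reads per cell over unit lengths
{2, 5, 10, 20, 50, 100, 200} × copies {10, 50, 200} at 2% error — 1050
reads up to 120 knt each, chosen so the whole sweep completes in
minutes on one core.  Oracle comparisons run the DP against explicit
enumeration on 500 random unit/region pairs (|region| ≤ 60) and
chaining against exhaustive subset search on 200 instances (n ≤ 10).
All randomness flows from explicit seeds; identical seeds give
byte-identical generator output and identical calls.

## Known limitations

* Sensitivity degrades for long units with few copies at raw-read error
  rates (e.g. a 200 nt unit repeated 10 times at 20% error): short
  k-mers of a long, low-coverage unit collide and the greedy cycle
  shortcuts.  This is the macro-repeat regime and is out of scope.
* Higher-order repeat structure (a long unit itself composed of
  monomers) is reported at the monomer level; the HOR unit is not
  reconstructed.
* The caller reports genuine micro-repeats (spans of tens of nt) that
  random sequence contains; downstream users interested only in long
  arrays should filter on `repeat_len` or `copies`.
* FASTQ qualities are ignored; reverse complements are not searched (a
  tandem array lies on one strand of one read).
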