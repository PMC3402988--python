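# Methods

## The map and its two parameterizations

The Chaos Game Representation of a DNA string S over {A, C, G, T}
places each base at a corner of the unit square (A=(0,0), C=(0,1),
G=(1,0), T=(1,1)) and maps every prefix S[..i] to

    x_i = x_{i-1} + r (y_i - x_{i-1}),    equivalently
    x_i = (1-r)^i x0 + r * sum_{k=1..i} (1-r)^{i-k} y_k.

Two presets are pinned:

| preset   | r   | x0         | role |
|----------|-----|------------|------|
| standard | 1/2 | (1/2, 1/2) | visualization, m-mer counting; proximity below 2^-L is *necessary* for an L-shared suffix |
| cantor   | 2/3 | (2/3, 2/3) | all search algorithms; proximity below 3^-L is *equivalent* to an L-shared suffix |

Arbitrary r in [1/2, 1) and arbitrary x0 (including a random point or
circular seeding) are accepted for coordinate dumps only; every matching
algorithm requires the cantor preset because the equivalence theorem is
proven there. The contraction ratio is dimensionless; positions and
lengths are in bases, 1-based and inclusive throughout the API, with
0-based half-open converters at the BED output boundary only.

Under the cantor preset the base-3 fractional expansion of x_i per axis
is, most significant digit first,

    2*bit(S[i]), 2*bit(S[i-1]), ..., 2*bit(S[1]), 2, 0, 0, ...

— content digits in reversed sequence order, then the x0 = 2/3 tail.
All digits lie in {0, 2}, so subtracting two coordinates can never hide
a digit mismatch behind a carry; the first differing digit position k
pins the L-infinity distance into (3^-k, 3^-(k-1)), and counting shared
leading digits answers the longest-common-suffix query.

## Backends

**float** stores an (N+1) x 2 float64 matrix built by the recurrence
(row 0 is x0). A suffix query takes one subtraction and one logarithm,
with an explicit power-of-3 boundary verification against rounding.
Base-3 digits beyond position ~32 are below double resolution, so
queries whose answer would reach the cap L_max = 30 fall back to direct
symbol comparison; results are therefore always correct, and the O(1)
bound holds whenever answers stay under the cap (random sequences
essentially always do).

**exact** (cantor only) stores the digit/2 bits of the whole sequence
as one packed integer per axis; the digit string of any prefix is a bit
slice, and a query is an XOR plus a bit-length — O(1 + l/w) on w-bit
words, exact at any sequence length. The search algorithms build their
internal indexes on this backend.

The theorem's guarantee is stated for equal prefix lengths. For unequal
(i, j) the shorter prefix's terminator digit can coincide with a content
digit of the longer one ("G" vs "GG" would over-report), so all query
results are clamped to min(i, j).

The retained base-2 estimate on the standard map is implemented as
max{L : d < 2^-L}. Sharing an L-suffix forces d strictly below 2^-L, so
this form never under-reports a genuine shared suffix — which is exactly
the property that makes its over-reporting on the AT/TA family (1
instead of 0, N-1 instead of 0) a demonstration of the carry artifact
rather than noise.

## Algorithms on top of LCE

- **Longest common extension** of S1[i..] and S2[j..]: one suffix query
  on the reverse indexes at the mirrored positions (N-i+1, M-j+1).
- **Scan matching**: one LCE per text position; a hit iff the extension
  reaches |P|. O(N).
- **Quadtree (CGR-tree)**: a digital search tree over reversed prefixes,
  children in fixed A, C, G, T order, one stored position per node,
  naive first-empty-slot insertion (worst-case quadratic; chosen over a
  linear suffix-tree construction so the tree agrees node-for-node with
  the bracket-notation description it implements). Search descends along
  reverse(P); path nodes at depth < L are certified by one LCE query at
  (p, L) on the direct indexes, and the whole subtree at depth L
  matches. O(L + occ) per query.
- **k-mismatch**: the kangaroo walk — extend, hop over one mismatch,
  repeat, at most k+1 extensions per window (asserted in code). Because
  extensions are maximal, the accumulated skip count is the window's
  exact Hamming distance, which every hit reports even when below k.
- **Palindromes**: a complemented palindrome's backward arm comparison
  is a forward comparison on the reverse complement, so the maximal
  radius at centre i with gap g is one suffix query between the direct
  index at i and the revcomp index at N-i-g (kangaroo walk under a
  mismatch budget). Only complemented palindromes (even total length
  2*radius + gap) are in scope; mirror repeats are not. Centres are
  reported as the last position of the left arm.
- **Tandem repeats**: midpoint divide-and-conquer. At each recursion
  midpoint mid and period rho, the anchor pairs (mid, mid+rho) and
  (mid-rho, mid) are probed with one backward and one forward LCE; the
  extensions delimit a maximal run of positions t with S[t] = S[t+rho],
  and every window of rho consecutive run positions containing the
  anchor is a tandem start. Any tandem's span crosses the midpoint
  boundary of the smallest recursion segment containing it, with its
  first or second copy covering the corresponding anchor, so every
  tandem is found; rediscoveries at coarser levels are deduplicated by
  (start, radius). Primitive and non-primitive repeats are both
  reported (TTATTA yields the nested (1,1) and (1,3)). With a mismatch
  budget the two extensions become walks that stop after k+1 recorded
  mismatches, and window mismatch counts are read off the recorded
  positions. O(N log N + z) LCE queries exact (instrumented in tests),
  O(kN log N + z) with mismatches.
- **Longest common substring**: all prefixes of both strings are sorted
  in quadrant order — lexicographic on reversed prefixes under
  A < C < T < G, one LCE plus one symbol comparison per comparator call;
  ties between identical reversed prefixes break by (length, origin,
  position), a refinement that preserves the key property that the
  maximal cross-string common suffix occurs at an adjacent sorted pair
  (the same argument as for suffix arrays, checked exhaustively in
  tests). One scan over cross-origin adjacencies returns the length and
  one witness end position per string (the witness is free, so it is
  reported even though only the length defines the result).
- **Rolling hash / Rabin–Karp**: the CGR recurrence is already a rolling
  hash — h(S[i..i+L-1]) is the window's last coordinate and sliding is
  one left-deletion plus one step, h <- (1-r)h - r(1-r)^L(y_out - x0) +
  r*y_in. The float mode keeps that literal form; iterating it erodes
  the low digits, so the default modular mode carries the same base-3
  digit polynomial per axis reduced modulo the Mersenne prime 2^61 - 1
  (a hit requires both axes to agree), which makes roll and re-init
  bit-identical at any window length. Every hash candidate is verified
  by one LCE query before being reported, so hash collisions can never
  produce a false positive.

## Edit operations

Left deletion subtracts the first symbol's contribution,
x - r(1-r)^{N-1}(y_first - x0); left insertion is its inverse,
x + r(1-r)^N (y_alpha - x0). The insertion exponent N (not N+1) is
forced by the closed form and by requiring the two operations to be
mutual inverses — both checked bit-exactly on the packed-digit backend,
where the four edits are one-bit shifts and masks. Right
insertion/deletion apply/invert one recurrence step. Deleting from the
empty string is an error; float round trips hold to 1e-12, exact round
trips are bit-equal.

## Numerical and degenerate-input choices

- Non-ACGT input is rejected with the record name and 1-based position;
  the opt-in `split` policy cuts records at ambiguous symbols into
  maximal clean runs with original coordinates in the id. Lowercase is
  folded up. The core modules stay strict; policy lives at the I/O layer.
- Coincident coordinates (distance exactly 0) return the clamped
  maximum min(i, j) — the logarithm form is undefined there.
- A nonzero distance between cantor coordinates is never an exact power
  of 3 (the digit bound is strict on both sides), so flooring the
  logarithm is safe in principle; the boundary verification step guards
  float rounding only.
- m-mer counting floors standard-map coordinates onto a 2^m x 2^m grid
  (clamped at the top edge) and skips prefixes shorter than m, whose
  cell still carries the x0 contribution; this makes cell occupancies
  equal sliding-window counts exactly. Limitation: when the ~50+
  symbols preceding a window all share one vertex bit on an axis, the
  float coordinate can round onto a cell boundary and misassign that
  single point; unreachable at the m <= 4, random-sequence scales
  exercised here, and the exact backend digits would be the remedy.
- The k-mismatch walks place a skipped mismatch inside the reported
  span when the budget allows, so a maximal radius may end on a
  mismatched pair; maximality is asserted directly (growing any
  reported radius violates the budget).

## Synthetic data

`random_dna` draws i.i.d. uniform bases from a seeded numpy generator —
the background model for the coordinate-map demonstrations (length
5,000 there) and for all randomized tests. `make_fixture` overwrites
planted payloads (matches, complemented palindromes, tandem repeats) at
stated positions and returns the ground truth alongside, so recovery
tests are anchored to construction rather than to re-derivation. What
uniform background does *not* emulate: base-composition skew, long
homopolymer runs, the repeat density of real genomes, or ambiguity
codes. Passing tests therefore certify algorithmic correctness (the
oracle equivalences hold for any input and are additionally checked on
adversarial literals such as homopolymers and the AT/TA family), not
performance on genome-scale data, which the quadratic quadtree
construction in particular does not target.

## Problem sizes and test design

Oracle equivalences run on seeded batches: exhaustive
theorem/LCE sweeps at lengths <= 64 (plus one length-512 exact-backend
grid), 100-200 random (text, pattern) pairs for the four matching
engines, palindrome oracles at N <= 200, tandem oracles at N <= 100,
DP cross-checks for the longest common substring at N, M <= 300, and a
10^4-base text for rolling-hash drift. These sizes keep the full suite
in a few seconds while leaving every algorithmic branch exercised;
complexity contracts are checked by instrumentation (query counters,
per-window extension caps) rather than wall-clock, with one loose flat-
time check for the O(1) query claim.

## Known limitations

- The float backend's O(1) query degrades to a symbol-comparison
  fallback past 30 shared base-3 digits; the exact backend has no cap
  but its prefix extraction is O(i/w) rather than strictly O(1).
- Quadtree construction is the naive quadratic scheme by design;
  Ukkonen-style linear construction is out of scope.
- Separated palindromes are supported for a *fixed* gap only; the
  unbounded-gap problem (all inverted repeats) is out of scope, as are
  alignment, longest common subsequence, and non-DNA alphabets.
- `coordinate_order` sorting cost is O(1) per comparison only in the
  word-RAM sense on the exact backend (digit extraction is O(length/w)).
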