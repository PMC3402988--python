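# cgrmatch

String matching for DNA through the **Chaos Game Representation (CGR)**,
embedded in the Cantor set so that geometric proximity *is* suffix
sharing.

## The idea

CGR assigns each base a corner of the unit square — A=(0,0), C=(0,1),
G=(1,0), T=(1,1) — and maps every prefix S[..i] of a sequence to a point
by the iterated-function-system step

    x_i = x_{i-1} + r (y_i - x_{i-1}),        x_0 given,

with contraction ratio r. In the classical map (r = 1/2, x0 = (1/2,1/2))
two prefixes sharing an L-long suffix always land within 2^-L of each
other — but the converse fails: binary carries can put unrelated
prefixes just as close (AT and TA sit 0.25 apart yet share nothing), so
the distance cannot be trusted to *measure* the shared suffix.

Taking r = 2/3 and x0 = (2/3, 2/3) squeezes the map onto the Cantor set:
every coordinate has a base-3 expansion using only digits {0, 2}, the
carry artifact disappears, and

    |x_i^{S1} - x_i^{S2}|_inf < 3^-L   <=>   S1 and S2 share an L-suffix at i.

One logarithm (or one XOR of packed digits, on the exact backend) then
answers a **longest-common-extension (LCE)** query in constant time
after linear indexing — and LCE is the subtask behind a whole family of
classical string algorithms, all provided here:

- exact pattern matching by scanning (`matches_scan`), by a quadtree /
  CGR-tree index (`qt_matches`, O(L + occ)), and by Rabin–Karp with the
  CGR recurrence as the rolling hash (`rabin_karp_search`, `rk_index`);
- k-mismatch matching by the kangaroo walk (`k_mismatch_matches`, O(kN));
- all maximal complemented palindromes, with optional fixed gap and
  mismatch budget (`all_maximal_palindromes`, O(N) / O(kN));
- all tandem repeats by midpoint divide-and-conquer
  (`all_tandem_repeats`, `k_mismatch_tandem_repeats`, O(N log N + z));
- longest common substring by quadrant-order sorting
  (`longest_common_substring`, O((N+M) log(N+M)));
- constant-time coordinate edits (left/right insertion and deletion),
  lossless decoding, and m-mer counting by sub-square occupancy.

Two index backends are provided: `float` (an (N+1)x2 float64 matrix,
faithful to the numeric formulation, automatically falling back to exact
comparison past ~30 base-3 digits of agreement) and `exact` (per-axis
packed digit integers; correct at any length, used by default inside the
search algorithms).

## Worked example

```python
>>> from cgrmatch import build_index, longest_common_suffix, naive_base2_estimate
>>> from cgrmatch.encoding import CgrParams
>>> at = build_index("AT", CgrParams.standard()); ta = build_index("TA", CgrParams.standard())
>>> at.coordinate(2), ta.coordinate(2)
((0.625, 0.625), (0.375, 0.375))
>>> naive_base2_estimate(at, 2, ta, 2)      # classical map: claims a shared suffix
1
>>> atc = build_index("AT", backend="exact"); tac = build_index("TA", backend="exact")
>>> atc.exact_coordinate(2).digits(1)       # Cantor digits of "AT": 0.202... base 3
'20'
>>> longest_common_suffix(atc, 2, tac, 2)   # Cantor map: the truth
0
>>> from cgrmatch import all_tandem_repeats
>>> [(h.start, h.radius) for h in all_tandem_repeats("TTATTA")]
[(1, 1), (1, 3), (4, 1)]
```

The classical r = 1/2 map puts AT and TA within 2^-1 of each other, so
the base-2 distance estimate reports a (false) shared suffix of length
1; the Cantor-embedded query returns the correct 0. TTATTA carries the
tandem repeat TT at positions 1 and 4 (radius 1) and is itself a tandem
repeat of TTA (radius 3).

The same operations are available from the shell:

```sh
cgrmatch tandems genome.fa --min-radius 3 --bed
cgrmatch match genome.fa GATTACA --engine quadtree
cgrmatch coords genome.fa --variant cantor --backend exact
```

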