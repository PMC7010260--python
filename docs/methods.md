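# Methods

## Model

Two DNA sequences S₁, S₂ (lengths L₁, L₂) are assumed to have diverged
under the Jukes-Cantor substitution model: equal substitution rates between
all nucleotide pairs, sites independent. Homologous positions match with
probability p = 1/4 + (3/4)e^(−4d/3), where d is the distance in
substitutions per site; non-homologous positions match with the background
probability q (1/4 for uniform composition). N_k denotes the number of
ordered position pairs whose weight-k words (or spaced words) are equal,
with multiplicity: a word occurring a times in one sequence and b times in
the other contributes a·b pairs.

Two regimes are used:

* **Indel-free, global homology** (validation only): L₁ = L₂ = L, position
  i is homologous to position i, and
  E[N_k] = (L−k+1)p^k + (L−k+1)(L−k)q^k exactly.
* **General** (default): indels, local homology and reverse-complement
  homology allowed; with L_H the total homologous length,
  E[N_k] ≈ L_H p^k + 2 L₁ L₂ q^k. The approximation ignores, among other
  things, word matches that straddle homologous and background positions.

The estimator transforms the observed count, F(k) = ln(N_k − B(k)) with
B(k) the regime's background term, and reads ln p off the slope of F.
Because L_H enters only the intercept, the slope — and hence the distance —
is unaffected by how much of the sequences is homologous. F(k) is undefined
(NaN) when N_k ≤ B(k); this is a hard information limit, not a numerical
artifact.

## Choice of k_min and k_max

The affine-linear range requires homologous matches to dominate the
background (L p^k ≥ α · 2 L² q^k) while at least β homologous matches are
still expected (L p^k ≥ β). Evaluated at design probabilities p′ (lower
bounds on the true p for which the range is guaranteed to be valid):

    k_min = ceil( (ln L̄ + ln 2 + ln α) / (ln p′_kmin − ln q) )
    k_max = floor( (ln β − ln L̄) / ln p′_kmax )

with L̄ the arithmetic mean of the two sequence lengths (for
self-comparison, the single length). Defaults q = 0.25, α = β = 1,
p′_kmin = 0.6, p′_kmax = 0.53 reduce these to ⌈(ln L̄ + 0.69)/0.875⌉ and
⌊ln L̄/0.634⌋. An empty range (k_min ≥ k_max, i.e. sequences shorter than
roughly 2 kb under the defaults) raises an error rather than producing an
estimate outside the theory's reach. `min_match_probability` exposes the
companion diagnostic bound exp[ln q (ln L̄ − ln β)/(2 ln L̄ + ln 2 + ln α −
ln β)], the smallest p the method can resolve at a given length; it is
computed exactly as written (no rounding of intermediate logs).

Only N_{k_min} and N_{k_max} are counted during a fit — this two-point
shortcut is what makes the method fast. The full F(k) curve (range padded
by 2 on both sides) is computed only on demand for diagnostics.

## Parameters

| parameter | default | meaning |
|---|---|---|
| q | 0.25 | background match probability; 1/4 for uniform DNA |
| alpha | 1 | required homologous/background dominance factor at k_min |
| beta | 1 | minimum expected homologous matches at k_max |
| p_prime_kmin | 0.6 | design match probability for the k_min bound |
| p_prime_kmax | 0.53 | design match probability for the k_max bound |
| mode | spaced | spaced words (random pattern per weight) vs contiguous k-mers |
| match_prob | 0.5 | per-symbol probability of a match position in random patterns |
| strand_mode | both | also count matches against the reverse complement of the second sequence |

## Counting and numerical choices

* Words are projected onto the match positions of a binary pattern, packed
  into 64-bit integers (2 bits per position; weights up to 32 — sufficient
  for average lengths up to ~1.2 Gb under the default k_max), grouped by
  sorting, and pair counts accumulated as products of per-sequence block
  multiplicities. A quadratic double-loop oracle (`count_matches_naive`)
  validates the fast path in the tests.
* Multi-record FASTA is one genome; words never span record boundaries.
* IUPAC ambiguity codes are normalized to N; a word is dropped iff an N
  falls on a *match* position (an N at a don't-care position is never
  compared). Sequence length L includes N's.
* Random patterns force the first symbol to be a match position and draw
  Bernoulli(match_prob) symbols until the k-th match position, so first and
  last symbols are match positions and the expected length is ≈ 2k−1. One
  pattern per weight is generated from the run's single seed and shared by
  every genome pair in the run.
* Positive slopes (possible for near-identical sequences through sampling
  noise) are clamped to p̂ = 1 and flagged; p̂ ≤ 1/4 is outside the
  Jukes-Cantor domain and reported as status `p_out_of_range` with a NaN
  distance. Undefined F at either endpoint gives status `F_undefined`.
  Distance matrices carry NaN for failed pairs; the PHYLIP writer emits -1
  with a comment line (strict mode refuses instead).
* Identical sequence content short-circuits to d = 0.
* With a non-palindromic spaced pattern, the pair-of-strands count is not
  exactly invariant under swapping the two sequences (swapping implicitly
  reverses the pattern on the reverse strand). The model therefore
  canonicalizes the pair order by name before counting, making the reported
  distance exactly symmetric; for contiguous patterns the count itself is
  symmetric.

## Simulator

`simulate_jc_pair` draws an i.i.d. uniform-ACGT sequence and copies it with
independent per-site substitutions at probability (3/4)(1 − e^(−4d/3)) —
child-from-parent at total divergence d, which under Jukes-Cantor has
exactly the same marginal match probability as two lineages of d/2 each.
`embed_local_homology` surrounds a homologous core pair with independent
uniform flanks so the core is a fraction ρ of each output sequence; flank
totals are equal in the two sequences, split half left / half right (odd
remainder to the right).

What the simulator does *not* emulate: indels inside the homologous region,
compositional bias, repeats and low-complexity sequence, rearrangements,
and sequencing error. Passing recovery tests therefore demonstrate
correctness of the estimator under its own model assumptions, and
robustness to *local* homology specifically; they do not bound the error on
real genomes, where repeat-induced excess matches can bias N_k.

## Experiment scales

The recovery experiment uses 100 replicate pairs of length 100 kb per
distance-grid point (d from 0.05 to 0.5) and the local-homology experiment
20 replicate 20 kb cores at d = 0.1 embedded down to homology fraction 0.1
— sizes chosen so the full validation suite runs on a laptop in minutes
while keeping Monte-Carlo standard errors an order of magnitude below the
tested tolerances. Estimator accuracy improves with sequence length
(relative count fluctuations shrink), so these scales are the conservative
end; a separate test checks 500 kb pairs are no less accurate than 50 kb
ones.

## Known limitations

* The estimator degrades beyond roughly d ≈ 0.5 (match probabilities
  approaching the design bound p′) and fails outright — by construction,
  with an explicit status — when homologous matches at k_max drown in
  background, e.g. for short or very distant sequences.
* One random pattern per weight; multiple-pattern averaging would reduce
  variance further but is out of scope.
* Jukes-Cantor only; no transition/transversion or compositional
  asymmetry corrections.
* Assembled sequences only (no read sets); tree building is left to
  standard Neighbor-Joining tools consuming the PHYLIP output.
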