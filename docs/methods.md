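# Methods

## Model and scope

`trieprofile` treats a sequence as emitted by a memoryless (Bernoulli)
source: each character is drawn independently with probabilities
`p_1..p_V` over an alphabet of `V ≥ 2` symbols. The object of study is
the profile `B(n, k)` of unique k-mers of a set of `n` random words — a
word `wχ` counts at length k when its stem `w` (length k−1) prefixes at
least two words while `wχ` prefixes exactly one; equivalently, the
number of leaves at depth k of the trie built on the words. Word sets
are realized in practice as the suffix set of a single sequence of
length n, which is the natural genomic reading (leaf depth = shortest
unique prefix length of a suffix = one more than the longest match of
that suffix elsewhere in the sequence).

Assumptions worth keeping in mind: independence between positions (no
Markov structure), stationarity, and a single sequence standing in for
n independent words. The last introduces a correlation between
overlapping suffixes whose effect on the expectation is far below the
precision of any table printed here; the first two are genuinely
violated by real genomes, which is precisely what the
prediction-vs-observation comparison is designed to surface.

## Exact expectation

The expectation `μ(n,k)` of `B(n,k+1)` is a finite sum over character
compositions `(k_1..k_V)` of k (see README for the formula). The
implementation enumerates all `C(k+V−1, V−1)` compositions in
lexicographic order and assembles each term in log space:
`ln(term) = ln n + ln multinomial (via lgamma) + Σ k_i ln p_i + ln ψ_n`.

Numerical choices, each forced by a concrete failure mode:

- `(1−x)^{n−1}` is computed as `exp((n−1)·log1p(−x))`; for `x ≈ 1e−10`
  and `n ≈ 10⁷` the naive power loses every significant digit.
- The difference in `ψ_n` is taken as
  `e^y · expm1((n−1)(x_i − y))` with `x_i = log1p(−φp_i)`,
  `y = log1p(−φ)`: when `(n−1)φ ≪ 1` both powers are ≈ 1 and direct
  subtraction cancels catastrophically, while `x_i − y` is computed from
  two quantities of size O(φ) and keeps full relative precision. When
  `(n−1)·y < −700` (the base underflows) the subtrahend is dropped and
  the term is `exp((n−1)x_i)` alone. The `φ = 1` empty-word convention
  at k = 0 falls out of the same branch.
- Terms are sorted by descending magnitude and accumulated with exact
  summation (`math.fsum`), so the S/T split and the total agree to the
  last bit with an unpartitioned evaluation.
- The D/E side of a composition (rare/transition vs common) and the sign
  of the objective ρ are both derived from the single quantity
  `ln φ + ln n`, making the two equivalent criteria agree bit-for-bit;
  the tie `ρ = 0` goes to the rare/transition side (the choice cannot
  move μ, only the split).

Double precision suffices: spot checks against a 40–50 digit mpmath
evaluation agree to ~1e−12 relative, which is also the tolerance of the
brute-force oracle test (exhaustive enumeration of all prefix
assignments on instances with at most 10⁶ states).

`k = 0` is admitted (predicting unique 1-mers); `n = 1` is rejected
because the formula degenerates there while one unique 1-mer plainly
exists. Composition counts above a configurable budget (default 10⁷)
raise rather than grind — at that point the asymptotic branch is the
right tool anyway.

## Rate function and second order

`τ_α` is found with Brent's method on the tilt equation after expanding
the initial bracket `[−1, 3]` outward until the (strictly decreasing)
residual changes sign; the root is polished to ~1e−13. Ratios within
1e−9 of the domain endpoints short-circuit to the limit values (ψ = 0)
instead of chasing τ to ±∞. Beyond the transition ratio ᾱ the ψ₂ branch
is a closed form; continuity at ᾱ (where τ = 2) is a tested invariant,
as are ψ(α̃) = 1 and the unimodal shape. For binary alphabets the tilt
has an explicit closed form, kept as an independent cross-check of the
root-finder rather than a fast path.

`ξ` uses `−(V−1)/2 · ln(k)/ln n` on the first branch (note
`k = α ln n`) and `ln(1−σ₂)/ln n` on the second. Uniform sources have
an empty first branch (α_min = ᾱ); the tilt equation is then
degenerate and `tau_root` refuses it explicitly, while ψ₂ still covers
`[1/ln V, 2/ln V]`.

Outside `[α_min, α_ext]` the exponent is only bounded (≤ 0), not
estimated; `log_profile_estimate` reports the regime label
(`below_completion` / `transition_phase` / `decay_phase` /
`beyond_extinction`) and leaves ψ undefined there. The bounded
oscillation of `ln μ` caused by the integer composition lattice
(amplitude ≤ ln(p_max/p_min)) is documented but not computed: at any n
where it would be visible the exact sum is affordable and supersedes
the asymptotics.

## Empirical profiler

The profiler appends to each sequence segment a sentinel ordered before
every symbol (distinct sentinels per segment, so no repeat can span a
segment boundary), builds a suffix array, computes adjacent LCPs with
Kasai's algorithm, and sets the depth of suffix i to
`1 + max(LCP with its two suffix-array neighbours)`. Sentinel suffixes
are excluded; suffixes unique only thanks to the sentinel get depth
(suffix length + 1) and are counted as-is — a boundary effect confined
to the last few positions of each segment and negligible for n far
above the profile depths.

The suffix array uses prefix doubling over numpy `lexsort` passes with
early termination once all ranks are distinct. That happens as soon as
the doubling step exceeds the longest repeat length, so a random
five-megabase sequence needs about seven passes — the pragmatic reason
this construction was preferred over an O(n) but far more intricate
SA-IS implementation. Kasai's scan is sequential and JIT-compiled with
numba. The profiler is validated against an independent quadratic-DP
oracle (pairwise suffix LCP recurrence) on hundreds of small random
sequences, and against the exact expectation statistically (50
replicates at n = 10⁵, mean B(k) within 3 standard errors of μ(n,k−1)
wherever μ ≥ 10).

Sequence generation inverts the CDF on `numpy.random.default_rng`
(PCG64) uniforms; replicate r of a run uses seed `base_seed + r`, and
the generator identity is recorded in profile metadata, so summaries
are reproducible given (model, n, reps, base_seed).

FASTA input is read with Biopython; records are uppercased and split
into hard segments at record boundaries and at any character outside
ACGT. Splitting (rather than deleting ambiguity characters) avoids
manufacturing artificial repeats across the excised gaps. Model
estimation from a sequence offers the exact per-symbol frequencies and
the strand-symmetric "degenerate" DNA parameterization
`p_A = p_T = (f_A+f_T)/2`, `p_C = p_G = (f_C+f_G)/2`; the two give
slightly different predicted profiles and both are exposed.

## What the simulations do and do not show

The synthetic generator emulates exactly the stated study conditions: a
biased binary source with `p_max = 0.7` at `n = 5·10⁶`, and a
degenerate quaternary source with GC-content 0.6664 at `n = 2,847,757`
(the composition and length of a GC-rich archaeal chromosome). Passing
tests show that prediction, asymptotics and measurement agree *for
memoryless sequences*. They deliberately do not show agreement for real
genomes, which carry long duplications, skewed dinucleotide structure
and compositional heterogeneity; the package's `compare` report exists
to expose those departures (rows with `|B_obs − μ| > 5√μ`), and the
injected-duplication test demonstrates the mechanism: one duplicated
block of length L leaves one extra unique k-mer at every length up to
≈ L, flagged wherever the random model predicts essentially none.

## Problem sizes and defaults

- Exact sums: any (n, k) with composition count under 10⁷; the shipped
  analyses need at most a few thousand compositions.
- Empirical consistency check: 10 replicates of n = 5·10⁶ binary
  sequences (about 8 s each with the prefix-doubling backend), mean
  B(26) checked within 1% of the reference 522,788.19 and extinction
  levels within the 51–64 support.
- Departure threshold: 5·√μ, i.e. five standard deviations under the
  Poisson-like fluctuation of B around μ — conservative enough that
  random data essentially never flags.
- Renormalization tolerance for probability vectors: 1e−6 (frequency
  estimates from finite sequences rarely sum exactly to 1); larger
  deviations are treated as user error.

## Known limitations

- No Markov or higher-order source models; no Patricia-trie profile;
  no variance or distributional statement about B(n,k) — expectations
  only.
- The reference threshold tables this package reproduces were printed
  from 4-decimal intermediates; full-precision values differ in the
  fourth decimal for some ratios (e.g. computed ᾱ = 2.04854 vs printed
  2.0484). Tests account for that one-ulp noise explicitly.
- The profiler counts each segment's sentinel-truncated tail depths
  as-is; for sequences whose length is comparable to their repeat
  lengths the edge convention becomes material.
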