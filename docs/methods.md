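# Methods

## Model and estimation

A dataset is N fixed-length series T⁽ʲ⁾ = x₁⁽ʲ⁾…x_L⁽ʲ⁾ (each xₖ an
m-feature symbol vector) with class labels c⁽ʲ⁾. For a split point n the
prefix configuration a concatenates all m features of time points 1…n in
time-major, feature-minor order; the suffix configuration b covers
n+1…L (the empty tuple at n = L). All probabilities are plug-in
frequencies of exact integer counts — deliberately unsmoothed, because the
two identities the scoring rests on hold *exactly* only for the maximum-
likelihood estimate:

1. **Likelihood/entropy duality.** The structured log-likelihood
   Σⱼ log₂[P(a)P(b|a)P(c|a)] equals −N·[H(Aₙ) + H(Bₙ|Aₙ) + H(C|Aₙ)], which
   is how it is computed (via count-table entropies, one pass per n). The
   tests verify the identity to 1e−9 against an independent per-instance
   summation.
2. **Maximum-entropy factorization.** The product form
   P(Aₙ)P(Bₙ|Aₙ)P(C|Aₙ) is the entropy-maximizing distribution subject to
   matching the empirical (Aₙ,Bₙ) and (Aₙ,C) marginals. Because the
   structure is decomposable, iterative proportional fitting (IPF) from
   the uniform distribution converges to it in one cycle;
   `maxent_structure_check` runs IPF on the observed-support grid and
   reports the max-norm distance (≤ 1e−6 required, ~1e−16 observed). It is
   a test-scale verifier and refuses grids beyond 2048 cells.

Entropies are in bits throughout, computed as log₂N − (1/N)Σ c·log₂c over
count tables to avoid forming per-cell probabilities. Count dictionaries
are ordered (sorted keys), so every sum — and hence every report — is
bit-reproducible across runs and platforms.

The conditional-entropy gap g(n) = H(C|Aₙ) − H(C|A,B) is non-negative and
non-increasing in n for the plug-in estimate (conditioning on a superset
of variables can only lower empirical conditional entropy), and is exactly
0.0 at n = L: at full length the two terms are the same sum evaluated in
the same order, so the subtraction cancels in floating point, not just in
expectation. The CH-70 acceptance test exploits this — no tolerance is
needed for the n = L endpoint.

## Criteria and tie-breaking

* MDL(n) = (log₂N/2)·dim(n) − LL(n); AIC(n) = dim(n) − LL(n);
  dim(n) = ‖Aₙ‖·‖C‖ − 1 from *observed* support sizes, counting only the
  (prefix, class) table. Since H(Aₙ) + H(Bₙ|Aₙ) = H(X₁…X_L) is constant in
  n, both criteria effectively trade N·H(C|Aₙ) against the dimension term;
  dim(n) is non-decreasing in n, which is what stops the sweep from
  drifting late on noise.
* CH-70's score is n itself when g(n) ≤ ρ·g(1) and +∞ otherwise (a real
  `inf`, so the argmin needs no special casing). ρ defaults to 0.3 — the
  criterion's name refers to the 70% *reduction* of the baseline gap. The
  baseline is g(1), i.e. conditioned on the first time point, not the
  unconditional H(C). A zero baseline accepts every n.
* At N = 4 the MDL coefficient log₂4/2 = 1 equals AIC's, and the two
  curves coincide exactly — a useful exact fixture.
* Ties in the sweep break toward the earliest n (strict-less update),
  because earliness is the objective; `tie="latest"` is available.

## Synthetic study conditions

The generator plants a ground-truth split n\*: classes are uniform over K
labels; each prefix symbol is, with probability `signal`, a deterministic
class pattern and otherwise uniform; suffix symbols never consult the
class (i.i.d. uniform, or a shared sticky Markov chain continued from the
last prefix symbol — class-conditionally independent either way, since
the dependence runs through the prefix). The class pattern is a shared
base sequence except in the trailing prefix cells, which spell the class
index in base-a digits. This concentrates the class information at the
*end* of the prefix, which is what makes n\* identifiable: positions
before n\* are needed to populate the prefix configurations but the gap
collapses only once the digit cells are read, so at `signal = 1` the
closed forms are H(C|A_n\*) = 0 and g(n) = H(C) for n < n\*. A pattern
that separated classes at every position would let the criteria stop
earlier than n\* with no loss — the planted point would not be the right
answer. Randomness is one counter-based stream per instance, keyed by
(seed, instance index), so growing N never reshuffles earlier instances.

Defaults — N = 500, L = 12, m = 1, a = 3, K = 2, n\* = 4, signal = 0.9,
uniform suffix — are the package's benchmark study conditions, sized so
that the prefix table is well-populated (≈ 500 instances over ≤ 81 prefix
states) while the full joint is sparse, the regime the method targets.
Under them AIC recovers n = 4 in ≥ 95 of 100 seeds (100/100 measured) and
MDL, with its heavier penalty, never chooses later than n\*.

What the generator does *not* emulate: temporal autocorrelation within
the prefix, class imbalance, label noise, per-class suffix dynamics, and
continuous-valued structure beyond class-dependent level shifts (the raw
embedding maps symbols to equiprobable-bin centers plus Gaussian noise).
Passing tests therefore demonstrate correctness of the estimator and the
criteria under clean conditional-independence structure, not robustness
on arbitrary real signals.

One caveat worth stating: with no class signal at all, the *population*
gap is zero at every n, but the plug-in g(1) is not — when full
configurations are near-unique, H(C|A,B) is biased toward zero while
H(C|A₁) is not, so the empirical baseline is large. The tests assert the
population statement only where the empirical joint is well-populated
(short series, large N), and the exact zero-baseline branch on a
construction that is class-balanced by design.

## Discretization choices

Per-series, per-channel z-normalization (population sd; numerically
constant series map to zeros rather than amplifying rounding noise), PAA
with exact fractional mass splitting when the word length does not divide
the series length, and breakpoints at standard-normal quantiles i/a.
Symbol intervals are right-open: a value equal to a breakpoint takes the
higher code, a deterministic and testable tie rule. Word length and
alphabet size are explicit configuration (defaults a = 4); no automatic
per-dataset parameter selection is attempted.

## Numerical and degenerate-input conventions

* "Distribution sums to 1" tolerance: 1e−9 absolute; entropy uses
  0·log₂0 = 0.
* Empty suffix at n = L: P(Bₙ|Aₙ) := 1, H(Bₙ|Aₙ) := 0, so the sweep is
  well-defined at the endpoint.
* A single-class dataset is legal: dim(n) = ‖Aₙ‖ − 1 and every H(C|·)
  is 0.
* The paired Wilcoxon comparison drops zero differences and reports the
  effective sample size; with all differences zero it returns a
  degenerate report with no p-value instead of a spurious one.
* The earliness/accuracy trade-off statistic BEA(p) = p(100−E) + (1−p)A
  is provided for comparing criteria when an external classifier supplies
  accuracies; no classifier is bundled, since the method characterizes
  the dataset, not a decision rule.

## Problem sizes

The default test suite and the acceptance script run on datasets up to
N = 1000, L = 50, m = 2 (single-seed smoke) and N = 500, L = 12 over 100
seeds (recovery rates); a full sweep at the latter size takes ~60 ms, so
the complete acceptance run finishes in well under a minute on one core.

## Known limitations

* The method outputs one global split for the dataset; it does not make
  per-instance early decisions or streaming cut-offs.
* Plug-in entropies are biased in sparse regimes (many near-unique
  configurations); MDL/AIC's dimension term compensates within the sweep,
  but the reported gap values themselves are not debiased.
* Fixed length is required; no missing values, no imputation.
* Benchmark archives are not bundled or downloaded; validation against
  them is possible through the CSV reader but reproducing published
  numbers depends on discretization settings the archives do not fix.
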