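# mcec

**How early can a collection of labelled time-series be classified?**

`mcec` answers that question for a dataset as a whole. Given N fixed-length
discrete series (univariate or multivariate) with one class label each, it
finds the earliest time point n from which the class can be predicted
without material loss of information — before any classifier is trained.
Typical users are biostatisticians and time-series miners triaging signals
such as ECG heartbeats, sensor traces or spectrograms: knowing that the
first 30–40% of a signal already carries the class information tells you
where to focus modelling effort, and how early a downstream early-warning
system can plausibly fire.

## The method

Write a series of length L as variables X₁…X_L with class C. A split point
n partitions it into the prefix Aₙ = {X₁…Xₙ} and suffix Bₙ = {Xₙ₊₁…X_L}.
The structured model at n keeps only the dependencies {Aₙ, Bₙ} and
{Aₙ, C}: it is the Bayesian network with Aₙ the sole parent of both Bₙ and
C, whose joint factors as

    P_Sₙ = P(Aₙ) · P(Bₙ | Aₙ) · P(C | Aₙ)

with every factor a plug-in frequency from the data (no smoothing). This
factorization is exactly the maximum-entropy distribution matching the
empirical marginals on (Aₙ, Bₙ) and (Aₙ, C) — the package verifies that
numerically by iterative proportional fitting. Three criteria score each
n = 1…L (everything in bits):

* **CH-70** — the conditional-entropy gap g(n) = H(C|Aₙ) − H(C|A,B)
  measures the class information the suffix still holds. CH-70 accepts the
  earliest n whose gap has fallen to ≤ 30% of its n = 1 baseline (a 70%
  reduction; the residual fraction ρ is tunable).
* **MDL** — (log₂N / 2)·|Sₙ| − LL(D|Sₙ), the BIC-style description length.
* **AIC** — |Sₙ| − LL(D|Sₙ), charging one bit per parameter.

Here LL(D|Sₙ) = Σⱼ log₂ P_Sₙ(instance j) and the model dimension counts
only the (prefix, class) table, |Sₙ| = ‖Aₙ‖·‖C‖ − 1, with ‖Aₙ‖ the number
of *observed* distinct prefix configurations. The chosen n is the earliest
minimizer of the criterion; earliness is reported as n/L × 100%. MDL's
heavier penalty makes it the most aggressive (earliest) of the three, AIC
balances earliness against fit, and CH-70 tracks pure information loss.

Real-valued series are first made symbolic by the standard SAX pipeline:
per-series z-normalization, piecewise aggregate approximation to W
segments, and coding against equiprobable standard-normal breakpoints.

## Worked example

Generate a synthetic collection with a planted earliness point — 200
binary series of length 8 whose class is decodable from the first 3 time
points only (signal strength 0.9), with a class-independent suffix — then
sweep the criteria:

```
$ mcec simulate --N 200 --L 8 --n-star 3 --alphabet 2 --seed 5 --output fixture.csv
wrote 200 series (L=8, m=1, planted n*=3) to fixture.csv
$ mcec run --input fixture.csv --discrete --criterion all --output report.json
aic: n = 3 / 8 (earliness 37.50%)
ch70: n = 3 / 8 (earliness 37.50%)
mdl: n = 3 / 8 (earliness 37.50%)
```

All three criteria recover the planted split: after 3 of 8 time points
(37.5% of the series) the remaining measurements add no usable class
information. The JSON report carries the full curves behind that choice.
On this run the entropy gap g(n) drops from 0.845 bits at n = 1 to 0.191
at n = 3 — a 77% reduction, crossing the CH-70 threshold — and then decays
to exactly 0 at n = L; the AIC curve bottoms out at n = 3 (1276.6 bits vs
1399.4 at n = 1) before the growing number of observed prefix
configurations makes larger models more expensive than their fit gain.

The same `mcec run` works on real-valued CSV collections (label first or
last, univariate or multivariate) via `--word-length` / `--alphabet-size`,
which route the data through the SAX discretizer first.

From Python:

```python
from mcec import SyntheticSpec, generate, mcec

data = generate(SyntheticSpec(N=200, L=8, alphabet_size=2, n_star=3, seed=5))
result = mcec(data)                      # all three criteria
print(result.criteria["aic"].n)          # -> 3
print(result.entropy_gap_curve[-1])      # -> 0.0, exactly
```

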