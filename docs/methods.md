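# Methods

## Problem and data model

The package analyzes cohorts of SNP-array intensity profiles: tumor
arrays from two exposure groups (default 26 exposed, 17 unexposed) plus a
pool of germline reference arrays (default 14).  Probe signal is modelled
as proportional to locus copy number with multiplicative nuisance
factors:

```
I(p, s) = a(p) · g(s) · (c(p,s) / 2) · exp(ε),   ε ~ N(0, σ_noise²)
```

where `a(p)` is a probe affinity (log-normal, σ_affinity = 0.25 by
default), `g(s)` a per-array scale factor (log-normal, σ_scale = 0.3) and
`c(p,s)` the underlying integer copy number.  A homozygous deletion
(c = 0) emits at the small positive floor 0.05 · a · g instead of zero so
the log domain stays regular.  The simulator draws all three factors from
a single seeded generator; a global seed fans out to fixed child seeds
(map, carrier draws, noise) so each stage reruns identically in
isolation.

The default simulated genome uses chromosome lengths rounded to the Mb
for human chromosomes 1–22 and X, with 10,000 probes allocated
proportionally to length (largest-remainder rounding, ties by chromosome
order) and placed uniformly without replacement.  The four default
planted segments are gains (3 copies) at the coordinates and per-group
carrier frequencies of the strongest contrasts in the motivating study
(16/26 vs 3/17, 15/26 vs 3/17, 3/26 vs 9/17, 1/26 vs 8/17).  Carrier
status is an independent Bernoulli draw per tumor per segment, so
realized counts vary binomially around those frequencies — deliberately,
since the downstream test must work on realized cohorts, not idealized
ones.

What the simulator does **not** emulate: allele-specific signal and LOH,
probe cross-hybridization, GC/fragment-length waves, tumor purity or
subclonality.  Passing recovery tests therefore demonstrate correctness
of the inference chain under the stated multiplicative model, not
robustness to every artifact of real chemistry.

## Normalization

The baseline array is the array whose per-array mean intensity is the
median across arrays (lower of the two middle arrays when the count is
even, so the baseline is always a real array).  Every other array is
normalized to it:

* **Invariant set.**  Starting from all probes, within-set ranks are
  recomputed each iteration and probes with
  `|rank_target − rank_baseline| / set_size ≥ 0.02` are dropped, until
  the set shrinks by < 1% in an iteration, or falls to the minimum size
  (100) or the iteration cap (30).  Ranks are scale-free, so the
  selection is invariant to multiplying either array by a constant.
* **Normalization curve.**  Over the invariant set, duplicate target
  values are first collapsed to the median baseline value at that target
  value (this keeps the curve a function and makes noise-free, discrete
  data normalize exactly); a centered running median (window = 1% of the
  set, minimum 3, symmetric truncation at the ends) smooths the curve,
  and all probes are mapped through piecewise-linear interpolation with
  constant-ratio extrapolation beyond the curve ends.  Medians of
  positive values are positive, so normalized intensities stay positive.

Copy ratios are `2 · tumor(p) / trimmed-mean(refs(p))` with 10% trimmed
from each side of the normalized reference pool; the trimmed mean guards
the denominator against an outlying germline array.

## Copy-number HMM

States are integer copy levels 0–5 with stationary prior
(0.02, 0.04, 0.84, 0.06, 0.03, 0.01) — heavily diploid, mildly
gain-skewed to match tumor cohorts where gains outnumber losses.
Emissions are Gaussian around the state level (σ = 0.35; state 0 emits at
the 0.05 floor).  Transitions depend on the inter-probe gap `d`:

```
q(d) = ρ (1 − e^{−d/L}),   ρ = 0.1,  L = 1 Mb
```

is the probability of leaving the current state, distributed over
destinations proportionally to the prior.  Adjacent probes are therefore
strongly correlated while probes separated by ≫ 1 Mb decouple to the
event rate; only gaps matter, so posteriors are invariant to translating
all positions.  σ = 0.35 places the 2.8/1.2 calling thresholds roughly
2.3 σ from the diploid level while keeping single-copy steps (distance
1.0 ≈ 2.9 σ) well separated.

Decoding is by forward–backward (scaled, vectorized across samples;
emission rows are rescaled by their maximum, which cancels in the
posterior) and the reported value is the posterior mean `Σₖ k·γₜ(k)` — a
continuous quantity against which the fractional thresholds 2.8 and 1.2
are meaningful.  Viterbi decoding is available via `decode="viterbi"`.
The decoded profile is median-smoothed within each chromosome with a
3-SNP centered window (edges truncate); smoothing never leaves the input
range.  Parameters are fixed, not learned: the cohorts are small, the
state levels are physically pinned at integer copies, and fixed
parameters keep the pipeline deterministic.

Correctness is anchored by an exhaustive-path oracle: on instances with
≤ 8 probes and 3 states, forward–backward posteriors equal explicit
summation over all 3⁸ paths to 1e−10.

## Calling, recurrence, region statistics

Gain requires copies > 2.8 and loss copies < 1.2 — strict inequalities —
sustained over ≥ 3 consecutive SNPs within one chromosome; shorter runs
revert to normal (enforcement is idempotent).  Per-sample burden is the
count of maximal altered runs.

A recurrent region is a maximal run of ≥ 3 consecutive probes, each
altered in the same direction in ≥ 15% of tumors; the per-probe reading
of the frequency condition is the strictest one and makes maximal runs
well defined.  Gains and losses are detected separately.  Region sizes in
Mb are **truncated** (floored) at two decimals, computed in integer
arithmetic to avoid float artifacts; the bundled study coordinates
regenerate all twelve published sizes only under truncation (13.9286 Mb
prints as 13.92), which is how the convention was identified.

## Exposure association

Within each region a sample is *gain* (*loss*) if it has ≥ 3 consecutive
gain (loss) probes inside the region; if both, the direction with more
called probes wins, ties to gain; otherwise *normal*.  The resulting
3×2 table (gain/loss/normal × exposed/unexposed) is tested with the exact
conditional test: with both margins fixed, the table probability is
multivariate hypergeometric, and the two-sided p-value sums all
margin-compatible tables whose probability does not exceed the observed
table's.  The minimum-likelihood two-sided rule (rather than doubling a
one-sided tail) is required to reproduce the published values: on the
printed counts 7/26 vs 0/17 it gives 0.031 (printed 0.03) where the
one-sided tail gives 0.02.  Probabilities are exact `Fraction`s — ties
are included exactly, with no floating-point slack rule — and a zero row
margin reduces the test exactly to the 2×2 hypergeometric test, which is
cross-checked exhaustively against `scipy.stats.fisher_exact` for every
2×2 table with grand total ≤ 30.

Reported p-values are truncated, not rounded (3 decimals when p < 0.01,
else 2): enumeration gives 0.005821 and 0.037441 for two bundled regions
whose published values are 0.005 and 0.03 — consistent only with
truncation.  Full precision is always carried alongside, and BH step-up
q-values are computed from the full-precision values
(`statsmodels.stats.multitest`).  The `truncate_p` helper snaps its input
to 9 decimals first so a float like 0.29 (stored as 0.28999…96)
truncates as the decimal it denotes.

Burden and annotation-overlap comparisons use Welch's unequal-variance
t-test; with two zero-variance groups the degenerate result is defined
explicitly (equal means → t = 0, p = 1; different means → t = ±∞,
p = 0).  Annotation-overlap incidence is the percentage of a sample's
gain segments sharing ≥ 1 bp with any track interval (BED input, 0-based
half-open, converted to 1-based closed on read); samples with no gains
contribute 0% rather than being dropped, so every tumor enters the
comparison.

## Design choices and open points

* **Model/Results API.**  The pipeline is exposed as
  `CnaCohortModel.fit() → CnaCohortResults` so parameters, data and
  fitted artifacts have one home each; the stage functions remain
  importable for piecemeal use, and the CLI is a thin wrapper.
* **One global baseline.**  All arrays — tumor and reference — are
  normalized to a single baseline before ratios are taken; normalizing
  references to a separate baseline would introduce an arbitrary scale
  between numerator and denominator.
* **Burden units.**  Group burden is compared on raw per-sample segment
  counts; percentage-of-genome variants are a display choice, not a
  different test.
* **Problem sizes.**  Default analyses run at 10,000 probes × 57 arrays
  (a full fit takes a few seconds); oracle sweeps use 8-probe HMM
  instances and all 2×2 tables to N = 30.  These sizes exercise every
  code path at full cohort scale.
* **Limitations.**  No allele-specific states, purity/ploidy correction
  or EM parameter learning; recurrent-region counts at cohort scale
  depend on the noise realization, so only their invariants — not a
  fixed count — are asserted.
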