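# Methods

## The simulated trial

A trial is a table of 200 subjects: ID, arm (A/B), baseline value,
binary outcome. The allocation column comes from permuted-block
randomisation with block size 4 (each block an independent uniform draw
over the 6 balanced arrangements), giving exactly 100 subjects per arm.
The baseline column is 200 i.i.d. draws from uniform[1.00, 4.50],
rounded to 2 decimals (half away from zero, spreadsheet-style, applied
at generation; values are exact thereafter) and listed ascending.
The outcome is success (0) iff baseline ≤ 2.00 — the boundary value
itself is a success — so the baseline is perfectly prognostic and the
two treatments are exactly equivalent: any between-arm difference in
outcomes is attributable to who got into which arm.

### Pairing values with subjects

`assignment="sequential"` (default) matches the ascending value list
positionally against the allocation column, which is what sorting a
spreadsheet's rows by the allocation column does. This has a strong
statistical consequence: each block of four *consecutive order
statistics* is split two/two between the arms, so unbiased arms are
nearly exchangeable copies and the between-arm baseline MD has a
standard deviation an order of magnitude below the √(s²_A/n + s²_B/n)
that the significance test assumes. Under this protocol the baseline
test's false-positive rate is ≈0, not the nominal 5% — which is exactly
why a simulated study of 50 unbiased trials can observe zero false
positives for both detectors.

`assignment="shuffled"` pairs values with subjects by a uniform random
permutation (simple random assignment). It is the idealised benchmark:
under it the baseline z-test shows its textbook ~5% type-I error (a
property the test suite verifies at 1000 trials). It is not the default
because the default must be the protocol whose operating
characteristics the package studies.

### Bias injection

Severity-k subversion forces the k lowest baseline values into the
first k arm-A slots of the allocation sequence; the remaining 200−k
values fill the remaining slots under the configured assignment scheme.
The k smallest values are therefore always a subset of arm A — the
exact invariant a subverted allocation produces. Under sequential
assignment the values displaced from those early slots (ranks k+1..~2k,
still low) land in early arm-B slots, so the induced baseline MD is
roughly −0.000175·k² (≈ −0.19 at k=33, −0.31 at k=42): large enough to
inflate the outcome RD, small enough that the baseline z-test usually
misses it. This is the regime in which the two detectors genuinely
disagree. (Redistributing the remainder uniformly at random instead
would hand arm A *all* low values and arm B none, an MD of ≈ −0.58
that every detector flags — gross subversion, not the subtle kind.)

## Detectors

**Baseline significance test.** Two-sided z-test on the baseline MD;
flagged iff p < α (default 0.05). Strict inequality implements the
boundary convention that p exactly α — equivalently a CI limit exactly
zero — is non-significant.

**Single-trial I² test.** For each SCT group size m ∈ {100, 200, 400,
600}: build two null comparator trials on the test trial's observed
value range [lo, hi] (its min/max), confirm the pair pools to I² = 0%,
add the test trial's baseline MD as a third study, and record the
three-study fixed-effect I². Flagged iff I² > 0% at any size (the
`rule` option also offers "all" and "largest"; "any" is the literal
reading of the positivity criterion). I² is compared to zero exactly —
after the max(0, ·) truncation, I² = 0 ⇔ Q ≤ df, no epsilon.

**SCT construction.** Two modes:

- `sct_mode="moment"` (default): each comparator arm carries the exact
  uniform moments of [lo, hi] — mean (lo+hi)/2, SD (hi−lo)/√12 — at
  group size m. Both arms identical means the pair's I² = 0% holds by
  construction, and the test is a deterministic function of the trial:
  it flags iff the trial's |MD| exceeds √(2/w_eff(m)) for some m, where
  w_eff is the harmonic combination of the trial's and the comparators'
  inverse variances. Larger m shrinks comparator SEs, grows w_eff and
  so never lowers the per-size I²: sensitivity is nondecreasing in m.
- `sct_mode="sampled"`: comparator arms are fresh uniform samples from
  [lo, hi], summarised, with accept/reject regeneration until the pair
  pools to 0% I² (regeneration counts are reported; the attempt budget
  defaults to 1000). This adds comparator noise and, across four
  independently sampled pairs, a multiplicity effect that raises both
  sensitivity (to ≈0.95) and the false-positive rate (a few percent)
  relative to the moment mode.

The moment mode is the default because an idealised null comparator is
what the 0%-I²-confirmed pair is meant to be, and because the
benchmark's reported operating characteristics (≈24% vs ≈76%
sensitivity, no false positives) are reproduced by it; the sampled mode
is retained for sensitivity analysis of the comparator recipe itself.

When only arm summaries are available (the CLI `detect` path on real
trial data), the unobserved range is moment-matched as mean ± √3·SD
(the uniform relation between SD and half-range), using pooled
statistics of the two arms.

## Statistical engine

MD: point x̄_A − x̄_B, SE √(s²_A/n_A + s²_B/n_B) with n−1 sample SDs.
RD: risks are failure proportions; unpooled binomial SE. Inference is
z-based throughout (matching meta-analysis software convention; no t
correction), with CI half-width z_{1−α/2}·SE. A zero SE raises a typed
`DegenerateEstimateError` rather than fabricating p ∈ {0, 1}: zero-cell
corrections are deliberately not applied because the study conditions
(event risks ≈ 0.6–0.85 at n = 100) cannot produce them, and silent
guessing would corrupt the accuracy bookkeeping on pathological input.

Fixed-effect pooling uses inverse-variance weights; Q, df = k−1, and
I² = max(0, (Q−df)/Q)·100 are reported as point estimates only. The
implementation is cross-checked in the tests against independent
routes (statsmodels `combine_effects` and R's metafor `rma(method=
"FE")`), which are never used as the implementation itself.

Accuracy bookkeeping: flagged-biased → TP, unflagged-biased → FN,
flagged-unbiased → FP, unflagged-unbiased → TN. Sensitivity and
specificity carry exact Clopper–Pearson intervals (beta quantiles;
endpoints pinned to 0/1 at the boundary counts) — exact intervals are
the ones that reproduce printed bounds like 92.89–100% for 50/50.
Sensitivities are compared with the pooled two-proportion z-test.
Buderer sizing returns the formula's ceiling; the protocol's 100-trial
study is that 98 rounded up for convenience.

## Study-level defaults and seeds

`StudyConfig()` is the full protocol: 100 trials, 100 subjects/arm,
uniform[1.00, 4.50] baseline, threshold 2.00, block size 4, severities
33..42 × 5 biased trials + 50 unbiased, sequential assignment. One
master seed; trial i uses the independent substream seeded [seed, i]
(and its detector RNG [seed, i, 101]), so any trial is reproducible in
isolation and CSV outputs are byte-identical across reruns. Replicate
studies derive per-replicate seeds from [seed, r] via a seed sequence,
keeping them independent and below 2³¹.

## What the generator does and does not emulate

It emulates the benchmark's idealised world: a single perfectly
prognostic baseline variable, deterministic outcomes, equally effective
treatments, uniform covariate, and subversion that always targets the
lowest values. Real trials have noisy multi-variable prognosis,
stochastic outcomes, and subtler subversion; a detector's accuracy here
is an upper bound on what the same detector can do in practice, and
passing tests show internal consistency with this model, not field
performance. The severity range k = 33..42 (16.5–21% of subjects) is
the only regime examined; both detectors' sensitivities depend strongly
on k, so numbers do not extrapolate outside it.

## Numerical and scale choices

Replicated accuracy measurements use 10 replicate studies (1000 trials,
500 biased) — enough to pin the mean sensitivities to ±2 percentage
points, while a single 50-biased-trial study has ±6-point Monte-Carlo
error. The severity-curve check uses 20 trials per severity. At k = 39
the per-trial probability of a significant RD favouring A is ≈0.91
(directly: RD = (N−78)/100 with N = #values ≤ 2.00 ~ Binomial(200,
2/7), significant iff N ≲ 66), reaching ≈0.999 at k = 42, so the
curve's high-severity plateau is asserted as a pooled ≥85% rather than
a literal 100%, which a 20-trial sample attains only by luck.

## Known limitations

- The sequential-assignment coupling makes the unbiased baseline MD
  nearly degenerate; consumers wanting a calibrated null must opt into
  `assignment="shuffled"`.
- The I² test's moment-mode decision boundary is sharp in |MD|; trials
  sitting exactly at the boundary flip with the observed min/max, which
  is itself a random quantity.
- No random-effects models, no CIs on I², no multi-variable baselines,
  and no modelling of measurement error in the baseline covariate.
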