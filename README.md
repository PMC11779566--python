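# rctbias

Simulation of selection bias in two-arm randomised controlled trials
(RCTs), and a benchmark of two single-trial methods for detecting it:

- the **baseline significance test** — the conventional practice of
  z-testing the between-arm mean difference (MD) of a baseline variable
  and calling p < 0.05 an indication of bias, and
- the **single-trial I² test** — a trial-adjusted procedure that pools
  the test trial's baseline MD with two *simulated comparator trials*
  (SCTs) built on the trial's own value range, in a fixed-effect
  meta-analysis at SCT group sizes 100/200/400/600, and calls
  I² > 0% at any size an indication of bias.

The package is for methodologists studying trial appraisal: it lets you
generate trials whose allocation was (or was not) subverted, with known
severity, and measure each detector's sensitivity and specificity
against that ground truth.

## The simulation model

Each trial mirrors a spreadsheet with four parallel columns: subject ID;
allocation to arm A or B from permuted-block randomisation (block size
4, 100 subjects per arm); a baseline covariate drawn i.i.d. uniform on
[1.00, 4.50], rounded to 2 decimals and listed ascending; and a binary
outcome that is a deterministic function of the baseline (failure, score
1, iff baseline > 2.00 — so the covariate is maximally prognostic).
Unbiased trials pair the ascending value column positionally with the
allocation column, as a spreadsheet sort by the allocation column does.
A trial is biased with severity *k* by forcing the *k* lowest baseline
values into arm A's first *k* allocation slots (k = 33..42, five trials
each; 50 biased and 50 unbiased trials per study), which systematically
hands arm A healthier subjects and inflates its apparent success rate.

Core statistics, in standard notation:

- MD = x̄_A − x̄_B, SE = √(s_A²/n_A + s_B²/n_B); RD = p̂_A − p̂_B with the
  unpooled binomial SE; z-based CIs and p-values throughout.
- Fixed-effect pooling: w_i = 1/SE_i², Q = Σ w_i (θ_i − θ̂)²,
  I² = max(0, (Q − df)/Q) · 100.
- Sensitivity = TP/(TP+FN), specificity = TN/(FP+TN) with exact
  Clopper–Pearson 95% CIs; sensitivities compared by a pooled
  two-proportion z-test; study sizing by Buderer's formula.

## Worked example

```sh
python examples/03_full_study.py
```

prints (seed 1):

```
           method  tp  fp  fn  tn  sensitivity  sens_ci_low  sens_ci_high  specificity  spec_ci_low  spec_ci_high
significance_test  12   0  38  50         0.24     0.130610      0.381691          1.0     0.928878           1.0
          i2_test  37   0  13  50         0.74     0.596552      0.853699          1.0     0.928878           1.0

sensitivity comparison (pooled z): z = 5.0, p = 5.7e-07

severity curve (T% = trials with RD significant favouring A):
 severity_k  n_trials  t_percent
         33         5       40.0
         34         5       20.0
         ...
         42         5      100.0
```

Reading: of the 50 subverted trials, the baseline significance test
caught 12 (sensitivity 24%) while the I² test caught 37 (74%); neither
produced a false positive among the 50 clean trials (specificity 100%,
exact 95% CI 92.89–100%). The pooled z confirms the sensitivity gap is
far beyond chance. The severity curve shows the fraction of biased
trials whose outcome risk difference becomes spuriously significant in
favour of arm A, rising from ~40% at k = 33 to 100% at high severity.
`examples/02_detect_bias.py` shows the two detectors disagreeing on a
single deterministic trial, and the CLI mirrors the library:

```sh
rct-biasim run --out results/ --seed 1
rct-biasim detect --summaries arms.csv --method both
rct-biasim samplesize --sens 0.85 --prev 0.5 --precision 0.1 --conf 0.95
```

## Layout

- `src/rctbias/trial_sim.py` — trial and study generation
- `src/rctbias/meta_engine.py` — MD/RD estimates, fixed-effect pooling, Q, I²
- `src/rctbias/detectors.py` — the two bias detectors and SCT construction
- `src/rctbias/accuracy.py` — confusion matrices, exact CIs, z-test, Buderer
- `src/rctbias/experiment.py` — end-to-end study orchestration and reports
- `src/rctbias/fixtures.py` — deterministic fixtures with derived expectations
- `docs/methods.md` — modelling assumptions, design choices, limitations
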