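# Methods

## Model and assumptions

The package implements exact Bayesian inference in a seven-variable
binary network describing one act of testimony about a politically
charged hypothesis. Five root variables — Hypothesis (H), Hypothesis
Leaning (HL), Source Leaning (SL), Bias Intensity (BI), Expertise (E) —
carry independent marginal priors. Bias Direction (BD) is a
deterministic child: *for* the hypothesis when SL and HL match,
*against* when they clash, so its prior is
`f = sl·hl + (1−sl)(1−hl)`. Testimony (T) is the only observed node;
its conditional probability is deterministic or fair-coin in every
cell:

```
P(T = true | H, BD, BI, E) = BI·[BD = for] + (1 − BI)·(E·[H] + (1 − E)/2)
```

A fully biased source parrots its agenda; an impartial expert reports
the truth; an impartial non-expert flips a coin. There are no soft CPT
parameters and no fitting anywhere: the model's entire behaviour
follows from the priors fed into it. The CPT entries are exposed
read-only through `joint_enumerate`.

Two inference routes exist on purpose. `posterior_marginals` and
`variable_llr` marginalise analytically (each target's conditional
likelihood is a one-line expression in the other priors);
`posterior_marginals_from_joint` / `variable_llr_from_joint` enumerate
all 32 root configurations. The closed form is used by the pipelines;
the enumeration is the independent oracle, and the test suite holds
them together to 1e-12 over a 5⁵ prior grid. Updating is reported as a
base-2 log likelihood ratio; `logit2(post) = logit2(prior) + LLR`
wherever both sides are finite.

## Numerical conventions and degenerate inputs

* Elicited sliders are divided by 100; elicited priors of exactly 0 or
  1 are clamped to 0.01/0.99 before entering the network, because
  degenerate priors can make likelihood ratios infinite or undefined.
  Clamping happens at slider conversion, i.e. *before* the
  bias-direction prior is composed from SL and HL.
* HL is exempt from clamping and defaults to exactly 1: every
  hypothesis in the supported designs is phrased in its pro-Government
  polarity, and this particular degenerate prior never produces an
  undefined posterior. `PriorSet.clamped(clamp_hl=True)` switches to
  0.99; the difference is negligible.
* Infinite LLRs are returned as signed infinities, never capped. A 0/0
  likelihood ratio raises `UndefinedLLRError`; evidence with
  probability zero raises `EvidenceImpossibleError`. Neither can occur
  once h, sl, bi, e are clamped into (0, 1).
* Constant-vector detection in the metrics uses an exact range test
  (`ptp == 0`), since the floating-point std of a constant vector need
  not be exactly zero.
* Tests compare probabilities at 1e-12 where both sides are exact
  arithmetic and 1e-9 for the logit identity.

## Prediction pipelines

Both pipelines fix hl = 1 and carry all claim-polarity logic in the
testimony mapping (pro-Government claim → T = true).

* **Within-subjects design (S1)**: the hypothesis prior is assumed flat
  (0.5), because the listener in the vignette professes no opinion;
  SL/BI/E priors come from the participant's sliders; the pipeline
  predicts the posterior belief in the hypothesis for each of six
  sources (3 leanings × 2 expertise levels).
* **Between-subjects design (S2), stage 1**: the elicited post-evidence
  hypothesis prior and prior source perceptions enter the network; the
  pipeline predicts posterior BI, SL and E after the source's first
  claim.
* **Stage 2**: the participant's *observed* posterior source
  perceptions re-enter the network as fresh independent priors together
  with the prior for a second hypothesis, predicting belief after the
  source's second claim. This deliberately discards the posterior
  dependence between perception variables induced by stage 1 —
  re-entering elicited marginals is the procedure the pipelines model,
  and it trades probabilistic purity for fidelity to how such
  predictions are generated from elicited data.

Missing or out-of-range sliders fail loudly with row numbers; there is
no imputation. Non-integer sliders within [0, 100] are accepted with a
warning because export formats vary.

## Behaviour sweeps and trend checks

`run_sweep` tabulates LLR and posterior over prior grids;
`check_trends` machine-checks the qualitative behaviour: hypothesis
updating increases with expertise and decreases with bias intensity
and claim-consistent leaning; bias-intensity and bias-direction
attributions grow as the claim gets less plausible; expertise
attribution flips sign at a flat hypothesis prior and is damped by bias
intensity and claim-consistency; asserting a hypothesis shifts the
source's perceived leaning toward the hypothesis's side; swapping the
HL and SL priors exchanges their posteriors and leaves the hypothesis
LLR unchanged; complementing testimony, hypothesis prior and
bias-direction prior negates the hypothesis LLR exactly.

Default grids run 0.1–0.9 in steps of 0.1 with endpoints excluded so
that every LLR is finite; the exact grids behind the original behaviour
figures are not documented, so these are this package's reconstruction.
Monotonicity checks are non-strict with 1e-9 slack because boundary
plateaus (e.g. f = 0 making the hypothesis LLR constant in BI) are
legitimate. Two amplification claims hold only where the claim is a
priori implausible and are checked there: expertise amplifies the
leaning shift, and the BI-spread of the bias-direction LLR, only for
hypothesis priors below 0.5 (at 0.5 expertise has no effect and above
it the sign reverses); expertise amplifies the *hypothesis-prior*
spread of the bias-direction LLR everywhere.

## Evaluation statistics

* **Pearson r** across trials, plus the **mean individual r** over
  per-participant correlations (participants with a constant observed
  or predicted vector are excluded and counted — e.g. someone answering
  50 in every condition).
* **Brier score**: mean squared difference between observed and
  predicted posteriors; absolute accuracy.
* **Variance in Means (VM)**: per-design-cell means of observations and
  predictions, OLS of the former on the latter, reported as adjusted R²
  (one regressor, so the adjustment factor is (n−1)/(n−2)) × 100.
  Condition cells: 12 for the within-subjects design (3×2×2); 10 for
  between-subjects source perceptions (5 evidence × 2 first-claim); 20
  for the second hypothesis (5×2×2). VM is invariant to affine
  rescaling of predictions — it measures trend fidelity, not
  calibration.
* Derived variables for trend analysis: **persuasion** (posterior
  movement from 0.5 signed toward the claim), **lean shift** (leaning
  update signed toward the claim), **ev_support** (1–5 coding of how
  strongly presented evidence supports the first claim), **flip**
  (±0.5 for whether the second claim reverses the first). The
  multi-level regressions these feed are ordinary mixed-model fits and
  are out of scope; the package computes their inputs.
* `sensitivity_power_r` gives the minimum detectable two-tailed Pearson
  correlation by the Fisher-z approximation,
  `tanh((z_{1−α/2} + z_{power})/√(n−3))`: 0.095 at n = 870 and 0.104
  at n = 724 (80% power, α = .05).

## Synthetic data generator

The generator emulates the *shape and statistical structure* of the two
designs so that every pipeline stage is testable without participant
data; its defaults are declared stand-ins, not estimates of any
empirical distribution.

* Priors are drawn from two-parameter Beta profiles chosen to match the
  source descriptions qualitatively: expertise Beta(8,2) for the
  high-expertise exemplar vs Beta(2,8) for the low; leaning Beta(8,2) /
  Beta(2,8) / Beta(5,5) for pro-Government / anti-Government / neutral
  sources; bias intensity Beta(6,3) for partisan descriptions, Beta(3,6)
  for neutral. In the between-subjects design the post-evidence
  hypothesis prior has Beta means 0.15/0.35/0.5/0.65/0.85 across the
  five evidence levels (concentration 10), and perceptions of the
  unknown source are Beta(5,5) because the vignette enforces neutral
  priors.
* Observed posterior sliders are the model posterior plus additive
  Gaussian noise on the probability scale (default sd 0.05, roughly the
  residual scatter a 0–100 slider task produces), truncated to [0, 1]
  and rounded to the integer slider — the simplest mechanism that
  reproduces slider granularity and boundary pile-up.
* Each participant uses an independent counter-keyed substream of one
  seeded generator, so enlarging a table never perturbs earlier rows;
  the within-subjects testimony layout alternates between the two
  counterbalancing streams by participant parity (reproducibility over
  realism).
* Hidden `*_truth` columns carry the noise-free model posteriors and
  equal a fresh run of the prediction module on the same rows exactly;
  stage-2 truths are computed from the *noisy observed* stage-1
  posteriors, because that is what the prediction procedure consumes.

What passing recovery tests shows: the pipeline is self-consistent —
data generated by the model, perturbed by slider noise, is recovered
with r > 0.9 and VM > 95% at the default noise. What it does not show:
that human participants behave like the model; the generator contains
no motivated reasoning, no attention lapses, no individual differences
in scale use, and its response noise is homoscedastic, which real
slider data is not.

## Problem sizes

The recovery runs use 150 within-subjects participants (900 trials) and
724 between-subjects participants — the scale of the original samples —
and the inference-oracle comparison uses all 6,250 grid inferences; the
full suite and the acceptance script each complete in a few seconds on
one core.

## Known limitations

* Binary leanings only; no continuous or multi-valued political
  dimensions, no learned CPTs, no multi-source or repeated-testimony
  joint tracking (stage 2's marginal re-entry is the documented
  approximation), and no rival credibility models.
* The published fit statistics for human data cannot be reproduced here
  without the original participant tables; the package's recovery
  numbers characterise the pipeline on synthetic data only.
* The sensitivity correlation at n = 724 computed by the Fisher-z form
  (0.104) is reported as computed; printed figures derived from other
  power-analysis conventions may differ.
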