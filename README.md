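# biasnet

A Bayesian-network model of **source credibility** for political
testimony, for researchers studying belief updating, persuasion, and
bias perception. When a source claims a hypothesis is true, how much
should a listener update their belief — given that the source may be an
expert, and may be *biased* toward one political side? And, running the
inference the other way, what should hearing a surprising claim do to
the listener's perception of the source's bias and expertise?

## The model

Seven binary variables describe one act of testimony:

| Variable | States (1 / 0) | Role |
|---|---|---|
| Hypothesis `H` | true / false | the state of the world the claim concerns |
| Hypothesis Leaning `HL` | pro-Gov / anti-Gov | which side the hypothesis, if true, supports |
| Source Leaning `SL` | pro-Gov / anti-Gov | which side the source favours, if biased |
| Bias Intensity `BI` | biased / impartial | whether the source's claims follow its agenda |
| Expertise `E` | expert / non-expert | whether an impartial source knows the truth |
| Bias Direction `BD` | for / against | `SL` and `HL` match / clash (deterministic) |
| Testimony `T` | "true" / "false" | the observed claim |

The conditional probability table for the testimony is deterministic or
fair-coin throughout: a biased source asserts the hypothesis iff its
bias direction is *for* it; an impartial expert reports the ground
truth; an impartial non-expert testifies at random,

```
P(T = true | H, BD, BI, E) = BI·[BD = for] + (1 − BI)·(E·[H = true] + (1 − E)/2).
```

The five root variables carry independent priors, elicited on 0–100
slider scales, divided by 100, with 0/1 clamped to 0.01/0.99. Updating
is exact (the network has 32 root configurations) and is reported
either as posterior marginals or as the base-2 log likelihood ratio
(LLR), the quantity added to the prior on the logit scale:
`logit2(posterior) = logit2(prior) + LLR`. **The model has no free
parameters**: every prediction follows from elicited or assumed priors
and the fixed network.

The signature behaviour, which reliability-only models of credibility
cannot produce, is that a source whose claim *conflicts* with its own
leaning is at least as persuasive as one whose claim is
leaning-consistent — the claim cannot be explained away as bias.

## Worked example

```python
from biasnet import PriorSet, posterior_marginals, variable_llr

# a listener with no opinion on the hypothesis hears the head of a
# pro-Government think-tank (leaning .9, bias intensity .7, expertise .8)
# assert that a Government policy worked
priors = PriorSet(h=0.5, sl=0.9, bi=0.7, e=0.8)
post = posterior_marginals(priors, "TRUE")
print(f"posterior belief in the hypothesis: {post.h:.3f}")
print(f"hypothesis LLR (bits):             {variable_llr(priors, 'TRUE', 'H'):.3f}")

conflicting = PriorSet(h=0.5, sl=0.1, bi=0.7, e=0.8)  # anti-Gov leaning
print(f"same source leaning anti-Gov:      {posterior_marginals(conflicting, 'TRUE').h:.3f}")
print(f"posterior bias intensity:          {post.bi:.3f}")
print(f"posterior source leaning:          {post.sl:.3f}")
```

prints

```
posterior belief in the hypothesis: 0.577
hypothesis LLR (bits):             0.447
same source leaning anti-Gov:      0.773
posterior bias intensity:          0.808
posterior source leaning:          0.981
```

The leaning-consistent claim moves belief only to 0.577 — it is partly
explained away as bias — while the identical claim from a source leaning
the *other* way moves belief to 0.773. Asserting a pro-Government
hypothesis also raises the perceived probability that the source leans
pro-Government (0.9 → 0.981) and, because the claim was a priori 50:50,
slightly raises perceived bias intensity.

## Command line

```bash
biasnet synth    --design S1 --n 150 --seed 7 --out trials.csv --truth truth.csv
biasnet predict  --study S1 --in trials.csv --out predictions.csv
biasnet evaluate --design S1 --in joined.csv --out metrics.json
biasnet simulate --spec sweep.yaml --out sweep.csv --report trends.json
```

`synth` generates seeded synthetic participant tables for the two
supported designs (a 3×2×2 within-subjects design with six trials per
participant, and a 5×2×2 between-subjects design with two sequential
claims per trial); `predict` runs the per-participant prediction
pipelines; `evaluate` reports Pearson r, mean individual r, Brier score
and the adjusted-R² variance-in-condition-means (VM); `simulate` sweeps
LLR surfaces and machine-checks the model's qualitative trends.

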