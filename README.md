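# affectbandit

Adaptive virtual agents that deliver structured content — questionnaires,
coaching dialogues, behaviour-change interventions — can tailor *how* they
phrase each item to the individual in front of them. `affectbandit`
implements the adaptation engine for that setting: a valence-based reward
computed from the user's facial-emotion stream, and a Thompson Sampling
bandit that learns online which communicative style ("neutral" vs
"enthusiastic") keeps the user's affect stable or improving. A synthetic
affective-user simulator lets the whole closed loop — convergence, regret,
trait–style correlations — be exercised and tested offline at desk scale.

It is intended for researchers in affective computing and digital health who
want a reproducible, fully seeded reference implementation of this
adaptation mechanism, without cameras, classifiers, or LLM services: inputs
begin at the emotion-label level and prompt construction stops at the string.

## The model

During each interaction turn the user's face is classified per frame into
one of seven basic emotions, each carrying a fixed valence score `V(e)`:
Happy **+0.76**, Surprise **+0.40**, Neutral **0.00**, Angry **−0.43**,
Disgust **−0.60**, Sad **−0.63**, Fear **−0.64**. The turn reward is the
mean valence over its `T` frames,

```
R = (1/T) · Σ_t V(e_t),
```

and the learning signal is its change between consecutive turns,
`ΔR = R_t − R_{t−1}`. Each style `i` holds a Beta(α_i, β_i) posterior over
its probability of a successful turn, starting from uniform priors
α_i = β_i = 1. Per turn the policy samples `θ_i ~ Beta(α_i, β_i)`, plays the
argmax style, and — from the second turn onward — increments the played
arm's α when `ΔR ≥ 0` (success) or its β when `ΔR < 0` (failure). Rewarding
the *change* rather than the level makes the policy robust to baseline
expressiveness differences between users. ε-greedy, UCB1 and uniform
selection are included as benchmarking baselines, and cumulative regret
against simulator ground truth as the standard diagnostic.

The simulator generates users whose per-style emotion emissions are convex
mixtures of a positive- and a negative-leaning anchor distribution; a
personality trait on a 0–32 scale shifts, through a monotone logistic link,
which style carries the higher expected valence (higher trait ⇒ larger
advantage for the neutral style). See `docs/methods.md` for details and
assumptions.

## Worked example

```yaml
# demo.yaml
session: {n_turns: 32, frames_per_turn: 30, seed: 7}
user:    {kind: simulated, trait: 26.0}
cohort:  {n_users: 10, seed: 7}
```

```
$ affectbandit simulate --config demo.yaml --out demo.jsonl
session of 32 turns -> demo.jsonl; final alpha {"neutral": 15.0, "enthusiastic": 1.0}
```

A high-trait user (26 on the 0–32 scale) reinforces the neutral style: of
the 31 bandit updates, 15 credited successes to "neutral" and only 1 to
"enthusiastic". Running a ten-user cohort and correlating traits with the
final α values:

```
$ affectbandit cohort --config demo.yaml --out demo_cohort
$ affectbandit analyze --logs demo_cohort --traits demo_cohort/traits.csv --out demo_analysis
$ cat demo_analysis/correlations.csv
style,rho,p_value,n
neutral,0.6729549061404445,0.03873015873015873,10
enthusiastic,-0.6196785503312473,0.06220238095238095,10
```

Trait rank-correlates positively with α_neutral (Spearman ρ = 0.67,
exact-permutation p = 0.039 at n = 10) and negatively with α_enthusiastic —
the built-in trait→style link recovered from the adaptive sessions alone.
The same library calls are available in Python (`run_session`,
`run_cohort`, `trait_style_correlation`, `cumulative_regret`, ...).

The prompt builder produces the style-conditioned rephrasing instruction
verbatim:

```
$ affectbandit prompt --style enthusiastic --item-id 3
Rephrase the following user-facing question in a enthusiastic manner, as defined below. Do not alter the meaning or structure of the item.
Style definition: supportive, motivational, and positively expressive
Question: 'Item 3: I have been thinking about whether my behaviour needs to change.'
```

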