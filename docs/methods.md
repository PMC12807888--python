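# Methods

## The adaptation mechanism

An *interaction turn* spans from the agent delivering a script item to the
user responding. During a turn the system observes a stream of categorical
emotion labels (one per video frame) from the 7-class set {Happy, Surprise,
Neutral, Angry, Disgust, Sad, Fear}. Each label has a fixed valence score
(the default calibration is Happy +0.76, Surprise +0.40, Neutral 0.00,
Angry −0.43, Disgust −0.60, Sad −0.63, Fear −0.64), and the turn reward is
the mean valence over the turn's frames. Averaging suppresses frame-level
classifier noise; using the *change* ΔR = R_t − R_{t−1} as the learning
signal, rather than the absolute level, removes each user's expressive
baseline from the credit assignment.

Style selection is a Beta-Bernoulli Thompson Sampling bandit. Each
communicative style i holds Beta(α_i, β_i), initialised to the uniform
prior (1, 1). Per turn: sample θ_i per arm in fixed arm-index order from
one seeded generator, play argmax θ_i (floating-point ties break to the
lowest index), observe the next reward, and credit the played arm with a
success (ΔR ≥ 0, α += 1) or failure (ΔR < 0, β += 1). No update happens at
the first turn: a baseline reward of zero is logged for completeness, but
the first credit is assigned only once two real rewards exist, so a 32-turn
session applies exactly 31 updates. A zero change counts as success —
*maintaining* affect is the desired behaviour, not only improving it.

ΔR always compares consecutive global rewards, regardless of which arm was
played the turn before; there is no per-arm reward memory. The user's
numerical item response is logged but never reaches the policy.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `n_turns` | 32 | session length; matches a standard 32-item profiling script |
| `frames_per_turn` | 30 | frames sampled per turn (the real frame budget depends on camera rate and response latency and is a free parameter here) |
| priors (α, β) | (1, 1) per arm | uniform Beta priors; real values ≥ 1 accepted for sensitivity studies, updates stay +1 |
| `dominance_margin` | 2 | final-α lead (in success counts) required to call a session's dominant style; an exact tie is never a preference |
| valence scores | table above | configurable, but a map must cover all 7 labels |

Emotion labels parse case-insensitively and accept the synonym spellings
Happiness/Happy, Sadness/Sad, Anger/Angry, since both conventions are
common in emotion-recognition tooling.

## The synthetic user

No deposited interaction data exist for this setting, so the simulator
generates them. A user profile holds, per style, a categorical emission
distribution over the 7 labels, built as a convex mixture of two fixed
anchors: a positive-leaning distribution (mass on Happy/Surprise/Neutral,
expected valence ≈ +0.50) and a negative-leaning one (mass on
Sad/Angry/Fear/Disgust/Neutral, ≈ −0.43). The style's mixture weight m sets
its expected valence linearly, so a closed-form oracle exists for every
sampled stream.

A scalar trait on a 0–32 scale (the range of the EPQ Psychoticism
dimension, chosen for interpretability) controls the *gap* between the two
styles' weights through a logistic link in the standardised trait:

```
gap = preference_strength · (2·sigmoid(slope·z + intercept) − 1),   z = (trait − mean)/sd
m_neutral = base ± gap/2,  m_enthusiastic = base ∓ gap/2
```

The link is the simplest strictly monotone form that reproduces the target
direction: higher trait ⇒ larger expected-valence advantage for the neutral
style. Defaults — trait mean 16, sd 6 (mid-scale, since no participant
trait statistics are available), slope 1.5, intercept 0, preference
strength 0.6, base positivity 0.5, emission noise 0.1 (mixing 10% uniform
over the 7 labels) — were fixed once as a plausible medium-strong effect; a
strength of 0 produces null users whose two styles share one emission.

Frame labels are i.i.d. within and across turns given the style. Real
streams are temporally autocorrelated, item content modulates affect, and
faces go undetected occasionally; none of that is modelled (an empty turn
is handled explicitly: strict mode raises, lenient mode logs a missing
reward and suppresses that turn's update). Passing tests therefore show
that the *mechanism* behaves correctly under its own assumptions — exact
bookkeeping, convergence, sign recovery — not that the effect sizes match
any human population.

A second user type, `DeltaBernoulliUser`, provides bandit ground truth: the
played style succeeds with a configured probability, and the user emits a
Happy/Fear frame composition whose mean valence realises that outcome under
the ΔR rule (success re-pegs the reward at the top of the valence ladder;
failure steps one rung — one frame's worth of valence — below the previous
reward). With T frames per turn the construction is exact unless T
consecutive failures floor the ladder (probability (1−p)^T per episode), in
which case one drawn failure registers as a zero-delta success; tests use
T = 64, making this negligible.

## Numerical and design choices

- **Seeding.** One master seed per session is split (via seed sequences)
  into independent sub-streams for the policy, the user's emissions, and
  the logged-only item responses; cohort runs derive per-user child seeds
  from the master. Identical seeds give bit-identical logs.
- **Spearman correlation.** Computed on average ranks. For n ≤ 10 the
  two-sided p-value is exact, by full enumeration of the n! pairings
  (vectorised in chunks); above that the t approximation with n − 2 degrees
  of freedom is used. Small cohorts sit exactly where the approximation is
  weakest, hence the exact branch.
- **Regret.** Defined against simulator ground truth as the per-turn
  shortfall in success probability versus the best style, summed over all
  turns including the first (selection happens there even though no update
  does).
- **Dominant style.** The criterion (final-α lead ≥ margin, default 2) is a
  reporting convention, surfaced as a config knob rather than hidden.
- **Serialisation.** Policy state round-trips through JSON including the
  RNG bit-generator state, so a restored policy resumes its draw stream
  exactly. Session logs are JSONL (one turn record per line plus a footer)
  and include the per-turn frame labels by default so rewards are exactly
  replayable; `log_frames=False` drops them for large simulation studies.

## Problem sizes used in the test suite

Monte-Carlo suites run at sizes chosen to make their statistics
well-separated from their thresholds: selection symmetry uses 10,000 draws
(±0.02 band ≈ 4σ of binomial noise); convergence/regret uses 100 replicates
of 500-turn sessions with success probabilities (0.9, 0.1); trait
sign-recovery uses 100 replicate cohorts of 50 users × 200 turns, where the
observed ρ ≈ ±0.85 makes a wrong sign vanishingly rare; the null-cohort
exchangeability check averages 2,000 sessions, putting the ±1 bound about
6σ from the exact expectation of 0.

## Known limitations

- The valence map treats classifier output as hard labels; confidence
  weighting is not modelled.
- Exactly two styles are supported by the trait link (the bandit itself is
  N-ary).
- The simulator's logistic link and anchor distributions are conventions,
  not estimates — no generative ground truth exists to fit them to.
- No speech, timing, or item-content effects; the prompt builder emits the
  instruction string and stops.
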