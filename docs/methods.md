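# Methods

## 1. Fuzzy profile generation

### Variables and membership functions

Age lives on [0, 100] (1001-point grid) with five trapezoidal sets:
children (0, 0, 14, 16), teenagers (14, 16, 22, 25), youths (22, 25, 32,
42), adults (32, 42, 68, 71), seniors (68, 70, 100, 100), written as
(a, b, c, d) with a linear rise a→b, plateau b→c and fall c→d. The
published category ranges leave 32–42 uncovered and describe overlaps only
visually, so the youth and adult shoulders are extended linearly to cross
at 37, and the adult fall runs to 71 so that the stated adult/senior
overlap region (68–70) has both memberships strictly positive throughout,
including at age 70 exactly. Gender, region and locality size are
categorical and fuzzify to singletons (degree 1 on their own label).

Output variables (diet, innovation, one per taste tag) live on [0, 1].
Taste/innovation sets are low (0, 0, 0.15, 0.35), medium (0.25, 0.5, 0.5,
0.75), high (0.65, 0.85, 1, 1); the diet axis has vegan (0, 0, 0.08,
0.22), vegetarian (0.15, 0.3, 0.4, 0.55), flexitarian (0.45, 0.55, 0.65,
0.8), omnivore (0.7, 0.85, 1, 1).

### Inference and defuzzification

Mamdani scheme: a rule's firing degree is the minimum (AND) or maximum
(OR) of its term memberships, times an optional weight in (0, 1];
implication clips the consequent set at the firing degree; aggregation is
the pointwise maximum; the crisp output is the centroid by trapezoidal
quadrature on the output grid. A zero-mass aggregate falls back to the
universe midpoint (0.5) — this is the *expected* path for taste tags no
rule addresses (a neutral preference) and is logged at debug level there,
but logged as a warning for diet/innovation, whose rule blocks cover the
whole input space.

### Rule base

The three blocks (17 diet / 30 taste / 15 innovation rules) ship as an
editable YAML file; rules are data, not code. Their content encodes
standard dietary-sociology regularities: coastal residents favor fish,
inland residents meat and tubers; children prefer pasta, rice, fried food
and dislike vegetables and legumes; young urban women are the most likely
plant-based dieters; innovation declines with age and rises with city
size. Seniors receive deliberately flat taste profiles (all tags ≈ 0.5):
their rules pin the traditional categories to "medium" and no other rule
targets them, reflecting the design premise that the senior population has
no sharply defined preferences — which is what makes recommenders barely
beat random there.

### Stochastic perturbations and calibration

Three zero-mean Gaussian perturbations individualize profiles: on the
defuzzified diet score before thresholding (σ = 0.065), on the innovation
score (σ = 0.08), and on each nonzero taste probability (σ = 0.05,
truncated symmetrically around the original value by resampling so the
perturbation is mean-preserving; diet-forbidden zeros are never touched).
The diet-rule weights and σ were calibrated once, by Monte-Carlo over a
1300-user national population, so that emergent shares reproduce the
reference statistics — 87 ± 3% omnivores overall and 6 ± 2%
vegetarian+vegan above age 15 — across independent seeds (measured means
86.0% and 5.8% over 12 seeds). They were then frozen.

### Populations: emergent vs quota

A national population samples attributes from the demographic spec (age
from a piecewise-linear density over 5-year bins approximating the Spanish
population pyramid; 51% female; 58% coastal; 20/30/50% small/medium/large
localities) and lets diet and innovation *emerge* from inference — this is
the regime whose running omnivore share converges like n^(−1/2) to the
calibrated marginal (`calibration_curve`).

A target-group spec (e.g. Veggies: 70% female, any age, 0/50/30/20 diet
split, 88% innovative) is a *specification*: gender, diet shares and the
innovative-user share are enforced exactly. Diets are assigned by ranking
users on their perturbed diet score and cutting the ranking at
largest-remainder quota counts, preserving the attribute–diet correlation
while pinning the marginals; innovation is handled the same way, with
scores monotonically rescaled into [0.5, 1] (designated innovative) or
[0, 0.5) (not). "Any age" draws uniformly from 16–80; the Senior group
from 70–90.

## 2. Catalog and menus

The default catalog has 60/60/25 dishes per course spread as evenly as
possible over the course's available tags (firsts: rice, pasta, potato,
legume, vegetables; seconds: white meat, red meat, fish, fried, egg,
legume, vegetables, potato; desserts: fruit, dairy — 15 course–tag pairs,
which is the recommendation action space). Innovative flags go to a random
subset of exactly 10/23/4 dishes. Vegetarian flags: meat/fish tags never;
plant tags always; egg/dairy ovo-lacto; ambiguous tags (rice, pasta,
potato, fried) with a configurable 60% share, at least one vegetarian dish
per tag.

Menus draw k distinct tags per course (3/3/2) uniformly, then one dish
uniformly within each tag, resampling until the first and second courses
each contain a vegetarian option. Distinct tags per course is a stricter
default than the structure strictly requires; it makes a recommended tag
identify a unique option and gives the uniform-random policy the exact
expected daily reward 1/3 + 1/3 + 1/2 = 7/6 regardless of user
preferences, which serves as an analytic baseline check. Because desserts
have exactly two tags, every dessert pair contains fruit, so vegans always
have a dessert.

## 3. Choice environment

Selection is per course: weight(option) = taste[tag] × (0.5 + innovation
if the dish is innovative) × permitted, renormalized over the course's
options. Vegetarians and vegans only consider vegetarian-flagged dishes
(vegan strictness beyond that is already encoded in their zeroed egg/dairy
tastes); flexitarians have meat/fish tastes damped by 0.5 at profile
construction, so the constraint is visible on the profile itself. If all
weights are zero the user picks uniformly among permitted options. The
state is a FIFO window of the last w days of selected tag triples; since
selections depend only on profile and menu, the environment is a
contextual bandit wearing MDP clothes — a fact that matters for the DQN
discount (below).

## 4. Policies

All policies implement `recommend(user_id, state, menu, rng)` →
one offered tag per course, and `observe(transition)`.

* **random** — uniform over options; expected 7/6 per day.
* **optimum** — argmax of the true selection weights, ties alphabetical.
  Upper-bounds every policy that recommends offered tags. Note it does not
  reach 3/day: selections are stochastic, so even the oracle matches a
  0.6-probability favorite only 60% of the time.
* **mab** — ε-greedy (ε = 0.15) over per-(course, tag) propensities. The
  default update is bandit feedback: p̂ᵢ is the match rate observed when
  tag i was recommended; only a match increases p̂ᵢ. A full-information
  variant (`update_rule="selection"`, p̂ᵢ = selection frequency k/n) is
  config-exposed; it converges to the same argmax (selections are
  recommendation-independent) but much faster, and is strictly stronger
  than the described update. Greedy ties break at random.
* **sarsa** — per course, state = last selected tag, table over
  (state, candidate tag), α = 0.1, γ = 0.9, ε = 0.15; the on-policy update
  is applied when the next day's action is drawn.
* **dqn** — one shared network per group. State: last d = 3 days of
  selections, one-hot per course position (3 × 12 per day), zero-padded;
  action: one-hot course ⊕ one-hot tag (15 dims). Architecture: LSTM(32) →
  concat with action → dense(16, ReLU) → scalar Q; trained with Adam
  (lr 5 × 10⁻⁴, β₁ = 0.9, β₂ = 0.999) on MSE against
  y = r + γ·max over next-day offered actions of Q_target, with inverted
  dropout (0.2) on the hidden layer during training only. Training fires
  every 20 recommendations from day 10 on, doing 24 gradient steps on
  batches of 64 drawn without replacement from an unbounded replay memory
  (transitions are finalized when the next day's menu is seen, so the
  bootstrap max ranges over actually-offered actions); the target network
  syncs every 3 trainings; ε decays from 0.15 by 0.01 per training to a
  0.01 floor; total gradient steps are capped at 15,000.

MAB and SARSA default to one pooled table per group
(`scope="shared"`; per-user is config-exposed). This is a deliberate
modeling choice: a per-user bandit converges to ≈ 98% of the Optimum match
rate within ~120 days and would dominate any history-based network at any
horizon, which is inconsistent with the benchmark premise that the deep
model's ability to generalize across users is an advantage. With pooled
baselines, the DQN's two levers are personalization through the selection
history and its decayed exploration rate.

The DQN discount defaults to γ = 0.25 rather than a conventional 0.9:
the next state depends only on the user's selections, which are
independent of the recommendation, so the bootstrap term is an
action-independent offset whose only effect is to inflate target noise by
1/(1 − γ). A small γ keeps the target-network machinery exercised with
modest noise; γ is config-exposed. The remaining DQN defaults
(burn-in day, batch size, replay sample, epochs per training, dropout)
were fixed by a small grid search maximizing accumulated reward — the same
selection procedure the benchmark methodology prescribes for
hyperparameters.

## 5. Benchmark protocol

For each group, each simulated day and each user: sample a menu
(independently per user-day), let every policy recommend, draw *one*
selection per course from the profile and score every policy against it
(selections are recommendation-independent, so a shared stream is
unbiased and removes between-policy sampling noise; independent streams
are config-exposed). MAB/SARSA update daily; the DQN on its
20-recommendation schedule. All randomness flows from the experiment seed
through named `SeedSequence` streams, so runs are bit-reproducible and the
manifest (config + seed + log hash) fully determines the outputs.

Metrics per (algorithm, group): accumulated reward mean and sample
standard deviation (ddof = 1; a single user reports 0 by convention) over
per-user totals; improvement = 100(R − R_random)/R_random against the same
run's random policy; efficiency = matches/(users × days) over the full
horizon; precision/recall/F1 with the recommended tag as predicted label
and the selected tag as true label, macro-averaged over tags within each
course then averaged over courses (micro variant config-exposed).
Pairwise population comparisons use the two-sided Mann–Whitney U test
(the effect-size companion Cliff's delta is computed by exact pair
counting), on per-user totals and on per-user Optimum-minus-algorithm
gaps; no multiple-testing correction is applied, matching the reporting
convention of raw pairwise p-values.

## 6. Problem sizes and what the tests show

The test suite runs a reduced benchmark — 4 groups × 10 users × 120 days,
all five policies — chosen to exercise every code path and the qualitative
group structure in a few minutes: the Optimum dominates everywhere,
MAB and DQN clearly beat random on preference-rich groups, SARSA stays
near random (its 15-ish-row tables see too few visits per cell), and all
learners cluster within 15% of random on the Senior group. The population
calibration check regenerates 1300 users; the analytic 7/6 baseline uses
10 users × 1000 days.

Two caveats are documented rather than hidden. First, at 10 users ×
120 days the DQN and the pooled MAB are statistically tied (the DQN landed
2–4% below MAB on two of three preference-rich groups in the frozen-seed
run): the 3-day selection window carries little extra information beyond
the group marginal on homogeneous groups (an offline probe: Bayes-optimal
top-1 match rate with the window is 0.442 vs 0.436 for the plain marginal
table, and the 32/16-unit network itself plateaus at 0.418 even with 20k
offline gradient steps), so the DQN's decayed-ε advantage over MAB's
constant 15% exploration is of the same order as seed noise. Second, the
printed efficiency of a converged recommender (≈ 2 of 3 courses) requires
the stronger within-group preference homogeneity of a 365-day, 50-user
run with converged policies; the reduced run reports the whole horizon
including the learning ramp.

## 7. What the generator does and does not emulate

It emulates: demographically patterned preference heterogeneity,
hard dietary constraints, innovation-seeking, day-to-day stochastic choice
with stable underlying tastes, and group specifications with exact quotas.
It does not emulate: temporal preference drift, satiation or novelty
fatigue, intra-day meals, nutritional/seasonal/logistical constraints,
social or psychographic covariates, or real survey-derived rule learning.
Passing tests therefore demonstrate internal consistency and calibrated
marginals, not fidelity to any real population beyond the encoded
regularities.

## 8. Numerical choices and degenerate inputs

Grids: 1001 points per unit universe (centroid error < 10⁻³ vs 10×
resolution). Ties: argmax ties break alphabetically for deterministic
policies (Optimum, greedy DQN), at random for the MAB's greedy step
(required for the bandit-feedback variant to escape its all-zero start
under ε = 0). Quota apportionment: largest remainder. Perturbation at a
boundary value (taste exactly 0 or 1) is left unchanged — no symmetric
window exists. Zero-mass defuzzification falls back to the universe
midpoint. Menus that cannot satisfy the vegetarian guarantee raise after
a bounded number of resamples. The empty replay / pre-burn-in training
call is a logged no-op.
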