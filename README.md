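# menurec

Population-level benchmarking of menu-recommendation algorithms on
synthetic, demographically grounded food-preference profiles.

Public recommender datasets contain interactions but almost never the
demographic context (age, gender, region, city size) needed to ask how a
recommender performs across *different kinds of users*. `menurec` sidesteps
this by simulating the users themselves: a Mamdani fuzzy-inference engine
turns demographic attributes into individual preference profiles, a small
Markov decision process simulates a year of daily menu choices, and a suite
of reinforcement-learning recommenders is evaluated against those choices,
population by population. It is aimed at researchers in nutrition
informatics and recommender systems who want a controlled, reproducible
test bed with explicit user diversity.

## What it implements

**Fuzzy profile generator.** Crisp inputs (age on five overlapping
trapezoidal sets — children, teenagers, youths, adults, seniors — plus
categorical gender, coastal/inland region and locality size) are fed
through three editable YAML rule blocks (17 diet rules, 30 taste rules, 15
innovation rules). Rules fire at min(antecedent degrees) (AND), clip their
consequent sets, aggregate by pointwise max, and defuzzify by centroid
x&#773; = ∫x·μ(x)dx / ∫μ(x)dx. The diet axis is partitioned at
0.25/0.5/0.75 into vegan / vegetarian / flexitarian / omnivore; vegans and
vegetarians get hard zeros on animal-derived tags. A calibrated Gaussian
perturbation makes profiles individually diverse while national-population
shares converge to reference values (87% omnivores; 6% vegetarian+vegan
above age 15).

**Choice environment.** A dish catalog of 60 firsts / 60 seconds / 25
desserts over 12 category tags (10/23/4 innovative dishes). Each day a user
faces 3/3/2 options, and selects per course with probability proportional
to taste[tag], innovative dishes weighted by (0.5 + innovation). A
recommender emits one (course, tag) action per course from a 15-action
space; reward is 1 per matched course.

**Policies.** Uniform random (analytic expected reward 1/3+1/3+1/2 = 7/6
per day), the Optimum oracle (argmax of true selection weights — an upper
bound), an ε-greedy multi-armed bandit over per-(course, tag) match rates,
tabular SARSA with Q(s,a) ← Q(s,a) + α(r + γQ(s',a') − Q(s,a)) on the
last-selected-tag state, and a DQN whose LSTM encodes the last 3 days of
selections, with replay memory, target network and ε decaying 1 pp per
training to 1%.

**Evaluation.** Accumulated reward (mean ± sd of per-user totals),
improvement over random, efficiency (correct courses/day out of 3),
macro precision/recall/F1, and pairwise population comparisons with
two-sided Mann-Whitney U and Cliff's delta
δ = (#{xᵢ>yⱼ} − #{xᵢ<yⱼ}) / (nm), on absolute rewards and on
Optimum-minus-algorithm gaps.

## Worked example

```python
import numpy as np
from menurec import generate_population
from menurec.population import load_demographic_spec

users = generate_population(load_demographic_spec(), 500, np.random.default_rng(10))
```

prints, when summarized (`diet shares (n=500)`):

```
{'omnivore': '85.8%', 'flexitarian': '8.8%', 'vegetarian': '5.0%', 'vegan': '0.4%'}
first user: age 84, male, coastal, large city -> diet=omnivore, innovation=0.50
top tastes: rice=0.54, pasta=0.52, egg=0.52
```

The omnivore share sits near the 87% national reference; an 84-year-old
male gets a flat taste profile (everything ≈ 0.5), which is exactly why
recommenders struggle on senior populations. A reduced benchmark
(2 groups × 5 users × 60 days):

```python
from dataclasses import replace
from menurec.benchmark import ExperimentConfig, run_benchmark
from menurec.population import load_group_specs

groups = [replace(g, n_users=5) for g in load_group_specs() if g.name in ("veggies", "senior")]
res = run_benchmark(ExperimentConfig(seed=10, n_days=60, groups=groups))
print(res.metrics.pivot(index="group", columns="algorithm", values="accumulated_reward"))
```

```
algorithm   dqn   mab  optimum  random  sarsa
group
senior     70.2  65.6     77.6    69.2   69.6
veggies    89.8  93.2    111.0    71.6   87.6
```

On the preference-rich Veggie group the learners clearly beat random
(71.6) and the Optimum bounds them all at 111; on the Senior group every
policy clusters near random — flat preferences leave nothing to learn.

The same experiment is available from the shell:

```bash
menurec simulate-population --n 1300 --out pop.csv --calibration
menurec generate-catalog --out catalog.csv --map-out availability.json
menurec run-benchmark --seed 10 --days 365 --out results/
menurec grid-search --space space.yaml --group foodies --out grid.csv
```

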