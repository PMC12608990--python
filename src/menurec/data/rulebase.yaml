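# Default rule base: three blocks (diet, tastes, innovation).
# Rules are data, not code: edit freely, keeping variable/label names valid.
# Antecedent terms are joined by the block connective (AND = min, OR = max);
# `weight` scales the firing degree (0, 1].
block: diet
rules:
  - {if: [{var: age, is: children}], then: {var: diet, is: omnivore}}
  - {if: [{var: age, is: seniors}], then: {var: diet, is: omnivore}}
  - {if: [{var: age, is: adults}], then: {var: diet, is: omnivore}}
  - {if: [{var: age, is: teenagers}, {var: gender, is: male}], then: {var: diet, is: omnivore}}
  - {if: [{var: age, is: youths}, {var: gender, is: male}], then: {var: diet, is: omnivore}, weight: 0.9}
  - {if: [{var: age, is: teenagers}, {var: gender, is: female}], then: {var: diet, is: flexitarian}, weight: 0.5}
  - {if: [{var: age, is: youths}, {var: gender, is: female}], then: {var: diet, is: flexitarian}, weight: 0.6}
  - {if: [{var: age, is: teenagers}, {var: gender, is: female}, {var: locality, is: large}], then: {var: diet, is: vegetarian}, weight: 1.0}
  - {if: [{var: age, is: youths}, {var: gender, is: female}, {var: locality, is: large}], then: {var: diet, is: vegetarian}, weight: 0.9}
  - {if: [{var: age, is: youths}, {var: gender, is: female}, {var: locality, is: large}, {var: region, is: coastal}], then: {var: diet, is: vegan}, weight: 0.65}
  - {if: [{var: age, is: teenagers}, {var: gender, is: female}, {var: locality, is: medium}], then: {var: diet, is: vegetarian}, weight: 0.62}
  - {if: [{var: age, is: adults}, {var: gender, is: female}, {var: locality, is: large}], then: {var: diet, is: flexitarian}, weight: 0.1}
  - {if: [{var: age, is: youths}, {var: gender, is: male}, {var: locality, is: large}], then: {var: diet, is: flexitarian}, weight: 0.2}
  - {if: [{var: age, is: teenagers}, {var: gender, is: female}, {var: locality, is: small}], then: {var: diet, is: omnivore}, weight: 0.95}
  - {if: [{var: age, is: teenagers}, {var: gender, is: female}, {var: locality, is: medium}], then: {var: diet, is: omnivore}, weight: 0.85}
  - {if: [{var: age, is: youths}, {var: gender, is: female}, {var: locality, is: small}], then: {var: diet, is: omnivore}, weight: 1.0}
  - {if: [{var: age, is: youths}, {var: gender, is: female}, {var: locality, is: medium}], then: {var: diet, is: omnivore}, weight: 0.9}
---
block: tastes
rules:
  - {if: [{var: region, is: coastal}, {var: age, is: adults}], then: {var: taste_fish, is: high}}
  - {if: [{var: region, is: coastal}, {var: age, is: youths}], then: {var: taste_fish, is: high}}
  - {if: [{var: region, is: coastal}, {var: age, is: teenagers}], then: {var: taste_fish, is: medium}}
  - {if: [{var: region, is: inland}, {var: age, is: adults}], then: {var: taste_red_meat, is: high}}
  - {if: [{var: region, is: inland}, {var: age, is: youths}], then: {var: taste_red_meat, is: high}}
  - {if: [{var: age, is: children}], then: {var: taste_pasta, is: high}}
  - {if: [{var: age, is: children}], then: {var: taste_rice, is: high}}
  - {if: [{var: age, is: children}], then: {var: taste_fried, is: high}}
  - {if: [{var: age, is: children}], then: {var: taste_white_meat, is: high}}
  - {if: [{var: age, is: children}], then: {var: taste_vegetables, is: low}}
  - {if: [{var: age, is: children}], then: {var: taste_fish, is: low}}
  - {if: [{var: age, is: children}], then: {var: taste_legume, is: low}}
  - {if: [{var: age, is: teenagers}], then: {var: taste_pasta, is: high}}
  - {if: [{var: age, is: teenagers}], then: {var: taste_fried, is: high}}
  - {if: [{var: age, is: teenagers}, {var: gender, is: male}], then: {var: taste_red_meat, is: high}}
  - {if: [{var: age, is: teenagers}], then: {var: taste_dairy, is: high}}
  - {if: [{var: age, is: youths}], then: {var: taste_pasta, is: medium}}
  - {if: [{var: age, is: youths}, {var: locality, is: large}], then: {var: taste_vegetables, is: high}}
  - {if: [{var: age, is: youths}], then: {var: taste_egg, is: medium}}
  - {if: [{var: age, is: youths}, {var: gender, is: female}], then: {var: taste_vegetables, is: high}}
  - {if: [{var: age, is: adults}], then: {var: taste_legume, is: high}}
  - {if: [{var: age, is: adults}, {var: region, is: inland}], then: {var: taste_potato, is: high}}
  - {if: [{var: age, is: adults}, {var: gender, is: female}], then: {var: taste_vegetables, is: high}}
  - {if: [{var: age, is: adults}, {var: gender, is: female}], then: {var: taste_fruit, is: high}}
  - {if: [{var: age, is: adults}, {var: gender, is: male}], then: {var: taste_red_meat, is: high}}
  - {if: [{var: age, is: adults}, {var: gender, is: male}], then: {var: taste_white_meat, is: high}}
  - {if: [{var: age, is: adults}, {var: locality, is: small}], then: {var: taste_potato, is: high}}
  - {if: [{var: age, is: seniors}], then: {var: taste_vegetables, is: medium}}
  - {if: [{var: age, is: seniors}], then: {var: taste_legume, is: medium}}
  - {if: [{var: age, is: seniors}], then: {var: taste_fish, is: medium}}
---
block: innovation
rules:
  - {if: [{var: age, is: children}], then: {var: innovation, is: medium}}
  - {if: [{var: age, is: teenagers}], then: {var: innovation, is: high}}
  - {if: [{var: age, is: youths}], then: {var: innovation, is: high}}
  - {if: [{var: age, is: adults}], then: {var: innovation, is: medium}}
  - {if: [{var: age, is: seniors}], then: {var: innovation, is: low}}
  - {if: [{var: locality, is: large}], then: {var: innovation, is: high}, weight: 0.6}
  - {if: [{var: locality, is: small}], then: {var: innovation, is: low}, weight: 0.6}
  - {if: [{var: locality, is: medium}], then: {var: innovation, is: medium}, weight: 0.6}
  - {if: [{var: age, is: teenagers}, {var: locality, is: large}], then: {var: innovation, is: high}}
  - {if: [{var: age, is: youths}, {var: locality, is: large}], then: {var: innovation, is: high}}
  - {if: [{var: age, is: adults}, {var: locality, is: large}], then: {var: innovation, is: high}, weight: 0.7}
  - {if: [{var: age, is: adults}, {var: locality, is: small}], then: {var: innovation, is: low}}
  - {if: [{var: age, is: seniors}, {var: locality, is: small}], then: {var: innovation, is: low}}
  - {if: [{var: region, is: coastal}, {var: age, is: youths}], then: {var: innovation, is: high}, weight: 0.7}
  - {if: [{var: age, is: children}, {var: locality, is: large}], then: {var: innovation, is: medium}}
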