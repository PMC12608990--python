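# Default target-group specifications. diet_shares are percentages
# (omnivore, flexitarian, vegetarian, vegan) and are quota-enforced;
# pct_innovative is likewise a quota on users with innovation score >= 0.5.
# age_rule: "demographic" (national curve), "any" (uniform 16-80), or [lo, hi].
- name: spanish
  n_users: 50
  pct_female: 52
  age_rule: demographic
  diet_shares: {omnivore: 80, flexitarian: 16, vegetarian: 2, vegan: 2}
  pct_innovative: 45
- name: foodies
  n_users: 50
  pct_female: 44
  age_rule: any
  diet_shares: {omnivore: 72, flexitarian: 20, vegetarian: 6, vegan: 2}
  pct_innovative: 88
- name: veggies
  n_users: 50
  pct_female: 70
  age_rule: any
  diet_shares: {omnivore: 0, flexitarian: 50, vegetarian: 30, vegan: 20}
  pct_innovative: 88
- name: senior
  n_users: 50
  pct_female: 54
  age_rule: [70, 90]
  diet_shares: {omnivore: 98, flexitarian: 2, vegetarian: 0, vegan: 0}
  pct_innovative: 10
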