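"""Fuzzy satisfaction grades: how a fold change maps to [0, 1].

Therapeutic objectives use a fuzzy-equal membership (grade 1 at the healthy
level, falling linearly to 0 at 0.1x and 10x); adverse objectives use a
fuzzy-minimize membership (grade 1 at or below the healthy level, 0 at 10x).
The printed examples are concentration folds reported for the dopamine case
under different treatments.
"""

from fmdd import MembershipSpec, target_count_factor

therapeutic = MembershipSpec.equal_around(1.0)   # fold scale: basal = 1
adverse = MembershipSpec.minimize_above(1.0)

print("therapeutic grade at DA-e fold 0.486 (untreated VM50):",
      round(therapeutic.grade(0.486), 3))
print("therapeutic grade at DA-e fold 0.806 (dopamine agonist):",
      round(therapeutic.grade(0.806), 3))
print("adverse grade at DOPA-Q fold 7.962 (L-DOPA):",
      round(adverse.grade(7.962), 3))
print("adverse grade at DA-Q fold 6.953 (dopamine agonist):",
      round(adverse.grade(6.953), 3))

# the overall objective multiplies the minimum grade by a target-count
# factor (Z_UB - #targets)/(Z_UB - 1): fewer targets are preferred
for k in (1, 2, 4):
    print(f"count factor with {k} target(s), Z_UB=10:",
          round(target_count_factor(k, 10), 3))
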