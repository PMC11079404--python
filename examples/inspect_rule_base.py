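"""Generate the weighted rule base and look inside it.

Two experts rate the importance of each parameter on a 0-5 scale; the
normalized, averaged ratings weight the category codes (0 best, 1 worst)
of every one of the 108 category combinations. A combination whose
weighted code sum exceeds 0.5 is Not Safe; a tie at exactly 0.5 stays
Safe.
"""

from fractions import Fraction

import pestsafe as ps

weights = ps.normalize_weights([(2, 3, 5, 4, 1), (5, 3, 2, 1, 4)])
print("averaged weights:", [f"{float(w):.2f}" for w in weights.averaged])

model = ps.build_default_model()
rb = model.rule_base
n_not_safe = sum(r.consequent == ps.NOT_SAFE for r in rb)
ties = [r for r in rb if r.weighted_score == Fraction(1, 2)]
print(f"{len(rb)} rules: {len(rb) - n_not_safe} Safe, {n_not_safe} Not Safe,"
      f" {len(ties)} exact-0.5 ties (classified Safe)")

print("\nfirst and last rules in canonical order:")
for rule in (rb[0], rb[-1]):
    ante = ", ".join(f"{p}={c}" for p, c in rule.antecedent.items())
    print(f"  IF {ante}")
    print(f"     -> {rule.consequent} (weighted score {float(rule.weighted_score):.3f})")
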