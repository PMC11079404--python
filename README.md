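# pestsafe

Fuzzy-logic decision support for scoring how safe a pesticide is toward
the agricultural environment — in particular toward honey bees, the
bio-indicator organism at the centre of the model. Written for
agronomists, ecotoxicologists and decision-support builders who need a
transparent, reproducible ranking of candidate pesticides rather than a
black-box score.

## The model

A pesticide is described by five crisp ecotoxicological inputs:

| parameter | units | universe | categories (best → worst) |
|---|---|---|---|
| soil half-life (persistency) | days | [0, 200] | non-persistent / moderate / persistent |
| AEQ (bee exposure quotient) | – | [0, 20] | low / moderate / high contaminate |
| contact LD50 toward bees | µg/bee | [0, 200] | low / moderate / high toxicity |
| exposure likelihood | score 0–4 | [0, 4] | no likely exposure / high exposure |
| maximum residue limit (MRL) | mg/kg | [0, 400] | high / low residue limit |

Each parameter is a linguistic variable with calibrated membership
functions (triangular/trapezoidal for the three-way splits, smooth z/s
saturation curves for the two-way splits). The rule base is *generated*,
not hand-written: every category carries a code $p_i \in \{0, 0.5, 1\}$
(0 environmentally best) and every parameter a weight $w_i$ obtained by
normalizing and averaging two experts' 0–5 importance ratings
($w_i = p_i / \sum_j p_j$ per expert, then averaged; the defaults are
exactly $7/30, 6/30, 7/30, 5/30, 5/30$). Each of the
$3{\times}3{\times}3{\times}2{\times}2 = 108$ category combinations
becomes a rule whose consequent is

$$\text{Not Safe} \iff \textstyle\sum_i p_i w_i > 0.5$$

(ties at exactly 0.5 are Safe). Inference is Mamdani min/max: a rule's
activation is the minimum of its five antecedent degrees, the Safe and
NotSafe activations are aggregated by maximum, the output sets
(trapezoids NotSafe (0, 0, 3, 7) and Safe (3, 7, 10, 10) on [0, 10]) are
clipped at their aggregate degrees, and the crisp safety level point is
the centroid of the combined curve. Every score therefore lands in
[2.63, 7.37], the centroids of the fully-activated output sets.

The AEQ sub-model derives the bee exposure quotient from a field dose:
`concentration = dose × 0.99 × 1000 / 50 000` (99 % of a spray misses the
target pest; 50 000 bees per colony), `TU_bee = concentration / LD50`,
`AEQ = 1 / TU_bee`.

## Worked example

```python
import pestsafe as ps

model = ps.build_default_model()          # calibrated model, 108 rules
rec = ps.PesticideRecord("Abamectin", persistency=28, aeq=0.002,
                         ld50_bee=0.03, likely_exposure=3, mrl=0.02)
res = ps.assess(rec, model)
print(res.score_2dp, res.oracle_2dp, res.verification_value)
```

prints `2.63 2.63 1`: abamectin saturates the worst category of all five
parameters, every fired rule is Not Safe at full activation, and the
centroid of the fully-clipped NotSafe set is 2.63 — the model's floor.
The verification value 1 says the grid centroid and the closed-form
oracle agree to 2 dp.

Running `python examples/assess_sample_pesticides.py` ranks the ten
embedded sample pesticides:

```
Pesticide     Safety Level Point
Dodine        7.37
Iprodione     7.37
Clofentezine  5.44
Fenthion      2.93
DDT           2.74
Acephate      2.64
Abamectin     2.63
Dimethoate    2.63
Chlorpyrifos  2.63
Methidathion  2.63

Best option(s):  Dodine, Iprodione
Worst option(s): Abamectin, Dimethoate, Chlorpyrifos, Methidathion
```

Dodine and iprodione are the recommended options; the four compounds at
the 2.63 floor combine high bee toxicity, high contamination and a tight
residue limit. The other examples in `examples/` walk through the AEQ
chain, the rule-base generator, and the dual-route centroid parity check.

There is also a thin CLI (`pestsafe assess table.csv`, `pestsafe aeq`,
`pestsafe rules`, `pestsafe verify`, `pestsafe model`) over the same
library calls; input tables are plain CSV with columns
`name,persistency_days,aeq,ld50_ug_per_bee,likely_exposure,mrl_mg_per_kg`
(a blank `aeq` is computed from a `dose_ml_per_ha` column).

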