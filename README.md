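# poultrychain

Phase-quality KPIs, abrupt-movement detection and rule-based decision
support for broiler production chains.

A broiler flock passes through four phases on its way to market —
**breeding** (≈7 weeks in the rearing house), **loading** (manual catching
into transport cages), **transport** (the truck journey) and the
**slaughterhouse** (inspection, processing, grading).  Stress anywhere
along the chain degrades welfare and, ultimately, the meat grade the chain
manager is paid for.  This package computes the 32 indicators that
quantify each phase's quality — 5 breeding, 3 loading, 5 transport and 19
slaughterhouse KPIs — and turns a history of chain KPIs into actionable
rules for reaching grade-A meat.  It is aimed at precision-livestock
analysts and chain managers working from ordinary CSV sensor exports.

## The indicators

**Breeding.** Two KPIs measure deviation from the farmer-set optimal
temperature profile `opt(t)` (a step function per growth stage):
*Temperature Warning* = % of time with 1.5 °C ≤ |T − opt(t)| ≤ 3 °C and
*Temperature Alarm* = % of time with |T − opt(t)| > 3 °C.  Three more are
driven by a heat-stress index combining temperature and humidity (default
is the classical livestock temperature–humidity index
THI = 0.8 T + (RH/100)(T − 14.4) + 46.4): *Alert* (index in [70, 76)),
*Danger* ([76, 81]) and *Emergency* (> 81) situation time fractions.

**Loading.** From the operator wristband's tri-axial log (range −8.00 g to
+7.98 g): *Saturation Rate* (rail-pinned seconds per minute), and the
*Mean* and *Standard Deviation* of the per-minute accumulation
Σ<sub>sec</sub> max<sub>sec</sub> √(aₓ² + a_y² + a_z²), in g·s.

**Transport.** Four thermal-comfort fractions (T > 31 °C, T < 18 °C,
RH > 80 %, RH < 60 %) and *Abrupt Movements*: the acceleration module is
passed through a smoothed z-score peak detector (moving mean/SD over a
`lag`-sample window; a point more than `threshold` SDs away is signalled
±1; signalled points enter the filtered series with weight `influence`),
and the KPI is the % of evaluated samples signalled.

**Slaughterhouse.** The 19 fields of the operators' inspection template
(weights, injury and defect counts for a 200-bird sample, lot-level
losses, and the binary *Meat Quality* grade A/B), validated and
round-tripped as CSV.

**Decision support.** A CART classifier (in-repo: Gini impurity, midpoint
thresholds, deterministic tie-breaks) fitted on historical chain KPIs is
flattened to its disjunctive normal form — one IF-THEN rule per leaf, e.g.
`ES > 65 ∧ AM ≤ 40 ∧ HT ≤ 50 → MQ = A` — and queried: `predict` grades a
complete KPI vector, `recommend` filters the rules against already-fixed
KPIs and returns what must still be controlled to reach the desired grade.

No public chain dataset exists, so the `synth` module generates every
input with planted ground truth (exact stratified band fractions, inserted
spike episodes, Poisson rail pinning, rule-labelled KPI tables), which is
what the test suite measures recovery against.

## Worked example

```python
from poultrychain import reference_rule_set, predict, recommend

rules = reference_rule_set()          # the six demonstration rules
kpis = {"emergency_situation": 68.30, # % of rearing time in heat emergency
        "abrupt_movements": 9.32,     # % of journey with abrupt driving
        "high_temperature": 0.0, "high_relative_humidity": 17.0,
        "low_temperature": 0.0}
print(predict(rules, kpis))
for rule, residual in recommend(rules, {"emergency_situation": 68.30}, "A"):
    print(rule, "| still required:", " AND ".join(map(str, residual)))
```

prints

```
A
emergency_situation > 65 AND abrupt_movements <= 40 AND high_temperature <= 50 -> A | still required: abrupt_movements <= 40 AND high_temperature <= 50
emergency_situation > 65 AND abrupt_movements > 40 AND high_relative_humidity <= 20 -> A | still required: abrupt_movements > 40 AND high_relative_humidity <= 20
```

i.e. this chain's lot is graded A (its journey stayed calm and cool), and
a manager who can only take the hot breeding record as given still has two
routes to grade A: keep abrupt movements below 40 %, or accept a rough
ride but keep transport humidity excess below 20 %.

The same flows are available from the shell:

```sh
poultrychain simulate chains --n 2000 --seed 1 --out chains.csv
poultrychain advisor fit --table chains.csv --rules-out rules.json
poultrychain simulate farm --days 1 --seed 1 --out-dir data/
poultrychain kpi breeding --temps data/farm_temps.csv --rhs data/farm_rh.csv \
    --profile data/comfort_profile.csv --store kpis.jsonl
```

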