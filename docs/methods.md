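# Methods

This note records the measurement conventions, the model behind each
indicator, the synthetic-data design and the numerical choices the package
makes where the underlying field practice leaves the design open.

## Time-fraction semantics

Every "% of time" KPI is computed as a fraction of *samples*, which equals
the fraction of time under uniform sampling.  Irregular series are first
regularised onto their nominal grid: the last observation is carried
forward across gaps of at most two sample periods; grid points beyond a
longer gap become explicitly missing (NaN).  Missing samples are excluded
from both numerator and denominator, so a sensor outage neither inflates
nor deflates a KPI — an all-missing series makes the KPI undefined (an
error), never 0.  Second- and minute-level aggregation is aligned to
integer epoch boundaries, half-open `[s, s+1)`, which makes grouping
deterministic and independent of sample order; partial leading/trailing
minutes are dropped from minute statistics to avoid downward-biased
accumulations.

## Breeding

The optimal-temperature profile is a step function: farmers set discrete
setpoints per growth stage and edit them mid-rearing, so no interpolation
between segments.  Deviation bands: warning is the closed interval
1.5–3 °C of |T − opt|, alarm is strictly above 3 °C ("between" read
inclusively, "more than" strictly); the bands are disjoint by
construction.

The heat-stress scale is published only as a chart, so the index is a
pluggable registry keyed by `formula_id`.  The shipped default
`thi_default` is the classical livestock temperature–humidity index

    THI = 0.8·T + (RH/100)·(T − 14.4) + 46.4        (T in °C, RH in %)

chosen because it lands on the same 70–81 scale the stress bands use.  Any
registered formula must be monotone non-decreasing in both arguments; the
band KPIs inherit weak monotonicity from that contract (warming every
sample cannot lower the emergency fraction).  The published band wording
leaves (75, 76) unassigned; the implementation tiles the scale as alert
[70, 76), danger [76, 81], emergency (81, ∞).

## Loading

"Acceleration exceeding the sensor range" is unobservable directly — the
logger clips — so saturation is detected as equality with a rail value
(−8.00 g or +7.98 g), with a configurable epsilon defaulting to exact
equality: rails are the only footprint clipping leaves.  The Saturation
Rate counts saturated *seconds* per minute (data is first aggregated to
seconds; one pinned sample marks its whole second).  Accumulation is the
per-minute sum of per-second maxima of the acceleration module; its spread
is reported as the sample standard deviation (n−1 denominator,
configurable), matching common statistical software defaults.

## Transport

The smoothed z-score peak detector processes the per-sample acceleration
module sequentially.  Initialisation: the first `lag` samples seed the
filtered series with the raw values, receive signal 0, and their
mean/population-SD seed the moving filters.  From sample `lag` on, a point
strictly more than `threshold` moving SDs from the moving mean is
signalled (+1 above, −1 below; a tie at exactly `threshold` SDs is *not* a
signal); it enters the filtered series with weight `influence`, so at
influence 0 signalled points never move the detection threshold.  The
moving statistics use the population (n) denominator — they are a
descriptive filter, not an inferential estimate.  Defaults
(lag 25, threshold 5, influence 0) follow the published configuration.
The Abrupt Movements KPI divides by the evaluated samples only (warm-up
excluded, where signals are undefined).  Thermal comfort bounds are strict
inequalities: exactly 31 °C or exactly 80 % RH is still comfortable.

## Slaughterhouse template

The native format is CSV (header: `flock_id`, `sample_size`, then the 19
KPI fields), locale-independent and column-order-free.  Counts are
validated against their scope: injury/defect counts against the inspected
sample size (default 200 birds), `dead_in_transport` and `confiscated`
against the lot size.  `weight_range` is stored as a scalar in kg: the
source template prints a single number under that heading and never
clarifies whether it is a range width or a mean — a known ambiguity, kept
as-is.  Writing uses integer formatting for counts and `repr` for floats
so a write/parse cycle is bit-identical.

## Decision support

CART is implemented in-repo because rule extraction, prediction and
recommendation need full access to node internals.  Splitting: greedy
binary partitioning minimising Gini impurity (variance for numeric
targets), candidate thresholds at midpoints between consecutive distinct
sorted values, growth stopped by purity, `max_depth`, `min_leaf`, or when
the node's impurity decrease falls below `min_impurity_decrease` (the
stand-in for a complexity parameter; no pruning or cross-validated cost
selection is attempted).  Determinism: among equal-quality splits the
lexicographically smallest feature wins, then the smallest threshold;
mixed leaves predict the majority class with ties to the lexicographically
first label.  The left branch is always `≤ threshold`.  Rules are
root-to-leaf conjunctions, hence mutually exclusive and exhaustive: exactly
one rule fires for any complete feature vector, and `recommend` simplifies
a surviving rule's residual conditions to the tightest bound per feature.

A caveat documented deliberately: the greedy learner recovers the planted
*partition*, not necessarily the planted *tree shape*.  With independent
uniform KPI marginals, the root split with the largest Gini decrease need
not be the planted root (in the shipped scenario it is the low-temperature
boundary, not the emergency-situation one), and a tree grown to purity
acquires auxiliary splits inside regions that are pure by chance.  The
recovery tests therefore assert partition equivalence — exact agreement on
training rows, ≥99 % agreement on fresh vectors, every planted boundary
present among the learned thresholds — rather than structural identity.

## Synthetic data

The generators are pure functions of their scenario (seed included) and
exist to make every KPI testable against planted ground truth:

* **Farm climate** — each sample is assigned a (deviation band, stress
  band) pair by *stratified exact allocation* (nearest-integer counts), so
  realised fractions equal planted fractions up to 1/n.  Pairs are matched
  cool-to-cool (the two sorted allocations are zipped, then shuffled in
  time), temperature is drawn inside the intersection of the deviation
  interval and the stress band's feasible-temperature interval, and
  humidity is solved from a target index value; deviations may take either
  sign, so cold alarms without heat stress are realisable.  Under the
  default THI an index value h is reachable iff
  (h − 32)/1.8 ≤ T ≤ (h − 46.4)/0.8, which is why the default profile
  keeps setpoints at 30/29/28 °C: every stress band (including "no
  stress") stays reachable from every deviation band.  A genuinely
  unreachable combination (e.g. a 38 °C setpoint with planted "no stress"
  time) raises a configuration error.
* **Journey** — humidity is stratified exactly; temperature stays inside
  the comfort envelope.  The acceleration module is a 1 g base with
  *bounded* uniform noise (±0.03 g) plus +2 g spikes at the planted share
  of post-warm-up positions: bounded noise cannot cross 5 moving SDs, and
  with influence 0 a spike cannot contaminate the filters, so the detector
  flags exactly the inserted spikes and the planted fraction is recovered
  to rounding.
* **Wristband** — per-minute accumulations are drawn from the planted
  normal distribution and realised *exactly* by the per-second maxima.
  Rail pinning arrives as a per-minute Poisson process; a pinned sample's
  module (≈8 g) necessarily dominates its second, so the remaining seconds
  are scaled down to keep the minute's total on target — the planted
  distribution describes the realised accumulation, saturation included,
  and recovery is unbiased.
* **Chain tables** — the five advisor KPIs are drawn i.i.d. U(0, 100) and
  labelled by the planted rules, with optional label-flip noise.

What the generators do **not** emulate: diurnal and seasonal structure,
autocorrelated climate drift, the physics of arm motion or truck
vibration spectra, sensor drift/calibration error, and any correlation
between phases (a hot rearing period does not make a rough ride more
likely).  Passing recovery tests therefore demonstrates that the KPI
arithmetic and detectors are correct, not that the pipeline is robust to
every artefact of field data.

## Problem sizes

Desk-scale defaults keep the full test suite and the acceptance script in
seconds on one CPU, chosen as the package's own working scale: 1 rearing
day at a 30 s period for breeding tests (7 days in the acceptance script),
1 h journeys at 1 Hz, 10-minute wristband sessions at 100 Hz in tests (a
realistic 4 h session in the acceptance script; the hardware's native
1000 Hz is supported but oversampled for these statistics), and 2000
simulated chains for the advisor.  Monte-Carlo tolerances follow from
these sizes: stratified band fractions are exact to 0.1 percentage point,
spike fractions to 0.5, and wristband statistics to three standard errors
of the planted distribution at the session length used.

## Known limitations

* The heat-stress default is an index chosen for scale compatibility, not
  a digitisation of the original chart; swap in a lookup-table formula via
  the registry for chart-faithful bands.
* Saturation detection assumes clipping lands exactly on the rails; ADCs
  that dither near the rails need a non-zero `rail_epsilon`.
* The advisor assumes numeric KPI features and a categorical target for
  rule extraction; regression trees predict but yield no DNF.
* The KPI store is a flat JSON-lines file: adequate for thousands of
  chains, not for concurrent writers.
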