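# Methods

This note documents the models implemented in `riverfce`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and known limitations.

## The assessment model

A multifunctional river is scored on a four-layer tree: target →
criterion (river functions A1–A4) → sub-criterion (secondary functions
B1–B12) → indicator (C1–C22). Each indicator has five grade intervals,
I (excellent) through V (poor), in its own units. Indicator direction
governs the interval ladder: *positive* (larger is better, e.g. dissolved
oxygen C6), *negative* (smaller is better, e.g. landscape fragmentation
C11), *bidirectional* (best inside a central band, only C16 — water
resource utilization, where both under-use and over-exploitation are
penalized), and *categorical* (an ordinal class score, only C4 — surface
water quality class). The packaged default system encodes the Xiaoqing
River main-stem criteria; any system with the same structure can be
supplied as YAML.

Interval conventions: bracket notation is kept verbatim; a bare "> v"
extreme grade is the open half-line (v, ∞). Two rows print an open upper
end in grade IV against a "> v" grade V (substrate contamination C5 at 5,
water consumption C19 at 80), which would leave the boundary value in no
grade; grade V is stored closed at that boundary ([5, ∞), [80, ∞)) so the
grades tile the domain — validation rejects both overlaps and gaps. The
per-capita-GDP row (C18) is printed with inverted interval notation and is
normalized to the ascending orientation forced by the monotone grade
ladder. Degenerate single-point grades (a diversity index of exactly 0 for
C7/C8/C9, a tourist flow index of 0 for C21) are closed singletons.

## Weighting

**AHP.** Judgment matrices are validated as positive reciprocal matrices.
Priorities are the normalized principal eigenvector, computed by power
iteration with L1 normalization (tolerance 1e−12 on the weight vector,
cap 10,000 iterations). Positive matrices have a simple dominant
eigenvalue, so power iteration is exact in the limit and dependency-free;
the test suite cross-checks it against a dense eigendecomposition. The
consistency chain is λ_max = Σ_k (Aw)_k/(n w_k), CI = (λ_max − n)/(n − 1),
CR = CI/RI with Saaty's random index (tabulated for n ≤ 15; larger orders
are rejected). CR < 0.1 accepts; n ≤ 2 is always consistent (CR defined
as 0). The hierarchy-level combined test is reported as the
parent-weighted mean CI over the parent-weighted mean RI — the standard
aggregate convention, since no single formula is canonical.

**Entropy method.** Columns are min-max normalized by direction; the
bidirectional indicator is first transformed to the distance |x − c| from
the center c of its grade-I band (c = 27.5 for C16) and then treated as
negative — this preserves the "closer to the ideal band is better"
semantics. The shifted proportions f = (1+r)/Σ(1+r) keep the logarithm
finite. The normalized entropy is implemented with the conventional minus
sign, H′ = −Σ f ln f / ln n ∈ [0, 1], which makes a constant column reach
the entropy ceiling and receive weight exactly 0. A constant column
normalizes to all ones by convention (the min-max formula is 0/0 there); a
constant indicator carries no discriminating information, so weight 0 is
the only consistent assignment. If *every* column is constant the weights
are undefined and the package raises instead of guessing.

**Fusion.** combined_i = λ·ahp_i + (1−λ)·entropy_i with λ = 0.5 by
default. The published combined column is the arithmetic mean of its AHP
and entropy columns in all 22 rows (to ±0.0001), which pins λ = 0.5;
λ remains configurable. Criterion-layer combined weights are sums of
member indicators' combined weights — not means of the criterion-level
AHP/entropy aggregates; only the member-sum rule reproduces the published
criterion column. (The published criterion-level entropy entry for A4,
0.2945, is inconsistent with its own indicator column, whose entries sum
to 0.2495; the package reports the column sum and the combined weights are
unaffected.) Criticality ranks are competition ranks on descending
combined weight; ties are judged at 4 decimals (the precision of published
tables; configurable) and share the better rank, skipping the next.

## Cauchy membership and grading

Grade membership is r(x) = 1/(1 + a2·(x − a1)²):

* interior grades — a1 = interval midpoint, a2 = 4/width². This makes
  r = 1 at the center and exactly 0.5 at both boundaries, so two adjacent
  interior grades tie at 0.5 on their shared boundary.
* extreme grades — a1 sits at the pole (the endpoint *not* shared with the
  neighboring grade: the ideal end of grade I, the worst end of grade V,
  orientation-aware by construction), a2 = 4/width², and the membership
  saturates at 1 beyond the pole. Putting the peak at the shared boundary
  instead would make grade I peak where grade II begins, contradicting
  maximum-affiliation semantics.
* unbounded extreme grades ("> 3") — the width is borrowed from the
  adjacent grade; a1 = shared boundary + borrowed width (the virtual
  bound), saturating past it.
* single-point grades — the zero-width limit of the interval formula is a
  point mass (a2 → ∞). The implementation uses a finite surrogate:
  effective width = 1e−6 × the adjacent grade's width. This keeps r(a1)=1
  and strict monotone decay while making the point grade's membership
  negligible anywhere strictly inside the neighboring grade; borrowing the
  neighbor's full width instead would let "exactly zero" claim a quarter
  of the adjacent interval, breaking crisp/fuzzy agreement.
* categorical indicators — unit-width parameterization around each class
  value (a1 = the value, a2 = 4).
* bidirectional grades evaluate both branches and keep the larger
  membership; the central band itself is an interior grade.

A consequence worth knowing: crisp classification and fuzzy argmax agree
everywhere strictly inside *interior* grades, but near the inner edge of a
bounded extreme grade the adjacent interior grade can out-score it (e.g. a
value just inside grade I's band may argmax to II). This is inherent to
pole-peaked extreme grades, not a defect; the agreement guarantee covers
interior grades, and extreme-grade midpoints always recover.

**Composition.** D = W·R is implemented as the ordinary weighted-average
matrix product — the natural operator when W sums to 1, and the only one
that preserves every indicator's influence. The classical max–min operator
is available as an option for comparison. Criterion-layer weights are the
combined indicator weights renormalized within each criterion; the target
layer uses the global vector. Assigned grades are argmax with exact ties
resolved to the worse grade (conservative assessment; ties occur
structurally at boundary values where two adjacent memberships are both
0.5). Evaluation vectors are reported raw, with a sum-1 normalization
available for display; the argmax is unaffected.

## Synthetic scenarios

The generator emulates the study conditions: five river sections ordered
upstream to downstream (Jinan, Binzhou, Zibo, Dongying, Weifang), a
planted per-cell grade table, and judgment matrices drawn around the
published AHP weights. Defaults:

* the planted table is a deteriorating ladder (grade I upstream through V
  downstream) with the ecological-flow indicator C2 held at grade I
  everywhere — the published pattern whose constant column forces entropy
  weight exactly 0;
* an indicator planted at one grade in *all* sections receives a single
  deterministic value (exactly constant column); otherwise values are
  placed per cell — `midpoint` placement is deterministic (lowest branch
  for two-branch grades), `uniform` placement samples inside the interval
  with a relative margin of 1e−6 off each boundary, picking a branch at
  random for bidirectional grades. Unbounded grades sample between the
  shared boundary and the virtual bound, keeping values in the membership
  model's informative range;
* judgment matrices use a_ij = (w_i/w_j)·exp(ε), ε ~ N(0, σ²) on the upper
  triangle, reciprocals filled in; σ = 0 gives exactly consistent
  matrices, σ = 0.1 keeps CR < 0.1 in practice (a 200-draw calibration at
  n = 6 gives mean absolute weight-recovery error ≈ 0.005 and 100%
  CR-acceptance). Optional snapping rounds entries to the 1–9 scale.

All randomness flows through one seeded NumPy generator recorded in the
scenario manifest, so scenarios are bit-reproducible.

What the generator does **not** emulate: spatial or temporal correlation
between indicators, measurement error, hydrologically realistic dynamics,
or the real Xiaoqing segment values (never published). Passing tests
therefore demonstrate that the pipeline recovers known planted structure
and reproduces the published weight arithmetic — not that the package
reproduces the study's per-segment grade maps, which are out of reach
without the raw data.

## Problem sizes and runtime

The test suite and the acceptance script use desk-scale sizes: 5 segments
× 22 indicators per scenario, ≥ 1,000 uniformly placed cells for the
recovery check, 100 random matrices (orders 3–8) for the eigen
cross-check, and 200 Monte-Carlo draws for judgment recovery. The whole
suite runs in a few seconds; the acceptance script in under two.

## Known limitations

* Grade assignment near bounded extreme-grade edges follows fuzzy
  semantics rather than crisp intervals (see above).
* The consistency test is Saaty's CR, limited to matrix orders ≤ 15.
* Single-expert judgments only; no group aggregation or fuzzy AHP.
* No defuzzification to a continuous score: output is the five-grade
  membership vector plus the argmax grade.
* Computing indicator values from primary data (diversity indices from
  species counts, GIS landscape metrics, questionnaire scores) is out of
  scope; indicator values are pipeline inputs.
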