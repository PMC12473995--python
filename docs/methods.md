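# Methods

## The evaluation problem

A drinking-water reservoir is monitored at n sites, each with five
indicators in mg/L: dissolved oxygen (DO, higher is better) and four
pollutants — total nitrogen (TN), ammonia nitrogen (NH3-N), total
phosphorus (TP) and the permanganate index (COD_Mn) — lower is better.
Each site is to be graded into the Chinese surface-water classes I
(cleanest) to V (worst). Crisp interval lookups ("single-factor" grading)
are discontinuous at class boundaries and are driven entirely by the worst
indicator; the fuzzy comprehensive evaluation (FCE) implemented here
replaces both defects with graded class membership and weighted evidence
pooling.

## Grade schemes

Two built-in threshold tables are provided: the GB 3838-2002 national
standard and a customized scheme that tightens the COD_Mn column (grade
bounds 1/2/3/4/5 mg/L instead of 2/4/6/10/15) and the lower DO grades, as
appropriate for a drinking-water source. Intervals are half-open `(lower,
upper]` for pollutants with the grade-I regulatory bound inclusive
(TN ≤ 0.2 is grade I); DO mirrors downward (grade I is DO ≥ 7.5).
Concentrations beyond the grade-V outer bound are classified as grade V
and flagged `exceeds_V`. Below-detection readings are stored as 0.0 — no
half-LOD imputation — so a reported minimum of 0.000 round-trips exactly.

## Entropy weights

Weights are objective functions of the data. Each column is min-max
standardized to [0, 1] (cost columns reversed), proportions
p_ij = x*_ij / Σ_i x*_ij are formed per column, and the information
entropy is

    E_j = -(1/ln n) Σ_i p_ij ln p_ij ,     0·ln 0 := 0,

with weights w_j = (1 − E_j) / Σ_j (1 − E_j). A constant column is
standardized to all ones rather than 0/0: that yields uniform proportions,
E_j = 1 and weight 0, the correct "no information" outcome. If *every*
column is uninformative the fit raises rather than silently returning
0/0; `uniform_weights()` is the explicit fallback. Weights are computed
over whichever sample set is passed to the model; the default pipeline
computes one joint vector over all sites.

A caveat this package makes measurable: min-max entropy weighting is very
sensitive to single extreme values. A heavy-tailed pollutant column (TN
here, max ≈ 8× its mean) compresses, after cost reversal, into a narrow
band near 1; its proportions become nearly uniform, its entropy nearly
maximal, and its weight small — while a roughly symmetric indicator such
as DO collects the largest weight. On synthetic cohorts reproducing the
published summary moments, DO's weight is ~0.45–0.52 and TN's below 0.12.
Consequences are discussed under *Known limitations*.

## Fuzzy membership construction

Each indicator gets five membership functions over concentration, one per
grade: a semi-trapezoid saturating toward clean values (grade I), a
semi-trapezoid saturating toward polluted values (grade V), and triangles
for grades II–IV. The defining parameters are the grade apexes c_1..c_5:
the apex of grade k is the **midpoint of grade k's interval**; the
unbounded ends use the midpoint of [0, t_1] for a pollutant's grade I and
the regulatory bound itself (7.5 mg/L) for DO's grade I. Triangle feet sit
at the neighbouring apexes. This is a modeling choice, not a unique
construction — the function families are standard but their mapping to the
threshold tables is not canonical. The midpoint-apex/neighbour-feet rule is
adopted because it makes the five functions an exact partition of unity
between the outer apexes (membership vectors sum to 1 with at most two
nonzero entries) and saturates cleanly outside them; both properties are
enforced by tests at 1e-9. The triangle's overlapping branch conditions at
the apex are resolved by continuity (value 1). DO is evaluated by mirroring
(x → −x) so one increasing-apex code path serves both polarities.

## Composite evaluation and grading

For one sample, R is the 5×5 matrix of per-indicator membership rows and
the composite vector is B = W·R, i.e. b_k = Σ_j w_j r_jk. Since rows sum
to 1 and Σw = 1, ΣB = 1 (checked at 1e-9). The grade is argmax_k b_k
(maximum membership principle), with exact ties broken toward the worse
grade — the conservative call for a drinking-water source; the underlying
data are continuous so ties essentially only arise in constructed cases.

Grade calls with a thin margin are unreliable. After normalizing B to sum
1, a gap below 0.2 between the two largest memberships flags the
assessment as *ambiguous*; the threshold is a configurable parameter
defaulting to 0.2. The margin is always reported alongside the grade.

## EWQI comparator

A scalar entropy-weighted water quality index is provided for
cross-method comparison. It is a reconstruction of the standard form (the
comparator is not otherwise specified): each pollutant contributes
q_j = 100·C_j/S_j with S_j its Class III bound; DO contributes
100·S_DO/C_DO capped at 500 (so C → 0 cannot blow up); the index is
Σ w_j q_j, so a sample with every indicator exactly at its Class III
bound scores 100. Class bands default to I ≤ 50 < II ≤ 100 < III ≤ 150
< IV ≤ 200 < V and are configurable. `compare_methods` reports per-site
grade pairs, the 5×5 confusion matrix, the discordant-site list ordered by
|grade difference| and both mean grades.

## Compliance statistics and emission accounting

Single-factor grades are crisp interval lookups; the worst-factor grade of
a sample is their maximum. Compliance/exceedance rates are computed per
(reach, section) stratum and per indicator at a configurable class level
(default Class III); every rate is derived from integer counts over the
data — denominators are never taken from external totals — and the counts
are reported with the rate. Displayed percentages use half-up rounding at
one decimal. Descriptive statistics use the sample standard deviation
(ddof = 1) and CV = sd/mean, flagged undefined at zero mean.

The emission ledger consumes already-computed annual discharges
(source type, subcategory, pollutant, tonnes/year); deriving them from
headcount × emission-coefficient accounting is out of scope because the
coefficient handbooks are not machine-readable inputs here. A "/" entry
means *not assessed* and is distinct from zero: it is excluded from sums
and ratio denominators. Subtotals by source type and subcategory
contribution ratios (summing to 1 per pollutant within 1e-12) follow by
summation. The packaged Wan'an Reservoir inventory ships as a CSV.

## Synthetic site generator

The 83-site field campaign is not public, so the generator emulates its
published structure: 18 main-stream sites and 65 tributary sites (23
upstream, 23 midstream, 19 downstream — the denominators behind the
published per-section rates).

Marginals (all mg/L, targets = published n = 83 moments):

| indicator | family            | mean  | sd    | bounds         | LOD  |
|-----------|-------------------|-------|-------|----------------|------|
| DO        | truncated normal  | 9.219 | 2.567 | [4.89, 18.36]  | —    |
| TN        | clipped lognormal | 2.277 | 3.714 | [0, 18.94]     | 0.05 |
| NH3-N     | lognormal         | 0.271 | 0.374 | [0.02, ∞)      | —    |
| TP        | clipped lognormal | 0.031 | 0.039 | [0, 0.300]     | 0.01 |
| COD_Mn    | truncated normal  | 1.942 | 1.236 | [0, 4.84]      | —    |

TN and TP are lognormal because their sd is comparable to or far exceeds
their mean on a positive support (TN's published sd is 1.6× its mean with
an 8.5× outlier); DO and COD_Mn are truncated normals over their published
ranges. TN/TP draws below the detection limits above are reported as 0.0,
mimicking the published 0.000 minima; the LODs are the conventional method
detection limits for those determinations.

Because truncation, clipping, additive gradient shifts and left-censoring
all move moments, the generator does not plug the targets into the
distribution parameters. Instead it solves, once per configuration, for
the underlying (μ, σ) / (loc, scale) such that the **realized** mean and
sd — computed in closed form from normal/lognormal partial moments of the
full piecewise-linear transform, mixed over the section shifts — equal the
targets (a naive plug-in misses the clipped-lognormal TN sd by ~20%). The
solve uses `scipy.optimize.root` and is cached.

The spatial gradient is additive per section: pollutants shift by
±0.25·mean from upstream to downstream and DO by ∓1.4 mg/L (set once from
the published section means, e.g. tributary DO 11.29/9.32/8.55 mg/L);
shifts are centered with the layout's stratum weights so the basin-wide
mean is preserved. Indicators are drawn independently by default — the
field data's TN–NH3N–TP dependence is not modeled — so passing tests show
the pipeline's arithmetic and invariances, not realism of joint behaviour.
No seasonality, hydrology or transport is simulated.

Planted-truth cohorts draw every indicator uniformly from the central 60%
of one grade's intervals (unbounded outer intervals are given the
neighbouring grade's width), making grades nearly separable; uniform-weight
evaluation recovers ≥ 90% of planted grades on 500-site cohorts, which
validates the membership/composition chain end to end.

Problem sizes: the test suite evaluates cohorts of 83–500 sites and checks
generator moments on ~10,000-site draws; these sizes give sampling noise
well inside the asserted tolerance bands while keeping the full suite in
seconds.

## Known limitations

1. **The argmax grade is not monotone under dominance.** If every
   indicator of sample A is weakly worse than sample B's, the composite
   vector of A dominates B's stochastically (cumulative sums never
   increase — provable, and property-tested). The *assigned grade* however
   can improve: membership mass draining from grade k to k+1 can hand the
   maximum back to grade k−1. Concrete equal-weight example: worsening
   {DO 10.74, TN 0.36, NH3N 0.31, TP 0.19, COD_Mn 0.56} (grade II, B =
   (0.397, 0.398, 0.004, 0, 0.2)) on every indicator to {8.94, 0.64, 0.34,
   0.23, 0.69} yields grade I (B = (0.361, 0.290, 0.149, 0, 0.2)). This is
   an inherent deficiency of the maximum membership principle, one reason
   the ambiguity margin is always reported.

2. **The fuzzy method is not reliably "more pessimistic" than the EWQI.**
   On synthetic cohorts matching the published moments, the entropy
   weights are DO-dominated (see the entropy caveat above), the fuzzy
   grades saturate on clean DO memberships (mean grade ≈ 1.5), and the
   EWQI — whose ratio scores sit near 100 at the Class III bounds — grades
   the same cohorts more harshly (mean ≈ 1.9–2.2), across seeds and also
   under uniform weights. An extreme discordance of fuzzy grade V against
   EWQI class I at one site is arithmetically impossible when both methods
   share one weight vector over all five indicators: a TN weight large
   enough to drive the fuzzy grade to V forces the TN ratio term alone
   above the class V band. Field reports of the opposite ordering
   therefore imply weights or comparator inputs that differ from what the
   published formulas and summary statistics can produce.

3. Entropy weights inherit min-max's outlier sensitivity (above); a single
   extreme value can effectively silence its own indicator.

4. The generator reproduces marginal moments and a mean spatial gradient,
   not joint dependence, seasonality or within-section spatial
   autocorrelation.
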