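# Methods

## The monitoring model

A deployed scoring AI is treated as a categorical process: each analyzed
exam yields one integer suspicion score in 1..10, and under stable
operation the scores of a center are draws from a fixed distribution — the
one measured during the tool's retrospective evaluation for that exact
(AI version major.minor, modality, manufacturer) combination. Monitoring
is therefore a sequence of goodness-of-fit questions: does the 10-bin
histogram of a center's window of reports still look like its reference?

Windows are the center's whole extraction period ("global") and each
calendar month ("local"). Monthly windows catch transient malfunctions
the pooled histogram averages away; the global window gives the
high-precision long-run view. Months are calendar months of the report
date, with no partial-window exclusion.

### Assumptions

* One record = one score. Whether an upstream report carries per-lesion or
  per-exam scores is irrelevant to the statistics, but the toolkit treats
  each input record as a single draw.
* Reports within a window are exchangeable; no within-month trend is
  modeled.
* The reference is treated as a known distribution (its sampling noise is
  ignored when deriving expected counts). This is adequate when the
  reference is an order of magnitude larger than the window, which holds
  for the shipped worlds (references 13k–25k vs. windows ≤ 1.7k); see
  "χ² construction" for the consequence of violating it.

## Decision rule

A window is a **deviation** when any of:

1. PCC < `pcc_threshold` (default 0.95);
2. χ² p-value < `alpha` (default 0.05);
3. the stream key disagrees with the reference key on any component
   (wrong-version / wrong-modality / wrong-manufacturer), or no reference
   matched at all.

The disjunction is this package's design choice: each condition is
individually alert-worthy, and a key mismatch is a configuration error
that deserves an alert regardless of what the histograms say. Conversely,
metric-based causes (1–2) are suppressed on windows smaller than
`min_window_n` (default 50 reports), which are flagged
`insufficient-data`: correlations over 10 bins estimated from a handful
of cases invite hasty conclusions. Key-level causes (3) still fire on
such windows.

Severity of a deviation is graded from the normalized Wasserstein
distance with cutpoints (0.02, 0.10) for low / moderate / high. These
defaults are invented and explicitly configurable: 0.02 corresponds to
moving ~2% of all mass across the full scale (or more mass a shorter
distance), 0.10 to a shift no plausible population change explains.

## Statistics: numerical choices

**PCC** is evaluated by the direct Pearson formula on raw bin counts
(scale invariance makes counts and frequencies equivalent), clipped to
[−1, 1] to absorb float round-off of a few ulp. A histogram with zero
across-bin variance (all bins equal — a uniform or empty window) has no
defined correlation; the result is an explicit `None` plus a
`pcc-undefined` flag, never a silent number and never an exception, so
monthly pipelines continue past degenerate windows.

**χ² construction.** The χ² test is a classical Pearson goodness of fit:
expected counts are the reference bin proportions scaled to the window
total. Bins whose expectation falls below `min_expected` (default 5) are
pooled rightward — groups accumulate toward higher scores until they
reach the floor, and an underweight tail group folds back into its left
neighbour — and df = pooled bins − 1. The p-value is the upper tail of
the χ² distribution. If pooling collapses everything into one cell the
test errors out (`degenerate after merging`) and the window is flagged
instead. Note the one-sample construction is exactly calibrated only
when windows are compared against the distribution they were truly drawn
from; comparing against an independently *sampled* finite reference
inflates the statistic by roughly (1 + n_window/n_reference), which is why
the synthetic null worlds draw streams from the realized reference
proportions (below) and why real references should dwarf the windows.

**Wasserstein distance** uses the exact closed form on the ordered
integer support — the sum of absolute CDF differences over the nine
interior cut points with unit spacing — rather than any sampling or LP
approximation: on a 10-point support exactness is free. The maximum is 9
(all mass at 1 vs. all at 10) and the normalized value divides by it.
The test suite cross-checks the closed form against both
`scipy.stats.wasserstein_distance` and an exhaustive transport linear
program.

**Score-by-score differences** are reported in percentage points of each
histogram's own total (they sum to zero); this is the unit that makes
centers of different volume comparable.

**Summaries** report mean, minimum, maximum and *population* standard
deviation of the monthly PCCs (a center with one month has sd 0), with an
explicit note that the monthly mean is a different quantity from the
global PCC.

All floating-point assertions in the test suite use absolute tolerance
1e−9 unless the quantity is an exact identity (1e−12): double precision
on ≤ 5-digit counts leaves orders of magnitude of headroom.

## The synthetic world

The generator emulates multi-center report streams: per month, one
multinomial draw of that month's volume from a 10-bin categorical
distribution; report dates uniform within the month; everything
deterministic given the seed, with the realized per-month tallies exposed
as exact ground truth for downstream oracles.

* **Base distribution.** The default is right-skewed,
  (0.45, 0.15, 0.095, 0.075, 0.055, 0.045, 0.04, 0.035, 0.03, 0.025):
  screening populations are dominated by unremarkable exams, so most mass
  sits at the lowest scores and decays monotonically. It is an invented
  stand-in — no real retrospective distribution is distributable — and
  every analytic expectation in the tests is a closed form valid for any
  base. At realistic volumes it reproduces the qualitative behavior of
  real deployments: monthly PCC ≈ 0.999 at ~1,700 reports/month and
  ≈ 0.98 with occasional dips at ~90 reports/month.
* **Null calibration.** In generated workspaces, center streams are drawn
  by default from the *realized* empirical distribution of their matched
  reference entry (not from the underlying base probabilities). A
  no-shift world is then an exact null for the χ² test; a center may
  instead declare its own base or a shift.
* **Shift scenarios.** Drift is injected by moving a fraction *f* of one
  score's probability mass from score *a* to score *b*, optionally only
  in listed months. The induced Wasserstein distance has the closed form
  `f · μ_a · |b − a|`, which the tests use as the severity oracle; the
  inverse move with the mass-consistent fraction restores the base
  exactly.
* **Volumes.** The shipped 4-center demo world uses monthly volumes of
  1,679 / 1,038 / 854 / 87 over 11 / 6 / 13 / 9 months — the orders of
  magnitude of real single-center deployments — and reference sizes of
  13,433 / 25,330 / 14,187 exams.

What the generator does **not** model: patient demographics, cancer
prevalence, radiologist behavior, serial correlation between months,
within-month drift, or multiple lesions per exam. A green test therefore
establishes that the statistics, the windowing and the decision rule
behave correctly on a stationary categorical process with known truth —
not that the thresholds are clinically optimal for any particular
population.

## Known limitations

* With the default OR rule the χ² arm alone consumes the entire nominal
  false-alarm budget: under an exact null, the expected fraction of quiet
  months is 1 − α = 95% by construction, and small-volume centers
  (~90 reports/month) add PCC-threshold breaches on top (~4% of such
  months), giving realistic null worlds a measured quiet fraction of
  ~94–95%, concentrated in the smallest center. Operators who want fewer
  small-center false alarms should raise `min_window_n` above the
  smallest monthly volume, lower `alpha`, or treat χ² significance as
  informational rather than alerting; all three are configuration
  choices, deliberately not defaults.
* The χ² p-value's df convention depends on the pooling path, so
  p-values from tools using a different expected-count construction are
  not directly comparable.
* References are geographically and temporally specific; a population
  change can produce a genuine, persistent deviation without any software
  malfunction. The toolkit detects and grades the drift but cannot
  attribute root cause beyond key mismatches.
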