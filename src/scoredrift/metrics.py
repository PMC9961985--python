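"""Comparison statistics between a monitored score histogram and its reference.

Three complementary views of the same question — "is the deployed AI still
producing the score distribution it produced in its retrospective
evaluation?":

* **Histogram correlation (PCC)** — the Pearson correlation coefficient
  computed across the ten corresponding bins of the two histograms,

  .. math::

      \\mathrm{PCC} = \\frac{\\sum_{i=1}^{10}(p_i-\\bar p)(q_i-\\bar q)}
      {\\sqrt{\\sum_{i=1}^{10}(p_i-\\bar p)^2 \\sum_{i=1}^{10}(q_i-\\bar q)^2}}.

  1 means identical shape; values near 0 mean no association.  The PCC is
  invariant under positive rescaling of either histogram, so raw counts and
  relative frequencies give the same value.

* **χ² goodness of fit** — a classical Pearson test of the monitored window's
  bin counts against expected counts derived from the reference proportions;
  the p-value grades the statistical significance of an observed difference.

* **Wasserstein distance (WD)** — the minimal mass-times-displacement cost of
  turning one distribution into the other.  On the ordered integer support
  1..10 it has the exact closed form :math:`\\sum_{i=1}^{9} |F_p(i)-F_q(i)|`
  (unit bin spacing), with maximum 9 (all mass at score 1 vs. all at score
  10); dividing by 9 normalizes it to [0, 1].  Unlike the PCC, the WD grows
  with how *far* mass has moved, so it grades the severity of a shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .histogram import N_BINS, ScoreHistogram

__all__ = [
    "WD_MAX",
    "MetricResult",
    "pcc",
    "chi2_gof",
    "wasserstein",
    "bin_differences",
]

#: Largest possible raw Wasserstein distance on the 1..10 support.
WD_MAX = float(N_BINS - 1)


@dataclass(frozen=True, slots=True)
class MetricResult:
    """The full metric battery for one (window, reference) comparison.

    ``pcc`` is ``None`` — never a silent number — when either histogram has
    zero across-bin variance, in which case ``pcc_undefined_reason`` says why.
    """

    pcc: float | None
    chi2_stat: float
    chi2_pvalue: float
    chi2_df: int
    wd_raw: float
    wd_normalized: float
    pcc_undefined_reason: str | None = None

    def to_dict(self) -> dict:
        return {
            "pcc": self.pcc,
            "chi2_stat": self.chi2_stat,
            "chi2_pvalue": self.chi2_pvalue,
            "chi2_df": self.chi2_df,
            "wd_raw": self.wd_raw,
            "wd_normalized": self.wd_normalized,
        }


def pcc(p: ScoreHistogram, q: ScoreHistogram) -> float | None:
    """Histogram correlation between two 10-bin histograms.

    Evaluates the Pearson formula directly on the raw bin counts.  Returns
    ``None`` when either histogram is flat across bins (all counts equal,
    including all-zero), because the denominator vanishes and the
    correlation is undefined.
    """
    x = p.counts()
    y = q.counts()
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        return None
    r = float(dx @ dy) / math.sqrt(sxx * syy)
    # guard against |r| creeping past 1 by a few ulp
    return max(-1.0, min(1.0, r))


def chi2_gof(
    center: ScoreHistogram,
    reference: ScoreHistogram,
    min_expected: float = 5.0,
) -> tuple[float, float, int]:
    """Pearson χ² goodness of fit of a monitored window against a reference.

    Expected counts are the reference bin proportions scaled to the window
    total.  Low-expectation bins (< ``min_expected``) are pooled with their
    higher-score neighbours — groups grow rightward until their expected
    count reaches the floor, and an underweight tail group is folded back
    into the previous group — the standard remedy for the χ² approximation
    breaking down on sparse cells.  Degrees of freedom are (pooled bins − 1).

    Returns ``(statistic, p_value, df)``.

    Raises
    ------
    ValueError
        ``"empty window"`` when the center histogram has no counts;
        ``"empty distribution"`` when the reference has none;
        ``"degenerate after merging"`` when pooling collapses everything
        into a single cell (df would be 0).
    """
    n = center.total
    if n == 0:
        raise ValueError("empty window")
    expected = reference.probabilities() * n
    observed = center.counts()

    groups: list[tuple[float, float]] = []
    acc_obs = 0.0
    acc_exp = 0.0
    for o, e in zip(observed, expected):
        acc_obs += o
        acc_exp += e
        if acc_exp >= min_expected:
            groups.append((acc_obs, acc_exp))
            acc_obs = acc_exp = 0.0
    if acc_exp > 0.0 or acc_obs > 0.0:
        if groups:
            lo, le = groups[-1]
            groups[-1] = (lo + acc_obs, le + acc_exp)
        else:
            groups = [(acc_obs, acc_exp)]

    if len(groups) < 2:
        raise ValueError("degenerate after merging")

    stat = float(sum((o - e) ** 2 / e for o, e in groups))
    df = len(groups) - 1
    pvalue = float(stats.chi2.sf(stat, df))
    return stat, pvalue, df


def wasserstein(p: ScoreHistogram, q: ScoreHistogram) -> tuple[float, float]:
    """Raw and normalized 1-D Wasserstein distance between two histograms.

    Both histograms are normalized to probability mass; the distance is the
    exact closed-form optimal transport cost on the ordered support 1..10
    with unit spacing.  The normalized value divides by the maximum 9.
    """
    diff = p.cdf() - q.cdf()
    raw = float(np.abs(diff[:-1]).sum())
    return raw, raw / WD_MAX


def bin_differences(center: ScoreHistogram, reference: ScoreHistogram) -> np.ndarray:
    """Score-by-score difference of relative frequencies, in percentage points.

    Element ``i`` is ``100 * (center_i/center_total - ref_i/ref_total)``;
    the ten elements sum to zero up to rounding.  A negative tail-score
    entry paired with a positive low-score entry is the signature of the
    dangerous shift pattern (high-suspicion mass drifting downward).
    """
    return 100.0 * (center.probabilities() - reference.probabilities())
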