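"""10-bin score histograms over the integer support 1..10."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .records import SCORE_MAX, SCORE_MIN, ScoreReport

__all__ = ["N_BINS", "ScoreHistogram", "build_histogram"]

N_BINS = SCORE_MAX - SCORE_MIN + 1


@dataclass(frozen=True, slots=True)
class ScoreHistogram:
    """Counts of reports per score: ``bins[i]`` holds the number of cases
    whose score equals ``i + 1``."""

    bins: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bins) != N_BINS:
            raise ValueError(f"expected {N_BINS} bins, got {len(self.bins)}")
        if any(b < 0 for b in self.bins):
            raise ValueError("negative bin count")
        object.__setattr__(self, "bins", tuple(int(b) for b in self.bins))

    @property
    def total(self) -> int:
        return sum(self.bins)

    def counts(self) -> np.ndarray:
        return np.asarray(self.bins, dtype=float)

    def probabilities(self) -> np.ndarray:
        """Bin counts normalized to probability mass; errors on an empty histogram."""
        total = self.total
        if total == 0:
            raise ValueError("empty distribution")
        return self.counts() / total

    def cdf(self) -> np.ndarray:
        return np.cumsum(self.probabilities())

    @classmethod
    def from_scores(cls, scores: Iterable[int]) -> "ScoreHistogram":
        counts = np.bincount(
            np.asarray(list(scores), dtype=int), minlength=SCORE_MAX + 1
        )
        if len(counts) > SCORE_MAX + 1 or (counts[:SCORE_MIN] != 0).any():
            raise ValueError("score outside the 1..10 support")
        return cls(tuple(int(c) for c in counts[SCORE_MIN : SCORE_MAX + 1]))

    @classmethod
    def from_counts(cls, counts: Sequence[int]) -> "ScoreHistogram":
        return cls(tuple(int(c) for c in counts))


def build_histogram(reports: Iterable[ScoreReport]) -> ScoreHistogram:
    """Tally validated reports into a 10-bin histogram.

    The empty input yields the all-zero histogram; validation of individual
    records is assumed to have happened upstream in the readers.
    """
    return ScoreHistogram.from_scores(r.score for r in reports)
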