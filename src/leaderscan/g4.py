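"""G4Hunter: G-quadruplex propensity scoring for mRNA 5' leaders.

Implements the G4Hunter score from scratch.  Each base receives an integer
score from the G/C run it sits in: a G inside a run of n consecutive Gs
scores +min(n, 4); a C in a run of n Cs scores -min(n, 4); A, U/T and N
score 0 (N also breaks runs).  Window means (default 25 nt, step 1) at or
above the calling threshold (default 1.4) are merged into maximal
non-overlapping regions.  Because the scanned molecule is a single-stranded
mRNA leader, only G-rich (positive) regions count as G-quadruplexes;
C-rich troughs are reported separately.  Group-level density is a pooled
ratio: total regions over total leader length, per 1000 nt.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

DEFAULT_WINDOW = 25
DEFAULT_THRESHOLD = 1.4

_COMPLEMENT = str.maketrans("ACGTUN", "UGCAAN")


@dataclass(frozen=True)
class G4Region:
    """A maximal run of above-threshold windows, in 1-based leader coords."""

    transcript_id: str
    start: int
    end: int
    mean_score: float
    max_window_score: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")


def base_scores(sequence: str) -> np.ndarray:
    """Per-base G4Hunter scores (ints in [-4, 4])."""
    seq = sequence.upper().replace("T", "U")
    scores = np.zeros(len(seq), dtype=np.int64)
    i = 0
    while i < len(seq):
        base = seq[i]
        j = i
        while j < len(seq) and seq[j] == base:
            j += 1
        if base == "G":
            scores[i:j] = min(j - i, 4)
        elif base == "C":
            scores[i:j] = -min(j - i, 4)
        i = j
    return scores


def window_means(scores: Sequence[float], window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Mean score of every ``window``-long stretch at step 1 (empty if short)."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) < window:
        return np.empty(0)
    kernel = np.ones(window) / window
    return np.convolve(scores, kernel, mode="valid")


def call_regions(
    means: Sequence[float],
    threshold: float = DEFAULT_THRESHOLD,
    window: int = DEFAULT_WINDOW,
    scores: Sequence[float] | None = None,
    transcript_id: str = "",
) -> list[G4Region]:
    """Merge above-threshold windows into maximal regions.

    A window starting at 0-based offset i spans bases [i, i+window).
    Windows whose mean is >= ``threshold`` (inclusive) are marked; marked
    windows that overlap or directly abut merge, and each region reports
    the union span (1-based inclusive), the mean per-base score over that
    span (when ``scores`` given) and the best window mean.
    """
    means = np.asarray(means, dtype=float)
    hits = np.flatnonzero(means >= threshold)
    regions: list[G4Region] = []
    if hits.size == 0:
        return regions
    # split marked window starts into maximal stretches of abutting windows
    breaks = np.flatnonzero(np.diff(hits) > window)
    groups = np.split(hits, breaks + 1)
    for grp in groups:
        start0, end0 = int(grp[0]), int(grp[-1]) + window  # 0-based half-open
        span_scores = (
            np.asarray(scores, float)[start0:end0] if scores is not None else None
        )
        regions.append(
            G4Region(
                transcript_id=transcript_id,
                start=start0 + 1,
                end=end0,
                mean_score=float(span_scores.mean()) if span_scores is not None else float("nan"),
                max_window_score=float(means[grp].max()),
            )
        )
    return regions


def scan_leader(
    sequence: str,
    transcript_id: str = "",
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[list[G4Region], list[G4Region]]:
    """Full scan of one leader; returns (G-rich regions, C-rich regions).

    Only the first list counts toward G4 density; C-rich troughs (windows
    whose mean is <= -threshold) are reported for completeness.
    """
    scores = base_scores(sequence)
    means = window_means(scores, window)
    g_regions = call_regions(means, threshold, window, scores, transcript_id)
    c_regions = call_regions(-means, threshold, window, -scores, transcript_id)
    return g_regions, c_regions


def g4_density(n_regions: int, total_length_nts: int) -> float:
    """Regions per 1000 nt."""
    if total_length_nts <= 0:
        raise ValueError("total length must be positive")
    return 1000.0 * n_regions / total_length_nts


def pooled_density(counts: Iterable[int], lengths: Iterable[int]) -> float:
    """Group density: sum of region counts over sum of leader lengths x1000."""
    counts = list(counts)
    lengths = list(lengths)
    if len(counts) != len(lengths):
        raise ValueError("counts and lengths differ in size")
    return g4_density(int(np.sum(counts)), int(np.sum(lengths)))


def reverse_complement(sequence: str) -> str:
    return sequence.upper().replace("T", "U").translate(_COMPLEMENT)[::-1]
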