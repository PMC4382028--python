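"""Per-SNP zygosity calling and LOH segmentation of allele-ratio profiles.

A sector's normalized hybridization ratios are called per SNP into HET /
HOM_A / HOM_B / AMBIGUOUS, lightly smoothed, and collapsed into contiguous
same-state segments.  A transition between adjacent segments is reported as
the interval bracketed by the flanking observed SNPs — the last SNP of the
left-hand state and the first SNP of the right-hand state — with no
interpolation, mirroring how LOH transition coordinates are tabulated from
array profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .snpmap import SnpMap

__all__ = [
    "Zygosity",
    "CallingThresholds",
    "RatioProfile",
    "Segment",
    "TransitionInterval",
    "call_zygosity",
    "segment_profile",
    "transition_coordinates",
]


class Zygosity(str, Enum):
    HET = "HET"
    HOM_A = "HOM_A"
    HOM_B = "HOM_B"
    AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class CallingThresholds:
    """Ratio bands for the three-state zygosity call.

    Heterozygous when both allele ratios fall in [het_lo, het_hi]; homozygous
    for an allele when its ratio is >= hom_present_min and the other allele's
    ratio is <= hom_absent_max.  The bands sit inside the conventional ranges
    (~1 single copy, 1.5-2 two copies, 0-0.5 zero copies) with a deliberate
    guard gap; ratios falling in the gap are AMBIGUOUS rather than forced.
    """

    het_lo: float = 0.7
    het_hi: float = 1.3
    hom_present_min: float = 1.4
    hom_absent_max: float = 0.6

    def __post_init__(self) -> None:
        if not (0 <= self.het_lo < self.het_hi < self.hom_present_min):
            raise ValueError("bands must satisfy 0 <= het_lo < het_hi < hom_present_min")
        if not (0 <= self.hom_absent_max < self.het_lo):
            raise ValueError("hom_absent_max must fall below het_lo")


@dataclass
class RatioProfile:
    """Per-SNP (ratio_A, ratio_B) pairs for one sector, tied to a SnpMap."""

    snp_map: SnpMap
    ratio_a: np.ndarray
    ratio_b: np.ndarray

    def __post_init__(self) -> None:
        self.ratio_a = np.asarray(self.ratio_a, dtype=float)
        self.ratio_b = np.asarray(self.ratio_b, dtype=float)
        n = len(self.snp_map)
        if self.ratio_a.shape != (n,) or self.ratio_b.shape != (n,):
            raise ValueError("ratio arrays must match the SNP map length")
        for arr in (self.ratio_a, self.ratio_b):
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError("ratios must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.snp_map)


@dataclass(frozen=True)
class Segment:
    """A maximal run of SNPs sharing one zygosity state."""

    state: Zygosity
    first_index: int
    last_index: int
    first_pos: int
    last_pos: int


@dataclass(frozen=True)
class TransitionInterval:
    """Interval bracketing a state change, bounded by observed SNPs."""

    left_pos: int
    right_pos: int
    left_state: Zygosity
    right_state: Zygosity


def call_zygosity(
    profile: RatioProfile, thresholds: CallingThresholds | None = None
) -> np.ndarray:
    """Call each SNP of a ratio profile; returns an array of Zygosity."""
    t = thresholds or CallingThresholds()
    a, b = profile.ratio_a, profile.ratio_b
    # note: np.full would coerce the str-enum fill to a truncated str
    calls = np.array([Zygosity.AMBIGUOUS] * len(profile), dtype=object)
    het = (a >= t.het_lo) & (a <= t.het_hi) & (b >= t.het_lo) & (b <= t.het_hi)
    hom_a = (a >= t.hom_present_min) & (b <= t.hom_absent_max)
    hom_b = (b >= t.hom_present_min) & (a <= t.hom_absent_max)
    calls[het] = Zygosity.HET
    calls[hom_a] = Zygosity.HOM_A
    calls[hom_b] = Zygosity.HOM_B
    return calls


def _runs(states: list[Zygosity]) -> list[tuple[Zygosity, int, int]]:
    """Maximal runs as (state, start, stop-exclusive) over a state list."""
    runs = []
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            runs.append((states[start], start, i))
            start = i
    return runs


def _smooth(states: list[Zygosity], min_run: int, smooth_window: int) -> list[Zygosity]:
    """Reassign isolated short flips to the flanking state, to convergence.

    An interior run shorter than ``min_run`` whose neighbours agree with each
    other, and whose length does not exceed ``smooth_window`` minus its two
    flanking SNPs, is absorbed.  Edge runs are never reassigned — a genuine
    LOH transition at the profile edge must survive.
    """
    states = list(states)
    # synchronous passes: all absorptions in a pass are decided from the same
    # run structure, keeping the rule symmetric under profile reversal
    for _ in range(len(states)):
        runs = _runs(states)
        flips = []
        for k in range(1, len(runs) - 1):
            state, start, stop = runs[k]
            length = stop - start
            if length >= min_run or length > smooth_window - 2:
                continue
            left_state = runs[k - 1][0]
            if left_state != runs[k + 1][0]:
                continue
            flips.append((start, stop, left_state))
        if not flips:
            break
        for start, stop, new_state in flips:
            states[start:stop] = [new_state] * (stop - start)
    return states


def segment_profile(
    calls: np.ndarray,
    snp_map: SnpMap,
    min_run: int = 2,
    smooth_window: int = 3,
) -> tuple[list[Segment], list[TransitionInterval]]:
    """Collapse per-SNP calls into alternating-state segments.

    AMBIGUOUS calls are skipped (segments are built over the informative
    SNPs only, though segment coordinates are real map positions).  Isolated
    flips shorter than ``min_run`` flanked by agreeing states are reassigned
    before segmenting.  Returns ``(segments, transitions)``; an all-ambiguous
    profile yields ``([], [])``.
    """
    if len(calls) != len(snp_map):
        raise ValueError("calls length must match the SNP map")
    informative = [i for i, c in enumerate(calls) if c != Zygosity.AMBIGUOUS]
    if not informative:
        return [], []
    states = _smooth([calls[i] for i in informative], min_run, smooth_window)
    pos = snp_map.positions
    segments = [
        Segment(
            state=state,
            first_index=informative[start],
            last_index=informative[stop - 1],
            first_pos=int(pos[informative[start]]),
            last_pos=int(pos[informative[stop - 1]]),
        )
        for state, start, stop in _runs(states)
    ]
    return segments, transition_coordinates(segments)


def transition_coordinates(segments: list[Segment]) -> list[TransitionInterval]:
    """Transition intervals between adjacent segments, flanking-SNP exact."""
    return [
        TransitionInterval(
            left_pos=left.last_pos,
            right_pos=right.first_pos,
            left_state=left.state,
            right_state=right.state,
        )
        for left, right in zip(segments[:-1], segments[1:])
    ]
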