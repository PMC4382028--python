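"""Genome-element association analysis at crossover breakpoints.

For each crossover a window is delineated as the region most likely to have
contained the recombinogenic DNA break: from the last heterozygous SNP to the
first homozygous SNP across the conversion span.  Window lengths are summed
and divided by the total screened sequence (interval length x number of
sectors) to give the window fraction f; the expected number of features
falling in windows is then (features in the screened interval) x (sectors) x
f, and a 1-df two-cell chi-square compares it with the observed overlap
count.  Large dispersed elements (Ty retrotransposons) are reduced to their
midpoints before overlap testing so that sheer size does not inflate their
representation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree
from scipy import stats as sps

from .classify import ConversionEvent
from .snpmap import SnpMap

__all__ = [
    "CoWindow",
    "FeatureTrack",
    "EnrichmentResult",
    "co_windows",
    "window_fraction",
    "expected_count",
    "observed_count",
    "enrichment_test",
    "run_enrichment",
]


@dataclass(frozen=True)
class CoWindow:
    """Crossover window: last-heterozygous to first-homozygous SNP, 1-based."""

    event_id: str
    left: int
    right: int

    def __post_init__(self) -> None:
        if self.left >= self.right:
            raise ValueError("window must have left < right")

    @property
    def length(self) -> int:
        return self.right - self.left


@dataclass(frozen=True)
class FeatureTrack:
    """A class of genomic features (ARS, tRNA, Ty, delta elements, ...).

    ``intervals`` are (start, end) 1-based inclusive on one chromosome.  With
    ``midpoint_rule`` each interval collapses to its midpoint before overlap
    testing.
    """

    name: str
    intervals: tuple[tuple[int, int], ...]
    midpoint_rule: bool = False
    chromosome: str = "chrIV"

    def __post_init__(self) -> None:
        ivs = tuple(sorted((int(a), int(b)) for a, b in self.intervals))
        for a, b in ivs:
            if a > b:
                raise ValueError(f"feature interval start {a} > end {b}")
        object.__setattr__(self, "intervals", ivs)

    def __len__(self) -> int:
        return len(self.intervals)

    def effective_intervals(self) -> tuple[tuple[int, int], ...]:
        if not self.midpoint_rule:
            return self.intervals
        return tuple(((a + b) // 2, (a + b) // 2) for a, b in self.intervals)


@dataclass(frozen=True)
class EnrichmentResult:
    feature_class: str
    n_features_total: int
    window_fraction: float
    expected: float
    observed: int
    chi2: float
    p_value: float
    low_expected: bool = False


def co_windows(events: list[ConversionEvent], snp_map: SnpMap) -> list[CoWindow]:
    """One window per event spanning the full conversion span.

    The window runs from the SNP immediately proximal to the conversion span
    (the last SNP still heterozygous in both sectors) to the first SNP of the
    reciprocal-LOH zone.  Events whose span cannot be bracketed (open-ended
    at the map edge) are skipped with a warning.
    """
    pos = snp_map.positions
    windows = []
    for ev in events:
        if ev.span_first_index < 0:
            warnings.warn(f"event {ev.event_id!r} has no transitions; skipped")
            continue
        if ev.event_class == "NO_GC":
            left_idx, right_idx = ev.span_first_index, ev.span_last_index
        else:
            left_idx = ev.span_first_index - 1
            right_idx = ev.span_last_index + 1
            if left_idx < 0 or right_idx >= len(snp_map):
                warnings.warn(f"event {ev.event_id!r} is open-ended; skipped")
                continue
        windows.append(
            CoWindow(ev.event_id, int(pos[left_idx]), int(pos[right_idx]))
        )
    return windows


def window_fraction(
    windows: list[CoWindow],
    region_length: float,
    n_sectors: int,
    merge_overlaps: bool = False,
) -> float:
    """Summed window length over total screened sequence.

    ``region_length`` is the screened interval per sector (bp); the screened
    total is region_length x n_sectors.  Per-event windows are summed without
    merging by default (each sector is an independent screen); merging is
    available for sensitivity analysis.
    """
    if region_length <= 0 or n_sectors < 1:
        raise ValueError("region_length must be > 0 and n_sectors >= 1")
    if merge_overlaps:
        tree = IntervalTree.from_tuples((w.left, w.right) for w in windows)
        tree.merge_overlaps()
        total = sum(iv.end - iv.begin for iv in tree)
    else:
        total = sum(w.length for w in windows)
    f = total / (region_length * n_sectors)
    if f > 1:
        raise ValueError(f"windows exceed the screened space (f = {f:.3g})")
    return f


def expected_count(n_features_region: int, n_sectors: int, f: float) -> float:
    """Expected in-window feature count: features per sector x sectors x f."""
    if n_features_region < 0 or n_sectors < 0:
        raise ValueError("counts must be non-negative")
    return n_features_region * n_sectors * f


def observed_count(features: FeatureTrack, windows: list[CoWindow]) -> int:
    """Count feature-window overlaps (a feature counts once per window it hits).

    Each sector's window is an independent screen of the same chromosome, so
    a feature overlapping the windows of k events contributes k to the
    observed count — matching the expected count's per-sector replication.
    Interval features overlap on any intersection; midpoint-rule features
    only when the midpoint falls inside the window.
    """
    if not windows:
        return 0
    # half-open tree over 1-based inclusive windows
    tree = IntervalTree.from_tuples((w.left, w.right + 1) for w in windows)
    n = 0
    for a, b in features.effective_intervals():
        n += len(tree.overlap(a, b + 1))
    return n


def enrichment_test(observed: int, expected: float, n_total: int) -> tuple[float, float]:
    """Two-cell 1-df chi-square goodness of fit (in-window vs out-of-window)."""
    if expected <= 0:
        raise ValueError("expected count must be positive")
    if n_total < observed:
        raise ValueError("observed exceeds the total feature count")
    out_obs = n_total - observed
    out_exp = n_total - expected
    if out_exp <= 0:
        raise ValueError("expected out-of-window count must be positive")
    chi2 = (observed - expected) ** 2 / expected + (out_obs - out_exp) ** 2 / out_exp
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


def run_enrichment(
    features: FeatureTrack,
    windows: list[CoWindow],
    region_length: float,
    n_sectors: int,
    merge_overlaps: bool = False,
) -> EnrichmentResult:
    """Full observed-vs-expected test for one feature class."""
    f = window_fraction(windows, region_length, n_sectors, merge_overlaps)
    n_total = len(features) * n_sectors
    exp = expected_count(len(features), n_sectors, f)
    obs = observed_count(features, windows)
    chi2, p = enrichment_test(obs, exp, n_total)
    return EnrichmentResult(
        feature_class=features.name,
        n_features_total=n_total,
        window_fraction=f,
        expected=exp,
        observed=obs,
        chi2=chi2,
        p_value=p,
        low_expected=exp < 5,
    )
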