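"""Sector-pair conversion-tract classification and lesion-timing inference.

A red/white sectored colony holds the four chromatids of the mitotic division
in which a reciprocal crossover occurred: two in each daughter sector.  Laying
the two sectors' zygosity segmentations side by side partitions the
chromosome into regions labelled by the parental-allele count among the four
chromatids — 2:2 (heterozygous ground state or the distal reciprocal LOH),
3:1 (one chromatid converted; G2-type lesion) or 4:0 (both sister chromatids
converted; G1-type lesion).  The crossover-associated conversion is then
classified as NO_GC, simple 3:1, simple 4:0, hybrid 4:0/3:1, or complex, and
timing / donor / tract lengths are derived from the region pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segmentation import (
    CallingThresholds,
    RatioProfile,
    Segment,
    TransitionInterval,
    Zygosity,
    call_zygosity,
    segment_profile,
)
from .snpmap import ALLELE_A, ALLELE_B, SnpMap

__all__ = [
    "NotAnRCOError",
    "RegionState",
    "TractLengths",
    "ConversionEvent",
    "combine_sectors",
    "classify_event",
    "infer_timing",
    "infer_donor",
    "tract_length",
    "breakpoint_histogram",
    "hotspot_event_count",
    "analyze_sector_pair",
]

NO_GC = "NO_GC"
SIMPLE_3_1 = "SIMPLE_3_1"
SIMPLE_4_0 = "SIMPLE_4_0"
HYBRID_4_0_3_1 = "HYBRID_4_0_3_1"
COMPLEX = "COMPLEX"

EVENT_CLASSES = (NO_GC, SIMPLE_3_1, SIMPLE_4_0, HYBRID_4_0_3_1, COMPLEX)

_COPIES_A = {Zygosity.HET: 1, Zygosity.HOM_A: 2, Zygosity.HOM_B: 0}


class NotAnRCOError(ValueError):
    """The sector pair lacks the reciprocal distal LOH of a crossover."""


@dataclass(frozen=True)
class RegionState:
    """A maximal run of SNPs with one (red, white) zygosity combination."""

    first_index: int
    last_index: int
    first_pos: int
    last_pos: int
    count_a: int  # copies of allele A among the four chromatids
    red_state: Zygosity
    white_state: Zygosity

    @property
    def count_b(self) -> int:
        return 4 - self.count_a

    @property
    def is_ground(self) -> bool:
        return self.red_state == Zygosity.HET and self.white_state == Zygosity.HET

    @property
    def is_reciprocal(self) -> bool:
        return {self.red_state, self.white_state} == {Zygosity.HOM_A, Zygosity.HOM_B}

    @property
    def is_conversion(self) -> bool:
        return not (self.is_ground or self.is_reciprocal)

    @property
    def donor(self) -> str | None:
        """Over-represented allele, for conversion regions."""
        if self.count_a > 2:
            return ALLELE_A
        if self.count_a < 2:
            return ALLELE_B
        return None

    @property
    def ratio_label(self) -> str:
        return f"{self.count_a}:{self.count_b}"


@dataclass(frozen=True)
class TractLengths:
    """Minimum/maximum/average conversion-tract length in bp.

    min spans the outermost SNPs inside the tract; max spans the closest
    flanking SNPs outside it; avg = (min + max) / 2.  When a flanking SNP is
    missing at the map edge the tract is open-ended: max and avg are None.
    """

    min_bp: int
    max_bp: int | None
    avg_bp: float | None
    open_ended: bool = False


@dataclass
class ConversionEvent:
    """A fully classified crossover-associated conversion event."""

    event_class: str
    timing: str  # "G1" | "G2" | "UNCLASSIFIED"
    donor: str | None  # "A" | "B" | "MIXED" | None for NO_GC
    tract: TractLengths
    regions: list[RegionState]
    red_transitions: list[TransitionInterval]
    white_transitions: list[TransitionInterval]
    event_id: str = ""
    # map indices of the first/last SNP of the conversion span (NO_GC: the
    # flanking SNPs of the shared transition)
    span_first_index: int = -1
    span_last_index: int = -1


def _per_snp_states(segments: list[Segment], n: int) -> np.ndarray:
    states = np.full(n, None, dtype=object)
    for seg in segments:
        states[seg.first_index : seg.last_index + 1] = seg.state
    return states


def combine_sectors(
    red_segments: list[Segment],
    white_segments: list[Segment],
    snp_map: SnpMap,
) -> list[RegionState]:
    """Partition the map into four-chromatid allele-count regions.

    Each sector contributes HET→(1,1), HOM_A→(2,0), HOM_B→(0,2) copies; SNPs
    assigned a state in only one sector (ambiguous or transition-gap SNPs)
    are skipped.  Adjacent SNPs sharing the same (red, white) state pair are
    merged, so the partition breaks exactly at the union of the two sectors'
    transition points.
    """
    n = len(snp_map)
    red = _per_snp_states(red_segments, n)
    white = _per_snp_states(white_segments, n)
    pos = snp_map.positions
    # SNPs lacking a state in either sector are skipped; a run continues
    # across such gaps so that one region is never split by a stray
    # ambiguous call
    runs: list[list] = []  # [first_index, last_index, (red_state, white_state)]
    for i in range(n):
        if red[i] is None or white[i] is None:
            continue
        pair = (red[i], white[i])
        if runs and runs[-1][2] == pair:
            runs[-1][1] = i
        else:
            runs.append([i, i, pair])
    return [
        RegionState(
            first_index=first,
            last_index=last,
            first_pos=int(pos[first]),
            last_pos=int(pos[last]),
            count_a=_COPIES_A[pair[0]] + _COPIES_A[pair[1]],
            red_state=pair[0],
            white_state=pair[1],
        )
        for first, last, pair in runs
    ]


def _conversion_zone(regions: list[RegionState]) -> tuple[list[RegionState], int]:
    """Regions between the proximal ground state and the distal reciprocal zone.

    Returns ``(zone, reciprocal_index)``.  Raises NotAnRCOError when the
    distal-most region is not reciprocal LOH.
    """
    if not regions or not regions[-1].is_reciprocal:
        raise NotAnRCOError(
            "sector pair has no reciprocal homozygosity distal to the breakpoint"
        )
    recip = len(regions) - 1
    while recip > 0 and regions[recip - 1].is_reciprocal:
        recip -= 1
    first_non_ground = 0
    while first_non_ground < recip and regions[first_non_ground].is_ground:
        first_non_ground += 1
    return regions[first_non_ground:recip], recip


def classify_event(regions: list[RegionState]) -> str:
    """Five-way class of the crossover-associated conversion.

    NO_GC when the two sectors' transitions coincide (no conversion region);
    SIMPLE_3_1 / SIMPLE_4_0 for a single contiguous region of that count;
    HYBRID_4_0_3_1 for one contiguous block of exactly one 4:0 region plus
    adjacent 3:1 region(s) sharing its donor; COMPLEX for anything else
    (interior returns to 2:2, donor switches, several 4:0 blocks, or
    non-contiguous converted regions).
    """
    zone, _ = _conversion_zone(regions)
    if not zone:
        return NO_GC
    if any(not r.is_conversion for r in zone):
        return COMPLEX
    donors = {r.donor for r in zone}
    if len(donors) > 1:
        return COMPLEX
    four_zero = [r for r in zone if r.count_a in (0, 4)]
    if len(zone) == 1:
        return SIMPLE_4_0 if four_zero else SIMPLE_3_1
    if len(four_zero) == 1:
        return HYBRID_4_0_3_1
    return COMPLEX


def infer_timing(event_class: str, regions: list[RegionState]) -> str:
    """G1/G2 lesion timing from the conversion pattern.

    A 4:0 region requires both sister chromatids broken, hence a G1 lesion;
    a pure 3:1 pattern reflects a single broken chromatid (G2).  Complex
    events with at least one 4:0 region are taken as G1.  NO_GC events carry
    no timing information.
    """
    if event_class == NO_GC:
        return "UNCLASSIFIED"
    if event_class in (SIMPLE_4_0, HYBRID_4_0_3_1):
        return "G1"
    if event_class == SIMPLE_3_1:
        return "G2"
    zone, _ = _conversion_zone(regions)
    return "G1" if any(r.count_a in (0, 4) for r in zone) else "G2"


def infer_donor(event_class: str, regions: list[RegionState]) -> str | None:
    """Donor homolog: the allele over-represented in the conversion regions."""
    if event_class == NO_GC:
        return None
    zone, _ = _conversion_zone(regions)
    donors = {r.donor for r in zone if r.is_conversion}
    if len(donors) == 1:
        return donors.pop()
    return "MIXED"


def tract_length(
    regions: list[RegionState], snp_map: SnpMap
) -> tuple[TractLengths, int, int]:
    """Minimum/maximum/average tract length plus the in-tract SNP span.

    min = distance between the outermost SNPs inside the conversion tract;
    max = distance between the closest flanking SNPs outside it;
    avg = (min + max) / 2.  Complex tracts use only the first and last
    transitions (the overall converted span).  A crossover with no detectable
    conversion uses the minimal possible tract (1 bp) and the maximal tract
    (the distance between the heterozygous and homozygous SNPs closest to
    the breakpoint).  Returns ``(lengths, first_index, last_index)``.
    """
    zone, recip = _conversion_zone(regions)
    pos = snp_map.positions
    if not zone:
        left = recip - 1
        if left < 0:
            raise NotAnRCOError("no heterozygous region proximal to the breakpoint")
        left_idx = regions[left].last_index
        right_idx = regions[recip].first_index
        max_bp = int(pos[right_idx] - pos[left_idx])
        return (
            TractLengths(min_bp=1, max_bp=max_bp, avg_bp=(1 + max_bp) / 2),
            left_idx,
            right_idx,
        )
    first_idx = zone[0].first_index
    last_idx = zone[-1].last_index
    min_bp = max(int(pos[last_idx] - pos[first_idx]), 1)
    if first_idx == 0 or last_idx == len(snp_map) - 1:
        return (
            TractLengths(min_bp=min_bp, max_bp=None, avg_bp=None, open_ended=True),
            first_idx,
            last_idx,
        )
    max_bp = int(pos[last_idx + 1] - pos[first_idx - 1])
    return (
        TractLengths(min_bp=min_bp, max_bp=max_bp, avg_bp=(min_bp + max_bp) / 2),
        first_idx,
        last_idx,
    )


def analyze_sector_pair(
    red: RatioProfile,
    white: RatioProfile,
    thresholds: CallingThresholds | None = None,
    min_run: int = 2,
    smooth_window: int = 3,
    event_id: str = "",
) -> ConversionEvent:
    """Full pipeline for one sectored colony: call, segment, combine, classify."""
    if red.snp_map != white.snp_map:
        raise ValueError("red and white profiles must share a SNP map")
    snp_map = red.snp_map
    red_segs, red_trans = segment_profile(
        call_zygosity(red, thresholds), snp_map, min_run, smooth_window
    )
    white_segs, white_trans = segment_profile(
        call_zygosity(white, thresholds), snp_map, min_run, smooth_window
    )
    regions = combine_sectors(red_segs, white_segs, snp_map)
    event_class = classify_event(regions)
    lengths, first_idx, last_idx = tract_length(regions, snp_map)
    return ConversionEvent(
        event_class=event_class,
        timing=infer_timing(event_class, regions),
        donor=infer_donor(event_class, regions),
        tract=lengths,
        regions=regions,
        red_transitions=red_trans,
        white_transitions=white_trans,
        event_id=event_id,
        span_first_index=first_idx,
        span_last_index=last_idx,
    )


def breakpoint_histogram(
    events: list[ConversionEvent], snp_map: SnpMap
) -> np.ndarray:
    """Per-SNP count of inclusion in crossover-associated conversion tracts.

    Every SNP within an event's conversion span (for NO_GC events, within the
    shared transition interval) increments that SNP's count by one.
    """
    counts = np.zeros(len(snp_map), dtype=np.int64)
    for ev in events:
        if ev.span_first_index < 0:
            continue
        counts[ev.span_first_index : ev.span_last_index + 1] += 1
    return counts


def hotspot_event_count(
    events: list[ConversionEvent],
    snp_map: SnpMap,
    interval: tuple[int, int],
) -> int:
    """Number of events whose conversion span overlaps ``interval`` (bp)."""
    lo, hi = interval
    pos = snp_map.positions
    n = 0
    for ev in events:
        if ev.span_first_index < 0:
            continue
        if pos[ev.span_first_index] <= hi and pos[ev.span_last_index] >= lo:
            n += 1
    return n
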