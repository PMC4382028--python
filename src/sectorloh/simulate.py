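"""Synthetic sectored-colony data for a W303-1A x YJM789-like hybrid diploid.

The generator mimics the selectable reciprocal-crossover (RCO) assay: a DSB on
one homolog is repaired off the intact homolog, leaving a gene-conversion tract
adjacent to the exchange point, and the crossover segregates so that the two
daughter cells (the red and white halves of a sectored colony) are homozygous
for opposite parental alleles distal to the exchange.  A G2 lesion breaks one
chromatid and yields a 3:1 tract; a G1 lesion breaks both sister chromatids and
yields a 4:0 tract (equal repair lengths) or a hybrid 4:0/3:1 tract (unequal
lengths).  Ground truth is emitted alongside noisy per-SNP hybridization-ratio
profiles so that the segmentation and classification modules can be validated
by round-trip recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .snpmap import ALLELE_A, ALLELE_B, SnpMap

__all__ = [
    "NoiseModel",
    "SimTruth",
    "TandemArrayState",
    "CnvTrajectory",
    "generate_snp_map",
    "simulate_rco_event",
    "sample_rco_events",
    "emit_ratio_profiles",
    "simulate_cup1_cnv",
]


def _other(allele: str) -> str:
    return ALLELE_B if allele == ALLELE_A else ALLELE_A


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian noise around the three hybridization-ratio levels.

    A normalized allele-specific ratio of ~1 marks one copy of the SNP
    (heterozygous), ~1.75 two copies (homozygous present) and ~0.25 zero
    copies (homozygous absent); the homozygous means sit at the midpoints of
    the conventional calling ranges (1.5-2 and 0-0.5).
    """

    mean_het: float = 1.0
    mean_hom_present: float = 1.75
    mean_hom_absent: float = 0.25
    sd: float = 0.12
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.mean_hom_absent < self.mean_het < self.mean_hom_present):
            raise ValueError("ratio means must be ordered absent < het < present")
        if self.sd < 0:
            raise ValueError("noise sd must be non-negative")


@dataclass(frozen=True)
class TractInterval:
    """A converted interval on one chromatid: (start, end] received ``donor``."""

    chromatid: str  # e.g. "broken_1", "broken_2"
    start: int
    end: int
    donor: str


@dataclass
class SimTruth:
    """Ground truth for one simulated sectored colony.

    ``red_chromatids`` / ``white_chromatids`` are the two (n_snps,) allele
    vectors ('A'/'B') carried by each daughter cell.  The red sector is the
    daughter homozygous for the A (W303-1A-like) allele distal to the
    crossover; the white sector for B.
    """

    snp_map: SnpMap
    timing: str  # "G1" | "G2"
    broken_homolog: str
    co_pos: int
    tracts: list[TractInterval]
    red_chromatids: tuple[np.ndarray, np.ndarray]
    white_chromatids: tuple[np.ndarray, np.ndarray]

    @property
    def donor(self) -> str:
        return _other(self.broken_homolog)

    def donor_copy_counts(self) -> np.ndarray:
        """Per-SNP count (0..4) of the donor allele among the four chromatids."""
        d = self.donor
        counts = np.zeros(len(self.snp_map), dtype=np.int64)
        for chromatid in (*self.red_chromatids, *self.white_chromatids):
            counts += chromatid == d
        return counts

    def expected_class(self) -> str:
        """Observable event class implied by the truth at marker resolution.

        Derived directly from tract coverage of the SNP positions (not via the
        ratio/segmentation path), so it can serve as an independent oracle: a
        tract narrower than the local marker spacing is invisible and the
        expected class degrades accordingly.
        """
        pos = self.snp_map.positions
        proximal = pos <= self.co_pos
        counts = self.donor_copy_counts()[proximal]
        converted = counts > 2
        if not converted.any():
            return "NO_GC"
        # the conversion zone runs from the first converted SNP all the way to
        # the crossover: unconverted 2:2 SNPs inside it (interior gaps or a
        # gap against the reciprocal boundary) make the event complex
        zone = counts[np.flatnonzero(converted)[0] :]
        if (zone == 2).any():
            return "COMPLEX"
        has4 = zone == 4
        if has4.all():
            return "SIMPLE_4_0"
        if not has4.any():
            return "SIMPLE_3_1"
        i4 = np.flatnonzero(has4)
        if i4[-1] - i4[0] + 1 == i4.size:  # one contiguous 4:0 core
            return "HYBRID_4_0_3_1"
        return "COMPLEX"

    def expected_timing(self) -> str:
        cls = self.expected_class()
        if cls == "NO_GC":
            return "UNCLASSIFIED"
        if cls in ("SIMPLE_4_0", "HYBRID_4_0_3_1"):
            return "G1"
        if cls == "SIMPLE_3_1":
            return "G2"
        pos = self.snp_map.positions
        counts = self.donor_copy_counts()[pos <= self.co_pos]
        return "G1" if (counts == 4).any() else "G2"


def generate_snp_map(
    n_snps: int,
    chrom_length: int,
    seed: int,
    chromosome: str = "chrIV",
    selected_marker_pos: int | None = None,
) -> SnpMap:
    """Draw ``n_snps`` distinct marker positions uniformly on [1, chrom_length].

    The default scale of interest is ~2300 SNPs over the ~1.1 Mb interval
    between CEN4 and the selectable SUP4-o/KANMX insertion on chromosome IV.
    """
    if n_snps < 2:
        raise ValueError("need at least 2 SNPs")
    if chrom_length <= n_snps:
        raise ValueError("chrom_length must exceed n_snps")
    rng = np.random.default_rng(seed)
    positions = np.sort(rng.choice(chrom_length, size=n_snps, replace=False)) + 1
    return SnpMap(
        chromosome=chromosome,
        positions=positions,
        selected_marker_pos=selected_marker_pos,
    )


def _patchy_subintervals(
    start: float, end: float, switch_rate: float, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Split (start, end] into alternating converted/unconverted pieces.

    Emulates patchy correction of a heteroduplex: switch points follow a
    Poisson process with ``switch_rate`` per bp; the piece nearest the break
    (the ``end`` side, anchored at the crossover) is always converted.
    """
    points: list[float] = []
    x = end
    while True:
        x -= rng.exponential(1.0 / switch_rate)
        if x <= start:
            break
        points.append(x)
    bounds = [start] + sorted(points) + [end]
    pieces = list(zip(bounds[:-1], bounds[1:]))
    # walk from the break end; alternate converted / skipped
    return [p for i, p in enumerate(reversed(pieces)) if i % 2 == 0]


def simulate_rco_event(
    snp_map: SnpMap,
    timing: str,
    tract_len_bp: float | tuple[float, float],
    co_pos: int,
    broken_homolog: str = ALLELE_B,
    seed: int | None = None,
    patchy_switch_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> SimTruth:
    """Simulate one reciprocal crossover with its conversion tract(s).

    A ``G2`` event breaks one chromatid of ``broken_homolog`` and converts a
    single tract of ``tract_len_bp`` (scalar) immediately proximal to
    ``co_pos``; a ``G1`` event breaks both sisters and takes a pair of
    lengths, equal lengths giving a 4:0 tract and unequal lengths a nested
    hybrid 4:0/3:1 tract.  ``patchy_switch_rate`` > 0 breaks each tract into
    alternating converted/unconverted patches (complex events).
    """
    pos = snp_map.positions
    if not (pos[0] <= co_pos <= pos[-1]):
        raise ValueError(f"co_pos {co_pos} outside map span {snp_map.span}")
    if timing not in ("G1", "G2"):
        raise ValueError(f"timing must be 'G1' or 'G2', got {timing!r}")
    if broken_homolog not in (ALLELE_A, ALLELE_B):
        raise ValueError(f"unknown homolog {broken_homolog!r}")
    if rng is None:
        rng = np.random.default_rng(seed)

    if timing == "G2":
        if np.ndim(tract_len_bp) != 0:
            raise ValueError("G2 events take a single tract length")
        lengths = [float(tract_len_bp), 0.0]
    else:
        if np.ndim(tract_len_bp) == 0 or len(tract_len_bp) != 2:
            raise ValueError("G1 events take a pair of tract lengths")
        lengths = [float(tract_len_bp[0]), float(tract_len_bp[1])]
    if any(l < 0 for l in lengths):
        raise ValueError("tract lengths must be non-negative")

    donor = _other(broken_homolog)
    n = len(snp_map)
    # four chromatids: two donor-homolog sisters, two broken-homolog sisters
    donor_1 = np.full(n, donor, dtype="<U1")
    donor_2 = np.full(n, donor, dtype="<U1")
    broken_1 = np.full(n, broken_homolog, dtype="<U1")
    broken_2 = np.full(n, broken_homolog, dtype="<U1")

    tracts: list[TractInterval] = []
    for chromatid, arr, length in (
        ("broken_1", broken_1, lengths[0]),
        ("broken_2", broken_2, lengths[1]),
    ):
        if length <= 0:
            continue
        start, end = co_pos - length, float(co_pos)
        if patchy_switch_rate > 0:
            pieces = _patchy_subintervals(start, end, patchy_switch_rate, rng)
        else:
            pieces = [(start, end)]
        for a, b in pieces:
            arr[(pos > a) & (pos <= b)] = donor
            tracts.append(
                TractInterval(chromatid, int(math.floor(a)) + 1, int(b), donor)
            )

    # crossover between broken_1 and donor_1: exchange everything distal
    distal = pos > co_pos
    broken_1_x = broken_1.copy()
    donor_1_x = donor_1.copy()
    broken_1_x[distal], donor_1_x[distal] = donor_1[distal], broken_1[distal]

    daughter_1 = (donor_2, broken_1_x)  # homozygous `donor` distal
    daughter_2 = (donor_1_x, broken_2)  # homozygous `broken` distal
    if donor == ALLELE_A:
        red, white = daughter_1, daughter_2
    else:
        red, white = daughter_2, daughter_1
    return SimTruth(
        snp_map=snp_map,
        timing=timing,
        broken_homolog=broken_homolog,
        co_pos=int(co_pos),
        tracts=tracts,
        red_chromatids=red,
        white_chromatids=white,
    )


def sample_rco_events(
    snp_map: SnpMap,
    n_events: int,
    seed: int,
    p_no_gc: float = 0.13,
    p_g1: float = 0.75,
    median_tract_bp: float = 10_600.0,
    tract_sigma: float = 0.9,
    patchy_switch_rate: float = 0.0,
) -> list[SimTruth]:
    """Draw random RCO events with the event mix seen for spontaneous RCOs.

    Defaults: 13% of crossovers carry no detectable conversion, ~75% of
    lesions are G1, and tract lengths are log-normal with median 10.6 kb.
    """
    rng = np.random.default_rng(seed)
    pos = snp_map.positions
    events = []
    for _ in range(n_events):
        co_pos = int(rng.integers(pos[1], pos[-1]))
        broken = ALLELE_A if rng.random() < 0.5 else ALLELE_B
        if rng.random() < p_no_gc:
            timing, tract = "G2", 0.0
        elif rng.random() < p_g1:
            timing = "G1"
            l1 = rng.lognormal(math.log(median_tract_bp), tract_sigma)
            # half of G1 events repair both sisters over the same interval
            l2 = l1 if rng.random() < 0.5 else rng.lognormal(
                math.log(median_tract_bp), tract_sigma
            )
            tract = (min(l1, co_pos - pos[0]), min(l2, co_pos - pos[0]))
        else:
            timing = "G2"
            tract = min(
                rng.lognormal(math.log(median_tract_bp), tract_sigma),
                co_pos - pos[0],
            )
        events.append(
            simulate_rco_event(
                snp_map,
                timing,
                tract,
                co_pos,
                broken_homolog=broken,
                patchy_switch_rate=patchy_switch_rate,
                rng=rng,
            )
        )
    return events


def emit_ratio_profiles(truth: SimTruth, noise: NoiseModel):
    """Noisy (ratio_A, ratio_B) profiles for the red and white sectors.

    Each sector carries two chromatids; the per-SNP copy number of each
    parental allele (0, 1 or 2) sets the mean normalized hybridization ratio,
    around which independent Gaussian noise is added.  Ratios are floored at
    zero.  Returns ``(red_profile, white_profile)``.
    """
    from .segmentation import RatioProfile

    rng = np.random.default_rng(noise.seed)
    means = np.array([noise.mean_hom_absent, noise.mean_het, noise.mean_hom_present])
    profiles = []
    for chromatids in (truth.red_chromatids, truth.white_chromatids):
        copies_a = sum((c == ALLELE_A).astype(np.int64) for c in chromatids)
        ratio_a = means[copies_a]
        ratio_b = means[2 - copies_a]
        if noise.sd > 0:
            ratio_a = ratio_a + rng.normal(0.0, noise.sd, size=ratio_a.shape)
            ratio_b = ratio_b + rng.normal(0.0, noise.sd, size=ratio_b.shape)
        profiles.append(
            RatioProfile(
                snp_map=truth.snp_map,
                ratio_a=np.maximum(ratio_a, 0.0),
                ratio_b=np.maximum(ratio_b, 0.0),
            )
        )
    return profiles[0], profiles[1]


@dataclass(frozen=True)
class TandemArrayState:
    """One homolog's tandem gene array (e.g. CUP1 on chromosome VIII).

    The diagnostic restriction fragment spans the whole array plus fixed
    flanking sequence, so fragment size = flank + unit * copies.  The
    reference arrays are 14 copies of a 2-kb repeat (W303-1A) and 7 copies of
    a 1.2-kb repeat (YJM789).
    """

    homolog: str
    unit_kb: float
    copies: int
    flank_kb: float = 2.0

    def __post_init__(self) -> None:
        if self.copies < 0:
            raise ValueError("copy count must be >= 0")
        if self.unit_kb <= 0 or self.flank_kb < 0:
            raise ValueError("invalid array geometry")

    @property
    def fragment_kb(self) -> float:
        return self.flank_kb + self.unit_kb * self.copies


#: Parental CUP1 arrays: ~30 kb (W303-1A) and ~12 kb (YJM789) EcoRI fragments.
CUP1_PARENTAL = (
    TandemArrayState(ALLELE_A, unit_kb=2.0, copies=14, flank_kb=2.0),
    TandemArrayState(ALLELE_B, unit_kb=1.2, copies=7, flank_kb=3.6),
)


@dataclass
class CnvTrajectory:
    """Subculture-by-subculture history of a tandem-array pair."""

    states: list[tuple[TandemArrayState, TandemArrayState]]
    n_events: tuple[int, int]  # unequal-exchange events applied per homolog

    @property
    def initial(self) -> tuple[TandemArrayState, TandemArrayState]:
        return self.states[0]

    @property
    def final(self) -> tuple[TandemArrayState, TandemArrayState]:
        return self.states[-1]

    def altered(self) -> tuple[bool, bool]:
        return tuple(n > 0 for n in self.n_events)  # type: ignore[return-value]


def simulate_cup1_cnv(
    initial: tuple[TandemArrayState, TandemArrayState] = CUP1_PARENTAL,
    n_subcultures: int = 10,
    event_prob: float = 0.1,
    deletion_fraction: float = 0.78,
    max_step: int = 5,
    seed: int | None = None,
) -> CnvTrajectory:
    """Simulate repeat-number drift in a tandem array pair across subcultures.

    Per subculture and per homolog, an unequal sister-chromatid exchange fires
    with probability ``event_prob``; it deletes repeats with probability
    ``deletion_fraction`` (default reflecting the observed deletion bias,
    47 of 60 alterations) and otherwise adds them.  Step sizes are
    geometric-like (p=0.5), truncated at ``max_step``; copy number never
    drops below 1.
    """
    if not (0.0 <= event_prob <= 1.0 and 0.0 <= deletion_fraction <= 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    if n_subcultures < 1:
        raise ValueError("need at least one subculture")
    rng = np.random.default_rng(seed)
    states = [tuple(initial)]
    current = list(initial)
    n_events = [0, 0]
    for _ in range(n_subcultures):
        for h, state in enumerate(current):
            if rng.random() >= event_prob:
                continue
            n_events[h] += 1
            step = min(int(rng.geometric(0.5)), max_step)
            if rng.random() < deletion_fraction:
                step = -step
            current[h] = TandemArrayState(
                homolog=state.homolog,
                unit_kb=state.unit_kb,
                copies=max(1, state.copies + step),
                flank_kb=state.flank_kb,
            )
        states.append(tuple(current))
    return CnvTrajectory(states=states, n_events=(n_events[0], n_events[1]))
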