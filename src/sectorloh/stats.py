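"""Rates, score confidence intervals, and the hypothesis tests of the study.

Sectored-colony counts behave as rate measurements (one opportunity per
plated cell division), so proportions come with Wilson score intervals
(Newcombe's method 3, i.e. the score interval without continuity
correction).  Class-count comparisons use the Fisher exact test or the 1-df
Pearson chi-square; tract-length distributions use the Mann-Whitney
rank-sum test.  The module also carries the tandem-array arithmetic (EcoRI
fragment size -> repeat copies for the CUP1 arrays) and the SpeI
restriction-fragment genotype call used to score LOH distal to the rDNA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "RateEstimate",
    "SpeiGenotype",
    "sectoring_rate",
    "wilson_ci",
    "fisher_exact",
    "chi_square_2x2",
    "mann_whitney",
    "fold_change",
    "binomial_symmetry_test",
    "estimate_repeat_copies",
    "classify_spei_genotype",
]


@dataclass(frozen=True)
class RateEstimate:
    """Events per division with a Wilson 95% score interval."""

    n_events: int
    n_trials: int
    rate: float
    ci95: tuple[float, float]


@dataclass(frozen=True)
class SpeiGenotype:
    call: str  # HET | HOM_W303 | HOM_YJM789 | UNRESOLVED
    fragment_sizes: tuple[float, ...]


def wilson_ci(
    n_events: int, n_trials: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion (Newcombe method 3)."""
    if n_trials <= 0 or not (0 <= n_events <= n_trials):
        raise ValueError("need 0 <= n_events <= n_trials, n_trials > 0")
    low, high = proportion_confint(
        n_events, n_trials, alpha=1 - confidence, method="wilson"
    )
    # the score interval is exact at the boundaries; clear rounding residue
    if n_events == 0:
        low = 0.0
    if n_events == n_trials:
        high = 1.0
    return float(low), float(high)


def sectoring_rate(n_sectors: int, n_colonies: int) -> RateEstimate:
    """Sectored colonies per colony screened = recombination events/division."""
    if n_colonies <= 0:
        raise ValueError("n_colonies must be positive")
    if n_sectors > n_colonies:
        raise ValueError("cannot have more sectored colonies than colonies")
    return RateEstimate(
        n_events=n_sectors,
        n_trials=n_colonies,
        rate=n_sectors / n_colonies,
        ci95=wilson_ci(n_sectors, n_colonies),
    )


def _as_table(table) -> np.ndarray:
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float)
        if np.any(arr < 0) or np.any(arr != np.round(arr)):
            raise ValueError("table cells must be non-negative integers")
        arr = arr.astype(np.int64)
    return arr


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p (sum of hypergeometric probabilities <= observed)."""
    arr = _as_table(table)
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        return 1.0
    return float(sps.fisher_exact(arr, alternative="two-sided").pvalue)


def chi_square_2x2(table, continuity: bool = False) -> tuple[float, float]:
    """Pearson 1-df chi-square on a 2x2 table, no Yates correction by default."""
    arr = _as_table(table)
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("chi-square is undefined with a zero margin")
    res = sps.chi2_contingency(arr, correction=continuity)
    return float(res.statistic), float(res.pvalue)


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test; returns (U, p).

    Exact enumeration for small tie-free samples (both n <= 20), otherwise
    the tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size <= 20 and y.size <= 20 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def fold_change(numerator: RateEstimate, denominator: RateEstimate) -> float:
    """Ratio of two point rates."""
    if denominator.rate == 0:
        raise ValueError("denominator rate is zero")
    return numerator.rate / denominator.rate


def binomial_symmetry_test(n_one: int, n_other: int) -> float:
    """Two-sided exact binomial test of a 50:50 split (e.g. deletions vs
    additions of tandem repeats)."""
    if n_one < 0 or n_other < 0:
        raise ValueError("counts must be non-negative")
    return float(sps.binomtest(n_one, n_one + n_other, p=0.5).pvalue)


def estimate_repeat_copies(
    fragment_kb: float, unit_kb: float, flank_kb: float
) -> int:
    """Repeat copies in a tandem array from its restriction-fragment size.

    fragment = flank + unit x copies, so copies = round((fragment - flank) /
    unit), floored at zero.  For the CUP1 arrays: the ~30 kb W303-1A EcoRI
    fragment with a 2-kb unit gives 14 copies; the ~12 kb YJM789 fragment
    with a 1.2-kb unit gives 7.
    """
    if unit_kb <= 0:
        raise ValueError("repeat unit must be positive")
    if fragment_kb < flank_kb:
        raise ValueError("fragment cannot be smaller than its flanks")
    return max(int(round((fragment_kb - flank_kb) / unit_kb)), 0)


#: Diagnostic SpeI fragment sizes (bp) for the rDNA-distal polymorphism.
_SPEI_W303 = 750.0
_SPEI_YJM = (500.0, 250.0)


def classify_spei_genotype(
    fragment_sizes, tolerance: float = 30.0
) -> SpeiGenotype:
    """Genotype at the SpeI restriction-site polymorphism distal to the rDNA.

    The YJM789 allele carries the SpeI site (~500 + ~250 bp products); the
    W303-1A allele does not (~750 bp).  Three fragments -> heterozygous; only
    the cut products -> homozygous YJM789; only the uncut product ->
    homozygous W303-1A; any other pattern is unresolved.
    """
    sizes = tuple(float(s) for s in fragment_sizes)
    if not sizes:
        raise ValueError("need at least one fragment size")

    def has(target: float) -> bool:
        return any(abs(s - target) <= tolerance for s in sizes)

    def only(targets: tuple[float, ...]) -> bool:
        return all(
            any(abs(s - t) <= tolerance for t in targets) for s in sizes
        )

    w = has(_SPEI_W303)
    y = has(_SPEI_YJM[0]) and has(_SPEI_YJM[1])
    if w and y and only((_SPEI_W303, *_SPEI_YJM)):
        call = "HET"
    elif y and not w and only(_SPEI_YJM):
        call = "HOM_YJM789"
    elif w and not y and only((_SPEI_W303,)):
        call = "HOM_W303"
    else:
        call = "UNRESOLVED"
    return SpeiGenotype(call=call, fragment_sizes=sizes)
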