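"""Ordered heterozygous-SNP scaffold for a hybrid diploid chromosome.

All genomic coordinates in this package are 1-based and inclusive (the SGD
convention).  The two parental allele labels are ``"A"`` (W303-1A-like) and
``"B"`` (YJM789-like) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Parental allele labels: A is the W303-1A-like parent, B the YJM789-like one.
ALLELE_A = "A"
ALLELE_B = "B"
ALLELES = (ALLELE_A, ALLELE_B)


@dataclass(frozen=True)
class SnpMap:
    """Ordered map of heterozygous SNP markers on one chromosome.

    Parameters
    ----------
    chromosome
        Chromosome identifier, e.g. ``"chrIV"``.
    positions
        Strictly increasing 1-based bp coordinates, one per marker.
    names
        Marker names, same length as ``positions``.
    selected_marker_pos
        Coordinate of the selectable insertion (the SUP4-o/KANMX site) used to
        recover reciprocal crossovers, or ``None`` if absent.  When present it
        must lie at or beyond the last marker so that every crossover proximal
        to it is recoverable by the colony-color assay.
    """

    chromosome: str
    positions: np.ndarray
    names: tuple[str, ...] = ()
    selected_marker_pos: int | None = None
    allele_labels: tuple[str, str] = field(default=ALLELES)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        object.__setattr__(self, "positions", pos)
        if pos.size < 2:
            raise ValueError("a SNP map needs at least 2 markers")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("SNP positions must be strictly increasing")
        if not self.names:
            object.__setattr__(
                self, "names", tuple(f"snp_{p}" for p in pos)
            )
        elif len(self.names) != pos.size:
            raise ValueError("names and positions length mismatch")
        if self.selected_marker_pos is not None and self.selected_marker_pos < pos[-1]:
            raise ValueError(
                "selected marker must lie at or beyond the last SNP "
                f"({self.selected_marker_pos} < {pos[-1]})"
            )

    def __len__(self) -> int:
        return int(self.positions.size)

    @property
    def span(self) -> tuple[int, int]:
        return int(self.positions[0]), int(self.positions[-1])

    def index_of(self, position: int) -> int:
        """Index of the marker at ``position`` (exact match required)."""
        i = int(np.searchsorted(self.positions, position))
        if i >= len(self) or self.positions[i] != position:
            raise KeyError(f"no SNP at position {position}")
        return i

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SnpMap):
            return NotImplemented
        return (
            self.chromosome == other.chromosome
            and np.array_equal(self.positions, other.positions)
            and self.names == other.names
            and self.selected_marker_pos == other.selected_marker_pos
        )
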