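"""Genome containers: chromosome sets and genetic maps.

All genomic coordinates in this package are genetic positions in
centimorgans (cM), 0-based, half-open ``[start, end)``.  Physical (bp)
coordinates appear only at file-format boundaries and are converted to cM
by linear interpolation on a genetic map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["ChromosomeSet", "GeneticMap"]


@dataclass(frozen=True)
class ChromosomeSet:
    """Ordered set of chromosomes with genetic lengths in cM."""

    names: tuple[str, ...]
    lengths_cM: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.lengths_cM):
            raise ValueError("names and lengths differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("chromosome names must be unique")
        if len(self.names) == 0:
            raise ValueError("at least one chromosome is required")
        for name, length in zip(self.names, self.lengths_cM):
            if not length > 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        object.__setattr__(self, "lengths_cM", tuple(float(x) for x in self.lengths_cM))

    @classmethod
    def uniform(cls, n: int, length_cM: float, prefix: str = "chr") -> "ChromosomeSet":
        """``n`` equal-length chromosomes named ``chr1..chrn``."""
        return cls(tuple(f"{prefix}{i + 1}" for i in range(n)), tuple([length_cM] * n))

    @classmethod
    def from_dict(cls, lengths: Mapping[str, float]) -> "ChromosomeSet":
        return cls(tuple(lengths.keys()), tuple(lengths.values()))

    @property
    def total_cM(self) -> float:
        return float(sum(self.lengths_cM))

    def length_of(self, name: str) -> float:
        try:
            return self.lengths_cM[self.names.index(name)]
        except ValueError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(zip(self.names, self.lengths_cM))

    def __len__(self) -> int:
        return len(self.names)

    def to_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.lengths_cM))


@dataclass
class GeneticMap:
    """Per-chromosome piecewise-linear bp <-> cM interpolation tables.

    Positions outside the mapped interval are clamped to the terminal cM
    value (constant extrapolation); each clamped query is counted and
    reported once through the module logger.
    """

    positions_bp: Mapping[str, np.ndarray]
    positions_cM: Mapping[str, np.ndarray]
    _n_clamped: int = field(default=0, repr=False)

    def __post_init__(self) -> None:
        for chrom in self.positions_bp:
            bp = np.asarray(self.positions_bp[chrom], dtype=float)
            cm = np.asarray(self.positions_cM[chrom], dtype=float)
            if bp.shape != cm.shape or bp.ndim != 1 or bp.size < 2:
                raise ValueError(f"map for {chrom!r} needs >=2 matched (bp, cM) rows")
            if np.any(np.diff(bp) < 0) or np.any(np.diff(cm) < 0):
                raise ValueError(f"map for {chrom!r} must be nondecreasing")

    def bp_to_cM(self, chrom: str, bp: Sequence[float] | np.ndarray) -> np.ndarray:
        if chrom not in self.positions_bp:
            raise KeyError(f"no genetic map for chromosome {chrom!r}")
        bp = np.asarray(bp, dtype=float)
        xs, ys = self.positions_bp[chrom], self.positions_cM[chrom]
        out = np.interp(bp, xs, ys)
        clamped = int(np.sum((bp < xs[0]) | (bp > xs[-1])))
        if clamped:
            self._n_clamped += clamped
            logger.warning(
                "%d position(s) on %s outside the genetic map; cM clamped to map ends",
                clamped,
                chrom,
            )
        return out

    def cM_to_bp(self, chrom: str, cm: Sequence[float] | np.ndarray) -> np.ndarray:
        if chrom not in self.positions_cM:
            raise KeyError(f"no genetic map for chromosome {chrom!r}")
        cm = np.asarray(cm, dtype=float)
        return np.interp(cm, self.positions_cM[chrom], self.positions_bp[chrom])
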