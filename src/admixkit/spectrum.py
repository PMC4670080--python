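"""Tract-length spectra: the observed statistic the tract model fits.

A spectrum is, per ancestry, a histogram of tract lengths (cM) over bins
``[e0, e1), ..., [e_{B-2}, e_{B-1}), [e_{B-1}, inf)`` plus a dedicated
whole-chromosome category per chromosome: a haplotype consisting of a
single tract contributes there rather than to the bins, because its length
is fixed by the chromosome, not by the recombination process.  Tracts
shorter than ``e0`` (default 0.2 cM, the local-ancestry call resolution)
are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import bin_tracts
from .genome import ChromosomeSet

__all__ = ["TractLengthSpectrum", "ExpectedSpectrum", "default_bin_edges"]


def default_bin_edges(chroms: ChromosomeSet, n_bins: int = 50, floor_cM: float = 0.2) -> np.ndarray:
    """Equal-width bin edges from the resolution floor to the longest
    chromosome."""
    return np.linspace(floor_cM, max(chroms.lengths_cM), n_bins + 1)[:-1]


def _check_edges(edges: np.ndarray) -> np.ndarray:
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or edges.size < 1:
        raise ValueError("bin edges must be a non-empty 1-D array")
    if edges.size > 1 and np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    return edges


@dataclass
class TractLengthSpectrum:
    """Observed binned tract counts per ancestry.

    ``counts[a, b]`` is the number of tracts of ancestry ``a`` in bin ``b``;
    ``full_counts[a, c]`` the number of whole-chromosome tracts of ancestry
    ``a`` on chromosome ``c``.
    """

    edges: np.ndarray  # (B,) left edges; last bin open-ended
    ancestries: tuple[str, ...]
    counts: np.ndarray  # (A, B)
    full_counts: np.ndarray  # (A, C)
    n_haplotypes: int
    chromosomes: ChromosomeSet

    def __post_init__(self) -> None:
        self.edges = _check_edges(self.edges)
        if self.counts.shape != (len(self.ancestries), self.edges.size):
            raise ValueError("counts shape mismatch")
        if self.full_counts.shape != (len(self.ancestries), len(self.chromosomes)):
            raise ValueError("full_counts shape mismatch")
        if np.any(self.counts < 0) or np.any(self.full_counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def total_tracts(self) -> int:
        return int(self.counts.sum() + self.full_counts.sum())

    def cells(self) -> np.ndarray:
        """All Poisson cells (bins then whole-chromosome categories) as a
        flat vector, ancestry-major."""
        return np.concatenate([self.counts.ravel(), self.full_counts.ravel()])

    # ------------------------------------------------------------------
    @classmethod
    def from_cohort(cls, cohort, edges) -> "TractLengthSpectrum":
        """Fast path: bin a simulated cohort's true tracts."""
        edges = _check_edges(np.asarray(edges, dtype=float))
        A = len(cohort.populations)
        counts = np.zeros((A, edges.size), dtype=np.int64)
        full = np.zeros((A, len(cohort.chromosomes)), dtype=np.int64)
        lmass = np.zeros(A)
        for ci, (chrom, _) in enumerate(cohort.chromosomes):
            bin_tracts(
                cohort.tract_ends[chrom],
                cohort.tract_anc[chrom],
                cohort.tract_offsets[chrom],
                A,
                edges,
                counts,
                full[:, ci],
                lmass,
            )
        return cls(
            edges=edges,
            ancestries=cohort.populations,
            counts=counts,
            full_counts=full,
            n_haplotypes=cohort.n_haplotypes,
            chromosomes=cohort.chromosomes,
        )

    @classmethod
    def from_tracts(
        cls,
        tracts,
        edges,
        chroms: ChromosomeSet,
        ancestries: tuple[str, ...] | None = None,
        n_haplotypes: int | None = None,
    ) -> "TractLengthSpectrum":
        """Bin a sequence of :class:`~admixkit.ancestry.AncestryTract` (or a
        DataFrame with the tract columns).

        A tract is a whole-chromosome tract when it covers ``[0, L)`` of its
        chromosome.
        """
        import pandas as pd

        from .ancestry import tracts_to_frame

        df = tracts if isinstance(tracts, pd.DataFrame) else tracts_to_frame(tracts)
        edges = _check_edges(np.asarray(edges, dtype=float))
        if ancestries is None:
            ancestries = tuple(sorted(df["ancestry"].unique()))
        anc_idx = {a: i for i, a in enumerate(ancestries)}
        chrom_idx = {c: i for i, c in enumerate(chroms.names)}
        A = len(ancestries)
        counts = np.zeros((A, edges.size), dtype=np.int64)
        full = np.zeros((A, len(chroms)), dtype=np.int64)
        n_haps = df["haplotype_id"].nunique() if n_haplotypes is None else n_haplotypes
        if len(df):
            lengths = (df["end_cM"] - df["start_cM"]).to_numpy()
            anc = df["ancestry"].map(anc_idx).to_numpy()
            chrom_len = df["chrom"].map(dict(zip(chroms.names, chroms.lengths_cM))).to_numpy()
            is_full = (df["start_cM"].to_numpy() == 0.0) & np.isclose(
                df["end_cM"].to_numpy(), chrom_len
            )
            ci = df["chrom"].map(chrom_idx).to_numpy()
            np.add.at(full, (anc[is_full], ci[is_full]), 1)
            keep = ~is_full & (lengths >= edges[0])
            b = np.clip(np.searchsorted(edges, lengths[keep], side="right") - 1, 0, None)
            np.add.at(counts, (anc[keep], b), 1)
        return cls(
            edges=edges,
            ancestries=tuple(ancestries),
            counts=counts,
            full_counts=full,
            n_haplotypes=int(n_haps),
            chromosomes=chroms,
        )


@dataclass
class ExpectedSpectrum:
    """Expected (real-valued) counterpart of :class:`TractLengthSpectrum`,
    produced by the analytic tract model.  ``length_mass`` is the expected
    total binned tract length (cM) per ancestry, used for conservation
    checks; ``proportions`` the schedule-implied genome fractions."""

    edges: np.ndarray
    ancestries: tuple[str, ...]
    mu: np.ndarray  # (A, B) expected bin counts
    full_mu: np.ndarray  # (A, C) expected whole-chromosome counts
    length_mass: np.ndarray  # (A,) expected total tract length incl. whole-chrom, cM
    n_haplotypes: int
    chromosomes: ChromosomeSet
    proportions: dict[str, float]

    def cells(self) -> np.ndarray:
        return np.concatenate([self.mu.ravel(), self.full_mu.ravel()])

    def to_frame(self, observed: TractLengthSpectrum | None = None):
        """Long-format table (ancestry, bin_lo, bin_hi, expected[, observed])
        for decay-curve plotting and export."""
        import pandas as pd

        hi = np.append(self.edges[1:], np.inf)
        rows = []
        for a, anc in enumerate(self.ancestries):
            for b in range(self.edges.size):
                rows.append(
                    {
                        "ancestry": anc,
                        "bin_lo": self.edges[b],
                        "bin_hi": hi[b],
                        "expected": self.mu[a, b],
                    }
                )
        df = pd.DataFrame(rows)
        if observed is not None:
            df["observed"] = observed.counts.ravel()
        return df
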