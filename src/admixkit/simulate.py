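"""Forward simulation of admixed cohorts with known migration history.

The simulator is an explicit pedigree model, not a Markov approximation:
generation ``T0`` (founding) individuals are migrants drawn from the
founding fractions; at each later generation ``t`` an individual is with
probability ``sum_p m_p(t)`` a new migrant and otherwise the child of a
monogamous pair drawn uniformly from generation ``t + 1``.  Transmitted
chromosomes are meiotic recombinants with Poisson(length in Morgans)
crossovers at uniform positions, no interference, and a fair-coin starting
haplotype.  Generation-1 haplotypes carry exact ancestry tracts, which is
what makes this module a valid independent oracle for the analytic tract
model.

Because source haplotypes are exchangeable within a source population, the
simulation tracks tracts only; alleles are painted afterwards from
ancestry-specific allele frequencies (:func:`draw_ancestral_frequencies`,
:func:`paint_haplotypes`) under a Balding-Nichols model, and ground-truth
IBD segments can be copied in with :func:`plant_ibd_segment`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._kernels import ancestry_lengths, meiose_batch
from .genome import ChromosomeSet
from .schedule import MigrationSchedule

__all__ = [
    "AncestralFrequencies",
    "SimulatedCohort",
    "simulate_pedigree_tracts",
    "draw_ancestral_frequencies",
    "paint_haplotypes",
    "plant_ibd_segment",
]


# ----------------------------------------------------------------------
@dataclass
class AncestralFrequencies:
    """Ancestry-specific allele frequencies on a genetic map.

    ``freqs[l, p]`` is the frequency of the "1" allele of locus ``l`` in
    source population ``p``; ``chrom_index``/``pos_cM`` place each locus,
    with positions nondecreasing within a chromosome.
    """

    populations: tuple[str, ...]
    chromosomes: ChromosomeSet
    chrom_index: np.ndarray  # (n_loci,) int32, index into chromosomes.names
    pos_cM: np.ndarray  # (n_loci,) float64
    freqs: np.ndarray  # (n_loci, n_pops) float64 in (0, 1)

    def __post_init__(self) -> None:
        if self.freqs.shape != (self.pos_cM.size, len(self.populations)):
            raise ValueError("frequency matrix shape mismatch")
        if self.freqs.size and (np.any(self.freqs <= 0) or np.any(self.freqs >= 1)):
            raise ValueError("allele frequencies must lie strictly in (0, 1)")
        for c in np.unique(self.chrom_index):
            p = self.pos_cM[self.chrom_index == c]
            if np.any(np.diff(p) < 0):
                raise ValueError("locus positions must be nondecreasing within chromosome")

    @property
    def n_loci(self) -> int:
        return self.pos_cM.size

    def loci_on(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.chrom_index == self.chromosomes.names.index(chrom))


@dataclass
class PlantedSegment:
    hap_a: int
    hap_b: int
    chrom: str
    start_cM: float
    end_cM: float


@dataclass
class SimulatedCohort:
    """A simulated admixed cohort: true ancestry tracts per haplotype and,
    once painted, phased 0/1 alleles.

    Haplotype ``2 i`` and ``2 i + 1`` belong to individual ``i``; tracts on
    each chromosome are stored CSR-style (``ends``/``anc``/``offsets``) and
    tile ``[0, L)`` exactly.
    """

    populations: tuple[str, ...]
    chromosomes: ChromosomeSet
    tract_ends: dict[str, np.ndarray]
    tract_anc: dict[str, np.ndarray]
    tract_offsets: dict[str, np.ndarray]
    n_individuals: int
    seed: int
    labels: list[str] = field(default_factory=list)
    alleles: dict[str, np.ndarray] | None = None
    frequencies: AncestralFrequencies | None = None
    planted_ibd: list[PlantedSegment] = field(default_factory=list)

    @property
    def n_haplotypes(self) -> int:
        return 2 * self.n_individuals

    def individual_ids(self) -> list[str]:
        return [f"ind{i:05d}" for i in range(self.n_individuals)]

    def haplotype_ids(self) -> list[str]:
        return [f"ind{i // 2:05d}.{i % 2}" for i in range(self.n_haplotypes)]

    # ------------------------------------------------------------------
    def ancestry_fractions(self, level: str = "haplotype") -> np.ndarray:
        """Genome-wide ancestry fractions, shape ``(units, n_pops)``."""
        out = np.zeros((self.n_haplotypes, len(self.populations)))
        for chrom, _ in self.chromosomes:
            ancestry_lengths(
                self.tract_ends[chrom],
                self.tract_anc[chrom],
                self.tract_offsets[chrom],
                len(self.populations),
                out,
            )
        out /= self.chromosomes.total_cM
        if level == "haplotype":
            return out
        if level == "individual":
            return 0.5 * (out[0::2] + out[1::2])
        raise ValueError(f"unknown level {level!r}")

    def tracts_dataframe(self):
        """All tracts as a tidy table (haplotype_id, chrom, start/end cM,
        ancestry, posterior = 1.0 for simulated truth)."""
        import pandas as pd

        ids = self.haplotype_ids()
        frames = []
        for chrom, _ in self.chromosomes:
            ends = self.tract_ends[chrom]
            anc = self.tract_anc[chrom]
            off = self.tract_offsets[chrom]
            counts = np.diff(off)
            starts = ends.copy()
            starts[1:] = ends[:-1]
            starts[off[:-1]] = 0.0
            hap_idx = np.repeat(np.arange(self.n_haplotypes), counts)
            frames.append(
                pd.DataFrame(
                    {
                        "haplotype_id": [ids[i] for i in hap_idx],
                        "chrom": chrom,
                        "start_cM": starts,
                        "end_cM": ends,
                        "ancestry": [self.populations[a] for a in anc],
                        "posterior": 1.0,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def haplotype_matrix(self, is_reference: bool = False):
        """Painted alleles as a :class:`~admixkit.ancestry.MaskedHaplotypeMatrix`
        (fully observed; loci ordered by chromosome then position)."""
        from .ancestry import MaskedHaplotypeMatrix

        if self.alleles is None or self.frequencies is None:
            raise ValueError("cohort must be painted first")
        fr = self.frequencies
        return MaskedHaplotypeMatrix(
            haplotype_ids=self.haplotype_ids(),
            locus_ids=[f"snp_{fr.chromosomes.names[c]}_{i}" for i, c in
                       zip(self._per_chrom_locus_index(), fr.chrom_index)],
            chrom=np.array([fr.chromosomes.names[c] for c in fr.chrom_index], dtype=object),
            pos_cM=fr.pos_cM.copy(),
            alleles=np.hstack([self.alleles[c] for c, _ in self.chromosomes]),
            populations=(
                [l for l in self.labels for _ in (0, 1)]
                if len(self.labels) == self.n_individuals
                else ["" for _ in range(self.n_haplotypes)]
            ),
            is_reference=np.full(self.n_haplotypes, is_reference, dtype=bool),
        )

    def _per_chrom_locus_index(self) -> np.ndarray:
        fr = self.frequencies
        idx = np.zeros(fr.n_loci, dtype=np.int64)
        for c in np.unique(fr.chrom_index):
            sel = fr.chrom_index == c
            idx[sel] = np.arange(sel.sum())
        return idx

    def n_switch_points(self) -> int:
        """Total number of ancestry switch points over all haplotypes."""
        total = 0
        for chrom, _ in self.chromosomes:
            total += int(self.tract_ends[chrom].size - (self.tract_offsets[chrom].size - 1))
        return total


# ----------------------------------------------------------------------
def simulate_pedigree_tracts(
    schedule: MigrationSchedule,
    chroms: ChromosomeSet,
    n_individuals: int,
    seed: int,
    pedigree_size: int | None = None,
) -> SimulatedCohort:
    """Forward-simulate true ancestry tracts for ``n_individuals`` diploids.

    ``pedigree_size`` is the (constant) number of individuals per ancestral
    generation; it defaults to ``max(200, 10 * n_individuals)`` to limit
    pedigree collapse.  Only individuals ancestral to the sample are
    materialised, which does not change the sampling distribution.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    T0 = schedule.founding_time
    N = int(pedigree_size) if pedigree_size is not None else max(200, 10 * n_individuals)
    if N % 2:
        N += 1  # mating pairs need an even census
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_pops = schedule.n_pops
    M = schedule.total_inflow()
    rates = schedule.rates

    # -- structure pass: migrant status, sources and parent pairs ------
    sizes = {t: (n_individuals if t == 1 else N) for t in range(1, T0 + 1)}
    is_migrant: dict[int, np.ndarray] = {}
    mig_src: dict[int, np.ndarray] = {}
    pair_choice: dict[int, np.ndarray] = {}
    perm: dict[int, np.ndarray] = {}
    for t in range(1, T0 + 1):
        size = sizes[t]
        if t == T0:
            is_migrant[t] = np.ones(size, dtype=bool)
            mig_src[t] = rng.choice(n_pops, size=size, p=rates[T0] / rates[T0].sum())
            continue
        u = rng.random(size)
        is_migrant[t] = u < M[t]
        src = np.zeros(size, dtype=np.int64)
        nm = int(is_migrant[t].sum())
        if nm and M[t] > 0:
            src[is_migrant[t]] = rng.choice(n_pops, size=nm, p=rates[t] / M[t])
        mig_src[t] = src
        perm[t + 1] = rng.permutation(sizes[t + 1])
        pair_choice[t] = rng.integers(0, sizes[t + 1] // 2, size=size)

    # -- mark individuals ancestral to the sample ----------------------
    needed = {1: np.ones(sizes[1], dtype=bool)}
    for t in range(1, T0):
        nxt = np.zeros(sizes[t + 1], dtype=bool)
        kids = np.flatnonzero(needed[t] & ~is_migrant[t])
        pairs = pair_choice[t][kids]
        nxt[perm[t + 1][2 * pairs]] = True
        nxt[perm[t + 1][2 * pairs + 1]] = True
        needed[t + 1] = nxt

    # -- forward pass, founding generation downwards -------------------
    cohort_ends: dict[str, np.ndarray] = {}
    cohort_anc: dict[str, np.ndarray] = {}
    cohort_off: dict[str, np.ndarray] = {}
    chrom_names = list(chroms.names)
    lengths = dict(chroms)

    # generation T0: all migrants
    gen_haps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    src_h = np.repeat(mig_src[T0], 2).astype(np.int8)
    for chrom in chrom_names:
        L = lengths[chrom]
        ends = np.full(2 * sizes[T0], L)
        off = np.arange(2 * sizes[T0] + 1, dtype=np.int64)
        gen_haps[chrom] = (ends, src_h.copy(), off)

    for t in range(T0 - 1, 0, -1):
        size = sizes[t]
        n_haps = 2 * size
        mode = np.full(n_haps, -1, dtype=np.int8)
        skip = ~needed[t] | is_migrant[t]
        mode[0::2][skip] = np.where(is_migrant[t], mig_src[t], 0)[skip].astype(np.int8)
        mode[1::2][skip] = mode[0::2][skip]
        # parent individual per haplotype: hap 0 from father, hap 1 from mother
        pairs = pair_choice[t]
        father = perm[t + 1][2 * pairs]
        mother = perm[t + 1][2 * pairs + 1]
        pind = np.empty(n_haps, dtype=np.int64)
        pind[0::2] = father
        pind[1::2] = mother
        meiotic = mode == -1
        new_gen: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom in chrom_names:
            L = lengths[chrom]
            n_xo = np.zeros(n_haps, dtype=np.int64)
            n_xo[meiotic] = rng.poisson(L / 100.0, size=int(meiotic.sum()))
            xo_off = np.zeros(n_haps + 1, dtype=np.int64)
            np.cumsum(n_xo, out=xo_off[1:])
            total_xo = int(xo_off[-1])
            xo_pos = rng.random(total_xo) * L
            if total_xo:
                hap_of_xo = np.repeat(np.arange(n_haps), n_xo)
                order = np.lexsort((xo_pos, hap_of_xo))
                xo_pos = xo_pos[order]
            coin = rng.integers(0, 2, size=n_haps).astype(np.int8)
            p_ends, p_anc, p_off = gen_haps[chrom]
            p_counts = np.diff(p_off)
            cap = int(
                np.sum(~meiotic)
                + np.sum(p_counts[2 * pind[meiotic]])
                + np.sum(p_counts[2 * pind[meiotic] + 1])
                + np.sum(n_xo)
            )
            out_ends = np.empty(cap)
            out_anc = np.empty(cap, dtype=np.int8)
            out_off = np.empty(n_haps + 1, dtype=np.int64)
            n_used = meiose_batch(
                p_ends,
                p_anc,
                p_off,
                mode,
                pind,
                xo_pos,
                xo_off,
                coin,
                L,
                out_ends,
                out_anc,
                out_off,
            )
            new_gen[chrom] = (out_ends[:n_used].copy(), out_anc[:n_used].copy(), out_off)
        gen_haps = new_gen

    for chrom in chrom_names:
        cohort_ends[chrom], cohort_anc[chrom], cohort_off[chrom] = gen_haps[chrom]

    return SimulatedCohort(
        populations=schedule.populations,
        chromosomes=chroms,
        tract_ends=cohort_ends,
        tract_anc=cohort_anc,
        tract_offsets=cohort_off,
        n_individuals=n_individuals,
        seed=int(seed),
    )


# ----------------------------------------------------------------------
def draw_ancestral_frequencies(
    n_loci: int,
    n_pops: int,
    fst: float,
    chroms: ChromosomeSet,
    seed: int,
    populations: Sequence[str] | None = None,
) -> AncestralFrequencies:
    """Balding-Nichols ancestry-specific allele frequencies.

    Per locus an ancestral frequency ``p ~ Uniform(0.05, 0.95)`` is drawn;
    each population's frequency is ``Beta(p (1 - F) / F, (1 - p)(1 - F)/F)``
    so that E = ``p`` and the expected differentiation between populations
    is ``F``.  Loci are placed uniformly on the genetic map.
    """
    if not 0 < fst < 1:
        raise ValueError("fst must lie strictly in (0, 1)")
    pops = tuple(populations) if populations is not None else tuple(
        f"POP{i}" for i in range(n_pops)
    )
    if len(pops) != n_pops:
        raise ValueError("populations length must equal n_pops")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    lengths = np.asarray(chroms.lengths_cM)
    if n_loci == 0:
        return AncestralFrequencies(
            pops,
            chroms,
            np.empty(0, dtype=np.int32),
            np.empty(0),
            np.empty((0, n_pops)),
        )
    chrom_index = rng.choice(len(lengths), size=n_loci, p=lengths / lengths.sum()).astype(
        np.int32
    )
    pos = rng.random(n_loci) * lengths[chrom_index]
    order = np.lexsort((pos, chrom_index))
    chrom_index, pos = chrom_index[order], pos[order]
    p_anc = rng.uniform(0.05, 0.95, size=n_loci)
    scale = (1.0 - fst) / fst
    freqs = rng.beta(
        np.repeat(p_anc[:, None], n_pops, axis=1) * scale,
        np.repeat((1.0 - p_anc)[:, None], n_pops, axis=1) * scale,
    )
    np.clip(freqs, 1e-9, 1 - 1e-9, out=freqs)
    return AncestralFrequencies(pops, chroms, chrom_index, pos, freqs)


def paint_haplotypes(
    cohort: SimulatedCohort, freqs: AncestralFrequencies, seed: int
) -> SimulatedCohort:
    """Draw phased 0/1 alleles: Bernoulli(frequency in the ancestry of the
    overlapping tract) at every locus of every haplotype."""
    if tuple(freqs.chromosomes.names) != tuple(cohort.chromosomes.names):
        raise ValueError("frequencies do not cover the cohort's chromosomes")
    if freqs.populations != cohort.populations:
        raise ValueError("frequency populations do not match cohort populations")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    alleles: dict[str, np.ndarray] = {}
    for ci, (chrom, _) in enumerate(cohort.chromosomes):
        loci = np.flatnonzero(freqs.chrom_index == ci)
        pos = freqs.pos_cM[loci]
        fmat = freqs.freqs[loci]  # (n_loci_c, n_pops)
        ends = cohort.tract_ends[chrom]
        anc = cohort.tract_anc[chrom]
        off = cohort.tract_offsets[chrom]
        out = np.empty((cohort.n_haplotypes, loci.size), dtype=np.int8)
        u = rng.random(out.shape)
        for h in range(cohort.n_haplotypes):
            e = ends[off[h] : off[h + 1]]
            a = anc[off[h] : off[h + 1]]
            idx = np.searchsorted(e, pos, side="right")
            if idx.size and idx.max() >= a.size:
                raise RuntimeError(
                    f"locus beyond tract cover on {chrom} haplotype {h}"
                )
            out[h] = u[h] < fmat[np.arange(loci.size), a[idx]]
        alleles[chrom] = out
    cohort.alleles = alleles
    cohort.frequencies = freqs
    return cohort


def plant_ibd_segment(
    cohort: SimulatedCohort,
    hap_a: int,
    hap_b: int,
    chrom: str,
    start_cM: float,
    end_cM: float,
) -> SimulatedCohort:
    """Overwrite ``hap_b``'s alleles with ``hap_a``'s on ``[start, end)``
    and record the interval as ground truth for IBD-detector tests."""
    if cohort.alleles is None or cohort.frequencies is None:
        raise ValueError("cohort must be painted before planting IBD segments")
    if end_cM <= start_cM:
        raise ValueError("end_cM must exceed start_cM")
    L = cohort.chromosomes.length_of(chrom)
    if start_cM < 0 or end_cM > L:
        raise ValueError(f"interval [{start_cM}, {end_cM}) outside chromosome {chrom}")
    pair = frozenset((hap_a, hap_b))
    for seg in cohort.planted_ibd:
        if (
            seg.chrom == chrom
            and frozenset((seg.hap_a, seg.hap_b)) == pair
            and seg.start_cM < end_cM
            and start_cM < seg.end_cM
        ):
            raise ValueError("overlapping planted segment on the same haplotype pair")
    ci = cohort.chromosomes.names.index(chrom)
    loci = np.flatnonzero(cohort.frequencies.chrom_index == ci)
    pos = cohort.frequencies.pos_cM[loci]
    sel = (pos >= start_cM) & (pos < end_cM)
    cohort.alleles[chrom][hap_b, sel] = cohort.alleles[chrom][hap_a, sel]
    cohort.planted_ibd.append(PlantedSegment(hap_a, hap_b, chrom, start_cM, end_cM))
    return cohort
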