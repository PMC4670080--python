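"""Identity-by-descent detection and ancestry overlay.

Haploid IBD detection follows the GERMLINE hashing strategy: markers are
partitioned into consecutive slices ("bits", 128 markers by default);
exact slice matches between haplotypes are hashed as seeds; seed runs are
extended across adjacent slices while each slice has at most
``max_mismatch_per_slice`` allele mismatches (the haploid reading of
GERMLINE's ``-err_hom 2``; heterozygous mismatches do not exist on
haplotypes, mirroring ``-err_het 0``); and merged segments shorter than
3 cM are discarded.  Haploid mode is conservative: a phase-switch error
interrupts a match.

Detected (or GERMLINE-file) segments are then profiled against local-
ancestry calls, summed into normalized between/within-population sharing
matrices with chromosome-weighted jackknife standard errors, and related
to ancestry through the segment-length regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .ancestry import LocalAncestryCalls
from .genome import ChromosomeSet, GeneticMap

__all__ = [
    "IBDSegment",
    "SharingMatrix",
    "find_ibd_haploid",
    "read_germline_match",
    "write_germline_match",
    "segment_ancestry_profile",
    "sharing_matrix",
    "jackknife_se",
    "length_ancestry_regression",
]


@dataclass
class IBDSegment:
    """A shared haplotype interval between two haploid genomes."""

    hap_a: str
    hap_b: str
    chrom: str
    start_cM: float
    end_cM: float
    n_markers: int = 0
    ancestry_profile: dict[str, float] = field(default_factory=dict)
    discordant_ancestry: bool = False

    def __post_init__(self) -> None:
        if self.end_cM <= self.start_cM:
            raise ValueError("IBD segment end must exceed start")

    @property
    def length_cM(self) -> float:
        return self.end_cM - self.start_cM

    @property
    def majority_ancestry(self) -> str | None:
        if not self.ancestry_profile:
            return None
        return max(self.ancestry_profile, key=self.ancestry_profile.get)


# ----------------------------------------------------------------------
# detection
# ----------------------------------------------------------------------
def find_ibd_haploid(
    haplotypes: np.ndarray,
    pos_cM: np.ndarray,
    hap_ids: Sequence[str] | None = None,
    chrom: str = "chr1",
    slice_markers: int = 128,
    max_mismatch_per_slice: int = 2,
    min_cM: float = 3.0,
) -> list[IBDSegment]:
    """GERMLINE-style haploid IBD detection on one chromosome.

    ``haplotypes`` is an (n_haps, n_markers) 0/1 matrix with markers
    ordered by ``pos_cM``.  Seeds are exact matches of ``slice_markers``-
    marker slices (hashed); matches are extended slice-by-slice while a
    slice carries at most ``max_mismatch_per_slice`` mismatches, then
    refined to the marker level inside the terminal slices; segments with
    genetic length below ``min_cM`` are not reported.
    """
    H = np.ascontiguousarray(haplotypes, dtype=np.int8)
    n_haps, n_markers = H.shape
    if n_haps < 2:
        raise ValueError("need at least 2 haplotypes")
    pos = np.asarray(pos_cM, dtype=float)
    if pos.size != n_markers:
        raise ValueError("marker map length does not match haplotypes")
    if np.any(np.diff(pos) < 0):
        raise ValueError("marker map must be sorted by cM position")
    if hap_ids is None:
        hap_ids = [f"hap{i}" for i in range(n_haps)]
    if slice_markers > n_markers:
        import warnings

        warnings.warn(
            f"slice_markers={slice_markers} exceeds marker count {n_markers}; "
            "falling back to a single slice"
        )
        slice_markers = n_markers
    bounds = list(range(0, n_markers, slice_markers))
    n_slices = len(bounds)
    ends = bounds[1:] + [n_markers]

    # seed pass: hash exact slice contents
    pair_seeds: dict[tuple[int, int], set[int]] = {}
    for s in range(n_slices):
        buckets: dict[bytes, list[int]] = {}
        block = H[:, bounds[s] : ends[s]]
        for h in range(n_haps):
            buckets.setdefault(block[h].tobytes(), []).append(h)
        for members in buckets.values():
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    pair_seeds.setdefault((members[i], members[j]), set()).add(s)

    def slice_mismatches(a: int, b: int, s: int) -> int:
        return int(np.count_nonzero(H[a, bounds[s] : ends[s]] != H[b, bounds[s] : ends[s]]))

    out: list[IBDSegment] = []
    for (a, b), seeds in pair_seeds.items():
        diff = H[a] != H[b]
        # group seed slices, extend each group while the mismatch budget
        # holds, then merge overlapping extensions
        intervals: list[tuple[int, int]] = []  # inclusive marker indices
        for s in sorted(seeds):
            lo, hi = s, s
            while lo - 1 >= 0 and slice_mismatches(a, b, lo - 1) <= max_mismatch_per_slice:
                lo -= 1
            while hi + 1 < n_slices and slice_mismatches(a, b, hi + 1) <= max_mismatch_per_slice:
                hi += 1
            m0, m1 = bounds[lo], ends[hi] - 1
            # marker-level refinement into the flanking failed slices:
            # extend while the running mismatch count in the partial slice
            # stays within budget
            if lo > 0:
                budget = max_mismatch_per_slice
                i = bounds[lo] - 1
                stop = bounds[lo - 1]
                while i >= stop and (budget := budget - int(diff[i])) >= 0:
                    if not diff[i]:
                        m0 = i
                    i -= 1
            if hi + 1 < n_slices:
                budget = max_mismatch_per_slice
                i = ends[hi]
                stop = ends[min(hi + 1, n_slices - 1)]
                while i < stop and (budget := budget - int(diff[i])) >= 0:
                    if not diff[i]:
                        m1 = i
                    i += 1
            intervals.append((m0, m1))
        intervals.sort()
        merged: list[list[int]] = []
        for m0, m1 in intervals:
            if merged and m0 <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], m1)
            else:
                merged.append([m0, m1])
        for m0, m1 in merged:
            length = pos[m1] - pos[m0]
            if length >= min_cM:
                out.append(
                    IBDSegment(
                        hap_a=hap_ids[a],
                        hap_b=hap_ids[b],
                        chrom=chrom,
                        start_cM=float(pos[m0]),
                        end_cM=float(pos[m1]),
                        n_markers=int(m1 - m0 + 1),
                    )
                )
    out.sort(key=lambda s: (s.hap_a, s.hap_b, s.start_cM))
    return out


# ----------------------------------------------------------------------
# GERMLINE .match files
# ----------------------------------------------------------------------
_MATCH_COLS = [
    "fam_a", "hap_a", "fam_b", "hap_b", "chrom", "start_bp", "end_bp",
    "start_snp", "end_snp", "n_markers", "length", "unit", "mismatches",
    "is_hom_a", "is_hom_b",
]


def read_germline_match(path, genetic_map: GeneticMap | None = None) -> list[IBDSegment]:
    """Read a GERMLINE ``.match`` file.  Lengths in cM pass through;
    ``MB`` lengths are converted via the genetic map (flagged in the
    log)."""
    import logging

    logger = logging.getLogger(__name__)
    path = Path(path)
    out: list[IBDSegment] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != len(_MATCH_COLS):
                raise ValueError(
                    f"{path}:{ln}: expected {len(_MATCH_COLS)} fields, got {len(parts)}"
                )
            rec = dict(zip(_MATCH_COLS, parts))
            chrom = rec["chrom"]
            try:
                bp_s, bp_e = float(rec["start_bp"]), float(rec["end_bp"])
                n_mark = int(rec["n_markers"])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed numeric field") from exc
            if rec["unit"].lower() == "cm" and genetic_map is None:
                start, end = bp_s / 1e6, bp_e / 1e6
            elif genetic_map is not None:
                start = float(genetic_map.bp_to_cM(chrom, [bp_s])[0])
                end = float(genetic_map.bp_to_cM(chrom, [bp_e])[0])
                if rec["unit"].lower() != "cm":
                    logger.info("%s:%d: %s-unit record converted via map", path, ln, rec["unit"])
            else:
                raise ValueError(
                    f"{path}:{ln}: length unit {rec['unit']!r} needs a genetic map"
                )
            out.append(
                IBDSegment(
                    hap_a=rec["hap_a"], hap_b=rec["hap_b"], chrom=chrom,
                    start_cM=start, end_cM=end, n_markers=n_mark,
                )
            )
    return out


def write_germline_match(segments: Iterable[IBDSegment], path) -> None:
    """Write segments in the GERMLINE ``.match`` layout (bp columns carry
    cM * 1e6, unit ``cM``)."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(
                "\t".join(
                    [
                        "0", s.hap_a, "0", s.hap_b, s.chrom,
                        str(int(round(s.start_cM * 1e6))), str(int(round(s.end_cM * 1e6))),
                        "snpS", "snpE", str(s.n_markers),
                        f"{s.length_cM:.4f}", "cM", "0", "0", "0",
                    ]
                )
                + "\n"
            )


# ----------------------------------------------------------------------
# ancestry overlay
# ----------------------------------------------------------------------
def segment_ancestry_profile(
    segment: IBDSegment, calls: LocalAncestryCalls
) -> IBDSegment:
    """Length-weighted ancestry proportions of an IBD segment.

    Each haplotype's calls are intersected with the segment; the segment
    profile is the average of the two haplotypes' profiles, with a
    discordance flag when the two disagree on the majority ancestry
    (disagreements arise from local-ancestry call errors — a truly IBD
    interval has one ancestry).
    """
    profiles = []
    for hap in (segment.hap_a, segment.hap_b):
        grp = calls.for_haplotype(hap, segment.chrom)
        if not len(grp):
            raise ValueError(f"no local-ancestry calls for {hap} on {segment.chrom}")
        s = np.maximum(grp["start_cM"].to_numpy(), segment.start_cM)
        e = np.minimum(grp["end_cM"].to_numpy(), segment.end_cM)
        w = np.clip(e - s, 0.0, None)
        covered = w.sum()
        if covered < segment.length_cM - 1e-6:
            raise ValueError(
                f"calls cover only {covered:.3f}/{segment.length_cM:.3f} cM of the "
                f"segment for {hap} on {segment.chrom}"
            )
        prof: dict[str, float] = {}
        for anc, wi in zip(grp["ancestry"], w):
            if wi > 0:
                prof[anc] = prof.get(anc, 0.0) + wi / covered
        profiles.append(prof)
    ancs = set(profiles[0]) | set(profiles[1])
    segment.ancestry_profile = {
        a: 0.5 * (profiles[0].get(a, 0.0) + profiles[1].get(a, 0.0)) for a in sorted(ancs)
    }
    maj = [max(p, key=p.get) for p in profiles]
    segment.discordant_ancestry = maj[0] != maj[1]
    return segment


# ----------------------------------------------------------------------
# sharing matrices
# ----------------------------------------------------------------------
@dataclass
class SharingMatrix:
    """Population-by-population normalized IBD sharing.

    ``total_cM[p, q]`` sums segment lengths between units of populations
    ``p`` and ``q``; ``normalized`` divides by the number of unit pairs
    (``n_p * n_q`` between populations, ``n_p (n_p - 1) / 2`` within);
    ``se`` holds chromosome-weighted jackknife standard errors when
    computed.
    """

    populations: list[str]
    total_cM: np.ndarray
    pair_counts: np.ndarray
    normalized: np.ndarray
    se: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.normalized, index=self.populations, columns=self.populations)
        return df


def sharing_matrix(
    segments: Iterable[IBDSegment],
    labels: dict[str, str],
    level: Literal["within", "between", "both"] = "both",
) -> SharingMatrix:
    """Total IBD length between (and within) populations, normalized by
    the number of unit pairs."""
    segments = list(segments)
    pops = sorted(set(labels.values()))
    pidx = {p: i for i, p in enumerate(pops)}
    n_units = pd.Series(list(labels.values())).value_counts()
    P = len(pops)
    total = np.zeros((P, P))
    for s in segments:
        for h in (s.hap_a, s.hap_b):
            if h not in labels:
                raise ValueError(f"haplotype {h!r} has no population label")
        i, j = pidx[labels[s.hap_a]], pidx[labels[s.hap_b]]
        if i == j and level == "between":
            continue
        if i != j and level == "within":
            continue
        total[i, j] += s.length_cM
        if i != j:
            total[j, i] += s.length_cM
    pairs = np.zeros((P, P))
    for p in pops:
        for q in pops:
            if p == q:
                n = n_units[p]
                pairs[pidx[p], pidx[p]] = n * (n - 1) / 2
            else:
                pairs[pidx[p], pidx[q]] = n_units[p] * n_units[q]
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(pairs > 0, total / pairs, 0.0)
    return SharingMatrix(pops, total, pairs, norm)


def jackknife_se(
    segments: Iterable[IBDSegment],
    chroms: ChromosomeSet,
    labels: dict[str, str],
    level: Literal["within", "between", "both"] = "both",
) -> SharingMatrix:
    """Chromosome-weighted (delete-one, unequal block size) jackknife SEs
    for the normalized sharing matrix.

    Leave-one-chromosome-out estimates are rescaled to the full genome
    (``x M / (M - m_j)``), so identical per-cM sharing across chromosomes
    gives SE = 0.  With weights ``h_j = M / m_j`` the variance is
    ``(1/g) sum_j (tau_j - theta_J)^2 / (h_j - 1)`` with pseudovalues
    ``tau_j = h_j theta - (h_j - 1) theta_(j)``.
    """
    segments = list(segments)
    if len(chroms) < 2:
        raise ValueError("chromosome-weighted jackknife needs >= 2 chromosomes")
    full = sharing_matrix(segments, labels, level)
    m = np.asarray(chroms.lengths_cM, dtype=float)
    M = m.sum()
    g = len(chroms)
    theta = full.normalized
    loo = []
    h = M / m
    for j, (cname, _) in enumerate(chroms):
        sub = [s for s in segments if s.chrom != cname]
        sj = sharing_matrix(sub, labels, level) if sub else None
        base = sj.normalized if sj is not None else np.zeros_like(theta)
        if sj is not None and sj.populations != full.populations:
            big = np.zeros_like(theta)
            for a, p in enumerate(sj.populations):
                for b, q in enumerate(sj.populations):
                    big[full.populations.index(p), full.populations.index(q)] = sj.normalized[a, b]
            base = big
        loo.append(base * (M / (M - m[j])))
    loo = np.array(loo)
    theta_J = g * theta - np.tensordot(1.0 - m / M, loo, axes=(0, 0))
    tau = h[:, None, None] * theta[None] - (h - 1.0)[:, None, None] * loo
    var = np.mean((tau - theta_J[None]) ** 2 / (h - 1.0)[:, None, None], axis=0)
    full.se = np.sqrt(var)
    return full


# ----------------------------------------------------------------------
def length_ancestry_regression(
    segments: Iterable[IBDSegment], ancestry: str = "EUR"
) -> tuple[float, float, float]:
    """OLS of an ancestry's segment proportion on segment length (cM).

    Returns ``(slope, se, p_value)`` (two-sided).  Longer IBD segments
    reflect more recent shared ancestors, so a positive European slope
    indicates that recent coancestry is disproportionately European.
    """
    import statsmodels.api as sm

    segments = [s for s in segments if s.ancestry_profile]
    if len(segments) < 3:
        raise ValueError("need at least 3 profiled segments")
    x = np.array([s.length_cM for s in segments])
    y = np.array([s.ancestry_profile.get(ancestry, 0.0) for s in segments])
    if np.ptp(x) == 0:
        raise ValueError("segment lengths have zero variance")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return float(res.params[1]), float(res.bse[1]), float(res.pvalues[1])


def segments_to_frame(segments: Iterable[IBDSegment]) -> pd.DataFrame:
    rows = []
    for s in segments:
        row = {
            "hap_a": s.hap_a, "hap_b": s.hap_b, "chrom": s.chrom,
            "start_cM": s.start_cM, "end_cM": s.end_cM, "length_cM": s.length_cM,
            "n_markers": s.n_markers, "discordant": s.discordant_ancestry,
        }
        for a, v in s.ancestry_profile.items():
            row[f"prop_{a}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
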