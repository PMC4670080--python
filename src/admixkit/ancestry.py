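"""Local-ancestry data model, masking and cohort-filter rules.

Local-ancestry inference (RFMix-style) assigns each window of each phased
haplotype a continental ancestry with a posterior probability.  This
module turns window calls into maximal same-ancestry tracts, computes
tract-based global ancestry proportions, masks haplotype alleles outside
a target ancestry, and applies the study's cohort filters:

* admixed haplotypes enter ancestry-specific PCA only with >= 25% target
  ancestry, and loci are masked where the call is not the target or its
  posterior is below 0.95;
* reference-panel individuals are excluded above 10% European ancestry;
* individuals above 95% of a single continental ancestry are excluded
  from tract-based demographic inference.

Threshold comparisons are strict, matching the wording of the exclusion
rules ("less than 25%" excludes fraction < 0.25, "greater than 10%"
excludes fraction > 0.10).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .genome import ChromosomeSet

__all__ = [
    "AncestryTract",
    "LocalAncestryCalls",
    "CohortFilters",
    "MaskedHaplotypeMatrix",
    "MISSING",
    "calls_to_tracts",
    "tracts_to_frame",
    "frame_to_tracts",
    "ancestry_proportions",
    "mask_haplotypes",
    "apply_cohort_filters",
    "cohort_truth_calls",
]

MISSING: int = -1  # allele code for masked / unobserved entries


@dataclass(frozen=True)
class AncestryTract:
    """One contiguous run of a single continental ancestry on one
    haplotype; cM coordinates, half-open ``[start, end)``; ``posterior``
    is the minimum call posterior over the run."""

    haplotype_id: str
    chrom: str
    start_cM: float
    end_cM: float
    ancestry: str
    posterior: float = 1.0

    def __post_init__(self) -> None:
        if not self.end_cM > self.start_cM:
            raise ValueError(
                f"tract end {self.end_cM} must exceed start {self.start_cM} "
                f"({self.haplotype_id}:{self.chrom})"
            )
        if not 0.0 <= self.posterior <= 1.0:
            raise ValueError(f"posterior {self.posterior} outside [0, 1]")

    @property
    def length_cM(self) -> float:
        return self.end_cM - self.start_cM


def tracts_to_frame(tracts: Iterable[AncestryTract]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (t.haplotype_id, t.chrom, t.start_cM, t.end_cM, t.ancestry, t.posterior)
            for t in tracts
        ],
        columns=["haplotype_id", "chrom", "start_cM", "end_cM", "ancestry", "posterior"],
    )


def frame_to_tracts(df: pd.DataFrame) -> list[AncestryTract]:
    return [
        AncestryTract(
            str(r.haplotype_id), str(r.chrom), float(r.start_cM), float(r.end_cM),
            str(r.ancestry), float(r.posterior),
        )
        for r in df.itertuples(index=False)
    ]


@dataclass
class LocalAncestryCalls:
    """Per-window local-ancestry calls with posteriors.

    ``windows`` is a tidy table with columns ``haplotype_id, chrom,
    start_cM, end_cM, ancestry, posterior``; windows of one haplotype and
    chromosome must be ordered and non-overlapping.  The expected input
    resolution is the 0.2 cM window granularity of RFMix output, but any
    window widths are accepted.
    """

    windows: pd.DataFrame
    window_cM: float = 0.2

    def __post_init__(self) -> None:
        need = {"haplotype_id", "chrom", "start_cM", "end_cM", "ancestry", "posterior"}
        missing = need - set(self.windows.columns)
        if missing:
            raise ValueError(f"calls table missing columns {sorted(missing)}")
        w = self.windows
        if len(w):
            if (w["end_cM"] <= w["start_cM"]).any():
                raise ValueError("call windows must have end > start")
            p = w["posterior"].to_numpy()
            if np.any((p < 0) | (p > 1)):
                raise ValueError("posteriors must lie in [0, 1]")
            for (h, c), grp in w.groupby(["haplotype_id", "chrom"], sort=False):
                s = grp["start_cM"].to_numpy()
                e = grp["end_cM"].to_numpy()
                if np.any(np.diff(s) < 0) or np.any(s[1:] < e[:-1] - 1e-9):
                    raise ValueError(
                        f"overlapping or unordered call windows for {h} on {c}"
                    )

    @property
    def haplotype_ids(self) -> list[str]:
        return list(dict.fromkeys(self.windows["haplotype_id"]))

    def for_haplotype(self, hap_id: str, chrom: str) -> pd.DataFrame:
        w = self.windows
        return w[(w["haplotype_id"] == hap_id) & (w["chrom"] == chrom)]


def calls_to_tracts(calls: LocalAncestryCalls) -> list[AncestryTract]:
    """Merge maximal runs of identical ancestry into tracts.

    The tract posterior is the minimum window posterior over the run.
    Adjacent windows separated by a gap smaller than one window width are
    treated as contiguous (the gap is bridged; tract boundaries follow the
    window edges).
    """
    out: list[AncestryTract] = []
    gap_tol = calls.window_cM
    for (hap, chrom), grp in calls.windows.groupby(["haplotype_id", "chrom"], sort=False):
        start = end = None
        anc = None
        post = 1.0
        for r in grp.itertuples(index=False):
            contiguous = end is not None and (r.start_cM - end) < gap_tol
            if anc == r.ancestry and contiguous:
                end = r.end_cM
                post = min(post, r.posterior)
            else:
                if anc is not None:
                    out.append(AncestryTract(hap, chrom, start, end, anc, post))
                start, end, anc, post = r.start_cM, r.end_cM, r.ancestry, r.posterior
        if anc is not None:
            out.append(AncestryTract(hap, chrom, start, end, anc, post))
    return out


def ancestry_proportions(
    tracts: Iterable[AncestryTract] | pd.DataFrame,
    chroms: ChromosomeSet,
    level: Literal["haplotype", "individual"] = "haplotype",
) -> pd.DataFrame:
    """Per-unit genome-wide ancestry fractions from tract lengths.

    ``fraction = sum of tract lengths of the ancestry / total genome
    length``; fractions sum to 1 per unit.  Tracts of each haplotype must
    tile the genome.  At ``individual`` level, a haplotype id of the form
    ``"<individual>.<0|1>"`` is collapsed to its individual and the two
    haplotypes averaged.
    """
    df = tracts if isinstance(tracts, pd.DataFrame) else tracts_to_frame(tracts)
    if not len(df):
        raise ValueError("no tracts supplied")
    total = chroms.total_cM
    lengths = df["end_cM"] - df["start_cM"]
    table = (
        df.assign(length=lengths)
        .pivot_table(index="haplotype_id", columns="ancestry", values="length", aggfunc="sum", fill_value=0.0)
        / total
    )
    sums = table.sum(axis=1)
    bad = sums[np.abs(sums - 1.0) > 1e-6]
    if len(bad):
        raise ValueError(
            f"tracts do not tile the genome for haplotype(s) {list(bad.index)[:5]} "
            f"(covered fraction {bad.iloc[0]:.4f})"
        )
    if level == "haplotype":
        return table
    if level == "individual":
        ind = table.index.to_series().str.rsplit(".", n=1).str[0]
        return table.groupby(ind.values).mean().rename_axis("individual_id")
    raise ValueError(f"unknown level {level!r}")


# ----------------------------------------------------------------------
@dataclass
class CohortFilters:
    """The study's cohort filter thresholds (all configurable; these
    defaults are the published rules)."""

    min_target_ancestry: float = 0.25
    min_posterior: float = 0.95
    max_reference_contamination: float = 0.10
    max_single_ancestry: float = 0.95

    def __post_init__(self) -> None:
        for name in (
            "min_target_ancestry",
            "min_posterior",
            "max_reference_contamination",
            "max_single_ancestry",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def apply_cohort_filters(
    proportions: pd.DataFrame,
    filters: CohortFilters,
    mode: Literal["aspca_admixed", "aspca_reference", "tracts"],
    target: str | None = None,
    contaminant: str = "EUR",
) -> tuple[list[str], pd.DataFrame]:
    """Apply one of the study's exclusion rules to an ancestry-proportion
    table (units x ancestries; haplotype level for ASPCA modes,
    individual level for tract mode).

    Returns ``(retained ids, exclusion log)``; the log has one row per
    excluded unit with the rule and the offending value.
    """
    sums = proportions.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError("proportions must sum to 1 per unit")
    log_rows = []
    if mode == "aspca_admixed":
        if target is None:
            raise ValueError("aspca_admixed mode needs a target ancestry")
        frac = proportions.get(target, pd.Series(0.0, index=proportions.index))
        keep = frac >= filters.min_target_ancestry
        rule = f"{target} ancestry < {filters.min_target_ancestry}"
    elif mode == "aspca_reference":
        frac = proportions.get(contaminant, pd.Series(0.0, index=proportions.index))
        keep = frac <= filters.max_reference_contamination
        rule = f"{contaminant} ancestry > {filters.max_reference_contamination}"
    elif mode == "tracts":
        frac = proportions.max(axis=1)
        keep = frac <= filters.max_single_ancestry
        rule = f"max single ancestry > {filters.max_single_ancestry}"
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    for uid in proportions.index[~keep]:
        log_rows.append({"unit": uid, "rule": rule, "value": float(frac.loc[uid])})
    log = pd.DataFrame(log_rows, columns=["unit", "rule", "value"])
    return list(proportions.index[keep]), log


# ----------------------------------------------------------------------
@dataclass
class MaskedHaplotypeMatrix:
    """Haplotypes x loci allele matrix with structured missingness from
    ancestry masking; the input to ancestry-specific PCA.

    ``alleles`` entries are 0/1 or :data:`MISSING`; ``is_reference`` marks
    fully-observed reference-panel rows.
    """

    haplotype_ids: list[str]
    locus_ids: list[str]
    chrom: np.ndarray  # per-locus chromosome name (object array)
    pos_cM: np.ndarray
    alleles: np.ndarray  # (n_haps, n_loci) int8
    populations: list[str] = field(default_factory=list)
    is_reference: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.alleles.shape != (len(self.haplotype_ids), len(self.locus_ids)):
            raise ValueError("allele matrix shape mismatch")
        if self.is_reference is None:
            self.is_reference = np.zeros(len(self.haplotype_ids), dtype=bool)
        if not self.populations:
            self.populations = ["" for _ in self.haplotype_ids]

    @property
    def fraction_observed(self) -> np.ndarray:
        if self.alleles.shape[1] == 0:
            return np.ones(self.alleles.shape[0])
        return (self.alleles != MISSING).mean(axis=1)


def mask_haplotypes(
    haplotypes: MaskedHaplotypeMatrix,
    calls: LocalAncestryCalls,
    target: str,
    min_posterior: float = 0.95,
) -> MaskedHaplotypeMatrix:
    """Mask alleles outside the target ancestry or below the posterior
    threshold: a locus is kept iff its covering call is ``target`` AND the
    posterior is >= ``min_posterior``; otherwise it becomes MISSING.
    Every locus must be covered by a call; masking never changes an
    observed allele value, only its observability."""
    out = haplotypes.alleles.copy()
    w = calls.windows
    for h, hap_id in enumerate(haplotypes.haplotype_ids):
        for chrom in np.unique(haplotypes.chrom):
            sel = np.flatnonzero(haplotypes.chrom == chrom)
            pos = haplotypes.pos_cM[sel]
            grp = w[(w["haplotype_id"] == hap_id) & (w["chrom"] == chrom)]
            if not len(grp) and len(sel):
                raise ValueError(f"no local-ancestry calls for {hap_id} on {chrom}")
            starts = grp["start_cM"].to_numpy()
            ends = grp["end_cM"].to_numpy()
            anc = grp["ancestry"].to_numpy()
            post = grp["posterior"].to_numpy()
            idx = np.searchsorted(starts, pos, side="right") - 1
            covered = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
            if not covered.all():
                missing_pos = pos[~covered][:3]
                raise ValueError(
                    f"loci not covered by calls for {hap_id} on {chrom} at cM {missing_pos}"
                )
            keep = (anc[idx] == target) & (post[idx] >= min_posterior)
            out[h, sel[~keep]] = MISSING
    return MaskedHaplotypeMatrix(
        haplotype_ids=list(haplotypes.haplotype_ids),
        locus_ids=list(haplotypes.locus_ids),
        chrom=haplotypes.chrom,
        pos_cM=haplotypes.pos_cM,
        alleles=out,
        populations=list(haplotypes.populations),
        is_reference=haplotypes.is_reference.copy(),
    )


def cohort_truth_calls(cohort) -> LocalAncestryCalls:
    """True-tract local-ancestry calls (posterior 1.0) for a simulated
    cohort, in the same table format the RFMix reader produces."""
    df = cohort.tracts_dataframe()
    return LocalAncestryCalls(windows=df)
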