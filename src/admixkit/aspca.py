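"""Ancestry-specific PCA (ASPCA).

Admixed haplotypes are masked down to one continental ancestry (all other
loci missing), then embedded in a single PCA space together with an
unmasked subcontinental reference panel of that ancestry.  Because the
masking produces heavy structured missingness, the PCA is a subspace
("EM") PCA: iterative rank-k completion in which missing entries are
re-imputed from the current low-rank reconstruction until convergence.
With no missing data the procedure reduces to ordinary PCA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ancestry import (
    MISSING,
    CohortFilters,
    LocalAncestryCalls,
    MaskedHaplotypeMatrix,
    ancestry_proportions,
    apply_cohort_filters,
    calls_to_tracts,
    mask_haplotypes,
    tracts_to_frame,
)

logger = logging.getLogger(__name__)

__all__ = ["ASPCAResult", "assemble_aspca_matrix", "subspace_pca", "aspca_pipeline"]


@dataclass
class ASPCAResult:
    """Joint coordinates of reference and masked admixed haplotypes.

    ``coords`` has one row per retained haplotype on ``k`` components
    (ASPC1..k); reference and admixed rows share the same basis.
    """

    haplotype_ids: list[str]
    populations: list[str]
    is_reference: np.ndarray
    coords: np.ndarray  # (n, k)
    variance_shares: np.ndarray  # (k,)
    n_iter: int
    converged: bool
    convergence_delta: float
    excluded: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "haplotype_id": self.haplotype_ids,
                "population": self.populations,
                "is_reference": self.is_reference,
            }
        )
        for k in range(self.coords.shape[1]):
            df[f"ASPC{k + 1}"] = self.coords[:, k]
        return df

    def plot(self, ax=None, components=(0, 1)):
        """Reference populations as letter markers, admixed haplotypes as
        points, in the shared ASPC space."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        a, b = components
        ref = self.is_reference
        for pop in sorted(set(np.asarray(self.populations)[ref])):
            sel = ref & (np.asarray(self.populations) == pop)
            ax.scatter(self.coords[sel, a], self.coords[sel, b], marker="s", s=14, label=pop)
        ax.scatter(
            self.coords[~ref, a], self.coords[~ref, b],
            c="grey", s=6, alpha=0.6, label="admixed",
        )
        ax.set_xlabel(f"ASPC{a + 1}")
        ax.set_ylabel(f"ASPC{b + 1}")
        ax.legend(fontsize=7)
        return ax


def assemble_aspca_matrix(
    masked: MaskedHaplotypeMatrix,
    reference: MaskedHaplotypeMatrix,
    max_locus_missingness: float = 0.99,
) -> MaskedHaplotypeMatrix:
    """Row-concatenate masked admixed haplotypes with the (fully observed)
    reference panel on the shared locus set.

    Loci missing in more than ``max_locus_missingness`` of all rows are
    dropped (and logged); a locus masked in every admixed row but present
    in the reference is retained.
    """
    shared = [l for l in reference.locus_ids if l in set(masked.locus_ids)]
    if not shared:
        raise ValueError(
            f"no shared loci between admixed ({len(masked.locus_ids)}) and "
            f"reference ({len(reference.locus_ids)}) matrices"
        )
    mi = [masked.locus_ids.index(l) for l in shared]
    ri = [reference.locus_ids.index(l) for l in shared]
    if np.any(reference.alleles[:, ri] == MISSING):
        raise ValueError("reference panel must be fully observed")
    alleles = np.vstack([reference.alleles[:, ri], masked.alleles[:, mi]])
    keep = (alleles == MISSING).mean(axis=0) <= max_locus_missingness
    if not keep.all():
        logger.info("dropping %d loci with missingness > %.0f%%",
                    int((~keep).sum()), 100 * max_locus_missingness)
    alleles = alleles[:, keep]
    kept = [l for l, k in zip(shared, keep) if k]
    ridx = np.asarray(ri)[keep]
    return MaskedHaplotypeMatrix(
        haplotype_ids=list(reference.haplotype_ids) + list(masked.haplotype_ids),
        locus_ids=kept,
        chrom=reference.chrom[ridx],
        pos_cM=reference.pos_cM[ridx],
        alleles=alleles,
        populations=list(reference.populations) + list(masked.populations),
        is_reference=np.concatenate(
            [np.ones(len(reference.haplotype_ids), bool), np.zeros(len(masked.haplotype_ids), bool)]
        ),
    )


def _truncated_svd(X: np.ndarray, k: int):
    """Deterministic rank-k SVD (LAPACK full SVD on the smaller side)."""
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    return U[:, :k], s[:k], Vt[:k]


def subspace_pca(
    matrix: MaskedHaplotypeMatrix,
    k: int = 2,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int | None = None,
    min_observed_fraction: float = 0.0,
    standardize: bool = False,
) -> ASPCAResult:
    """Iterative rank-``k`` completion PCA of a matrix with missing
    entries.

    Columns are centred on their observed entries (optionally scaled to
    unit observed variance); missing entries start at the column mean and
    are re-imputed from the rank-``k`` reconstruction each iteration until
    the largest imputed-entry change falls below ``tol``.  Rows with no
    observed entries (or below ``min_observed_fraction``) are excluded and
    logged.  Component signs are fixed so the first reference population's
    centroid is nonnegative on each component.
    """
    del seed  # deterministic: LAPACK SVD, mean initialisation
    if k < 1:
        raise ValueError("k must be >= 1")
    obs_frac = matrix.fraction_observed
    keep = obs_frac > max(min_observed_fraction, 0.0)
    keep &= obs_frac > 0.0
    excluded = pd.DataFrame(
        {
            "unit": [h for h, kp in zip(matrix.haplotype_ids, keep) if not kp],
            "rule": "observed fraction too low",
            "value": obs_frac[~keep],
        }
    )
    if len(excluded):
        logger.info("subspace_pca: excluding %d rows with too few observed entries", len(excluded))
    X = matrix.alleles[keep].astype(float)
    n, p = X.shape
    if k >= min(n, p):
        raise ValueError(f"k={k} must be < min(rows, cols) = {min(n, p)}")
    miss = X == MISSING
    X[miss] = np.nan
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    Xc = X - col_mean
    if standardize:
        sd = np.nanstd(Xc, axis=0)
        sd[sd == 0] = 1.0
        Xc /= sd
    Xc[miss] = 0.0  # == column mean after centring
    n_iter = 0
    delta = np.inf
    converged = not miss.any()
    U = s = Vt = None
    for n_iter in range(1, max_iter + 1):
        U, s, Vt = _truncated_svd(Xc, k)
        if converged or not miss.any():
            converged = True
            delta = 0.0
            break
        recon = (U * s) @ Vt
        delta = float(np.max(np.abs(recon[miss] - Xc[miss]))) if miss.any() else 0.0
        Xc[miss] = recon[miss]
        if delta < tol:
            converged = True
            break
    else:
        logger.warning("subspace_pca did not converge after %d iterations (delta=%.3g)",
                       max_iter, delta)
    if U is None:
        U, s, Vt = _truncated_svd(Xc, k)
    coords = U * s
    total_var = float(np.sum(Xc**2))
    shares = (s**2) / total_var if total_var > 0 else np.zeros(k)
    pops = [p_ for p_, kp in zip(matrix.populations, keep) if kp]
    is_ref = matrix.is_reference[keep]
    # sign convention: first reference population's centroid nonnegative
    ref_pops = [p_ for p_, r in zip(pops, is_ref) if r]
    anchor = (np.asarray(pops) == ref_pops[0]) & is_ref if ref_pops else np.ones(len(pops), bool)
    for c in range(coords.shape[1]):
        if coords[anchor, c].mean() < 0:
            coords[:, c] *= -1
    return ASPCAResult(
        haplotype_ids=[h for h, kp in zip(matrix.haplotype_ids, keep) if kp],
        populations=pops,
        is_reference=is_ref,
        coords=coords,
        variance_shares=shares,
        n_iter=n_iter,
        converged=converged,
        convergence_delta=float(delta if np.isfinite(delta) else 0.0),
        excluded=excluded,
    )


def aspca_pipeline(
    haplotypes: MaskedHaplotypeMatrix,
    calls: LocalAncestryCalls,
    reference: MaskedHaplotypeMatrix,
    target: str,
    chroms,
    filters: CohortFilters | None = None,
    reference_proportions: pd.DataFrame | None = None,
    k: int = 2,
    contaminant: str = "EUR",
    **pca_kwargs,
) -> ASPCAResult:
    """The full ancestry-specific PCA stage: mask admixed haplotypes to
    the target ancestry (posterior >= 0.95), drop haplotypes below 25%
    target ancestry, drop reference units above 10% contaminant ancestry
    (when reference proportions are supplied), assemble, and run subspace
    PCA.  The exclusion log is attached to the result."""
    filters = filters or CohortFilters()
    tracts = tracts_to_frame(calls_to_tracts(calls))
    props = ancestry_proportions(tracts, chroms, level="haplotype")
    keep_ids, log_adm = apply_cohort_filters(props, filters, "aspca_admixed", target=target)
    masked = mask_haplotypes(haplotypes, calls, target, filters.min_posterior)
    sel = [i for i, h in enumerate(masked.haplotype_ids) if h in set(keep_ids)]
    masked = MaskedHaplotypeMatrix(
        haplotype_ids=[masked.haplotype_ids[i] for i in sel],
        locus_ids=masked.locus_ids,
        chrom=masked.chrom,
        pos_cM=masked.pos_cM,
        alleles=masked.alleles[sel],
        populations=[masked.populations[i] for i in sel],
        is_reference=masked.is_reference[sel],
    )
    log_ref = pd.DataFrame(columns=["unit", "rule", "value"])
    if reference_proportions is not None:
        keep_ref, log_ref = apply_cohort_filters(
            reference_proportions, filters, "aspca_reference", contaminant=contaminant
        )
        rsel = [i for i, h in enumerate(reference.haplotype_ids) if h in set(keep_ref)]
        reference = MaskedHaplotypeMatrix(
            haplotype_ids=[reference.haplotype_ids[i] for i in rsel],
            locus_ids=reference.locus_ids,
            chrom=reference.chrom,
            pos_cM=reference.pos_cM,
            alleles=reference.alleles[rsel],
            populations=[reference.populations[i] for i in rsel],
            is_reference=np.ones(len(rsel), bool),
        )
    joint = assemble_aspca_matrix(masked, reference)
    if joint.alleles.shape[0] < k + 1:
        raise ValueError(
            f"only {joint.alleles.shape[0]} haplotypes survive the filters; need > {k}"
        )
    result = subspace_pca(joint, k=k, **pca_kwargs)
    frames = [f for f in (result.excluded, log_adm, log_ref) if len(f)]
    if frames:
        result.excluded = pd.concat(frames, ignore_index=True)
    return result
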