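"""Pipeline orchestration: configuration, seeding, stage composition,
the X-vs-autosome sex-bias comparison and A/B run comparison.

All randomness descends from a single master seed through named
substreams (stage-name hashing), so each stage is independently
reproducible and a full run is idempotent for a fixed configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ancestry import CohortFilters, ancestry_proportions, apply_cohort_filters
from .genome import ChromosomeSet
from .spectrum import TractLengthSpectrum, default_bin_edges

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "RunReport",
    "stage_seed",
    "run_full_analysis",
    "sexbias_compare",
    "ab_compare",
]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, derived by hashing the
    stage name into the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31 - 1)


@dataclass
class AnalysisConfig:
    """Everything a full run needs; serialisable to/from YAML.

    The filter, IBD and selection defaults are the study's published
    constants (posterior 0.95; ancestry filters 0.25 / 0.10 / 0.95; 3 cM
    IBD floor with 128-marker slices and 2 mismatches; 1000 null
    simulations with the 95% rejection rule).
    """

    tracts_path: str | None = None
    calls_path: str | None = None
    vcf_path: str | None = None
    map_path: str | None = None
    labels_path: str | None = None
    reference_vcf_path: str | None = None
    reference_labels_path: str | None = None
    chromosomes: dict[str, float] = field(default_factory=dict)
    ancestries: list[str] = field(default_factory=lambda: ["EUR", "NAT", "AFR"])
    target_ancestry: str = "NAT"
    filters: dict = field(
        default_factory=lambda: asdict(CohortFilters())
    )
    n_bins: int = 50
    fit_n_starts: int = 10
    alt_models: list[str] = field(default_factory=lambda: ["base+eur_pulse", "base+afr_pulse"])
    n_sim: int = 1000
    alpha: float = 0.05
    aspca_k: int = 2
    aspca_tol: float = 1e-6
    aspca_max_iter: int = 200
    ibd_slice_markers: int = 128
    ibd_max_mismatch: int = 2
    ibd_min_cM: float = 3.0
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self) -> None:
        f = CohortFilters(**self.filters)  # validates ranges
        self.filters = asdict(f)
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_bins < 1 or self.n_sim < 0 or self.aspca_k < 1:
            raise ValueError("invalid pipeline sizes")

    # -- YAML round trip ------------------------------------------------
    def to_yaml(self, path=None) -> str:
        s = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_yaml(cls, path_or_str) -> "AnalysisConfig":
        text = str(path_or_str)
        if "\n" not in text and Path(text).exists():
            text = Path(text).read_text()
        return cls(**yaml.safe_load(text))

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (the output
        directory does not affect results and is excluded)."""
        payload = asdict(self)
        payload.pop("outdir", None)
        return hashlib.sha256(yaml.safe_dump(payload, sort_keys=True).encode()).hexdigest()[:16]

    def cohort_filters(self) -> CohortFilters:
        return CohortFilters(**self.filters)


@dataclass
class RunReport:
    """Per-stage outputs and provenance of a pipeline run."""

    config_hash: str
    seed: int
    stages: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    failed: bool = False

    def record(self, stage: str, **payload) -> None:
        self.stages[stage] = payload

    def to_json(self, path=None) -> str:
        s = json.dumps(
            {
                "config_hash": self.config_hash,
                "seed": self.seed,
                "stages": self.stages,
                "warnings": self.warnings,
                "failed": self.failed,
            },
            indent=2,
            default=str,
        )
        if path is not None:
            Path(path).write_text(s)
        return s

    def report_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def run_full_analysis(config: AnalysisConfig) -> RunReport:
    """Execute the pipeline on file inputs: tract extraction and filters,
    tract-model fits with simulation-calibrated selection, ASPCA (when a
    VCF and reference labels are available) and IBD with ancestry
    overlay.  A stage failure marks the report failed and skips dependent
    stages."""
    from . import io as akio
    from .ancestry import calls_to_tracts, cohort_truth_calls, tracts_to_frame
    from .model import TractModel
    from .selection import compare_models

    if not config.chromosomes:
        raise ValueError("config.chromosomes is required")
    for key in ("tracts_path", "calls_path", "vcf_path", "map_path", "labels_path"):
        p = getattr(config, key)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"config.{key}: {p} does not exist")
    chroms = ChromosomeSet.from_dict(config.chromosomes)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=config.config_hash(), seed=config.seed)
    filters = config.cohort_filters()

    # -- stage: tracts ---------------------------------------------------
    try:
        if config.tracts_path is not None:
            tracts = akio.read_tracts_bed(config.tracts_path, allowed_ancestries=None)
            tdf = tracts_to_frame(tracts)
        elif config.calls_path is not None:
            calls = akio.read_rfmix_calls(config.calls_path)
            tdf = tracts_to_frame(calls_to_tracts(calls))
        else:
            raise ValueError("either tracts_path or calls_path is required")
        hap_props = ancestry_proportions(tdf, chroms, level="haplotype")
        ind_props = ancestry_proportions(tdf, chroms, level="individual")
        keep, excl = apply_cohort_filters(ind_props, filters, "tracts")
        report.record(
            "tracts",
            n_haplotypes=int(len(hap_props)),
            n_individuals=int(len(ind_props)),
            retained=len(keep),
            excluded=excl.to_dict("records"),
        )
    except Exception as exc:  # noqa: BLE001 - stage boundary
        logger.exception("tract stage failed")
        report.record("tracts", error=str(exc))
        report.failed = True
        return report

    # -- stage: tract model + selection ---------------------------------
    try:
        kept_haps = [
            h for h in hap_props.index if h.rsplit(".", 1)[0] in set(keep)
        ]
        sub = tdf[tdf["haplotype_id"].isin(kept_haps)]
        edges = default_bin_edges(chroms, config.n_bins)
        spectrum = TractLengthSpectrum.from_tracts(
            sub, edges, chroms, ancestries=tuple(config.ancestries),
            n_haplotypes=len(kept_haps),
        )
        props_mean = hap_props.loc[kept_haps].mean(axis=0)
        props = {a: float(props_mean.get(a, 0.0)) for a in config.ancestries}
        total = sum(props.values())
        props = {a: v / total for a, v in props.items()}
        base_fit = TractModel(spectrum, "base", props).fit(
            n_starts=config.fit_n_starts, seed=stage_seed(config.seed, "fit")
        )
        base_fit.to_json(outdir / "fit_base.json")
        comparisons = {}
        for alt in config.alt_models:
            cmp_res = compare_models(
                spectrum, props, chroms, alt,
                n_sim=config.n_sim,
                seed=stage_seed(config.seed, f"select:{alt}"),
                alpha=config.alpha,
            )
            cmp_res.to_json(outdir / f"select_{alt.replace('+', '_')}.json")
            comparisons[alt] = {
                "p_value": cmp_res.p_value,
                "rejected": cmp_res.rejected,
                "observed_delta": cmp_res.observed_delta,
            }
        report.record(
            "tract_model",
            base_params=base_fit.params,
            base_llf=base_fit.llf,
            proportions=props,
            comparisons=comparisons,
        )
    except Exception as exc:  # noqa: BLE001
        logger.exception("tract-model stage failed")
        report.record("tract_model", error=str(exc))
        report.failed = True

    # -- stage: ASPCA (needs phased alleles, calls and a reference) ------
    calls_obj = None
    if config.calls_path is not None:
        try:
            calls_obj = akio.read_rfmix_calls(config.calls_path)
        except Exception:  # noqa: BLE001 - tract-TSV dialect fallback
            from .ancestry import LocalAncestryCalls

            calls_obj = LocalAncestryCalls(windows=pd.read_csv(config.calls_path, sep="\t"))
    if (
        config.vcf_path is not None
        and calls_obj is not None
        and config.reference_vcf_path is not None
    ):
        try:
            from .aspca import aspca_pipeline

            haps = akio.read_phased_vcf(config.vcf_path)
            ref = akio.read_phased_vcf(config.reference_vcf_path)
            if config.reference_labels_path is not None:
                lab = akio.read_labels(config.reference_labels_path)
                ref.populations = [
                    lab.get(h.rsplit(".", 1)[0], "") for h in ref.haplotype_ids
                ]
            ref.is_reference = np.ones(len(ref.haplotype_ids), bool)
            res = aspca_pipeline(
                haps, calls_obj, ref, config.target_ancestry, chroms,
                filters=filters, k=config.aspca_k,
                tol=config.aspca_tol, max_iter=config.aspca_max_iter,
            )
            res.to_frame().to_csv(outdir / "aspca_coords.tsv", sep="\t", index=False)
            res.excluded.to_csv(outdir / "aspca_excluded.tsv", sep="\t", index=False)
            report.record(
                "aspca",
                n_haplotypes=len(res.haplotype_ids),
                n_excluded=int(len(res.excluded)),
                variance_shares=[float(v) for v in res.variance_shares],
                converged=res.converged,
                coords=np.round(res.coords, 6).tolist(),
            )
        except Exception as exc:  # noqa: BLE001
            logger.exception("aspca stage failed")
            report.record("aspca", error=str(exc))
            report.failed = True

    # -- stage: IBD with ancestry overlay --------------------------------
    if config.vcf_path is not None:
        try:
            from .ibd import find_ibd_haploid, segment_ancestry_profile, segments_to_frame

            haps = akio.read_phased_vcf(config.vcf_path)
            segments = []
            for chrom in dict.fromkeys(haps.chrom):
                sel = np.flatnonzero(haps.chrom == chrom)
                segments += find_ibd_haploid(
                    haps.alleles[:, sel], haps.pos_cM[sel], haps.haplotype_ids,
                    str(chrom), slice_markers=config.ibd_slice_markers,
                    max_mismatch_per_slice=config.ibd_max_mismatch,
                    min_cM=config.ibd_min_cM,
                )
            if calls_obj is not None:
                for s in segments:
                    segment_ancestry_profile(s, calls_obj)
            segments_to_frame(segments).to_csv(outdir / "ibd_segments.tsv", sep="\t", index=False)
            hist: dict[str, list[int]] = {}
            if segments and calls_obj is not None:
                for anc in config.ancestries:
                    lens = [s.length_cM for s in segments if s.majority_ancestry == anc]
                    hist[anc] = np.histogram(lens, bins=10, range=(0, 50))[0].tolist()
            report.record(
                "ibd",
                n_segments=len(segments),
                total_cM=float(sum(s.length_cM for s in segments)),
                length_hist=hist,
            )
        except Exception as exc:  # noqa: BLE001
            logger.exception("ibd stage failed")
            report.record("ibd", error=str(exc))
            report.failed = True

    report.to_json(outdir / "report.json")
    return report


# ----------------------------------------------------------------------
def sexbias_compare(
    autosomal_props: pd.DataFrame,
    x_props: pd.DataFrame,
    ancestry: str,
) -> tuple[float, float, float]:
    """Paired X-vs-autosome test for sex-biased admixture.

    Two-sided Wilcoxon signed-rank on the per-individual difference
    ``X - autosome`` for the chosen ancestry (exact null for n <= 25
    without ties, normal approximation with tie correction otherwise).
    Returns ``(median difference, statistic, p_value)``.  Sex-biased
    contributions (e.g. mostly male European migrants) raise the ancestry
    of the X relative to the autosomes for the other source.
    """
    from scipy.stats import wilcoxon

    if set(autosomal_props.index) != set(x_props.index):
        raise ValueError("autosomal and X tables must cover the same individuals")
    if len(autosomal_props) < 2:
        raise ValueError("need at least 2 individuals")
    d = (
        x_props[ancestry].reindex(autosomal_props.index)
        - autosomal_props[ancestry]
    ).to_numpy(dtype=float)
    med = float(np.median(d))
    nz = d[d != 0]
    if nz.size == 0:
        import warnings

        warnings.warn("all paired differences are zero; p = 1")
        return med, 0.0, 1.0
    method = "exact" if (nz.size <= 25 and np.unique(np.abs(nz)).size == nz.size) else "approx"
    res = wilcoxon(nz, alternative="two-sided", method=method)
    return med, float(res.statistic), float(res.pvalue)


def ab_compare(run_a: RunReport | dict, run_b: RunReport | dict) -> pd.DataFrame:
    """Stage-wise comparison of two pipeline runs (e.g. trio-phased vs
    population-phased inputs, or two seeds): differences in fitted times,
    Spearman correlation of IBD length distributions per ancestry and the
    Procrustes distance of ASPCA coordinates after sign alignment.

    Stages present in only one run are reported as warnings; disjoint
    runs give an empty table.
    """
    import warnings

    from scipy.spatial import procrustes
    from scipy.stats import spearmanr

    a = run_a.stages if isinstance(run_a, RunReport) else dict(run_a)
    b = run_b.stages if isinstance(run_b, RunReport) else dict(run_b)
    rows = []
    shared = set(a) & set(b)
    for missing in sorted(set(a) ^ set(b)):
        warnings.warn(f"stage {missing!r} present in only one run; skipped")
    if "tract_model" in shared and "error" not in a["tract_model"] and "error" not in b["tract_model"]:
        pa, pb = a["tract_model"]["base_params"], b["tract_model"]["base_params"]
        for name in pa:
            rows.append(
                {"stage": "tract_model", "metric": f"delta_{name}",
                 "value": float(pa[name]) - float(pb[name])}
            )
    if "ibd" in shared:
        for anc in set(a["ibd"].get("length_hist", {})) & set(b["ibd"].get("length_hist", {})):
            ha = np.asarray(a["ibd"]["length_hist"][anc], dtype=float)
            hb = np.asarray(b["ibd"]["length_hist"][anc], dtype=float)
            rho = spearmanr(ha, hb).statistic if ha.size == hb.size and ha.size > 1 else np.nan
            rows.append({"stage": "ibd", "metric": f"spearman_{anc}", "value": float(rho)})
    if "aspca" in shared and "coords" in a["aspca"] and "coords" in b["aspca"]:
        ca = np.asarray(a["aspca"]["coords"], dtype=float)
        cb = np.asarray(b["aspca"]["coords"], dtype=float)
        if ca.shape == cb.shape and ca.shape[0] > ca.shape[1]:
            for c in range(ca.shape[1]):  # sign alignment
                if np.dot(ca[:, c], cb[:, c]) < 0:
                    cb = cb.copy()
                    cb[:, c] *= -1
            _, _, disparity = procrustes(ca, cb)
            rows.append({"stage": "aspca", "metric": "procrustes", "value": float(disparity)})
    return pd.DataFrame(rows, columns=["stage", "metric", "value"])
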