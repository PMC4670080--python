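"""Readers and writers for the file formats around local-ancestry
analysis: tract BED-like TSV, RFMix local-ancestry output (v2 ``msp.tsv``
and legacy per-SNP Viterbi), phased VCF, PLINK-style genetic maps and
population-label tables.

Simulated truth uses the same formats, so pipelines can run identically
on simulated and real inputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ancestry import (
    AncestryTract,
    LocalAncestryCalls,
    MaskedHaplotypeMatrix,
    frame_to_tracts,
)
from .genome import ChromosomeSet, GeneticMap

__all__ = [
    "write_tracts_bed",
    "read_tracts_bed",
    "read_rfmix_calls",
    "write_msp",
    "write_phased_vcf",
    "read_phased_vcf",
    "write_plink_map",
    "read_plink_map",
    "genetic_map_from_plink",
    "read_labels",
    "write_labels",
    "write_cohort",
]

_TRACT_COLUMNS = ["haplotype_id", "chrom", "start_cM", "end_cM", "ancestry", "posterior"]


class FormatError(ValueError):
    """Malformed input file."""


# ----------------------------------------------------------------------
# tract BED-like TSV
# ----------------------------------------------------------------------
def write_tracts_bed(tracts, path) -> None:
    """Write tracts as TSV with columns haplotype_id, chrom, start_cM,
    end_cM, ancestry, posterior."""
    from .ancestry import tracts_to_frame

    df = tracts if isinstance(tracts, pd.DataFrame) else tracts_to_frame(tracts)
    df.to_csv(path, sep="\t", index=False, columns=_TRACT_COLUMNS)


def read_tracts_bed(path, allowed_ancestries: Sequence[str] | None = None) -> list[AncestryTract]:
    """Read and validate a tract TSV (half-open cM intervals).

    Overlapping tracts on one haplotype/chromosome and unknown ancestry
    labels are rejected with the offending line reported.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"haplotype_id": str, "chrom": str})
    except pd.errors.EmptyDataError:
        return []
    missing = set(_TRACT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if not len(df):
        return []
    if allowed_ancestries is not None:
        bad = set(df["ancestry"]) - set(allowed_ancestries)
        if bad:
            raise FormatError(
                f"{path}: unknown ancestry label(s) {sorted(bad)}; "
                f"allowed: {sorted(allowed_ancestries)}"
            )
    bad_rows = df.index[df["end_cM"] <= df["start_cM"]]
    if len(bad_rows):
        raise FormatError(f"{path}: end <= start at line {bad_rows[0] + 2}")
    for (h, c), grp in df.groupby(["haplotype_id", "chrom"], sort=False):
        grp = grp.sort_values("start_cM")
        s, e = grp["start_cM"].to_numpy(), grp["end_cM"].to_numpy()
        if np.any(s[1:] < e[:-1] - 1e-9):
            line = int(grp.index[np.argmax(s[1:] < e[:-1] - 1e-9) + 1]) + 2
            raise FormatError(f"{path}: overlapping tracts for {h} on {c} at line {line}")
    return frame_to_tracts(df)


# ----------------------------------------------------------------------
# RFMix output
# ----------------------------------------------------------------------
def read_rfmix_calls(
    path,
    genetic_map: GeneticMap | None = None,
    fb_path=None,
    marker_map_path=None,
) -> LocalAncestryCalls:
    """Read local-ancestry calls from RFMix output.

    Two dialects are auto-detected from the header:

    * v2 ``msp.tsv``: first line ``#Subpopulation order/codes: NAME=0 ...``,
      second line the column header (``#chm spos epos sgpos egpos n snps``
      followed by one column per haplotype, named ``sample.0``/``sample.1``);
      window rows carry genetic positions (cM) directly.
    * legacy per-SNP Viterbi matrix (one row per marker, one integer
      ancestry code per haplotype, 1-based), which requires
      ``marker_map_path`` (PLINK-style map: chrom, id, cM, bp) naming the
      markers; runs of constant call are collapsed to windows spanning
      from each marker to the next.

    Posteriors default to 1.0; a forward-backward companion table
    (``fb_path``, TSV with the same window-by-haplotype layout holding the
    posterior of the called ancestry) overrides them when supplied.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#Subpopulation"):
        return _read_msp(path, fb_path)
    if marker_map_path is None:
        raise FormatError(
            f"{path}: not an msp.tsv header and no marker map given for the "
            "legacy per-SNP dialect"
        )
    return _read_viterbi(path, marker_map_path, fb_path)


def _read_msp(path, fb_path) -> LocalAncestryCalls:
    with open(path) as fh:
        code_line = fh.readline().strip()
        header = fh.readline().strip()
    if not header.startswith("#"):
        raise FormatError(f"{path}: truncated msp header")
    codes = {}
    for tok in code_line.split(":", 1)[1].replace(",", "\t").split():
        name, _, num = tok.partition("=")
        if num:
            codes[int(num)] = name
    cols = header.lstrip("#").split("\t")
    if len(cols) <= 6:
        raise FormatError(f"{path}: msp header has no haplotype columns")
    hap_cols = cols[6:]
    if len(hap_cols) % 2:
        raise FormatError(f"{path}: odd number of haplotype columns ({len(hap_cols)})")
    df = pd.read_csv(path, sep="\t", skiprows=2, header=None, names=cols)
    fb = None
    if fb_path is not None:
        fb = pd.read_csv(fb_path, sep="\t", comment="#", header=None).to_numpy(dtype=float)
        if fb.shape != (len(df), len(hap_cols)):
            raise FormatError(f"{fb_path}: shape {fb.shape} does not match msp windows")
    rows = []
    for w in range(len(df)):
        chrom = str(df.iloc[w, 0])
        s, e = float(df.iloc[w, 3]), float(df.iloc[w, 4])
        for h, hap in enumerate(hap_cols):
            code = int(df.iloc[w, 6 + h])
            rows.append(
                (hap, chrom, s, e, codes.get(code, str(code)),
                 float(fb[w, h]) if fb is not None else 1.0)
            )
    windows = pd.DataFrame(
        rows, columns=["haplotype_id", "chrom", "start_cM", "end_cM", "ancestry", "posterior"]
    )
    widths = windows["end_cM"] - windows["start_cM"]
    return LocalAncestryCalls(windows=windows, window_cM=float(np.median(widths)))


def _read_viterbi(path, marker_map_path, fb_path) -> LocalAncestryCalls:
    mp = read_plink_map(marker_map_path)
    vit = pd.read_csv(path, sep=r"\s+", header=None).to_numpy(dtype=int)
    if vit.shape[0] != len(mp):
        raise FormatError(
            f"{path}: {vit.shape[0]} marker rows but map has {len(mp)} markers"
        )
    if vit.shape[1] % 2:
        raise FormatError(f"{path}: odd haplotype count {vit.shape[1]}")
    fb = None
    if fb_path is not None:
        fb = pd.read_csv(fb_path, sep=r"\s+", header=None).to_numpy(dtype=float)
        if fb.shape != vit.shape:
            raise FormatError(f"{fb_path}: shape does not match Viterbi matrix")
    rows = []
    for chrom, grp in mp.groupby("chrom", sort=False):
        gi = grp.index.to_numpy()
        pos = grp["cM"].to_numpy()
        # marker i covers [pos_i, pos_{i+1}); the last marker gets the
        # median spacing as width
        width = float(np.median(np.diff(pos))) if len(pos) > 1 else 0.2
        edges = np.append(pos, pos[-1] + width)
        for h in range(vit.shape[1]):
            hap = f"hap{h // 2}.{h % 2}"
            calls = vit[gi, h]
            post = fb[gi, h] if fb is not None else np.ones(len(gi))
            start = 0
            for i in range(1, len(gi) + 1):
                if i == len(gi) or calls[i] != calls[start]:
                    rows.append(
                        (hap, str(chrom), float(edges[start]), float(edges[i]),
                         str(int(calls[start])), float(post[start:i].min()))
                    )
                    start = i
    windows = pd.DataFrame(
        rows, columns=["haplotype_id", "chrom", "start_cM", "end_cM", "ancestry", "posterior"]
    )
    return LocalAncestryCalls(windows=windows)


def write_msp(calls: LocalAncestryCalls, path, codes: dict[str, int] | None = None) -> None:
    """Write calls in the RFMix v2 msp.tsv dialect (one row per window
    pattern; windows must align across haplotypes)."""
    w = calls.windows
    haps = list(dict.fromkeys(w["haplotype_id"]))
    ancs = sorted(w["ancestry"].unique()) if codes is None else list(codes)
    codes = codes or {a: i for i, a in enumerate(ancs)}
    pivot_a = w.pivot_table(
        index=["chrom", "start_cM", "end_cM"], columns="haplotype_id",
        values="ancestry", aggfunc="first",
    )[haps]
    with open(path, "w") as fh:
        fh.write(
            "#Subpopulation order/codes: "
            + "\t".join(f"{a}={codes[a]}" for a in codes)
            + "\n"
        )
        fh.write("#chm\tspos\tepos\tsgpos\tegpos\tn snps\t" + "\t".join(haps) + "\n")
        for (chrom, s, e), row in pivot_a.iterrows():
            bp_s, bp_e = int(round(s * 1e6)), int(round(e * 1e6))
            vals = "\t".join(str(codes[a]) for a in row)
            fh.write(f"{chrom}\t{bp_s}\t{bp_e}\t{s:.6f}\t{e:.6f}\t1\t{vals}\n")


# ----------------------------------------------------------------------
# phased VCF + PLINK map
# ----------------------------------------------------------------------
def write_phased_vcf(cohort, path) -> None:
    """Write a painted cohort's alleles as a phased VCF (GT with ``|``),
    with bp = round(cM * 1e6)."""
    if cohort.alleles is None:
        raise ValueError("cohort has no alleles; run paint_haplotypes first")
    freqs = cohort.frequencies
    inds = cohort.individual_ids()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=admixkit-simulate\n")
        for chrom, length in cohort.chromosomes:
            fh.write(f"##contig=<ID={chrom},length={int(length * 1e6) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(inds) + "\n")
        for ci, (chrom, _) in enumerate(cohort.chromosomes):
            loci = np.flatnonzero(freqs.chrom_index == ci)
            alle = cohort.alleles[chrom]
            for k, l in enumerate(loci):
                bp = int(round(freqs.pos_cM[l] * 1e6)) + 1
                gts = "\t".join(
                    f"{alle[2 * i, k]}|{alle[2 * i + 1, k]}" for i in range(cohort.n_individuals)
                )
                fh.write(f"{chrom}\t{bp}\tsnp_{chrom}_{k}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def read_phased_vcf(path, genetic_map: GeneticMap | None = None) -> MaskedHaplotypeMatrix:
    """Read phased genotypes into a haplotype matrix (two rows per
    sample, ids ``sample.0``/``sample.1``).  Positions become cM via the
    genetic map, or bp / 1e6 when no map is given (the convention used by
    the simulator's writer)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, pos_bp, rows, ids = [], [], [], []
    for var in vcf:
        gt = np.asarray(var.genotype.array())[:, :2]
        if np.any(gt < 0):
            gt = np.where(gt < 0, -1, gt)
        rows.append(gt.reshape(-1))
        chroms.append(var.CHROM)
        pos_bp.append(var.POS)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
    if not rows:
        raise FormatError(f"{path}: no variants")
    alleles = np.asarray(rows, dtype=np.int8).T  # (2 n_samples, n_loci)
    chrom_arr = np.asarray(chroms, dtype=object)
    pos_bp = np.asarray(pos_bp, dtype=float)
    if genetic_map is not None:
        pos_cM = np.concatenate(
            [genetic_map.bp_to_cM(c, pos_bp[chrom_arr == c]) for c in dict.fromkeys(chroms)]
        )
    else:
        pos_cM = (pos_bp - 1) / 1e6
    hap_ids = [f"{s}.{a}" for s in samples for a in (0, 1)]
    return MaskedHaplotypeMatrix(
        haplotype_ids=hap_ids,
        locus_ids=ids,
        chrom=chrom_arr,
        pos_cM=pos_cM,
        alleles=alleles,
    )


def write_plink_map(freqs, path) -> None:
    """PLINK-style 4-column map: chrom, id, cM, bp (bp = round(cM*1e6))."""
    with open(path, "w") as fh:
        for l in range(freqs.n_loci):
            chrom = freqs.chromosomes.names[freqs.chrom_index[l]]
            cm = freqs.pos_cM[l]
            fh.write(f"{chrom}\tsnp_{chrom}_{l}\t{cm:.6f}\t{int(round(cm * 1e6)) + 1}\n")


def read_plink_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["chrom", "id", "cM", "bp"],
                     dtype={"chrom": str})
    if df[["cM", "bp"]].isna().any().any():
        raise FormatError(f"{path}: malformed PLINK map")
    return df


def genetic_map_from_plink(path) -> GeneticMap:
    df = read_plink_map(path)
    bp = {c: g["bp"].to_numpy(dtype=float) for c, g in df.groupby("chrom", sort=False)}
    cm = {c: g["cM"].to_numpy(dtype=float) for c, g in df.groupby("chrom", sort=False)}
    return GeneticMap(bp, cm)


# ----------------------------------------------------------------------
# labels and cohort truth
# ----------------------------------------------------------------------
def read_labels(path) -> dict[str, str]:
    """Two-column TSV (id, population) -> mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "population"], dtype=str)
    return dict(zip(df["id"], df["population"]))


def write_labels(labels: dict[str, str], path) -> None:
    pd.DataFrame(sorted(labels.items()), columns=["id", "population"]).to_csv(
        path, sep="\t", index=False, header=False
    )


def write_cohort(cohort, outdir, prefix: str = "cohort") -> dict[str, Path]:
    """Write a simulated cohort's full truth set: tract TSV, phased VCF +
    PLINK map (when painted), schedule-compatible chromosome table and
    planted-IBD truth TSV.  Returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["tracts"] = outdir / f"{prefix}.tracts.tsv"
    write_tracts_bed(cohort.tracts_dataframe(), paths["tracts"])
    paths["chromosomes"] = outdir / f"{prefix}.chroms.json"
    with open(paths["chromosomes"], "w") as fh:
        json.dump(cohort.chromosomes.to_dict(), fh, indent=2)
    if cohort.alleles is not None:
        paths["vcf"] = outdir / f"{prefix}.vcf"
        write_phased_vcf(cohort, paths["vcf"])
        paths["map"] = outdir / f"{prefix}.map"
        write_plink_map(cohort.frequencies, paths["map"])
    if cohort.planted_ibd:
        paths["planted_ibd"] = outdir / f"{prefix}.planted_ibd.tsv"
        pd.DataFrame(
            [(s.hap_a, s.hap_b, s.chrom, s.start_cM, s.end_cM) for s in cohort.planted_ibd],
            columns=["hap_a", "hap_b", "chrom", "start_cM", "end_cM"],
        ).to_csv(paths["planted_ibd"], sep="\t", index=False)
    return paths
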