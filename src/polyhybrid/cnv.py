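"""Dosage-aware CNV calling against an in-silico F1 mixture control.

Gene-level calls compare ``log2(GPM_hybrid / GPM_mixed)`` to a two-fold band
around the genotype-expected dosage log-ratio ``log2(B / C)``, where B is the
allelic read fraction in the hybrid (1/2 in F1 diploids; 1/3 or 2/3 in
triploids depending on the allele) and C = 1/2 is the allelic fraction in the
1:1 mixture:

* gain  iff log2 ratio > log2(2 B / C)
* loss  iff log2 ratio < log2(B / (2 C))

Allelic calls use the log10 ratio-of-ratios
``log10[(R/C)_hybrid / (R/C)_mixed]`` with genotype-specific bounds that are
the same two-fold band on the log10 scale (F1: log10 2 / log10 0.5;
R-dominant triploids: log10 4 / log10 1; C-dominant triploids:
log10 1 / log10 0.25).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from polyhybrid.config import MIXTURE_RATIO, GenotypeSpec

PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class CNVCall:
    gene: str
    sample: str
    allele: str
    log2_ratio: float
    expected_log2: float
    call: str  # gain | loss | none


@dataclass(frozen=True)
class AllelicRatioCall:
    agp: str
    sample: str
    log10_ratio: float
    upper: float
    lower: float
    call: str  # R_gain_or_C_loss | C_gain_or_R_loss | none | undetermined


@dataclass(frozen=True)
class SegmentCall:
    chromosome: str
    start: int  # 0-based, half-open over catalog positional order
    end: int
    n_genes: int
    allele: str
    call: str
    sample: str


def cnv_thresholds(b: float, c: float = MIXTURE_RATIO) -> tuple[float, float]:
    """(gain, loss) log2 bounds: expected log2(B/C) +/- 1."""
    if b <= 0 or c <= 0:
        raise ValueError("allelic ratios must be positive")
    return math.log2(2 * b / c), math.log2(b / (2 * c))


def allelic_thresholds(genotype: GenotypeSpec) -> tuple[float, float]:
    """(upper, lower) log10 bounds for the allelic ratio-of-ratios statistic."""
    expected = (genotype.allelic_ratio("R") / genotype.allelic_ratio("C")) / (
        MIXTURE_RATIO / MIXTURE_RATIO
    )
    return math.log10(2 * expected), math.log10(expected / 2)


def gene_cnv_call(
    gpm_hybrid: float,
    gpm_mixed: float,
    genotype: GenotypeSpec,
    allele: str,
    gene: str = "",
    sample: str = "",
    pseudocount: float = PSEUDOCOUNT,
) -> CNVCall:
    """Call one gene in one sample against the mixture control."""
    if gpm_hybrid < 0 or gpm_mixed < 0:
        raise ValueError("GPM values must be non-negative")
    b = genotype.allelic_ratio(allele)
    if b == 0:
        raise ValueError(
            f"allele {allele} absent from genotype {genotype.name}; no expected dosage"
        )
    gain_bound, loss_bound = cnv_thresholds(b)
    log2_ratio = math.log2((gpm_hybrid + pseudocount) / (gpm_mixed + pseudocount))
    if log2_ratio > gain_bound:
        call = "gain"
    elif log2_ratio < loss_bound:
        call = "loss"
    else:
        call = "none"
    return CNVCall(
        gene=gene,
        sample=sample,
        allele=allele,
        log2_ratio=log2_ratio,
        expected_log2=math.log2(b / MIXTURE_RATIO),
        call=call,
    )


def call_gene_cnvs(
    gpm_hybrid: pd.DataFrame,
    gpm_mixed: pd.Series,
    metadata: pd.DataFrame,
    catalog: pd.DataFrame,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Vectorized per-gene CNV calls for every sample.

    `metadata` must carry r_copies / c_copies per sample; genes whose allele
    is absent from a sample's genotype (expected zero copies) are skipped.
    Returns a long DataFrame: gene, sample, allele, log2_ratio,
    expected_log2, call.
    """
    genes = gpm_hybrid.index
    sub = catalog["subgenome"].reindex(genes).to_numpy()
    mixed = gpm_mixed.reindex(genes).to_numpy(dtype=float) + pseudocount
    frames = []
    for sample in gpm_hybrid.columns:
        r = int(metadata.loc[sample, "r_copies"])
        c = int(metadata.loc[sample, "c_copies"])
        ploidy = r + c
        b = np.where(sub == "R", r / ploidy, c / ploidy)
        keep = b > 0
        ratio = np.log2(
            (gpm_hybrid[sample].to_numpy(dtype=float) + pseudocount) / mixed
        )
        expected = np.log2(b[keep] / MIXTURE_RATIO)
        gain = expected + 1.0
        loss = expected - 1.0
        call = np.where(
            ratio[keep] > gain, "gain", np.where(ratio[keep] < loss, "loss", "none")
        )
        frames.append(
            pd.DataFrame(
                {
                    "gene": genes[keep],
                    "sample": sample,
                    "allele": sub[keep],
                    "log2_ratio": ratio[keep],
                    "expected_log2": expected,
                    "call": call,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def allelic_cnv_call(
    r_gpm_h: float,
    c_gpm_h: float,
    r_gpm_m: float,
    c_gpm_m: float,
    genotype: GenotypeSpec,
    agp: str = "",
    sample: str = "",
    pseudocount: float = PSEUDOCOUNT,
) -> AllelicRatioCall:
    """Allelic CNV call for one AGP from hybrid and mixture GPM of both alleles."""
    upper, lower = allelic_thresholds(genotype)
    if r_gpm_h == 0 and c_gpm_h == 0:
        return AllelicRatioCall(agp, sample, float("nan"), upper, lower, "undetermined")
    ratio_h = (r_gpm_h + pseudocount) / (c_gpm_h + pseudocount)
    ratio_m = (r_gpm_m + pseudocount) / (c_gpm_m + pseudocount)
    stat = math.log10(ratio_h / ratio_m)
    if stat > upper:
        call = "R_gain_or_C_loss"
    elif stat < lower:
        call = "C_gain_or_R_loss"
    else:
        call = "none"
    return AllelicRatioCall(agp, sample, stat, upper, lower, call)


def call_allelic_cnvs(
    gpm_hybrid: pd.DataFrame,
    gpm_mixed: pd.Series,
    agps: pd.DataFrame,
    metadata: pd.DataFrame,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Vectorized allelic-ratio calls for every AGP x sample."""
    r_ids = agps["gene_r"].to_numpy()
    c_ids = agps["gene_c"].to_numpy()
    rm = gpm_mixed.reindex(r_ids).to_numpy(dtype=float)
    cm = gpm_mixed.reindex(c_ids).to_numpy(dtype=float)
    ratio_m = (rm + pseudocount) / (cm + pseudocount)
    frames = []
    for sample in gpm_hybrid.columns:
        r = int(metadata.loc[sample, "r_copies"])
        c = int(metadata.loc[sample, "c_copies"])
        genotype = GenotypeSpec(
            metadata.loc[sample, "variety"], r, c, metadata.loc[sample, "mito_origin"]
        )
        upper, lower = allelic_thresholds(genotype)
        rh = gpm_hybrid[sample].reindex(r_ids).to_numpy(dtype=float)
        ch = gpm_hybrid[sample].reindex(c_ids).to_numpy(dtype=float)
        stat = np.log10(((rh + pseudocount) / (ch + pseudocount)) / ratio_m)
        call = np.where(
            stat > upper,
            "R_gain_or_C_loss",
            np.where(stat < lower, "C_gain_or_R_loss", "none"),
        )
        undetermined = (rh == 0) & (ch == 0)
        call = np.where(undetermined, "undetermined", call)
        stat = np.where(undetermined, np.nan, stat)
        frames.append(
            pd.DataFrame(
                {
                    "agp": r_ids,
                    "sample": sample,
                    "log10_ratio": stat,
                    "upper": upper,
                    "lower": lower,
                    "call": call,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def detect_allele_loss(
    counts: pd.DataFrame,
    gpm_values: pd.DataFrame,
    metadata: pd.DataFrame,
    catalog: pd.DataFrame,
    max_reads: int = 5,
    gpm_fraction: float = 0.02,
) -> pd.DataFrame:
    """Boolean allele-loss matrix (genes x samples).

    A gene's allele is lost in a sample iff mapped reads < `max_reads` AND
    its GPM is below `gpm_fraction` of the cohort's median single-copy GPM
    for that gene (per-sample GPM divided by the genotype-expected copy
    number, median over samples expected to carry the allele).  Samples
    whose genotype does not carry the allele are never flagged.
    """
    sub = catalog["subgenome"].reindex(counts.index).to_numpy()
    expected = np.empty((len(counts.index), counts.shape[1]), dtype=float)
    for j, sample in enumerate(counts.columns):
        r = int(metadata.loc[sample, "r_copies"])
        c = int(metadata.loc[sample, "c_copies"])
        expected[:, j] = np.where(sub == "R", r, c)
    gpm_arr = gpm_values.reindex(counts.index)[counts.columns].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_copy = np.where(expected > 0, gpm_arr / np.maximum(expected, 1), np.nan)
    single_copy = np.nanmedian(per_copy, axis=1)
    low_depth = counts.to_numpy() < max_reads
    low_gpm = gpm_arr < gpm_fraction * single_copy[:, None]
    lost = low_depth & low_gpm & (expected > 0)
    return pd.DataFrame(lost, index=counts.index, columns=counts.columns)


def segment_cnv(
    calls: pd.DataFrame,
    catalog: pd.DataFrame,
    min_run: int = 10,
) -> tuple[list[SegmentCall], list[SegmentCall]]:
    """Aggregate per-gene calls into contiguous same-call runs per chromosome.

    `calls` is the long frame from :func:`call_gene_cnvs` (or any frame with
    gene/sample/call columns).  Returns ``(segments, short_runs)`` where
    `segments` holds maximal runs of length >= `min_run` and `short_runs`
    the remaining sub-threshold runs (including singletons).
    """
    segments: list[SegmentCall] = []
    short: list[SegmentCall] = []
    cat = catalog[["chrom", "pos_index", "subgenome"]]
    merged = calls.merge(cat, left_on="gene", right_index=True, how="left")
    for (sample, chrom), grp in merged.groupby(["sample", "chrom"], sort=True):
        grp = grp.sort_values("pos_index")
        pos = grp["pos_index"].to_numpy()
        call = grp["call"].to_numpy()
        allele = grp["subgenome"].iloc[0]
        i = 0
        while i < len(grp):
            if call[i] == "none":
                i += 1
                continue
            j = i
            while (
                j + 1 < len(grp)
                and call[j + 1] == call[i]
                and pos[j + 1] == pos[j] + 1
            ):
                j += 1
            seg = SegmentCall(
                chromosome=chrom,
                start=int(pos[i]),
                end=int(pos[j]) + 1,
                n_genes=j - i + 1,
                allele=allele,
                call=call[i],
                sample=sample,
            )
            (segments if seg.n_genes >= min_run else short).append(seg)
            i = j + 1
    return segments, short


def cnv_subgenome_summary(calls: pd.DataFrame, catalog: pd.DataFrame) -> pd.DataFrame:
    """Per-sample fractions of CNV-called genes in subgenome R vs C,
    stratified by AGP membership.

    Samples with zero calls are absent from the result.
    """
    called = calls[calls["call"].isin(["gain", "loss"])]
    if called.empty:
        return pd.DataFrame(
            columns=["sample", "n_cnv", "frac_r", "frac_c", "frac_agp", "frac_ssg"]
        )
    is_agp = (catalog["agp_partner"] != "").reindex(called["gene"]).to_numpy()
    sub = catalog["subgenome"].reindex(called["gene"]).to_numpy()
    df = pd.DataFrame(
        {"sample": called["sample"].to_numpy(), "is_r": sub == "R", "is_agp": is_agp}
    )
    out = (
        df.groupby("sample")
        .agg(n_cnv=("is_r", "size"), frac_r=("is_r", "mean"), frac_agp=("is_agp", "mean"))
        .reset_index()
    )
    out["frac_c"] = 1.0 - out["frac_r"]
    out["frac_ssg"] = 1.0 - out["frac_agp"]
    return out[["sample", "n_cnv", "frac_r", "frac_c", "frac_agp", "frac_ssg"]]
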