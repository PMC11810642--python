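"""Count normalization (GPM/TPM), expression filtering, genotype verification.

GPM ("gene per million") is a length-normalized per-gene depth statistic for
genomic counts: ``A_g = count_g * 1e6 / length_g`` and
``GPM_g = A_g / sum(A) * 1e6``, so every sample column sums to one million.
TPM applies identical arithmetic to transcriptomic counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class NormalizedMatrix:
    """Length- and depth-normalized values (GPM or TPM), genes x samples.

    Samples with zero total length-normalized signal are left as NaN columns
    and listed in `flagged_samples` rather than divided through.
    """

    values: pd.DataFrame
    method: str
    flagged_samples: list[str] = field(default_factory=list)


def _normalize(counts: pd.DataFrame, lengths: pd.Series, method: str) -> NormalizedMatrix:
    squeeze = isinstance(counts, pd.Series)
    if squeeze:
        counts = counts.to_frame()
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][:5].tolist()
        raise ValueError(f"missing gene lengths for {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    a = counts.div(lengths, axis=0) * 1e6
    totals = a.sum(axis=0)
    flagged = totals.index[totals <= 0].tolist()
    safe = totals.replace(0, np.nan)
    values = a.div(safe, axis=1) * 1e6
    return NormalizedMatrix(values=values, method=method, flagged_samples=flagged)


def gpm(counts: pd.DataFrame, lengths: pd.Series) -> NormalizedMatrix:
    """Gene-per-million normalization of genomic counts."""
    return _normalize(counts, lengths, "GPM")


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> NormalizedMatrix:
    """Transcripts-per-million normalization of transcriptomic counts."""
    return _normalize(counts, lengths, "TPM")


def filter_expressed(
    counts: pd.DataFrame,
    tpm_values: pd.DataFrame,
    min_reads: int = 10,
    min_tpm: float = 1.0,
) -> pd.Series:
    """Boolean keep-mask per gene.

    A gene is dropped only when it fails *both* conditions
    (reads < min_reads AND TPM < min_tpm) in every sample of the cohort;
    a gene expressed in any sample is retained.
    """
    counts, tpm_values = counts.align(tpm_values, join="left")
    fails = (counts < min_reads) & (tpm_values < min_tpm)
    return ~fails.all(axis=1)


#: dosage classes keyed by the nearest log2(R/C) mean-depth ratio
_DOSAGE_CLASSES = {-1: "1:2", 0: "1:1", 1: "2:1"}


def infer_subgenome_ratio(gpm_values: pd.Series, catalog: pd.DataFrame) -> str:
    """Classify one sample's subgenome dosage from mean GPM over R vs C genes.

    Returns one of '1:1', '1:2', '2:1' (nearest on the log2 scale with
    midpoint boundaries at +/-0.5).
    """
    sub = catalog["subgenome"].reindex(gpm_values.index)
    mean_r = gpm_values[sub == "R"].mean()
    mean_c = gpm_values[sub == "C"].mean()
    if not np.isfinite(mean_r) or not np.isfinite(mean_c) or mean_c == 0 or mean_r == 0:
        raise ValueError("degenerate subgenome depth (empty or all-zero side)")
    log_ratio = np.log2(mean_r / mean_c)
    if log_ratio >= 0.5:
        return _DOSAGE_CLASSES[1]
    if log_ratio < -0.5:
        return _DOSAGE_CLASSES[-1]
    return _DOSAGE_CLASSES[0]


def infer_mito_origin(reads_r: float, reads_c: float, min_fold: float = 5.0) -> str:
    """Mitochondrial origin from reads mapped to the two mito genomes.

    The winner must exceed the loser by `min_fold`, otherwise 'ambiguous'.
    """
    if reads_r < 0 or reads_c < 0:
        raise ValueError("read counts must be non-negative")
    hi, lo = max(reads_r, reads_c), min(reads_r, reads_c)
    if hi == 0 or (lo > 0 and hi < min_fold * lo):
        return "ambiguous"
    return "R" if reads_r > reads_c else "C"
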