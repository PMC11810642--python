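"""Allele-specific expression between reciprocal mitochondrial backgrounds.

The in-repo differential-expression engine is a negative-binomial Wald test
on size-factor-normalized counts (median-of-ratios size factors, per-gene
method-of-moments dispersion with a floor).  A gene's direction is only set
when it clears all three gates: fold change > 3, P < 0.001 and
Benjamini-Hochberg adjusted P < 0.001.

Nine-pattern classification places each allelic gene pair in the 3x3 grid of
(direction of allele R, direction of allele C) between the two mitochondrial
backgrounds; directions are the change from the mito-R-background group to
the mito-C-background group.  Category groupings are normative:
single-allele {II, IV, VI, VIII}, both-same {III, IX}, opposite {I, VII},
none {V}.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DIRECTIONS = ("up", "none", "down")

#: Numeral map consistent with the normative category groupings.  The grid is
#: keyed by (direction_R, direction_C); override via `pattern_map=` to match
#: an alternative layout.
DEFAULT_PATTERN_MAP: dict[tuple[str, str], str] = {
    ("up", "down"): "I",
    ("up", "none"): "II",
    ("up", "up"): "III",
    ("none", "up"): "IV",
    ("none", "none"): "V",
    ("none", "down"): "VI",
    ("down", "up"): "VII",
    ("down", "none"): "VIII",
    ("down", "down"): "IX",
}

CATEGORY_OF_PATTERN = {
    "I": "opposite", "VII": "opposite",
    "II": "single-allele", "IV": "single-allele",
    "VI": "single-allele", "VIII": "single-allele",
    "III": "both-same", "IX": "both-same",
    "V": "none",
}


def category_of(direction_r: str, direction_c: str) -> str:
    """Pattern category as a function of the two allele directions."""
    non_none = (direction_r != "none") + (direction_c != "none")
    if non_none == 0:
        return "none"
    if non_none == 1:
        return "single-allele"
    return "both-same" if direction_r == direction_c else "opposite"


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Uses genes with non-zero counts in all samples for the geometric-mean
    reference; falls back to library-size factors when none exist.
    """
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if positive.sum() == 0:
        lib = arr.sum(axis=0)
        if (lib == 0).any():
            raise ValueError("sample with all-zero library size")
        sf = lib / np.exp(np.mean(np.log(lib)))
        return pd.Series(sf, index=counts.columns)
    logs = np.log(arr[positive])
    ref = logs.mean(axis=1)
    sf = np.exp(np.median(logs - ref[:, None], axis=0))
    if (sf <= 0).any() or not np.isfinite(sf).all():
        raise ValueError("degenerate size factors (all-zero sample?)")
    return pd.Series(sf, index=counts.columns)


def de_test(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    fc_min: float = 3.0,
    p_max: float = 0.001,
    padj_max: float = 0.001,
    dispersion_floor: float = 0.01,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene NB Wald test between two sample groups.

    Group A is the mito-R background, group B the mito-C background; the
    reported direction is the change from A to B.  Returns a DataFrame
    indexed by gene with columns mean_a, mean_b, fc, log2_fc, dispersion,
    stat, p, padj, direction.
    """
    counts_a, counts_b = counts_a.align(counts_b, join="inner", axis=0)
    n_a, n_b = counts_a.shape[1], counts_b.shape[1]
    if n_a < 3 or n_b < 3:
        raise ValueError("at least 3 samples per group required")
    combined = pd.concat([counts_a, counts_b], axis=1)
    sf = size_factors(combined)
    norm = combined.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    a = norm[:, :n_a]
    b = norm[:, n_a:]

    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    # pooled method-of-moments dispersion: var = mu + alpha mu^2
    pooled_var = ((n_a - 1) * var_a + (n_b - 1) * var_b) / (n_a + n_b - 2)
    pooled_mean = (n_a * mean_a + n_b * mean_b) / (n_a + n_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = (pooled_var - pooled_mean) / np.square(pooled_mean)
    alpha = np.where(np.isfinite(alpha), alpha, dispersion_floor)
    alpha = np.maximum(alpha, dispersion_floor)

    ma = mean_a + pseudocount
    mb = mean_b + pseudocount
    log_ratio = np.log(mb / ma)
    model_var_a = ma + alpha * np.square(ma)
    model_var_b = mb + alpha * np.square(mb)
    se = np.sqrt(model_var_a / (n_a * np.square(ma)) + model_var_b / (n_b * np.square(mb)))
    stat = log_ratio / se
    # t reference with the two-group df guards the Wald statistic against
    # anticonservative tails at small n
    df = n_a + n_b - 2
    p = 2.0 * stats.t.sf(np.abs(stat), df)
    padj = multipletests(p, method="fdr_bh")[1]

    fc = np.maximum(mb / ma, ma / mb)
    significant = (fc > fc_min) & (p < p_max) & (padj < padj_max)
    direction = np.where(
        significant, np.where(mb > ma, "up", "down"), "none"
    )
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fc": fc,
            "log2_fc": log_ratio / np.log(2.0),
            "dispersion": alpha,
            "stat": stat,
            "p": p,
            "padj": padj,
            "direction": direction,
        },
        index=combined.index,
    )


def classify_nine_patterns(
    de_r: pd.DataFrame,
    de_c: pd.DataFrame,
    agps: pd.DataFrame,
    pattern_map: dict[tuple[str, str], str] | None = None,
) -> pd.DataFrame:
    """Assign each AGP its nine-pattern cell and category.

    `de_r` / `de_c` are :func:`de_test` results indexed by the R-side and
    C-side gene ids; `agps` has columns gene_r / gene_c.  AGPs missing a
    tested allele are returned as 'unclassified'.
    """
    pattern_map = dict(DEFAULT_PATTERN_MAP if pattern_map is None else pattern_map)
    rows = []
    dir_r = de_r["direction"]
    dir_c = de_c["direction"]
    for gene_r, gene_c in agps[["gene_r", "gene_c"]].itertuples(index=False):
        dr = dir_r.get(gene_r)
        dc = dir_c.get(gene_c)
        if dr is None or dc is None:
            rows.append((gene_r, gene_c, dr or "missing", dc or "missing",
                         "unclassified", "unclassified"))
            continue
        rows.append(
            (gene_r, gene_c, dr, dc, pattern_map[(dr, dc)], category_of(dr, dc))
        )
    return pd.DataFrame(
        rows,
        columns=["agp", "gene_c", "direction_r", "direction_c", "pattern", "category"],
    ).set_index("agp")


def detect_allele_silencing(
    tpm_values: pd.DataFrame,
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    variety_a: str,
    variety_b: str,
    max_tpm: float = 1.0,
    max_reads: int = 10,
) -> pd.DataFrame:
    """Silencing of a gene in one variety of a reciprocal pair.

    A gene is *silenced* in variety X iff TPM < `max_tpm` and reads <
    `max_reads` in every individual of X while TPM >= `max_tpm` in at least
    half the individuals of the reciprocal variety.  Returns records with
    columns gene, silenced_in, expressed_in.
    """
    records = []
    samples = {
        v: metadata.index[metadata["variety"] == v] for v in (variety_a, variety_b)
    }
    for v in (variety_a, variety_b):
        if len(samples[v]) == 0:
            raise ValueError(f"no samples for variety {v!r}")
    for silent, active in ((variety_a, variety_b), (variety_b, variety_a)):
        t_s = tpm_values[samples[silent]]
        c_s = counts[samples[silent]]
        t_a = tpm_values[samples[active]]
        off = ((t_s < max_tpm) & (c_s < max_reads)).all(axis=1)
        on = (t_a >= max_tpm).mean(axis=1) >= 0.5
        for gene in tpm_values.index[off & on]:
            records.append(
                {"gene": gene, "silenced_in": silent, "expressed_in": active}
            )
    return pd.DataFrame(records, columns=["gene", "silenced_in", "expressed_in"])
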