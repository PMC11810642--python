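"""Allelic synchrony: correlation between allele-R and allele-C expression.

Per allelic gene pair (AGP) the Pearson correlation between the two alleles'
expression profiles across a cohort's individuals quantifies shared (trans)
regulation; a shuffled non-orthologous background pair set provides the null
reference.  Cross-variety comparisons use two-sample t-tests on Fisher
z-transformed correlations (a raw-PCC mode is retained).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

MIN_COHORT = 3


@dataclass
class BackgroundPairSet:
    """Non-orthologous (gene_r, gene_c) pairs mirroring an AGP set."""

    pairs: pd.DataFrame  # columns: gene_r, gene_c
    seed: int


def _pair_corr(x_r: np.ndarray, x_c: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation between paired matrices."""
    rc = x_r - x_r.mean(axis=1, keepdims=True)
    cc = x_c - x_c.mean(axis=1, keepdims=True)
    denom = np.sqrt((rc**2).sum(axis=1) * (cc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (rc * cc).sum(axis=1) / denom
    return np.clip(out, -1.0, 1.0)


def agp_pcc(
    expr: pd.DataFrame,
    pairs: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    cohort: str | None = None,
) -> pd.DataFrame:
    """PCC between allele-R and allele-C expression for each pair.

    `expr` is genes x individuals (any consistent transform); `cohort`
    restricts to one variety via `metadata`.  Pairs whose either profile is
    constant get PCC NaN and flag 'constant'.  Raises when the cohort has
    fewer than MIN_COHORT individuals.
    """
    if cohort is not None:
        if metadata is None:
            raise ValueError("metadata required to select a cohort")
        samples = metadata.index[metadata["variety"] == cohort]
        expr = expr[samples]
    n = expr.shape[1]
    if n < MIN_COHORT:
        raise ValueError(f"cohort has {n} individuals; >= {MIN_COHORT} required")
    x_r = expr.reindex(pairs["gene_r"]).to_numpy(dtype=float)
    x_c = expr.reindex(pairs["gene_c"]).to_numpy(dtype=float)
    pcc = _pair_corr(x_r, x_c)
    constant = (x_r.std(axis=1) == 0) | (x_c.std(axis=1) == 0)
    pcc = np.where(constant, np.nan, pcc)
    from polyhybrid.growth import pcc_classify

    return pd.DataFrame(
        {
            "agp": pairs["gene_r"].to_numpy(),
            "gene_c": pairs["gene_c"].to_numpy(),
            "cohort": cohort if cohort is not None else "pooled",
            "n": n,
            "pcc": pcc,
            "pcc_class": [pcc_classify(v) for v in pcc],
            "flag": np.where(constant, "constant", ""),
        }
    ).set_index("agp")


def make_background(agps: pd.DataFrame, seed: int = 7) -> BackgroundPairSet:
    """Derangement-style shuffle of C-side genes against R-side genes.

    No output pair coincides with a true AGP; deterministic under `seed`.
    """
    rng = np.random.default_rng(seed)
    gene_r = agps["gene_r"].to_numpy()
    gene_c = agps["gene_c"].to_numpy()
    n = len(agps)
    if n < 2:
        raise ValueError("need at least 2 AGPs to build a background")
    perm = rng.permutation(n)
    for _ in range(10_000):
        fixed = np.flatnonzero(perm == np.arange(n))
        if fixed.size == 0:
            break
        if fixed.size == 1:
            other = int(rng.integers(n - 1))
            other += other >= fixed[0]
            perm[[fixed[0], other]] = perm[[other, fixed[0]]]
        else:
            perm[fixed] = perm[np.roll(fixed, 1)]
    pairs = pd.DataFrame({"gene_r": gene_r, "gene_c": gene_c[perm]})
    return BackgroundPairSet(pairs=pairs, seed=seed)


def compare_pcc_distributions(
    pcc_a,
    pcc_b,
    fisher: bool = True,
    equal_var: bool = False,
) -> tuple[float, float, float]:
    """Two-sample t-test between two PCC collections.

    NaNs are dropped.  With `fisher` (default) the PCCs are arctanh
    (Fisher z) transformed first; `equal_var=True` selects the pooled
    instead of the Welch variant.  Returns (t, two-sided p, df).
    """
    a = np.asarray(pcc_a, dtype=float)
    b = np.asarray(pcc_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if fisher:
        a = np.arctanh(np.clip(a, -1 + 1e-12, 1 - 1e-12))
        b = np.arctanh(np.clip(b, -1 + 1e-12, 1 - 1e-12))
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df = a.size + b.size - 2
    else:
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        if va + vb == 0:
            df = a.size + b.size - 2
        else:
            df = (va + vb) ** 2 / (
                va**2 / (a.size - 1) + vb**2 / (b.size - 1)
            )
    return float(res.statistic), float(res.pvalue), float(df)


def shared_strong_pairs(strong_sets: dict[str, set]) -> dict:
    """Intersection bookkeeping for per-variety strong-positive AGP sets.

    Returns per-set sizes, the union and all-set intersection, pairwise
    intersection sizes, and upset-style exclusive membership counts.
    """
    names = sorted(strong_sets)
    sets = {k: set(v) for k, v in strong_sets.items()}
    union = set().union(*sets.values()) if names else set()
    inter = set.intersection(*sets.values()) if names else set()
    exclusive: dict[str, int] = {}
    for agp in union:
        key = "&".join(n for n in names if agp in sets[n])
        exclusive[key] = exclusive.get(key, 0) + 1
    return {
        "sets": {k: len(v) for k, v in sets.items()},
        "union": len(union),
        "intersection_all": len(inter),
        "intersection_all_ids": sorted(inter),
        "pairwise": {
            f"{a}&{b}": len(sets[a] & sets[b]) for a, b in combinations(names, 2)
        },
        "exclusive_counts": exclusive,
    }
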