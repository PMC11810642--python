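"""Coexpression-network growth screen and cohort diversity metrics.

A deliberately compact unsigned WGCNA-style workflow: soft-threshold power
selection by scale-free topology fit, adjacency ``|PCC|^power``, topological
overlap, average-linkage clustering with a static cut plus eigengene-based
module merging, module eigengenes (first principal component), gene
significance (gene-trait PCC) / module membership (gene-eigengene PCC)
filtering, PCC classification, and coefficient-of-variation diversity
records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

UNASSIGNED = 0


def log_expression(tpm_values: pd.DataFrame) -> pd.DataFrame:
    """Variance-stabilizing transform log2(TPM + 1)."""
    return np.log2(tpm_values + 1.0)


def _corr(expr: pd.DataFrame) -> np.ndarray:
    """Gene-gene Pearson correlation (genes are rows)."""
    x = np.asarray(expr, dtype=float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        raise ValueError("constant expression rows; filter before correlating")
    c = np.corrcoef(x)
    return np.clip(c, -1.0, 1.0)


def adjacency(expr: pd.DataFrame, power: int) -> np.ndarray:
    """Unsigned adjacency a_ij = |PCC(x_i, x_j)|^power."""
    if power < 1:
        raise ValueError("power must be >= 1")
    return np.abs(_corr(expr)) ** power


def scale_free_fit(adj: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log10 p(k) vs log10 k linear fit over connectivity bins."""
    k = adj.sum(axis=1) - 1.0  # exclude the self-edge
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    counts, _ = np.histogram(k, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    if keep.sum() < 3:
        return 0.0
    x = np.log10(centers[keep])
    y = np.log10(counts[keep] / counts.sum())
    if np.allclose(x, x[0]):
        return 0.0
    slope, intercept = np.polyfit(x, y, 1)
    if slope >= 0:  # p(k) must decay with k for scale-free topology
        return 0.0
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return 0.0
    return float(1.0 - np.sum(resid**2) / ss_tot)


def soft_power_select(
    expr: pd.DataFrame,
    powers=range(1, 21),
    r2_min: float = 0.8,
    n_bins: int = 10,
    fallback: int = 6,
    min_max_k: float = 1.0,
) -> int:
    """Smallest power whose scale-free fit reaches `r2_min`; else `fallback`.

    Powers whose network is vacuous (maximum connectivity below `min_max_k`)
    are ineligible: on iid noise high powers shrink every adjacency toward
    zero, which would otherwise pass the power-law fit trivially.
    """
    corr = np.abs(_corr(expr))
    for power in powers:
        adj = corr**power
        k = adj.sum(axis=1) - 1.0
        if k.max() < min_max_k:
            continue
        if scale_free_fit(adj, n_bins=n_bins) >= r2_min:
            return int(power)
    return int(fallback)


def tom(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    ``TOM_ij = (sum_u a_iu a_uj - 2 a_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)``
    with ``k_i = sum_{u != i} a_iu``; shared-neighbor sums exclude i and j
    themselves (the diagonal of `adj` is 1).  Diagonal is 1 by convention.
    """
    a = np.asarray(adj, dtype=float)
    if a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    k = a.sum(axis=1) - np.diag(a)
    shared = a @ a
    # remove the i==u and j==u terms contributed by the diagonal
    shared = shared - a * np.diag(a)[:, None] - a * np.diag(a)[None, :]
    numer = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        t = numer / denom
    np.fill_diagonal(t, 1.0)
    return np.clip(t, 0.0, 1.0)


def _zscore(x: np.ndarray, axis: int = -1) -> np.ndarray:
    mean = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, ddof=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mean) / sd


def module_eigengene(expr: pd.DataFrame, genes=None) -> np.ndarray:
    """First principal component of the standardized module submatrix.

    Returned as a unit-variance vector over samples, sign-oriented so the
    mean gene-eigengene correlation is >= 0.  A one-gene module yields the
    z-scored gene itself.
    """
    sub = expr if genes is None else expr.loc[genes]
    x = _zscore(np.asarray(sub, dtype=float))
    if x.shape[0] == 1:
        return x[0]
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    e = vt[0]
    corr = x @ e / (np.linalg.norm(x, axis=1) * np.linalg.norm(e) + 1e-300)
    if corr.mean() < 0:
        e = -e
    return _zscore(e)


def module_eigengenes(expr: pd.DataFrame, labels: np.ndarray) -> pd.DataFrame:
    """Eigengene per module label (unassigned excluded); samples x modules."""
    out = {}
    for lab in sorted(set(labels) - {UNASSIGNED}):
        out[lab] = module_eigengene(expr, expr.index[labels == lab])
    return pd.DataFrame(out, index=expr.columns)


def detect_modules(
    tom_matrix: np.ndarray,
    expr: pd.DataFrame | None = None,
    min_module_size: int = 30,
    cut_height: float = 0.25,
    merge_corr: float = 0.75,
    min_kme: float = 0.3,
) -> np.ndarray:
    """Module labels from average-linkage clustering of TOM dissimilarity.

    The static tree cut is placed `cut_height` of the way down from the
    dendrogram top: clusters are branches joining below
    ``h_min + (1 - cut_height) * (h_max - h_min)``.  (An absolute cut in raw
    1 - TOM units is useless in practice: background dissimilarity
    concentrates near 1 while real modules join around 0.3-0.6, so any fixed
    low threshold shatters everything into singletons.)

    Clusters below `min_module_size` are set UNASSIGNED (0); modules whose
    eigengenes correlate above `merge_corr` are merged iteratively; finally
    unassigned genes whose eigengene correlation (kME) with some module
    exceeds `min_kme` are rescued into their best module.  The eigengene
    steps require `expr`.  Labels are renumbered 1..m by decreasing size.
    """
    dissim = 1.0 - np.asarray(tom_matrix, dtype=float)
    np.fill_diagonal(dissim, 0.0)
    dissim = (dissim + dissim.T) / 2.0  # enforce exact symmetry
    z = linkage(squareform(dissim, checks=False), method="average")
    heights = z[:, 2]
    threshold = float(
        heights.min() + (1.0 - cut_height) * (heights.max() - heights.min())
    )
    labels = fcluster(z, t=threshold, criterion="distance").astype(int)

    # undersized clusters go to grey BEFORE the eigengene merge: merging is
    # quadratic in module count and singleton clusters are not modules
    labels = _drop_small(labels, min_module_size)
    if expr is not None and (labels != UNASSIGNED).any():
        assigned = labels != UNASSIGNED
        merged = _merge_by_eigengene(expr[assigned], labels[assigned], merge_corr)
        labels = labels.copy()
        labels[assigned] = merged
        labels = _rescue_by_kme(expr, labels, min_kme)
        labels = _drop_small(labels, min_module_size)

    # renumber 1..m by decreasing module size
    sizes = pd.Series(labels[labels != UNASSIGNED]).value_counts()
    order = sizes.sort_values(ascending=False).index
    remap = {old: new for new, old in enumerate(order, start=1)}
    return np.array([remap.get(lab, UNASSIGNED) for lab in labels], dtype=int)


def _rescue_by_kme(
    expr: pd.DataFrame, labels: np.ndarray, min_kme: float
) -> np.ndarray:
    """Assign unclustered genes to the module with the strongest kME.

    Signed: eigengenes are oriented toward their members, so genuine members
    correlate positively; library-composition artifacts (highly variable
    modules depress the normalized expression of everything else) show up as
    negative correlations and must not be rescued.
    """
    mods = sorted(set(labels) - {UNASSIGNED})
    unassigned = np.flatnonzero(labels == UNASSIGNED)
    if not mods or unassigned.size == 0:
        return labels
    eig = np.vstack([module_eigengene(expr, expr.index[labels == m]) for m in mods])
    x = np.asarray(expr, dtype=float)[unassigned]
    kme = np.vstack([_row_corr(x, e) for e in eig])  # modules x genes
    best = np.argmax(kme, axis=0)
    best_val = kme[best, np.arange(kme.shape[1])]
    labels = labels.copy()
    for idx, mod_pos, val in zip(unassigned, best, best_val):
        if val > min_kme:
            labels[idx] = mods[mod_pos]
    return labels


def _drop_small(labels: np.ndarray, min_module_size: int) -> np.ndarray:
    sizes = pd.Series(labels).value_counts()
    small = set(sizes.index[sizes < min_module_size])
    return np.array(
        [UNASSIGNED if lab in small else lab for lab in labels], dtype=int
    )


def _merge_by_eigengene(
    expr: pd.DataFrame, labels: np.ndarray, merge_corr: float
) -> np.ndarray:
    labels = labels.copy()
    while True:
        mods = sorted(set(labels))
        if len(mods) < 2:
            return labels
        eig = np.vstack(
            [module_eigengene(expr, expr.index[labels == m]) for m in mods]
        )
        c = np.corrcoef(eig)
        np.fill_diagonal(c, -np.inf)
        i, j = np.unravel_index(np.argmax(c), c.shape)
        if c[i, j] <= merge_corr:
            return labels
        labels[labels == mods[j]] = mods[i]


@dataclass
class GrowthScreen:
    """Bundled outputs of :func:`gene_trait_stats`."""

    stats: pd.DataFrame  # per gene: module, mm, gs, gs_class
    module_trait: pd.Series  # eigengene-trait PCC per module
    eigengenes: pd.DataFrame


def _row_corr(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of x with vector y."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (xc @ yc) / denom
    return np.clip(out, -1.0, 1.0)


def gene_trait_stats(
    expr: pd.DataFrame,
    trait: pd.Series,
    labels: np.ndarray,
) -> GrowthScreen:
    """Gene significance, module membership, and module-trait correlations.

    GS = PCC(gene expression, trait); MM = PCC(gene, own module eigengene);
    the module-trait PCC uses each module's eigengene.  Unassigned genes get
    MM = NaN.
    """
    trait = trait.reindex(expr.columns)
    if trait.isna().any():
        raise ValueError("trait missing for some samples")
    x = np.asarray(expr, dtype=float)
    y = trait.to_numpy(dtype=float)
    gs = _row_corr(x, y)
    eig = module_eigengenes(expr, labels)
    mm = np.full(len(expr), np.nan)
    for lab in eig.columns:
        idx = np.flatnonzero(labels == lab)
        mm[idx] = _row_corr(x[idx], eig[lab].to_numpy())
    module_trait = pd.Series(
        {lab: _row_corr(eig[lab].to_numpy()[None, :], y)[0] for lab in eig.columns},
        dtype=float,
    )
    stats = pd.DataFrame(
        {
            "module": labels,
            "mm": mm,
            "gs": gs,
            "gs_class": [pcc_classify(v) for v in gs],
        },
        index=expr.index,
    )
    return GrowthScreen(stats=stats, module_trait=module_trait, eigengenes=eig)


def filter_hub_genes(
    screen: GrowthScreen,
    mm_min: float = 0.8,
    gs_min: float = 0.3,
    module: int | None = None,
) -> pd.Index:
    """Candidate growth genes: |MM| > mm_min and |GS| > gs_min (strict) in
    the most trait-correlated module (largest |eigengene-trait PCC|)."""
    if len(screen.module_trait) == 0:
        return pd.Index([])
    if module is None:
        module = screen.module_trait.abs().idxmax()
    s = screen.stats
    keep = (
        (s["module"] == module)
        & (s["mm"].abs() > mm_min)
        & (s["gs"].abs() > gs_min)
    )
    return s.index[keep.fillna(False)]


def pcc_classify(pcc: float) -> str:
    """Correlation class with the published boundaries.

    strong_neg: pcc < -0.5; neg: -0.5 <= pcc < -0.3;
    pos: 0.3 < pcc <= 0.5; strong_pos: pcc > 0.5; else unclassified.
    """
    if np.isnan(pcc):
        return "unclassified"
    if pcc < -0.5:
        return "strong_neg"
    if pcc < -0.3:
        return "neg"
    if pcc > 0.5:
        return "strong_pos"
    if pcc > 0.3:
        return "pos"
    return "unclassified"


def diversity(
    metadata: pd.DataFrame,
    tpm_values: pd.DataFrame,
    gene_set,
    weight_col: str = "body_weight",
) -> pd.DataFrame:
    """Per-variety growth and expression diversity.

    weight_diversity = SD(weight) / mean(weight) (coefficient of variation);
    expression_diversity = mean over `gene_set` of the per-gene SD of TPM
    across the variety's individuals.
    """
    gene_set = [g for g in gene_set if g in tpm_values.index]
    rows = []
    for variety, grp in metadata.groupby("variety", sort=True):
        w = grp[weight_col].to_numpy(dtype=float)
        wd = w.std(ddof=1) / w.mean() if len(w) > 1 and w.mean() != 0 else 0.0
        sub = tpm_values.loc[gene_set, grp.index]
        ed = float(sub.std(axis=1, ddof=1).mean()) if len(gene_set) else np.nan
        rows.append(
            {
                "variety": variety,
                "n": len(grp),
                "weight_diversity": float(wd),
                "expression_diversity": ed,
            }
        )
    return pd.DataFrame(rows).set_index("variety")
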