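"""Synthetic two-subgenome count data with planted truth.

Generates a gene catalog (subgenome R and C chromosomes with allelic gene
pairs), genomic and transcriptomic negative-binomial count matrices, a 1:1
in-silico F1 mixture control, sample metadata with mitochondrial read counts,
trait values driven by designated growth genes, and machine-readable truth
tables covering every planted event.

Counts follow a gamma-Poisson (negative binomial) model with
``variance = mu + mu**2 / dispersion``; the mean of gene *g* in sample *s* is
proportional to ``copies(g, s) * length(g)`` (genomic) or
``copies(g, s) * baseline(g) * ase_factor(g, s)`` (transcriptomic), rescaled
so each sample's expected total equals its jittered sequencing depth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from polyhybrid.config import (
    ALLELES,
    ConfigError,
    SimulationConfig,
    sample_ids,
)

# Stream tags keep each stage's RNG independent of the others while remaining
# fully determined by the config seed.
_STREAMS = {
    "catalog": 1,
    "genomic": 2,
    "expression": 3,
    "traits": 4,
    "mito": 5,
    "hits": 6,
}

MIXED_SAMPLE_ID = "mixed_control"


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STREAMS[stream]])


# --------------------------------------------------------------------- catalog


def simulate_catalog(config: SimulationConfig) -> pd.DataFrame:
    """Generate the gene catalog.

    Returns a DataFrame indexed by gene_id with columns ``subgenome``,
    ``chrom``, ``pos_index``, ``length_bp``, ``agp_partner`` (empty string
    for species-specific genes).  Each chromosome exists in an R and a C
    copy with ``genes_per_chromosome`` positional loci; a fraction
    ``agp_fraction`` of loci are cross-linked as allelic gene pairs.
    """
    rng = _rng(config, "catalog")
    rows = []
    for allele in ALLELES:
        for k in range(1, config.n_chromosomes + 1):
            chrom = f"{allele}{k:02d}"
            for j in range(config.genes_per_chromosome):
                rows.append(
                    {
                        "gene_id": f"{chrom}g{j:04d}",
                        "subgenome": allele,
                        "chrom": chrom,
                        "pos_index": j,
                        "length_bp": 0,
                        "agp_partner": "",
                    }
                )
    catalog = pd.DataFrame(rows).set_index("gene_id")
    lo, hi = config.gene_length_range
    catalog["length_bp"] = rng.integers(lo, hi + 1, size=len(catalog))

    n_loci = config.n_chromosomes * config.genes_per_chromosome
    n_pairs = int(round(config.agp_fraction * n_loci))
    paired = rng.choice(n_loci, size=n_pairs, replace=False)
    chrom_no = paired // config.genes_per_chromosome + 1
    pos = paired % config.genes_per_chromosome
    r_ids = [f"R{k:02d}g{j:04d}" for k, j in zip(chrom_no, pos)]
    c_ids = [f"C{k:02d}g{j:04d}" for k, j in zip(chrom_no, pos)]
    catalog.loc[r_ids, "agp_partner"] = c_ids
    catalog.loc[c_ids, "agp_partner"] = r_ids

    catalog = catalog.sort_values(["chrom", "pos_index"])
    return catalog


def catalog_agps(catalog: pd.DataFrame) -> pd.DataFrame:
    """Allelic gene pairs of a catalog as a DataFrame (gene_r, gene_c)."""
    r_side = catalog[(catalog["subgenome"] == "R") & (catalog["agp_partner"] != "")]
    return pd.DataFrame(
        {"gene_r": r_side.index, "gene_c": r_side["agp_partner"].to_numpy()}
    ).reset_index(drop=True)


# -------------------------------------------------------------------- metadata


def simulate_metadata(config: SimulationConfig) -> pd.DataFrame:
    """Sample metadata: variety, copy numbers, mito origin, mito read counts."""
    rng = _rng(config, "mito")
    rows = []
    for v in config.varieties:
        for i in range(v.n_individuals):
            rows.append(
                {
                    "sample_id": f"{v.name}-{i + 1}",
                    "variety": v.name,
                    "r_copies": v.r_copies,
                    "c_copies": v.c_copies,
                    "mito_origin": v.mito_origin,
                }
            )
    meta = pd.DataFrame(rows).set_index("sample_id")
    own = rng.poisson(0.005 * config.sequencing_depth, size=len(meta))
    other = rng.poisson(1e-5 * config.sequencing_depth, size=len(meta))
    is_r = (meta["mito_origin"] == "R").to_numpy()
    meta["mito_reads_r"] = np.where(is_r, own, other)
    meta["mito_reads_c"] = np.where(is_r, other, own)
    return meta


# ---------------------------------------------------------------- copy numbers


def true_copy_numbers(config: SimulationConfig, catalog: pd.DataFrame) -> pd.DataFrame:
    """Per-gene per-sample true copy numbers after applying cnv_events."""
    samples = sample_ids(config.varieties)
    base = np.zeros((len(catalog), len(samples)), dtype=int)
    col = 0
    is_r = (catalog["subgenome"] == "R").to_numpy()
    for v in config.varieties:
        for _ in range(v.n_individuals):
            base[:, col] = np.where(is_r, v.r_copies, v.c_copies)
            col += 1
    cn = pd.DataFrame(base, index=catalog.index, columns=samples)

    chrom = catalog["chrom"].to_numpy()
    pos = catalog["pos_index"].to_numpy()
    for ev in config.cnv_events:
        sample = f"{ev.variety}-{ev.individual + 1}"
        target = f"{ev.allele}{ev.chromosome:02d}"
        mask = (chrom == target) & (pos >= ev.start) & (pos < ev.end)
        cn.loc[mask, sample] += ev.copy_delta
    if (cn.to_numpy() < 0).any():
        bad = cn.index[(cn.to_numpy() < 0).any(axis=1)][:5].tolist()
        raise ConfigError(f"cnv_events drive copy number below zero (e.g. {bad})")
    return cn


# ---------------------------------------------------------------------- counts


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Gamma-Poisson draw with variance mu + mu^2 / dispersion; mean 0 -> 0."""
    shape = np.full_like(mean, dispersion, dtype=float)
    lam = rng.gamma(shape, np.asarray(mean, dtype=float) / dispersion)
    return rng.poisson(lam)


def _depth_scaled_means(
    weights: np.ndarray, depth: float, jitter: np.ndarray
) -> np.ndarray:
    """Scale per-gene weights (genes x samples) so expected column totals
    equal ``depth * jitter``."""
    totals = weights.sum(axis=0)
    totals = np.where(totals > 0, totals, 1.0)
    return weights / totals * (depth * jitter)


def simulate_genomic_counts(
    config: SimulationConfig, catalog: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Simulate WGS gene counts for all samples plus the mixture control.

    Returns ``(counts, mixed, copy_number)`` where `counts` is genes x
    samples, `mixed` is the in-silico F1 control column (every gene at one
    copy), and `copy_number` is the truth table used for the means.
    """
    rng = _rng(config, "genomic")
    cn = true_copy_numbers(config, catalog)
    lengths = catalog["length_bp"].to_numpy(dtype=float)[:, None]
    weights = cn.to_numpy(dtype=float) * lengths
    jitter = rng.uniform(1 - config.depth_jitter, 1 + config.depth_jitter, cn.shape[1])
    means = _depth_scaled_means(weights, config.sequencing_depth, jitter)
    counts = pd.DataFrame(
        _nb_counts(rng, means, config.nb_dispersion),
        index=cn.index,
        columns=cn.columns,
    )

    mixed_jitter = rng.uniform(1 - config.depth_jitter, 1 + config.depth_jitter, 1)
    mixed_means = _depth_scaled_means(lengths, config.sequencing_depth, mixed_jitter)
    mixed = pd.Series(
        _nb_counts(rng, mixed_means, config.nb_dispersion)[:, 0],
        index=cn.index,
        name=MIXED_SAMPLE_ID,
    )
    return counts, mixed, cn


def baseline_expression(config: SimulationConfig, catalog: pd.DataFrame) -> pd.Series:
    """Per-gene log-normal baseline expression level (relative units)."""
    rng = _rng(config, "expression")
    vals = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, len(catalog))
    return pd.Series(vals, index=catalog.index, name="baseline")


def ase_factors(
    config: SimulationConfig, catalog: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Multiplicative mito-conditional expression factors (genes x samples)."""
    factors = pd.DataFrame(
        1.0, index=catalog.index, columns=metadata.index, dtype=float
    )
    for ev in config.ase_events:
        if ev.gene not in factors.index:
            raise ConfigError(f"ase_event references unknown gene {ev.gene!r}")
        hit = (metadata["mito_origin"] == ev.when_mito).to_numpy()
        factors.loc[ev.gene, hit] *= ev.fold_change
    return factors


def simulate_expression_counts(
    config: SimulationConfig,
    catalog: pd.DataFrame,
    copy_number: pd.DataFrame,
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Simulate RNA-seq gene counts (genes x samples).

    Expression mean is proportional to copy number x baseline x
    mito-conditional ASE factor, so planted CNVs shift allelic expression
    ratios toward the new copy ratio.
    """
    rng = _rng(config, "expression")
    # consume the baseline draw from the same stream so it matches
    # baseline_expression(); re-draw explicitly for clarity
    baseline = rng.lognormal(
        config.baseline_log_mean, config.baseline_log_sd, len(catalog)
    )
    factors = ase_factors(config, catalog, metadata)
    weights = (
        copy_number.to_numpy(dtype=float)
        * baseline[:, None]
        * factors.to_numpy(dtype=float)
    )
    if config.latent_factors:
        n_samples = weights.shape[1]
        f = rng.standard_normal((len(config.latent_factors), n_samples))
        for i, lf in enumerate(config.latent_factors):
            rows = catalog.index.get_indexer(list(lf.genes))
            if (rows < 0).any():
                missing = [g for g, r in zip(lf.genes, rows) if r < 0]
                raise ConfigError(
                    f"latent factor {lf.name!r} references unknown genes {missing}"
                )
            eps = rng.standard_normal((len(rows), n_samples))
            shared = lf.loading * f[i][None, :]
            private = np.sqrt(1.0 - lf.loading**2) * eps
            weights[rows] *= np.exp(lf.scale * (shared + private))
    jitter = rng.uniform(
        1 - config.depth_jitter, 1 + config.depth_jitter, weights.shape[1]
    )
    means = _depth_scaled_means(weights, config.sequencing_depth, jitter)
    return pd.DataFrame(
        _nb_counts(rng, means, config.nb_dispersion),
        index=copy_number.index,
        columns=copy_number.columns,
    )


# ---------------------------------------------------------------------- traits


def simulate_traits(
    config: SimulationConfig,
    expression: pd.DataFrame,
    catalog: pd.DataFrame,
) -> pd.Series:
    """Trait (body weight) per individual.

    ``trait = baseline + sum_g effect * sign * z(log2(TPM_g + 1)) + noise``
    with z-scores taken across all individuals.
    """
    from polyhybrid.quantify import tpm

    rng = _rng(config, "traits")
    trait = np.full(expression.shape[1], float(config.trait_baseline))
    if config.growth_genes:
        tpm_vals = tpm(expression, catalog["length_bp"]).values
        logx = np.log2(tpm_vals + 1.0)
        for gg in config.growth_genes:
            if gg.gene not in logx.index:
                raise ConfigError(f"growth gene {gg.gene!r} not in catalog")
            x = logx.loc[gg.gene].to_numpy(dtype=float)
            sd = x.std(ddof=1)
            z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
            trait += gg.effect_size * gg.sign * z
    trait += rng.normal(0.0, config.trait_noise_sd, size=trait.size)
    return pd.Series(trait, index=expression.columns, name="body_weight")


# ------------------------------------------------------------------ hit tables


def simulate_hit_tables(
    config: SimulationConfig, catalog: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic 12-column protein-similarity hit tables (R->C and C->R).

    True AGP partners receive mutually best high-scoring reciprocal hits;
    species-specific genes receive weaker one-sided distractor hits against
    paired genes of the other subgenome, so reciprocal-best-hit pairing
    recovers exactly the catalog's AGPs.
    """
    rng = _rng(config, "hits")
    agps = catalog_agps(catalog)
    cols = [
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ]

    def row(q, s, bitscore, evalue):
        aln = int(rng.integers(100, 500))
        return {
            "qseqid": q, "sseqid": s,
            "pident": float(np.round(rng.uniform(70, 99), 2)),
            "length": aln, "mismatch": int(rng.integers(0, 50)),
            "gapopen": int(rng.integers(0, 5)),
            "qstart": 1, "qend": aln, "sstart": 1, "send": aln,
            "evalue": evalue, "bitscore": bitscore,
        }

    rc_rows, cr_rows = [], []
    for gene_r, gene_c in agps.itertuples(index=False):
        score = float(np.round(rng.uniform(500, 900), 1))
        ev = 10.0 ** float(rng.uniform(-200, -50))
        rc_rows.append(row(gene_r, gene_c, score, ev))
        cr_rows.append(row(gene_c, gene_r, score, ev))

    # distractors: SSGs hit already-paired subjects with low scores
    paired_c = agps["gene_c"].to_numpy()
    paired_r = agps["gene_r"].to_numpy()
    ssg_r = catalog.index[
        (catalog["subgenome"] == "R") & (catalog["agp_partner"] == "")
    ]
    ssg_c = catalog.index[
        (catalog["subgenome"] == "C") & (catalog["agp_partner"] == "")
    ]
    if len(paired_c):
        for g in ssg_r:
            target = paired_c[int(rng.integers(len(paired_c)))]
            score = float(np.round(rng.uniform(60, 250), 1))
            ev = 10.0 ** float(rng.uniform(-30, -7))
            rc_rows.append(row(g, target, score, ev))
            cr_rows.append(row(target, g, score, ev))
    if len(paired_r):
        for g in ssg_c:
            target = paired_r[int(rng.integers(len(paired_r)))]
            score = float(np.round(rng.uniform(60, 250), 1))
            ev = 10.0 ** float(rng.uniform(-30, -7))
            cr_rows.append(row(g, target, score, ev))
            rc_rows.append(row(target, g, score, ev))

    hits_rc = pd.DataFrame(rc_rows, columns=cols)
    hits_cr = pd.DataFrame(cr_rows, columns=cols)
    return hits_rc, hits_cr


# ----------------------------------------------------------------- truth table


@dataclass
class TruthTables:
    """Machine-readable planted truth for downstream recovery scoring."""

    copy_number: pd.DataFrame
    cnv_events: list[dict] = field(default_factory=list)
    lost_alleles: list[dict] = field(default_factory=list)
    ase_patterns: dict[str, str] = field(default_factory=dict)
    growth_genes: list[dict] = field(default_factory=list)

    def cnv_gene_sample_pairs(self, catalog: pd.DataFrame) -> set[tuple[str, str]]:
        """Set of (gene_id, sample_id) with a planted copy-number change."""
        out = set()
        chrom = catalog["chrom"]
        pos = catalog["pos_index"]
        for ev in self.cnv_events:
            target = f"{ev['allele']}{ev['chromosome']:02d}"
            genes = catalog.index[
                (chrom == target) & (pos >= ev["start"]) & (pos < ev["end"])
            ]
            sample = f"{ev['variety']}-{ev['individual'] + 1}"
            out.update((g, sample) for g in genes)
        return out

    def to_json_dict(self) -> dict:
        return {
            "cnv_events": self.cnv_events,
            "lost_alleles": self.lost_alleles,
            "ase_patterns": self.ase_patterns,
            "growth_genes": self.growth_genes,
        }


def build_truth(
    config: SimulationConfig,
    catalog: pd.DataFrame,
    copy_number: pd.DataFrame,
) -> TruthTables:
    lost = [
        {"gene": g, "sample": s}
        for g, s in zip(*np.where(copy_number.to_numpy() == 0))
    ]
    # translate positional indices to labels
    lost_alleles = [
        {"gene": copy_number.index[rec["gene"]], "sample": copy_number.columns[rec["sample"]]}
        for rec in lost
    ]
    # a gene is a *lost allele* only if its genotype expected >= 1 copy
    expected = {}
    for v in config.varieties:
        g = v.genotype()
        for allele in ALLELES:
            expected[(v.name, allele)] = g.copies(allele)
    sub = catalog["subgenome"]
    lost_alleles = [
        rec
        for rec in lost_alleles
        if expected[(rec["sample"].rsplit("-", 1)[0], sub[rec["gene"]])] >= 1
    ]
    patterns = {ev.gene: ev.pattern for ev in config.ase_events}
    return TruthTables(
        copy_number=copy_number,
        cnv_events=[dataclasses.asdict(ev) for ev in config.cnv_events],
        lost_alleles=lost_alleles,
        ase_patterns=patterns,
        growth_genes=[dataclasses.asdict(g) for g in config.growth_genes],
    )


# ------------------------------------------------------------- full simulation


@dataclass
class SimulatedDataset:
    """Everything one simulation run produces."""

    config: SimulationConfig
    catalog: pd.DataFrame
    metadata: pd.DataFrame
    genomic_counts: pd.DataFrame
    mixed_control: pd.Series
    expression_counts: pd.DataFrame
    traits: pd.Series
    hits_rc: pd.DataFrame
    hits_cr: pd.DataFrame
    truth: TruthTables

    def write(self, out_dir) -> None:
        """Write all tables as TSV/JSON under `out_dir`."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.catalog.to_csv(out / "catalog.tsv", sep="\t")
        meta = self.metadata.copy()
        meta["body_weight"] = self.traits
        meta.to_csv(out / "metadata.tsv", sep="\t")
        genomic = self.genomic_counts.copy()
        genomic[MIXED_SAMPLE_ID] = self.mixed_control
        genomic.to_csv(out / "genomic_counts.tsv", sep="\t")
        self.expression_counts.to_csv(out / "expression_counts.tsv", sep="\t")
        self.hits_rc.to_csv(out / "hits_rc.tsv", sep="\t", index=False)
        self.hits_cr.to_csv(out / "hits_cr.tsv", sep="\t", index=False)
        self.truth.copy_number.to_csv(out / "truth_copy_number.tsv", sep="\t")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth.to_json_dict(), fh, indent=1, sort_keys=True)


def validate_ase_patterns(config: SimulationConfig, catalog: pd.DataFrame) -> None:
    """Check each ase_event's pattern label against its injected fold changes."""
    from polyhybrid.ase import DEFAULT_PATTERN_MAP, category_of

    by_agp: dict[str, dict[str, float]] = {}
    for ev in config.ase_events:
        if ev.gene not in catalog.index:
            raise ConfigError(f"ase_event references unknown gene {ev.gene!r}")
        allele = catalog.loc[ev.gene, "subgenome"]
        partner = catalog.loc[ev.gene, "agp_partner"]
        agp = ev.gene if allele == "R" else partner
        if not agp:
            continue  # SSG events carry no nine-pattern truth
        entry = by_agp.setdefault(agp, {"R": 1.0, "C": 1.0, "pattern": None})
        # direction convention: change from mito-R background to mito-C
        fold = ev.fold_change if ev.when_mito == "C" else 1.0 / ev.fold_change
        entry[allele] *= fold
        entry["pattern"] = ev.pattern
    inv = {v: k for k, v in DEFAULT_PATTERN_MAP.items()}
    for agp, entry in by_agp.items():
        dir_r = "up" if entry["R"] > 1 else ("down" if entry["R"] < 1 else "none")
        dir_c = "up" if entry["C"] > 1 else ("down" if entry["C"] < 1 else "none")
        want = category_of(dir_r, dir_c)
        labelled = category_of(*inv[entry["pattern"]])
        if want != labelled:
            raise ConfigError(
                f"ase pattern label {entry['pattern']} for AGP {agp} implies "
                f"category {labelled!r} but injected folds imply {want!r}"
            )


def simulate_all(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator; byte-identical outputs under identical config."""
    catalog = simulate_catalog(config)
    validate_ase_patterns(config, catalog)
    metadata = simulate_metadata(config)
    genomic, mixed, cn = simulate_genomic_counts(config, catalog)
    expression = simulate_expression_counts(config, catalog, cn, metadata)
    traits = simulate_traits(config, expression, catalog)
    hits_rc, hits_cr = simulate_hit_tables(config, catalog)
    truth = build_truth(config, catalog, cn)
    return SimulatedDataset(
        config=config,
        catalog=catalog,
        metadata=metadata,
        genomic_counts=genomic,
        mixed_control=mixed,
        expression_counts=expression,
        traits=traits,
        hits_rc=hits_rc,
        hits_cr=hits_cr,
        truth=truth,
    )
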