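"""Genotype definitions and simulation configuration.

A *genotype* fixes the nuclear subgenome copy numbers (r_copies, c_copies),
the expected allelic read fraction B for each allele, and the mitochondrial
origin.  The six study genotypes are registered in :data:`GENOTYPES`; custom
varieties may declare any copy combination in {0, 1, 2} per subgenome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import yaml

ALLELES = ("R", "C")

#: Allelic read fraction of either allele in the 1:1 in-silico F1 mixture.
MIXTURE_RATIO = 0.5


class ConfigError(ValueError):
    """Raised for invalid configuration values."""


@dataclass(frozen=True)
class GenotypeSpec:
    """Nuclear dosage and mitochondrial origin of one hybrid variety."""

    name: str
    r_copies: int
    c_copies: int
    mito_origin: str

    def __post_init__(self) -> None:
        if self.r_copies not in (0, 1, 2) or self.c_copies not in (0, 1, 2):
            raise ConfigError(
                f"{self.name}: subgenome copy numbers must be in {{0, 1, 2}}"
            )
        if self.r_copies + self.c_copies == 0:
            raise ConfigError(f"{self.name}: at least one subgenome copy required")
        if self.mito_origin not in ALLELES:
            raise ConfigError(f"{self.name}: mito_origin must be 'R' or 'C'")

    @property
    def ploidy(self) -> int:
        return self.r_copies + self.c_copies

    def copies(self, allele: str) -> int:
        """Baseline copy number of one allele (no CNV events)."""
        _check_allele(allele)
        return self.r_copies if allele == "R" else self.c_copies

    def allelic_ratio(self, allele: str) -> float:
        """Expected read fraction B of `allele` in this genotype."""
        _check_allele(allele)
        return self.copies(allele) / self.ploidy


def _check_allele(allele: str) -> None:
    if allele not in ALLELES:
        raise ConfigError(f"allele must be one of {ALLELES}, got {allele!r}")


#: The six study genotypes.  Names follow maternal-first convention; the
#: mitochondrial genome is inherited from the maternal lineage (the two
#: triploids bred from the allotetraploid dam carry the goldfish-derived
#: mitochondrion of that dam).
GENOTYPES: dict[str, GenotypeSpec] = {
    "2nRC": GenotypeSpec("2nRC", 1, 1, "R"),
    "2nCR": GenotypeSpec("2nCR", 1, 1, "C"),
    "3nR2C": GenotypeSpec("3nR2C", 2, 1, "R"),
    "3nCR2": GenotypeSpec("3nCR2", 2, 1, "R"),
    "3nRC2": GenotypeSpec("3nRC2", 1, 2, "C"),
    "3nC2R": GenotypeSpec("3nC2R", 1, 2, "R"),
}


@dataclass(frozen=True)
class VarietySpec:
    """A simulated cohort: one genotype with `n_individuals` members."""

    name: str
    r_copies: int
    c_copies: int
    mito_origin: str
    n_individuals: int

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ConfigError(f"{self.name}: n_individuals must be >= 1")
        # construction validates copy numbers / mito origin
        self.genotype()

    def genotype(self) -> GenotypeSpec:
        return GenotypeSpec(self.name, self.r_copies, self.c_copies, self.mito_origin)


@dataclass(frozen=True)
class CnvEvent:
    """A planted copy-number change.

    Applies `copy_delta` to the `allele` genes with positional index in
    [start, end) on `chromosome` (1-based) for one individual of `variety`
    (`individual` is a 0-based index into the variety's cohort).
    """

    variety: str
    individual: int
    chromosome: int
    start: int
    end: int
    allele: str
    copy_delta: int

    def __post_init__(self) -> None:
        _check_allele(self.allele)
        if self.end <= self.start or self.start < 0:
            raise ConfigError(f"invalid gene range [{self.start}, {self.end})")
        if not -4 <= self.copy_delta <= 2:
            raise ConfigError("copy_delta out of supported range [-4, 2]")


@dataclass(frozen=True)
class AseEvent:
    """A planted mito-conditional expression change on one allele gene.

    Expression of `gene` is multiplied by `fold_change` in every sample whose
    mitochondrial origin equals `when_mito`.  `pattern` is the truth label
    (one of the nine-pattern numerals) for the AGP the gene belongs to.
    """

    gene: str
    fold_change: float
    when_mito: str
    pattern: str

    def __post_init__(self) -> None:
        _check_allele(self.when_mito)
        if self.fold_change <= 0:
            raise ConfigError("fold_change must be positive")


@dataclass(frozen=True)
class LatentFactor:
    """A shared trans-acting expression factor.

    Each member gene's expression is multiplied by
    ``exp(scale * (loading * f_s + sqrt(1 - loading^2) * eps_gs))`` where
    `f_s` is a per-sample standard-normal factor value and `eps_gs` is
    gene-sample noise, so on the log scale pairwise gene correlation tracks
    loading^2.  loading = 0 yields the matched no-sharing null.
    """

    name: str
    genes: tuple[str, ...]
    loading: float
    scale: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        if not 0.0 <= self.loading <= 1.0:
            raise ConfigError("loading must lie in [0, 1]")
        if self.scale <= 0:
            raise ConfigError("scale must be positive")
        if len(self.genes) < 1:
            raise ConfigError("a latent factor needs at least one gene")


@dataclass(frozen=True)
class GrowthGene:
    """A planted trait-driving gene: trait += effect_size * sign * z(expr)."""

    gene: str
    sign: int
    effect_size: float

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise ConfigError("sign must be -1 or +1")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")


def _default_varieties() -> tuple[VarietySpec, ...]:
    return tuple(
        VarietySpec(g.name, g.r_copies, g.c_copies, g.mito_origin, 3)
        for g in GENOTYPES.values()
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of the synthetic dataset.

    Counts are negative-binomial with variance mu + mu^2 / nb_dispersion.
    Per-sample depth scalars are drawn uniformly within +/- depth_jitter of
    sequencing_depth.  Baseline expression per gene is log-normal with
    natural-log parameters (baseline_log_mean, baseline_log_sd).
    """

    seed: int = 0
    n_chromosomes: int = 2
    genes_per_chromosome: int = 50
    agp_fraction: float = 1.0
    gene_length_range: tuple[int, int] = (500, 3000)
    varieties: tuple[VarietySpec, ...] = field(default_factory=_default_varieties)
    sequencing_depth: float = 1e6
    nb_dispersion: float = 100.0
    depth_jitter: float = 0.2
    baseline_log_mean: float = 1.0
    baseline_log_sd: float = 1.0
    cnv_events: tuple[CnvEvent, ...] = ()
    ase_events: tuple[AseEvent, ...] = ()
    latent_factors: tuple[LatentFactor, ...] = ()
    growth_genes: tuple[GrowthGene, ...] = ()
    trait_baseline: float = 500.0
    trait_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.genes_per_chromosome < 1:
            raise ConfigError("chromosome and gene counts must be positive")
        if not 0.0 <= self.agp_fraction <= 1.0:
            raise ConfigError("agp_fraction must lie in [0, 1]")
        lo, hi = self.gene_length_range
        if lo < 1 or hi < lo:
            raise ConfigError("gene_length_range must satisfy 1 <= lo <= hi")
        if self.sequencing_depth <= 0:
            raise ConfigError("sequencing_depth must be positive")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if not 0.0 <= self.depth_jitter < 1.0:
            raise ConfigError("depth_jitter must lie in [0, 1)")
        if self.trait_noise_sd < 0:
            raise ConfigError("trait_noise_sd must be >= 0")
        if not self.varieties:
            raise ConfigError("at least one variety required")
        names = [v.name for v in self.varieties]
        if len(names) != len(set(names)):
            raise ConfigError("variety names must be unique")
        by_name = {v.name: v for v in self.varieties}
        for ev in self.cnv_events:
            if ev.variety not in by_name:
                raise ConfigError(f"cnv_event references unknown variety {ev.variety!r}")
            if not 0 <= ev.individual < by_name[ev.variety].n_individuals:
                raise ConfigError(
                    f"cnv_event individual {ev.individual} out of range for {ev.variety}"
                )
            if not 1 <= ev.chromosome <= self.n_chromosomes:
                raise ConfigError(f"cnv_event chromosome {ev.chromosome} out of range")
            if ev.end > self.genes_per_chromosome:
                raise ConfigError("cnv_event gene range exceeds chromosome length")

    def variety(self, name: str) -> VarietySpec:
        for v in self.varieties:
            if v.name == name:
                return v
        raise ConfigError(f"unknown variety {name!r}")

    @property
    def n_samples(self) -> int:
        return sum(v.n_individuals for v in self.varieties)

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        if "gene_length_range" in kwargs:
            kwargs["gene_length_range"] = tuple(kwargs["gene_length_range"])
        if "varieties" in kwargs:
            kwargs["varieties"] = tuple(
                v if isinstance(v, VarietySpec) else VarietySpec(**v)
                for v in kwargs["varieties"]
            )
        for key, klass in (
            ("cnv_events", CnvEvent),
            ("ase_events", AseEvent),
            ("latent_factors", LatentFactor),
            ("growth_genes", GrowthGene),
        ):
            if key in kwargs:
                kwargs[key] = tuple(
                    v if isinstance(v, klass) else klass(**v) for v in kwargs[key]
                )
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)


def sample_ids(varieties: Sequence[VarietySpec]) -> list[str]:
    """Deterministic sample identifiers: ``<variety>-<1-based index>``."""
    out = []
    for v in varieties:
        out.extend(f"{v.name}-{i + 1}" for i in range(v.n_individuals))
    return out
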