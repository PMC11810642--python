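"""End-to-end orchestration: simulate -> quantify -> orthology -> cnv ->
ase -> growth -> allelic, with a run manifest and a recovery report.

The pipeline consumes either a `simulation` block (synthetic data with
planted truth, in which case the report includes truth-recovery metrics) or
an `inputs` block of file paths.  All stage parameters have the module
defaults and can be overridden per stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import polyhybrid
from polyhybrid import allelic as allelic_mod
from polyhybrid import ase as ase_mod
from polyhybrid import cnv as cnv_mod
from polyhybrid import growth as growth_mod
from polyhybrid import orthology as orth_mod
from polyhybrid import quantify
from polyhybrid.config import ConfigError, SimulationConfig
from polyhybrid.simulate import MIXED_SAMPLE_ID, SimulatedDataset, simulate_all

_TOP_KEYS = {
    "simulation", "inputs", "stages", "out_dir",
    "orthology", "cnv", "ase", "growth", "allelic",
}
_ALL_STAGES = ("simulate", "quantify", "orthology", "cnv", "ase", "growth", "allelic")
_REQUIRED_INPUTS = ("catalog", "genomic_counts", "expression_counts", "metadata")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineResult:
    report: dict
    manifest: dict
    dataset: SimulatedDataset | None = None
    tables: dict = field(default_factory=dict)


def _digest(obj) -> str:
    if isinstance(obj, pd.DataFrame) or isinstance(obj, pd.Series):
        payload = obj.to_csv().encode()
    else:
        payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _load_inputs(inputs: dict) -> SimulatedDataset | dict:
    missing = [k for k in _REQUIRED_INPUTS if k not in inputs]
    if missing:
        raise ConfigError(
            f"simulation disabled and required input(s) missing: {missing}"
        )
    catalog = pd.read_csv(inputs["catalog"], sep="\t", index_col=0).fillna({"agp_partner": ""})
    genomic = pd.read_csv(inputs["genomic_counts"], sep="\t", index_col=0)
    expression = pd.read_csv(inputs["expression_counts"], sep="\t", index_col=0)
    metadata = pd.read_csv(inputs["metadata"], sep="\t", index_col=0)
    mixed = None
    if MIXED_SAMPLE_ID in genomic.columns:
        mixed = genomic[MIXED_SAMPLE_ID]
        genomic = genomic.drop(columns=[MIXED_SAMPLE_ID])
    hits_rc = hits_cr = None
    if "hits_rc" in inputs and "hits_cr" in inputs:
        hits_rc = orth_mod.read_hit_table(inputs["hits_rc"])
        hits_cr = orth_mod.read_hit_table(inputs["hits_cr"])
    return {
        "catalog": catalog,
        "metadata": metadata,
        "genomic_counts": genomic,
        "mixed_control": mixed,
        "expression_counts": expression,
        "hits_rc": hits_rc,
        "hits_cr": hits_cr,
    }


def run_pipeline(config: dict) -> PipelineResult:
    """Execute the pipeline described by `config`; see module docstring."""
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
    stages = tuple(config.get("stages", _ALL_STAGES))
    bad = set(stages) - set(_ALL_STAGES)
    if bad:
        raise ConfigError(f"unknown stages: {sorted(bad)}")

    report: dict = {"stages": {}}
    tables: dict = {}
    dataset = None
    truth = None

    # ------------------------------------------------------------- simulate
    if "simulation" in config:
        sim_cfg = config["simulation"]
        if not isinstance(sim_cfg, SimulationConfig):
            sim_cfg = SimulationConfig.from_dict(sim_cfg)
        try:
            dataset = simulate_all(sim_cfg)
        except Exception as exc:  # pragma: no cover - defensive
            raise StageError(f"stage 'simulate' failed: {exc}") from exc
        truth = dataset.truth
        data = {
            "catalog": dataset.catalog,
            "metadata": dataset.metadata.assign(body_weight=dataset.traits),
            "genomic_counts": dataset.genomic_counts,
            "mixed_control": dataset.mixed_control,
            "expression_counts": dataset.expression_counts,
            "hits_rc": dataset.hits_rc,
            "hits_cr": dataset.hits_cr,
        }
        report["stages"]["simulate"] = {
            "n_genes": len(dataset.catalog),
            "n_samples": dataset.metadata.shape[0],
            "n_cnv_events": len(sim_cfg.cnv_events),
            "n_ase_events": len(sim_cfg.ase_events),
            "n_growth_genes": len(sim_cfg.growth_genes),
        }
    else:
        data = _load_inputs(config.get("inputs", {}))

    catalog = data["catalog"]
    metadata = data["metadata"]

    # ------------------------------------------------------------- quantify
    lengths = catalog["length_bp"]
    gpm_n = quantify.gpm(data["genomic_counts"], lengths)
    tpm_n = quantify.tpm(data["expression_counts"], lengths)
    mixed_gpm = None
    if data["mixed_control"] is not None:
        mixed_gpm = quantify.gpm(data["mixed_control"].to_frame(), lengths).values.iloc[:, 0]
    expressed = quantify.filter_expressed(data["expression_counts"], tpm_n.values)
    genotype_rows = {}
    for sample in gpm_n.values.columns:
        try:
            dosage = quantify.infer_subgenome_ratio(gpm_n.values[sample], catalog)
        except ValueError:
            dosage = "undetermined"
        row = {"dosage_class": dosage}
        if {"mito_reads_r", "mito_reads_c"} <= set(metadata.columns):
            row["mito_origin"] = quantify.infer_mito_origin(
                metadata.loc[sample, "mito_reads_r"],
                metadata.loc[sample, "mito_reads_c"],
            )
        genotype_rows[sample] = row
    tables["tpm"] = tpm_n.values
    tables["gpm"] = gpm_n.values
    tables["expressed_mask"] = expressed
    report["stages"]["quantify"] = {
        "n_expressed": int(expressed.sum()),
        "flagged_samples": gpm_n.flagged_samples + tpm_n.flagged_samples,
        "genotype_report": genotype_rows,
    }
    if "r_copies" in metadata.columns:
        expected = {
            s: f"{'2:1' if r > c else ('1:2' if c > r else '1:1')}"
            for s, r, c in zip(
                metadata.index, metadata["r_copies"], metadata["c_copies"]
            )
        }
        agree = sum(
            genotype_rows[s]["dosage_class"] == expected[s] for s in genotype_rows
        )
        report["stages"]["quantify"]["dosage_class_accuracy"] = agree / len(
            genotype_rows
        )

    # ------------------------------------------------------------ orthology
    if "orthology" in stages and data["hits_rc"] is not None:
        params = config.get("orthology", {})
        partition = orth_mod.reciprocal_best_pairs(
            data["hits_rc"], data["hits_cr"], catalog=catalog, **params
        )
        tables["agps"] = partition.agps
        entry = {
            "n_agps": partition.n_agps,
            "n_ssg_r": len(partition.ssg_r),
            "n_ssg_c": len(partition.ssg_c),
        }
        if "agp_partner" in catalog.columns:
            true_pairs = {
                (g, p)
                for g, p in catalog["agp_partner"].items()
                if p and catalog.loc[g, "subgenome"] == "R"
            }
            found = set(map(tuple, partition.agps.to_numpy()))
            tp = len(true_pairs & found)
            entry["agp_precision"] = tp / len(found) if found else float("nan")
            entry["agp_recall"] = tp / len(true_pairs) if true_pairs else float("nan")
        report["stages"]["orthology"] = entry
    else:
        tables["agps"] = _catalog_agps(catalog)

    agps = tables["agps"]

    # ------------------------------------------------------------------ cnv
    if "cnv" in stages:
        if mixed_gpm is None:
            raise StageError(
                "stage 'cnv' failed: no mixed_control column in genomic counts"
            )
        params = dict(config.get("cnv", {}))
        min_run = params.pop("min_run", 10)
        calls = cnv_mod.call_gene_cnvs(
            gpm_n.values, mixed_gpm, metadata, catalog, **params
        )
        allelic_calls = cnv_mod.call_allelic_cnvs(
            gpm_n.values, mixed_gpm, agps, metadata
        )
        losses = cnv_mod.detect_allele_loss(
            data["genomic_counts"], gpm_n.values, metadata, catalog
        )
        segments, short_runs = cnv_mod.segment_cnv(calls, catalog, min_run=min_run)
        summary = cnv_mod.cnv_subgenome_summary(calls, catalog)
        tables.update(
            cnv_calls=calls, allelic_calls=allelic_calls, allele_losses=losses,
            cnv_segments=segments, cnv_summary=summary,
        )
        entry = {
            "n_gene_calls": int((calls["call"] != "none").sum()),
            "n_allelic_calls": int(
                allelic_calls["call"].isin(
                    ["R_gain_or_C_loss", "C_gain_or_R_loss"]
                ).sum()
            ),
            "n_allele_losses": int(losses.to_numpy().sum()),
            "n_segments": len(segments),
            "n_short_runs": len(short_runs),
        }
        if truth is not None:
            entry["recovery"] = _cnv_recovery(calls, losses, truth, catalog)
        report["stages"]["cnv"] = entry

    # ------------------------------------------------------------------ ase
    if "ase" in stages:
        report["stages"]["ase"] = _ase_stage(
            config.get("ase", {}), data, metadata, agps, tables, truth
        )

    # ---------------------------------------------------------------- growth
    if "growth" in stages:
        report["stages"]["growth"] = _growth_stage(
            config.get("growth", {}), catalog, metadata, tables, truth
        )

    # --------------------------------------------------------------- allelic
    if "allelic" in stages:
        report["stages"]["allelic"] = _allelic_stage(
            config.get("allelic", {}), metadata, agps, tables
        )

    manifest = {
        "polyhybrid_version": polyhybrid.__version__,
        "stages": list(stages),
        "seed": (
            config["simulation"].seed
            if isinstance(config.get("simulation"), SimulationConfig)
            else config.get("simulation", {}).get("seed")
            if "simulation" in config
            else None
        ),
        "config_digest": _digest(_serializable_config(config)),
        "table_digests": {
            k: _digest(v)
            for k, v in tables.items()
            if isinstance(v, (pd.DataFrame, pd.Series))
        },
    }
    result = PipelineResult(
        report=report, manifest=manifest, dataset=dataset, tables=tables
    )
    if "out_dir" in config:
        _write_outputs(Path(config["out_dir"]), result)
    return result


def _serializable_config(config: dict) -> dict:
    out = {}
    for k, v in config.items():
        if isinstance(v, SimulationConfig):
            out[k] = dataclasses.asdict(v)
        else:
            out[k] = v
    return out


def _catalog_agps(catalog: pd.DataFrame) -> pd.DataFrame:
    r_side = catalog[(catalog["subgenome"] == "R") & (catalog["agp_partner"] != "")]
    return pd.DataFrame(
        {"gene_r": r_side.index, "gene_c": r_side["agp_partner"].to_numpy()}
    ).reset_index(drop=True)


def _cnv_recovery(calls, losses, truth, catalog) -> dict:
    true_pairs = truth.cnv_gene_sample_pairs(catalog)
    called = calls[calls["call"] != "none"]
    called_pairs = set(zip(called["gene"], called["sample"]))
    tp = len(called_pairs & true_pairs)
    out = {
        "cnv_precision": tp / len(called_pairs) if called_pairs else float("nan"),
        "cnv_recall": tp / len(true_pairs) if true_pairs else float("nan"),
    }
    true_losses = {(r["gene"], r["sample"]) for r in truth.lost_alleles}
    arr = losses.to_numpy()
    found = {
        (losses.index[i], losses.columns[j]) for i, j in zip(*np.where(arr))
    }
    tp = len(found & true_losses)
    out["loss_precision"] = tp / len(found) if found else float("nan")
    out["loss_recall"] = tp / len(true_losses) if true_losses else float("nan")
    return out


def _ase_stage(params, data, metadata, agps, tables, truth) -> dict:
    group_ploidy = params.get("within", "diploid")
    if group_ploidy == "diploid":
        sel = (metadata["r_copies"] == 1) & (metadata["c_copies"] == 1)
    else:
        sel = metadata["r_copies"] + metadata["c_copies"] == 3
    meta = metadata[sel]
    group_a = meta.index[meta["mito_origin"] == "R"]
    group_b = meta.index[meta["mito_origin"] == "C"]
    if len(group_a) < 3 or len(group_b) < 3:
        return {"skipped": f"need >=3 samples per mito background, have "
                           f"{len(group_a)} vs {len(group_b)}"}
    counts = data["expression_counts"]
    expressed = tables["expressed_mask"]
    counts = counts[expressed]
    de_kwargs = {
        k: v for k, v in params.items() if k not in {"within"}
    }
    de = ase_mod.de_test(counts[group_a], counts[group_b], **de_kwargs)
    patterns = ase_mod.classify_nine_patterns(de, de, agps)
    tables["de"] = de
    tables["patterns"] = patterns
    entry = {
        "n_tested": len(de),
        "n_de": int((de["direction"] != "none").sum()),
        "category_counts": patterns["category"].value_counts().to_dict(),
    }
    # silencing across the two mito backgrounds when exactly two varieties
    varieties = sorted(meta["variety"].unique())
    if len(varieties) == 2:
        sil = ase_mod.detect_allele_silencing(
            tables["tpm"], data["expression_counts"], metadata,
            varieties[0], varieties[1],
        )
        tables["silencing"] = sil
        entry["n_silenced"] = len(sil)
    if truth is not None and truth.ase_patterns:
        cat = ase_mod.CATEGORY_OF_PATTERN
        sub = {}
        hits = total = 0
        for gene, pattern in truth.ase_patterns.items():
            agp = gene if gene in patterns.index else None
            if agp is None:
                row = agps[agps["gene_c"] == gene]
                agp = row["gene_r"].iloc[0] if len(row) else None
            if agp is None or agp not in patterns.index:
                continue
            total += 1
            hits += patterns.loc[agp, "category"] == cat[pattern]
        sub["pattern_category_accuracy"] = hits / total if total else float("nan")
        entry["recovery"] = sub
    return entry


def _growth_stage(params, catalog, metadata, tables, truth) -> dict:
    if "body_weight" not in metadata.columns:
        return {"skipped": "no body_weight column in metadata"}
    expr = growth_mod.log_expression(tables["tpm"][tables["expressed_mask"]])
    expr = expr[expr.std(axis=1) > 0]
    trait = metadata["body_weight"]
    power = params.get("power") or growth_mod.soft_power_select(expr)
    adj = growth_mod.adjacency(expr, power)
    tom_m = growth_mod.tom(adj)
    labels = growth_mod.detect_modules(
        tom_m,
        expr,
        min_module_size=params.get("min_module_size", 30),
        cut_height=params.get("cut_height", 0.25),
        merge_corr=params.get("merge_corr", 0.75),
    )
    screen = growth_mod.gene_trait_stats(expr, trait, labels)
    hubs = growth_mod.filter_hub_genes(
        screen, mm_min=params.get("mm_min", 0.8), gs_min=params.get("gs_min", 0.3)
    )
    div = growth_mod.diversity(metadata, tables["tpm"], hubs)
    tables["growth_stats"] = screen.stats
    tables["hub_genes"] = list(hubs)
    tables["diversity"] = div
    entry = {
        "power": int(power),
        "n_modules": int(len(set(labels) - {0})),
        "n_hub_genes": int(len(hubs)),
    }
    if truth is not None and truth.growth_genes:
        planted = {g["gene"] for g in truth.growth_genes}
        found = set(hubs)
        tp = len(planted & found)
        entry["recovery"] = {
            "hub_precision": tp / len(found) if found else float("nan"),
            "hub_recall": tp / len(planted) if planted else float("nan"),
        }
    return entry


def _allelic_stage(params, metadata, agps, tables) -> dict:
    expr = growth_mod.log_expression(tables["tpm"])
    records = allelic_mod.agp_pcc(expr, agps)
    background = allelic_mod.make_background(
        agps, seed=params.get("background_seed", 7)
    )
    bg_records = allelic_mod.agp_pcc(expr, background.pairs)
    t, p, df = allelic_mod.compare_pcc_distributions(
        records["pcc"], bg_records["pcc"]
    )
    entry = {
        "mean_agp_pcc": float(np.nanmean(records["pcc"])),
        "mean_background_pcc": float(np.nanmean(bg_records["pcc"])),
        "agp_vs_background": {"t": t, "p": p, "df": df},
    }
    strong_sets = {}
    per_variety = {}
    for variety, grp in metadata.groupby("variety"):
        if len(grp) < allelic_mod.MIN_COHORT:
            continue
        rec = allelic_mod.agp_pcc(expr, agps, metadata, cohort=variety)
        per_variety[variety] = rec
        strong_sets[variety] = set(rec.index[rec["pcc"] > 0.5])
    if strong_sets:
        entry["shared_strong"] = allelic_mod.shared_strong_pairs(strong_sets)
    tables["agp_pcc"] = records
    tables["agp_pcc_background"] = bg_records
    tables["agp_pcc_by_variety"] = per_variety
    return entry


def _write_outputs(out: Path, result: PipelineResult) -> None:
    out.mkdir(parents=True, exist_ok=True)
    if result.dataset is not None:
        result.dataset.write(out / "simulated")
    for name in (
        "tpm", "gpm", "cnv_calls", "allelic_calls", "cnv_summary",
        "de", "patterns", "growth_stats", "diversity", "agp_pcc",
        "agp_pcc_background",
    ):
        obj = result.tables.get(name)
        if isinstance(obj, (pd.DataFrame, pd.Series)):
            obj.to_csv(out / f"{name}.tsv", sep="\t")
    with open(out / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=1, sort_keys=True, default=str)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=1, sort_keys=True, default=str)
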