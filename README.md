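# polyhybrid

Subgenome-aware analysis of gene-level count data from intergeneric hybrid
fish (goldfish-derived subgenome **R** × common-carp-derived subgenome **C**):
CNV and allele-loss calling against an in-silico F1 mixture control,
nine-pattern allele-specific expression (ASE) classification under reciprocal
mitochondrial backgrounds, a WGCNA-style coexpression screen for
growth-regulating genes, and allelic-synchrony correlation analysis — plus a
synthetic-data generator with planted truth so the entire pipeline is
testable offline.

## Modules

| module | purpose |
| --- | --- |
| `polyhybrid.simulate` | synthetic catalog, genomic/transcriptomic NB counts, mixture control, planted CNVs / allele losses / ASE patterns / latent coexpression factors / trait effects, truth tables |
| `polyhybrid.quantify` | GPM/TPM normalization (columns sum to 10⁶), expression filter (reads < 10 AND TPM < 1 in every sample), subgenome dosage class and mito-origin verification |
| `polyhybrid.orthology` | allelic gene pairs (AGPs) by reciprocal best hit from 12-column hit tables; species-specific gene (SSG) partition |
| `polyhybrid.cnv` | per-gene calls via log₂(GPM_hybrid/GPM_mixed) against a 2-fold band around the genotype-expected dosage log₂(B/C); allelic ratio-of-ratios calls; allele-loss detection; contiguous-gene segments; subgenome summaries |
| `polyhybrid.ase` | in-repo NB Wald DE test (size factors, moment dispersion, BH; gates FC > 3, P < 0.001, Padj < 0.001) and the 3×3 nine-pattern grid; allele-silencing detection |
| `polyhybrid.growth` | soft-threshold power selection, adjacency, topological overlap, module detection (static cut + eigengene merge + kME rescue), module eigengenes, GS/MM hub filtering, PCC classes, diversity metrics |
| `polyhybrid.allelic` | per-AGP allele-R vs allele-C PCC, shuffled non-AGP background, Fisher-z t-tests between cohorts, shared strong-pair intersections |
| `polyhybrid.pipeline` | end-to-end orchestration with manifest and truth-recovery report |
| `polyhybrid.worked_examples` | registered arithmetic checks behind `polyhybrid check-paper` |

## CLI

```sh
polyhybrid simulate  --config sim.yaml --out data/          # synthetic data + truth
polyhybrid quantify  --counts counts.tsv --catalog catalog.tsv --method tpm
polyhybrid genotype  --genomic genomic.tsv --catalog catalog.tsv --metadata meta.tsv
polyhybrid orthology --hits-rc rc.tsv --hits-cr cr.tsv --catalog catalog.tsv
polyhybrid cnv       --genomic genomic.tsv --catalog catalog.tsv --metadata meta.tsv
polyhybrid ase       --expr expr.tsv --catalog catalog.tsv --metadata meta.tsv --within diploid
polyhybrid growth    --expr tpm.tsv --metadata meta.tsv --mm 0.8 --gs 0.3
polyhybrid allelic   --expr tpm.tsv --agps agps.tsv --metadata meta.tsv
polyhybrid run       --config pipeline.yaml                 # full pipeline
polyhybrid check-paper                                      # worked-example table
```

A pipeline YAML contains either a `simulation:` block (the
`SimulationConfig` fields; see `polyhybrid/config.py`) or an `inputs:` block
of TSV paths, plus optional per-stage parameter overrides
(`cnv: {min_run: 10}`, `growth: {mm_min: 0.8, gs_min: 0.3}`, …). All tabular
I/O is TSV; truth tables are JSON. Identical config + seed ⇒ byte-identical
outputs.

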