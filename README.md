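# lncseed

A variant-to-function annotation pipeline for disease-associated long
non-coding RNAs (lncRNAs), exercisable end to end on synthetic data with
planted ground truth.

Given genomic variants and a gene annotation, the pipeline

1. **identifies hit lncRNAs** by interval intersection under three modes
   (gene body, exon union, gene body + 5 kb strand-aware promoter), with
   cross-mode containment reporting and independent CNV validation;
2. **characterizes expression**: tissue-specificity index τ, brain
   expression index (median brain / median all-tissue expression),
   Wilcoxon rank-sum hit-vs-background comparisons, and a fold-change +
   rank-sum differential-expression caller;
3. **infers three classes of functional neighbor genes** per hit lncRNA —
   genomic (±50 kb flank), ceRNA (≥2 shared miRNA regulators with a
   hypergeometric test and joint BH FDR), and co-expression (unsigned
   WGCNA-style weighted network per tissue: top-75% MAD filter,
   hierarchical outlier removal, scale-free soft-threshold selection,
   |Pearson r|^β adjacency thresholding);
4. **runs over-representation analysis** (hypergeometric + BH FDR) of each
   neighbor category against GMT collections, including a per-brain-region
   comparison matrix and a known-disease-gene proportion test;
5. **intersects categories** into a high-reliability neighbor set
   (genes in ≥2 of 3 categories, pooled or per-lncRNA);
6. **ranks candidate drugs** by one-sided Fisher enrichment of each drug's
   induced pathway set within the altered pathway list (ORA FDR ≤ 0.5).

The `synthetic_data` module generates every input format the pipeline
consumes (GTF, BED, expression TSV, miRNA–target TSV, GMT collections,
known-gene list) with planted variant hits, co-expression modules,
ceRNA pairs, enriched pathways and effective drugs, so each stage's
recovery can be asserted against ground truth.

## CLI

```bash
# generate a synthetic dataset (deterministic per seed)
lncseed simulate --seed 1 --outdir data/

# individual stages
lncseed identify --variants data/variants.bed --gtf data/annotation.gtf --mode gene --out hits.tsv
lncseed metrics  --expr data/expression.tsv --tissues data/samples.tsv --hits hits.tsv
lncseed coexpr   --expr data/expression.tsv --tissues data/samples.tsv --hits hits.tsv \
                 --gtf data/annotation.gtf --tissue cortex --adj-min 0.1 --out coexpr.tsv
lncseed cerna    --interactions data/interactions.tsv --hits hits.tsv --gtf data/annotation.gtf \
                 --min-shared 2 --alpha 0.01 --out cerna.tsv
lncseed enrich   --genes genes.txt --gmt data/pathways.gmt --universe coding.txt --out ora.tsv
lncseed drugs    --altered altered.txt --drug-gmt data/drugs.gmt --background kegg_ids.txt --out drugs.tsv

# or the whole pipeline from a YAML config
lncseed run --config run.yaml --outdir out/
```

`run.yaml` needs an `inputs:` block with `annotation`, `variants`,
`expression`, `samples`, `interactions`, `pathways` and `drugs` paths;
any keyword of `lncseed.integration.run_pipeline` (e.g. `mode`,
`adjacency_min`, `cerna_alpha`, `altered_fdr_max`, `hr_mode`) can be set
at the top level.

## Layout

| module | contents |
| --- | --- |
| `lncseed.synthetic_data` | config, ground truth, all input generators |
| `lncseed.variant_mapping` | hit identification, containment, CNV validation, genomic neighbors |
| `lncseed.expression_metrics` | τ, brain index, rank-sum comparisons, DE caller |
| `lncseed.coexpression` | MAD filter, outlier removal, soft threshold, adjacency, neighbors |
| `lncseed.cerna` | shared-miRNA hypergeometric test, ceRNA pair calling, null calibration |
| `lncseed.enrichment` | ORA, BH FDR, region comparison, known-gene proportions |
| `lncseed.drug_repositioning` | altered-pathway selection, per-drug Fisher ranking |
| `lncseed.integration` | high-reliability intersection, report assembly, `run_pipeline` |
| `lncseed.models` / `lncseed.io` | domain types; GTF/BED/GMT/TSV readers and writers |
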