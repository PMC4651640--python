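# intrameth

Gene-level analysis of Illumina 450K-style DNA methylation for
discriminating two cell states — e.g. embryonic stem cells (ESC) versus
induced pluripotent stem cells (iPSC) — from intragene methylation
profiles, with transparent, accuracy-driven feature selection and
gene-set enrichment of the best-discriminating genes.

Site-level beta values are noisy, extremely high-dimensional (hundreds
of thousands of CpG probes against a few dozen samples) and hard to
interpret one probe at a time. This package instead summarizes each
gene's ordered probe profile β₁,…,β_n(g) (probes sorted by chromosomal
coordinate, genes with ≥ 5 probes) by five scalar descriptors:

- **MEAN(g)** = (1/n) Σ βᵢ — overall methylation level;
- **VAR(g)** = (1/(n−1)) Σ (βᵢ − MEAN)² — within-gene spread;
- **DERIV(g)** = (1/(n−1)) Σ |βᵢ − βᵢ₊₁| — probe-to-probe roughness;
- **DEV(g)** = Σ |chord(coordᵢ) − βᵢ| — deviation from the straight
  line through the first and last probe (a linearity defect);
- **ASYMM(g)** = Σ(βᵢ−βᵢ₊₁)·1[βᵢ>βᵢ₊₁] / Σ|βᵢ−βᵢ₊₁| — the fraction of
  total variation contributed by decreasing steps, in [0, 1].

A per-sample Kendall-concordance diagnostic (measures as judges
ranking the genes) verifies the five descriptors are not redundant.
On top of the resulting samples × (gene, measure) table the package
provides:

- **Classification** with L1-regularized logistic regression (inner-loop
  regularization tuning) and random forests (1000 trees of depth 3)
  under nested 5-fold stratified cross-validation, reporting type I
  (induced-class called base-class), type II (base called induced) and
  total misclassification errors as mean ± sd over folds.
- **Recursive best-feature elimination (RBFE):** the model's *best*
  feature batch is repeatedly moved out of the pool while the errors of
  classifiers on the accumulated, current-batch and remaining features
  are tracked — showing whether the top genes are irreplaceable or one
  of many equally discriminating subsets.
- **Decision-stump ranking:** each gene scored by the cross-validated
  error of a depth-1 tree on that single feature; genes with mean error
  strictly below 10% are retained.
- **Progressive enrichment:** every prefix of the retained ranking is
  tested for over-representation of a user-supplied gene set (GMT) by
  the upper-tail hypergeometric probability, with rejection at p < 0.01.

A synthetic-data module generates 450K-shaped inputs (probe manifest
with coordinates, beta matrix for 31 + 35 samples, sample sheet, GMT
collections) with class effects planted in any chosen measure, so the
whole pipeline runs and is testable without any download.

## Worked example

```python
import numpy as np
from intrameth import (
    EffectSpec, generate_manifest, generate_betas, generate_gene_sets,
    compute_measure_matrix, nested_cv_evaluate, stump_rank,
    progressive_enrichment,
)
from intrameth.classify import ModelSpec
from intrameth.io import Dataset

man = generate_manifest(n_genes=500, probes_per_gene=(5, 20), seed=7)
genes = sorted(set(man["gene"]))
planted = sorted(np.random.default_rng(8).choice(genes, 30, replace=False))
effect = EffectSpec(tuple(planted), "MEAN", effect_size=0.15, noise_sd=0.05)
data = generate_betas(man, n_class0=31, n_class1=35, effects=[effect], seed=9)
ds = Dataset(betas=data.betas, manifest=man, labels=data.labels)

matrix = compute_measure_matrix(ds, ["MEAN"])
rep = nested_cv_evaluate(matrix, ds.labels, ModelSpec(family="l1_logistic"), seed=1)
print(f"L1 logistic misclassification: {rep.misclassification_mean:.3f} "
      f"(+/- {rep.misclassification_sd:.3f})")

ranking = stump_rank(matrix, ds.labels, seed=2)
retained = ranking.loc[ranking["retained"], "gene"].tolist()
gene_set = generate_gene_sets(man, planted, n_sets=1, overlap_fraction=0.5,
                              set_size=30, seed=3)["SET001"]
curve = progressive_enrichment(retained, gene_set, genes)
print(f"min enrichment p: {curve.min_p:.3g}  rejected: {curve.any_rejected}")
```

Output:

```
L1 logistic misclassification: 0.000 (+/- 0.000)
min enrichment p: 6.21e-14  rejected: True
```

A 0.15 shift in mean gene methylation across 30 of 500 genes is
separable essentially perfectly at these sample sizes, and a gene set
sharing half its members with the planted genes is detected far below
the p < 0.01 rejection threshold when scanned along the retained
stump ranking.

The same analysis is available from the shell:

```sh
intrameth simulate --genes 500 --samples 31,35 --effect MEAN:0.15:30 \
    --seed 7 --out run/
intrameth measures --betas run/simulated/betas.tsv \
    --manifest run/simulated/manifest.csv \
    --samplesheet run/simulated/samplesheet.csv --out run/measures.tsv
intrameth rank --measures run/measures.tsv \
    --samplesheet run/simulated/samplesheet.csv --seed 2 --out run/ranking.csv
intrameth enrich --ranking run/ranking.csv \
    --gmt run/simulated/gene_sets.gmt --out run/enrichment.csv
```

or end-to-end from a YAML config with `intrameth all --config cfg.yaml`.
To analyze real array data instead, point `load_dataset` (or the config's
path block) at a beta-value TSV, a probe manifest CSV
(`probe_id,chromosome,coordinate,gene`, i.e. the Illumina
IlmnID/CHR/MAPINFO/UCSC_RefGene_Name fields) and a sample sheet CSV.

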