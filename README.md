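# conetwork

Weighted gene co-expression network analysis for bulk expression
residuals: signed/unsigned soft-threshold networks, topological-overlap
module detection with eigengene merging, module annotation (marker-list
enrichment, trait correlation, cross-network overlap, guilt-by-association
calls for lncRNAs) and four query tools over a saved network bundle.
A seeded simulator plants latent-factor module structure with full ground
truth, so every stage is testable against known answers.

## Pipeline overview

1. **preprocess** — per-gene OLS residualization against age and sex;
   optional variance-quantile gene filter.
2. **netbuild** — Pearson correlation → soft-threshold adjacency
   (signed: `((1+r)/2)^β`, default β=10; unsigned: `|r|^β`, default β=3),
   scale-free fit diagnostic, topological overlap matrix (TOM).
3. **moddetect** — average-linkage clustering on 1−TOM, two-stage dynamic
   tree cut (minimum module size 30, deepSplit 2), module eigengenes
   (first PC), module membership (MM) with within-module quantile ranks,
   iterative merging of modules whose eigengenes correlate > 0.8, hub
   (top 90th |MM| quantile) and unreliable (|MM| < 0.10) flags.
4. **annotate** — hypergeometric marker-list enrichment with Bonferroni,
   eigengene–trait Pearson correlations with Student asymptotic p-values,
   Fisher cross-tabulation of two module labelings, guilt-by-association
   predicted functions (|MM| > 0.20 in labeled modules), closest-partner
   summaries, stratified (e.g. per-sex) re-runs.
5. **query** — tools over a saved bundle: closest genes in a module
   (tool1), gene-set enrichment per module (tool2), genes in a genomic
   region (tool3), a gene's MM profile across modules (tool4).

## CLI

```bash
conetwork simulate --config sim.yaml --out data/ --seed 1
conetwork preprocess --expr data/expression.tsv --covariates data/covariates.tsv --out resid.tsv
conetwork network --expr resid.tsv --mode signed --out net/
conetwork modules --tom net/tom.tsv --expr resid.tsv --out mod/
conetwork run-all --config run.yaml --out results/ --seed 1
conetwork query tool1 --bundle results/bundle_signed --gene G00012
conetwork query tool3 --bundle results/bundle_signed --region chr1:1-50000
```

`run-all` accepts `network.mode: both` to build the signed (β=10) and
unsigned (β=3) networks plus their module cross-tabulation, and writes a
`manifest.json` with input/output digests; identical seed and inputs
reproduce identical digests.

## Library use

```python
from conetwork.simdata import SimConfig, generate_dataset
from conetwork.netbuild import NetworkConfig
from conetwork.workflow import run_pipeline

ds = generate_dataset(SimConfig(n_samples=300, n_modules=5, seed=1))
result = run_pipeline(ds.expression, ds.covariates, ds.traits,
                      NetworkConfig(mode="signed"))
result.labels          # gene -> module color ('grey' = unassigned)
result.eigengenes      # samples x modules
result.membership.mm   # genes x modules MM matrix
result.hubs            # hub / unreliable flags
```

## Tests and acceptance

```bash
python -m pytest -q tests/               # unit, property and acceptance suites
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` checks oracle equivalence (brute-force TOM,
covariance-eigendecomposition eigengenes, exhaustive hypergeometric and
Fisher enumeration, quadrature of the t density), planted-module
recovery (ARI ≥ 0.9 over 20 seeds), the signed/unsigned contrast on
sign-flipped modules, eigengene merge behavior, trait recovery, null
calibration of the enrichment tools, and exact rule conformance for the
hub/assignment/prediction/size/merge thresholds.  The acceptance script
has no numeric targets to reproduce (the source cohort is controlled
access); it runs a seeded end-to-end verification and writes an empty
target report.
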