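# germnet

Cross-kingdom (plant × rhizosphere microbiome) co-expression and
trait-association analysis, exercised end-to-end on a synthetic factorial
dataset with a known truth registry.

The pipeline implements:

- **Synthetic data** (`germnet.simulate`) — a fully crossed
  genotype × soil × temperature × replicate design; negative-binomial plant
  counts; compositional (log-normal → multinomial) microbial counts;
  cross-kingdom feature pairs whose Spearman correlation switches with
  temperature (Gaussian copula on log-scale latents); an ordinal 0–4 heat
  score and continuous traits (shoot biomass, root volume, root:shoot)
  driven by planted features. Everything planted is recorded in a
  `TruthRegistry`.
- **Preprocessing** (`germnet.preprocess`) — prevalence/abundance filters
  (≥75 reads in ≥4 samples for plant genes; ≥250 in ≥3 for microbial genes;
  ≥10 reads in ≥2 samples for taxa), relative abundance, centered log-ratio
  transform, DESeq2-style median-of-ratios normalization, rarefaction
  without replacement, and EC/pathway aggregation of gene counts.
- **Community statistics** (`germnet.community`) — Euclidean beta-diversity
  distances, PCA scores, sequential (Type-I) PERMANOVA with label
  permutations, a Spearman Mantel test, and the one-sided platform-slope
  test (H1: slope < 1).
- **Differential correlation** (`germnet.diffcorr`) — pairwise Spearman
  correlations between all plant and microbial features per temperature
  condition (cross-kingdom pairs only), Fisher z-transformation,
  `Δz = z_B − z_A` with `SE = sqrt(1/(n_A−3) + 1/(n_B−3))`, two-tailed
  normal test, Benjamini–Hochberg FDR, the two-threshold significance rule
  (q < 0.05 and |Δz| > 1), bipartite network extraction at rho > 0.7, and
  the one-tailed hypergeometric overlap test.
- **Trait models** (`germnet.traits`) — univariate Spearman prefilter
  (|rho| > 0.05), elastic net (α = 0.5, λ by 10-fold CV), random forest
  (2000 trees, top-25 per feature-type stratum), and the 2-of-3 consensus
  across {diffcorr, elastic net, random forest} with the cross-trait
  "k of methods × traits" tally.
- **Orchestration** (`germnet.pipeline`, `germnet.cli`) — a YAML-configured
  pipeline with per-stage seeds, SHA-256 checksummed outputs, and a resume
  manifest.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the binding acceptance criteria
(closed-form Fisher-z chain, null calibration, planted-pair recovery,
brute-force oracle equivalence, permutation-test uniformity, transform
contracts, trait-consensus recovery, filter-rule fidelity).

## CLI

```sh
# simulate a dataset (counts, annotation, metadata, truth registry)
germnet simulate --outdir out/sim --seed 1

# filter + transform a count matrix
germnet preprocess --counts out/sim/microbe_counts.tsv --kind microbial_gene \
    --filter 250,3 --transform clr --out out/microbe_clr.tsv

# permutation statistics
germnet permanova --dist dist.tsv --meta meta.csv --terms genotype,soil,temperature --nperm 999 --seed 1
germnet mantel --dist1 plant_dist.tsv --dist2 microbe_dist.tsv --nperm 5000 --seed 1

# differential correlation and networks
germnet diffcorr --plant plant.tsv --microbe microbe.tsv --meta meta.csv \
    --condition-col temperature --group-a 28C --group-b 38C --fdr 0.05 --min-dz 1.0 --out diffcorr.tsv
germnet network --plant plant.tsv --microbe microbe.tsv --threshold 0.7 --out edges.tsv

# trait association + consensus
germnet traits --plant plant.tsv --microbe microbe.tsv --meta meta.csv \
    --traits shoot_biomass,root_volume,heat_score --ntrees 2000 --out consensus.tsv

# full pipeline from one config
germnet run --config config.yaml
```

A minimal `config.yaml`:

```yaml
outdir: out/run1
seed: 1
simulate: {}          # generator defaults; any DesignSpec/GeneratorParams key works
n_perm_permanova: 999
n_perm_mantel: 5000
fdr: 0.05
min_dz: 1.0
```

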