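# hormonescan

Comparative genomics of sexual size dimorphism (SSD) and hormone
response elements (HREs). Across species, the magnitude of SSD — the
log ratio of male to female body mass — may scale with the number of
androgen/estrogen response elements (AREs/EREs), the DNA motifs that
sex-hormone receptors bind near genes. `hormonescan` provides the full
analysis chain for testing that hypothesis on per-species genome
assemblies, gene annotations, body-mass tables, and a phylogeny:

1. **Motif scanning** — degenerate IUPAC matching of the canonical ARE
   (`AGAACANNNTGTTCT`) and ERE (`GGTCANNNTGACC`) plus user-supplied
   variants, on both strands with correct palindrome handling (a
   palindromic motif is counted once per site, never doubled).
2. **TSS windows** — symmetric flanks (10/50/100/1 000 kb) around
   transcription start sites of `Intact` and `ParalogousProjection`
   genes; merged for once-only genome-wide counting, or kept per gene
   for the gene-centric scan where one element may count toward several
   genes.
3. **Phylogenetically controlled regression** — the headline model

       SSD ~ ln(HRE count) + ln(body size)

   fit by generalized least squares with residual covariance
   σ²·V(λ), where V(λ) is the Brownian-motion covariance of the tree
   with its off-diagonal scaled by Pagel's λ, estimated by maximum
   likelihood on [0, 1]. A contig-N50 regression checks genome-quality
   confounding, and a phylogenetic PCA summarizes log10 motif counts.
4. **Gene-centric scan** — per-gene PGLS of SSD on `ln(count + 1) +
   ln(body)` for every gene with ≥ 10 species and variable counts,
   with direction summaries, BH q-values and a significant-gene export.
5. **Synthetic data** — a generator that plants motifs in simulated
   genomes, evolves motif rates and body mass by Brownian motion on a
   Yule tree (optionally with a clade-specific ARE burst), and draws SSD
   from the generative inverse of the headline model, so every stage can
   be validated against known truth.

The statistical cores are scikit-learn-style estimators (`PhyloGLS`,
`PhyloPCA`) that compose with sklearn tooling; module functions such as
`model_ssd`, `qc_n50`, `phylo_pca` and `scan_genes` wrap them.

## Worked example

Simulate 64 species with a 4× ARE burst clade, then fit the species
model:

```python
from hormonescan import (SimulationConfig, simulate_species_dataset,
                         build_species_table, model_ssd)
from hormonescan.phylo import tip_labels

cfg = SimulationConfig(seed=42, n_species=64, burst_fraction=0.33)
ds = simulate_species_dataset(cfg)
table = build_species_table(ds.traits, ds.counts, tip_labels(ds.tree))
fit = model_ssd(table, ds.tree, hre_class="ARE", lam="ML")
```

This prints (via the snippet in the docstring):

```
n species      : 64
ARE effect     : 0.562  (p = 1.84e-23)
body effect    : 0.237  (p = 1.60e-06)
Pagel's lambda : 0.114
R^2 (phylo)    : 0.815
burst clade ARE mean: 348  vs outgroup: 69
```

The generator planted an ARE effect of 0.5 and a body effect of 0.3;
the fit recovers both within sampling error, detects the effect at tiny
p, and the burst clade shows the intended several-fold excess of AREs.
`fit` is a `PhyloGLSFit` carrying coefficients, standard errors,
t/p-values, λ, σ², log-likelihood and the phylogenetically controlled
R².

The same pipeline runs from the shell on files:

```bash
hormonescan simulate --seed 42 --out data/         # synthetic dataset
hormonescan scan --genome data/genomes/sp01.fa --out hits.bed
hormonescan count --genome data/genomes/sp01.fa \
    --annotations data/annotations/sp01.tsv --flank 50000 \
    --mode dedup --out counts.tsv
hormonescan run --config run.yaml                  # full analysis
```

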