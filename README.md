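# cellqtl

One-pot single-cell eQTL mapping for two-parent crosses.

`cellqtl` implements the analysis stack for experiments in which a large
pool of recombinant individuals (e.g. an F4 *C. elegans* N2 × CB4856
obligate-outcross population) is dissociated and profiled in a single
droplet scRNA-seq run. Every cell then carries both a transcriptome and —
through UMIs overlapping transcribed SNVs that distinguish the founders —
a sparse readout of its own genotype. The package turns those two signals
into cell-type-resolved genetic maps of gene expression:

- **Genotyping HMM** (`cellqtl.hmm`): a three-state hidden Markov chain
  over ordered variant sites with binomial emissions
  (`P(Y|NN) = C(D,r)(1−e)^r e^{D−r}`, error rate `e = 0.002`),
  Haldane/genetic-map transitions and Mendelian priors — (¼, ½, ¼) on
  autosomes, (0.44, 0.44, 0.11) on X for a hermaphrodite × male cross.
  Forward–backward smoothing posteriors are collapsed to an additive
  dosage `P(CC) + ½·P(NC)`; no hard genotype calls are made.
- **eQTL mapping** (`cellqtl.eqtl`, `cellqtl.nbglm`): per transcript and
  cell type, a negative-binomial GLM
  `log μ = β_i + X_t β_t + X_b β_b + X_c β_c` with overdispersion θ
  (`Var = μ + μ²/θ`) fit by IRLS; θ is estimated once per transcript on
  the cis model and reused genome-wide. Significance is a
  likelihood-ratio test expressed as `LOD = LRT / (2 ln 10)`, with
  1.5-LOD-drop support intervals, within-batch permutation FDR
  (10 permutations, thresholds 0.1 … max LOD + 0.1 in 0.01 steps), BH
  adjustment for small cell populations, a bulk correlation-to-LOD mapper
  `−n ln(1−R²)/(2 ln 10)`, Stouffer's weighted-Z combination and an exact
  binomial test of effect-direction concordance.
- **Hotspot detection** (`cellqtl.hotspots`): 5-cM genome bins, one-sided
  Poisson excess tests at a Bonferroni-corrected level (e.g. 0.05/130 ≈
  3.8e-4), cis linkages removed when the target gene lies within the
  peak's padded (±1 Mb) confidence interval, adjacent significant bins
  reduced to local maxima.
- **Cell-type classifier** (`cellqtl.classify`): the standard normalize /
  log1p / HVG / scale-and-clip recipe feeding an L2-penalized multinomial
  logistic regression (C = 7.74e-4, five-fold CV), with doublet
  (≥2 class probabilities > 0.2) and low-quality (max < 0.4) calls.
- **Cross simulator** (`cellqtl.simulate`): an obligate-outcross pedigree
  with Poisson crossovers and the asymmetric X transmission of a
  hermaphrodite × male cross, sparse genotype-informative UMI counts
  (median 69 per cell), and gamma-Poisson expression with planted
  cis/trans effects, batch effects and hotspots — the study conditions
  used by the test suite.

## Worked example

```python
import numpy as np, scipy.sparse as sp
from cellqtl import simulate as sim, eqtl
from cellqtl.hmm import infer_genotypes

# a compact synthetic experiment: 2 autosomes + X, 500 cells, 12 planted cis eQTLs
genome = sim.default_genome(n_autosomes=2, sites_per_chrom=40, genes_per_chrom=60, seed=11)
design = sim.CrossDesign(n_seeded=2000, dissociation_rate=0.5, n_cells=500,
                         generations=4, n_founders=300, batches=2)
ds = sim.simulate_dataset(design=design, genome=genome, seed=21,
                          n_cis=12, cis_effect=0.8)

# genotype every cell from its sparse allele counts
post = infer_genotypes(ds.allele_counts, genome.genetic_map)
true_dosage = ds.truth.dosage()[ds.cells["individual"].to_numpy(), :]
print(f"dosage correlation (inferred vs true): "
      f"{np.corrcoef(post.dosage.ravel(), true_dosage.ravel())[0, 1]:.3f}")

# cis eQTL scan with permutation FDR
adata = ds.expression
markers = eqtl.prune_markers(post.dosage, post.sites.copy())
cov = eqtl.build_design(np.log(adata.obs["total_umis"].to_numpy()),
                        adata.obs["batch"].to_numpy())
Y = sp.csc_matrix(adata.X)
cis = eqtl.cis_scan(Y, genome.genes, markers, cov)
cis, _ = eqtl.permutation_fdr(Y, genome.genes, markers, cov,
                              adata.obs["batch"].to_numpy(), cis,
                              mode="cis", n_perm=10, seed=21)
sig = cis[cis["fdr"] <= 0.1]
planted = set(ds.truth.planted_cis["gene"])
print(f"significant cis eQTLs at 10% FDR: {len(sig)} "
      f"({sum(g in planted for g in sig['gene'])} of {len(planted)} planted)")
print(sig.nlargest(3, "lod")[["gene", "marker_chrom", "marker_pos",
                              "lod", "effect", "fdr"]].to_string(index=False))
```

Output:

```
dosage correlation (inferred vs true): 0.907
significant cis eQTLs at 10% FDR: 13 (12 of 12 planted)
    gene marker_chrom  marker_pos       lod    effect  fdr
   X.g20            X     5876159 41.682389  0.371980  0.0
   X.g59            X    14224123 24.319054  0.305887  0.0
chrI.g23         chrI     4791843 23.273550 -0.292611  0.0
```

The dosage correlation says the HMM reconstructs each cell's genome-wide
genotype from a median of ~69 informative UMIs with high fidelity; the
scan recovers all twelve planted cis effects at 10% permutation FDR with
one false call, and `effect` is the log-scale coefficient per standard
deviation of genotype dosage (its sign says which founder allele raises
expression).

A command-line interface mirrors the library
(`cellqtl simulate | genotype | map | hotspots | classify | pipeline`);
`cellqtl pipeline --config cfg.yaml` runs simulate → genotype → map →
hotspots end to end from a YAML config.

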