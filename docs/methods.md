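# Methods

This note documents the models behind `cellqtl`, the defaults and why
they were chosen, what the simulator does and does not emulate, and the
numerical choices a maintainer should know about.

## Genotyping HMM

Each cell of a two-founder recombinant population is a mosaic of N2 and
CB4856 haplotypes. At transcribed SNVs distinguishing the founders we
observe `r` N2-supporting UMIs out of `D` total. The hidden state at each
ordered site is the genotype in {NN, NC, CC}.

**Emissions.** Reads are binomial samples of the alleles present, with
independent per-read errors at rate `e` (default 0.002):
`P(Y|NN) = C(D,r)(1−e)^r e^{D−r}`, `P(Y|NC) = C(D,r)/2^D`,
`P(Y|CC) = C(D,r) e^r (1−e)^{D−r}`. Sites with `D = 0` contribute flat
emissions, so a cell with no coverage on a chromosome falls back to the
prior. Emissions are computed in log space; within the forward–backward
pass the shared binomial coefficient is omitted because it cancels in
the posterior normalization.

**Priors.** Autosomes: (0.25, 0.5, 0.25), the stationary intercross
frequencies. X: (0.44, 0.44, 0.11), normalized internally to (4/9, 4/9,
1/9). These are the Hardy–Weinberg frequencies at CB-allele frequency
1/3, the limit of the X recursion for a cross founded by N2
hermaphrodites × CB males (hermaphrodites contribute two X per offspring,
males one). Hemizygous male X chromosomes are not modeled separately;
the same three-state prior is applied to all cells, which slightly
overstates X heterozygosity in male cells. Their dosage is still
consistent because male X genotypes are coded homozygous.

**Transitions.** Map positions are linearly interpolated from a
reference genetic map to every variant site; positions outside the
anchored range are extrapolated with the terminal segment's slope (and
logged). Distances between adjacent sites are multiplied by
`scale_factor` (default 0.4) before Haldane conversion
`ρ = (1 − e^{−2d/100})/2`; 0.4 converts a 10-generation
advanced-intercross map, whose expansion grows as g/2, to the F4
expectation. The two homologs are transmitted independently, giving the
F2-style 3×3 kernel with stationary distribution (¼, ½, ¼). This Markov
kernel ignores the residual non-Markov linkage of an F4 population; the
exhaustive-enumeration tests check the smoother against the declared
model, and the simulation-based fidelity test checks the declared model
against a true pedigree process.

**Numerics.** Scaled (per-site normalized) forward–backward; chains
restart at each chromosome with the prior; posteriors at all variant
sites; dosage = P(CC) + ½·P(NC) ∈ [0, 1].

**Utilities.** The expected number of cells with a unique genotype when
C cells are drawn from I individuals is the birthday-problem quantity
`C(1 − 1/I)^{C−1}`. The empirical collision counter reports cells whose
dosage-vector Pearson correlation with any other cell exceeds 0.9
(constant vectors excluded and logged). Parental cells are labeled N2 or
CB4856 when ≥50 summed UMIs support one founder and <50 the other.

## Negative-binomial eQTL mapping

Counts are gamma-Poisson: `E[Y] = μ`, `Var(Y) = μ + μ²/θ`,
`log μ = β_i + X_t β_t + X_b β_b + X_c β_c`, where `X_t = log(total
UMIs)` controls compositional effects, `X_b` are batch indicators
(first level absorbed into the intercept) and `X_c` is the standardized
dosage at the closest pruned marker (cis) or each marker in turn
(trans). Dosage columns use population (1/n) variance for
standardization; markers are pruned greedily left-to-right within
chromosome when their correlation with the last kept marker exceeds
0.9999 (with posterior dosages this approximates a ~5 cM grid).
Transcripts enter a cell type's scans when ≥20 cells have ≥1 UMI.

**Fitting.** IRLS with log link; working weights `μθ/(θ+μ)`; at most 50
iterations to a relative log-likelihood tolerance of 1e-8, with step
halving whenever an update decreases the likelihood (certainty of
convergence over speed). The linear predictor is clamped at ±30 and
such fits flagged. θ is profiled by alternating a bounded 1-D
maximization over log θ with the IRLS updates. θ is estimated once per
transcript per cell type on the full cis model and reused for every
other fit of that transcript: this is the conservative choice — trans
effects left unmodeled inflate the θ̂-implied overdispersion — and makes
genome-wide scans tractable.

**Inference.** `LRT = −2(l_reduced − l_full)` against the model without
the genetic term (β re-estimated, θ fixed); `LOD = LRT/(2 ln 10)`;
p from χ²₁. A negative LRT within 1e-6 is truncated to zero; beyond
that the full model is refit at fixed θ before failing. Per chromosome
the peak is the leftmost maximum-LOD marker, with a 1.5-LOD-drop
interval taken as the outermost markers within 1.5 LOD of the peak
(clamped to chromosome ends).

**Permutation FDR.** Genotype rows are permuted within batch, the same
ordering for all transcripts in a permutation instance; 10 permutations
by default. Cells can be permuted individually (each cell its own
segregant) or as whole individuals when cell→individual assignments are
known; both modes are exposed. For each LOD threshold on the grid 0.1 …
max observed LOD + 0.1 (step 0.01), FDR = (mean permuted count above
threshold)/(observed count above threshold), clipped to [0, 1] and
monotonized by a running minimum over increasing thresholds; per-peak
adjusted p-values interpolate this curve piecewise-linearly, clamping
outside the supported (observed > 0) range. Whether to monotonize was a
genuinely open choice; without it, sparse permutation tails make the
curve noisy exactly where decisions are made. cis FDR uses the LOD at
the closest marker only; trans FDR is per chromosome on the max LOD.
For small populations (e.g. neuronal subtypes) Benjamini–Hochberg
adjustment of the χ²₁ p-values is provided instead.

**Auxiliary statistics.** Bulk eQTL LOD from a marker-trait Pearson
correlation: `−n ln(1−R²)/(2 ln 10)` (the Gaussian nested-model log10
likelihood ratio). Stouffer combination `Σwᵢzᵢ/√(Σwᵢ²)` for
standardized effects across cell types. Direction concordance between
two mappings: sign-agreement counts with a two-sided exact binomial test
against 1/2 (two-sided because no direction of disagreement is
privileged a priori; zero effects are excluded and logged).

## Hotspots

The scaled (mapping-scale) genetic map is tiled with 5-cM bins per
chromosome, last bin possibly short. Significant trans linkages (FDR ≤
0.1; target gene outside the peak's confidence interval ±1 Mb, on the
peak chromosome) are assigned to the bin containing the peak position.
Per cell type, λ is the mean count over all bins — including any tested
bin, since excluding it barely moves λ and keeps the test simple — and
a bin is significant when the one-sided Poisson upper tail
P(X ≥ count) < α/n_bins (α = 0.05). Runs of adjacent significant bins
collapse to the highest-count bin, leftmost on ties. Hotspot target
lists for downstream enrichment can use a relaxed FDR ≤ 0.2 via the
`fdr_max` argument.

## Cell-type classifier

Genes seen in <10 cells are dropped; cells are scaled to 10,000 total
counts; log(1+x); highly variable genes selected by mean window
(0.0125–3) and normalized dispersion ≥ 0.5 using the standard
mean-binned variance/mean estimator on the log-normalized data (the
estimator itself was an open choice; the bin-normalized one is the field
default and the bounds are exposed); per-gene z-scoring with values
clipped at +20. An L2-penalized multinomial logistic regression at
C = 7.74e-4 produces fold-wise class probabilities via stratified
five-fold CV (seeded). Decision rules, in order: doublet if ≥2 class
probabilities exceed 0.2; low quality if the best class is below 0.4;
otherwise argmax. Rule precedence matters: a cell with probabilities
(0.39, 0.31, 0.30) is a doublet even though no class reaches 0.4.

## Simulator

The simulator generates the study conditions the tests run under.

**Pedigree.** F0 is N2 hermaphrodites × CB males (500 per sex by
default); each later generation draws, per offspring, a random
hermaphrodite dam and male sire (obligate outcrossing; selfing
impossible), to generation 4 by default. Meioses place crossovers as a
Poisson process on the single-meiosis cM scale (Haldane, no
interference). Hermaphrodite offspring receive a maternal recombinant X
and the paternal X; males a maternal recombinant X only, coded
homozygous. The final generation is thinned by the dissociation rate to
the effective individual count; cells are drawn uniformly with
replacement from those individuals, so genotype collisions arise
naturally. The bundled reference map stores cM on a 10-generation
intercross scale (5× a single meiosis), so the genotyping default
`scale_factor = 0.4` is exercised end-to-end. Defaults (7,000 seeded,
50% dissociation, 2,000 cells) keep the individuals-to-cells ratio of
the motivating design (~1.7).

**Allele counts.** Per-cell totals are negative binomial (shape 3)
parameterized by bisection so the median equals the requested value
(default 69) — only the median is reported for real data, so the
distribution family is a stand-in. UMIs scatter uniformly over sites;
each reports the true allele with probability 1−e (heterozygous sites:
each allele ½).

**Expression.** `μ = T·α_g·exp(batch + cell-type program + Σ effects ×
dosage)` with lognormal library sizes (median ~2,000 UMIs), lognormal
relative abundances, per-gene batch log-effects ~N(0, 0.1), per-gene θ
lognormal around 2, counts gamma-Poisson. A mean with log μ > 30 raises
rather than overflowing. Planted cis effects attach to the variant site
closest to the gene; a planted hotspot gives one marker many trans
targets. Cell-type programs upregulate ~15% of genes ~7-fold per type,
emulating major cell classes (muscle vs neuron vs hypodermis scale);
with much weaker separation the heavily regularized classifier splits
probability mass across classes and spuriously flags singlets as
doublets, so classifier guarantees shown on these simulations do not
transfer to closely related subtypes.

**Not emulated:** ambient RNA, read-level sequencing artifacts,
developmental trajectories or any continuous structure within cell
types, cell-type-biased capture rates, and doublets (available only as
explicit mixtures constructed by the tests). Passing tests therefore
demonstrate correctness of the statistical machinery under the declared
generative model, not robustness to these real-data pathologies.

## Problem sizes in the test suite

The acceptance-level checks run at desk scale, chosen to keep each
statistical bound well-powered: genotyping fidelity uses 2,000 cells ×
500 sites on one chromosome (dosage correlation ≥ 0.9 at median 69
informative UMIs); GLM recovery uses n = 50,000; null calibration ~2,000
transcripts × 400 cells; FDR control 2,004 transcripts (200 planted) ×
800 cells with 10 permutations; hotspot false-positive rates use 200
simulated null genomes of 130 bins. Full-suite runtime is about one
minute on one CPU.

## Known limitations

- The Markov transition model understates F4 linkage disequilibrium
  between distant markers; posteriors are exact only under the declared
  HMM.
- θ reuse from the cis model is conservative by construction; power
  could be gained by re-estimating or regularizing θ per marker, which
  is deliberately out of scope.
- The permutation FDR needs observed counts > 0 to be defined at a
  threshold; outside that range adjusted p-values clamp to the nearest
  supported value.
- `collision_count` builds a dense cell × cell correlation matrix;
  it is quadratic in cells and intended for cohort-level QC, not
  million-cell matrices.
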