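"""Synthetic F4 obligate-outcross population and single-cell readouts.

This module emulates, at desk scale, the study design the pipeline is
built for: an N2 x CB4856 *C. elegans* cross propagated for four
generations under obligate outcrossing (*fog-2*), a pool of F4
segregants dissociated into single cells, and droplet scRNA-seq of those
cells. It produces

* a pedigree simulation with Poisson (no-interference) crossovers on the
  genetic-map scale, including the asymmetric X-chromosome transmission
  of a hermaphrodite (XX) x male (X0) cross — hermaphrodite offspring
  receive one maternal recombinant X plus the paternal X, males one
  maternal recombinant X only;
* sparse genotype-informative allele counts per cell, with a
  negative-binomial total-UMI distribution parameterized by its median
  (69 by default) and per-read error rate 0.002;
* gamma-Poisson (negative binomial) expression counts whose log-mean is
  intercept + log(total UMIs) + batch + cell-type program + planted
  cis/trans genetic effects times the additive CB dosage.

Genetic-map convention: `SimGenome.genetic_map` stores cM on the scale of
a 10-generation advanced-intercross reference map (as a published map
would). One meiosis corresponds to 2/10 of those cM, and the genotyping
HMM's default distance scaling of 0.4 recovers the F4 expectation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import nbinom

from .genome import GeneticMap
from .hmm import AlleleCountMatrix, haldane_rho

logger = logging.getLogger(__name__)

#: generations of intercrossing reflected by the reference-map cM scale
MAP_GENERATIONS = 10


@dataclass
class CrossDesign:
    """Experiment-scale parameters of the simulated cross.

    ``n_individuals`` — the effective number of genotypes cells are drawn
    from — is the number of seeded segregants times the dissociation
    rate.
    """

    n_seeded: int = 7000
    dissociation_rate: float = 0.5
    n_cells: int = 2000
    generations: int = 4
    batches: int = 5
    n_founders: int = 500  # per sex at F0

    def __post_init__(self) -> None:
        if not (0.0 < self.dissociation_rate <= 1.0):
            raise ValueError("dissociation_rate must be in (0, 1]")
        if self.generations < 2:
            raise ValueError(
                "need generations >= 2: a single generation has no recombinant pool"
            )
        if self.n_cells < 1 or self.n_seeded < 1 or self.batches < 1:
            raise ValueError("counts must be positive")

    @property
    def n_individuals(self) -> int:
        return int(round(self.n_seeded * self.dissociation_rate))


@dataclass
class SimGenome:
    """Chromosomes, genetic map, variant sites and gene coordinates.

    ``chromosomes`` is a list of (name, length_bp, is_x). ``variant_sites``
    and ``genes`` are DataFrames with chrom/pos (and gene id) sorted by
    (chromosome order, position).
    """

    chromosomes: list[tuple[str, float, bool]]
    genetic_map: GeneticMap
    variant_sites: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        names = [c[0] for c in self.chromosomes]
        if set(self.variant_sites["chrom"]) - set(names):
            raise ValueError("variant site on undeclared chromosome")
        self.variant_sites = (
            self.variant_sites.assign(
                _c=pd.Categorical(self.variant_sites["chrom"], names, ordered=True)
            )
            .sort_values(["_c", "pos"], kind="stable")
            .drop(columns="_c")
            .reset_index(drop=True)
        )

    @property
    def n_sites(self) -> int:
        return len(self.variant_sites)

    def is_x(self, chrom: str) -> bool:
        return dict((c[0], c[2]) for c in self.chromosomes)[chrom]

    def site_meiosis_cm(self, chrom: str) -> np.ndarray:
        """Single-meiosis cM positions of the variant sites on ``chrom``."""
        pos = self.variant_sites.loc[
            self.variant_sites["chrom"] == chrom, "pos"
        ].to_numpy()
        return self.genetic_map.interpolate(chrom, pos) * (2.0 / MAP_GENERATIONS)


def default_genome(
    n_autosomes: int = 5,
    meiosis_cm_per_chrom: float = 50.0,
    chrom_bp: float = 15e6,
    sites_per_chrom: int = 100,
    genes_per_chrom: int = 200,
    with_x: bool = True,
    seed: int = 0,
) -> SimGenome:
    """A compact stand-in genome echoing the *C. elegans* cross layout.

    Five autosomes plus X, ~50 single-meiosis cM each (stored on the
    10-generation reference scale, i.e. x5), with jittered uniformly
    spaced variant sites and random gene positions.
    """
    rng = np.random.default_rng(seed)
    names = [f"chr{i}" for i in ["I", "II", "III", "IV", "V"][:n_autosomes]]
    if with_x:
        names.append("X")
    chroms = [(n, chrom_bp, n == "X") for n in names]
    ref_cm = meiosis_cm_per_chrom * (MAP_GENERATIONS / 2.0)
    anchors = {
        n: np.array(
            [[0.0, 0.0], [0.45 * chrom_bp, 0.55 * ref_cm], [chrom_bp, ref_cm]]
        )
        for n in names
    }
    sites, genes = [], []
    for n in names:
        step = chrom_bp / (sites_per_chrom + 1)
        pos = np.sort(
            (np.arange(1, sites_per_chrom + 1) * step
             + rng.uniform(-0.3 * step, 0.3 * step, sites_per_chrom)).astype(int)
        )
        pos = np.unique(np.clip(pos, 1, int(chrom_bp) - 1))
        sites.append(pd.DataFrame({"chrom": n, "pos": pos}))
        gpos = np.sort(rng.integers(1, int(chrom_bp), size=genes_per_chrom))
        genes.append(
            pd.DataFrame(
                {"gene": [f"{n}.g{k}" for k in range(genes_per_chrom)],
                 "chrom": n, "pos": gpos}
            )
        )
    return SimGenome(
        chromosomes=chroms,
        genetic_map=GeneticMap(anchors, scale_factor=0.4),
        variant_sites=pd.concat(sites, ignore_index=True),
        genes=pd.concat(genes, ignore_index=True),
    )


@dataclass
class SimTruth:
    """Ground truth of one simulated cross.

    ``genotypes`` holds the CB-allele count in {0, 1, 2} per individual x
    variant site; hemizygous male X genotypes are coded 0/2 so the
    additive dosage (genotype / 2) stays in [0, 1]. Planted-effect tables
    are filled by :func:`plant_eqtls` / :func:`simulate_expression`.
    """

    genome: SimGenome
    genotypes: np.ndarray  # (I, M) int8
    sex: np.ndarray  # 'H' or 'M' per individual
    seed: int
    planted_cis: pd.DataFrame | None = None
    planted_trans: pd.DataFrame | None = None
    batch_effects: np.ndarray | None = None
    theta: np.ndarray | None = None

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    def dosage(self) -> np.ndarray:
        """True additive CB dosage per individual x site."""
        return self.genotypes.astype(float) / 2.0


def _meiosis(
    rng: np.random.Generator,
    h1: np.ndarray,
    h2: np.ndarray,
    parents: np.ndarray,
    rho: np.ndarray,
) -> np.ndarray:
    """Recombinant gametes for ``parents`` given marker-gap switch probs."""
    n = len(parents)
    m = h1.shape[1]
    state = np.empty((n, m), dtype=bool)
    state[:, 0] = rng.random(n) < 0.5
    if m > 1:
        switches = rng.random((n, m - 1)) < rho[None, :]
        state[:, 1:] = np.cumsum(switches, axis=1) % 2
        state[:, 1:] ^= state[:, [0]]
    a1 = h1[parents]
    a2 = h2[parents]
    return np.where(state, a2, a1)


def simulate_pedigree(
    design: CrossDesign, genome: SimGenome, seed: int = 0
) -> SimTruth:
    """Random-mating obligate-outcross pedigree down to generation F_g.

    F0 is ``n_founders`` N2 hermaphrodites x ``n_founders`` CB males.
    Every offspring draws a random hermaphrodite dam and male sire from
    the previous generation; selfing is impossible by construction.
    Autosomal meioses place crossovers as a Poisson process on the
    single-meiosis cM scale (Haldane, no interference). The final
    generation is thinned to ``design.n_individuals`` survivors.
    """
    rng = np.random.default_rng(seed)
    chrom_names = [c[0] for c in genome.chromosomes]
    site_idx = {
        c: genome.variant_sites.index[genome.variant_sites["chrom"] == c].to_numpy()
        for c in chrom_names
    }
    rhos = {}
    for c in chrom_names:
        cm = genome.site_meiosis_cm(c)
        if not np.all(np.isfinite(cm)):
            raise ValueError(f"non-finite map on {c}")
        rhos[c] = haldane_rho(np.diff(cm))

    # founder haplotypes: hermaphrodites N2 (0), males CB (1)
    nf = design.n_founders
    sex = np.array(["H"] * nf + ["M"] * nf)
    hap = {}
    for c in chrom_names:
        m = len(site_idx[c])
        h1 = np.zeros((2 * nf, m), dtype=np.int8)
        h2 = np.zeros((2 * nf, m), dtype=np.int8)
        h1[nf:] = 1
        h2[nf:] = 1  # male X coded as duplicated hemizygous allele
        hap[c] = (h1, h2)

    for gen in range(1, design.generations + 1):
        herms = np.flatnonzero(sex == "H")
        males = np.flatnonzero(sex == "M")
        if len(herms) == 0 or len(males) == 0:
            raise RuntimeError(
                f"generation F{gen}: no {'hermaphrodites' if not len(herms) else 'males'} to mate"
            )
        n_off = design.n_seeded
        dams = rng.choice(herms, size=n_off)
        sires = rng.choice(males, size=n_off)
        sex_off = np.where(rng.random(n_off) < 0.5, "H", "M")
        new_hap = {}
        for c in chrom_names:
            h1, h2 = hap[c]
            maternal = _meiosis(rng, h1, h2, dams, rhos[c])
            if genome.is_x(c):
                # paternal X passed intact to hermaphrodite offspring;
                # male offspring are hemizygous for the maternal X
                paternal = h1[sires].copy()
                is_m = sex_off == "M"
                paternal[is_m] = maternal[is_m]
            else:
                paternal = _meiosis(rng, h1, h2, sires, rhos[c])
            new_hap[c] = (maternal, paternal)
        hap = new_hap
        sex = sex_off

    survivors = rng.choice(design.n_seeded, size=design.n_individuals, replace=False)
    survivors.sort()
    genotypes = np.empty((design.n_individuals, genome.n_sites), dtype=np.int8)
    for c in chrom_names:
        h1, h2 = hap[c]
        genotypes[:, site_idx[c]] = h1[survivors] + h2[survivors]
    return SimTruth(genome=genome, genotypes=genotypes, sex=sex[survivors], seed=seed)


def sample_cells(
    design: CrossDesign, truth: SimTruth, seed: int = 0
) -> pd.DataFrame:
    """Draw cells uniformly from individuals and assign library batches."""
    rng = np.random.default_rng(seed)
    ind = rng.integers(0, truth.n_individuals, size=design.n_cells)
    batch = rng.integers(0, design.batches, size=design.n_cells)
    return pd.DataFrame(
        {
            "cell": [f"cell{i:05d}" for i in range(design.n_cells)],
            "individual": ind,
            "batch": [f"batch{b}" for b in batch],
            "sex": truth.sex[ind],
        }
    )


def _nb_mean_for_median(median: float, shape: float) -> float:
    """Mean of NB(shape, mean) whose median equals ``median`` (bisection)."""
    lo, hi = median / 4.0, median * 4.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        med = nbinom.median(shape, shape / (shape + mid))
        if med < median:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_allele_counts(
    truth: SimTruth,
    cells: pd.DataFrame,
    median_informative_umis: int = 69,
    error_rate: float = 0.002,
    seed: int = 0,
    nb_shape: float = 3.0,
) -> AlleleCountMatrix:
    """Sparse genotype-informative UMI counts per cell.

    Per cell the total informative-UMI count is negative binomial with
    the requested median (the field reports medians, not means); UMIs are
    scattered uniformly over variant sites; each UMI reports the true
    allele with probability 1 - ``error_rate`` (heterozygous sites emit
    each allele with probability 1/2).
    """
    if median_informative_umis < 1:
        raise ValueError("median_informative_umis must be >= 1")
    rng = np.random.default_rng(seed)
    n_cells = len(cells)
    n_sites = truth.genome.n_sites
    mean = _nb_mean_for_median(median_informative_umis, nb_shape)
    totals = rng.negative_binomial(nb_shape, nb_shape / (nb_shape + mean), n_cells)

    cell_rep = np.repeat(np.arange(n_cells), totals)
    site_rep = rng.integers(0, n_sites, size=cell_rep.size)
    ind_rep = cells["individual"].to_numpy()[cell_rep]
    g = truth.genotypes[ind_rep, site_rep]
    p_cb = np.where(g == 2, 1.0 - error_rate, np.where(g == 1, 0.5, error_rate))
    is_cb = rng.random(cell_rep.size) < p_cb

    shape = (n_cells, n_sites)
    ref = sp.coo_matrix(
        (np.ones((~is_cb).sum()), (cell_rep[~is_cb], site_rep[~is_cb])), shape=shape
    ).tocsr()
    alt = sp.coo_matrix(
        (np.ones(is_cb.sum()), (cell_rep[is_cb], site_rep[is_cb])), shape=shape
    ).tocsr()
    return AlleleCountMatrix(
        ref=ref,
        alt=alt,
        sites=truth.genome.variant_sites.copy(),
        barcodes=list(cells["cell"]),
    )


def plant_eqtls(
    truth: SimTruth,
    n_cis: int = 0,
    cis_effect: float = 0.5,
    n_hotspot_targets: int = 0,
    hotspot_marker: int | None = None,
    trans_effect: float = 0.5,
    seed: int = 0,
) -> SimTruth:
    """Plant cis effects and (optionally) one trans hotspot into the truth.

    cis: ``n_cis`` random genes get an effect of +/- ``cis_effect`` at the
    variant site closest to the gene. Hotspot: ``n_hotspot_targets``
    random genes respond to ``hotspot_marker`` (random if None) with
    +/- ``trans_effect``. Effects are log-scale coefficients multiplying
    the additive CB dosage.
    """
    rng = np.random.default_rng(seed)
    genome = truth.genome
    sites = genome.variant_sites
    genes = genome.genes.reset_index(drop=True)

    def closest_site(chrom, pos):
        on = sites.index[sites["chrom"] == chrom].to_numpy()
        return int(on[np.argmin(np.abs(sites.loc[on, "pos"].to_numpy() - pos))])

    pick = rng.choice(len(genes), size=n_cis + n_hotspot_targets, replace=False)
    cis_genes, hot_genes = pick[:n_cis], pick[n_cis:]
    truth.planted_cis = pd.DataFrame(
        {
            "gene": genes.loc[cis_genes, "gene"].to_numpy(),
            "marker": [
                closest_site(genes.loc[i, "chrom"], genes.loc[i, "pos"])
                for i in cis_genes
            ],
            "effect": rng.choice([-1.0, 1.0], n_cis) * cis_effect,
        }
    )
    if n_hotspot_targets > 0:
        hm = (
            int(hotspot_marker)
            if hotspot_marker is not None
            else int(rng.integers(0, genome.n_sites))
        )
        truth.planted_trans = pd.DataFrame(
            {
                "gene": genes.loc[hot_genes, "gene"].to_numpy(),
                "marker": hm,
                "effect": rng.choice([-1.0, 1.0], len(hot_genes)) * trans_effect,
            }
        )
    else:
        truth.planted_trans = pd.DataFrame(columns=["gene", "marker", "effect"])
    return truth


def make_celltype_programs(
    n_types: int,
    n_genes: int,
    rng: np.random.Generator,
    marker_frac: float = 0.15,
    strength: float = 2.0,
) -> np.ndarray:
    """Log-scale expression programs: each type upregulates its markers.

    Defaults emulate major cell classes (muscle vs neuron vs hypodermis
    scale of divergence): ~15% of genes are markers at e^2 ~ 7-fold.
    Closely related subtypes are far less separable; see the methods
    note for what that implies for classifier tests.
    """
    programs = np.zeros((n_types, n_genes))
    n_mark = max(1, int(marker_frac * n_genes))
    for t in range(n_types):
        idx = rng.choice(n_genes, size=n_mark, replace=False)
        programs[t, idx] = rng.normal(strength, 0.3, size=n_mark)
    return programs


def simulate_expression(
    truth: SimTruth,
    cells: pd.DataFrame,
    seed: int = 0,
    mean_log_total: float = np.log(2000.0),
    sd_log_total: float = 0.3,
    batch_sd: float = 0.1,
    theta_log_mean: float = np.log(2.0),
    theta_log_sd: float = 0.4,
    cell_type_programs: np.ndarray | None = None,
    cell_types: np.ndarray | None = None,
) -> ad.AnnData:
    """Gamma-Poisson expression counts for the sampled cells.

    Per gene g and cell n the expected count is

        mu = T_n * alpha_g * exp(batch + program + sum_k effect_k * dosage_k)

    with T_n ~ lognormal library size, alpha_g a lognormal-Dirichlet
    relative abundance, and counts drawn NB with per-gene overdispersion
    theta ~ lognormal. Returns an AnnData (cells x genes) whose ``obs``
    carries batch, individual, sex and cell type.
    """
    rng = np.random.default_rng(seed)
    genome = truth.genome
    genes = genome.genes.reset_index(drop=True)
    n_genes = len(genes)
    n_cells = len(cells)

    w = rng.lognormal(0.0, 1.2, size=n_genes)
    alpha = w / w.sum()
    T = rng.lognormal(mean_log_total, sd_log_total, size=n_cells)

    batches = pd.Categorical(cells["batch"])
    if truth.batch_effects is None:
        truth.batch_effects = rng.normal(0.0, batch_sd, (len(batches.categories), n_genes))
    if truth.theta is None:
        truth.theta = rng.lognormal(theta_log_mean, theta_log_sd, size=n_genes)

    log_mu = np.log(alpha)[None, :] + np.log(T)[:, None]
    log_mu += truth.batch_effects[batches.codes, :]

    if cell_type_programs is not None:
        if cell_types is None:
            cell_types = rng.integers(0, cell_type_programs.shape[0], size=n_cells)
        log_mu += cell_type_programs[np.asarray(cell_types), :]
        type_labels = np.array([f"type{t}" for t in np.asarray(cell_types)])
    else:
        type_labels = np.array(["type0"] * n_cells)

    dose = truth.dosage()[cells["individual"].to_numpy(), :]  # (cells, sites)
    gene_ix = {g: j for j, g in enumerate(genes["gene"])}
    for table in (truth.planted_cis, truth.planted_trans):
        if table is None or table.empty:
            continue
        for _, row in table.iterrows():
            j = gene_ix[row["gene"]]
            log_mu[:, j] += row["effect"] * dose[:, int(row["marker"])]

    if np.max(log_mu) > 30.0:
        raise OverflowError("expression mean overflow: |log mu| too large")
    mu = np.exp(log_mu)
    lam = rng.gamma(shape=truth.theta[None, :], scale=mu / truth.theta[None, :])
    counts = rng.poisson(lam)

    adata = ad.AnnData(
        X=sp.csr_matrix(counts),
        obs=pd.DataFrame(
            {
                "batch": batches,
                "individual": cells["individual"].to_numpy(),
                "sex": cells["sex"].to_numpy(),
                "cell_type": type_labels,
            },
            index=cells["cell"].to_numpy(),
        ),
        var=genes.set_index("gene"),
    )
    adata.obs["total_umis"] = np.asarray(adata.X.sum(axis=1)).ravel()
    adata.uns["sim_seed"] = seed
    return adata


@dataclass
class SimDataset:
    """Bundle of everything one simulated experiment produces."""

    design: CrossDesign
    truth: SimTruth
    cells: pd.DataFrame
    allele_counts: AlleleCountMatrix
    expression: ad.AnnData


def simulate_dataset(
    design: CrossDesign | None = None,
    genome: SimGenome | None = None,
    seed: int = 0,
    n_cis: int = 0,
    cis_effect: float = 0.5,
    n_hotspot_targets: int = 0,
    trans_effect: float = 0.5,
    n_cell_types: int = 1,
    median_informative_umis: int = 69,
) -> SimDataset:
    """End-to-end synthetic experiment with one master seed.

    Stage seeds are derived from ``seed`` so each component is
    reproducible on its own.
    """
    design = design or CrossDesign()
    genome = genome or default_genome(seed=seed)
    ss = np.random.SeedSequence(seed).spawn(5)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    truth = simulate_pedigree(design, genome, seed=seeds[0])
    cells = sample_cells(design, truth, seed=seeds[1])
    if n_cis or n_hotspot_targets:
        plant_eqtls(
            truth,
            n_cis=n_cis,
            cis_effect=cis_effect,
            n_hotspot_targets=n_hotspot_targets,
            trans_effect=trans_effect,
            seed=seeds[2],
        )
    acm = simulate_allele_counts(
        truth, cells, median_informative_umis=median_informative_umis, seed=seeds[3]
    )
    rng = np.random.default_rng(seeds[4])
    programs = (
        make_celltype_programs(n_cell_types, len(genome.genes), rng)
        if n_cell_types > 1
        else None
    )
    adata = simulate_expression(
        truth, cells, seed=seeds[4], cell_type_programs=programs
    )
    return SimDataset(design, truth, cells, acm, adata)
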