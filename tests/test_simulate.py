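"""Cross simulator: pedigree genetics, allele counts, expression model."""

import numpy as np
import pytest

from cellqtl import simulate as sim
from cellqtl.hmm import haldane_rho
from cellqtl.simulate import CrossDesign, _meiosis


def x_genotype_frequencies(generations: int):
    """Exact hermaphrodite X genotype frequencies by pedigree recursion.

    Tracks the CB-allele frequency in the hermaphrodite (h) and male (m)
    X pools: h' = (h + m)/2, m' = h, starting from N2 dams x CB sires.
    An F_g individual's maternal gamete draws from the generation g-1
    hermaphrodite pool and its paternal X from the g-1 male pool;
    genotypes assume random mating (alleles independent).
    """
    h, m = 0.0, 1.0
    for _ in range(generations - 1):
        h, m = (h + m) / 2.0, h
    return (1 - h) * (1 - m), h * (1 - m) + (1 - h) * m, h * m


@pytest.fixture(scope="module")
def genome():
    return sim.default_genome(
        n_autosomes=1, with_x=True, sites_per_chrom=30, genes_per_chrom=20, seed=1
    )


class TestPedigree:
    def test_f2_autosomal_mendelian_ratios(self, genome):
        d = CrossDesign(n_seeded=10000, dissociation_rate=1.0, n_cells=1,
                        generations=2, n_founders=1000)
        tr = sim.simulate_pedigree(d, genome, seed=1)
        auto = (tr.genome.variant_sites["chrom"] != "X").to_numpy()
        g = tr.genotypes[:, auto]
        freqs = np.array([(g == k).mean() for k in range(3)])
        assert np.abs(freqs - [0.25, 0.5, 0.25]).max() < 0.02

    def test_f4_x_hermaphrodite_frequencies(self, genome):
        d = CrossDesign(n_seeded=20000, dissociation_rate=1.0, n_cells=1,
                        generations=4, n_founders=1000)
        tr = sim.simulate_pedigree(d, genome, seed=2)
        xm = (tr.genome.variant_sites["chrom"] == "X").to_numpy()
        g = tr.genotypes[np.ix_(tr.sex == "H", xm)]
        obs = np.array([(g == k).mean() for k in range(3)])
        expect = np.array(x_genotype_frequencies(4))
        assert np.allclose(expect, [15 / 32, 14 / 32, 3 / 32])  # oracle sanity
        assert np.abs(obs - expect).max() < 0.02

    def test_autosomal_cb_allele_frequency_stays_half(self, genome):
        d = CrossDesign(n_seeded=20000, dissociation_rate=1.0, n_cells=1,
                        generations=4, n_founders=1000)
        tr = sim.simulate_pedigree(d, genome, seed=3)
        auto = (tr.genome.variant_sites["chrom"] != "X").to_numpy()
        assert tr.genotypes[:, auto].mean() / 2.0 == pytest.approx(0.5, abs=0.02)

    def test_single_generation_rejected(self):
        with pytest.raises(ValueError, match="generations"):
            CrossDesign(generations=1)

    def test_crossovers_per_meiosis_match_map_length(self, genome):
        # one chromosome of ~50 single-meiosis cM -> ~0.5 crossovers/gamete
        cm = genome.site_meiosis_cm("chrI")
        rho = haldane_rho(np.diff(cm))
        rng = np.random.default_rng(4)
        n = 40000
        h1 = np.zeros((1, len(cm)), dtype=np.int8)
        h2 = np.ones((1, len(cm)), dtype=np.int8)
        gam = _meiosis(rng, h1, h2, np.zeros(n, dtype=int), rho)
        switches = (np.diff(gam, axis=1) != 0).sum(axis=1).mean()
        morgans = (cm[-1] - cm[0]) / 100.0
        # marker-resolution switches slightly undercount double crossovers
        assert switches == pytest.approx(morgans, rel=0.08)

    def test_n_individuals_derives_from_dissociation(self):
        d = CrossDesign(n_seeded=1001, dissociation_rate=0.5)
        assert d.n_individuals == round(1001 * 0.5)


class TestAlleleCounts:
    def test_error_free_counts_match_genotype(self, genome):
        d = CrossDesign(n_seeded=400, dissociation_rate=1.0, n_cells=200,
                        generations=4, n_founders=100)
        tr = sim.simulate_pedigree(d, genome, seed=5)
        cells = sim.sample_cells(d, tr, seed=6)
        acm = sim.simulate_allele_counts(tr, cells, error_rate=0.0, seed=7)
        g = tr.genotypes[cells["individual"].to_numpy(), :]
        ref = acm.ref.toarray()
        alt = acm.alt.toarray()
        assert (alt[g == 0] == 0).all()  # NN sites only emit N2
        assert (ref[g == 2] == 0).all()  # CC sites only emit CB

    def test_median_informative_umis(self, genome):
        d = CrossDesign(n_seeded=400, dissociation_rate=1.0, n_cells=10000,
                        generations=4, n_founders=100)
        tr = sim.simulate_pedigree(d, genome, seed=8)
        cells = sim.sample_cells(d, tr, seed=9)
        acm = sim.simulate_allele_counts(tr, cells, median_informative_umis=69, seed=10)
        totals = np.asarray((acm.ref + acm.alt).sum(axis=1)).ravel()
        assert abs(np.median(totals) - 69) <= 3

    def test_cells_of_one_individual_share_genotype(self, genome):
        d = CrossDesign(n_seeded=400, dissociation_rate=1.0, n_cells=4,
                        generations=4, n_founders=100)
        tr = sim.simulate_pedigree(d, genome, seed=11)
        cells = sim.sample_cells(d, tr, seed=12)
        cells.loc[1, "individual"] = cells.loc[0, "individual"]
        g = tr.genotypes[cells["individual"].to_numpy(), :]
        assert (g[0] == g[1]).all()
        acm = sim.simulate_allele_counts(tr, cells, seed=13)
        # counts are independent draws, not copies
        assert (acm.ref[0].toarray() != acm.ref[1].toarray()).any()


@pytest.fixture(scope="module")
def flat_truth():
    genome = sim.default_genome(
        n_autosomes=1, with_x=False, sites_per_chrom=10, genes_per_chrom=8, seed=2
    )
    d = CrossDesign(n_seeded=200, dissociation_rate=1.0, n_cells=50000,
                    generations=4, n_founders=100, batches=1)
    tr = sim.simulate_pedigree(d, genome, seed=14)
    cells = sim.sample_cells(d, tr, seed=15)
    return tr, cells


class TestExpression:
    def test_marginal_gamma_poisson_moments(self, flat_truth):
        tr, cells = flat_truth
        tr.theta = np.full(8, 2.0)
        tr.batch_effects = np.zeros((1, 8))
        adata = sim.simulate_expression(tr, cells, seed=16, sd_log_total=0.0)
        X = np.asarray(adata.X.todense())
        j = int(X.mean(axis=0).argmax())  # best-expressed gene
        mu, var = X[:, j].mean(), X[:, j].var()
        assert var == pytest.approx(mu + mu**2 / 2.0, rel=0.1)

    def test_poisson_limit_at_large_theta(self, flat_truth):
        tr, cells = flat_truth
        tr.theta = np.full(8, 1e8)
        tr.batch_effects = np.zeros((1, 8))
        adata = sim.simulate_expression(tr, cells, seed=17, sd_log_total=0.0)
        X = np.asarray(adata.X.todense())
        j = int(X.mean(axis=0).argmax())
        assert X[:, j].var() / X[:, j].mean() == pytest.approx(1.0, rel=0.05)

    def test_planted_effect_scales_mean_by_exp_beta(self, flat_truth):
        tr, cells = flat_truth
        tr.theta = np.full(8, 2.0)
        tr.batch_effects = np.zeros((1, 8))
        gene = tr.genome.genes["gene"].iloc[0]
        import pandas as pd

        tr.planted_cis = pd.DataFrame(
            {"gene": [gene], "marker": [0], "effect": [1.0]}
        )
        adata = sim.simulate_expression(tr, cells, seed=18, sd_log_total=0.0)
        X = np.asarray(adata.X.todense())
        g = tr.genotypes[cells["individual"].to_numpy(), 0]
        ratio = X[g == 2, 0].mean() / X[g == 0, 0].mean()
        assert ratio == pytest.approx(np.e, rel=0.1)  # delta dosage = 1

    def test_mean_overflow_rejected(self, flat_truth):
        tr, cells = flat_truth
        import pandas as pd

        tr.theta = np.full(8, 2.0)
        tr.planted_cis = pd.DataFrame(
            {"gene": [tr.genome.genes["gene"].iloc[0]], "marker": [0],
             "effect": [80.0]}
        )
        with pytest.raises(OverflowError):
            sim.simulate_expression(tr, cells, seed=19)
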