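import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import HealthCheck, settings

from cellqtl import eqtl, simulate as sim

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def enumerate_posteriors(ref, alt, gaps_cm, prior, error_rate=0.002):
    """Exhaustive-path oracle for the genotyping HMM (<= ~8 sites).

    Sums prior x transition x emission over all 3^k state paths and
    returns the per-site marginals; independent of the forward-backward
    implementation it checks.
    """
    from itertools import product

    from cellqtl.hmm import emission_probs, transition_matrix

    ref = np.asarray(ref, float)
    alt = np.asarray(alt, float)
    k = len(ref)
    emis = np.empty((k, 3))
    for j in range(k):
        emis[j] = emission_probs(ref[j], ref[j] + alt[j], error_rate)
    trans = [transition_matrix(d) for d in gaps_cm]
    marg = np.zeros((k, 3))
    for path in product(range(3), repeat=k):
        p = prior[path[0]] * emis[0, path[0]]
        for j in range(1, k):
            p *= trans[j - 1][path[j - 1], path[j]] * emis[j, path[j]]
        for j in range(k):
            marg[j, path[j]] += p
    return marg / marg.sum(axis=1, keepdims=True)


@pytest.fixture(scope="session")
def small_genome():
    """Two autosomes + X, 40 sites and 60 genes per chromosome."""
    return sim.default_genome(
        n_autosomes=2, with_x=True, sites_per_chrom=40, genes_per_chrom=60, seed=11
    )


@pytest.fixture(scope="session")
def planted_dataset(small_genome):
    """Simulated F4 experiment with 12 planted cis effects, 500 cells."""
    design = sim.CrossDesign(
        n_seeded=2000, dissociation_rate=0.5, n_cells=500,
        generations=4, n_founders=300, batches=2,
    )
    return sim.simulate_dataset(
        design=design, genome=small_genome, seed=21, n_cis=12, cis_effect=0.8
    )


@pytest.fixture(scope="session")
def mapping_inputs(planted_dataset):
    """(Y, genes, pruned true-dosage markers, covariates, batch) for scans."""
    ds = planted_dataset
    adata = ds.expression
    Y = sp.csc_matrix(adata.X)
    dose = ds.truth.dosage()[ds.cells["individual"].to_numpy(), :]
    markers = eqtl.prune_markers(dose, ds.truth.genome.variant_sites.copy())
    cov = eqtl.build_design(
        np.log(adata.obs["total_umis"].to_numpy()), adata.obs["batch"].to_numpy()
    )
    return Y, ds.truth.genome.genes, markers, cov, adata.obs["batch"].to_numpy()
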