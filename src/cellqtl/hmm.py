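"""Per-cell genotype inference from sparse transcribed-variant UMI counts.

Each cell of a two-parent recombinant population carries an unknown mosaic
of the two founder genomes (here called N2 and CB, after the *C. elegans*
founder strains whose cross motivates the defaults). A handful of UMIs per
cell overlap transcribed SNVs that distinguish the founders; at each such
site we observe ``r`` UMIs supporting the N2 allele out of ``D`` total.
A three-state hidden Markov chain over the ordered sites — states NN
(homozygous N2), NC (heterozygous), CC (homozygous CB) — combines these
sparse observations along the chromosome:

* priors: Mendelian (1/4, 1/2, 1/4) on autosomes; on X the hermaphrodite
  founders contribute twice as many X chromosomes, giving ~(0.44, 0.44, 0.11);
* emissions: binomial sampling of alleles with a per-read error rate ``e``;
* transitions: Haldane recombination fractions from genetic-map distances,
  with the two homologs transmitted independently.

The forward-backward algorithm yields exact smoothing posteriors, which
are collapsed to an additive allele dosage P(CC) + P(NC)/2 for eQTL
mapping, avoiding hard genotype calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genome import GeneticMap

logger = logging.getLogger(__name__)

#: Default chromosome names treated as the sex chromosome.
X_CHROM_NAMES = frozenset({"X", "chrX", "ChrX"})


@dataclass
class HMMParams:
    """Priors and error rate of the genotyping HMM.

    ``x_prior`` is stored as printed, (0.44, 0.44, 0.11), and normalized to
    sum to one when used.
    """

    error_rate: float = 0.002
    autosomal_prior: tuple[float, float, float] = (0.25, 0.5, 0.25)
    x_prior: tuple[float, float, float] = (0.44, 0.44, 0.11)

    def __post_init__(self) -> None:
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        if any(p < 0 for p in self.autosomal_prior + self.x_prior):
            raise ValueError("priors must be non-negative")
        a = np.asarray(self.autosomal_prior, float)
        if abs(a.sum() - 1.0) > 1e-9:
            raise ValueError("autosomal prior must sum to 1")

    def prior(self, is_x: bool) -> np.ndarray:
        p = np.asarray(self.x_prior if is_x else self.autosomal_prior, float)
        return p / p.sum()


@dataclass
class AlleleCountMatrix:
    """Sparse per-cell UMI counts supporting each founder allele.

    ``ref`` holds N2-supporting counts and ``alt`` CB-supporting counts,
    both cells x sites. ``sites`` is a DataFrame with ``chrom`` and ``pos``
    columns, strictly ordered by (chromosome, position).
    """

    ref: sp.csr_matrix
    alt: sp.csr_matrix
    sites: pd.DataFrame
    barcodes: list[str]

    def __post_init__(self) -> None:
        self.ref = sp.csr_matrix(self.ref)
        self.alt = sp.csr_matrix(self.alt)
        if self.ref.shape != self.alt.shape:
            raise ValueError(
                f"ref/alt shapes differ: {self.ref.shape} vs {self.alt.shape}"
            )
        if self.ref.shape[1] != len(self.sites):
            raise ValueError(
                f"{self.ref.shape[1]} matrix columns vs {len(self.sites)} sites"
            )
        if self.ref.shape[0] != len(self.barcodes):
            raise ValueError(
                f"{self.ref.shape[0]} matrix rows vs {len(self.barcodes)} barcodes"
            )
        if (self.ref.data < 0).any() or (self.alt.data < 0).any():
            raise ValueError("allele counts must be non-negative")
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            if np.any(np.diff(grp["pos"].to_numpy()) <= 0):
                raise ValueError(f"sites not strictly ordered on {chrom}")

    @property
    def n_cells(self) -> int:
        return self.ref.shape[0]

    @property
    def n_sites(self) -> int:
        return self.ref.shape[1]

    def total_support(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-cell summed (N2-supporting, CB-supporting) UMI counts."""
        return (
            np.asarray(self.ref.sum(axis=1)).ravel(),
            np.asarray(self.alt.sum(axis=1)).ravel(),
        )


@dataclass
class GenotypePosterior:
    """Smoothing posteriors per cell x site over (NN, NC, CC)."""

    probs: np.ndarray  # (n_cells, n_sites, 3)
    sites: pd.DataFrame
    barcodes: list[str]

    def __post_init__(self) -> None:
        if self.probs.ndim != 3 or self.probs.shape[2] != 3:
            raise ValueError("probs must have shape (cells, sites, 3)")

    @property
    def dosage(self) -> np.ndarray:
        """Additive CB-allele dosage in [0, 1]: P(CC) + 0.5 P(NC)."""
        return self.probs[..., 2] + 0.5 * self.probs[..., 1]


def emission_probs(r, D, e: float = 0.002):
    """Binomial emission probabilities for (NN, NC, CC) given counts.

    ``r`` N2-supporting reads out of ``D`` total at a site. Homozygotes
    emit the matching allele with probability 1 - e, the other with e;
    heterozygotes emit each allele with probability 1/2. Computed in log
    space; includes the shared binomial coefficient.
    """
    r = np.asarray(r, dtype=float)
    D = np.asarray(D, dtype=float)
    if np.any(r < 0) or np.any(r > D):
        raise ValueError("require 0 <= r <= D")
    from scipy.special import gammaln

    logc = gammaln(D + 1) - gammaln(r + 1) - gammaln(D - r + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_e = np.log(e) if e > 0 else -np.inf
        log_1me = np.log1p(-e)
        p_nn = np.exp(logc + r * log_1me + np.where(D - r > 0, (D - r) * log_e, 0.0))
        p_nc = np.exp(logc - D * np.log(2.0))
        p_cc = np.exp(logc + np.where(r > 0, r * log_e, 0.0) + (D - r) * log_1me)
    return p_nn, p_nc, p_cc


def haldane_rho(d_cm) -> np.ndarray:
    """Haldane map function: cM distance -> recombination fraction."""
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))


def transition_matrix(d_cm_scaled: float) -> np.ndarray:
    """3x3 genotype transition matrix over a scaled cM distance.

    The two homologs recombine independently with Haldane fraction rho,
    giving the classic F2-style transition kernel; rows sum to 1 and the
    stationary distribution is (1/4, 1/2, 1/4).
    """
    rho = float(haldane_rho(d_cm_scaled))
    q = 1.0 - rho
    return np.array(
        [
            [q * q, 2 * rho * q, rho * rho],
            [rho * q, q * q + rho * rho, rho * q],
            [rho * rho, 2 * rho * q, q * q],
        ]
    )


def _log_emissions(ref: np.ndarray, alt: np.ndarray, e: float) -> np.ndarray:
    """Log emissions (cells, sites, 3), binomial coefficient omitted.

    The coefficient is common to all three states and cancels in the
    posterior normalization.
    """
    with np.errstate(divide="ignore"):
        log_e = np.log(e) if e > 0 else -np.inf
    log_1me = np.log1p(-e)
    ln2 = np.log(2.0)
    out = np.empty(ref.shape + (3,), dtype=float)
    # 0 * -inf -> 0 for the e = 0 limit
    with np.errstate(invalid="ignore"):
        out[..., 0] = ref * log_1me + np.where(alt > 0, alt * log_e, 0.0)
        out[..., 1] = -(ref + alt) * ln2
        out[..., 2] = np.where(ref > 0, ref * log_e, 0.0) + alt * log_1me
    return out


def forward_backward(
    ref: np.ndarray,
    alt: np.ndarray,
    d_cm_scaled: np.ndarray,
    prior: np.ndarray,
    error_rate: float = 0.002,
) -> np.ndarray:
    """Vectorized forward-backward smoothing over one chromosome.

    Parameters
    ----------
    ref, alt
        Dense (cells, sites) N2- and CB-supporting counts.
    d_cm_scaled
        Scaled cM gaps between adjacent sites, length ``n_sites - 1``.
    prior
        Initial state distribution over (NN, NC, CC).

    Returns
    -------
    (cells, sites, 3) posterior probabilities; rows sum to one. Sites
    with zero depth contribute flat emissions, so a cell with no counts
    anywhere has posterior equal to the prior at every site.
    """
    ref = np.atleast_2d(np.asarray(ref, float))
    alt = np.atleast_2d(np.asarray(alt, float))
    n_cells, n_sites = ref.shape
    if n_sites == 0:
        raise ValueError("need at least one site")
    if len(d_cm_scaled) != n_sites - 1:
        raise ValueError("need one gap per adjacent site pair")

    logb = _log_emissions(ref, alt, error_rate)
    # per (cell, site) max-normalization keeps emissions in a safe range
    b = np.exp(logb - logb.max(axis=2, keepdims=True))
    trans = [transition_matrix(d) for d in np.asarray(d_cm_scaled, float)]

    alpha = np.empty((n_cells, n_sites, 3))
    a = prior[None, :] * b[:, 0, :]
    norm = a.sum(axis=1, keepdims=True)
    if np.any(norm <= 0):
        raise AssertionError("all-zero emission row; unreachable for D=0 flat")
    alpha[:, 0, :] = a / norm
    for j in range(1, n_sites):
        a = (alpha[:, j - 1, :] @ trans[j - 1]) * b[:, j, :]
        a /= a.sum(axis=1, keepdims=True)
        alpha[:, j, :] = a

    beta = np.empty((n_cells, n_sites, 3))
    beta[:, -1, :] = 1.0
    for j in range(n_sites - 2, -1, -1):
        bb = (b[:, j + 1, :] * beta[:, j + 1, :]) @ trans[j].T
        bb /= bb.sum(axis=1, keepdims=True)
        beta[:, j, :] = bb

    post = alpha * beta
    post /= post.sum(axis=2, keepdims=True)
    return post


def infer_genotypes(
    counts: AlleleCountMatrix,
    gmap: GeneticMap,
    params: HMMParams | None = None,
    x_chroms=X_CHROM_NAMES,
) -> GenotypePosterior:
    """Run the genotyping HMM chromosome by chromosome for every cell.

    Chains restart at each chromosome with the chromosome-appropriate
    prior (autosomal or X). Map distances are interpolated at the variant
    sites and scaled by ``gmap.scale_factor`` before the Haldane
    conversion.
    """
    params = params or HMMParams()
    n_cells = counts.n_cells
    probs = np.empty((n_cells, counts.n_sites, 3))
    ref = counts.ref.tocsc()
    alt = counts.alt.tocsc()
    for chrom, grp in counts.sites.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        cm = gmap.interpolate(chrom, grp["pos"].to_numpy())
        gaps = np.diff(cm) * gmap.scale_factor
        prior = params.prior(chrom in x_chroms)
        r = ref[:, idx].toarray()
        a = alt[:, idx].toarray()
        probs[:, idx, :] = forward_backward(r, a, gaps, prior, params.error_rate)
    return GenotypePosterior(probs=probs, sites=counts.sites, barcodes=counts.barcodes)


def dosage(posterior: np.ndarray) -> np.ndarray:
    """Additive CB dosage from posterior probabilities (..., 3)."""
    p = np.asarray(posterior, float)
    return p[..., 2] + 0.5 * p[..., 1]


def expected_unique_genotypes(n_cells: int, n_individuals: int) -> float:
    """Birthday-problem expectation of cells carrying a unique genotype.

    With C cells sampled uniformly from I individuals, the expected number
    of cells whose individual was sampled exactly once is C (1 - 1/I)^(C-1).
    """
    if n_cells < 1 or n_individuals < 1:
        raise ValueError("need C >= 1 and I >= 1")
    return float(n_cells * (1.0 - 1.0 / n_individuals) ** (n_cells - 1))


def collision_count(dosage_matrix: np.ndarray, threshold: float = 0.9) -> int:
    """Count cells whose genotype profile nearly duplicates another cell's.

    A cell is counted when the maximal Pearson correlation of its
    genome-wide dosage vector with any other cell exceeds ``threshold``.
    Cells with constant dosage vectors are excluded (and logged) because
    their correlation is undefined.
    """
    d = np.asarray(dosage_matrix, float)
    if d.ndim != 2 or d.shape[0] < 2:
        raise ValueError("need a (cells, markers) matrix with >= 2 cells")
    sd = d.std(axis=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("excluding %d constant-dosage cell(s)", (~keep).sum())
    z = d[keep]
    z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, keepdims=True)
    corr = (z @ z.T) / z.shape[1]
    np.fill_diagonal(corr, -np.inf)
    return int((corr.max(axis=1) > threshold).sum())


def assign_parental(
    ref_support: np.ndarray, alt_support: np.ndarray, min_support: int = 50
) -> np.ndarray:
    """Assign cells to a parental strain from summed allele support.

    A cell is called N2 if at least ``min_support`` UMIs support N2 and
    fewer than ``min_support`` support CB; symmetrically for CB; otherwise
    it is left unassigned.
    """
    ref_support = np.asarray(ref_support)
    alt_support = np.asarray(alt_support)
    out = np.full(ref_support.shape, "unassigned", dtype=object)
    out[(ref_support >= min_support) & (alt_support < min_support)] = "N2"
    out[(alt_support >= min_support) & (ref_support < min_support)] = "CB4856"
    return out
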