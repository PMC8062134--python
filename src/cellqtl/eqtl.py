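"""cis/trans eQTL mapping with negative-binomial GLMs.

For each expressed transcript in a cell type the full model is

    log mu = beta_i + X_t beta_t + X_b beta_b + X_c beta_c

where X_t = log(total UMIs per cell) absorbs compositional effects, X_b
are batch indicators and X_c is the standardized genotype dosage at the
closest pruned marker (cis) or at each marker in turn (trans scan).
Overdispersion theta is estimated once per transcript on the full cis
model and reused for all other fits of that transcript. Significance is
a likelihood-ratio test against the model without the genetic term,
expressed as a LOD score LRT / (2 ln 10); peaks get 1.5-LOD-drop support
intervals and permutation-based FDR-adjusted p-values (genotype rows are
permuted within batch, with the same ordering for every transcript).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import binomtest

from .nbglm import fit_nb_glm, lrt_lod

logger = logging.getLogger(__name__)

LN10_2 = 2.0 * np.log(10.0)


# ---------------------------------------------------------------------------
# marker handling


@dataclass
class MarkerDosage:
    """Standardized per-cell dosages at LD-pruned markers.

    ``values`` is (cells, markers) with each column standardized to mean 0
    and population variance 1; ``coords`` carries chrom / pos (bp) and,
    when available, cM for every retained marker.
    """

    values: np.ndarray
    coords: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.coords):
            raise ValueError("values/coords marker count mismatch")

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]


def standardize(x: np.ndarray) -> np.ndarray:
    """Column-standardize with population (1/n) variance."""
    x = np.asarray(x, float)
    mu = x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


def prune_markers(
    dosage: np.ndarray, coords: pd.DataFrame, r_max: float = 0.9999
) -> MarkerDosage:
    """Greedy LD pruning of near-duplicate markers.

    Scanning left to right within each chromosome, a marker is kept
    unless its Pearson correlation with the last kept marker exceeds
    ``r_max``. Retained columns are standardized. With posterior-based
    dosages this is approximately a fixed-cM marker grid.
    """
    dosage = np.asarray(dosage, float)
    if dosage.shape[1] != len(coords):
        raise ValueError("dosage/coords marker count mismatch")
    z = standardize(dosage)
    n = dosage.shape[0]
    keep: list[int] = []
    coords = coords.reset_index(drop=True)
    for chrom, grp in coords.groupby("chrom", sort=False):
        last = None
        for j in grp.index:
            if np.all(dosage[:, j] == dosage[0, j]):
                continue  # constant marker carries no information
            if last is not None:
                r = float(z[:, last] @ z[:, j]) / n
                if abs(r) > r_max:
                    continue
            keep.append(j)
            last = j
    kept = np.array(keep, dtype=int)
    return MarkerDosage(
        values=standardize(dosage[:, kept]),
        coords=coords.iloc[kept].reset_index(drop=True),
    )


def closest_marker(markers: pd.DataFrame, chrom: str, pos: float) -> int | None:
    """Index of the marker nearest to (chrom, pos); None if none on chrom."""
    on = markers.index[markers["chrom"] == chrom]
    if len(on) == 0:
        return None
    d = (markers.loc[on, "pos"] - pos).abs()
    return int(d.idxmin())


# ---------------------------------------------------------------------------
# expression filtering and design matrices


def filter_expressed(Y: sp.spmatrix, min_cells: int = 20) -> np.ndarray:
    """Boolean mask of genes with >= 1 UMI in at least ``min_cells`` cells."""
    ncells = np.asarray((Y > 0).sum(axis=0)).ravel()
    mask = ncells >= min_cells
    if not mask.any():
        logger.warning("no gene passes the expression filter")
    return mask


def build_design(log_totals: np.ndarray, batch: np.ndarray) -> np.ndarray:
    """Covariate matrix: intercept, log total UMIs, batch indicators.

    The first batch level is the reference (absorbed by the intercept).
    """
    log_totals = np.asarray(log_totals, float)
    batch = pd.Categorical(batch)
    cols = [np.ones_like(log_totals), log_totals]
    for lev in batch.categories[1:]:
        cols.append((batch == lev).astype(float))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# scans


def _gene_column(Y: sp.csc_matrix, j: int) -> np.ndarray:
    return np.asarray(Y[:, [j]].todense()).ravel()


def cis_scan(
    Y: sp.spmatrix,
    genes: pd.DataFrame,
    markers: MarkerDosage,
    covariates: np.ndarray,
    min_cells: int = 20,
) -> pd.DataFrame:
    """Single-marker cis test per gene at its closest pruned marker.

    ``genes`` needs columns ``gene``, ``chrom``, ``pos`` aligned with the
    columns of ``Y``. Returns one row per tested gene with the estimated
    theta (reused downstream), the genetic effect on the standardized
    dosage scale, LOD and the chi2(1) p-value.
    """
    Y = sp.csc_matrix(Y)
    expressed = filter_expressed(Y, min_cells=min_cells)
    rows = []
    for j, g in genes.reset_index(drop=True).iterrows():
        if not expressed[j]:
            continue
        m = closest_marker(markers.coords, g["chrom"], g["pos"])
        if m is None:
            logger.info("gene %s: no marker on %s, skipped", g["gene"], g["chrom"])
            continue
        y = _gene_column(Y, j)
        Xf = np.column_stack([covariates, markers.values[:, m]])
        try:
            full = fit_nb_glm(y, Xf)  # theta estimated here, once per transcript
        except np.linalg.LinAlgError:
            logger.warning(
                "gene %s: degenerate design at marker %d, skipped", g["gene"], m
            )
            continue
        red = fit_nb_glm(y, covariates, theta=full.theta)
        try:
            lrt, lod, p = lrt_lod(full.loglik, red.loglik)
        except ValueError:
            full = fit_nb_glm(y, Xf, theta=full.theta)
            lrt, lod, p = lrt_lod(full.loglik, red.loglik)
        rows.append(
            {
                "gene": g["gene"],
                "gene_chrom": g["chrom"],
                "gene_pos": g["pos"],
                "marker": m,
                "marker_chrom": markers.coords.loc[m, "chrom"],
                "marker_pos": markers.coords.loc[m, "pos"],
                "theta": full.theta,
                "effect": full.beta[-1],
                "lod": lod,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def _lod_curve_for_gene(
    y: np.ndarray,
    covariates: np.ndarray,
    marker_values: np.ndarray,
    theta: float,
    l_reduced: float,
) -> np.ndarray:
    """LOD at every marker for one transcript, theta fixed."""
    n_markers = marker_values.shape[1]
    lods = np.empty(n_markers)
    for m in range(n_markers):
        Xf = np.column_stack([covariates, marker_values[:, m]])
        fit = fit_nb_glm(y, Xf, theta=theta)
        _, lods[m], _ = lrt_lod(fit.loglik, l_reduced, slack=1e-4)
    return lods


def lod_drop_ci(lods: np.ndarray, peak: int, drop: float = 1.5) -> tuple[int, int]:
    """1.5-LOD-drop support interval around a peak (indices, inclusive).

    Returns the outermost markers with LOD >= peak LOD - drop, clamped to
    the ends of the curve. A flat curve spans everything; an isolated
    spike collapses to the peak itself.
    """
    lods = np.asarray(lods, float)
    if lods.size == 0:
        raise ValueError("empty LOD curve")
    thr = lods[peak] - drop
    above = np.flatnonzero(lods >= thr)
    return int(above.min()), int(above.max())


def trans_scan(
    Y: sp.spmatrix,
    genes: pd.DataFrame,
    markers: MarkerDosage,
    covariates: np.ndarray,
    thetas: pd.Series | None = None,
    min_cells: int = 20,
    lod_drop: float = 1.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genome-wide single-marker scan for every expressed transcript.

    theta per transcript is taken from ``thetas`` (indexed by gene name,
    typically from :func:`cis_scan`) or estimated on the covariate-only
    model when missing. Returns (peaks, lod_matrix): one peak per gene
    per chromosome (ties broken leftmost) with a 1.5-LOD-drop interval,
    plus the full genes x markers LOD matrix as a tidy DataFrame.
    """
    Y = sp.csc_matrix(Y)
    expressed = filter_expressed(Y, min_cells=min_cells)
    chrom_groups = list(markers.coords.groupby("chrom", sort=False))
    peaks = []
    lodmat = {}
    for j, g in genes.reset_index(drop=True).iterrows():
        if not expressed[j]:
            continue
        y = _gene_column(Y, j)
        if thetas is not None and g["gene"] in thetas.index:
            theta = float(thetas[g["gene"]])
            red = fit_nb_glm(y, covariates, theta=theta)
        else:
            red = fit_nb_glm(y, covariates)
            theta = red.theta
        lods = _lod_curve_for_gene(y, covariates, markers.values, theta, red.loglik)
        lodmat[g["gene"]] = lods
        for chrom, grp in chrom_groups:
            idx = grp.index.to_numpy()
            sub = lods[idx]
            k = int(np.argmax(sub))  # argmax returns the leftmost maximum
            lo, hi = lod_drop_ci(sub, k, drop=lod_drop)
            m = idx[k]
            Xf = np.column_stack([covariates, markers.values[:, m]])
            eff = fit_nb_glm(y, Xf, theta=theta).beta[-1]
            peaks.append(
                {
                    "gene": g["gene"],
                    "gene_chrom": g["chrom"],
                    "gene_pos": g["pos"],
                    "marker": m,
                    "marker_chrom": chrom,
                    "marker_pos": grp.loc[m, "pos"],
                    "theta": theta,
                    "effect": eff,
                    "lod": float(sub[k]),
                    "ci_lo_marker": idx[lo],
                    "ci_hi_marker": idx[hi],
                    "ci_lo_pos": grp.loc[idx[lo], "pos"],
                    "ci_hi_pos": grp.loc[idx[hi], "pos"],
                }
            )
    lod_df = pd.DataFrame(lodmat).T
    return pd.DataFrame(peaks), lod_df


# ---------------------------------------------------------------------------
# permutation FDR


@dataclass
class FdrCurve:
    """Mapping from LOD thresholds to permutation-based FDR.

    thresholds run from 0.1 to max observed LOD + 0.1 in steps of 0.01;
    expected counts are means over permutations; FDR = expected/observed,
    clipped to [0, 1] and monotonized (non-increasing in the threshold,
    q-value style).
    """

    thresholds: np.ndarray
    expected: np.ndarray
    observed: np.ndarray
    fdr: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.where(self.observed > 0, self.expected / self.observed, np.nan)
        raw = np.clip(raw, 0.0, 1.0)
        # monotonize (non-increasing in the threshold) over the supported
        # (observed > 0) range: running minimum over increasing thresholds
        ok = self.observed > 0
        raw[ok] = np.minimum.accumulate(raw[ok])
        self.fdr = raw

    def fdr_at(self, lod) -> np.ndarray:
        """Interpolated FDR-adjusted p for peak LOD scores (clamped)."""
        ok = np.isfinite(self.fdr)
        if not ok.any():
            logger.warning("FDR curve unsupported everywhere; returning 1.0")
            return np.ones_like(np.atleast_1d(np.asarray(lod, float)))
        t, f = self.thresholds[ok], self.fdr[ok]
        return np.interp(np.asarray(lod, float), t, f, left=f[0], right=f[-1])


def _threshold_grid(max_lod: float) -> np.ndarray:
    n = int(np.floor(max_lod / 0.01)) + 1
    return 0.1 + 0.01 * np.arange(n + 1)


def permute_within_batch(
    rng: np.random.Generator, batch: np.ndarray, units: np.ndarray | None = None
) -> np.ndarray:
    """A permutation of cell indices that shuffles genotypes within batch.

    With ``units`` given (cell -> individual), whole individuals swap
    genotypes within each batch so that cells of one individual stay
    genotypically identical; otherwise each cell is treated as its own
    segregant.
    """
    batch = np.asarray(batch)
    perm = np.arange(len(batch))
    for b in pd.unique(batch):
        idx = np.flatnonzero(batch == b)
        if units is None:
            perm[idx] = rng.permutation(idx)
        else:
            u = np.asarray(units)[idx]
            levels = pd.unique(u)
            shuffled = rng.permutation(levels)
            donor = {lev: shuffled[i] for i, lev in enumerate(levels)}
            first_cell = {lev: idx[u == lev][0] for lev in levels}
            perm[idx] = [first_cell[donor[lev]] for lev in u]
    return perm


def permutation_fdr(
    Y: sp.spmatrix,
    genes: pd.DataFrame,
    markers: MarkerDosage,
    covariates: np.ndarray,
    batch: np.ndarray,
    peaks: pd.DataFrame,
    mode: str = "cis",
    n_perm: int = 10,
    seed: int = 0,
    units: np.ndarray | None = None,
    min_cells: int = 20,
) -> tuple[pd.DataFrame, dict]:
    """Permutation-based FDR for cis or trans peaks.

    Segregant genotypes are permuted within batch (the same ordering for
    all transcripts in a permutation instance) and the scan statistic is
    recomputed with each transcript's theta held at its observed-data
    estimate. For ``mode='cis'`` the statistic is the LOD at the closest
    marker; for ``mode='trans'`` it is the per-chromosome maximum LOD and
    a separate FDR curve is built per chromosome. Returns the ``peaks``
    table with an ``fdr`` column appended, and the FDR curves.
    """
    if mode not in {"cis", "trans"}:
        raise ValueError("mode must be 'cis' or 'trans'")
    if peaks.empty:
        return peaks.assign(fdr=[]), {}
    peaks = peaks.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    Y = sp.csc_matrix(Y)
    gene_ix = {g: j for j, g in enumerate(genes["gene"])}

    # the reduced (no-genotype) model is invariant under genotype
    # permutation: fit it once per transcript
    red_ll: dict[str, float] = {}
    for _, pk in peaks.iterrows():
        if pk["gene"] not in red_ll:
            y = _gene_column(Y, gene_ix[pk["gene"]])
            red_ll[pk["gene"]] = fit_nb_glm(y, covariates, theta=pk["theta"]).loglik

    def perm_stats(perm: np.ndarray) -> pd.DataFrame:
        vals = markers.values[perm]
        rows = []
        for _, pk in peaks.iterrows():
            y = _gene_column(Y, gene_ix[pk["gene"]])
            theta = pk["theta"]
            if mode == "cis":
                Xf = np.column_stack([covariates, vals[:, int(pk["marker"])]])
                fit = fit_nb_glm(y, Xf, theta=theta)
                _, lod, _ = lrt_lod(fit.loglik, red_ll[pk["gene"]], slack=1e-4)
                rows.append(
                    {"gene": pk["gene"], "chrom": pk["marker_chrom"], "lod": lod}
                )
            else:
                on = markers.coords.index[
                    markers.coords["chrom"] == pk["marker_chrom"]
                ].to_numpy()
                lods = _lod_curve_for_gene(
                    y, covariates, vals[:, on], theta, red_ll[pk["gene"]]
                )
                rows.append(
                    {
                        "gene": pk["gene"],
                        "chrom": pk["marker_chrom"],
                        "lod": float(lods.max()),
                    }
                )
        return pd.DataFrame(rows)

    perm_frames = []
    for _ in range(n_perm):
        perm = permute_within_batch(rng, batch, units)
        perm_frames.append(perm_stats(perm))

    curves: dict = {}
    fdr_col = np.ones(len(peaks))
    if mode == "cis":
        groups = [("all", peaks)]
    else:
        groups = list(peaks.groupby("marker_chrom", sort=False))
    for key, obs in groups:
        obs_lod = obs["lod"].to_numpy()
        grid = _threshold_grid(float(obs_lod.max()))
        observed = (obs_lod[None, :] > grid[:, None]).sum(axis=1).astype(float)
        exp_counts = np.zeros_like(grid)
        for pf in perm_frames:
            if mode == "cis":
                pl = pf["lod"].to_numpy()
            else:
                pl = pf.loc[pf["chrom"] == key, "lod"].to_numpy()
            exp_counts += (pl[None, :] > grid[:, None]).sum(axis=1)
        exp_counts /= n_perm
        curve = FdrCurve(grid, exp_counts, observed)
        curves[key] = curve
        fdr_col[obs.index.to_numpy()] = curve.fdr_at(obs_lod)
    out = peaks.copy()
    out["fdr"] = fdr_col
    return out, curves


# ---------------------------------------------------------------------------
# auxiliary statistics


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def lod_from_correlation(r2, n: int) -> float:
    """LOD score of a marker-trait Pearson correlation: -n ln(1-R^2)/(2 ln 10).

    This is the Gaussian nested-model log10 likelihood ratio for a single
    regressor; used for bulk (whole-organism) eQTL data.
    """
    r2 = float(r2)
    if not (0.0 <= r2 < 1.0):
        raise ValueError("R^2 must lie in [0, 1)")
    if n < 2:
        raise ValueError("need n >= 2")
    return float(-n * np.log1p(-r2) / LN10_2)


def stouffer_combine(z, weights=None) -> float:
    """Stouffer's weighted-Z combination: sum(w z) / sqrt(sum(w^2))."""
    z = np.asarray(z, float)
    if z.size == 0:
        raise ValueError("need at least one effect")
    w = np.ones_like(z) if weights is None else np.asarray(weights, float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return float((w * z).sum() / np.sqrt((w**2).sum()))


def direction_concordance(effects_a, effects_b) -> tuple[int, int, float]:
    """Sign agreement between two sets of paired effect estimates.

    Zero effects are excluded (and logged). Returns (n_same, n_opposite,
    two-sided exact binomial p against chance agreement of 1/2).
    """
    a = np.asarray(effects_a, float)
    b = np.asarray(effects_b, float)
    if a.shape != b.shape:
        raise ValueError("effect vectors must be paired")
    keep = (a != 0) & (b != 0)
    if not keep.all():
        logger.info("excluding %d zero-effect pair(s)", (~keep).sum())
    same = int((np.sign(a[keep]) == np.sign(b[keep])).sum())
    n = int(keep.sum())
    p = float(binomtest(same, n, 0.5, alternative="two-sided").pvalue) if n else 1.0
    return same, n - same, p
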