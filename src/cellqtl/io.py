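"""Readers and writers for the on-disk formats, plus the pipeline driver.

Formats follow the upstream single-cell conventions: variant sites as a
plain VCF; allele-count and expression matrices as MatrixMarket triplets
with features in rows and cells in columns (the orientation emitted by
droplet-sequencing allele counters); genetic map, metadata, gene
coordinates and result tables as TSV. Coordinates are 1-based inclusive
throughout, matching VCF.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp
import yaml

from .genome import GeneticMap
from .hmm import AlleleCountMatrix, GenotypePosterior, HMMParams, infer_genotypes

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# VCF


def write_vcf(sites: pd.DataFrame, path) -> None:
    """Write biallelic variant sites as a minimal VCF (CHROM/POS/REF/ALT)."""
    path = Path(path)
    ref = sites["ref"] if "ref" in sites else pd.Series(["A"] * len(sites))
    alt = sites["alt"] if "alt" in sites else pd.Series(["T"] * len(sites))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for (_, row), r, a in zip(sites.iterrows(), ref, alt):
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t.\t{r}\t{a}\t.\tPASS\t.\n"
            )


def read_vcf_sites(path) -> pd.DataFrame:
    """Read variant sites (chrom, pos, ref, alt) from a VCF."""
    from cyvcf2 import VCF

    rows = []
    for v in VCF(str(path)):
        alt = v.ALT[0] if v.ALT else "."
        rows.append({"chrom": v.CHROM, "pos": v.POS, "ref": v.REF, "alt": alt})
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])


# ---------------------------------------------------------------------------
# allele counts


def write_allele_counts(counts: AlleleCountMatrix, outdir) -> None:
    """VCF + two MTX triplet matrices (sites x cells) + barcode list."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_vcf(counts.sites, outdir / "variants.vcf")
    sio.mmwrite(outdir / "ref.mtx", sp.coo_matrix(counts.ref.T, dtype=int))
    sio.mmwrite(outdir / "alt.mtx", sp.coo_matrix(counts.alt.T, dtype=int))
    pd.Series(counts.barcodes).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )


def read_allele_counts(vcf_path, ref_mtx, alt_mtx, barcodes_path) -> AlleleCountMatrix:
    """Assemble an :class:`AlleleCountMatrix` from on-disk pieces.

    Matrices are sites x cells on disk and transposed on read. Sites are
    sorted by (chromosome in order of first appearance, position), with
    the same permutation applied to the matrices; dimension mismatches
    raise with both shapes printed.
    """
    sites = read_vcf_sites(vcf_path)
    ref = sp.csr_matrix(sio.mmread(str(ref_mtx)).T)
    alt = sp.csr_matrix(sio.mmread(str(alt_mtx)).T)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()
    if ref.shape != (len(barcodes), len(sites)):
        raise ValueError(
            f"matrix shape {ref.shape} does not match "
            f"({len(barcodes)} barcodes, {len(sites)} VCF sites)"
        )
    chrom_rank = {c: i for i, c in enumerate(pd.unique(sites["chrom"]))}
    order = np.lexsort((sites["pos"], sites["chrom"].map(chrom_rank)))
    if not np.array_equal(order, np.arange(len(sites))):
        logger.info("VCF sites were unsorted; applying permutation")
        sites = sites.iloc[order].reset_index(drop=True)
        ref = ref[:, order]
        alt = alt[:, order]
    acm = AlleleCountMatrix(ref=ref, alt=alt, sites=sites, barcodes=barcodes)
    logger.info(
        "allele counts: %d cells x %d sites, %d informative UMIs",
        acm.n_cells, acm.n_sites, int(acm.ref.sum() + acm.alt.sum()),
    )
    return acm


# ---------------------------------------------------------------------------
# genetic map


def write_map(gmap: GeneticMap, path) -> None:
    rows = [
        {"chrom": chrom, "bp": int(bp), "cM": cm}
        for chrom, arr in gmap.anchors.items()
        for bp, cm in arr
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_map(path, scale_factor: float = 0.4) -> GeneticMap:
    df = pd.read_csv(path, sep="\t")
    anchors = {
        chrom: grp[["bp", "cM"]].to_numpy(float)
        for chrom, grp in df.groupby("chrom", sort=False)
    }
    return GeneticMap(anchors, scale_factor=scale_factor)


# ---------------------------------------------------------------------------
# expression + metadata


def write_expression(adata: ad.AnnData, outdir) -> None:
    """Expression MTX (genes x cells) + gene coordinates + cell metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = sp.csr_matrix(adata.X)
    sio.mmwrite(outdir / "expression.mtx", sp.coo_matrix(X.T, dtype=int))
    genes = adata.var.reset_index().rename(columns={"index": "gene"})
    genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    meta = adata.obs.reset_index().rename(columns={"index": "cell"})
    meta.to_csv(outdir / "metadata.tsv", sep="\t", index=False)


def read_expression(mtx_path, genes_path, metadata_path) -> ad.AnnData:
    """Read expression counts with covariates; X_t = log(total UMIs).

    Fails when metadata and matrix disagree on cells or when a cell
    lacks a batch assignment.
    """
    X = sp.csr_matrix(sio.mmread(str(mtx_path)).T)
    genes = pd.read_csv(genes_path, sep="\t")
    meta = pd.read_csv(metadata_path, sep="\t")
    if len(meta) != X.shape[0]:
        raise ValueError(
            f"metadata lists {len(meta)} cells but matrix has {X.shape[0]}"
        )
    if len(genes) != X.shape[1]:
        raise ValueError(
            f"gene table lists {len(genes)} genes but matrix has {X.shape[1]}"
        )
    if "batch" not in meta.columns or meta["batch"].isna().any():
        raise ValueError("every cell needs a batch assignment")
    adata = ad.AnnData(
        X=X,
        obs=meta.set_index("cell"),
        var=genes.set_index("gene"),
    )
    totals = np.asarray(X.sum(axis=1)).ravel()
    adata.obs["total_umis"] = totals
    adata.obs["log_total"] = np.log(totals)
    return adata


# ---------------------------------------------------------------------------
# posteriors / dosage


def write_dosage(post: GenotypePosterior, outdir) -> None:
    """Dense TSV dosage matrix (cells x sites) with a site sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        post.dosage,
        index=post.barcodes,
        columns=[f"{c}:{p}" for c, p in zip(post.sites["chrom"], post.sites["pos"])],
    ).to_csv(outdir / "dosage.tsv", sep="\t", float_format="%.6g")
    post.sites.to_csv(outdir / "sites.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# run configuration and pipeline


@dataclass
class RunConfig:
    """Flat pipeline configuration; serializable to YAML."""

    outdir: str = "cellqtl_out"
    seed: int = 0
    schema_version: int = SCHEMA_VERSION
    # inputs (unset -> the simulate stage generates them)
    vcf: str | None = None
    ref_mtx: str | None = None
    alt_mtx: str | None = None
    barcodes: str | None = None
    expression_mtx: str | None = None
    genes_tsv: str | None = None
    metadata_tsv: str | None = None
    map_tsv: str | None = None
    # parameters (defaults follow the motivating study)
    map_scale_factor: float = 0.4
    hmm_error_rate: float = 0.002
    ld_r_max: float = 0.9999
    min_cells_expressed: int = 20
    fdr: float = 0.1
    n_perm: int = 10
    hotspot_bin_cm: float = 5.0
    hotspot_alpha: float = 0.05
    cis_pad_bp: float = 1_000_000.0
    mode: str = "cis"  # cis | trans | both
    # simulate-stage knobs
    simulate: bool = False
    n_cells: int = 800
    n_cis: int = 40
    n_cell_types: int = 1
    sim_autosomes: int = 5
    sim_with_x: bool = True
    sim_sites_per_chrom: int = 100
    sim_genes_per_chrom: int = 200

    def config_hash(self) -> str:
        return hashlib.sha1(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def pipeline(config: RunConfig, dry_run: bool = False) -> dict:
    """Run simulate (optional) -> genotype -> eQTL map -> hotspots.

    Returns a dict of the main in-memory artifacts; every table written
    to ``config.outdir`` carries the config hash and seed in a run
    manifest. Deterministic given the config.
    """
    from . import eqtl, hotspots, simulate

    stages = ["simulate"] if config.simulate else []
    stages += ["genotype", "map", "hotspots"]
    if dry_run:
        print("pipeline plan:", " -> ".join(stages))
        return {"stages": stages}

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config.config_hash(), "seed": config.seed}
    config.to_yaml(outdir / "config.yaml")

    if config.simulate:
        design = simulate.CrossDesign(n_cells=config.n_cells)
        genome = simulate.default_genome(
            n_autosomes=config.sim_autosomes,
            with_x=config.sim_with_x,
            sites_per_chrom=config.sim_sites_per_chrom,
            genes_per_chrom=config.sim_genes_per_chrom,
            seed=config.seed,
        )
        ds = simulate.simulate_dataset(
            design=design,
            genome=genome,
            seed=config.seed,
            n_cis=config.n_cis,
            n_cell_types=config.n_cell_types,
        )
        write_allele_counts(ds.allele_counts, outdir / "sim")
        write_expression(ds.expression, outdir / "sim")
        write_map(ds.truth.genome.genetic_map, outdir / "sim" / "map.tsv")
        if ds.truth.planted_cis is not None:
            ds.truth.planted_cis.to_csv(
                outdir / "sim" / "truth_cis.tsv", sep="\t", index=False
            )
        config.vcf = str(outdir / "sim" / "variants.vcf")
        config.ref_mtx = str(outdir / "sim" / "ref.mtx")
        config.alt_mtx = str(outdir / "sim" / "alt.mtx")
        config.barcodes = str(outdir / "sim" / "barcodes.tsv")
        config.expression_mtx = str(outdir / "sim" / "expression.mtx")
        config.genes_tsv = str(outdir / "sim" / "genes.tsv")
        config.metadata_tsv = str(outdir / "sim" / "metadata.tsv")
        config.map_tsv = str(outdir / "sim" / "map.tsv")

    for name in ("vcf", "ref_mtx", "alt_mtx", "barcodes",
                 "expression_mtx", "genes_tsv", "metadata_tsv", "map_tsv"):
        p = getattr(config, name)
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"pipeline input {name!r} missing: {p}")

    try:
        acm = read_allele_counts(
            config.vcf, config.ref_mtx, config.alt_mtx, config.barcodes
        )
        gmap = read_map(config.map_tsv, scale_factor=config.map_scale_factor)
        post = infer_genotypes(acm, gmap, HMMParams(error_rate=config.hmm_error_rate))
        write_dosage(post, outdir / "genotype")
    except Exception as err:
        raise RuntimeError(f"stage 'genotype' failed: {err}") from err

    adata = read_expression(
        config.expression_mtx, config.genes_tsv, config.metadata_tsv
    )
    genes = adata.var.reset_index().rename(columns={"index": "gene"})
    # marker cM on the mapping (scaled) scale, for hotspot binning
    site_cm = np.concatenate(
        [
            gmap.interpolate(chrom, grp["pos"].to_numpy()) * gmap.scale_factor
            for chrom, grp in post.sites.groupby("chrom", sort=False)
        ]
    )
    coords = post.sites.assign(cm=site_cm)
    markers = eqtl.prune_markers(post.dosage, coords, r_max=config.ld_r_max)
    covariates = eqtl.build_design(
        adata.obs["log_total"].to_numpy(), adata.obs["batch"].to_numpy()
    )

    results: dict = {"manifest": manifest, "markers": markers}
    all_peaks = []
    cell_types = pd.unique(adata.obs.get("cell_type", pd.Series(["all"] * adata.n_obs)))
    for ct in cell_types:
        mask = (
            (adata.obs["cell_type"] == ct).to_numpy()
            if "cell_type" in adata.obs
            else np.ones(adata.n_obs, bool)
        )
        try:
            ct_res = _map_cell_type(config, adata, genes, markers, covariates, mask, ct)
        except Exception as err:
            raise RuntimeError(f"stage 'map' failed for cell type {ct!r}: {err}") from err
        if ct_res is not None:
            all_peaks.append(ct_res)
    if all_peaks:
        peaks = pd.concat(all_peaks, ignore_index=True).sort_values(
            ["cell_type", "gene_chrom", "gene_pos", "gene"], kind="stable"
        )
        peaks.to_csv(outdir / "eqtl_peaks.tsv", sep="\t", index=False)
        results["peaks"] = peaks

        if config.mode in ("trans", "both") and {"ci_lo_pos", "marker_cm"} <= set(
            peaks.columns
        ):
            chrom_lengths = {
                c[0] if isinstance(c, tuple) else c: gmap.length_cm(c, scaled=True)
                for c in gmap.chromosomes
            }
            bins = hotspots.bin_genome(chrom_lengths, width_cm=config.hotspot_bin_cm)
            counts = hotspots.count_trans_linkages(
                peaks, bins, fdr_max=config.fdr, cis_pad_bp=config.cis_pad_bp
            )
            hs = hotspots.detect_hotspots(counts, bins, alpha=config.hotspot_alpha)
            hs_df = hotspots.hotspots_to_frame(hs)
            hs_df.to_csv(outdir / "hotspots.tsv", sep="\t", index=False)
            results["hotspots"] = hs_df

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return results


def _map_cell_type(config, adata, genes, markers, covariates, mask, ct):
    """cis (and optionally trans) scan with permutation FDR for one cell type."""
    from . import eqtl

    Y = sp.csc_matrix(adata.X)[mask]
    cov = covariates[mask]
    vals = markers.values[mask]
    vals_std = eqtl.standardize(vals)
    sub = eqtl.MarkerDosage(values=vals_std, coords=markers.coords)
    expressed = eqtl.filter_expressed(Y, min_cells=config.min_cells_expressed)
    if not expressed.any():
        logger.warning("cell type %s: nothing expressed, skipped", ct)
        return None
    batch = adata.obs["batch"].to_numpy()[mask]
    cis = eqtl.cis_scan(Y, genes, sub, cov, min_cells=config.min_cells_expressed)
    if cis.empty:
        return None
    cis, _ = eqtl.permutation_fdr(
        Y, genes, sub, cov, batch, cis,
        mode="cis", n_perm=config.n_perm, seed=config.seed,
    )
    cis["cell_type"] = ct
    cis["scan"] = "cis"
    frames = [cis]
    if config.mode in ("trans", "both"):
        thetas = cis.set_index("gene")["theta"]
        peaks, _ = eqtl.trans_scan(
            Y, genes, sub, cov, thetas=thetas,
            min_cells=config.min_cells_expressed,
        )
        peaks, _ = eqtl.permutation_fdr(
            Y, genes, sub, cov, batch, peaks,
            mode="trans", n_perm=config.n_perm, seed=config.seed,
        )
        peaks["cell_type"] = ct
        peaks["scan"] = "trans"
        peaks["marker_cm"] = markers.coords.loc[peaks["marker"], "cm"].to_numpy()
        frames.append(peaks)
    return pd.concat(frames, ignore_index=True)
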