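"""Trans-eQTL hotspot detection by genome binning and Poisson excess tests.

The genetic map is tiled with fixed-width cM bins (5 cM by default).
Significant trans linkages — peaks passing the FDR cutoff whose target
gene lies outside the peak's 1.5-LOD-drop interval padded by 1 Mb — are
assigned to the bin containing the peak position. Per cell type, a bin is
an excess-linkage bin when its count exceeds the upper tail of a Poisson
distribution with rate equal to that cell type's mean count per bin, at a
Bonferroni-corrected level alpha / n_bins. Runs of adjacent significant
bins are reduced to their local maximum (leftmost on ties).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import poisson

logger = logging.getLogger(__name__)


@dataclass
class Hotspot:
    cell_type: str
    chrom: str
    bin_id: int
    start_cm: float
    end_cm: float
    count: int
    pvalue: float


def bin_genome(chrom_lengths_cm: dict[str, float], width_cm: float = 5.0) -> pd.DataFrame:
    """Tile each chromosome with contiguous ``width_cm`` bins.

    The last bin of a chromosome may be short. Returns a DataFrame with
    bin_id, chrom, start_cm, end_cm.
    """
    if width_cm <= 0:
        raise ValueError("bin width must be positive")
    rows = []
    bin_id = 0
    for chrom, length in chrom_lengths_cm.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive cM length")
        n_bins = int(np.ceil(length / width_cm))
        for k in range(n_bins):
            rows.append(
                {
                    "bin_id": bin_id,
                    "chrom": chrom,
                    "start_cm": k * width_cm,
                    "end_cm": min((k + 1) * width_cm, length),
                }
            )
            bin_id += 1
    return pd.DataFrame(rows)


def assign_bin(bins: pd.DataFrame, chrom: str, cm: float) -> int | None:
    """bin_id containing position ``cm`` on ``chrom`` (end-exclusive)."""
    on = bins[bins["chrom"] == chrom]
    if on.empty:
        return None
    hit = on[(on["start_cm"] <= cm) & (cm < on["end_cm"])]
    if hit.empty:  # clamp positions at/past the chromosome end into the last bin
        return int(on["bin_id"].iloc[-1]) if cm >= on["end_cm"].iloc[-1] else None
    return int(hit["bin_id"].iloc[0])


def count_trans_linkages(
    peaks: pd.DataFrame,
    bins: pd.DataFrame,
    fdr_max: float = 0.1,
    cis_pad_bp: float = 1e6,
    cell_type_col: str = "cell_type",
) -> pd.DataFrame:
    """Per-bin, per-cell-type counts of significant trans linkages.

    ``peaks`` needs columns gene_chrom, gene_pos, marker_chrom,
    marker_cm, ci_lo_pos, ci_hi_pos, fdr (and optionally a cell-type
    column). A linkage is cis — and excluded — when its target gene lies
    on the peak chromosome within the confidence interval extended by
    ``cis_pad_bp`` on both sides. Returns a tidy frame (cell_type,
    bin_id, count) covering every bin.
    """
    if cell_type_col not in peaks.columns:
        peaks = peaks.assign(**{cell_type_col: "all"})
    counts: dict[tuple[str, int], int] = {}
    cell_types = list(pd.unique(peaks[cell_type_col]))
    for _, pk in peaks.iterrows():
        if pk["fdr"] > fdr_max:
            continue
        if pd.isna(pk["gene_pos"]) or pd.isna(pk["gene_chrom"]):
            logger.info("gene %s lacks coordinates; linkage excluded", pk.get("gene"))
            continue
        if pk["gene_chrom"] == pk["marker_chrom"] and (
            pk["ci_lo_pos"] - cis_pad_bp <= pk["gene_pos"] <= pk["ci_hi_pos"] + cis_pad_bp
        ):
            continue  # cis linkage
        b = assign_bin(bins, pk["marker_chrom"], pk["marker_cm"])
        if b is None:
            logger.warning("peak outside binned map: %s", pk.get("gene"))
            continue
        key = (pk[cell_type_col], b)
        counts[key] = counts.get(key, 0) + 1
    rows = [
        {"cell_type": ct, "bin_id": b, "count": counts.get((ct, int(b)), 0)}
        for ct in cell_types
        for b in bins["bin_id"]
    ]
    return pd.DataFrame(rows)


def detect_hotspots(
    bin_counts: pd.DataFrame, bins: pd.DataFrame, alpha: float = 0.05
) -> list[Hotspot]:
    """Poisson excess test per bin with Bonferroni correction.

    For each cell type, lambda is the mean linkage count over all bins
    and a bin is significant when P(X >= count) < alpha / n_bins. Runs of
    adjacent significant bins on a chromosome are reduced to the bin with
    the highest count (leftmost on ties).
    """
    n_bins = len(bins)
    if n_bins == 0:
        raise ValueError("no bins")
    threshold = alpha / n_bins
    bins_idx = bins.set_index("bin_id")
    hotspots: list[Hotspot] = []
    for ct, grp in bin_counts.groupby("cell_type", sort=False):
        grp = grp.set_index("bin_id").reindex(bins["bin_id"], fill_value=0)
        counts = grp["count"].to_numpy()
        lam = counts.mean()
        if lam == 0:
            continue
        pvals = poisson.sf(counts - 1, lam)  # upper tail P(X >= count)
        sig = pvals < threshold
        # reduce runs of adjacent significant bins within a chromosome
        bid = bins["bin_id"].to_numpy()
        chroms = bins["chrom"].to_numpy()
        i = 0
        while i < n_bins:
            if not sig[i]:
                i += 1
                continue
            j = i
            while j + 1 < n_bins and sig[j + 1] and chroms[j + 1] == chroms[i]:
                j += 1
            run = np.arange(i, j + 1)
            peak = run[np.argmax(counts[run])]  # argmax: leftmost on ties
            row = bins_idx.loc[bid[peak]]
            hotspots.append(
                Hotspot(
                    cell_type=ct,
                    chrom=row["chrom"],
                    bin_id=int(bid[peak]),
                    start_cm=float(row["start_cm"]),
                    end_cm=float(row["end_cm"]),
                    count=int(counts[peak]),
                    pvalue=float(pvals[peak]),
                )
            )
            i = j + 1
    return hotspots


def hotspots_to_frame(hotspots: list[Hotspot]) -> pd.DataFrame:
    """Tidy table of detected hotspots."""
    return pd.DataFrame([h.__dict__ for h in hotspots])
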