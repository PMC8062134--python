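"""Genetic map representation and bp -> cM interpolation.

A genetic map is a set of per-chromosome anchor points (bp, cM) from a
reference cross. Positions between anchors are linearly interpolated;
positions beyond the terminal anchors are extrapolated with the terminal
segment slope. Because reference maps are often built from deeper
intercrosses than the population being genotyped, interpolated distances
are multiplied by ``scale_factor`` before being converted to recombination
fractions (0.4 converts a 10-generation advanced-intercross map to the
expectation for an F4 population, since map expansion grows as g/2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class GeneticMap:
    """Piecewise-linear genetic map.

    Parameters
    ----------
    anchors
        Mapping of chromosome name to an (n, 2) float array of
        (bp, cM) anchor points, sorted by bp with non-decreasing cM.
    scale_factor
        Multiplier applied to interpolated cM distances before they are
        used as transition distances (default 0.4).
    """

    anchors: dict[str, np.ndarray]
    scale_factor: float = 0.4

    def __post_init__(self) -> None:
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        clean = {}
        for chrom, arr in self.anchors.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
                raise ValueError(
                    f"chromosome {chrom!r}: need >= 2 (bp, cM) anchors"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"chromosome {chrom!r}: non-finite anchors")
            order = np.argsort(arr[:, 0], kind="stable")
            arr = arr[order]
            if np.any(np.diff(arr[:, 1]) < 0):
                raise ValueError(
                    f"chromosome {chrom!r}: cM must be non-decreasing in bp"
                )
            clean[chrom] = arr
        self.anchors = clean

    @property
    def chromosomes(self) -> list[str]:
        return list(self.anchors)

    def length_cm(self, chrom: str, scaled: bool = False) -> float:
        """Total cM span of a chromosome (optionally ``scale_factor``-scaled)."""
        arr = self.anchors[chrom]
        span = float(arr[-1, 1] - arr[0, 1])
        return span * self.scale_factor if scaled else span

    def interpolate(self, chrom: str, positions) -> np.ndarray:
        """Interpolate cM coordinates for bp ``positions`` on ``chrom``.

        Positions outside the anchored range are extrapolated with the
        slope of the terminal segment (and logged), so downstream
        transition distances stay finite and monotone.
        """
        arr = self.anchors[chrom]
        pos = np.asarray(positions, dtype=float)
        bp, cm = arr[:, 0], arr[:, 1]
        out = np.interp(pos, bp, cm)
        below = pos < bp[0]
        above = pos > bp[-1]
        if below.any():
            slope = (cm[1] - cm[0]) / max(bp[1] - bp[0], 1.0)
            out[below] = cm[0] + (pos[below] - bp[0]) * slope
            logger.info(
                "%d site(s) before first %s anchor: extrapolated", below.sum(), chrom
            )
        if above.any():
            slope = (cm[-1] - cm[-2]) / max(bp[-1] - bp[-2], 1.0)
            out[above] = cm[-1] + (pos[above] - bp[-1]) * slope
            logger.info(
                "%d site(s) past last %s anchor: extrapolated", above.sum(), chrom
            )
        return out


def interpolate_map(gmap: GeneticMap, chrom: str, positions) -> np.ndarray:
    """Functional wrapper around :meth:`GeneticMap.interpolate`."""
    return gmap.interpolate(chrom, positions)
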