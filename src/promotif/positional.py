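"""Motif positions on the genome and on the TSS-relative axis.

Windows are stored 5'->3' with the TSS at offset ``upstream``, so a motif
occurrence at string offset o sits at TSS-relative distance ``o - upstream``
(negative = upstream of the TSS) on either strand. Mapping back to the
reference is strand-dependent: on the plus strand the occurrence starts at
``genomic_start + o``; on the minus strand the stored string is the reverse
complement of the reference slice, so the occurrence's 5'-most reference
base is ``genomic_end - o - motif_len``.

Positional preference is summarised by 100-bp bins of the TSS-relative axis
(per-bin instance count and mean attention, empty bins reported as missing
rather than 0), a centered 3-bin rolling average (~300 bp smoothing), and a
Gaussian KDE (Silverman bandwidth) of the distance distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .errors import ConfigError, CoordinateError, DegenerateInputError
from .windows import PromoterWindow


@dataclass
class PositionalProfile:
    """Binned attention profile plus a density table on the TSS axis."""

    bin_edges: np.ndarray
    counts: np.ndarray
    mean_attention: np.ndarray  # NaN where a bin is empty
    smoothed: np.ndarray
    density: pd.DataFrame  # columns: distance, density (empty if not computed)

    def as_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "count": self.counts,
                "mean_attention": self.mean_attention,
                "smoothed": self.smoothed,
            }
        )


def _check_offset(window: PromoterWindow, offset: int, motif_len: int) -> None:
    if offset < 0 or offset + motif_len > len(window.sequence):
        raise CoordinateError(
            f"occurrence [{offset}, {offset + motif_len}) outside window "
            f"of length {len(window.sequence)}"
        )


def motif_genomic_start(window: PromoterWindow, offset: int, motif_len: int) -> int:
    """Reference coordinate of the occurrence's 5'-most genomic base."""
    _check_offset(window, offset, motif_len)
    if window.strand == "+":
        return window.genomic_start + offset
    return window.genomic_end - offset - motif_len


def motif_tss_distance(window: PromoterWindow, offset: int) -> int:
    """Signed TSS-relative start of the occurrence (upstream negative).

    Identical formula on both strands because the window string is already
    5'->3' with the TSS at offset ``upstream``.
    """
    _check_offset(window, offset, 1)
    return offset - window.upstream


def rolling_average(values: Sequence[float], window: int = 3) -> np.ndarray:
    """Centered rolling mean that ignores missing (NaN) entries and lets the
    window shrink at the edges instead of padding."""
    if window < 1 or window % 2 == 0:
        raise ConfigError(f"smoothing window must be odd and >= 1, got {window}")
    s = pd.Series(np.asarray(values, dtype=float))
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def density_estimate(
    distances: Sequence[float],
    grid_step: float = 10.0,
    extent: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Gaussian KDE (Silverman bandwidth) of motif-TSS distances on a regular
    grid; returns a (distance, density) table."""
    d = np.asarray(distances, dtype=float)
    if grid_step <= 0:
        raise ConfigError("grid_step must be positive")
    if np.unique(d).size < 2:
        raise DegenerateInputError(
            "KDE needs >= 2 distinct distances; fall back to histogram-only output"
        )
    kde = gaussian_kde(d, bw_method="silverman")
    if extent is None:
        pad = 3 * d.std()
        extent = (d.min() - pad, d.max() + pad)
    grid = np.arange(extent[0], extent[1] + grid_step, grid_step)
    return pd.DataFrame({"distance": grid, "density": kde(grid)})


def bin_attention(
    instances: Sequence[tuple[float, float]],
    bin_width: int = 100,
    extent: tuple[int, int] = (-2000, 1000),
    smooth_window: int = 3,
    with_density: bool = True,
) -> PositionalProfile:
    """Aggregate (distance, s_hat) instance pairs into left-closed bins of
    ``bin_width`` bp over ``extent`` with per-bin mean attention, smoothing,
    and (optionally) a KDE table of the distances."""
    if bin_width <= 0:
        raise ConfigError(f"bin width must be positive, got {bin_width}")
    lo, hi = extent
    if hi <= lo:
        raise ConfigError(f"invalid extent {extent}")
    edges = np.arange(lo, hi + bin_width, bin_width, dtype=float)
    nbins = edges.size - 1
    counts = np.zeros(nbins, dtype=int)
    sums = np.zeros(nbins, dtype=float)
    dists = []
    for dist, s in instances:
        if not lo <= dist < edges[-1]:
            raise CoordinateError(f"distance {dist} outside extent [{lo}, {edges[-1]})")
        b = int((dist - lo) // bin_width)
        counts[b] += 1
        sums[b] += s
        dists.append(dist)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    smoothed = rolling_average(mean, smooth_window)
    if with_density and len(dists) >= 2 and np.unique(dists).size >= 2:
        density = density_estimate(dists, extent=(lo, hi))
    else:
        density = pd.DataFrame(columns=["distance", "density"])
    return PositionalProfile(
        bin_edges=edges, counts=counts, mean_attention=mean,
        smoothed=smoothed, density=density,
    )
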