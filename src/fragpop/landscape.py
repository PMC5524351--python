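"""Fragmentation metrics on binary cover rasters.

Computes the landscape summary used to characterize how broken-up the
natural cover supporting a wildlife population is: percent of land area
that is natural habitat, patch density (patches/km² under 8-neighbour
connectivity), mean patch size (km²), and contagion (0 = maximally
interspersed, 100 = fully aggregated), plus the moving-circular-window
percent-natural-cover surface used as an SCR density covariate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from fragpop.core_data import NODATA, CoverRaster

EIGHT = np.ones((3, 3), dtype=int)
FOUR = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)


# ---------------------------------------------------------------------------
# Moving-window percent cover
# ---------------------------------------------------------------------------


def focal_percent_cover(raster: CoverRaster, radius: float) -> np.ndarray:
    """Fraction of natural cover within a circular window around each cell.

    Window membership is by cell-center inclusion (center-to-center
    distance ≤ radius).  At the raster edge the within-raster part of the
    window is used; nodata cells are excluded from the mean.  Returns a
    float grid aligned with ``raster.values`` (NaN where the window holds
    no data cells).
    """
    if radius < raster.cell_size:
        raise ValueError("window radius must be at least one cell")
    r_cells = int(np.floor(radius / raster.cell_size))
    yy, xx = np.mgrid[-r_cells : r_cells + 1, -r_cells : r_cells + 1]
    kernel = ((xx**2 + yy**2) * raster.cell_size**2 <= radius**2 + 1e-9).astype(float)

    vals = raster.values.astype(float)
    data = vals != NODATA
    natural = np.where(data, vals, 0.0)
    num = ndimage.convolve(natural, kernel, mode="constant", cval=0.0)
    den = ndimage.convolve(data.astype(float), kernel, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    return out


# ---------------------------------------------------------------------------
# Patch labelling
# ---------------------------------------------------------------------------


def label_patches(
    raster: CoverRaster, rule: int = 8
) -> tuple[np.ndarray, np.ndarray]:
    """Connected natural patches and their areas (km²).

    ``rule`` is 8 (diagonals connect, the default) or 4.
    """
    if rule not in (4, 8):
        raise ValueError("connectivity rule must be 4 or 8")
    struct = EIGHT if rule == 8 else FOUR
    labels, n = ndimage.label(raster.values == 1, structure=struct)
    if n == 0:
        return labels, np.empty(0)
    counts = np.bincount(labels.ravel())[1:]
    cell_km2 = _cell_area_km2(raster)
    return labels, counts * cell_km2


def _cell_area_km2(raster: CoverRaster) -> float:
    size_km = raster.cell_size / 1000.0 if raster.unit == "m" else raster.cell_size
    return size_km**2


# ---------------------------------------------------------------------------
# Contagion and the metric bundle
# ---------------------------------------------------------------------------


def _adjacency_counts(values: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Double-count 8-neighbour adjacency matrix g[i, k] among data cells.

    Each ordered neighbouring pair is counted once in each direction;
    pairs involving nodata (or the outside of the raster) are excluded.
    """
    m = len(classes)
    index = {c: i for i, c in enumerate(classes)}
    g = np.zeros((m, m), dtype=float)
    data = values != NODATA
    shifts = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for dr, dc in shifts:
        a = values[max(dr, 0) or None : values.shape[0] + min(dr, 0) or None,
                   max(dc, 0) or None : values.shape[1] + min(dc, 0) or None]
        b = values[max(-dr, 0) or None : values.shape[0] + min(-dr, 0) or None,
                   max(-dc, 0) or None : values.shape[1] + min(-dc, 0) or None]
        da = data[max(dr, 0) or None : values.shape[0] + min(dr, 0) or None,
                  max(dc, 0) or None : values.shape[1] + min(dc, 0) or None]
        db = data[max(-dr, 0) or None : values.shape[0] + min(-dr, 0) or None,
                  max(-dc, 0) or None : values.shape[1] + min(-dc, 0) or None]
        ok = da & db
        va = a[ok]
        vb = b[ok]
        for ci in classes:
            for ck in classes:
                g[index[ci], index[ck]] += np.count_nonzero((va == ci) & (vb == ck))
    return g


def contagion(raster: CoverRaster) -> float:
    """Contagion (%) from class proportions and 8-neighbour adjacencies.

    CONTAG = 100 · [1 + Σ_i Σ_k q_ik ln q_ik / (2 ln m)], with
    q_ik = P_i · g_ik / Σ_k g_ik; undefined (NaN) with fewer than two
    classes present.
    """
    vals = raster.values
    data = vals != NODATA
    classes = np.unique(vals[data])
    m = len(classes)
    if m < 2:
        return float("nan")
    P = np.array([(vals[data] == c).mean() for c in classes])
    g = _adjacency_counts(vals, classes)
    row = g.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = P[:, None] * np.where(row > 0, g / row, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(q > 0, q * np.log(q), 0.0)
    return float(100.0 * (1.0 + terms.sum() / (2.0 * np.log(m))))


@dataclass
class FragMetrics:
    pct_habitat: float  # % of land area natural
    patch_density: float  # patches / km²
    mean_patch_size: float  # km²
    contagion: float  # %
    n_patches: int
    landscape_area: float  # km² of data (land) cells
    habitat_area: float  # km² natural

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "pct_habitat": self.pct_habitat,
                    "patch_density": self.patch_density,
                    "mean_patch_size": self.mean_patch_size,
                    "contagion": self.contagion,
                    "n_patches": self.n_patches,
                    "landscape_area_km2": self.landscape_area,
                    "habitat_area_km2": self.habitat_area,
                }
            ]
        )


def frag_metrics(raster: CoverRaster, rule: int = 8) -> FragMetrics:
    """Full fragmentation summary of a binary cover raster.

    Nodata (e.g. water) cells are excluded from the landscape area, so
    ``pct_habitat`` is a percentage of *land* area.  Satisfies
    patch_density × mean_patch_size = pct_habitat / 100.
    """
    vals = raster.values
    data = vals != NODATA
    n_land = int(data.sum())
    if n_land == 0:
        raise ValueError("raster has no data cells")
    cell_km2 = _cell_area_km2(raster)
    land_km2 = n_land * cell_km2
    n_nat = int((vals == 1).sum())
    _, areas = label_patches(raster, rule)
    n_patches = len(areas)
    return FragMetrics(
        pct_habitat=100.0 * n_nat / n_land,
        patch_density=n_patches / land_km2,
        mean_patch_size=(n_nat * cell_km2 / n_patches) if n_patches else 0.0,
        contagion=contagion(raster),
        n_patches=n_patches,
        landscape_area=land_km2,
        habitat_area=n_nat * cell_km2,
    )
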