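"""Analytic flight-performance proxies and performance landscapes.

Two planform-only metrics:

* aspect ratio AR = R^2 / S for a single wing of span R and area S
  (induced-drag-reduction proxy; slender wings score high), and
* the non-dimensional radius of the second moment of area,
  r2hat = sqrt( int_0^1 chat(rhat) rhat^2 drhat ), computed from the
  normalized chord distribution chat = c R / S (lift-production proxy;
  tip-heavy wings score high, and r2hat in (0, 1) for any planform).

Landscapes map a metric over the viable cells of a theoretical grid and
discretize it into 10 equal-interval contour bands.
"""

from __future__ import annotations

import warnings

import numpy as np
from shapely.geometry import LineString, Polygon

from wingmorph.outlines import as_outline, orient_standard, polygon_area, wing_span

__all__ = [
    "aspect_ratio",
    "chord_distribution",
    "radius_second_moment",
    "performance_landscape",
    "contour_bands",
]


def aspect_ratio(outline) -> float:
    """AR = span^2 / area for a single wing planform."""
    v = as_outline(outline)
    return wing_span(v) ** 2 / polygon_area(v)


def chord_distribution(outline, n_stations: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Normalized chord chat at spanwise stations rhat in (0, 1).

    The outline is standardized (base at min x, span along +x); at each
    of ``n_stations`` equal spanwise intervals the chord is the total
    y-extent of the polygon's intersection with the vertical line at the
    interval midpoint (extents summed if the slice is multiply
    connected).  Chords are normalized by R/S so that the midpoint-rule
    integral of chat over rhat is 1.

    Returns (rhat, chat) arrays of length n_stations.
    """
    if n_stations < 20:
        raise ValueError("n_stations must be >= 20")
    v = orient_standard(as_outline(outline))
    R = wing_span(v)
    S = polygon_area(v)
    poly = Polygon(v)
    if not poly.is_valid:
        raise ValueError("self-intersecting outline has no chord distribution")
    x0 = v[:, 0].min()
    ymin, ymax = v[:, 1].min() - 1.0, v[:, 1].max() + 1.0
    rhat = (np.arange(n_stations) + 0.5) / n_stations
    chords = np.empty(n_stations)
    for i, r in enumerate(rhat):
        x = x0 + r * R
        cut = poly.intersection(LineString([(x, ymin), (x, ymax)]))
        chords[i] = cut.length
        if cut.is_empty:
            warnings.warn(f"station rhat={r:.3f} misses the polygon; chord 0")
    return rhat, chords * R / S


def radius_second_moment(outline, n_stations: int = 200) -> float:
    """r2hat = sqrt( int chat rhat^2 drhat ), midpoint rule over stations."""
    rhat, chat = chord_distribution(outline, n_stations=n_stations)
    return float(np.sqrt(np.sum(chat * rhat**2) / len(rhat)))


def contour_bands(values: np.ndarray, n_bands: int = 10) -> np.ndarray:
    """Equal-interval band index (1..n_bands) between observed min and max.

    NaN values get band 0 (missing).  A constant field maps to band 1.
    """
    v = np.asarray(values, dtype=float)
    bands = np.zeros(v.shape, dtype=int)
    ok = np.isfinite(v)
    if not ok.any():
        return bands
    lo, hi = v[ok].min(), v[ok].max()
    if hi == lo:
        bands[ok] = 1
        return bands
    idx = np.floor((v[ok] - lo) / (hi - lo) * n_bands).astype(int)
    bands[ok] = np.clip(idx, 0, n_bands - 1) + 1
    return bands


def performance_landscape(
    grid, metric_values: dict, metric: str, n_bands: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell values and contour bands for one metric over a grid.

    ``metric_values`` maps metric name -> array over all grid cells with
    NaN at non-viable cells (as produced by the pipeline's scoring step).
    Returns (values, bands); non-viable cells carry NaN / band 0.
    """
    if metric not in metric_values:
        raise ValueError(f"metric {metric!r} not scored")
    values = np.asarray(metric_values[metric], dtype=float)
    if values.shape[0] != grid.n_cells:
        raise ValueError("metric array does not match grid size")
    if not np.isfinite(values).any():
        raise ValueError("all cells non-viable: empty landscape")
    return values, contour_bands(values, n_bands=n_bands)
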