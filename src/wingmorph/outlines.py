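"""Reading, standardizing, resampling and measuring closed 2-D outlines.

An outline is an ordered list of (x, y) vertices describing a closed
polygon; the last vertex connects implicitly back to the first (no
duplicated endpoint).  Coordinates are continuous, in arbitrary but
consistent length units.

The standard orientation convention used throughout the package: the
wing base (proximal, humeral end) sits at minimum x, the span runs along
+x, vertices are ordered counter-clockwise (signed area > 0), and
traversal starts at the minimum-x vertex.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import LineString

__all__ = [
    "Outline",
    "read_outline",
    "write_outline_csv",
    "write_outline_tps",
    "orient_standard",
    "resample_equal_arclength",
    "polygon_area",
    "signed_area",
    "wing_span",
    "centroid_size",
    "is_self_intersecting",
]

# An Outline is simply an (n, 2) float array; helpers below validate it.
Outline = np.ndarray


def as_outline(vertices) -> Outline:
    """Coerce to an (n, 2) float array and validate basic invariants."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2:
        raise ValueError("outline must be an (n, 2) array of vertices")
    if v.shape[0] < 3:
        raise ValueError(f"outline needs >= 3 vertices, got {v.shape[0]}")
    if not np.all(np.isfinite(v)):
        raise ValueError("outline contains non-finite coordinates")
    # drop consecutive duplicates (incl. a repeated closing vertex)
    keep = np.ones(len(v), dtype=bool)
    keep[1:] = np.any(np.diff(v, axis=0) != 0.0, axis=1)
    if np.array_equal(v[0], v[-1]) and keep[-1]:
        keep[-1] = False
    v = v[keep]
    if v.shape[0] < 3:
        raise ValueError("outline degenerate after removing duplicate vertices")
    return v


def read_outline(source, dialect: str = "csv") -> Outline:
    """Read an outline from ``source`` in the given dialect.

    ``csv``: two numeric columns x,y, one vertex per row, optional header.
    ``tps``: TPS outline records; coordinates only (landmarks ignored).
    """
    if dialect == "csv":
        return _read_csv(source)
    if dialect == "tps":
        return _read_tps(source)
    raise ValueError(f"unknown outline dialect: {dialect!r}")


def _read_csv(source) -> Outline:
    pts = []
    with open(source) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            tokens = line.replace(",", " ").split()
            if len(tokens) != 2:
                raise ValueError(f"{source}:{lineno}: expected two columns")
            try:
                pts.append((float(tokens[0]), float(tokens[1])))
            except ValueError:
                if lineno == 1 and not pts:
                    continue  # header row
                raise ValueError(
                    f"{source}:{lineno}: non-numeric token in {line!r}"
                ) from None
    if len(pts) < 3:
        raise ValueError(f"{source}: outline needs >= 3 points, got {len(pts)}")
    return as_outline(pts)


def _read_tps(source) -> Outline:
    """Minimal TPS outline reader: POINTS=... blocks after an OUTLINES line."""
    pts: list[tuple[float, float]] = []
    in_points = 0
    with open(source) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            up = s.upper()
            if up.startswith(("LM=", "OUTLINES=", "ID=", "IMAGE=", "SCALE=")):
                in_points = 0
                continue
            if up.startswith("POINTS="):
                in_points = int(s.split("=", 1)[1])
                continue
            if in_points > 0:
                tokens = s.split()
                if len(tokens) != 2:
                    raise ValueError(f"{source}:{lineno}: expected two coordinates")
                try:
                    pts.append((float(tokens[0]), float(tokens[1])))
                except ValueError:
                    raise ValueError(
                        f"{source}:{lineno}: non-numeric token in {s!r}"
                    ) from None
                in_points -= 1
    if len(pts) < 3:
        raise ValueError(f"{source}: outline needs >= 3 points, got {len(pts)}")
    return as_outline(pts)


def write_outline_csv(outline: Outline, path) -> None:
    """Write an outline as a two-column x,y CSV (mirrors :func:`read_outline`)."""
    v = as_outline(outline)
    with open(path, "w") as fh:
        fh.write("x,y\n")
        for x, y in v:
            fh.write(f"{float(x)!r},{float(y)!r}\n")


def write_outline_tps(outline: Outline, path, specimen_id: int = 1) -> None:
    """Write an outline as a single-record TPS outline file."""
    v = as_outline(outline)
    with open(path, "w") as fh:
        fh.write("LM=0\nOUTLINES=1\n")
        fh.write(f"POINTS={len(v)}\n")
        for x, y in v:
            fh.write(f"{float(x)!r} {float(y)!r}\n")
        fh.write(f"ID={specimen_id}\n")


def signed_area(outline: Outline) -> float:
    """Shoelace signed area; positive for counter-clockwise traversal."""
    v = np.asarray(outline, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_area(outline: Outline) -> float:
    """Absolute enclosed area of the closed polygon."""
    a = abs(signed_area(as_outline(outline)))
    if a <= 0.0:
        raise ValueError("degenerate polygon: zero area")
    return a


def orient_standard(outline: Outline) -> Outline:
    """Standardize orientation: CCW order, centroid at origin, start at min-x.

    Raises on degenerate (zero-area) polygons.
    """
    v = as_outline(outline)
    a = signed_area(v)
    if a == 0.0:
        raise ValueError("degenerate polygon: zero signed area")
    if a < 0.0:
        v = v[::-1]
    v = v - _area_centroid(v)
    start = int(np.lexsort((v[:, 1], v[:, 0]))[0])  # min-x, ties by min-y
    return np.roll(v, -start, axis=0)


def _area_centroid(v: np.ndarray) -> np.ndarray:
    """Centroid of the enclosed area (not the vertex mean)."""
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


def resample_equal_arclength(outline: Outline, P: int = 150) -> Outline:
    """Resample the closed polygon to P points equally spaced by arc length.

    Point 0 coincides with the input's first vertex; points are placed at
    arc-length positions k/P of the perimeter, traversed in input order.
    Idempotent for an already equally spaced outline.
    """
    if P < 8:
        raise ValueError(f"P must be >= 8, got {P}")
    v = as_outline(outline)
    closed = np.vstack([v, v[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    perimeter = s[-1]
    targets = np.arange(P) * (perimeter / P)
    x = np.interp(targets, s, closed[:, 0])
    y = np.interp(targets, s, closed[:, 1])
    return np.column_stack([x, y])


def wing_span(outline: Outline) -> float:
    """Span R = extent along x (max x - min x)."""
    v = as_outline(outline)
    r = float(v[:, 0].max() - v[:, 0].min())
    if r <= 0.0:
        raise ValueError("degenerate polygon: zero span")
    return r


def centroid_size(outline: Outline) -> float:
    """sqrt of summed squared distances of vertices from their mean point.

    Depends on vertex count; compute on a fixed-P resampled outline when
    comparing across shapes.
    """
    v = as_outline(outline)
    d = v - v.mean(axis=0)
    return float(np.sqrt(np.sum(d * d)))


def is_self_intersecting(outline: Outline) -> bool:
    """True iff two non-adjacent edges of the closed polyline properly
    intersect or overlap (collinear overlap and mid-edge touching count;
    the shared endpoints of adjacent edges do not)."""
    v = as_outline(outline)
    ring = LineString(np.vstack([v, v[:1]]))
    return not ring.is_simple
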