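"""Multi-objective Pareto dominance ranking and the rank-ratio optimality score.

Solutions are metric vectors with per-metric optimization directions
(default: maximize AR, maximize r2hat, minimize median VMS — all
equally weighted, as dominance depends only on per-metric order).
Goldberg ranking peels non-dominated fronts iteratively: rank 1 is the
Pareto front, rank 2 the front of the remainder, and so on.  The Pareto
rank ratio combines the forward rank f with the reverse rank b obtained
by inverting every direction:

    ratio = (b - 1) / (f + b - 2),

with f = 1 taking precedence (ratio 1, the optimal front) and otherwise
b = 1 giving ratio 0 (dominated in the reverse sense by everything).  A
single solution scores 1.  Identical vectors share ranks and ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from wingmorph.performance import contour_bands

__all__ = [
    "ObjectiveSpec",
    "dominates",
    "goldberg_ranks",
    "pareto_rank_ratio",
    "optimality_landscape",
    "OptimalityLandscape",
]


@dataclass(frozen=True)
class ObjectiveSpec:
    """Ordered metric names with per-metric optimization directions."""

    names: tuple = ("AR", "r2hat", "median_vms")
    directions: tuple = ("max", "max", "min")

    def __post_init__(self):
        if len(self.names) != len(self.directions):
            raise ValueError("names and directions must have equal length")
        if any(d not in ("max", "min") for d in self.directions):
            raise ValueError("directions must be 'max' or 'min'")

    @property
    def signs(self) -> np.ndarray:
        """+1 for maximize, -1 for minimize (so 'larger is better' everywhere)."""
        return np.array([1.0 if d == "max" else -1.0 for d in self.directions])

    def inverted(self) -> "ObjectiveSpec":
        flip = tuple("min" if d == "max" else "max" for d in self.directions)
        return ObjectiveSpec(names=self.names, directions=flip)

    def subset(self, names) -> "ObjectiveSpec":
        idx = [self.names.index(n) for n in names]
        return ObjectiveSpec(
            names=tuple(self.names[i] for i in idx),
            directions=tuple(self.directions[i] for i in idx),
        )


def dominates(a, b, spec: ObjectiveSpec) -> bool:
    """True iff a is at least as good as b everywhere and strictly better once."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.shape[0] != len(spec.names):
        raise ValueError("metric vectors must match the objective spec")
    if np.any(np.isnan(a)) or np.any(np.isnan(b)):
        raise ValueError("missing value in metric vector")
    s = spec.signs
    ge = np.all(s * a >= s * b)
    gt = np.any(s * a > s * b)
    return bool(ge and gt)


def goldberg_ranks(solutions, spec: ObjectiveSpec) -> np.ndarray:
    """Iterative front-peeling ranks; 1 = Pareto front.

    Identical vectors are mutually non-dominating, hence share a rank.
    """
    X = np.atleast_2d(np.asarray(solutions, dtype=float))
    if np.any(np.isnan(X)):
        raise ValueError("missing value in solutions")
    n = X.shape[0]
    Y = X * spec.signs  # larger-is-better throughout
    ranks = np.zeros(n, dtype=int)
    remaining = np.arange(n)
    rank = 0
    while remaining.size:
        rank += 1
        Z = Y[remaining]
        # dominated[i]: some j is >= everywhere and > somewhere vs i
        ge_all = np.all(Z[:, None, :] >= Z[None, :, :], axis=2)
        gt_any = np.any(Z[:, None, :] > Z[None, :, :], axis=2)
        dominated = np.any(ge_all & gt_any, axis=0)
        front = remaining[~dominated]
        ranks[front] = rank
        remaining = remaining[dominated]
    return ranks


def pareto_rank_ratio(solutions, spec: ObjectiveSpec) -> np.ndarray:
    """Per-solution optimality in [0, 1]: 1 on the Pareto front, 0 when
    dominated by every other solution."""
    X = np.atleast_2d(np.asarray(solutions, dtype=float))
    if X.shape[0] == 1:
        return np.array([1.0])
    f = goldberg_ranks(X, spec)
    b = goldberg_ranks(X, spec.inverted())
    ratio = np.empty(len(f))
    for i, (fi, bi) in enumerate(zip(f, b)):
        if fi == 1:
            ratio[i] = 1.0
        elif bi == 1:
            ratio[i] = 0.0
        else:
            ratio[i] = (bi - 1.0) / (fi + bi - 2.0)
    return ratio


@dataclass(frozen=True)
class OptimalityLandscape:
    """Rank-ratio optimality over the viable cells of a theoretical grid."""

    cell_ids: np.ndarray  # viable cell ids in grid order
    forward_rank: np.ndarray
    reverse_rank: np.ndarray
    rank_ratio: np.ndarray
    bands: np.ndarray  # 10-level contour band per viable cell
    n_fronts: int
    spec: ObjectiveSpec = field(default_factory=ObjectiveSpec)


def optimality_landscape(
    records, spec: ObjectiveSpec | None = None, pairwise=None, n_bands: int = 10
) -> OptimalityLandscape:
    """Pareto rank-ratio landscape from a per-cell metric table.

    ``records``: DataFrame-like with a ``cell_id`` column plus one column
    per metric named in the spec, rows = viable cells only.  ``pairwise``
    optionally restricts the trade-off to a 2-metric subset of the spec.
    """
    spec = spec or ObjectiveSpec()
    if pairwise is not None:
        spec = spec.subset(tuple(pairwise))
    missing = [n for n in spec.names if n not in records]
    if missing:
        raise ValueError(f"metrics missing from records: {missing}")
    if len(records) < 2:
        raise ValueError("need >= 2 viable cells for a trade-off")
    X = np.column_stack([np.asarray(records[n], dtype=float) for n in spec.names])
    if np.any(np.isnan(X)):
        raise ValueError("missing metric value in viable records")
    f = goldberg_ranks(X, spec)
    b = goldberg_ranks(X, spec.inverted())
    ratio = pareto_rank_ratio(X, spec)
    return OptimalityLandscape(
        cell_ids=np.asarray(records["cell_id"], dtype=int),
        forward_rank=f,
        reverse_rank=b,
        rank_ratio=ratio,
        bands=contour_bands(ratio, n_bands=n_bands),
        n_fronts=int(f.max()),
        spec=spec,
    )
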