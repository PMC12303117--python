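"""Elliptical Fourier analysis (EFA) of closed outlines.

A closed curve sampled at P points is decomposed into H harmonically
related ellipses, each described by four coefficients (a_n, b_n, c_n,
d_n), following the chord-length parameterization of Kuhl & Giardina.
Normalization removes size, rotation, position and starting point,
pinning a_1 = 1, b_1 = 0, c_1 = 0 so that H harmonics carry 4H - 3 free
values (33 for the 9 harmonics used by default downstream).

The inverse transform evaluates the truncated series back to a polygon,
which is how theoretical shapes are reconstructed from morphospace
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from wingmorph.outlines import as_outline

__all__ = [
    "EFACoefficients",
    "efa_forward",
    "efa_normalize",
    "efa_inverse",
    "harmonic_power",
    "coeffs_to_vector",
    "vector_to_coeffs",
]


@dataclass(frozen=True)
class EFACoefficients:
    """Per-harmonic (a, b, c, d) Fourier descriptors of a closed outline.

    ``harmonics`` is an (H, 4) array with columns a_n, b_n, c_n, d_n;
    ``offset`` holds the bias terms (A0, C0) locating the curve centroid.
    """

    harmonics: np.ndarray
    offset: tuple[float, float] = (0.0, 0.0)
    normalized: bool = False

    def __post_init__(self):
        h = np.asarray(self.harmonics, dtype=float)
        if h.ndim != 2 or h.shape[1] != 4 or h.shape[0] < 1:
            raise ValueError("harmonics must be an (H, 4) array with H >= 1")
        if not np.all(np.isfinite(h)):
            raise ValueError("non-finite EFA coefficients")
        object.__setattr__(self, "harmonics", h)
        if self.normalized:
            a1, b1, c1, _ = h[0]
            if not (a1 == 1.0 and b1 == 0.0 and c1 == 0.0):
                raise ValueError(
                    "normalized coefficients must satisfy a1=1, b1=0, c1=0"
                )

    @property
    def n_harmonics(self) -> int:
        return self.harmonics.shape[0]


def efa_forward(outline, H: int = 9) -> EFACoefficients:
    """Kuhl–Giardina EFA of a closed polygon sampled at P vertices.

    The curve is parameterized by cumulative chord length; the result is
    un-normalized (offset holds the curve centroid terms A0, C0).
    H must satisfy 1 <= H <= floor(P/2) - 1.
    """
    v = as_outline(outline)
    P = len(v)
    if not (1 <= H <= P // 2 - 1):
        raise ValueError(f"H must be in [1, {P // 2 - 1}] for P={P}, got {H}")

    d = np.diff(np.vstack([v, v[:1]]), axis=0)  # (P, 2) edge vectors
    dt = np.linalg.norm(d, axis=1)
    if np.any(dt == 0.0):
        raise ValueError("repeated consecutive vertices")
    t = np.concatenate([[0.0], np.cumsum(dt)])  # (P+1,)
    T = t[-1]

    n = np.arange(1, H + 1)[:, None]  # (H, 1)
    phi = 2.0 * np.pi * t / T  # (P+1,)
    cos_diff = np.cos(n * phi[1:]) - np.cos(n * phi[:-1])  # (H, P)
    sin_diff = np.sin(n * phi[1:]) - np.sin(n * phi[:-1])

    dx_dt = d[:, 0] / dt
    dy_dt = d[:, 1] / dt
    k = T / (2.0 * (n.ravel() ** 2) * np.pi**2)  # (H,)
    a = k * (cos_diff @ dx_dt)
    b = k * (sin_diff @ dx_dt)
    c = k * (cos_diff @ dy_dt)
    dcoef = k * (sin_diff @ dy_dt)

    # bias terms (curve "DC" offset)
    xi = np.concatenate([[0.0], np.cumsum(d[:-1, 0])]) - dx_dt * t[:-1]
    delta = np.concatenate([[0.0], np.cumsum(d[:-1, 1])]) - dy_dt * t[:-1]
    t2diff = t[1:] ** 2 - t[:-1] ** 2
    A0 = v[0, 0] + (np.sum(dx_dt * t2diff / 2.0 + xi * dt)) / T
    C0 = v[0, 1] + (np.sum(dy_dt * t2diff / 2.0 + delta * dt)) / T

    return EFACoefficients(
        harmonics=np.column_stack([a, b, c, dcoef]),
        offset=(float(A0), float(C0)),
        normalized=False,
    )


def _rotate_coeffs(h: np.ndarray, psi: float, theta: float) -> np.ndarray:
    """Apply orientation rotation psi (left) and start-phase shift theta
    (right, scaled per harmonic) to every harmonic's 2x2 block."""
    H = h.shape[0]
    out = np.empty_like(h)
    R_psi = np.array([[np.cos(psi), np.sin(psi)], [-np.sin(psi), np.cos(psi)]])
    for i in range(H):
        n = i + 1
        M = h[i].reshape(2, 2)
        R_th = np.array(
            [
                [np.cos(n * theta), -np.sin(n * theta)],
                [np.sin(n * theta), np.cos(n * theta)],
            ]
        )
        out[i] = (R_psi @ M @ R_th).ravel()
    return out


def efa_normalize(coeffs: EFACoefficients) -> EFACoefficients:
    """Standardize size, rotation, position and starting point.

    The first harmonic's ellipse defines the canonical frame: the start
    phase is shifted to a semi-major-axis crossing, the shape is rotated
    so that axis lies along +x, and all coefficients are divided by its
    magnitude.  Of the two semi-major crossings (180 degrees apart) the
    one mapping the input curve's parameter-0 point (the wing base when
    the outline was standardized to start at minimum x) to the
    negative-x side is chosen, so the base-to-tip direction is stable
    across shapes.  Reflection is never applied, so the sign of d_1 is
    meaningful (traversal handedness is preserved).
    """
    if coeffs.normalized:
        return coeffs
    a1, b1, c1, d1 = coeffs.harmonics[0]
    if a1 * a1 + b1 * b1 + c1 * c1 + d1 * d1 == 0.0:
        raise ValueError("degenerate first harmonic")

    theta = 0.5 * np.arctan2(
        2.0 * (a1 * b1 + c1 * d1), a1 * a1 + c1 * c1 - b1 * b1 - d1 * d1
    )
    # position of the input's parameter-0 point relative to the curve centre
    Sa = float(np.sum(coeffs.harmonics[:, 0]))
    Sc = float(np.sum(coeffs.harmonics[:, 2]))

    best = None
    for th in (theta, theta + np.pi):
        a_s = a1 * np.cos(th) + b1 * np.sin(th)
        c_s = c1 * np.cos(th) + d1 * np.sin(th)
        scale = np.hypot(a_s, c_s)
        if scale == 0.0:
            raise ValueError("degenerate first harmonic (zero semi-major axis)")
        psi = np.arctan2(c_s, a_s)
        # normalized-frame x of the input's parameter-0 point (the base)
        base_x = (np.cos(psi) * Sa + np.sin(psi) * Sc) / scale
        if best is None or base_x < best[0]:
            best = (base_x, th, psi, scale)
    _, th, psi, scale = best
    h = _rotate_coeffs(coeffs.harmonics, psi, th) / scale
    h[0, 0], h[0, 1], h[0, 2] = 1.0, 0.0, 0.0  # exact pinning
    return EFACoefficients(harmonics=h, offset=(0.0, 0.0), normalized=True)


def efa_inverse(coeffs: EFACoefficients, P: int = 150) -> np.ndarray:
    """Evaluate the truncated Fourier series at P uniform parameter steps.

    Normalized coefficients are evaluated starting from the base-side
    (negative x) semi-major crossing so the reconstruction begins at the
    wing base, matching the standard outline convention; forward +
    normalize of the reconstruction then reproduces the coefficients
    closely for smooth shapes.
    """
    if P < 8:
        raise ValueError(f"P must be >= 8, got {P}")
    h = coeffs.harmonics
    H = h.shape[0]
    phase = 0.5 if coeffs.normalized else 0.0
    tt = phase + np.arange(P) / P  # t/T over one period
    n = np.arange(1, H + 1)[:, None]
    cos = np.cos(2.0 * np.pi * n * tt)  # (H, P)
    sin = np.sin(2.0 * np.pi * n * tt)
    x = coeffs.offset[0] + h[:, 0] @ cos + h[:, 1] @ sin
    y = coeffs.offset[1] + h[:, 2] @ cos + h[:, 3] @ sin
    return np.column_stack([x, y])


def harmonic_power(
    coeffs: EFACoefficients, reference: EFACoefficients | None = None
) -> np.ndarray:
    """Cumulative harmonic power fractions.

    Power of harmonic n is (a_n^2 + b_n^2 + c_n^2 + d_n^2) / 2.  Without
    a reference the fractions are relative to the total over the H
    computed harmonics (last entry exactly 1).  With ``reference`` (a
    higher-order decomposition of the same outline) fractions are
    relative to the reference's total, which is the sufficiency check
    used to validate the retained harmonic count.
    """
    pw = 0.5 * np.sum(coeffs.harmonics**2, axis=1)
    if reference is not None:
        total = float(np.sum(0.5 * np.sum(reference.harmonics**2, axis=1)))
    else:
        total = float(np.sum(pw))
    if total <= 0.0:
        raise ValueError("zero total harmonic power")
    return np.cumsum(pw) / total


def coeffs_to_vector(coeffs: EFACoefficients) -> np.ndarray:
    """Flatten to a 4H vector (a1,b1,c1,d1, a2,...) for PCA."""
    return coeffs.harmonics.ravel().copy()


def vector_to_coeffs(vec: np.ndarray, normalized: bool = True) -> EFACoefficients:
    """Inverse of :func:`coeffs_to_vector`; re-imposes the pinned values
    when ``normalized``."""
    h = np.asarray(vec, dtype=float).reshape(-1, 4).copy()
    if normalized:
        h[0, 0], h[0, 1], h[0, 2] = 1.0, 0.0, 0.0
    return EFACoefficients(harmonics=h, offset=(0.0, 0.0), normalized=normalized)
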