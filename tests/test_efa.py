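import numpy as np
import pytest

from wingmorph.efa import (
    EFACoefficients,
    coeffs_to_vector,
    efa_forward,
    efa_inverse,
    efa_normalize,
    harmonic_power,
    vector_to_coeffs,
)
from wingmorph.outlines import (
    is_self_intersecting,
    orient_standard,
    resample_equal_arclength,
    wing_span,
)


def circle_outline(r=1.0, n=1000):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def analytic_fundamental_axes(a, b, n=200_000):
    """Semi-axes of the Fourier fundamental of an arc-length-parameterized
    ellipse, by dense quadrature (independent of the EFA code path)."""
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x, y = a * np.cos(t), b * np.sin(t)
    ds = np.sqrt((a * np.sin(t)) ** 2 + (b * np.cos(t)) ** 2) * (t[1] - t[0])
    s = np.concatenate([[0.0], np.cumsum(ds)])[:-1]
    T = np.sum(ds)
    w = 2.0 * np.pi * s / T
    M = np.array(
        [
            [np.sum(x * np.cos(w) * ds), np.sum(x * np.sin(w) * ds)],
            [np.sum(y * np.cos(w) * ds), np.sum(y * np.sin(w) * ds)],
        ]
    ) * (2.0 / T)
    return np.linalg.svd(M)[1]


class TestForward:
    def test_circle_is_single_harmonic(self):
        res = resample_equal_arclength(circle_outline(), 150)
        c = efa_forward(res, 9)
        a1, b1, c1, d1 = c.harmonics[0]
        assert np.isclose(a1, 1.0, atol=1e-3)
        assert np.isclose(d1, 1.0, atol=1e-3)
        assert abs(b1) < 1e-3 and abs(c1) < 1e-3
        assert np.abs(c.harmonics[1:]).max() < 1e-3

    def test_ellipse_fundamental_matches_quadrature_oracle(self):
        th = np.linspace(0, 2 * np.pi, 2000, endpoint=False)
        ell = np.column_stack([2.0 * np.cos(th), np.sin(th)])
        c = efa_forward(resample_equal_arclength(ell, 150), 9)
        axes = np.linalg.svd(c.harmonics[0].reshape(2, 2))[1]
        expected = analytic_fundamental_axes(2.0, 1.0)
        assert np.allclose(axes, expected, rtol=1e-3)

    def test_h_out_of_range_rejected(self, wing_outline):
        P = len(wing_outline)
        with pytest.raises(ValueError):
            efa_forward(wing_outline, P)
        with pytest.raises(ValueError):
            efa_forward(wing_outline, 0)

    def test_offset_holds_translation(self, wing_outline):
        c = efa_forward(wing_outline + [7.0, -2.0], 9)
        c0 = efa_forward(wing_outline, 9)
        assert np.isclose(c.offset[0] - c0.offset[0], 7.0, atol=1e-9)
        assert np.isclose(c.offset[1] - c0.offset[1], -2.0, atol=1e-9)


class TestNormalize:
    def test_pinning_and_free_count(self, wing_outline):
        c = efa_normalize(efa_forward(wing_outline, 9))
        h = c.harmonics
        assert h[0, 0] == 1.0 and h[0, 1] == 0.0 and h[0, 2] == 0.0
        # 4H values minus 3 pinned = 33 free at H = 9
        assert h.size - 3 == 33

    def test_invariance_to_similarity_and_start_vertex(self, wing_outline):
        base = coeffs_to_vector(efa_normalize(efa_forward(wing_outline, 9)))
        ang = 1.1
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        variants = [
            wing_outline @ R.T,
            wing_outline + [3.0, -2.0],
            wing_outline * 2.7,
            np.roll(wing_outline, 37, axis=0),
            (np.roll(wing_outline, 11, axis=0) @ R.T) * 0.5 + [1.0, 2.0],
        ]
        for v in variants:
            got = coeffs_to_vector(efa_normalize(efa_forward(v, 9)))
            assert np.allclose(got, base, atol=1e-6)

    def test_circle_d1_unit_higher_negligible(self):
        res = resample_equal_arclength(circle_outline(), 150)
        c = efa_normalize(efa_forward(res, 9))
        assert np.isclose(abs(c.harmonics[0, 3]), 1.0, atol=1e-3)
        assert np.abs(c.harmonics[1:]).max() < 1e-3

    def test_degenerate_first_harmonic_rejected(self):
        h = np.zeros((3, 4))
        h[1, 0] = 1.0
        with pytest.raises(ValueError, match="degenerate"):
            efa_normalize(EFACoefficients(harmonics=h))


class TestInverse:
    def test_circle_reconstruction_round(self):
        res = resample_equal_arclength(circle_outline(), 150)
        c = efa_normalize(efa_forward(res, 9))
        rec = efa_inverse(c, 150)
        radii = np.linalg.norm(rec - rec.mean(axis=0), axis=1)
        assert radii.std() / radii.mean() < 1e-3

    def test_roundtrip_error_small_on_wing_population(self, wing_population):
        std, _ = wing_population
        errs = []
        for o in std:
            c = efa_forward(o, 9)
            rec = efa_inverse(c, len(o))
            errs.append(
                np.linalg.norm(rec - o, axis=1).mean() / wing_span(o)
            )
        assert np.mean(errs) < 0.005  # < 0.5% of span

    def test_roundtrip_drift_contracts(self, wing_outline):
        c = efa_normalize(efa_forward(wing_outline, 9))
        drifts = []
        for _ in range(3):
            rec = efa_inverse(c, 150)
            c2 = efa_normalize(efa_forward(rec, 9))
            drifts.append(
                np.abs(coeffs_to_vector(c2) - coeffs_to_vector(c)).max()
            )
            c = c2
        assert drifts[0] < 0.01
        assert drifts[2] < drifts[0]

    def test_reconstruction_error_monotone_in_h(self, wing_outline):
        errs = []
        for H in (2, 4, 9, 20):
            rec = efa_inverse(efa_forward(wing_outline, H), len(wing_outline))
            errs.append(np.linalg.norm(rec - wing_outline, axis=1).mean())
        assert all(e2 <= e1 + 1e-12 for e1, e2 in zip(errs, errs[1:]))

    def test_small_p_rejected(self, wing_outline):
        with pytest.raises(ValueError):
            efa_inverse(efa_forward(wing_outline, 9), 4)


class TestHarmonicPower:
    def test_circle_first_harmonic_dominates(self):
        res = resample_equal_arclength(circle_outline(), 150)
        hp = harmonic_power(efa_forward(res, 9))
        assert hp[0] > 0.999999

    def test_cumulative_non_decreasing_ends_at_one(self, wing_outline):
        hp = harmonic_power(efa_forward(wing_outline, 9))
        assert np.all(np.diff(hp) >= 0)
        assert np.isclose(hp[-1], 1.0)

    def test_nine_harmonics_capture_995_of_reference(self, wing_population):
        std, _ = wing_population
        fracs = []
        for o in std:
            ref = efa_forward(o, len(o) // 2 - 1)
            hp = harmonic_power(efa_forward(o, 9), reference=ref)
            fracs.append(hp[-1])
        assert np.mean(fracs) >= 0.995


class TestVectorRoundtrip:
    def test_vector_roundtrip_reimposes_pinning(self, wing_outline):
        c = efa_normalize(efa_forward(wing_outline, 9))
        vec = coeffs_to_vector(c)
        vec[0] = 0.9  # corrupt a pinned entry
        back = vector_to_coeffs(vec, normalized=True)
        assert back.harmonics[0, 0] == 1.0
        assert np.allclose(back.harmonics[1:], c.harmonics[1:])
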