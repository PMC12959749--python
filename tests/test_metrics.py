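"""AAVS, qVSA, VSAhull, shift vectors, and coverage ellipses."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vowelspace import (
    CORNER_VOWELS,
    InsufficientDataError,
    MissingCornerError,
    VowelLabel,
    VowelMeans,
    compute_aavs,
    compute_qvsa,
    compute_vsa_hull,
    compute_vowel_means,
    confidence_ellipse,
    session_metrics,
    shift_vectors,
)
from vowelspace.metrics import MEAN_LEVEL, TOKEN_LEVEL, ellipse_contains

from conftest import make_session_tokens


def hand_aavs(points):
    """Independent oracle: elementwise 2×2 covariance, explicit determinant."""
    n = len(points)
    m1 = sum(p[0] for p in points) / n
    m2 = sum(p[1] for p in points) / n
    s11 = sum((p[0] - m1) ** 2 for p in points) / (n - 1)
    s22 = sum((p[1] - m2) ** 2 for p in points) / (n - 1)
    s12 = sum((p[0] - m1) * (p[1] - m2) for p in points) / (n - 1)
    return (s11 * s22 - s12**2) ** 0.5


def corner_means(coords):
    """VowelMeans for the four corner vowels from {code: (f1, f2)}."""
    return [
        VowelMeans("S", "baseline", VowelLabel(code), f1, f2, 3)
        for code, (f1, f2) in coords.items()
    ]


class TestAAVS:
    def test_independent_axes_closed_form(self):
        # marginal sample variances 4/3, zero covariance
        assert compute_aavs([(0, 0), (0, 2), (2, 0), (2, 2)]) == pytest.approx(4 / 3)

    def test_identical_points_have_zero_dispersion(self):
        assert compute_aavs([(500.0, 1500.0)] * 5) == 0.0

    def test_hand_picked_points_match_determinant_oracle(self):
        pts = [(460, 1805), (480, 1790), (530, 1900), (610, 2050), (455, 1760)]
        assert compute_aavs(pts) == pytest.approx(hand_aavs(pts), rel=1e-12)

    def test_collinear_points_give_zero(self):
        pts = [(i, 3.0 * i + 7.0) for i in range(8)]
        assert compute_aavs(pts) == pytest.approx(0.0, abs=1e-6)

    def test_fewer_than_three_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            compute_aavs([(1, 2), (3, 4)])

    def test_symmetric_in_coordinate_order(self, rng):
        pts = rng.uniform(200, 2500, size=(20, 2))
        assert compute_aavs(pts) == pytest.approx(compute_aavs(pts[:, ::-1]))


class TestQVSA:
    def test_trapezoid_corner_configuration(self):
        coords = {
            "IY": (300, 2500),
            "AE": (800, 2000),
            "AA": (800, 1000),
            "UW": (300, 1000),
        }
        assert compute_qvsa(corner_means(coords)) == pytest.approx(625_000)

    def test_published_baseline_corner_means(self, ds_means):
        # hand shoelace over the group corner means gives 116,996 Hz²
        corners = [m for m in ds_means if m.vowel in CORNER_VOWELS]
        assert compute_qvsa(corners) == pytest.approx(116_996.0)

    def test_missing_corner_named(self):
        coords = {"IY": (300, 2500), "AE": (800, 2000), "AA": (800, 1000)}
        with pytest.raises(MissingCornerError, match="u"):
            compute_qvsa(corner_means(coords))

    def test_collapsed_quadrilateral_is_zero(self):
        coords = {c: (500.0, 1500.0) for c in ("IY", "AE", "AA", "UW")}
        assert compute_qvsa(corner_means(coords)) == 0.0

    def test_self_intersecting_quadrilateral_warns(self):
        # crossing /i/->/æ/ and /ɑ/->/u/ edges
        coords = {
            "IY": (300, 2500),
            "AE": (800, 1000),
            "AA": (800, 2000),
            "UW": (300, 1100),
        }
        with pytest.warns(UserWarning, match="self-intersect"):
            compute_qvsa(corner_means(coords))


class TestVSAHull:
    def test_duplicate_repetitions_do_not_change_hull(self, ds_means):
        reps = [
            (m.vowel, m.f1_mean, m.f2_mean) for m in ds_means for _ in range(3)
        ]
        tokens = make_session_tokens(reps)
        mean_pts = [(m.f2_mean, m.f1_mean) for m in ds_means]
        from vowelspace import convex_hull

        assert compute_vsa_hull(tokens) == pytest.approx(convex_hull(mean_pts).area)

    def test_unit_square_with_interior_jitter(self, rng):
        square = [("IY", 0, 0), ("AE", 0, 1), ("AA", 1, 1), ("UW", 1, 0)]
        jitter = [("AH", f1, f2) for f1, f2 in rng.uniform(0.2, 0.8, size=(10, 2))]
        assert compute_vsa_hull(make_session_tokens(square + jitter)) == pytest.approx(1.0)


class TestSessionMetrics:
    def full_tokens(self, ds_means, rng, session="baseline"):
        triples = []
        for m in ds_means:
            for _ in range(3):
                triples.append(
                    (m.vowel, m.f1_mean + rng.normal(0, 20), m.f2_mean + rng.normal(0, 20))
                )
        return make_session_tokens(triples, session=session)

    def test_complete_session_yields_all_three_metrics(self, ds_means, rng):
        result = session_metrics(self.full_tokens(ds_means, rng))
        assert result.aavs is not None and result.aavs > 0
        assert result.qvsa is not None and result.qvsa > 0
        assert result.vsahull is not None and result.vsahull > 0
        assert result.n_tokens == 30
        assert result.mode == TOKEN_LEVEL

    def test_missing_corner_vowel_marks_qvsa_absent(self, ds_means, rng):
        tokens = [t for t in self.full_tokens(ds_means, rng) if t.vowel is not VowelLabel.UW]
        result = session_metrics(tokens)
        assert result.qvsa is None
        assert any("qvsa" in note and "u" in note for note in result.notes)
        assert result.aavs is not None
        assert result.vsahull is not None

    def test_mean_level_aavs_collapses_duplicates(self, ds_means):
        triples = [(m.vowel, m.f1_mean, m.f2_mean) for m in ds_means for _ in range(3)]
        tokens = make_session_tokens(triples)
        mean_mode = session_metrics(tokens, MEAN_LEVEL)
        # with identical repetitions, per-vowel means equal the 10 distinct points
        expected = hand_aavs([(m.f1_mean, m.f2_mean) for m in ds_means])
        assert mean_mode.aavs == pytest.approx(expected, rel=1e-12)

    def test_mixed_speakers_rejected(self):
        tokens = make_session_tokens([("IY", 400, 1800)], speaker="A") + make_session_tokens(
            [("IY", 500, 1900)], speaker="B"
        )
        with pytest.raises(ValueError):
            session_metrics(tokens)


class TestShiftVectors:
    def test_identical_sessions_give_zero_vectors(self, ds_means):
        post = [
            VowelMeans(m.speaker, "post", m.vowel, m.f1_mean, m.f2_mean, m.n_tokens)
            for m in ds_means
        ]
        vecs = shift_vectors(ds_means, post)
        assert len(vecs) == 10
        assert all(v.d_f1 == 0 and v.d_f2 == 0 for v in vecs)

    def test_post_minus_baseline_subtraction(self):
        base = [VowelMeans("S", "baseline", VowelLabel.IY, 462, 1810, 3)]
        post = [VowelMeans("S", "post", VowelLabel.IY, 450, 1900, 3)]
        (v,) = shift_vectors(base, post)
        assert (v.d_f1, v.d_f2) == (-12, 90)

    def test_no_shared_vowels_warns_and_returns_empty(self):
        base = [VowelMeans("S", "baseline", VowelLabel.IY, 462, 1810, 3)]
        post = [VowelMeans("S", "post", VowelLabel.UW, 500, 1400, 3)]
        with pytest.warns(UserWarning):
            assert shift_vectors(base, post) == []

    def test_group_vectors_are_mean_of_speaker_vectors(self, rng):
        # linearity of averaging when every speaker contributes every vowel
        speakers = ["A", "B", "C"]
        base_tokens, post_tokens = [], []
        for sp in speakers:
            for v in VowelLabel:
                f1, f2 = rng.uniform(300, 900), rng.uniform(900, 2500)
                base_tokens += make_session_tokens([(v, f1, f2)], speaker=sp)
                post_tokens += make_session_tokens(
                    [(v, f1 + rng.normal(0, 30), f2 + rng.normal(0, 60))],
                    speaker=sp,
                    session="post",
                )
        per_speaker = {}
        for sp in speakers:
            b = compute_vowel_means([t for t in base_tokens if t.speaker == sp])
            p = compute_vowel_means([t for t in post_tokens if t.speaker == sp])
            per_speaker[sp] = {v.vowel: v for v in shift_vectors(b, p)}
        from vowelspace.plots import group_mean_shift_vectors

        _, group_vecs = group_mean_shift_vectors(base_tokens, post_tokens)
        for gv in group_vecs:
            mean_d_f1 = np.mean([per_speaker[sp][gv.vowel].d_f1 for sp in speakers])
            mean_d_f2 = np.mean([per_speaker[sp][gv.vowel].d_f2 for sp in speakers])
            assert gv.d_f1 == pytest.approx(mean_d_f1)
            assert gv.d_f2 == pytest.approx(mean_d_f2)


class TestConfidenceEllipse:
    def test_isotropic_closed_form(self, rng):
        pts = rng.normal(0, 1, size=(2000, 2))
        ell = confidence_ellipse(pts, 0.95)
        sd = np.sqrt(np.cov(pts, rowvar=False, ddof=1).diagonal().mean())
        # q = chi²₂(0.95) ≈ 5.991; near-circular at large n
        assert ell.semi_major == pytest.approx(sd * np.sqrt(5.991), rel=0.1)
        assert ell.semi_minor / ell.semi_major > 0.9

    def test_zero_coverage_collapses_to_point(self, rng):
        pts = rng.normal(0, 50, size=(100, 2))
        ell = confidence_ellipse(pts, 0.0)
        assert ell.semi_major == 0.0 and ell.semi_minor == 0.0

    def test_monte_carlo_coverage_near_nominal(self, rng):
        cov = np.array([[2500.0, 1200.0], [1200.0, 3600.0]])
        pts = rng.multivariate_normal([1500, 600], cov, size=20_000)
        ell = confidence_ellipse(pts, 0.95)
        frac = ellipse_contains(ell, pts).mean()
        assert frac == pytest.approx(0.95, abs=0.02)

    def test_degenerate_covariance_rejected(self):
        from vowelspace import DegenerateGeometryError

        with pytest.raises(DegenerateGeometryError):
            confidence_ellipse([(0, 0), (1, 1), (2, 2), (3, 3)])


class TestInvariances:
    """Translation, scaling, and containment properties of the metrics."""

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_translation_leaves_all_metrics_unchanged(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(200, 2500, size=(15, 2))
        shift = rng.uniform(-500, 500, size=2)
        assert compute_aavs(pts + shift) == pytest.approx(compute_aavs(pts), rel=1e-9)
        from vowelspace import convex_hull

        assert convex_hull(pts + shift).area == pytest.approx(
            convex_hull(pts).area, rel=1e-9
        )

    @given(st.integers(0, 2**32 - 1), st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_coordinate_scaling_scales_areas_by_k_squared(self, seed, k):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(200, 2500, size=(12, 2))
        from vowelspace import convex_hull

        assert compute_aavs(pts * k) == pytest.approx(k**2 * compute_aavs(pts), rel=1e-9)
        assert convex_hull(pts * k).area == pytest.approx(
            k**2 * convex_hull(pts).area, rel=1e-9
        )

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_corner_quadrilateral_inside_token_hull(self, seed):
        rng = np.random.default_rng(seed)
        triples = []
        for v in VowelLabel:
            f1, f2 = rng.uniform(300, 900), rng.uniform(900, 2600)
            for _ in range(3):
                triples.append((v, f1 + rng.normal(0, 40), f2 + rng.normal(0, 40)))
        tokens = make_session_tokens(triples)
        means = compute_vowel_means(tokens)
        import warnings

        with warnings.catch_warnings():
            # random corner placements may legitimately self-intersect
            warnings.simplefilter("ignore", UserWarning)
            qvsa = compute_qvsa([m for m in means if m.vowel in CORNER_VOWELS])
        assert qvsa <= compute_vsa_hull(tokens) + 1e-9
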