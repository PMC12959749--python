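"""The three vowel-space statistics and supporting geometry.

* **AAVS** (articulatory-acoustic vowel space): square root of the
  generalised variance — ``sqrt(det(S))`` with ``S`` the 2×2 sample
  covariance of (F1, F2) — a dispersion measure over all vowel tokens.
* **qVSA** (quadrilateral vowel space area): shoelace area of the
  quadrilateral through the mean coordinates of the four corner vowels
  /i/, /æ/, /ɑ/, /u/, traversed in that perimeter order.
* **VSAhull** (convex-hull vowel space area): area of the smallest
  convex polygon enclosing all tokens, all vowels pooled.

All computations are in raw Hz (no Bark/mel/log transform and no
speaker normalisation), so areas are in Hz². Each metric is computed
separately per speaker and session; change scores are post − baseline.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import (
    DegenerateGeometryError,
    InsufficientDataError,
    MissingCornerError,
)
from .geometry import convex_hull, polygon_area
from .io import FormantToken, VowelMeans, compute_vowel_means
from .vowels import CORNER_ORDER, CORNER_VOWELS, VowelLabel

TOKEN_LEVEL = "token-level"
MEAN_LEVEL = "mean-level"


@dataclass(frozen=True)
class VowelSpaceMetrics:
    """The (AAVS, qVSA, VSAhull) triple for one speaker-session.

    A metric that could not be computed is ``None`` (never zero), with
    the reason recorded in ``notes``.
    """

    speaker: str
    session: str
    aavs: Optional[float]
    qvsa: Optional[float]
    vsahull: Optional[float]
    n_tokens: int
    mode: str
    notes: tuple[str, ...] = field(default=())


@dataclass(frozen=True)
class ShiftVector:
    """Post-minus-baseline movement of one vowel's mean formants."""

    vowel: VowelLabel
    d_f1: float
    d_f2: float


@dataclass(frozen=True)
class EllipseParams:
    """Coverage ellipse of a bivariate point cloud in the (F2, F1) plane."""

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    angle: float  # radians, major axis from the F2 (x) axis
    coverage: float


def compute_aavs(points: Sequence) -> float:
    """Square root of the generalised variance of (F1, F2) points.

    ``sqrt(det(S))`` with S the sample covariance (n−1 denominator).
    Zero iff the points are exactly collinear. Symmetric in the two
    coordinates, so (F1, F2) and (F2, F1) inputs agree.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected (n, 2) points, got shape {pts.shape}")
    if len(pts) < 3:
        raise InsufficientDataError(f"AAVS needs at least 3 points, got {len(pts)}")
    s = np.cov(pts, rowvar=False, ddof=1)
    det = s[0, 0] * s[1, 1] - s[0, 1] * s[1, 0]
    return float(np.sqrt(max(det, 0.0)))


def corner_means_quad(means: Sequence[VowelMeans]) -> np.ndarray:
    """Corner-vowel quadrilateral vertices in fixed perimeter order.

    Order /i/ → /æ/ → /ɑ/ → /u/ in the (F2, F1) plane; raises
    :class:`MissingCornerError` naming the first absent corner.
    """
    by_vowel = {m.vowel: m for m in means}
    verts = []
    for vowel in CORNER_ORDER:
        if vowel not in by_vowel:
            raise MissingCornerError(f"corner vowel /{vowel.ipa}/ ({vowel.value}) missing")
        m = by_vowel[vowel]
        verts.append((m.f2_mean, m.f1_mean))
    return np.array(verts)


def compute_qvsa(means: Sequence[VowelMeans]) -> float:
    """Quadrilateral vowel space area from the four corner-vowel means.

    Absolute shoelace area over /i/ → /æ/ → /ɑ/ → /u/. If the
    quadrilateral self-intersects (possible for heavily centralised
    vowel spaces) a ``UserWarning`` is emitted and the shoelace value
    returned as-is.
    """
    quad = corner_means_quad(means)
    area, crossed = polygon_area(quad, check_simple=True)
    if crossed:
        _warnings.warn(
            "corner-vowel quadrilateral self-intersects; qVSA area is unreliable",
            UserWarning,
            stacklevel=2,
        )
    return area


def compute_vsa_hull(tokens: Sequence[FormantToken]) -> float:
    """Convex-hull area over every token's (F2, F1), all vowels pooled."""
    pts = tokens_to_xy(tokens)
    return convex_hull(pts).area


def tokens_to_xy(tokens: Sequence[FormantToken]) -> np.ndarray:
    """(F2, F1) coordinate array for a token collection."""
    return np.array([(t.f2, t.f1) for t in tokens], dtype=float)


def session_metrics(
    tokens: Sequence[FormantToken], mode: str = TOKEN_LEVEL
) -> VowelSpaceMetrics:
    """Bundle the three metrics for one speaker-session token set.

    ``mode`` selects the AAVS input convention: ``token-level`` uses
    every token (the default); ``mean-level`` uses the per-vowel mean
    coordinates. qVSA always uses per-vowel means of the corner vowels;
    VSAhull always pools all tokens. A sub-metric that cannot be
    computed is ``None`` with a note, not zero.
    """
    if mode not in (TOKEN_LEVEL, MEAN_LEVEL):
        raise ValueError(f"mode must be {TOKEN_LEVEL!r} or {MEAN_LEVEL!r}")
    if not tokens:
        raise InsufficientDataError("no tokens for this speaker-session")
    speakers = {t.speaker for t in tokens}
    sessions = {t.session for t in tokens}
    if len(speakers) != 1 or len(sessions) != 1:
        raise ValueError("session_metrics expects tokens from a single speaker-session")

    means = compute_vowel_means(tokens)
    notes: list[str] = []

    aavs: Optional[float] = None
    try:
        if mode == TOKEN_LEVEL:
            aavs = compute_aavs([(t.f1, t.f2) for t in tokens])
        else:
            aavs = compute_aavs([(m.f1_mean, m.f2_mean) for m in means])
    except InsufficientDataError as exc:
        notes.append(f"aavs: {exc}")

    qvsa: Optional[float] = None
    try:
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            qvsa = compute_qvsa([m for m in means if m.vowel in CORNER_VOWELS])
        notes.extend(f"qvsa: {w.message}" for w in caught)
    except MissingCornerError as exc:
        notes.append(f"qvsa: {exc}")

    vsahull: Optional[float] = None
    try:
        vsahull = compute_vsa_hull(tokens)
    except DegenerateGeometryError as exc:
        notes.append(f"vsahull: {exc}")

    return VowelSpaceMetrics(
        speaker=speakers.pop(),
        session=sessions.pop(),
        aavs=aavs,
        qvsa=qvsa,
        vsahull=vsahull,
        n_tokens=len(tokens),
        mode=mode,
        notes=tuple(notes),
    )


def shift_vectors(
    baseline: Sequence[VowelMeans], post: Sequence[VowelMeans]
) -> list[ShiftVector]:
    """Per-vowel mean-formant movement, post − baseline.

    Only vowels present in both sessions contribute; an empty overlap
    returns an empty list with a warning.
    """
    base = {m.vowel: m for m in baseline}
    after = {m.vowel: m for m in post}
    shared = [v for v in VowelLabel if v in base and v in after]
    if not shared:
        _warnings.warn("no vowels shared between sessions", UserWarning, stacklevel=2)
        return []
    return [
        ShiftVector(
            vowel=v,
            d_f1=after[v].f1_mean - base[v].f1_mean,
            d_f2=after[v].f2_mean - base[v].f2_mean,
        )
        for v in shared
    ]


def confidence_ellipse(points: Sequence, coverage: float = 0.95) -> EllipseParams:
    """Normal-theory coverage ellipse of (F2, F1) points.

    Center is the sample mean; axes follow the eigenvectors of the
    sample covariance, with semi-axis lengths ``sqrt(λ_i · q)`` where
    ``q`` is the chi-square(2 df) quantile at ``coverage`` (≈ 5.991 at
    0.95).
    """
    if not 0 <= coverage < 1:
        raise ValueError("coverage must be in [0, 1)")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise InsufficientDataError("confidence ellipse needs at least 3 (x, y) points")
    cov = np.cov(pts, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    if eigvals[0] <= 0:
        raise DegenerateGeometryError("sample covariance is singular")
    q = stats.chi2.ppf(coverage, df=2)
    lengths = np.sqrt(eigvals * q)
    major = eigvecs[:, 1]  # eigh sorts ascending
    return EllipseParams(
        center=(float(pts[:, 0].mean()), float(pts[:, 1].mean())),
        semi_major=float(lengths[1]),
        semi_minor=float(lengths[0]),
        angle=float(np.arctan2(major[1], major[0])),
        coverage=coverage,
    )


def ellipse_contains(ellipse: EllipseParams, points: Sequence) -> np.ndarray:
    """Boolean mask of points on/inside a coverage ellipse."""
    pts = np.asarray(points, dtype=float) - np.asarray(ellipse.center)
    c, s = np.cos(-ellipse.angle), np.sin(-ellipse.angle)
    u = c * pts[:, 0] - s * pts[:, 1]
    v = s * pts[:, 0] + c * pts[:, 1]
    if ellipse.semi_major == 0 or ellipse.semi_minor == 0:
        return (u == 0) & (v == 0)
    return (u / ellipse.semi_major) ** 2 + (v / ellipse.semi_minor) ** 2 <= 1.0
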