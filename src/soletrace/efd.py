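"""Elliptical Fourier analysis of closed outlines.

A closed contour (x(t), y(t)), parameterized by arc length t over one period T,
is expanded as a sum of rotating ellipses (harmonics). Harmonic k is described
by four coefficients (a_k, b_k, c_k, d_k):

    x(t) = a0 + sum_k a_k cos(2 pi k t / T) + b_k sin(2 pi k t / T)
    y(t) = c0 + sum_k c_k cos(2 pi k t / T) + d_k sin(2 pi k t / T)

Coefficients are obtained in closed form for a polygonal chain (the classical
chain-integral formulation), normalized with respect to the first harmonic for
invariance to size, rotation and the starting point of the contour trace, and
truncated by cumulative Fourier power

    F(n) = sum_{k<=n} (a_k^2 + b_k^2 + c_k^2 + d_k^2) / 2,

expressed as a fraction of the total power at K_max. The harmonic count kept
for an otolith j is the smallest n_j with F(n_j) at or above a precision
threshold (default 99.9%); a sample of otoliths is described with
n = max_j(n_j) harmonics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.decomposition import PCA

from .contour import Contour

__all__ = [
    "EFDSet",
    "ShapeMatrix",
    "compute_efd",
    "normalize_efd",
    "fourier_power",
    "adjust_harmonics",
    "inverse_efd",
    "mean_shape",
    "shape_pca",
    "descriptor_matrix",
]

DEFAULT_K_MAX = 99
DEFAULT_POWER_THRESHOLD = 0.999


@dataclass
class EFDSet:
    """Elliptical Fourier coefficients of one otolith outline.

    ``coeffs`` has shape (K_max, 4) with columns (a_k, b_k, c_k, d_k) for
    k = 1..K_max. ``locus`` carries the DC terms (a0, c0) of the expansion.
    After normalization a_1 = 1, b_1 = 0, c_1 = 0 (within 1e-9) and the
    coefficients are dimensionless.
    """

    coeffs: np.ndarray
    locus: tuple[float, float] = (0.0, 0.0)
    normalized: bool = False
    otolith_id: str = ""
    fish_id: str = ""
    side: str = "R"
    n_j: int | None = None  # adjusted harmonic count, set by adjust_harmonics
    power_threshold: float = DEFAULT_POWER_THRESHOLD

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim != 2 or self.coeffs.shape[1] != 4:
            raise ValueError("coeffs must have shape (K_max, 4)")
        if self.normalized:
            a1, b1, c1, _ = self.coeffs[0]
            if abs(a1 - 1.0) > 1e-9 or abs(b1) > 1e-9 or abs(c1) > 1e-9:
                raise ValueError("normalized flag set but first harmonic is not (1, 0, 0, d1)")

    @property
    def k_max(self) -> int:
        return self.coeffs.shape[0]


@dataclass
class ShapeMatrix:
    """PCA scores of the EFD descriptor matrix (rows = otoliths).

    ``scores`` columns are ordered by decreasing variance;
    ``explained_variance_ratio`` matches; ``n_components`` is the retained
    count (cumulative explained variance >= the threshold used).
    """

    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    n_components: int
    otolith_ids: list[str] = field(default_factory=list)
    var_threshold: float = 0.99


def compute_efd(contour: Contour, k_max: int = DEFAULT_K_MAX) -> EFDSet:
    """Chain-integral elliptical Fourier coefficients of a closed polygon.

    Exact integrals of the piecewise-linear parameterization (arc-length
    parameter); unnormalized and deterministic.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    pts = contour.points
    d = np.roll(pts, -1, axis=0) - pts
    dt = np.sqrt((d**2).sum(axis=1))
    if np.all(dt < 1e-300):
        raise ValueError("degenerate contour: zero perimeter")
    keep = dt > 0
    d, dt = d[keep], dt[keep]
    pts = pts[keep]
    if len(pts) < 3:
        raise ValueError("degenerate contour: fewer than 3 distinct points")
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    phi = 2.0 * np.pi * t / T  # (m+1,)
    k = np.arange(1, k_max + 1)[:, None]  # (K, 1)
    cos_k = np.cos(k * phi)  # (K, m+1)
    sin_k = np.sin(k * phi)
    dcos = cos_k[:, 1:] - cos_k[:, :-1]
    dsin = sin_k[:, 1:] - sin_k[:, :-1]
    const = T / (2.0 * np.pi**2 * k[:, 0] ** 2)  # (K,)
    vx = d[:, 0] / dt
    vy = d[:, 1] / dt
    a = const * (dcos @ vx)
    b = const * (dsin @ vx)
    c = const * (dcos @ vy)
    dd = const * (dsin @ vy)
    # DC terms (locus of the expansion)
    xi = np.concatenate([[0.0], np.cumsum(d[:-1, 0])])
    delta = np.concatenate([[0.0], np.cumsum(d[:-1, 1])])
    t0, t1 = t[:-1], t[1:]
    a0 = (1.0 / T) * np.sum(
        vx / 2.0 * (t1**2 - t0**2) + (xi - vx * t0) * (t1 - t0)
    ) + pts[0, 0]
    c0 = (1.0 / T) * np.sum(
        vy / 2.0 * (t1**2 - t0**2) + (delta - vy * t0) * (t1 - t0)
    ) + pts[0, 1]
    coeffs = np.column_stack([a, b, c, dd])
    return EFDSet(
        coeffs=coeffs,
        locus=(float(a0), float(c0)),
        normalized=False,
        otolith_id=contour.otolith_id,
        fish_id=contour.fish_id,
        side=contour.side,
    )


def _rotate_start(coeffs: np.ndarray, theta: float) -> np.ndarray:
    """Shift the starting point of the trace by phase theta (per harmonic k: k*theta)."""
    k = np.arange(1, coeffs.shape[0] + 1)
    ck, sk = np.cos(k * theta), np.sin(k * theta)
    a, b, c, d = coeffs.T
    return np.column_stack(
        [a * ck + b * sk, -a * sk + b * ck, c * ck + d * sk, -c * sk + d * ck]
    )


def _rotate_space(coeffs: np.ndarray, psi: float) -> np.ndarray:
    """Rotate the coordinate frame by -psi (align the semi-major axis with x)."""
    cp, sp = np.cos(psi), np.sin(psi)
    a, b, c, d = coeffs.T
    return np.column_stack(
        [cp * a + sp * c, cp * b + sp * d, -sp * a + cp * c, -sp * b + cp * d]
    )


def normalize_efd(efd: EFDSet, side: str | None = None) -> EFDSet:
    """First-harmonic normalization: size, rotation and start-point invariant.

    Left-side outlines are mirrored about the vertical axis first so both
    sides share one reference frame. The starting point is rotated so the
    trace begins on the semi-major axis of the first-harmonic ellipse, the
    frame is rotated so that axis lies along x, and all coefficients are
    divided by the semi-major length. The residual half-period/180-degree
    ambiguity is resolved by requiring the first clearly nonzero even-harmonic
    coefficient to be positive, which makes the result deterministic.
    """
    if efd.normalized:
        raise ValueError("EFDSet is already normalized")
    side = side or efd.side
    coeffs = efd.coeffs.copy()
    if side == "L":
        # mirror x -> -x combined with trace reversal keeps orientation CCW:
        # x-cos and y-sin coefficients flip sign
        coeffs[:, 0] *= -1.0
        coeffs[:, 3] *= -1.0
    a1, b1, c1, d1 = coeffs[0]
    denom = a1**2 + c1**2 - b1**2 - d1**2
    theta = 0.5 * np.arctan2(2.0 * (a1 * b1 + c1 * d1), denom)
    out = _rotate_start(coeffs, theta)
    # theta locates an extremum of the first-harmonic radius; make sure it is
    # the maximum (semi-major), not the minimum
    if np.hypot(out[0, 0], out[0, 2]) < np.hypot(out[0, 1], out[0, 3]):
        out = _rotate_start(coeffs, theta + np.pi / 2.0)
    psi = np.arctan2(out[0, 2], out[0, 0])
    out = _rotate_space(out, psi)
    scale = out[0, 0]
    if abs(scale) < 1e-300:
        raise ValueError("zero first-harmonic magnitude; cannot normalize")
    out = out / scale
    out[0, 1] = 0.0
    out[0, 2] = 0.0
    # resolve the joint (theta + pi, psi + pi) ambiguity, which flips the sign
    # of every even harmonic: pick the branch whose first even-harmonic
    # coefficient above tolerance is positive
    if out.shape[0] >= 2:
        even = out[1::2].ravel()  # harmonics 2, 4, 6, ...
        big = np.flatnonzero(np.abs(even) > 1e-7)
        if big.size and even[big[0]] < 0:
            out[1::2] *= -1.0
    return replace(
        efd,
        coeffs=out,
        locus=(0.0, 0.0),
        normalized=True,
        side="R" if side == "L" else side,
    )


def harmonic_power(efd: EFDSet) -> np.ndarray:
    """Per-harmonic power (a^2 + b^2 + c^2 + d^2) / 2 for k = 1..K_max."""
    return 0.5 * (efd.coeffs**2).sum(axis=1)


def fourier_power(efd: EFDSet, n: int) -> float:
    """Cumulative Fourier power F(n) as a fraction of total power at K_max."""
    if not 1 <= n <= efd.k_max:
        raise ValueError(f"n must be in [1, {efd.k_max}]")
    p = harmonic_power(efd)
    total = p.sum()
    if total <= 0:
        raise ValueError("zero total power")
    return float(p[:n].sum() / total)


def adjust_harmonics(
    efds: list[EFDSet], threshold: float = DEFAULT_POWER_THRESHOLD
) -> int:
    """Smallest harmonic count reaching ``threshold`` power for every otolith.

    Sets ``n_j`` on each EFDSet (its own smallest count) and returns
    max_j(n_j) over the sample.
    """
    if not efds:
        raise ValueError("empty EFD list")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    n_max = 0
    for e in efds:
        p = harmonic_power(e)
        frac = np.cumsum(p) / p.sum()
        n_j = int(np.searchsorted(frac, threshold - 1e-12) + 1)
        n_j = min(n_j, e.k_max)
        e.n_j = n_j
        e.power_threshold = threshold
        n_max = max(n_max, n_j)
    return n_max


def inverse_efd(efd: EFDSet, n: int | None = None, n_points: int = 256) -> Contour:
    """Evaluate the truncated Fourier series: the reverse transform outline."""
    n = n if n is not None else efd.k_max
    if not 1 <= n <= efd.k_max:
        raise ValueError(f"n must be in [1, {efd.k_max}]")
    if n_points < 16:
        raise ValueError("n_points must be >= 16")
    t = np.linspace(0.0, 1.0, n_points, endpoint=False)
    k = np.arange(1, n + 1)[:, None]
    cos_kt = np.cos(2.0 * np.pi * k * t)
    sin_kt = np.sin(2.0 * np.pi * k * t)
    a, b, c, d = efd.coeffs[:n].T
    x = efd.locus[0] + a @ cos_kt + b @ sin_kt
    y = efd.locus[1] + c @ cos_kt + d @ sin_kt
    return Contour(
        points=np.column_stack([x, y]),
        otolith_id=efd.otolith_id,
        fish_id=efd.fish_id,
        side=efd.side,
    )


def mean_shape(
    efds: list[EFDSet],
    groups: list[str] | np.ndarray,
    n: int | None = None,
    n_points: int = 256,
) -> dict[str, Contour]:
    """Per-group mean outline: coefficient-wise mean then reverse transform.

    ``n`` defaults to the adjusted harmonic count max_j(n_j) if recorded,
    else K_max. Outlines are centered at the origin and unit-scaled (first
    harmonic semi-major = 1) because inputs are normalized.
    """
    if len(efds) != len(groups):
        raise ValueError("efds and groups must align")
    if not all(e.normalized for e in efds):
        raise ValueError("mean_shape requires normalized EFDs")
    if n is None:
        njs = [e.n_j for e in efds if e.n_j is not None]
        n = max(njs) if njs else efds[0].k_max
    out: dict[str, Contour] = {}
    groups = np.asarray(groups)
    for g in np.unique(groups):
        members = [e for e, gg in zip(efds, groups) if gg == g]
        mean_coeffs = np.mean([e.coeffs for e in members], axis=0)
        m = EFDSet(coeffs=mean_coeffs, normalized=False, otolith_id=str(g))
        out[str(g)] = inverse_efd(m, n=n, n_points=n_points)
    return out


def descriptor_matrix(efds: list[EFDSet], n: int | None = None) -> np.ndarray:
    """Stack normalized coefficients of harmonics 2..n into a descriptor matrix.

    Harmonic 1 is fixed by normalization (1, 0, 0, d1 with d1 the aspect
    ratio of the first ellipse) and is excluded, giving 4*(n-1) columns per
    otolith (e.g. 392 descriptors for n = 99).
    """
    if not efds:
        raise ValueError("empty EFD list")
    if n is None:
        njs = [e.n_j for e in efds if e.n_j is not None]
        n = max(njs) if njs else efds[0].k_max
    if n < 2:
        raise ValueError("need n >= 2 to build a descriptor matrix")
    return np.stack([e.coeffs[1:n].ravel() for e in efds])


def shape_pca(
    efds: list[EFDSet],
    var_threshold: float = 0.99,
    n: int | None = None,
) -> ShapeMatrix:
    """Centered (unscaled) PCA of the EFD descriptor matrix.

    Retains the smallest leading set of components whose cumulative explained
    variance reaches ``var_threshold``.
    """
    if len(efds) < 3:
        raise ValueError("need at least 3 otoliths for a shape PCA")
    if not all(e.normalized for e in efds):
        raise ValueError("shape_pca requires normalized EFDs")
    X = descriptor_matrix(efds, n=n)
    pca = PCA(n_components=min(X.shape), svd_solver="full")
    scores = pca.fit_transform(X)
    ratio = pca.explained_variance_ratio_
    cum = np.cumsum(ratio)
    if var_threshold >= 1.0:
        n_comp = int(np.sum(pca.explained_variance_ > 1e-12 * pca.explained_variance_[0]))
    else:
        n_comp = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
    n_comp = max(1, min(n_comp, scores.shape[1]))
    return ShapeMatrix(
        scores=scores[:, :n_comp],
        explained_variance_ratio=ratio[:n_comp],
        n_components=n_comp,
        otolith_ids=[e.otolith_id for e in efds],
        var_threshold=var_threshold,
    )
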