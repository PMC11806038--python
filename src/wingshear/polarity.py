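"""Planar-polarity nematics, circular statistics and cell-shape metrics.

Cell polarity is estimated from the intensity-weighted second moment of unit
directions from the cell centroid to its boundary pixels: a cell with
protein concentrated on two opposite junctions (bipolarity) has a large
eigenvalue gap, an evenly decorated cell has none.  Optional shape
normalisation whitens boundary positions by the inverse square root of the
unweighted shape covariance so elongated cells do not bias the polarity
axis toward their long axis.

Magnitude is (l1 - l2)/(l1 + l2) in [0, 1]; for a circular cell painted
I(phi) = 1 + A cos 2(phi - phi0) this estimator returns magnitude A/2 at
axis phi0 (closed form of the weighted second-moment integral).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._angles import wrap_axial

__all__ = [
    "PolarityVector",
    "cell_polarity",
    "polarity_from_junctions",
    "coarse_grain_polarity",
    "polarity_angle_variance",
    "weighted_circular_histogram",
    "cell_eccentricity",
]


@dataclasses.dataclass(frozen=True)
class PolarityVector:
    """Nematic (axial) polarity: magnitude in [0, 1], angle in [-90, 90)."""

    magnitude: float
    angle_deg: float

    def __post_init__(self):
        if not (0.0 <= self.magnitude <= 1.0 + 1e-12):
            raise ValueError(f"polarity magnitude outside [0, 1]: {self.magnitude}")


def _second_moment_polarity(directions, weights):
    u = directions / np.linalg.norm(directions, axis=1, keepdims=True)
    w = weights / weights.sum()
    m = np.einsum("p,pa,pb->ab", w, u, u)
    evals, evecs = np.linalg.eigh(m)
    l1, l2 = evals[1], evals[0]
    mag = float((l1 - l2) / (l1 + l2))
    lead = evecs[:, 1]
    ang = float(wrap_axial(np.degrees(np.arctan2(-lead[1], lead[0]))))  # y flip
    return PolarityVector(min(mag, 1.0), ang)


def cell_polarity(boundary_xy, intensities, centroid, shape_normalize=True):
    """Polarity of one cell from boundary pixel positions and intensities.

    boundary_xy: (n, 2) boundary pixel coordinates (image convention, y down).
    intensities: (n,) non-negative weights, total > 0.
    centroid: (2,) cell centroid in the same coordinates.
    shape_normalize: whiten positions by the inverse square root of the
    unweighted shape covariance before forming direction vectors.
    """
    xy = np.asarray(boundary_xy, float)
    w = np.asarray(intensities, float)
    if xy.shape[0] < 8:
        raise ValueError("cell_polarity needs >= 8 boundary pixels")
    if np.any(w < 0):
        raise ValueError("intensities must be non-negative")
    if w.sum() <= 0:
        raise ValueError("zero total intensity")
    r = xy - np.asarray(centroid, float)
    if shape_normalize:
        cov = np.cov(r.T)
        evals, evecs = np.linalg.eigh(cov)
        if evals[0] <= 1e-12 * max(evals[1], 1.0):
            raise ValueError("degenerate (collinear) boundary")
        whiten = evecs @ np.diag(evals ** -0.5) @ evecs.T
        r = r @ whiten.T
    norms = np.linalg.norm(r, axis=1)
    keep = norms > 0
    if keep.sum() < 8:
        raise ValueError("degenerate boundary: too many pixels at the centroid")
    return _second_moment_polarity(r[keep], w[keep])


def polarity_from_junctions(junction_mid_xy, junction_weights, centroid,
                            shape_normalize=True):
    """Cell polarity from junction midpoints weighted by junctional intensity.

    Convenience for table-level pipelines where per-pixel boundary samples
    are unavailable: each junction contributes its midpoint direction,
    weighted by its summed intensity.  Same estimator as cell_polarity, with
    the >= 8 sample requirement relaxed to >= 3 junctions.
    """
    xy = np.asarray(junction_mid_xy, float)
    w = np.asarray(junction_weights, float)
    if xy.shape[0] < 3:
        raise ValueError("needs >= 3 junctions")
    if w.sum() <= 0:
        raise ValueError("zero total intensity")
    r = xy - np.asarray(centroid, float)
    if shape_normalize and xy.shape[0] >= 4:
        cov = np.cov(r.T)
        evals, evecs = np.linalg.eigh(cov)
        if evals[0] > 1e-12 * max(evals[1], 1.0):
            r = r @ (evecs @ np.diag(evals ** -0.5) @ evecs.T).T
    return _second_moment_polarity(r, w)


def coarse_grain_polarity(magnitudes, angles_deg):
    """Nematic average polarity of a group of cells.

    (Qxx, Qxy) = mean over cells of m_c (cos 2phi_c, sin 2phi_c);
    magnitude = |Q|, angle = 0.5 atan2(Qxy, Qxx).
    """
    m = np.asarray(magnitudes, float)
    phi2 = 2.0 * np.radians(np.asarray(angles_deg, float))
    if m.size < 1:
        raise ValueError("coarse_grain_polarity needs >= 1 cell")
    qxx = float(np.mean(m * np.cos(phi2)))
    qxy = float(np.mean(m * np.sin(phi2)))
    mag = float(np.hypot(qxx, qxy))
    ang = float(wrap_axial(np.degrees(0.5 * np.arctan2(qxy, qxx))))
    return PolarityVector(min(mag, 1.0), ang)


def polarity_angle_variance(angles_deg, magnitudes=None):
    """Axial circular variance V = 1 - |mean exp(2i phi)| in [0, 1].

    Unweighted over cells by default (the per-image statistic); pass
    magnitudes for the magnitude-weighted variant.
    """
    phi2 = 2.0 * np.radians(np.asarray(angles_deg, float))
    if phi2.size < 2:
        raise ValueError("polarity_angle_variance needs >= 2 cells")
    if magnitudes is None:
        w = np.ones_like(phi2)
    else:
        w = np.asarray(magnitudes, float)
    z = np.sum(w * np.exp(1j * phi2)) / w.sum()
    return float(1.0 - np.abs(z))


def weighted_circular_histogram(angles_deg, magnitudes, n_bins=20):
    """Weighted circular histogram of polarity angles over [0, 360).

    Axial angles are duplicated at phi and phi + 180 before binning into
    `n_bins` half-open bins [a, a + width); each bin's radial value is its
    count times the mean polarity magnitude of its members.
    Returns (bin_edges_deg, weights) with len(bin_edges) = n_bins + 1.
    """
    phi = np.asarray(angles_deg, float) % 360.0
    m = np.asarray(magnitudes, float)
    if phi.size < 1:
        raise ValueError("histogram needs >= 1 cell")
    phi_dup = np.concatenate([phi, (phi + 180.0) % 360.0])
    m_dup = np.concatenate([m, m])
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    idx = np.minimum((phi_dup // (360.0 / n_bins)).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=m_dup, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean_m = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    weights = counts * mean_m
    return edges, weights


def cell_eccentricity(pixel_xy):
    """Eccentricity from the unweighted second-moment matrix of member pixels.

    With eigenvalues l1 >= l2: e = sqrt(1 - l2/l1), in [0, 1); rotation
    invariant.
    """
    xy = np.asarray(pixel_xy, float)
    if xy.shape[0] < 2:
        raise ValueError("degenerate region")
    r = xy - xy.mean(axis=0)
    cov = (r.T @ r) / len(r)
    evals = np.linalg.eigvalsh(cov)
    l2, l1 = evals
    if l1 <= 0:
        raise ValueError("degenerate region (zero spread)")
    return float(np.sqrt(max(0.0, 1.0 - l2 / l1)))
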