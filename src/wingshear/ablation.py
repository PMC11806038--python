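"""Laser-ablation recoil anisotropy and FRAP recovery fitting.

A circular wound (5 um radius in the source protocol) recoils into an
ellipse under anisotropic tissue stress; the recoil anisotropy
v_a = (v_maj - v_min)/2 is the stress-anisotropy proxy, with the stress
axis given by the fitted ellipse orientation.  FRAP recovery curves are
background-subtracted, normalised to the pre-bleach mean and fitted with a
one-phase exponential association F(t) = F0 + (plateau - F0)(1 - e^{-kt}).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import curve_fit
from skimage.measure import EllipseModel

from ._angles import wrap_axial

__all__ = [
    "fit_ellipse",
    "recoil_velocities",
    "anisotropic_recoil",
    "AblationSeries",
    "normalize_frap",
    "frap_fit",
    "FrapFit",
]


def fit_ellipse(points_xy):
    """Least-squares ellipse fit to boundary points.

    points_xy: (n, 2) in um (image convention, y down); n >= 6,
    non-collinear.  Returns (a, b, orientation_deg) with a >= b and the
    axial orientation of the major axis in the mathematical convention.
    """
    pts = np.asarray(points_xy, float)
    if pts.shape[0] < 6:
        raise ValueError("fit_ellipse needs >= 6 points")
    if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        raise ValueError("degenerate fit: collinear points")
    if hasattr(EllipseModel, "from_estimate"):
        model = EllipseModel.from_estimate(pts)
        if not model:
            raise ValueError("degenerate or non-elliptical fit")
        a, b = model.axis_lengths
        theta = model.theta
    else:  # scikit-image < 0.26
        model = EllipseModel()
        if not model.estimate(pts):
            raise ValueError("degenerate or non-elliptical fit")
        _, _, a, b, theta = model.params
    if a < b:
        a, b = b, a
        theta += np.pi / 2
    if not (np.isfinite(a) and np.isfinite(b) and b > 0):
        raise ValueError("degenerate or non-elliptical fit")
    orientation = float(wrap_axial(-np.degrees(theta)))  # y flip to math convention
    return float(a), float(b), orientation


@dataclasses.dataclass
class AblationSeries:
    """Post-ablation ellipse time series.

    r0_um: pre-ablation circular ROI radius; times_s since ablation;
    a_um/b_um/orientation_deg: fitted semi-axes (a >= b) and axial
    orientation per time point.
    """

    r0_um: float
    times_s: np.ndarray
    a_um: np.ndarray
    b_um: np.ndarray
    orientation_deg: np.ndarray

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, float)
        self.a_um = np.asarray(self.a_um, float)
        self.b_um = np.asarray(self.b_um, float)
        self.orientation_deg = np.asarray(self.orientation_deg, float)
        if np.any(self.a_um < self.b_um):
            raise ValueError("semi-major axis must satisfy a >= b")
        if np.any(self.b_um <= 0):
            raise ValueError("semi-minor axis must be positive")


def recoil_velocities(series, t_eval_s=None):
    """Initial recoil velocities along the semi-major and semi-minor axes.

    v_maj = (a(t) - r0)/t and v_min = (b(t) - r0)/t, um/s.  By default t is
    the first post-ablation frame (60-s cadence in the protocol); pass
    t_eval_s=120 for the snapshot convention used in figures.
    """
    if t_eval_s is None:
        t_eval_s = float(series.times_s[series.times_s > 0].min())
    if not t_eval_s > 0:
        raise ValueError("t_eval must be > 0")
    idx = int(np.argmin(np.abs(series.times_s - t_eval_s)))
    if not np.isclose(series.times_s[idx], t_eval_s):
        raise ValueError(f"no ellipse at t = {t_eval_s} s")
    v_maj = (series.a_um[idx] - series.r0_um) / t_eval_s
    v_min = (series.b_um[idx] - series.r0_um) / t_eval_s
    return float(v_maj), float(v_min)


def anisotropic_recoil(v_maj, v_min):
    """Anisotropic recoil velocity v_a = (v_maj - v_min) / 2, um/s."""
    return (float(v_maj) - float(v_min)) / 2.0


def normalize_frap(times_s, raw, background=0.0, n_prebleach=3):
    """Background-subtract and normalise a FRAP trace to its pre-bleach mean.

    The first `n_prebleach` samples are pre-bleach; returns
    (post_times_s, normalized_post) with the post-bleach clock starting at 0.
    """
    raw = np.asarray(raw, float) - float(background)
    pre = raw[:n_prebleach]
    if pre.size == 0 or pre.mean() <= 0:
        raise ValueError("invalid pre-bleach reference")
    norm = raw / pre.mean()
    times_s = np.asarray(times_s, float)
    post_t = times_s[n_prebleach:] - times_s[n_prebleach]
    return post_t, norm[n_prebleach:]


@dataclasses.dataclass(frozen=True)
class FrapFit:
    plateau: float
    k_per_s: float
    f0: float
    r_squared: float
    flagged: bool


def _one_phase(t, f0, plateau, k):
    return f0 + (plateau - f0) * (1.0 - np.exp(-k * t))


def frap_fit(times_s, normalized, r2_threshold=0.5):
    """Fit a one-phase exponential association to a normalised FRAP trace.

    times_s start at 0 at the first post-bleach frame.  Fits with R^2 below
    `r2_threshold` are flagged (the exclusion rule standing in for a formal
    lack-of-fit test).  Invariant to a shift of the post-bleach time origin
    and to uniform intensity gain (gain rescales plateau/F0 together).
    """
    t = np.asarray(times_s, float)
    y = np.asarray(normalized, float)
    if t.size < 8:
        raise ValueError("frap_fit needs >= 8 post-bleach points")
    t = t - t[0]
    f0_guess = float(y[0])
    plat_guess = float(np.mean(y[-3:]))
    if plat_guess <= f0_guess:
        plat_guess = f0_guess + max(0.1, abs(f0_guess) * 0.1)
    k_guess = 1.0 / max(t[-1] / 3.0, 1e-6)
    try:
        popt, _ = curve_fit(
            _one_phase, t, y,
            p0=[f0_guess, plat_guess, k_guess],
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as err:
        raise ValueError(f"FRAP fit did not converge: {err}") from err
    f0, plateau, k = (float(v) for v in popt)
    if plateau <= f0:
        raise ValueError("degenerate fit: plateau <= bleach floor")
    resid = y - _one_phase(t, *popt)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return FrapFit(plateau=plateau, k_per_s=k, f0=f0, r_squared=r2,
                   flagged=r2 < r2_threshold)


# the acquisition schedule of the FRAP protocol: 5 frames every 5 s, then
# 10 every 10 s, 10 every 15 s and 8 every 30 s after the bleach
def frap_sampling_times():
    t = [0.0]
    for n, dt in [(4, 5.0), (10, 10.0), (10, 15.0), (8, 30.0)]:
        for _ in range(n):
            t.append(t[-1] + dt)
    return np.asarray(t)
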