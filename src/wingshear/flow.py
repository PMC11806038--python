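"""Tissue velocity-gradient analysis.

Per-cell velocities from tracked centroids are coarse-grained onto a square
grid sized so each element holds one to two centroids (fine mode; up to four
in coarse mode).  Forward finite differences between neighbouring elements
give a 2x2 velocity-gradient tensor per element, which is rotated into the
frame of the nematic mean flow direction.  The tissue-wide gradient is the
mean absolute off-diagonal component over valid elements; the two diagonal
components are carried along diagnostically (they were found negligible in
the source data and do not enter the headline statistic).

Internally all geometry is converted to the mathematical convention (y up);
positions in um, time in minutes, gradients in 1/min.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from ._angles import wrap_axial

__all__ = [
    "cell_velocities",
    "assign_grid",
    "grid_velocity",
    "local_gradient_tensor",
    "flow_direction",
    "rotate_tensor",
    "aggregate_gradient",
    "gradient_time_series",
    "GridField",
    "GradientField",
]


def cell_velocities(cells, frame, interval_min=None):
    """Velocities of cells present at both `frame` and the next frame.

    v = (centroid(t+dt) - centroid(t)) / dt, in um/min, mathematical y.
    Returns a DataFrame (cell_id, x_um, y_um, vx, vy, speed, phi_deg) where
    (x_um, y_um) is the start-frame position (y flipped to mathematical
    convention) and phi is the direction of motion in degrees.  Cells absent
    at either endpoint are skipped; the skipped count is in df.attrs.
    """
    a = cells[cells["frame"] == frame]
    b = cells[cells["frame"] == frame + 1]
    if interval_min is None:
        ta, tb = a["time_hapf"].iloc[0], b["time_hapf"].iloc[0]
        interval_min = (tb - ta) * 60.0
    if not interval_min > 0:
        raise ValueError(f"frame interval must be > 0, got {interval_min}")
    merged = a.merge(b, on="cell_id", suffixes=("_0", "_1"))
    vx = (merged["x_um_1"] - merged["x_um_0"]).to_numpy() / interval_min
    vy = -(merged["y_um_1"] - merged["y_um_0"]).to_numpy() / interval_min  # y flip
    out = pd.DataFrame({
        "cell_id": merged["cell_id"],
        "x_um": merged["x_um_0"],
        "y_um": -merged["y_um_0"].to_numpy(),
        "vx": vx,
        "vy": vy,
        "speed": np.hypot(vx, vy),
        "phi_deg": np.degrees(np.arctan2(vy, vx)),
    })
    out.attrs["n_skipped"] = len(a) + len(b) - 2 * len(merged)
    return out


@dataclasses.dataclass
class GridField:
    """Coarse-graining grid: per-element member lists, positions, velocities.

    2-D arrays are indexed [i, j] with i the row (increasing y) and j the
    column (increasing x).  Element position is the mean member centroid by
    default (the denominators of the finite differences divide by data
    positions); `geometric_centers=True` in assign_grid switches to fixed
    grid centres.
    """

    pitch: float
    origin: np.ndarray           # (2,) lower corner (x0, y0)
    n: np.ndarray                # (ni, nj) member counts
    x: np.ndarray                # (ni, nj) element x positions
    y: np.ndarray
    vx: np.ndarray | None
    vy: np.ndarray | None
    members: dict                # (i, j) -> index array into the sample table
    valid: np.ndarray            # (ni, nj) bool, element has >= 1 member

    @property
    def shape(self):
        return self.n.shape

    @property
    def median_occupancy(self):
        return float(np.median(self.n[self.valid]))


def _grid_assign(points, pitch, origin):
    """Nearest-element assignment with lexicographic (i, j) tie-break."""
    u = (points[:, 0] - origin[0]) / pitch
    v = (points[:, 1] - origin[1]) / pitch
    eps = 1e-9
    j = np.floor(u).astype(int)
    i = np.floor(v).astype(int)
    # a point exactly on an internal boundary is equidistant to two element
    # centres; assign it to the smaller (i, j)
    on_edge_u = np.isclose(u, np.round(u), atol=eps) & (np.round(u) > 0)
    on_edge_v = np.isclose(v, np.round(v), atol=eps) & (np.round(v) > 0)
    j[on_edge_u] = np.round(u[on_edge_u]).astype(int) - 1
    i[on_edge_v] = np.round(v[on_edge_v]).astype(int) - 1
    return i, j


def assign_grid(points, mean_area, mode="fine", geometric_centers=False,
                max_iter=40):
    """Build the coarse-graining grid over cell centroid positions.

    points: (n, 2) array of (x, y) centroids (mathematical y), um.
    mean_area: mean cell apical area, um^2 (sets the initial pitch).
    mode: 'fine' targets a median occupancy of 1-2 centroids per element,
    'coarse' targets 2-4; the pitch coefficient is adjusted by bisection on
    realised median occupancy.
    """
    points = np.asarray(points, float)
    if len(points) < 4:
        raise ValueError("assign_grid needs >= 4 cells")
    lo_t, hi_t = (1.0, 2.0) if mode == "fine" else (2.0, 4.0)
    c0 = 1.2 if mode == "fine" else 2.4
    base = float(np.sqrt(mean_area))
    span = points.max(axis=0) - points.min(axis=0)
    if min(span) < c0 * base:
        raise ValueError("degenerate extent: centroids span less than one grid pitch")

    def realised(c):
        pitch = c * base
        origin = points.min(axis=0) - 1e-9
        i, j = _grid_assign(points, pitch, origin)
        counts = {}
        for ii, jj in zip(i, j):
            counts[(ii, jj)] = counts.get((ii, jj), 0) + 1
        return float(np.median(list(counts.values()))), pitch, origin, i, j

    c = c0
    lo_c, hi_c = 0.4, 8.0
    med, pitch, origin, i, j = realised(c)
    it = 0
    while not (lo_t <= med <= hi_t) and it < max_iter:
        if med < lo_t:
            lo_c = c
        else:
            hi_c = c
        c = 0.5 * (lo_c + hi_c)
        med, pitch, origin, i, j = realised(c)
        it += 1

    ni, nj = i.max() + 1, j.max() + 1
    n = np.zeros((ni, nj), int)
    sx = np.zeros((ni, nj))
    sy = np.zeros((ni, nj))
    members = {}
    for idx, (ii, jj) in enumerate(zip(i, j)):
        n[ii, jj] += 1
        sx[ii, jj] += points[idx, 0]
        sy[ii, jj] += points[idx, 1]
        members.setdefault((ii, jj), []).append(idx)
    valid = n > 0
    with np.errstate(invalid="ignore"):
        x = np.where(valid, sx / np.maximum(n, 1), np.nan)
        y = np.where(valid, sy / np.maximum(n, 1), np.nan)
    if geometric_centers:
        jj_idx, ii_idx = np.meshgrid(np.arange(nj), np.arange(ni))
        x = np.where(valid, origin[0] + (jj_idx + 0.5) * pitch, np.nan)
        y = np.where(valid, origin[1] + (ii_idx + 0.5) * pitch, np.nan)
    members = {k: np.asarray(v, int) for k, v in members.items()}
    return GridField(pitch=pitch, origin=origin, n=n, x=x, y=y,
                     vx=None, vy=None, members=members, valid=valid)


def grid_velocity(field, vx, vy):
    """Mean member velocity per element: v(i,j) = (1/n_ij) sum_k v(k)."""
    vx = np.asarray(vx, float)
    vy = np.asarray(vy, float)
    gvx = np.full(field.shape, np.nan)
    gvy = np.full(field.shape, np.nan)
    for (i, j), idx in field.members.items():
        gvx[i, j] = vx[idx].mean()
        gvy[i, j] = vy[idx].mean()
    field.vx = gvx
    field.vy = gvy
    return field


@dataclasses.dataclass
class GradientField:
    """Per-element 2x2 velocity-gradient tensors with validity masks.

    d[..., 0, 0] = dvx/dx, d[..., 0, 1] = dvx/dy,
    d[..., 1, 0] = dvy/dx, d[..., 1, 1] = dvy/dy (all 1/min).
    A component is valid only where the forward neighbour exists and the
    coordinate denominator exceeds pitch/10.
    """

    d: np.ndarray       # (ni, nj, 2, 2)
    valid: np.ndarray   # (ni, nj, 2, 2) bool


def local_gradient_tensor(field):
    """Forward finite differences between neighbouring grid elements."""
    if field.vx is None:
        raise ValueError("grid velocities not set; call grid_velocity first")
    ni, nj = field.shape
    if ni < 2 or nj < 2:
        raise ValueError("grid must have >= 2 valid rows and columns")
    d = np.full((ni, nj, 2, 2), np.nan)
    valid = np.zeros((ni, nj, 2, 2), bool)
    min_den = field.pitch / 10.0

    # x-derivatives: forward neighbour in j
    dx = field.x[:, 1:] - field.x[:, :-1]
    okx = field.valid[:, 1:] & field.valid[:, :-1] & (np.abs(dx) > min_den)
    with np.errstate(invalid="ignore", divide="ignore"):
        d[:, :-1, 0, 0] = np.where(okx, (field.vx[:, 1:] - field.vx[:, :-1]) / dx, np.nan)
        d[:, :-1, 1, 0] = np.where(okx, (field.vy[:, 1:] - field.vy[:, :-1]) / dx, np.nan)
    valid[:, :-1, 0, 0] = okx
    valid[:, :-1, 1, 0] = okx

    # y-derivatives: forward neighbour in i
    dy = field.y[1:, :] - field.y[:-1, :]
    oky = field.valid[1:, :] & field.valid[:-1, :] & (np.abs(dy) > min_den)
    with np.errstate(invalid="ignore", divide="ignore"):
        d[:-1, :, 0, 1] = np.where(oky, (field.vx[1:, :] - field.vx[:-1, :]) / dy, np.nan)
        d[:-1, :, 1, 1] = np.where(oky, (field.vy[1:, :] - field.vy[:-1, :]) / dy, np.nan)
    valid[:-1, :, 0, 1] = oky
    valid[:-1, :, 1, 1] = oky
    return GradientField(d=d, valid=valid)


def flow_direction(vx, vy, axis_mode="PD", literal=False):
    """Nematic mean flow direction across cells.

    The nematic average velocity vector is
    (vbar_x, vbar_y) = (1/n) sum_k |v_k|^2 (cos 2phi_k, sin 2phi_k),
    weighting each cell by squared speed.  By default the flow axis is the
    half-angle theta = 0.5*atan2(vbar_y, vbar_x), mapped to axial [-90, 90);
    `literal=True` instead takes atan(vbar_y/vbar_x) of the doubled-angle
    vector directly (the printed formula, a 2-theta quantity).  In AP mode
    the axis is rotated by 90 degrees (axial) so the gradient components are
    reported relative to the anterior-posterior flow.
    Returns (vbar_x, vbar_y, theta_deg).
    """
    vx = np.asarray(vx, float)
    vy = np.asarray(vy, float)
    speed2 = vx * vx + vy * vy
    if not np.any(speed2 > 0):
        raise ValueError("flow direction undefined: all velocities are zero")
    phi = np.arctan2(vy, vx)
    vbar_x = float(np.mean(speed2 * np.cos(2 * phi)))
    vbar_y = float(np.mean(speed2 * np.sin(2 * phi)))
    if literal:
        den = vbar_y if axis_mode == "AP" else vbar_x
        num = vbar_x if axis_mode == "AP" else vbar_y
        theta = float(np.degrees(np.arctan(num / den))) if den != 0 else 90.0
    else:
        theta = float(np.degrees(0.5 * np.arctan2(vbar_y, vbar_x)))
        if axis_mode == "AP":
            theta -= 90.0
    return vbar_x, vbar_y, float(wrap_axial(theta))


def rotate_tensor(grad, theta_deg):
    """Express tensors in the flow-aligned frame (x' along the flow axis).

    Tensor transformation law D' = R D R^-1 where R is the 2-D rotation
    matrix taking lab axes onto the flow axes, i.e. conjugation by
    R(-theta) for a flow at angle theta: a pure shear at angle theta maps
    back onto the canonical dv'_x/dy' component.  Elements with any invalid
    component are excluded (masked) from rotation.  Returns a new
    GradientField.
    """
    th = np.radians(theta_deg)
    c, s = np.cos(-th), np.sin(-th)
    rot = np.array([[c, -s], [s, c]])
    full = grad.valid.all(axis=(2, 3))
    d = np.full_like(grad.d, np.nan)
    d[full] = np.einsum("ab,nbc,dc->nad", rot, grad.d[full], rot)
    valid = np.zeros_like(grad.valid)
    valid[full] = True
    return GradientField(d=d, valid=valid)


def aggregate_gradient(grad):
    """Tissue-wide gradient: mean |component| over valid elements.

    Returns a dict with the two off-diagonal aggregates (the headline
    quantities), the diagonal aggregates (diagnostic only) and the number of
    elements entering each mean.  All values in 1/min.
    """
    out = {}
    names = {(0, 0): "dvx_dx_abs", (0, 1): "dvx_dy_abs",
             (1, 0): "dvy_dx_abs", (1, 1): "dvy_dy_abs"}
    for (a, b), name in names.items():
        mask = grad.valid[..., a, b]
        vals = grad.d[..., a, b][mask]
        out[name] = float(np.mean(np.abs(vals))) if vals.size else np.nan
        out[f"n_{name}"] = int(vals.size)
    if out["n_dvx_dy_abs"] == 0 and out["n_dvy_dx_abs"] == 0:
        raise ValueError("no valid rotated tensors to aggregate")
    out["n_valid_elements"] = max(out["n_dvx_dy_abs"], out["n_dvy_dx_abs"])
    return out


def _interval_gradient(cells, frame, interval_min, mode, theta_deg,
                       geometric_centers=False):
    samples = cell_velocities(cells, frame, interval_min)
    pts = samples[["x_um", "y_um"]].to_numpy()
    sub = cells[cells["frame"] == frame]
    mean_area = float(sub["area_um2"].mean())
    field = assign_grid(pts, mean_area, mode=mode, geometric_centers=geometric_centers)
    grid_velocity(field, samples["vx"].to_numpy(), samples["vy"].to_numpy())
    grad = local_gradient_tensor(field)
    rotated = rotate_tensor(grad, theta_deg)
    return aggregate_gradient(rotated), field, rotated


def gradient_time_series(cells, meta, window_min=120.0, mode="fine",
                         theta_literal=False, geometric_centers=False):
    """Instantaneous and window-averaged tissue velocity gradients.

    Instantaneous gradients are computed per consecutive frame pair (15-min
    cadence in the source data); the flow direction theta is estimated once
    per window from all velocity samples inside it, and window averages are
    arithmetic means of the instantaneous values (8 values for a 2-h window
    at 15-min intervals).

    Returns (per_interval, per_window) DataFrames.  per_interval matches the
    gradients.csv schema.
    """
    interval = meta.frame_interval_min
    if window_min < interval:
        raise ValueError("window shorter than one frame interval")
    frames = sorted(cells["frame"].unique().tolist())
    if len(frames) < 2:
        raise ValueError("gradient_time_series needs >= 2 frames")
    pair_frames = [t for t in frames[:-1] if t + 1 in frames]
    per_window_len = max(1, int(round(window_min / interval)))
    rows = []
    window_rows = []
    for w_start in range(0, len(pair_frames), per_window_len):
        w_frames = pair_frames[w_start:w_start + per_window_len]
        all_vx, all_vy = [], []
        for t in w_frames:
            s = cell_velocities(cells, t, interval)
            all_vx.append(s["vx"].to_numpy())
            all_vy.append(s["vy"].to_numpy())
        vx = np.concatenate(all_vx)
        vy = np.concatenate(all_vy)
        if np.any(vx != 0) or np.any(vy != 0):
            _, _, theta = flow_direction(vx, vy, axis_mode=meta.axis_mode,
                                         literal=theta_literal)
        else:
            theta = 0.0  # stationary window: gradients are zero in any frame
        w_vals = {k: [] for k in ("dvx_dy_abs", "dvy_dx_abs", "dvx_dx_abs", "dvy_dy_abs")}
        for t in w_frames:
            agg, _, _ = _interval_gradient(cells, t, interval, mode, theta,
                                           geometric_centers)
            rows.append({
                "t_start_hapf": meta.frame_time_hapf(t),
                "t_end_hapf": meta.frame_time_hapf(t + 1),
                "theta_deg": theta,
                "dvx_dy_abs": agg["dvx_dy_abs"],
                "dvy_dx_abs": agg["dvy_dx_abs"],
                "dvx_dx_abs": agg["dvx_dx_abs"],
                "dvy_dy_abs": agg["dvy_dy_abs"],
                "n_valid_elements": agg["n_valid_elements"],
            })
            for k in w_vals:
                w_vals[k].append(agg[k])
        window_rows.append({
            "t_start_hapf": meta.frame_time_hapf(w_frames[0]),
            "t_end_hapf": meta.frame_time_hapf(w_frames[-1] + 1),
            "theta_deg": theta,
            **{k: float(np.nanmean(v)) for k, v in w_vals.items()},
            "n_intervals": len(w_frames),
        })
    per_interval = pd.DataFrame(rows)
    per_window = pd.DataFrame(window_rows)
    return per_interval, per_window
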