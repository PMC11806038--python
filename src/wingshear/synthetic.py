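"""Ground-truthed synthetic tracked epithelia.

A jittered hexagonal lattice is turned into a Voronoi polygon mesh; its
topology is frozen (perfect tracking) and every vertex is advected by an
imposed kinematic flow field with Euler steps at the acquisition interval.
Two-channel junction intensities emulate a tandem fluorescent timer
(fast-maturing channel 1 / slow-maturing channel 2) whose stable fraction
can be coupled to the local shear on flow-parallel junctions, and T1 and
sliding (4-way to 3-way vertex) events can be injected with exact
ground-truth logs.  Flows are kinematically imposed, not emergent: there is
no mechanical energy minimisation here, by design.

Default study conditions: 15-min frame cadence starting at 24 hAPF,
~16 um^2 cells, 0.1 um pixels, flow speeds of order 0.1 um/min.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi

from . import io as wio
from ._angles import axial_deg, axial_diff, wrap_axial

__all__ = [
    "FlowSpec",
    "Mesh",
    "Scene",
    "generate_mesh",
    "advect_scene",
    "paint_channels",
    "inject_t1_events",
    "inject_sliding_events",
    "simulate_scene",
]


@dataclasses.dataclass
class FlowSpec:
    """Kinematic flow field, in image coordinates (um, minutes).

    kind: 'uniform' | 'linear_shear' | 'rigid_rotation' | 'composite'
    v0: uniform velocity (um/min)
    gamma: shear rate (1/min); with shear_axis='x' the field is
        v = (gamma * (y - y_ref), 0) — flow along x, gradient along y
    omega: angular velocity (1/min) about `center`
    time_scale: optional callable t_min -> multiplier (e.g. a ramp)
    members: member specs for 'composite'
    """

    kind: str = "uniform"
    v0: tuple = (0.1, 0.0)
    gamma: float = 0.01
    shear_axis: str = "x"
    omega: float = 0.005
    center: tuple | None = None
    ref: tuple | None = None
    time_scale: object = None
    members: tuple = ()

    def _scale(self, t_min):
        return 1.0 if self.time_scale is None else float(self.time_scale(t_min))

    def velocity(self, xy, t_min=0.0):
        xy = np.asarray(xy, float)
        s = self._scale(t_min)
        v = np.zeros_like(xy)
        if self.kind == "uniform":
            v[:, 0] = self.v0[0]
            v[:, 1] = self.v0[1]
        elif self.kind == "linear_shear":
            ref = self.ref if self.ref is not None else xy.mean(axis=0)
            if self.shear_axis == "x":
                v[:, 0] = self.gamma * (xy[:, 1] - ref[1])
            else:
                v[:, 1] = self.gamma * (xy[:, 0] - ref[0])
        elif self.kind == "rigid_rotation":
            c = self.center if self.center is not None else xy.mean(axis=0)
            dx = xy[:, 0] - c[0]
            dy = xy[:, 1] - c[1]
            v[:, 0] = -self.omega * dy
            v[:, 1] = self.omega * dx
        elif self.kind == "composite":
            for m in self.members:
                v += m.velocity(xy, t_min)
            return s * v
        else:
            raise ValueError(f"unknown flow kind {self.kind!r}")
        return s * v

    def true_offdiag_gradient(self, t_min=0.0):
        """Analytic |dv'_x/dy'| of the field in its own flow frame (1/min)."""
        s = abs(self._scale(t_min))
        if self.kind == "uniform":
            return 0.0
        if self.kind == "linear_shear":
            return s * abs(self.gamma)
        if self.kind == "rigid_rotation":
            return s * abs(self.omega)
        raise ValueError("no closed form for composite flows")

    def flow_axis_deg(self):
        """Imposed flow axis (axial, mathematical convention), if defined."""
        if self.kind == "uniform":
            return float(axial_deg(self.v0[0], self.v0[1]))
        if self.kind == "linear_shear":
            return 0.0 if self.shear_axis == "x" else 90.0
        return None


@dataclasses.dataclass
class Mesh:
    """Frozen-topology polygon mesh derived from a Voronoi diagram."""

    seeds: np.ndarray           # (n, 2) um, image coords
    cell_ids: np.ndarray        # (n,) tracked ids, 1-based
    interior: np.ndarray        # (n,) bool — cells exported to tables
    vertices: np.ndarray        # (m, 2) Voronoi vertex coordinates
    regions: list               # per cell: vertex index list (ordered) or None
    junction_list: list         # dicts: cell_a, cell_b, iv1, iv2, quartet
    vertex_cells: list          # per vertex: set of incident interior cell ids
    target_area_um2: float

    @property
    def n_interior(self):
        return int(self.interior.sum())


def _shoelace(poly):
    x, y = poly[:, 0], poly[:, 1]
    cross = x * np.roll(y, -1) - np.roll(x, -1) * y
    area = 0.5 * cross.sum()
    if area == 0:
        return 0.0, poly.mean(axis=0), 0.0
    cx = np.sum((x + np.roll(x, -1)) * cross) / (6.0 * area)
    cy = np.sum((y + np.roll(y, -1)) * cross) / (6.0 * area)
    return abs(area), np.array([cx, cy]), np.sign(area)


def generate_mesh(rows=12, cols=12, mean_area_um2=16.0, jitter=0.15, seed=0):
    """Perturbed hexagonal lattice -> Voronoi polygon mesh.

    rows, cols >= 4; jitter is the seed-point displacement as a fraction of
    the lattice spacing (uniform per axis).  With jitter 0 the mesh is a
    regular honeycomb (all interior vertex degrees 3).  The outermost ring
    of cells pads the tracked interior so every interior cell has a closed
    polygon; interior mean area lands within ~10% of the target.
    """
    if rows < 4 or cols < 4:
        raise ValueError("generate_mesh needs rows, cols >= 4")
    rng = np.random.default_rng(seed)
    s = float(np.sqrt(2.0 * mean_area_um2 / np.sqrt(3.0)))
    h = s * np.sqrt(3.0) / 2.0
    pts, rc = [], []
    for r in range(rows):
        for c in range(cols):
            pts.append([c * s + (r % 2) * s / 2.0, r * h])
            rc.append((r, c))
    pts = np.asarray(pts)
    if jitter > 0:
        pts = pts + rng.uniform(-jitter * s, jitter * s, size=pts.shape)
        if jitter >= 0.5:
            # displacements of half a spacing or more can collapse cells
            raise ValueError("jitter too large: cells may vanish")
    vor = Voronoi(pts)
    interior = np.zeros(len(pts), bool)
    regions = [None] * len(pts)
    for idx, (r, c) in enumerate(rc):
        reg = vor.regions[vor.point_region[idx]]
        if 1 <= r < rows - 1 and 1 <= c < cols - 1 and reg and -1 not in reg:
            interior[idx] = True
            regions[idx] = list(reg)
    cell_ids = np.arange(1, len(pts) + 1)

    vertex_cells = [set() for _ in range(len(vor.vertices))]
    junction_list = []
    for (p, q), (iv1, iv2) in zip(vor.ridge_points, vor.ridge_vertices):
        if iv1 == -1 or iv2 == -1:
            continue
        if not (interior[p] and interior[q]):
            continue
        a, b = sorted((int(cell_ids[p]), int(cell_ids[q])))
        junction_list.append({"cell_a": a, "cell_b": b, "iv1": int(iv1), "iv2": int(iv2)})
        vertex_cells[iv1].update((a, b))
        vertex_cells[iv2].update((a, b))
    # quartet partners for T1 injection: third cell at each endpoint vertex
    for j in junction_list:
        pair = {j["cell_a"], j["cell_b"]}
        others1 = vertex_cells[j["iv1"]] - pair
        others2 = vertex_cells[j["iv2"]] - pair
        j["quartet"] = (sorted(others1), sorted(others2))
    return Mesh(seeds=pts, cell_ids=cell_ids, interior=interior,
                vertices=vor.vertices.copy(), regions=regions,
                junction_list=junction_list, vertex_cells=vertex_cells,
                target_area_um2=mean_area_um2)


@dataclasses.dataclass
class Scene:
    """A generated movie: tracked tables plus exported ground truth."""

    meta: wio.AcquisitionMeta
    flow: FlowSpec
    mesh: Mesh
    n_frames: int
    cells: pd.DataFrame
    adjacency: pd.DataFrame
    junctions: pd.DataFrame
    ground_truth: dict
    vertex_frames: np.ndarray   # (T, m, 2) advected vertex coordinates

    def write(self, outdir):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        wio.write_tables(self.cells, self.adjacency, self.junctions, outdir)
        truth = {k: v for k, v in self.ground_truth.items()}
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, default=_json_default)

    def rasterize(self, frame=0, pad_px=2):
        """Label mask + channel images for one frame (small fixtures only).

        Pixels take the label of the polygon containing them; pixels whose
        right or down neighbour belongs to a different cell become the 1-px
        membrane skeleton (label 0).  Channel images paint each junction's
        mean intensity on its chord.
        """
        from skimage.draw import line as sk_line
        from skimage.draw import polygon as sk_polygon

        px = self.meta.pixel_size_um
        verts = self.vertex_frames[frame]
        all_xy = verts[np.concatenate([r for r in self.mesh.regions if r])]
        origin = all_xy.min(axis=0) - pad_px * px
        shape_xy = np.ceil((all_xy.max(axis=0) - origin) / px).astype(int) + 2 * pad_px
        H, W = int(shape_xy[1]), int(shape_xy[0])
        labels = np.zeros((H, W), np.uint16)
        for idx in np.nonzero(self.mesh.interior)[0]:
            poly = (verts[self.mesh.regions[idx]] - origin) / px
            rr, cc = sk_polygon(poly[:, 1], poly[:, 0], shape=(H, W))
            labels[rr, cc] = self.mesh.cell_ids[idx]
        skel = np.zeros_like(labels, bool)
        skel[:, :-1] |= (labels[:, :-1] != labels[:, 1:]) & (labels[:, :-1] > 0) & (labels[:, 1:] > 0)
        skel[:-1, :] |= (labels[:-1, :] != labels[1:, :]) & (labels[:-1, :] > 0) & (labels[1:, :] > 0)
        labels[skel] = 0
        ch1 = np.zeros((H, W))
        ch2 = np.zeros((H, W))
        jt = self.junctions[self.junctions["frame"] == frame]
        for _, row in jt.iterrows():
            p1 = ((np.array([row["v1x_um"], row["v1y_um"]]) - origin) / px).astype(int)
            p2 = ((np.array([row["v2x_um"], row["v2y_um"]]) - origin) / px).astype(int)
            p1 = np.clip(p1, 0, [W - 1, H - 1])
            p2 = np.clip(p2, 0, [W - 1, H - 1])
            rr, cc = sk_line(p1[1], p1[0], p2[1], p2[0])
            if np.isfinite(row["mean_ch1"]):
                ch1[rr, cc] = row["mean_ch1"]
            if np.isfinite(row["mean_ch2"]):
                ch2[rr, cc] = row["mean_ch2"]
        return labels, ch1, ch2


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def advect_scene(mesh, flow, n_frames=9, meta=None, track_jitter_um=0.0, seed=0):
    """Advect the mesh and build tracked tables (perfect tracking).

    Vertices move with per-frame Euler steps at the acquisition interval;
    labels persist.  track_jitter_um adds Gaussian measurement noise to the
    reported centroids only (the geometry is untouched).  Raises if any
    polygon inverts (mesh inversion under too-stiff a flow).
    """
    if meta is None:
        meta = wio.AcquisitionMeta()
    rng = np.random.default_rng(seed)
    dt = meta.frame_interval_min
    verts = mesh.vertices.copy()
    frames = [verts.copy()]
    for t in range(1, n_frames):
        verts = verts + flow.velocity(verts, (t - 1) * dt) * dt
        frames.append(verts.copy())
    vertex_frames = np.stack(frames)

    interior_idx = np.nonzero(mesh.interior)[0]
    ref_sign = {}
    cell_rows = []
    for t in range(n_frames):
        vt = vertex_frames[t]
        time_hapf = meta.frame_time_hapf(t)
        for idx in interior_idx:
            poly = vt[mesh.regions[idx]]
            area, cen, sign = _shoelace(poly)
            if idx in ref_sign and sign != ref_sign[idx]:
                raise ValueError("mesh inversion: flow too stiff for Euler advection")
            ref_sign.setdefault(idx, sign)
            jit = rng.normal(0.0, track_jitter_um, 2) if track_jitter_um > 0 else (0.0, 0.0)
            cell_rows.append({
                "frame": t, "time_hapf": time_hapf,
                "cell_id": int(mesh.cell_ids[idx]),
                "x_um": cen[0] + jit[0], "y_um": cen[1] + jit[1],
                "area_um2": area,
            })
    cells = pd.DataFrame(cell_rows)

    adj_rows = [
        {"frame": t, "cell_a": j["cell_a"], "cell_b": j["cell_b"]}
        for t in range(n_frames) for j in mesh.junction_list
    ]
    adjacency = pd.DataFrame(adj_rows)

    jrows = []
    for t in range(n_frames):
        vt = vertex_frames[t]
        for jid, j in enumerate(mesh.junction_list):
            v1, v2 = vt[j["iv1"]], vt[j["iv2"]]
            jrows.append({
                "frame": t, "junction_id": jid,
                "cell_a": j["cell_a"], "cell_b": j["cell_b"],
                "v1x_um": v1[0], "v1y_um": v1[1],
                "v2x_um": v2[0], "v2y_um": v2[1],
                "length_um": float(np.hypot(*(v2 - v1))),
                "angle_deg": float(axial_deg(v2[0] - v1[0], v2[1] - v1[1])),
                "mean_ch1": np.nan, "mean_ch2": np.nan,
                "sum_ch1": np.nan, "sum_ch2": np.nan,
                "deg_v1": 3, "deg_v2": 3,
            })
    junctions = pd.DataFrame(jrows, columns=wio.JUNCTIONS_COLUMNS + wio.JUNCTIONS_EXTRA_COLUMNS)

    truth = {
        "flow_kind": flow.kind,
        "flow_axis_deg": flow.flow_axis_deg(),
        "true_offdiag_gradient_per_min": (
            flow.true_offdiag_gradient() if flow.kind != "composite" else None
        ),
        "n_frames": n_frames,
        "n_cells": mesh.n_interior,
        "track_jitter_um": track_jitter_um,
        "t1_events": [],
        "sliding_events": [],
    }
    return Scene(meta=meta, flow=flow, mesh=mesh, n_frames=n_frames,
                 cells=cells, adjacency=adjacency, junctions=junctions,
                 ground_truth=truth, vertex_frames=vertex_frames)


def inject_t1_events(scene, n_events, seed=0, min_frame=1, tail_frames=1,
                     growth_um_per_min=0.02):
    """Inject neighbour exchanges: edge A-B is lost and edge C-D gained.

    Candidate junctions need both quartet partners (the third cells at each
    endpoint vertex) to be distinct interior cells not already adjacent;
    each cell participates in at most one event.  The gained junction grows
    orthogonally to the lost one from the old midpoint and persists to the
    end of the movie (no reversion).  Exact ground truth is logged.
    """
    rng = np.random.default_rng(seed)
    mesh = scene.mesh
    adjacency_pairs = {(j["cell_a"], j["cell_b"]) for j in mesh.junction_list}
    interior_ids = set(mesh.cell_ids[mesh.interior].tolist())
    used = set()
    candidates = []
    for jid, j in enumerate(mesh.junction_list):
        o1, o2 = j["quartet"]
        if len(o1) != 1 or len(o2) != 1:
            continue
        c, d = o1[0], o2[0]
        if c == d or c not in interior_ids or d not in interior_ids:
            continue
        if tuple(sorted((c, d))) in adjacency_pairs:
            continue
        candidates.append((jid, j["cell_a"], j["cell_b"], c, d))
    rng.shuffle(candidates)
    last = scene.n_frames - 1 - tail_frames
    if last < min_frame:
        raise ValueError("movie too short to schedule T1 events")
    scheduled = []
    new_pairs = set()
    for jid, a, b, c, d in candidates:
        if len(scheduled) >= n_events:
            break
        quartet = {a, b, c, d}
        if quartet & used:
            continue
        cd = tuple(sorted((c, d)))
        if cd in new_pairs:
            continue
        used |= quartet
        new_pairs.add(cd)
        f = int(rng.integers(min_frame, last + 1))
        scheduled.append((jid, a, b, cd[0], cd[1], f))
    if len(scheduled) < n_events:
        raise ValueError(
            f"only {len(scheduled)} feasible T1 sites for {n_events} requested"
        )

    adj = scene.adjacency
    jt = scene.junctions
    next_jid = int(jt["junction_id"].max()) + 1
    drop_adj, drop_jun = [], []
    add_adj, add_jun = [], []
    dt = scene.meta.frame_interval_min
    for jid, a, b, c, d, f in scheduled:
        drop_adj.append((a, b, f))
        drop_jun.append((a, b, f))
        old = jt[(jt["cell_a"] == a) & (jt["cell_b"] == b) & (jt["frame"] == f)]
        row0 = old.iloc[0]
        mid = np.array([(row0["v1x_um"] + row0["v2x_um"]) / 2,
                        (row0["v1y_um"] + row0["v2y_um"]) / 2])
        direc = np.array([row0["v2x_um"] - row0["v1x_um"],
                          row0["v2y_um"] - row0["v1y_um"]])
        direc = direc / max(np.hypot(*direc), 1e-12)
        ortho = np.array([-direc[1], direc[0]])
        for t in range(f, scene.n_frames):
            add_adj.append({"frame": t, "cell_a": c, "cell_b": d})
            length = growth_um_per_min * dt * (t - f + 1)
            v1 = mid - ortho * length / 2
            v2 = mid + ortho * length / 2
            add_jun.append({
                "frame": t, "junction_id": next_jid,
                "cell_a": c, "cell_b": d,
                "v1x_um": v1[0], "v1y_um": v1[1],
                "v2x_um": v2[0], "v2y_um": v2[1],
                "length_um": float(length),
                "angle_deg": float(axial_deg(*ortho)),
                "mean_ch1": np.nan, "mean_ch2": np.nan,
                "sum_ch1": np.nan, "sum_ch2": np.nan,
                "deg_v1": 3, "deg_v2": 3,
            })
        scene.ground_truth["t1_events"].append({
            "cell_a": a, "cell_b": b, "cell_c": c, "cell_d": d,
            "frame_lost": f, "frame_gained": f, "new_junction_id": next_jid,
        })
        next_jid += 1

    mask_adj = np.ones(len(adj), bool)
    for a, b, f in drop_adj:
        mask_adj &= ~((adj["cell_a"] == a) & (adj["cell_b"] == b) & (adj["frame"] >= f))
    mask_jun = np.ones(len(jt), bool)
    for a, b, f in drop_jun:
        mask_jun &= ~((jt["cell_a"] == a) & (jt["cell_b"] == b) & (jt["frame"] >= f))
    scene.adjacency = pd.concat(
        [adj[mask_adj], pd.DataFrame(add_adj)], ignore_index=True
    ).sort_values(["frame", "cell_a", "cell_b"]).reset_index(drop=True)
    scene.junctions = pd.concat(
        [jt[mask_jun], pd.DataFrame(add_jun)], ignore_index=True
    ).sort_values(["frame", "junction_id"]).reset_index(drop=True)
    return scene


def inject_sliding_events(scene, n_events, seed=0, effect_pct=-24.0,
                          prefer_horizontal=True):
    """Inject sliding junctions: a 4-way -> 3-way vertex transition.

    For each selected junction a transition frame f is drawn; deg_v1 is 4
    on frames before f and 3 from f on.  The slow-maturing channel of the
    junction is multiplied by (1 + effect_pct/100) from frame f when the
    channels are painted (logged as ground truth).
    """
    rng = np.random.default_rng(seed)
    jt = scene.junctions
    t1_cells = set()
    for ev in scene.ground_truth["t1_events"]:
        t1_cells |= {ev["cell_a"], ev["cell_b"], ev["cell_c"], ev["cell_d"]}
    axis = scene.flow.flow_axis_deg()
    pairs = []
    frame0 = jt[jt["frame"] == 0]
    for _, row in frame0.iterrows():
        if row["cell_a"] in t1_cells or row["cell_b"] in t1_cells:
            continue
        if prefer_horizontal and axis is not None:
            if abs(axial_diff(row["angle_deg"], axis)) >= 45.0:
                continue
        pairs.append((int(row["cell_a"]), int(row["cell_b"])))
    rng.shuffle(pairs)
    if len(pairs) < n_events:
        raise ValueError(f"only {len(pairs)} candidate junctions for {n_events} events")
    if scene.n_frames < 2:
        raise ValueError("movie too short for sliding events")
    for pair in pairs[:n_events]:
        f = int(rng.integers(1, scene.n_frames))
        sel = (jt["cell_a"] == pair[0]) & (jt["cell_b"] == pair[1])
        jt.loc[sel & (jt["frame"] < f), "deg_v1"] = 4
        scene.ground_truth["sliding_events"].append({
            "cell_a": pair[0], "cell_b": pair[1],
            "frame_pre": f - 1, "frame_post": f,
            "effect_pct": effect_pct,
        })
    return scene


def paint_channels(scene, base=100.0, polarity_magnitude=0.0,
                   polarity_angle_deg=0.0, stable_fraction=0.5, gain=1.0,
                   beta=0.0, noise_sigma=0.0, control_drift_pct=0.0, seed=0):
    """Paint two-channel junction intensities with exported ground truth.

    Channel 1 (fast-maturing) carries the polarity pattern.  The polarity
    axis convention follows the tissue: a polarity axis phi_pol means the
    protein is enriched on junctions oriented perpendicular to phi_pol (PD
    polarity = bright vertical junctions), so
    I1 = base * (1 - m cos 2(phi_j - phi_pol)) + noise,
    which a centroid-to-boundary polarity estimator recovers at axis
    phi_pol.
    Channel 2 (slow-maturing) is s_j * gain * I1_signal + noise, where the
    per-junction stable fraction s_j = stable_fraction is reduced by
    beta * |local off-diagonal velocity gradient| on flow-parallel
    (horizontal) junctions, clamped at 0.  Sliding events multiply channel 2
    by (1 + effect_pct/100) from their post frame; control_drift_pct is a
    per-interval multiplicative drift of channel 2 on all junctions
    (compounding), emulating background maturation of the timer.
    Negative draws are clipped at 0 and counted in the ground truth.
    """
    rng = np.random.default_rng(seed)
    jt = scene.junctions
    meta = scene.meta
    axis = scene.flow.flow_axis_deg()
    sliding = {
        (ev["cell_a"], ev["cell_b"]): ev
        for ev in scene.ground_truth["sliding_events"]
    }
    n_clipped = 0
    mean1 = np.empty(len(jt))
    mean2 = np.empty(len(jt))
    npx = np.empty(len(jt))
    for i, row in enumerate(jt.itertuples(index=False)):
        t_min = row.frame * meta.frame_interval_min
        phi = row.angle_deg
        sig1 = base * (1.0 - polarity_magnitude
                       * np.cos(2.0 * np.radians(phi - polarity_angle_deg)))
        s_j = stable_fraction
        if beta != 0.0 and axis is not None:
            if abs(axial_diff(phi, axis)) < 45.0:
                g_loc = scene.flow.true_offdiag_gradient(t_min)
                s_j = max(0.0, s_j - beta * g_loc)
        sig2 = s_j * gain * sig1
        ev = sliding.get((row.cell_a, row.cell_b))
        if ev is not None and row.frame >= ev["frame_post"]:
            sig2 *= 1.0 + ev["effect_pct"] / 100.0
        if control_drift_pct:
            sig2 *= (1.0 + control_drift_pct / 100.0) ** row.frame
        m1 = sig1 + (rng.normal(0.0, noise_sigma * base) if noise_sigma > 0 else 0.0)
        m2 = sig2 + (rng.normal(0.0, noise_sigma * base) if noise_sigma > 0 else 0.0)
        if m1 < 0 or m2 < 0:
            n_clipped += 1
        mean1[i] = max(m1, 0.0)
        mean2[i] = max(m2, 0.0)
        npx[i] = max(1, round(row.length_um / meta.pixel_size_um))
    jt["mean_ch1"] = mean1
    jt["mean_ch2"] = mean2
    jt["sum_ch1"] = mean1 * npx
    jt["sum_ch2"] = mean2 * npx
    scene.ground_truth.update({
        "paint": {
            "base": base,
            "polarity_magnitude": polarity_magnitude,
            "polarity_angle_deg": float(wrap_axial(polarity_angle_deg)),
            "stable_fraction": stable_fraction,
            "gain": gain,
            "beta": beta,
            "noise_sigma": noise_sigma,
            "control_drift_pct": control_drift_pct,
            "n_clipped": n_clipped,
        }
    })
    return scene


_PRESETS = {
    "uniform": dict(kind="uniform", v0=(0.1, 0.0)),
    "shear": dict(kind="linear_shear", gamma=0.01),
    "rotation": dict(kind="rigid_rotation", omega=0.005),
    # fig4-like: PD flow with an AP gradient plus timer coupling
    "fig4-like": dict(kind="linear_shear", gamma=0.01),
    # fig6-like: rotational flow (the early-stage control condition)
    "fig6-like": dict(kind="rigid_rotation", omega=0.005),
}


def simulate_scene(preset="shear", rows=12, cols=12, mean_area_um2=16.0,
                   jitter=0.15, n_frames=9, seed=0, gamma=None, omega=None,
                   v0=None, beta=0.0, noise_sigma=0.0, track_jitter_um=0.0,
                   polarity_magnitude=0.4, polarity_angle_deg=0.0,
                   stable_fraction=0.5, n_t1=0, n_sliding=0,
                   sliding_effect_pct=-24.0, control_drift_pct=0.0, meta=None):
    """One-call scene builder used by the CLI and the test fixtures."""
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}")
    spec = dict(_PRESETS[preset])
    if gamma is not None:
        spec["gamma"] = gamma
    if omega is not None:
        spec["omega"] = omega
    if v0 is not None:
        spec["v0"] = tuple(v0)
    flow = FlowSpec(**spec)
    rng = np.random.default_rng(seed)
    mesh = generate_mesh(rows=rows, cols=cols, mean_area_um2=mean_area_um2,
                         jitter=jitter, seed=int(rng.integers(2**31)))
    scene = advect_scene(mesh, flow, n_frames=n_frames, meta=meta,
                         track_jitter_um=track_jitter_um,
                         seed=int(rng.integers(2**31)))
    if n_t1:
        inject_t1_events(scene, n_t1, seed=int(rng.integers(2**31)))
    if n_sliding:
        inject_sliding_events(scene, n_sliding, seed=int(rng.integers(2**31)),
                              effect_pct=sliding_effect_pct)
    paint_channels(scene, polarity_magnitude=polarity_magnitude,
                   polarity_angle_deg=polarity_angle_deg,
                   stable_fraction=stable_fraction, beta=beta,
                   noise_sigma=noise_sigma,
                   control_drift_pct=control_drift_pct,
                   seed=int(rng.integers(2**31)))
    scene.ground_truth["preset"] = preset
    scene.ground_truth["seed"] = seed
    return scene
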