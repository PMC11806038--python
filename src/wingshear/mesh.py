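"""Cells, junctions and topological events from segmented label stacks.

The segmentation convention is a skeletonised one: label 0 is a one-pixel
membrane skeleton separating cell regions, positive labels are tracked cell
identities.  Skeleton adjacency uses 8-connectivity and cell regions
4-connectivity, the standard choice for one-pixel skeletons (prevents
diagonal leaks).  Junction pixels touch exactly two cells; pixels touching
three or more cells are vertices.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy import ndimage

from ._angles import axial_deg

__all__ = [
    "extract_cells",
    "extract_junctions",
    "detect_t1_events",
    "detect_sliding_junctions",
    "T1_COLUMNS",
    "SLIDING_COLUMNS",
]

T1_COLUMNS = [
    "event_id", "cell_a", "cell_b", "cell_c", "cell_d",
    "frame_lost", "frame_gained", "ambiguous",
]
SLIDING_COLUMNS = [
    "event_id", "junction_id", "cell_a", "cell_b",
    "frame_pre", "frame_post", "vertex", "both_vertices",
]

_SHIFTS8 = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]


def _neighbor_labels(frame):
    """For every skeleton (zero) pixel return the padded 8-neighbourhood labels.

    Returns (rows, cols, nbrs) where nbrs is an (n, 8) int array of the labels
    around each skeleton pixel (0 entries are skeleton/outside).
    """
    padded = np.pad(frame, 1, mode="constant", constant_values=0)
    rows, cols = np.nonzero(frame == 0)
    nbrs = np.empty((rows.size, 8), dtype=frame.dtype)
    for k, (di, dj) in enumerate(_SHIFTS8):
        nbrs[:, k] = padded[rows + 1 + di, cols + 1 + dj]
    return rows, cols, nbrs


def _distinct_pos(nbrs):
    """Row-wise sorted distinct positive labels (as a list of small arrays)."""
    out = []
    for row in nbrs:
        pos = row[row > 0]
        out.append(np.unique(pos))
    return out


def extract_cells(stack):
    """Per-frame cell records and tracked adjacency from a label stack.

    Returns (cells, adjacency) DataFrames in the fixed CSV schemas.  Centroids
    are means of member pixel centres scaled by pixel size; area is the pixel
    count times pixel_size**2; two cells are neighbours when they share a
    skeleton pixel within its 8-neighbourhood.
    """
    px = stack.meta.pixel_size_um
    cell_rows, adj_rows = [], []
    for t in range(stack.n_frames):
        frame = stack.frames[t]
        labels = np.unique(frame)
        labels = labels[labels > 0]
        if labels.size:
            count = np.bincount(frame.ravel())
            ii, jj = np.indices(frame.shape)
            sum_i = np.bincount(frame.ravel(), weights=ii.ravel())
            sum_j = np.bincount(frame.ravel(), weights=jj.ravel())
            time_hapf = stack.meta.frame_time_hapf(t)
            for lab in labels:
                n = count[lab]
                cell_rows.append({
                    "frame": t,
                    "time_hapf": time_hapf,
                    "cell_id": int(lab),
                    "x_um": sum_j[lab] / n * px,
                    "y_um": sum_i[lab] / n * px,
                    "area_um2": n * px * px,
                })
            _, _, nbrs = _neighbor_labels(frame)
            pairs = set()
            for distinct in _distinct_pos(nbrs):
                if distinct.size >= 2:
                    for a, b in itertools.combinations(distinct.tolist(), 2):
                        pairs.add((a, b))
            for a, b in sorted(pairs):
                adj_rows.append({"frame": t, "cell_a": a, "cell_b": b})
    cells = pd.DataFrame(
        cell_rows, columns=["frame", "time_hapf", "cell_id", "x_um", "y_um", "area_um2"]
    )
    adjacency = pd.DataFrame(adj_rows, columns=["frame", "cell_a", "cell_b"])
    return cells, adjacency


@dataclasses.dataclass
class _Vertex:
    pixels: np.ndarray          # (n, 2) row/col skeleton pixels of the cluster
    labels: frozenset           # distinct adjacent cell labels
    center: np.ndarray          # (2,) mean pixel position

    @property
    def degree(self):
        return len(self.labels)


def _find_vertices(frame):
    """Cluster vertex pixels (skeleton pixels touching >= 3 cells).

    Near-coincident vertex pixels (8-connected clusters) are merged into a
    single vertex; the degree is the number of distinct labels adjacent to
    the whole cluster, so a four-fold vertex split over two pixels still
    reports degree 4.
    """
    rows, cols, nbrs = _neighbor_labels(frame)
    distinct = _distinct_pos(nbrs)
    is_vertex = np.array([d.size >= 3 for d in distinct])
    vmask = np.zeros(frame.shape, bool)
    vmask[rows[is_vertex], cols[is_vertex]] = True
    lab, n = ndimage.label(vmask, structure=np.ones((3, 3), int))
    by_pixel = {(r, c): d for r, c, d in zip(rows, cols, distinct)}
    vertices = []
    for k in range(1, n + 1):
        pix = np.argwhere(lab == k)
        labs = set()
        for r, c in pix:
            labs.update(by_pixel[(r, c)].tolist())
        vertices.append(_Vertex(pix, frozenset(labs), pix.mean(axis=0)))
    return vertices


def extract_junctions(stack, channels=None):
    """Junction records from a label stack, with per-channel band intensities.

    channels: optional dict {'ch1': (T,H,W) array, 'ch2': ...} co-registered
    with the labels.  Intensities are measured on the junction skeleton
    dilated to a 3-pixel-wide band.  Junction endpoints are the two adjacent
    vertices (or the two most separated junction pixels when a junction runs
    off the field of view); the angle is the axial angle of the endpoint
    chord.
    """
    channels = channels or {}
    for name, arr in channels.items():
        if np.asarray(arr).shape != stack.frames.shape:
            raise ValueError(
                f"channel {name!r} shape {np.asarray(arr).shape} does not match "
                f"labels {stack.frames.shape}"
            )
    px = stack.meta.pixel_size_um
    rows_out = []
    jid = 0
    for t in range(stack.n_frames):
        frame = stack.frames[t]
        rows, cols, nbrs = _neighbor_labels(frame)
        distinct = _distinct_pos(nbrs)
        vertices = _find_vertices(frame)
        pair_pixels = {}
        for r, c, d in zip(rows, cols, distinct):
            if d.size == 2:
                pair_pixels.setdefault((int(d[0]), int(d[1])), []).append((r, c))
        H, W = frame.shape
        for (a, b), pix in sorted(pair_pixels.items()):
            pix = np.asarray(pix, float)
            # candidate endpoints: the junction's own pixels plus any vertex
            # cluster centres within 2 px of the pixel set; the endpoints are
            # the two mutually farthest candidates
            cand = [pix]
            for v in vertices:
                if np.min(np.abs(v.pixels[:, None, :] - pix[None, :, :]).max(axis=2)) <= 2:
                    cand.append(v.center[None, :])
            cand = np.concatenate(cand, axis=0)
            dist = np.sum((cand[:, None, :] - cand[None, :, :]) ** 2, axis=2)
            i1, i2 = np.unravel_index(np.argmax(dist), dist.shape)
            p1, p2 = cand[i1], cand[i2]
            if (p1[0], p1[1]) > (p2[0], p2[1]):
                p1, p2 = p2, p1

            def _degree(p):
                # vertex degree from the labels within a 2-px radius
                r, c = int(round(p[0])), int(round(p[1]))
                win = frame[max(r - 2, 0):r + 3, max(c - 2, 0):c + 3]
                return max(2, int(np.unique(win[win > 0]).size))

            d1, d2 = _degree(p1), _degree(p2)
            band = np.zeros(frame.shape, bool)
            band[pix[:, 0].astype(int), pix[:, 1].astype(int)] = True
            band = ndimage.binary_dilation(band, structure=np.ones((3, 3), bool))
            v1 = np.array([p1[1], p1[0]]) * px  # (x, y) um
            v2 = np.array([p2[1], p2[0]]) * px
            rec = {
                "frame": t,
                "junction_id": jid,
                "cell_a": a,
                "cell_b": b,
                "v1x_um": v1[0], "v1y_um": v1[1],
                "v2x_um": v2[0], "v2y_um": v2[1],
                "length_um": float(np.hypot(*(v2 - v1))),
                "angle_deg": float(axial_deg(v2[0] - v1[0], v2[1] - v1[1])),
                "deg_v1": d1,
                "deg_v2": d2,
            }
            for idx, name in enumerate(["ch1", "ch2"], start=1):
                if name in channels:
                    vals = np.asarray(channels[name])[t][band]
                    rec[f"mean_ch{idx}"] = float(vals.mean())
                    rec[f"sum_ch{idx}"] = float(vals.sum())
                else:
                    rec[f"mean_ch{idx}"] = np.nan
                    rec[f"sum_ch{idx}"] = np.nan
            rows_out.append(rec)
            jid += 1
    cols_order = [
        "frame", "junction_id", "cell_a", "cell_b",
        "v1x_um", "v1y_um", "v2x_um", "v2y_um", "length_um", "angle_deg",
        "mean_ch1", "mean_ch2", "sum_ch1", "sum_ch2", "deg_v1", "deg_v2",
    ]
    return pd.DataFrame(rows_out, columns=cols_order)


def _edges_by_frame(adjacency):
    frames = sorted(adjacency["frame"].unique().tolist())
    out = {}
    for t in frames:
        sub = adjacency[adjacency["frame"] == t]
        out[t] = set(zip(sub["cell_a"].astype(int), sub["cell_b"].astype(int)))
    return frames, out


def detect_t1_events(adjacency, persistence_horizon=4, max_gap=2):
    """Neighbour-exchange (T1) events from tracked adjacency.

    An event is a lost edge A-B followed (within max_gap frames) by a gained
    edge C-D where A, B, C, D are the four cells around the exchange (each of
    C, D was adjacent to both A and B before the exchange).  The gained edge
    must persist to the end of the observation or for at least
    `persistence_horizon` frames without reverting; exchanges that revert are
    excluded.  Ambiguous multi-cell rosettes are reported with ambiguous=True.
    """
    if adjacency["frame"].nunique() < 2:
        raise ValueError("detect_t1_events needs tracked adjacency for >= 2 frames")
    frames, edges = _edges_by_frame(adjacency)
    last = frames[-1]
    events = []
    eid = 0
    for idx in range(1, len(frames)):
        t_prev, t = frames[idx - 1], frames[idx]
        gained = edges[t] - edges[t_prev]
        for (c, d) in sorted(gained):
            # persistence: present until the end or for >= horizon frames
            future = [u for u in frames if u >= t]
            horizon_frames = future[: persistence_horizon]
            if not all((c, d) in edges[u] for u in horizon_frames):
                continue
            # a "gained" edge that existed shortly before is a reversion of
            # an earlier exchange, not a new junction
            recent_past = [u for u in frames if u < t][-persistence_horizon:]
            if any((c, d) in edges[u] for u in recent_past):
                continue
            # find the lost edge among recent frames
            cand = []
            for back in range(idx - 1, max(-1, idx - 1 - max_gap), -1):
                tb, tb_next = frames[back], frames[back + 1]
                lost_here = edges[tb] - edges[tb_next]
                for (a, b) in sorted(lost_here):
                    if {a, b} & {c, d}:
                        continue
                    before = edges[tb]
                    quartet_ok = all(
                        (min(x, y), max(x, y)) in before
                        for x, y in [(a, c), (a, d), (b, c), (b, d)]
                    )
                    if quartet_ok:
                        cand.append((a, b, tb_next))
                if cand:
                    break
            if not cand:
                continue
            a, b, frame_lost = cand[0]
            # reversion check: A-B must not reappear within the horizon
            if any((a, b) in edges[u] for u in horizon_frames):
                continue
            events.append({
                "event_id": eid,
                "cell_a": a, "cell_b": b, "cell_c": c, "cell_d": d,
                "frame_lost": frame_lost, "frame_gained": t,
                "ambiguous": len(cand) > 1,
            })
            eid += 1
    return pd.DataFrame(events, columns=T1_COLUMNS)


def detect_sliding_junctions(junctions):
    """Sliding junctions: a 4-way -> 3-way vertex-degree transition.

    Junction identity across frames is the tracked cell pair.  An event is
    flagged whenever deg_v1 or deg_v2 drops from 4 to 3 between consecutive
    analysis frames.  Junctions with no transition over the observation are
    the eligible control junctions (returned separately).
    Returns (events, control_pairs).
    """
    if "deg_v1" not in junctions.columns:
        raise ValueError("junctions table lacks vertex degrees (deg_v1/deg_v2)")
    events = []
    eid = 0
    flagged = set()
    for (a, b), grp in junctions.groupby(["cell_a", "cell_b"]):
        grp = grp.sort_values("frame")
        fr = grp["frame"].to_numpy()
        d1 = grp["deg_v1"].to_numpy()
        d2 = grp["deg_v2"].to_numpy()
        for i in range(1, len(grp)):
            v1_drop = d1[i - 1] == 4 and d1[i] == 3
            v2_drop = d2[i - 1] == 4 and d2[i] == 3
            if v1_drop or v2_drop:
                events.append({
                    "event_id": eid,
                    "junction_id": int(grp["junction_id"].iloc[i]),
                    "cell_a": int(a), "cell_b": int(b),
                    "frame_pre": int(fr[i - 1]), "frame_post": int(fr[i]),
                    "vertex": "v1" if v1_drop else "v2",
                    "both_vertices": bool(v1_drop and v2_drop),
                })
                eid += 1
                flagged.add((int(a), int(b)))
    all_pairs = set(
        zip(junctions["cell_a"].astype(int), junctions["cell_b"].astype(int))
    )
    controls = sorted(all_pairs - flagged)
    return pd.DataFrame(events, columns=SLIDING_COLUMNS), controls
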