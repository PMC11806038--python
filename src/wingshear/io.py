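"""On-disk representations: label-mask stacks, tracked tables and configs.

Schemas are fixed.  cells.csv / adjacency.csv / junctions.csv round-trip
losslessly at >= 9 significant digits; labels.tif is a multi-page unsigned
integer TIFF where label 0 is the one-pixel membrane skeleton between cells
and a positive label denotes the same tracked cell in every frame.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("wingshear")

CELLS_COLUMNS = ["frame", "time_hapf", "cell_id", "x_um", "y_um", "area_um2"]
ADJACENCY_COLUMNS = ["frame", "cell_a", "cell_b"]
JUNCTIONS_COLUMNS = [
    "frame", "junction_id", "cell_a", "cell_b",
    "v1x_um", "v1y_um", "v2x_um", "v2y_um",
    "length_um", "angle_deg",
    "mean_ch1", "mean_ch2", "sum_ch1", "sum_ch2",
]
# Trailing extras beyond the core schema: per-frame vertex degrees, needed to
# round-trip sliding-junction (4-way -> 3-way) detection through CSV.
JUNCTIONS_EXTRA_COLUMNS = ["deg_v1", "deg_v2"]

_FLOAT_FMT = "%.10g"


@dataclasses.dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition metadata shared by every frame of a movie.

    pixel_size_um: physical size of one pixel (0.08-0.14 um in the source data)
    frame_interval_min: time between frames (15 min cadence)
    t0_hapf: developmental time of frame 0, hours After Pupa Formation
    axis_mode: 'PD' or 'AP' — which anatomical axis the flow frame refers to
    """

    pixel_size_um: float = 0.1
    frame_interval_min: float = 15.0
    t0_hapf: float = 24.0
    axis_mode: str = "PD"

    def __post_init__(self):
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if not self.frame_interval_min > 0:
            raise ValueError(
                f"frame_interval_min must be > 0, got {self.frame_interval_min}"
            )
        if self.axis_mode not in ("PD", "AP"):
            raise ValueError(f"axis_mode must be 'PD' or 'AP', got {self.axis_mode!r}")

    def frame_time_hapf(self, frame):
        return self.t0_hapf + np.asarray(frame, float) * self.frame_interval_min / 60.0


@dataclasses.dataclass
class LabelStack:
    """Ordered 2-D integer label frames plus acquisition metadata."""

    frames: np.ndarray  # (T, H, W) non-negative integers
    meta: AcquisitionMeta

    def __post_init__(self):
        frames = np.asarray(self.frames)
        if frames.ndim == 2:
            frames = frames[None]
        if frames.ndim != 3:
            raise ValueError(f"expected 2-D or 3-D label array, got ndim={frames.ndim}")
        if not np.issubdtype(frames.dtype, np.integer):
            raise ValueError(f"non-integer labels (dtype {frames.dtype})")
        if frames.size and frames.min() < 0:
            raise ValueError("labels must be non-negative")
        self.frames = frames

    @property
    def n_frames(self):
        return self.frames.shape[0]

    @property
    def shape(self):
        return self.frames.shape[1:]

    def labels(self, frame=None):
        """Sorted positive labels present in one frame (or in the whole stack)."""
        arr = self.frames if frame is None else self.frames[frame]
        u = np.unique(arr)
        return u[u > 0]


def read_label_stack(path, meta):
    """Read a multi-page integer TIFF into a LabelStack.

    Rejects floating-point pixel types and inconsistent frame shapes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(str(path)) as tif:
        pages = [p.asarray() for p in tif.pages]
    if not pages:
        raise ValueError(f"{path}: empty TIFF")
    shapes = {p.shape for p in pages}
    if len(shapes) != 1:
        raise ValueError(f"{path}: inconsistent frame shapes {sorted(shapes)}")
    arr = np.stack(pages)
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"{path}: non-integer labels (dtype {arr.dtype})")
    return LabelStack(frames=arr, meta=meta)


def write_label_stack(path, stack):
    frames = stack.frames
    dtype = np.uint16 if frames.max(initial=0) < 2**16 else np.uint32
    tifffile.imwrite(str(path), frames.astype(dtype), photometric="minisblack")


def _check_columns(df, required, name):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{name}: missing columns {missing}")


def validate_tables(cells, adjacency=None, junctions=None):
    """Schema and referential-integrity checks shared by write and read."""
    _check_columns(cells, CELLS_COLUMNS, "cells")
    keys = cells[["frame", "cell_id"]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0]
        raise ValueError(
            f"cells: duplicate (frame, cell_id) key ({dup['frame']}, {dup['cell_id']})"
        )
    known = set(zip(cells["frame"].astype(int), cells["cell_id"].astype(int)))
    if adjacency is not None and len(adjacency):
        _check_columns(adjacency, ADJACENCY_COLUMNS, "adjacency")
        if (adjacency["cell_a"] >= adjacency["cell_b"]).any():
            raise ValueError("adjacency: requires cell_a < cell_b")
        for col in ("cell_a", "cell_b"):
            pairs = set(zip(adjacency["frame"].astype(int), adjacency[col].astype(int)))
            unknown = pairs - known
            if unknown:
                raise ValueError(f"adjacency: unknown cell reference {sorted(unknown)[0]}")
    if junctions is not None and len(junctions):
        _check_columns(junctions, JUNCTIONS_COLUMNS, "junctions")


def write_tables(cells, adjacency, junctions, outdir):
    """Write cells.csv, adjacency.csv and junctions.csv with fixed schemas."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    validate_tables(cells, adjacency, junctions)
    cells[CELLS_COLUMNS].to_csv(outdir / "cells.csv", index=False, float_format=_FLOAT_FMT)
    adjacency[ADJACENCY_COLUMNS].to_csv(
        outdir / "adjacency.csv", index=False, float_format=_FLOAT_FMT
    )
    jcols = JUNCTIONS_COLUMNS + [
        c for c in JUNCTIONS_EXTRA_COLUMNS if c in junctions.columns
    ]
    junctions[jcols].to_csv(outdir / "junctions.csv", index=False, float_format=_FLOAT_FMT)


def read_tables(indir):
    """Read the three CSV tables back; returns (cells, adjacency, junctions)."""
    indir = Path(indir)
    cells = pd.read_csv(indir / "cells.csv")
    adjacency = pd.read_csv(indir / "adjacency.csv")
    junctions = pd.read_csv(indir / "junctions.csv")
    validate_tables(cells, adjacency, junctions)
    return cells, adjacency, junctions


_CONFIG_DEFAULTS = {
    "pixel_size_um": 0.1,
    "frame_interval_min": 15.0,
    "t0_hapf": 24.0,
    "axis_mode": "PD",
    "grid_target_occupancy": "fine",  # fine: 1-2 centroids/element; coarse: up to 4
    "window_min": 120.0,
    "theta_literal": False,
    "seed": 0,
}


@dataclasses.dataclass
class PipelineConfig:
    """Fully-resolved pipeline parameters (every default applied and logged)."""

    pixel_size_um: float = 0.1
    frame_interval_min: float = 15.0
    t0_hapf: float = 24.0
    axis_mode: str = "PD"
    grid_target_occupancy: str = "fine"
    window_min: float = 120.0
    theta_literal: bool = False
    seed: int = 0

    def __post_init__(self):
        # reuse AcquisitionMeta validation for the shared fields
        self.meta  # noqa: B018 - triggers validation
        if self.grid_target_occupancy not in ("fine", "coarse"):
            raise ValueError(
                f"grid_target_occupancy must be 'fine' or 'coarse', "
                f"got {self.grid_target_occupancy!r}"
            )
        if not self.window_min > 0:
            raise ValueError(f"window_min must be > 0, got {self.window_min}")

    @property
    def meta(self):
        return AcquisitionMeta(
            pixel_size_um=self.pixel_size_um,
            frame_interval_min=self.frame_interval_min,
            t0_hapf=self.t0_hapf,
            axis_mode=self.axis_mode,
        )


def read_config(path):
    """Read a JSON config; unknown keys warn, invalid values raise, defaults log."""
    with open(path) as fh:
        raw = json.load(fh)
    unknown = set(raw) - set(_CONFIG_DEFAULTS)
    for key in sorted(unknown):
        logger.warning("config: ignoring unknown key %r", key)
    resolved = {}
    for key, default in _CONFIG_DEFAULTS.items():
        if key in raw:
            resolved[key] = raw[key]
        else:
            resolved[key] = default
            logger.info("config: default applied %s=%r", key, default)
    return PipelineConfig(**resolved)
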