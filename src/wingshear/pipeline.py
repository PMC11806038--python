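"""End-to-end orchestration: tables in, CSV result bundle out.

Stages run in order: velocities -> coarse-grained gradients -> junction
classification -> timer stability -> per-cell polarity.  Every run writes
run.log (seed, version, resolved config) and report.md; identical
config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as wio
from .flow import flow_direction, cell_velocities, gradient_time_series
from .junctions import classify_junction, stable_fraction
from .polarity import (coarse_grain_polarity, polarity_angle_variance,
                       polarity_from_junctions)

logger = logging.getLogger("wingshear")

__all__ = ["run_pipeline"]


def _polarity_table(cells, junctions):
    """Per-cell polarity from junction midpoints weighted by total intensity."""
    rows = []
    jt = junctions.dropna(subset=["sum_ch1"])
    mids = pd.DataFrame({
        "frame": jt["frame"],
        "x": (jt["v1x_um"] + jt["v2x_um"]) / 2.0,
        "y": (jt["v1y_um"] + jt["v2y_um"]) / 2.0,
        "w": jt["sum_ch1"],
        "cell_a": jt["cell_a"], "cell_b": jt["cell_b"],
    })
    long = pd.concat([
        mids.rename(columns={"cell_a": "cell_id"})[["frame", "cell_id", "x", "y", "w"]],
        mids.rename(columns={"cell_b": "cell_id"})[["frame", "cell_id", "x", "y", "w"]],
    ])
    cent = cells.set_index(["frame", "cell_id"])
    for (frame, cid), grp in long.groupby(["frame", "cell_id"]):
        if len(grp) < 3 or (frame, cid) not in cent.index:
            continue
        c = cent.loc[(frame, cid)]
        try:
            pv = polarity_from_junctions(
                grp[["x", "y"]].to_numpy(), grp["w"].to_numpy(),
                (c["x_um"], c["y_um"]),
            )
        except ValueError:
            continue
        rows.append({
            "frame": frame, "cell_id": cid,
            "magnitude": pv.magnitude, "angle_deg": pv.angle_deg,
            "area_um2": c["area_um2"],
        })
    return pd.DataFrame(rows, columns=["frame", "cell_id", "magnitude",
                                       "angle_deg", "area_um2"])


def run_pipeline(config, indir, outdir):
    """Run all table-level stages; returns a dict of result DataFrames.

    Any stage failure aborts with the stage name; outputs written before the
    failure are retained with a .partial suffix.
    """
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = config.meta
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    written = []
    results = {}
    stage = "read"
    try:
        logger.info("version=%s seed=%d", __version__, config.seed)
        logger.info("config=%s", vars(config))
        cells, adjacency, junctions = wio.read_tables(indir)

        stage = "gradient"
        per_interval, per_window = gradient_time_series(
            cells, meta, window_min=config.window_min,
            mode=config.grid_target_occupancy,
            theta_literal=config.theta_literal,
        )
        per_interval.to_csv(outdir / "gradients.csv", index=False, float_format="%.10g")
        written.append("gradients.csv")
        per_window.to_csv(outdir / "gradients_window.csv", index=False,
                          float_format="%.10g")
        written.append("gradients_window.csv")
        results["gradients"] = per_interval
        results["gradients_window"] = per_window

        stage = "stability"
        samples = pd.concat([
            cell_velocities(cells, t, meta.frame_interval_min)
            for t in sorted(cells["frame"].unique())[:-1]
        ])
        _, _, theta = flow_direction(samples["vx"], samples["vy"],
                                     axis_mode=meta.axis_mode,
                                     literal=config.theta_literal)
        jt = junctions.dropna(subset=["mean_ch1"]).copy()
        stab_rows = []
        if len(jt):
            jt["class"] = classify_junction(jt["angle_deg"].to_numpy(), theta,
                                            mode=meta.axis_mode)
            s_wing = stable_fraction(jt, scope="wing")
            stab_rows.append({"scope": "wing", "class": "all",
                              "n_junctions": jt["junction_id"].nunique(),
                              "S": s_wing})
            for klass, s in stable_fraction(jt, scope="class").items():
                stab_rows.append({
                    "scope": "class", "class": klass,
                    "n_junctions": jt.loc[jt["class"] == klass, "junction_id"].nunique(),
                    "S": s,
                })
        stability = pd.DataFrame(stab_rows, columns=["scope", "class", "n_junctions", "S"])
        stability.to_csv(outdir / "stability.csv", index=False, float_format="%.10g")
        written.append("stability.csv")
        results["stability"] = stability
        results["theta_deg"] = theta

        stage = "polarity"
        pol = _polarity_table(cells, junctions)
        pol.to_csv(outdir / "polarity.csv", index=False, float_format="%.10g")
        written.append("polarity.csv")
        results["polarity"] = pol

        stage = "report"
        lines = ["# wingshear run report", ""]
        lines.append(f"- seed: {config.seed}")
        lines.append(f"- flow direction theta (deg, axial): {theta:.3f}")
        if len(per_window):
            w = per_window.iloc[0]
            lines.append(f"- window |dv'x/dy'| (1/min): {w['dvx_dy_abs']:.6g}")
            lines.append(f"- window |dv'y/dx'| (1/min): {w['dvy_dx_abs']:.6g}")
        for _, r in stability.iterrows():
            lines.append(f"- S[{r['scope']}/{r['class']}] = {r['S']:.6g} "
                         f"(n={r['n_junctions']})")
        if len(pol):
            cg = coarse_grain_polarity(pol["magnitude"], pol["angle_deg"])
            lines.append(f"- coarse-grain polarity: magnitude {cg.magnitude:.4f}, "
                         f"angle {cg.angle_deg:.2f} deg")
            if len(pol) >= 2:
                lines.append(f"- polarity angle variance: "
                             f"{polarity_angle_variance(pol['angle_deg']):.4f}")
        (outdir / "report.md").write_text("\n".join(lines) + "\n")
        written.append("report.md")
    except Exception:
        for name in written:
            p = outdir / name
            if p.exists():
                p.rename(p.with_suffix(p.suffix + ".partial"))
        logger.error("pipeline aborted at stage %r", stage)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    return results
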