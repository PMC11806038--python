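"""Timer-based stability statistics and junction dynamics metrics.

The tandem fluorescent timer couples a fast-maturing sfGFP (channel 1) to a
slow-maturing mKate (channel 2) on the same protein; the mKate/sfGFP
intensity ratio S reports the relative long-resident ("stable") protein
fraction on a junction or a population of junctions.  S is relative only:
it depends on acquisition settings, so it is never converted to absolute
residence times and is only compared within an imaging session.

Population-scope S pools summed intensities (a total-intensity ratio, not a
mean of per-junction ratios); single-junction S is the ratio of mean
intensities, matching the sliding-junction protocol.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._angles import axial_diff

__all__ = [
    "classify_junction",
    "stable_fraction",
    "percent_change",
    "t1_accumulation_profile",
    "sliding_junction_stability",
    "normalized_density_in_cell",
    "gradient_stability_correlation",
]


def classify_junction(angle_deg, theta_flow_deg, mode="PD"):
    """Classify junction orientation relative to the flow axis.

    In PD mode a junction is 'horizontal' (flow-parallel) when its axial
    angle lies strictly within +/-45 degrees of the flow direction, and
    'vertical' otherwise; AP mode swaps the band (the +/-45 window defines
    'vertical').  The |delta| = 45 boundary goes to the "otherwise" class.
    Vectorised: returns a scalar string or an object array.
    """
    delta = np.abs(axial_diff(angle_deg, theta_flow_deg))
    in_band = delta < 45.0
    if mode == "PD":
        res = np.where(in_band, "horizontal", "vertical")
    elif mode == "AP":
        res = np.where(in_band, "vertical", "horizontal")
    else:
        raise ValueError(f"mode must be 'PD' or 'AP', got {mode!r}")
    return res.item() if res.ndim == 0 else res


def stable_fraction(junctions, scope="wing", use="sum"):
    """Relative stable protein fraction S = mKate / sfGFP.

    scope='wing'      -> one pooled S over all rows
    scope='class'     -> S per value of the 'class' column
    scope='junction'  -> per-row S from mean intensities
    use='sum' pools sum_ch columns (total junctional intensities, the wing/
    class default); use='mean' pools mean_ch columns.
    """
    cols = ("sum_ch2", "sum_ch1") if use == "sum" else ("mean_ch2", "mean_ch1")

    def pooled(df):
        den = df[cols[1]].sum()
        if den <= 0:
            raise ValueError("zero sfGFP denominator")
        return float(df[cols[0]].sum() / den)

    if scope == "wing":
        return pooled(junctions)
    if scope == "class":
        if "class" not in junctions.columns:
            raise ValueError("scope='class' requires a 'class' column")
        return {k: pooled(g) for k, g in junctions.groupby("class")}
    if scope == "junction":
        den = junctions["mean_ch1"].to_numpy(float)
        if np.any(den <= 0):
            raise ValueError("zero sfGFP denominator")
        return junctions["mean_ch2"].to_numpy(float) / den
    raise ValueError(f"unknown scope {scope!r}")


def percent_change(x0, xt):
    """(X_t - X_0) / X_0 * 100; the density/length/stability change metric."""
    x0 = np.asarray(x0, float)
    if np.any(x0 <= 0):
        raise ValueError("percent_change undefined for reference value <= 0")
    return (np.asarray(xt, float) - x0) / x0 * 100.0


def t1_accumulation_profile(events, junctions, interval_min=15.0,
                            horizon_min=180.0, theta_flow_deg=0.0, mode="PD"):
    """Post-T1 accumulation of junctional protein on nascent junctions.

    For each exchange event the gained junction (cell pair c-d) is followed
    from its formation frame t0 for up to `horizon_min`; the percent change
    in density (mean channel-1 intensity) and in junction length relative to
    t0 is recorded per 15-min step, grouped by the new junction's
    orientation class and averaged per step.

    Returns a tidy DataFrame (t_min, class, n, mean_pct_density,
    mean_pct_length); events whose junction is lost before the first
    post-t0 frame are excluded and counted in df.attrs['n_excluded'].
    """
    n_steps = int(round(horizon_min / interval_min))
    by_pair = {
        (int(a), int(b)): g.sort_values("frame").set_index("frame")
        for (a, b), g in junctions.groupby(["cell_a", "cell_b"])
    }
    records = []
    n_excluded = 0
    for _, ev in events.iterrows():
        pair = (min(ev["cell_c"], ev["cell_d"]), max(ev["cell_c"], ev["cell_d"]))
        grp = by_pair.get((int(pair[0]), int(pair[1])))
        if grp is None:
            n_excluded += 1
            continue
        t0 = int(ev["frame_gained"])
        if t0 not in grp.index or (t0 + 1) not in grp.index:
            n_excluded += 1
            continue
        i0 = grp.loc[t0, "mean_ch1"]
        l0 = grp.loc[t0, "length_um"]
        if not (i0 > 0 and l0 > 0):
            n_excluded += 1
            continue
        jclass = classify_junction(grp.loc[t0, "angle_deg"], theta_flow_deg, mode)
        for step in range(0, n_steps + 1):
            t = t0 + step
            if t not in grp.index:
                break
            records.append({
                "t_min": step * interval_min,
                "class": jclass,
                "pct_density": float(percent_change(i0, grp.loc[t, "mean_ch1"])),
                "pct_length": float(percent_change(l0, grp.loc[t, "length_um"])),
            })
    raw = pd.DataFrame(records, columns=["t_min", "class", "pct_density", "pct_length"])
    if len(raw):
        out = (raw.groupby(["t_min", "class"])
                  .agg(n=("pct_density", "size"),
                       mean_pct_density=("pct_density", "mean"),
                       mean_pct_length=("pct_length", "mean"))
                  .reset_index())
    else:
        out = pd.DataFrame(
            columns=["t_min", "class", "n", "mean_pct_density", "mean_pct_length"]
        )
    out.attrs["n_excluded"] = n_excluded
    return out


def sliding_junction_stability(events, junctions, control_pairs=None):
    """Stability change on sliding vs control junctions across one interval.

    Per sliding event: S_pre and S_post are single-junction mean-intensity
    ratios at frame_pre/frame_post and the percent change follows the
    stability-change formula; per-channel percent density changes are also
    reported (to separate the slow- from the fast-maturing population).
    Control junctions are the unflagged pairs measured over the same frame
    intervals.  Returns a DataFrame with a 'group' column in
    {'sliding', 'control'}.
    """
    by_pair = {
        (int(a), int(b)): g.sort_values("frame").set_index("frame")
        for (a, b), g in junctions.groupby(["cell_a", "cell_b"])
    }
    rows = []

    def measure(pair, f_pre, f_post, group):
        grp = by_pair.get(pair)
        if grp is None or f_pre not in grp.index or f_post not in grp.index:
            return False
        pre, post = grp.loc[f_pre], grp.loc[f_post]
        if not (pre["mean_ch1"] > 0 and post["mean_ch1"] > 0):
            return False
        s_pre = pre["mean_ch2"] / pre["mean_ch1"]
        s_post = post["mean_ch2"] / post["mean_ch1"]
        rows.append({
            "group": group,
            "cell_a": pair[0], "cell_b": pair[1],
            "frame_pre": f_pre, "frame_post": f_post,
            "s_pre": float(s_pre), "s_post": float(s_post),
            "pct_stability": float(percent_change(s_pre, s_post)),
            "pct_ch1": float(percent_change(pre["mean_ch1"], post["mean_ch1"])),
            "pct_ch2": float(percent_change(pre["mean_ch2"], post["mean_ch2"])),
            "pct_length": float(percent_change(pre["length_um"], post["length_um"])),
        })
        return True

    intervals = []
    for _, ev in events.iterrows():
        pair = (int(ev["cell_a"]), int(ev["cell_b"]))
        f_pre, f_post = int(ev["frame_pre"]), int(ev["frame_post"])
        if not measure(pair, f_pre, f_post, "sliding"):
            raise ValueError(f"sliding event {pair} lacks pre/post measurements")
        intervals.append((f_pre, f_post))
    if control_pairs is None:
        flagged = {(int(ev["cell_a"]), int(ev["cell_b"])) for _, ev in events.iterrows()}
        control_pairs = sorted(set(by_pair) - flagged)
    for pair in control_pairs:
        for f_pre, f_post in sorted(set(intervals)):
            measure(tuple(int(c) for c in pair), f_pre, f_post, "control")
    return pd.DataFrame(rows)


def normalized_density_in_cell(junction_mean, sibling_means):
    """Mean intensity of a junction relative to its cell's other junctions.

    A value below 1 means the junction is dimmer than the cell's other
    junctions; above 1, brighter.  Invariant to global intensity gain.
    """
    sib = np.asarray(sibling_means, float)
    if sib.size < 2:
        raise ValueError("needs >= 2 sibling junctions in the same cell")
    ref = sib.mean()
    if ref <= 0:
        raise ValueError("sibling mean intensity is zero")
    return float(junction_mean / ref)


def gradient_stability_correlation(gradients, stabilities):
    """Ordinary least squares of per-wing S on per-wing velocity gradient.

    Returns (slope, intercept, r_squared).
    """
    x = np.asarray(gradients, float)
    y = np.asarray(stabilities, float)
    if x.size < 3:
        raise ValueError("needs >= 3 (gradient, S) pairs")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in gradient values")
    if np.allclose(y, y[0]):
        return 0.0, float(y[0]), 0.0  # response independent of the gradient
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)
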