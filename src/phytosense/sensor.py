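"""Bioristor signal processing: response R, normalized response NR, phase
segmentation and early stress-onset detection.

The implanted organic-electrochemical-transistor sensor reports two drain
currents per sample: ``i_ds`` with the gate biased and ``i_ds0`` with the
gate off. The response parameter is

    R_t = (i_ds,t - i_ds0,t) / i_ds0,t

which is invariant to common rescaling of both currents. Averaging R over
each 24 h cycle and taking the ratio of stressed-group to control-group
daily means yields the normalized response NR, whose slope changes define
the drought phases (PI insertion, PII drought decline, DA drought-avoidance
rebound, PIII post-rewatering recovery, PIV second drought).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import CONTROL, STRESSED, ExperimentDesign, phase_label_template

__all__ = [
    "PhaseSegmentation",
    "Segment",
    "OnsetReport",
    "compute_response",
    "daily_mean",
    "normalize_nr",
    "subdaily_nr",
    "segment_phases",
    "best_breakpoints",
    "piecewise_linear_fit",
    "detect_onset",
    "recovery_deficit",
]

logger = logging.getLogger(__name__)

I_DS0_FLOOR_UA = 1e-3  # samples with |i_ds0| below this are dropped


# ---------------------------------------------------------------------------
# response computation


def compute_response(
    trace: pd.DataFrame, i_ds0_floor: float = I_DS0_FLOOR_UA
) -> pd.DataFrame:
    """Per-sample sensor response R = (i_ds - i_ds0) / i_ds0.

    Accepts a trace table with columns plant_id, group, time_min, i_ds_uA,
    i_ds0_uA (one or many plants). Samples whose |i_ds0| falls below
    ``i_ds0_floor`` are dropped and counted in the log. Raises on an empty
    trace or when every sample is dropped.
    """
    if len(trace) == 0:
        raise ValueError("empty sensor trace")
    for plant, sub in trace.groupby("plant_id"):
        t = sub["time_min"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"time_min not strictly increasing for {plant}")
    ok = trace["i_ds0_uA"].abs() >= i_ds0_floor
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("dropped %d samples with |i_ds0| < %g uA", n_dropped, i_ds0_floor)
    kept = trace.loc[ok]
    if len(kept) == 0:
        raise ValueError("all samples dropped by the i_ds0 floor")
    r = (kept["i_ds_uA"] - kept["i_ds0_uA"]) / kept["i_ds0_uA"]
    out = kept[["plant_id", "time_min"]].copy()
    if "group" in kept.columns:
        out.insert(1, "group", kept["group"])
    out["r"] = r.to_numpy()
    return out.reset_index(drop=True)


def daily_mean(
    response: pd.DataFrame,
    design: ExperimentDesign,
    min_coverage: float = 0.5,
    keep_incomplete: bool = False,
) -> pd.DataFrame:
    """Arithmetic mean of R per plant over each [d*24 h, (d+1)*24 h) window.

    The day boundary is midnight of the implantation clock. Windows with
    fewer than ``min_coverage`` of the expected samples are flagged incomplete
    and excluded unless ``keep_incomplete``.
    """
    expected = 1440 // design.sampling_interval_min
    df = response.copy()
    df["day"] = (df["time_min"] // 1440).astype(int)
    keys = ["plant_id", "day"] + (["group"] if "group" in df.columns else [])
    agg = (
        df.groupby(keys, sort=True)["r"]
        .agg(r_mean="mean", n_samples="count")
        .reset_index()
    )
    agg["complete"] = agg["n_samples"] >= min_coverage * expected
    if not agg["complete"].any():
        raise ValueError("no complete 24 h window in the response series")
    if not keep_incomplete:
        agg = agg.loc[agg["complete"]].reset_index(drop=True)
    return agg


def normalize_nr(
    daily: pd.DataFrame, control_floor: float = 1e-6
) -> pd.DataFrame:
    """Normalized response: stressed-group mean over control-group mean per day.

    ``daily`` is the output of :func:`daily_mean` with a ``group`` column.
    Days where the control mean lies within ``control_floor`` of zero are
    masked with a warning. Raises if the groups share no day.
    """
    gmeans = (
        daily.groupby(["day", "group"])["r_mean"]
        .agg(["mean", "count"])
        .unstack("group")
    )
    if STRESSED not in gmeans["mean"] or CONTROL not in gmeans["mean"]:
        raise ValueError("both groups required to normalize")
    both = gmeans.dropna(subset=[("mean", STRESSED), ("mean", CONTROL)])
    if len(both) == 0:
        raise ValueError("groups have disjoint day coverage")
    ctrl = both[("mean", CONTROL)]
    masked = ctrl.abs() < control_floor
    if masked.any():
        logger.warning(
            "masked %d days with near-zero control mean", int(masked.sum())
        )
    both = both.loc[~masked]
    return pd.DataFrame(
        {
            "day": both.index.to_numpy(dtype=int),
            "nr": (both[("mean", STRESSED)] / both[("mean", CONTROL)]).to_numpy(),
            "n_stressed": both[("count", STRESSED)].to_numpy(dtype=int),
            "n_control": both[("count", CONTROL)].to_numpy(dtype=int),
        }
    ).reset_index(drop=True)


def subdaily_nr(response: pd.DataFrame, control_floor: float = 1e-6) -> pd.DataFrame:
    """Per-timestamp NR: ratio of group mean responses at each sample time."""
    g = (
        response.groupby(["time_min", "group"])["r"].mean().unstack("group")
    )
    g = g.dropna()
    keep = g[CONTROL].abs() >= control_floor
    g = g.loc[keep]
    return pd.DataFrame(
        {"time_min": g.index.to_numpy(), "nr": (g[STRESSED] / g[CONTROL]).to_numpy()}
    )


# ---------------------------------------------------------------------------
# piecewise-linear phase segmentation


def _pwl_design_matrix(x: np.ndarray, breaks: tuple[float, ...]) -> np.ndarray:
    cols = [np.ones_like(x), x]
    for b in breaks:
        cols.append(np.clip(x - b, 0.0, None))
    return np.stack(cols, axis=1)


def piecewise_linear_fit(
    x: np.ndarray, y: np.ndarray, breaks: tuple[float, ...]
) -> tuple[np.ndarray, float]:
    """Least-squares continuous piecewise-linear fit with fixed breakpoints.

    Returns (coefficients, residual sum of squares). The basis is
    {1, x, (x - b)_+ ...}, so the fit is continuous at every breakpoint.
    """
    X = _pwl_design_matrix(np.asarray(x, float), breaks)
    coef, _, _, _ = np.linalg.lstsq(X, np.asarray(y, float), rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid)


def best_breakpoints(
    x: np.ndarray, y: np.ndarray, k: int, min_seg: int = 2
) -> tuple[tuple[float, ...], float]:
    """Exhaustive search for the k integer breakpoints minimising RSS.

    Candidate breakpoints are the integer grid values strictly inside the
    data range; each resulting segment must contain at least ``min_seg``
    points. Ties resolve to the lexicographically first combination.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if k == 0:
        return (), piecewise_linear_fit(x, y, ())[1]
    lo, hi = int(np.ceil(x.min())), int(np.floor(x.max()))
    candidates = [c for c in range(lo + 1, hi) if x.min() < c < x.max()]
    best: tuple[tuple[float, ...], float] | None = None
    for combo in itertools.combinations(candidates, k):
        # a point at x == b has hinge value 0, so it belongs to the segment
        # left of the breakpoint
        seg_of = np.searchsorted(np.asarray(combo, float), x, side="left")
        counts = np.bincount(seg_of, minlength=k + 1)
        if counts.min() < min_seg:
            continue
        _, rss = piecewise_linear_fit(x, y, combo)
        if best is None or rss < best[1] - 1e-12:
            best = (tuple(float(c) for c in combo), rss)
    if best is None:
        raise ValueError(f"not enough data for {k} breakpoints")
    return best


@dataclass(frozen=True)
class Segment:
    label: str
    start_day: float
    end_day: float
    slope: float  # NR units / day


@dataclass
class PhaseSegmentation:
    segments: list[Segment]
    breakpoints: tuple[float, ...]
    coefficients: np.ndarray
    k: int
    bic: float

    def labels(self) -> list[str]:
        return [s.label for s in self.segments]


def _bic(n: int, rss: float, k: int) -> float:
    # 2 base coefficients + 2 per breakpoint (slope change + position)
    p = 2 + 2 * k
    return n * np.log(max(rss, 1e-12) / n) + p * np.log(n)


def _label_segments(
    breaks: tuple[float, ...],
    coef: np.ndarray,
    x: np.ndarray,
    design: ExperimentDesign,
    slope_tol: float = 1e-3,
) -> list[Segment]:
    template = phase_label_template(design)
    windows = [
        (w.label, w.start_day, w.end_day) for w in template if w.start_day is not None
    ]
    blocks = design.drought_blocks
    drought = blocks[0] if blocks else None

    edges = (float(x.min()),) + breaks + (float(x.max()),)
    # snap fitted breakpoints to the nearest expected phase boundary within
    # +-2 d for labelling purposes (the fitted positions are kept as-is)
    boundaries = sorted({w[1] for w in windows} | {w[2] for w in windows})
    snapped = list(edges)
    for i in range(1, len(snapped) - 1):
        near = min(boundaries, key=lambda b: abs(b - snapped[i]))
        if abs(near - snapped[i]) <= 2.0:
            snapped[i] = float(near)
    segments: list[Segment] = []
    for i in range(len(edges) - 1):
        start, end = edges[i], edges[i + 1]
        slope = coef[1] + sum(coef[2 + j] for j in range(i))
        mid = 0.5 * (snapped[i] + snapped[i + 1])
        lbl = windows[-1][0]
        for name, w0, w1 in windows:
            if w0 <= mid < w1:
                lbl = name
                break
        if (
            drought is not None
            and slope > slope_tol
            and start > drought[0]
            and end < drought[1]
        ):
            lbl = "DA"  # positive-slope rebound strictly inside the drought
        segments.append(Segment(lbl, start, end, float(slope)))
    return segments


def segment_phases(
    nr: pd.DataFrame,
    design: ExperimentDesign,
    k_max: int = 5,
    min_seg: int = 2,
) -> PhaseSegmentation:
    """Fit a continuous piecewise-linear model to the daily NR series.

    The number of breakpoints k is chosen over 0..``k_max`` by BIC, with an
    exhaustive integer-grid search for the breakpoint positions at each k.
    Segments are labelled from the design's phase template by the window
    containing their midpoint; a positive-slope segment strictly inside the
    drought window is relabelled DA.
    """
    x = nr["day"].to_numpy(dtype=float)
    y = nr["nr"].to_numpy(dtype=float)
    if len(x) < 6:
        raise ValueError("need at least 6 days of NR to segment")
    n = len(x)
    best_k, best_bic, best_breaks = 0, np.inf, ()
    for k in range(0, k_max + 1):
        if n < min_seg * (k + 1):
            break
        try:
            breaks, rss = best_breakpoints(x, y, k, min_seg)
        except ValueError:
            break
        bic = _bic(n, rss, k)
        if bic < best_bic - 1e-9:
            best_k, best_bic, best_breaks = k, bic, breaks
    coef, _ = piecewise_linear_fit(x, y, best_breaks)
    segments = _label_segments(best_breaks, coef, x, design)
    return PhaseSegmentation(
        segments=segments,
        breakpoints=best_breaks,
        coefficients=coef,
        k=best_k,
        bic=float(best_bic),
    )


# ---------------------------------------------------------------------------
# onset detection


@dataclass
class OnsetReport:
    detected: bool
    onset_h: float | None
    window_slope: float | None  # NR / day at the detection window
    p_slope: float | None
    n_windows: int = 0
    alpha_effective: float | None = None


def detect_onset(
    nr: pd.DataFrame,
    design: ExperimentDesign,
    window_h: float = 12.0,
    alpha: float = 0.05,
    scan_h: float = 72.0,
    bonferroni: bool = True,
) -> OnsetReport:
    """Earliest post-withholding time with a significantly negative NR slope.

    ``nr`` holds columns ``time_min`` (or ``day``) and ``nr``. For each grid
    time t >= stress start, the OLS slope of NR over [t - window_h, t] is
    tested one-sided against zero using the residual variance of a linear fit
    to the 24 h pre-stress baseline; the first window with p below the
    (Bonferroni-corrected, by default) level is the onset. ``detected`` is
    False when no window within ``scan_h`` qualifies.
    """
    if design.stress_start_day is None:
        raise ValueError("design has no drought; nothing to detect")
    s0_h = design.stress_start_day * 24.0
    if "time_min" in nr.columns:
        t_h = nr["time_min"].to_numpy(dtype=float) / 60.0
    else:
        t_h = nr["day"].to_numpy(dtype=float) * 24.0 + 12.0
    y = nr["nr"].to_numpy(dtype=float)

    pre = (t_h >= s0_h - 24.0) & (t_h < s0_h)
    if t_h.min() > s0_h - 24.0 + 1e-9 or pre.sum() < 4:
        raise ValueError("insufficient pre-stress baseline (< 24 h)")
    xb, yb = t_h[pre], y[pre]
    Xb = np.stack([np.ones_like(xb), xb], axis=1)
    coef, _, _, _ = np.linalg.lstsq(Xb, yb, rcond=None)
    resid = yb - Xb @ coef
    df0 = len(xb) - 2
    sigma0 = float(np.sqrt(resid @ resid / df0)) if df0 > 0 else 0.0

    grid = t_h[(t_h >= s0_h) & (t_h <= s0_h + scan_h)]
    grid = grid[grid - window_h >= t_h.min() - 1e-9]
    n_windows = len(grid)
    alpha_eff = alpha / n_windows if (bonferroni and n_windows) else alpha

    report = OnsetReport(False, None, None, None, n_windows, alpha_eff)
    for t in grid:
        w = (t_h > t - window_h - 1e-9) & (t_h <= t + 1e-9)
        if w.sum() < 3:
            continue
        xw = t_h[w] / 24.0  # slope in NR/day
        yw = y[w]
        xc = xw - xw.mean()
        sxx = float(xc @ xc)
        if sxx <= 0:
            continue
        slope = float(xc @ (yw - yw.mean()) / sxx)
        if sigma0 > 0:
            se = sigma0 / np.sqrt(sxx)
            tstat = slope / se
            p = float(stats.t.cdf(tstat, df0))
        else:
            p = 0.0 if slope < -1e-12 else 1.0
        if p < alpha_eff:
            return OnsetReport(
                True, float(t - s0_h), slope, p, n_windows, alpha_eff
            )
    return report


# ---------------------------------------------------------------------------
# recovery


def recovery_deficit(
    nr: pd.DataFrame, segmentation: PhaseSegmentation, plateau_skip_d: float = 2.0
) -> float:
    """Post-rewatering NR plateau relative to the pre-stress (PI) level.

    Returns mean NR over the PIII plateau (PIII excluding its first
    ``plateau_skip_d`` days of rise) divided by mean NR over PI; values < 1
    indicate incomplete recovery (irreversible damage).
    """
    by_label: dict[str, list[Segment]] = {}
    for seg in segmentation.segments:
        by_label.setdefault(seg.label, []).append(seg)
    if "PI" not in by_label or "PIII" not in by_label:
        raise ValueError("segmentation lacks PI or PIII")
    x = nr["day"].to_numpy(dtype=float)
    y = nr["nr"].to_numpy(dtype=float)

    pi = by_label["PI"][0]
    pi_mask = (x >= pi.start_day) & (x <= pi.end_day)
    p3 = by_label["PIII"][-1]
    start = p3.start_day + plateau_skip_d
    if start >= p3.end_day:
        start = p3.start_day
    p3_mask = (x >= start) & (x <= p3.end_day)
    if not pi_mask.any() or not p3_mask.any():
        raise ValueError("no NR data inside PI or PIII windows")
    return float(np.mean(y[p3_mask]) / np.mean(y[pi_mask]))
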