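"""Time-resolved and topographic regression of EEG on model predictors,
plus fractional-area latency of effect curves.

One mixed model of the N400 structure is fit per time point (or per
50 ms electrode window), the predictor-of-interest coefficients form an
effect curve beta(t), Benjamini-Hochberg correction is applied across the
cells of each analysis, and the temporal center of gravity of an effect is
summarized as the time point splitting the rectified area under beta(t)
into a chosen fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import cumulative_trapezoid

from .erp_stats import fdr_correct, fit_mixed_model

logger = logging.getLogger("sgn400")


@dataclass
class TimecourseResult:
    times: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    p_adj: np.ndarray
    mask: np.ndarray          # FDR rejections; failed fits are NaN and excluded
    predictor: str
    window: tuple[float, float]
    electrode: str = "ROI"


def roi_average(eeg: pd.DataFrame, electrodes: Sequence[str]) -> pd.DataFrame:
    """Collapse a set of electrodes into one virtual ROI electrode by
    averaging amplitudes per (subject, word, time)."""
    electrodes = list(electrodes)
    if not electrodes:
        raise ValueError("empty electrode set")
    present = set(eeg["electrode"].unique())
    missing = set(electrodes) - present
    if missing:
        raise ValueError(f"electrodes not in table: {sorted(missing)}")
    sub = eeg[eeg["electrode"].isin(electrodes)]
    out = (sub.groupby(["subject", "word", "time"], as_index=False)["amplitude"]
           .mean())
    out["electrode"] = "ROI"
    return out[["subject", "word", "electrode", "time", "amplitude"]]


def _fit_cell(df: pd.DataFrame, trials: pd.DataFrame, predictor: str,
              random_slopes: Sequence[str], include_baseline: bool):
    merged = df.merge(trials, on=["subject", "word"], how="inner")
    merged = merged.rename(columns={"amplitude": "n400"})
    res = fit_mixed_model(merged, fixed=(predictor,), random_slopes=random_slopes,
                          include_baseline=include_baseline)
    eff = res.fixed[predictor]
    return eff.beta, eff.se, eff.p


def fit_timepointwise(
    eeg: pd.DataFrame,
    trials: pd.DataFrame,
    predictor: str = "su",
    window: tuple[float, float] = (0.0, 650.0),
    random_slopes: Sequence[str] = (),
    include_baseline: bool = True,
    alpha: float = 0.05,
) -> TimecourseResult:
    """One mixed model per time point of a single-electrode (or ROI) table;
    FDR is applied across the time points of this analysis.  Time points
    whose fit fails are recorded as NaN and excluded from the FDR family.
    """
    times = np.array(sorted(eeg["time"].unique()))
    times = times[(times >= window[0]) & (times <= window[1])]
    if times.size == 0:
        raise ValueError("no time points inside analysis window")
    beta = np.full(times.size, np.nan)
    se = np.full(times.size, np.nan)
    p = np.full(times.size, np.nan)
    for i, t in enumerate(times):
        try:
            beta[i], se[i], p[i] = _fit_cell(
                eeg[eeg["time"] == t], trials, predictor,
                random_slopes, include_baseline)
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("timepoint %.0f ms failed to fit: %s", t, exc)
    ok = np.isfinite(p)
    p_adj = np.full(times.size, np.nan)
    mask = np.zeros(times.size, dtype=bool)
    if ok.any():
        p_adj[ok], mask[ok] = fdr_correct(p[ok], alpha)
    return TimecourseResult(times, beta, se, p, p_adj, mask, predictor, window)


def fit_topography(
    eeg: pd.DataFrame,
    trials: pd.DataFrame,
    predictor: str = "su",
    window_width: float = 50.0,
    span: tuple[float, float] | None = None,
    random_slopes: Sequence[str] = (),
    include_baseline: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-electrode, per-window effect map.

    Amplitudes are averaged inside non-overlapping ``window_width`` ms
    windows, one mixed model is fit per (electrode, window) cell, and BH
    correction runs across all cells of the map.  A span remainder shorter
    than one window is truncated with a warning.
    """
    electrodes = sorted(eeg["electrode"].unique())
    if not electrodes:
        raise ValueError("no electrodes in table")
    tmin, tmax = span if span is not None else (
        float(eeg["time"].min()), float(eeg["time"].max()))
    n_win = int(np.floor((tmax - tmin) / window_width))
    if n_win < 1:
        raise ValueError("analysis span shorter than one window")
    if tmin + n_win * window_width < tmax - 1e-9:
        logger.warning("topography: span remainder %.0f ms truncated",
                       tmax - (tmin + n_win * window_width))
    sub = eeg[(eeg["time"] >= tmin) & (eeg["time"] < tmin + n_win * window_width)]
    win = ((sub["time"] - tmin) // window_width).astype(int)
    sub = sub.assign(window=win)
    cells = (sub.groupby(["electrode", "window", "subject", "word"],
                         as_index=False)["amplitude"].mean())
    rows = []
    for (el, w), df in cells.groupby(["electrode", "window"]):
        rec = {"electrode": el, "win_start": tmin + w * window_width,
               "win_end": tmin + (w + 1) * window_width,
               "beta": np.nan, "se": np.nan, "p": np.nan}
        try:
            rec["beta"], rec["se"], rec["p"] = _fit_cell(
                df, trials, predictor, random_slopes, include_baseline)
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("topography cell (%s, window %d) failed: %s", el, w, exc)
        rows.append(rec)
    out = pd.DataFrame(rows)
    ok = out["p"].notna().to_numpy()
    p_adj = np.full(len(out), np.nan)
    reject = np.zeros(len(out), dtype=bool)
    if ok.any():
        p_adj[ok], reject[ok] = fdr_correct(out.loc[ok, "p"].to_numpy(), alpha)
    out["p_adj"] = p_adj
    out["reject"] = reject
    return out


def fractional_area_latency(
    times: np.ndarray,
    curve: np.ndarray,
    fraction: float = 0.5,
    window: tuple[float, float] | None = None,
    rectify: bool = True,
) -> float:
    """Smallest t* at which the cumulative (by default rectified) area
    under the curve reaches ``fraction`` of its total area.

    The curve is treated as piecewise linear between grid points; under
    rectification, sign changes contribute a kink at the interpolated zero
    crossing.  Within a segment the cumulative area is quadratic in t and
    is inverted exactly, so the result matches dense-grid numerical
    integration to well under a millisecond."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(curve, dtype=float)
    if window is not None:
        keep = (t >= window[0]) & (t <= window[1])
        t, c = t[keep], c[keep]
    if t.size < 2:
        raise ValueError("need at least two grid points")
    if not np.isfinite(c).all():
        raise ValueError("curve contains non-finite values")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if rectify:
        # insert interpolated zero crossings, then rectify
        ts, cs = [t[0]], [c[0]]
        for i in range(1, t.size):
            if c[i - 1] * c[i] < 0:
                tz = t[i - 1] - c[i - 1] * (t[i] - t[i - 1]) / (c[i] - c[i - 1])
                ts.append(tz)
                cs.append(0.0)
            ts.append(t[i])
            cs.append(c[i])
        t = np.array(ts)
        c = np.abs(cs)
    cum = cumulative_trapezoid(c, t, initial=0.0)
    total = cum[-1]
    if total <= 0.0:
        raise ValueError("total area is zero; latency undefined")
    target = fraction * total
    idx = int(np.argmax(cum >= target))
    if idx == 0:
        return float(t[0])
    t0, h = t[idx - 1], t[idx] - t[idx - 1]
    a, b = c[idx - 1], c[idx]
    r = target - cum[idx - 1]
    slope = (b - a) / h
    if abs(slope) < 1e-300:
        dt = r / a if a > 0 else h
    else:
        disc = max(a * a + 2.0 * slope * r, 0.0)
        dt = (-a + np.sqrt(disc)) / slope
        if not 0.0 <= dt <= h:   # other quadratic root
            dt = (-a - np.sqrt(disc)) / slope
    return float(t0 + min(max(dt, 0.0), h))


def plot_topography(topo: pd.DataFrame, path: str, mask_nonsig: bool = True):
    """Render a fit_topography result as an electrode x window heat map of
    beta coefficients (optionally blanking cells that fail FDR).  Requires
    matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = topo.pivot(index="electrode", columns="win_start", values="beta")
    if mask_nonsig:
        rej = topo.pivot(index="electrode", columns="win_start", values="reject")
        pivot = pivot.where(rej.astype(bool))
    fig, ax = plt.subplots(figsize=(1 + 0.5 * pivot.shape[1],
                                    1 + 0.4 * pivot.shape[0]))
    vmax = np.nanmax(np.abs(topo["beta"])) or 1.0
    im = ax.imshow(pivot.to_numpy(), aspect="auto", cmap="RdBu_r",
                   vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(pivot.shape[1]),
                  [f"{int(c)}" for c in pivot.columns], rotation=45)
    ax.set_yticks(range(pivot.shape[0]), pivot.index)
    ax.set_xlabel("window start (ms)")
    fig.colorbar(im, ax=ax, label="beta")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass
class LatencyTestResult:
    mean_a: float
    mean_b: float
    t: float
    p: float
    n: int
    excluded: int


def per_subject_latency_test(latencies_a: Sequence[float],
                             latencies_b: Sequence[float]) -> LatencyTestResult:
    """Paired two-sided t test on per-subject latency differences; subjects
    with an undefined (NaN) latency for either predictor are excluded."""
    a = np.asarray(latencies_a, dtype=float)
    b = np.asarray(latencies_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("latency vectors differ in length")
    ok = np.isfinite(a) & np.isfinite(b)
    excluded = int((~ok).sum())
    if excluded:
        logger.info("latency test: excluded %d subjects with undefined latency",
                    excluded)
    a, b = a[ok], b[ok]
    if a.size < 2:
        raise ValueError("need at least 2 subjects with defined latencies")
    diff = a - b
    if np.allclose(diff, diff[0]):
        # zero-variance differences: the t statistic degenerates
        t_stat, p = (0.0, 1.0) if np.isclose(diff[0], 0.0) \
            else (float(np.sign(diff[0]) * np.inf), 0.0)
    else:
        t_stat, p = stats.ttest_rel(a, b)
    return LatencyTestResult(float(a.mean()), float(b.mean()),
                             float(t_stat), float(p), int(a.size), excluded)


def per_subject_curves(
    eeg: pd.DataFrame,
    trials: pd.DataFrame,
    predictor: str = "su",
    window: tuple[float, float] = (0.0, 650.0),
    include_baseline: bool = True,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-subject effect curves: within each subject the subject-level
    random terms drop out, so each time point is an ordinary least-squares
    regression of amplitude on (baseline and) the predictor across words.
    Returns subject -> (times, beta(t))."""
    times = np.array(sorted(eeg["time"].unique()))
    times = times[(times >= window[0]) & (times <= window[1])]
    merged = eeg.merge(trials, on=["subject", "word"], how="inner")
    out = {}
    for subj, df in merged.groupby("subject"):
        betas = np.full(times.size, np.nan)
        for i, t in enumerate(times):
            d = df[df["time"] == t]
            cols = ["baseline", predictor] if include_baseline else [predictor]
            X = np.column_stack([np.ones(len(d))] +
                                [d[c].to_numpy(float) for c in cols])
            coef, *_ = np.linalg.lstsq(X, d["amplitude"].to_numpy(float),
                                       rcond=None)
            betas[i] = coef[-1]
        out[subj] = (times, betas)
    return out
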