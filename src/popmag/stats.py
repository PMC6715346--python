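"""Headline statistics of the magnitude-memorability analysis.

The central quantity is the population response magnitude of one image:
the L2 norm sqrt(sum_i r_i^2) of the vector of per-unit spike counts
r_i. The main analysis correlates per-slot magnitudes with per-slot
memorability scores (Pearson r, two-sided p from the t transform with
n - 2 df). Supporting statistics: grand mean firing rate, repetition
suppression (proportional novel-to-familiar reduction), the
point-biserial correlation between memorability and binary behavioral
outcomes, sliding-window sweeps, high-rate-unit exclusion, and binned
behavior for plotting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from popmag.pseudopop import Pseudopopulation

__all__ = [
    "MagnitudeResult",
    "l2_magnitude",
    "magnitude_memorability_correlation",
    "grand_mean_rate",
    "exclude_top_rate_units",
    "repetition_suppression",
    "point_biserial",
    "window_sweep",
    "bin_behavior_for_plot",
]


@dataclass
class MagnitudeResult:
    """Per-image magnitudes and their correlation with memorability."""

    magnitudes: np.ndarray
    memorability: np.ndarray
    window_ms: tuple[float, float]
    r: float
    p: float
    slope: float
    intercept: float
    #: Per-image grand mean rate in spikes/s (populated by grand_mean_rate).
    rates: np.ndarray | None = None

    def __post_init__(self):
        if np.any(np.asarray(self.magnitudes) < 0):
            raise ValueError("magnitudes must be nonnegative")
        if not (-1.0 - 1e-12 <= self.r <= 1.0 + 1e-12):
            raise ValueError("|r| must be <= 1")

    @property
    def magnitude_spread(self) -> float:
        """Max/min slot magnitude minus 1 (this package's definition of the
        proportional magnitude difference across images)."""
        lo = float(np.min(self.magnitudes))
        if lo <= 0:
            return float("inf")
        return float(np.max(self.magnitudes) / lo - 1.0)


def l2_magnitude(counts) -> float | np.ndarray:
    """Population response magnitude: sqrt(sum of squared unit counts).

    Accepts one per-unit count vector, or a (n_images, n_units) matrix
    (one magnitude per row).
    """
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0:
        raise ValueError("counts must be nonempty")
    if not np.all(np.isfinite(arr)):
        raise ValueError("counts must be finite")
    if np.any(arr < 0):
        raise ValueError("counts must be nonnegative")
    if arr.ndim == 1:
        return float(np.linalg.norm(arr))
    if arr.ndim == 2:
        return np.linalg.norm(arr, axis=1)
    raise ValueError("counts must be 1- or 2-dimensional")


def _pearson_with_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    if len(x) < 3:
        raise ValueError("need at least 3 points for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    r, p = sps.pearsonr(x, y)
    fit = sps.linregress(x, y)
    return float(r), float(p), float(fit.slope), float(fit.intercept)


def _windowed_response(pop: Pseudopopulation, window_ms) -> tuple[np.ndarray, tuple]:
    if window_ms is None or tuple(window_ms) == tuple(pop.window_ms):
        return pop.response, tuple(pop.window_ms)
    return pop.with_window(window_ms).response, tuple(window_ms)


def magnitude_memorability_correlation(
    pop: Pseudopopulation, window_ms: tuple[float, float] | None = None
) -> MagnitudeResult:
    """Pearson correlation between slot memorability and slot magnitude."""
    response, window = _windowed_response(pop, window_ms)
    mags = l2_magnitude(response)
    r, p, slope, intercept = _pearson_with_line(pop.memorability, mags)
    return MagnitudeResult(
        magnitudes=mags,
        memorability=pop.memorability,
        window_ms=window,
        r=r,
        p=p,
        slope=slope,
        intercept=intercept,
    )


def grand_mean_rate(
    pop: Pseudopopulation, window_ms: tuple[float, float] | None = None
) -> MagnitudeResult:
    """Grand mean firing rate per image and its memorability correlation.

    The rate is the mean spike count across units divided by the window
    duration, in spikes/s.
    """
    response, window = _windowed_response(pop, window_ms)
    duration_s = (window[1] - window[0]) / 1000.0
    if duration_s <= 0:
        raise ValueError("window must have positive duration")
    rates = response.mean(axis=1) / duration_s
    r, p, slope, intercept = _pearson_with_line(pop.memorability, rates)
    return MagnitudeResult(
        magnitudes=l2_magnitude(response),
        memorability=pop.memorability,
        window_ms=window,
        r=r,
        p=p,
        slope=slope,
        intercept=intercept,
        rates=rates,
    )


def exclude_top_rate_units(
    pop: Pseudopopulation, top_fraction: float
) -> Pseudopopulation:
    """Drop the ceil(top_fraction * N) units with the highest mean rate.

    The control for the possibility that a few high-rate units carry the
    correlation: after exclusion, downstream statistics are recomputed on
    the reduced population.
    """
    if not (0 <= top_fraction < 1):
        raise ValueError("top_fraction must lie in [0, 1)")
    n = pop.n_units
    k = math.ceil(top_fraction * n)
    if k == 0:
        return pop
    unit_means = pop.response.mean(axis=0)
    order = np.argsort(unit_means, kind="stable")  # ascending; drop the tail
    return pop.select_units(np.sort(order[: n - k]))


def repetition_suppression(
    novel: np.ndarray, familiar: np.ndarray, per_unit: bool = False
) -> float:
    """Mean proportional reduction of the familiar response vs novel.

    Default (population level): 1 - grand_mean(familiar) / grand_mean(novel).
    ``per_unit=True`` instead averages each unit's proportional reduction
    (units with zero novel mean are excluded from that average).
    """
    novel = np.asarray(novel, dtype=float)
    familiar = np.asarray(familiar, dtype=float)
    if novel.shape != familiar.shape:
        raise ValueError("novel and familiar matrices must have matching shapes")
    if not per_unit:
        g = novel.mean()
        if g <= 0:
            raise ValueError("zero novel grand mean: suppression undefined")
        return float(1.0 - familiar.mean() / g)
    unit_novel = novel.mean(axis=0)
    ok = unit_novel > 0
    if not ok.any():
        raise ValueError("zero novel mean for every unit: suppression undefined")
    return float(np.mean(1.0 - familiar.mean(axis=0)[ok] / unit_novel[ok]))


def point_biserial(memorability, outcomes) -> tuple[float, float]:
    """Point-biserial correlation between scores and binary outcomes.

    Computed by the closed-form mean-difference formula
    r = (M1 - M0) / s_n * sqrt(n1 n0 / n^2), which equals the Pearson
    correlation with the outcomes encoded 0/1; the two-sided p-value uses
    the t transform with n - 2 df.
    """
    x = np.asarray(memorability, dtype=float)
    y = np.asarray(outcomes)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("memorability and outcomes must be matching 1-d arrays")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 records")
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0, 1])):
        raise ValueError("outcomes must be binary 0/1")
    if len(classes) < 2:
        raise ValueError("both outcome classes must be present")
    y = y.astype(bool)
    n1 = int(y.sum())
    n0 = n - n1
    s = x.std()  # population (1/n) sd, cancels the 1/n^2 inside the sqrt
    if s == 0:
        raise ValueError("zero-variance scores: correlation undefined")
    r = (x[y].mean() - x[~y].mean()) / s * math.sqrt(n1 * n0 / n**2)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return r, p


def window_sweep(
    pop: Pseudopopulation,
    window_length_ms: float,
    step_ms: float | None = None,
) -> pd.DataFrame:
    """Magnitude-memorability correlation per sliding count window.

    Slides a window of ``window_length_ms`` across the trial period in
    steps of ``step_ms`` (default: one bin). Windows with zero-variance
    magnitudes yield missing r/p with a warning rather than an error.

    Returns a table with window_start_ms, window_end_ms, r, p.
    """
    if pop.novel_binned is None or pop.bin_edges_ms is None:
        raise ValueError("binned counts were not retained; cannot sweep windows")
    edges = pop.bin_edges_ms
    bw = edges[1] - edges[0]
    if step_ms is None:
        step_ms = bw
    for name, value in (("window_length_ms", window_length_ms), ("step_ms", step_ms)):
        if abs(value / bw - round(value / bw)) > 1e-9 or value <= 0:
            raise ValueError(f"{name} must be a positive whole number of bins")

    rows = []
    start = edges[0]
    while start + window_length_ms <= edges[-1] + 1e-9:
        window = (start, start + window_length_ms)
        sub = pop.with_window(window)
        mags = l2_magnitude(sub.response)
        if np.std(mags) == 0 or np.std(sub.memorability) == 0:
            warnings.warn(
                f"zero-variance magnitudes in window {window}; r reported missing",
                stacklevel=2,
            )
            r = p = float("nan")
        else:
            r, p = sps.pearsonr(sub.memorability, mags)
        rows.append((window[0], window[1], float(r), float(p)))
        start += step_ms
    return pd.DataFrame(rows, columns=["window_start_ms", "window_end_ms", "r", "p"])


def bin_behavior_for_plot(behavior: pd.DataFrame, n_bins: int) -> pd.DataFrame:
    """Bin behavioral performance across images by memorability rank.

    ``behavior`` has one row per (session, image) with columns
    session_id, image_id, memorability, correct. Images are assigned to
    ``n_bins`` equal-count bins by memorability rank; each bin reports
    the mean memorability, the mean performance, and the standard error
    of the per-session bin means across sessions. The grand mean
    performance is attached to every row (the no-correlation reference
    line).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    images = (
        behavior[["image_id", "memorability"]]
        .groupby("image_id", as_index=True)["memorability"]
        .mean()
        .sort_values(kind="stable")
    )
    if n_bins > len(images):
        raise ValueError("n_bins exceeds the number of distinct images")
    # Equal-count bins by rank; remainder images go to the lowest bins.
    ranks = pd.Series(np.arange(len(images)), index=images.index)
    bin_of_image = (ranks * n_bins // len(images)).astype(int)

    df = behavior.copy()
    df["bin"] = df["image_id"].map(bin_of_image)
    grand_mean = float(df["correct"].mean())

    rows = []
    for b, group in df.groupby("bin"):
        per_session = group.groupby("session_id")["correct"].mean()
        sem = (
            float(per_session.std(ddof=1) / math.sqrt(len(per_session)))
            if len(per_session) > 1
            else float("nan")
        )
        rows.append(
            (
                int(b),
                float(group["memorability"].mean()),
                float(group["correct"].mean()),
                sem,
                len(group),
                grand_mean,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "bin",
            "memorability",
            "performance",
            "sem",
            "n_records",
            "grand_mean",
        ],
    ).sort_values("bin", ignore_index=True)
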