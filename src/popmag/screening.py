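"""Unit and session quality control.

Units are screened for stimulus-evoked activity by comparing each
trial's spike count in a 200 ms pre-stimulus window (-200 to 0 ms)
against a post-stimulus window (80 to 280 ms) with a paired two-sided
t-test at p < 0.01. Sessions are screened on three criteria, in order:

1. stability — the grand mean firing rate changes less than 2-fold
   across the session (operationalized as max/min over four equal
   trial quarters);
2. responsiveness — more than 50% of units are visually responsive
   (the same evoked t-test at a looser alpha of 0.05, a reproducible
   proxy for raster inspection);
3. pair count — the number of completed novel/familiar pairs strictly
   exceeds 100.

A failing session is labeled with the first violated criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from popmag.synthetic import SessionRecording

__all__ = [
    "UnitScreen",
    "SessionScreen",
    "ScreeningReport",
    "PRE_WINDOW_MS",
    "POST_WINDOW_MS",
    "screen_unit_counts",
    "screen_unit",
    "screen_session",
    "screen_sessions",
]

PRE_WINDOW_MS = (-200.0, 0.0)
POST_WINDOW_MS = (80.0, 280.0)

CRITERION_LABELS = {1: "stability", 2: "responsiveness", 3: "pair_count"}


@dataclass
class UnitScreen:
    unit_id: str
    pre_mean: float
    post_mean: float
    t: float
    p: float
    passed: bool
    #: Set when the t statistic is undefined (zero-variance difference).
    degenerate: bool = False


@dataclass
class SessionScreen:
    session_id: str
    passed: bool
    #: 1, 2 or 3 for the first violated criterion; None when passing.
    failed_criterion: int | None
    stability_ratio: float
    responsive_fraction: float
    n_pairs: int
    units: list[UnitScreen] = field(default_factory=list)
    #: Indices of units passing the evoked screen at the strict alpha.
    kept_unit_indices: np.ndarray = field(default_factory=lambda: np.array([], int))

    @property
    def failed_criterion_label(self) -> str | None:
        if self.failed_criterion is None:
            return None
        return CRITERION_LABELS[self.failed_criterion]


@dataclass
class ScreeningReport:
    """Batch screening outcome with removal accounting."""

    sessions: list[SessionScreen]

    @property
    def n_recorded(self) -> int:
        return len(self.sessions)

    @property
    def n_retained(self) -> int:
        return sum(s.passed for s in self.sessions)

    def removed_by_criterion(self) -> dict[int, int]:
        out = {1: 0, 2: 0, 3: 0}
        for s in self.sessions:
            if not s.passed:
                out[s.failed_criterion] += 1
        return out

    def unit_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.sessions:
            for u in s.units:
                rows.append(
                    (s.session_id, u.unit_id, u.pre_mean, u.post_mean, u.t, u.p,
                     u.passed, u.degenerate)
                )
        return pd.DataFrame(
            rows,
            columns=["session_id", "unit_id", "pre_mean", "post_mean", "t", "p",
                     "passed", "degenerate"],
        )

    def session_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (s.session_id, s.passed, s.failed_criterion,
                 s.failed_criterion_label, s.stability_ratio,
                 s.responsive_fraction, s.n_pairs, len(s.kept_unit_indices))
                for s in self.sessions
            ],
            columns=["session_id", "passed", "failed_criterion",
                     "failed_criterion_label", "stability_ratio",
                     "responsive_fraction", "n_pairs", "n_units_kept"],
        )

    def summary(self) -> dict:
        removed = self.removed_by_criterion()
        return {
            "n_recorded": self.n_recorded,
            "n_retained": self.n_retained,
            "removed_by_criterion": {CRITERION_LABELS[k]: v for k, v in removed.items()},
            "n_units_kept": int(
                sum(len(s.kept_unit_indices) for s in self.sessions if s.passed)
            ),
        }


def screen_unit_counts(
    pre: np.ndarray, post: np.ndarray, alpha: float = 0.01
) -> tuple[bool, float, float, bool]:
    """Paired two-sided t-test on per-trial pre vs post counts.

    Returns (passed, t, p, degenerate). A zero-variance difference makes
    the statistic undefined; such units are reported as failing with
    p = NaN and flagged degenerate.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be matching 1-d per-trial counts")
    if pre.size < 2:
        raise ValueError("need at least 2 trials for the evoked t-test")
    diff = post - pre
    if np.all(diff == diff[0]) and diff[0] == 0:
        return False, float("nan"), float("nan"), True
    t, p = stats.ttest_rel(post, pre)
    if np.isnan(p):
        return False, float(t), float("nan"), True
    return bool(p < alpha), float(t), float(p), False


def screen_unit(
    session: SessionRecording,
    unit_index: int,
    pre_window: tuple[float, float] = PRE_WINDOW_MS,
    post_window: tuple[float, float] = POST_WINDOW_MS,
    alpha: float = 0.01,
) -> UnitScreen:
    """Screen one unit of a session for stimulus-evoked activity."""
    pre = session.window_counts(pre_window)[:, unit_index]
    post = session.window_counts(post_window)[:, unit_index]
    passed, t, p, degenerate = screen_unit_counts(pre, post, alpha)
    return UnitScreen(
        unit_id=session.unit_ids[unit_index],
        pre_mean=float(pre.mean()),
        post_mean=float(post.mean()),
        t=t,
        p=p,
        passed=passed,
        degenerate=degenerate,
    )


def _stability_ratio(session: SessionRecording, n_blocks: int = 4) -> float:
    """Max/min of the grand mean rate over equal contiguous trial blocks."""
    per_trial = session.counts.sum(axis=(1, 2)).astype(float)
    if len(per_trial) < n_blocks:
        n_blocks = max(1, len(per_trial))
    blocks = np.array_split(per_trial, n_blocks)
    means = np.array([b.mean() for b in blocks])
    lo = means.min()
    if lo <= 0:
        return float("inf")
    return float(means.max() / lo)


def _unit_screens(
    session: SessionRecording,
    pre_window: tuple[float, float],
    post_window: tuple[float, float],
    alpha: float,
) -> tuple[list[UnitScreen], np.ndarray]:
    """Vectorized paired t-tests over all units of one session."""
    pre = session.window_counts(pre_window).astype(float)
    post = session.window_counts(post_window).astype(float)
    t, p = stats.ttest_rel(post, pre, axis=0)
    t = np.atleast_1d(t)
    p = np.atleast_1d(p)
    degenerate = np.isnan(p)
    passed = np.where(degenerate, False, p < alpha)
    units = [
        UnitScreen(
            unit_id=session.unit_ids[u],
            pre_mean=float(pre[:, u].mean()),
            post_mean=float(post[:, u].mean()),
            t=float(t[u]),
            p=float(p[u]),
            passed=bool(passed[u]),
            degenerate=bool(degenerate[u]),
        )
        for u in range(session.n_units)
    ]
    return units, p


def screen_session(
    session: SessionRecording,
    stability_max_ratio: float = 2.0,
    responsive_fraction_min: float = 0.5,
    min_pairs: int = 100,
    unit_alpha: float = 0.01,
    responsive_alpha: float = 0.05,
    pre_window: tuple[float, float] = PRE_WINDOW_MS,
    post_window: tuple[float, float] = POST_WINDOW_MS,
) -> SessionScreen:
    """Apply the three session QC criteria, in order, to one session.

    Responsiveness (criterion 2) uses the evoked t-test at the looser
    ``responsive_alpha``; unit retention for downstream analysis uses the
    strict ``unit_alpha``. Both the responsiveness threshold and the pair
    count are strict inequalities.
    """
    if session.n_units < 1 or session.n_pairs < 1:
        raise ValueError("session must contain at least one unit and one pair")
    units, p = _unit_screens(session, pre_window, post_window, unit_alpha)

    ratio = _stability_ratio(session)
    with np.errstate(invalid="ignore"):
        responsive = np.where(np.isnan(p), False, p < responsive_alpha)
    responsive_fraction = float(np.mean(responsive))
    n_pairs = session.n_pairs

    failed = None
    if not (ratio < stability_max_ratio):
        failed = 1
    elif not (responsive_fraction > responsive_fraction_min):
        failed = 2
    elif not (n_pairs > min_pairs):
        failed = 3

    kept = np.flatnonzero([u.passed for u in units])
    return SessionScreen(
        session_id=session.session_id,
        passed=failed is None,
        failed_criterion=failed,
        stability_ratio=ratio,
        responsive_fraction=responsive_fraction,
        n_pairs=n_pairs,
        units=units,
        kept_unit_indices=kept,
    )


def screen_sessions(
    sessions: list[SessionRecording], **kwargs
) -> tuple[list[tuple[SessionRecording, np.ndarray]], ScreeningReport]:
    """Screen a batch of sessions.

    Returns the retained (session, kept-unit-indices) pairs together with
    the full :class:`ScreeningReport` (removal accounting included).
    """
    screens = [screen_session(s, **kwargs) for s in sessions]
    retained = [
        (sess, scr.kept_unit_indices)
        for sess, scr in zip(sessions, screens)
        if scr.passed and len(scr.kept_unit_indices) > 0
    ]
    return retained, ScreeningReport(screens)
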