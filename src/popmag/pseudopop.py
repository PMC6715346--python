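"""Memorability-aligned pseudopopulation construction.

Accurate estimates of population response magnitude need many hundreds
of units, so units recorded in separate sessions are concatenated into
one large virtual population. Within each n-back level, each session's
novel/familiar image pairs are subselected to a common count (limited by
the session with the fewest pairs), ranked by memorability, and slotted
by rank, so that every image slot combines responses to images with
similar memorability scores across all sessions. Each slot's score is
the mean of the contributing images' scores; each unit's response is its
spike count in the analysis window, averaged over the image's novel and
familiar presentations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from popmag import regime
from popmag.synthetic import SessionRecording

__all__ = [
    "Pseudopopulation",
    "subselect_images",
    "align_sessions",
    "build_pseudopopulation",
    "exclude_content_subset",
]


@dataclass
class Pseudopopulation:
    """Aligned image-slot x unit matrix of averaged spike counts."""

    #: (n_slots, n_units): (novel + familiar) / 2 when both are available.
    response: np.ndarray
    memorability: np.ndarray
    n_back: np.ndarray
    window_ms: tuple[float, float]
    unit_ids: list[str]
    unit_sessions: list[str]
    novel: np.ndarray | None = None
    familiar: np.ndarray | None = None
    #: Per-slot standard deviation of the contributing scores.
    score_sd: np.ndarray | None = None
    #: Per-slot list of contributing (session_id, image_id) pairs.
    contributors: list[list[tuple[str, str]]] | None = None
    #: Optional (n_slots, n_units, n_bins) binned counts for window sweeps.
    novel_binned: np.ndarray | None = None
    familiar_binned: np.ndarray | None = None
    bin_edges_ms: np.ndarray | None = None

    def __post_init__(self):
        self.response = np.asarray(self.response, dtype=float)
        self.memorability = np.asarray(self.memorability, dtype=float)
        self.n_back = np.asarray(self.n_back, dtype=int)
        n_slots, n_units = self.response.shape
        if len(self.memorability) != n_slots or len(self.n_back) != n_slots:
            raise ValueError("per-slot metadata must match response rows")
        if len(self.unit_ids) != n_units or len(self.unit_sessions) != n_units:
            raise ValueError("per-unit metadata must match response columns")
        if np.any(self.response < 0):
            raise ValueError("spike counts must be nonnegative")
        if self.novel is not None and self.familiar is not None:
            if not np.allclose(self.response, (self.novel + self.familiar) / 2.0):
                raise ValueError("response must equal (novel + familiar) / 2")

    @property
    def n_slots(self) -> int:
        return self.response.shape[0]

    @property
    def n_units(self) -> int:
        return self.response.shape[1]

    def slot_frame(self) -> pd.DataFrame:
        data = {
            "slot": np.arange(self.n_slots),
            "n_back": self.n_back,
            "memorability": self.memorability,
        }
        if self.score_sd is not None:
            data["score_sd"] = self.score_sd
        return pd.DataFrame(data)

    def select_units(self, indices) -> "Pseudopopulation":
        """A copy restricted to the given unit columns."""
        idx = np.asarray(indices, dtype=int)
        return replace(
            self,
            response=self.response[:, idx],
            novel=None if self.novel is None else self.novel[:, idx],
            familiar=None if self.familiar is None else self.familiar[:, idx],
            unit_ids=[self.unit_ids[i] for i in idx],
            unit_sessions=[self.unit_sessions[i] for i in idx],
            novel_binned=(
                None if self.novel_binned is None else self.novel_binned[:, idx]
            ),
            familiar_binned=(
                None if self.familiar_binned is None else self.familiar_binned[:, idx]
            ),
        )

    def with_window(self, window_ms: tuple[float, float]) -> "Pseudopopulation":
        """Recompute the response matrices in a different count window.

        Requires the binned counts to have been retained at construction.
        """
        if self.novel_binned is None or self.bin_edges_ms is None:
            raise ValueError("binned counts were not retained; cannot re-window")
        sl = _bin_slice(self.bin_edges_ms, window_ms)
        novel = self.novel_binned[:, :, sl].sum(axis=2)
        familiar = self.familiar_binned[:, :, sl].sum(axis=2)
        return replace(
            self,
            response=(novel + familiar) / 2.0,
            novel=novel,
            familiar=familiar,
            window_ms=tuple(window_ms),
        )


def _bin_slice(edges: np.ndarray, window_ms: tuple[float, float]) -> slice:
    starts = edges[:-1]
    lo, hi = window_ms
    i0 = np.flatnonzero(np.abs(starts - lo) < 1e-9)
    i1 = np.flatnonzero(np.abs(edges - hi) < 1e-9)
    if i0.size != 1 or i1.size != 1 or i1[0] <= i0[0]:
        raise ValueError(f"window {window_ms} is not representable by whole bins")
    return slice(int(i0[0]), int(i1[0]))


def subselect_images(scores: Mapping[str, float], target_count: int) -> list[str]:
    """Retain ``target_count`` images spanning the group's score range.

    Keeps the minimum- and maximum-score images and fills the remaining
    slots with the images whose scores are nearest to evenly spaced
    values strictly between the two extremes, assigned greedily from the
    lowest spacing target upward, without replacement. Ties are broken
    by score and then image id (stable and deterministic).

    Returns the retained ids sorted by (score, id).
    """
    items = sorted(scores.items(), key=lambda kv: (kv[1], kv[0]))
    n = len(items)
    if target_count > n:
        raise ValueError(f"group of {n} images is smaller than target {target_count}")
    if n == target_count:
        return [k for k, _ in items]
    lo_id, lo_s = items[0]
    hi_id, hi_s = items[-1]
    if target_count < 2:
        if lo_s == hi_s and target_count == 1:
            return [lo_id]
        raise ValueError("target_count must be >= 2 when the extremes are distinct")
    retained = [items[0], items[-1]]
    pool = items[1:-1]
    spacing = np.linspace(lo_s, hi_s, target_count)[1:-1]
    for tval in spacing:
        best = min(pool, key=lambda kv: (abs(kv[1] - tval), kv[1], kv[0]))
        pool.remove(best)
        retained.append(best)
    retained.sort(key=lambda kv: (kv[1], kv[0]))
    return [k for k, _ in retained]


def _session_pairs(sess: SessionRecording) -> pd.DataFrame:
    """Completed pairs: image_id, n_back, novel/familiar trial positions."""
    pos = {
        (img, exp): i
        for i, (img, exp) in enumerate(
            zip(sess.trials["image_id"], sess.trials["exposure"])
        )
    }
    fam = sess.trials[sess.trials["exposure"] == "familiar"]
    rows = []
    for img, nb in zip(fam["image_id"], fam["n_back"]):
        if (img, "novel") not in pos:
            raise ValueError(
                f"image {img!r} has a familiar but no novel presentation"
            )
        rows.append((img, int(nb), pos[(img, "novel")], pos[(img, "familiar")]))
    return pd.DataFrame(rows, columns=["image_id", "n_back", "novel_pos", "fam_pos"])


def align_sessions(
    screened: Sequence[tuple[SessionRecording, np.ndarray]],
    window_ms: tuple[float, float] = regime.ANALYSIS_WINDOW_MS,
    target_counts: Mapping[int, int] | None = None,
    keep_bins: bool = False,
) -> Pseudopopulation:
    """Build the cross-session pseudopopulation from screened sessions.

    ``screened`` pairs each session with the indices of its retained
    units. Within each n-back level, every session is subselected to the
    same image count (by default the minimum across sessions), retained
    images are ranked by memorability, and rank-matched images share a
    slot. Unit columns are concatenated in session order.
    """
    if len(screened) == 0:
        raise ValueError("no sessions to align")
    sessions = [s for s, _ in screened]
    pairs = [_session_pairs(s) for s in sessions]
    levels = sorted(set.union(*(set(p["n_back"]) for p in pairs)))
    for sess, p in zip(sessions, pairs):
        missing = set(levels) - set(p["n_back"])
        if missing:
            raise ValueError(
                f"{sess.session_id} is missing n-back level(s) {sorted(missing)}"
            )
    if target_counts is None:
        target_counts = {
            nb: min(int((p["n_back"] == nb).sum()) for p in pairs) for nb in levels
        }
    else:
        for sess, p in zip(sessions, pairs):
            for nb in levels:
                if (p["n_back"] == nb).sum() < target_counts[nb]:
                    raise ValueError(
                        f"{sess.session_id} has fewer n-back {nb} pairs than the "
                        f"target {target_counts[nb]}"
                    )

    # Per session and level: retained image ids in memorability rank order.
    ranked: list[dict[int, list[str]]] = []
    for sess, p in zip(sessions, pairs):
        by_level: dict[int, list[str]] = {}
        for nb in levels:
            group = p.loc[p["n_back"] == nb, "image_id"]
            scores = dict(zip(group, sess.memorability_of(group)))
            by_level[nb] = subselect_images(scores, target_counts[nb])
        ranked.append(by_level)

    # Window counts per trial, once per session.
    win = [s.window_counts(window_ms).astype(float) for s in sessions]
    pair_pos = [
        p.set_index("image_id")[["novel_pos", "fam_pos"]].astype(int) for p in pairs
    ]

    n_units = sum(len(idx) for _, idx in screened)
    slots = [(nb, r) for nb in levels for r in range(target_counts[nb])]
    n_slots = len(slots)
    novel = np.empty((n_slots, n_units))
    familiar = np.empty((n_slots, n_units))
    memorability = np.empty(n_slots)
    score_sd = np.empty(n_slots)
    n_back = np.empty(n_slots, dtype=int)
    contributors: list[list[tuple[str, str]]] = []

    n_bins = sessions[0].counts.shape[2] if keep_bins else 0
    if keep_bins:
        edges0 = sessions[0].bin_edges_ms
        for s in sessions[1:]:
            if not np.array_equal(s.bin_edges_ms, edges0):
                raise ValueError("sessions must share bin edges to retain bins")
        novel_binned = np.empty((n_slots, n_units, n_bins))
        familiar_binned = np.empty((n_slots, n_units, n_bins))

    for k, (nb, rank) in enumerate(slots):
        col = 0
        slot_scores = []
        contrib = []
        for j, (sess, unit_idx) in enumerate(screened):
            image_id = ranked[j][nb][rank]
            npos, fpos = pair_pos[j].loc[image_id]
            ncols = len(unit_idx)
            novel[k, col : col + ncols] = win[j][npos, unit_idx]
            familiar[k, col : col + ncols] = win[j][fpos, unit_idx]
            if keep_bins:
                novel_binned[k, col : col + ncols] = sess.counts[npos, unit_idx, :]
                familiar_binned[k, col : col + ncols] = sess.counts[fpos, unit_idx, :]
            slot_scores.append(float(sess.memorability_of([image_id])[0]))
            contrib.append((sess.session_id, image_id))
            col += ncols
        memorability[k] = np.mean(slot_scores)
        score_sd[k] = np.std(slot_scores)
        n_back[k] = nb
        contributors.append(contrib)

    unit_ids = []
    unit_sessions = []
    for sess, unit_idx in screened:
        unit_ids.extend(sess.unit_ids[i] for i in unit_idx)
        unit_sessions.extend([sess.session_id] * len(unit_idx))

    return Pseudopopulation(
        response=(novel + familiar) / 2.0,
        memorability=memorability,
        n_back=n_back,
        window_ms=tuple(window_ms),
        unit_ids=unit_ids,
        unit_sessions=unit_sessions,
        novel=novel,
        familiar=familiar,
        score_sd=score_sd,
        contributors=contributors,
        novel_binned=novel_binned if keep_bins else None,
        familiar_binned=familiar_binned if keep_bins else None,
        bin_edges_ms=sessions[0].bin_edges_ms.copy() if keep_bins else None,
    )


def build_pseudopopulation(
    sessions: Sequence[SessionRecording],
    window_ms: tuple[float, float] = regime.ANALYSIS_WINDOW_MS,
    keep_bins: bool = False,
    **screen_kwargs,
):
    """Screen sessions and units, then align: the standard construction.

    Returns ``(pseudopopulation, screening_report)``.
    """
    from popmag.screening import screen_sessions

    retained, report = screen_sessions(list(sessions), **screen_kwargs)
    if not retained:
        raise ValueError("no sessions survived screening")
    pop = align_sessions(retained, window_ms=window_ms, keep_bins=keep_bins)
    return pop, report


def exclude_content_subset(
    screened: Sequence[tuple[SessionRecording, np.ndarray]],
    flagged_image_ids: set[str] | None = None,
    window_ms: tuple[float, float] = regime.ANALYSIS_WINDOW_MS,
    keep_bins: bool = False,
) -> Pseudopopulation:
    """Rebuild the pseudopopulation after excluding flagged images.

    ``flagged_image_ids`` defaults to each session's ``content_flag``
    column (images containing faces and/or body parts). Subselection and
    alignment are re-run from scratch on the unflagged subset.
    """
    filtered = []
    for sess, unit_idx in screened:
        if flagged_image_ids is None:
            flags = set(sess.images.loc[sess.images["content_flag"], "image_id"])
        else:
            flags = flagged_image_ids
        keep = ~sess.trials["image_id"].isin(flags).to_numpy()
        if not keep.any():
            raise ValueError(f"all images flagged in {sess.session_id}")
        trials = sess.trials.loc[keep].reset_index(drop=True)
        counts = sess.counts[keep]
        images = sess.images[~sess.images["image_id"].isin(flags)].reset_index(
            drop=True
        )
        filtered.append(
            (
                replace_session(sess, trials=trials, counts=counts, images=images),
                unit_idx,
            )
        )
    return align_sessions(filtered, window_ms=window_ms, keep_bins=keep_bins)


def replace_session(sess: SessionRecording, **changes) -> SessionRecording:
    """Shallow copy of a session with selected fields replaced."""
    fields = dict(
        session_id=sess.session_id,
        session_index=sess.session_index,
        seed=sess.seed,
        unit_ids=sess.unit_ids,
        bin_edges_ms=sess.bin_edges_ms,
        trials=sess.trials,
        counts=sess.counts,
        images=sess.images,
        config=sess.config,
        responsive_truth=sess.responsive_truth,
    )
    fields.update(changes)
    return SessionRecording(**fields)
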