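"""Reference recording-study conditions.

Constants describing the shape of the multi-session inferotemporal (IT)
recording study the pipeline targets: two animals performing a
single-exposure visual memory task while ~26-unit populations were
recorded per session. These values are used as synthetic-generator
defaults and as the shapes of equivalently structured fixtures; none of
them is an analysis result.
"""

from __future__ import annotations

#: Sessions recorded per animal.
SESSIONS_RECORDED = {"monkey1": 21, "monkey2": 16}

#: Sessions removed per QC criterion (stability, responsiveness, pair count).
SESSIONS_REMOVED_BY_CRITERION = {"monkey1": (2, 2, 2), "monkey2": (1, 2, 1)}

#: Candidate units identified by spike sorting, per animal.
CANDIDATE_UNITS = {"monkey1": 403, "monkey2": 396}

#: Units surviving the evoked-activity screen (two-sided t-test, p < 0.01).
SCREENED_UNITS = {"monkey1": 353, "monkey2": 354}

#: Novel/familiar delay levels, in intervening trials.
N_BACK_LEVELS = (1, 2, 4, 8, 16, 32, 64)

#: Aligned image slots per n-back level in the pooled pseudopopulation.
SLOTS_PER_NBACK = {1: 15, 2: 15, 4: 16, 8: 17, 16: 17, 32: 15, 64: 12}

#: Total aligned image slots (sums SLOTS_PER_NBACK).
N_IMAGES = sum(SLOTS_PER_NBACK.values())

#: Mean recorded population size per session.
MEAN_UNITS_PER_SESSION = 26

#: Spike-count analysis window, ms after stimulus onset.
ANALYSIS_WINDOW_MS = (180.0, 260.0)


def sessions_retained(animal: str | None = None) -> int:
    """Sessions surviving QC: recorded minus removals, summed over animals."""
    animals = [animal] if animal is not None else sorted(SESSIONS_RECORDED)
    return sum(
        SESSIONS_RECORDED[a] - sum(SESSIONS_REMOVED_BY_CRITERION[a]) for a in animals
    )


def screened_units_total() -> int:
    """Units entering the pseudopopulation, pooled over animals."""
    return sum(SCREENED_UNITS.values())


def units_per_session_schedule() -> list[int]:
    """Per-session screened unit counts consistent with the study totals.

    Distributes each animal's screened units as evenly as possible over its
    retained sessions (the study reports only the totals and the mean).
    """
    sizes: list[int] = []
    for animal in sorted(SESSIONS_RECORDED):
        n_sessions = sessions_retained(animal)
        total = SCREENED_UNITS[animal]
        base, extra = divmod(total, n_sessions)
        sizes.extend([base + 1] * extra + [base] * (n_sessions - extra))
    return sizes
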