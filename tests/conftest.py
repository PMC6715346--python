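import numpy as np
import pandas as pd
import pytest

from popmag.synthetic import GeneratorConfig, SessionRecording, generate_sessions


@pytest.fixture(scope="session")
def tiny_sessions():
    """Three small sessions, all pairs completed (fast, deterministic)."""
    cfg = GeneratorConfig(
        n_sessions=3,
        units_per_session=(8, 10, 9),
        images_per_session=28,
        completion_prob=1.0,
        seed=11,
    )
    return generate_sessions(cfg)


@pytest.fixture(scope="session")
def qc_sessions():
    """Two sessions large enough to pass all three session QC criteria."""
    cfg = GeneratorConfig(
        n_sessions=2,
        units_per_session=(12, 14),
        images_per_session=115,
        completion_prob=1.0,
        seed=13,
    )
    return generate_sessions(cfg)


def manual_session(session_id, session_index, unit_count, pair_spec, counts_by_trial):
    """Hand-built session: one 80 ms bin covering the analysis window.

    ``pair_spec``: list of (image_id, memorability, n_back, content_flag).
    ``counts_by_trial``: dict (image_id, exposure) -> per-unit counts.
    Trials are laid out novel-first in pair order (positions are only
    identifiers for alignment; separations are not re-derived from them).
    """
    rows = []
    pos = 0
    for image_id, _m, nb, _f in pair_spec:
        rows.append((pos, image_id, "novel", nb))
        pos += 1
    for image_id, _m, nb, _f in pair_spec:
        rows.append((pos, image_id, "familiar", nb))
        pos += 1
    trials = pd.DataFrame(
        rows, columns=["trial_index", "image_id", "exposure", "n_back"]
    )
    counts = np.array(
        [
            counts_by_trial[(img, exp)]
            for img, exp in zip(trials["image_id"], trials["exposure"])
        ],
        dtype=float,
    )[:, :, None]
    images = pd.DataFrame(
        {
            "image_id": [p[0] for p in pair_spec],
            "memorability": [p[1] for p in pair_spec],
            "content_flag": [p[3] for p in pair_spec],
        }
    )
    return SessionRecording(
        session_id=session_id,
        session_index=session_index,
        seed=0,
        unit_ids=[f"{session_id}_u{u}" for u in range(unit_count)],
        bin_edges_ms=np.array([180.0, 260.0]),
        trials=trials,
        counts=counts,
        images=images,
    )
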