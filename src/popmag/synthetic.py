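"""Synthetic multi-session recordings, behavior, images and activations.

The generator emulates the structure of a single-exposure visual memory
experiment: per session, a population of units is recorded while images
are shown once as *novel* and exactly once more as *familiar* after a
delay of n intervening trials (n-back in {1, 2, 4, 8, 16, 32, 64}).
Spike counts are Poisson around a rate that is flat before stimulus
onset and, from a fixed latency onward, scaled by an image-specific gain

    gain(image) = max(0, 1 + beta * (m - m_bar)) * L,

where ``m`` is the image's memorability score in [0, 1], ``beta`` is the
memorability-magnitude coupling, and ``L`` is a lognormal content gain
capturing image-driven response variation unrelated to memorability.
Familiar presentations are suppressed by a fixed fraction (repetition
suppression). Binary familiarity reports are correct with probability
0.5 + m * (ceiling - 0.5): chance at memorability 0, ceiling at 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from popmag import regime
from popmag._streams import stream

__all__ = [
    "GeneratorConfig",
    "SessionRecording",
    "LayerMagnitudeProfile",
    "generate_sessions",
    "generate_behavior",
    "generate_layer_activations",
    "generate_test_images",
    "make_source_data_tables",
]

_EXPOSURES = ("novel", "familiar")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic recording generator.

    Defaults reproduce the reference recording regime: 27 sessions of
    ~26 units, novel/familiar pairs at seven n-back levels, a 6%
    familiar-response suppression, and a memorability-magnitude coupling
    whose pooled pseudopopulation correlation lands near the regime the
    pipeline is designed to detect (slot magnitudes spanning ~20%).
    """

    n_sessions: int = 27
    units_per_session_mean: float = float(regime.MEAN_UNITS_PER_SESSION)
    #: Exact per-session unit counts; overrides the Poisson draw when set.
    units_per_session: tuple[int, ...] | None = None
    images_per_session: int = 140
    n_back_levels: tuple[int, ...] = regime.N_BACK_LEVELS
    bin_width_ms: float = 20.0
    trial_window_ms: tuple[float, float] = (-200.0, 400.0)
    baseline_rate_range: tuple[float, float] = (2.0, 10.0)
    #: Multiplicative evoked response of a visually responsive unit.
    evoked_gain: float = 2.0
    #: Evoked activity begins this long after stimulus onset.
    evoked_latency_ms: float = 80.0
    #: beta: dimensionless memorability-to-gain coupling (>= 0).
    magnitude_coupling: float = 0.2
    #: Lognormal sd of the image-specific content gain L.
    image_gain_sd: float = 0.25
    #: Proportional reduction of the evoked response on familiar trials.
    suppression_fraction: float = 0.06
    #: Fraction of units with stimulus-evoked activity.
    responsive_fraction: float = 0.88
    #: Probability a scheduled novel/familiar pair is completed.
    completion_prob: float = 0.93
    #: Probability an image contains a face and/or body part.
    content_flag_prob: float = 0.19
    behavioral_ceiling: float = 1.0
    noise_model: str = "poisson"
    #: Optional global image scores shared by all sessions.
    memorability_scores: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_sessions <= 0:
            raise ValueError("n_sessions must be positive")
        if self.units_per_session_mean <= 0:
            raise ValueError("units_per_session_mean must be positive")
        if self.units_per_session is not None:
            if len(self.units_per_session) != self.n_sessions:
                raise ValueError("units_per_session length must equal n_sessions")
            if any(u <= 0 for u in self.units_per_session):
                raise ValueError("units_per_session entries must be positive")
        if self.images_per_session <= 0 and self.memorability_scores is None:
            raise ValueError("images_per_session must be positive")
        if len(self.n_back_levels) == 0 or any(n < 1 for n in self.n_back_levels):
            raise ValueError("n_back_levels must be positive counts")
        if self.bin_width_ms <= 0:
            raise ValueError("bin_width_ms must be positive")
        start, end = self.trial_window_ms
        span = end - start
        if span <= 0:
            raise ValueError("trial_window_ms must be a nonempty interval")
        n_bins = span / self.bin_width_ms
        if abs(n_bins - round(n_bins)) > 1e-9:
            raise ValueError("bin_width_ms must tile trial_window_ms exactly")
        lo, hi = self.baseline_rate_range
        if lo < 0 or hi < lo:
            raise ValueError("baseline_rate_range must be nonnegative and ordered")
        if self.evoked_gain < 0:
            raise ValueError("evoked_gain must be nonnegative")
        if self.magnitude_coupling < 0:
            raise ValueError("magnitude_coupling (beta) must be >= 0")
        if self.image_gain_sd < 0:
            raise ValueError("image_gain_sd must be nonnegative")
        if not (0 <= self.suppression_fraction < 1):
            raise ValueError("suppression_fraction must lie in [0, 1)")
        if not (0 <= self.responsive_fraction <= 1):
            raise ValueError("responsive_fraction must lie in [0, 1]")
        if not (0 < self.completion_prob <= 1):
            raise ValueError("completion_prob must lie in (0, 1]")
        if not (0 <= self.content_flag_prob <= 1):
            raise ValueError("content_flag_prob must lie in [0, 1]")
        if not (0.5 <= self.behavioral_ceiling <= 1):
            raise ValueError("behavioral_ceiling must lie in [0.5, 1]")
        if self.noise_model != "poisson":
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.memorability_scores is not None:
            scores = np.asarray(self.memorability_scores, dtype=float)
            if scores.size == 0 or np.any(scores < 0) or np.any(scores > 1):
                raise ValueError("memorability_scores must be nonempty, in [0, 1]")

    @property
    def bin_edges_ms(self) -> np.ndarray:
        start, end = self.trial_window_ms
        n_bins = round((end - start) / self.bin_width_ms)
        return start + self.bin_width_ms * np.arange(n_bins + 1)

    @property
    def score_center(self) -> float:
        """m_bar: the mean of the configured memorability distribution."""
        if self.memorability_scores is not None:
            return float(np.mean(self.memorability_scores))
        return 0.5


@dataclass
class SessionRecording:
    """One session's units, trials and binned spike counts."""

    session_id: str
    session_index: int
    seed: int
    unit_ids: list[str]
    bin_edges_ms: np.ndarray
    #: trial_index, image_id, exposure, n_back (familiar rows only).
    trials: pd.DataFrame
    #: (n_trials, n_units, n_bins) nonnegative integer counts.
    counts: np.ndarray
    #: image_id, memorability, content_flag (and gain_noise when synthetic).
    images: pd.DataFrame
    config: GeneratorConfig | None = None
    #: Ground-truth responsiveness flags (synthetic sessions only).
    responsive_truth: np.ndarray | None = None

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_pairs(self) -> int:
        """Completed novel/familiar pairs (= number of familiar trials)."""
        return int((self.trials["exposure"] == "familiar").sum())

    def memorability_of(self, image_ids) -> np.ndarray:
        scores = self.images.set_index("image_id")["memorability"]
        return scores.loc[list(image_ids)].to_numpy(dtype=float)

    def bin_slice(self, window_ms: tuple[float, float]) -> slice:
        """Index slice of the bins tiling ``window_ms`` exactly."""
        starts = self.bin_edges_ms[:-1]
        lo, hi = window_ms
        tol = 1e-9
        i0 = np.flatnonzero(np.abs(starts - lo) < tol)
        i1 = np.flatnonzero(np.abs(self.bin_edges_ms - hi) < tol)
        if i0.size != 1 or i1.size != 1 or i1[0] <= i0[0]:
            raise ValueError(
                f"window {window_ms} is not representable by whole bins "
                f"(edges {self.bin_edges_ms[0]}..{self.bin_edges_ms[-1]} "
                f"step {self.bin_edges_ms[1] - self.bin_edges_ms[0]})"
            )
        return slice(int(i0[0]), int(i1[0]))

    def window_counts(self, window_ms: tuple[float, float]) -> np.ndarray:
        """(n_trials, n_units) spike counts summed over ``window_ms``."""
        sl = self.bin_slice(window_ms)
        return self.counts[:, :, sl].sum(axis=2)


def _schedule_pairs(n_backs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Place each pair at positions (i, i + n_back + 1), both free.

    Greedy earliest-fit over a random image order; separations are exact
    by construction. Returns an (n_pairs, 2) array of trial positions.
    """
    order = rng.permutation(len(n_backs))
    occupied: set[int] = set()
    pos = np.empty((len(n_backs), 2), dtype=int)
    for idx in order:
        gap = int(n_backs[idx]) + 1
        i = 0
        while i in occupied or (i + gap) in occupied:
            i += 1
        occupied.update((i, i + gap))
        pos[idx] = (i, i + gap)
    return pos


def _session_images(config: GeneratorConfig, s: int) -> pd.DataFrame:
    """Image table for session ``s``: ids, scores, content gains, flags."""
    if config.memorability_scores is not None:
        n = len(config.memorability_scores)
        ids = [f"img{i:04d}" for i in range(n)]
        scores = np.asarray(config.memorability_scores, dtype=float)
        # Content gain and flags are properties of the image itself: keyed
        # by image index, identical in every session.
        g = stream(config.seed, "image_gain")
        z = g.standard_normal(n)
        flags = g.random(n) < config.content_flag_prob
    else:
        n = config.images_per_session
        ids = [f"s{s:02d}_img{i:03d}" for i in range(n)]
        g = stream(config.seed, "images", s)
        scores = g.random(n)
        z = g.standard_normal(n)
        flags = g.random(n) < config.content_flag_prob
    sd = config.image_gain_sd
    gain_noise = np.exp(sd * z - 0.5 * sd * sd)
    return pd.DataFrame(
        {
            "image_id": ids,
            "memorability": scores,
            "gain_noise": gain_noise,
            "content_flag": flags,
        }
    )


def _generate_one_session(config: GeneratorConfig, s: int) -> SessionRecording:
    unit_rng = stream(config.seed, "units", s)
    if config.units_per_session is not None:
        n_units = int(config.units_per_session[s])
    else:
        n_units = max(1, int(unit_rng.poisson(config.units_per_session_mean)))
    base = unit_rng.uniform(*config.baseline_rate_range, size=n_units)
    responsive = unit_rng.random(n_units) < config.responsive_fraction

    images = _session_images(config, s)
    sched_rng = stream(config.seed, "schedule", s)
    completed = sched_rng.random(len(images)) < config.completion_prob
    images = images.loc[completed].reset_index(drop=True)
    if len(images) == 0:
        raise ValueError("no completed image pairs in session; raise completion_prob")
    levels = np.asarray(config.n_back_levels)
    n_backs = np.resize(levels, len(images))  # round-robin over levels...
    sched_rng.shuffle(n_backs)  # ...in random image order

    positions = _schedule_pairs(n_backs, sched_rng)
    rows = []
    for i, image_id in enumerate(images["image_id"]):
        rows.append((positions[i, 0], image_id, "novel", n_backs[i]))
        rows.append((positions[i, 1], image_id, "familiar", n_backs[i]))
    trials = pd.DataFrame(
        rows, columns=["trial_index", "image_id", "exposure", "n_back"]
    ).sort_values("trial_index", ignore_index=True)

    # Image gain: coupling to memorability times content noise, floored at 0.
    beta = config.magnitude_coupling
    m = images.set_index("image_id")["memorability"]
    coupling = np.maximum(0.0, 1.0 + beta * (m - config.score_center))
    gain = (coupling * images.set_index("image_id")["gain_noise"]).to_dict()

    trial_gain = np.array([gain[i] for i in trials["image_id"]])
    fam = (trials["exposure"] == "familiar").to_numpy()
    trial_gain = trial_gain * np.where(fam, 1.0 - config.suppression_fraction, 1.0)

    # Evoked multiplier per (trial, unit): responsive units express the
    # evoked gain and the image gain; others stay at baseline throughout.
    mult = np.ones((len(trials), n_units))
    mult[:, responsive] = config.evoked_gain * trial_gain[:, None]

    edges = config.bin_edges_ms
    evoked_bins = edges[:-1] >= config.evoked_latency_ms
    rate = base[None, :, None] * (
        1.0 + (mult - 1.0)[:, :, None] * evoked_bins[None, None, :]
    )
    count_rng = stream(config.seed, "counts", s)
    counts = count_rng.poisson(rate * (config.bin_width_ms / 1000.0))

    return SessionRecording(
        session_id=f"session{s:02d}",
        session_index=s,
        seed=config.seed,
        unit_ids=[f"session{s:02d}_u{u:03d}" for u in range(n_units)],
        bin_edges_ms=edges,
        trials=trials,
        counts=counts,
        images=images,
        config=config,
        responsive_truth=responsive,
    )


def generate_sessions(config: GeneratorConfig) -> list[SessionRecording]:
    """Generate ``config.n_sessions`` independent session recordings.

    Deterministic: identical configs give bit-identical sessions. Each
    session draws from named substreams of ``config.seed``, so the trial
    schedule, spike counts and (later) behavior are independent streams.
    """
    return [_generate_one_session(config, s) for s in range(config.n_sessions)]


def generate_behavior(
    sessions: list[SessionRecording],
    behavioral_ceiling: float | None = None,
) -> pd.DataFrame:
    """Sample binary familiarity reports for every familiar trial.

    P(correct) = 0.5 + m * (ceiling - 0.5): chance for memorability 0,
    ceiling for memorability 1. Returns one row per (session, image):
    session_id, image_id, n_back, memorability, correct. Also annotates
    each session's familiar trials with a ``report_correct`` column.
    """
    frames = []
    for sess in sessions:
        ceiling = behavioral_ceiling
        if ceiling is None:
            ceiling = sess.config.behavioral_ceiling if sess.config else 1.0
        if not (0.5 <= ceiling <= 1.0):
            raise ValueError("behavioral_ceiling must lie in [0.5, 1]")
        fam = sess.trials[sess.trials["exposure"] == "familiar"]
        m = sess.memorability_of(fam["image_id"])
        p = 0.5 + m * (ceiling - 0.5)
        rng = stream(sess.seed, "behavior", sess.session_index)
        correct = (rng.random(len(fam)) < p).astype(int)
        sess.trials.loc[fam.index, "report_correct"] = correct
        frames.append(
            pd.DataFrame(
                {
                    "session_id": sess.session_id,
                    "image_id": fam["image_id"].to_numpy(),
                    "n_back": fam["n_back"].to_numpy(),
                    "memorability": m,
                    "correct": correct,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class LayerMagnitudeProfile:
    """Per-layer, per-image activation magnitudes for one network condition."""

    condition: str
    layer_names: list[str]
    #: (n_images, n_layers) L2 magnitudes.
    magnitudes: np.ndarray
    memorability: np.ndarray

    def __post_init__(self):
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        self.memorability = np.asarray(self.memorability, dtype=float)
        if self.magnitudes.shape != (len(self.memorability), len(self.layer_names)):
            raise ValueError("magnitudes must be (n_images, n_layers)")
        if not np.all(np.isfinite(self.magnitudes)):
            raise ValueError("magnitudes must be finite")


def generate_layer_activations(
    n_images: int,
    n_layers: int,
    coupling_by_layer,
    seed: int = 0,
    units_per_layer: int = 128,
    activation_noise_sd: float = 0.3,
) -> tuple[LayerMagnitudeProfile, LayerMagnitudeProfile]:
    """Synthetic layer-magnitude profiles for two network conditions.

    The "coupled" condition couples each layer's per-image magnitude to
    memorability with the layer's beta (standing in for a task-trained
    network); the "uncoupled" condition uses beta = 0 at every layer
    (standing in for random initialization). Both share the same image
    scores but use independent noise streams.
    """
    if n_images < 0 or n_layers < 0 or units_per_layer <= 0:
        raise ValueError("counts must be nonnegative (units_per_layer positive)")
    betas = np.asarray(list(coupling_by_layer), dtype=float)
    if betas.shape != (n_layers,):
        raise ValueError("coupling_by_layer length must equal n_layers")
    if np.any(betas < 0):
        raise ValueError("coupling betas must be >= 0")

    scores = stream(seed, "activation_scores").random(n_images)
    layer_names = [f"layer{i + 1}" for i in range(n_layers)]
    sd = activation_noise_sd
    base = math.sqrt(units_per_layer)

    def magnitudes(condition: str, layer_betas: np.ndarray) -> np.ndarray:
        mags = np.empty((n_images, n_layers))
        for l, b in enumerate(layer_betas):
            noise_rng = stream(seed, f"activations_{condition}", l)
            noise = np.exp(sd * noise_rng.standard_normal(n_images) - 0.5 * sd * sd)
            mags[:, l] = base * np.maximum(0.0, 1.0 + b * (scores - 0.5)) * noise
        return mags

    coupled = LayerMagnitudeProfile(
        "coupled", layer_names, magnitudes("coupled", betas), scores
    )
    uncoupled = LayerMagnitudeProfile(
        "uncoupled", layer_names, magnitudes("uncoupled", np.zeros(n_layers)), scores
    )
    return coupled, uncoupled


def generate_test_images(n: int, side: int = 256, seed: int = 0) -> list[np.ndarray]:
    """Deterministic RGB test images: constant, mirror-symmetric, gradient
    and pseudo-random patterns, cycling in that order.

    Returns uint8 arrays of shape (side, side, 3). ``side`` must be at
    least 227 so the images survive 10-crop preprocessing.
    """
    if side < 227:
        raise ValueError("side must be >= 227 pixels")
    if n < 0:
        raise ValueError("n must be nonnegative")
    rng = stream(seed, "test_images")
    out: list[np.ndarray] = []
    for i in range(n):
        kind = i % 4
        if kind == 0:
            value = rng.integers(0, 256, size=3)
            img = np.broadcast_to(value, (side, side, 3)).astype(np.uint8)
        elif kind == 1:
            half = rng.integers(0, 256, size=(side, (side + 1) // 2, 3))
            img = np.concatenate([half, half[:, : side // 2][:, ::-1]], axis=1)
            img = img.astype(np.uint8)
        elif kind == 2:
            ramp = np.linspace(0, 255, side)
            img = np.broadcast_to(ramp[None, :, None], (side, side, 3))
            img = img.astype(np.uint8)
        else:
            img = rng.integers(0, 256, size=(side, side, 3)).astype(np.uint8)
        out.append(np.ascontiguousarray(img))
    return out


def make_source_data_tables(
    seed: int = 0,
    units_per_session: list[int] | None = None,
    n_images: int = regime.N_IMAGES,
    config: GeneratorConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Synthetic tables shaped like the published source-data layout.

    The published files contain the *already aligned* pseudopopulation:
    per-unit spike counts per image slot, averaged across novel and
    familiar presentations, plus per-image memorability scores, and a
    per-(session, image) binary behavioral table. This generator emits
    equivalently shaped synthetic tables (707 units x 107 images and
    27 x 107 behavioral records under the default study conditions).

    Returns ``(responses, scores, behavior)``: long-format
    (unit_id, image_id, count); (image_id, memorability);
    (session_id, image_id, memorability, correct).
    """
    if units_per_session is None:
        units_per_session = regime.units_per_session_schedule()
    if config is None:
        config = GeneratorConfig(seed=seed)
    rng = stream(seed, "source_data")

    scores = np.sort(rng.random(n_images))
    image_ids = [f"img{i + 1:03d}" for i in range(n_images)]
    beta = config.magnitude_coupling
    coupling = np.maximum(0.0, 1.0 + beta * (scores - 0.5))
    window_s = (regime.ANALYSIS_WINDOW_MS[1] - regime.ANALYSIS_WINDOW_MS[0]) / 1000.0
    sd = config.image_gain_sd

    resp_rows = []
    for s, n_units in enumerate(units_per_session):
        base = rng.uniform(*config.baseline_rate_range, size=n_units)
        noise = np.exp(sd * rng.standard_normal(n_images) - 0.5 * sd * sd)
        lam = (
            base[:, None]
            * config.evoked_gain
            * (coupling * noise)[None, :]
            * window_s
        )
        novel = rng.poisson(lam)
        familiar = rng.poisson(lam * (1.0 - config.suppression_fraction))
        counts = (novel + familiar) / 2.0
        for u in range(n_units):
            uid = f"session{s:02d}_u{u:03d}"
            for i, image_id in enumerate(image_ids):
                resp_rows.append((uid, image_id, counts[u, i]))
    responses = pd.DataFrame(resp_rows, columns=["unit_id", "image_id", "count"])

    scores_df = pd.DataFrame({"image_id": image_ids, "memorability": scores})

    ceiling = config.behavioral_ceiling
    beh_rows = []
    for s in range(len(units_per_session)):
        p = 0.5 + scores * (ceiling - 0.5)
        correct = (rng.random(n_images) < p).astype(int)
        for i, image_id in enumerate(image_ids):
            beh_rows.append((f"session{s:02d}", image_id, scores[i], correct[i]))
    behavior = pd.DataFrame(
        beh_rows, columns=["session_id", "image_id", "memorability", "correct"]
    )
    return responses, scores_df, behavior


def regime_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """The default study-condition configuration with a given seed."""
    return replace(GeneratorConfig(seed=seed), **overrides)
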