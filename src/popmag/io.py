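"""Table layouts, run configuration and the end-to-end pipeline.

Canonical table dialect: comma-delimited text with a one-line header.

Layouts:

- session (long): session_id, trial_index, image_id, exposure, n_back,
  unit_id, bin_start_ms, count — plus a JSON sidecar with the generator
  config, seed, bin edges and the per-image score table.
- source data: responses (unit_id, image_id, count) with counts averaged
  across novel and familiar presentations; scores (image_id,
  memorability); behavior (session_id, image_id, memorability, correct).
- pseudopopulation: a wide responses table (slot x unit), a slot
  metadata table, and a JSON sidecar (window, unit sessions).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from popmag import regime
from popmag.pseudopop import Pseudopopulation, build_pseudopopulation
from popmag.stats import (
    bin_behavior_for_plot,
    grand_mean_rate,
    magnitude_memorability_correlation,
    point_biserial,
    repetition_suppression,
)
from popmag.synthetic import GeneratorConfig, SessionRecording, generate_behavior, generate_sessions

__all__ = [
    "RunConfig",
    "write_session",
    "read_session",
    "write_pseudopop",
    "read_pseudopop",
    "read_source_data",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# session tables

def write_session(session: SessionRecording, out_dir: str | Path) -> Path:
    """Serialize one session as a long-format table plus a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_trials, n_units, n_bins = session.counts.shape
    starts = session.bin_edges_ms[:-1]

    trial_idx = np.repeat(session.trials["trial_index"].to_numpy(), n_units * n_bins)
    image_id = np.repeat(session.trials["image_id"].to_numpy(), n_units * n_bins)
    exposure = np.repeat(session.trials["exposure"].to_numpy(), n_units * n_bins)
    n_back = np.repeat(session.trials["n_back"].to_numpy(), n_units * n_bins)
    unit_id = np.tile(np.repeat(session.unit_ids, n_bins), n_trials)
    bin_start = np.tile(starts, n_trials * n_units)
    table = pd.DataFrame(
        {
            "session_id": session.session_id,
            "trial_index": trial_idx,
            "image_id": image_id,
            "exposure": exposure,
            "n_back": n_back,
            "unit_id": unit_id,
            "bin_start_ms": bin_start,
            "count": session.counts.ravel(),
        }
    )
    csv_path = out_dir / f"{session.session_id}.csv"
    table.to_csv(csv_path, index=False)

    sidecar = {
        "session_id": session.session_id,
        "session_index": session.session_index,
        "seed": session.seed,
        "unit_ids": list(session.unit_ids),
        "bin_edges_ms": [float(e) for e in session.bin_edges_ms],
        "images": session.images.to_dict(orient="list"),
        "config": None
        if session.config is None
        else dataclasses.asdict(session.config),
    }
    (out_dir / f"{session.session_id}.json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True)
    )
    return csv_path


def read_session(csv_path: str | Path) -> SessionRecording:
    """Read a session written by :func:`write_session`."""
    csv_path = Path(csv_path)
    sidecar = json.loads(csv_path.with_suffix(".json").read_text())
    table = pd.read_csv(csv_path)
    unit_ids = sidecar["unit_ids"]
    edges = np.asarray(sidecar["bin_edges_ms"], dtype=float)
    n_bins = len(edges) - 1

    trials = (
        table[["trial_index", "image_id", "exposure", "n_back"]]
        .drop_duplicates("trial_index")
        .sort_values("trial_index", ignore_index=True)
    )
    n_trials = len(trials)
    unit_pos = {u: i for i, u in enumerate(unit_ids)}
    start_pos = {s: i for i, s in enumerate(edges[:-1])}
    counts = np.zeros((n_trials, len(unit_ids), n_bins), dtype=int)
    trial_pos = {t: i for i, t in enumerate(trials["trial_index"])}
    counts[
        table["trial_index"].map(trial_pos),
        table["unit_id"].map(unit_pos),
        table["bin_start_ms"].map(start_pos),
    ] = table["count"]

    config = sidecar.get("config")
    if config is not None:
        for key in ("n_back_levels", "trial_window_ms", "baseline_rate_range",
                    "units_per_session", "memorability_scores"):
            if config.get(key) is not None:
                config[key] = tuple(config[key])
        config = GeneratorConfig(**config)
    return SessionRecording(
        session_id=sidecar["session_id"],
        session_index=sidecar["session_index"],
        seed=sidecar["seed"],
        unit_ids=unit_ids,
        bin_edges_ms=edges,
        trials=trials,
        counts=counts,
        images=pd.DataFrame(sidecar["images"]),
        config=config,
    )


# ---------------------------------------------------------------------------
# pseudopopulation tables

def write_pseudopop(pop: Pseudopopulation, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    responses = pd.DataFrame(pop.response, columns=pop.unit_ids)
    responses.insert(0, "slot", np.arange(pop.n_slots))
    responses.to_csv(out_dir / "responses.csv", index=False)
    pop.slot_frame().to_csv(out_dir / "slots.csv", index=False)
    meta = {
        "window_ms": list(pop.window_ms),
        "unit_sessions": list(pop.unit_sessions),
    }
    (out_dir / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_pseudopop(in_dir: str | Path) -> Pseudopopulation:
    in_dir = Path(in_dir)
    responses = pd.read_csv(in_dir / "responses.csv")
    slots = pd.read_csv(in_dir / "slots.csv")
    meta = json.loads((in_dir / "meta.json").read_text())
    unit_ids = [c for c in responses.columns if c != "slot"]
    return Pseudopopulation(
        response=responses[unit_ids].to_numpy(dtype=float),
        memorability=slots["memorability"].to_numpy(dtype=float),
        n_back=slots["n_back"].to_numpy(dtype=int),
        window_ms=tuple(meta["window_ms"]),
        unit_ids=unit_ids,
        unit_sessions=list(meta["unit_sessions"]),
        score_sd=slots["score_sd"].to_numpy(dtype=float)
        if "score_sd" in slots
        else None,
    )


# ---------------------------------------------------------------------------
# source-data layout

def _load_table(table, required: tuple[str, ...], name: str) -> pd.DataFrame:
    if not isinstance(table, pd.DataFrame):
        path = Path(table)
        if not path.exists():
            raise FileNotFoundError(f"{name} table not found: {path}")
        table = pd.read_csv(path)
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"{name} table is missing column(s) {missing}")
    return table


def read_source_data(
    responses, scores, behavior=None
) -> tuple[Pseudopopulation, pd.DataFrame | None]:
    """Read and validate tables in the published source-data layout.

    ``responses``: long (unit_id, image_id, count), counts averaged over
    novel and familiar presentations; ``scores``: (image_id,
    memorability); ``behavior`` (optional): (session_id, image_id,
    correct [, memorability]). Paths or DataFrames. n-back labels are
    not part of this layout; slots carry the sentinel -1.
    """
    responses = _load_table(responses, ("unit_id", "image_id", "count"), "responses")
    scores = _load_table(scores, ("image_id", "memorability"), "scores")

    bad = scores.index[
        (scores["memorability"] < 0) | (scores["memorability"] > 1)
    ].tolist()
    if bad:
        raise ValueError(
            f"memorability scores outside [0, 1] at row(s) {bad[:5]} "
            f"of the scores table"
        )
    bad = responses.index[responses["count"] < 0].tolist()
    if bad:
        raise ValueError(f"negative counts at row(s) {bad[:5]} of the responses table")
    dup = responses.duplicated(["unit_id", "image_id"])
    if dup.any():
        raise ValueError(
            f"duplicate (unit_id, image_id) entries at row(s) "
            f"{responses.index[dup].tolist()[:5]}"
        )
    unknown = set(responses["image_id"]) - set(scores["image_id"])
    if unknown:
        raise ValueError(f"images without scores: {sorted(unknown)[:5]}")

    wide = responses.pivot(index="image_id", columns="unit_id", values="count")
    if wide.isna().any().any():
        raise ValueError("responses table is not a complete unit x image grid")
    score_map = scores.set_index("image_id")["memorability"]
    wide = wide.loc[score_map.index.intersection(wide.index)]

    unit_ids = list(wide.columns)
    unit_sessions = [u.rsplit("_", 1)[0] if "_" in u else "unknown" for u in unit_ids]
    pop = Pseudopopulation(
        response=wide.to_numpy(dtype=float),
        memorability=score_map.loc[wide.index].to_numpy(dtype=float),
        n_back=np.full(len(wide), -1),
        window_ms=regime.ANALYSIS_WINDOW_MS,
        unit_ids=unit_ids,
        unit_sessions=unit_sessions,
    )

    beh = None
    if behavior is not None:
        beh = _load_table(behavior, ("session_id", "image_id", "correct"), "behavior")
        if not set(np.unique(beh["correct"])) <= {0, 1}:
            raise ValueError("behavior 'correct' column must be binary 0/1")
        if "memorability" not in beh.columns:
            beh = beh.merge(scores, on="image_id", how="left")
    return pop, beh


# ---------------------------------------------------------------------------
# run configuration and pipeline

@dataclasses.dataclass
class RunConfig:
    """Everything a full pipeline run needs, serializable to YAML/JSON."""

    generator: GeneratorConfig = dataclasses.field(default_factory=GeneratorConfig)
    window_ms: tuple[float, float] = regime.ANALYSIS_WINDOW_MS
    stability_max_ratio: float = 2.0
    responsive_fraction_min: float = 0.5
    min_pairs: int = 100
    unit_alpha: float = 0.01
    responsive_alpha: float = 0.05
    behavior_bins: int = 10
    exclude_top_fraction: float = 0.05
    bootstrap_replicates: int = 10_000
    #: Optional source-data inputs; when set, simulation is skipped.
    input_responses: str | None = None
    input_scores: str | None = None
    input_behavior: str | None = None

    def __post_init__(self):
        if not (0 < self.unit_alpha < 1) or not (0 < self.responsive_alpha < 1):
            raise ValueError("alphas must lie in (0, 1)")
        if self.stability_max_ratio <= 1:
            raise ValueError("stability_max_ratio must exceed 1")
        if not (0 <= self.responsive_fraction_min <= 1):
            raise ValueError("responsive_fraction_min must lie in [0, 1]")
        if self.min_pairs < 1 or self.behavior_bins < 1:
            raise ValueError("min_pairs and behavior_bins must be >= 1")
        if not (0 <= self.exclude_top_fraction < 1):
            raise ValueError("exclude_top_fraction must lie in [0, 1)")
        if self.bootstrap_replicates < 1:
            raise ValueError("bootstrap_replicates must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window_ms"] = list(self.window_ms)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        gen = d.get("generator") or {}
        if not isinstance(gen, GeneratorConfig):
            for key in ("n_back_levels", "trial_window_ms", "baseline_rate_range",
                        "units_per_session", "memorability_scores"):
                if gen.get(key) is not None:
                    gen[key] = tuple(gen[key])
            gen = GeneratorConfig(**gen)
        d["generator"] = gen
        if "window_ms" in d:
            d["window_ms"] = tuple(d["window_ms"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=1, sort_keys=True)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=True)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Simulate (or load) -> screen -> build -> analyze -> report.

    Writes result tables, a JSON summary and a manifest (config, seeds
    and output hashes) under ``out_dir``; reruns with the same config
    are byte-identical. Returns the summary as a dict.
    """
    from popmag import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_seed": config.generator.seed}

    if config.input_responses is not None:
        if config.input_scores is None:
            raise ValueError("input_scores is required with input_responses")
        pop, behavior = read_source_data(
            config.input_responses, config.input_scores, config.input_behavior
        )
        summary["stage"] = "loaded source data"
        screen_frame = None
    else:
        sessions = generate_sessions(config.generator)
        behavior = generate_behavior(sessions)
        pop, report = build_pseudopopulation(
            sessions,
            window_ms=config.window_ms,
            keep_bins=False,
            stability_max_ratio=config.stability_max_ratio,
            responsive_fraction_min=config.responsive_fraction_min,
            min_pairs=config.min_pairs,
            unit_alpha=config.unit_alpha,
            responsive_alpha=config.responsive_alpha,
        )
        retained_ids = {
            s.session_id for s, scr in zip(sessions, report.sessions) if scr.passed
        }
        behavior = behavior[behavior["session_id"].isin(retained_ids)].reset_index(
            drop=True
        )
        summary["screening"] = report.summary()
        screen_frame = report.session_frame()

    summary["n_units"] = pop.n_units
    summary["n_image_slots"] = pop.n_slots

    mag = magnitude_memorability_correlation(pop)
    gmr = grand_mean_rate(pop)
    summary["magnitude"] = {
        "window_ms": list(mag.window_ms),
        "r": mag.r,
        "p": mag.p,
        "slope": mag.slope,
        "intercept": mag.intercept,
        # max/min slot magnitude minus 1: this package's definition of the
        # proportional magnitude spread across images.
        "magnitude_spread": mag.magnitude_spread,
    }
    summary["grand_mean_rate"] = {"r": gmr.r, "p": gmr.p}

    if pop.novel is not None and pop.familiar is not None:
        summary["repetition_suppression"] = repetition_suppression(
            pop.novel, pop.familiar
        )
        from popmag.stats import l2_magnitude  # split-condition controls
        from scipy import stats as sps

        for name, matrix in (("novel", pop.novel), ("familiar", pop.familiar)):
            r, p = sps.pearsonr(pop.memorability, l2_magnitude(matrix))
            summary[f"magnitude_{name}_only"] = {"r": float(r), "p": float(p)}

    if config.exclude_top_fraction > 0:
        from popmag.stats import exclude_top_rate_units

        reduced = exclude_top_rate_units(pop, config.exclude_top_fraction)
        red = magnitude_memorability_correlation(reduced)
        summary["excluding_top_rate_units"] = {
            "top_fraction": config.exclude_top_fraction,
            "n_units": reduced.n_units,
            "r": red.r,
            "p": red.p,
        }

    if behavior is not None and len(behavior) > 0:
        r_pb, p_pb = point_biserial(
            behavior["memorability"].to_numpy(), behavior["correct"].to_numpy()
        )
        summary["behavior"] = {
            "n_records": int(len(behavior)),
            "point_biserial_r": r_pb,
            "p": p_pb,
        }
        binned = bin_behavior_for_plot(behavior, config.behavior_bins)
        binned.to_csv(out_dir / "behavior_binned.csv", index=False)

    slot_table = pop.slot_frame()
    slot_table["magnitude"] = mag.magnitudes
    slot_table["grand_mean_rate"] = gmr.rates
    slot_table.to_csv(out_dir / "magnitude_by_slot.csv", index=False)
    if screen_frame is not None:
        screen_frame.to_csv(out_dir / "session_screen.csv", index=False)

    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))

    outputs = sorted(
        p for p in out_dir.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "popmag_version": __version__,
        "config": config.to_dict(),
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return summary
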