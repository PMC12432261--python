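"""End-to-end pipeline: simulate → preprocess → rank montages → saccade
analysis → gaze-angle prediction, with deterministic artifacts.

A single global seed fans out to per-participant sub-seeds through a
counter scheme (``SeedSequence([seed, participant])``), so adding
participants never perturbs the data of existing ones.  Identical configs
produce bitwise-identical CSV outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, ValidationError

from . import __version__
from .core import GazeTrace, MultiChannelRecording, write_gaze_csv, write_recording_csv
from .montage import (
    HORIZONTAL_CANDIDATES,
    VERTICAL_CANDIDATES,
    CorrelationResult,
    MontagePair,
    PursuitTrial,
    fisher_mean,
    friedman_across_montages,
    pairwise_wilcoxon,
    rank_montages,
)
from .preprocess import bandpass_recording
from .prediction import bland_altman, evaluate_mae
from .saccades import deflection_table, extract_epochs, label_epochs
from .stimulus import StimulusSchedule, pursuit_schedule, saccade_schedule
from .synth import GOLD_HORIZONTAL, GOLD_VERTICAL, SynthConfig, default_layout, simulate_camera, simulate_recording

__all__ = [
    "PipelineConfig",
    "ParticipantData",
    "simulate_participant",
    "collect_pursuit_trials",
    "participant_mean_r_matrix",
    "run_pipeline",
    "participant_seed",
]


class PipelineConfig(BaseModel):
    """Validated configuration of one pipeline run."""

    seed: int = 0
    participants: int = Field(default=2, ge=1)
    cycles: int = Field(default=1, ge=1)
    synth: SynthConfig = SynthConfig()
    saccade_latency_s: float = Field(default=0.2, ge=0.0, le=1.0)
    horizontal_pairs: list[str] = Field(
        default_factory=lambda: [p.label for p in HORIZONTAL_CANDIDATES]
    )
    vertical_pairs: list[str] = Field(
        default_factory=lambda: [p.label for p in VERTICAL_CANDIDATES]
    )
    best_pair: str = "L8-R8"
    cv: str = "loo"

    def horizontal_candidates(self) -> list[MontagePair]:
        return [MontagePair.from_label(l, "horizontal") for l in self.horizontal_pairs]

    def vertical_candidates(self) -> list[MontagePair]:
        return [MontagePair.from_label(l, "vertical") for l in self.vertical_pairs]


def participant_seed(seed: int, participant_id: int) -> int:
    """Stable 31-bit sub-seed for one participant."""
    state = np.random.SeedSequence([seed, participant_id]).generate_state(1)[0]
    return int(state & 0x7FFFFFFF)


class ParticipantData:
    """Simulated session of one participant: pursuit and saccade runs."""

    def __init__(self, participant_id, pursuit, saccade):
        self.participant_id = participant_id
        # each entry: (schedule, recording, truth, camera)
        self.pursuit = pursuit
        self.saccade = saccade


def simulate_participant(
    config: PipelineConfig, participant_id: int, tasks=("pursuit", "saccade")
) -> ParticipantData:
    """Simulate both tasks for one participant with its fanned-out seed."""
    sub = participant_seed(config.seed, participant_id)
    layout = default_layout()
    runs = {}
    for task in tasks:
        synth = config.synth.model_copy(update={"rng_seed": participant_seed(sub, 0 if task == "pursuit" else 1)})
        if task == "pursuit":
            schedule = pursuit_schedule(cycles=config.cycles, seed=sub)
        else:
            schedule = saccade_schedule(cycles=config.cycles)
        recording, truth = simulate_recording(
            schedule, layout, synth, saccade_latency_s=config.saccade_latency_s
        )
        camera = simulate_camera(truth, synth)
        runs[task] = (schedule, recording, truth, camera)
    return ParticipantData(participant_id, runs.get("pursuit"), runs.get("saccade"))


def collect_pursuit_trials(
    recording: MultiChannelRecording,
    camera: GazeTrace,
    schedule: StimulusSchedule,
    orientation: str,
    participant_id: int = 0,
    gold_channel: str | None = None,
) -> list[PursuitTrial]:
    """Cut per-event pursuit trial windows matching an orientation.

    ``recording`` should already be band-pass filtered at ingest.
    """
    gold_channel = gold_channel or (
        GOLD_HORIZONTAL if orientation == "horizontal" else GOLD_VERTICAL
    )
    trials = []
    for event in schedule.events_of_kind("pursuit"):
        if event.axis != orientation:
            continue
        window = recording.slice_time(event.start_s, event.end_s)
        cam = camera.slice_time(event.start_s, event.end_s)
        trials.append(
            PursuitTrial(
                recording=window,
                gold=window.channels[gold_channel],
                camera=cam,
                event=event,
                participant_id=participant_id,
            )
        )
    return trials


def participant_mean_r_matrix(
    trials_by_participant: dict[int, list[PursuitTrial]],
    candidates,
    reference: str = "gold_eog",
) -> tuple[np.ndarray, list[str]]:
    """Participant × montage matrix of Fisher-mean correlations — the
    observation unit for the Friedman/Wilcoxon montage comparison."""
    candidates = list(candidates)
    labels = [c.label for c in candidates]
    rows = []
    for pid in sorted(trials_by_participant):
        results = rank_montages(trials_by_participant[pid], candidates, reference)
        by_label = {res.pair.label: res.mean_r for res in results}
        rows.append([by_label[l] for l in labels])
    return np.asarray(rows, dtype=float), labels


def _ranking_rows(results: list[CorrelationResult], orientation: str) -> list[dict]:
    rows = []
    for rank, res in enumerate(results, start=1):
        rows.append(
            {
                "orientation": orientation,
                "reference": res.reference,
                "rank": rank,
                "channel_a": res.pair.channel_a,
                "channel_b": res.pair.channel_b,
                "n_trials": len(res.per_trial_r),
                "mean_r": res.mean_r,
                "mean_lag_samples": res.mean_lag_samples,
            }
        )
    return rows


def run_pipeline(config: PipelineConfig | dict, out_dir: str | Path) -> Path:
    """Run the full analysis and write CSV/JSON artifacts plus a manifest.

    Artifacts: ``ranking.csv`` (montage correlations per orientation and
    reference), ``montage_stats.csv`` (Friedman and post-hoc summaries),
    ``epochs.csv`` (per-saccade deflections), ``mae_report.csv`` (MAE per
    model × direction × amplitude), ``bland_altman.csv`` and
    ``manifest.json``.
    """
    if isinstance(config, dict):
        config = PipelineConfig(**config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    participants = [
        simulate_participant(config, pid) for pid in range(config.participants)
    ]

    # ---- montage ranking on pursuit data
    candidates = {
        "horizontal": config.horizontal_candidates(),
        "vertical": config.vertical_candidates(),
    }
    trials: dict[str, dict[int, list[PursuitTrial]]] = {"horizontal": {}, "vertical": {}}
    for pdata in participants:
        schedule, recording, _truth, camera = pdata.pursuit
        filtered = bandpass_recording(recording)
        for orientation in ("horizontal", "vertical"):
            trials[orientation][pdata.participant_id] = collect_pursuit_trials(
                filtered, camera, schedule, orientation, pdata.participant_id
            )

    ranking_rows, stats_rows = [], []
    for orientation in ("horizontal", "vertical"):
        pooled = [t for ts in trials[orientation].values() for t in ts]
        for reference in ("gold_eog", "camera"):
            ranking_rows += _ranking_rows(
                rank_montages(pooled, candidates[orientation], reference), orientation
            )
            if len(participants) >= 2:
                matrix, labels = participant_mean_r_matrix(
                    trials[orientation], candidates[orientation], reference
                )
                fr = friedman_across_montages(matrix)
                stats_rows.append(
                    {
                        "orientation": orientation,
                        "reference": reference,
                        "test": "friedman",
                        "statistic": fr.statistic,
                        "p_value": fr.p_value,
                        "n": fr.n,
                    }
                )
                if fr.p_value < 0.05:
                    corrected = pairwise_wilcoxon(matrix)
                    for i in range(len(labels)):
                        for j in range(i + 1, len(labels)):
                            stats_rows.append(
                                {
                                    "orientation": orientation,
                                    "reference": reference,
                                    "test": f"wilcoxon:{labels[i]}|{labels[j]}",
                                    "statistic": float("nan"),
                                    "p_value": corrected[i, j],
                                    "n": matrix.shape[0],
                                }
                            )
    pd.DataFrame(ranking_rows).to_csv(out / "ranking.csv", index=False, float_format="%.9g")
    pd.DataFrame(stats_rows).to_csv(out / "montage_stats.csv", index=False, float_format="%.9g")

    # ---- saccade epochs and deflections
    all_pairs = candidates["horizontal"] + candidates["vertical"]
    epochs = []
    for pdata in participants:
        schedule, recording, _truth, _camera = pdata.saccade
        filtered = bandpass_recording(recording)
        eps, _skipped = extract_epochs(filtered, schedule, participant_id=pdata.participant_id)
        label_epochs(eps)
        epochs += eps
    table = deflection_table(epochs, all_pairs)
    table.to_csv(out / "epochs.csv", index=False, float_format="%.9g")

    # ---- gaze-angle prediction (horizontal only)
    feature_sets = {
        "best_pair": [config.best_pair],
        "all_pairs": [p.label for p in all_pairs],
        "gold_standard": [GOLD_HORIZONTAL],
    }
    horiz = table[(table["axis"] == "horizontal") & table["valid"]].copy()
    horiz = horiz.dropna(subset=sorted({f for fs in feature_sets.values() for f in fs}))
    cv = config.cv if config.participants >= 2 else "insample"
    mae_frames, predictions = [], {}
    for name, features in feature_sets.items():
        report, per = evaluate_mae(horiz, features, cv=cv)
        report.insert(0, "model", name)
        mae_frames.append(report)
        predictions[name] = per["predicted_deg"].to_numpy()
    pd.concat(mae_frames, ignore_index=True).to_csv(
        out / "mae_report.csv", index=False, float_format="%.9g"
    )

    ba_rows = []
    for name in ("best_pair", "all_pairs"):
        stats_ba = bland_altman(predictions[name], predictions["gold_standard"])
        ba_rows.append(
            {
                "comparison": f"{name}_vs_gold",
                "mean_diff_deg": stats_ba.mean_diff,
                "sd_diff_deg": stats_ba.sd_diff,
                "loa_low_deg": stats_ba.loa_low,
                "loa_high_deg": stats_ba.loa_high,
                "n": len(stats_ba.points),
            }
        )
        truth_ba = bland_altman(predictions[name], horiz["angle_change_deg"].to_numpy())
        ba_rows.append(
            {
                "comparison": f"{name}_vs_truth",
                "mean_diff_deg": truth_ba.mean_diff,
                "sd_diff_deg": truth_ba.sd_diff,
                "loa_low_deg": truth_ba.loa_low,
                "loa_high_deg": truth_ba.loa_high,
                "n": len(truth_ba.points),
            }
        )
    pd.DataFrame(ba_rows).to_csv(out / "bland_altman.csv", index=False, float_format="%.9g")

    config_json = config.model_dump_json(indent=1)
    manifest = {
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": config.seed,
        "eareog_version": __version__,
        "artifacts": sorted(
            p.name for p in out.iterdir() if p.suffix in (".csv",) and p.name != "manifest.json"
        ),
    }
    (out / "config.json").write_text(config_json + "\n")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return out
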