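"""End-to-end glue: raw visits -> preprocessed sessions -> datasets -> runs.

Also defines the *desk-scale* profile: a reduced-width model and a shorter
training schedule sized for single-CPU experiments and the test suite. The
published-scale hyperparameters remain the defaults of ``ModelConfig`` and
``TrainConfig``; desk scale only overrides widths, epochs and the learning
rate, and coarsens the training stride from 0.1 s to 0.3 s.
"""

from __future__ import annotations

import numpy as np

from .gait import labels_from_force, normalize_across_visits
from .model import ModelConfig, build_model
from .preprocess import preprocess_force, preprocess_lfp
from .synth import RawSession, SynthParams, generate_participant
from .training import TrainConfig, restore_best, train
from .windows import SessionRecord, chronological_split
from .evaluate import eval_report, variance_ratio

#: Reduced sizes for single-CPU experiments; see docs/methods.md.
DESK_SCALE_MODEL = dict(
    n_filters_per_lead=8, kernel_len=53, pool_len=53, pool_stride=40,
    se_reduction=4, lstm_hidden=12, lstm_layers=3, head_channels=8,
    head_kernel_len=5)
DESK_SCALE_TRAIN = dict(
    learning_rate=1e-3, batch_size=16, max_epochs=60, patience_epochs=15)
#: Training/validation windows are taken every 3rd stride (0.3 s) at desk
#: scale; test evaluation always uses the full 0.1-s grid.
DESK_SCALE_SUBSAMPLE = 3
#: Session length used for desk-scale synthetic participants (seconds).
DESK_SCALE_DURATION_S = 60.0


def desk_scale_configs(seed: int = 0) -> tuple[ModelConfig, TrainConfig]:
    return (ModelConfig(seed=seed, **DESK_SCALE_MODEL),
            TrainConfig(seed=seed, **DESK_SCALE_TRAIN))


def desk_scale_params(seed: int = 0, **overrides) -> SynthParams:
    """Synthetic-participant settings for desk-scale runs."""
    return SynthParams(duration_s=DESK_SCALE_DURATION_S, seed=seed,
                       **overrides)


def prepare_sessions(raw_sessions: list[RawSession],
                     lfp_band: tuple[float, float] = (8.0, 100.0),
                     force_cutoff_hz: float = 2.0
                     ) -> tuple[list[SessionRecord], float]:
    """Preprocess raw visits and attach cross-visit-normalized labels.

    Returns the session records and the participant-level label scaling
    constant (the maximum 2-s shift over the provided visits).
    """
    lfps = [preprocess_lfp(s.lfp, lfp_band[0], lfp_band[1])
            for s in raw_sessions]
    forces = [preprocess_force(s.force, force_cutoff_hz)
              for s in raw_sessions]
    raw_labels = [labels_from_force(f) for f in forces]
    labels, scale = normalize_across_visits(raw_labels)
    sessions = [
        SessionRecord(lfp=l, force=f, labels=lab,
                      visit_index=s.visit_index, contacts_id=s.contacts_id)
        for s, l, f, lab in zip(raw_sessions, lfps, forces, labels)]
    return sessions, scale


def prepare_datasets(raw_sessions: list[RawSession],
                     subsample: int = 1,
                     lfp_band: tuple[float, float] = (8.0, 100.0)) -> dict:
    """Chronological-split datasets from three raw visits.

    ``subsample`` coarsens the train/validation stride (test keeps the
    full 0.1-s grid). The returned dict also carries the session records
    and label scale for downstream analyses.
    """
    sessions, scale = prepare_sessions(raw_sessions, lfp_band=lfp_band)
    train_ds, val_ds, test_ds = chronological_split(sessions)
    if subsample > 1:
        train_ds = train_ds.subsample(subsample)
        val_ds = val_ds.subsample(subsample)
    by_visit = {s.visit_index: s for s in sessions}
    return {
        "train": train_ds, "validation": val_ds, "test": test_ds,
        "sessions": by_visit, "label_scale": scale,
        "train_session": by_visit[train_ds.visit_index],
        "validation_session": by_visit[val_ds.visit_index],
        "test_session": by_visit[test_ds.visit_index],
    }


def run_participant(raw_sessions: list[RawSession],
                    model_cfg: ModelConfig, train_cfg: TrainConfig,
                    subsample: int = 1, attribution: bool = False,
                    verbose: bool = False) -> dict:
    """Train one model on one participant and evaluate it end to end.

    Returns the trained model, training history, validation/test
    :class:`~n2gnet.evaluate.EvalReport` objects, and (optionally) the
    frequency-band variance-ratio report computed on the training visit.
    """
    data = prepare_datasets(raw_sessions, subsample=subsample)
    model = build_model(model_cfg)
    history = train(model, data["train"].inputs, data["train"].labels,
                    data["validation"].inputs, data["validation"].labels,
                    train_cfg, verbose=verbose)
    restore_best(model, history)
    result = {
        "model": model, "history": history, "data": data,
        "validation_report": eval_report(model, data["validation"],
                                         data["validation_session"].lfp),
        "test_report": eval_report(model, data["test"],
                                   data["test_session"].lfp),
    }
    if attribution:
        result["variance_ratio"] = variance_ratio(
            model, data["train_session"].lfp,
            data["train"].label_times_s)
    return result


def synthetic_participant(seed: int, desk_scale: bool = True,
                          **param_overrides) -> list[RawSession]:
    """Three chronologically indexed synthetic visits for one participant."""
    params = (desk_scale_params(seed=seed, **param_overrides)
              if desk_scale else SynthParams(seed=seed, **param_overrides))
    return generate_participant(params, n_visits=3)
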