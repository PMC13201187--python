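"""End-to-end orchestration: feature extraction and LOSO train/evaluate.

Used by the command-line interface and the acceptance script; all entry
points are pure functions of (sessions, configs, seed) so a run is
reproducible from its config alone.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from bcgsleep import evaluation as ev
from bcgsleep import features as ft
from bcgsleep import model as md
from bcgsleep.signal_io import Hypnogram, Session, STAGES, STAGES_3CLASS


@dataclasses.dataclass
class SessionFeatures:
    subject_id: str
    session_id: str
    matrix: ft.FeatureMatrix
    hypnogram: Optional[Hypnogram]


def extract_features(sessions: Sequence[Session]) -> list[SessionFeatures]:
    out = []
    for s in sessions:
        m = ft.assemble(s)
        hyp = s.hypnogram
        if hyp is not None and len(hyp) > m.n_epochs:
            hyp = Hypnogram(hyp.stages[: m.n_epochs])
        out.append(SessionFeatures(s.subject_id, s.session_id, m, hyp))
    return out


def _labels(sf: SessionFeatures, classes) -> Hypnogram:
    hyp = sf.hypnogram
    if hyp is None:
        raise ValueError(f"session {sf.session_id} lacks a reference hypnogram")
    if classes == STAGES_3CLASS:
        hyp = ev.relabel_3class(hyp)
    return hyp


def run_loso(session_features: Sequence[SessionFeatures],
             model_config: Optional[md.ModelConfig] = None,
             training: md.TrainingConfig = md.TrainingConfig(),
             three_class: bool = True,
             impute_policy: str = "carry-forward"
             ) -> tuple[ev.AggregateReport, list[ev.MetricReport]]:
    """Leave-one-subject-out cross-validation over assembled sessions.

    Per fold: normalization statistics are fit on the training subjects
    only (audited at runtime: the held-out subject never intersects the
    training set), the model is trained on whole-session sequences, and
    the held-out sessions scored.
    """
    classes = STAGES_3CLASS if three_class else STAGES
    if model_config is None:
        model_config = md.ModelConfig(input_dim=len(ft.FEATURE_NAMES),
                                      n_classes=len(classes))
    subjects = list(dict.fromkeys(sf.subject_id for sf in session_features))
    folds = ev.loso_folds(subjects)
    reports = []
    for fold in folds:
        train_sf = [sf for sf in session_features
                    if sf.subject_id in fold.training]
        test_sf = [sf for sf in session_features
                   if sf.subject_id == fold.held_out]
        assert not {sf.subject_id for sf in train_sf} & \
            {sf.subject_id for sf in test_sf}, "fold leakage"
        train_mats = [ft.impute(sf.matrix, impute_policy) for sf in train_sf]
        test_mats = [ft.impute(sf.matrix, impute_policy) for sf in test_sf]
        norm = ft.Normalizer.fit(train_mats)

        def seq(sf: SessionFeatures, mat: ft.FeatureMatrix):
            X = norm.apply(mat).values.to_numpy()
            y = md.encode_labels(_labels(sf, classes).stages, classes)
            return X, y

        train_seqs = [seq(sf, m) for sf, m in zip(train_sf, train_mats)]
        fold_training = dataclasses.replace(
            training, seed=training.seed + 1000 * fold.fold_id)
        trained = md.train(model_config, train_seqs, fold_training,
                           classes=classes)
        ref_all, pred_all = [], []
        for sf, m in zip(test_sf, test_mats):
            X, _ = seq(sf, m)
            _, labels = md.predict(trained, X)
            ref_all.extend(_labels(sf, classes).stages)
            pred_all.extend(labels)
        reports.append(ev.confusion_and_metrics(ref_all, pred_all, classes))
    return ev.aggregate_folds(reports), reports


def permuted_label_control(session_features: Sequence[SessionFeatures],
                           seed: int, **kwargs) -> ev.AggregateReport:
    """Null control: labels permuted within each session before LOSO.

    Held-out accuracy should collapse to roughly the label marginals.
    """
    rng = np.random.default_rng(seed)
    shuffled = []
    for sf in session_features:
        stages = list(sf.hypnogram.stages)
        rng.shuffle(stages)
        shuffled.append(SessionFeatures(sf.subject_id, sf.session_id,
                                        sf.matrix, Hypnogram(tuple(stages))))
    agg, _ = run_loso(shuffled, **kwargs)
    return agg
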