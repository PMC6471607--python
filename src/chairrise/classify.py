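"""Hierarchical activity classification over windowed IMU features.

Stage 1 classifies the *state* of each window (static / dynamic /
transition); stage 2 resolves static windows into SIT vs STAND and stage 3
resolves transition windows into SIT_STAND vs STAND_SIT.  Each stage windows
and filters the raw stream with its own configuration; the default
configurations are:

====== =============== ========= ======== ======= ==========================
stage  model            window    step     filter  features
====== =============== ========= ======== ======= ==========================
state  boosted trees    1.405 s   0.072 s  6.1 Hz  AC, C, Mean (Acc); RMS,
                                                   SD, SE (Acc+Gyro)
static MLP 5x7          2.511 s   0.427 s  --      Mean, SMA (Acc), Pitch;
                                                   AC, C (Acc+Gyro)
trans. MLP 4x40         1.135 s   0.073 s  4.5 Hz  RMS (Acc); Mean, SE
                                                   (Gyro); AC, C, SMA, SD
                                                   (Acc+Gyro); Pitch
====== =============== ========= ======== ======= ==========================

The model follows the statsmodels convention: build a
:class:`HierarchicalActivityClassifier` from labelled sessions, call
``fit()``, and work with the returned :class:`ActivityClassifierResults`
(prediction, evaluation, ``summary()``, save/load).
"""

from __future__ import annotations

import pickle
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import InputError, ParameterError, TrainingError
from .features import FeatureSpec, feature_matrix
from .io import (
    DYNAMIC,
    OTHER,
    SIT,
    SIT_STAND,
    STAND,
    STAND_SIT,
    TRANSITION_LABELS,
    ImuRecording,
    LabelTrack,
    Segment,
    SessionBundle,
)
from .preprocessing import WindowSpec, lowpass, windowed_channels

ARCHIVE_VERSION = 1

STAGE_STATE, STAGE_STATIC, STAGE_TRANSITION = "state", "static", "transition"

#: stage-1 class of each activity label
STATE_OF_LABEL = {
    SIT: "static", STAND: "static",
    SIT_STAND: "transition", STAND_SIT: "transition",
    DYNAMIC: "dynamic", OTHER: "dynamic",
}


@dataclass(frozen=True)
class ClassifierConfig:
    """Configuration of one classifier stage."""

    stage: str
    model_kind: str                      # 'boosted_trees' or 'mlp'
    window_s: float
    step_s: float
    filter_fc: float | None
    feature_set: tuple[FeatureSpec, ...]
    hidden_layers: tuple[int, ...] = ()  # mlp architecture
    n_estimators: int = 100              # boosted-trees ensemble size
    max_depth: int = 3                   # boosted-trees depth
    autocorr_lag: int = 1

    def __post_init__(self) -> None:
        if self.stage not in (STAGE_STATE, STAGE_STATIC, STAGE_TRANSITION):
            raise ParameterError(f"unknown stage {self.stage!r}")
        if self.model_kind not in ("boosted_trees", "mlp"):
            raise ParameterError(f"unknown model kind {self.model_kind!r}")

    def window_spec(self, sample_rate: float) -> WindowSpec:
        return WindowSpec(self.window_s, self.step_s, sample_rate)

    def fingerprint(self) -> str:
        feats = ",".join(f"{f.name}:{f.scope}" for f in self.feature_set)
        return (f"{self.stage}|{self.model_kind}|w={self.window_s}|s={self.step_s}"
                f"|fc={self.filter_fc}|hl={self.hidden_layers}"
                f"|ne={self.n_estimators}|md={self.max_depth}|feats={feats}")


def default_configs() -> dict[str, ClassifierConfig]:
    """The three default stage configurations (table above)."""
    return {
        STAGE_STATE: ClassifierConfig(
            stage=STAGE_STATE, model_kind="boosted_trees",
            window_s=1.405, step_s=0.072, filter_fc=6.1,
            feature_set=(
                FeatureSpec("autocorr", "acc"), FeatureSpec("corr", "acc"),
                FeatureSpec("mean", "acc"), FeatureSpec("rms", "both"),
                FeatureSpec("sd", "both"), FeatureSpec("signal_energy", "both"),
            )),
        STAGE_STATIC: ClassifierConfig(
            stage=STAGE_STATIC, model_kind="mlp",
            window_s=2.511, step_s=0.427, filter_fc=None,
            hidden_layers=(7,) * 5,
            feature_set=(
                FeatureSpec("mean", "acc"), FeatureSpec("sma", "acc"),
                FeatureSpec("pitch", "acc"), FeatureSpec("autocorr", "both"),
                FeatureSpec("corr", "both"),
            )),
        STAGE_TRANSITION: ClassifierConfig(
            stage=STAGE_TRANSITION, model_kind="mlp",
            window_s=1.135, step_s=0.073, filter_fc=4.5,
            hidden_layers=(40,) * 4,
            feature_set=(
                FeatureSpec("rms", "acc"), FeatureSpec("mean", "gyro"),
                FeatureSpec("signal_energy", "gyro"), FeatureSpec("autocorr", "both"),
                FeatureSpec("corr", "both"), FeatureSpec("sma", "both"),
                FeatureSpec("sd", "both"), FeatureSpec("pitch", "acc"),
            )),
    }


# ---------------------------------------------------------------------------
# windowing + ground-truth assignment
# ---------------------------------------------------------------------------

def stage_windows(imu: ImuRecording, config: ClassifierConfig
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Filter, window and featurize a recording for one stage.

    Returns ``(X, t_starts, t_ends)``.
    """
    spec = config.window_spec(imu.sample_rate)
    filtered = None
    if config.filter_fc is not None:
        filtered = {c: lowpass(getattr(imu, c), config.filter_fc, imu.sample_rate)
                    for c in imu.channel_names()}
    channels, starts, ends = windowed_channels(imu, spec, filtered=filtered)
    X, _ = feature_matrix(channels, list(config.feature_set),
                          autocorr_lag=config.autocorr_lag)
    return X, starts, ends


def window_truth_labels(track: LabelTrack, t_starts: np.ndarray,
                        t_ends: np.ndarray) -> np.ndarray:
    """Majority-time-overlap label per window.

    Window time not covered by any segment counts as OTHER.  Ties are broken
    toward the transition classes (transitions are short and rare; recall
    matters most for them), then by vocabulary order.
    """
    n = len(t_starts)
    overlap = {lab: np.zeros(n) for lab in STATE_OF_LABEL}
    for seg in track.segments:
        o = np.minimum(t_ends, seg.end) - np.maximum(t_starts, seg.start)
        overlap[seg.label] += np.maximum(o, 0.0)
    covered = sum(overlap.values())
    overlap[OTHER] += np.maximum((t_ends - t_starts) - covered, 0.0)
    # transition labels first so argmax-style ties resolve toward them
    order = list(TRANSITION_LABELS) + [l for l in STATE_OF_LABEL
                                       if l not in TRANSITION_LABELS]
    stacked = np.column_stack([overlap[lab] for lab in order])
    best = np.argmax(stacked, axis=1)   # first (transition) wins ties
    return np.array([order[i] for i in best])


# ---------------------------------------------------------------------------
# stage models
# ---------------------------------------------------------------------------

@dataclass
class StageModel:
    """One trained stage: sklearn estimator + config fingerprint."""

    config: ClassifierConfig
    estimator: object
    classes: tuple[str, ...]
    fingerprint: str

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(X))


def _make_estimator(config: ClassifierConfig, seed: int):
    if config.model_kind == "boosted_trees":
        from sklearn.ensemble import GradientBoostingClassifier

        return GradientBoostingClassifier(
            n_estimators=config.n_estimators, max_depth=config.max_depth,
            random_state=seed)
    from sklearn.neural_network import MLPClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    return make_pipeline(
        StandardScaler(),
        MLPClassifier(hidden_layer_sizes=config.hidden_layers or (40,) * 4,
                      max_iter=800, random_state=seed))


def train_stage(X: np.ndarray, y: np.ndarray, config: ClassifierConfig,
                seed: int = 0) -> StageModel:
    """Train one stage model; deterministic for a fixed seed."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(X) != len(y):
        raise InputError("features and labels differ in length")
    classes = tuple(sorted(set(map(str, y))))
    if len(classes) < 2:
        raise TrainingError(
            f"stage {config.stage!r} training set contains a single class "
            f"{classes}; need at least 2")
    est = _make_estimator(config, seed)
    import warnings

    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
    return StageModel(config=config, estimator=est, classes=classes,
                      fingerprint=config.fingerprint())


# ---------------------------------------------------------------------------
# evaluation metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvalReport:
    """Precision / recall / F1 for one positive class.

    ``precision = tp / (tp + fp)``, ``recall = tp / (tp + fn)`` and
    ``f1 = 2 * precision * recall / (precision + recall)``; a zero
    denominator yields 0 by convention.
    """

    positive_class: str
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def f1(self) -> float:
        d = self.precision + self.recall
        return 2.0 * self.precision * self.recall / d if d else 0.0

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int,
                    positive_class: str = "positive") -> "EvalReport":
        return cls(positive_class=positive_class, tp=tp, fp=fp, fn=fn)


def evaluate(pred, truth, positive_class: str) -> EvalReport:
    """One-vs-rest precision/recall/F1 of ``positive_class``."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if len(pred) != len(truth):
        raise InputError("prediction and truth differ in length")
    tp = int(np.sum((pred == positive_class) & (truth == positive_class)))
    fp = int(np.sum((pred == positive_class) & (truth != positive_class)))
    fn = int(np.sum((pred != positive_class) & (truth == positive_class)))
    return EvalReport(positive_class=positive_class, tp=tp, fp=fp, fn=fn)


def evaluate_all(pred, truth) -> dict[str, EvalReport]:
    """Per-class evaluation over all classes present in either sequence."""
    classes = sorted(set(np.asarray(pred)) | set(np.asarray(truth)))
    return {c: evaluate(pred, truth, c) for c in classes}


# ---------------------------------------------------------------------------
# window labels -> segments
# ---------------------------------------------------------------------------

def _mode_filter(labels: list[str], width: int) -> list[str]:
    if width == 1:
        return list(labels)
    half = width // 2
    out = []
    for i in range(len(labels)):
        neigh = labels[max(0, i - half):i + half + 1]
        counts = Counter(neigh)
        top = counts.most_common()
        best, best_n = top[0]
        # stable tie-break: keep the original label if it ties for the mode
        if counts[labels[i]] == best_n:
            best = labels[i]
        out.append(best)
    return out


def merge_short_segments(track: LabelTrack, min_segment_s: float) -> LabelTrack:
    """Absorb segments shorter than ``min_segment_s`` into a neighbour.

    Classifier noise shows up as isolated sub-second label runs that break
    the test grammar; true activities (transitions >= ~0.8 s, sustained
    postures) survive.  The shortest offending run is repeatedly relabelled
    to its longer adjacent segment's label until none remain.
    """
    segs = [list(s) for s in track.segments]
    while len(segs) > 1:
        durations = [s[1] - s[0] for s in segs]
        i = int(np.argmin(durations))
        if durations[i] >= min_segment_s:
            break
        left = segs[i - 1] if i > 0 else None
        right = segs[i + 1] if i < len(segs) - 1 else None
        target = left if (right is None or (
            left is not None and (left[1] - left[0]) >= (right[1] - right[0]))) \
            else right
        segs[i][2] = target[2]
        merged: list[list] = []
        for s in segs:
            if merged and merged[-1][2] == s[2] and abs(s[0] - merged[-1][1]) < 1e-9:
                merged[-1][1] = s[1]
            else:
                merged.append(s)
        segs = merged
    return LabelTrack(tuple(s) for s in segs)


def windows_to_segments(window_labels, step_s: float, window_s: float,
                        smoothing_width: int = 3,
                        t_first_center: float | None = None) -> LabelTrack:
    """Turn a window-label sequence into a maximal-merged label track.

    A mode filter of ``smoothing_width`` windows (odd; 1 = no smoothing) is
    applied first; runs of equal labels are merged and segment boundaries
    placed at midpoints between adjacent window centers.  The track spans
    from half a step before the first center to half a step after the last.
    """
    labels = list(window_labels)
    if len(labels) < 1:
        raise InputError("need at least one window label")
    if smoothing_width < 1 or smoothing_width % 2 == 0:
        raise ParameterError("smoothing_width must be a positive odd integer")
    if t_first_center is None:
        t_first_center = window_s / 2.0
    labels = _mode_filter(labels, smoothing_width)
    centers = t_first_center + step_s * np.arange(len(labels))
    segments: list[Segment] = []
    run_start = centers[0] - step_s / 2.0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[i - 1]:
            run_end = (centers[i] + centers[i - 1]) / 2.0 if i < len(labels) \
                else centers[-1] + step_s / 2.0
            segments.append(Segment(run_start, run_end, labels[i - 1]))
            run_start = run_end
    return LabelTrack(segments)


def _merge_hierarchy(state_pred: np.ndarray, centers: np.ndarray,
                     sub: dict) -> np.ndarray:
    """Merge stage-2/3 decisions onto the stage-1 grid by nearest center."""
    labels = np.empty(len(centers), dtype=object)
    for stage, state_name in ((STAGE_STATIC, "static"),
                              (STAGE_TRANSITION, "transition")):
        mask = state_pred == state_name
        if not np.any(mask):
            continue
        pred2, c2 = sub[stage]
        idx = np.clip(np.searchsorted(c2, centers[mask]), 0, len(c2) - 1)
        left = np.clip(idx - 1, 0, len(c2) - 1)
        use_left = (np.abs(c2[left] - centers[mask])
                    <= np.abs(c2[idx] - centers[mask]))
        nearest = np.where(use_left, left, idx)
        labels[mask] = pred2[nearest]
    labels[state_pred == "dynamic"] = DYNAMIC
    return labels.astype(str)


# ---------------------------------------------------------------------------
# the hierarchical model
# ---------------------------------------------------------------------------

class HierarchicalActivityClassifier:
    """Hierarchical activity model built from labelled sessions.

    Parameters
    ----------
    sessions
        Labelled :class:`SessionBundle` objects (``truth`` required).
    configs
        Mapping of stage name to :class:`ClassifierConfig`; defaults to the
        stock three-stage configuration.
    """

    def __init__(self, sessions: list[SessionBundle],
                 configs: dict[str, ClassifierConfig] | None = None):
        if not sessions:
            raise InputError("need at least one training session")
        for b in sessions:
            if b.truth is None:
                raise InputError("every training session needs a truth track")
        self.sessions = list(sessions)
        self.configs = configs or default_configs()

    # -- training data assembly --------------------------------------------
    @staticmethod
    def stage_dataset(bundle: SessionBundle, config: ClassifierConfig
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(features, window truth labels, window centers) for one session."""
        X, starts, ends = stage_windows(bundle.imu, config)
        y = window_truth_labels(bundle.truth, starts, ends)
        centers = (starts + ends) / 2.0
        return X, y, centers

    def _training_matrices(self, sessions) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        out = {}
        for stage, config in self.configs.items():
            xs, ys = [], []
            for b in sessions:
                X, y, _ = self.stage_dataset(b, config)
                if stage == STAGE_STATE:
                    keep = np.ones(len(y), dtype=bool)
                    y = np.array([STATE_OF_LABEL[l] for l in y])
                elif stage == STAGE_STATIC:
                    keep = np.isin(y, (SIT, STAND))
                else:
                    keep = np.isin(y, TRANSITION_LABELS)
                xs.append(X[keep])
                ys.append(y[keep])
            out[stage] = (np.vstack(xs), np.concatenate(ys))
        return out

    def fit(self, seed: int = 0) -> "ActivityClassifierResults":
        """Train all three stages; deterministic for a fixed seed."""
        data = self._training_matrices(self.sessions)
        models = {}
        train_reports = {}
        for stage, (X, y) in data.items():
            model = train_stage(X, y, self.configs[stage], seed=seed)
            models[stage] = model
            pred = model.predict(X)
            train_reports[stage] = evaluate_all(pred, y)
        return ActivityClassifierResults(models=models, seed=seed,
                                         train_reports=train_reports)


@dataclass
class ActivityClassifierResults:
    """Fitted three-stage model: prediction, evaluation, persistence."""

    models: dict[str, StageModel]
    seed: int = 0
    train_reports: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = {STAGE_STATE, STAGE_STATIC, STAGE_TRANSITION} - set(self.models)
        if missing:
            raise InputError(f"missing trained stages: {sorted(missing)}")

    # -- prediction ----------------------------------------------------------
    def predict_session(self, imu: ImuRecording
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Hierarchical window labels for a recording.

        Each stage windows the raw stream with its own configuration; the
        stage-2/3 decisions are merged onto the stage-1 (state) window grid
        by nearest window center.  Returns ``(labels, t_starts, t_ends)`` on
        the state grid.
        """
        state = self.models[STAGE_STATE]
        Xs, starts, ends = stage_windows(imu, state.config)
        sub = {}
        for stage in (STAGE_STATIC, STAGE_TRANSITION):
            m = self.models[stage]
            X2, s2, e2 = stage_windows(imu, m.config)
            sub[stage] = (m.predict(X2), (s2 + e2) / 2.0)
        labels = _merge_hierarchy(state.predict(Xs), (starts + ends) / 2.0, sub)
        return labels, starts, ends

    def predict_track(self, imu: ImuRecording, smoothing_width: int = 3,
                      min_segment_s: float = 0.5) -> LabelTrack:
        """Predicted label track (windows -> smoothed, merged segments).

        After the window-level mode filter, label runs shorter than
        ``min_segment_s`` are absorbed into their neighbours (see
        :func:`merge_short_segments`); set it to 0 to disable.
        """
        labels, starts, ends = self.predict_session(imu)
        # the realized grid: step quantized to whole samples, not the nominal
        # config step, so boundaries stay aligned over long sessions
        step = float(starts[1] - starts[0]) if len(starts) > 1 else \
            self.models[STAGE_STATE].config.step_s
        track = windows_to_segments(
            labels, step_s=step, window_s=float(ends[0] - starts[0]),
            smoothing_width=smoothing_width,
            t_first_center=float((starts[0] + ends[0]) / 2.0))
        if min_segment_s > 0:
            track = merge_short_segments(track, min_segment_s)
        return track

    def calibrate_duration(self, sessions: list[SessionBundle],
                           max_hold_s: float = 30.0,
                           smoothing_width: int = 3):
        """Fit the IMU-vs-reference duration relation on labelled sessions.

        Runs the full predict -> detect pipeline on sessions with a known
        reference duration (``stopwatch_5crt``) and regresses the detected
        duration on the reference, exactly the calibration a stopwatch
        comparison provides in practice.  Returns the
        :class:`~chairrise.patterns.AgreementResult`; feed its slope and
        intercept to :func:`chairrise.performance.bias_correct_duration` to
        map detected durations onto the reference scale.
        """
        from .detector import detect_5crt

        ref, det = [], []
        for b in sessions:
            if b.stopwatch_5crt is None:
                continue
            tests = detect_5crt(self.predict_track(
                b.imu, smoothing_width=smoothing_width), max_hold_s=max_hold_s)
            if len(tests) != 1:
                continue
            ref.append(b.stopwatch_5crt)
            det.append(tests[0].duration_s)
        from .patterns import agreement

        return agreement(ref, det)   # detected = slope * reference + intercept

    # -- reporting -----------------------------------------------------------
    def summary(self) -> str:
        lines = ["Hierarchical activity classifier",
                 "=" * 34,
                 f"seed: {self.seed}"]
        for stage, model in self.models.items():
            cfg = model.config
            lines.append(
                f"[{stage}] {cfg.model_kind}, window {cfg.window_s} s, "
                f"step {cfg.step_s} s, fc {cfg.filter_fc}, "
                f"classes {list(model.classes)}")
            for cls, rep in self.train_reports.get(stage, {}).items():
                lines.append(
                    f"    {cls:<12} P={rep.precision:.3f} R={rep.recall:.3f} "
                    f"F1={rep.f1:.3f} (tp={rep.tp} fp={rep.fp} fn={rep.fn})")
        return "\n".join(lines)

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        """Save as a versioned archive (config fingerprints + estimators)."""
        payload = {
            "version": ARCHIVE_VERSION,
            "seed": self.seed,
            "stages": {
                s: {"config": m.config, "estimator": m.estimator,
                    "classes": m.classes, "fingerprint": m.fingerprint}
                for s, m in self.models.items()
            },
        }
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "ActivityClassifierResults":
        with open(Path(path), "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("version") != ARCHIVE_VERSION:
            raise InputError(f"unsupported model archive version "
                             f"{payload.get('version')!r}")
        models = {
            s: StageModel(config=d["config"], estimator=d["estimator"],
                          classes=d["classes"], fingerprint=d["fingerprint"])
            for s, d in payload["stages"].items()
        }
        return cls(models=models, seed=payload.get("seed", 0))


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def cross_validate(sessions: list[SessionBundle],
                   configs: dict[str, ClassifierConfig] | None = None,
                   k: int = 5, seed: int = 0,
                   smoothing_width: int = 3) -> dict:
    """Subject-grouped k-fold cross-validation of the full hierarchy.

    Sessions are partitioned by subject (no subject appears in two folds).
    For each fold the three stages are trained on the remaining subjects and
    the held-out sessions are predicted end to end; per-class precision,
    recall and F1 on the state-grid window labels are aggregated as mean and
    SD over folds.  Features are computed once per session and shared across
    folds.  Returns a dict with per-class fold metrics plus, per fold, the
    fitted results object and the predicted label track of *every* session
    under that fold's models (training-session tracks support duration
    calibration; see ``ActivityClassifierResults.calibrate_duration``).
    """
    subjects = sorted({b.imu.subject_id for b in sessions})
    if k > len(subjects):
        raise ParameterError(f"k={k} exceeds the {len(subjects)} subjects")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    folds = [sorted(subjects[i] for i in order[j::k]) for j in range(k)]
    configs = configs or default_configs()

    # featurize every session once; folds only re-fit and re-predict
    cache: list[dict] = []
    for b in sessions:
        entry = {"bundle": b}
        for stage, config in configs.items():
            X, starts, ends = stage_windows(b.imu, config)
            y = window_truth_labels(b.truth, starts, ends)
            entry[stage] = (X, y, starts, ends)
        cache.append(entry)

    def train_matrices(entries, stage):
        xs, ys = [], []
        for e in entries:
            X, y, _, _ = e[stage]
            if stage == STAGE_STATE:
                keep = np.ones(len(y), dtype=bool)
                y = np.array([STATE_OF_LABEL[l] for l in y])
            elif stage == STAGE_STATIC:
                keep = np.isin(y, (SIT, STAND))
            else:
                keep = np.isin(y, TRANSITION_LABELS)
            xs.append(X[keep])
            ys.append(y[keep])
        return np.vstack(xs), np.concatenate(ys)

    per_class: dict[str, list] = {}
    fold_results = []
    for fold_subjects in folds:
        train_e = [e for e in cache
                   if e["bundle"].imu.subject_id not in fold_subjects]
        models = {}
        for stage, config in configs.items():
            X, y = train_matrices(train_e, stage)
            models[stage] = train_stage(X, y, config, seed=seed)
        res = ActivityClassifierResults(models=models, seed=seed)

        # predicted window labels and tracks for every session, from cache
        tracks: dict[str, LabelTrack] = {}
        preds, truths = [], []
        for e in cache:
            sid = e["bundle"].imu.subject_id
            Xs, ys, starts, ends = e[STAGE_STATE]
            sub = {}
            for stage in (STAGE_STATIC, STAGE_TRANSITION):
                X2, _, s2, e2 = e[stage]
                sub[stage] = (models[stage].predict(X2), (s2 + e2) / 2.0)
            labels = _merge_hierarchy(models[STAGE_STATE].predict(Xs),
                                      (starts + ends) / 2.0, sub)
            step = float(starts[1] - starts[0]) if len(starts) > 1 else \
                configs[STAGE_STATE].step_s
            track = windows_to_segments(
                labels, step_s=step, window_s=float(ends[0] - starts[0]),
                smoothing_width=smoothing_width,
                t_first_center=float((starts[0] + ends[0]) / 2.0))
            tracks[sid] = merge_short_segments(track, 0.5)
            if sid in fold_subjects:
                preds.append(labels)
                truths.append(ys)
        pred = np.concatenate(preds)
        truth = np.concatenate(truths)
        for cls, rep in evaluate_all(pred, truth).items():
            per_class.setdefault(cls, []).append(rep)
        fold_results.append({
            "subjects": fold_subjects, "results": res, "tracks": tracks,
            "test": [e["bundle"] for e in cache
                     if e["bundle"].imu.subject_id in fold_subjects]})

    summary = {}
    for cls, reps in per_class.items():
        f1 = np.array([r.f1 for r in reps])
        summary[cls] = {
            "precision_mean": float(np.mean([r.precision for r in reps])),
            "recall_mean": float(np.mean([r.recall for r in reps])),
            "f1_mean": float(f1.mean()),
            "f1_sd": float(f1.std(ddof=1)) if len(f1) > 1 else 0.0,
            "n_folds": len(reps),
        }
    return {"per_class": summary, "folds": fold_results, "k": k, "seed": seed}
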