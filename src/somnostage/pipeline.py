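"""Night-level pipeline: featurization, subject-independent CV, ablations.

The unit of data is a night: preprocessed signal epochs are turned into a
(T, F) feature matrix with per-epoch stage labels and a subject id. Folds
assign whole subjects to train or test (never both), balancing total night
counts greedily; results pool the per-fold confusion matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .estimator import SleepStageClassifier
from .evaluation import MetricsReport, confusion
from .features import FEATURES_PER_CHANNEL, FeatureMatrix, extract_features
from .io import Hypnogram, Recording, align_labels
from .preprocess import (
    EpochedRecording,
    NIGHT_EPOCHS,
    epoch_segment,
    filter_recording,
    standardize_night,
)

__all__ = [
    "TrainConfig",
    "FoldSplit",
    "NightFeatures",
    "make_folds",
    "featurize_night",
    "select_channels",
    "train_fold",
    "predict_night",
    "cross_validate",
    "channel_ablation",
]


@dataclass
class TrainConfig:
    """Training hyperparameters (Adam; one whole night per step)."""

    learning_rate: float = 1e-4
    weight_decay: float = 1e-2
    max_epochs: int = 100
    patience: int = 10
    val_fraction: float = 0.1
    class_weights: tuple = (1.0, 1.0, 1.0, 1.0, 1.0)
    channels: tuple = ()  # empty = use all channels present
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if len(self.class_weights) != 5 or any(w <= 0 for w in self.class_weights):
            raise ValueError("class_weights must be 5 positive values")

    def estimator(self) -> SleepStageClassifier:
        weights = None
        if tuple(self.class_weights) != (1.0, 1.0, 1.0, 1.0, 1.0):
            weights = tuple(self.class_weights)
        return SleepStageClassifier(
            learning_rate=self.learning_rate,
            weight_decay=self.weight_decay,
            max_epochs=self.max_epochs,
            patience=self.patience,
            val_fraction=self.val_fraction,
            class_weights=weights,
            random_state=self.seed,
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FoldSplit:
    fold_id: int
    train_subjects: list[str]
    test_subjects: list[str]


@dataclass
class NightFeatures:
    """Extracted features and labels of one night."""

    subject_id: str
    night_id: str
    features: FeatureMatrix
    stages: np.ndarray

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype=np.int64)
        if self.features.n_epochs != self.stages.size:
            raise ValueError("feature rows and labels differ in length")


def make_folds(subject_nights: dict[str, int], k: int = 5, seed=None) -> list[FoldSplit]:
    """Partition subjects into k test groups balancing night counts.

    Greedy largest-first bin packing: subjects in decreasing night count go
    to the currently lightest fold; the seed shuffles subjects before the
    (stable) sort so ties break reproducibly but not alphabetically.
    """
    subjects = list(subject_nights)
    if len(subjects) < k:
        raise ValueError(f"need at least {k} subjects for {k} folds, got {len(subjects)}")
    rng = np.random.default_rng(seed)
    subjects = [subjects[i] for i in rng.permutation(len(subjects))]
    subjects.sort(key=lambda s: -subject_nights[s])  # stable: shuffled tie order kept
    loads = [0] * k
    groups: list[list[str]] = [[] for _ in range(k)]
    for s in subjects:
        j = int(np.argmin(loads))
        groups[j].append(s)
        loads[j] += subject_nights[s]
    folds = []
    for fid in range(k):
        test = sorted(groups[fid])
        train = sorted(s for j, g in enumerate(groups) if j != fid for s in g)
        folds.append(FoldSplit(fold_id=fid + 1, train_subjects=train, test_subjects=test))
    return folds


def featurize_night(
    rec: Recording,
    hyp: Hypnogram,
    channels=None,
    standard_epochs: int | None = None,
) -> NightFeatures:
    """Filter, epoch, optionally standardize night length, extract features.

    ``standard_epochs`` (e.g. 1140) trims/pads the night before extraction;
    None leaves the length as-is.
    """
    if channels:
        rec = Recording(
            channels=[rec.channel(c) for c in channels],
            start_time=rec.start_time,
            subject_id=rec.subject_id,
            night_id=rec.night_id,
        )
    rec, hyp = align_labels(rec, hyp)
    filtered = filter_recording(rec)
    epochs = epoch_segment(filtered)
    if len(hyp) != epochs.n_epochs:  # alignment guaranteed a match pre-epoching
        hyp = Hypnogram(stages=hyp.stages[: epochs.n_epochs], start_time=hyp.start_time)
    if standard_epochs is not None:
        epochs, hyp = standardize_night(epochs, hyp, target=standard_epochs)
    fm = extract_features(epochs.data, epochs.channel_labels, epochs.rate)
    return NightFeatures(
        subject_id=rec.subject_id,
        night_id=rec.night_id,
        features=fm,
        stages=hyp.stages,
    )


def select_channels(fm: FeatureMatrix, channels) -> FeatureMatrix:
    """Restrict a multi-channel feature matrix to the named channel blocks."""
    missing = [c for c in channels if c not in fm.channel_order]
    if missing:
        raise KeyError(f"channel(s) {missing} not in feature matrix {fm.channel_order}")
    keep = [c for c in fm.channel_order if c in set(channels)]  # canonical order
    cols: list[int] = []
    for c in keep:
        base = fm.channel_order.index(c) * FEATURES_PER_CHANNEL
        cols.extend(range(base, base + FEATURES_PER_CHANNEL))
    return FeatureMatrix(
        values=fm.values[:, cols],
        feature_names=[fm.feature_names[i] for i in cols],
        channel_order=keep,
    )


def _night_matrices(nights: list[NightFeatures], channels):
    X, y = [], []
    for n in nights:
        fm = select_channels(n.features, channels) if channels else n.features
        X.append(fm.values)
        y.append(n.stages)
    return X, y


def train_fold(train_nights: list[NightFeatures], cfg: TrainConfig) -> SleepStageClassifier:
    """Fit the stager on the training nights of one fold."""
    if len(train_nights) < 2:
        raise ValueError("training a fold needs at least 2 nights")
    X, y = _night_matrices(train_nights, cfg.channels)
    clf = cfg.estimator()
    clf.fit(X, y)
    return clf


def predict_night(clf: SleepStageClassifier, night: NightFeatures, channels=None):
    """Viterbi hypnogram and posterior marginals for one night."""
    fm = select_channels(night.features, channels) if channels else night.features
    stages = clf.predict(fm.values)
    marginals = clf.predict_marginals(fm.values)
    return Hypnogram(stages=stages), marginals


def cross_validate(
    nights: list[NightFeatures], cfg: TrainConfig, k: int = 5
) -> MetricsReport:
    """Subject-independent k-fold CV; pooled confusion across folds.

    Asserts the no-leak invariant: no test-fold subject contributes to
    training (normalization statistics included, since the estimator fits
    them on its training nights only).
    """
    counts: dict[str, int] = {}
    for n in nights:
        counts[n.subject_id] = counts.get(n.subject_id, 0) + 1
    folds = make_folds(counts, k=k, seed=cfg.seed)
    pooled = np.zeros((5, 5), dtype=np.int64)
    per_fold = []
    for fold in folds:
        train = [n for n in nights if n.subject_id in fold.train_subjects]
        test = [n for n in nights if n.subject_id in fold.test_subjects]
        assert not {n.subject_id for n in train} & {n.subject_id for n in test}
        clf = train_fold(train, cfg)
        Xt, yt = _night_matrices(test, cfg.channels)
        preds = clf.predict(Xt)
        cm = sum(confusion(t, p) for t, p in zip(yt, preds))
        pooled += cm
        fold_report = MetricsReport(confusion=cm)
        per_fold.append(
            {
                "fold": fold.fold_id,
                "test_subjects": fold.test_subjects,
                "accuracy": fold_report.accuracy,
                "sen_n1": fold_report.sen_n1,
                "kappa": fold_report.kappa,
            }
        )
    return MetricsReport(confusion=pooled, per_fold=per_fold)


def channel_ablation(
    nights: list[NightFeatures], channel_sets: list[list[str]], cfg: TrainConfig, k: int = 5
) -> dict[str, MetricsReport]:
    """Full CV per channel set; keyed '+'-joined (e.g. 'C4+LEOG+REOG')."""
    results = {}
    for channels in channel_sets:
        sub_cfg = TrainConfig(**{**cfg.to_dict(), "channels": tuple(channels)})
        results["+".join(channels)] = cross_validate(nights, sub_cfg, k=k)
    return results
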