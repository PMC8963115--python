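"""Cybersickness severity prediction from motion features.

Per-scene visual feature vectors are regressed onto the per-trial 1-5
sickness ratings with an epsilon support vector regressor (RBF kernel,
standardized features).  Evaluation is repeated-random-split cross
validation at the participant level: each trial holds out whole
participants (all their scene rows travel together) so that no
participant's ratings leak between train and test, and reports Spearman
rank-order (SROCC) and Pearson linear (PLCC) correlations between
predictions and held-out ratings, averaged over trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .visual import FEATURE_NAMES

__all__ = [
    "LabeledDataset",
    "CVSummary",
    "build_dataset",
    "participant_split",
    "fit_predictor",
    "evaluate",
    "cv_run",
    "DEFAULT_SUBSETS",
]

DEFAULT_SUBSETS = (
    ("f1", "f2"),
    ("f1", "f2", "f3", "f4"),
    ("f1", "f2", "f5", "f6"),
    ("f1", "f2", "f3", "f4", "f5", "f6"),
)

# SVR hyperparameters are fixed, not searched; recorded in output metadata.
SVR_PARAMS = {"kernel": "rbf", "C": 1.0, "epsilon": 0.1, "gamma": "scale"}


@dataclass
class LabeledDataset:
    """Rows of (participant_id, scene_id, f1..f6, label)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"participant_id", "scene_id", "label"} | set(FEATURE_NAMES)
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"dataset lacks columns {sorted(missing)}")
        if self.table.duplicated(["participant_id", "scene_id"]).any():
            raise ValueError("one row per (participant, scene) required")
        labels = self.table["label"]
        if not labels.isin([1, 2, 3, 4, 5]).all():
            raise ValueError("labels must be integers 1..5")

    @property
    def participants(self) -> np.ndarray:
        return self.table["participant_id"].unique()

    def __len__(self) -> int:
        return len(self.table)


def build_dataset(features: pd.DataFrame, scores: pd.DataFrame) -> LabeledDataset:
    """Join per-scene features with the participants x scenes rating matrix.

    ``features`` has one row per scene_id with columns f1..f6; every rated
    scene must be present.  Each participant's rating of a scene becomes one
    labelled row carrying that scene's feature vector.
    """
    feats = features.set_index("scene_id") if "scene_id" in features.columns else features
    long = scores.stack().rename("label").reset_index()
    long.columns = ["participant_id", "scene_id", "label"]
    merged = long.merge(feats[list(FEATURE_NAMES)], left_on="scene_id", right_index=True)
    return LabeledDataset(merged.reset_index(drop=True))


def participant_split(dataset: LabeledDataset, train_fraction: float = 0.8,
                      seed: int | np.random.Generator = 0):
    """Partition whole participants into train/test row sets.

    The train side receives ``floor(train_fraction * P)`` participants; all
    52 rows of a participant stay on one side.  With the full 154-person
    study this yields 123 train / 31 test participants, i.e. 6396 and 1612
    rows.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train fraction must lie in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    participants = np.sort(dataset.participants)
    if len(participants) < 2:
        raise ValueError("need at least two participants to split")
    n_train = int(len(participants) * train_fraction)
    n_train = min(max(n_train, 1), len(participants) - 1)
    shuffled = rng.permutation(participants)
    train_ids = set(shuffled[:n_train])
    mask = dataset.table["participant_id"].isin(train_ids)
    return dataset.table[mask], dataset.table[~mask]


def fit_predictor(train: pd.DataFrame, feature_subset=FEATURE_NAMES):
    """Fit a standardized RBF support vector regressor on the training rows.

    Zero-variance features are dropped with a warning (the scaler cannot
    standardize them); the fitted pipeline records which columns it used.
    """
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVR

    unknown = set(feature_subset) - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown features {sorted(unknown)}")
    if train.empty:
        raise ValueError("empty training set")
    cols = list(feature_subset)
    x = train[cols].to_numpy(float)
    keep = x.std(axis=0) > 0
    if not keep.all():
        dropped = [c for c, k in zip(cols, keep) if not k]
        warnings.warn(f"dropping zero-variance features {dropped}", stacklevel=2)
        cols = [c for c, k in zip(cols, keep) if k]
        x = x[:, keep]
    if not cols:
        raise ValueError("no features left after dropping zero-variance columns")
    model = Pipeline([("scale", StandardScaler()), ("svr", SVR(**SVR_PARAMS))])
    model.fit(x, train["label"].to_numpy(float))
    model.feature_columns_ = cols
    return model


def evaluate(model, test: pd.DataFrame):
    """SROCC and PLCC of model predictions against held-out labels."""
    pred = model.predict(test[model.feature_columns_].to_numpy(float))
    truth = test["label"].to_numpy(float)
    srocc = spstats.spearmanr(pred, truth).statistic
    plcc = spstats.pearsonr(pred, truth).statistic
    return float(srocc), float(plcc), pred


@dataclass
class CVSummary:
    subset: tuple
    srocc: np.ndarray  # per trial
    plcc: np.ndarray
    n_trials: int

    @property
    def mean_srocc(self) -> float:
        return float(np.mean(self.srocc))

    @property
    def mean_plcc(self) -> float:
        return float(np.mean(self.plcc))


def cv_run(dataset: LabeledDataset, subsets=DEFAULT_SUBSETS, n_trials: int = 100,
           train_fraction: float = 0.8, seed: int = 0) -> list:
    """Repeated participant-level train/test evaluation of feature subsets.

    Per-trial split seeds derive from the master seed through a seed
    sequence, so results are reproducible bit for bit; every trial asserts
    that no participant appears on both sides of its split.
    """
    rngs = [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n_trials)]
    summaries = []
    for subset in subsets:
        sroccs, plccs = [], []
        for rng in rngs:
            train, test = participant_split(dataset, train_fraction, rng)
            overlap = set(train["participant_id"]) & set(test["participant_id"])
            assert not overlap, f"participant leakage: {sorted(overlap)[:3]}"
            model = fit_predictor(train, subset)
            srocc, plcc, _ = evaluate(model, test)
            sroccs.append(srocc)
            plccs.append(plcc)
        summaries.append(
            CVSummary(tuple(subset), np.array(sroccs), np.array(plccs), n_trials)
        )
    return summaries
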