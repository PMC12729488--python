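"""Chronological splitting, Random-Forest training/tuning, and metrics.

The training protocol guards against sequence leakage: within every
(behaviour, individual) stratum the windows are ordered in time and cut
60/20/20 into train/validation/test, so no continuous behavioural sequence
spans two sets. Hyperparameters are tuned on validation macro-F1 (unweighted
mean over classes) with a seeded, pluggable search. Final per-second labels
come from the windows that start on whole clock seconds; the off-grid
overlapping windows act as oversampling for training only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .features import PURITY_THRESHOLD

META_COLUMNS = ("start_s", "label", "purity", "individual_id")


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def training_table(table: pd.DataFrame,
                   purity_threshold: float = PURITY_THRESHOLD) -> pd.DataFrame:
    """Labelled windows pure enough to train on."""
    mask = (table["label"] != "") & (table["purity"] >= purity_threshold)
    return table.loc[mask].reset_index(drop=True)


# ---------------------------------------------------------------------------
# chronological split

@dataclass(frozen=True)
class SplitSpec:
    """60/20/20 chronological split per (behaviour, individual) stratum."""

    fractions: tuple[float, float, float] = (0.60, 0.20, 0.20)
    min_stratum: int = 5

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def chronological_split(
    table: pd.DataFrame, spec: SplitSpec = SplitSpec()
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Split windows chronologically within each stratum.

    Input order is irrelevant (windows are sorted by start time internally).
    Strata smaller than ``min_stratum`` go wholly to training with a warning.
    """
    if (table["label"] == "").any():
        raise ValueError("all windows must be labelled before splitting")
    f_train, f_val, _ = spec.fractions
    parts: dict[str, list[pd.DataFrame]] = {"train": [], "val": [], "test": []}
    for (_, _), grp in table.groupby(["label", "individual_id"], sort=True):
        grp = grp.sort_values("start_s", kind="mergesort")
        n = len(grp)
        if n < spec.min_stratum:
            warnings.warn(
                f"stratum with {n} windows placed wholly in training")
            parts["train"].append(grp)
            continue
        a = int(np.floor(f_train * n))
        b = a + int(np.floor(f_val * n))
        parts["train"].append(grp.iloc[:a])
        parts["val"].append(grp.iloc[a:b])
        parts["test"].append(grp.iloc[b:])
    out = tuple(
        pd.concat(parts[k], ignore_index=True) if parts[k] else pd.DataFrame()
        for k in ("train", "val", "test")
    )
    return out


# ---------------------------------------------------------------------------
# model configuration and training

@dataclass(frozen=True)
class ModelConfig:
    """Random-Forest hyperparameters."""

    number_trees: int = 300
    mtry: int = 7
    max_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.number_trees, self.mtry, self.max_depth) <= 0:
            raise ValueError("hyperparameters must be positive")


@dataclass
class ForestModel:
    """Fitted forest plus its feature-name manifest."""

    estimator: RandomForestClassifier
    feature_names: tuple[str, ...]
    classes: tuple[str, ...]
    config: ModelConfig


def train_forest(train: pd.DataFrame, config: ModelConfig) -> ForestModel:
    feats = feature_columns(train)
    if config.mtry > len(feats):
        raise ValueError("mtry exceeds the feature count")
    est = RandomForestClassifier(
        n_estimators=config.number_trees,
        max_features=config.mtry,
        max_depth=config.max_depth,
        random_state=config.seed,
        n_jobs=1,
    )
    est.fit(train[feats].to_numpy(), train["label"].to_numpy())
    return ForestModel(est, tuple(feats), tuple(est.classes_), config)


def predict(model: ForestModel, windows: pd.DataFrame) -> np.ndarray:
    """Predict a behaviour label for each window row."""
    feats = feature_columns(windows)
    if tuple(feats) != model.feature_names:
        raise ValueError("feature names do not match the trained model")
    return model.estimator.predict(windows[list(feats)].to_numpy())


def predict_per_second(model: ForestModel, windows: pd.DataFrame) -> pd.DataFrame:
    """Per-second labels: each clock second takes the prediction of the
    window starting at that second (off-grid windows are ignored here)."""
    on_grid = windows[np.isclose(windows["start_s"] % 1.0, 0.0)]
    labels = predict(model, on_grid)
    return pd.DataFrame(
        {
            "second": on_grid["start_s"].to_numpy().astype(int),
            "individual_id": on_grid["individual_id"].to_numpy(),
            "label": labels,
        }
    )


# ---------------------------------------------------------------------------
# hyperparameter search

def default_search_space(n_features: int) -> dict[str, tuple[int, int]]:
    """Inclusive integer ranges for the three free hyperparameters."""
    lo_mtry = max(1, int(np.ceil(np.sqrt(n_features)) // 2))
    hi_mtry = max(lo_mtry, n_features // 2)
    return {
        "number_trees": (100, 1000),
        "mtry": (lo_mtry, hi_mtry),
        "max_depth": (4, 32),
    }


def _random_candidates(space, budget, rng) -> list[ModelConfig]:
    return [
        ModelConfig(
            number_trees=int(rng.integers(*space["number_trees"], endpoint=True)),
            mtry=int(rng.integers(*space["mtry"], endpoint=True)),
            max_depth=int(rng.integers(*space["max_depth"], endpoint=True)),
        )
        for _ in range(budget)
    ]


def _grid_candidates(space, budget) -> list[ModelConfig]:
    per_dim = max(1, int(round(budget ** (1 / 3))))

    def levels(lo, hi):
        return sorted({int(round(v)) for v in np.linspace(lo, hi, per_dim)})

    return [
        ModelConfig(number_trees=nt, mtry=mt, max_depth=md)
        for nt in levels(*space["number_trees"])
        for mt in levels(*space["mtry"])
        for md in levels(*space["max_depth"])
    ][:budget]


def tune(
    train: pd.DataFrame,
    validation: pd.DataFrame,
    search_budget: int = 10,
    seed: int = 0,
    search="random",
    space: dict | None = None,
    return_history: bool = False,
):
    """Pick the hyperparameter configuration maximising validation macro-F1.

    ``search`` is pluggable: "random" (default), "grid", or a callable
    ``(space, budget, rng) -> list[ModelConfig]``. The whole search is
    deterministic for a fixed seed; ties go to the earlier candidate.
    """
    if len(validation) == 0:
        raise ValueError("validation set is empty")
    space = space or default_search_space(len(feature_columns(train)))
    rng = np.random.default_rng(seed)
    if callable(search):
        candidates = search(space, search_budget, rng)
    elif search == "random":
        candidates = _random_candidates(space, search_budget, rng)
    elif search == "grid":
        candidates = _grid_candidates(space, search_budget)
    else:
        raise ValueError(f"unknown search strategy {search!r}")

    history = []
    best, best_score = None, -np.inf
    truth = validation["label"].to_numpy()
    for cand in candidates:
        cand = ModelConfig(cand.number_trees, cand.mtry, cand.max_depth, seed)
        model = train_forest(train, cand)
        preds = predict(model, validation)
        cm = ConfusionMatrix.from_labels(truth, preds)
        score = classification_metrics(cm).macro["f1"]
        history.append({**cand.__dict__, "macro_f1": score})
        if score > best_score:
            best, best_score = cand, score
    if return_history:
        return best, pd.DataFrame(history)
    return best


# ---------------------------------------------------------------------------
# metrics

@dataclass
class ConfusionMatrix:
    """Truth-by-prediction count table over an ordered label set."""

    classes: tuple[str, ...]
    counts: np.ndarray  # rows = truth, columns = predicted

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square over classes")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_labels(cls, truth, predicted, classes=None) -> "ConfusionMatrix":
        truth = np.asarray(truth)
        predicted = np.asarray(predicted)
        if classes is None:
            classes = tuple(sorted(set(truth) | set(predicted)))
        index = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)))
        for t, p in zip(truth, predicted):
            counts[index[t], index[p]] += 1
        return cls(tuple(classes), counts)


@dataclass
class ClassMetrics:
    """Per-class precision/recall/F1/balanced-accuracy plus macro averages."""

    table: pd.DataFrame  # indexed by class
    macro: pd.Series
    absent_classes: tuple[str, ...] = field(default=())

    def summary(self) -> pd.DataFrame:
        """Per-class rows plus an unweighted macro-average row."""
        out = self.table.copy()
        macro = self.macro.copy()
        macro["prevalence"] = np.nan
        out.loc["Macro-average"] = macro
        return out


def classification_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """Compute the full metric set from a confusion matrix.

    F1 is the harmonic mean of precision and recall (0 where both are 0);
    balanced accuracy is the mean of recall and specificity; macro values
    are unweighted class means. A class absent from the truth gets recall 0
    and is flagged in ``absent_classes``.
    """
    c = cm.counts
    if c.sum() == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(c)
    row = c.sum(axis=1)
    col = c.sum(axis=0)
    total = c.sum()
    fn, fp = row - tp, col - tp
    tn = total - tp - fn - fp

    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1e-300), 0.0)
        recall = np.where(row > 0, tp / np.maximum(row, 1e-300), 0.0)
        f1 = np.where(precision + recall > 0,
                      2 * precision * recall
                      / np.maximum(precision + recall, 1e-300), 0.0)
        specificity = np.where(tn + fp > 0, tn / np.maximum(tn + fp, 1e-300), 0.0)
    balanced = (recall + specificity) / 2.0

    table = pd.DataFrame(
        {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "balanced_accuracy": balanced,
            "prevalence": row,
        },
        index=list(cm.classes),
    )
    macro = table[["precision", "recall", "f1", "balanced_accuracy"]].mean()
    absent = tuple(np.array(cm.classes)[row == 0])
    if absent:
        warnings.warn(f"classes absent from truth: {absent}; recall set to 0")
    return ClassMetrics(table=table, macro=macro, absent_classes=absent)
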