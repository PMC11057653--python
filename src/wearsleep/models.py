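"""Classifier suite and the memory-step sweep.

The memoryless models (logistic regression, random forest, k-nearest
neighbours, RBF support vector machine, multilayer perceptron) are standard
scikit-learn estimators selected by cross-validated weighted F1 over a
small grid; they consume flattened windows.  The memory-based model is the
in-repo LSTM (:mod:`wearsleep.lstm`) consuming the sequences directly.
The memory sweep re-windows the feature table for each history depth ns,
splits, trains and evaluates, mirroring the experiment that asks how far
back a model must look before sleep-stage prediction stops improving.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .evaluation import EvalReport, score
from .features import minmax_scale
from .lstm import FittedLSTM, TrainConfig, train_lstm
from .records import EpochTable
from .windowing import WindowedDataset, make_windows

logger = logging.getLogger(__name__)

MODEL_NAMES = ("LR", "RF", "kNN", "SVM", "MLP")


@dataclass(frozen=True)
class SplitSpec:
    """Train/test partition conditions."""

    strategy: str = "stratified_random"  # or "subject_held_out"
    train_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.strategy not in ("stratified_random", "subject_held_out"):
            raise ValueError(f"unknown split strategy {self.strategy!r}")


def split(ds: WindowedDataset, spec: SplitSpec) -> tuple[WindowedDataset, WindowedDataset]:
    """Partition a windowed dataset into train and test sets.

    ``stratified_random`` preserves class proportions; ``subject_held_out``
    assigns whole subjects (groups) to one side, for leakage studies.
    Deterministic given ``spec.seed``.
    """
    n = len(ds)
    if spec.strategy == "stratified_random":
        idx_train, idx_test = train_test_split(
            np.arange(n),
            train_size=spec.train_fraction,
            stratify=ds.y,
            random_state=spec.seed,
        )
    else:
        if ds.groups is None:
            raise ValueError("subject_held_out split needs group labels")
        rng = np.random.default_rng(spec.seed)
        subjects = rng.permutation(np.unique(ds.groups))
        sizes = np.array([(ds.groups == s).sum() for s in subjects])
        cut = np.searchsorted(np.cumsum(sizes) / n, spec.train_fraction) + 1
        train_subj = set(subjects[:cut].tolist())
        mask = np.isin(ds.groups, list(train_subj))
        idx_train, idx_test = np.flatnonzero(mask), np.flatnonzero(~mask)

    def take(idx):
        return WindowedDataset(
            ns=ds.ns, X=ds.X[idx], y=ds.y[idx],
            feature_names=ds.feature_names,
            groups=None if ds.groups is None else ds.groups[idx],
        )

    train, test = take(np.sort(idx_train)), take(np.sort(idx_test))
    missing = set(np.unique(ds.y)) - set(np.unique(train.y))
    if missing:
        raise ValueError(f"classes {sorted(missing)} absent from the training split")
    return train, test


DEFAULT_GRIDS: dict[str, dict] = {
    # grids sized so a full search fits in the tens-to-hundreds of fits
    "LR": {"C": [0.1, 1.0, 10.0]},
    "RF": {"n_estimators": [100, 200], "max_depth": [None, 12]},
    "kNN": {"n_neighbors": [3, 5, 7]},
    "SVM": {"C": [1.0, 10.0], "gamma": ["scale", 0.1]},
    "MLP": {"hidden_layer_sizes": [(32,), (64,)], "alpha": [1e-4]},
}


def _estimator(model_name: str, seed: int):
    if model_name == "LR":
        return LogisticRegression(max_iter=2000)
    if model_name == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if model_name == "kNN":
        return KNeighborsClassifier(n_neighbors=3)
    if model_name == "SVM":
        return SVC(kernel="rbf")
    if model_name == "MLP":
        return MLPClassifier(max_iter=800, random_state=seed)
    raise ValueError(f"unknown model {model_name!r}; choose from {MODEL_NAMES}")


def fit_memoryless(
    X: np.ndarray,
    y: np.ndarray,
    model_name: str,
    grid: dict | None = None,
    *,
    cv: int = 3,
    seed: int = 0,
):
    """Fit one classical classifier, selecting grid points by weighted F1.

    Returns the fitted estimator with the chosen parameters recorded on
    ``.chosen_params_``.  A grid of size one (or ``grid={}``) skips the
    cross-validated search.
    """
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain at least two classes")
    est = _estimator(model_name, seed)
    if grid is None:
        grid = DEFAULT_GRIDS[model_name]
    n_points = int(np.prod([len(v) for v in grid.values()])) if grid else 1
    if n_points > 1:
        search = GridSearchCV(est, grid, scoring="f1_weighted", cv=cv, n_jobs=1)
        search.fit(X, y)
        model = search.best_estimator_
        model.chosen_params_ = dict(search.best_params_)
    else:
        params = {k: v[0] for k, v in grid.items()}
        est.set_params(**params)
        est.fit(X, y)
        model = est
        model.chosen_params_ = params
    logger.info("fit_memoryless(%s): chose %s", model_name, model.chosen_params_)
    return model


@dataclass
class SweepResult:
    reports: list[EvalReport]
    best_ns: int


def evaluate_at_ns(
    table: EpochTable,
    ns: int,
    cfg: TrainConfig,
    split_spec: SplitSpec | None = None,
    model: str = "lstm",
    feature_cols: list[str] | None = None,
) -> EvalReport:
    """Window → split → scale → train → score at one history depth."""
    import pandas as pd

    if split_spec is None:
        split_spec = SplitSpec(seed=cfg.seed)
    ds = make_windows(table, ns, feature_cols=feature_cols)
    train, test = split(ds, split_spec)
    # min-max scale with train-fitted bounds applied to both sides
    tr2 = train.X.reshape(len(train.X), -1)
    te2 = test.X.reshape(len(test.X), -1)
    tr_df, te_df, _ = minmax_scale(pd.DataFrame(tr2), pd.DataFrame(te2))
    Xtr = tr_df.to_numpy().reshape(train.X.shape)
    Xte = te_df.to_numpy().reshape(test.X.shape)

    if model == "lstm":
        fit = train_lstm(Xtr, train.y, cfg)
        y_pred = fit.predict(Xte)
        proba = fit.predict_proba(Xte)
    else:
        clf = fit_memoryless(
            Xtr.reshape(len(Xtr), -1), train.y, model,
            grid={}, seed=cfg.seed,
        )
        y_pred = clf.predict(Xte.reshape(len(Xte), -1))
        proba = None
    rep = score(test.y, y_pred, proba)
    rep.metadata.update({"model": model, "ns": ns, "seed": cfg.seed})
    return rep


def memory_sweep(
    table: EpochTable,
    ns_values: list[int],
    cfg: TrainConfig,
    split_spec: SplitSpec | None = None,
    model: str = "lstm",
) -> SweepResult:
    """Evaluate the model at each history depth; best ns by accuracy
    (first occurrence on ties)."""
    reports = [evaluate_at_ns(table, ns, cfg, split_spec, model) for ns in ns_values]
    accs = [r.accuracy for r in reports]
    best = ns_values[int(np.argmax(accs))]
    return SweepResult(reports=reports, best_ns=best)


def predict_sequence(
    model,
    night: EpochTable,
    ns: int,
    feature_cols: list[str] | None = None,
    scaler=None,
) -> EpochTable:
    """Roll a fitted model over one night, emitting a full predicted
    hypnogram aligned with the truth (the first ns epochs repeat the first
    available prediction)."""
    import pandas as pd

    ds = make_windows(night, ns, feature_cols=feature_cols)
    X = ds.X
    if scaler is not None:
        flat = scaler.transform(pd.DataFrame(X.reshape(len(X), -1)))
        X = np.asarray(flat).reshape(ds.X.shape)
    if isinstance(model, FittedLSTM):
        preds = model.predict(X)
    else:
        preds = model.predict(X.reshape(len(X), -1))
    full = np.r_[np.repeat(preds[:1], ns), preds]
    frame = pd.DataFrame({"stage": full}, index=night.timestamps[: len(full)])
    return EpochTable(frame, night.interval)
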