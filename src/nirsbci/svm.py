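"""Linear SVM classification, between-run adaptation and rest-bias correction.

The classifier is the canonical soft-margin linear SVM minimizing
0.5 * ||W||^2 + C * sum(slack) with unit-margin constraints; the decision
value is W'S - b and values >= 0 (after bias correction) map to the right
hand.  Between runs the model is retrained on the previous run (run 2) or
the previous two runs (run 3 onward).  Within a run, the mean decision
value over each rest block is subtracted from the following task block.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .features import FeatureTable, SelectorModel, fit_selector
from .montage import ChannelLayout

LABEL_SIGN = {"right": 1, "left": -1}
DEFAULT_C = 1.0


@dataclass
class TrainingSet:
    """Selected-feature training samples with +/-1 labels and provenance."""

    X: np.ndarray                       # (K, N)
    y: np.ndarray                       # (K,) +1 right, -1 left
    run_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if len(self.X) != len(self.y):
            raise ValueError("sample and label counts differ")
        if len(self.y) < 2 or len(np.unique(self.y)) < 2:
            raise ValueError("training needs at least two samples covering both classes")

    @property
    def n_samples(self) -> int:
        return len(self.y)


def training_set_from_tables(
    tables: Sequence[FeatureTable], selector: SelectorModel
) -> TrainingSet:
    """Task-block seconds of the given runs, restricted to selected channels."""
    xs, ys, runs = [], [], []
    for t in tables:
        m = t.task_mask
        xs.append(selector.transform(t.X[m]))
        ys.append(np.array([LABEL_SIGN[lab] for lab in t.label[m]]))
        runs.append(t.run_index)
    return TrainingSet(X=np.vstack(xs), y=np.concatenate(ys), run_indices=tuple(runs))


@dataclass
class SvmModel:
    """Trained linear discriminant W'S - b with training diagnostics."""

    w: np.ndarray
    b: float
    c_param: float = DEFAULT_C
    objective: float = float("nan")
    run_indices: tuple[int, ...] = ()

    @property
    def n_features(self) -> int:
        return len(self.w)

    def to_dict(self) -> dict:
        return {
            "w": list(map(float, self.w)),
            "b": float(self.b),
            "c_param": float(self.c_param),
            "objective": float(self.objective),
            "run_indices": list(self.run_indices),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SvmModel":
        return cls(
            w=np.asarray(d["w"], dtype=float),
            b=float(d["b"]),
            c_param=float(d["c_param"]),
            objective=float(d["objective"]),
            run_indices=tuple(d["run_indices"]),
        )


def train_linear_svm(data: TrainingSet, c_param: float = DEFAULT_C) -> SvmModel:
    """Fit the soft-margin linear SVM; decision function is W'S - b."""
    if c_param <= 0:
        raise ValueError(f"penalty must be positive, got {c_param}")
    clf = SVC(kernel="linear", C=c_param, tol=1e-10, shrinking=False)
    clf.fit(data.X, data.y)
    w = clf.coef_[0].copy()
    b = -float(clf.intercept_[0])
    margins = data.y * (data.X @ w - b)
    slack = np.maximum(0.0, 1.0 - margins)
    objective = 0.5 * float(w @ w) + c_param * float(slack.sum())
    return SvmModel(w=w, b=b, c_param=c_param, objective=objective, run_indices=data.run_indices)


def decision_value(model: SvmModel, s: np.ndarray) -> float:
    """W'.s - b for one selected-feature vector."""
    s = np.asarray(s, dtype=float).ravel()
    if len(s) != model.n_features:
        raise ValueError(f"expected {model.n_features} features, got {len(s)}")
    return float(model.w @ s - model.b)


def decision_values(model: SvmModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(f"expected {model.n_features} features, got {X.shape[1]}")
    return X @ model.w - model.b


def classify(model: SvmModel, s: np.ndarray, bias: float = 0.0) -> str:
    """Label the sample: right iff the bias-corrected value is >= 0."""
    return "right" if decision_value(model, s) - bias >= 0 else "left"


def training_runs_for(r: int) -> list[int]:
    """Runs whose data train the model applied during run ``r``.

    Run 2 is classified by a model built on run 1 alone; run 3 onward by a
    model built on the two preceding runs.  The model for run r never sees
    run r itself.
    """
    if r < 2:
        raise ValueError(f"no training data exists before run 2 (got r={r})")
    return [1] if r == 2 else [r - 2, r - 1]


def rest_bias(decision_values_during_rest: Sequence[float]) -> float:
    """Mean decision value over a rest block; subtracted from the next task block."""
    vals = np.asarray(decision_values_during_rest, dtype=float)
    if vals.size == 0:
        raise ValueError("rest trace is empty; cannot estimate a bias offset")
    return float(vals.mean())


@dataclass
class AdaptState:
    """Between-run adaptation bookkeeping: stored runs, current model, bias."""

    run_tables: dict[int, FeatureTable] = field(default_factory=dict)
    selector: SelectorModel | None = None
    model: SvmModel | None = None
    bias: float = 0.0

    def store_run(self, table: FeatureTable) -> None:
        self.run_tables[table.run_index] = table

    def retrain_for(
        self,
        r: int,
        layout: ChannelLayout,
        n_select: int,
        c_param: float = DEFAULT_C,
    ) -> tuple[SelectorModel, SvmModel]:
        """Refit feature selector and SVM for run ``r`` on the scheduled runs."""
        sources = training_runs_for(r)
        missing = [i for i in sources if i not in self.run_tables]
        if missing:
            raise ValueError(f"runs {missing} have not been stored; cannot retrain for run {r}")
        tables = [self.run_tables[i] for i in sources]
        self.selector = fit_selector(tables, layout, n_select)
        ts = training_set_from_tables(tables, self.selector)
        self.model = train_linear_svm(ts, c_param)
        return self.selector, self.model


def fit_model(
    tables: Sequence[FeatureTable],
    layout: ChannelLayout,
    n_select: int = 12,
    c_param: float = DEFAULT_C,
) -> tuple[SelectorModel, SvmModel]:
    """Feature selection then SVM training on the pooled task seconds."""
    selector = fit_selector(list(tables), layout, n_select)
    ts = training_set_from_tables(tables, selector)
    return selector, train_linear_svm(ts, c_param)


def build_subject_independent_model(
    subject_tables: Sequence[Sequence[FeatureTable]],
    layout: ChannelLayout,
    n_select: int = 12,
    c_param: float = DEFAULT_C,
) -> tuple[SelectorModel, SvmModel]:
    """One frozen selector+classifier from pooled multi-subject training runs.

    Feature selection and SVM training run once on the concatenated
    ensemble; the model is applied to new subjects without retraining
    (rest-bias correction stays active per run).
    """
    pooled: list[FeatureTable] = []
    for tables in subject_tables:
        for t in tables:
            if t.n_channels != layout.n_channels:
                raise ValueError(
                    f"run with {t.n_channels} channels cannot pool into a "
                    f"{layout.n_channels}-channel ensemble"
                )
            pooled.append(t)
    if not pooled:
        raise ValueError("no training runs supplied")
    return fit_model(pooled, layout, n_select, c_param)


def save_model(path, selector: SelectorModel, model: SvmModel, meta: dict | None = None) -> None:
    payload = {"selector": selector.to_dict(), "svm": model.to_dict(), "meta": meta or {}}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_model(path) -> tuple[SelectorModel, SvmModel, dict]:
    with open(path) as fh:
        payload = json.load(fh)
    return (
        SelectorModel.from_dict(payload["selector"]),
        SvmModel.from_dict(payload["svm"]),
        payload.get("meta", {}),
    )
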