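"""Streaming per-second classification, thermometer feedback, and the
run/experiment orchestration.

The online loop mirrors the deployed system: each elapsed second yields one
feature vector; during rest blocks the decision values accumulate to form
the bias offset for the following task block; during task blocks the
bias-corrected value is classified, scored, and fed to the thermometer
(one level up per correct classification, one down per error, reset to the
middle at block end and during rest).  Accuracy is the percentage of
correctly classified task seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureTable, SelectorModel, extract_features, fit_selector
from .montage import ChannelLayout
from .protocol import ExperimentPlan
from .svm import (
    LABEL_SIGN,
    AdaptState,
    SvmModel,
    decision_values,
    rest_bias,
    train_linear_svm,
    training_runs_for,
    training_set_from_tables,
)
from .synth import RunData

THERMOMETER_MAX = 10  # grade range [-10, +10]: a 20-level dynamic range


@dataclass(frozen=True)
class ThermometerState:
    grade: int = 0
    lo: int = -THERMOMETER_MAX
    hi: int = THERMOMETER_MAX

    def __post_init__(self) -> None:
        if not (self.lo <= self.grade <= self.hi):
            raise ValueError("thermometer grade outside its dynamic range")


def step_thermometer(
    state: ThermometerState, correct: bool, in_task: bool, block_ended: bool
) -> ThermometerState:
    """One feedback update: +/-1 within a task block, reset at rest/block end."""
    if block_ended or not in_task:
        return replace(state, grade=0)
    grade = state.grade + (1 if correct else -1)
    return replace(state, grade=int(np.clip(grade, state.lo, state.hi)))


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    operating_point: tuple[float, float]  # (FPR, TPR) at threshold 0


def evaluate_roc(decision_vals: np.ndarray, labels: np.ndarray) -> RocResult:
    """ROC over all thresholds (trapezoid AUC) plus the zero-threshold point.

    ``labels`` may be +/-1 integers or "left"/"right" strings; right is the
    positive class.
    """
    from sklearn.metrics import roc_curve

    v = np.asarray(decision_vals, dtype=float)
    y = np.asarray(labels)
    if y.dtype.kind in "UO":
        y = np.array([LABEL_SIGN[lab] for lab in y])
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = roc_curve(y, v, pos_label=1)
    auc = float(np.trapezoid(tpr, fpr))
    pred_pos = v >= 0
    pos, neg = y == 1, y == -1
    op = (float(pred_pos[neg].mean()), float(pred_pos[pos].mean()))
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc, operating_point=op)


@dataclass
class SessionResult:
    """Per-second traces and summary scores of one streamed run."""

    run_index: int
    task_type: str
    second: np.ndarray
    block_kind: np.ndarray
    block_index: np.ndarray
    label: np.ndarray                # true label per second
    raw_value: np.ndarray            # uncorrected decision trace
    bias_trace: np.ndarray           # offset applied at each second
    corrected_value: np.ndarray
    prediction: np.ndarray           # "left"/"right"/"" (rest)
    thermometer: np.ndarray
    feedback: bool
    accuracy_pct: float
    roc: RocResult | None
    model_runs: tuple[int, ...] = ()

    @property
    def task_mask(self) -> np.ndarray:
        return self.block_kind == "task"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "second": self.second,
                "block": self.block_kind,
                "label": self.label,
                "raw_value": self.raw_value,
                "bias": self.bias_trace,
                "corrected_value": self.corrected_value,
                "prediction": self.prediction,
                "thermometer": self.thermometer,
            }
        )

    def summary(self) -> dict:
        out = {
            "run_index": self.run_index,
            "task_type": self.task_type,
            "accuracy_pct": self.accuracy_pct,
            "n_task_seconds": int(self.task_mask.sum()),
            "model_runs": list(self.model_runs),
            "feedback": self.feedback,
        }
        if self.roc is not None:
            out["auc"] = self.roc.auc
            out["operating_point"] = list(self.roc.operating_point)
        return out


def run_online_session(
    run: RunData,
    selector: SelectorModel,
    model: SvmModel,
    feedback: bool = True,
) -> SessionResult:
    """Stream a run through the per-second classification loop."""
    if model.n_features != selector.n_select:
        raise ValueError(
            f"model expects {model.n_features} features but selector provides "
            f"{selector.n_select}"
        )
    if selector.layout_hash and selector.layout_hash != run.layout.layout_hash():
        raise ValueError("selector was fitted on a different channel layout")

    ft = extract_features(run)
    values = decision_values(model, selector.transform(ft.X))
    n = len(values)

    bias = 0.0
    rest_buffer: list[float] = []
    therm = ThermometerState()

    bias_trace = np.zeros(n)
    corrected = np.zeros(n)
    predictions = np.full(n, "", dtype=object)
    thermo_trace = np.zeros(n, dtype=int)
    n_correct = 0
    n_task = 0

    for i in range(n):
        in_task = ft.block_kind[i] == "task"
        block_ended = i + 1 >= n or ft.block_index[i + 1] != ft.block_index[i]
        if in_task:
            bias_trace[i] = bias
            corrected[i] = values[i] - bias
            pred = "right" if corrected[i] >= 0 else "left"
            predictions[i] = pred
            correct = pred == ft.label[i]
            n_correct += int(correct)
            n_task += 1
            therm = step_thermometer(therm, correct, True, block_ended)
        else:
            bias_in_effect = bias
            rest_buffer.append(values[i])
            if block_ended:
                # a completed rest block fixes the bias of the next task block
                bias = rest_bias(rest_buffer)
                rest_buffer = []
            bias_trace[i] = bias_in_effect
            corrected[i] = values[i] - bias_in_effect
            therm = step_thermometer(therm, False, False, block_ended)
        thermo_trace[i] = therm.grade

    accuracy = 100.0 * n_correct / n_task if n_task else float("nan")
    task = ft.block_kind == "task"
    roc = None
    if task.any() and len(np.unique(ft.label[task])) == 2:
        roc = evaluate_roc(corrected[task], ft.label[task])

    return SessionResult(
        run_index=run.spec.run_index,
        task_type=run.task_type,
        second=ft.second,
        block_kind=ft.block_kind,
        block_index=ft.block_index,
        label=ft.label,
        raw_value=values,
        bias_trace=bias_trace,
        corrected_value=corrected,
        prediction=np.asarray(predictions, dtype=object),
        thermometer=thermo_trace,
        feedback=feedback,
        accuracy_pct=accuracy,
        roc=roc,
        model_runs=model.run_indices,
    )


def trial_averaged_decision(
    results: SessionResult | Sequence[SessionResult],
) -> tuple[np.ndarray, np.ndarray]:
    """Label-aligned average of the bias-corrected decision output.

    Task-block outputs (from one or several streamed sessions) are aligned
    to cue onset and signed so the correct direction is positive; returns
    (seconds_after_onset, mean trace) over the offsets every block covers.
    """
    if isinstance(results, SessionResult):
        results = [results]
    traces = []
    for result in results:
        task = result.task_mask
        for b in np.unique(result.block_index[task]):
            m = result.block_index == b
            sign = LABEL_SIGN[result.label[m][0]]
            traces.append(sign * result.corrected_value[m])
    if not traces:
        raise ValueError("no task blocks to average")
    min_len = min(len(tr) for tr in traces)
    stacked = np.vstack([tr[:min_len] for tr in traces])
    return np.arange(1, min_len + 1, dtype=float), stacked.mean(axis=0)


def decision_peak_latency(
    results: SessionResult | Sequence[SessionResult], refine: bool = True
) -> float:
    """Seconds from cue onset to the peak of the trial-averaged output.

    The classifier output at second k integrates data from (k-1, k] after
    onset, so the raw latency is the 1-based index of the peak bin.  With
    ``refine`` the average is lightly smoothed and the peak position
    interpolated by a parabolic fit through the three bins around the
    maximum, giving a sub-second estimate that is robust to bin-level noise.
    """
    offsets, mean_trace = trial_averaged_decision(results)
    if not refine or len(mean_trace) < 3:
        return float(offsets[int(np.argmax(mean_trace))])
    s = np.convolve(mean_trace, [0.25, 0.5, 0.25], mode="same")
    s[0], s[-1] = mean_trace[0], mean_trace[-1]
    k = int(np.argmax(s))
    delta = 0.0
    if 0 < k < len(s) - 1:
        curvature = s[k - 1] - 2.0 * s[k] + s[k + 1]
        if curvature < 0:
            delta = float(np.clip(0.5 * (s[k - 1] - s[k + 1]) / curvature, -0.5, 0.5))
    return float(offsets[k] + delta)


def crossvalidate_5fold(
    tables: FeatureTable | Sequence[FeatureTable],
    layout: ChannelLayout,
    seed: int = 0,
    n_select: int = 12,
    c_param: float = 1.0,
    n_folds: int = 5,
) -> tuple[float, float, list[float]]:
    """Seeded k-fold accuracy (mean %, sd %, per-fold) with per-fold selection.

    Task seconds are randomly split into five near-equal subsets; each fold
    refits the feature selector and the SVM on the other four.
    """
    if isinstance(tables, FeatureTable):
        tables = [tables]
    X = np.vstack([t.X[t.task_mask] for t in tables])
    y = np.concatenate([t.label[t.task_mask] for t in tables])
    K = len(y)
    if K < 2 * n_folds:
        raise ValueError(f"{K} task seconds are too few for {n_folds}-fold validation")

    rng = np.random.default_rng(seed)
    order = rng.permutation(K)
    folds = np.array_split(order, n_folds)

    accs = []
    for held_out in folds:
        train_idx = np.setdiff1d(order, held_out, assume_unique=False)
        pseudo = FeatureTable(
            second=np.arange(1, len(train_idx) + 1),
            X=X[train_idx],
            label=y[train_idx],
            block_kind=np.full(len(train_idx), "task"),
            block_index=np.zeros(len(train_idx), dtype=int),
        )
        selector = fit_selector(pseudo, layout, n_select)
        ts = training_set_from_tables([pseudo], selector)
        model = train_linear_svm(ts, c_param)
        vals = decision_values(model, selector.transform(X[held_out]))
        pred = np.where(vals >= 0, "right", "left")
        accs.append(100.0 * float((pred == y[held_out]).mean()))
    return float(np.mean(accs)), float(np.std(accs)), accs


@dataclass
class ExperimentResult:
    plan: ExperimentPlan
    sessions: dict[int, SessionResult]

    def accuracy_table(self) -> pd.DataFrame:
        rows = [
            {
                "run": r,
                "task_type": s.task_type,
                "accuracy_pct": s.accuracy_pct,
                "auc": s.roc.auc if s.roc else float("nan"),
                "model_runs": ",".join(map(str, s.model_runs)),
            }
            for r, s in sorted(self.sessions.items())
        ]
        return pd.DataFrame(rows)


def run_experiment(
    plan: ExperimentPlan,
    subject_runs: Sequence[RunData],
    sic: tuple[SelectorModel, SvmModel] | None = None,
    n_select: int = 12,
    c_param: float = 1.0,
) -> ExperimentResult:
    """Orchestrate one subject's session per the experiment plan.

    Subject-dependent plans retrain between runs (run r's model sees runs
    r-1 and r-2 only, never run r).  The subject-independent plan applies
    the supplied frozen model to every test run.
    """
    if len(subject_runs) != plan.n_runs:
        raise ValueError(f"plan expects {plan.n_runs} runs, got {len(subject_runs)}")
    for run, task_type in zip(subject_runs, plan.run_task_types):
        if run.task_type != task_type:
            raise ValueError(
                f"run {run.spec.run_index} is {run.task_type} but the plan says {task_type}"
            )
    if plan.subject_independent and sic is None:
        raise ValueError("experiment 3 requires a subject-independent model")

    layout = subject_runs[0].layout
    sessions: dict[int, SessionResult] = {}

    if plan.subject_independent:
        selector, model = sic
        for r in plan.test_runs:
            sessions[r] = run_online_session(
                subject_runs[r - 1], selector, model, feedback=r in plan.feedback_runs
            )
        return ExperimentResult(plan=plan, sessions=sessions)

    state = AdaptState()
    for run in subject_runs:
        state.store_run(extract_features(run))
    for r in plan.test_runs:
        selector, model = state.retrain_for(r, layout, n_select, c_param)
        assert r not in model.run_indices, "training data leaked from the tested run"
        sessions[r] = run_online_session(
            subject_runs[r - 1], selector, model, feedback=r in plan.feedback_runs
        )
    return ExperimentResult(plan=plan, sessions=sessions)


def channel_tmap(run: RunData, alpha: float = 0.001, adjust: bool = True) -> pd.DataFrame:
    """Per-channel two-sample t of task vs. rest feature seconds, per class.

    Flags channels whose p-value clears ``alpha`` (Bonferroni-adjusted over
    channels when ``adjust``).  Channels with degenerate (constant) data get
    an NA flag instead of a statistic.
    """
    ft = extract_features(run)
    rest = ft.X[ft.block_kind == "rest"]
    if rest.size == 0:
        raise ValueError("run has no rest seconds")
    rows = []
    m = run.layout.n_channels
    threshold = alpha / m if adjust else alpha
    for cls in ("left", "right"):
        task_cls = ft.X[ft.label == cls]
        if task_cls.size == 0:
            continue
        for ch in range(m):
            a, b = task_cls[:, ch], rest[:, ch]
            if np.ptp(a) == 0 and np.ptp(b) == 0:
                rows.append(
                    {"channel": ch + 1, "class": cls, "t": float("nan"),
                     "p": float("nan"), "significant": False, "na": True}
                )
                continue
            t, p = stats.ttest_ind(a, b, equal_var=True)
            rows.append(
                {"channel": ch + 1, "class": cls, "t": float(t), "p": float(p),
                 "significant": bool(p < threshold), "na": False}
            )
    return pd.DataFrame(rows)
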