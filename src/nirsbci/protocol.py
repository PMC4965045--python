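"""Block-design run schedules and the three experiment paradigms.

A run is an alternating sequence of rest and task blocks, beginning and
ending with rest (the canonical run has six task blocks separated by seven
rest blocks).  Task blocks are labelled left or right hand in a balanced,
seeded random order.  Experiments 1-3 differ in which runs use motor
execution (ME) vs. motor imagery (MI), which runs train the classifier,
and whether the classifier is subject-independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

BlockKind = Literal["rest", "task"]
TaskClass = Literal["left", "right", "none"]
TaskType = Literal["ME", "MI"]


@dataclass(frozen=True)
class Block:
    kind: BlockKind
    label: TaskClass
    duration_s: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(f"block duration must be positive, got {self.duration_s}")
        if self.kind == "rest" and self.label != "none":
            raise ValueError("rest blocks carry no class label")
        if self.kind == "task" and self.label not in ("left", "right"):
            raise ValueError(f"task blocks must be labelled left/right, got {self.label!r}")


@dataclass(frozen=True)
class RunSpec:
    """One run's block schedule plus its identity within an experiment."""

    blocks: tuple[Block, ...]
    task_type: TaskType
    run_index: int
    seed: int

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("a run needs at least one block")
        if self.blocks[0].kind != "rest" or self.blocks[-1].kind != "rest":
            raise ValueError("a run must begin and end with a rest block")
        for a, b in zip(self.blocks, self.blocks[1:]):
            if a.kind == b.kind:
                raise ValueError("rest and task blocks must strictly alternate")
        labels = [b.label for b in self.blocks if b.kind == "task"]
        if labels.count("left") != labels.count("right"):
            raise ValueError("task labels must be balanced between left and right")

    @property
    def n_task_blocks(self) -> int:
        return sum(1 for b in self.blocks if b.kind == "task")

    @property
    def duration_s(self) -> float:
        return sum(b.duration_s for b in self.blocks)

    @property
    def block_onsets_s(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum([b.duration_s for b in self.blocks])[:-1]])

    def to_dict(self) -> dict:
        return {
            "task_type": self.task_type,
            "run_index": self.run_index,
            "seed": self.seed,
            "blocks": [
                {"kind": b.kind, "label": b.label, "duration_s": b.duration_s}
                for b in self.blocks
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunSpec":
        return cls(
            blocks=tuple(Block(b["kind"], b["label"], b["duration_s"]) for b in d["blocks"]),
            task_type=d["task_type"],
            run_index=d["run_index"],
            seed=d["seed"],
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "RunSpec":
        return cls.from_dict(json.loads(s))


def make_run_spec(
    n_task_blocks: int = 6,
    task_type: TaskType = "ME",
    task_dur_s: float = 20.0,
    rest_dur_s: float = 20.0,
    run_index: int = 1,
    seed: int = 0,
) -> RunSpec:
    """Build a balanced alternating rest/task schedule.

    ``n_task_blocks`` task blocks are separated by ``n_task_blocks + 1`` rest
    blocks; exactly half the task blocks are labelled left and half right,
    in a uniformly random order drawn from ``seed``.  ``n_task_blocks`` must
    therefore be even (zero gives a single rest block).
    """
    if n_task_blocks < 0 or n_task_blocks % 2 != 0:
        raise ValueError(
            f"n_task_blocks must be even and >= 0 for left/right balance, got {n_task_blocks}"
        )
    if task_dur_s <= 0 or rest_dur_s <= 0:
        raise ValueError("block durations must be positive")

    half = n_task_blocks // 2
    labels = ["left"] * half + ["right"] * half
    rng = np.random.default_rng(seed)
    labels = [labels[i] for i in rng.permutation(n_task_blocks)]

    blocks: list[Block] = [Block("rest", "none", rest_dur_s)]
    for lab in labels:
        blocks.append(Block("task", lab, task_dur_s))
        blocks.append(Block("rest", "none", rest_dur_s))
    return RunSpec(blocks=tuple(blocks), task_type=task_type, run_index=run_index, seed=seed)


def sample_timeline(
    spec: RunSpec, fs: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample (time_s, block kind, class label, block index) at rate ``fs``.

    Timestamps are exactly ``j / fs``; no resampling at non-integer rates.
    """
    if fs <= 0:
        raise ValueError(f"sampling frequency must be positive, got {fs}")
    n = int(np.floor(spec.duration_s * fs - 1e-9)) + 1
    t = np.arange(n) / fs
    edges = np.cumsum([b.duration_s for b in spec.blocks])
    block_idx = np.searchsorted(edges, t, side="right")
    block_idx = np.clip(block_idx, 0, len(spec.blocks) - 1)
    kind = np.array([spec.blocks[i].kind for i in block_idx])
    label = np.array([spec.blocks[i].label for i in block_idx])
    return t, kind, label, block_idx


@dataclass(frozen=True)
class ExperimentPlan:
    """Which runs use ME vs. MI, which train, and which receive feedback."""

    experiment_id: int
    run_task_types: tuple[TaskType, ...]
    training_runs: tuple[int, ...]
    test_runs: tuple[int, ...]
    feedback_runs: tuple[int, ...]
    subject_independent: bool = False

    @property
    def n_runs(self) -> int:
        return len(self.run_task_types)

    def to_dict(self) -> dict:
        return {
            "experiment_id": self.experiment_id,
            "run_task_types": list(self.run_task_types),
            "training_runs": list(self.training_runs),
            "test_runs": list(self.test_runs),
            "feedback_runs": list(self.feedback_runs),
            "subject_independent": self.subject_independent,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def experiment_plan(experiment_id: int) -> ExperimentPlan:
    """The three five-run paradigms.

    Experiment 1: three ME runs then two MI runs; runs 1-2 train, the rest
    are tested with between-run retraining and feedback.
    Experiment 2: four MI runs then an ME run; run 1 trains.
    Experiment 3: the classifier is supplied externally (subject-independent,
    pooled from other subjects' ME data); runs 2-5 are tested, feedback in
    every run, no retraining.
    """
    if experiment_id == 1:
        return ExperimentPlan(
            experiment_id=1,
            run_task_types=("ME", "ME", "ME", "MI", "MI"),
            training_runs=(1, 2),
            test_runs=(3, 4, 5),
            feedback_runs=(3, 4, 5),
        )
    if experiment_id == 2:
        return ExperimentPlan(
            experiment_id=2,
            run_task_types=("MI", "MI", "MI", "MI", "ME"),
            training_runs=(1,),
            test_runs=(2, 3, 4, 5),
            feedback_runs=(2, 3, 4, 5),
        )
    if experiment_id == 3:
        return ExperimentPlan(
            experiment_id=3,
            run_task_types=("ME", "MI", "MI", "MI", "ME"),
            training_runs=(),
            test_runs=(2, 3, 4, 5),
            feedback_runs=(1, 2, 3, 4, 5),
            subject_independent=True,
        )
    raise ValueError(f"unknown experiment id {experiment_id}; must be 1, 2 or 3")
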