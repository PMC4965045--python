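"""Per-second feature extraction and mutual-information channel selection.

The feature of channel n at second k is the sum of that channel's HbO
samples with timestamps in [k-1, k) — at a 7.69 Hz rate the window holds
7 or 8 samples.  Channels are ranked by the mutual information between
their feature and the binary left/right task label, I(F; w) = H(w) - H(w|F),
with the class-conditional densities estimated by a Gaussian Parzen window
(per-class Silverman bandwidth).  The best-individual-feature selector
keeps the top N/2 channels per hemisphere (N = 12 by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .montage import ChannelLayout
from .synth import RunData

DEFAULT_N_SELECT = 12


@dataclass
class FeatureTable:
    """Per-second feature vectors of one run, with block annotation.

    ``X[k - 1, n - 1]`` is channel n's feature at the k-th elapsed second.
    """

    second: np.ndarray       # (K,) 1-based second index within the run
    X: np.ndarray            # (K, n_channels)
    label: np.ndarray        # (K,) "left"/"right"/"none"
    block_kind: np.ndarray   # (K,) "rest"/"task"
    block_index: np.ndarray  # (K,)
    run_index: int = 0
    task_type: str = "ME"

    @property
    def n_channels(self) -> int:
        return self.X.shape[1]

    @property
    def task_mask(self) -> np.ndarray:
        return self.block_kind == "task"

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"second": self.second, "block": self.block_kind, "label": self.label}
        )
        for n in range(self.n_channels):
            df[f"ch{n + 1:02d}"] = self.X[:, n]
        return df


def extract_features(run: RunData) -> FeatureTable:
    """Sum each channel's HbO samples over consecutive one-second windows.

    One feature vector per elapsed second; the vector carries the block
    kind and class label of the window's first sample.
    """
    sec_of_sample = np.floor(run.time_s).astype(int)
    n_seconds = int(sec_of_sample[-1]) + 1

    X = np.zeros((n_seconds, run.n_channels))
    np.add.at(X, sec_of_sample, run.hbo)

    first_sample = np.searchsorted(sec_of_sample, np.arange(n_seconds), side="left")
    return FeatureTable(
        second=np.arange(1, n_seconds + 1),
        X=X,
        label=run.label[first_sample],
        block_kind=run.block_kind[first_sample],
        block_index=run.block_index[first_sample],
        run_index=run.spec.run_index,
        task_type=run.task_type,
    )


def _silverman_bandwidth(x: np.ndarray) -> float:
    sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    if sd == 0.0:
        sd = max(abs(float(np.mean(x))), 1.0) * 1e-6  # degenerate class: near-delta kernel
    return 1.06 * sd * len(x) ** (-0.2)


def parzen_mi(features: np.ndarray, labels: np.ndarray) -> float:
    """Mutual information (bits) between one scalar feature and a binary label.

    I = H(w) - H(w|F).  Class priors come from label frequencies; p(w|f)
    from Gaussian-kernel class-conditional Parzen densities with a
    per-class Silverman bandwidth; H(w|F) is the sample average of the
    pointwise conditional entropy.  The result is clipped to [0, H(w)].
    """
    x = np.asarray(features, dtype=float).ravel()
    y = np.asarray(labels).ravel()
    if len(x) != len(y):
        raise ValueError("features and labels must have equal length")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"labels must contain exactly two classes, got {len(classes)}")
    groups = [x[y == c] for c in classes]
    if min(len(g) for g in groups) < 2:
        raise ValueError("need at least two samples per class")

    priors = np.array([len(g) / len(x) for g in groups])
    h_class = float(-(priors * np.log2(priors)).sum())

    # class-conditional Parzen densities evaluated at every sample
    dens = np.empty((len(x), 2))
    for j, g in enumerate(groups):
        h = _silverman_bandwidth(g)
        z = (x[:, None] - g[None, :]) / h
        dens[:, j] = np.exp(-0.5 * z**2).sum(axis=1) / (len(g) * h * np.sqrt(2.0 * np.pi))

    joint = dens * priors[None, :]
    total = joint.sum(axis=1)
    total[total <= 0] = np.finfo(float).tiny
    post = joint / total[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(post > 0, post * np.log2(post), 0.0)
    h_cond = float(-plogp.sum(axis=1).mean())

    return float(np.clip(h_class - h_cond, 0.0, h_class))


@dataclass
class SelectorModel:
    """Per-channel MI scores and the selected channel subset."""

    mi_scores: np.ndarray          # (n_channels,) bits
    selected: tuple[int, ...]      # 1-based channel indices, ascending
    n_select: int
    layout_hash: str = ""

    def __post_init__(self) -> None:
        if len(self.selected) != self.n_select:
            raise ValueError("selected subset size does not match n_select")
        if np.any(np.asarray(self.mi_scores) < 0):
            raise ValueError("MI scores must be non-negative")

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Restrict a (K, n_channels) feature matrix to the selected channels."""
        return np.asarray(X)[:, [i - 1 for i in self.selected]]

    def to_dict(self) -> dict:
        return {
            "mi_scores": list(map(float, self.mi_scores)),
            "selected": list(self.selected),
            "n_select": self.n_select,
            "layout_hash": self.layout_hash,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SelectorModel":
        return cls(
            mi_scores=np.asarray(d["mi_scores"], dtype=float),
            selected=tuple(d["selected"]),
            n_select=d["n_select"],
            layout_hash=d.get("layout_hash", ""),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def score_channels(tables: "FeatureTable | list[FeatureTable]") -> np.ndarray:
    """Per-channel MI between the feature and the left/right label.

    Only task-block seconds enter the estimate; rest seconds carry no class.
    Accepts one table or a list to be pooled.
    """
    if isinstance(tables, FeatureTable):
        tables = [tables]
    X = np.vstack([t.X[t.task_mask] for t in tables])
    y = np.concatenate([t.label[t.task_mask] for t in tables])
    return np.array([parzen_mi(X[:, n], y) for n in range(X.shape[1])])


def select_channels(
    mi_scores: np.ndarray, layout: ChannelLayout, n_select: int = DEFAULT_N_SELECT
) -> SelectorModel:
    """Keep the N/2 highest-MI channels per hemisphere; ties favour lower index."""
    scores = np.asarray(mi_scores, dtype=float)
    if len(scores) != layout.n_channels:
        raise ValueError(
            f"got {len(scores)} scores for a {layout.n_channels}-channel layout"
        )
    if n_select < 0 or n_select % 2 != 0:
        raise ValueError(f"n_select must be even for hemisphere balance, got {n_select}")
    if n_select > layout.n_channels:
        raise ValueError("cannot select more channels than the layout provides")

    half = n_select // 2
    selected: list[int] = []
    for hemi in ("left", "right"):
        members = layout.hemisphere_channels(hemi)
        if len(members) < half:
            raise ValueError(f"{hemi} hemisphere has fewer than {half} channels")
        ranked = sorted(members, key=lambda i: (-scores[i - 1], i))
        selected.extend(ranked[:half])

    return SelectorModel(
        mi_scores=scores,
        selected=tuple(sorted(selected)),
        n_select=n_select,
        layout_hash=layout.layout_hash(),
    )


def fit_selector(
    tables: "FeatureTable | list[FeatureTable]",
    layout: ChannelLayout,
    n_select: int = DEFAULT_N_SELECT,
) -> SelectorModel:
    """Score all channels on task seconds and select the best subset."""
    return select_channels(score_channels(tables), layout, n_select)


def mi_map(selector: SelectorModel, layout: ChannelLayout) -> pd.DataFrame:
    """Grid-position table of MI scores with the selected channels flagged."""
    chosen = set(selector.selected)
    rows = []
    for ch in layout.channels:
        rows.append(
            {
                "channel": ch.index,
                "x_mm": ch.midpoint_mm[0],
                "y_mm": ch.midpoint_mm[1],
                "hemisphere": ch.hemisphere,
                "mi_bits": float(selector.mi_scores[ch.index - 1]),
                "selected": ch.index in chosen,
            }
        )
    return pd.DataFrame(rows)
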