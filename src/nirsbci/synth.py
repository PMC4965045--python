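"""Synthetic multi-channel HbO/HbR run generation.

Each task block drives a hemodynamic response in a small "motor area"
subset of channels: the hemisphere contralateral to the moving hand at
full gain, the ipsilateral homologues at a reduced gain.  The response is
a neural drive convolved with a canonical double-gamma impulse response.
The drive is a boxcar with a phasic onset component that habituates over a
few seconds toward a smaller sustained plateau, so the evoked output peaks
3-5 s after cue onset and then declines — the temporal signature the
classifier output is expected to reproduce.  Motor imagery differs from
execution by a global amplitude factor ``mi_gain`` < 1 and a slightly
anterior, broader active-channel subset.  All channels additionally carry
white noise, Mayer-wave/respiratory/cardiac oscillations and slow linear
drift.  HbR mirrors HbO inverted, smaller and lagged.

Everything is deterministic given (spec, params, seed).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import gamma as _gamma

from .montage import ChannelLayout
from .protocol import ExperimentPlan, RunSpec, make_run_spec, sample_timeline


@dataclass(frozen=True)
class HemoParams:
    """Hemodynamic and noise parameters of the generator (amplitudes in uM)."""

    fs: float = 7.69

    # impulse response; defaults calibrated so the trial-averaged classifier
    # output peaks 3-5 s after cue onset at the default SNR
    peak_delay_s: float = 2.1
    undershoot_delay_s: float = 5.0
    undershoot_ratio: float = 0.6

    # neural drive: phasic onset habituating toward a sustained plateau
    sustained_gain: float = 0.16
    habituation_tau_s: float = 0.5

    # response amplitudes
    hbo_amp_um: float = 0.5
    mi_gain: float = 0.6
    hbr_ratio: float = 0.35
    hbr_lag_s: float = 1.0
    contra_gain: float = 1.0
    ipsi_gain: float = 0.3

    # nuisance terms
    noise_sd_um: float = 0.45
    mayer_amp_um: float = 0.15
    mayer_freq_hz: float = 0.1
    resp_amp_um: float = 0.1
    resp_freq_hz: float = 0.3
    cardiac_amp_um: float = 0.05
    cardiac_freq_hz: float = 1.1
    drift_slope_um_per_s: float = 0.002

    active_channel_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not (0 < self.mi_gain <= 1):
            raise ValueError(f"mi_gain must be in (0, 1], got {self.mi_gain}")
        if not (0 <= self.ipsi_gain < self.contra_gain):
            raise ValueError("ipsi_gain must be in [0, contra_gain)")
        if self.peak_delay_s <= 0 or self.undershoot_delay_s <= 0:
            raise ValueError("response delays must be positive")
        if self.habituation_tau_s <= 0:
            raise ValueError("habituation_tau_s must be positive")
        if not (0 <= self.sustained_gain <= 1):
            raise ValueError("sustained_gain must be in [0, 1]")
        if not (0 < self.active_channel_fraction <= 1):
            raise ValueError("active_channel_fraction must be in (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


@lru_cache(maxsize=32)
def _hrf_calibration(
    peak_delay_s: float, undershoot_delay_s: float, undershoot_ratio: float
) -> tuple[float, float]:
    """(positive-lobe gamma shape, peak value) such that the combined
    double-gamma attains its maximum at ``peak_delay_s`` exactly.

    The undershoot pulls the combined peak earlier than the positive lobe's
    mode, so the lobe is recentred by fixed-point iteration.
    """
    t = np.arange(0.0, max(peak_delay_s, undershoot_delay_s) * 8.0, 0.002)
    mode = peak_delay_s
    for _ in range(40):
        v = _gamma.pdf(t, mode + 1.0) - undershoot_ratio * _gamma.pdf(
            t, undershoot_delay_s + 1.0
        )
        argmax = t[int(np.argmax(v))]
        err = peak_delay_s - argmax
        if abs(err) < 0.002:
            break
        mode += err
        if mode <= 0:
            raise ValueError("cannot place the response peak at the requested delay")
    return mode, float(v.max())


def canonical_hrf(t, params: HemoParams | None = None) -> np.ndarray | float:
    """Double-gamma hemodynamic impulse response, peak-normalized to 1.

    Causal (zero for t < 0), single positive peak at ``peak_delay_s``
    followed by an undershoot, decaying to zero.
    """
    p = params if params is not None else HemoParams()
    if p.peak_delay_s <= 0 or p.undershoot_delay_s <= 0:
        raise ValueError("response delays must be positive")
    mode, peak = _hrf_calibration(p.peak_delay_s, p.undershoot_delay_s, p.undershoot_ratio)
    t_arr = np.asarray(t, dtype=float)
    v = _gamma.pdf(t_arr, mode + 1.0) - p.undershoot_ratio * _gamma.pdf(
        t_arr, p.undershoot_delay_s + 1.0
    )
    v = np.where(t_arr < 0, 0.0, v) / peak
    return float(v) if np.isscalar(t) else v


@dataclass
class RunData:
    """Sampled HbO/HbR series plus the per-sample block annotation."""

    spec: RunSpec
    layout: ChannelLayout
    fs: float
    time_s: np.ndarray              # (n_samples,)
    hbo: np.ndarray                 # (n_samples, n_channels), uM change
    hbr: np.ndarray                 # (n_samples, n_channels), uM change
    block_kind: np.ndarray          # (n_samples,) "rest"/"task"
    label: np.ndarray               # (n_samples,) "left"/"right"/"none"
    block_index: np.ndarray         # (n_samples,)
    task_type: str = "ME"
    seed: int | None = None
    params: HemoParams | None = None

    def __post_init__(self) -> None:
        n = len(self.time_s)
        for name in ("hbo", "hbr", "block_kind", "label", "block_index"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match the time axis")
        if self.hbo.shape[1] != self.layout.n_channels:
            raise ValueError(
                f"series has {self.hbo.shape[1]} channels but layout declares "
                f"{self.layout.n_channels}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.time_s)

    @property
    def n_channels(self) -> int:
        return self.layout.n_channels


def _drive_envelope(t_in_block: np.ndarray, params: HemoParams) -> np.ndarray:
    """Neural drive at ``t_in_block`` seconds after block onset."""
    phasic = np.exp(-t_in_block / params.habituation_tau_s)
    return params.sustained_gain + (1.0 - params.sustained_gain) * phasic


def _response_scale(params: HemoParams, block_dur_s: float) -> float:
    """Peak of one block's drive*HRF response, used to express amplitudes in uM."""
    dt = 1.0 / params.fs
    t = np.arange(0.0, block_dur_s + 40.0, dt)
    drive = np.where(t < block_dur_s, _drive_envelope(np.minimum(t, block_dur_s), params), 0.0)
    kern = canonical_hrf(np.arange(0.0, 40.0, dt), params)
    resp = np.convolve(drive, kern)[: len(t)] * dt
    peak = float(np.max(np.abs(resp)))
    return peak if peak > 0 else 1.0


def active_channel_sets(
    layout: ChannelLayout,
    params: HemoParams,
    task_type: str = "ME",
    center_jitter_mm: tuple[float, float] = (0.0, 0.0),
) -> dict[str, list[int]]:
    """Designated "motor area" channel subset per hemisphere (1-based indices).

    Channels nearest the grid centre are chosen; imagery uses a slightly
    anterior target (one optode spacing toward the top row) and a slightly
    broader subset, reflecting the more anterior activation pattern of
    covert movement.
    """
    out: dict[str, list[int]] = {}
    for grid in layout.grids:
        cx = grid.x_offset_mm + (grid.cols - 1) * grid.spacing_mm / 2.0
        cy = (grid.rows - 1) * grid.spacing_mm / 2.0
        if task_type == "MI":
            cy -= 0.5 * grid.spacing_mm  # anterior shift by one channel position
        cx += center_jitter_mm[0]
        cy += center_jitter_mm[1]
        members = [ch for ch in layout.channels if ch.hemisphere == grid.hemisphere]
        frac = params.active_channel_fraction + (0.08 if task_type == "MI" else 0.0)
        n_active = max(1, int(round(frac * len(members))))
        dist = [
            ((ch.midpoint_mm[0] - cx) ** 2 + (ch.midpoint_mm[1] - cy) ** 2, ch.index)
            for ch in members
        ]
        dist.sort()
        out[grid.hemisphere] = sorted(idx for _, idx in dist[:n_active])
    return out


def generate_run(
    spec: RunSpec,
    layout: ChannelLayout,
    params: HemoParams | None = None,
    seed: int = 0,
    amp_scale: float = 1.0,
    center_jitter_mm: tuple[float, float] = (0.0, 0.0),
) -> RunData:
    """Generate one synthetic run.

    For each task block of class ``c``, active channels in the hemisphere
    contralateral to ``c`` receive the drive*HRF response scaled to
    ``hbo_amp_um`` (times ``mi_gain`` for imagery runs); their ipsilateral
    homologues receive the ``ipsi_gain``-scaled response.  HbR receives the
    inverted, ``hbr_ratio``-scaled and ``hbr_lag_s``-delayed response.
    Noise, physiological oscillations and linear drift are added to every
    channel from the given seed.
    """
    p = params if params is not None else HemoParams()
    rng = np.random.default_rng(seed)
    t, kind, label, block_idx = sample_timeline(spec, p.fs)
    n = len(t)
    n_ch = layout.n_channels
    dt = 1.0 / p.fs

    hbo = np.zeros((n, n_ch))
    hbr = np.zeros((n, n_ch))

    amp = p.hbo_amp_um * amp_scale * (p.mi_gain if spec.task_type == "MI" else 1.0)
    active = active_channel_sets(layout, p, spec.task_type, center_jitter_mm)

    if amp != 0.0 and spec.n_task_blocks > 0:
        # per-class neural drive over the run
        task_durs = {b.duration_s for b in spec.blocks if b.kind == "task"}
        scale = 1.0 / _response_scale(p, max(task_durs))
        kern = canonical_hrf(np.arange(0.0, 40.0, dt), p)

        onsets = spec.block_onsets_s
        responses: dict[str, np.ndarray] = {}
        for cls in ("left", "right"):
            drive = np.zeros(n)
            mask = label == cls
            if mask.any():
                onset_per_sample = onsets[block_idx]
                drive[mask] = _drive_envelope(t[mask] - onset_per_sample[mask], p)
            responses[cls] = np.convolve(drive, kern)[:n] * dt * scale

        lag = int(round(p.hbr_lag_s * p.fs))
        for cls, contra_hemi in (("left", "right"), ("right", "left")):
            resp = responses[cls] * amp
            resp_lagged = np.concatenate([np.zeros(lag), resp[: n - lag]]) if lag else resp
            for hemi, gain in ((contra_hemi, p.contra_gain), (_other(contra_hemi), p.ipsi_gain)):
                for ch in active[hemi] if hemi in active else []:
                    hbo[:, ch - 1] += gain * resp
                    hbr[:, ch - 1] -= gain * p.hbr_ratio * resp_lagged

    # nuisance terms (drawn in a fixed order for determinism)
    if p.noise_sd_um > 0:
        hbo += rng.normal(0.0, p.noise_sd_um, (n, n_ch))
        hbr += rng.normal(0.0, p.noise_sd_um / 3.0, (n, n_ch))
    for amp_osc, freq in (
        (p.mayer_amp_um, p.mayer_freq_hz),
        (p.resp_amp_um, p.resp_freq_hz),
        (p.cardiac_amp_um, p.cardiac_freq_hz),
    ):
        if amp_osc > 0:
            phases = rng.uniform(0.0, 2.0 * np.pi, n_ch)
            osc = amp_osc * np.sin(2.0 * np.pi * freq * t[:, None] + phases[None, :])
            hbo += osc
            hbr += osc / 3.0
    if p.drift_slope_um_per_s != 0:
        slopes = p.drift_slope_um_per_s * rng.uniform(-1.0, 1.0, n_ch)
        hbo += t[:, None] * slopes[None, :]
        hbr += t[:, None] * slopes[None, :] / 3.0

    return RunData(
        spec=spec,
        layout=layout,
        fs=p.fs,
        time_s=t,
        hbo=hbo,
        hbr=hbr,
        block_kind=kind,
        label=label,
        block_index=block_idx,
        task_type=spec.task_type,
        seed=seed,
        params=p,
    )


def _other(hemisphere: str) -> str:
    return "right" if hemisphere == "left" else "left"


def generate_subject(
    plan: ExperimentPlan,
    layout: ChannelLayout,
    params: HemoParams | None = None,
    seed: int = 0,
    n_task_blocks: int = 6,
    task_dur_s: float = 20.0,
    rest_dur_s: float = 20.0,
) -> list[RunData]:
    """One RunData per run of the plan, with subject-level variability.

    The subject draws a global amplitude factor U(0.8, 1.25) and an
    active-area jitter of at most one channel position (half an optode
    spacing) in each direction, so
    different seeds produce different active-channel subsets and effect
    sizes (inter-subject variability for subject-independent training).
    """
    p = params if params is not None else HemoParams()
    rng = np.random.default_rng(seed)
    amp_scale = float(rng.uniform(0.8, 1.25))
    jitter = 0.5 * layout.spacing_mm * rng.integers(-1, 2, 2)
    run_seeds = rng.integers(0, 2**31 - 1, plan.n_runs)

    runs = []
    for i, task_type in enumerate(plan.run_task_types):
        spec = make_run_spec(
            n_task_blocks=n_task_blocks,
            task_type=task_type,
            task_dur_s=task_dur_s,
            rest_dur_s=rest_dur_s,
            run_index=i + 1,
            seed=int(run_seeds[i]),
        )
        runs.append(
            generate_run(
                spec,
                layout,
                p,
                seed=int(run_seeds[i]),
                amp_scale=amp_scale,
                center_jitter_mm=(float(jitter[0]), float(jitter[1])),
            )
        )
    return runs
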