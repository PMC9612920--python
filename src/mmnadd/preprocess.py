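"""Epoch-level cleaning chain.

Stages: SQUID-jump rejection (z-score of absolute first differences),
zero-phase 1-40 Hz Butterworth band-pass with reflection padding to 3 s,
condition averaging, planar-pair root-mean-square combination, and 50 ms
pre-stimulus baseline correction.

Rejection and filtering operate on raw (uncombined) single trials.  The RMS
combination is nonlinear, so it is applied to condition *averages* (the way
combined planar gradients are conventionally computed); at realistic
single-trial signal-to-noise ratios, rectifying individual trials before
averaging would make the evoked response a nearly quadratic function of the
underlying field and would break the additivity bookkeeping this package
exists to test.  See docs/methods.md.  All MMNm subtraction happens after
combination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .paradigm import DeviantType
from .simulate import EpochSet

logger = logging.getLogger(__name__)


@dataclass
class Evoked:
    """Per-condition trial average for one subject and paradigm."""

    data: np.ndarray  # channels x time
    channel_names: list[str]
    condition: DeviantType
    n_trials: int
    subject_id: str
    group: str
    paradigm: str
    fs_hz: float
    t0_s: float
    combined: bool = False

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_times) / self.fs_hz

    def copy(self) -> "Evoked":
        return replace(self, data=self.data.copy())


@dataclass
class RejectionReport:
    n_total: int
    n_rejected: int
    per_trial_max_z: np.ndarray
    rejected_indices: list[int]

    @property
    def retained_fraction(self) -> float:
        return (self.n_total - self.n_rejected) / self.n_total

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_rejected": self.n_rejected,
            "retained_fraction": self.retained_fraction,
            "rejected_indices": self.rejected_indices,
            "per_trial_max_z": [float(z) for z in self.per_trial_max_z],
        }


def reject_jumps(
    epochs: EpochSet, z_cutoff: float = 30.0
) -> tuple[EpochSet, RejectionReport]:
    """Discard trials containing step-like (SQUID-jump) artifacts.

    For each channel, the absolute first differences of all trials are pooled
    and z-scored against their own mean and SD; a trial is rejected when its
    maximum z over channels and samples exceeds ``z_cutoff``.
    """
    if epochs.combined:
        raise ValueError("jump rejection must run on raw (uncombined) epochs")
    d = np.abs(np.diff(epochs.data, axis=2))
    mu = d.mean(axis=(0, 2))
    sd = np.maximum(d.std(axis=(0, 2)), 1e-30)
    # z is monotone in |diff| per channel, so the per-trial max z is the z of
    # the per-trial max |diff|
    d_max = d.max(axis=2)
    max_z = ((d_max - mu[None, :]) / sd[None, :]).max(axis=1)
    keep = max_z <= z_cutoff
    if not keep.any():
        raise ValueError(
            "all trials rejected; review the z-value cutoff or the noise model"
        )
    rejected = [int(i) for i in np.flatnonzero(~keep)]
    out = replace(
        epochs,
        data=epochs.data[keep],
        condition=epochs.condition[keep],
        is_analysis_standard=epochs.is_analysis_standard[keep],
        meta=dict(epochs.meta),
    )
    report = RejectionReport(
        n_total=epochs.n_trials,
        n_rejected=len(rejected),
        per_trial_max_z=max_z,
        rejected_indices=rejected,
    )
    logger.info(
        "jump rejection: %d/%d trials retained (%.1f%%)",
        report.n_total - report.n_rejected, report.n_total,
        100.0 * report.retained_fraction,
    )
    return out, report


def bandpass(
    epochs: EpochSet,
    low_hz: float = 1.0,
    high_hz: float = 40.0,
    order: int = 4,
    pad_s: float = 3.0,
) -> EpochSet:
    """Two-pass (zero-phase) Butterworth band-pass.

    Each trial/channel is symmetrically reflection-padded to ``pad_s`` total
    duration before forward-backward filtering, then cropped back.
    """
    if low_hz >= high_hz:
        raise ValueError("low edge must be below high edge")
    if high_hz >= epochs.fs_hz / 2:
        raise ValueError("high edge must be below the Nyquist frequency")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=epochs.fs_hz, output="sos")
    T = epochs.n_times
    n_target = int(round(pad_s * epochs.fs_hz))
    pad = max((n_target - T + 1) // 2, 0)
    x = np.pad(epochs.data, ((0, 0), (0, 0), (pad, pad)), mode="reflect")
    y = sps.sosfiltfilt(sos, x, axis=2, padtype=None)
    out = epochs.copy()
    out.data = np.ascontiguousarray(y[..., pad : pad + T])
    return out


def _combine_array(data: np.ndarray, convention: str) -> np.ndarray:
    if data.shape[-2] % 2:
        raise ValueError("odd channel count: channels do not form planar pairs")
    a = data[..., 0::2, :]
    b = data[..., 1::2, :]
    den = {"mean": 2.0, "sum": 1.0}[convention]
    return np.sqrt((a**2 + b**2) / den)


def _pair_names(channel_names: list[str]) -> list[str]:
    names = []
    for i in range(0, len(channel_names), 2):
        a, b = channel_names[i], channel_names[i + 1]
        stem_a, stem_b = a.rsplit("_", 1)[0], b.rsplit("_", 1)[0]
        if stem_a != stem_b:
            raise ValueError(f"unpaired channel: {a!r} is not paired with {b!r}")
        names.append(stem_a)
    return names


def combine_planar(x: EpochSet | Evoked, convention: str = "mean"):
    """Root-mean-square combination of the two gradients at each sensor site.

    The default convention is sqrt((a^2 + b^2)/2); ``convention="sum"`` gives
    the sqrt(a^2 + b^2) variant (a global factor sqrt(2), without inferential
    consequence).  Output channels are nonnegative and half as many.
    """
    if convention not in ("mean", "sum"):
        raise ValueError("convention must be 'mean' or 'sum'")
    if x.combined:
        raise ValueError("input is already combined")
    names = _pair_names(x.channel_names)
    out = x.copy()
    out.data = _combine_array(x.data, convention)
    out.channel_names = names
    out.combined = True
    return out


def baseline_correct(x: EpochSet | Evoked, window_s: tuple[float, float] = (-0.050, 0.0)):
    """Subtract the per-channel (and per-trial) mean over the baseline window."""
    t = x.times()
    mask = (t >= window_s[0]) & (t <= window_s[1])
    if not mask.any():
        raise ValueError(f"baseline window {window_s} contains no samples")
    out = x.copy()
    out.data = x.data - x.data[..., mask].mean(axis=-1, keepdims=True)
    return out


def average_condition(epochs: EpochSet, condition: DeviantType) -> Evoked:
    """Arithmetic trial mean for one condition.

    Standard trials are restricted to the flagged analysis standards (the
    third standard after each deviant).
    """
    mask = epochs.condition == condition.value
    if condition is DeviantType.STD:
        mask &= epochs.is_analysis_standard
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"no trials for condition {condition.value}")
    return Evoked(
        data=epochs.data[mask].mean(axis=0),
        channel_names=list(epochs.channel_names),
        condition=condition,
        n_trials=n,
        subject_id=epochs.subject_id,
        group=epochs.group,
        paradigm=epochs.paradigm,
        fs_hz=epochs.fs_hz,
        t0_s=epochs.t0_s,
        combined=epochs.combined,
    )


@dataclass
class PreprocessParams:
    z_cutoff: float = 30.0
    low_hz: float = 1.0
    high_hz: float = 40.0
    filter_order: int = 4
    pad_s: float = 3.0
    baseline_s: tuple[float, float] = (-0.050, 0.0)
    combine_convention: str = "mean"


def preprocess_pipeline(
    epochs: EpochSet, params: PreprocessParams | None = None
) -> tuple[dict[DeviantType, Evoked], RejectionReport]:
    """Full cleaning chain for one subject's raw epochs.

    reject -> band-pass -> average per condition -> combine planar pairs ->
    baseline-correct.  Returns the per-condition combined evokeds and the
    rejection report.
    """
    params = params or PreprocessParams()
    clean, report = reject_jumps(epochs, params.z_cutoff)
    clean = bandpass(clean, params.low_hz, params.high_hz, params.filter_order, params.pad_s)
    present = [c for c in DeviantType if (clean.condition == c.value).any()]
    evokeds: dict[DeviantType, Evoked] = {}
    for cond in present:
        if cond is DeviantType.STD and not (
            clean.is_analysis_standard & (clean.condition == cond.value)
        ).any():
            continue
        ev = average_condition(clean, cond)
        ev = combine_planar(ev, params.combine_convention)
        evokeds[cond] = baseline_correct(ev, params.baseline_s)
    return evokeds, report
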