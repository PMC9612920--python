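"""Generative model of planar-gradiometer epochs.

The simulator stands in for raw MEG recordings of the oddball experiment.
Each trial is a deterministic evoked field plus spatiotemporally correlated
Gaussian noise:

* the standard tone evokes a transient at 100 ms over superior-central
  sensors;
* each deviant feature f in {F, I, L} adds a mismatch component: a Gaussian
  time course peaking at ~156 ms, with a bilateral topography centred on two
  supratemporal "hotspot" regions;
* for double/triple deviants the summed single-feature components are shrunk
  by a factor (1 - kappa), where kappa in [0, 1] is the ground-truth
  subadditivity coefficient, configurable per group and deviant type.

Each sensor site carries two orthogonally oriented gradiometer channels.
The evoked field u at a site is emitted as (sqrt(2) u cos(psi),
sqrt(2) u sin(psi)) with a fixed per-site angle psi, so that the default
root-mean-square combination sqrt((a^2 + b^2)/2) recovers |u| exactly.

Topographies use compactly supported bumps.  By default the three feature
components share one temporal waveform and the standard-response support is
spatially disjoint from the mismatch supports; together these make MMNm
additivity exact on the combined (rectified) scale for noise-free data,
which pins down the ground truth the analysis pipeline is meant to recover.

Noise has exp(-d/lambda) spatial covariance across sensor sites (applied
independently to the two orientations of a pair) and AR(1) temporal
structure, plus optional SQUID-jump step artifacts for exercising trial
rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import signal as sps

from .paradigm import DeviantType

GROUPS = ("musician", "nonmusician")

_FEATURE_OFFSET_DIRECTIONS = {
    # unit vectors (tangential, roughly anterior/posterior) displacing each
    # feature's topography centre from the hotspot
    DeviantType.F: np.array([0.0, 1.0, 0.0]),
    DeviantType.I: np.array([0.0, -0.5, 0.5]),
    DeviantType.L: np.array([0.0, -1.0, 0.0]),
}


@dataclass
class SensorLayout:
    """Planar-gradiometer pair positions on a spherical cap.

    positions are in head coordinates (meters): x lateral (right positive),
    y anterior, z superior.  ``psi`` is the per-site orientation angle of the
    evoked field within the two channels of the pair.
    """

    pair_ids: np.ndarray  # (n,)
    pair_names: list[str]
    positions: np.ndarray  # (n, 3)
    hemispheres: np.ndarray  # (n,) of {"left","right","midline"}
    psi: np.ndarray  # (n,)
    radius_m: float
    hotspot_left: np.ndarray
    hotspot_right: np.ndarray
    seed: int = 0

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)

    @property
    def channel_names(self) -> list[str]:
        names = []
        for nm in self.pair_names:
            names.extend([f"{nm}_x", f"{nm}_y"])
        return names

    def hemisphere_indices(self, hemisphere: str) -> np.ndarray:
        return np.flatnonzero(self.hemispheres == hemisphere)

    def distances(self) -> np.ndarray:
        diff = self.positions[:, None, :] - self.positions[None, :, :]
        return np.linalg.norm(diff, axis=-1)


def make_layout(n_pairs: int = 51, seed: int = 0) -> SensorLayout:
    """Quasi-uniform sensor-pair layout on an upper spherical cap.

    Pairs are placed on a golden-angle spiral over the cap (radius 0.09 m,
    polar angle up to ~78 deg) with a seeded azimuthal rotation.  Two
    supratemporal hotspot regions (left/right) mark where mismatch
    topographies peak.
    """
    if n_pairs < 10:
        raise ValueError("need at least 10 sensor pairs for a usable neighborhood")
    rng = np.random.default_rng(seed)
    radius = 0.09
    cos_max = np.cos(np.deg2rad(78.0))
    i = np.arange(n_pairs)
    cos_theta = 1.0 - (i + 0.5) / n_pairs * (1.0 - cos_max)
    theta = np.arccos(cos_theta)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = i * golden + rng.uniform(0.0, 2.0 * np.pi)
    pos = radius * np.column_stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )
    hemis = np.where(pos[:, 0] > 1e-3, "right", np.where(pos[:, 0] < -1e-3, "left", "midline"))
    hot_dir = np.array([0.95, -0.10, 0.30])
    hot_l = radius * np.array([-1.0, 1.0, 1.0]) * hot_dir / np.linalg.norm(hot_dir)
    hot_r = radius * hot_dir / np.linalg.norm(hot_dir)
    layout = SensorLayout(
        pair_ids=np.arange(n_pairs),
        pair_names=[f"MEG{k:03d}" for k in range(n_pairs)],
        positions=pos,
        hemispheres=hemis.astype(object),
        psi=rng.uniform(0.0, 2.0 * np.pi, n_pairs),
        radius_m=radius,
        hotspot_left=hot_l,
        hotspot_right=hot_r,
        seed=seed,
    )
    d = layout.distances()
    if np.any(d[np.triu_indices(n_pairs, 1)] <= 0):
        raise ValueError("degenerate layout: coincident sensor positions")
    return layout


@dataclass
class FeatureParams:
    """Mismatch-component parameters for one acoustic feature."""

    amplitude: float = 12.0  # combined-scale peak, arbitrary units (nominally fT/cm)
    latency_s: float = 0.156
    width_s: float = 0.030
    center_offset_m: float = 0.010  # tangential displacement of the topography centre
    spread_m: float = 0.045  # compact-support radius of the topography bump


@dataclass
class StandardParams:
    """Evoked response to the standard tone (shared by all conditions)."""

    amplitude: float = 20.0
    latency_s: float = 0.100
    width_s: float = 0.040
    spread_m: float = 0.030  # support radius around the vertex


@dataclass
class NoiseParams:
    sigma: float = 40.0  # single-trial noise SD per channel
    spatial_scale_m: float = 0.04  # exp(-d/lambda) length scale across sites
    ar1_phi: float = 0.6  # lag-1 temporal autocorrelation
    subject_cv: float = 0.2  # log-normal inter-subject amplitude CV


@dataclass
class ArtifactParams:
    p_jump: float = 0.02
    amplitude: float = 2000.0


def default_kappa() -> dict[str, dict[str, float]]:
    """Feature-selective ground truth: experts show subadditivity only for
    frequency-containing combinations."""
    return {
        "musician": {"FI": 0.4, "LF": 0.4, "FIL": 0.4},
        "nonmusician": {},
    }


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohorts."""

    n_subjects_per_group: int = 25
    trials_per_deviant: int = 144
    fs_hz: float = 250.0
    epoch_window_s: tuple[float, float] = (-0.100, 0.400)
    n_pairs: int = 51
    features: dict[DeviantType, FeatureParams] = field(
        default_factory=lambda: {
            DeviantType.F: FeatureParams(),
            DeviantType.I: FeatureParams(),
            DeviantType.L: FeatureParams(),
        }
    )
    standard: StandardParams = field(default_factory=StandardParams)
    kappa: dict[str, dict[str, float]] = field(default_factory=default_kappa)
    noise: NoiseParams = field(default_factory=NoiseParams)
    artifact: ArtifactParams = field(default_factory=ArtifactParams)
    conditions: tuple[DeviantType, ...] = tuple(DeviantType)
    seed: int = 0

    @property
    def n_times(self) -> int:
        t0, t1 = self.epoch_window_s
        return int(round((t1 - t0) * self.fs_hz)) + 1

    def times(self) -> np.ndarray:
        t0, t1 = self.epoch_window_s
        n0 = int(round(t0 * self.fs_hz))
        n1 = int(round(t1 * self.fs_hz))
        return np.arange(n0, n1 + 1) / self.fs_hz

    def kappa_for(self, group: str, dev: DeviantType) -> float:
        if group not in GROUPS:
            raise ValueError(f"unknown group: {group!r}")
        if dev.n_features < 2:
            return 0.0
        k = float(self.kappa.get(group, {}).get(dev.value, 0.0))
        if not 0.0 <= k <= 1.0:
            raise ValueError(f"kappa must lie in [0, 1], got {k}")
        return k


@dataclass
class EpochSet:
    """Trials x channels x time container with per-trial condition labels."""

    data: np.ndarray
    channel_names: list[str]
    fs_hz: float
    t0_s: float
    condition: np.ndarray  # (n_trials,) of condition codes (str)
    is_analysis_standard: np.ndarray  # (n_trials,) bool
    subject_id: str
    group: str
    paradigm: str
    combined: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_times) / self.fs_hz

    def copy(self) -> "EpochSet":
        return replace(
            self,
            data=self.data.copy(),
            condition=self.condition.copy(),
            is_analysis_standard=self.is_analysis_standard.copy(),
            meta=dict(self.meta),
        )


def component_waveform(
    latency_s: float,
    width_s: float,
    amplitude: float,
    fs_hz: float,
    window_s: tuple[float, float],
) -> np.ndarray:
    """Gaussian monophasic component w(t) = A exp(-(t-mu)^2 / (2 sigma^2))."""
    if width_s <= 0:
        raise ValueError("width must be positive")
    t0, t1 = window_s
    if not t0 <= latency_s <= t1:
        raise ValueError(f"latency {latency_s} s outside window {window_s}")
    n0 = int(round(t0 * fs_hz))
    n1 = int(round(t1 * fs_hz))
    t = np.arange(n0, n1 + 1) / fs_hz
    return amplitude * np.exp(-((t - latency_s) ** 2) / (2.0 * width_s**2))


def _bump(positions: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    """Compactly supported smooth bump (1 - (d/r)^2)^2 for d < r, else 0."""
    d = np.linalg.norm(positions - center, axis=1)
    return np.clip(1.0 - (d / radius) ** 2, 0.0, None) ** 2


def feature_topography(dev: DeviantType, config: SimulationConfig, layout: SensorLayout) -> np.ndarray:
    """Bilateral pair-level topography of one single-feature mismatch component."""
    p = config.features[dev]
    offset = p.center_offset_m * _FEATURE_OFFSET_DIRECTIONS[dev]
    topo = np.zeros(layout.n_pairs)
    for hot in (layout.hotspot_left, layout.hotspot_right):
        center = hot + offset
        center *= layout.radius_m / np.linalg.norm(center)
        topo += _bump(layout.positions, center, p.spread_m)
    # unit sensor maximum: the configured amplitude is the amplitude actually
    # seen at the best sensor, independent of layout discretization
    peak = topo.max()
    if peak <= 0:
        raise ValueError(
            f"no sensor falls within the {dev.value} topography support; "
            "increase spread_m or the sensor count"
        )
    return topo / peak


def standard_topography(config: SimulationConfig, layout: SensorLayout) -> np.ndarray:
    center = np.array([0.0, 0.0, layout.radius_m])
    topo = _bump(layout.positions, center, config.standard.spread_m)
    peak = topo.max()
    return topo / peak if peak > 0 else topo


def _pair_field(layout: SensorLayout, u: np.ndarray) -> np.ndarray:
    """Emit a pair-level field u (n_pairs x T) on interleaved raw channels."""
    n, T = u.shape
    raw = np.empty((2 * n, T))
    raw[0::2] = np.sqrt(2.0) * np.cos(layout.psi)[:, None] * u
    raw[1::2] = np.sqrt(2.0) * np.sin(layout.psi)[:, None] * u
    return raw


def true_evoked(
    dev: DeviantType, group: str, config: SimulationConfig, layout: SensorLayout
) -> np.ndarray:
    """Noise-free raw-channel evoked field for one condition.

    E = S + (1 - kappa(group, dev)) * sum_f M_f over the constituent features,
    returned as a (2 * n_pairs) x n_times array of raw gradiometer channels.
    """
    window = config.epoch_window_s
    s_wave = component_waveform(
        config.standard.latency_s, config.standard.width_s, config.standard.amplitude,
        config.fs_hz, window,
    )
    u = standard_topography(config, layout)[:, None] * s_wave[None, :]
    shrink = 1.0 - config.kappa_for(group, dev)
    for f in sorted(dev.constituents, key=lambda d: d.value):
        p = config.features[f]
        w = component_waveform(p.latency_s, p.width_s, 1.0, config.fs_hz, window)
        u = u + shrink * p.amplitude * feature_topography(f, config, layout)[:, None] * w[None, :]
    return _pair_field(layout, u)


def _colored_noise(
    rng: np.random.Generator,
    n_trials: int,
    layout: SensorLayout,
    noise: NoiseParams,
    n_times: int,
) -> np.ndarray:
    """Stationary Gaussian noise, exp(-d/lambda) across sites, AR(1) over time.

    The two orientations of each pair receive independent realizations of the
    same spatial process.  Returns (n_trials, 2 * n_pairs, n_times).
    """
    n = layout.n_pairs
    if noise.sigma < 0:
        raise ValueError("noise sigma must be nonnegative")
    if noise.sigma == 0:
        return np.zeros((n_trials, 2 * n, n_times))
    C = np.exp(-layout.distances() / noise.spatial_scale_m)
    L = np.linalg.cholesky(C + 1e-9 * np.eye(n)).astype(np.float32)
    # single-precision generation (the analysis chain stays double); one
    # gaussian block in site-major layout so the spatial mixing is one gemm
    z = rng.standard_normal((n, n_trials * 2 * (n_times + 1)), dtype=np.float32)
    z = (L @ z).reshape(n, n_trials, 2, n_times + 1)
    # exact stationary AR(1): the first sample seeds the filter state
    phi = noise.ar1_phi
    zi = phi * z[..., :1]
    y, _ = sps.lfilter(
        np.array([np.sqrt(1.0 - phi**2)], np.float32),
        np.array([1.0, -phi], np.float32),
        z[..., 1:], axis=-1, zi=zi,
    )
    out = np.empty((n_trials, 2 * n, n_times))
    out[:, 0::2] = y.transpose(1, 0, 2, 3)[:, :, 0]
    out[:, 1::2] = y.transpose(1, 0, 2, 3)[:, :, 1]
    return noise.sigma * out


def default_trial_plan(config: SimulationConfig) -> dict[DeviantType, int]:
    """trials_per_deviant for every deviant condition and equally many standards."""
    plan = {}
    for cond in config.conditions:
        plan[cond] = config.trials_per_deviant
    if DeviantType.STD in config.conditions:
        plan[DeviantType.STD] = config.trials_per_deviant
    return plan


def simulate_subject(
    config: SimulationConfig,
    layout: SensorLayout,
    group: str,
    subject_seed: int,
    subject_id: str = "S00",
    paradigm: str = "complex",
    trial_plan: Mapping[DeviantType, int] | None = None,
) -> EpochSet:
    """Raw-pair epochs for one subject: gain * evoked(condition) + noise.

    The subject gain is a single log-normal scalar (mean 1, CV from config).
    Standard trials are all flagged as analysis standards.
    """
    if trial_plan is None:
        trial_plan = default_trial_plan(config)
    if any(n < 1 for n in trial_plan.values()):
        raise ValueError("every planned condition needs at least one trial")
    rng = np.random.default_rng(subject_seed)
    cv = config.noise.subject_cv
    if cv > 0:
        s2 = np.log1p(cv**2)
        gain = float(np.exp(rng.normal(-0.5 * s2, np.sqrt(s2))))
    else:
        gain = 1.0

    conds = [c for c in DeviantType if c in trial_plan]
    n_total = sum(trial_plan[c] for c in conds)
    T = config.n_times
    data = np.empty((n_total, 2 * layout.n_pairs, T))
    labels = np.empty(n_total, dtype=object)
    row = 0
    for cond in conds:
        n = trial_plan[cond]
        evo = gain * true_evoked(cond, group, config, layout)
        data[row : row + n] = evo[None, :, :]
        labels[row : row + n] = cond.value
        row += n
    data += _colored_noise(rng, n_total, layout, config.noise, T)

    return EpochSet(
        data=data,
        channel_names=layout.channel_names,
        fs_hz=config.fs_hz,
        t0_s=config.epoch_window_s[0],
        condition=labels,
        is_analysis_standard=(labels == DeviantType.STD.value),
        subject_id=subject_id,
        group=group,
        paradigm=paradigm,
        combined=False,
        meta={"subject_seed": int(subject_seed), "gain": gain},
    )


def simulate_subject_means(
    config: SimulationConfig,
    layout: SensorLayout,
    group: str,
    subject_seed: int,
    subject_id: str = "S00",
    paradigm: str = "complex",
    trial_plan: Mapping[DeviantType, int] | None = None,
    halves: bool = False,
) -> EpochSet:
    """Per-condition trial means, generated without materializing trials.

    The mean of n iid realizations of the Gaussian noise process is one
    realization at sigma/sqrt(n), so each condition's trial average can be
    drawn directly: one epoch per condition (or per split half when
    ``halves`` is set, with the odd/even cell sizes) carrying
    gain * evoked + averaged noise.  Distributionally identical to
    ``simulate_subject`` followed by condition averaging on artifact-free
    data; used by the validation experiments for speed.
    """
    if trial_plan is None:
        trial_plan = default_trial_plan(config)
    rng = np.random.default_rng(subject_seed)
    cv = config.noise.subject_cv
    if cv > 0:
        s2 = np.log1p(cv**2)
        gain = float(np.exp(rng.normal(-0.5 * s2, np.sqrt(s2))))
    else:
        gain = 1.0
    conds = [c for c in DeviantType if c in trial_plan]
    cells: list[tuple[DeviantType, int, int]] = []  # (condition, half id, n_trials)
    for cond in conds:
        n = trial_plan[cond]
        if halves:
            cells.append((cond, 0, (n + 1) // 2))
            cells.append((cond, 1, n // 2))
        else:
            cells.append((cond, 0, n))
    if any(n < 1 for _, _, n in cells):
        raise ValueError("every cell needs at least one trial")
    T = config.n_times
    data = np.empty((len(cells), 2 * layout.n_pairs, T))
    raw_noise = _colored_noise(rng, len(cells), layout, config.noise, T)
    labels = np.empty(len(cells), dtype=object)
    half_ids = np.empty(len(cells), dtype=int)
    for k, (cond, h, n) in enumerate(cells):
        data[k] = gain * true_evoked(cond, group, config, layout)
        data[k] += raw_noise[k] / np.sqrt(n)
        labels[k] = cond.value
        half_ids[k] = h
    return EpochSet(
        data=data,
        channel_names=layout.channel_names,
        fs_hz=config.fs_hz,
        t0_s=config.epoch_window_s[0],
        condition=labels,
        is_analysis_standard=(labels == DeviantType.STD.value),
        subject_id=subject_id,
        group=group,
        paradigm=paradigm,
        combined=False,
        meta={
            "subject_seed": int(subject_seed),
            "gain": gain,
            "collapsed": True,
            "half": half_ids.tolist(),
            "cell_trials": {f"{c.value}:{h}": n for c, h, n in cells},
        },
    )


def inject_jumps(
    epochs: EpochSet, p_jump: float, amplitude: float, seed: int
) -> EpochSet:
    """Add SQUID-like step artifacts to a random fraction of trials.

    Each affected trial receives one step of the given amplitude on one random
    channel at a random sample; affected trial indices are recorded in
    ``meta['jump_trials']``.
    """
    if not 0.0 <= p_jump <= 1.0:
        raise ValueError("p_jump must lie in [0, 1]")
    out = epochs.copy()
    rng = np.random.default_rng(seed)
    hit = rng.random(epochs.n_trials) < p_jump
    n_ch, n_t = epochs.data.shape[1], epochs.data.shape[2]
    for tr in np.flatnonzero(hit):
        ch = int(rng.integers(0, n_ch))
        s = int(rng.integers(1, n_t))
        out.data[tr, ch, s:] += amplitude
    out.meta["jump_trials"] = [int(i) for i in np.flatnonzero(hit)]
    return out
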