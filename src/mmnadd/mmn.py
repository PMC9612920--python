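"""Empirical and modeled mismatch-response construction.

The *empirical* MMNm of a deviant type is its combined-gradiometer evoked
response minus the (analysis-)standard evoked response of the same subject
and paradigm.  The *modeled* MMNm of a double or triple deviant is the sum of
the empirical MMNms of its constituent single-feature deviants -- the
additive-model prediction.  Subadditivity shows up as the empirical wave
falling below the modeled one.

Sensor selection follows the grand-average approach: the combined pair with
the largest grand-average mismatch amplitude in the 100-300 ms window is
located in each hemisphere, and its eight nearest same-hemisphere neighbours
are added, yielding 2 x 9 analysis sensors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .paradigm import DeviantType
from .preprocess import Evoked
from .simulate import SensorLayout

ANALYSIS_WINDOW_S = (0.100, 0.300)
N_NEIGHBORS = 8


@dataclass
class MMNmWave:
    """Per-subject combined-gradiometer difference wave."""

    data: np.ndarray  # combined channels x time
    channel_names: list[str]
    deviant_type: DeviantType
    kind: str  # "empirical" | "modeled"
    subject_id: str
    group: str
    paradigm: str
    fs_hz: float
    t0_s: float
    n_trials_deviant: int = 0
    n_trials_standard: int = 0

    def __post_init__(self) -> None:
        if self.deviant_type is DeviantType.STD:
            raise ValueError("an MMNm is defined for deviant conditions only")
        if self.kind == "modeled" and self.deviant_type.n_features < 2:
            raise ValueError("modeled MMNms exist only for double/triple deviants")

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_times) / self.fs_hz

    def copy(self) -> "MMNmWave":
        return replace(self, data=self.data.copy())


def _check_axes(a, b) -> None:
    if a.data.shape != b.data.shape:
        raise ValueError(f"shape mismatch: {a.data.shape} vs {b.data.shape}")
    if a.fs_hz != b.fs_hz or a.t0_s != b.t0_s:
        raise ValueError("time-axis mismatch")
    if list(a.channel_names) != list(b.channel_names):
        raise ValueError("channel mismatch")


def empirical_mmnm(dev: Evoked, std: Evoked) -> MMNmWave:
    """Deviant evoked minus the average analysis standard."""
    _check_axes(dev, std)
    if std.condition is not DeviantType.STD:
        raise ValueError("second argument must be the standard evoked response")
    if (dev.subject_id, dev.paradigm) != (std.subject_id, std.paradigm):
        raise ValueError("deviant and standard must share subject and paradigm")
    return MMNmWave(
        data=dev.data - std.data,
        channel_names=list(dev.channel_names),
        deviant_type=dev.condition,
        kind="empirical",
        subject_id=dev.subject_id,
        group=dev.group,
        paradigm=dev.paradigm,
        fs_hz=dev.fs_hz,
        t0_s=dev.t0_s,
        n_trials_deviant=dev.n_trials,
        n_trials_standard=std.n_trials,
    )


def modeled_mmnm(singles: Sequence[MMNmWave]) -> MMNmWave:
    """Additive-model prediction: the sum of single-feature empirical MMNms."""
    if len(singles) not in (2, 3):
        raise ValueError("a modeled MMNm sums two or three single-deviant MMNms")
    feats: set[DeviantType] = set()
    for w in singles:
        if w.kind != "empirical":
            raise ValueError("modeled MMNms are built from empirical single MMNms")
        if w.deviant_type.n_features != 1:
            raise ValueError(f"{w.deviant_type.value} is not a single-feature deviant")
        if (w.subject_id, w.paradigm) != (singles[0].subject_id, singles[0].paradigm):
            raise ValueError("all constituents must share subject and paradigm")
        _check_axes(w, singles[0])
        if w.deviant_type in feats:
            raise ValueError(f"duplicate constituent {w.deviant_type.value}")
        feats.add(w.deviant_type)
    combo = DeviantType.from_constituents(feats)
    data = np.sum([w.data for w in singles], axis=0)
    first = singles[0]
    return MMNmWave(
        data=data,
        channel_names=list(first.channel_names),
        deviant_type=combo,
        kind="modeled",
        subject_id=first.subject_id,
        group=first.group,
        paradigm=first.paradigm,
        fs_hz=first.fs_hz,
        t0_s=first.t0_s,
        n_trials_deviant=sum(w.n_trials_deviant for w in singles),
        n_trials_standard=first.n_trials_standard,
    )


def additivity_difference(empirical: MMNmWave, modeled: MMNmWave) -> np.ndarray:
    """empirical - modeled; negative values indicate subadditivity."""
    _check_axes(empirical, modeled)
    if empirical.deviant_type is not modeled.deviant_type:
        raise ValueError("waves must refer to the same deviant type")
    if empirical.subject_id != modeled.subject_id:
        raise ValueError("waves must come from the same subject")
    if empirical.kind == modeled.kind:
        raise ValueError("one wave must be empirical, the other modeled")
    return empirical.data - modeled.data


def grand_average(waves: Sequence[Evoked] | Sequence[MMNmWave]):
    """Unweighted mean across waves (equal weight per entry)."""
    if not waves:
        raise ValueError("nothing to average")
    for w in waves[1:]:
        _check_axes(w, waves[0])
    out = waves[0].copy()
    out.data = np.mean([w.data for w in waves], axis=0)
    return out


@dataclass
class SensorSelection:
    """Peak pair plus eight neighbours per hemisphere (2 x 9 = 18 pairs)."""

    peak_pairs: dict[str, int]  # hemisphere -> pair index
    pairs_by_hemisphere: dict[str, list[int]]  # hemisphere -> 9 pair indices
    window_s: tuple[float, float] = ANALYSIS_WINDOW_S

    def __post_init__(self) -> None:
        left = set(self.pairs_by_hemisphere.get("left", ()))
        right = set(self.pairs_by_hemisphere.get("right", ()))
        if left & right:
            raise ValueError("hemisphere selections overlap")
        for hemi, pairs in self.pairs_by_hemisphere.items():
            if len(set(pairs)) != len(pairs):
                raise ValueError(f"duplicate pairs in {hemi} selection")
            if self.peak_pairs[hemi] not in pairs:
                raise ValueError(f"{hemi} peak pair missing from its selection")

    @property
    def all_pairs(self) -> list[int]:
        out: list[int] = []
        for hemi in sorted(self.pairs_by_hemisphere):
            out.extend(self.pairs_by_hemisphere[hemi])
        return out

    @property
    def n_selected(self) -> int:
        return len(self.all_pairs)

    def to_dict(self) -> dict:
        return {
            "peak_pairs": {h: int(i) for h, i in self.peak_pairs.items()},
            "pairs_by_hemisphere": {
                h: [int(i) for i in p] for h, p in self.pairs_by_hemisphere.items()
            },
            "window_s": list(self.window_s),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SensorSelection":
        return cls(
            peak_pairs={h: int(i) for h, i in d["peak_pairs"].items()},
            pairs_by_hemisphere={
                h: [int(i) for i in p] for h, p in d["pairs_by_hemisphere"].items()
            },
            window_s=tuple(d["window_s"]),
        )


def select_peak_sensors(
    grand,
    layout: SensorLayout,
    window_s: tuple[float, float] = ANALYSIS_WINDOW_S,
) -> SensorSelection:
    """Peak combined pair per hemisphere and its 8 nearest neighbours.

    The peak is the pair maximizing the grand wave over the window within its
    hemisphere (ties broken by lowest pair id); neighbours are the nearest
    same-hemisphere pairs by Euclidean distance.  Midline pairs are excluded.
    """
    t = grand.times()
    tmask = (t >= window_s[0]) & (t <= window_s[1])
    scores = grand.data[:, tmask].max(axis=1)
    dists = layout.distances()
    peak_pairs: dict[str, int] = {}
    pairs_by_hemi: dict[str, list[int]] = {}
    for hemi in ("left", "right"):
        idx = layout.hemisphere_indices(hemi)
        if len(idx) < N_NEIGHBORS + 1:
            raise ValueError(
                f"{hemi} hemisphere has {len(idx)} pairs; need at least {N_NEIGHBORS + 1}"
            )
        idx = idx[np.argsort(layout.pair_ids[idx], kind="stable")]
        peak = int(idx[np.argmax(scores[idx])])
        others = idx[idx != peak]
        order = np.lexsort((layout.pair_ids[others], dists[peak, others]))
        neighbors = [int(i) for i in others[order][:N_NEIGHBORS]]
        peak_pairs[hemi] = peak
        pairs_by_hemi[hemi] = [peak] + neighbors
    return SensorSelection(peak_pairs, pairs_by_hemi, window_s)


def peak_latency(grand, selection: SensorSelection) -> float:
    """Latency of the maximum of the selection-mean wave within the window."""
    if selection.n_selected == 0:
        raise ValueError("empty sensor selection")
    t = grand.times()
    tmask = (t >= selection.window_s[0]) & (t <= selection.window_s[1])
    mean_wave = grand.data[selection.all_pairs].mean(axis=0)
    win_t = t[tmask]
    return float(win_t[np.argmax(mean_wave[tmask])])


def stack_maps(
    waves: Sequence[Evoked] | Sequence[MMNmWave] | Sequence[np.ndarray],
    selection: SensorSelection,
    times: np.ndarray | None = None,
) -> np.ndarray:
    """Stack per-subject waves restricted to selection pairs x analysis window.

    Accepts wave objects or bare channels x time arrays (then ``times`` is
    required).  Returns an (n_subjects, n_pairs_selected, n_times_window)
    array.
    """
    rows = []
    for w in waves:
        if isinstance(w, np.ndarray):
            if times is None:
                raise ValueError("times must be given for bare arrays")
            t = times
            data = w
        else:
            t = w.times()
            data = w.data
        tmask = (t >= selection.window_s[0]) & (t <= selection.window_s[1])
        rows.append(data[np.ix_(selection.all_pairs, np.flatnonzero(tmask))])
    return np.asarray(rows)
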