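"""File formats: HDF5 epoch/evoked containers, TSV layouts and event logs,
YAML configuration, JSON selections and reports."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from .mmn import MMNmWave, SensorSelection
from .paradigm import BlockSequence, DeviantType, TrialEvent
from .preprocess import Evoked
from .simulate import (
    ArtifactParams,
    FeatureParams,
    NoiseParams,
    SensorLayout,
    SimulationConfig,
    StandardParams,
)


# ---------------------------------------------------------------------------
# EpochSet / Evoked / MMNm HDF5 containers
# ---------------------------------------------------------------------------

def save_epochs(path: str | Path, epochs) -> None:
    """Write an EpochSet to HDF5: /data, /time, /channels + JSON attrs."""
    from .simulate import EpochSet  # local to avoid cycle at import time

    assert isinstance(epochs, EpochSet)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip", compression_opts=1)
        f.create_dataset("time", data=epochs.times())
        f.create_dataset("channels", data=np.array(epochs.channel_names, dtype="S"))
        f.create_dataset("condition", data=np.array([str(c) for c in epochs.condition], dtype="S"))
        f.create_dataset("is_analysis_standard", data=epochs.is_analysis_standard.astype(bool))
        f.attrs["meta"] = json.dumps(
            {
                "fs_hz": epochs.fs_hz,
                "t0_s": epochs.t0_s,
                "subject_id": epochs.subject_id,
                "group": epochs.group,
                "paradigm": epochs.paradigm,
                "combined": epochs.combined,
                **{k: v for k, v in epochs.meta.items()},
            }
        )


def load_epochs(path: str | Path):
    from .simulate import EpochSet

    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["meta"])
        data = f["data"][()]
        channels = [c.decode() for c in f["channels"][()]]
        condition = np.array([c.decode() for c in f["condition"][()]], dtype=object)
        ias = f["is_analysis_standard"][()]
    return EpochSet(
        data=data,
        channel_names=channels,
        fs_hz=meta.pop("fs_hz"),
        t0_s=meta.pop("t0_s"),
        condition=condition,
        is_analysis_standard=ias,
        subject_id=meta.pop("subject_id"),
        group=meta.pop("group"),
        paradigm=meta.pop("paradigm"),
        combined=meta.pop("combined"),
        meta=meta,
    )


def save_waves(path: str | Path, waves: Sequence[Evoked | MMNmWave]) -> None:
    """Write evokeds and/or MMNm waves to one HDF5 container.

    Evokeds go under /conditions, MMNm waves under /mmnm, one group per wave.
    """
    with h5py.File(path, "w") as f:
        for w in waves:
            if isinstance(w, MMNmWave):
                base, key = "mmnm", f"{w.subject_id}_{w.paradigm}_{w.deviant_type.value}_{w.kind}"
                extra = {
                    "deviant_type": w.deviant_type.value,
                    "kind": w.kind,
                    "n_trials_deviant": w.n_trials_deviant,
                    "n_trials_standard": w.n_trials_standard,
                }
            else:
                base, key = "conditions", f"{w.subject_id}_{w.paradigm}_{w.condition.value}"
                extra = {
                    "condition": w.condition.value,
                    "n_trials": w.n_trials,
                    "combined": w.combined,
                }
            g = f.require_group(base).create_group(key)
            g.create_dataset("data", data=w.data)
            g.create_dataset("channels", data=np.array(w.channel_names, dtype="S"))
            g.attrs["meta"] = json.dumps(
                {
                    "fs_hz": w.fs_hz,
                    "t0_s": w.t0_s,
                    "subject_id": w.subject_id,
                    "group": w.group,
                    "paradigm": w.paradigm,
                    **extra,
                }
            )


def load_waves(path: str | Path) -> list[Evoked | MMNmWave]:
    out: list[Evoked | MMNmWave] = []
    with h5py.File(path, "r") as f:
        for base in ("conditions", "mmnm"):
            if base not in f:
                continue
            for key in sorted(f[base]):
                g = f[base][key]
                meta = json.loads(g.attrs["meta"])
                data = g["data"][()]
                channels = [c.decode() for c in g["channels"][()]]
                common = dict(
                    data=data,
                    channel_names=channels,
                    subject_id=meta["subject_id"],
                    group=meta["group"],
                    paradigm=meta["paradigm"],
                    fs_hz=meta["fs_hz"],
                    t0_s=meta["t0_s"],
                )
                if base == "mmnm":
                    out.append(
                        MMNmWave(
                            deviant_type=DeviantType(meta["deviant_type"]),
                            kind=meta["kind"],
                            n_trials_deviant=meta["n_trials_deviant"],
                            n_trials_standard=meta["n_trials_standard"],
                            **common,
                        )
                    )
                else:
                    out.append(
                        Evoked(
                            condition=DeviantType(meta["condition"]),
                            n_trials=meta["n_trials"],
                            combined=meta["combined"],
                            **common,
                        )
                    )
    return out


# ---------------------------------------------------------------------------
# Layout and event-log TSV
# ---------------------------------------------------------------------------

def layout_to_tsv(layout: SensorLayout, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "pair_id": layout.pair_ids,
            "name_a": [f"{n}_x" for n in layout.pair_names],
            "name_b": [f"{n}_y" for n in layout.pair_names],
            "x": layout.positions[:, 0],
            "y": layout.positions[:, 1],
            "z": layout.positions[:, 2],
            "hemisphere": layout.hemispheres,
            "psi": layout.psi,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def layout_from_tsv(path: str | Path, radius_m: float = 0.09) -> SensorLayout:
    df = pd.read_csv(path, sep="\t")
    pos = df[["x", "y", "z"]].to_numpy()
    hot_dir = np.array([0.95, -0.10, 0.30])
    hot_dir = hot_dir / np.linalg.norm(hot_dir)
    return SensorLayout(
        pair_ids=df["pair_id"].to_numpy(),
        pair_names=[n.rsplit("_", 1)[0] for n in df["name_a"]],
        positions=pos,
        hemispheres=df["hemisphere"].to_numpy(dtype=object),
        psi=df["psi"].to_numpy() if "psi" in df else np.zeros(len(df)),
        radius_m=radius_m,
        hotspot_left=radius_m * hot_dir * np.array([-1.0, 1.0, 1.0]),
        hotspot_right=radius_m * hot_dir,
    )


def events_to_tsv(blocks: Sequence[BlockSequence], path: str | Path) -> None:
    pd.concat([blk.to_frame() for blk in blocks], ignore_index=True).to_csv(
        path, sep="\t", index=False
    )


def events_from_tsv(path: str | Path) -> list[BlockSequence]:
    df = pd.read_csv(path, sep="\t")
    blocks = []
    for (block_id, paradigm), sub in df.groupby(["block_id", "paradigm"], sort=False):
        events = [
            TrialEvent(
                onset_s=float(r.onset_s),
                role=r.role,
                deviant_type=DeviantType(r.deviant_type),
                pitch_index=int(r.pitch_index),
                pattern_position=None if r.pattern_position < 0 else int(r.pattern_position),
                is_analysis_standard=bool(r.is_analysis_standard),
            )
            for r in sub.itertuples()
        ]
        blocks.append(BlockSequence(paradigm, str(block_id), events, seed=-1))
    return blocks


# ---------------------------------------------------------------------------
# Config YAML, selection JSON
# ---------------------------------------------------------------------------

def config_to_yaml(config: SimulationConfig, path: str | Path) -> None:
    d = dataclasses.asdict(config)
    d["features"] = {k.value: v for k, v in d["features"].items()}
    d["conditions"] = [c.value for c in config.conditions]
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def config_from_yaml(path: str | Path) -> SimulationConfig:
    d = yaml.safe_load(Path(path).read_text())
    d["features"] = {
        DeviantType(k): FeatureParams(**v) for k, v in d.get("features", {}).items()
    }
    d["standard"] = StandardParams(**d.get("standard", {}))
    d["noise"] = NoiseParams(**d.get("noise", {}))
    d["artifact"] = ArtifactParams(**d.get("artifact", {}))
    d["conditions"] = tuple(DeviantType(c) for c in d.get("conditions", []))
    d["epoch_window_s"] = tuple(d["epoch_window_s"])
    return SimulationConfig(**d)


def selection_to_json(selection: SensorSelection, path: str | Path) -> None:
    Path(path).write_text(json.dumps(selection.to_dict(), indent=2))


def selection_from_json(path: str | Path) -> SensorSelection:
    return SensorSelection.from_dict(json.loads(Path(path).read_text()))
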