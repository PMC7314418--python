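"""Container formats and reproducibility metadata.

Epochs are stored as an HDF5 file (datasets ``/data``, ``/times_ms``,
``/channel_ids``, ``/planar_pairs``, optional ``/hemisphere`` and
``/posterior``; attribute ``sfreq_hz``) with the trial table as a sidecar
CSV next to it (``<stem>_trials.csv``) — lowest-common-denominator interop.
Decoding timecourses use the same pattern. Configs are YAML (unknown keys
are errors); every pipeline stage can emit a JSON run manifest with the
config snapshot, seeds, package version and content hashes of its inputs
and outputs.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import EpochSet, SimulationConfig, validate_trial_table
from .decoding import DecodingTimecourse

__all__ = [
    "write_epochs", "read_epochs",
    "write_timecourse", "read_timecourse",
    "load_config", "save_config",
    "write_manifest",
]


def _trials_path(path: Path) -> Path:
    return path.with_name(path.stem + "_trials.csv")


def write_epochs(epochs: EpochSet, path: str | Path) -> Path:
    """Write an EpochSet to HDF5 + sidecar trial CSV. Returns the HDF5 path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times_ms", data=epochs.times_ms)
        f.create_dataset("channel_ids",
                         data=np.array(epochs.channel_ids, dtype="S"))
        pairs = np.array(epochs.planar_pairs, dtype=np.int64).reshape(-1, 2)
        f.create_dataset("planar_pairs", data=pairs)
        f.attrs["sfreq_hz"] = epochs.sfreq_hz
        if epochs.channel_info is not None:
            f.create_dataset("hemisphere",
                             data=epochs.channel_info["hemisphere"].to_numpy(dtype="S"))
            f.create_dataset("posterior",
                             data=epochs.channel_info["posterior"].to_numpy(bool))
    if epochs.trials is not None:
        epochs.trials.to_csv(_trials_path(path), index=False)
    return path


def read_epochs(path: str | Path) -> EpochSet:
    """Read an EpochSet written by :func:`write_epochs` (lossless)."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        for name in ("data", "times_ms", "channel_ids", "planar_pairs"):
            if name not in f:
                raise ValueError(f"{path}: missing dataset /{name}")
        data = f["data"][()].astype(float)
        times = f["times_ms"][()].astype(float)
        chans = [c.decode() for c in f["channel_ids"][()]]
        pairs = [tuple(int(v) for v in row) for row in f["planar_pairs"][()]]
        sfreq = float(f.attrs["sfreq_hz"])
        info = None
        if "hemisphere" in f:
            info = pd.DataFrame({
                "channel": chans,
                "hemisphere": [h.decode() for h in f["hemisphere"][()]],
                "posterior": f["posterior"][()].astype(bool),
            })
    trials = None
    tpath = _trials_path(path)
    if tpath.exists():
        trials = pd.read_csv(tpath)
        validate_trial_table(trials)
        if len(trials) != data.shape[0]:
            raise ValueError(
                f"{path}: trial table has {len(trials)} rows but data has "
                f"{data.shape[0]} trials")
    return EpochSet(data=data, times_ms=times, sfreq_hz=sfreq,
                    channel_ids=chans, planar_pairs=pairs, trials=trials,
                    channel_info=info)


def write_timecourse(tc: DecodingTimecourse, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("delta", data=tc.delta)
        f.create_dataset("trial_index", data=tc.trial_index)
        f.create_dataset("times_ms", data=tc.times_ms)
        f.attrs["sfreq_hz"] = tc.sfreq_hz
        f.attrs["scheme"] = tc.scheme
        f.attrs["condition"] = tc.condition
        f.attrs["params"] = json.dumps(tc.params)
    return path


def read_timecourse(path: str | Path) -> DecodingTimecourse:
    with h5py.File(path, "r") as f:
        return DecodingTimecourse(
            delta=f["delta"][()],
            trial_index=f["trial_index"][()],
            times_ms=f["times_ms"][()],
            sfreq_hz=float(f.attrs["sfreq_hz"]),
            scheme=str(f.attrs["scheme"]),
            condition=str(f.attrs["condition"]),
            params=json.loads(f.attrs["params"]),
        )


def load_config(path: str | Path) -> SimulationConfig:
    """Load a SimulationConfig from YAML; unknown keys raise."""
    with open(path) as f:
        d = yaml.safe_load(f) or {}
    return SimulationConfig.from_dict(d)


def save_config(config: SimulationConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        yaml.safe_dump(config.to_dict(), f, sort_keys=False)
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str | Path, stage: str, config: dict | None,
                   seeds: dict | None, inputs: list[str | Path] = (),
                   outputs: list[str | Path] = ()) -> Path:
    """Emit a per-stage run manifest with config, seeds and content hashes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": config,
        "seeds": seeds,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs if Path(p).exists()},
        "outputs": {str(p): _sha256(Path(p)) for p in outputs if Path(p).exists()},
    }
    path = out_dir / f"manifest_{stage}.json"
    with open(path, "w") as f:
        json.dump(manifest, f, indent=2)
    return path
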