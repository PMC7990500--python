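"""Plain-text / TIFF serialization for sessions, spike tables and movies."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate.behavior import Session
from .simulate.timing import TaskConfig

__all__ = [
    "write_session",
    "read_session",
    "write_spikes",
    "read_spikes",
    "write_movie",
    "read_movie",
]


def write_session(session: Session, csv_path, config=None, params=None, seed=None) -> None:
    """Session trials to CSV (one row per trial) plus a YAML sidecar with the
    generating configuration, observer parameters and seed."""
    csv_path = Path(csv_path)
    session.to_frame().to_csv(csv_path, index=False)
    sidecar = {
        "spot_id": session.spot_id,
        "area_label": session.area_label,
        "intensities": [float(v) for v in session.intensities],
        "metadata": session.metadata,
    }
    if config is not None:
        sidecar["task_config"] = {
            k: v for k, v in asdict(config).items() if k != "retry_budget"
        }
    if params is not None:
        sidecar["observer_params"] = asdict(params)
    if seed is not None:
        sidecar["seed"] = int(seed)
    with open(csv_path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)


def read_session(csv_path) -> Session:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = {}
    sidecar = csv_path.with_suffix(".yaml")
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
    kwargs = {}
    for key in ("spot_id", "area_label"):
        if key in meta:
            kwargs[key] = meta[key]
    if "intensities" in meta:
        kwargs["intensities"] = tuple(meta["intensities"])
    return Session.from_frame(df, **kwargs)


def write_spikes(spikes: pd.DataFrame, events: pd.DataFrame, out_dir, prefix="unit") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spikes.to_csv(out / f"{prefix}_spikes.csv", index=False)
    events.to_csv(out / f"{prefix}_events.csv", index=False)


def read_spikes(out_dir, prefix="unit") -> tuple[pd.DataFrame, pd.DataFrame]:
    out = Path(out_dir)
    return (
        pd.read_csv(out / f"{prefix}_spikes.csv"),
        pd.read_csv(out / f"{prefix}_events.csv"),
    )


def write_movie(movie: np.ndarray, stim_frames, tiff_path) -> None:
    import tifffile

    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, np.asarray(movie, dtype=np.float32))
    pd.DataFrame({"stim_frame": np.asarray(stim_frames, dtype=int)}).to_csv(
        tiff_path.with_suffix(".stims.csv"), index=False
    )


def read_movie(tiff_path) -> tuple[np.ndarray, np.ndarray]:
    import tifffile

    tiff_path = Path(tiff_path)
    movie = tifffile.imread(tiff_path).astype(float)
    stims = pd.read_csv(tiff_path.with_suffix(".stims.csv"))["stim_frame"].to_numpy()
    return movie, stims


def default_task_config() -> TaskConfig:
    return TaskConfig()
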