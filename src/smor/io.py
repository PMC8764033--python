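"""Reading and writing movies, ground truth, configs and reports.

Movies travel as multi-page grayscale TIFF (8/16-bit); the acquisition
interval is not stored in plain TIFF, so it must always be supplied
explicitly -- silently defaulting it would confuse the 32 ms and
multi-second acquisition regimes.  Ground truth and analysis reports are
JSON; configurations echo as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from smor.preprocess import MovieStack
from smor.simulate import GroundTruth, SimConfig


class UnsupportedFormatError(ValueError):
    """The file is not a grayscale multi-page movie this package reads."""


def read_movie(path: str | Path, frame_interval: float | None = None,
               pixel_size: float = 16.0) -> MovieStack:
    """Read a multi-page grayscale TIFF as a ``(T, H, W)`` movie stack."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim == 4 or (arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[-1] < min(arr.shape[:2])):
        raise UnsupportedFormatError(
            f"{path}: RGB/multichannel TIFF is not supported; supply a grayscale stack"
        )
    if arr.ndim != 3:
        raise UnsupportedFormatError(f"{path}: expected a (T, H, W) stack, got shape {arr.shape}")
    if arr.dtype not in (np.uint8, np.uint16):
        raise UnsupportedFormatError(
            f"{path}: unsupported bit depth {arr.dtype}; expected 8- or 16-bit grayscale"
        )
    if frame_interval is None:
        raise ValueError(
            "frame_interval is required: plain TIFF does not carry it; pass the "
            "acquisition interval in seconds (e.g. --frame-interval 0.1)"
        )
    return MovieStack(arr.astype(np.float32), frame_interval, pixel_size)


def write_movie(movie: MovieStack, path: str | Path) -> None:
    """Write the stack as 16-bit multi-page TIFF (values rounded and clipped)."""
    data = np.clip(np.rint(movie.frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), data, photometric="minisblack")


def save_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "coordinate_convention": "0-based, (x, y) = (column, row)",
        "sites": [
            {
                "x": float(truth.positions[s, 0]),
                "y": float(truth.positions[s, 1]),
                "amplitude_multiplier": float(truth.multipliers[s]),
                "is_stuck": bool(truth.is_stuck[s]),
            }
            for s in range(len(truth.positions))
        ],
        "state_trajectories": [
            [[state, float(a), float(b)] for state, a, b in traj]
            for traj in truth.trajectories
        ],
        "true_dwells": [float(d) for d in truth.true_dwells()],
        "drift_track": truth.drift_track.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    sites = payload["sites"]
    return GroundTruth(
        positions=np.array([[s["x"], s["y"]] for s in sites]),
        multipliers=np.array([s["amplitude_multiplier"] for s in sites]),
        is_stuck=np.array([s["is_stuck"] for s in sites], dtype=bool),
        trajectories=[
            [(state, a, b) for state, a, b in traj]
            for traj in payload["state_trajectories"]
        ],
        drift_track=np.asarray(payload["drift_track"], dtype=float),
    )


def save_sim_config(config: SimConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def load_sim_config(path: str | Path) -> SimConfig:
    data = yaml.safe_load(Path(path).read_text())
    known = set(SimConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    if "multimer_amplitudes" in data:
        data["multimer_amplitudes"] = tuple(data["multimer_amplitudes"])
    if "drift_velocity" in data:
        data["drift_velocity"] = tuple(data["drift_velocity"])
    return SimConfig(**data)


def save_simulation(movie: MovieStack, truth: GroundTruth, config: SimConfig,
                    movie_path: str | Path) -> None:
    """Write movie TIFF plus ground-truth JSON and config YAML sidecars."""
    movie_path = Path(movie_path)
    write_movie(movie, movie_path)
    save_ground_truth(truth, movie_path.with_suffix(".truth.json"))
    save_sim_config(config, movie_path.with_suffix(".config.yaml"))
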