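"""Readers and writers for worm trajectories, feature tables and pulse protocols.

All coordinates are micrometres and all times seconds.  The HDF5 layout is
one group per worm with datasets ``skeleton`` (T x P x 2), ``widths`` (T x P),
``timestamps`` (T) and attributes ``strain``, ``ventral_side``, ``fps``.  The
CSV dialect is one row per (frame, point) with columns
``frame, time_s, point_index, x_um, y_um, width_um``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

VENTRAL_SIDES = ("left", "right", "unknown")


class FormatError(ValueError):
    """A file does not match the documented layout."""


class ValidationError(ValueError):
    """A container violates its invariants."""


@dataclass
class WormTrajectory:
    """Posture-resolved trajectory of a single worm.

    ``skeleton[t, 0]`` is the head tip and ``skeleton[t, P-1]`` the tail tip.
    Frames where tracking failed are masked via ``frame_valid``; their
    coordinates are NaN and are never interpolated on read.
    """

    worm_id: str
    skeleton: np.ndarray  # (T, P, 2) um
    timestamps: np.ndarray  # (T,) s
    fps: float
    strain: str = ""
    widths: np.ndarray | None = None  # (T, P) um
    ventral_side: str = "unknown"
    frame_valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.skeleton = np.asarray(self.skeleton, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.widths is not None:
            self.widths = np.asarray(self.widths, dtype=float)
        if self.skeleton.ndim != 3 or self.skeleton.shape[2] != 2:
            raise ValidationError("skeleton must have shape (T, P, 2)")
        if self.n_points < 5:
            raise ValidationError("need at least 5 skeleton points per frame")
        if self.timestamps.shape != (self.n_frames,):
            raise ValidationError("timestamps length must equal frame count")
        if self.n_frames > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValidationError("timestamps must be strictly increasing")
        if not self.fps > 0:
            raise ValidationError("fps must be positive")
        if self.ventral_side not in VENTRAL_SIDES:
            raise ValidationError(
                f"ventral_side must be one of {VENTRAL_SIDES}, got {self.ventral_side!r}"
            )
        if self.widths is not None and self.widths.shape != (self.n_frames, self.n_points):
            raise ValidationError("widths must have shape (T, P)")
        finite = np.isfinite(self.skeleton).all(axis=(1, 2))
        if self.frame_valid is None:
            self.frame_valid = finite
        else:
            self.frame_valid = np.asarray(self.frame_valid, dtype=bool)
            if self.frame_valid.shape != (self.n_frames,):
                raise ValidationError("frame_valid length must equal frame count")
            # a frame with non-finite coordinates can never be valid
            self.frame_valid = self.frame_valid & finite

    @property
    def n_frames(self) -> int:
        return self.skeleton.shape[0]

    @property
    def n_points(self) -> int:
        return self.skeleton.shape[1]


@dataclass
class FeatureTable:
    """Worms x features matrix with strain labels."""

    values: np.ndarray  # (W, F)
    feature_names: list[str]
    worm_ids: list[str]
    strain_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_names = list(self.feature_names)
        self.worm_ids = [str(w) for w in self.worm_ids]
        self.strain_labels = [str(s) for s in self.strain_labels]
        w, f = self.values.shape
        if w == 0:
            raise ValidationError("feature table must contain at least one worm")
        if len(self.feature_names) != f:
            raise ValidationError("feature_names length must match value columns")
        if len(set(self.feature_names)) != f:
            raise ValidationError("feature names must be unique")
        if len(self.worm_ids) != w or len(self.strain_labels) != w:
            raise ValidationError("worm_ids/strain_labels length must match rows")
        if any(not s for s in self.strain_labels):
            raise ValidationError("strain labels must be non-empty")

    @property
    def n_worms(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "strain", self.strain_labels)
        df.insert(0, "worm_id", self.worm_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureTable":
        for col in ("worm_id", "strain"):
            if col not in df.columns:
                raise FormatError(f"feature table is missing the {col!r} column")
        names = [c for c in df.columns if c not in ("worm_id", "strain")]
        return cls(
            values=df[names].to_numpy(dtype=float),
            feature_names=names,
            worm_ids=df["worm_id"].tolist(),
            strain_labels=df["strain"].tolist(),
        )

    def select(self, names: Sequence[str]) -> "FeatureTable":
        idx = [self.feature_names.index(n) for n in names]
        return replace(self, values=self.values[:, idx], feature_names=list(names))


@dataclass
class PulseProtocol:
    """Stimulation schedule: lists of (start, stop) seconds from recording start."""

    short_pulses: list[tuple[float, float]]
    long_pulses: list[tuple[float, float]]
    inter_pulse_gap: float = 60.0
    pre_stimulus: float = 420.0

    def __post_init__(self) -> None:
        self.short_pulses = [(float(a), float(b)) for a, b in self.short_pulses]
        self.long_pulses = [(float(a), float(b)) for a, b in self.long_pulses]
        pulses = sorted(self.short_pulses + self.long_pulses)
        for start, stop in pulses:
            if start < 0 or stop <= start:
                raise ValidationError(f"pulse ({start}, {stop}) is empty or negative")
        for (_, s0), (s1, _) in zip(pulses, pulses[1:]):
            if s1 < s0:
                raise ValidationError("pulses overlap")

    def to_json(self) -> dict:
        return {
            "short_pulses": [list(p) for p in self.short_pulses],
            "long_pulses": [list(p) for p in self.long_pulses],
            "inter_pulse_gap": self.inter_pulse_gap,
            "pre_stimulus": self.pre_stimulus,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "PulseProtocol":
        try:
            return cls(
                short_pulses=[tuple(p) for p in obj["short_pulses"]],
                long_pulses=[tuple(p) for p in obj["long_pulses"]],
                inter_pulse_gap=float(obj.get("inter_pulse_gap", 60.0)),
                pre_stimulus=float(obj.get("pre_stimulus", 420.0)),
            )
        except KeyError as exc:  # pragma: no cover - message formatting
            raise FormatError(f"pulse protocol is missing field {exc}") from exc

    @classmethod
    def default(cls) -> "PulseProtocol":
        """Five 5 s pulses and one 90 s pulse, separated by 60 s, after a 7 min baseline."""
        pre, gap = 420.0, 60.0
        short = []
        t = pre
        for _ in range(5):
            short.append((t, t + 5.0))
            t += 5.0 + gap
        long = [(t, t + 90.0)]
        return cls(short_pulses=short, long_pulses=long, inter_pulse_gap=gap, pre_stimulus=pre)


# ---------------------------------------------------------------------------
# trajectory I/O


def write_trajectory(traj: WormTrajectory, path: str | Path, format: str = "hdf5") -> None:
    path = Path(path)
    if format == "hdf5":
        _write_trajectory_hdf5(traj, path)
    elif format == "csv":
        _write_trajectory_csv(traj, path)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")


def read_trajectory(path: str | Path, format: str | None = None) -> WormTrajectory:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "hdf5"
    if format == "hdf5":
        return _read_trajectory_hdf5(path)
    if format == "csv":
        return _read_trajectory_csv(path)
    raise ValueError(f"unknown trajectory format {format!r}")


def _write_trajectory_hdf5(traj: WormTrajectory, path: Path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group(traj.worm_id or "worm")
        g.create_dataset("skeleton", data=traj.skeleton)
        g.create_dataset("timestamps", data=traj.timestamps)
        if traj.widths is not None:
            g.create_dataset("widths", data=traj.widths)
        g.create_dataset("frame_valid", data=traj.frame_valid.astype(np.uint8))
        g.attrs["strain"] = traj.strain
        g.attrs["ventral_side"] = traj.ventral_side
        g.attrs["fps"] = traj.fps


def _read_trajectory_hdf5(path: Path) -> WormTrajectory:
    with h5py.File(path, "r") as f:
        names = list(f.keys())
        if not names:
            raise FormatError(f"{path}: no worm group found")
        g = f[names[0]]
        for ds in ("skeleton", "timestamps"):
            if ds not in g:
                raise FormatError(f"{path}: missing dataset {ds!r}")
        skeleton = g["skeleton"][()]
        timestamps = g["timestamps"][()]
        widths = g["widths"][()] if "widths" in g else None
        frame_valid = g["frame_valid"][()].astype(bool) if "frame_valid" in g else None
        attrs = dict(g.attrs)
        if "fps" not in attrs:
            raise FormatError(f"{path}: missing attribute 'fps'")
        return WormTrajectory(
            worm_id=names[0],
            skeleton=skeleton,
            timestamps=timestamps,
            widths=widths,
            frame_valid=frame_valid,
            strain=str(attrs.get("strain", "")),
            ventral_side=str(attrs.get("ventral_side", "unknown")),
            fps=float(attrs["fps"]),
        )


_CSV_COLUMNS = ["frame", "time_s", "point_index", "x_um", "y_um", "width_um"]


def _write_trajectory_csv(traj: WormTrajectory, path: Path) -> None:
    t_idx, p_idx = np.meshgrid(
        np.arange(traj.n_frames), np.arange(traj.n_points), indexing="ij"
    )
    widths = traj.widths if traj.widths is not None else np.full(
        (traj.n_frames, traj.n_points), np.nan
    )
    df = pd.DataFrame(
        {
            "frame": t_idx.ravel(),
            "time_s": np.repeat(traj.timestamps, traj.n_points),
            "point_index": p_idx.ravel(),
            "x_um": traj.skeleton[:, :, 0].ravel(),
            "y_um": traj.skeleton[:, :, 1].ravel(),
            "width_um": widths.ravel(),
        }
    )
    with open(path, "w") as fh:
        fh.write(
            f"# worm_id={traj.worm_id} strain={traj.strain} "
            f"ventral_side={traj.ventral_side} fps={traj.fps!r}\n"
        )
        df.to_csv(fh, index=False, float_format="%.17g")


def _read_trajectory_csv(path: Path) -> WormTrajectory:
    meta: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
            df = pd.read_csv(fh, float_precision="round_trip")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, float_precision="round_trip")
    missing = [c for c in _CSV_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    frames = np.sort(df["frame"].unique())
    points = np.sort(df["point_index"].unique())
    T, P = len(frames), len(points)
    if len(df) != T * P:
        raise FormatError(f"{path}: expected {T * P} rows (frames x points), got {len(df)}")
    df = df.sort_values(["frame", "point_index"])
    skeleton = np.stack(
        [
            df["x_um"].to_numpy().reshape(T, P),
            df["y_um"].to_numpy().reshape(T, P),
        ],
        axis=-1,
    )
    widths = None
    if "width_um" in df.columns:
        widths = df["width_um"].to_numpy().reshape(T, P)
        if np.isnan(widths).all():
            widths = None
    timestamps = df.groupby("frame")["time_s"].first().to_numpy()
    if T > 1 and not np.all(np.diff(timestamps) > 0):
        raise ValidationError(f"{path}: timestamps are not strictly increasing")
    fps = float(meta.get("fps", 1.0 / np.median(np.diff(timestamps)) if T > 1 else 1.0))
    return WormTrajectory(
        worm_id=meta.get("worm_id", path.stem),
        skeleton=skeleton,
        timestamps=timestamps,
        widths=widths,
        strain=meta.get("strain", ""),
        ventral_side=meta.get("ventral_side", "unknown"),
        fps=fps,
    )


# ---------------------------------------------------------------------------
# feature table I/O


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> FeatureTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return FeatureTable.from_frame(pd.read_csv(path, float_precision="round_trip"))


# ---------------------------------------------------------------------------
# pulse protocol I/O


def write_protocol(protocol: PulseProtocol, path: str | Path) -> None:
    Path(path).write_text(json.dumps(protocol.to_json(), indent=2))


def read_protocol(path: str | Path) -> PulseProtocol:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return PulseProtocol.from_json(json.loads(path.read_text()))
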