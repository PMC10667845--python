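"""Domain types and on-disk interchange format for recording sessions.

A session is a directory holding ``session.json`` (metadata and shapes),
``trials.csv``, ``spikes.csv``, ``waveforms.bin`` (float32 little-endian,
one block per unit in unit order) and optionally ``raw.bin`` (channels x
samples float32, row-major).  Everything is plain text or flat binary so a
session can be produced or consumed from any language.

Units: time in seconds (float64), voltage in microvolt, electrode geometry
in micrometre, stimulus coordinates in visual degrees with fixation at
(0, 0), cursor coordinates in centimetre.  Angles are degrees; grating
orientation lives on [0, 180), movement direction on [0, 360).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SCHEMA_VERSION = 1

#: snippet window around the spike peak/trough, milliseconds
SNIPPET_PRE_MS = 0.4
SNIPPET_POST_MS = 1.2

TRIAL_COLUMNS = [
    "trial_id",
    "onset_s",
    "offset_s",
    "orientation_deg",
    "grid_x_deg",
    "grid_y_deg",
    "direction_deg",
    "movement_onset_s",
]


class SchemaError(ValueError):
    """A required field is missing or ill-typed in the on-disk layout."""


class ValidationError(ValueError):
    """An in-memory object violates a domain invariant."""


def snippet_length(sampling_rate: float) -> int:
    """Number of samples saved per spike (0.4 ms before + 1.2 ms after peak)."""
    return int(round((SNIPPET_PRE_MS + SNIPPET_POST_MS) * 1e-3 * sampling_rate))


@dataclass
class ChannelInfo:
    """One recording site: id, shank, depth below pia and position on the shank."""

    channel_id: int
    shank_id: str
    depth_um: float
    position_um: tuple[float, float]

    def validate(self) -> None:
        if self.depth_um < 0:
            raise ValidationError(
                f"channel {self.channel_id}: depth_um must be >= 0, got {self.depth_um}"
            )


@dataclass
class SortedUnit:
    """A sorted single unit: spike times, primary channel and waveform snippets.

    ``waveforms`` holds one snippet per spike (n_spikes x n_samples, microvolt)
    taken on the primary channel.  ``isolation`` and ``noise_overlap`` are
    optional pass-through quality metrics produced by an external sorter.
    """

    unit_id: str
    spike_times: np.ndarray
    primary_channel: int
    waveforms: np.ndarray
    isolation: float | None = None
    noise_overlap: float | None = None

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=np.float64)
        self.waveforms = np.atleast_2d(np.asarray(self.waveforms, dtype=np.float32))
        if self.waveforms.size == 0:
            self.waveforms = self.waveforms.reshape(0, self.waveforms.shape[-1] if self.waveforms.ndim > 1 else 0)

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def validate(self, sampling_rate: float | None = None, duration_s: float | None = None) -> None:
        if self.spike_times.size and np.any(np.diff(self.spike_times) <= 0):
            raise ValidationError(f"unit {self.unit_id}: spike_times must be strictly increasing")
        if duration_s is not None and self.spike_times.size:
            if self.spike_times[0] < 0 or self.spike_times[-1] > duration_s:
                raise ValidationError(
                    f"unit {self.unit_id}: spike times outside [0, {duration_s}] s"
                )
        if sampling_rate is not None and self.waveforms.shape[0] > 0:
            expect = snippet_length(sampling_rate)
            if self.waveforms.shape[1] != expect:
                raise ValidationError(
                    f"unit {self.unit_id}: snippet length {self.waveforms.shape[1]} "
                    f"!= round(1.6 ms * fs) = {expect}"
                )


@dataclass
class CursorTrial:
    """One center-out trial: a timestamped 2D cursor path plus task geometry."""

    times: np.ndarray
    positions: np.ndarray
    target_direction_deg: float
    target_distance_cm: float = 7.5
    target_radius_cm: float = 1.85
    mode: str = "hand"
    success: bool = False
    timeout_s: float = 10.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.positions = np.asarray(self.positions, dtype=np.float64).reshape(-1, 2)

    @property
    def target_center(self) -> np.ndarray:
        a = np.deg2rad(self.target_direction_deg)
        return self.target_distance_cm * np.array([np.cos(a), np.sin(a)])

    def validate(self) -> None:
        if self.times.size != self.positions.shape[0]:
            raise ValidationError("cursor trial: times and positions length mismatch")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValidationError("cursor trial: times must be strictly increasing")
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError("cursor trial: positions must be finite")
        if self.mode not in ("hand", "brain"):
            raise ValidationError(f"cursor trial: unknown mode {self.mode!r}")


def empty_trials() -> pd.DataFrame:
    """A trial table with the canonical columns and zero rows."""
    return pd.DataFrame({c: pd.Series(dtype="float64" if c != "trial_id" else "int64")
                         for c in TRIAL_COLUMNS})


def validate_trials(trials: pd.DataFrame) -> None:
    for col in ("trial_id", "onset_s", "offset_s"):
        if col not in trials.columns:
            raise SchemaError(f"trial table missing column {col!r}")
    if len(trials) == 0:
        return
    if not (trials["onset_s"] < trials["offset_s"]).all():
        raise ValidationError("trial table: onset_s must precede offset_s in every row")
    if "orientation_deg" in trials.columns:
        ori = trials["orientation_deg"].dropna()
        if len(ori) and ((ori < 0) | (ori >= 180)).any():
            raise ValidationError("trial table: orientation_deg must lie in [0, 180)")
    if "direction_deg" in trials.columns:
        d = trials["direction_deg"].dropna()
        if len(d) and (~np.isclose(np.mod(d, 45.0), 0.0)).any():
            raise ValidationError("trial table: direction_deg must be one of 8 values at 45 deg spacing")


@dataclass
class RecordingSession:
    """A full recording session: geometry, raw traces, trials and sorted units."""

    session_id: str
    sampling_rate: float
    duration_s: float
    channels: list[ChannelInfo] = field(default_factory=list)
    raw: np.ndarray | None = None
    trials: pd.DataFrame = field(default_factory=empty_trials)
    units: list[SortedUnit] = field(default_factory=list)
    day_post_implant: int = 0

    def validate(self) -> None:
        if not self.sampling_rate > 0:
            raise ValidationError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if not self.duration_s > 0:
            raise ValidationError(f"duration_s must be > 0, got {self.duration_s}")
        ids = [c.channel_id for c in self.channels]
        if len(ids) != len(set(ids)):
            raise ValidationError("channel ids must be unique")
        for c in self.channels:
            c.validate()
        validate_trials(self.trials)
        for u in self.units:
            u.validate(sampling_rate=self.sampling_rate, duration_s=self.duration_s)
        if self.raw is not None and self.raw.ndim != 2:
            raise ValidationError("raw must be a channels x samples matrix")

    def channel_positions(self) -> dict[int, tuple[float, float]]:
        return {c.channel_id: c.position_um for c in self.channels}

    def unit(self, unit_id: str) -> SortedUnit:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)


# ---------------------------------------------------------------------------
# serialization

def _fmt(x) -> str:
    """Shortest round-trip decimal for floats; empty string for missing."""
    if x is None:
        return ""
    if isinstance(x, (float, np.floating)):
        if np.isnan(x):
            return ""
        return repr(float(x))
    return str(x)


def _write_csv(path: Path, columns: list[str], rows) -> None:
    lines = [",".join(columns)]
    for row in rows:
        lines.append(",".join(_fmt(v) for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def save_session(session: RecordingSession, path: str | Path) -> None:
    """Write ``session`` to directory ``path`` in the interchange layout.

    The byte layout is deterministic for a given session: fixed field order,
    shortest round-trip float formatting, float32 little-endian binaries.
    """
    session.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    meta = {
        "schema_version": SCHEMA_VERSION,
        "session_id": session.session_id,
        "sampling_rate": float(session.sampling_rate),
        "duration_s": float(session.duration_s),
        "day_post_implant": int(session.day_post_implant),
        "channels": [
            {
                "channel_id": int(c.channel_id),
                "shank_id": c.shank_id,
                "depth_um": float(c.depth_um),
                "position_um": [float(c.position_um[0]), float(c.position_um[1])],
            }
            for c in session.channels
        ],
        "units": [
            {
                "unit_id": u.unit_id,
                "primary_channel": int(u.primary_channel),
                "n_spikes": u.n_spikes,
                "waveform_shape": [int(s) for s in u.waveforms.shape],
                "isolation": None if u.isolation is None else float(u.isolation),
                "noise_overlap": None if u.noise_overlap is None else float(u.noise_overlap),
            }
            for u in session.units
        ],
        "raw_shape": None if session.raw is None else [int(s) for s in session.raw.shape],
    }
    (path / "session.json").write_text(
        json.dumps(meta, indent=2, ensure_ascii=False) + "\n", encoding="utf-8"
    )

    cols = [c for c in TRIAL_COLUMNS if c in session.trials.columns]
    _write_csv(
        path / "trials.csv",
        cols,
        (
            [None if (isinstance(v, float) and np.isnan(v)) else v for v in row]
            for row in session.trials[cols].itertuples(index=False)
        ),
    )

    spike_rows = (
        (u.unit_id, t) for u in session.units for t in u.spike_times
    )
    _write_csv(path / "spikes.csv", ["unit_id", "time_s"], spike_rows)

    if session.units:
        blocks = [u.waveforms.astype("<f4").tobytes(order="C") for u in session.units]
        (path / "waveforms.bin").write_bytes(b"".join(blocks))

    if session.raw is not None:
        (path / "raw.bin").write_bytes(session.raw.astype("<f4").tobytes(order="C"))


def _require(meta: dict, key: str, types) -> object:
    if key not in meta:
        raise SchemaError(f"session.json missing field {key!r}")
    v = meta[key]
    if not isinstance(v, types):
        raise SchemaError(f"session.json field {key!r} has wrong type {type(v).__name__}")
    return v


def load_session(path: str | Path) -> RecordingSession:
    """Load and fully validate a session directory written by :func:`save_session`."""
    path = Path(path)
    meta_path = path / "session.json"
    if not meta_path.exists():
        raise SchemaError(f"no session.json in {path}")
    meta = json.loads(meta_path.read_text(encoding="utf-8"))

    version = _require(meta, "schema_version", int)
    if version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema_version {version}")
    session_id = _require(meta, "session_id", str)
    sampling_rate = float(_require(meta, "sampling_rate", (int, float)))
    duration_s = float(_require(meta, "duration_s", (int, float)))
    day = int(_require(meta, "day_post_implant", int))

    channels = []
    for ch in _require(meta, "channels", list):
        channels.append(
            ChannelInfo(
                channel_id=int(_require(ch, "channel_id", int)),
                shank_id=str(_require(ch, "shank_id", str)),
                depth_um=float(_require(ch, "depth_um", (int, float))),
                position_um=tuple(_require(ch, "position_um", list)),
            )
        )

    trials_path = path / "trials.csv"
    if trials_path.exists():
        # header columns are preserved even for zero rows so save/load round-trips
        trials = pd.read_csv(trials_path, float_precision="round_trip")
    else:
        trials = empty_trials()

    spikes_path = path / "spikes.csv"
    if spikes_path.exists():
        spikes = pd.read_csv(spikes_path, float_precision="round_trip")
    else:
        spikes = pd.DataFrame({"unit_id": [], "time_s": []})

    units: list[SortedUnit] = []
    unit_meta = _require(meta, "units", list)
    wf_path = path / "waveforms.bin"
    wf_bytes = wf_path.read_bytes() if wf_path.exists() else b""
    offset = 0
    for um in unit_meta:
        unit_id = str(_require(um, "unit_id", str))
        shape = tuple(int(s) for s in _require(um, "waveform_shape", list))
        n = int(np.prod(shape)) if shape else 0
        block = np.frombuffer(wf_bytes, dtype="<f4", count=n, offset=offset).reshape(shape)
        offset += n * 4
        times = spikes.loc[spikes["unit_id"] == unit_id, "time_s"].to_numpy(dtype=np.float64)
        units.append(
            SortedUnit(
                unit_id=unit_id,
                spike_times=times,
                primary_channel=int(_require(um, "primary_channel", int)),
                waveforms=block.copy(),
                isolation=um.get("isolation"),
                noise_overlap=um.get("noise_overlap"),
            )
        )

    raw = None
    if meta.get("raw_shape") is not None:
        shape = tuple(int(s) for s in meta["raw_shape"])
        raw = np.frombuffer((path / "raw.bin").read_bytes(), dtype="<f4").reshape(shape).copy()

    session = RecordingSession(
        session_id=session_id,
        sampling_rate=sampling_rate,
        duration_s=duration_s,
        channels=channels,
        raw=raw,
        trials=trials,
        units=units,
        day_post_implant=day,
    )
    session.validate()
    return session
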