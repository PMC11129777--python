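"""Domain types and readers for laminar-probe recording sessions.

The pipeline consumes three kinds of input: an LFP stream in the SpikeGLX
dialect (interleaved little-endian int16 ``.bin`` plus a plain-text
``key=value`` ``.meta`` file), a Kilosort/Phy-style sorted-spike directory
(NPY spike-time and cluster arrays plus a ``cluster_info.tsv`` table), and a
probe-geometry JSON.  All public times are in seconds; all depths are in
micrometres on a canonical axis that is 0 at the most superficial channel
and increases toward the probe tip.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ProbeLayout",
    "LfpRecording",
    "EventTrain",
    "SpikeTable",
    "AnalysisConfig",
    "SpikeGlxMeta",
    "FormatError",
    "GeometryError",
    "ConsistencyError",
    "DegenerateInputError",
    "EmptyEpochError",
    "read_spikeglx_meta",
    "read_lfp_binary",
    "read_events_csv",
    "read_sorted_spikes",
    "epoch_lfp",
    "common_average_reference",
]


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class GeometryError(ValueError):
    """Probe geometry is inconsistent with the data it describes."""


class ConsistencyError(ValueError):
    """Companion arrays or tables disagree with each other."""


class DegenerateInputError(ValueError):
    """Input is structurally too small for the requested operation."""


class EmptyEpochError(ValueError):
    """No stimulus event yields a full peri-stimulus window."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProbeLayout:
    """Channel geometry of a dense two-column linear probe.

    ``depth_um`` is the canonical axial position per channel: 0 at the most
    superficial site, increasing downward.  Channels ordered canonically
    (by index) must be non-decreasing in depth, and the distinct depths
    (rows) must be equispaced at ``row_pitch_um``.
    """

    channel_ids: np.ndarray
    x_um: np.ndarray
    depth_um: np.ndarray
    row_pitch_um: float = 20.0
    n_columns: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "channel_ids", np.asarray(self.channel_ids, dtype=int))
        object.__setattr__(self, "x_um", np.asarray(self.x_um, dtype=float))
        object.__setattr__(self, "depth_um", np.asarray(self.depth_um, dtype=float))
        n = self.channel_ids.size
        if self.x_um.size != n or self.depth_um.size != n:
            raise GeometryError("channel_ids, x_um and depth_um must have equal length")
        if n == 0:
            raise GeometryError("empty probe layout")
        if np.any(np.diff(self.depth_um) < -1e-9):
            raise GeometryError("depth_um must be non-decreasing in canonical channel order")
        rows = np.unique(self.depth_um)
        if rows.size > 1:
            gaps = np.diff(rows)
            if np.any(np.abs(gaps - self.row_pitch_um) > 1e-6):
                raise GeometryError(
                    f"rows are not equispaced at row_pitch_um={self.row_pitch_um}"
                )

    @property
    def n_channels(self) -> int:
        return int(self.channel_ids.size)

    @property
    def row_depths_um(self) -> np.ndarray:
        """Distinct axial positions, sorted superficial to deep."""
        return np.unique(self.depth_um)

    @property
    def row_index(self) -> np.ndarray:
        """Row membership per channel (0 = most superficial row)."""
        rows = self.row_depths_um
        return np.searchsorted(rows, self.depth_um)

    @classmethod
    def default(
        cls, n_channels: int = 384, row_pitch_um: float = 20.0, n_columns: int = 2
    ) -> "ProbeLayout":
        """Checkerboard two-column layout: channels i, i+1 share row i//2."""
        idx = np.arange(n_channels)
        return cls(
            channel_ids=idx,
            x_um=(idx % n_columns) * 32.0,
            depth_um=(idx // n_columns) * row_pitch_um,
            row_pitch_um=row_pitch_um,
            n_columns=n_columns,
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "channel_ids": self.channel_ids.tolist(),
            "x_um": self.x_um.tolist(),
            "depth_um": self.depth_um.tolist(),
            "row_pitch_um": self.row_pitch_um,
            "n_columns": self.n_columns,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ProbeLayout":
        payload = json.loads(Path(path).read_text())
        return cls(
            channel_ids=np.asarray(payload["channel_ids"]),
            x_um=np.asarray(payload["x_um"]),
            depth_um=np.asarray(payload["depth_um"]),
            row_pitch_um=float(payload.get("row_pitch_um", 20.0)),
            n_columns=int(payload.get("n_columns", 2)),
        )


@dataclass
class LfpRecording:
    """Channels x samples voltage matrix (microvolts) with its geometry."""

    data: np.ndarray
    fs_hz: float
    layout: ProbeLayout
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data))
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.data.shape[0] != self.layout.n_channels:
            raise GeometryError(
                f"data has {self.data.shape[0]} channels, layout has "
                f"{self.layout.n_channels}"
            )
        if not np.isfinite(self.data).all():
            raise FormatError("non-finite samples in LFP data")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    @property
    def time_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_samples) / self.fs_hz


@dataclass(frozen=True)
class EventTrain:
    """Stimulus onset times (seconds), strictly increasing."""

    event_times_s: np.ndarray
    label: str = "flash"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "event_times_s", np.asarray(self.event_times_s, dtype=float)
        )
        if self.event_times_s.size > 1 and np.any(np.diff(self.event_times_s) <= 0):
            raise ValueError("event times must be strictly increasing")

    @property
    def n_events(self) -> int:
        return int(self.event_times_s.size)


@dataclass(frozen=True)
class SpikeTable:
    """Sorted spikes: per-spike time and cluster, per-cluster depth."""

    spike_times_s: np.ndarray
    cluster_id: np.ndarray
    cluster_ids: np.ndarray
    cluster_depth_um: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "spike_times_s", np.asarray(self.spike_times_s, float))
        object.__setattr__(self, "cluster_id", np.asarray(self.cluster_id, int))
        object.__setattr__(self, "cluster_ids", np.asarray(self.cluster_ids, int))
        object.__setattr__(
            self, "cluster_depth_um", np.asarray(self.cluster_depth_um, float)
        )
        if self.spike_times_s.size != self.cluster_id.size:
            raise ConsistencyError("spike time and cluster arrays differ in length")
        if self.cluster_ids.size != self.cluster_depth_um.size:
            raise ConsistencyError("cluster id and depth tables differ in length")
        if self.spike_times_s.size and self.spike_times_s.min() < 0:
            raise ValueError("spike times must be non-negative")
        missing = np.setdiff1d(np.unique(self.cluster_id), self.cluster_ids)
        if missing.size:
            raise ConsistencyError(f"spikes reference clusters without depth: {missing[:5]}")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times_s.size)

    def depth_of_cluster(self) -> dict[int, float]:
        return dict(zip(self.cluster_ids.tolist(), self.cluster_depth_um.tolist()))

    def spike_depths_um(self) -> np.ndarray:
        """Per-spike depth, via the cluster table."""
        lut = np.full(int(self.cluster_ids.max()) + 1 if self.cluster_ids.size else 1, np.nan)
        lut[self.cluster_ids] = self.cluster_depth_um
        return lut[self.cluster_id]


@dataclass
class AnalysisConfig:
    """Tunable parameters of the laminar-identification pipeline.

    Defaults follow the study paradigm: 5-35 Hz four-pole zero-phase
    Butterworth band, depth groups of 10 channels, a 120-channel x 20 ms
    Gaussian smoothing kernel with SD 12 (channel/ms units) for the dense
    CSD and a (3, 5 ms, SD 1.1) kernel for the chunked CSD, and a 15 min
    spike-field analysis window.
    """

    band_lo_hz: float = 5.0
    band_hi_hz: float = 35.0
    filter_order: int = 4  # total pole count of the band-pass
    group_size: int = 10
    smooth_window_ch: int = 120
    smooth_window_ms: float = 20.0
    smooth_sd: float = 12.0
    chunk_smooth_window: int = 3
    chunk_smooth_window_ms: float = 5.0
    chunk_smooth_sd: float = 1.1
    analysis_minutes: float = 15.0
    min_spikes_per_cell: int = 50
    seed: int = 0
    # epoching / detection knobs (engineering defaults, configurable)
    epoch_pre_s: float = 0.25
    epoch_post_s: float = 0.3
    response_window_s: tuple[float, float] = (0.0, 0.25)
    threshold_k: float = 4.0
    sustain_ms: float = 5.0
    min_flip_rad: float = float(np.pi / 2)
    max_offset_um: float = 300.0
    l4_half_thickness_um: float = 250.0
    apply_car: bool = True
    phase_sampling: str = "nearest"  # or "linear"

    def validate(self, fs_hz: float | None = None) -> None:
        if not (0 < self.band_lo_hz < self.band_hi_hz):
            raise ValueError("require 0 < band_lo_hz < band_hi_hz")
        if fs_hz is not None and self.band_hi_hz >= fs_hz / 2:
            raise ValueError("band_hi_hz must lie below the Nyquist frequency")
        if self.group_size < 1:
            raise ValueError("group_size must be >= 1")
        if self.smooth_window_ch < 1 or self.smooth_window_ms <= 0:
            raise ValueError("smoothing windows must be >= 1")
        if self.filter_order < 2 or self.filter_order % 2:
            raise ValueError("filter_order counts band-pass poles; must be even and >= 2")

    def replace(self, **kw) -> "AnalysisConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# SpikeGLX dialect
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpikeGlxMeta:
    """Parsed ``.meta`` sidecar of a SpikeGLX binary stream.

    Required keys: ``imSampRate`` (Hz), ``nSavedChans``; the microvolt
    scale comes from ``uVPerBit`` when present, otherwise from
    ``imAiRangeMax``/``imAiRangeMin`` with gain ``lfGain`` (default 250)
    assuming a full 16-bit code range.  Unknown keys pass through.
    """

    fs_hz: float
    n_channels: int
    uv_per_bit: float
    file_size_bytes: int | None = None
    extras: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float | None:
        if self.file_size_bytes is None:
            return None
        return self.file_size_bytes / (2 * self.n_channels) / self.fs_hz


def read_spikeglx_meta(path: str | Path) -> SpikeGlxMeta:
    """Parse a SpikeGLX-style ``key=value`` metadata file."""
    path = Path(path)
    kv: dict[str, str] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or "=" not in line:
            continue
        key, _, value = line.partition("=")
        kv[key.strip().lstrip("~")] = value.strip()

    for key in ("imSampRate", "nSavedChans"):
        if key not in kv:
            raise FormatError(f"{path.name}: missing mandatory key {key!r}")
    fs_hz = float(kv["imSampRate"])
    n_channels = int(kv["nSavedChans"])

    if "uVPerBit" in kv:
        uv_per_bit = float(kv["uVPerBit"])
    elif "imAiRangeMax" in kv and "imAiRangeMin" in kv:
        vrange = float(kv["imAiRangeMax"]) - float(kv["imAiRangeMin"])
        gain = float(kv.get("lfGain", 250.0))
        uv_per_bit = vrange / 65536.0 / gain * 1e6
    else:
        raise FormatError(
            f"{path.name}: missing voltage-scale key (uVPerBit or imAiRangeMax/Min)"
        )

    file_size = int(kv["fileSizeBytes"]) if "fileSizeBytes" in kv else None
    consumed = {"imSampRate", "nSavedChans", "uVPerBit", "fileSizeBytes"}
    extras = {k: v for k, v in kv.items() if k not in consumed}
    return SpikeGlxMeta(fs_hz, n_channels, uv_per_bit, file_size, extras)


def read_lfp_binary(
    bin_path: str | Path, meta: SpikeGlxMeta, layout: ProbeLayout
) -> LfpRecording:
    """De-interleave an int16 SpikeGLX binary into a microvolt matrix."""
    bin_path = Path(bin_path)
    raw = np.fromfile(bin_path, dtype="<i2")
    if raw.size % meta.n_channels:
        raise FormatError(
            f"{bin_path.name}: {raw.size * 2} bytes is not a whole number of "
            f"{meta.n_channels}-channel frames (truncated file?)"
        )
    if meta.n_channels != layout.n_channels:
        raise GeometryError(
            f"meta says {meta.n_channels} channels, layout has {layout.n_channels}"
        )
    data = raw.reshape(-1, meta.n_channels).T.astype(np.float32) * np.float32(meta.uv_per_bit)
    return LfpRecording(data=data, fs_hz=meta.fs_hz, layout=layout)


def read_events_csv(path: str | Path) -> EventTrain:
    """Read stimulus events from a two-column CSV (onset_s, label)."""
    df = pd.read_csv(path)
    if "onset_s" not in df.columns:
        raise FormatError(f"{Path(path).name}: missing onset_s column")
    label = str(df["label"].iloc[0]) if ("label" in df.columns and len(df)) else "flash"
    return EventTrain(event_times_s=df["onset_s"].to_numpy(float), label=label)


# ---------------------------------------------------------------------------
# Kilosort/Phy dialect
# ---------------------------------------------------------------------------


def read_sorted_spikes(dir_path: str | Path, fs_hz: float | None = None) -> SpikeTable:
    """Load a Kilosort/Phy-style output directory.

    Expects ``spike_times.npy`` (sample indices), ``spike_clusters.npy``
    and ``cluster_info.tsv`` with ``cluster_id``, ``depth`` and ``group``
    columns.  Clusters labelled ``noise`` are excluded.  The sampling rate
    is taken from ``params.py`` unless passed explicitly.
    """
    dir_path = Path(dir_path)
    for name in ("spike_times.npy", "spike_clusters.npy", "cluster_info.tsv"):
        if not (dir_path / name).exists():
            raise FileNotFoundError(f"{dir_path}: missing {name}")

    spike_samples = np.load(dir_path / "spike_times.npy").ravel()
    clusters = np.load(dir_path / "spike_clusters.npy").ravel()
    if spike_samples.size != clusters.size:
        raise ConsistencyError(
            f"spike_times ({spike_samples.size}) and spike_clusters "
            f"({clusters.size}) differ in length"
        )

    if fs_hz is None:
        params = dir_path / "params.py"
        if not params.exists():
            raise FileNotFoundError(f"{dir_path}: missing params.py and no fs_hz given")
        for line in params.read_text().splitlines():
            key, _, value = line.partition("=")
            if key.strip() == "sample_rate":
                fs_hz = float(value.strip())
                break
        else:
            raise FormatError("params.py has no sample_rate entry")

    info = pd.read_csv(dir_path / "cluster_info.tsv", sep="\t")
    for col in ("cluster_id", "depth", "group"):
        if col not in info.columns:
            raise FormatError(f"cluster_info.tsv: missing column {col!r}")
    keep = info[info["group"].astype(str) != "noise"]
    good_ids = keep["cluster_id"].to_numpy(int)
    mask = np.isin(clusters, good_ids)
    if not mask.any():
        warnings.warn("all clusters are labelled noise; spike table is empty")
    return SpikeTable(
        spike_times_s=spike_samples[mask].astype(float) / fs_hz,
        cluster_id=clusters[mask],
        cluster_ids=good_ids,
        cluster_depth_um=keep["depth"].to_numpy(float),
    )


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def epoch_lfp(
    rec: LfpRecording,
    events: EventTrain,
    window_s: tuple[float, float] = (0.1, 0.3),
) -> tuple[np.ndarray, np.ndarray]:
    """Cut baseline-subtracted peri-stimulus epochs.

    ``window_s = (pre, post)`` extends from ``-pre`` to ``+post`` seconds
    around each event.  The per-trial, per-channel mean over the
    pre-stimulus interval is subtracted.  Events whose window falls partly
    outside the recording are dropped (count logged).

    Returns ``(epochs, t_axis)`` with epochs shaped trials x channels x time
    and ``t_axis`` in seconds relative to event onset.
    """
    pre, post = window_s
    if pre < 0 or post <= 0:
        raise ValueError("window_s must be (pre >= 0, post > 0)")
    n_pre = int(round(pre * rec.fs_hz))
    n_post = int(round(post * rec.fs_hz))
    onsets = np.round((events.event_times_s - rec.t0_s) * rec.fs_hz).astype(int)
    ok = (onsets - n_pre >= 0) & (onsets + n_post <= rec.n_samples)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("epoch_lfp: dropped %d/%d events with partial windows",
                    n_dropped, onsets.size)
    onsets = onsets[ok]
    if onsets.size == 0:
        raise EmptyEpochError("no event has a full peri-stimulus window")

    n_t = n_pre + n_post
    epochs = np.empty((onsets.size, rec.n_channels, n_t), dtype=np.float64)
    for i, s in enumerate(onsets):
        epochs[i] = rec.data[:, s - n_pre : s + n_post]
    if n_pre > 0:
        baseline = epochs[:, :, :n_pre].mean(axis=2, keepdims=True)
        epochs -= baseline
    t_axis = (np.arange(n_t) - n_pre) / rec.fs_hz
    return epochs, t_axis


def common_average_reference(rec: LfpRecording) -> LfpRecording:
    """Subtract the across-channel mean signal from every channel."""
    if rec.n_channels < 2:
        raise DegenerateInputError("common average reference needs >= 2 channels")
    mean = rec.data.mean(axis=0, dtype=np.float64)
    data = rec.data - mean.astype(rec.data.dtype)
    return LfpRecording(data=data, fs_hz=rec.fs_hz, layout=rec.layout, t0_s=rec.t0_s)
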