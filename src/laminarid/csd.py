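"""Flash-evoked current source density (CSD) estimation.

The CSD is the negated second spatial derivative of the trial-averaged
stimulus-evoked LFP along the probe's depth axis, in arbitrary units (no
conductivity scaling) — sufficient to localize the earliest mid-cortical
sink marking the thalamorecipient input layer (layer 4).

Two smoothing variants are provided for the dense two-column probe:

* ``gaussian`` — 2D Gaussian smoothing across the raw channel axis
  (default 120-channel x 20 ms window, SD 12 in channel/ms units), then
  column collapse to one value per 20 µm row;
* ``chunk`` — average chunks of ``group_size`` (default 10) channels into
  ~100 µm depth groups, then a small (3, 5 ms, SD 1.1) kernel.

Both end in the same centred second difference, so their results can be
compared on a common depth support.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.interpolate import RectBivariateSpline

from .core_io import (
    AnalysisConfig,
    DegenerateInputError,
    EventTrain,
    LfpRecording,
    ProbeLayout,
    epoch_lfp,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CsdResult",
    "InputLayerEstimate",
    "average_evoked_lfp",
    "collapse_columns",
    "smooth_gaussian_2d",
    "chunk_average",
    "second_spatial_derivative",
    "compute_csd",
    "detect_input_layer",
    "interpolate_csd",
    "export_csd",
]


@dataclass
class CsdResult:
    """Depth x time CSD matrix in arbitrary units (sink-negative)."""

    csd: np.ndarray
    depth_axis_um: np.ndarray
    time_axis_s: np.ndarray
    method: str
    input_layer_depth_um: float | None = None
    input_layer_onset_s: float | None = None

    def __post_init__(self) -> None:
        self.csd = np.asarray(self.csd, dtype=float)
        self.depth_axis_um = np.asarray(self.depth_axis_um, dtype=float)
        self.time_axis_s = np.asarray(self.time_axis_s, dtype=float)
        if self.csd.shape != (self.depth_axis_um.size, self.time_axis_s.size):
            raise ValueError("csd shape must match depth and time axes")
        if self.depth_axis_um.size > 1 and np.any(np.diff(self.depth_axis_um) <= 0):
            raise ValueError("depth axis must be strictly increasing")


@dataclass(frozen=True)
class InputLayerEstimate:
    """Earliest evoked sink: depth centroid and onset latency."""

    depth_um: float
    onset_s: float


def average_evoked_lfp(epochs: np.ndarray) -> np.ndarray:
    """Mean over trials of a trials x channels x time epoch stack."""
    epochs = np.asarray(epochs)
    if epochs.ndim != 3 or epochs.shape[0] < 1:
        raise ValueError("epochs must be trials x channels x time with >= 1 trial")
    return epochs.mean(axis=0)


def collapse_columns(mat: np.ndarray, layout: ProbeLayout) -> tuple[np.ndarray, np.ndarray]:
    """Average channels sharing an axial row; returns (rows x time, row depths)."""
    mat = np.asarray(mat)
    if mat.shape[0] != layout.n_channels:
        raise ValueError("matrix row count must equal layout channel count")
    rows = layout.row_depths_um
    idx = layout.row_index
    out = np.zeros((rows.size, mat.shape[1]))
    counts = np.bincount(idx, minlength=rows.size).astype(float)
    np.add.at(out, idx, mat)
    out /= counts[:, None]
    return out, rows


def _gaussian_kernel_1d(window: int, sd: float) -> np.ndarray:
    """Unit-sum truncated Gaussian; window is widened to odd length."""
    half = max(int(np.ceil(window / 2)), 1)
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (x / sd) ** 2)
    return k / k.sum()


def smooth_gaussian_2d(
    mat: np.ndarray,
    window_ch: int,
    window_ms: float,
    sd: float,
    fs_hz: float = 1000.0,
) -> np.ndarray:
    """2D Gaussian smoothing with reflection at the edges.

    The kernel is a truncated Gaussian of ``window_ch`` rows by
    ``window_ms`` milliseconds with a single SD applied to both axes in
    native units (rows of the input matrix; milliseconds).  The kernel is
    separable and normalized to unit sum, so a constant matrix is
    unchanged.
    """
    mat = np.asarray(mat, dtype=float)
    if window_ch > mat.shape[0]:
        raise ValueError(
            f"smoothing window of {window_ch} rows exceeds the {mat.shape[0]}-row matrix"
        )
    window_t = window_ms * fs_hz / 1000.0
    sd_t = sd * fs_hz / 1000.0
    k_ch = _gaussian_kernel_1d(window_ch, sd)
    k_t = _gaussian_kernel_1d(int(round(window_t)), sd_t)
    out = ndimage.convolve1d(mat, k_ch, axis=0, mode="reflect")
    out = ndimage.convolve1d(out, k_t, axis=1, mode="reflect")
    return out


def chunk_average(
    mat: np.ndarray, group_size: int, depths_um: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Average blocks of ``group_size`` consecutive channels.

    Channels are taken in canonical depth order; a trailing partial group
    is dropped with a warning.  Group depth = mean depth of its members.
    """
    mat = np.asarray(mat)
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    n = mat.shape[0]
    n_groups = n // group_size
    if n_groups == 0:
        raise DegenerateInputError("fewer channels than one group")
    if n % group_size:
        logger.warning("chunk_average: dropping trailing partial group of %d channels",
                       n % group_size)
    trimmed = mat[: n_groups * group_size]
    grouped = trimmed.reshape(n_groups, group_size, -1).mean(axis=1)
    centers = None
    if depths_um is not None:
        depths_um = np.asarray(depths_um, dtype=float)[: n_groups * group_size]
        centers = depths_um.reshape(n_groups, group_size).mean(axis=1)
    return grouped, centers


def second_spatial_derivative(mat: np.ndarray, spacing_um: float) -> np.ndarray:
    """Negated centred second difference along depth (sink-negative CSD).

    ``out[i] = -(V[i-1] - 2 V[i] + V[i+1]) / spacing**2`` for interior rows;
    the result has two fewer rows than the input.
    """
    mat = np.asarray(mat, dtype=float)
    if mat.shape[0] < 3:
        raise DegenerateInputError("second spatial derivative needs >= 3 rows")
    if spacing_um <= 0:
        raise ValueError("spacing_um must be positive")
    return -(mat[:-2] - 2.0 * mat[1:-1] + mat[2:]) / spacing_um**2


def compute_csd(
    rec: LfpRecording,
    events: EventTrain,
    cfg: AnalysisConfig | None = None,
    method: str = "gaussian",
) -> CsdResult:
    """Flash-evoked CSD: epoch, average, smooth, collapse, differentiate.

    ``gaussian`` smooths the channels x time evoked average with the dense
    kernel, collapses the two columns to rows, and differentiates at the
    row pitch.  ``chunk`` first averages groups of ``cfg.group_size``
    channels, smooths with the small kernel, and differentiates at the
    group spacing.
    """
    cfg = cfg or AnalysisConfig()
    cfg.validate(rec.fs_hz)
    epochs, t_axis = epoch_lfp(rec, events, (cfg.epoch_pre_s, cfg.epoch_post_s))
    evoked = average_evoked_lfp(epochs)

    if method == "gaussian":
        window = min(cfg.smooth_window_ch, evoked.shape[0])
        smoothed = smooth_gaussian_2d(
            evoked, window, cfg.smooth_window_ms, cfg.smooth_sd, rec.fs_hz
        )
        rows, depths = collapse_columns(smoothed, rec.layout)
        spacing = rec.layout.row_pitch_um
    elif method == "chunk":
        rows, depths = chunk_average(evoked, cfg.group_size, rec.layout.depth_um)
        spacing = float(np.diff(depths).mean()) if depths.size > 1 else rec.layout.row_pitch_um
        if depths.size > 1 and not np.allclose(np.diff(depths), spacing, atol=1e-6):
            raise ValueError("chunked depth axis is not uniform")
        rows = smooth_gaussian_2d(
            rows, min(cfg.chunk_smooth_window, rows.shape[0]),
            cfg.chunk_smooth_window_ms, cfg.chunk_smooth_sd, rec.fs_hz
        )
    else:
        raise ValueError(f"unknown CSD method {method!r}")

    csd = second_spatial_derivative(rows, spacing)
    return CsdResult(
        csd=csd, depth_axis_um=depths[1:-1], time_axis_s=t_axis, method=method
    )


def _first_sustained_run(below: np.ndarray, n_sustain: int) -> int | None:
    """Index of the first run of >= n_sustain consecutive True values."""
    if n_sustain <= 1:
        hits = np.flatnonzero(below)
        return int(hits[0]) if hits.size else None
    padded = np.concatenate(([0], below.astype(int), [0]))
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    for s, e in zip(starts, ends):
        if e - s >= n_sustain:
            return int(s)
    return None


def detect_input_layer(
    result: CsdResult,
    response_window_s: tuple[float, float] = (0.0, 0.25),
    threshold_k: float = 4.0,
    sustain_ms: float = 5.0,
) -> InputLayerEstimate | None:
    """Locate the earliest evoked sink (input layer).

    Per depth row, the sink onset is the first post-stimulus time at which
    the CSD stays below (baseline mean - threshold_k x baseline SD) for at
    least ``sustain_ms``.  The estimate is the |CSD|-weighted depth
    centroid of the contiguous sink region containing the earliest-onset
    row, evaluated at that row's peak-sink time.  Returns None when no row
    crosses threshold.
    """
    t = result.time_axis_s
    base_mask = t < 0
    if not base_mask.any():
        raise ValueError("CSD has no pre-stimulus baseline samples")
    dt = float(np.median(np.diff(t)))
    n_sustain = max(int(round(sustain_ms / 1000.0 / dt)), 1)
    resp_mask = (t >= response_window_s[0]) & (t <= response_window_s[1])
    if not resp_mask.any():
        raise ValueError("response window contains no samples")
    resp_t = t[resp_mask]

    base = result.csd[:, base_mask]
    mu = base.mean(axis=1)
    sd = base.std(axis=1)
    sd = np.maximum(sd, 1e-12 * max(np.abs(result.csd).max(), 1.0))
    thr = mu - threshold_k * sd

    onsets = np.full(result.csd.shape[0], np.nan)
    for i in range(result.csd.shape[0]):
        below = result.csd[i, resp_mask] < thr[i]
        start = _first_sustained_run(below, n_sustain)
        if start is not None:
            onsets[i] = resp_t[start]
    if np.all(np.isnan(onsets)):
        return None

    order = np.lexsort((result.csd.min(axis=1), onsets))
    i0 = int(order[0])
    onset = float(onsets[i0])

    # sink region at the earliest row's peak-sink time
    peak_mask = resp_mask & (t >= onset) & (t <= onset + 0.05)
    j_peak = np.flatnonzero(peak_mask)[np.argmin(result.csd[i0, peak_mask])]
    col = result.csd[:, j_peak]
    in_sink = col < thr
    lo = i0
    while lo > 0 and in_sink[lo - 1]:
        lo -= 1
    hi = i0
    while hi < col.size - 1 and in_sink[hi + 1]:
        hi += 1
    weights = np.clip(mu[lo : hi + 1] - col[lo : hi + 1], 0.0, None)
    if weights.sum() <= 0:
        depth = float(result.depth_axis_um[i0])
    else:
        depth = float(
            np.average(result.depth_axis_um[lo : hi + 1], weights=weights)
        )
    return InputLayerEstimate(depth_um=depth, onset_s=onset)


def attach_input_layer(result: CsdResult, est: InputLayerEstimate | None) -> CsdResult:
    """Copy of ``result`` with the input-layer fields filled in."""
    if est is None:
        return replace(result, input_layer_depth_um=None, input_layer_onset_s=None)
    return replace(
        result, input_layer_depth_um=est.depth_um, input_layer_onset_s=est.onset_s
    )


def interpolate_csd(
    result: CsdResult, factor: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bicubic upsampling for display; original grid nodes are preserved.

    Returns ``(matrix, depth_axis_um, time_axis_s)`` on a grid with
    ``factor`` times denser spacing (size ``(n-1)*factor + 1`` per axis).
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    if factor == 1:
        return result.csd.copy(), result.depth_axis_um.copy(), result.time_axis_s.copy()
    d, t = result.depth_axis_um, result.time_axis_s
    spline = RectBivariateSpline(
        d, t, result.csd, kx=min(3, d.size - 1), ky=min(3, t.size - 1)
    )
    d_new = np.linspace(d[0], d[-1], (d.size - 1) * factor + 1)
    t_new = np.linspace(t[0], t[-1], (t.size - 1) * factor + 1)
    return spline(d_new, t_new), d_new, t_new


def export_csd(result: CsdResult, out_dir: str | Path, stem: str | None = None) -> dict:
    """Write a TSV matrix (depth µm rows, time ms columns) plus JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or f"csd_{result.method}"
    tsv = out_dir / f"{stem}.tsv"
    header = "depth_um\t" + "\t".join(
        f"{1000.0 * tv:.3f}" for tv in result.time_axis_s
    )
    body = np.column_stack([result.depth_axis_um, result.csd])
    np.savetxt(tsv, body, fmt="%.6g", delimiter="\t", header=header, comments="")
    sidecar = {
        "method": result.method,
        "units": "arbitrary (sink-negative)",
        "input_layer_depth_um": result.input_layer_depth_um,
        "input_layer_onset_s": result.input_layer_onset_s,
        "n_depths": int(result.depth_axis_um.size),
        "n_times": int(result.time_axis_s.size),
    }
    js = out_dir / f"{stem}.json"
    js.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return {"tsv": str(tsv), "json": str(js)}
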