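"""Spike-LFP phase analysis and phase-reversal depth detection.

For each depth group of ``group_size`` channels (channels 1-10, 11-20, ...)
the mean LFP is band-pass filtered 5-35 Hz with a zero-phase Butterworth
filter and converted to instantaneous phase via the Hilbert transform.
Each (spike group, LFP group) cell of the phase matrix is the circular
mean of the LFP phase sampled at that spike group's spike times.  A ~pi
reversal of the depth profile of these phases marks the transition between
the input layer (IV) and the deep layers.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .core_io import AnalysisConfig, LfpRecording, SpikeTable
from .csd import chunk_average

logger = logging.getLogger(__name__)

__all__ = [
    "PhaseMatrix",
    "ReversalEstimate",
    "bandpass_zero_phase",
    "instantaneous_phase",
    "group_lfp",
    "circular_mean",
    "rayleigh_p",
    "spike_phase_matrix",
    "detect_phase_reversal",
    "export_phase_matrix",
]


class EmptySpikesError(ValueError):
    """No spike falls into any depth group."""


@dataclass
class PhaseMatrix:
    """Spike-group x LFP-group circular mean phases with counts.

    ``mean_phase`` is NaN where a cell is masked (fewer than
    ``min_spikes_per_cell`` spikes, or an undefined circular mean).
    ``resultant`` holds the per-cell resultant length R.
    """

    mean_phase: np.ndarray
    n_spikes: np.ndarray
    resultant: np.ndarray
    spike_group_depths_um: np.ndarray
    lfp_group_depths_um: np.ndarray
    reversal_depth_um: float | None = None
    flip_magnitude_rad: float | None = None

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.mean_phase)


@dataclass(frozen=True)
class ReversalEstimate:
    """Phase-flip localization across adjacent LFP depth groups.

    ``depth_um`` is None when the maximal adjacent circular distance
    stays below the flip criterion; ``magnitude_rad`` is reported either
    way.
    """

    depth_um: float | None
    magnitude_rad: float


def bandpass_zero_phase(
    x: np.ndarray, fs_hz: float, lo_hz: float, hi_hz: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward).

    ``order`` counts the poles of the band-pass (an order-4 filter is a
    second-order design applied to both band edges); forward-backward
    application squares the magnitude response and cancels the phase.
    """
    if not (0 < lo_hz < hi_hz < fs_hz / 2):
        raise ValueError("require 0 < lo_hz < hi_hz < Nyquist")
    if order < 2 or order % 2:
        raise ValueError("order counts band-pass poles; must be even and >= 2")
    sos = sp_signal.butter(order // 2, [lo_hz, hi_hz], btype="bandpass",
                           fs=fs_hz, output="sos")
    return sp_signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def instantaneous_phase(x: np.ndarray) -> np.ndarray:
    """Phase of the analytic signal, in (-pi, pi].

    The input must already be band-limited (the analytic-signal phase is
    only meaningful for a narrow-band signal).
    """
    return np.angle(sp_signal.hilbert(np.asarray(x, dtype=float), axis=-1))


def group_lfp(
    rec: LfpRecording, group_size: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean LFP per block of ``group_size`` channels in depth order.

    Returns ``(group_signals, group_center_depths, group_edges)`` where
    ``group_edges`` has ``n_groups + 1`` depth boundaries assigning any
    depth to the group whose channel span contains it (used for spikes).
    """
    grouped, centers = chunk_average(rec.data, group_size, rec.layout.depth_um)
    n_groups = grouped.shape[0]
    member_depths = rec.layout.depth_um[: n_groups * group_size].reshape(
        n_groups, group_size
    )
    starts = member_depths.min(axis=1)
    ends = member_depths.max(axis=1)
    pitch = rec.layout.row_pitch_um
    edges = np.concatenate([starts, [ends[-1] + pitch]])
    return grouped, centers, edges


def circular_mean(
    angles: np.ndarray, weights: np.ndarray | None = None
) -> tuple[float, float]:
    """Angle and length of the (weighted) resultant vector.

    Returns ``(mean_angle, R)`` with the angle in (-pi, pi].  When the
    resultant length is numerically zero (e.g., antipodal input) the mean
    is undefined: returns ``(nan, 0.0)`` rather than raising.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("circular_mean of an empty set")
    if weights is None:
        z = np.exp(1j * angles).mean()
    else:
        weights = np.asarray(weights, dtype=float)
        if np.any(weights < 0):
            raise ValueError("weights must be non-negative")
        wsum = weights.sum()
        if wsum <= 0:
            raise ValueError("weights sum to zero")
        z = (weights * np.exp(1j * angles)).sum() / wsum
    r = float(np.abs(z))
    if r < 1e-12:
        return float("nan"), 0.0
    return float(np.angle(z)), r


def rayleigh_p(r: float, n: int) -> float:
    """Rayleigh-test p-value for uniformity of ``n`` angles with resultant R.

    Uses the standard large-sample correction
    ``p = exp(sqrt(1 + 4n + 4(n^2 - Rn^2)) - (1 + 2n))`` with ``Rn = n R``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rn = n * r
    arg = 1.0 + 4.0 * n + 4.0 * (n * n - rn * rn)
    p = np.exp(np.sqrt(arg) - (1.0 + 2.0 * n))
    return float(min(max(p, 0.0), 1.0))


def circular_distance(a: float | np.ndarray, b: float | np.ndarray) -> np.ndarray:
    """Absolute wrapped angular difference, in [0, pi]."""
    return np.abs(np.angle(np.exp(1j * (np.asarray(a) - np.asarray(b)))))


def spike_phase_matrix(
    rec: LfpRecording, spikes: SpikeTable, cfg: AnalysisConfig | None = None
) -> PhaseMatrix:
    """Circular mean spike phase for every (spike group, LFP group) pair.

    The recording should already be common-average re-referenced (see
    ``common_average_reference``); only the first ``cfg.analysis_minutes``
    of data are used (all of it, with a warning, when the recording is
    shorter).  Spikes are assigned to depth groups by their cluster depth
    using the same group boundaries as the LFP groups; phases are sampled
    at the nearest LFP sample (or linearly, per ``cfg.phase_sampling``).
    """
    cfg = cfg or AnalysisConfig()
    cfg.validate(rec.fs_hz)

    n_want = int(round(cfg.analysis_minutes * 60.0 * rec.fs_hz))
    if rec.n_samples < n_want:
        warnings.warn(
            f"recording shorter than {cfg.analysis_minutes} min; using all "
            f"{rec.duration_s:.1f} s"
        )
        n_use = rec.n_samples
    else:
        n_use = n_want

    group_sig, centers, edges = group_lfp(rec, cfg.group_size)
    group_sig = group_sig[:, :n_use]
    n_groups = group_sig.shape[0]

    # spike -> depth-group assignment via cluster depth
    t_max = n_use / rec.fs_hz
    tsel = (spikes.spike_times_s >= rec.t0_s) & (spikes.spike_times_s < rec.t0_s + t_max)
    times = spikes.spike_times_s[tsel] - rec.t0_s
    depths = spikes.spike_depths_um()[tsel]
    g_of_spike = np.digitize(depths, edges) - 1
    in_span = (g_of_spike >= 0) & (g_of_spike < n_groups)
    if (~in_span).any():
        logger.info("spike_phase_matrix: %d spikes outside the probe span excluded",
                    int((~in_span).sum()))
    times, g_of_spike = times[in_span], g_of_spike[in_span]
    if times.size == 0:
        raise EmptySpikesError("no spikes fall into any depth group")

    spike_idx_by_group = [np.flatnonzero(g_of_spike == g) for g in range(n_groups)]

    mean_phase = np.full((n_groups, n_groups), np.nan)
    n_mat = np.zeros((n_groups, n_groups), dtype=int)
    r_mat = np.zeros((n_groups, n_groups))

    nearest_idx = np.clip(np.round(times * rec.fs_hz).astype(int), 0, n_use - 1)
    for h in range(n_groups):
        filt = bandpass_zero_phase(
            group_sig[h], rec.fs_hz, cfg.band_lo_hz, cfg.band_hi_hz, cfg.filter_order
        )
        phase = instantaneous_phase(filt)
        if cfg.phase_sampling == "linear":
            # interpolate the analytic phasor, not the wrapped angle
            phasor = np.exp(1j * phase)
            sampled_all = np.angle(
                np.interp(times * rec.fs_hz, np.arange(n_use), phasor.real)
                + 1j * np.interp(times * rec.fs_hz, np.arange(n_use), phasor.imag)
            )
        else:
            sampled_all = phase[nearest_idx]
        for g in range(n_groups):
            idx = spike_idx_by_group[g]
            n_mat[g, h] = idx.size
            if idx.size == 0:
                continue
            ang, r = circular_mean(sampled_all[idx])
            r_mat[g, h] = r
            if idx.size >= cfg.min_spikes_per_cell and not np.isnan(ang):
                mean_phase[g, h] = ang

    # spike-group depths: mean cluster depth of contributing units, else center
    spike_depths = centers.copy()
    for g in range(n_groups):
        idx = spike_idx_by_group[g]
        if idx.size:
            spike_depths[g] = float(np.mean(depths[idx]))

    return PhaseMatrix(
        mean_phase=mean_phase,
        n_spikes=n_mat,
        resultant=r_mat,
        spike_group_depths_um=spike_depths,
        lfp_group_depths_um=centers,
    )


def detect_phase_reversal(
    pm: PhaseMatrix, min_flip_rad: float = float(np.pi / 2)
) -> ReversalEstimate:
    """Locate the depth at which the spike-phase profile flips by ~pi.

    Each LFP depth group gets an aggregate phase: the spike-count-weighted
    circular mean over spike groups of that column of the matrix.  The
    reversal is the midpoint of the adjacent (in depth) pair of LFP groups
    with maximal circular distance, reported only when that distance
    reaches ``min_flip_rad``.
    """
    agg_phase: list[float] = []
    agg_depth: list[float] = []
    for h in range(pm.mean_phase.shape[1]):
        col_valid = pm.valid[:, h]
        if not col_valid.any():
            continue
        ang, r = circular_mean(
            pm.mean_phase[col_valid, h], weights=pm.n_spikes[col_valid, h]
        )
        if np.isnan(ang):
            continue
        agg_phase.append(ang)
        agg_depth.append(float(pm.lfp_group_depths_um[h]))
    if len(agg_phase) < 2:
        return ReversalEstimate(depth_um=None, magnitude_rad=0.0)

    phases = np.asarray(agg_phase)
    depths = np.asarray(agg_depth)
    dists = circular_distance(phases[1:], phases[:-1])
    k = int(np.argmax(dists))
    magnitude = float(dists[k])
    if magnitude < min_flip_rad:
        return ReversalEstimate(depth_um=None, magnitude_rad=magnitude)
    return ReversalEstimate(
        depth_um=float(0.5 * (depths[k] + depths[k + 1])), magnitude_rad=magnitude
    )


def export_phase_matrix(pm: PhaseMatrix, out_dir, stem: str = "spike_phase") -> dict:
    """TSV exports (mean phases in degrees, counts) plus a JSON sidecar."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = "spike_depth_um\t" + "\t".join(
        f"{d:.1f}" for d in pm.lfp_group_depths_um
    )
    deg = np.degrees(pm.mean_phase)
    phase_tsv = out_dir / f"{stem}_deg.tsv"
    np.savetxt(
        phase_tsv,
        np.column_stack([pm.spike_group_depths_um, deg]),
        fmt="%.4f", delimiter="\t", header=header, comments="",
    )
    counts_tsv = out_dir / f"{stem}_counts.tsv"
    np.savetxt(
        counts_tsv,
        np.column_stack([pm.spike_group_depths_um, pm.n_spikes]),
        fmt="%.1f", delimiter="\t", header=header, comments="",
    )
    sidecar = {
        "reversal_depth_um": pm.reversal_depth_um,
        "flip_magnitude_rad": pm.flip_magnitude_rad,
        "n_spike_groups": int(pm.mean_phase.shape[0]),
        "n_lfp_groups": int(pm.mean_phase.shape[1]),
        "n_valid_cells": int(pm.valid.sum()),
    }
    js = out_dir / f"{stem}.json"
    js.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return {"phase_tsv": str(phase_tsv), "counts_tsv": str(counts_tsv), "json": str(js)}
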