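"""Ground-truthed synthetic laminar-probe sessions.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage can be tested without raw recordings:

* a flash-evoked mid-cortical current sink with flanking sources, planted
  as a CSD profile and integrated (exactly, by the discrete inverse of the
  second-difference operator) into an LFP depth profile;
* a 5-35 Hz band oscillation whose sign inverts below a planted depth
  (the spike-phase flip), with a short amplitude taper at the flip;
* spatially correlated pink (1/f) noise, optional common-mode artifact;
* a few hundred units firing as inhomogeneous Poisson processes with
  von Mises phase locking to the global rhythm; below the flip depth the
  locking phase relative to the local (inverted) field is offset by pi.

Sessions can be exported to the same SpikeGLX / Kilosort-Phy dialect the
readers in :mod:`laminarid.core_io` consume, plus a ground-truth JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import fft as sp_fft
from scipy import ndimage
from scipy.special import i0

from .core_io import (
    EventTrain,
    LfpRecording,
    ProbeLayout,
    SpikeTable,
    read_events_csv,
    read_lfp_binary,
    read_sorted_spikes,
    read_spikeglx_meta,
)

__all__ = [
    "GroundTruth",
    "SimulatedSession",
    "planted_csd_profile",
    "csd_to_lfp",
    "simulate_session",
    "export_session",
    "load_session",
]

UV_PER_BIT = 0.1  # int16 quantization step used on export (microvolts)


@dataclass(frozen=True)
class GroundTruth:
    """Planted parameters of a synthetic session.

    Depths are on the canonical axis (µm, superficial -> deep).  The
    evoked dipole is a Gaussian sink of SD ``sink_width_um`` at
    ``sink_depth_um`` with flanking sources at +-2 SD; its time course is
    an alpha function of rise ``sink_tau_s`` starting at ``sink_onset_s``
    after each flash.  Units lock to the planted oscillation with von
    Mises concentration ``kappa`` at global phase ``preferred_phase_rad``;
    since the field inverts below ``flip_depth_um``, the locking phase
    relative to the local LFP is offset by pi for deep units.
    """

    sink_depth_um: float = 900.0
    sink_onset_s: float = 0.04
    sink_width_um: float = 150.0
    sink_tau_s: float = 0.02
    flip_depth_um: float = 1000.0
    osc_freq_hz: float = 12.0
    kappa: float = 1.5
    preferred_phase_rad: float = float(-np.pi / 2)
    n_units: int = 220
    unit_depths_um: tuple[float, ...] | None = None
    unit_rates_hz: tuple[float, ...] | None = None
    osc_amp_uv: float = 50.0
    osc_phase_diffusion_rad2_s: float = 2.0
    evoked_amp_uv: float = 150.0
    noise_amp_uv: float = 25.0
    channel_noise_uv: float = 5.0
    common_mode_amp_uv: float = 0.0
    noise_corr_len_um: float = 100.0
    taper_um: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (5.0 <= self.osc_freq_hz <= 35.0):
            raise ValueError("osc_freq_hz must lie in the 5-35 Hz analysis band")
        if self.unit_rates_hz is not None and min(self.unit_rates_hz) <= 0:
            raise ValueError("unit rates must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimulatedSession:
    rec: LfpRecording
    events: EventTrain
    spikes: SpikeTable
    gt: GroundTruth


def planted_csd_profile(
    gt: GroundTruth, depth_axis_um: np.ndarray, time_axis_s: np.ndarray
) -> np.ndarray:
    """Planted depth x time CSD: Gaussian sink with balancing sources.

    The sink (negative lobe) sits at ``sink_depth_um``; two positive
    source lobes at +-2 sink widths are scaled so every time slice sums
    exactly to zero over depth (sources balance sinks).  The time course
    is an alpha function ``(t'/tau) exp(1 - t'/tau)`` for ``t' >= 0``.
    """
    z = np.asarray(depth_axis_um, dtype=float)
    t = np.asarray(time_axis_s, dtype=float)
    w = gt.sink_width_um

    sink = np.exp(-0.5 * ((z - gt.sink_depth_um) / w) ** 2)
    src_a = np.exp(-0.5 * ((z - gt.sink_depth_um + 2 * w) / w) ** 2)
    src_b = np.exp(-0.5 * ((z - gt.sink_depth_um - 2 * w) / w) ** 2)
    half = 0.5 * sink.sum()
    profile = -sink
    if src_a.sum() > 0:
        profile = profile + src_a * (half / src_a.sum())
    if src_b.sum() > 0:
        profile = profile + src_b * (half / src_b.sum())

    tp = (t - gt.sink_onset_s) / gt.sink_tau_s
    alpha = np.where(tp >= 0, tp * np.exp(1.0 - tp), 0.0)
    return np.outer(profile, alpha)


def csd_to_lfp(csd_profile: np.ndarray, spacing_um: float) -> np.ndarray:
    """Exact discrete inverse of the sink-negative second difference.

    Double summation over depth of ``-csd * spacing**2`` with zero value
    and zero slope at the top boundary, so that
    ``second_spatial_derivative(csd_to_lfp(C), spacing)`` reproduces C on
    the interior rows exactly.
    """
    arr = np.asarray(csd_profile, dtype=float)
    c = arr[:, None] if arr.ndim == 1 else arr
    h2 = float(spacing_um) ** 2
    # first differences D[i] = V[i+1] - V[i]; D[0] = 0, D[i] = D[i-1] - h^2 C[i]
    d = np.zeros_like(c)
    d[1:] = -h2 * np.cumsum(c[1:], axis=0)
    v = np.zeros_like(c)
    v[1:] = np.cumsum(d[:-1], axis=0)
    return v[:, 0] if arr.ndim == 1 else v


def _pink_noise(rng: np.random.Generator, n_rows: int, n_samples: int,
                block: int = 48) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise, independent across rows."""
    n_f = n_samples // 2 + 1
    amp = np.zeros(n_f, dtype=np.float32)
    amp[1:] = 1.0 / np.sqrt(np.arange(1, n_f, dtype=np.float32))
    out = np.empty((n_rows, n_samples), dtype=np.float32)
    for lo in range(0, n_rows, block):
        hi = min(lo + block, n_rows)
        re = rng.standard_normal((hi - lo, n_f), dtype=np.float32) * amp
        im = rng.standard_normal((hi - lo, n_f), dtype=np.float32) * amp
        out[lo:hi] = sp_fft.irfft(re + 1j * im, n=n_samples, axis=1)
    out /= out.std()
    return out


def _correlated_pink_noise(
    rng: np.random.Generator, n_rows: int, n_samples: int,
    corr_len_rows: float
) -> np.ndarray:
    """Pink noise with exponential across-row correlation (unit variance)."""
    noise = _pink_noise(rng, n_rows, n_samples)
    if corr_len_rows > 0 and n_rows > 1:
        half = int(np.ceil(3 * corr_len_rows))
        taps = np.exp(-np.abs(np.arange(-half, half + 1)) / corr_len_rows)
        taps /= np.sqrt((taps**2).sum())  # preserve variance for white inputs
        noise = ndimage.convolve1d(noise, taps.astype(np.float32), axis=0,
                                   mode="reflect")
        noise /= noise.std()
    return noise


class ParameterError(ValueError):
    """Simulation parameters are mutually inconsistent."""


def simulate_session(
    gt: GroundTruth,
    n_trials: int = 75,
    iti_s: float = 5.0,
    fs_hz: float = 1000.0,
    n_channels: int = 384,
    duration_s: float = 380.0,
    first_flash_s: float = 1.0,
    layout: ProbeLayout | None = None,
) -> SimulatedSession:
    """Generate one session: LFP, flash events, spikes and ground truth.

    All randomness is drawn from a single generator seeded with
    ``gt.seed``, so identical parameters give bit-identical sessions.
    """
    rng = np.random.default_rng(gt.seed)
    layout = layout or ProbeLayout.default(n_channels, n_columns=2)
    if layout.n_channels != n_channels:
        raise ParameterError("layout channel count disagrees with n_channels")
    rows = layout.row_depths_um
    span = float(rows[-1])
    for name, depth in (("sink", gt.sink_depth_um), ("flip", gt.flip_depth_um)):
        if not (0 <= depth <= span):
            raise ParameterError(f"{name} depth {depth} um outside probe span 0-{span}")

    n_samples = int(round(duration_s * fs_hz))
    last_flash = first_flash_s + (n_trials - 1) * iti_s if n_trials else 0.0
    if n_trials and last_flash + 0.5 > duration_s:
        raise ParameterError(
            f"{n_trials} trials at {iti_s} s ITI do not fit in {duration_s} s"
        )

    t = np.arange(n_samples) / fs_hz

    # oscillation with a sign flip (amplitude-tapered) below flip_depth_um;
    # its phase performs a slow random walk so successive flashes sample
    # unrelated phases (a perfectly periodic rhythm would survive trial
    # averaging and contaminate the evoked CSD)
    sign_profile = np.tanh((gt.flip_depth_um - rows) / gt.taper_um)
    step_sd = np.sqrt(gt.osc_phase_diffusion_rad2_s / fs_hz)
    phase_walk = np.cumsum(rng.standard_normal(n_samples)) * step_sd
    theta = 2 * np.pi * gt.osc_freq_hz * t + phase_walk
    osc = np.sin(theta).astype(np.float32)
    rows_sig = (gt.osc_amp_uv * sign_profile).astype(np.float32)[:, None] * osc[None, :]

    # evoked response: planted CSD integrated to an LFP depth profile
    event_times = first_flash_s + np.arange(n_trials) * iti_s
    if n_trials:
        ep_t = np.arange(0.0, 0.4, 1.0 / fs_hz)
        profile = planted_csd_profile(gt, rows, ep_t)
        v = csd_to_lfp(profile, layout.row_pitch_um)
        peak = np.abs(v).max()
        if peak > 0:
            v *= gt.evoked_amp_uv / peak
        v32 = v.astype(np.float32)
        for et in event_times:
            s0 = int(round(et * fs_hz))
            s1 = min(s0 + v32.shape[1], n_samples)
            rows_sig[:, s0:s1] += v32[:, : s1 - s0]

    # spatially correlated pink noise on the row lattice
    corr_rows = gt.noise_corr_len_um / layout.row_pitch_um
    noise = _correlated_pink_noise(rng, rows.size, n_samples, corr_rows)
    np.multiply(noise, np.float32(gt.noise_amp_uv), out=noise)
    rows_sig += noise
    del noise

    data = rows_sig[layout.row_index]
    del rows_sig
    if gt.channel_noise_uv > 0:
        data += np.float32(gt.channel_noise_uv) * rng.standard_normal(
            data.shape, dtype=np.float32
        )
    if gt.common_mode_amp_uv > 0:
        # reference-contamination artifact, identical on every channel: the
        # reference electrode sits in the brain, so every channel inherits a
        # copy of the rhythm as seen at the reference site.  Being coherent
        # with the oscillation, it drags all channels to the reference's
        # phase and masks the depth flip until the common average is removed.
        data += np.float32(gt.common_mode_amp_uv) * osc

    rec = LfpRecording(data=data, fs_hz=fs_hz, layout=layout)
    events = EventTrain(event_times_s=event_times, label="flash")

    # units: depths around the input layer, lognormal rates
    if gt.unit_depths_um is not None:
        unit_depths = np.asarray(gt.unit_depths_um, dtype=float)
    else:
        lo = max(0.0, gt.sink_depth_um - 1000.0)
        hi = min(span, gt.sink_depth_um + 1000.0)
        unit_depths = rng.uniform(lo, hi, gt.n_units)
    if gt.unit_rates_hz is not None:
        unit_rates = np.asarray(gt.unit_rates_hz, dtype=float)
    else:
        unit_rates = rng.lognormal(mean=np.log(4.0), sigma=0.5, size=unit_depths.size)
    if unit_rates.size != unit_depths.size:
        raise ParameterError("unit_depths_um and unit_rates_hz differ in length")

    # inhomogeneous Poisson spiking locked to the oscillation's phase track
    # phi(t) = theta(t) - pi/2 (analytic phase of sin).  Units at every depth
    # lock to the same global rhythm; because the field itself inverts below
    # flip_depth_um, a deep unit's preferred phase relative to its LOCAL LFP
    # is offset by pi, which is what the measured phase matrix shows.
    phi_track = theta - np.pi / 2
    norm = i0(gt.kappa)
    all_samples: list[np.ndarray] = []
    all_clusters: list[np.ndarray] = []
    for u, (depth, rate) in enumerate(zip(unit_depths, unit_rates)):
        mu = gt.preferred_phase_rad
        lam_max = rate * np.exp(gt.kappa) / norm
        n_cand = rng.poisson(lam_max * duration_s)
        cand = rng.uniform(0.0, duration_s, n_cand)
        cand_idx = np.minimum(np.round(cand * fs_hz).astype(np.int64), n_samples - 1)
        accept = rng.uniform(0.0, 1.0, n_cand) < np.exp(
            gt.kappa * (np.cos(phi_track[cand_idx] - mu) - 1.0)
        )
        # sample-align spike times so the exported integer samples round-trip
        samples = cand_idx[accept]
        all_samples.append(samples)
        all_clusters.append(np.full(samples.size, u, dtype=np.int64))

    samples = np.concatenate(all_samples) if all_samples else np.empty(0, np.int64)
    clusters = np.concatenate(all_clusters) if all_clusters else np.empty(0, np.int64)
    order = np.lexsort((clusters, samples))
    spikes = SpikeTable(
        spike_times_s=samples[order] / fs_hz,
        cluster_id=clusters[order],
        cluster_ids=np.arange(unit_depths.size),
        cluster_depth_um=unit_depths,
    )
    return SimulatedSession(rec=rec, events=events, spikes=spikes, gt=gt)


# ---------------------------------------------------------------------------
# Export / load in the core_io dialects
# ---------------------------------------------------------------------------


def export_session(session: SimulatedSession, dir_path: str | Path) -> dict:
    """Write SpikeGLX-format LFP, a Phy-style sort directory and truth JSON."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    rec = session.rec

    codes = np.clip(
        np.round(rec.data / UV_PER_BIT), -32768, 32767
    ).astype("<i2")
    bin_path = dir_path / "sim.lf.bin"
    np.ascontiguousarray(codes.T).tofile(bin_path)

    meta_path = dir_path / "sim.lf.meta"
    meta_lines = [
        f"imSampRate={rec.fs_hz:g}",
        f"nSavedChans={rec.n_channels}",
        f"uVPerBit={UV_PER_BIT:g}",
        f"fileSizeBytes={bin_path.stat().st_size}",
        f"fileTimeSecs={rec.duration_s:g}",
        "typeThis=imec",
    ]
    meta_path.write_text("\n".join(meta_lines) + "\n")

    rec.layout.to_json(dir_path / "probe_layout.json")

    with open(dir_path / "events.csv", "w") as fh:
        fh.write("onset_s,label\n")
        for et in session.events.event_times_s:
            fh.write(f"{et:.6f},{session.events.label}\n")

    sort_dir = dir_path / "sort"
    sort_dir.mkdir(exist_ok=True)
    samples = np.round(session.spikes.spike_times_s * rec.fs_hz).astype(np.uint64)
    np.save(sort_dir / "spike_times.npy", samples)
    np.save(sort_dir / "spike_clusters.npy", session.spikes.cluster_id.astype(np.int32))
    with open(sort_dir / "cluster_info.tsv", "w") as fh:
        fh.write("cluster_id\tdepth\tgroup\n")
        for cid, depth in zip(session.spikes.cluster_ids, session.spikes.cluster_depth_um):
            fh.write(f"{cid}\t{depth:.4f}\tgood\n")
    (sort_dir / "params.py").write_text(
        f"sample_rate = {rec.fs_hz:g}\nn_channels_dat = {rec.n_channels}\n"
    )

    (dir_path / "ground_truth.json").write_text(
        json.dumps(session.gt.to_dict(), indent=1, sort_keys=True)
    )
    return {
        "bin": str(bin_path),
        "meta": str(meta_path),
        "sort": str(sort_dir),
        "events": str(dir_path / "events.csv"),
        "ground_truth": str(dir_path / "ground_truth.json"),
    }


def load_session(dir_path: str | Path) -> SimulatedSession:
    """Read back an exported session (LFP quantized to int16 steps)."""
    dir_path = Path(dir_path)
    meta = read_spikeglx_meta(dir_path / "sim.lf.meta")
    layout = ProbeLayout.from_json(dir_path / "probe_layout.json")
    rec = read_lfp_binary(dir_path / "sim.lf.bin", meta, layout)
    events = read_events_csv(dir_path / "events.csv")
    spikes = read_sorted_spikes(dir_path / "sort")
    gt_file = dir_path / "ground_truth.json"
    if gt_file.exists():
        payload = json.loads(gt_file.read_text())
        for key in ("unit_depths_um", "unit_rates_hz"):
            if payload.get(key) is not None:
                payload[key] = tuple(payload[key])
        gt = GroundTruth(**payload)
    else:
        gt = GroundTruth()
    return SimulatedSession(rec=rec, events=events, spikes=spikes, gt=gt)
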