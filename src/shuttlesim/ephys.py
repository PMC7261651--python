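"""Noise floor and unit SNR for band-pass-filtered extracellular recordings.

The noise floor of a channel is the RMS voltage of spike-free data: five
100 ms snippets of filtered recording, chosen to contain no sorted units and
no amplifier saturation, are concatenated into one 500 ms block whose RMS is
Vrms-channel.  A sorted unit's signal-to-noise ratio is its waveform
peak-to-peak voltage divided by three times that noise floor:

    SNR = Vpp / (3 * Vrms-channel)

Snippet selection is the caller's responsibility (mirroring manual snippet
choice); :func:`flag_artifacts` helps by marking large threshold crossings
and rail-saturated samples.  Band-pass filtering is assumed upstream.

A synthetic trace generator (Gaussian noise + inserted spike templates with
ground-truth times) supports testing the metric end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import json
import numpy as np
import pandas as pd

__all__ = [
    "RecordingTrace",
    "UnitWaveform",
    "SnrResult",
    "noise_floor",
    "unit_snr",
    "synth_trace",
    "flag_artifacts",
    "read_trace_text",
    "read_trace_binary",
]


@dataclass(frozen=True)
class RecordingTrace:
    """A filtered voltage trace: (n_channels, n_samples) array in µV."""

    sampling_rate_hz: float
    samples_uv: np.ndarray

    def __post_init__(self) -> None:
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling rate must be positive")
        s = np.atleast_2d(np.asarray(self.samples_uv, dtype=float))
        if not np.isfinite(s).all():
            raise ValueError("trace contains non-finite samples")
        object.__setattr__(self, "samples_uv", s)

    @property
    def n_channels(self) -> int:
        return self.samples_uv.shape[0]

    @property
    def duration_s(self) -> float:
        return self.samples_uv.shape[1] / self.sampling_rate_hz


@dataclass(frozen=True)
class UnitWaveform:
    """A sorted unit's mean spike waveform (µV)."""

    waveform_uv: np.ndarray

    @property
    def vpp_uv(self) -> float:
        w = np.asarray(self.waveform_uv, dtype=float)
        return float(w.max() - w.min())


@dataclass(frozen=True)
class SnrResult:
    vrms_channel_uv: float
    snr: float


def noise_floor(
    trace: RecordingTrace,
    snippet_windows: list[tuple[float, float]],
    channel: int = 0,
    exclude_mask: np.ndarray | None = None,
    n_windows: int = 5,
    window_s: float = 0.1,
) -> float:
    """Vrms of the concatenated spike-free block, µV.

    ``snippet_windows`` are (start_s, stop_s) pairs; by default exactly five
    100 ms windows are required (length tolerance: one sample), they must be
    non-overlapping and inside the trace, and none may intersect the
    caller-supplied boolean ``exclude_mask`` of detected spikes/saturation.
    """
    fs = trace.sampling_rate_hz
    x = trace.samples_uv[channel]
    if len(snippet_windows) != n_windows:
        raise ValueError(
            f"expected {n_windows} snippet windows, got {len(snippet_windows)}"
        )
    tol = 1.0 / fs  # one sample of slack on the window length
    spans = []
    for start, stop in snippet_windows:
        if stop <= start:
            raise ValueError(f"window ({start}, {stop}) is empty or reversed")
        if abs((stop - start) - window_s) > tol + 1e-12:
            raise ValueError(
                f"window ({start}, {stop}) is not {window_s * 1e3:.0f} ms long"
            )
        i0, i1 = int(round(start * fs)), int(round(stop * fs))
        if i0 < 0 or i1 > x.size:
            raise ValueError(f"window ({start}, {stop}) lies outside the trace")
        spans.append((i0, i1))
    spans.sort()
    for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
        if b0 < a1:
            raise ValueError("snippet windows overlap")
    if exclude_mask is not None:
        mask = np.asarray(exclude_mask, dtype=bool)
        for i0, i1 in spans:
            if mask[i0:i1].any():
                raise ValueError(
                    f"window samples [{i0}, {i1}) intersect the exclusion mask"
                )
    block = np.concatenate([x[i0:i1] for i0, i1 in spans])
    return float(np.sqrt(np.mean(block ** 2)))


def unit_snr(unit: UnitWaveform, vrms_uv: float) -> SnrResult:
    """SNR = Vpp / (3 * Vrms-channel); scale-equivariant by construction."""
    if not vrms_uv > 0:
        raise ValueError("Vrms must be positive")
    return SnrResult(vrms_channel_uv=vrms_uv, snr=unit.vpp_uv / (3.0 * vrms_uv))


def synth_trace(
    noise_sigma_uv: float,
    spike_template_uv: np.ndarray | None,
    spike_rate_hz: float,
    duration_s: float,
    sampling_rate_hz: float = 30000.0,
    seed: int = 0,
) -> tuple[RecordingTrace, np.ndarray]:
    """Gaussian noise plus spike templates at Poisson times; fully seeded.

    Returns the trace and the ground-truth spike onset times (s).  Spikes
    whose template would run past the end of the trace are dropped; overlap
    between spikes is allowed (amplitudes add).
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sampling_rate_hz))
    x = rng.normal(0.0, noise_sigma_uv, n)
    times: list[float] = []
    if spike_template_uv is not None and spike_rate_hz > 0:
        template = np.asarray(spike_template_uv, dtype=float)
        n_spikes = rng.poisson(spike_rate_hz * duration_s)
        onsets = np.sort(rng.uniform(0.0, duration_s, n_spikes))
        for t0 in onsets:
            i0 = int(round(t0 * sampling_rate_hz))
            if i0 + template.size <= n:
                x[i0 : i0 + template.size] += template
                times.append(i0 / sampling_rate_hz)
    return (
        RecordingTrace(sampling_rate_hz, x[None, :]),
        np.asarray(times),
    )


def flag_artifacts(
    trace: RecordingTrace,
    channel: int = 0,
    threshold_sigmas: float = 5.0,
    rail_uv: float | None = None,
) -> np.ndarray:
    """Boolean mask of putative spikes/saturation to exclude from the noise floor.

    Threshold crossings beyond ``threshold_sigmas`` times a robust (MAD-based)
    noise estimate are flagged, as are samples at or beyond ``rail_uv``.
    """
    x = trace.samples_uv[channel]
    sigma = np.median(np.abs(x - np.median(x))) / 0.6744897501960817
    mask = np.abs(x - np.median(x)) > threshold_sigmas * sigma
    if rail_uv is not None:
        mask |= np.abs(x) >= rail_uv
    return mask


# ---------------------------------------------------------------------------
# Trace file I/O
# ---------------------------------------------------------------------------

def read_trace_text(path: str | Path, sampling_rate_hz: float) -> RecordingTrace:
    """Delimited text, one column per channel, values in µV."""
    df = pd.read_csv(path, sep=None, engine="python")
    return RecordingTrace(sampling_rate_hz, df.to_numpy(dtype=float).T)


def read_trace_binary(path: str | Path) -> RecordingTrace:
    """Raw binary with a JSON sidecar ``<path>.json``.

    Sidecar keys: ``sampling_rate_hz``, ``n_channels``, ``dtype`` (numpy
    name), ``uv_per_unit`` (scale to µV).  Samples are interleaved
    channel-major (C order, shape (n_channels, n_samples)).
    """
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        meta = json.load(fh)
    raw = np.fromfile(path, dtype=np.dtype(meta["dtype"]))
    n_ch = int(meta["n_channels"])
    samples = raw.reshape(n_ch, -1).astype(float) * float(meta["uv_per_unit"])
    return RecordingTrace(float(meta["sampling_rate_hz"]), samples)
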