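"""Sensor-space preprocessing: notch, band-pass, resampling, epoching,
planar-gradiometer combination and Morlet time-frequency transform.

The canonical order for the evoked-response pipeline is enforced by
:func:`preprocess_continuous`: notch -> (downsample) -> band-pass on the
continuous data -> epoch with baseline correction.  Band-pass filtering uses
a zero-phase windowed-sinc FIR (symmetric taps, applied once by FFT
convolution with the group delay compensated); phase preservation matters
for evoked latencies.  The 0.1 Hz high-pass edge implies a long filter
(several thousand taps at 150 Hz); continuous recordings are padded by
reflection and must be at least one filter length long.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy import signal

from .synthetic import SensorDataset

logger = logging.getLogger(__name__)

__all__ = [
    "BandSpec",
    "SLOW_BAND",
    "FAST_BAND",
    "ALPHA_BAND",
    "notch_filter",
    "bandpass",
    "downsample",
    "epoch",
    "combine_planar",
    "morlet_tfr",
    "preprocess_continuous",
]


class BandSpec:
    """A named frequency band [low, high) Hz."""

    def __init__(self, name: str, low: float, high: float):
        if not (0 <= low < high):
            raise ValueError("need 0 <= low < high")
        self.name, self.low, self.high = name, float(low), float(high)

    def validate(self, sfreq: float) -> None:
        if self.high >= sfreq / 2:
            raise ValueError(
                f"band {self.name}: high cut {self.high} Hz >= Nyquist "
                f"({sfreq / 2} Hz)"
            )

    def __repr__(self):
        return f"BandSpec({self.name!r}, {self.low}-{self.high} Hz)"

    def __eq__(self, other):
        return (self.name, self.low, self.high) == (other.name, other.low, other.high)


SLOW_BAND = BandSpec("slow", 0.1, 1.0)    # whole-sequence "global" response
FAST_BAND = BandSpec("fast", 2.0, 8.0)    # per-tone "local" response
ALPHA_BAND = BandSpec("alpha", 8.0, 12.0)


def _require_continuous(ds: SensorDataset, op: str) -> None:
    if ds.is_epoched:
        raise ValueError(f"{op} operates on continuous data")


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def notch_filter(ds: SensorDataset, low: float = 48.0, high: float = 52.0
                 ) -> SensorDataset:
    """Remove power-line interference in [low, high] Hz (default 48-52)."""
    _require_continuous(ds, "notch_filter")
    nyq = ds.sfreq / 2
    if high >= nyq:
        raise ValueError(f"notch stop band {low}-{high} Hz reaches Nyquist {nyq} Hz")
    f0 = 0.5 * (low + high)
    bw = high - low
    b, a = signal.iirnotch(f0, f0 / bw, fs=ds.sfreq)
    out = signal.filtfilt(b, a, ds.data, axis=-1)
    return ds.copy_with(data=out)


def _fir_taps(low: float, high: float, sfreq: float) -> np.ndarray:
    """Windowed-sinc band-pass taps (Hamming).  Transition bandwidths are
    a quarter of the corresponding edge, floored at 0.05 Hz and capped at
    the edge frequency itself."""
    tw_low = min(max(0.25 * low, 0.05), low) if low > 0 else np.inf
    tw_high = min(max(0.25 * high, 0.05), max(sfreq / 2 - high, 0.05))
    tw = min(tw_low, tw_high)
    numtaps = int(math.ceil(3.3 / (tw / sfreq)))
    numtaps |= 1  # odd length -> integer group delay, exact linear phase
    if low > 0:
        return signal.firwin(numtaps, [low, high], pass_zero=False, fs=sfreq)
    return signal.firwin(numtaps, high, pass_zero=True, fs=sfreq)


def _zero_phase_fir(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a symmetric FIR once, zero-phase, with reflection padding."""
    n = data.shape[-1]
    ntaps = taps.size
    if n <= ntaps:
        raise ValueError(
            f"signal too short for the filter: need more than {ntaps} samples "
            f"(got {n}); provide a longer continuous recording"
        )
    pad = ntaps  # generous reflection padding on both sides
    left = data[..., 1:pad + 1][..., ::-1]
    right = data[..., -pad - 1:-1][..., ::-1]
    padded = np.concatenate([left, data, right], axis=-1)
    out = signal.fftconvolve(padded, taps[np.newaxis, :], mode="same", axes=-1)
    return out[..., pad:pad + n]


def bandpass(ds: SensorDataset, band: BandSpec) -> SensorDataset:
    """Zero-phase FIR band-pass of continuous data."""
    _require_continuous(ds, "bandpass")
    band.validate(ds.sfreq)
    taps = _fir_taps(band.low, band.high, ds.sfreq)
    out = _zero_phase_fir(ds.data, taps)
    return ds.copy_with(data=out)


def downsample(ds: SensorDataset, target_sfreq: float) -> SensorDataset:
    """Anti-aliased polyphase resampling to ``target_sfreq``."""
    _require_continuous(ds, "downsample")
    if target_sfreq >= ds.sfreq:
        raise ValueError("target sampling rate must be below the current one")
    from fractions import Fraction

    frac = Fraction(target_sfreq / ds.sfreq).limit_denominator(1000)
    out = signal.resample_poly(ds.data, frac.numerator, frac.denominator, axis=-1)
    return ds.copy_with(data=out, sfreq=float(target_sfreq))


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------

def epoch(
    ds: SensorDataset,
    onsets=None,
    window: tuple[float, float] = (-0.1, 3.5),
    baseline: tuple[float, float] | None = (-0.1, 0.0),
) -> SensorDataset:
    """Cut trials around stimulus onsets and baseline-correct.

    Sample convention is half-open [start, end): a [-0.1, 3.5] s window at
    150 Hz yields 540 samples.  Trials whose window would fall outside the
    recording are rejected with a log entry.  The per-trial baseline mean
    (default the 100 ms pre-stimulus interval) is subtracted channel-wise.
    """
    _require_continuous(ds, "epoch")
    if onsets is None:
        onsets = ds.onsets
    if onsets is None:
        raise ValueError("no stimulus onsets available")
    tmin, tmax = window
    if baseline is not None and (baseline[0] < tmin or baseline[1] > tmax):
        raise ValueError("window must cover the baseline interval")
    n_samp = int(round((tmax - tmin) * ds.sfreq))
    times = tmin + np.arange(n_samp) / ds.sfreq
    n_total = ds.data.shape[-1]
    trials, kept = [], []
    for k, onset in enumerate(np.asarray(onsets, dtype=float)):
        s0 = int(round((onset + tmin) * ds.sfreq))
        if s0 < 0 or s0 + n_samp > n_total:
            logger.warning(
                "trial %d at onset %.3f s rejected: window outside recording", k, onset
            )
            continue
        trials.append(ds.data[:, s0:s0 + n_samp])
        kept.append(k)
    if not trials:
        raise ValueError("no trial fits inside the recording")
    data = np.stack(trials, axis=-1)  # channels x samples x trials
    if baseline is not None:
        sel = (times >= baseline[0]) & (times < baseline[1])
        if not np.any(sel):
            raise ValueError("baseline interval contains no samples")
        data = data - data[:, sel, :].mean(axis=1, keepdims=True)
    labels = (
        tuple(ds.condition_labels[k] for k in kept) if ds.condition_labels else ()
    )
    return ds.copy_with(
        data=data, times=times, onsets=None,
        condition_labels=labels, is_epoched=True,
    )


# ---------------------------------------------------------------------------
# planar combination
# ---------------------------------------------------------------------------

def combine_planar(ds: SensorDataset) -> SensorDataset:
    """Combine each planar-gradiometer pair by root sum square
    (sqrt(x^2 + y^2) per sample); magnetometers pass through untouched."""
    paired = {i for pair in ds.grad_pairs for i in pair}
    for i, role in enumerate(ds.ch_roles):
        if role == "grad" and i not in paired:
            raise ValueError(f"unpaired gradiometer channel {ds.ch_names[i]}")
    rows, names, roles = [], [], []
    for i, role in enumerate(ds.ch_roles):
        if role == "mag":
            rows.append(ds.data[i])
            names.append(ds.ch_names[i])
            roles.append("mag")
    for a, b in ds.grad_pairs:
        rows.append(np.sqrt(ds.data[a] ** 2 + ds.data[b] ** 2))
        names.append(ds.ch_names[a].rstrip("ab") + "_rss")
        roles.append("grad_rss")
    return ds.copy_with(
        data=np.stack(rows, axis=0), ch_names=tuple(names),
        ch_roles=tuple(roles), grad_pairs=(),
    )


# ---------------------------------------------------------------------------
# Morlet time-frequency transform
# ---------------------------------------------------------------------------

def morlet_tfr(ds: SensorDataset, frequencies, n_cycles: float = 7.0
               ) -> np.ndarray:
    """Complex-Morlet power, channels x frequencies x samples (trial mean
    for epoched input)."""
    from mne.time_frequency import tfr_array_morlet

    freqs = np.atleast_1d(np.asarray(frequencies, dtype=float))
    if np.any(freqs >= ds.sfreq / 2):
        raise ValueError("frequencies must be below Nyquist")
    if np.min(n_cycles) < 1:
        raise ValueError("n_cycles must be >= 1")
    if ds.is_epoched:
        arr = np.transpose(ds.data, (2, 0, 1))  # epochs x channels x samples
    else:
        arr = ds.data[np.newaxis]
    n_times = arr.shape[-1]
    # Morlet support is ~ +/- 5 temporal sigmas, sigma_t = n_cycles / (2 pi f)
    longest = int(np.ceil(10.0 * np.max(n_cycles / (2 * np.pi * freqs)) * ds.sfreq))
    if n_times < longest:
        raise ValueError(
            f"epoch ({n_times} samples) shorter than the longest wavelet "
            f"({longest} samples at {freqs.min()} Hz)"
        )
    power = tfr_array_morlet(
        arr, sfreq=ds.sfreq, freqs=freqs, n_cycles=n_cycles, output="power",
        zero_mean=False,
    )
    return power.mean(axis=0)


# ---------------------------------------------------------------------------
# canonical chain
# ---------------------------------------------------------------------------

def preprocess_continuous(
    ds: SensorDataset,
    band: BandSpec,
    target_sfreq: float | None = None,
    window: tuple[float, float] = (-0.1, 3.5),
    baseline: tuple[float, float] | None = (-0.1, 0.0),
    notch: bool = True,
) -> SensorDataset:
    """Enforced stage order: notch -> downsample -> band-pass (continuous)
    -> epoch with baseline correction."""
    if notch and ds.sfreq / 2 > 52.0:
        logger.info("stage 1: notch filter 48-52 Hz")
        ds = notch_filter(ds)
    if target_sfreq is not None and target_sfreq < ds.sfreq:
        logger.info("stage 2: downsample to %g Hz", target_sfreq)
        ds = downsample(ds, target_sfreq)
    logger.info("stage 3: band-pass %g-%g Hz on continuous data", band.low, band.high)
    ds = bandpass(ds, band)
    logger.info("stage 4: epoch %s s, baseline %s s", window, baseline)
    return epoch(ds, window=window, baseline=baseline)
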