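"""Resampling, band-pass filtering, and sliding band-power estimation.

All filters are applied forward-backward (zero-phase) so event timing is not
biased. Ripple-band filtering is a Chebyshev Type II design of order 4 with a
100-250 Hz passband; the EMG band is 250-350 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import ParameterError, SignalRecording

RIPPLE_BAND = (100.0, 250.0)
EMG_BAND = (250.0, 350.0)
DELTA_BAND = (1.0, 5.0)
THETA_BAND = (5.0, 10.0)

# Stopband edges / attenuation completing the Chebyshev II designs (the band
# and order alone do not pin down a filter). Edges are the widest that keep
# an order-4, 40 dB design within 0.5 dB of unity across the passband.
RIPPLE_STOP = (50.0, 400.0)
EMG_STOP = (130.0, 570.0)
STOP_ATTEN_DB = 40.0


def downsample(rec: SignalRecording, target_fs: float) -> SignalRecording:
    """Anti-aliased rational-ratio resampling (e.g. 32 kHz -> 1250 Hz = 5/128).

    Polyphase implementation with a Kaiser-windowed anti-alias filter; output
    length is ``ceil(n * target / source)`` and DC is preserved.
    """
    if target_fs <= 0:
        raise ParameterError("target sampling rate must be positive")
    if target_fs >= rec.fs:
        raise ParameterError(
            f"target rate {target_fs} must be below the source rate {rec.fs}"
        )
    from fractions import Fraction

    frac = Fraction(target_fs / rec.fs).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    out = signal.resample_poly(rec.samples, up, down, axis=1, padtype="line")
    return SignalRecording(
        samples=out, fs=rec.fs * up / down, channel_roles=list(rec.channel_roles), t0=rec.t0
    )


def _cheby2_bandpass_sos(fs: float, stop: tuple[float, float]) -> np.ndarray:
    return signal.cheby2(
        4, STOP_ATTEN_DB, stop, btype="bandpass", fs=fs, output="sos"
    )


def filter_ripple_band(x: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase 100-250 Hz band-pass (Chebyshev II, order 4) of an LFP trace."""
    if fs <= 2 * RIPPLE_BAND[1]:
        raise ParameterError(f"fs={fs} too low to resolve the 100-250 Hz band")
    sos = _cheby2_bandpass_sos(fs, RIPPLE_STOP)
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float))


def filter_emg(x: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase 250-350 Hz band-pass of an EMG trace."""
    if fs <= 2 * EMG_BAND[1]:
        raise ParameterError(f"fs={fs} too low to resolve the 250-350 Hz band")
    sos = _cheby2_bandpass_sos(fs, EMG_STOP)
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float))


@dataclass
class BandPowerSeries:
    """Sliding-window delta/theta power and EMG tone.

    ``times`` are window centers; ``delta_power``/``theta_power`` are PSD
    integrals over 1-5 and 5-10 Hz (a.u.); ``emg_tone`` is the per-window RMS
    of the band-filtered EMG.
    """

    times: np.ndarray
    delta_power: np.ndarray
    theta_power: np.ndarray
    emg_tone: np.ndarray
    window: float
    step: float

    def __post_init__(self) -> None:
        n = len(self.times)
        for arr in (self.delta_power, self.theta_power, self.emg_tone):
            if len(arr) != n:
                raise ParameterError("band-power arrays must share one length")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ParameterError("window times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


def band_power(
    lfp: np.ndarray,
    emg_filtered: np.ndarray,
    fs: float,
    window: float = 1.0,
    step: float = 0.5,
) -> BandPowerSeries:
    """Continuous delta (1-5 Hz) / theta (5-10 Hz) power plus EMG tone.

    Hann-tapered periodogram per window; windows tile the recording with the
    given step and never extend past the signal end.
    """
    if window < 1.0:
        raise ParameterError("window must be >= 1 s to resolve the 1 Hz edge")
    lfp = np.asarray(lfp, dtype=float)
    emg_filtered = np.asarray(emg_filtered, dtype=float)
    nwin = int(round(window * fs))
    nstep = int(round(step * fs))
    n = min(len(lfp), len(emg_filtered))
    if n < nwin:
        raise ParameterError("signal shorter than one analysis window")
    starts = np.arange(0, n - nwin + 1, nstep)
    taper = signal.get_window("hann", nwin)
    freqs = np.fft.rfftfreq(nwin, d=1.0 / fs)
    scale = 1.0 / (fs * np.sum(taper**2))
    delta_mask = (freqs >= DELTA_BAND[0]) & (freqs < DELTA_BAND[1])
    theta_mask = (freqs >= THETA_BAND[0]) & (freqs < THETA_BAND[1])
    df = freqs[1] - freqs[0]

    idx = starts[:, None] + np.arange(nwin)[None, :]
    seg = lfp[idx] * taper
    psd = (np.abs(np.fft.rfft(seg, axis=1)) ** 2) * scale
    psd[:, 1:-1] *= 2.0  # one-sided
    delta = psd[:, delta_mask].sum(axis=1) * df
    theta = psd[:, theta_mask].sum(axis=1) * df
    emg_tone = np.sqrt(np.mean(emg_filtered[idx] ** 2, axis=1))

    times = (starts + nwin / 2.0) / fs
    return BandPowerSeries(
        times=times,
        delta_power=delta,
        theta_power=theta,
        emg_tone=emg_tone,
        window=window,
        step=step,
    )
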