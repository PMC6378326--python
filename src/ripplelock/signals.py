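"""Shared signal primitives.

Band-pass filtering (zero-phase Butterworth), bipolar re-montaging,
Hilbert phase/envelope extraction, Stockwell and Morlet time-frequency
transforms, and event-locked epoch extraction.  Every downstream analysis
module builds on these.

Conventions
-----------
* All filtering is zero-phase (forward-backward, ``sosfiltfilt``); the
  analyses are phase-sensitive and must not introduce group delay.
* Epoch slicing is half-open ``[onset + w_lo, onset + w_hi)`` in samples,
  with the onset mapped to the nearest sample at or before the event time,
  so all epochs have identical length.
* Transform inputs are padded by reflection by one window length and the
  pad discarded, which keeps edge ringing out of 1 s analysis windows.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .core import AnalyticSignal, Channel, TFMap, TimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "bandpass_filter",
    "bipolar_montage",
    "analytic_phase_amplitude",
    "stockwell_transform",
    "morlet_transform",
    "extract_epochs",
    "decimate_timeseries",
]


class InvalidBandError(ValueError):
    """The requested band does not fit under the Nyquist frequency."""


class TooShortError(ValueError):
    """The signal is shorter than the filter warm-up length."""


class MontageError(ValueError):
    """The channel layout does not admit the requested montage."""


def _check_band(f_lo: float, f_hi: float, fs: float) -> None:
    if not (0 < f_lo < f_hi < fs / 2):
        raise InvalidBandError(
            f"band ({f_lo}, {f_hi}) Hz invalid at fs={fs} Hz (need 0 < lo < hi < fs/2)"
        )


def _design_sos(f_lo: float, f_hi: float, fs: float, order: int) -> np.ndarray:
    return sps.butter(order, [f_lo, f_hi], btype="bandpass", fs=fs, output="sos")


def bandpass_filter(ts: TimeSeries, f_lo: float, f_hi: float, order: int = 2) -> TimeSeries:
    """Zero-phase Butterworth band-pass of every channel.

    Default is an order-2 Butterworth applied forward-backward
    (effective magnitude response is the squared one-pass response).
    """
    _check_band(f_lo, f_hi, ts.fs)
    sos = _design_sos(f_lo, f_hi, ts.fs, order)
    # sosfiltfilt needs > 3 * (padlen) samples; reject clearly too-short input
    ntaps = 6 * (order + 1)
    if ts.n_samples <= 3 * ntaps:
        raise TooShortError(
            f"signal of {ts.n_samples} samples too short for order-{order} band-pass"
        )
    out = sps.sosfiltfilt(sos, ts.data, axis=-1)
    return ts.copy_with(data=out)


def bipolar_montage(ts: TimeSeries) -> TimeSeries:
    """Difference of successive contacts along each probe.

    Channels are grouped by region; within a region, contacts ordered by
    depth yield ``N-1`` bipolar channels, each ``contact[k] - contact[k+1]``.
    Bipolar channel metadata records the ordered source pair.
    """
    if ts.n_channels < 2:
        raise MontageError("bipolar montage needs at least two contacts")
    groups: dict[tuple, list[int]] = {}
    for i, ch in enumerate(ts.channels):
        groups.setdefault((ch.region, ch.kind), []).append(i)
    rows, chans = [], []
    for (region, kind), idx in groups.items():
        # superficial-first: probes are numbered from the top contact down
        idx = sorted(idx, key=lambda i: -ts.channels[i].depth_um)
        if len(idx) < 2:
            raise MontageError(f"region {region!r} has a single contact")
        for a, b in zip(idx[:-1], idx[1:]):
            rows.append(ts.data[a] - ts.data[b])
            ca, cb = ts.channels[a], ts.channels[b]
            chans.append(
                Channel(
                    id=f"{ca.id}-{cb.id}",
                    region=region,
                    depth_um=0.5 * (ca.depth_um + cb.depth_um),
                    montage="bipolar",
                    kind=kind,
                    sources=(ca.id, cb.id),
                )
            )
    return TimeSeries(data=np.array(rows), fs=ts.fs, t0=ts.t0, channels=chans)


def analytic_phase_amplitude(
    ts: TimeSeries, band: tuple, order: int = 2, channel: int = 0
) -> AnalyticSignal:
    """Instantaneous phase and envelope of one band-limited channel.

    The channel is band-passed (zero-phase Butterworth) and the Hilbert
    analytic signal taken; phase 0 falls at local maxima of the filtered
    trace.
    """
    filt = bandpass_filter(ts, band[0], band[1], order=order)
    analytic = sps.hilbert(filt.data[channel])
    return AnalyticSignal(
        phase=np.angle(analytic),
        amplitude=np.abs(analytic),
        band=tuple(band),
        fs=ts.fs,
        t0=ts.t0,
    )


def _stockwell_rows(x: np.ndarray) -> np.ndarray:
    """Frequency-domain Stockwell transform of a 1-D signal.

    Classic definition with the frequency-dependent Gaussian window of
    scale sigma(f) = 1/f: for frequency row ``n`` (in bins),
    ``S[n, :] = IFFT_m( H[(m+n) mod N] * exp(-2 pi^2 m^2 / n^2) )`` with
    ``H = FFT(x)/N``; the zero row is the signal mean.
    """
    x = np.asarray(x, dtype=float)
    n_samp = x.size
    H = np.fft.fft(x) / n_samp
    m = np.fft.fftfreq(n_samp) * n_samp  # signed bin indices
    rows = np.empty((n_samp // 2 + 1, n_samp), dtype=complex)
    rows[0] = np.mean(x)
    for n in range(1, n_samp // 2 + 1):
        gauss = np.exp(-2.0 * np.pi**2 * m**2 / n**2)
        rows[n] = np.fft.ifft(np.roll(H, -n) * gauss) * n_samp
    return rows


def stockwell_transform(ts: TimeSeries, f_max: float, channel: int = 0) -> TFMap:
    """S-transform of one channel up to ``f_max`` Hz.

    Frequency resolution is ``fs / n_samples`` (one row per FFT bin).
    """
    if f_max > ts.fs / 2:
        raise InvalidBandError(f"f_max={f_max} Hz above Nyquist {ts.fs / 2} Hz")
    x = ts.data[channel]
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    rows = _stockwell_rows(x)
    df = ts.fs / ts.n_samples
    n_keep = int(np.floor(f_max / df)) + 1
    n_keep = min(n_keep, rows.shape[0])
    freqs = np.arange(n_keep) * df
    return TFMap(values=rows[:n_keep], freqs=freqs, times=ts.times, kind="stockwell")


def morlet_wavelet(freq: float, fs: float, width: float = 7.0) -> np.ndarray:
    """Complex Morlet wavelet sampled at ``fs``, unit L2 norm.

    ``width`` is the number of cycles: sigma_t = width / (2 pi f).
    Support is +-4 sigma_t.
    """
    sigma_t = width / (2.0 * np.pi * freq)
    half = max(int(np.ceil(4.0 * sigma_t * fs)), 1)
    t = np.arange(-half, half + 1) / fs
    w = np.exp(-(t**2) / (2.0 * sigma_t**2)) * np.exp(2j * np.pi * freq * t)
    return w / np.linalg.norm(w)


def default_morlet_freqs(n_bins: int = 199, f_lo: float = 1.0, f_hi: float = 100.0) -> np.ndarray:
    """Default wavelet frequency grid: 199 bins between 1 and 100 Hz."""
    return np.linspace(f_lo, f_hi, n_bins)


def morlet_transform(
    ts: TimeSeries,
    freqs: Sequence[float] | None = None,
    width: float = 7.0,
    channel: int = 0,
) -> TFMap:
    """Complex Morlet coefficients of one channel on a frequency grid.

    Edges are handled by reflection padding of one wavelet half-length,
    discarded after convolution.
    """
    if freqs is None:
        freqs = default_morlet_freqs()
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise ValueError("empty frequency grid")
    if np.any(freqs <= 0) or np.any(freqs >= ts.fs / 2):
        raise InvalidBandError("Morlet frequencies must lie in (0, fs/2)")
    x = ts.data[channel]
    n = x.size
    out = np.empty((freqs.size, n), dtype=complex)
    for i, f in enumerate(freqs):
        w = morlet_wavelet(f, ts.fs, width=width)
        half = (w.size - 1) // 2
        pad = min(half, n - 1)
        xp = np.pad(x, pad, mode="reflect")
        conv = sps.fftconvolve(xp, w, mode="same")
        out[i] = conv[pad : pad + n]
    return TFMap(values=out, freqs=freqs, times=ts.times, kind="morlet")


def extract_epochs(
    ts: TimeSeries, onsets: Sequence[float], window: tuple
) -> list[TimeSeries]:
    """Equal-length epochs around event onsets.

    ``window = (w_lo, w_hi)`` in seconds relative to onset; the slice is
    half-open ``[onset + w_lo, onset + w_hi)`` in samples and t=0 of each
    epoch is the onset sample.  Out-of-bounds epochs are dropped and
    logged, not raised.
    """
    w_lo, w_hi = window
    if w_hi <= w_lo:
        raise ValueError("window must satisfy w_lo < w_hi")
    n_lo = int(round(w_lo * ts.fs))
    n_hi = int(round(w_hi * ts.fs))
    epochs = []
    for t_on in onsets:
        i_on = ts.index_of(t_on)
        a, b = i_on + n_lo, i_on + n_hi
        if a < 0 or b > ts.n_samples:
            logger.info("epoch at %.4f s outside recording bounds; dropped", t_on)
            continue
        epochs.append(
            TimeSeries(data=ts.data[:, a:b], fs=ts.fs, t0=n_lo / ts.fs, channels=list(ts.channels))
        )
    return epochs


def decimate_timeseries(ts: TimeSeries, target_fs: float) -> TimeSeries:
    """Anti-aliased decimation to (approximately) ``target_fs``.

    The decimation factor is the integer ``fs / target_fs``; identity if
    the factor is 1.
    """
    q = int(round(ts.fs / target_fs))
    if q <= 1:
        return ts
    out = sps.decimate(ts.data, q, axis=-1, ftype="fir", zero_phase=True)
    return TimeSeries(data=out, fs=ts.fs / q, t0=ts.t0, channels=list(ts.channels))
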