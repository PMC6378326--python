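"""Event detection: fast ripples, multiunit spikes, IED association,
band-power onsets.

Fast ripples (FRs) are detected on the 200-550 Hz band-passed trace as
events with at least four oscillations (four negative plus four positive
peaks) whose amplitude exceeds three times the SD of the +-250 ms
surrounding baseline (the candidate's own samples are excluded from the
baseline so large events do not inflate it).  MUA spikes are detected on
the 300-6000 Hz band with the robust median-based threshold
``4 * median(|x|) / 0.6745``.  Both criteria are ratios to a baseline
scale, so detection is invariant to an overall scaling of the signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import TFMap, TimeSeries
from .signals import InvalidBandError, bandpass_filter

__all__ = [
    "FastRippleEvent",
    "MuaSpike",
    "EventCatalog",
    "detect_fast_ripples",
    "detect_mua_spikes",
    "mua_threshold",
    "classify_ied_association",
    "band_onset",
]


@dataclass(frozen=True)
class FastRippleEvent:
    onset: float          # s, first suprathreshold peak
    channel: str
    peak_freq_hz: float
    n_cycles: int
    amplitude_ratio: float  # peak amplitude / baseline SD

    def __post_init__(self):
        if self.n_cycles < 4:
            raise ValueError("a fast ripple has at least four cycles")
        if self.amplitude_ratio <= 3:
            raise ValueError("a fast ripple exceeds 3x the baseline SD")


@dataclass(frozen=True)
class MuaSpike:
    time: float   # s
    channel: str
    polarity: int  # sign of the extremum


@dataclass
class EventCatalog:
    """Flat table of detected events across channels and types."""

    events: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=[
                "onset_s", "region", "channel", "type",
                "n_cycles", "peak_freq_hz", "z20_30", "ied_associated",
            ]
        )
    )

    def add_fast_ripples(self, frs: list[FastRippleEvent], region: str) -> None:
        rows = [
            dict(
                onset_s=e.onset, region=region, channel=e.channel, type="fast_ripple",
                n_cycles=e.n_cycles, peak_freq_hz=e.peak_freq_hz,
                z20_30=np.nan, ied_associated=pd.NA,
            )
            for e in frs
        ]
        self._append(rows)

    def add_mua(self, spikes: list[MuaSpike], region: str) -> None:
        rows = [
            dict(
                onset_s=s.time, region=region, channel=s.channel, type="mua_spike",
                n_cycles=np.nan, peak_freq_hz=np.nan, z20_30=np.nan, ied_associated=pd.NA,
            )
            for s in spikes
        ]
        self._append(rows)

    def _append(self, rows: list[dict]) -> None:
        if not rows:
            return
        new = pd.DataFrame(rows)
        if self.events.empty:
            self.events = new
        else:
            self.events = pd.concat([self.events, new], ignore_index=True)

    def of_type(self, kind: str, region: str | None = None) -> pd.DataFrame:
        df = self.events[self.events["type"] == kind]
        if region is not None:
            df = df[df["region"] == region]
        return df.sort_values("onset_s").reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.events.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EventCatalog":
        return cls(events=pd.read_csv(path))


def _local_baseline_sd(x: np.ndarray, fs: float, a: int, b: int, pad_s: float = 0.25) -> float:
    """SD of the +-pad_s surrounding baseline, excluding samples [a, b)."""
    lo = max(int(a - pad_s * fs), 0)
    hi = min(int(b + pad_s * fs), x.size)
    seg = np.concatenate([x[lo:a], x[b:hi]])
    if seg.size < 8:
        return float(np.std(x))
    return float(np.std(seg))


def detect_fast_ripples(
    ts: TimeSeries,
    band: tuple = (200.0, 550.0),
    sd_factor: float = 3.0,
    min_cycles: int = 4,
    merge_gap_s: float = 0.010,
) -> list[FastRippleEvent]:
    """Fast-ripple events per channel.

    Pipeline per channel: order-2 zero-phase Butterworth band-pass; find
    candidate segments where |x| exceeds ``sd_factor`` times a robust
    global scale, merge segments closer than ``merge_gap_s``; re-test each
    candidate against the SD of its +-250 ms surrounding baseline
    (candidate excluded); count suprathreshold positive and negative peaks
    (sign changes of the derivative) and keep events with at least
    ``min_cycles`` of each.  Onset is the time of the first suprathreshold
    peak.
    """
    if ts.fs <= 2 * band[1]:
        raise InvalidBandError(f"FR band {band} needs fs > {2 * band[1]} Hz")
    filt = bandpass_filter(ts, band[0], band[1], order=2)
    out: list[FastRippleEvent] = []
    for k, ch in enumerate(ts.channels):
        x = filt.data[k]
        robust_sd = np.median(np.abs(x)) / 0.6745
        if robust_sd == 0:
            continue
        above = np.abs(x) > sd_factor * robust_sd
        if not above.any():
            continue
        # merge suprathreshold runs separated by < merge_gap
        idx = np.flatnonzero(above)
        gaps = np.diff(idx) > merge_gap_s * ts.fs
        starts = np.concatenate([[idx[0]], idx[1:][gaps]])
        ends = np.concatenate([idx[:-1][gaps], [idx[-1]]]) + 1
        for a, b in zip(starts, ends):
            sd = _local_baseline_sd(x, ts.fs, int(a), int(b))
            if sd == 0:
                continue
            thr = sd_factor * sd
            # widen to a small context so flanking peaks are countable
            lo = max(int(a - 0.002 * ts.fs), 0)
            hi = min(int(b + 0.002 * ts.fs), x.size)
            seg = x[lo:hi]
            d = np.diff(seg)
            peak_idx = np.flatnonzero((d[:-1] > 0) & (d[1:] <= 0)) + 1  # maxima
            trough_idx = np.flatnonzero((d[:-1] < 0) & (d[1:] >= 0)) + 1
            pos = peak_idx[seg[peak_idx] > thr]
            neg = trough_idx[seg[trough_idx] < -thr]
            if pos.size < min_cycles or neg.size < min_cycles:
                continue
            all_peaks = np.sort(np.concatenate([pos, neg]))
            # within the burst, successive suprathreshold extrema are at most
            # ~1.5 half-cycles of the band's low edge apart; split at larger
            # gaps and keep the dominant cluster so flanking noise excursions
            # cannot claim the onset
            trim_gap = int(np.ceil(0.75 * ts.fs / band[0]))
            splits = np.flatnonzero(np.diff(all_peaks) > trim_gap)
            clusters = np.split(all_peaks, splits + 1)
            all_peaks = max(clusters, key=len)
            pos = pos[(pos >= all_peaks[0]) & (pos <= all_peaks[-1])]
            neg = neg[(neg >= all_peaks[0]) & (neg <= all_peaks[-1])]
            if pos.size < min_cycles or neg.size < min_cycles:
                continue
            # an oscillation alternates sign: collapse consecutive
            # same-sign extrema (noise doubles) before counting cycles
            signs = np.where(np.isin(all_peaks, pos), 1, -1)
            keep = np.ones(all_peaks.size, dtype=bool)
            for q in range(1, all_peaks.size):
                if signs[q] == signs[q - 1]:
                    prev = q - 1
                    while prev >= 0 and not keep[prev]:
                        prev -= 1
                    if abs(seg[all_peaks[q]]) >= abs(seg[all_peaks[prev]]):
                        keep[prev] = False
                    else:
                        keep[q] = False
            kept = all_peaks[keep]
            kept_signs = signs[keep]
            n_pos = int((kept_signs > 0).sum())
            n_neg = int((kept_signs < 0).sum())
            if n_pos < min_cycles or n_neg < min_cycles:
                continue
            all_peaks = kept
            first = lo + all_peaks[0]
            n_cycles = int(min(n_pos, n_neg))
            span = (all_peaks[-1] - all_peaks[0]) / ts.fs
            peak_freq = (all_peaks.size - 1) / (2 * span) if span > 0 else np.nan
            ratio = float(np.max(np.abs(seg)) / sd)
            out.append(
                FastRippleEvent(
                    onset=ts.t0 + first / ts.fs,
                    channel=ch.id,
                    peak_freq_hz=float(peak_freq),
                    n_cycles=n_cycles,
                    amplitude_ratio=ratio,
                )
            )
    return sorted(out, key=lambda e: e.onset)


def mua_threshold(x: np.ndarray, factor: float = 4.0) -> float:
    """Robust spike threshold ``factor * median(|x|) / 0.6745``.

    0.6745 is the median of |N(0,1)|, so the threshold is ``factor``
    robust-SD units for Gaussian noise.
    """
    return factor * float(np.median(np.abs(x))) / 0.6745


def detect_mua_spikes(
    ts: TimeSeries,
    band: tuple = (300.0, 6000.0),
    dead_time_s: float = 0.001,
    allow_reduced_band: bool = True,
) -> tuple[list[MuaSpike], dict]:
    """Multiunit spikes from the wideband signal.

    The signal is band-passed (default 300-6000 Hz) and |x| threshold
    crossings beyond the dead time are reported, timed at the local
    extremum.  If the band does not fit under Nyquist and
    ``allow_reduced_band`` is set, the upper edge is reduced to
    ``0.45 * fs`` and the fallback is recorded in the returned metadata;
    otherwise an error names the feasible band.
    """
    meta = {"band": tuple(band), "reduced_band": False}
    if band[1] >= ts.fs / 2:
        fallback = (band[0], 0.45 * ts.fs)
        if not allow_reduced_band:
            raise InvalidBandError(
                f"MUA band {band} infeasible at fs={ts.fs}; feasible fallback {fallback}"
            )
        band = fallback
        meta.update(band=tuple(band), reduced_band=True)
    filt = bandpass_filter(ts, band[0], band[1], order=2)
    dead = max(int(round(dead_time_s * ts.fs)), 1)
    spikes: list[MuaSpike] = []
    for k, ch in enumerate(ts.channels):
        x = filt.data[k]
        thr = mua_threshold(x)
        above = np.abs(x) > thr
        idx = np.flatnonzero(above)
        if idx.size == 0:
            continue
        gaps = np.diff(idx) > dead
        starts = np.concatenate([[idx[0]], idx[1:][gaps]])
        ends = np.concatenate([idx[:-1][gaps], [idx[-1]]]) + 1
        last = -np.inf
        for a, b in zip(starts, ends):
            seg = np.abs(x[a:b])
            peak = a + int(np.argmax(seg))
            if peak - last < dead:
                continue
            last = peak
            spikes.append(
                MuaSpike(
                    time=ts.t0 + peak / ts.fs,
                    channel=ch.id,
                    polarity=int(np.sign(x[peak])),
                )
            )
    return sorted(spikes, key=lambda s: s.time), meta


def classify_ied_association(
    z_map: TFMap, band: tuple = (20.0, 30.0), z_threshold: float = 2.0
) -> tuple[bool, float]:
    """Is this event associated with an IED?

    True iff the maximal z-score within the IED band (20-30 Hz) over the
    period of interest exceeds ``z_threshold``.  Returns the flag and the
    maximal z in the band.
    """
    mask = z_map.band_rows(band[0], band[1])
    zmax = float(np.max(np.real(z_map.values[mask])))
    return zmax > z_threshold, zmax


def band_onset(
    z_epochs: list[TFMap],
    band: tuple,
    z_threshold: float = 5.0,
) -> float | None:
    """Onset of band activity from event-locked z-scored maps.

    For each time frame, the band-averaged z of each event is reduced to
    an across-event median; the onset is the earliest frame where that
    median exceeds ``z_threshold``.  Returns ``None`` when the threshold
    is never exceeded.
    """
    if not z_epochs:
        raise ValueError("need at least one epoch")
    mask = z_epochs[0].band_rows(band[0], band[1])
    times = z_epochs[0].times
    traces = np.stack([np.real(z.values[mask]).mean(axis=0) for z in z_epochs])
    med = np.median(traces, axis=0)
    above = np.flatnonzero(med > z_threshold)
    if above.size == 0:
        return None
    return float(times[above[0]])
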