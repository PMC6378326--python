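"""Baseline-normalized event-locked spectrograms.

The workflow: sample event-free baseline windows of the same duration as
the periods of interest, compute their Stockwell magnitude spectrograms,
form per-frequency-bin (and per-time-frame) mean and SD, then z-score
each event spectrogram against those statistics.  Averaged z maps carry a
significance contour at z > 5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import TFMap, TimeSeries
from .signals import extract_epochs, stockwell_transform

__all__ = [
    "BaselineStats",
    "sample_baseline_epochs",
    "baseline_stats_from_epochs",
    "zscore_spectrogram",
    "average_spectrogram",
]

SD_FLOOR = 1e-12  # avoids division blow-ups in empty bins


@dataclass
class BaselineStats:
    """Per-frequency-bin baseline mean and SD.

    ``mean``/``sd`` have shape (n_freqs, n_times) when time-resolved
    (default) or (n_freqs, 1) when time-collapsed.  ``n_epochs`` and the
    sampling rule string record provenance.
    """

    mean: np.ndarray
    sd: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    n_epochs: int
    rule: str = "uniform outside events, 1 s guard"

    def __post_init__(self):
        self.sd = np.maximum(np.asarray(self.sd, dtype=float), SD_FLOOR)


class InsufficientBaselineError(RuntimeError):
    pass


def sample_baseline_epochs(
    ts: TimeSeries,
    event_times,
    n: int,
    window: tuple,
    guard_s: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[TimeSeries], np.ndarray]:
    """``n`` event-free epochs of the same duration as ``window``.

    Start times are sampled uniformly over the parts of the recording
    where the whole epoch stays at least ``guard_s`` away from every
    event.  Seeded and reproducible.  Returns the epochs and their onset
    times.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    w_lo, w_hi = window
    span = w_hi - w_lo
    t_min = ts.t0 - w_lo
    t_max = ts.t0 + ts.duration - w_hi
    if t_max <= t_min:
        raise InsufficientBaselineError("recording shorter than one epoch")
    event_times = np.sort(np.asarray(list(event_times), dtype=float))
    # forbidden onset intervals: any onset whose epoch comes within guard of an event
    forbidden = [(t - guard_s - w_hi, t + guard_s - w_lo) for t in event_times]
    allowed = []
    cur = t_min
    for a, b in forbidden:
        if a > cur:
            allowed.append((cur, min(a, t_max)))
        cur = max(cur, b)
        if cur >= t_max:
            break
    if cur < t_max:
        allowed.append((cur, t_max))
    allowed = [(a, b) for a, b in allowed if b > a]
    total = sum(b - a for a, b in allowed)
    if total < span:
        raise InsufficientBaselineError(
            f"only {total:.2f} s of clean signal for {n} epochs of {span:.2f} s"
        )
    u = rng.uniform(0, total, n)
    onsets = np.empty(n)
    for i, ui in enumerate(u):
        for a, b in allowed:
            if ui < b - a:
                onsets[i] = a + ui
                break
            ui -= b - a
    epochs = extract_epochs(ts, onsets, window)
    if len(epochs) < n:
        raise InsufficientBaselineError("baseline epochs fell out of bounds")
    return epochs, onsets


def baseline_stats_from_epochs(
    epochs: list[TimeSeries],
    f_max: float,
    channel: int = 0,
    time_resolved: bool = True,
) -> BaselineStats:
    """Stockwell-magnitude baseline statistics from event-free epochs."""
    mags = []
    tf0 = None
    for ep in epochs:
        tf = stockwell_transform(ep, f_max, channel=channel)
        if tf0 is None:
            tf0 = tf
        mags.append(tf.magnitude)
    stack = np.stack(mags)
    if time_resolved:
        mean = stack.mean(axis=0)
        sd = stack.std(axis=0)
    else:
        mean = stack.mean(axis=(0, 2), keepdims=False)[:, None]
        sd = stack.std(axis=(0, 2))[:, None]
    return BaselineStats(
        mean=mean, sd=sd, freqs=tf0.freqs, times=tf0.times, n_epochs=len(epochs)
    )


def zscore_spectrogram(epoch_tf: TFMap, baseline: BaselineStats) -> TFMap:
    """Elementwise ``(|S| - mean) / SD`` against the baseline statistics."""
    if epoch_tf.freqs.shape != baseline.freqs.shape or not np.allclose(
        epoch_tf.freqs, baseline.freqs
    ):
        raise ValueError("frequency axes of epoch and baseline do not match")
    if baseline.mean.shape[1] not in (1, epoch_tf.times.size):
        raise ValueError("time axes of epoch and baseline do not match")
    z = (epoch_tf.magnitude - baseline.mean) / baseline.sd
    return TFMap(values=z, freqs=epoch_tf.freqs, times=epoch_tf.times, kind="zscore")


def average_spectrogram(
    z_maps: list[TFMap], z_threshold: float = 5.0
) -> tuple[TFMap, np.ndarray]:
    """Across-event average z map and the z > threshold contour mask."""
    if not z_maps:
        raise ValueError("need at least one z map")
    avg = np.mean([np.real(z.values) for z in z_maps], axis=0)
    tf = TFMap(values=avg, freqs=z_maps[0].freqs, times=z_maps[0].times, kind="zscore")
    return tf, avg > z_threshold
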