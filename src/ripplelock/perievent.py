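"""Spike-train analyses around fast ripples.

Peri-event time histograms (PSTH) of multiunit activity, laminar firing
ratios contrasting the down state (-180 to -30 ms before FR onset) with
the FR window (-30 to +20 ms), laminar chronology of MUA onsets
(10 ms Hanning-smoothed trains thresholded at 3 SD of the preceding
baseline within +-30 ms of FR onset), and event precedence across
regions (fraction of reference FRs preceded by an FR elsewhere within a
short or long window, versus a matched baseline window).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as ss

from .detect import EventCatalog

__all__ = [
    "Psth",
    "psth",
    "laminar_rate_ratio",
    "laminar_onset_chronology",
    "precedence_analysis",
]

DOWN_WINDOW = (-0.180, -0.030)
FR_WINDOW = (-0.030, 0.020)
PRECEDING_BASELINE = (-0.500, -0.200)


@dataclass
class Psth:
    edges: np.ndarray      # bin edges, s
    counts: np.ndarray     # spikes per bin pooled over events
    n_events: int
    bin_width: float

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def rate(self) -> np.ndarray:
        """Counts converted to a rate in Hz per event."""
        return self.counts / (self.n_events * self.bin_width)


def _relative_times(spikes: np.ndarray, onsets: np.ndarray, window) -> np.ndarray:
    spikes = np.asarray(spikes, dtype=float)
    rel = []
    for t in onsets:
        m = (spikes >= t + window[0]) & (spikes < t + window[1])
        rel.append(spikes[m] - t)
    return np.concatenate(rel) if rel else np.empty(0)


def psth(
    spikes, event_onsets, window: tuple = (-1.0, 1.0), bin_width: float = 0.010
) -> Psth:
    """Spike counts per bin pooled over events, aligned to event onset."""
    onsets = np.asarray(list(event_onsets), dtype=float)
    if onsets.size == 0:
        raise ValueError("no events")
    n_bins = (window[1] - window[0]) / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin_width must divide the window")
    edges = window[0] + np.arange(int(round(n_bins)) + 1) * bin_width
    rel = _relative_times(np.asarray(spikes, dtype=float), onsets, window)
    counts, _ = np.histogram(rel, bins=edges)
    return Psth(edges=edges, counts=counts, n_events=onsets.size, bin_width=bin_width)


def laminar_rate_ratio(
    spikes_per_channel: dict,
    onsets,
    depths: dict,
    down_window: tuple = DOWN_WINDOW,
    fr_window: tuple = FR_WINDOW,
    baseline_window: tuple = PRECEDING_BASELINE,
) -> pd.DataFrame:
    """Per-channel down-state and FR firing, normalized over the
    preceding baseline.

    Channels with zero baseline spikes are flagged (``valid=False``) and
    should be excluded from across-depth comparisons.
    """
    onsets = np.asarray(list(onsets), dtype=float)
    if onsets.size == 0:
        raise ValueError("no events")
    base_dur = baseline_window[1] - baseline_window[0]
    rows = []
    for cid, spikes in spikes_per_channel.items():
        spikes = np.asarray(spikes, dtype=float)
        n_base = _relative_times(spikes, onsets, baseline_window).size
        n_down = _relative_times(spikes, onsets, down_window).size
        n_fr = _relative_times(spikes, onsets, fr_window).size
        base_rate = n_base / (onsets.size * base_dur)
        valid = n_base > 0
        down_rate = n_down / (onsets.size * (down_window[1] - down_window[0]))
        fr_rate = n_fr / (onsets.size * (fr_window[1] - fr_window[0]))
        rows.append(
            dict(
                channel=cid,
                depth_um=depths[cid],
                down_ratio=down_rate / base_rate if valid else np.nan,
                fr_ratio=fr_rate / base_rate if valid else np.nan,
                baseline_rate=base_rate,
                valid=valid,
            )
        )
    return pd.DataFrame(rows).sort_values("depth_um", ascending=False).reset_index(drop=True)


def laminar_onset_chronology(
    spikes_per_channel: dict,
    onsets,
    depths: dict,
    fs: float = 1000.0,
    search_window: tuple = (-0.030, 0.030),
    baseline_window: tuple = PRECEDING_BASELINE,
    hann_s: float = 0.010,
    sd_factor: float = 3.0,
) -> pd.DataFrame:
    """Per-channel MUA onset around FR onset, ranked across depth.

    For each channel the binary spike train (pooled over events, sampled
    at ``fs``) is convolved with a unit-area ``hann_s`` Hanning window
    (making the trace a local rate estimate); the onset is the first
    time inside ``search_window`` where it exceeds ``sd_factor`` times
    the SD of the preceding-baseline segment.  Channels that never cross
    get a null onset and are excluded from the ranking; ties share a
    rank.
    """
    onsets = np.asarray(list(onsets), dtype=float)
    if onsets.size == 0:
        raise ValueError("no events")
    t_lo, t_hi = baseline_window[0], search_window[1] + 0.01
    n = int(round((t_hi - t_lo) * fs))
    edges = t_lo + np.arange(n + 1) / fs
    win = sps.windows.hann(max(int(round(hann_s * fs)), 3))
    win = win / (win.sum() / fs)  # unit area in time -> rate estimate
    rows = []
    for cid, spikes in spikes_per_channel.items():
        rel = _relative_times(np.asarray(spikes, dtype=float), onsets, (t_lo, t_hi))
        train, _ = np.histogram(rel, bins=edges)
        smooth = np.convolve(train.astype(float), win, mode="same")
        tt = edges[:-1] + 0.5 / fs
        base = smooth[(tt >= baseline_window[0]) & (tt < baseline_window[1])]
        sd = base.std()
        mean = base.mean()
        search = (tt >= search_window[0]) & (tt < search_window[1])
        if sd == 0:
            onset = np.nan
        else:
            crossing = np.flatnonzero(search & (smooth > mean + sd_factor * sd))
            onset = float(tt[crossing[0]]) if crossing.size else np.nan
        rows.append(dict(channel=cid, depth_um=depths[cid], onset_s=onset))
    df = pd.DataFrame(rows)
    df["rank"] = df["onset_s"].rank(method="min")
    return df.sort_values(["onset_s", "depth_um"], na_position="last").reset_index(drop=True)


def precedence_analysis(
    catalog: EventCatalog,
    reference_region: str = "FC",
    other_regions=("LH", "RH"),
    short: float = 0.010,
    long: float = 0.500,
    baseline_window: tuple = (-1.0, -0.5),
) -> pd.DataFrame:
    """Fractions of reference-region FRs preceded by an FR elsewhere.

    For each other region and each window (short, long, and the matched
    baseline window): the fraction of reference events with at least one
    event of that region inside the window before the reference onset.
    The long window is compared with the baseline window by a Wilcoxon
    signed-rank test on the per-event indicators (contract wrapper).
    """
    ref = catalog.of_type("fast_ripple", reference_region)["onset_s"].to_numpy()
    if ref.size == 0:
        raise ValueError(f"no reference events in region {reference_region!r}")
    rows = []
    for region in other_regions:
        other = catalog.of_type("fast_ripple", region)["onset_s"].to_numpy()

        def preceded(window_lo, window_hi):
            return np.array(
                [np.any((other >= t + window_lo) & (other < t + window_hi)) for t in ref]
            )

        ind_short = preceded(-short, 0.0)
        ind_long = preceded(-long, 0.0)
        ind_base = preceded(baseline_window[0], baseline_window[1])
        diff = ind_long.astype(int) - ind_base.astype(int)
        if np.all(diff == 0):
            p = 1.0
        else:
            p = float(ss.wilcoxon(diff, zero_method="wilcox").pvalue)
        rows.append(
            dict(
                region=region,
                frac_short=float(ind_short.mean()),
                frac_long=float(ind_long.mean()),
                frac_baseline=float(ind_base.mean()),
                p_long_vs_baseline=p,
                n_reference=ref.size,
            )
        )
    return pd.DataFrame(rows)
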