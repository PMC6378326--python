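"""Core data containers shared across the analysis pipeline.

The pipeline operates on three kinds of objects: multichannel continuous
recordings (:class:`TimeSeries`), band-limited analytic signals carrying an
instantaneous phase and envelope (:class:`AnalyticSignal`), and
time-frequency maps (:class:`TFMap`).  Everything downstream — event
detection, z-scored spectrograms, phase statistics, coupling and
connectivity — is expressed in terms of these.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

REGIONS = ("FC", "LH", "RH", "other")


@dataclass(frozen=True)
class Channel:
    """Metadata for one recording channel.

    Parameters
    ----------
    id : str
        Unique channel identifier.
    region : str
        Anatomical region: ``FC`` (frontal cortex), ``LH`` / ``RH``
        (left / right hippocampus) or ``other``.
    depth_um : float
        Contact depth along the linear probe, micrometres (more negative =
        deeper is a convention of the caller; only monotone order matters).
    montage : str
        ``monopolar`` or ``bipolar``.
    kind : str
        ``lfp`` (field-potential stream) or ``wideband`` (spike stream).
    sources : tuple
        For bipolar channels, the ordered pair of source contact ids.
    """

    id: str
    region: str = "other"
    depth_um: float = 0.0
    montage: str = "monopolar"
    kind: str = "lfp"
    sources: tuple = ()

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}; expected one of {REGIONS}")
        if self.montage not in ("monopolar", "bipolar"):
            raise ValueError(f"unknown montage {self.montage!r}")
        if self.kind not in ("lfp", "wideband"):
            raise ValueError(f"unknown channel kind {self.kind!r}")


@dataclass
class TimeSeries:
    """Multichannel continuous signal.

    ``data`` is channel-major, shape ``(n_channels, n_samples)``, in
    microvolts.  ``fs`` is the sampling rate in Hz and ``t0`` the time of
    the first sample in seconds.
    """

    data: np.ndarray
    fs: float
    t0: float = 0.0
    channels: Sequence[Channel] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.channels and len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel entries for {self.data.shape[0]} rows"
            )
        if not self.channels:
            self.channels = [Channel(id=f"ch{i}") for i in range(self.data.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def index_of(self, t: float) -> int:
        """Index of the nearest sample at or before time ``t`` (seconds)."""
        return int(np.floor((t - self.t0) * self.fs + 1e-9))

    def channel(self, cid: str) -> np.ndarray:
        for i, ch in enumerate(self.channels):
            if ch.id == cid:
                return self.data[i]
        raise KeyError(cid)

    def select(self, idx) -> "TimeSeries":
        """Subset of channels by integer indices, preserving metadata."""
        idx = np.atleast_1d(idx)
        return TimeSeries(
            data=self.data[idx],
            fs=self.fs,
            t0=self.t0,
            channels=[self.channels[i] for i in idx],
        )

    def by_region(self, region: str) -> "TimeSeries":
        idx = [i for i, ch in enumerate(self.channels) if ch.region == region]
        if not idx:
            raise KeyError(f"no channels in region {region!r}")
        return self.select(idx)

    def copy_with(self, **kw) -> "TimeSeries":
        out = replace(self)
        for k, v in kw.items():
            setattr(out, k, v)
        return out


@dataclass
class AnalyticSignal:
    """Instantaneous phase and envelope of a band-limited signal.

    Phase is in radians in (-pi, pi] with the convention that phase 0
    falls at local maxima of the band-limited signal (Hilbert convention
    for a cosine).  ``amplitude`` is the non-negative envelope.
    """

    phase: np.ndarray
    amplitude: np.ndarray
    band: tuple
    fs: float
    t0: float = 0.0

    def __post_init__(self):
        self.phase = np.asarray(self.phase, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.phase.shape != self.amplitude.shape:
            raise ValueError("phase and amplitude must have the same shape")

    @property
    def n_samples(self) -> int:
        return self.phase.shape[-1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def phase_at(self, t) -> np.ndarray:
        """Phase sampled at times ``t`` (nearest sample at or before)."""
        idx = np.floor((np.asarray(t, dtype=float) - self.t0) * self.fs + 1e-9).astype(int)
        if np.any(idx < 0) or np.any(idx >= self.n_samples):
            raise IndexError("requested times outside phase coverage")
        return self.phase[..., idx]


@dataclass
class TFMap:
    """Time-frequency matrix with explicit axes.

    ``values`` has shape ``(n_freqs, n_times)`` and may be complex
    (transform coefficients) or real (magnitude or z-score).  ``kind``
    records the provenance: ``stockwell``, ``morlet`` or ``zscore``.
    """

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    kind: str = "stockwell"

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape != (self.freqs.size, self.times.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match axes "
                f"({self.freqs.size}, {self.times.size})"
            )
        if self.freqs.size > 1 and np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency axis must be strictly increasing")

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)

    def band_rows(self, f_lo: float, f_hi: float) -> np.ndarray:
        """Boolean mask of frequency rows with f_lo <= f <= f_hi."""
        mask = (self.freqs >= f_lo) & (self.freqs <= f_hi)
        if not mask.any():
            raise ValueError(f"no frequency rows cover [{f_lo}, {f_hi}] Hz")
        return mask
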