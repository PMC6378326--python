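"""Synthetic multichannel recording generator with ground truth.

Emulates the structure of awake intracerebral recordings from a unilateral
hippocampal-epilepsy model: three regions (left hippocampus LH, right
hippocampus RH, frontal cortex FC), each sampled by a multi-contact linear
probe, with

* 1/f-like Gaussian background (per-channel independent plus a common mode),
* transient ~800 ms epileptic complexes containing a 3-5 Hz slow
  oscillation, a 20-30 Hz interictal-discharge (IED) burst whose amplitude
  is coupled to the slow-oscillation phase, and one fast-ripple (FR) burst
  locked to a preferred slow-oscillation phase,
* von Mises phase-locked multiunit (MUA) spiking, more concentrated during
  complexes than at baseline,
* inter-regional slow-oscillation lags (both hippocampi leading frontal
  cortex by tens of ms) and a causal stochastic drive from the hippocampi
  into the frontal cortex in the slow band.

Every draw is determined by ``SynthConfig.seed``; the full ground truth
(event times, spike times, lags, coupling frequencies) is returned so
detector and estimator recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy import signal as sps
from scipy.special import i0

from .core import Channel, TimeSeries
from .signals import decimate_timeseries

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_background",
    "generate_complex",
    "generate_spike_train",
    "generate_recording",
]


@dataclass
class SynthConfig:
    """Generator parameters.

    Defaults reproduce the study conditions: 16 kHz acquisition, slow
    oscillation in the 3-5 Hz band, phase-amplitude coupling peaking at
    4.5 Hz (phase) x 27 Hz (amplitude), fast ripples in 200-550 Hz,
    MUA von Mises locking kappa 1.08 during events vs 0.32 at baseline
    (means 0.56 vs 0.18 rad), and the hippocampi leading the frontal
    cortex by 64 ms (LH) and 52 ms (RH).
    """

    fs: float = 16000.0           # Hz
    duration: float = 60.0        # s
    n_complexes: int = 20
    slow_freq: float = 4.0        # Hz, baseline slow-phase oscillator
    complex_duration: float = 0.8  # s
    pac_phase_freq: float = 4.5   # Hz, slow oscillation of the complex
    pac_amp_freq: float = 27.0    # Hz, IED burst carrier
    pac_depth: float = 0.8        # 0..1 modulation depth
    pac_phase_pref: float = 0.0   # rad, IED envelope peak phase
    fr_band: tuple = (200.0, 550.0)
    fr_freq: float = 450.0        # Hz, FR carrier
    fr_cycles: int = 8
    fr_snr: float = 5.0           # FR amplitude / background SD
    fr_phase: float = 1.57        # rad, slow phase at FR onset
    mua_rate: float = 20.0        # Hz mean MUA rate per channel
    mua_snr: float = 8.0          # spike amplitude / background SD
    slow_bg_snr: float = 0.5      # ongoing slow-oscillation amplitude / bg SD
    slow_bg_jitter: float = 0.4   # Hz, SD of the slow oscillator's frequency drift
    kappa_event: float = 1.08
    kappa_baseline: float = 0.32
    mu_event: float = 0.56        # rad
    mu_baseline: float = 0.18     # rad
    lag_LH_FC: float = 0.064      # s, LH leads FC
    lag_RH_FC: float = 0.052      # s, RH leads FC
    drive_gain: float = 1.0       # hippocampus->cortex slow-band drive
    bg_sd: float = 1.0            # background SD, uV
    bg_alpha: float = 1.0         # 1/f^alpha exponent
    common_gain: float = 0.2      # common-mode mixing weight, 0..1
    slow_snr: float = 3.0         # slow-oscillation amplitude / bg SD
    ied_snr: float = 2.5          # IED burst amplitude / bg SD
    n_contacts: int = 16          # contacts per probe
    contact_spacing_um: float = 50.0
    laminar_lead_s: float = 0.005  # deep-layer MUA onset lead
    laminar_down_factor: float = 0.8  # deep-layer down-state suppression
    fr_mua_boost: float = 4.0     # MUA rate multiplier around FR onset
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        nyq = self.fs / 2
        for f in (self.slow_freq, self.pac_phase_freq, self.pac_amp_freq,
                  self.fr_freq, self.fr_band[0], self.fr_band[1]):
            if not 0 < f < nyq:
                raise ValueError(f"frequency {f} Hz outside (0, {nyq}) Hz")
        if not self.fr_band[0] <= self.fr_freq <= self.fr_band[1]:
            raise ValueError("fr_freq must lie inside fr_band")
        if min(self.kappa_event, self.kappa_baseline) < 0:
            raise ValueError("kappa must be >= 0")
        if min(self.lag_LH_FC, self.lag_RH_FC) < 0:
            raise ValueError("lags must be >= 0")
        if not 0 <= self.pac_depth <= 1:
            raise ValueError("pac_depth must lie in [0, 1]")
        if self.complex_duration < 2.0 / self.pac_phase_freq:
            raise ValueError("complex must span >= 2 slow-oscillation cycles")
        if self.duration * self.fs > 2**31:
            raise ValueError("duration * fs overflows the sample budget")
        if self.fr_cycles < 4:
            raise ValueError("fr_cycles must be >= 4 (detector definition)")

    @classmethod
    def desk(cls, **overrides) -> "SynthConfig":
        """Reduced profile for fast runs: 4 kHz (keeps the 200-550 Hz FR
        band under Nyquist), 60 s, 30 complexes, 4 contacts per probe."""
        kw = dict(fs=4000.0, duration=60.0, n_complexes=30, n_contacts=4)
        kw.update(overrides)
        return cls(**kw)

    def replace(self, **kw) -> "SynthConfig":
        return replace(self, **kw)


@dataclass
class GroundTruth:
    """Everything the generator injected, for recovery scoring."""

    fr_onsets: dict = field(default_factory=dict)       # region -> array of s
    ied_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    complex_windows: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    spike_times: dict = field(default_factory=dict)     # channel id -> array of s
    lags: dict = field(default_factory=dict)            # (a, b) -> s, a leads b
    coupling_freqs: tuple = (4.5, 27.0)                 # (f_phase, f_amp) Hz
    duration: float = 0.0

    def validate(self) -> None:
        for region, t in self.fr_onsets.items():
            t = np.asarray(t)
            if t.size and (t.min() < 0 or t.max() > self.duration):
                raise ValueError(f"{region} FR onsets outside [0, duration]")
            for ti in t:
                inside = np.any(
                    (self.complex_windows[:, 0] - 1e-9 <= ti)
                    & (ti <= self.complex_windows[:, 1] + 1e-9)
                )
                if not inside:
                    raise ValueError(f"FR onset {ti} not inside any complex window")


def _one_over_f(rng: np.random.Generator, n: int, alpha: float) -> np.ndarray:
    """Unit-SD Gaussian noise with power spectrum ~ 1/f^alpha."""
    w = rng.standard_normal(n)
    if alpha == 0:
        return w
    W = np.fft.rfft(w)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    W *= f ** (-alpha / 2.0)
    x = np.fft.irfft(W, n)
    return x / x.std()


def generate_background(
    cfg: SynthConfig, n_channels: int, rng: np.random.Generator | None = None,
    n_samples: int | None = None,
) -> TimeSeries:
    """1/f^alpha Gaussian background: independent per channel plus a shared
    common-mode trace, mixed so each channel has SD ``cfg.bg_sd``."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.fs)) if n_samples is None else n_samples
    common = _one_over_f(rng, n, cfg.bg_alpha)
    c = cfg.common_gain
    data = np.empty((n_channels, n))
    for i in range(n_channels):
        indep = _one_over_f(rng, n, cfg.bg_alpha)
        data[i] = cfg.bg_sd * (np.sqrt(1.0 - c**2) * indep + c * common)
    return TimeSeries(data=data, fs=cfg.fs)


def generate_complex(
    cfg: SynthConfig, rng: np.random.Generator | None = None,
    ied_phase: float | None = None,
) -> tuple[TimeSeries, dict]:
    """One epileptic complex: slow oscillation + phase-coupled IED burst +
    one phase-locked FR burst, on a single channel.

    The slow oscillation runs at ``cfg.pac_phase_freq`` (the coupling phase
    frequency, inside the 3-5 Hz band) under a Hann envelope; the IED
    carrier at ``cfg.pac_amp_freq`` is amplitude-modulated by
    ``(1 + pac_depth * cos(phi_slow - pac_phase_pref)) / 2``; the FR burst
    (``fr_cycles`` cycles at ``fr_freq``, amplitude ``fr_snr * bg_sd``,
    Tukey(0.5) envelope) starts at slow phase ``fr_phase``.

    Returns the fragment and a truth dict with times relative to the
    fragment start.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    fs, T = cfg.fs, cfg.complex_duration
    n = int(round(T * fs))
    t = np.arange(n) / fs
    f_p = cfg.pac_phase_freq
    phi = 2.0 * np.pi * f_p * (t - T / 2.0)  # phase 0 (cosine peak) at centre
    hann = sps.windows.hann(n)

    slow = cfg.slow_snr * cfg.bg_sd * hann * np.cos(phi)

    env = (1.0 + cfg.pac_depth * np.cos(phi - cfg.pac_phase_pref)) / 2.0
    psi = rng.uniform(0, 2 * np.pi) if ied_phase is None else ied_phase
    ied = cfg.ied_snr * cfg.bg_sd * hann * env * np.cos(2 * np.pi * cfg.pac_amp_freq * t + psi)

    # FR onset: slow phase == fr_phase, occurrence nearest the complex centre
    k_candidates = np.arange(-3, 4)
    t_candidates = (cfg.fr_phase + 2 * np.pi * k_candidates) / (2 * np.pi * f_p) + T / 2.0
    t_candidates = t_candidates[(t_candidates > 0.05 * T) & (t_candidates < 0.85 * T)]
    t_on = float(t_candidates[np.argmin(np.abs(t_candidates - T / 2.0))])
    fr_dur = cfg.fr_cycles / cfg.fr_freq
    i_on = int(round(t_on * fs))
    n_fr = int(round(fr_dur * fs))
    fr = np.zeros(n)
    tb = np.arange(n_fr) / fs
    burst = cfg.fr_snr * cfg.bg_sd * sps.windows.tukey(n_fr, alpha=0.25) * np.cos(
        2 * np.pi * cfg.fr_freq * tb
    )
    fr[i_on : i_on + n_fr] = burst[: n - i_on]

    ts = TimeSeries(data=slow + ied + fr, fs=fs)
    truth = {
        "fr_onset": t_on,
        "ied_time": T / 2.0,
        "phase_freq": f_p,
        "amp_freq": cfg.pac_amp_freq,
    }
    return ts, truth


def generate_spike_train(
    cfg: SynthConfig,
    phase: np.ndarray,
    state: str = "event",
    fs: float | None = None,
    rng: np.random.Generator | None = None,
    rate_scale: np.ndarray | None = None,
) -> np.ndarray:
    """Inhomogeneous Poisson spike times phase-locked to ``phase``.

    Intensity is the von Mises modulation
    ``lambda(t) = rate * exp(kappa * cos(phi(t) - mu)) / I0(kappa)``,
    normalized so the mean rate over a full cycle equals ``cfg.mua_rate``.
    ``state`` selects the (kappa, mu) pair: ``event`` or ``baseline``.
    ``rate_scale`` optionally multiplies the intensity samplewise (laminar
    modulation).  Sampling is by thinning; deterministic given ``rng``.
    """
    if cfg.mua_rate <= 0:
        raise ValueError("mua_rate must be positive")
    if state not in ("event", "baseline"):
        raise ValueError("state must be 'event' or 'baseline'")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if fs is None:
        fs = cfg.fs
    kappa = cfg.kappa_event if state == "event" else cfg.kappa_baseline
    mu = cfg.mu_event if state == "event" else cfg.mu_baseline
    phase = np.asarray(phase, dtype=float)
    dur = phase.size / fs
    lam = cfg.mua_rate * np.exp(kappa * np.cos(phase - mu)) / i0(kappa)
    if rate_scale is not None:
        lam = lam * rate_scale
    lam_max = float(lam.max())
    if lam_max <= 0:
        return np.empty(0)
    n_cand = rng.poisson(lam_max * dur)
    t_cand = np.sort(rng.uniform(0, dur, n_cand))
    idx = np.minimum((t_cand * fs).astype(int), phase.size - 1)
    keep = rng.uniform(0, lam_max, n_cand) < lam[idx]
    return t_cand[keep]


def _resonator_ba(f0: float, fs: float, r: float = 0.97):
    """Causal AR(2) resonator with poles at +-f0 (stochastic drive path)."""
    theta = 2 * np.pi * f0 / fs
    a = [1.0, -2 * r * np.cos(theta), r**2]
    return [1.0 - r], a


def generate_recording(cfg: SynthConfig) -> tuple[TimeSeries, GroundTruth]:
    """Full three-region synthetic recording with ground truth.

    Each complex appears first in LH, then RH, then FC, with FC delayed by
    ``lag_LH_FC`` (``lag_RH_FC``) relative to LH (RH).  A causal slow-band
    stochastic drive from each hippocampal common mode is injected into
    the FC channels with gain ``drive_gain``.  MUA spikes, phase-locked to
    the slow oscillation (event vs baseline concentration), are injected
    into the FC channels.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs
    n = int(round(cfg.duration * fs))

    regions = ("LH", "RH", "FC")
    channels: list[Channel] = []
    for region in regions:
        for i in range(cfg.n_contacts):
            channels.append(
                Channel(
                    id=f"{region}{i}",
                    region=region,
                    depth_um=-(100.0 + i * cfg.contact_spacing_um),
                )
            )
    # dedicated wideband (spike) stream for the frontal cortex probe
    for i in range(cfg.n_contacts):
        channels.append(
            Channel(
                id=f"FCw{i}",
                region="FC",
                depth_um=-(100.0 + i * cfg.contact_spacing_um),
                kind="wideband",
            )
        )
    n_ch = len(channels)

    # laminar gain profile: LFP components scale from +1 (superficial) to
    # -0.5 (deep), emulating the depth-dependent polarity of laminar field
    # potentials; without it every field component would cancel exactly in
    # the bipolar montage
    def contact_gain(ch: Channel) -> float:
        i = int(ch.id.lstrip("FCLRHw"))
        depth_norm = i / max(cfg.n_contacts - 1, 1)
        return 1.0 - 1.5 * depth_norm

    # --- background: per-region common mode so the hippocampal noise can
    # be causally fed into FC (directed drive) -----------------------------
    c = cfg.common_gain
    commons = {r: _one_over_f(rng, n, cfg.bg_alpha) for r in regions}
    data = np.empty((n_ch, n))
    for k, ch in enumerate(channels):
        indep = _one_over_f(rng, n, cfg.bg_alpha)
        data[k] = cfg.bg_sd * (np.sqrt(1 - c**2) * indep + c * commons[ch.region])

    # --- ongoing slow-oscillation background, one independently drifting
    # oscillator per region (keeps baseline MUA phase-locking measurable in
    # the LFP while regions stay incoherent outside complexes) -------------
    eval_fs = min(1000.0, fs)
    n_eval = int(round(cfg.duration * eval_fs))
    te = np.arange(n_eval) / eval_fs
    t_full = np.arange(n) / fs
    region_phase = {}
    for region in regions:
        freq_noise = _one_over_f(rng, n_eval, 0.0)
        sos = sps.butter(2, 0.3, btype="lowpass", fs=eval_fs, output="sos")
        drift = sps.sosfiltfilt(sos, freq_noise)
        drift = drift / max(drift.std(), 1e-12) * cfg.slow_bg_jitter
        inst_freq = cfg.slow_freq + drift
        phase_unwrapped = 2 * np.pi * np.cumsum(inst_freq) / eval_fs
        region_phase[region] = phase_unwrapped
        slow_bg = cfg.slow_bg_snr * cfg.bg_sd * np.cos(
            np.interp(t_full, te, phase_unwrapped)
        )
        for k, ch in enumerate(channels):
            if ch.region == region and ch.kind == "lfp":
                data[k] += contact_gain(ch) * slow_bg


    # --- complex schedule -------------------------------------------------
    margin = 1.0 + cfg.lag_LH_FC + cfg.complex_duration
    usable = cfg.duration - 2 * margin
    spacing = usable / max(cfg.n_complexes, 1)
    if spacing < cfg.complex_duration + 0.4:
        raise ValueError(
            f"{cfg.n_complexes} complexes of {cfg.complex_duration} s do not "
            f"fit in {cfg.duration} s with safe spacing"
        )
    jitter = rng.uniform(0, 0.3 * (spacing - cfg.complex_duration), cfg.n_complexes)
    t_lh = margin + np.arange(cfg.n_complexes) * spacing + jitter

    region_offsets = {
        "LH": 0.0,
        "RH": cfg.lag_LH_FC - cfg.lag_RH_FC,
        "FC": cfg.lag_LH_FC,
    }
    fr_onsets = {r: [] for r in regions}
    ied_times = []
    windows = []
    for t0 in t_lh:
        truth = None
        for region in regions:
            # fresh fragment per region: slow and FR components are
            # deterministic (shared waveform, shifted by the lag), the IED
            # carrier phase is region-specific so only the slow oscillation
            # is coherent across regions
            frag, truth = generate_complex(cfg, rng)
            start = t0 + region_offsets[region]
            i0_ = int(round(start * fs))
            seg = frag.data[0][: n - i0_]
            for k, ch in enumerate(channels):
                if ch.region == region and ch.kind == "lfp":
                    data[k, i0_ : i0_ + seg.size] += contact_gain(ch) * seg
            fr_onsets[region].append(start + truth["fr_onset"])
        ied_times.append(t0 + region_offsets["FC"] + truth["ied_time"])
        windows.append((t0, t0 + region_offsets["FC"] + cfg.complex_duration))

    # --- hippocampus -> cortex stochastic drive ---------------------------
    # a causal slow-band filtered copy of each hippocampal common mode is
    # injected into the FC channels with the inter-regional lag; the drive
    # envelope is weak at baseline and ramps up around each complex, as the
    # directed hippocampal influence does around the events
    if cfg.drive_gain > 0:
        drive_env = np.full(n, 0.25)
        half_w = int(round(0.5 * cfg.complex_duration * fs))
        for a, b_ in windows:
            i, j = int(a * fs) - half_w, int(b_ * fs) + half_w
            drive_env[max(i, 0) : min(j, n)] = 1.0
        smooth = sps.windows.hann(max(int(0.2 * fs), 3))
        drive_env = sps.fftconvolve(drive_env, smooth / smooth.sum(), mode="same")
        for src, lag in (("LH", cfg.lag_LH_FC), ("RH", cfg.lag_RH_FC)):
            b, a = _resonator_ba(cfg.pac_phase_freq, fs)
            drive = sps.lfilter(b, a, commons[src])
            drive = drive / max(drive.std(), 1e-12) * cfg.bg_sd
            shift = int(round(lag * fs))
            delayed = np.zeros(n)
            delayed[shift:] = drive[: n - shift]
            delayed *= drive_env
            for k, ch in enumerate(channels):
                if ch.region == "FC" and ch.kind == "lfp":
                    data[k] += cfg.drive_gain * contact_gain(ch) * delayed

    # --- MUA spikes in FC -------------------------------------------------
    # slow-phase trajectory: the FC background oscillator, overridden by
    # the complex oscillation (pac_phase_freq, phase 0 at complex centre)
    # inside each FC complex window.
    phase = region_phase["FC"].copy()
    in_event = np.zeros(n_eval, dtype=bool)
    for t0 in t_lh:
        a = t0 + region_offsets["FC"]
        b = a + cfg.complex_duration
        m = (te >= a) & (te < b)
        centre = a + cfg.complex_duration / 2.0
        phase[m] = 2 * np.pi * cfg.pac_phase_freq * (te[m] - centre)
        in_event[m] = True
    phase = np.angle(np.exp(1j * phase))

    spike_times: dict[str, np.ndarray] = {}
    fc_fr = np.asarray(fr_onsets["FC"])
    fc_channels = [ch for ch in channels if ch.region == "FC" and ch.kind == "wideband"]
    n_fc = len(fc_channels)
    spike_wave = _spike_waveform(fs)
    for j, ch in enumerate(fc_channels):
        depth_norm = j / max(n_fc - 1, 1)  # 0 = superficial, 1 = deep
        scale = np.ones(n_eval)
        for t_fr in fc_fr:
            down = (te >= t_fr - 0.180) & (te < t_fr - 0.030)
            scale[down] *= 1.0 - cfg.laminar_down_factor * depth_norm
            lead = cfg.laminar_lead_s * depth_norm
            boost = (te >= t_fr - lead) & (te < t_fr + 0.020)
            scale[boost] *= cfg.fr_mua_boost
        ev = generate_spike_train(
            cfg, np.where(in_event, phase, 0.0), "event", fs=eval_fs, rng=rng,
            rate_scale=scale * in_event,
        )
        ba = generate_spike_train(
            cfg, np.where(in_event, 0.0, phase), "baseline", fs=eval_fs, rng=rng,
            rate_scale=scale * (~in_event),
        )
        times = np.sort(np.concatenate([ev, ba]))
        spike_times[ch.id] = times
        k = channels.index(ch)
        for t_sp in times:
            i_sp = int(round(t_sp * fs))
            seg = spike_wave[: n - i_sp]
            if seg.size:
                data[k, i_sp : i_sp + seg.size] += cfg.mua_snr * cfg.bg_sd * seg

    ts = TimeSeries(data=data, fs=fs, channels=channels)
    truth = GroundTruth(
        fr_onsets={r: np.asarray(v) for r, v in fr_onsets.items()},
        ied_times=np.asarray(ied_times),
        complex_windows=np.asarray(windows),
        spike_times=spike_times,
        lags={("LH", "FC"): cfg.lag_LH_FC, ("RH", "FC"): cfg.lag_RH_FC},
        coupling_freqs=(cfg.pac_phase_freq, cfg.pac_amp_freq),
        duration=cfg.duration,
    )
    truth.validate()
    return ts, truth


def _spike_waveform(fs: float) -> np.ndarray:
    """Biphasic ~1 ms extracellular spike shape, peak-normalized."""
    n = max(int(round(1e-3 * fs)), 3)
    t = np.linspace(0, 1, n)
    w = -np.sin(2 * np.pi * t) * sps.windows.hann(n)
    return w / np.abs(w).max()


def desk_recording(seed: int = 0, **overrides):
    """Convenience: desk-profile recording + truth for a given seed."""
    cfg = SynthConfig.desk(seed=seed, **overrides)
    return generate_recording(cfg)
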