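"""Directed and lagged inter-regional relationships.

A time-varying autoregressive (TVAR) model of the multichannel signal is
estimated sample-by-sample with a Kalman filter (random-walk coefficient
dynamics, adaptation rate ``c``).  The lag-domain coefficients are taken
to the spectral domain, A(f, t) = I - sum_m a_m(t) exp(-i 2 pi f m / fs),
and the adaptive partial directed coherence from source j to sink i is

    APDC_ij(f, t)^2 = |A_ij(f, t)|^2 / sum_k |A_ik(f, t)|^2 .

The denominator sums over the entries of row i (sink normalization, as
the method's printed formula does); the standard PDC source/column
normalization is available behind ``normalization='column'``.  The
band-integrated iAPDC_ij(t) is the mean of the normalized (squared)
quantity over the discrete frequency grid within [f1, f2].

Cross-correlation lags between band-limited signals follow the sign
convention that a negative lag means the second signal is delayed
relative to the first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as ss

from .core import TimeSeries
from .signals import bandpass_filter

__all__ = [
    "TvarModel",
    "DirectedConnectivityResult",
    "fit_tvar_kalman",
    "apdc_spectrum",
    "iapdc_band",
    "bandlimited_crosscorr_lag",
    "directed_comparison",
]


@dataclass
class TvarModel:
    """Time-varying AR coefficients a[t, m, i, j]: lag-(m+1) influence of
    channel j on channel i at sample t."""

    coeffs: np.ndarray        # (T, p, K, K)
    fs: float
    order: int
    rate: float               # adaptation (update) coefficient
    innovation_var: np.ndarray  # (T, K)
    stable: np.ndarray        # (T,) spectral radius of companion form <= 1 + tol
    flagged: bool = False     # ridge regularization engaged

    @property
    def K(self) -> int:
        return self.coeffs.shape[2]

    @property
    def n_samples(self) -> int:
        return self.coeffs.shape[0]

    def time_averaged(self, burn_frac: float = 0.1) -> np.ndarray:
        """Mean coefficients after discarding the initial transient."""
        burn = int(self.n_samples * burn_frac)
        return self.coeffs[burn:].mean(axis=0)


def fit_tvar_kalman(
    signals: TimeSeries, order: int = 5, rate: float = 0.02
) -> TvarModel:
    """Kalman-filtered TVAR fit.

    State = stacked AR coefficients per sink channel, random-walk state
    noise ``rate * I``; observation = the current sample regressed on the
    ``order`` past samples of all channels.  The regressor is shared
    across sinks, so one covariance recursion serves all of them.
    Deterministic given the input.
    """
    X = np.asarray(signals.data, dtype=float)
    K, T = X.shape
    p = order
    if K < 2:
        raise ValueError("need at least two channels")
    if T <= 10 * p:
        raise ValueError("signal too short for the requested order")
    d = K * p
    # normalize scale for conditioning; coefficients are scale-invariant
    scale = X.std(axis=1, keepdims=True)
    scale[scale == 0] = 1.0
    Xn = X / scale

    A = np.zeros((d, K))            # per-sink coefficient vectors
    P = np.eye(d)
    r_obs = np.ones(K)
    coeffs = np.zeros((T, p, K, K))
    innov_var = np.zeros((T, K))
    flagged = False

    for t in range(p, T):
        # z[i*p + m] = channel i at lag m+1
        z = Xn[:, t - p : t][:, ::-1].reshape(-1)
        P = P + rate * np.eye(d)
        Pz = P @ z
        s = float(z @ Pz) + 1.0  # observation noise folded into gain scale
        if not np.isfinite(s) or s <= 0:
            P = P + 1e-6 * np.eye(d)
            Pz = P @ z
            s = float(z @ Pz) + 1.0
            flagged = True
        gain = Pz / s
        innov = Xn[:, t] - z @ A
        A = A + np.outer(gain, innov)
        P = P - np.outer(gain, Pz)
        r_obs = (1 - rate) * r_obs + rate * innov**2
        innov_var[t] = r_obs
        # unpack: A[i*p + m, sink] is influence of channel i at lag m+1
        a = A.reshape(K, p, K)      # (source, lag, sink)
        coeffs[t] = np.transpose(a, (1, 2, 0))  # (lag, sink, source)

    coeffs[:p] = coeffs[p]
    # rescale coefficients back to raw units: a_ij <- a_ij * scale_i / scale_j
    coeffs *= (scale.ravel()[None, None, :, None] / scale.ravel()[None, None, None, :])

    stable = _stability(coeffs[:: max(T // 200, 1)])
    full_stable = np.ones(T, dtype=bool)
    full_stable[:: max(T // 200, 1)][: stable.size] = stable
    return TvarModel(
        coeffs=coeffs, fs=signals.fs, order=p, rate=rate,
        innovation_var=innov_var, stable=full_stable, flagged=flagged,
    )


def _stability(coeffs: np.ndarray, tol: float = 0.05) -> np.ndarray:
    """Spectral radius of the companion form per checked sample."""
    n, p, K, _ = coeffs.shape
    out = np.ones(n, dtype=bool)
    comp = np.zeros((K * p, K * p))
    comp[K:, :-K] = np.eye(K * (p - 1)) if p > 1 else comp[K:, :-K]
    for t in range(n):
        comp[:K] = np.concatenate([coeffs[t, m] for m in range(p)], axis=1)
        rho = np.max(np.abs(np.linalg.eigvals(comp)))
        out[t] = rho <= 1 + tol
    return out


@dataclass
class DirectedConnectivityResult:
    """Normalized directed-coherence quantity per (sink i, source j, f, t).

    ``apdc_sq[i, j, f, t] = |A_ij|^2 / sum_k |A_ik|^2`` (sink/row
    normalization by default); APDC itself is its square root.
    """

    apdc_sq: np.ndarray       # (K, K, n_freqs, n_times)
    freqs: np.ndarray
    times: np.ndarray
    normalization: str = "row"

    @property
    def apdc(self) -> np.ndarray:
        return np.sqrt(self.apdc_sq)


def apdc_spectrum(
    model: TvarModel,
    freqs,
    times_idx=None,
    normalization: str = "row",
    include_identity: bool = True,
) -> DirectedConnectivityResult:
    """Adaptive PDC from the TVAR coefficients.

    ``A(f, t) = I - sum_m a_m(t) e^{-i 2 pi f m / fs}`` by default
    (``include_identity=False`` uses the bare coefficient transform).
    ``normalization='row'`` divides |A_ij|^2 by ``sum_k |A_ik|^2``
    (sink-normalized, as printed); ``'column'`` divides by
    ``sum_k |A_kj|^2`` (standard PDC).
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs >= model.fs / 2):
        raise ValueError("frequencies must be below Nyquist")
    if times_idx is None:
        times_idx = np.arange(model.n_samples)
    times_idx = np.asarray(times_idx)
    a = model.coeffs[times_idx]     # (T', p, K, K)
    p = model.order
    m = np.arange(1, p + 1)
    # basis (n_freqs, p)
    E = np.exp(-2j * np.pi * np.outer(freqs, m) / model.fs)
    # Af (T', n_freqs, K, K)
    Af = -np.einsum("fp,tpij->tfij", E, a)
    if include_identity:
        Af += np.eye(a.shape[2])[None, None]
    mag2 = np.abs(Af) ** 2
    if normalization == "row":
        denom = mag2.sum(axis=3, keepdims=True)          # sum over sources k for sink i
    elif normalization == "column":
        denom = mag2.sum(axis=2, keepdims=True)          # sum over sinks k for source j
    else:
        raise ValueError("normalization must be 'row' or 'column'")
    q = mag2 / np.maximum(denom, 1e-300)
    # reorder to (K, K, n_freqs, T')
    q = np.transpose(q, (2, 3, 1, 0))
    return DirectedConnectivityResult(
        apdc_sq=q, freqs=freqs, times=times_idx / model.fs,
        normalization=normalization,
    )


def iapdc_band(
    result: DirectedConnectivityResult, f1: float, f2: float
) -> np.ndarray:
    """Band-integrated APDC: mean over the frequency grid in [f1, f2].

    Returns ``iapdc[i, j, t]``, the per-sample average of the normalized
    quantity ``|A_ij|^2 / sum_k |A_ik|^2`` over the band.
    """
    if f2 <= f1:
        raise ValueError("need f1 < f2")
    mask = (result.freqs >= f1) & (result.freqs <= f2)
    if not mask.any():
        raise ValueError(f"no frequency bins inside [{f1}, {f2}] Hz")
    return result.apdc_sq[:, :, mask, :].mean(axis=2)


def bandlimited_crosscorr_lag(
    ts_a: TimeSeries,
    ts_b: TimeSeries,
    band: tuple = (3.0, 5.0),
    max_lag: float = 0.25,
    channel: int = 0,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Lag of the cross-correlation maximum of band-limited signals.

    Sign convention: a negative lag means the second signal is delayed
    relative to the first.  Returns (lag_s, lags_s, correlation profile).
    """
    if ts_a.n_samples != ts_b.n_samples or ts_a.fs != ts_b.fs:
        raise ValueError("signals must share length and sampling rate")
    n = ts_a.n_samples
    L = int(round(max_lag * ts_a.fs))
    if L >= n // 2:
        raise ValueError("max_lag must be below half the signal length")
    xa = bandpass_filter(ts_a, *band).data[channel]
    xb = bandpass_filter(ts_b, *band).data[channel]
    # drop filter edge transients so a pure delay maps to an exact lag
    edge = int(2 * ts_a.fs / band[0])
    if n - 2 * edge > 4 * L:
        xa, xb = xa[edge : n - edge], xb[edge : n - edge]
        n = xa.size
    xa = xa - xa.mean()
    xb = xb - xb.mean()
    full = sps.correlate(xb, xa, mode="full")  # full[n-1+tau] = sum xa[t] xb[t+tau]
    taus = np.arange(-L, L + 1)
    prof = full[n - 1 + taus]
    norm = np.sqrt(np.sum(xa**2) * np.sum(xb**2))
    prof = prof / max(norm, 1e-300)
    tau_star = taus[int(np.argmax(prof))]
    lag = -tau_star / ts_a.fs
    return float(lag), -taus / ts_a.fs, prof


def directed_comparison(
    iapdc_poi: dict, iapdc_baseline: dict, labels: list[str] | None = None
) -> pd.DataFrame:
    """Per directed pair: median iAPDC in each condition, percent
    difference, and a Kruskal-Wallis rank-test p (thin contract wrapper).

    ``iapdc_poi`` / ``iapdc_baseline`` map ``(from, to)`` pairs to arrays
    of per-sample (or per-event) iAPDC values; the two dicts must cover
    the same pairs.
    """
    if set(iapdc_poi) != set(iapdc_baseline):
        raise ValueError("POI and baseline conditions cover different pairs")
    rows = []
    for (src, dst) in sorted(iapdc_poi):
        a = np.asarray(iapdc_poi[(src, dst)], dtype=float)
        b = np.asarray(iapdc_baseline[(src, dst)], dtype=float)
        med_p, med_b = float(np.median(a)), float(np.median(b))
        if np.allclose(a.mean(), b.mean()) and np.allclose(np.sort(a)[:min(a.size, b.size)],
                                                           np.sort(b)[:min(a.size, b.size)]):
            p = 1.0
        else:
            p = float(ss.kruskal(a, b).pvalue)
        diff = 100.0 * (med_p - med_b) / med_b if med_b != 0 else np.inf
        rows.append(
            dict(source=src, sink=dst, median_baseline=med_b, median_poi=med_p,
                 diff_percent=diff, p=p)
        )
    return pd.DataFrame(rows)
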