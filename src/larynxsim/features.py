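"""Acoustic and postural feature extraction.

Four acoustic features summarize each simulated phonation: fundamental
frequency fo (pitch), sound pressure level SPL at 30 cm (loudness),
normalized spectral centroid NSC (brightness) and approximate entropy ApEn
(aperiodicity roughness).  Postural features are steady-state means over
the final 100 ms.  A fixture generator produces deterministic synthetic
signals (pure tones, harmonic complexes, jittered tones, noise) for
validating the extractors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .config import SimConfig, DEFAULT_CONFIG

__all__ = [
    "FeatureSet",
    "estimate_f0",
    "spl",
    "nsc",
    "apen",
    "steady_state_postural",
    "make_fixture",
    "extract_features",
]

I0_CGS = 1.0e-9  # 1e-12 W/m^2 in erg/(s cm^2)


class SignalTooShortError(ValueError):
    pass


@dataclass
class FeatureSet:
    """Acoustic + postural features of one simulated (or measured) signal."""

    fo: float | None = None          # Hz
    SPL: float = -np.inf             # dB re 1e-12 W/m^2 at 30 cm
    NSC: float = np.nan              # dimensionless
    ApEn: float = np.nan             # dimensionless
    L_mean: float = np.nan           # cm
    sigma_SLLP: float = np.nan       # dyn/cm^2
    sigma_lig: float = np.nan
    sigma_mus: float = np.nan
    oscillating: bool = False


def estimate_f0(x, fs: float, f_min: float = 50.0, f_max: float = 600.0,
                conf_threshold: float = 0.3,
                window_s: float | None = None) -> float | None:
    """Fundamental frequency by autocorrelation with parabolic interpolation.

    Analysis is restricted to the final ``window_s`` seconds when given.
    Returns ``None`` when the normalized autocorrelation peak falls below
    the periodicity-confidence threshold (aperiodic input).
    """
    x = np.asarray(x, dtype=float)
    if window_s is not None:
        x = x[-int(window_s * fs):]
    min_len = int(4 * fs / f_min)
    if len(x) < min_len:
        raise SignalTooShortError(
            f"need >= 4 periods of {f_min} Hz ({min_len} samples), got {len(x)}")
    x = x - x.mean()
    if np.max(np.abs(x)) == 0.0:
        return None
    nfft = int(2 ** np.ceil(np.log2(2 * len(x))))
    spec = np.fft.rfft(x, nfft)
    ac = np.fft.irfft(spec * np.conj(spec))[:len(x)]
    if ac[0] <= 0:
        return None
    ac /= ac[0]
    lag_min = max(2, int(np.floor(fs / f_max)))
    lag_max = min(len(ac) - 2, int(np.ceil(fs / f_min)))
    if lag_max <= lag_min:
        return None
    seg = ac[lag_min:lag_max + 1]
    k = int(np.argmax(seg)) + lag_min
    if ac[k] < conf_threshold:
        return None
    # parabolic interpolation around the peak
    y0, y1, y2 = ac[k - 1], ac[k], ac[k + 1]
    denom = y0 - 2 * y1 + y2
    delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    lag = k + np.clip(delta, -0.5, 0.5)
    return float(fs / lag)


def spl(po, R_cm: float = 30.0, Rm: float = 1.0, offset_db: float = 0.0) -> float:
    """Sound pressure level (dB re 1e-12 W/m^2) at distance ``R_cm``.

    SPL = 10 log10( mean(po^2) / (4 pi R^2 Rm I0) ) + offset, with po the
    oral pressure in dyn/cm^2 and Rm the radiation resistance in normalized
    units.  Doubling the signal amplitude adds exactly 20 log10(2) dB.
    """
    po = np.asarray(po, dtype=float)
    if len(po) == 0:
        raise ValueError("empty signal")
    p2 = float(np.mean(po ** 2))
    if p2 == 0.0:
        return -np.inf
    return 10.0 * np.log10(p2 / (4.0 * np.pi * R_cm ** 2 * Rm * I0_CGS)) + offset_db


def nsc(x, fo: float | None, fs: float, window_s: float | None = None) -> float:
    """Normalized spectral centroid: spectral center of mass divided by fo.

    Hann-windowed magnitude spectrum of the (final) analysis window, bins up
    to Nyquist.  NaN when fo is unavailable.
    """
    if fo is None or not fo > 0:
        return np.nan
    x = np.asarray(x, dtype=float)
    if window_s is not None:
        x = x[-int(window_s * fs):]
    x = x - x.mean()
    w = sps.windows.hann(len(x))
    mag = np.abs(np.fft.rfft(x * w))
    freqs = np.fft.rfftfreq(len(x), 1.0 / fs)
    total = mag.sum()
    if total == 0.0:
        return np.nan
    return float((freqs * mag).sum() / total / fo)


def _template_max_dist(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    """Pairwise Chebyshev distances between m-dimensional delay templates."""
    n_templates = len(x) - (m - 1) * tau
    A = np.abs(x[:, None] - x[None, :])
    D = A[:n_templates, :n_templates].copy()
    for k in range(1, m):
        off = k * tau
        np.maximum(D, A[off:off + n_templates, off:off + n_templates], out=D)
    return D


def apen(x, m: int = 2, tau: int = 1, r_factor: float = 0.2,
         r_mode: str = "sd", r: float | None = None) -> float:
    """Approximate entropy ApEn(m, r) of a time series.

    Phi^m(r) is the mean log fraction of delay templates within Chebyshev
    distance r (self-matches included); ApEn = Phi^m - Phi^{m+1}.  The
    similarity radius defaults to ``r_factor`` times the standard deviation
    (``r_mode='variance'`` uses the variance instead).  A constant signal
    returns 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    N = len(x)
    if N < 50:
        raise SignalTooShortError(f"need >= 50 samples for ApEn, got {N}")
    if r is None:
        scale = np.var(x) if r_mode == "variance" else np.std(x)
        r = r_factor * scale
    if r == 0.0:
        return 0.0  # constant signal: perfectly predictable

    def phi(mm: int) -> float:
        D = _template_max_dist(x, mm, tau)
        C = np.mean(D <= r, axis=1)
        return float(np.mean(np.log(C)))

    return phi(m) - phi(m + 1)


def steady_state_postural(series, fs: float, window_s: float = 0.1) -> float:
    """Mean of the final ``window_s`` seconds of a postural time series."""
    series = np.asarray(series, dtype=float)
    n = int(round(window_s * fs))
    if len(series) < n:
        raise SignalTooShortError(
            f"record shorter than the {window_s * 1e3:.0f} ms steady-state window")
    return float(series[-n:].mean())


def make_fixture(kind: str, f0: float = 200.0, duration: float = 0.4,
                 fs: float = 44100.0, amplitude: float = 1.0,
                 harmonics: int = 1, harmonic_amps=None,
                 jitter: float = 0.05, seed: int = 0) -> np.ndarray:
    """Deterministic synthetic test signals.

    kinds: ``sine`` (pure tone), ``harmonic`` (equal- or given-amplitude
    harmonic complex), ``jittered`` (tone whose period lengths are perturbed
    by a fractional SD ``jitter``), ``noise`` (white Gaussian).
    """
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    if kind == "sine":
        return amplitude * np.sin(2 * np.pi * f0 * t)
    if kind == "harmonic":
        amps = (np.ones(harmonics) if harmonic_amps is None
                else np.asarray(harmonic_amps, dtype=float))
        out = np.zeros(n)
        for h, a in enumerate(amps, start=1):
            out += a * np.sin(2 * np.pi * h * f0 * t)
        return amplitude * out
    if kind == "jittered":
        rng = np.random.default_rng(seed)
        out = np.empty(n)
        i = 0
        phase_freq = f0
        while i < n:
            period = max(8, int(round(fs / f0 * (1.0 + jitter * rng.standard_normal()))))
            cycle = amplitude * np.sin(2 * np.pi * np.arange(period) / period)
            m = min(period, n - i)
            out[i:i + m] = cycle[:m]
            i += m
        return out
    if kind == "noise":
        rng = np.random.default_rng(seed)
        return amplitude * rng.standard_normal(n)
    raise ValueError(f"unknown fixture kind {kind!r}")


def extract_features(record, cfg: SimConfig = DEFAULT_CONFIG,
                     oscillating: bool = False) -> FeatureSet:
    """Full feature set from a vibro-acoustic record.

    ApEn is computed on the oral pressure decimated to ``cfg.apen_fs`` (the
    estimator is O(N^2) and insensitive to the excess bandwidth).
    """
    po = record.po
    fo = None
    NSC = np.nan
    ApEn = np.nan
    SPL = -np.inf
    if len(po) > 0 and np.any(po != 0.0):
        SPL = spl(po, cfg.R_cm, cfg.Rm, cfg.spl_offset_db)
        if oscillating:
            fo = estimate_f0(po, cfg.fs, cfg.f0_min, cfg.f0_max,
                             cfg.f0_conf_threshold, cfg.analysis_window_s)
            NSC = nsc(po, fo, cfg.fs, cfg.analysis_window_s)
            q = max(1, int(round(cfg.fs / cfg.apen_fs)))
            xd = sps.decimate(po, q, zero_phase=True) if q > 1 else po
            ApEn = apen(xd, cfg.apen_m, cfg.apen_tau, cfg.apen_r_factor,
                        cfg.apen_r_mode)
    L_mean = steady_state_postural(record.L, cfg.fs, cfg.steady_window_s) \
        if len(record.L) >= int(cfg.steady_window_s * cfg.fs) else np.nan
    sig = {}
    for key in ("SLLP", "LIG", "MUS"):
        arr = record.sigma[key]
        sig[key] = (steady_state_postural(arr, cfg.fs, cfg.steady_window_s)
                    if len(arr) >= int(cfg.steady_window_s * cfg.fs) else np.nan)
    return FeatureSet(fo=fo, SPL=SPL, NSC=NSC, ApEn=ApEn, L_mean=L_mean,
                      sigma_SLLP=sig["SLLP"], sigma_lig=sig["LIG"],
                      sigma_mus=sig["MUS"], oscillating=oscillating)
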