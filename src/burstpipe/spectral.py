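"""Time-frequency machinery: complex Morlet transform for burst detection,
filter-Hilbert event-related spectral perturbation (ERSP), and lagged
coherence.

The burst transform convolves the signal with complex Morlet wavelets

    w(t, f) = A * exp(-t^2 / (2 sigma_t^2)) * exp(2 i pi f t),

with sigma_t = m / (2 pi f) and m = 7 cycles, on a 1-Hz grid over the beta
band (15-29 Hz); |conv|^2 is the time-frequency power.  The amplitude
constant is A = 1 / (sigma_t * sqrt(2 pi)); because burst detection
thresholds at a multiple of each channel's own median power, any positive
constant yields identical burst sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

BETA_BAND = (15.0, 29.0)


@dataclass
class WaveletSpec:
    """Morlet wavelet family for the beta-burst transform."""

    m: float = 7.0  # cycles
    freqs: np.ndarray = field(
        default_factory=lambda: np.arange(BETA_BAND[0], BETA_BAND[1] + 1.0)
    )

    def sigma_t(self, f: float) -> float:
        return self.m / (2 * np.pi * f)


def morlet_kernel(f: float, fs: float, m: float = 7.0) -> np.ndarray:
    sigma = m / (2 * np.pi * f)
    half = int(np.ceil(4 * sigma * fs))
    t = np.arange(-half, half + 1) / fs
    a = 1.0 / (sigma * np.sqrt(2 * np.pi))
    return a * np.exp(-(t**2) / (2 * sigma**2)) * np.exp(2j * np.pi * f * t)


def morlet_power(
    x: np.ndarray, fs: float, spec: WaveletSpec | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Time-frequency power of a 1-D signal via complex Morlet convolution.

    Returns ``(power, valid)`` where power has shape (n_freqs, n_samples)
    and ``valid`` flags samples further than 3 sigma_t of every wavelet from
    the recording edges (edge-affected samples must not yield bursts).  The
    signal is reflect-padded for the convolution so no boundary wrap occurs.
    """
    spec = spec or WaveletSpec()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    n = x.size
    power = np.empty((spec.freqs.size, n))
    valid = np.ones((spec.freqs.size, n), dtype=bool)
    for i, f in enumerate(spec.freqs):
        k = morlet_kernel(f, fs, spec.m)
        pad = len(k) // 2
        xp = np.pad(x, pad, mode="reflect")
        conv = sps.fftconvolve(xp, k, mode="same")[pad : pad + n]
        power[i] = np.abs(conv) ** 2
        edge = int(np.ceil(3 * spec.sigma_t(f) * fs))
        valid[i, :edge] = False
        valid[i, n - edge :] = False
    return power, valid


def channel_median_power(power: np.ndarray, sample_mask=None) -> np.ndarray:
    """Per-frequency median of TF power across the artifact-free recording.

    ``sample_mask`` flags samples to exclude (artifact segments).  This
    median, computed once over the whole recording, anchors the 6x threshold
    of the burst detector.
    """
    if sample_mask is not None:
        keep = ~np.asarray(sample_mask, dtype=bool)
        power = power[:, keep]
    if power.size == 0:
        raise ValueError("no artifact-free samples to take the median over")
    return np.median(power, axis=1)


def _fir_bandpass(f_lo: float, f_hi: float, fs: float) -> np.ndarray:
    """Symmetric least-squares FIR band-pass (zero phase when applied
    forward-backward)."""
    width = f_hi - f_lo
    numtaps = int(round(3 * fs / width))
    numtaps += 1 - numtaps % 2  # odd
    trans = width / 2
    bands = [0, max(f_lo - trans, 0.01), f_lo, f_hi, f_hi + trans, fs / 2]
    desired = [0, 0, 1, 1, 0, 0]
    return sps.firls(numtaps, bands, desired, fs=fs)


def _zero_phase_filter(x: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Forward-backward application of a FIR filter via FFT convolution
    (two-way filtering: zero phase, squared magnitude response)."""
    pad = len(h)
    xp = np.pad(x, pad, mode="reflect")
    y = sps.fftconvolve(xp, h, mode="same")
    y = sps.fftconvolve(y[::-1], h, mode="same")[::-1]
    return y[pad:-pad]


def ersp_filter_hilbert(
    x: np.ndarray,
    fs: float,
    event_samples: np.ndarray,
    freqs: np.ndarray | None = None,
    window_ms: tuple = (-100.0, 1500.0),
    baseline_ms: tuple = (-500.0, -200.0),
    half_width_hz: float = 0.5,
    artifact_mask: np.ndarray | None = None,
) -> dict:
    """Filter-Hilbert ERSP around events, baseline-corrected in dB.

    For each frequency (default 1-Hz steps over 1-50 Hz) the continuous
    signal is band-passed +/- ``half_width_hz`` with a symmetric two-way
    least-squares FIR filter, the analytic amplitude squared yields power,
    epochs are cut around ``event_samples`` and averaged, and the average is
    expressed as 10*log10(power / mean baseline power) per frequency.
    Epochs overlapping masked samples are dropped.

    Returns a dict with ``ersp`` (n_freqs x n_times, dB), ``freqs``,
    ``times_ms`` and ``n_epochs``.
    """
    freqs = np.asarray(freqs if freqs is not None else np.arange(1.0, 51.0))
    a = int(round(min(window_ms[0], baseline_ms[0]) / 1000 * fs))
    b = int(round(max(window_ms[1], baseline_ms[1]) / 1000 * fs))
    event_samples = np.asarray(event_samples, dtype=int)
    keep = []
    for e in event_samples:
        if e + a < 0 or e + b >= x.size:
            continue
        if artifact_mask is not None and artifact_mask[e + a : e + b + 1].any():
            continue
        keep.append(e)
    if not keep:
        raise ValueError("no clean epochs available")
    keep = np.asarray(keep)

    w0 = int(round(window_ms[0] / 1000 * fs))
    w1 = int(round(window_ms[1] / 1000 * fs))
    b0 = int(round(baseline_ms[0] / 1000 * fs))
    b1 = int(round(baseline_ms[1] / 1000 * fs))
    times_ms = np.arange(w0, w1 + 1) / fs * 1000.0

    ersp = np.empty((freqs.size, w1 - w0 + 1))
    for i, f in enumerate(freqs):
        h = _fir_bandpass(max(f - half_width_hz, 0.05), f + half_width_hz, fs)
        power = np.abs(sps.hilbert(_zero_phase_filter(x, h))) ** 2
        ep = np.stack([power[e + w0 : e + w1 + 1] for e in keep])
        base = np.stack([power[e + b0 : e + b1 + 1] for e in keep])
        mean_power = ep.mean(axis=0)
        mean_base = base.mean()
        ersp[i] = 10 * np.log10(mean_power / mean_base)
    return {"ersp": ersp, "freqs": freqs, "times_ms": times_ms, "n_epochs": len(keep)}


def lagged_coherence(
    epochs: np.ndarray,
    fs: float,
    freqs: np.ndarray | None = None,
    lags: tuple = (1, 2, 3, 4),
    min_windows: int = 20,
) -> dict:
    """Lagged coherence: how well the phase at frequency f predicts itself
    n cycles later.  Near 1 for sustained rhythms, low for transient bursts.

    Each epoch is tiled with consecutive non-overlapping windows of n cycles
    at each frequency; the Hann-tapered Fourier coefficient at f is computed
    per window, and coherence between consecutive windows is

        |sum_j F_j conj(F_{j+1})| / sqrt(sum_j |F_j|^2 * sum_j |F_{j+1}|^2),

    pooled over epochs.  Cells with fewer than ``min_windows`` window pairs
    are NaN.  Returns ``{"coherence": (n_freqs x n_lags), "freqs", "lags"}``.
    """
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    freqs = np.asarray(freqs if freqs is not None else np.arange(8.0, 36.0))
    coh = np.full((freqs.size, len(lags)), np.nan)
    for i, f in enumerate(freqs):
        for j, n_cyc in enumerate(lags):
            L = int(round(n_cyc * fs / f))
            if L < 4 or L > epochs.shape[1]:
                continue
            taper = np.hanning(L)
            phasor = np.exp(-2j * np.pi * f * np.arange(L) / fs)
            num = 0.0 + 0.0j
            den1 = 0.0
            den2 = 0.0
            n_pairs = 0
            for ep in epochs:
                n_win = ep.size // L
                if n_win < 2:
                    continue
                segs = ep[: n_win * L].reshape(n_win, L)
                coeffs = (segs * taper) @ phasor
                a, b = coeffs[:-1], coeffs[1:]
                num += np.sum(a * np.conj(b))
                den1 += np.sum(np.abs(a) ** 2)
                den2 += np.sum(np.abs(b) ** 2)
                n_pairs += n_win - 1
            if n_pairs >= min_windows and den1 > 0 and den2 > 0:
                coh[i, j] = np.abs(num) / np.sqrt(den1 * den2)
    return {"coherence": coh, "freqs": freqs, "lags": np.asarray(lags)}
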