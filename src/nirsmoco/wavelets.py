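"""Analytic wavelet machinery: Morse CWT, masked inverse CWT, Morlet WCOH.

The continuous wavelet transform uses the analytic generalized Morse family
with symmetry exponent ``gamma`` and time-bandwidth product ``beta*gamma``
(defaults 3 and 60, i.e. order ``beta = 20``), evaluated diagonally in the
frequency domain:

    Psi(omega) = 2 * exp(beta*ln(omega) - omega**gamma - ln_peak)   (omega > 0)

normalized to peak value 2 at ``omega_p = (beta/gamma)**(1/gamma)``, so a
real sinusoid of amplitude A yields coefficient magnitude ~A at its scale
(L1 / amplitude normalization).  Scales are laid on a logarithmic grid with
a configurable number of voices per octave spanning [2/duration, fs/2] Hz.

Reconstruction is the single-integral (delta-function) formula: the real
part of the coefficient sum over scales divided by a constant determined
analytically from the scale grid itself (the transfer function of
"transform then sum" is flat across the covered band for >= 4 voices per
octave).  Passing a boolean mask zeroes the flagged coefficients before the
sum, which is how motion-related time-frequency content is excluded.

Wavelet coherence uses the analytic Morlet wavelet (omega0 = 6) with the
standard smoothing pair: a Gaussian in time whose width is proportional to
scale, then a boxcar of ~0.6 octave across scales.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter1d

from .containers import CoherenceMap, Scalogram, WaveletParams

__all__ = [
    "morse_wavelet_ft",
    "morse_peak_omega",
    "frequency_grid",
    "cwt_morse",
    "icwt",
    "wcoh_morlet",
]


def morse_peak_omega(symmetry: float, order: float) -> float:
    """Peak angular frequency of the Morse wavelet, (beta/gamma)**(1/gamma)."""
    return (order / symmetry) ** (1.0 / symmetry)


def morse_wavelet_ft(omega: np.ndarray, symmetry: float, order: float) -> np.ndarray:
    """Frequency-domain generalized Morse wavelet, unit-peak value 2.

    ``omega`` in radians/sample; the wavelet is analytic (zero for
    omega <= 0).  Evaluated in log space to stay finite at large order.
    """
    omega = np.asarray(omega, dtype=float)
    wp = morse_peak_omega(symmetry, order)
    ln_peak = order * np.log(wp) - wp ** symmetry
    out = np.zeros_like(omega)
    pos = omega > 0
    out[pos] = 2.0 * np.exp(order * np.log(omega[pos]) - omega[pos] ** symmetry - ln_peak)
    return out


def _morlet_ft(omega: np.ndarray, omega0: float) -> np.ndarray:
    """Analytic Morlet wavelet in the frequency domain, unit-peak value 2."""
    out = np.zeros_like(omega)
    pos = omega > 0
    out[pos] = 2.0 * np.exp(-0.5 * (omega[pos] - omega0) ** 2)
    return out


def frequency_grid(
    n_samples: int,
    fs: float,
    voices_per_octave: int,
    f_min: float | None = None,
    f_max: float | None = None,
) -> np.ndarray:
    """Logarithmic frequency grid (Hz), strictly decreasing.

    Defaults span two cycles per record up to the Nyquist frequency.
    """
    if f_max is None:
        f_max = fs / 2.0
    if f_min is None:
        f_min = 2.0 * fs / n_samples
    if not (0 < f_min < f_max):
        raise ValueError("need 0 < f_min < f_max")
    n_oct = np.log2(f_max / f_min)
    n_freq = int(np.ceil(n_oct * voices_per_octave)) + 1
    return f_max * 2.0 ** (-np.arange(n_freq) / voices_per_octave)


def _pad_reflect(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Symmetric (reflect) padding to the next power of two >= 2*len(x)."""
    n = len(x)
    m = 1 << int(np.ceil(np.log2(max(2 * n, 2))))
    left = (m - n) // 2
    right = m - n - left
    return np.pad(x, (left, right), mode="reflect"), left


def _cwt_analytic(
    x: np.ndarray,
    fs: float,
    frequencies: np.ndarray,
    wavelet_ft,
    peak_omega: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Shared diagonal-in-frequency CWT. Returns (coefficients, scales)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if len(x) < 32:
        raise ValueError("signal must have at least 32 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains NaN/inf; gap-fill before the CWT")
    padded, left = _pad_reflect(x)
    m = len(padded)
    xf = np.fft.fft(padded)
    omega = 2.0 * np.pi * np.fft.fftfreq(m)  # rad/sample, signed
    scales = peak_omega * fs / (2.0 * np.pi * frequencies)  # samples
    coeffs = np.empty((len(scales), len(x)), dtype=complex)
    for j, s in enumerate(scales):
        w = np.fft.ifft(xf * wavelet_ft(s * omega))
        coeffs[j] = w[left : left + len(x)]
    return coeffs, scales


def cwt_morse(
    signal: np.ndarray,
    fs: float,
    params: WaveletParams | None = None,
    frequencies: np.ndarray | None = None,
) -> Scalogram:
    """Continuous wavelet transform with the analytic Morse wavelet.

    The transform is linear and time-shift covariant (interior of the cone
    of influence).  ``frequencies`` overrides the default grid — used to
    force congruent grids across signals that must share a mask.
    """
    if params is None:
        params = WaveletParams()
    if frequencies is None:
        frequencies = frequency_grid(len(np.atleast_1d(signal)), fs, params.voices_per_octave)
    frequencies = np.asarray(frequencies, dtype=float)
    wp = morse_peak_omega(params.morse_symmetry, params.morse_order)
    coeffs, scales = _cwt_analytic(
        signal, fs, frequencies,
        lambda w: morse_wavelet_ft(w, params.morse_symmetry, params.morse_order),
        wp,
    )
    # conservative cone of influence: lowest edge-free frequency per sample,
    # taking the wavelet's time spread as sqrt(beta*gamma)/omega_p scale units
    n = coeffs.shape[1]
    sigma_t = np.sqrt(params.morse_time_bandwidth) / wp
    dist = np.minimum(np.arange(n), np.arange(n)[::-1]) + 1
    coi = np.minimum(fs / 2.0, wp * sigma_t * fs / (2.0 * np.pi * dist))
    return Scalogram(
        coefficients=coeffs,
        frequencies=frequencies,
        scales=scales,
        fs=fs,
        coi=coi,
        params=params,
    )


def _reconstruction_constant(scalogram: Scalogram) -> float:
    """Analytic normalization for the single-integral inverse.

    For input cos(omega0 * t) the summed analytic coefficients are
    cos(omega0 * t) * (1/2) * sum_j Psi(s_j * omega0); with a log-spaced
    scale grid this transfer value is flat in omega0 over the covered band,
    so its mid-band median serves as the (grid-determined, deterministic)
    reconstruction constant.
    """
    p = scalogram.params
    f = scalogram.frequencies
    # sample the transfer function across the central octaves of the grid
    probe = np.geomspace(f[len(f) // 4], f[max(0, 3 * len(f) // 4)], 64)
    omega = 2.0 * np.pi * probe / scalogram.fs
    transfer = 0.5 * np.array([
        morse_wavelet_ft(scalogram.scales * w, p.morse_symmetry, p.morse_order).sum()
        for w in omega
    ])
    return float(np.median(transfer))


def icwt(scalogram: Scalogram, mask: np.ndarray | None = None) -> np.ndarray:
    """Inverse CWT by the single-integral formula, with optional exclusion.

    ``mask`` is a boolean ``(n_scales, n_samples)`` array; True cells are
    zeroed before reconstruction (``None`` reconstructs everything).
    """
    coeffs = scalogram.coefficients
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != coeffs.shape:
            raise ValueError("mask shape must match the coefficient grid")
        coeffs = np.where(mask, 0.0, coeffs)
    c = _reconstruction_constant(scalogram)
    return coeffs.real.sum(axis=0) / c


def _gaussian_smooth_time(rows: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    """Per-row Gaussian smoothing in time, sigma in samples, via FFT.

    Rows are reflect-padded to avoid wrap-around; the Gaussian transfer
    function is exp(-(sigma*omega)^2 / 2) (unit DC gain, so nonnegative
    inputs stay nonnegative up to round-off).  Complex inputs are smoothed
    as separate real/imaginary parts so that conjugating the input
    conjugates the output bitwise (coherence stays exactly symmetric).
    """
    if np.iscomplexobj(rows):
        return _gaussian_smooth_time(rows.real, sigmas) + 1j * _gaussian_smooth_time(
            rows.imag, sigmas
        )
    n = rows.shape[1]
    m = 1 << int(np.ceil(np.log2(max(2 * n, 2))))
    left = (m - n) // 2
    padded = np.pad(rows, ((0, 0), (left, m - n - left)), mode="reflect")
    omega = 2.0 * np.pi * np.fft.fftfreq(m)
    rf = np.fft.fft(padded, axis=1)
    rf *= np.exp(-0.5 * (sigmas[:, None] * omega[None, :]) ** 2)
    return np.fft.ifft(rf, axis=1).real[:, left : left + n]


def wcoh_morlet(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    params: WaveletParams | None = None,
    frequencies: np.ndarray | None = None,
) -> CoherenceMap:
    """Squared wavelet coherence of two signals, analytic Morlet wavelet.

        C(s,t) = |S(W_x W_y* / s)|^2 / [ S(|W_x|^2/s) * S(|W_y|^2/s) ]

    where S smooths with a Gaussian in time (std = scale, in samples) then a
    boxcar of ~0.6 octave across scales.  Values are in [0, 1]; identical
    inputs give exactly 1 and the map is symmetric in (x, y).
    """
    if params is None:
        params = WaveletParams()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("signals must have equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input: coherence undefined")
    if frequencies is None:
        frequencies = frequency_grid(len(x), fs, params.voices_per_octave)
    frequencies = np.asarray(frequencies, dtype=float)
    w0 = params.morlet_omega0
    wx, scales = _cwt_analytic(x, fs, frequencies, lambda w: _morlet_ft(w, w0), w0)
    wy, _ = _cwt_analytic(y, fs, frequencies, lambda w: _morlet_ft(w, w0), w0)

    inv_s = 1.0 / scales[:, None]
    # explicit real/imag products keep wcoh(x, y) == wcoh(y, x) bitwise
    cross = (
        (wx.real * wy.real + wx.imag * wy.imag)
        + 1j * (wx.imag * wy.real - wx.real * wy.imag)
    ) * inv_s
    px = (np.abs(wx) ** 2) * inv_s
    py = (np.abs(wy) ** 2) * inv_s

    cross = _gaussian_smooth_time(cross, scales)
    px = _gaussian_smooth_time(px, scales)
    py = _gaussian_smooth_time(py, scales)

    width = max(1, int(round(0.6 * params.voices_per_octave)))
    cross = uniform_filter1d(cross.real, width, axis=0, mode="nearest") + 1j * uniform_filter1d(
        cross.imag, width, axis=0, mode="nearest"
    )
    px = uniform_filter1d(px, width, axis=0, mode="nearest")
    py = uniform_filter1d(py, width, axis=0, mode="nearest")

    denom = px * py
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.where(denom > 0, (np.abs(cross) ** 2) / denom, 0.0)
    np.clip(coh, 0.0, 1.0, out=coh)
    return CoherenceMap(values=coh, frequencies=frequencies, fs=fs)
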