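"""Harmonic coefficient estimation on integer-cycle bins.

The estimator fits sine and cosine regressors at the stimulus harmonics by
(recursive) least squares.  On a stationary window containing an integer
number of cycles of every requested frequency the regressors are mutually
orthogonal, so the unit-forgetting-factor fit coincides with the DFT
coefficient (scaled to single-sided sinusoid amplitude); :func:`dft_reference`
provides that independent oracle.

Phase convention used package-wide: the fit is a·cos(2πft) + b·sin(2πft) and
the reported complex coefficient is c = a + i·b, so amplitude = |c| and phase
delay θ = atan2(b, a) — a pure A·cos(2πft − θ) yields exactly A·e^{iθ}, and a
larger θ means a later response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np

__all__ = [
    "harmonic_set",
    "design_matrix",
    "rls_spectrum",
    "dft_reference",
    "SpectraSet",
    "trial_spectra",
]


def harmonic_set(stimulus_freq, n: int) -> list[Fraction]:
    """Exact harmonic frequencies [F, 2F, ..., nF]."""
    if n < 1:
        raise ValueError("need at least one harmonic")
    f = stimulus_freq if isinstance(stimulus_freq, Fraction) else Fraction(str(stimulus_freq))
    return [f * (h + 1) for h in range(n)]


def design_matrix(n_samples: int, sampling_rate: float, frequencies: Sequence) -> np.ndarray:
    """Columns [cos(2πf₁t), sin(2πf₁t), cos(2πf₂t), ...] with t=0 at window start."""
    t = np.arange(n_samples) / sampling_rate
    cols = []
    for f in frequencies:
        w = 2.0 * np.pi * float(f) * t
        cols.append(np.cos(w))
        cols.append(np.sin(w))
    return np.stack(cols, axis=1)


def _check_integer_cycles(n_samples: int, sampling_rate: float, frequencies) -> None:
    for f in frequencies:
        cycles = float(f) * n_samples / sampling_rate
        if abs(cycles - round(cycles)) > 1e-9:
            warnings.warn(
                f"window holds a non-integer number of cycles ({cycles:.6f}) of "
                f"{float(f):.6g} Hz; expect spectral leakage",
                stacklevel=3,
            )


def rls_spectrum(
    bin_samples: np.ndarray,
    sampling_rate: float,
    frequencies: Sequence,
    forgetting_factor: float = 1.0,
) -> np.ndarray:
    """Least-squares harmonic coefficients c = a + i·b per channel per frequency.

    ``forgetting_factor`` λ ∈ (0, 1] applies exponential weighting λ^(N−1−n)
    to sample n (the steady-state recursive least-squares solution); λ = 1 is
    the ordinary least-squares fit, equal to the DFT on integer-cycle windows.
    """
    x = np.asarray(bin_samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    squeeze = x.ndim == 1
    if squeeze:
        x = x[None, :]
    if not (0.0 < forgetting_factor <= 1.0):
        raise ValueError("forgetting_factor must lie in (0, 1]")
    n = x.shape[1]
    _check_integer_cycles(n, sampling_rate, frequencies)
    phi = design_matrix(n, sampling_rate, frequencies)
    if forgetting_factor == 1.0:
        coef, *_ = np.linalg.lstsq(phi, x.T, rcond=None)
    else:
        w = forgetting_factor ** np.arange(n - 1, -1, -1)
        phi_w = phi * w[:, None]
        gram = phi.T @ phi_w
        rhs = phi_w.T @ x.T
        coef = np.linalg.solve(gram, rhs)
    a = coef[0::2]
    b = coef[1::2]
    out = (a + 1j * b).T  # (channels, n_freq)
    return out[0] if squeeze else out


def dft_reference(bin_samples: np.ndarray, sampling_rate: float, frequencies: Sequence) -> np.ndarray:
    """Amplitude-scaled DFT coefficients at the requested on-grid frequencies.

    Independent oracle for :func:`rls_spectrum`; raises if a frequency is not
    on the DFT grid of the window.
    """
    x = np.asarray(bin_samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    squeeze = x.ndim == 1
    if squeeze:
        x = x[None, :]
    n = x.shape[1]
    ks = []
    for f in frequencies:
        k = float(f) * n / sampling_rate
        if abs(k - round(k)) > 1e-9:
            raise ValueError(f"{float(f):.6g} Hz is not on the DFT grid of a {n}-sample window")
        k = int(round(k))
        if not (0 < k < n / 2):
            raise ValueError("frequency out of the strictly-positive DFT range")
        ks.append(k)
    spec = np.fft.fft(x, axis=1)
    # x = a·cos + b·sin at bin k gives X_k = (N/2)(a − i·b); report c = a + i·b
    out = 2.0 / n * np.conj(spec[:, ks])
    return out[0] if squeeze else out


# --------------------------------------------------------------------------
# per-eye/condition containers
# --------------------------------------------------------------------------

@dataclass
class SpectraSet:
    """Harmonic coefficients for one eye/condition: all trials and bins.

    coefs: complex (n_trials, n_channels, n_harmonics, n_bins)
    valid: bool (n_trials, n_bins, n_channels) — channel-bin validity from the
    rejection masks (first/last bins and artifact rejections are False).
    """

    subject_id: str
    eye: str
    condition: str
    coefs: np.ndarray
    valid: np.ndarray
    frequencies: tuple = ()

    @property
    def n_trials(self) -> int:
        return self.coefs.shape[0]

    def n_valid_complex(self) -> int:
        """Number of valid complex estimates: usable channel-bins × harmonics,
        counted once per channel set (i.e. per bin, not per channel)."""
        usable_bins = self.valid.all(axis=2)  # (trials, bins): bin usable on all channels
        return int(usable_bins.sum()) * self.coefs.shape[2]

    def coefficient_count_per_trial(self) -> float:
        """Mean number of real sine/cosine coefficient estimates per trial
        (usable bins × harmonics × 2)."""
        usable_bins = self.valid.all(axis=2).sum(axis=1)  # per trial
        return float(usable_bins.mean()) * self.coefs.shape[2] * 2


def trial_spectra(bins: np.ndarray, mask, sampling_rate: float, frequencies) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients for every bin of one preprocessed trial.

    Returns (coefs (n_channels, n_harmonics, n_bins), valid (n_bins, n_channels)).
    Rejected entries are computed anyway but flagged invalid; downstream
    consumers must honor the mask.
    """
    n_bins, n_channels, m = bins.shape
    coefs = np.empty((n_channels, len(frequencies), n_bins), dtype=complex)
    for b in range(n_bins):
        coefs[:, :, b] = rls_spectrum(bins[b], sampling_rate, frequencies)
    return coefs, mask.channel_bin_valid()
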