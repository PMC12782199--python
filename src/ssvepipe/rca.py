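"""Frequency-domain reliable components analysis (RCA).

Spatial filters are learned by a generalized eigendecomposition that ranks
channel weightings w by trial-to-trial reliability, maximizing the cross-trial
covariance relative to the within-trial covariance:

    maximize  (wᵀ R_xy w) / (wᵀ R_xx w)

where each observation is the real or imaginary part of a per-bin harmonic
coefficient (so phase information enters the covariances while the
eigenproblem stays real-symmetric).  R_xx pools covariance of observations
within a trial; R_xy pools covariance between same-index observations of
distinct trial pairs — incoherent noise cancels in R_xy, so leading
eigenvectors isolate phase-locked activity.

Filters are trained on control eyes only and then applied unchanged to every
subject, which removes any possibility of the two groups being separated by a
component sign flip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.linalg

from .spectral import SpectraSet

__all__ = [
    "CovariancePair",
    "RCModel",
    "observation_matrices",
    "compute_covariances",
    "fit_rca",
    "project",
    "project_spectra",
    "component_topography",
]


@dataclass
class CovariancePair:
    """Pooled within-trial (R_xx) and cross-trial (R_xy) covariance."""

    r_xx: np.ndarray  # (channels, channels)
    r_xy: np.ndarray  # (channels, channels), symmetrized
    n_trials: int
    n_observations: int


@dataclass
class RCModel:
    """Control-trained spatial filters.

    W: (channels, K) weight matrix, columns ordered by descending reliability
    eigenvalue; sign fixed so each column's largest-|weight| entry is positive.
    A: forward topographies R_xx·W·(WᵀR_xx·W)⁻¹.
    """

    W: np.ndarray
    eigenvalues: np.ndarray
    A: np.ndarray
    regularization: float
    training_descriptor: str = "controls"

    @property
    def n_components(self) -> int:
        return self.W.shape[1]


def observation_matrices(coefs: np.ndarray, valid: np.ndarray) -> list[np.ndarray]:
    """Stack each trial's harmonic coefficients into a real observation matrix.

    coefs: complex (n_trials, n_channels, n_harmonics, n_bins)
    valid: bool (n_trials, n_bins, n_channels)

    A bin enters only if it is valid on *all* channels and in *all* trials of
    the block, so that cross-trial observation indices align.  Returns one
    (n_obs, n_channels) matrix per trial with n_obs = 2 × harmonics × bins.
    """
    n_trials, n_ch, n_h, n_bins = coefs.shape
    bin_ok = valid.all(axis=(0, 2))  # (n_bins,) valid across trials & channels
    if not bin_ok.any():
        raise ValueError("no bin is valid across all trials")
    xs = []
    for t in range(n_trials):
        c = coefs[t][:, :, bin_ok]  # (ch, H, B)
        flat = c.reshape(n_ch, -1)  # (ch, H·B)
        xs.append(np.concatenate([flat.real, flat.imag], axis=1).T)  # (2HB, ch)
    return xs


def compute_covariances(blocks: Iterable[Sequence[np.ndarray]]) -> CovariancePair:
    """Pool covariances over blocks of aligned trials.

    Each block is a list of per-trial observation matrices (n_obs, n_channels)
    with identical n_obs within the block (e.g. one block per eye/condition).
    Observations are mean-centered per channel within each block before the
    products are accumulated; R_xy averages over ordered pairs of distinct
    trials and is symmetric by construction.
    """
    sum_xx = None
    sum_xy = None
    n_obs_xx = 0
    n_obs_xy = 0
    n_trials = 0
    for block in blocks:
        xs = list(block)
        if len(xs) < 2:
            raise ValueError("cross-trial covariance needs at least 2 trials per block")
        n_obs = xs[0].shape[0]
        mean = np.mean([x.mean(axis=0) for x in xs], axis=0)
        xs = [x - mean for x in xs]
        within = sum(x.T @ x for x in xs)
        total = np.sum(xs, axis=0)
        cross = total.T @ total - within  # Σ_{t≠u} X_tᵀX_u
        if sum_xx is None:
            sum_xx = within
            sum_xy = cross
        else:
            sum_xx = sum_xx + within
            sum_xy = sum_xy + cross
        n_trials += len(xs)
        n_obs_xx += len(xs) * n_obs
        n_obs_xy += len(xs) * (len(xs) - 1) * n_obs
    if sum_xx is None:
        raise ValueError("no blocks supplied")
    r_xx = sum_xx / n_obs_xx
    r_xy = sum_xy / n_obs_xy
    r_xy = 0.5 * (r_xy + r_xy.T)
    return CovariancePair(r_xx=r_xx, r_xy=r_xy, n_trials=n_trials, n_observations=n_obs_xx)


def covariances_from_spectra(spectra: Iterable[SpectraSet]) -> CovariancePair:
    """Convenience wrapper: one covariance block per eye/condition SpectraSet.

    Eyes whose every bin was rejected contribute no block (logged upstream);
    at least one usable block is required.
    """
    blocks = []
    for s in spectra:
        try:
            blocks.append(observation_matrices(s.coefs, s.valid))
        except ValueError:
            continue
    if not blocks:
        raise ValueError("no eye/condition block has usable bins")
    return compute_covariances(blocks)


def fit_rca(
    cov: CovariancePair,
    n_components: int = 6,
    regularization: float = 1e-3,
    invert_ratio: bool = False,
) -> RCModel:
    """Solve the reliability eigenproblem on pooled covariances.

    Diagonal loading λ·trace(R_xx)/n_channels is added to R_xx before the
    generalized eigendecomposition.  ``invert_ratio`` swaps numerator and
    denominator (sensitivity analysis for the opposite reading of the
    objective); the default maximizes cross-trial reliability.
    """
    n_ch = cov.r_xx.shape[0]
    if n_components > n_ch:
        raise ValueError("cannot extract more components than channels")
    load = regularization * np.trace(cov.r_xx) / n_ch
    r_xx = cov.r_xx + load * np.eye(n_ch)
    num, den = (cov.r_xy, r_xx) if not invert_ratio else (r_xx, cov.r_xy)
    try:
        evals, evecs = scipy.linalg.eigh(num, den)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover
        raise np.linalg.LinAlgError(f"singular regularized covariance: {exc}") from exc
    order = np.argsort(evals)[::-1][:n_components]
    w = evecs[:, order]
    evals = evals[order]
    # sign convention: largest-|weight| entry of each column is positive
    peak = np.argmax(np.abs(w), axis=0)
    signs = np.sign(w[peak, np.arange(w.shape[1])])
    signs[signs == 0] = 1.0
    w = w * signs
    a = component_topography(w, cov.r_xx)
    return RCModel(W=w, eigenvalues=evals, A=a, regularization=regularization)


def project(coefs: np.ndarray, model: RCModel) -> np.ndarray:
    """Apply fixed spatial filters: component coefficients = Wᵀ × channel coefficients.

    ``coefs`` has the channel axis in position -3 (…, channels, harmonics, bins).
    Complex linearity is preserved (W is real).
    """
    w = model.W
    if coefs.shape[-3] != w.shape[0]:
        raise ValueError(
            f"channel dimension {coefs.shape[-3]} does not match filter rows {w.shape[0]}"
        )
    return np.einsum("ck,...chb->...khb", w, coefs)


def project_spectra(s: SpectraSet, model: RCModel) -> SpectraSet:
    """Project a per-eye/condition SpectraSet into component space.

    A (trial, bin) is valid in component space only when every channel was
    valid in that bin (a single contaminated channel contaminates all
    components).
    """
    comp = project(s.coefs, model)
    bin_ok = s.valid.all(axis=2)  # (trials, bins)
    valid = np.repeat(bin_ok[:, :, None], model.n_components, axis=2)
    return SpectraSet(
        subject_id=s.subject_id,
        eye=s.eye,
        condition=s.condition,
        coefs=comp,
        valid=valid,
        frequencies=s.frequencies,
    )


def component_topography(W: np.ndarray, r_xx: np.ndarray) -> np.ndarray:
    """Forward-model scalp patterns A = R_xx·W·(WᵀR_xx·W)⁻¹."""
    m = W.T @ r_xx @ W
    try:
        inv = np.linalg.inv(m)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"WᵀR_xxW is rank deficient: {exc}") from exc
    return r_xx @ W @ inv
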