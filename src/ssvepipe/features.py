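"""Per-eye feature construction.

Component-space harmonic coefficients are collapsed over usable bins and
trials by the complex (vector) mean, which preserves phase coherence —
phase-locked activity survives averaging while incoherent noise cancels.
Each complex mean becomes three real features: the amplitude ρ = |c| and the
circular phase-delay encoding (cos θ, sin θ).  With the defaults (2 pathways ×
6 components × 4 harmonics × 3 encodings) this yields 144 response features
per eye, plus age and sex indicator columns.

The per-eye SNR is the pooled RC1 vector-mean amplitude over 1F–4F divided by
the pooled standard error of those estimates across bins and trials (coherent
signal over incoherent noise).  The exact in-lab SNR rule is not published;
this definition is this package's documented stand-in and is monotone in the
planted signal-to-noise ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rca import RCModel, project_spectra
from .simulate import SubjectDemographics
from .spectral import SpectraSet

__all__ = [
    "PolarFeature",
    "vector_mean",
    "polar_features",
    "eye_snr",
    "feature_columns",
    "assemble_feature_table",
    "apply_snr_mask",
]

logger = logging.getLogger(__name__)

META_COLUMNS = ["subject_id", "eye", "label", "snr"]
DEMOGRAPHIC_COLUMNS = ["age", "sex_M", "sex_unknown"]


@dataclass(frozen=True)
class PolarFeature:
    """Amplitude + unit phase encoding of one complex mean.

    Invariant: cos² + sin² is exactly 1 when rho > 0 and all three are 0 for a
    zero mean (degenerate phase).
    """

    rho: float
    cos_theta: float
    sin_theta: float


def vector_mean(coefs: np.ndarray, valid: np.ndarray | None = None) -> np.ndarray:
    """Complex mean over the trailing (trial/bin) observation axes.

    coefs: (..., n_obs) or an arbitrary array with ``valid`` of the same shape
    marking usable entries.  Raises if nothing is valid.
    """
    coefs = np.asarray(coefs)
    if valid is None:
        if coefs.size == 0:
            raise ValueError("no estimates to average")
        return coefs.mean(axis=-1)
    valid = np.broadcast_to(valid, coefs.shape)
    counts = valid.sum(axis=-1)
    if np.any(counts == 0):
        raise ValueError("some entries have no usable estimates")
    return np.where(valid, coefs, 0).sum(axis=-1) / counts


def polar_features(c: complex) -> PolarFeature:
    rho = abs(c)
    if rho == 0:
        logger.warning("zero-amplitude complex mean: phase undefined, encoded as (0, 0)")
        return PolarFeature(0.0, 0.0, 0.0)
    theta = np.angle(c)
    return PolarFeature(float(rho), float(np.cos(theta)), float(np.sin(theta)))


def _component_means(spectra: SpectraSet) -> np.ndarray:
    """Vector mean per (component, harmonic) over all valid (trial, bin) cells."""
    coefs = spectra.coefs  # (trials, K, H, bins)
    valid = spectra.valid  # (trials, bins, K)
    n_t, n_k, n_h, n_b = coefs.shape
    v = valid.transpose(0, 2, 1)[:, :, None, :]  # (trials, K, 1, bins)
    v = np.broadcast_to(v, coefs.shape)
    flat = coefs.transpose(1, 2, 0, 3).reshape(n_k, n_h, -1)
    vflat = v.transpose(1, 2, 0, 3).reshape(n_k, n_h, -1)
    return vector_mean(flat, vflat)


def eye_snr(spectra_by_condition: dict[str, SpectraSet]) -> float:
    """Pooled RC1 signal-to-noise ratio over harmonics and conditions.

    snr = sqrt(Σ_h |mean_h|²) / sqrt(Σ_h var(c_h)/n_h), pooled over conditions;
    returns 0.0 when no estimate is usable.
    """
    sig2 = 0.0
    noise2 = 0.0
    any_valid = False
    for s in spectra_by_condition.values():
        coefs = s.coefs[:, 0, :, :]  # RC1: (trials, H, bins)
        valid = s.valid[:, :, 0][:, None, :]  # (trials, 1, bins)
        valid = np.broadcast_to(valid, coefs.shape)
        for h in range(coefs.shape[1]):
            c = coefs[:, h, :][valid[:, h, :]]
            n = c.size
            if n == 0:
                continue
            any_valid = True
            m = c.mean()
            sig2 += abs(m) ** 2
            if n > 1:
                noise2 += np.mean(np.abs(c - m) ** 2) / n
    if not any_valid or noise2 == 0.0:
        return 0.0 if not any_valid else float("inf")
    return float(np.sqrt(sig2) / np.sqrt(noise2))


def feature_columns(conditions=("ON", "OFF"), n_components: int = 6, n_harmonics: int = 4) -> list[str]:
    """Canonical column order: pathway → component → harmonic → (rho, cos, sin)."""
    cols = []
    for cond in conditions:
        for k in range(1, n_components + 1):
            for h in range(1, n_harmonics + 1):
                for enc in ("rho", "cos", "sin"):
                    cols.append(f"{cond}_rc{k}_h{h}_{enc}")
    return cols


def assemble_feature_table(
    component_spectra: dict[tuple[str, str, str], SpectraSet],
    demographics: dict[str, SubjectDemographics],
    conditions=("ON", "OFF"),
    eyes=("OD", "OS"),
) -> pd.DataFrame:
    """One row per eye: SSVEP features + demographics + label + SNR.

    ``component_spectra`` maps (subject_id, eye, condition) to component-space
    SpectraSet (already projected through one control-trained RCModel).  Eyes
    missing a condition are flagged and skipped with a log entry.
    """
    rows = []
    subjects = sorted({k[0] for k in component_spectra})
    for sid in subjects:
        demo = demographics[sid]
        for eye in eyes:
            per_cond = {}
            complete = True
            for cond in conditions:
                s = component_spectra.get((sid, eye, cond))
                if s is None:
                    complete = False
                    break
                per_cond[cond] = s
            if not complete:
                logger.warning("eye %s/%s incomplete (missing condition); skipped", sid, eye)
                continue
            row: dict[str, object] = {
                "subject_id": sid,
                "eye": eye,
                "label": 1 if demo.group == "patient" else 0,
                "age": demo.age,
                "sex_M": 1 if demo.sex == "M" else 0,
                "sex_unknown": 1 if demo.sex == "unknown" else 0,
            }
            try:
                means_by_cond = {cond: _component_means(per_cond[cond]) for cond in conditions}
            except ValueError:
                # every estimate rejected for some condition: flag and propagate
                logger.warning("eye %s/%s has no usable estimates; skipped", sid, eye)
                continue
            for cond in conditions:
                means = means_by_cond[cond]  # (K, H)
                n_k, n_h = means.shape
                for k in range(n_k):
                    for h in range(n_h):
                        pf = polar_features(means[k, h])
                        row[f"{cond}_rc{k + 1}_h{h + 1}_rho"] = pf.rho
                        row[f"{cond}_rc{k + 1}_h{h + 1}_cos"] = pf.cos_theta
                        row[f"{cond}_rc{k + 1}_h{h + 1}_sin"] = pf.sin_theta
            row["snr"] = eye_snr(per_cond)
            rows.append(row)
    if not rows:
        raise ValueError("no complete eyes")
    n_k = next(iter(component_spectra.values())).coefs.shape[1]
    n_h = next(iter(component_spectra.values())).coefs.shape[2]
    cols = META_COLUMNS + DEMOGRAPHIC_COLUMNS[:1] + ["sex_M", "sex_unknown"] + feature_columns(
        conditions, n_k, n_h
    )
    table = pd.DataFrame(rows)
    return table[[c for c in cols if c in table.columns]]


def apply_snr_mask(table: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Drop rows with snr < threshold; logs the per-group removal counts."""
    if "snr" not in table.columns:
        raise ValueError("snr column missing; compute SNR first")
    keep = table["snr"] >= threshold
    if not keep.any():
        raise ValueError("SNR threshold would drop every eye")
    dropped = table.loc[~keep]
    for label, grp in dropped.groupby("label"):
        name = "patient" if label == 1 else "control"
        logger.info("SNR mask removed %d %s eyes", len(grp), name)
    return table.loc[keep].reset_index(drop=True)
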