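"""End-to-end pipeline: simulate → preprocess → spectra → RCA → features →
classification grid → AUC statistics.

The classification grid crosses pathway {both, ON, OFF} × feature domain
{both, amplitude, phase} × CV scheme {paired, ignore-pairing} × SNR masking
{unmasked, masked}, mirroring the structure of the study's result tables.
AUC comparisons are grouped into hypothesis families (pairing inflation,
ON vs OFF, phase vs amplitude, masking) and Bonferroni-corrected within each
family.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    ClassifierConfig,
    ClassifierResult,
    Metrics,
    feature_subset,
    fit_elastic_net_cv,
    make_folds,
    performance,
)
from .features import apply_snr_mask, assemble_feature_table
from .preprocess import preprocess_trial
from .protocol import ProtocolConfig
from .rca import RCModel, covariances_from_spectra, fit_rca, project_spectra
from .simulate import EffectSpec, Montage, SensorTrial, TruthTable, iter_cohort_trials
from .spectral import SpectraSet, trial_spectra
from .stats import TestFamily, bonferroni_group, chi_square_retained, delong_paired, delong_unpaired

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "extract_spectra",
    "fit_control_rca",
    "project_cohort",
    "simulate_feature_table",
    "run_grid",
    "run_pipeline",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

_DEFAULT_GRID = {
    "pathways": ["both", "ON", "OFF"],
    "domains": ["both", "amplitude", "phase"],
    "cv": ["paired", "ignore-pairing"],
    "masks": ["unmasked", "masked"],
}


@dataclass
class PipelineConfig:
    """Nested pipeline settings; unknown keys are rejected on load."""

    protocol: dict = field(default_factory=dict)
    effect: dict = field(default_factory=dict)
    n_patients: int = 10
    n_controls: int = 10
    bandpass: bool = False
    n_components: int = 6
    regularization: float = 1e-3
    snr_mask_quantile: float = 0.15
    snr_threshold: float | None = None  # absolute override of the quantile rule
    cv_folds: int = 10
    classifier: dict = field(default_factory=lambda: {"alpha_grid": (0.5, 1.0), "n_lambda": 10, "inner_folds": 3})
    grid: dict = field(default_factory=lambda: dict(_DEFAULT_GRID))
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        grid_keys = set(cfg.grid) - set(_DEFAULT_GRID)
        if grid_keys:
            raise ValueError(f"unknown grid keys: {sorted(grid_keys)}")
        cfg.grid = {**_DEFAULT_GRID, **cfg.grid}
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["classifier"] = {k: list(v) if isinstance(v, tuple) else v for k, v in d["classifier"].items()}
        return d

    def settings_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True, default=str).encode()).hexdigest()[:16]


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def extract_spectra(
    protocol: ProtocolConfig,
    trials: Iterable[SensorTrial],
    montage: Montage | None = None,
    bandpass: bool = False,
) -> dict[tuple[str, str, str], SpectraSet]:
    """Preprocess and spectrally decompose trials one at a time (constant memory)."""
    freqs = protocol.harmonics
    acc: dict[tuple[str, str, str], list] = {}
    for trial in trials:
        bins, mask = preprocess_trial(trial, protocol, montage=montage, bandpass=bandpass)
        coefs, valid = trial_spectra(bins, mask, trial.sampling_rate, freqs)
        acc.setdefault((trial.subject_id, trial.eye, trial.condition), []).append((coefs, valid))
    out = {}
    for key, items in acc.items():
        out[key] = SpectraSet(
            subject_id=key[0], eye=key[1], condition=key[2],
            coefs=np.stack([c for c, _ in items]),
            valid=np.stack([v for _, v in items]),
            frequencies=tuple(float(f) for f in freqs),
        )
    return out


def fit_control_rca(
    spectra: dict[tuple[str, str, str], SpectraSet],
    demographics: dict,
    n_components: int = 6,
    regularization: float = 1e-3,
) -> RCModel:
    """Learn spatial filters on control eyes only (both conditions pooled)."""
    control = [
        s for (sid, _, _), s in sorted(spectra.items())
        if demographics[sid].group == "control"
    ]
    if not control:
        raise ValueError("no control eyes to train on")
    cov = covariances_from_spectra(control)
    return fit_rca(cov, n_components=n_components, regularization=regularization)


def project_cohort(
    spectra: dict[tuple[str, str, str], SpectraSet], model: RCModel
) -> dict[tuple[str, str, str], SpectraSet]:
    """Project every eye (patients and controls) through the same fixed filters."""
    return {k: project_spectra(s, model) for k, s in spectra.items()}


def simulate_feature_table(
    protocol: ProtocolConfig,
    effect: EffectSpec,
    n_patients: int,
    n_controls: int,
    seed: int,
    n_components: int = 6,
    regularization: float = 1e-3,
    bandpass: bool = False,
) -> tuple[pd.DataFrame, RCModel, TruthTable]:
    """Synthetic cohort straight to a classification-ready feature table."""
    montage, truth, trials = iter_cohort_trials(protocol, effect, n_patients, n_controls, seed)
    spectra = extract_spectra(protocol, trials, montage=montage, bandpass=bandpass)
    model = fit_control_rca(spectra, truth.demographics, n_components, regularization)
    comp = project_cohort(spectra, model)
    table = assemble_feature_table(comp, truth.demographics, protocol.conditions, protocol.eyes)
    return table, model, truth


# --------------------------------------------------------------------------
# classification grid + statistics
# --------------------------------------------------------------------------

def _metrics_dict(m: Metrics) -> dict:
    return {"accuracy": m.accuracy, "sensitivity": m.sensitivity, "specificity": m.specificity, "auc": m.auc}


def run_grid(
    table: pd.DataFrame,
    config: PipelineConfig,
    classifier_config: ClassifierConfig | None = None,
) -> tuple[dict, dict[tuple, ClassifierResult]]:
    """Fit one classifier per grid cell; returns (report dict, fitted results)."""
    if classifier_config is None:
        classifier_config = ClassifierConfig(**config.classifier, seed=config.seed)
    if config.snr_threshold is not None:
        thr = config.snr_threshold
    else:
        thr = float(np.quantile(table["snr"], config.snr_mask_quantile))
    masked_table = apply_snr_mask(table, thr)
    tables = {"unmasked": table, "masked": masked_table}
    grid = config.grid
    cells = {}
    results: dict[tuple, ClassifierResult] = {}
    for mask_name in grid["masks"]:
        tbl = tables[mask_name]
        for cv_name in grid["cv"]:
            grouped = cv_name == "paired"
            scheme = make_folds(tbl, k=config.cv_folds, grouped=grouped, seed=config.seed)
            for pathway in grid["pathways"]:
                for domain in grid["domains"]:
                    sub = feature_subset(tbl, pathway=pathway, domain=domain)
                    res = fit_elastic_net_cv(sub, scheme, classifier_config)
                    key = (pathway, domain, cv_name, mask_name)
                    results[key] = res
                    cells["|".join(key)] = {
                        "metrics": _metrics_dict(performance(res.oof_scores, res.labels)),
                        "n_rows": len(sub),
                        "alpha": res.final_alpha,
                        "lambda": res.final_lambda,
                        "n_retained": int(res.retained.sum()),
                    }
    report = {
        "snr_threshold": thr,
        "n_rows_unmasked": len(table),
        "n_rows_masked": len(masked_table),
        "cells": cells,
    }
    return report, results


def _retained_counts(result: ClassifierResult, pathway: str) -> tuple[int, int]:
    cols = [c for c in result.coefficients.index if c.startswith(f"{pathway}_")]
    k = int((result.coefficients[cols] != 0).sum())
    return k, len(cols)


def grid_statistics(results: dict[tuple, ClassifierResult], grid: dict) -> dict:
    """Hypothesis-family tests over the fitted grid, Bonferroni within family."""
    def cell(pathway, domain, cv, mask):
        return results.get((pathway, domain, cv, mask))

    families = []
    details: dict[str, list] = {}

    # 1. pairing inflation: ignore-pairing vs paired, per pathway (domain=both, unmasked)
    ps, det = [], []
    for pathway in grid["pathways"]:
        a = cell(pathway, "both", "ignore-pairing", "unmasked")
        b = cell(pathway, "both", "paired", "unmasked")
        if a is None or b is None:
            continue
        cmpr = delong_paired(a.oof_scores, b.oof_scores, b.labels)
        ps.append(cmpr.p_value)
        det.append({"pathway": pathway, "delta_auc": cmpr.delta_auc,
                    "ci": [cmpr.ci_low, cmpr.ci_high], "p": cmpr.p_value})
    if ps:
        families.append(TestFamily("pairing_inflation", tuple(ps)))
        details["pairing_inflation"] = det

    # 2. ON vs OFF, paired CV, per domain × mask
    ps, det = [], []
    for mask in grid["masks"]:
        for domain in grid["domains"]:
            a = cell("ON", domain, "paired", mask)
            b = cell("OFF", domain, "paired", mask)
            if a is None or b is None:
                continue
            cmpr = delong_paired(a.oof_scores, b.oof_scores, b.labels)
            ps.append(cmpr.p_value)
            det.append({"domain": domain, "mask": mask, "delta_auc": cmpr.delta_auc,
                        "ci": [cmpr.ci_low, cmpr.ci_high], "p": cmpr.p_value})
    if ps:
        families.append(TestFamily("on_vs_off", tuple(ps)))
        details["on_vs_off"] = det

    # 3. phase vs amplitude, paired CV, per pathway × mask
    ps, det = [], []
    for mask in grid["masks"]:
        for pathway in grid["pathways"]:
            a = cell(pathway, "amplitude", "paired", mask)
            b = cell(pathway, "phase", "paired", mask)
            if a is None or b is None:
                continue
            cmpr = delong_paired(a.oof_scores, b.oof_scores, b.labels)
            ps.append(cmpr.p_value)
            det.append({"pathway": pathway, "mask": mask, "delta_auc": cmpr.delta_auc,
                        "ci": [cmpr.ci_low, cmpr.ci_high], "p": cmpr.p_value})
    if ps:
        families.append(TestFamily("phase_vs_amplitude", tuple(ps)))
        details["phase_vs_amplitude"] = det

    # 4. masked vs unmasked, paired CV, per pathway (unpaired rows → unpaired test)
    ps, det = [], []
    for pathway in grid["pathways"]:
        a = cell(pathway, "both", "paired", "masked")
        b = cell(pathway, "both", "paired", "unmasked")
        if a is None or b is None:
            continue
        cmpr = delong_unpaired(a.oof_scores, a.labels, b.oof_scores, b.labels)
        ps.append(cmpr.p_value)
        det.append({"pathway": pathway, "delta_auc": cmpr.delta_auc,
                    "ci": [cmpr.ci_low, cmpr.ci_high], "p": cmpr.p_value})
    if ps:
        families.append(TestFamily("snr_masking", tuple(ps)))
        details["snr_masking"] = det

    adjusted = dict(bonferroni_group(families)) if families else {}
    out = {"families": {}}
    for fam in families:
        out["families"][fam.label] = {
            "m": fam.m,
            "tests": details[fam.label],
            "p_adjusted": list(adjusted[fam.label]),
        }

    # retained-feature χ² on the headline fit (both pathways, both domains, paired, unmasked)
    headline = cell("both", "both", "paired", "unmasked")
    if headline is not None:
        k_on, n_on = _retained_counts(headline, "ON")
        k_off, n_off = _retained_counts(headline, "OFF")
        if 0 < k_on + k_off < n_on + n_off:
            chi2, p = chi_square_retained(k_off, n_off, k_on, n_on)
        else:
            chi2, p = float("nan"), float("nan")
        coef = headline.coefficients
        top = coef.reindex(coef.abs().sort_values(ascending=False).index)[:15]
        out["retained_features"] = {
            "on": {"retained": k_on, "total": n_on},
            "off": {"retained": k_off, "total": n_off},
            "chi2": chi2,
            "p": p,
            "retained_mask": {c: bool(v) for c, v in headline.retained.items() if v},
            "top15_standardized_coefficients": {c: float(v) for c, v in top.items()},
        }
    return out


def run_pipeline(config: PipelineConfig, seed: int | None = None) -> dict:
    """Full experiment; deterministic under (config, seed)."""
    seed = config.seed if seed is None else seed
    protocol = ProtocolConfig.from_dict(config.protocol) if config.protocol else ProtocolConfig()
    effect = EffectSpec(**config.effect) if config.effect else EffectSpec()
    logger.info("simulating cohort: %d patients + %d controls", config.n_patients, config.n_controls)
    table, model, truth = simulate_feature_table(
        protocol, effect, config.n_patients, config.n_controls, seed,
        n_components=config.n_components, regularization=config.regularization,
        bandpass=config.bandpass,
    )
    grid_report, results = run_grid(table, config)
    stats_report = grid_statistics(results, {**_DEFAULT_GRID, **config.grid})
    return {
        "manifest": {
            "seed": seed,
            "settings_hash": config.settings_hash(),
            "package_version": __version__,
            "n_features": len([c for c in table.columns if c.endswith(("_rho", "_cos", "_sin"))]),
        },
        "rca_eigenvalues": [float(v) for v in model.eigenvalues],
        "grid": grid_report,
        "stats": stats_report,
    }
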