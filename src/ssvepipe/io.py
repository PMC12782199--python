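"""Readers/writers for the cohort container and derived artifacts.

Layout of the hierarchical container (HDF5):

    /montage/positions   (n_channels, 3) float
    /montage/names       (n_channels,) str
    /subjects/<id>/eyes/<OD|OS>/<ON|OFF>/trials    (n_trials, ch, samples) float32, µV
    /subjects/<id>/eyes/<OD|OS>/<ON|OFF>/spectra   (n_trials, ch, H, bins) complex64  [optional]
    /subjects/<id>/eyes/<OD|OS>/<ON|OFF>/valid     (n_trials, bins, ch) bool          [optional]

Protocol parameters are JSON attributes of the root; demographics are
attributes of each subject group.  Feature tables are tab-separated text;
classifier results and reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .protocol import ProtocolConfig
from .simulate import CohortDataset, Montage, SensorTrial, SubjectDemographics
from .spectral import SpectraSet

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_spectra",
    "read_spectra",
    "read_protocol",
    "read_montage_h5",
    "read_demographics",
    "write_montage",
    "read_montage",
    "write_table",
    "read_table",
    "write_result",
    "read_result",
    "load_yaml_config",
]

FORMAT_VERSION = 1


def _demo_attrs(d: SubjectDemographics) -> dict:
    a = {"subject_id": d.subject_id, "group": d.group, "age": d.age, "sex": d.sex}
    if d.md_od is not None:
        a["md_od"] = d.md_od
    if d.md_os is not None:
        a["md_os"] = d.md_os
    return a


def write_cohort(cohort: CohortDataset, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["protocol"] = json.dumps(cohort.protocol.to_dict(), sort_keys=True)
        g = f.create_group("montage")
        g.create_dataset("positions", data=cohort.montage.positions)
        g.create_dataset("names", data=np.array(cohort.montage.names, dtype="S16"))
        subs = f.create_group("subjects")
        for demo in cohort.demographics:
            sg = subs.create_group(demo.subject_id)
            for k, v in _demo_attrs(demo).items():
                sg.attrs[k] = v
            eyes = sg.create_group("eyes")
            for eye in cohort.protocol.eyes:
                eg = eyes.create_group(eye)
                for cond in cohort.protocol.conditions:
                    trials = cohort.trials.get((demo.subject_id, eye, cond), [])
                    cg = eg.create_group(cond)
                    data = np.stack([t.data for t in trials]).astype(np.float32) if trials else np.zeros(
                        (0, cohort.protocol.n_channels, cohort.protocol.samples_per_trial), np.float32
                    )
                    cg.create_dataset("trials", data=data)


def _read_montage_group(f) -> Montage:
    pos = np.asarray(f["montage/positions"])
    names = tuple(n.decode() for n in f["montage/names"][()])
    return Montage(positions=pos, names=names)


def read_protocol(path) -> ProtocolConfig:
    with h5py.File(path, "r") as f:
        return ProtocolConfig.from_dict(json.loads(f.attrs["protocol"]))


def read_montage_h5(path) -> Montage:
    with h5py.File(path, "r") as f:
        return _read_montage_group(f)


def read_demographics(path) -> dict[str, SubjectDemographics]:
    out = {}
    with h5py.File(path, "r") as f:
        for sid, sg in f["subjects"].items():
            out[sid] = SubjectDemographics(
                subject_id=sid,
                group=sg.attrs["group"],
                age=float(sg.attrs["age"]),
                sex=sg.attrs["sex"],
                md_od=float(sg.attrs["md_od"]) if "md_od" in sg.attrs else None,
                md_os=float(sg.attrs["md_os"]) if "md_os" in sg.attrs else None,
            )
    return out


def read_cohort(path) -> CohortDataset:
    with h5py.File(path, "r") as f:
        if "format_version" not in f.attrs or "protocol" not in f.attrs:
            raise ValueError("not a cohort container: missing protocol/format_version attributes")
        protocol = ProtocolConfig.from_dict(json.loads(f.attrs["protocol"]))
        montage = _read_montage_group(f)
        demographics = []
        trials: dict[tuple[str, str, str], list[SensorTrial]] = {}
        for sid in sorted(f["subjects"]):
            sg = f["subjects"][sid]
            demographics.append(
                SubjectDemographics(
                    subject_id=sid, group=sg.attrs["group"], age=float(sg.attrs["age"]),
                    sex=sg.attrs["sex"],
                    md_od=float(sg.attrs["md_od"]) if "md_od" in sg.attrs else None,
                    md_os=float(sg.attrs["md_os"]) if "md_os" in sg.attrs else None,
                )
            )
            for eye, eg in sg["eyes"].items():
                for cond, cg in eg.items():
                    data = np.asarray(cg["trials"], dtype=float)
                    trials[(sid, eye, cond)] = [
                        SensorTrial(sid, eye, cond, i, data[i], float(protocol.sampling_rate_hz), montage)
                        for i in range(data.shape[0])
                    ]
        return CohortDataset(protocol=protocol, montage=montage, demographics=demographics, trials=trials)


def write_spectra(path, spectra: dict[tuple[str, str, str], SpectraSet]) -> None:
    """Append per-eye/condition spectra (and validity masks) to a container."""
    with h5py.File(path, "a") as f:
        for (sid, eye, cond), s in spectra.items():
            grp = f.require_group(f"subjects/{sid}/eyes/{eye}/{cond}")
            for name in ("spectra", "valid"):
                if name in grp:
                    del grp[name]
            grp.create_dataset("spectra", data=s.coefs.astype(np.complex64))
            grp.create_dataset("valid", data=s.valid)
            grp.attrs["frequencies"] = [float(x) for x in s.frequencies]


def read_spectra(path) -> dict[tuple[str, str, str], SpectraSet]:
    out = {}
    with h5py.File(path, "r") as f:
        for sid, sg in f["subjects"].items():
            for eye, eg in sg["eyes"].items():
                for cond, cg in eg.items():
                    if "spectra" not in cg:
                        continue
                    out[(sid, eye, cond)] = SpectraSet(
                        subject_id=sid, eye=eye, condition=cond,
                        coefs=np.asarray(cg["spectra"]).astype(complex),
                        valid=np.asarray(cg["valid"], dtype=bool),
                        frequencies=tuple(cg.attrs.get("frequencies", ())),
                    )
    return out


# --------------------------------------------------------------------------
# flat-text formats
# --------------------------------------------------------------------------

def write_montage(montage: Montage, path) -> None:
    df = pd.DataFrame(montage.positions, columns=["x", "y", "z"])
    df.insert(0, "channel", montage.names)
    df.to_csv(path, sep="\t", index=False)


def read_montage(path) -> Montage:
    df = pd.read_csv(path, sep="\t")
    for col in ("channel", "x", "y", "z"):
        if col not in df.columns:
            raise ValueError(f"montage file missing column {col!r}")
    return Montage(positions=df[["x", "y", "z"]].to_numpy(float), names=tuple(df["channel"]))


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    for col in ("subject_id", "eye", "label"):
        if col not in table.columns:
            raise ValueError(f"feature table missing column {col!r}")
    return table


def write_result(result: dict, path) -> None:
    Path(path).write_text(json.dumps(result, indent=2, sort_keys=True) + "\n")


def read_result(path) -> dict:
    text = Path(path).read_text()
    try:
        return json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"cannot parse result file {path}: {exc}") from exc


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg
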