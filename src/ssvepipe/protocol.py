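"""Stimulation/recording protocol description.

The stimulus flickers at an exact rational frequency (default 30/11 Hz,
printed as 2.727 Hz) so that every 1.1-s analysis bin contains an integer
number of stimulus cycles (3) — and therefore an integer number of cycles of
every harmonic.  Integer-cycle bins make the sine/cosine least-squares fit
leakage-free and exactly equivalent to the DFT at those frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence


def _as_fraction(x) -> Fraction:
    """Convert to an exact Fraction; floats go through their shortest decimal."""
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    if isinstance(x, float):
        return Fraction(str(x))
    if isinstance(x, str):
        return Fraction(x)
    raise TypeError(f"cannot interpret {x!r} as a rational number")


@dataclass(frozen=True)
class ProtocolConfig:
    """Trial structure shared by the simulator and the analysis chain.

    Parameters
    ----------
    stimulus_freq_hz
        Flicker frequency F. Stored as an exact rational; the default 30/11 Hz
        puts exactly 3 cycles in each 1.1-s bin.
    n_harmonics
        Number of harmonics 1F..nF analysed (default 4).
    trial_duration_s, bin_duration_s
        Trial length and analysis-bin length in seconds; the trial must hold
        an integer number of bins and each bin an integer number of cycles.
    sampling_rate_hz
        EEG sampling rate; bin length must be an integer sample count.
    n_trials_per_condition
        Trials per eye per condition (default 10).
    """

    stimulus_freq_hz: Fraction = Fraction(30, 11)
    n_harmonics: int = 4
    trial_duration_s: Fraction = Fraction(66, 5)  # 13.2 s
    bin_duration_s: Fraction = Fraction(11, 10)  # 1.1 s
    sampling_rate_hz: int = 500
    n_trials_per_condition: int = 10
    conditions: Sequence[str] = ("ON", "OFF")
    eyes: Sequence[str] = ("OD", "OS")
    n_channels: int = 128

    def __post_init__(self):
        object.__setattr__(self, "stimulus_freq_hz", _as_fraction(self.stimulus_freq_hz))
        object.__setattr__(self, "trial_duration_s", _as_fraction(self.trial_duration_s))
        object.__setattr__(self, "bin_duration_s", _as_fraction(self.bin_duration_s))
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")
        cycles = self.bin_duration_s * self.stimulus_freq_hz
        if cycles.denominator != 1:
            raise ValueError(
                f"bin_duration × stimulus_freq = {cycles} is not an integer cycle count"
            )
        nbins = self.trial_duration_s / self.bin_duration_s
        if nbins.denominator != 1:
            raise ValueError("trial_duration must be an integer number of bins")
        nsamp = self.bin_duration_s * self.sampling_rate_hz
        if nsamp.denominator != 1:
            raise ValueError("bin_duration × sampling_rate must be an integer sample count")

    @property
    def cycles_per_bin(self) -> int:
        return int(self.bin_duration_s * self.stimulus_freq_hz)

    @property
    def n_bins(self) -> int:
        return int(self.trial_duration_s / self.bin_duration_s)

    @property
    def samples_per_bin(self) -> int:
        return int(self.bin_duration_s * self.sampling_rate_hz)

    @property
    def samples_per_trial(self) -> int:
        return self.n_bins * self.samples_per_bin

    @property
    def harmonics(self) -> list[Fraction]:
        from .spectral import harmonic_set

        return harmonic_set(self.stimulus_freq_hz, self.n_harmonics)

    def to_dict(self) -> dict:
        return {
            "stimulus_freq_hz": str(self.stimulus_freq_hz),
            "n_harmonics": self.n_harmonics,
            "trial_duration_s": str(self.trial_duration_s),
            "bin_duration_s": str(self.bin_duration_s),
            "sampling_rate_hz": self.sampling_rate_hz,
            "n_trials_per_condition": self.n_trials_per_condition,
            "conditions": list(self.conditions),
            "eyes": list(self.eyes),
            "n_channels": self.n_channels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolConfig":
        d = dict(d)
        for key in ("stimulus_freq_hz", "trial_duration_s", "bin_duration_s"):
            if key in d:
                d[key] = _as_fraction(d[key])
        for key in ("conditions", "eyes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)
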