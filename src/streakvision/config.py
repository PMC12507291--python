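"""TOML run configuration.

A configuration file groups the physical parameters of a simulation:

    [stimulus]   cutoff_lo, cutoff_hi, aperture_sd, distance, ...
    [saccade]    amplitude_mean, duration_mean, vertical_bias_mean, ...
    [canvas]     pitch, rate, extent, scale_mode ("full" | "test")
    [bank]       theta0, w0, beta0
    [trf]        beta_ps, delta, rate
    [normalization]  tau_n, gl_sd, sigma_semi, exponent, pool_radius, ...
    [switch]     wi_ms, c

Any omitted key falls back to the study defaults.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields

from .normalization import NormalizationSpec
from .spatial import BankSpec
from .stimulus import FULL_SCALE, TEST_SCALE, SimulationScale

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    stimulus: dict = field(default_factory=dict)
    saccade: dict = field(default_factory=dict)
    canvas: dict = field(default_factory=dict)
    bank: dict = field(default_factory=dict)
    trf: dict = field(default_factory=dict)
    normalization: dict = field(default_factory=dict)
    switch: dict = field(default_factory=dict)
    seed: int = 0

    def scale(self) -> SimulationScale:
        mode = self.canvas.get("scale_mode", "full")
        base = TEST_SCALE if mode == "test" else FULL_SCALE
        return SimulationScale(
            pitch=self.canvas.get("pitch", base.pitch),
            rate=self.canvas.get("rate", base.rate),
            extent=tuple(self.canvas.get("extent", base.extent)))

    def bank_spec(self) -> BankSpec:
        kw = {k: v for k, v in self.bank.items()
              if k in {f.name for f in fields(BankSpec)}}
        if "sf_set" in kw:
            kw["sf_set"] = tuple(kw["sf_set"])
        if "ori_set" in kw:
            kw["ori_set"] = tuple(kw["ori_set"])
        return BankSpec(**kw)

    def normalization_spec(self) -> NormalizationSpec:
        kw = {k: v for k, v in self.normalization.items()
              if k in {f.name for f in fields(NormalizationSpec)}}
        return NormalizationSpec(**kw)


def load_config(path) -> RunConfig:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    known = {f.name for f in fields(RunConfig)}
    return RunConfig(**{k: v for k, v in raw.items() if k in known})
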