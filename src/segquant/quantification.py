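"""Water-referenced, tissue- and relaxation-corrected MRS quantification.

The molar concentration of a metabolite M observed in an MRS voxel is
computed from the ratio of the modeled metabolite and unsuppressed-water
signal amplitudes, corrected for the tissue composition of the voxel:

    [M] = (S_M / S_H2O)
          * (f_GM*d_GM*R_GM + f_WM*d_WM*R_WM + f_CSF*d_CSF*R_CSF)
          / ((1 - f_CSF) * R_M)
          * [H2O]

where f_x are the fractional volumes of gray matter, white matter and
CSF, d_x the compartment water densities, R_x = exp(-TE/T2)*(1-exp(-TR/T1))
the compartment-specific water relaxation attenuation, R_M the metabolite
relaxation attenuation (T1/T2 averaged over GM and WM), and [H2O] the
molar concentration of pure water.  The (1 - f_CSF) denominator excludes
CSF from the metabolite-bearing volume.

The number of protons per metabolite is assumed to be absorbed into the
modeled amplitude S_M by the fitting basis set; no proton-count division
is applied here.

``forward_signal`` is the algebraic inverse used by the synthetic-study
generator: given a true concentration and a composition, it produces the
signal amplitude that quantification would map back onto that
concentration exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any

from .voxel_anatomy import TissueFractions

__all__ = [
    "AcquisitionParams",
    "QuantConstants",
    "AttenuationFactors",
    "ObservedSignals",
    "ConcentrationEstimate",
    "attenuation_factor",
    "attenuation_from_config",
    "correction_factor",
    "molar_concentration",
    "forward_signal",
]


@dataclass(frozen=True)
class AcquisitionParams:
    """Echo and repetition time in seconds."""

    te_s: float
    tr_s: float

    def __post_init__(self) -> None:
        if not (0 < self.te_s < self.tr_s):
            raise ValueError(f"need 0 < TE < TR, got TE={self.te_s}, TR={self.tr_s}")

    @classmethod
    def from_ms(cls, te_ms: float, tr_ms: float) -> "AcquisitionParams":
        return cls(te_s=te_ms / 1000.0, tr_s=tr_ms / 1000.0)


@dataclass(frozen=True)
class QuantConstants:
    """Compartment water densities (unitless) and [H2O] in mol/L."""

    d_gm: float = 0.78
    d_wm: float = 0.65
    d_csf: float = 0.97
    h2o_molar: float = 55.51

    def __post_init__(self) -> None:
        for name in ("d_gm", "d_wm", "d_csf"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name}={v} outside (0,1]")
        if self.h2o_molar <= 0:
            raise ValueError("h2o_molar must be positive")


@dataclass(frozen=True)
class AttenuationFactors:
    """Relaxation attenuation for water per compartment and the metabolite."""

    r_h2o_gm: float
    r_h2o_wm: float
    r_h2o_csf: float
    r_met: float

    def __post_init__(self) -> None:
        for name in ("r_h2o_gm", "r_h2o_wm", "r_h2o_csf", "r_met"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name}={v} outside (0,1)")


@dataclass(frozen=True)
class ObservedSignals:
    """Modeled metabolite and water amplitudes in matching arbitrary units."""

    s_met: float
    s_h2o: float

    def __post_init__(self) -> None:
        if self.s_h2o <= 0:
            raise ValueError("water signal must be positive")
        if self.s_met < 0:
            raise ValueError("metabolite signal must be nonnegative")


@dataclass(frozen=True)
class ConcentrationEstimate:
    metabolite: str
    molar_mM: float


def attenuation_factor(t1_s: float, t2_s: float, acq: AcquisitionParams) -> float:
    """Exponential relaxation attenuation R = exp(-TE/T2)*(1-exp(-TR/T1))."""
    if t1_s <= 0 or t2_s <= 0:
        raise ValueError("relaxation times must be positive")
    return math.exp(-acq.te_s / t2_s) * (1.0 - math.exp(-acq.tr_s / t1_s))


def attenuation_from_config(
    cfg: dict[str, Any], metabolite: str = "tCr"
) -> tuple[AttenuationFactors, AcquisitionParams, QuantConstants]:
    """Resolve attenuation factors and constants from a quant config dict."""
    acq = AcquisitionParams.from_ms(
        cfg["acquisition"]["te_ms"], cfg["acquisition"]["tr_ms"]
    )
    wr = cfg["water_relaxation"]
    if metabolite not in cfg["metabolite_relaxation"]:
        raise KeyError(f"no relaxation entry for metabolite {metabolite!r}")
    mr = cfg["metabolite_relaxation"][metabolite]
    att = AttenuationFactors(
        r_h2o_gm=attenuation_factor(wr["gm"]["t1_s"], wr["gm"]["t2_s"], acq),
        r_h2o_wm=attenuation_factor(wr["wm"]["t1_s"], wr["wm"]["t2_s"], acq),
        r_h2o_csf=attenuation_factor(wr["csf"]["t1_s"], wr["csf"]["t2_s"], acq),
        r_met=attenuation_factor(mr["t1_s"], mr["t2_s"], acq),
    )
    d = cfg["densities"]
    k = QuantConstants(
        d_gm=d["gm"], d_wm=d["wm"], d_csf=d["csf"], h2o_molar=cfg["h2o_molar"]
    )
    return att, acq, k


def correction_factor(
    f: TissueFractions, att: AttenuationFactors, k: QuantConstants
) -> float:
    """Water-side tissue-and-relaxation correction.

    (f_GM*d_GM*R_GM + f_WM*d_WM*R_WM + f_CSF*d_CSF*R_CSF) / (1 - f_CSF).
    The concentration is (S_M/S_H2O) * correction_factor / R_M * [H2O].
    """
    if f.f_csf >= 1 - 1e-9:
        raise ValueError("no metabolite-bearing tissue: f_csf >= 1")
    num = (
        f.f_gm * k.d_gm * att.r_h2o_gm
        + f.f_wm * k.d_wm * att.r_h2o_wm
        + f.f_csf * k.d_csf * att.r_h2o_csf
    )
    return num / (1.0 - f.f_csf)


def molar_concentration(
    sig: ObservedSignals,
    f: TissueFractions,
    att: AttenuationFactors,
    k: QuantConstants,
    metabolite: str = "tCr",
) -> ConcentrationEstimate:
    """Tissue- and relaxation-corrected molar concentration in mM."""
    cf = correction_factor(f, att, k)
    molar = (sig.s_met / sig.s_h2o) * cf / att.r_met * k.h2o_molar
    return ConcentrationEstimate(metabolite=metabolite, molar_mM=molar * 1000.0)


def forward_signal(
    true_mM: float,
    f: TissueFractions,
    att: AttenuationFactors,
    k: QuantConstants,
    s_h2o: float,
) -> ObservedSignals:
    """Metabolite amplitude that quantifies back to ``true_mM`` exactly."""
    if true_mM < 0:
        raise ValueError("concentration must be nonnegative")
    if s_h2o <= 0:
        raise ValueError("water signal must be positive")
    cf = correction_factor(f, att, k)
    s_met = (true_mM / 1000.0) / k.h2o_molar * att.r_met / cf * s_h2o
    return ObservedSignals(s_met=s_met, s_h2o=s_h2o)
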