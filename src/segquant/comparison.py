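"""Percent-difference and sensitivity summaries of segmentation propagation.

Quantifies how much metabolite concentration estimates move (a) between
test-retest sessions within one segmentation method and (b) between
segmentation methods, plus the local sensitivity of the concentration to
the CSF fraction.  Percent differences use the symmetric pair-mean
denominator, 100*|a-b| / ((a+b)/2), unless a signed variant is requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quantification import AttenuationFactors, QuantConstants, correction_factor
from .voxel_anatomy import TissueFractions

__all__ = [
    "PercentDifferenceRecord",
    "session_percent_change",
    "between_method_percent_difference",
    "group_percent_difference",
    "pairwise_method_deltas",
    "csf_sensitivity",
    "csf_sensitivity_analytic",
]


@dataclass(frozen=True)
class PercentDifferenceRecord:
    scope: str  # "within_method_between_sessions" | "between_methods"
    labels: tuple[str, ...]
    metabolite: str
    value_pct: float
    dispersion: float  # SD across participants (nan for group-level)
    n: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.value_pct):
            raise ValueError("percent difference must be finite")
        if self.scope == "between_methods" and len(set(self.labels)) < 2:
            raise ValueError("between-method record needs two distinct methods")


def _pair_pct(a: np.ndarray, b: np.ndarray, signed: bool) -> np.ndarray:
    mean = (a + b) / 2.0
    if np.any(mean <= 0):
        raise ValueError("nonpositive pair mean in percent-difference denominator")
    diff = (b - a) if signed else np.abs(b - a)
    return 100.0 * diff / mean


def session_percent_change(
    table: pd.DataFrame,
    method: str,
    metabolite: str = "tCr",
    value_col: str = "conc_mM",
    signed: bool = False,
) -> PercentDifferenceRecord:
    """Per-participant percent change between sessions 1 and 2 for one method.

    ``table`` is the long-format study table; the record holds the mean
    and SD across participants of 100*|c2-c1|/pair-mean.
    """
    sub = table[(table["method"] == method) & (table["metabolite"] == metabolite)]
    wide = sub.pivot(index="participant", columns="session", values=value_col)
    if wide.shape[1] != 2 or wide.isna().any().any():
        raise ValueError(f"unpaired sessions for method {method!r}")
    sessions = sorted(wide.columns)
    pct = _pair_pct(wide[sessions[0]].values, wide[sessions[1]].values, signed)
    return PercentDifferenceRecord(
        scope="within_method_between_sessions",
        labels=(method,),
        metabolite=metabolite,
        value_pct=float(pct.mean()),
        dispersion=float(pct.std(ddof=1)) if len(pct) > 1 else float("nan"),
        n=len(pct),
    )


def between_method_percent_difference(
    table: pd.DataFrame,
    method_a: str,
    method_b: str,
    metabolite: str = "tCr",
    value_col: str = "conc_mM",
) -> PercentDifferenceRecord:
    """Percent difference between two methods on session-averaged values.

    Concentrations are first averaged across sessions per participant
    and method; the per-participant percent difference between the two
    methods is then summarized as mean +/- SD.
    """
    if method_a == method_b:
        raise ValueError("methods must differ")
    sub = table[
        table["method"].isin([method_a, method_b])
        & (table["metabolite"] == metabolite)
    ]
    avg = (
        sub.groupby(["participant", "method"])[value_col].mean().unstack("method")
    )
    if avg.shape[1] != 2 or avg.isna().any().any():
        raise ValueError(f"missing method data for pair ({method_a}, {method_b})")
    pct = _pair_pct(avg[method_a].values, avg[method_b].values, signed=False)
    return PercentDifferenceRecord(
        scope="between_methods",
        labels=(method_a, method_b),
        metabolite=metabolite,
        value_pct=float(pct.mean()),
        dispersion=float(pct.std(ddof=1)) if len(pct) > 1 else float("nan"),
        n=len(pct),
    )


def group_percent_difference(
    mean_a: float, mean_b: float, labels: tuple[str, str] = ("A", "B"),
    metabolite: str = "tCr",
) -> PercentDifferenceRecord:
    """Group-level variant: percent difference of two method means."""
    pct = _pair_pct(np.array([mean_a]), np.array([mean_b]), signed=False)[0]
    return PercentDifferenceRecord(
        scope="between_methods",
        labels=labels,
        metabolite=metabolite,
        value_pct=float(pct),
        dispersion=float("nan"),
        n=1,
    )


def pairwise_method_deltas(means: dict[str, float]) -> pd.DataFrame:
    """Differences of method marginal means for every canonical pair.

    Pairs are ordered alphabetically within and across pairs
    (e.g. ANTS-FSL, ANTS-SPM, FSL-SPM); estimate = mean_A - mean_B.
    """
    if len(means) < 2:
        raise ValueError("need at least two methods")
    methods = sorted(means)
    rows = [
        {"pair": f"{a} - {b}", "estimate": means[a] - means[b]}
        for i, a in enumerate(methods)
        for b in methods[i + 1 :]
    ]
    return pd.DataFrame(rows)


def _cf_at_csf(
    f_csf: float, gm_share: float, att: AttenuationFactors, k: QuantConstants
) -> float:
    f = TissueFractions(
        f_gm=(1 - f_csf) * gm_share,
        f_wm=(1 - f_csf) * (1 - gm_share),
        f_csf=f_csf,
    )
    return correction_factor(f, att, k)


def csf_sensitivity(
    f: TissueFractions,
    att: AttenuationFactors,
    k: QuantConstants,
    conc_mM: float,
    delta: float = 1e-4,
) -> float:
    """d[M]/df_CSF (mM per unit fraction) at fixed signals.

    Central finite difference of the concentration with respect to
    f_CSF, holding the GM:WM ratio fixed (the perturbed composition
    stays on the simplex).  ``conc_mM`` is the concentration at ``f``;
    the concentration scales linearly with the correction factor at
    fixed signals, so d[M]/df = [M] * (dCF/df)/CF.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if f.f_csf + delta >= 1 or f.f_csf - delta < 0:
        raise ValueError("perturbation leaves the simplex")
    tissue = f.f_gm + f.f_wm
    if tissue <= 0:
        raise ValueError("no GM/WM tissue to hold the ratio of")
    gm_share = f.f_gm / tissue
    cf0 = correction_factor(f, att, k)
    cf_plus = _cf_at_csf(f.f_csf + delta, gm_share, att, k)
    cf_minus = _cf_at_csf(f.f_csf - delta, gm_share, att, k)
    dcf = (cf_plus - cf_minus) / (2 * delta)
    return conc_mM * dcf / cf0


def csf_sensitivity_analytic(
    f: TissueFractions,
    att: AttenuationFactors,
    k: QuantConstants,
    conc_mM: float,
) -> float:
    """Closed-form d[M]/df_CSF with the GM:WM ratio held fixed.

    With g = f_GM/(f_GM+f_WM), the numerator is
    (1-f_csf)*(g*d_GM*R_GM + (1-g)*d_WM*R_WM) + f_csf*d_CSF*R_CSF, so
    CF(f_csf) = tissue_term + f_csf/(1-f_csf)*d_CSF*R_CSF and
    dCF/df_csf = d_CSF*R_CSF/(1-f_csf)^2.
    """
    tissue = f.f_gm + f.f_wm
    if tissue <= 0:
        raise ValueError("no GM/WM tissue to hold the ratio of")
    cf0 = correction_factor(f, att, k)
    dcf = k.d_csf * att.r_h2o_csf / (1.0 - f.f_csf) ** 2
    return conc_mM * dcf / cf0
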