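"""Inference battery for the test-retest segmentation-comparison design.

The design is complete and balanced: every participant is measured in 2
sessions, and each session's data are analysed with each segmentation
method, giving one observation per participant x method x session cell.
The Method*Session model with a participant random intercept is, on this
design, exactly equivalent to the classical balanced repeated-measures
ANOVA: the three whole-plot strata (participant x method, participant x
session, participant x method x session) pool into a single
within-participant error stratum with (n-1)(ms-1) degrees of freedom,
which is the denominator for all fixed-effect F tests and for the Tukey
HSD pairwise contrasts.  Incomplete or unbalanced tables are rejected
rather than approximated, keeping every result deterministic and
checkable against a brute-force linear-model oracle.

Also provides the Shapiro-Wilk normality screen, Bonferroni-corrected
paired session t-tests, Pearson age associations, and Steiger's Z test
for dependent correlations sharing a common variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .voxel_anatomy import TissueFractions

__all__ = [
    "AnovaFixedEffect",
    "MarginalMean",
    "PairwiseContrast",
    "CorrelationResult",
    "SteigerResult",
    "MethodSessionFit",
    "shapiro_normality_screen",
    "paired_session_test",
    "method_session_model",
    "tukey_pairwise",
    "normalized_gm",
    "pearson_association",
    "steiger_dependent_z",
]


@dataclass(frozen=True)
class AnovaFixedEffect:
    term: str  # "Method" | "Session" | "Method:Session"
    df_num: int
    df_den: int
    F: float
    p: float


@dataclass(frozen=True)
class MarginalMean:
    factor: str  # "Method" | "Session"
    level: str
    mean: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class PairwiseContrast:
    pair: str
    estimate: float
    se: float
    df: int
    t_ratio: float
    p_adjusted: float


@dataclass(frozen=True)
class CorrelationResult:
    pair: str
    r: float
    r_squared: float
    p: float
    n: int


@dataclass(frozen=True)
class SteigerResult:
    comparison: str
    z: float
    p: float


@dataclass(frozen=True)
class MethodSessionFit:
    """Fitted balanced Method x Session repeated-measures model."""

    response: str
    methods: tuple[str, ...]
    sessions: tuple[str, ...]
    n_participants: int
    anova: tuple[AnovaFixedEffect, ...]
    marginal_means: tuple[MarginalMean, ...]
    method_means: dict[str, float]
    ms_error: float
    df_error: int


def shapiro_normality_screen(
    table: pd.DataFrame,
    value_col: str,
    group_cols: tuple[str, ...] = ("metabolite", "method", "session"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Shapiro-Wilk test per group with a Bonferroni-corrected threshold.

    The familywise threshold is alpha/m with m = number of groups; a
    group "passes" (no detected departure from normality) when its raw
    p-value exceeds that threshold.  Constant-valued groups are flagged
    rather than tested.
    """
    groups = list(table.groupby(list(group_cols)))
    m = len(groups)
    if m == 0:
        raise ValueError("no groups to screen")
    rows = []
    for key, sub in groups:
        vals = np.asarray(sub[value_col], float)
        if len(vals) < 3:
            raise ValueError(f"group {key} too small for Shapiro-Wilk (n={len(vals)})")
        if np.ptp(vals) == 0:
            rows.append(dict(zip(group_cols, key)) | {
                "n": len(vals), "W": np.nan, "p_raw": np.nan,
                "pass_after_correction": False, "constant": True,
            })
            continue
        W, p = stats.shapiro(vals)
        rows.append(dict(zip(group_cols, key)) | {
            "n": len(vals), "W": float(W), "p_raw": float(p),
            "pass_after_correction": bool(p > alpha / m), "constant": False,
        })
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_m"] = m
    out.attrs["alpha"] = alpha
    return out


def paired_session_test(
    values_s1, values_s2, bonferroni_m: int = 3
) -> tuple[float, float]:
    """Paired t-test between sessions; p multiplied by m, capped at 1."""
    a = np.asarray(values_s1, float)
    b = np.asarray(values_s2, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("sessions must be paired 1-D arrays of equal length")
    if len(a) < 2:
        raise ValueError("need at least two pairs")
    d = b - a
    if np.allclose(d, d[0]) and not np.allclose(d, 0):
        raise ValueError("zero-variance nonzero differences: t undefined")
    if np.allclose(d, 0):
        return 0.0, 1.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(min(1.0, p * bonferroni_m))


def _balanced_anova_arrays(
    y: np.ndarray, part: np.ndarray, meth: np.ndarray, sess: np.ndarray
) -> dict:
    """Sums-of-squares decomposition for the balanced one-obs-per-cell design.

    Index arrays are dense integer codes.  Returns F statistics for
    Method, Session and their interaction against the pooled
    within-participant error stratum.
    """
    n = part.max() + 1
    m = meth.max() + 1
    s = sess.max() + 1
    if len(y) != n * m * s:
        raise ValueError("unbalanced design: expected one observation per cell")
    # One observation per (participant, method, session) cell.
    cell = np.full((n, m, s), np.nan)
    cell[part, meth, sess] = y
    if np.isnan(cell).any():
        raise ValueError("unbalanced design: missing participant x method x session cells")
    g = cell.mean()
    p_means = cell.mean(axis=(1, 2))
    m_means = cell.mean(axis=(0, 2))
    s_means = cell.mean(axis=(0, 1))
    ms_means = cell.mean(axis=0)
    ss_p = m * s * np.sum((p_means - g) ** 2)
    ss_m = n * s * np.sum((m_means - g) ** 2)
    ss_s = n * m * np.sum((s_means - g) ** 2)
    ss_ms = n * np.sum(
        (ms_means - m_means[:, None] - s_means[None, :] + g) ** 2
    )
    ss_tot = np.sum((cell - g) ** 2)
    ss_e = ss_tot - ss_p - ss_m - ss_s - ss_ms
    df_e = (n - 1) * (m * s - 1)
    ms_e = ss_e / df_e
    ms_p = ss_p / (n - 1)

    def ftest(ss, df):
        if ms_e <= 1e-12 * max(ss_tot, 1.0):
            # noise-free fixture: F is 0 or infinite, not 0/0
            if ss <= 1e-12 * max(ss_tot, 1.0):
                return 0.0, 1.0
            return float("inf"), 0.0
        F = (ss / df) / ms_e
        return F, float(stats.f.sf(F, df, df_e))

    f_m, p_m = ftest(ss_m, m - 1)
    f_s, p_s = ftest(ss_s, s - 1)
    f_ms, p_ms = ftest(ss_ms, (m - 1) * (s - 1))
    return {
        "n": n, "m": m, "s": s,
        "F": (f_m, f_s, f_ms), "p": (p_m, p_s, p_ms),
        "df_num": (m - 1, s - 1, (m - 1) * (s - 1)),
        "df_e": df_e, "ms_e": ms_e, "ms_p": ms_p,
        "m_means": m_means, "s_means": s_means, "grand": g,
    }


def method_session_model(
    table: pd.DataFrame,
    response: str,
    participant_col: str = "participant",
    method_col: str = "method",
    session_col: str = "session",
) -> MethodSessionFit:
    """Fit the Method x Session model with a participant random intercept.

    Requires the complete balanced design (every participant x method x
    session exactly once).  Fixed effects are tested against the pooled
    within-participant error stratum; marginal means are cell means
    averaged over the other factor, with 95% CIs from the model's
    variance components.
    """
    df = table[[participant_col, method_col, session_col, response]].copy()
    if df[response].isna().any():
        raise ValueError(f"missing values in response {response!r}")
    parts, part_idx = np.unique(df[participant_col], return_inverse=True)
    meths, meth_idx = np.unique(df[method_col].astype(str), return_inverse=True)
    sess, sess_idx = np.unique(df[session_col].astype(str), return_inverse=True)
    if len(meths) < 2 or len(sess) != 2:
        raise ValueError("need >=2 methods and exactly 2 sessions")
    counts = pd.crosstab(
        df[participant_col], [df[method_col], df[session_col]]
    ).values
    if counts.shape[1] != len(meths) * len(sess) or not np.all(counts == 1):
        raise ValueError("unbalanced design: every participant x method x session "
                         "cell must appear exactly once")
    res = _balanced_anova_arrays(
        df[response].to_numpy(float), part_idx, meth_idx, sess_idx
    )
    n, m, s = res["n"], res["m"], res["s"]
    anova = tuple(
        AnovaFixedEffect(term, dfn, res["df_e"], float(F), float(p))
        for term, dfn, F, p in zip(
            ("Method", "Session", "Method:Session"),
            res["df_num"], res["F"], res["p"],
        )
    )
    # EMM variance: participant variance + residual, averaged over the
    # replicates contributing to each marginal mean.
    sigma_u2 = max(0.0, (res["ms_p"] - res["ms_e"]) / (m * s))
    tcrit = stats.t.ppf(0.975, res["df_e"])
    emms = []
    se_m = np.sqrt(sigma_u2 / n + res["ms_e"] / (n * s))
    for level, mean in zip(meths, res["m_means"]):
        emms.append(MarginalMean("Method", str(level), float(mean),
                                 float(mean - tcrit * se_m),
                                 float(mean + tcrit * se_m)))
    se_s = np.sqrt(sigma_u2 / n + res["ms_e"] / (n * m))
    for level, mean in zip(sess, res["s_means"]):
        emms.append(MarginalMean("Session", str(level), float(mean),
                                 float(mean - tcrit * se_s),
                                 float(mean + tcrit * se_s)))
    return MethodSessionFit(
        response=response,
        methods=tuple(str(x) for x in meths),
        sessions=tuple(str(x) for x in sess),
        n_participants=int(n),
        anova=anova,
        marginal_means=tuple(emms),
        method_means={str(l): float(v) for l, v in zip(meths, res["m_means"])},
        ms_error=float(res["ms_e"]),
        df_error=int(res["df_e"]),
    )


def tukey_pairwise(fit: MethodSessionFit) -> list[PairwiseContrast]:
    """Tukey-HSD all-pairs method contrasts from the fitted model.

    estimate = difference of marginal means; SE = sqrt(2*MSE/(n*s))
    (the participant intercept cancels in within-participant
    contrasts); p adjusted via the studentized-range distribution with
    the model's error df.
    """
    methods = sorted(fit.method_means)
    k = len(methods)
    if k < 2:
        raise ValueError("need at least two method levels")
    n_rep = fit.n_participants * len(fit.sessions)
    se = float(np.sqrt(2.0 * fit.ms_error / n_rep))
    out = []
    for i, a in enumerate(methods):
        for b in methods[i + 1 :]:
            est = fit.method_means[a] - fit.method_means[b]
            t = est / se
            q = abs(t) * np.sqrt(2.0)
            p = float(stats.studentized_range.sf(q, k, fit.df_error))
            out.append(PairwiseContrast(
                pair=f"{a} - {b}", estimate=float(est), se=se,
                df=fit.df_error, t_ratio=float(t),
                p_adjusted=float(min(1.0, p)),
            ))
    return out


def normalized_gm(f: TissueFractions) -> float:
    """CSF-independent gray-matter content: f_GM / (f_GM + f_WM)."""
    denom = f.f_gm + f.f_wm
    if denom <= 0:
        raise ValueError("f_gm + f_wm must be positive")
    return f.f_gm / denom


def pearson_association(x, y, pair: str = "x~y") -> CorrelationResult:
    """Pearson r, r^2 and two-sided p for two paired samples."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need paired 1-D samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(pair=pair, r=float(r), r_squared=float(r) ** 2,
                             p=float(p), n=len(x))


def steiger_dependent_z(
    r_xy: float, r_xz: float, r_yz: float, n: int,
    comparison: str = "r_xy vs r_xz",
) -> SteigerResult:
    """Steiger's Z for two dependent correlations sharing variable x.

    Compares r_xy against r_xz accounting for r_yz, the correlation
    between the two non-shared variables (Steiger 1980, Z1* with pooled
    r-bar).  Two-sided p from the standard normal.  Antisymmetric in the
    two compared correlations.
    """
    for r in (r_xy, r_xz, r_yz):
        if not -1 < r < 1:
            raise ValueError("correlations must lie strictly in (-1, 1)")
    if n < 4:
        raise ValueError("need n >= 4")
    z1 = np.arctanh(r_xy)
    z2 = np.arctanh(r_xz)
    rbar = (r_xy + r_xz) / 2.0
    cov = (
        r_yz * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r_yz**2)
    ) / (1 - rbar**2) ** 2
    z = (z1 - z2) * np.sqrt((n - 3) / (2.0 * (1.0 - cov)))
    p = 2.0 * stats.norm.sf(abs(z))
    return SteigerResult(comparison=comparison, z=float(z), p=float(min(1.0, p)))
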