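"""Table-level drivers tying quantification and statistics together.

The interchange format is a long-format CSV with one row per
participant x session x method x metabolite.  ``quantify_table`` adds
the tissue-corrected concentration column; ``analyze_study`` runs the
full inference battery and returns a JSON-serializable report.
"""

from __future__ import annotations

from itertools import combinations
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .comparison import (
    between_method_percent_difference,
    group_percent_difference,
    pairwise_method_deltas,
    session_percent_change,
)
from .quantification import (
    ObservedSignals,
    attenuation_from_config,
    molar_concentration,
)
from .study_stats import (
    method_session_model,
    normalized_gm,
    pearson_association,
    shapiro_normality_screen,
    steiger_dependent_z,
    tukey_pairwise,
)
from .voxel_anatomy import TissueFractions

__all__ = [
    "REQUIRED_QUANT_COLUMNS",
    "read_study_csv",
    "quantify_table",
    "analyze_study",
]

REQUIRED_QUANT_COLUMNS = (
    "participant", "session", "method", "metabolite",
    "s_met", "s_h2o", "f_gm", "f_wm", "f_csf",
)


def read_study_csv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    """Read the long-format study CSV, checking the schema."""
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"study CSV missing column(s): {', '.join(missing)}")
    return df


def quantify_table(
    table: pd.DataFrame,
    quant_cfg: dict[str, Any],
    fraction_cols: tuple[str, str, str] = ("f_gm", "f_wm", "f_csf"),
    out_col: str = "conc_mM",
) -> pd.DataFrame:
    """Add tissue- and relaxation-corrected concentrations per row."""
    missing = [c for c in (*fraction_cols, "s_met", "s_h2o", "metabolite")
               if c not in table.columns]
    if missing:
        raise ValueError(f"study CSV missing column(s): {', '.join(missing)}")
    out = table.copy()
    conc = np.empty(len(out))
    atts = {
        met: attenuation_from_config(quant_cfg, metabolite=met)
        for met in out["metabolite"].unique()
    }
    for pos, (_, row) in enumerate(out.iterrows()):
        att, _, k = atts[row["metabolite"]]
        f = TissueFractions(*(float(row[c]) for c in fraction_cols))
        sig = ObservedSignals(s_met=float(row["s_met"]), s_h2o=float(row["s_h2o"]))
        conc[pos] = molar_concentration(
            sig, f, att, k, metabolite=row["metabolite"]
        ).molar_mM
    out[out_col] = conc
    return out


def _session_means(table: pd.DataFrame, value_col: str) -> pd.DataFrame:
    """Per participant x method means across sessions (keeps age)."""
    return (
        table.groupby(["participant", "method"], as_index=False)
        .agg(age=("age", "mean"), value=(value_col, "mean"))
    )


def _age_correlations(
    table: pd.DataFrame, value_col: str, label: str
) -> tuple[list[dict], list[dict]]:
    """Per-method age correlations plus Steiger comparisons between methods."""
    methods = sorted(table["method"].unique())
    means = _session_means(table, value_col)
    wide = means.pivot(index="participant", columns="method", values="value")
    ages = means.groupby("participant")["age"].first().loc[wide.index]
    correlations, steiger = [], []
    rs = {}
    for mth in methods:
        res = pearson_association(ages, wide[mth], pair=f"age ~ {label} ({mth})")
        rs[mth] = res.r
        correlations.append(res.__dict__)
    n = len(ages)
    for a, b in combinations(methods, 2):
        r_ab = float(np.corrcoef(wide[a], wide[b])[0, 1])
        res = steiger_dependent_z(
            rs[a], rs[b], r_ab, n, comparison=f"{label}: age~{a} vs age~{b}"
        )
        steiger.append(res.__dict__)
    return correlations, steiger


def analyze_study(
    table: pd.DataFrame,
    conc_col: str = "conc_mM",
    run_normality: bool = True,
) -> dict[str, Any]:
    """Run the full inference battery on a quantified study table.

    Returns a nested dict: normality screen, Method x Session models
    (tissue fractions and each metabolite's concentration) with ANOVA
    tables, marginal means and Tukey contrasts, age correlations with
    Steiger comparisons, and within/between-method percent differences.
    """
    report: dict[str, Any] = {}
    metabolites = sorted(table["metabolite"].unique())
    methods = sorted(table["method"].unique())

    if run_normality:
        screen = shapiro_normality_screen(table, value_col=conc_col)
        report["normality"] = {
            "bonferroni_m": screen.attrs["bonferroni_m"],
            "groups": screen.to_dict(orient="records"),
        }

    # Tissue-fraction models use method/session rows once per metabolite.
    frac_table = table[table["metabolite"] == metabolites[0]]
    models: dict[str, Any] = {}
    for resp in ("f_gm", "f_wm", "f_csf"):
        fit = method_session_model(frac_table, resp)
        models[resp] = _fit_to_dict(fit)
    for met in metabolites:
        sub = table[table["metabolite"] == met]
        fit = method_session_model(sub, conc_col)
        models[f"conc:{met}"] = _fit_to_dict(fit)
    report["models"] = models

    # Age associations: normalized GM per method, concentration per method.
    gm_table = frac_table.copy()
    gm_table["norm_gm"] = [
        normalized_gm(TissueFractions(r.f_gm, r.f_wm, r.f_csf))
        for r in frac_table.itertuples()
    ]
    corr_gm, steiger_gm = _age_correlations(gm_table, "norm_gm", "normalized GM")
    report["age_normalized_gm"] = {"correlations": corr_gm, "steiger": steiger_gm}
    conc_assoc = {}
    for met in metabolites:
        sub = table[table["metabolite"] == met]
        corr_c, steiger_c = _age_correlations(sub, conc_col, met)
        conc_assoc[met] = {"correlations": corr_c, "steiger": steiger_c}
    report["age_concentration"] = conc_assoc

    # Percent differences (within-method across sessions, between methods).
    pct = []
    for met in metabolites:
        for mth in methods:
            rec = session_percent_change(table, mth, metabolite=met,
                                         value_col=conc_col)
            pct.append(_pct_to_dict(rec))
        fit = method_session_model(
            table[table["metabolite"] == met], conc_col
        )
        for a, b in combinations(methods, 2):
            rec = between_method_percent_difference(
                table, a, b, metabolite=met, value_col=conc_col
            )
            pct.append(_pct_to_dict(rec))
            grp = group_percent_difference(
                fit.method_means[a], fit.method_means[b], labels=(a, b),
                metabolite=met,
            )
            grp_d = _pct_to_dict(grp)
            grp_d["scope"] = "between_methods_group_means"
            pct.append(grp_d)
    report["percent_differences"] = pct

    # Marginal-mean deltas per response, canonical pair order.
    deltas = {}
    for name, fit_d in models.items():
        means = {m["level"]: m["mean"] for m in fit_d["marginal_means"]
                 if m["factor"] == "Method"}
        deltas[name] = pairwise_method_deltas(means).to_dict(orient="records")
    report["method_mean_deltas"] = deltas
    return _to_builtin(report)


def _to_builtin(obj):
    """Recursively convert numpy scalars so the report JSON-serializes."""
    if isinstance(obj, dict):
        return {_to_builtin(k): _to_builtin(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_builtin(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def _fit_to_dict(fit) -> dict[str, Any]:
    return {
        "response": fit.response,
        "n_participants": fit.n_participants,
        "anova": [a.__dict__ for a in fit.anova],
        "marginal_means": [m.__dict__ for m in fit.marginal_means],
        "tukey": [c.__dict__ for c in tukey_pairwise(fit)],
        "ms_error": fit.ms_error,
        "df_error": fit.df_error,
    }


def _pct_to_dict(rec) -> dict[str, Any]:
    d = rec.__dict__.copy()
    d["labels"] = list(d["labels"])
    return d
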