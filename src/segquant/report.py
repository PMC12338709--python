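"""Markdown report generation from a stats report dict.

Deterministic ordering (methods alphabetical, pairs canonical) and
2-decimal formatting throughout, so identical inputs give byte-identical
reports.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

__all__ = ["write_report", "render_report"]


def _fmt(x: float, nd: int = 2) -> str:
    return f"{x:.{nd}f}"


def _fmt_p(p: float) -> str:
    return "< 0.0001" if p < 1e-4 else f"{p:.4f}"


def _contrast_table(contrasts: list[dict]) -> list[str]:
    lines = [
        "| PAIR | ESTIMATE | SE | DF | T-RATIO | P-VALUE |",
        "|---|---|---|---|---|---|",
    ]
    for c in sorted(contrasts, key=lambda c: c["pair"]):
        lines.append(
            f"| {c['pair']} | {_fmt(c['estimate'])} | {_fmt(c['se'])} | "
            f"{c['df']} | {_fmt(c['t_ratio'])} | {_fmt_p(c['p_adjusted'])} |"
        )
    return lines


def render_report(report: dict[str, Any], provenance: dict[str, Any]) -> str:
    """Render the stats report as markdown."""
    if not report.get("models"):
        raise ValueError("empty stats report: nothing to render")
    lines = ["# Segmentation propagation report", ""]
    lines += [
        "Provenance: "
        + ", ".join(f"{k}={v}" for k, v in sorted(provenance.items())),
        "",
    ]
    for name in sorted(report["models"]):
        model = report["models"][name]
        lines += [f"## Model: {model['response']} ({name})", ""]
        lines += [
            "| TERM | DF | DF_DEN | F | P |",
            "|---|---|---|---|---|",
        ]
        for a in model["anova"]:
            lines.append(
                f"| {a['term']} | {a['df_num']} | {a['df_den']} | "
                f"{_fmt(a['F'])} | {_fmt_p(a['p'])} |"
            )
        lines += ["", "Estimated marginal means (95% CI):", ""]
        for m in model["marginal_means"]:
            lines.append(
                f"- {m['factor']} {m['level']}: {_fmt(m['mean'])} "
                f"[{_fmt(m['ci_low'])}, {_fmt(m['ci_high'])}]"
            )
        lines += ["", "Tukey-adjusted pairwise method comparisons:", ""]
        lines += _contrast_table(model["tukey"])
        lines.append("")
    if "percent_differences" in report:
        lines += ["## Percent differences", "",
                  "| SCOPE | LABELS | METABOLITE | MEAN % | SD % |",
                  "|---|---|---|---|---|"]
        for rec in report["percent_differences"]:
            sd = rec.get("dispersion")
            sd_s = _fmt(sd) if sd == sd else "-"  # NaN-safe
            lines.append(
                f"| {rec['scope']} | {' vs '.join(rec['labels'])} | "
                f"{rec['metabolite']} | {_fmt(rec['value_pct'])} | {sd_s} |"
            )
        lines.append("")
    if "age_normalized_gm" in report:
        lines += ["## Age associations (normalized GM)", ""]
        for c in report["age_normalized_gm"]["correlations"]:
            lines.append(
                f"- {c['pair']}: r = {_fmt(c['r'])}, r^2 = {_fmt(c['r_squared'])}, "
                f"p = {_fmt_p(c['p'])}, n = {c['n']}"
            )
        lines.append("")
        for s in report["age_normalized_gm"]["steiger"]:
            lines.append(
                f"- Steiger {s['comparison']}: z = {_fmt(s['z'])}, "
                f"p = {_fmt_p(s['p'])}"
            )
        lines.append("")
    return "\n".join(lines) + "\n"


def write_report(
    report: dict[str, Any], provenance: dict[str, Any], path: str | Path
) -> Path:
    path = Path(path)
    path.write_text(render_report(report, provenance))
    return path
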