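"""Human-readable reporting: formatted coefficient tables and summaries.

Formatted tables follow the journal convention of the source tables: standard
errors in parentheses under each estimate, significance stars at the
three-level convention *** p<0.01, ** p<0.05, * p<0.1.  Tidy (machine-read)
outputs always carry raw p-values instead of stars.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["stars", "format_regression_table", "format_suite_report"]

STAR_THRESHOLDS = ((0.01, "***"), (0.05, "**"), (0.1, "*"))


def stars(p: float) -> str:
    for thr, s in STAR_THRESHOLDS:
        if p < thr:
            return s
    return ""


def format_regression_table(params: pd.DataFrame, n_obs: int, r_squared: float) -> str:
    """One model as text: estimate+stars, then (SE) on the following line."""
    lines = []
    width = max(len(str(t)) for t in params.index) + 2
    for term, row in params.iterrows():
        est = f"{row['estimate']:.4g}{stars(row['p'])}"
        lines.append(f"{str(term):<{width}}{est}")
        lines.append(f"{'':<{width}}({row['se']:.4g})")
    lines.append("")
    lines.append(f"{'Observations':<{width}}{n_obs}")
    lines.append(f"{'R-squared':<{width}}{r_squared:.3f}")
    lines.append("")
    lines.append("Standard errors in parentheses. *** p<0.01, ** p<0.05, * p<0.1.")
    return "\n".join(lines)


def format_suite_report(suite: pd.DataFrame) -> str:
    """Render every successful model cell of a tidy suite table."""
    blocks = []
    for model_id, grp in suite.groupby("model_id", sort=True):
        grp_ok = grp[grp["term"].notna()]
        if grp_ok.empty:
            err = grp["error"].iloc[0]
            blocks.append(f"== {model_id} ==\nFAILED: {err}\n")
            continue
        params = grp_ok.set_index("term")[["estimate", "se", "t", "p", "ci_lo", "ci_hi"]]
        n = int(grp_ok["n"].iloc[0])
        r2 = float(grp_ok["r2"].iloc[0])
        blocks.append(f"== {model_id} ==\n" + format_regression_table(params, n, r2) + "\n")
    return "\n".join(blocks)
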