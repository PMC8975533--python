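"""Fit the full model suite: consumption and diet composite on the index.

For every product (raw and logged) and the composite, each formulation,
unadjusted and adjusted — writing the tidy table and a formatted report with
standard errors in parentheses under results/models, and printing the
headline adjusted coefficients.
"""

from pathlib import Path

import pandas as pd

from frei.composite import obesogenic_diet_index
from frei.index import FORMULATIONS, compute_frei
from frei.models import model_suite
from frei.report import format_suite_report
from frei.schema import load_default_schema, load_responses

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    schema = load_default_schema()
    data = ROOT / "results" / "data"
    responses = load_responses(str(data / "responses.csv"), schema)
    consumption = pd.read_csv(data / "consumption.csv", index_col=0)
    covariates = pd.read_csv(data / "covariates.csv", index_col=0)

    scores = {f: compute_frei(responses, schema, f) for f in FORMULATIONS}
    comp = obesogenic_diet_index(consumption)
    suite = model_suite(scores, consumption, comp.scores, covariates)

    outdir = ROOT / "results" / "models"
    outdir.mkdir(parents=True, exist_ok=True)
    suite.to_csv(outdir / "model_suite.csv", index=False)
    (outdir / "report.txt").write_text(format_suite_report(suite), encoding="utf-8")

    print(f"fitted {suite['model_id'].nunique()} models "
          f"({(suite['error'] != '').sum()} failures)")
    print("adjusted index coefficients (unweighted formulation):")
    sel = suite[(suite["formulation"] == "unweighted") & suite["adjusted"]
                & (suite["transform"] == "raw") & (suite["term"] == "frei")]
    for _, r in sel.iterrows():
        print(f"  {r['outcome']:<24} {r['estimate']:+8.3f} (SE {r['se']:.3f}) "
              f"95% CI [{r['ci_lo']:.2f}; {r['ci_hi']:.2f}]  R²={r['r2']:.3f}")


if __name__ == "__main__":
    main()
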