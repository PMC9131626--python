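"""Fit the log-logistic gamma shared frailty model (AFT metric) to the
simulated cohort and report the regression table, the heterogeneity
estimate theta with its implied Kendall's tau, and the boundary LR test
of theta = 0 against the nested no-frailty model.

Reads scratch/cohort.csv; writes results/fit_summary.{csv,txt} and
results/fit_meta.json.
"""

from pathlib import Path

import pandas as pd

from llfrailty.fit import ModelSpec, fit_model
from llfrailty.io import write_fit_outputs

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main() -> None:
    df = pd.read_csv(SCRATCH / "cohort.csv")
    spec = ModelSpec()  # survey covariate schema, AFT metric, frailty on
    fit = fit_model(df, spec)
    write_fit_outputs(fit, spec, OUT)

    print((OUT / "fit_summary.txt").read_text())
    print(
        f"heterogeneity: theta = {fit.theta:.4f} "
        f"(generating value 0.088), tau = {100 * fit.tau:.2f}%"
    )
    print(
        f"LR test of theta = 0: X = {fit.lr_stat:.2f}, "
        f"p = {fit.lr_pvalue:.3g}"
    )
    print(f"converged = {fit.converged} after {fit.n_iter} iterations")


if __name__ == "__main__":
    main()
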