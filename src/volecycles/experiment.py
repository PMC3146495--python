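"""The factorial simulation experiment and its variance decomposition.

``run_grid`` runs every scenario of the 3 (predator assembly) x 4
(fragmentation) x 3 (breeding season) factorial and extracts the endpoint
table: per replicate, log mean population size (N), amplitude (Amp), cycle
length (CL) and the direct/delayed density-dependence coefficients
(AR1, AR2).  ``anova_decompose`` performs the three-way fixed-effects ANOVA
with all interactions on one endpoint and reports, per source, the degrees
of freedom, sum of squares, the adjusted-R^2 percentage contribution

    R2_adj(source) = (SS_source - df_source * MS_error) / SS_total * 100

and the p-value.  The design is balanced, so the decomposition is
independent of source ordering and of factor-level relabelling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .config import ScenarioConfig, scenario_grid
from .engine import RunResult, run_scenario
from .tsanalysis import analyze_series

SOURCES = ("L", "Pr", "B", "L*Pr", "L*B", "Pr*B", "L*Pr*B")

_TERMS = {
    "L": "C(L)",
    "Pr": "C(Pr)",
    "B": "C(B)",
    "L*Pr": "C(L):C(Pr)",
    "L*B": "C(L):C(B)",
    "Pr*B": "C(Pr):C(B)",
    "L*Pr*B": "C(L):C(Pr):C(B)",
}


def endpoints_from_results(results: list[RunResult], config: ScenarioConfig) -> pd.DataFrame:
    rows = []
    for res in results:
        s = res.series
        ep = analyze_series(s.density_opt_ha)
        rows.append(
            {
                "scenario": s.scenario_id,
                "L": config.n_patches,
                "Pr": config.predator_assembly,
                "B": config.breeding_season,
                "replicate": s.replicate,
                "N": ep["meanN_log"],
                "Amp": ep["amplitude"],
                "CL": ep["cycle_length"],
                "AR1": ep["ar1"],
                "AR2": ep["ar2"],
                "extinct": ep["extinct"],
            }
        )
    return pd.DataFrame(rows)


def run_grid(base_config: ScenarioConfig, progress: bool = False) -> pd.DataFrame:
    """Endpoint table for the full 36-scenario factorial (one row per
    scenario x replicate)."""
    tables = []
    for cfg in scenario_grid(base_config):
        if progress:
            print(f"running {cfg.scenario_id} ...", flush=True)
        tables.append(endpoints_from_results(run_scenario(cfg), cfg))
    return pd.concat(tables, ignore_index=True)


def _check_balanced(table: pd.DataFrame) -> None:
    counts = table.groupby(["L", "Pr", "B"], observed=True).size()
    if counts.nunique() != 1:
        raise ValueError(
            "anova_decompose requires a balanced design "
            f"(cell counts ranged {counts.min()}..{counts.max()})"
        )


def anova_decompose(table: pd.DataFrame, response: str) -> pd.DataFrame:
    """Three-way factorial ANOVA of one endpoint with all interactions.

    Returns a DataFrame indexed by source (L, Pr, B, L*Pr, L*B, Pr*B,
    L*Pr*B) with columns df, sum_sq, r2_adj_pct and p_value, plus a final
    Residual row (r2_adj_pct left NaN).  Rows of ``table`` with a
    non-finite response (e.g. extinct replicates with undefined N) are not
    tolerated: clean or impute before calling.
    """
    if response not in table.columns:
        raise ValueError(f"no column {response!r} in the endpoint table")
    data = table[["L", "Pr", "B", response]].rename(columns={response: "y"})
    if not np.isfinite(data["y"]).all():
        raise ValueError(f"non-finite values in response {response!r}")
    _check_balanced(table)
    formula = "y ~ " + " + ".join(_TERMS[s] for s in SOURCES)
    fit = smf.ols(formula, data=data).fit()
    av = sm.stats.anova_lm(fit, typ=1)
    ss_total = float(av["sum_sq"].sum())
    ms_error = float(av.loc["Residual", "sum_sq"] / av.loc["Residual", "df"])
    rows = []
    for name in SOURCES:
        term = _TERMS[name]
        ss = float(av.loc[term, "sum_sq"])
        df = int(av.loc[term, "df"])
        rows.append(
            {
                "source": name,
                "df": df,
                "sum_sq": ss,
                "r2_adj_pct": (ss - df * ms_error) / ss_total * 100.0,
                "p_value": float(av.loc[term, "PR(>F)"]),
            }
        )
    rows.append(
        {
            "source": "Residual",
            "df": int(av.loc["Residual", "df"]),
            "sum_sq": float(av.loc["Residual", "sum_sq"]),
            "r2_adj_pct": float("nan"),
            "p_value": float("nan"),
        }
    )
    return pd.DataFrame(rows).set_index("source")


def decomposition_table(table: pd.DataFrame, responses=("N", "CL", "Amp", "AR1", "AR2")) -> pd.DataFrame:
    """Sources x responses table of adjusted-R^2 percentages."""
    cols = {}
    for resp in responses:
        sub = table[np.isfinite(table[resp])]
        cols[resp] = anova_decompose(sub, resp)["r2_adj_pct"]
    return pd.DataFrame(cols)
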