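"""Reaction norms and genotype-by-environment tests at QTL windows.

A reaction norm summarizes the mean phenotype per genotype class (dosage
0/1/2) within each environment; the G-by-E test fits the fixed-effects
linear model y ~ genotype + environment + genotype:environment (genotype
as numeric dosage, environment as a 0/1 indicator for two environments)
and reports the interaction-term F test. RILs measured in both
environments enter as independent records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .core import AncestryMatrix


def _records(matrix: AncestryMatrix, phenotypes_by_env: pd.DataFrame, window) -> pd.DataFrame:
    req = {"ril", "env", "phenotype"}
    if not req.issubset(phenotypes_by_env.columns):
        raise ValueError(f"phenotype table needs columns {sorted(req)}")
    g = pd.Series(matrix.column(window), index=matrix.rils)
    df = phenotypes_by_env.copy()
    df["g"] = df["ril"].map(g)
    return df.dropna(subset=["g", "phenotype"])


def reaction_norm(matrix: AncestryMatrix, phenotypes_by_env: pd.DataFrame, window) -> pd.DataFrame:
    """Cellwise phenotype means by genotype class and environment.

    Returns a table with one row per (genotype, env) cell: mean, n and
    standard error of the mean. Cells with no observations appear with
    n = 0 and NaN mean (no crash on an empty genotype class).
    """
    df = _records(matrix, phenotypes_by_env, window)
    envs = sorted(df["env"].unique())
    rows = []
    for geno in (0.0, 1.0, 2.0):
        for env in envs:
            y = df.loc[(df["g"] == geno) & (df["env"] == env), "phenotype"].to_numpy()
            rows.append(
                {
                    "genotype": int(geno),
                    "env": env,
                    "n": y.size,
                    "mean": float(y.mean()) if y.size else np.nan,
                    "se": float(y.std(ddof=1) / np.sqrt(y.size)) if y.size > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GxEResult:
    coef: float  # interaction coefficient (2-environment numeric model)
    f_stat: float
    p: float
    df_num: int
    df_den: int


def gxe_test(matrix: AncestryMatrix, phenotypes_by_env: pd.DataFrame, window) -> GxEResult:
    """F test of the genotype-by-environment interaction at one window.

    Two environments: y = b0 + b1*g + b2*env + b3*g*env with env coded
    0/1 (environments in sorted label order); the reported coefficient,
    F and P concern b3. More than two environments fall back to a
    categorical-environment model with a joint interaction F test
    (coefficient reported as NaN).
    """
    df = _records(matrix, phenotypes_by_env, window)
    envs = sorted(df["env"].unique())
    if len(envs) < 2:
        raise ValueError("need >= 2 environments")
    if df["g"].nunique() < 2:
        raise ValueError("need >= 2 genotype classes present")
    if len(envs) == 2:
        df = df.assign(e=(df["env"] == envs[1]).astype(float))
        full = smf.ols("phenotype ~ g + e + g:e", data=df).fit()
        if np.linalg.matrix_rank(full.model.exog) < full.model.exog.shape[1]:
            raise ValueError("rank-deficient design: genotype/environment confounded")
        reduced = smf.ols("phenotype ~ g + e", data=df).fit()
        tab = anova_lm(reduced, full)
        return GxEResult(
            coef=float(full.params["g:e"]),
            f_stat=float(tab["F"].iloc[1]),
            p=float(tab["Pr(>F)"].iloc[1]),
            df_num=int(tab["df_diff"].iloc[1]),
            df_den=int(full.df_resid),
        )
    full = smf.ols("phenotype ~ g * C(env)", data=df).fit()
    reduced = smf.ols("phenotype ~ g + C(env)", data=df).fit()
    tab = anova_lm(reduced, full)
    return GxEResult(
        coef=float("nan"),
        f_stat=float(tab["F"].iloc[1]),
        p=float(tab["Pr(>F)"].iloc[1]),
        df_num=int(tab["df_diff"].iloc[1]),
        df_den=int(full.df_resid),
    )
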