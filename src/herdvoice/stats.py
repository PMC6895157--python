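"""MANOVA (Pillai's trace), univariate follow-up ANOVAs and descriptives.

The multivariate test asks whether the 21-parameter acoustic profiles differ
between individuals at all; the univariate ANOVAs then locate which
parameters carry the individual signal.  No multiplicity correction is
applied to the follow-ups — each parameter is reported at its nominal p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as st

from .params import PARAM_NAMES


@dataclass
class ManovaResult:
    pillai_trace: float
    f_stat: float
    df1: int
    df2: int
    p_value: float
    s: int
    m: float          # (|p - (g-1)| - 1) / 2
    n_prime: float    # (N - g - p - 1) / 2
    n_obs: int
    n_groups: int
    n_vars: int


def pillai_dfs(n_groups: int, n_vars: int, n_obs: int,
               ) -> tuple[int, int, int, float, float]:
    """(df1, df2, s, m, n') for the Pillai approximate-F."""
    g, p, N = n_groups, n_vars, n_obs
    s = min(p, g - 1)
    m = (abs(p - (g - 1)) - 1) / 2.0
    n_prime = (N - g - p - 1) / 2.0
    df1 = int(round(s * (2 * m + s + 1)))
    df2 = int(round(s * (2 * n_prime + s + 1)))
    return df1, df2, s, m, n_prime


def manova_pillai(table: pd.DataFrame,
                  dependent_vars: list[str] | None = None,
                  group_col: str = "individual_id") -> ManovaResult:
    """One-way MANOVA, Pillai's trace V = tr(B(B+W)⁻¹) with approximate F.

    F = [(2n' + s + 1) / (2m + s + 1)] · [V / (s − V)], compared to
    F(df1, df2) with df1 = s(2m + s + 1), df2 = s(2n' + s + 1).
    """
    if dependent_vars is None:
        dependent_vars = [c for c in PARAM_NAMES if c in table.columns]
    X = table[list(dependent_vars)].to_numpy(float)
    if not np.all(np.isfinite(X)):
        raise ValueError("complete cases required")
    y = table[group_col].to_numpy()
    groups = pd.unique(y)
    N, p = X.shape
    g = len(groups)
    if N <= g + p:
        raise ValueError("need N > #groups + #variables")
    grand = X.mean(axis=0)
    T = (X - grand).T @ (X - grand)
    W = np.zeros((p, p))
    for k in groups:
        sub = X[y == k]
        d = sub - sub.mean(axis=0)
        W += d.T @ d
    B = T - W
    try:
        V = float(np.trace(np.linalg.solve(T.T, B.T).T))  # B (B+W)^-1
    except np.linalg.LinAlgError as err:
        raise ValueError("singular B + W matrix") from err
    df1, df2, s, m, n_prime = pillai_dfs(g, p, N)
    denom = max(s - V, 1e-12)
    f = (2 * n_prime + s + 1) / (2 * m + s + 1) * V / denom
    pval = float(st.f.sf(f, df1, df2))
    return ManovaResult(pillai_trace=V, f_stat=float(f), df1=df1, df2=df2,
                        p_value=pval, s=s, m=m, n_prime=n_prime,
                        n_obs=N, n_groups=g, n_vars=p)


def univariate_anovas(table: pd.DataFrame,
                      parameters: list[str] | None = None,
                      group_col: str = "individual_id",
                      alpha_labels: tuple[float, ...] = (0.002, 0.02),
                      ) -> pd.DataFrame:
    """One-way fixed-effects ANOVA per parameter (no multiplicity
    correction); degenerate parameters (zero within-group variance) are
    flagged rather than silently propagated.
    """
    if parameters is None:
        parameters = [c for c in PARAM_NAMES if c in table.columns]
    y = table[group_col].to_numpy()
    groups = pd.unique(y)
    g, N = len(groups), len(table)
    if g < 2 or min((y == k).sum() for k in groups) < 2:
        raise ValueError("need >= 2 groups with >= 2 rows each")
    rows = []
    for par in parameters:
        samples = [table.loc[y == k, par].to_numpy(float) for k in groups]
        within_var = sum(((s - s.mean()) ** 2).sum() for s in samples)
        row = {"parameter": par, "df_between": g - 1, "df_within": N - g}
        if within_var <= 1e-300:
            allv = table[par].to_numpy(float)
            if np.ptp(allv) == 0:
                row.update(F=np.nan, p_value=np.nan, degenerate=True)
            else:
                row.update(F=np.inf, p_value=0.0, degenerate=True)
        else:
            f, p = st.f_oneway(*samples)
            row.update(F=float(f), p_value=float(p), degenerate=False)
        for a in alpha_labels:
            row[f"sig_at_{a:g}"] = bool(row["p_value"] < a) \
                if np.isfinite(row["F"]) or row["p_value"] == 0.0 else False
        rows.append(row)
    return pd.DataFrame(rows)


def descriptive_stats(table: pd.DataFrame,
                      parameters: list[str] | None = None,
                      by: tuple[str, ...] = ("individual_id", "valence"),
                      ) -> pd.DataFrame:
    """Per-individual, per-valence mean ± SE for every parameter.

    SE = SD/√n with the sample SD (ddof=1); cells with a single call get a
    missing SE.
    """
    if table.empty:
        raise ValueError("empty feature table")
    if parameters is None:
        parameters = [c for c in PARAM_NAMES if c in table.columns]
    grp = table.groupby(list(by))
    out = []
    for key, sub in grp:
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(by, key))
        row["n"] = len(sub)
        for par in parameters:
            x = sub[par].to_numpy(float)
            row[f"{par}_mean"] = float(x.mean())
            row[f"{par}_se"] = (float(x.std(ddof=1) / np.sqrt(len(x)))
                                if len(x) > 1 else np.nan)
        out.append(row)
    return pd.DataFrame(out)
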