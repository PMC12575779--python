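"""Statistics on the bite-features table.

Two-factor linear models (individual as an independent effect, food
hardness as the fixed factor, plus their interaction) with per-term F tests
and partial eta squared, and least-squares EMG-force regression with
pointwise 95 % confidence and prediction limits.  Hardness is treated as a
categorical factor by default (its E values are carried as labels);
Type-III sums of squares with sum-to-zero contrasts are used so that main
effects are interpretable in the unbalanced designs that feeding data
produce (unequal bites per food), switchable to Type-I.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .errors import ConfigurationError

__all__ = [
    "GlmResult",
    "RegressionResult",
    "fit_two_factor_glm",
    "ols_regression_with_limits",
    "make_report",
]


@dataclass
class GlmResult:
    """Per-term ANOVA decomposition of a two-factor linear model."""

    response: str
    terms: list  # term names in SS-table order (residual last)
    SS: dict  # term -> sum of squares (includes "Residual")
    df: dict  # term -> degrees of freedom
    F_stats: dict  # term -> F
    p_values: dict  # term -> p
    partial_eta2: dict  # term -> SS_term / (SS_term + SS_residual)
    ss_type: int = 3
    n_obs: int = 0
    flags: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.terms:
            rows.append(
                {
                    "term": t,
                    "SS": self.SS[t],
                    "df": self.df[t],
                    "F": self.F_stats.get(t, np.nan),
                    "p": self.p_values.get(t, np.nan),
                    "partial_eta2": self.partial_eta2.get(t, np.nan),
                }
            )
        return pd.DataFrame(rows).set_index("term")


@dataclass
class RegressionResult:
    """Simple OLS with t-based pointwise confidence and prediction bands."""

    slope: float
    intercept: float
    r2: float
    F: float
    p: float
    n: int
    alpha: float
    grid: np.ndarray  # x values of the bands
    estimate: np.ndarray  # model estimate on the grid
    LCL: np.ndarray  # lower/upper confidence limits of the mean
    UCL: np.ndarray
    LPL: np.ndarray  # lower/upper prediction limits of a new observation
    UPL: np.ndarray


def fit_two_factor_glm(
    table: pd.DataFrame,
    response: str,
    individual: str = "subject",
    hardness: str = "food",
    ss_type: int = 3,
) -> GlmResult:
    """Linear model ``response ~ individual * hardness`` with partial eta2.

    Both factors are categorical; the interaction (IND*E) is included and
    its effect size reported as partial eta squared,
    ``SS_term / (SS_term + SS_residual)``.  Type-III sums of squares with
    sum-to-zero coding by default.
    """
    if ss_type not in (1, 3):
        raise ConfigurationError("ss_type must be 1 or 3")
    df = table[[response, individual, hardness]].dropna().copy()
    for factor in (individual, hardness):
        if df[factor].nunique() < 2:
            raise ConfigurationError(f"factor {factor!r} needs at least 2 levels")
    cells = df.groupby([individual, hardness], observed=True).size()
    full = pd.MultiIndex.from_product(
        [df[individual].unique(), df[hardness].unique()], names=[individual, hardness]
    )
    missing = full.difference(cells.index)
    if len(missing):
        raise ConfigurationError(
            "interaction inestimable; empty cells: "
            + ", ".join(str(tuple(m)) for m in missing)
        )
    df = df.rename(columns={response: "_y", individual: "_ind", hardness: "_hard"})
    df["_ind"] = df["_ind"].astype(str)
    df["_hard"] = df["_hard"].astype(str)
    formula = "_y ~ C(_ind, Sum) * C(_hard, Sum)"
    fit = smf.ols(formula, data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = anova_lm(fit, typ=ss_type)
    aov = aov.rename(
        index={
            "C(_ind, Sum)": individual,
            "C(_hard, Sum)": hardness,
            "C(_ind, Sum):C(_hard, Sum)": f"{individual}:{hardness}",
        }
    )
    if "Intercept" in aov.index:
        aov = aov.drop(index="Intercept")
    ss_col = "sum_sq"
    ss_res = float(aov.loc["Residual", ss_col])
    terms = list(aov.index)
    SS, dof, F, p, eta = {}, {}, {}, {}, {}
    flags = []
    total_ss = float(aov[ss_col].sum())
    if ss_res <= 1e-9 * max(total_ss, 1e-300):
        flags.append("zero_residual")
    for t in terms:
        SS[t] = float(aov.loc[t, ss_col])
        dof[t] = float(aov.loc[t, "df"])
        if t != "Residual":
            F[t] = float(aov.loc[t, "F"])
            p[t] = float(aov.loc[t, "PR(>F)"])
            denom = SS[t] + ss_res
            eta[t] = SS[t] / denom if denom > 0 else np.nan
    return GlmResult(
        response=response,
        terms=terms,
        SS=SS,
        df=dof,
        F_stats=F,
        p_values=p,
        partial_eta2=eta,
        ss_type=ss_type,
        n_obs=len(df),
        flags=flags,
    )


def ols_regression_with_limits(
    x, y, alpha: float = 0.05, grid: Optional[np.ndarray] = None
) -> RegressionResult:
    """Least-squares regression of y on x with 95 % confidence/prediction bands.

    Pointwise limits use the standard t-based formulas (statsmodels
    ``get_prediction``): LCL/UCL bound the conditional mean, LPL/UPL bound a
    new observation and always contain the confidence band.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    if grid is None:
        grid = np.linspace(float(x.min()), float(x.max()), 100)
    grid = np.asarray(grid, dtype=float)
    pred = fit.get_prediction(sm.add_constant(grid))
    ci = pred.conf_int(alpha=alpha)
    pi = pred.conf_int(obs=True, alpha=alpha)
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r2=float(fit.rsquared),
        F=float(fit.fvalue),
        p=float(fit.f_pvalue),
        n=int(x.size),
        alpha=alpha,
        grid=grid,
        estimate=np.asarray(pred.predicted_mean),
        LCL=ci[:, 0],
        UCL=ci[:, 1],
        LPL=pi[:, 0],
        UPL=pi[:, 1],
    )


def _versions() -> dict:
    import scipy
    import statsmodels

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
    }


def make_report(
    out_dir,
    glm_results: Optional[Sequence[GlmResult]] = None,
    regression: Optional[RegressionResult] = None,
    curves: Optional[Sequence] = None,
    points: Optional[Sequence] = None,
    shift_table: Optional[pd.DataFrame] = None,
    config_echo: Optional[dict] = None,
) -> dict:
    """Write a self-contained report bundle (JSON + CSV tables).

    Best-effort: missing sections are recorded explicitly rather than
    failing, and reruns with identical inputs produce byte-identical files
    (no timestamps).  Returns the report dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = {
        "software": _versions(),
        "config": config_echo or {},
        "notes": ["no multiple-testing correction applied"],
        "sections": {},
    }
    if not any(x is not None for x in (glm_results, regression, curves, points, shift_table)):
        report["sections"]["empty"] = "no analyses run"
    if glm_results:
        frames = []
        for g in glm_results:
            f = g.to_frame().reset_index()
            f.insert(0, "response", g.response)
            frames.append(f)
        glm_df = pd.concat(frames, ignore_index=True)
        glm_df.to_csv(out / "glm_results.csv", index=False)
        report["sections"]["glm"] = {
            g.response: {
                "partial_eta2": g.partial_eta2,
                "p_values": g.p_values,
                "F": g.F_stats,
            }
            for g in glm_results
        }
    if regression is not None:
        reg = {
            "slope": regression.slope,
            "intercept": regression.intercept,
            "r2": regression.r2,
            "F": regression.F,
            "p": regression.p,
            "n": regression.n,
        }
        report["sections"]["emg_force_regression"] = reg
        pd.DataFrame(
            {
                "x": regression.grid,
                "estimate": regression.estimate,
                "LCL": regression.LCL,
                "UCL": regression.UCL,
                "LPL": regression.LPL,
                "UPL": regression.UPL,
            }
        ).to_csv(out / "emg_force_regression.csv", index=False)
    if curves:
        bundle = []
        for c in curves:
            strain = np.linspace(*c.strain_range, 101)
            bundle.append(
                {
                    "protocol": c.protocol,
                    "L_O_mm": c.L_O,
                    "F_O_N": c.F_O,
                    "stress_O": c.stress_O,
                    "strain": strain.tolist(),
                    "active_stress": c.active_stress_at_strain(strain).tolist(),
                    "passive_stress": c.passive_stress_at_length(
                        c.L_O * (1 + strain)
                    ).tolist(),
                }
            )
        report["sections"]["fl_curves"] = bundle
    if points:
        pts = pd.DataFrame(
            {
                "strain": [p.strain_at_Fmax for p in points],
                "stress": [p.peak_stress for p in points],
                "region": [p.region for p in points],
                "subject": [p.subject for p in points],
                "food": [p.food for p in points],
                "food_E": [p.food_E for p in points],
            }
        )
        pts.to_csv(out / "operating_points.csv", index=False)
        report["sections"]["operating_points"] = {"n": len(pts)}
    if shift_table is not None:
        shift_table.to_csv(out / "plateau_shift.csv", index=False)
        report["sections"]["plateau_shift"] = {
            "n": len(shift_table),
            "mean_pct": float(shift_table["shift_pct"].mean())
            if "shift_pct" in shift_table
            else None,
        }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
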