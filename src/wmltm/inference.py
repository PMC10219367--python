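"""Bayesian summaries: within-group standardization, a default-prior
correlation Bayes factor, and BIC-approximate Bayes factors for
age / set-size / interaction effects on participant x set-size cell tables.

The effect Bayes factors deliberately approximate the mixed-model comparison
with nested ML regressions (participant intercepts absorbed by
within-participant centering for repeated-measures effects) and the BIC
bridge ``BF10 = exp((BIC_without - BIC_with) / 2)``; the method tag records
this in every result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats
import statsmodels.formula.api as smf

EFFECTS = ("age", "set_size", "interaction")


@dataclass(frozen=True)
class BFResult:
    effect: str
    bf10: float
    method: str

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    bf10: float
    prior_width: float
    method: str = "jeffreys-integral"


def standardize_within_group(
    values: np.ndarray | pd.Series, groups: np.ndarray | pd.Series
) -> np.ndarray:
    """z-score within each group (sample SD); order preserved."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    out = np.empty_like(values)
    for g in np.unique(groups):
        mask = groups == g
        if mask.sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
        sd = values[mask].std(ddof=1)
        if sd == 0:
            raise ValueError(f"group {g!r} has zero variance")
        out[mask] = (values[mask] - values[mask].mean()) / sd
    return out


def correlation_bf(
    x: np.ndarray | pd.Series,
    y: np.ndarray | pd.Series,
    prior_width: float = 1.0,
) -> CorrelationResult:
    """Pearson r with a default-prior Bayes factor for rho != 0 vs rho = 0.

    The prior on rho is a symmetric beta(1/w, 1/w) stretched to (-1, 1)
    (w = 1 gives the uniform prior).  The marginal likelihood uses Jeffreys'
    approximation to the sampling density of r and is integrated numerically.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input")
    r = float(np.corrcoef(x, y)[0, 1])
    if prior_width <= 0:
        raise ValueError("prior width must be positive")

    if abs(r) >= 1.0 - 1e-12:
        return CorrelationResult(r=r, n=n, bf10=float("inf"), prior_width=prior_width)

    a = 1.0 / prior_width

    def log_lr(rho: float) -> float:
        # likelihood ratio L(rho)/L(0) under Jeffreys' approximation
        return 0.5 * (n - 1) * np.log1p(-rho * rho) - (n - 1.5) * np.log1p(-rho * r)

    def integrand(rho: float) -> float:
        prior = 0.5 * stats.beta.pdf((rho + 1.0) / 2.0, a, a)
        return np.exp(log_lr(rho)) * prior

    bf10, _ = integrate.quad(integrand, -1.0, 1.0, points=[r], limit=200)
    return CorrelationResult(r=r, n=n, bf10=float(bf10), prior_width=prior_width)


def _check_table(table: pd.DataFrame, value_col: str) -> pd.DataFrame:
    required = {"participant_id", "age_group", "set_size", value_col}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cell table missing columns {sorted(missing)}")
    dup = table.duplicated(["participant_id", "set_size"]).any()
    if dup:
        raise ValueError("duplicated participant x set-size keys")
    df = table[["participant_id", "age_group", "set_size", value_col]].dropna()
    return df.rename(columns={value_col: "value"})


def effect_bf(table: pd.DataFrame, effect: str, value_col: str = "value") -> BFResult:
    """BIC-approximate Bayes factor for one effect on a cell table.

    * ``age`` — between-participant: compares models of per-participant mean
      values with vs without the group factor.
    * ``set_size`` — within-participant: values are participant-centered
      (absorbing participant intercepts), then models with vs without the
      set-size factor are compared.
    * ``interaction`` — on centered values, full ``set_size * age`` model vs
      the additive one.
    """
    if effect not in EFFECTS:
        raise ValueError(f"effect must be one of {EFFECTS}")
    df = _check_table(table, value_col)

    if effect == "age":
        data = (
            df.groupby(["participant_id", "age_group"], as_index=False)["value"].mean()
        )
        if data["age_group"].nunique() < 2:
            raise ValueError("need >= 2 age groups")
        full = smf.ols("value ~ C(age_group)", data).fit()
        null = smf.ols("value ~ 1", data).fit()
    else:
        if df["set_size"].nunique() < 2:
            raise ValueError("need >= 2 set sizes")
        data = df.copy()
        data["value"] = data["value"] - data.groupby("participant_id")["value"].transform("mean")
        if effect == "set_size":
            full = smf.ols("value ~ C(set_size)", data).fit()
            null = smf.ols("value ~ 1", data).fit()
        else:
            if data["age_group"].nunique() < 2:
                raise ValueError("need >= 2 age groups")
            full = smf.ols("value ~ C(set_size) * C(age_group)", data).fit()
            null = smf.ols("value ~ C(set_size) + C(age_group)", data).fit()

    bf10 = float(np.exp((null.bic - full.bic) / 2.0))
    return BFResult(effect=effect, bf10=bf10, method="bic-ols-centered")


def analysis_report(
    scored: dict[str, pd.DataFrame], prior_width: float = 1.0
) -> dict:
    """Full inferential summary of a scored cohort.

    Effect BFs for p(WM), p(LTM), the transfer ratio, and phase-wise binding
    error rates, plus the within-group-standardized WM-LTM capacity
    correlation (capacity averaged across set sizes per participant; delayed
    capacity = p(LTM) x origin set size).
    """
    ratios = scored["ratios"]
    binding = scored["binding"]
    report: dict = {"method": {"effects": "bic-ols-centered",
                               "correlation": "jeffreys-integral",
                               "prior_width": prior_width},
                    "effects": {}}

    measures = {
        "p_wm": ratios.rename(columns={"p_wm": "value"}),
        "p_ltm": ratios.rename(columns={"p_ltm": "value"}),
        "ratio": ratios.rename(columns={"ratio": "value"}),
    }
    wm_bind = binding[(binding["phase"] == "WM") & (binding["n_eligible"] > 0)]
    lt_bind = binding[(binding["phase"] == "LTM") & ~binding["excluded"]
                      & (binding["n_eligible"] > 0)]
    measures["wm_binding_error"] = wm_bind.rename(columns={"error_rate": "value"})
    measures["ltm_binding_error"] = lt_bind.rename(columns={"error_rate": "value"})

    for name, tab in measures.items():
        entry = {}
        for eff in EFFECTS:
            try:
                res = effect_bf(tab, eff)
                entry[eff] = {"bf10": res.bf10, "bf01": res.bf01, "method": res.method}
            except ValueError as exc:
                entry[eff] = {"error": str(exc)}
        report["effects"][name] = entry

    per = ratios.copy()
    per["ltm_capacity"] = per["p_ltm"] * per["set_size"]
    avg = per.groupby(["participant_id", "age_group"], as_index=False)[
        ["k", "ltm_capacity"]
    ].mean()
    zk = standardize_within_group(avg["k"], avg["age_group"])
    zl = standardize_within_group(avg["ltm_capacity"], avg["age_group"])
    corr = correlation_bf(zk, zl, prior_width=prior_width)
    report["wm_ltm_correlation"] = {
        "r": corr.r, "n": corr.n, "bf10": corr.bf10,
        "prior_width": corr.prior_width, "method": corr.method,
    }
    return report
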