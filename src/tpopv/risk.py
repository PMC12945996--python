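"""Logistic risk-factor modelling of thromboembolic-event reporting.

The outcome is per-report: did this spontaneous report mention a target
(thromboembolic) event?  Covariates are the categorical demographics —
age group, weight group, sex, treatment-duration group and drug — each with
a declared reference level.  Univariable fits screen covariates at
p < 0.05; the survivors enter one multivariable maximum-likelihood fit
(IRLS).  For a single categorical covariate, the fitted odds ratio of a
level against its reference is algebraically the cross-product ratio of the
corresponding 2x2 — kept as an internal cross-check column.

Odds ratios are *reporting* odds ratios: they quantify disproportional
reporting, not incidence or causal risk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import _dates
from .errors import ConfigurationError
from .ingest import CleanCases, bin_duration

__all__ = [
    "DEFAULT_REFERENCES",
    "LogisticFit",
    "build_model_input",
    "fit_univariable",
    "fit_univariable_from_counts",
    "screen_covariates",
    "fit_multivariable",
]

_Z = 1.959963984540054

DEFAULT_REFERENCES = {
    "age_group": "<18",
    "wt_group": "<50",
    "sex": "F",
    "time_group": "<365",
    "drug": None,  # alphabetically first canonical drug in the data
}

MODEL_COVARIATES = ("age_group", "wt_group", "sex", "time_group", "drug")


@dataclass
class LogisticFit:
    """Level-wise odds-ratio table plus fit metadata.

    ``table`` columns: covariate, level, n_no, n_yes, odds_ratio, ci_low,
    ci_high, p_value, reference, estimable (and, for univariable fits,
    ``or_crossprod`` — the closed-form cross-product check).
    """

    table: pd.DataFrame
    n_used: int
    converged: bool
    llf: float
    kind: str  # 'univariable' | 'multivariable'
    notes: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# model input
# ---------------------------------------------------------------------------

def build_model_input(clean: CleanCases) -> pd.DataFrame:
    """One modelling row per target-drug report.

    y = 1 when the report mentions at least one mapped target event.
    Treatment duration is therapy start to event onset in days (the only
    reading computable from the report schema), binned like the TTO groups
    used in the demographics tables.
    """
    cases = clean.cases[clean.cases["case_class"] == "target"].copy()
    hit = set(clean.events["case_id"])
    days = [
        _dates.days_between(s, e)
        for s, e in zip(cases["start_dt"], cases["event_dt"])
    ]
    out = pd.DataFrame({
        "case_id": cases["case_id"].to_numpy(),
        "y": cases["case_id"].isin(hit).astype(int).to_numpy(),
        "age_group": cases["age_group"].to_numpy(),
        "wt_group": cases["wt_group"].to_numpy(),
        "sex": cases["sex"].to_numpy(),
        "time_group": bin_duration(pd.Series(days)).to_numpy(),
        "drug": cases["target_drug"].to_numpy(),
    })
    return out


def _resolve_ref(levels, covariate: str, ref):
    if ref is None:
        ref = DEFAULT_REFERENCES.get(covariate)
    if ref is None:
        ref = sorted(levels)[0]
    if ref not in levels:
        raise ConfigurationError(
            f"reference level {ref!r} absent from covariate {covariate!r}")
    return ref


def _glm_from_counts(design: pd.DataFrame, n_yes: np.ndarray, n_no: np.ndarray):
    endog = np.column_stack([n_yes, n_no]).astype(float)
    model = sm.GLM(endog, design.astype(float), family=sm.families.Binomial())
    with warnings.catch_warnings():
        # saturated one-way fits have zero residual df; statsmodels then
        # warns about "perfect separation" and 0/0 scale — both expected
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.filterwarnings("ignore", message=".*[Pp]erfect separation.*")
        return model.fit(maxiter=100, tol=1e-8)


# ---------------------------------------------------------------------------
# univariable
# ---------------------------------------------------------------------------

def fit_univariable_from_counts(counts: pd.DataFrame, covariate: str = "x",
                                ref=None) -> LogisticFit:
    """One-way logistic fit from an aggregated level x outcome table.

    ``counts`` is indexed by level with columns ``n_no`` and ``n_yes``.
    Levels whose 2x2 against the reference contains a zero cell are flagged
    non-estimable and excluded from the likelihood.
    """
    counts = counts.copy()
    levels = list(counts.index)
    ref = _resolve_ref(levels, covariate, ref)
    ordered = [ref] + [l for l in levels if l != ref]
    counts = counts.loc[ordered]
    n_no = counts["n_no"].to_numpy(dtype=float)
    n_yes = counts["n_yes"].to_numpy(dtype=float)

    ref_ok = n_no[0] > 0 and n_yes[0] > 0
    estim = np.array([ref_ok and n_no[i] > 0 and n_yes[i] > 0
                      for i in range(len(ordered))])
    notes = []
    if not ref_ok:
        notes.append(f"reference level {ref!r} has a zero outcome cell; "
                     "no level is estimable")

    fit_levels = [l for l, ok in zip(ordered, estim) if ok]
    res = None
    if ref_ok and len(fit_levels) >= 2:
        idx = [ordered.index(l) for l in fit_levels]
        design = pd.DataFrame({"const": 1.0}, index=fit_levels)
        for l in fit_levels[1:]:
            design[l] = (np.asarray(fit_levels) == l).astype(float)
        res = _glm_from_counts(design, n_yes[idx], n_no[idx])

    rows = []
    for i, level in enumerate(ordered):
        row = {"covariate": covariate, "level": level,
               "n_no": int(n_no[i]), "n_yes": int(n_yes[i]),
               "odds_ratio": np.nan, "ci_low": np.nan, "ci_high": np.nan,
               "p_value": np.nan, "reference": level == ref,
               "estimable": bool(estim[i]), "or_crossprod": np.nan}
        if level == ref:
            row["odds_ratio"] = 1.0 if ref_ok else np.nan
        elif estim[i]:
            row["or_crossprod"] = (n_yes[i] * n_no[0]) / (n_no[i] * n_yes[0])
            if res is not None and level in res.params.index:
                beta = res.params[level]
                se = res.bse[level]
                row["odds_ratio"] = float(np.exp(beta))
                row["ci_low"] = float(np.exp(beta - _Z * se))
                row["ci_high"] = float(np.exp(beta + _Z * se))
                row["p_value"] = float(res.pvalues[level])
        rows.append(row)
    table = pd.DataFrame(rows)
    return LogisticFit(table=table, n_used=int(n_no.sum() + n_yes.sum()),
                       converged=bool(res.converged) if res is not None else False,
                       llf=float(res.llf) if res is not None else np.nan,
                       kind="univariable", notes=notes)


def fit_univariable(data: pd.DataFrame, covariate: str, ref=None,
                    outcome: str = "y") -> LogisticFit:
    """Available-case univariable logistic fit of ``outcome`` on one
    categorical covariate."""
    sub = data[[outcome, covariate]].dropna()
    if sub.empty:
        raise ConfigurationError(f"no available cases for covariate {covariate!r}")
    ct = pd.crosstab(sub[covariate], sub[outcome])
    for col in (0, 1):
        if col not in ct.columns:
            ct[col] = 0
    counts = pd.DataFrame({"n_no": ct[0], "n_yes": ct[1]})
    counts.index = counts.index.astype(object)
    return fit_univariable_from_counts(counts, covariate=covariate, ref=ref)


def screen_covariates(fits: dict[str, LogisticFit], alpha: float = 0.05) -> list[str]:
    """Covariates with any estimable non-reference level at p < alpha."""
    if not (0 < alpha <= 1):
        raise ConfigurationError("alpha must be in (0, 1]")
    selected = []
    for name, fit in fits.items():
        t = fit.table
        mask = (~t["reference"]) & t["estimable"] & t["p_value"].notna()
        if (t.loc[mask, "p_value"] < alpha).any():
            selected.append(name)
    return selected


# ---------------------------------------------------------------------------
# multivariable
# ---------------------------------------------------------------------------

def fit_multivariable(data: pd.DataFrame, covariates, refs=None,
                      outcome: str = "y") -> LogisticFit:
    """Joint logistic fit on complete cases across the selected covariates.

    Identical covariate patterns are aggregated to binomial counts before
    the IRLS fit, so the cost scales with the number of cells, not reports.
    Levels showing separation (a zero outcome margin within the complete
    cases) are flagged non-estimable.
    """
    covariates = list(covariates)
    if not covariates:
        raise ConfigurationError("no covariates selected")
    refs = dict(refs or {})
    sub = data[[outcome] + covariates].dropna().copy()
    if sub.empty:
        raise ConfigurationError("no complete cases for the multivariable model")

    level_order: dict[str, list] = {}
    for cov in covariates:
        levels = list(pd.unique(sub[cov]))
        ref = _resolve_ref(levels, cov, refs.get(cov))
        level_order[cov] = [ref] + sorted(l for l in levels if l != ref)
        sub[cov] = pd.Categorical(sub[cov], categories=level_order[cov])

    # aggregate to (pattern, n_no, n_yes)
    grp = (sub.groupby(covariates, observed=True)[outcome]
              .agg(n_yes="sum", n="count").reset_index())
    grp["n_no"] = grp["n"] - grp["n_yes"]

    design = pd.DataFrame({"const": np.ones(len(grp))})
    param_of = {}
    separated = set()
    for cov in covariates:
        margins = sub.groupby(cov, observed=False)[outcome].agg(["sum", "count"])
        for level in level_order[cov][1:]:
            name = f"{cov}:{level}"
            s, c = margins.loc[level, "sum"], margins.loc[level, "count"]
            if c == 0 or s == 0 or s == c:
                separated.add(name)
                continue
            design[name] = (grp[cov] == level).astype(float)
            param_of[name] = (cov, level)
        # a zero-margin reference makes the whole covariate ill-posed
        s, c = margins.loc[level_order[cov][0], "sum"], margins.loc[level_order[cov][0], "count"]
        if c == 0 or s == 0 or s == c:
            separated.add(f"{cov}:{level_order[cov][0]}")

    n_params = design.shape[1]
    notes = []
    if len(sub) < 10 * n_params:
        msg = (f"only {len(sub)} complete cases for {n_params} parameters "
               "(< 10 per parameter)")
        notes.append(msg)
        warnings.warn(msg, stacklevel=2)
    if separated:
        notes.append("separated levels: " + ", ".join(sorted(separated)))

    res = _glm_from_counts(design, grp["n_yes"].to_numpy(),
                           grp["n_no"].to_numpy())
    if not res.converged:
        raise RuntimeError(
            f"IRLS did not converge in 100 iterations; |params|max="
            f"{np.abs(res.params).max():.3g}")

    rows = []
    for cov in covariates:
        margins = sub.groupby(cov, observed=False)[outcome].agg(["sum", "count"])
        for level in level_order[cov]:
            name = f"{cov}:{level}"
            s, c = margins.loc[level, "sum"], margins.loc[level, "count"]
            row = {"covariate": cov, "level": level,
                   "n_no": int(c - s), "n_yes": int(s),
                   "odds_ratio": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                   "p_value": np.nan,
                   "reference": level == level_order[cov][0],
                   "estimable": name not in separated}
            if row["reference"]:
                row["odds_ratio"] = 1.0
            elif name in res.params.index:
                beta, se = res.params[name], res.bse[name]
                row["odds_ratio"] = float(np.exp(beta))
                row["ci_low"] = float(np.exp(beta - _Z * se))
                row["ci_high"] = float(np.exp(beta + _Z * se))
                row["p_value"] = float(res.pvalues[name])
            rows.append(row)
    return LogisticFit(table=pd.DataFrame(rows), n_used=int(len(sub)),
                       converged=bool(res.converged), llf=float(res.llf),
                       kind="multivariable", notes=notes)
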