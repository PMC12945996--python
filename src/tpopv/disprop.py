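"""Disproportionality statistics for spontaneous-report signal detection.

For a (drug, event) pair the database collapses to the classic 2x2 table

====================  ===========  ==========
\\                     target AE    other AEs
====================  ===========  ==========
target drug            a            b
other drugs            c            d
====================  ===========  ==========

on which three frequentist/Bayesian measures are computed:

* **ROR** (reporting odds ratio) ``ad/bc`` with a Wald CI on the log scale;
* **PRR** (proportional reporting ratio) ``[a/(a+b)] / [c/(c+d)]`` with its
  Wald CI, plus the Pearson chi-square of the table;
* **BCPNN information component** — the posterior expectation of
  ``log2 p(drug, event) / (p(drug) p(event))`` under independent Beta
  priors (Bate's closed-form approximation), reported with its variance and
  the conservative ``E(IC) - 2*sqrt(V(IC))`` bound.

A pair is declared a *suspected signal* only when all three methods are
positive: ``a >= 3`` with ROR and PRR lower 95% bounds above 1, and a
positive information component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .ingest import CleanCases

__all__ = [
    "ContingencyTable",
    "BcpnnPriors",
    "SignalStats",
    "build_contingency",
    "compute_ror",
    "compute_prr",
    "compute_bcpnn",
    "bcpnn_posterior_mc",
    "classify_tier",
    "gate_signal",
    "association_test",
    "fisher_exact_p",
    "compute_signal_stats",
    "scan_all_signals",
]

_Z = 1.959963984540054  # two-sided 95% normal quantile
_LN2 = math.log(2.0)


@dataclass(frozen=True)
class ContingencyTable:
    """Report counts a/b/c/d for one (drug, event) pair."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def expected(self) -> tuple[float, float, float, float]:
        """Expected cell counts under independence (for the test chooser)."""
        n = self.n
        r1, r0 = self.a + self.b, self.c + self.d
        c1, c0 = self.a + self.c, self.b + self.d
        return (r1 * c1 / n, r1 * c0 / n, r0 * c1 / n, r0 * c0 / n)


@dataclass(frozen=True)
class BcpnnPriors:
    """Beta/Dirichlet hyperparameters of the information-component model."""

    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0
    gamma11: float = 1.0


DEFAULT_PRIORS = BcpnnPriors()


@dataclass
class SignalStats:
    """All per-pair statistics plus the per-method positivity flags."""

    drug: str
    event: str
    a: int
    b: int
    c: int
    d: int
    ror: float
    ror_low: float
    ror_high: float
    prr: float
    prr_low: float
    prr_high: float
    chi2: float
    p_value: float
    test_method: str
    e_ic: float
    v_ic: float
    ic_minus_2sd: float
    tier: str
    positive_ror: bool
    positive_prr: bool
    positive_bcpnn: bool
    positive_all: bool

    def as_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# table construction
# ---------------------------------------------------------------------------

def build_contingency(clean: CleanCases, target_drug: str, target_event: str,
                      background_policy: str = "all-other-drugs") -> ContingencyTable:
    """Tally the 2x2 for one (drug, event) pair over the analysis cases.

    ``target_event`` may be a PT or an event-category label; a case counts
    once regardless of repeated PT rows.  The comparator (c, d) covers every
    analysis case whose matched suspect drug differs from the target
    (including cases with no target drug at all).
    """
    if background_policy != "all-other-drugs":
        raise ConfigurationError(f"unknown background policy {background_policy!r}")
    cases = clean.analysis_cases
    if cases.empty:
        raise ValueError("empty dataset: no analysis cases")
    ev = clean.events
    hit_ids = set(ev.loc[(ev["pt"] == target_event) |
                         (ev["category"] == target_event), "case_id"])
    exposed = cases["target_drug"] == target_drug
    has_event = cases["case_id"].isin(hit_ids)
    a = int((exposed & has_event).sum())
    b = int((exposed & ~has_event).sum())
    c = int((~exposed & has_event).sum())
    d = int((~exposed & ~has_event).sum())
    return ContingencyTable(a, b, c, d)


# ---------------------------------------------------------------------------
# individual measures
# ---------------------------------------------------------------------------

def compute_ror(table: ContingencyTable) -> tuple[float, float, float]:
    """ROR = ad/bc with 95% Wald CI; (nan, nan, nan) when any cell is zero
    (no continuity correction — the signal gate already requires a >= 3)."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        return (float("nan"),) * 3
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ror, ror * math.exp(-_Z * se), ror * math.exp(_Z * se)


def _pearson_chi2(table: ContingencyTable, yates: bool = False) -> float:
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return float("nan")
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2.0, 0.0)
    return n * diff * diff / denom


def compute_prr(table: ContingencyTable,
                yates: bool = False) -> tuple[float, float, float, float]:
    """PRR with 95% Wald CI and the Pearson chi-square of the table.

    Requires a > 0 and c > 0 for a finite estimate; undefined values are
    returned as NaN with chi-square still computed when possible.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    chi2 = _pearson_chi2(table, yates=yates)
    if a == 0 or c == 0 or (a + b) == 0 or (c + d) == 0:
        return float("nan"), float("nan"), float("nan"), chi2
    prr = (a / (a + b)) / (c / (c + d))
    inner = 1 / a - 1 / (a + b) + 1 / c - 1 / (c + d)
    se = math.sqrt(max(inner, 0.0))
    return prr, prr * math.exp(-_Z * se), prr * math.exp(_Z * se), chi2


def compute_bcpnn(table: ContingencyTable,
                  priors: BcpnnPriors = DEFAULT_PRIORS) -> tuple[float, float, float]:
    """Closed-form E(IC), V(IC) and E(IC) − 2·sqrt(V(IC)) in bits.

    Defined for a = 0; the joint-cell prior gamma is calibrated so the prior
    expectation of IC is zero under independence.
    """
    a = table.a
    n = table.n
    if n <= 0:
        raise ValueError("BCPNN needs N > 0")
    r1 = table.a + table.b
    c1 = table.a + table.c
    p = priors
    gamma = p.gamma11 * (n + p.alpha) * (n + p.beta) / ((r1 + p.alpha1) * (c1 + p.beta1))
    e_ic = math.log2((a + p.gamma11) * (n + p.alpha) * (n + p.beta)
                     / ((n + gamma) * (r1 + p.alpha1) * (c1 + p.beta1)))
    v_ic = (1 / _LN2 ** 2) * (
        (n - a + gamma - p.gamma11) / ((a + p.gamma11) * (1 + n + gamma))
        + (n - r1 + p.alpha - p.alpha1) / ((r1 + p.alpha1) * (1 + n + p.alpha))
        + (n - c1 + p.beta - p.beta1) / ((c1 + p.beta1) * (1 + n + p.beta)))
    return e_ic, v_ic, e_ic - 2.0 * math.sqrt(v_ic)


def bcpnn_posterior_mc(table: ContingencyTable, n_draws: int = 1_000_000,
                       rng=None, priors: BcpnnPriors = DEFAULT_PRIORS) -> float:
    """Monte-Carlo oracle for :func:`compute_bcpnn`.

    Samples the three independent Beta posteriors of p(drug,event), p(drug)
    and p(event) implied by the priors and returns
    ``log2( mean(p11) / (mean(px) * mean(py)) )``, which converges to the
    closed-form E(IC).  Used only as an in-repo validation route.
    """
    rng = np.random.default_rng(rng)
    a, n = table.a, table.n
    r1 = table.a + table.b
    c1 = table.a + table.c
    p = priors
    gamma = p.gamma11 * (n + p.alpha) * (n + p.beta) / ((r1 + p.alpha1) * (c1 + p.beta1))
    p11 = rng.beta(a + p.gamma11, n - a + gamma - p.gamma11, size=n_draws)
    px = rng.beta(r1 + p.alpha1, n - r1 + p.alpha - p.alpha1, size=n_draws)
    py = rng.beta(c1 + p.beta1, n - c1 + p.beta - p.beta1, size=n_draws)
    return math.log2(p11.mean() / (px.mean() * py.mean()))


def classify_tier(e_ic: float) -> str:
    """IC strength tier: '-' (<=0), '+' (<=1.5), '++' (<=3), '+++' (>3)."""
    if not math.isfinite(e_ic):
        raise ValueError("E(IC) must be finite")
    if e_ic <= 0:
        return "-"
    if e_ic <= 1.5:
        return "+"
    if e_ic <= 3:
        return "++"
    return "+++"


def fisher_exact_p(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p (sum of hypergeometric probabilities not
    exceeding the observed table's)."""
    arr = [[table.a, table.b], [table.c, table.d]]
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def association_test(table: ContingencyTable) -> tuple[float, str]:
    """Two-sided association p-value with the small-sample rule.

    Fisher's exact test whenever any expected cell count is below 5,
    otherwise the Pearson chi-square test (1 df, no continuity correction).
    """
    if table.n <= 0:
        raise ValueError("association test needs N > 0")
    if min(table.expected()) < 5:
        return fisher_exact_p(table), "fisher"
    chi2 = _pearson_chi2(table)
    return float(stats.chi2.sf(chi2, df=1)), "chi2"


# ---------------------------------------------------------------------------
# gating and scanning
# ---------------------------------------------------------------------------

def gate_signal(table: ContingencyTable, ror_low: float, prr_low: float,
                e_ic: float, ic_minus_2sd: float,
                bcpnn_gate: str = "e_ic") -> tuple[bool, bool, bool, bool]:
    """Per-method positivity flags and their conjunction.

    ROR and PRR are positive when a >= 3 and the lower 95% bound exceeds 1;
    BCPNN when E(IC) > 0 (or IC−2SD > 0 under the conservative gate).
    Undefined statistics (NaN bounds) are never positive.
    """
    if bcpnn_gate not in ("e_ic", "ic_minus_2sd"):
        raise ConfigurationError(f"unknown BCPNN gate {bcpnn_gate!r}")
    pos_ror = bool(table.a >= 3 and math.isfinite(ror_low) and ror_low > 1)
    pos_prr = bool(table.a >= 3 and math.isfinite(prr_low) and prr_low > 1)
    ic_stat = e_ic if bcpnn_gate == "e_ic" else ic_minus_2sd
    pos_bcpnn = bool(math.isfinite(ic_stat) and ic_stat > 0)
    return pos_ror, pos_prr, pos_bcpnn, pos_ror and pos_prr and pos_bcpnn


def compute_signal_stats(table: ContingencyTable, drug: str = "", event: str = "",
                         priors: BcpnnPriors = DEFAULT_PRIORS,
                         yates: bool = False,
                         bcpnn_gate: str = "e_ic") -> SignalStats:
    """Compute every measure and the combined gate for one pair."""
    ror, ror_lo, ror_hi = compute_ror(table)
    prr, prr_lo, prr_hi, chi2 = compute_prr(table, yates=yates)
    e_ic, v_ic, ic2sd = compute_bcpnn(table, priors=priors)
    p, method = association_test(table)
    pos_ror, pos_prr, pos_bcpnn, pos_all = gate_signal(
        table, ror_lo, prr_lo, e_ic, ic2sd, bcpnn_gate=bcpnn_gate)
    return SignalStats(
        drug=drug, event=event, a=table.a, b=table.b, c=table.c, d=table.d,
        ror=ror, ror_low=ror_lo, ror_high=ror_hi,
        prr=prr, prr_low=prr_lo, prr_high=prr_hi,
        chi2=chi2, p_value=p, test_method=method,
        e_ic=e_ic, v_ic=v_ic, ic_minus_2sd=ic2sd, tier=classify_tier(e_ic),
        positive_ror=pos_ror, positive_prr=pos_prr,
        positive_bcpnn=pos_bcpnn, positive_all=pos_all)


def scan_all_signals(clean: CleanCases, drugs=None, events=None,
                     level: str = "pt",
                     priors: BcpnnPriors = DEFAULT_PRIORS,
                     yates: bool = False,
                     bcpnn_gate: str = "e_ic") -> pd.DataFrame:
    """Signal table over every (drug, event) pair with a >= 1.

    ``level='pt'`` scans preferred terms, ``level='smq'`` the mapped event
    categories.  Rows failing the gate are retained with their flags —
    filtering is a presentation decision, not a computation one.  Output is
    sorted by drug, then descending a, ties by event name.
    """
    if level not in ("pt", "smq"):
        raise ConfigurationError(f"unknown scan level {level!r}")
    cases = clean.analysis_cases
    if cases.empty:
        return pd.DataFrame(columns=list(SignalStats.__dataclass_fields__))
    if drugs is None:
        drugs = sorted(cases.loc[cases["target_drug"].notna(), "target_drug"].unique())
    col = "pt" if level == "pt" else "category"
    ev = clean.events
    if events is None:
        events = sorted(ev[col].unique())

    # precompute case-id sets once; each pair tally is then set arithmetic
    ids_by_event = {e: set(ev.loc[ev[col] == e, "case_id"]) for e in events}
    ids_by_drug = {dg: set(cases.loc[cases["target_drug"] == dg, "case_id"])
                   for dg in drugs}
    n_total = len(cases)

    rows = []
    for dg in drugs:
        did = ids_by_drug[dg]
        n_drug = len(did)
        for e in events:
            eid = ids_by_event[e]
            a = len(did & eid)
            if a < 1:
                continue
            b = n_drug - a
            c = len(eid) - a
            d = n_total - n_drug - c
            t = ContingencyTable(a, b, c, d)
            rows.append(compute_signal_stats(t, drug=dg, event=e, priors=priors,
                                             yates=yates, bcpnn_gate=bcpnn_gate))
    df = pd.DataFrame([r.as_dict() for r in rows])
    if df.empty:
        return pd.DataFrame(columns=list(SignalStats.__dataclass_fields__))
    df = df.sort_values(["drug", "a", "event"], ascending=[True, False, True],
                        kind="mergesort").reset_index(drop=True)
    return df
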