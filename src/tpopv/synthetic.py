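"""Synthetic FAERS-dialect report generator with known ground truth.

Real FAERS extracts cannot be bundled, so every downstream stage is
exercised against simulated quarterly tables that reproduce the awkward
parts of the format: duplicate case versions with drifting fields, the four
drug role codes, partial ``YYYYMM``/``YYYY`` dates, heterogeneous age and
weight units, and heavy demographic missingness.  Drug–event association
strengths are *planted* as reporting-rate multipliers, giving an exact
oracle for signal-detection tests: a multiplier of 1 everywhere is the null
world, a multiplier of 8 on one pair is a strong known signal.

Onset intervals are drawn from a log-normal whose median (81 days) and
spread match the time-to-onset profile reported for thrombopoietin-receptor
agonists, so the TTO stage sees a realistic mix of early and late events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .ingest import REQUIRED_COLUMNS, ROLE_CODES

__all__ = ["DrugSpec", "EventSpec", "GeneratorConfig", "GroundTruth",
           "SyntheticDataset", "generate_reports", "plant_duplicates"]

_EPOCH = np.datetime64("1970-01-01")


@dataclass(frozen=True)
class DrugSpec:
    name: str
    synonyms: tuple
    share: float


@dataclass(frozen=True)
class EventSpec:
    pt: str
    background_rate: float


def _default_drugs():
    return (
        DrugSpec("Avatrombopag", ("Avatrombopag", "DOPTELET"), 0.10),
        DrugSpec("Eltrombopag", ("Eltrombopag", "PROMACTA", "Revolade"), 0.30),
        DrugSpec("Romiplostim", ("Romiplostim", "NPLATE"), 0.25),
        DrugSpec("Aspirin", ("ASPIRIN",), 0.20),
        DrugSpec("Metformin", ("METFORMIN",), 0.15),
    )


def _default_events():
    return (
        EventSpec("Pulmonary embolism", 0.010),
        EventSpec("Deep vein thrombosis", 0.008),
        EventSpec("Acute myocardial infarction", 0.006),
        EventSpec("Embolism", 0.003),
        EventSpec("Portal vein thrombosis", 0.002),
        EventSpec("Arterial thrombosis", 0.0015),
        EventSpec("Cerebral venous thrombosis", 0.001),
        EventSpec("Renal vein thrombosis", 0.0008),
    )


_FILLER_PTS = ("Headache", "Nausea", "Fatigue", "Pyrexia", "Rash", "Diarrhoea")


@dataclass
class GeneratorConfig:
    """The stated synthetic world; defaults mirror a plausible
    spontaneous-report mix for the three TPO-receptor agonists plus
    comparator background drugs."""

    n_cases: int = 5000
    drugs: tuple = field(default_factory=_default_drugs)
    events: tuple = field(default_factory=_default_events)
    filler_pts: tuple = _FILLER_PTS
    planted_signals: tuple = ()  # (drug, pt, rate multiplier)
    duplicate_fraction: float = 0.20
    partial_date_fraction: float = 0.10
    role_weights: dict = field(default_factory=lambda: {
        "PS": 0.70, "SS": 0.15, "C": 0.10, "I": 0.05})
    missingness: dict = field(default_factory=lambda: {
        "age": 0.30, "weight": 0.70, "sex": 0.08, "country": 0.05,
        "reporter": 0.15, "start_date": 0.35, "event_date": 0.25})
    age_mean: float = 58.0
    age_sd: float = 20.0
    weight_mean: float = 75.0
    weight_sd: float = 18.0
    sex_weights: dict = field(default_factory=lambda: {"F": 0.52, "M": 0.48})
    country_weights: dict = field(default_factory=lambda: {
        "US": 0.45, "JP": 0.12, "IT": 0.10, "ES": 0.08, "DE": 0.08,
        "GB": 0.07, "FR": 0.10})
    reporter_weights: dict = field(default_factory=lambda: {
        "MD": 0.50, "CN": 0.20, "OT": 0.15, "PH": 0.15})
    onset_median_days: float = 81.0
    onset_log_sd: float = 1.744  # matches an IQR ratio q3/q1 ~ 10.5
    concomitant_fraction: float = 0.30
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 0:
            raise ConfigurationError("n_cases must be >= 0")
        for label, probs in [("duplicate_fraction", [self.duplicate_fraction]),
                             ("partial_date_fraction", [self.partial_date_fraction]),
                             ("missingness", list(self.missingness.values())),
                             ("role_weights", list(self.role_weights.values()))]:
            for p in probs:
                if not (0.0 <= p <= 1.0):
                    raise ConfigurationError(f"{label} value {p} outside [0, 1]")
        for weights, label in [(self.role_weights, "role_weights"),
                               ([d.share for d in self.drugs], "drug shares"),
                               (self.sex_weights, "sex_weights"),
                               (self.country_weights, "country_weights"),
                               (self.reporter_weights, "reporter_weights")]:
            vals = list(weights.values()) if isinstance(weights, dict) else weights
            if sum(vals) <= 0 or any(v < 0 for v in vals):
                raise ConfigurationError(f"{label} not normalizable")
        if set(self.role_weights) != set(ROLE_CODES):
            raise ConfigurationError("role_weights must cover PS/SS/C/I")
        for drug, pt, mult in self.planted_signals:
            if not (math.isfinite(mult) and mult >= 0):
                raise ConfigurationError(f"bad multiplier {mult} for ({drug}, {pt})")
            if drug not in {d.name for d in self.drugs}:
                raise ConfigurationError(f"planted drug {drug!r} not in drug list")
            if pt not in {e.pt for e in self.events}:
                raise ConfigurationError(f"planted PT {pt!r} not in event list")
        for spec in self.events:
            if not (0.0 <= spec.background_rate <= 1.0):
                raise ConfigurationError(f"background rate for {spec.pt!r} outside [0,1]")


@dataclass
class GroundTruth:
    """What the generator actually did, for oracle-style assertions.

    ``cases`` has one row per patient case: the final (to-be-kept) report
    version, the true drug/role, the true onset day and the sampled target
    PTs.  ``pair_multipliers`` carries the planted reporting-rate ratio for
    every (drug, PT) pair (1.0 when not planted).
    """

    cases: pd.DataFrame
    pair_multipliers: pd.DataFrame
    seed: int

    def write(self, outdir) -> None:
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.cases.to_csv(outdir / "ground_truth_cases.csv", index=False)
        sidecar = {
            "seed": int(self.seed),
            "pair_multipliers": {
                f"{r.drug}|{r.pt}": float(r.multiplier)
                for r in self.pair_multipliers.itertuples()},
        }
        (outdir / "ground_truth.yaml").write_text(yaml.safe_dump(sidecar))


@dataclass
class SyntheticDataset:
    tables: dict
    truth: GroundTruth
    config: GeneratorConfig

    def write(self, outdir) -> None:
        from .ingest import write_faers_tables
        write_faers_tables(self.tables, outdir)
        self.truth.write(outdir)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _dates_to_str(day_numbers: np.ndarray) -> np.ndarray:
    """Days-since-epoch -> YYYYMMDD strings."""
    d = _EPOCH + day_numbers.astype("timedelta64[D]")
    return np.char.replace(np.datetime_as_string(d, unit="D"), "-", "")


def _truncate_partial(dates: np.ndarray, mask: np.ndarray, rng) -> np.ndarray:
    """Drop trailing components (day, or day+month) where mask is set."""
    out = dates.astype(object)
    idx = np.flatnonzero(mask)
    if idx.size:
        drop_month = rng.random(idx.size) < 0.3
        for i, dm in zip(idx, drop_month):
            out[i] = out[i][:4] if dm else out[i][:6]
    return out


def _weighted_choice(rng, options: dict, size: int) -> np.ndarray:
    keys = list(options)
    w = np.asarray([options[k] for k in keys], dtype=float)
    return rng.choice(np.asarray(keys, dtype=object), size=size, p=w / w.sum())


def _empty_tables() -> dict:
    return {name: pd.DataFrame(columns=cols, dtype=str)
            for name, cols in REQUIRED_COLUMNS.items()}


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_reports(config: GeneratorConfig):
    """Generate DEMO/DRUG/REAC/THER tables plus the matching ground truth.

    Identical configs (including ``config.seed``) produce byte-identical
    tables.  Returns a :class:`SyntheticDataset`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    drugs = list(config.drugs)
    events = list(config.events)
    n_drugs, n_events = len(drugs), len(events)

    mult = np.ones((n_drugs, n_events))
    name_idx = {d.name: i for i, d in enumerate(drugs)}
    pt_idx = {e.pt: j for j, e in enumerate(events)}
    for drug, pt, m in config.planted_signals:
        mult[name_idx[drug], pt_idx[pt]] = m
    pair_mult = pd.DataFrame(
        [(d.name, e.pt, mult[i, j]) for i, d in enumerate(drugs)
         for j, e in enumerate(events)],
        columns=["drug", "pt", "multiplier"])

    if n == 0:
        truth = GroundTruth(
            cases=pd.DataFrame(columns=["case_id", "final_primary_id",
                                        "n_versions", "drug", "role",
                                        "onset_days", "start_complete",
                                        "event_complete", "smq_pts"]),
            pair_multipliers=pair_mult, seed=config.seed)
        return SyntheticDataset(_empty_tables(), truth, config)

    case_id = (1_000_000 + np.arange(n)).astype(np.int64)

    # exposure, roles, events -------------------------------------------------
    shares = np.asarray([d.share for d in drugs], dtype=float)
    drug_i = rng.choice(n_drugs, size=n, p=shares / shares.sum())
    role = _weighted_choice(rng, config.role_weights, n)

    bg = np.asarray([e.background_rate for e in events])
    probs = np.clip(bg[None, :] * mult, 0.0, 0.95)
    occur = rng.random((n, n_events)) < probs[drug_i]
    filler = rng.integers(0, len(config.filler_pts), size=n)

    # demographics ------------------------------------------------------------
    age_true = np.clip(rng.normal(config.age_mean, config.age_sd, n), 1.0, 100.0)
    age_unit = _weighted_choice(rng, {"YR": 0.88, "MON": 0.05, "DY": 0.03,
                                      "DEC": 0.04}, n)
    age_val = np.empty(n, dtype=object)
    for unit, conv in [("YR", lambda a: np.round(a, 0)),
                       ("MON", lambda a: np.round(a * 12, 0)),
                       ("DY", lambda a: np.round(a * 365.25, 0)),
                       ("DEC", lambda a: np.round(a / 10.0, 1))]:
        m = age_unit == unit
        age_val[m] = [f"{v:g}" for v in conv(age_true[m])]

    wt_true = np.clip(rng.normal(config.weight_mean, config.weight_sd, n), 35.0, 160.0)
    wt_unit = _weighted_choice(rng, {"KG": 0.7, "LBS": 0.3}, n)
    wt_val = np.where(wt_unit == "KG", np.round(wt_true, 1),
                      np.round(wt_true / 0.45359237, 1))
    wt_val = np.asarray([f"{v:g}" for v in wt_val], dtype=object)

    sex = _weighted_choice(rng, config.sex_weights, n)
    country = _weighted_choice(rng, config.country_weights, n)
    reporter = _weighted_choice(rng, config.reporter_weights, n)

    # dates -------------------------------------------------------------------
    day0 = (np.datetime64("2015-01-01") - _EPOCH).astype(int)
    day1 = (np.datetime64("2023-12-31") - _EPOCH).astype(int)
    start_day = rng.integers(day0, day1, size=n)
    onset = np.floor(rng.lognormal(math.log(config.onset_median_days),
                                   config.onset_log_sd, n)).astype(int)
    onset = np.clip(onset, 0, 3650)
    event_day = start_day + onset
    fda_day = event_day + rng.integers(10, 400, size=n)

    start_str = _dates_to_str(start_day)
    event_str = _dates_to_str(event_day)
    fda_str = _dates_to_str(fda_day)

    miss = {k: rng.random(n) < p for k, p in config.missingness.items()}
    partial_start = (~miss["start_date"]) & (rng.random(n) < config.partial_date_fraction)
    partial_event = (~miss["event_date"]) & (rng.random(n) < config.partial_date_fraction)
    start_out = _truncate_partial(start_str, partial_start, rng)
    event_out = _truncate_partial(event_str, partial_event, rng)
    start_out[miss["start_date"]] = ""
    event_out[miss["event_date"]] = ""

    def blank(values, key):
        out = np.asarray(values, dtype=object).copy()
        out[miss[key]] = ""
        return out

    # duplicate versions ------------------------------------------------------
    n_versions = np.ones(n, dtype=int)
    dup = rng.random(n) < config.duplicate_fraction
    n_versions[dup] = rng.integers(2, 5, size=int(dup.sum()))
    total = int(n_versions.sum())
    case_rep = np.repeat(np.arange(n), n_versions)
    first = np.r_[0, np.cumsum(n_versions)[:-1]]
    version_no = np.arange(total) - np.repeat(first, n_versions) + 1
    is_final = version_no == np.repeat(n_versions, n_versions)

    pid = case_id[case_rep] * 100 + version_no
    delta = rng.integers(0, 91, size=total)
    delta[first] = 0
    csum = np.cumsum(delta)
    fda_rep = fda_day[case_rep] + (csum - np.repeat(csum[first] - delta[first],
                                                    n_versions))
    fda_rep_str = _dates_to_str(fda_rep)

    # non-final versions mutate weight and reporter so dedup is observable
    age_rep = blank(age_val, "age")[case_rep]
    age_unit_rep = blank(age_unit, "age")[case_rep]
    wt_rep = blank(wt_val, "weight")[case_rep].copy()
    wt_unit_rep = blank(wt_unit, "weight")[case_rep]
    rep_rep = blank(reporter, "reporter")[case_rep].copy()
    jitter = rng.uniform(0.85, 1.15, size=total)
    mut = ~is_final
    for i in np.flatnonzero(mut & (wt_rep != "")):
        wt_rep[i] = f"{float(wt_rep[i]) * jitter[i]:.1f}"
    resample = mut & (rng.random(total) < 0.5) & (rep_rep != "")
    rep_rep[resample] = _weighted_choice(rng, config.reporter_weights,
                                         int(resample.sum()))

    demo = pd.DataFrame({
        "PRIMARYID": pid.astype(str),
        "CASEID": case_id[case_rep].astype(str),
        "FDA_DT": fda_rep_str,
        "EVENT_DT": event_out[case_rep],
        "AGE": age_rep,
        "AGE_COD": age_unit_rep,
        "SEX": blank(sex, "sex")[case_rep],
        "WT": wt_rep,
        "WT_COD": wt_unit_rep,
        "REPORTER_COUNTRY": blank(country, "country")[case_rep],
        "OCCP_COD": rep_rep,
    }).astype(str)

    # DRUG table --------------------------------------------------------------
    syn_choice = np.empty(n, dtype=object)
    for i, spec in enumerate(drugs):
        m = drug_i == i
        picks = rng.integers(0, len(spec.synonyms), size=int(m.sum()))
        syn_choice[m] = np.asarray(spec.synonyms, dtype=object)[picks]
    upper = rng.random(n) < 0.4
    syn_choice[upper] = [s.upper() for s in syn_choice[upper]]

    if n_drugs > 1:
        conc = rng.random(n) < config.concomitant_fraction
        conc_drug = (drug_i + 1 + rng.integers(0, n_drugs - 1, size=n)) % n_drugs
    else:  # no alternative drug to list as concomitant
        conc = np.zeros(n, dtype=bool)
        conc_drug = np.zeros(n, dtype=int)

    drug_frames = []
    main = pd.DataFrame({"case": np.arange(n), "DRUG_SEQ": "1",
                         "ROLE_COD": role, "DRUGNAME": syn_choice})
    drug_frames.append(main)
    if conc.any():
        cidx = np.flatnonzero(conc)
        cnames = np.asarray([drugs[j].synonyms[0] for j in conc_drug[cidx]],
                            dtype=object)
        drug_frames.append(pd.DataFrame({
            "case": cidx, "DRUG_SEQ": "2", "ROLE_COD": "C", "DRUGNAME": cnames}))
    drug_base = pd.concat(drug_frames, ignore_index=True)

    # REAC table --------------------------------------------------------------
    ci, ei = np.nonzero(occur)
    reac_base = pd.concat([
        pd.DataFrame({"case": ci,
                      "PT": np.asarray([events[j].pt for j in ei], dtype=object)}),
        pd.DataFrame({"case": np.arange(n),
                      "PT": np.asarray(config.filler_pts, dtype=object)[filler]}),
    ], ignore_index=True)

    # THER table --------------------------------------------------------------
    has_start = np.asarray([bool(s) for s in start_out])
    ther_base = pd.DataFrame({"case": np.flatnonzero(has_start),
                              "DSG_DRUG_SEQ": "1",
                              "START_DT": np.asarray(start_out, dtype=object)[has_start]})

    def expand(base: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
        """Replicate per-case rows across that case's report versions."""
        reps = n_versions[base["case"].to_numpy()]
        rep_rows = base.loc[base.index.repeat(reps)].reset_index(drop=True)
        # version number within each replicated block
        offs = np.concatenate([np.arange(1, r + 1) for r in reps]) if len(reps) else \
            np.array([], dtype=int)
        c = rep_rows["case"].to_numpy()
        rep_rows["PRIMARYID"] = (case_id[c] * 100 + offs).astype(str)
        rep_rows["CASEID"] = case_id[c].astype(str)
        return rep_rows[["PRIMARYID", "CASEID"] + cols].astype(str)

    drug_tab = expand(drug_base, ["DRUG_SEQ", "ROLE_COD", "DRUGNAME"])
    reac_tab = expand(reac_base, ["PT"])
    ther_tab = expand(ther_base, ["DSG_DRUG_SEQ", "START_DT"])

    tables = {"DEMO": demo, "DRUG": drug_tab, "REAC": reac_tab, "THER": ther_tab}

    smq_join = ["|".join(events[j].pt for j in np.flatnonzero(occur[i]))
                for i in range(n)]
    truth_cases = pd.DataFrame({
        "case_id": case_id.astype(str),
        "final_primary_id": (case_id * 100 + n_versions).astype(str),
        "n_versions": n_versions,
        "drug": np.asarray([drugs[i].name for i in drug_i], dtype=object),
        "role": role,
        "onset_days": onset,
        "start_complete": has_start & ~partial_start,
        "event_complete": np.asarray([len(str(e)) == 8 for e in event_out]),
        "smq_pts": smq_join,
    })
    truth = GroundTruth(cases=truth_cases, pair_multipliers=pair_mult,
                        seed=config.seed)
    return SyntheticDataset(tables, truth, config)


def plant_duplicates(tables: dict, duplicate_fraction: float, seed: int) -> dict:
    """Augment single-version tables with 2–4 versions for a random subset
    of cases (standalone version of the generator's internal step).

    New versions share the CASEID, carry fresh PRIMARYIDs and non-decreasing
    FDA dates; deduplication must recover the last-emitted version.
    """
    if not (0.0 <= duplicate_fraction <= 1.0):
        raise ConfigurationError("duplicate_fraction outside [0, 1]")
    if duplicate_fraction == 0.0 or tables["DEMO"].empty:
        return {k: v.copy() for k, v in tables.items()}
    rng = np.random.default_rng(seed)
    demo = tables["DEMO"]
    out = {k: [v] for k, v in tables.items()}
    sel = rng.random(len(demo)) < duplicate_fraction
    for pos in np.flatnonzero(sel):
        row = demo.iloc[pos]
        extra = int(rng.integers(1, 4))
        fda = int(row["FDA_DT"]) if str(row["FDA_DT"]).isdigit() else 0
        for v in range(extra):
            new = row.copy()
            new["PRIMARYID"] = str(int(row["PRIMARYID"]) + v + 1)
            new["FDA_DT"] = str(fda)  # same-date versions exercise the pid tie-break
            out["DEMO"].append(new.to_frame().T)
            for name in ("DRUG", "REAC", "THER"):
                sub = tables[name][tables[name]["PRIMARYID"] == row["PRIMARYID"]].copy()
                sub["PRIMARYID"] = new["PRIMARYID"]
                out[name].append(sub)
    return {k: pd.concat(v, ignore_index=True) for k, v in out.items()}
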