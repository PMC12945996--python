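"""Reading and cleaning FAERS-dialect spontaneous-report tables.

The quarterly FAERS extracts ship four ``$``-delimited ASCII tables:

* ``DEMO`` — one row per report *version* (PRIMARYID) with patient
  demographics and the FDA receipt date;
* ``DRUG`` — one row per drug entry with the reporter-assigned role code
  (PS = primary suspect, SS = secondary suspect, C = concomitant,
  I = interacting);
* ``REAC`` — one MedDRA preferred term (PT) per row;
* ``THER`` — therapy episodes with start dates.

A patient case (CASEID) may appear as several versions; following FDA
guidance only the version with the latest FDA date is analysed (ties broken
by the highest PRIMARYID).  Cleaning then matches target drugs through a
generic+brand synonym dictionary, restricts to suspect role codes, maps
reaction PTs into event categories via a (user-supplied) SMQ-style lookup,
and normalizes the notoriously heterogeneous age and weight units.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _dates
from .errors import ConfigurationError, FormatError

__all__ = [
    "REQUIRED_COLUMNS",
    "ROLE_CODES",
    "DrugDictionary",
    "SmqMap",
    "CleanCases",
    "read_faers_tables",
    "write_faers_tables",
    "deduplicate",
    "match_drug",
    "map_events",
    "filter_by_role",
    "normalize_age",
    "normalize_weight",
    "bin_age",
    "bin_weight",
    "bin_duration",
    "build_clean_cases",
]

ROLE_CODES = ("PS", "SS", "C", "I")
_ROLE_RANK = {"PS": 0, "SS": 1, "C": 2, "I": 3}

REQUIRED_COLUMNS = {
    "DEMO": ["PRIMARYID", "CASEID", "FDA_DT", "EVENT_DT", "AGE", "AGE_COD",
             "SEX", "WT", "WT_COD", "REPORTER_COUNTRY", "OCCP_COD"],
    "DRUG": ["PRIMARYID", "CASEID", "DRUG_SEQ", "ROLE_COD", "DRUGNAME"],
    "REAC": ["PRIMARYID", "CASEID", "PT"],
    "THER": ["PRIMARYID", "CASEID", "DSG_DRUG_SEQ", "START_DT"],
}

_AGE_FACTORS = {"YR": 1.0, "DEC": 10.0, "MON": 1.0 / 12.0,
                "WK": 1.0 / 52.1775, "DY": 1.0 / 365.25}
_WEIGHT_FACTORS = {"KG": 1.0, "LBS": 0.45359237}

AGE_BIN_LABELS = ("<18", "18-65", "65-85", ">85")
WEIGHT_BIN_LABELS = ("<50", "50-100", ">100")
DURATION_BIN_LABELS = ("<365", "365-730", ">730")


# ---------------------------------------------------------------------------
# raw table I/O
# ---------------------------------------------------------------------------

def _read_one(path: Path, table: str) -> tuple[pd.DataFrame, int]:
    """Parse one '$'-delimited file; rows with a wrong field count are
    rejected (counted, not silently dropped into NaN padding)."""
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        header_line = fh.readline().rstrip("\n").rstrip("\r")
        columns = header_line.split("$")
        for col in REQUIRED_COLUMNS[table]:
            if col not in columns:
                raise FormatError(
                    f"{path}: missing mandatory column {col!r} in {table} header")
        ncol = len(columns)
        good: list[list[str]] = []
        bad = 0
        for line in fh:
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("$")
            if len(fields) != ncol:
                bad += 1
                continue
            good.append(fields)
    df = pd.DataFrame(good, columns=columns, dtype=str)
    if bad:
        warnings.warn(f"{path}: rejected {bad} malformed row(s)", stacklevel=3)
    return df, bad


def read_faers_tables(paths) -> dict[str, pd.DataFrame]:
    """Read DEMO/DRUG/REAC/THER tables.

    Parameters
    ----------
    paths : mapping table-name -> file path, or a directory containing
        ``DEMO.txt``/``DRUG.txt``/``REAC.txt``/``THER.txt``.

    Returns a dict of string-typed DataFrames; the number of rejected rows
    per table is attached as ``df.attrs['n_malformed']``.
    """
    if isinstance(paths, (str, Path)):
        base = Path(paths)
        paths = {t: base / f"{t}.txt" for t in REQUIRED_COLUMNS}
    tables: dict[str, pd.DataFrame] = {}
    for table in REQUIRED_COLUMNS:
        p = Path(paths[table])
        if not p.exists():
            raise FormatError(f"{table} file not found: {p}")
        df, bad = _read_one(p, table)
        df.attrs["n_malformed"] = bad
        tables[table] = df
    return tables


def write_faers_tables(tables: dict[str, pd.DataFrame], outdir) -> None:
    """Write tables back in the same '$'-delimited dialect."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        buf = io.StringIO()
        df.astype(str).replace("nan", "").to_csv(buf, sep="$", index=False)
        (outdir / f"{name}.txt").write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# dictionaries
# ---------------------------------------------------------------------------

def _norm_name(name: str) -> str:
    return " ".join(str(name).split()).casefold()


@dataclass
class DrugDictionary:
    """Canonical generic name -> synonym set (generic + brand spellings).

    Matching is exact on the normalized string (trimmed, internal whitespace
    collapsed, case-insensitive) — deliberately *not* substring matching,
    which would hit combination-product strings.
    """

    synonyms: dict[str, set[str]]
    _lookup: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self):
        canon_norm = [_norm_name(c) for c in self.synonyms]
        if len(set(canon_norm)) != len(canon_norm):
            raise ConfigurationError("canonical drug names collide case-insensitively")
        self._lookup = {}
        for canonical, syns in self.synonyms.items():
            if not syns:
                raise ConfigurationError(f"empty synonym set for {canonical!r}")
            self._lookup[_norm_name(canonical)] = canonical
            for s in syns:
                self._lookup[_norm_name(s)] = canonical

    @classmethod
    def from_csv(cls, path) -> "DrugDictionary":
        df = pd.read_csv(path, dtype=str, comment="#")
        syn: dict[str, set[str]] = {}
        for canonical, s in zip(df.iloc[:, 0], df.iloc[:, 1]):
            syn.setdefault(canonical, set()).add(s)
        return cls(syn)

    @property
    def canonical_names(self) -> list[str]:
        return sorted(self.synonyms)

    def match(self, verbatim_name) -> str | None:
        if verbatim_name is None or (isinstance(verbatim_name, float) and np.isnan(verbatim_name)):
            return None
        return self._lookup.get(_norm_name(verbatim_name))

    def match_series(self, names: pd.Series) -> pd.Series:
        return names.map(_norm_name).map(self._lookup)


def match_drug(verbatim_name, dictionary: DrugDictionary) -> str | None:
    """Exact-synonym drug matching; returns the canonical name or None."""
    return dictionary.match(verbatim_name)


@dataclass
class SmqMap:
    """MedDRA PT -> (event category, SMQ scope flag in {narrow, broad})."""

    mapping: dict[str, tuple[str, str]]
    _lookup: dict[str, tuple[str, str, str]] = field(init=False, repr=False)

    def __post_init__(self):
        self._lookup = {}
        for pt, (cat, scope) in self.mapping.items():
            if scope not in ("narrow", "broad"):
                raise ConfigurationError(f"bad scope {scope!r} for PT {pt!r}")
            self._lookup[_norm_name(pt)] = (pt, cat, scope)

    @classmethod
    def from_csv(cls, path) -> "SmqMap":
        df = pd.read_csv(path, dtype=str, comment="#")
        return cls({r.iloc[0]: (r.iloc[1], r.iloc[2]) for _, r in df.iterrows()})

    @property
    def categories(self) -> list[str]:
        return sorted({cat for cat, _ in self.mapping.values()})

    @property
    def pts(self) -> list[str]:
        return sorted(self.mapping)

    def lookup(self, pt: str):
        return self._lookup.get(_norm_name(pt))


def map_events(reactions, smq_map: SmqMap, scope: str = "narrow"):
    """Map reported PTs to event categories, dropping unmapped PTs.

    ``scope='narrow'`` keeps only narrow-scope PTs (the default, favouring
    specificity); ``scope='narrow+broad'`` keeps both.
    """
    if scope not in ("narrow", "narrow+broad"):
        raise ConfigurationError(f"unknown SMQ scope {scope!r}")
    out = []
    for pt in reactions:
        hit = smq_map.lookup(pt)
        if hit is None:
            continue
        canon_pt, cat, pt_scope = hit
        if pt_scope == "broad" and scope == "narrow":
            continue
        out.append((canon_pt, cat))
    return out


# ---------------------------------------------------------------------------
# deduplication & role filtering
# ---------------------------------------------------------------------------

def deduplicate(demo: pd.DataFrame) -> pd.DataFrame:
    """Keep one DEMO row per CASEID: latest FDA_DT, ties by highest PRIMARYID.

    Partial FDA dates order lexicographically at their available precision
    with missing components treated as earliest.  Output is sorted by
    CASEID, so the result is independent of input row order.
    """
    if demo.empty:
        return demo.copy()
    df = demo.copy()
    df["_fda_key"] = _dates.series_sort_key(df["FDA_DT"])
    df["_pid_key"] = pd.to_numeric(df["PRIMARYID"], errors="coerce").fillna(-1)
    df["_case_key"] = pd.to_numeric(df["CASEID"], errors="coerce")
    df = df.sort_values(["CASEID", "_fda_key", "_pid_key"], kind="mergesort")
    out = df.groupby("CASEID", sort=False).tail(1)
    out = out.sort_values(["_case_key", "CASEID"], kind="mergesort")
    return out.drop(columns=["_fda_key", "_pid_key", "_case_key"]).reset_index(drop=True)


def filter_by_role(cases: pd.DataFrame, allowed_roles=("PS",)) -> pd.DataFrame:
    """Retain clean cases whose matched target drug carries an allowed role.

    Cases with no matched target drug pass through untouched (they form the
    comparator background); target-drug cases whose best role is not allowed
    are dropped, mirroring the exclusion of concomitant/interacting reports.
    """
    allowed = set(allowed_roles)
    if not allowed or not allowed <= set(ROLE_CODES):
        raise ConfigurationError(f"allowed_roles must be a non-empty subset of {ROLE_CODES}")
    has_target = cases["target_drug"].notna()
    ok = ~has_target | cases["target_role"].isin(allowed)
    return cases[ok].reset_index(drop=True)


# ---------------------------------------------------------------------------
# demographic normalization
# ---------------------------------------------------------------------------

def normalize_age(value, unit_code) -> float:
    """Age in years; NaN (with a warning) for unknown units or values
    outside (0, 120]."""
    factor = _AGE_FACTORS.get(str(unit_code).strip().upper())
    if factor is None:
        warnings.warn(f"unknown age unit {unit_code!r}; age set to missing", stacklevel=2)
        return float("nan")
    try:
        years = float(value) * factor
    except (TypeError, ValueError):
        return float("nan")
    if not (0 < years <= 120):
        warnings.warn(f"implausible age {years:.1f} yr; set to missing", stacklevel=2)
        return float("nan")
    return years


def normalize_weight(value, unit_code) -> float:
    """Weight in kg; NaN (with a warning) for unknown units or values
    outside (0, 500]."""
    factor = _WEIGHT_FACTORS.get(str(unit_code).strip().upper())
    if factor is None:
        warnings.warn(f"unknown weight unit {unit_code!r}; weight set to missing", stacklevel=2)
        return float("nan")
    try:
        kg = float(value) * factor
    except (TypeError, ValueError):
        return float("nan")
    if not (0 < kg <= 500):
        warnings.warn(f"implausible weight {kg:.1f} kg; set to missing", stacklevel=2)
        return float("nan")
    return kg


def _normalize_series(values: pd.Series, units: pd.Series, factors, lo, hi):
    f = units.fillna("").str.strip().str.upper().map(factors)
    v = pd.to_numeric(values, errors="coerce") * f
    bad_unit = int((f.isna() & values.notna() & (values.astype(str).str.strip() != "")).sum())
    out_of_range = int(((v <= lo) | (v > hi)).sum())
    v = v.where((v > lo) & (v <= hi))
    return v, bad_unit + out_of_range


# ---------------------------------------------------------------------------
# covariate binning — boundary conventions are declared here once:
# age [0,18) [18,65) [65,85) [85,inf); weight (0,50) [50,100] (100,inf);
# duration [0,365) [365,730] (730,inf).  The printed group labels overlap
# ("18-65"/"65-85"); one convention has to be fixed for reproducibility.
# ---------------------------------------------------------------------------

def bin_age(age_years) -> pd.Series:
    a = pd.to_numeric(pd.Series(age_years), errors="coerce")
    out = pd.Series(pd.NA, index=a.index, dtype="object")
    out[a < 18] = "<18"
    out[(a >= 18) & (a < 65)] = "18-65"
    out[(a >= 65) & (a < 85)] = "65-85"
    out[a >= 85] = ">85"
    return out


def bin_weight(weight_kg) -> pd.Series:
    w = pd.to_numeric(pd.Series(weight_kg), errors="coerce")
    out = pd.Series(pd.NA, index=w.index, dtype="object")
    out[w < 50] = "<50"
    out[(w >= 50) & (w <= 100)] = "50-100"
    out[w > 100] = ">100"
    return out


def bin_duration(days) -> pd.Series:
    t = pd.to_numeric(pd.Series(days), errors="coerce")
    out = pd.Series(pd.NA, index=t.index, dtype="object")
    out[(t >= 0) & (t < 365)] = "<365"
    out[(t >= 365) & (t <= 730)] = "365-730"
    out[t > 730] = ">730"
    return out


BIN_CONVENTION = ("age [0,18)/[18,65)/[65,85)/[85,inf); "
                  "weight (0,50)/[50,100]/(100,inf) kg; "
                  "duration [0,365)/[365,730]/(730,inf) days")


# ---------------------------------------------------------------------------
# the clean-case container and full cleaning pass
# ---------------------------------------------------------------------------

@dataclass
class CleanCases:
    """Analysis-ready deduplicated cases.

    Attributes
    ----------
    cases : one row per CASEID — demographics (normalized + binned), the
        matched target drug and its best role, therapy start / event dates,
        and ``case_class`` in {'target', 'background', 'excluded_role'}.
    events : tidy frame, one row per (case_id, matched PT) with its event
        category; only SMQ-mapped PTs appear here.
    flow : stage-by-stage row accounting for the run log.
    """

    cases: pd.DataFrame
    events: pd.DataFrame
    flow: dict

    @property
    def analysis_cases(self) -> pd.DataFrame:
        """Cases entering the 2x2 universe (role-excluded reports dropped)."""
        return self.cases[self.cases["case_class"] != "excluded_role"]

    def to_tidy_csv(self, path) -> None:
        """One row per (case, matched PT); event-free cases keep one row
        with an empty PT."""
        merged = self.cases.merge(self.events, on="case_id", how="left")
        merged.to_csv(path, index=False)


_CASE_COLUMNS = ["case_id", "primary_id", "fda_dt", "event_dt", "age_yr",
                 "age_group", "sex", "wt_kg", "wt_group", "country",
                 "reporter", "target_drug", "target_role", "start_dt",
                 "n_reactions", "case_class"]


def _empty_clean() -> CleanCases:
    return CleanCases(
        cases=pd.DataFrame(columns=_CASE_COLUMNS),
        events=pd.DataFrame(columns=["case_id", "pt", "category"]),
        flow={"versions_in": 0, "cases_after_dedup": 0, "target_cases": 0,
              "background_cases": 0, "excluded_by_role": 0,
              "age_warnings": 0, "weight_warnings": 0},
    )


def build_clean_cases(tables: dict[str, pd.DataFrame],
                      drug_dict: DrugDictionary,
                      smq_map: SmqMap,
                      allowed_roles=("PS",),
                      scope: str = "narrow") -> CleanCases:
    """Run the full cleaning pass: dedup -> drug match -> role filter ->
    event mapping -> demographic normalization.

    Role-excluded target-drug reports are kept in ``cases`` (flagged
    ``excluded_role``) so the flow log conserves counts, but they are absent
    from :attr:`CleanCases.analysis_cases`.
    """
    allowed = set(allowed_roles)
    if not allowed or not allowed <= set(ROLE_CODES):
        raise ConfigurationError(f"allowed_roles must be a non-empty subset of {ROLE_CODES}")
    if scope not in ("narrow", "narrow+broad"):
        raise ConfigurationError(f"unknown SMQ scope {scope!r}")

    demo = tables["DEMO"]
    if demo.empty:
        return _empty_clean()

    final = deduplicate(demo)
    pid = final["PRIMARYID"]
    keep_pid = set(pid)

    # --- drug matching -----------------------------------------------------
    drug = tables["DRUG"]
    drug = drug[drug["PRIMARYID"].isin(keep_pid)].copy()
    drug["canonical"] = drug_dict.match_series(drug["DRUGNAME"].fillna(""))
    tgt = drug[drug["canonical"].notna()].copy()
    if not tgt.empty:
        tgt["_role_rank"] = tgt["ROLE_COD"].str.strip().str.upper().map(_ROLE_RANK).fillna(9)
        tgt = tgt.sort_values(["CASEID", "_role_rank", "canonical"], kind="mergesort")
        best = tgt.groupby("CASEID", sort=False).head(1)
        case_drug = best.set_index("CASEID")[["canonical", "ROLE_COD"]]
    else:
        case_drug = pd.DataFrame(columns=["canonical", "ROLE_COD"])

    cases = final[["CASEID", "PRIMARYID", "FDA_DT", "EVENT_DT"]].copy()
    cases.columns = ["case_id", "primary_id", "fda_dt", "event_dt"]
    cases["target_drug"] = cases["case_id"].map(case_drug["canonical"]) \
        if not case_drug.empty else pd.NA
    cases["target_role"] = (cases["case_id"].map(case_drug["ROLE_COD"])
                            if not case_drug.empty else pd.NA)
    cases["target_role"] = cases["target_role"].astype("string").str.strip().str.upper()

    has_target = cases["target_drug"].notna()
    role_ok = cases["target_role"].isin(allowed)
    cases["case_class"] = np.select(
        [has_target & role_ok, has_target & ~role_ok],
        ["target", "excluded_role"], default="background")

    # --- reactions / SMQ events -------------------------------------------
    reac = tables["REAC"]
    reac = reac[reac["PRIMARYID"].isin(keep_pid)].copy()
    n_reac = reac.groupby("CASEID")["PT"].nunique()
    cases["n_reactions"] = cases["case_id"].map(n_reac).fillna(0).astype(int)

    lut = {key: (pt, cat, sc) for key, (pt, cat, sc) in smq_map._lookup.items()}
    norm = reac["PT"].fillna("").map(_norm_name)
    hit = norm.map(lut)
    ev = reac[hit.notna()].copy()
    if not ev.empty:
        ev["pt"] = hit[hit.notna()].map(lambda t: t[0])
        ev["category"] = hit[hit.notna()].map(lambda t: t[1])
        ev["_scope"] = hit[hit.notna()].map(lambda t: t[2])
        if scope == "narrow":
            ev = ev[ev["_scope"] == "narrow"]
        # one deduplicated case contributes at most one row per PT
        events = (ev.rename(columns={"CASEID": "case_id"})
                    [["case_id", "pt", "category"]]
                    .drop_duplicates(["case_id", "pt"])
                    .sort_values(["case_id", "pt"], kind="mergesort")
                    .reset_index(drop=True))
    else:
        events = pd.DataFrame(columns=["case_id", "pt", "category"])

    # --- therapy start (earliest complete date for the matched drug) -------
    ther = tables["THER"]
    ther = ther[ther["PRIMARYID"].isin(keep_pid)].copy()
    if not ther.empty and not tgt.empty:
        link = ther.merge(
            tgt[["PRIMARYID", "DRUG_SEQ", "canonical"]],
            left_on=["PRIMARYID", "DSG_DRUG_SEQ"],
            right_on=["PRIMARYID", "DRUG_SEQ"], how="inner")
        link = link.merge(cases[["case_id", "target_drug"]],
                          left_on="CASEID", right_on="case_id", how="inner")
        link = link[link["canonical"] == link["target_drug"]]
        link = link[link["START_DT"].map(_dates.is_complete)]
        if not link.empty:
            link["_key"] = _dates.series_sort_key(link["START_DT"])
            link = link.sort_values(["case_id", "_key"], kind="mergesort")
            start = link.groupby("case_id", sort=False)["START_DT"].first()
        else:
            start = pd.Series(dtype=str)
    else:
        start = pd.Series(dtype=str)
    cases["start_dt"] = cases["case_id"].map(start)

    # --- demographics ------------------------------------------------------
    age_yr, n_age_warn = _normalize_series(final["AGE"], final["AGE_COD"],
                                           _AGE_FACTORS, 0.0, 120.0)
    wt_kg, n_wt_warn = _normalize_series(final["WT"], final["WT_COD"],
                                         _WEIGHT_FACTORS, 0.0, 500.0)
    cases["age_yr"] = age_yr.to_numpy()
    cases["wt_kg"] = wt_kg.to_numpy()
    cases["age_group"] = bin_age(cases["age_yr"]).to_numpy()
    cases["wt_group"] = bin_weight(cases["wt_kg"]).to_numpy()
    sex = final["SEX"].fillna("").str.strip().str.upper()
    cases["sex"] = sex.where(sex.isin(["F", "M"])).to_numpy()
    country = final["REPORTER_COUNTRY"].fillna("").str.strip()
    cases["country"] = country.where(country != "").to_numpy()
    occ = final["OCCP_COD"].fillna("").str.strip().str.upper()
    cases["reporter"] = occ.where(occ != "").to_numpy()

    cases = cases[_CASE_COLUMNS].reset_index(drop=True)
    flow = {
        "versions_in": int(len(demo)),
        "cases_after_dedup": int(len(cases)),
        "target_cases": int((cases["case_class"] == "target").sum()),
        "background_cases": int((cases["case_class"] == "background").sum()),
        "excluded_by_role": int((cases["case_class"] == "excluded_role").sum()),
        "age_warnings": n_age_warn,
        "weight_warnings": n_wt_warn,
    }
    return CleanCases(cases=cases, events=events, flow=flow)
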