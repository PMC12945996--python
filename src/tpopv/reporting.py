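"""Pipeline orchestration and machine-readable report tables.

Runs the full chain — (optional) synthetic generation, ingest/cleaning,
disproportionality scan, time-to-onset summary, logistic risk models — and
writes one tidy CSV per table a pharmacovigilance write-up needs:
per-drug demographics, PT- and category-level signal tables, forest-plot
data, TTO bins/quartiles, and the univariable + multivariable odds-ratio
tables.  Every file carries the manifest hash of the run options, and a
flow log accounts for every report at every stage.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import disprop, risk, tto
from .errors import PipelineError
from .ingest import (BIN_CONVENTION, CleanCases, DrugDictionary, SmqMap,
                     build_clean_cases, read_faers_tables)
from .resources import default_drug_dictionary, default_smq_map
from .synthetic import GeneratorConfig, generate_reports

__all__ = ["RunConfig", "run_pipeline", "summarize_demographics",
           "count_thromboembolic_reports", "forest_data"]


def _plain(obj):
    """Recursively convert dataclasses/tuples/numpy scalars for YAML."""
    if is_dataclass(obj) and not isinstance(obj, type):
        return _plain(asdict(obj))
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    return obj


@dataclass
class RunConfig:
    """Everything a run depends on; echoed into the manifest."""

    output_dir: str = "tpopv_out"
    input_dir: str | None = None           # FAERS-dialect directory ...
    synthetic: GeneratorConfig | None = None  # ... or a generator config
    drug_dictionary: str | None = None     # CSV path; bundled default if None
    smq_map: str | None = None             # CSV path; bundled default if None
    allowed_roles: tuple = ("PS",)
    scope: str = "narrow"
    background_policy: str = "all-other-drugs"
    bcpnn_gate: str = "e_ic"
    yates: bool = False
    alpha: float = 0.05
    seed: int = 0

    def manifest(self) -> dict:
        d = _plain(asdict(self))
        d["allowed_roles"] = sorted(self.allowed_roles)
        d["bin_convention"] = BIN_CONVENTION
        d["quantile_method"] = "linear interpolation between order statistics"
        return d

    def manifest_hash(self) -> str:
        opts = self.manifest()
        opts.pop("output_dir", None)  # where results land is not an analysis option
        payload = yaml.safe_dump(opts, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# descriptive tables
# ---------------------------------------------------------------------------

def summarize_demographics(clean: CleanCases, drug: str) -> pd.DataFrame:
    """Table-style descriptive summary for one drug's cases.

    Counts and percentages per category with an explicit NA row;
    percentages use all cases of the drug as denominator (so categories
    plus NA sum to 100%).  Countries list the top 5 by count, descending.
    """
    cases = clean.cases[(clean.cases["target_drug"] == drug)
                        & (clean.cases["case_class"] == "target")]
    total = len(cases)
    rows: list[dict] = []

    def block(characteristic: str, series: pd.Series, levels=None, top=None):
        s = series.astype("object")
        counts = s.value_counts(dropna=True)
        if levels is None:
            levels = list(counts.index)
            if top is not None:
                levels = levels[:top]
        for level in levels:
            n = int(counts.get(level, 0))
            rows.append({"characteristic": characteristic, "level": str(level),
                         "n": n, "pct": round(100.0 * n / total, 1) if total else np.nan})
        if top is None:  # NA row only for exhaustive blocks
            n_na = int(s.isna().sum())
            rows.append({"characteristic": characteristic, "level": "NA",
                         "n": n_na,
                         "pct": round(100.0 * n_na / total, 1) if total else np.nan})

    if total == 0:
        return pd.DataFrame(columns=["characteristic", "level", "n", "pct"])
    block("Gender", cases["sex"], levels=["F", "M"])
    block("Age", cases["age_group"], levels=["<18", "18-65", "65-85", ">85"])
    block("Weight", cases["wt_group"], levels=["<50", "50-100", ">100"])
    block("Country", cases["country"], top=5)
    block("Reporter", cases["reporter"])
    return pd.DataFrame(rows)


def count_thromboembolic_reports(clean: CleanCases) -> pd.DataFrame:
    """Per-drug unique thromboembolic report counts plus their total.

    A report counts when its matched target drug passed the role filter and
    it mentions at least one mapped event PT; the Total row is the sum of
    the per-drug counts (each case has exactly one matched drug, so the
    bookkeeping is conservative by construction).
    """
    cases = clean.cases[clean.cases["case_class"] == "target"]
    hit = cases[cases["case_id"].isin(set(clean.events["case_id"]))]
    per_drug = hit.groupby("target_drug").size().sort_index()
    out = per_drug.reset_index()
    out.columns = ["drug", "n_reports"]
    out.loc[len(out)] = ["Total", int(per_drug.sum())]
    return out


def forest_data(signals: pd.DataFrame) -> pd.DataFrame:
    """Log-scale ROR point estimates and CI bounds per pair, for forest
    plots."""
    cols = ["drug", "event", "a", "ror", "ror_low", "ror_high"]
    out = signals[cols].copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        out["log_ror"] = np.log(out["ror"])
        out["log_low"] = np.log(out["ror_low"])
        out["log_high"] = np.log(out["ror_high"])
    return out


# ---------------------------------------------------------------------------
# the orchestrated run
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: Path, mhash: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# manifest_hash={mhash}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the output bundle.

    Returns a dict with the in-memory results (clean cases, signal tables,
    TTO summary, fits, flow log).  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    mhash = config.manifest_hash()
    stage = "setup"
    try:
        stage = "load-dictionaries"
        ddict = (DrugDictionary.from_csv(config.drug_dictionary)
                 if config.drug_dictionary else default_drug_dictionary())
        smq = (SmqMap.from_csv(config.smq_map)
               if config.smq_map else default_smq_map())

        stage = "acquire-tables"
        if config.synthetic is not None:
            dataset = generate_reports(config.synthetic)
            tables = dataset.tables
            dataset.truth.write(outdir / "ground_truth")
        elif config.input_dir is not None:
            tables = read_faers_tables(config.input_dir)
        else:
            raise PipelineError("RunConfig needs input_dir or a synthetic config")

        stage = "clean"
        clean = build_clean_cases(tables, ddict, smq,
                                  allowed_roles=config.allowed_roles,
                                  scope=config.scope)

        stage = "demographics"
        drugs = sorted(set(clean.cases.loc[clean.cases["case_class"] == "target",
                                           "target_drug"].dropna()))
        for drug in drugs:
            _write_csv(summarize_demographics(clean, drug),
                       outdir / f"demographics_{drug}.csv", mhash)
        _write_csv(count_thromboembolic_reports(clean),
                   outdir / "report_counts.csv", mhash)

        stage = "signals"
        sig_pt = disprop.scan_all_signals(clean, level="pt", yates=config.yates,
                                          bcpnn_gate=config.bcpnn_gate)
        sig_smq = disprop.scan_all_signals(clean, level="smq", yates=config.yates,
                                           bcpnn_gate=config.bcpnn_gate)
        _write_csv(sig_pt, outdir / "signals_pt.csv", mhash)
        _write_csv(sig_smq, outdir / "signals_smq.csv", mhash)
        _write_csv(forest_data(sig_pt), outdir / "forest_data.csv", mhash)

        stage = "tto"
        records = tto.compute_tto_frame(clean)
        included = records.loc[records["status"] == tto.STATUS_INCLUDED, "tto_days"]
        summary = tto.summarize_tto(included.astype(float))
        _write_csv(records, outdir / "tto_records.csv", mhash)
        _write_csv(summary.to_frame(), outdir / "tto_summary.csv", mhash)

        stage = "regression"
        data = risk.build_model_input(clean)
        fits: dict[str, risk.LogisticFit] = {}
        uni_tables = []
        for cov in risk.MODEL_COVARIATES:
            sub = data[cov].dropna()
            if sub.nunique() < 2 or data.loc[sub.index, "y"].nunique() < 2:
                continue
            fit = risk.fit_univariable(data, cov)
            fits[cov] = fit
            uni_tables.append(fit.table)
        selected = risk.screen_covariates(fits, alpha=config.alpha)
        if uni_tables:
            _write_csv(pd.concat(uni_tables, ignore_index=True),
                       outdir / "regression_univariable.csv", mhash)
        multi = None
        if selected:
            multi = risk.fit_multivariable(data, selected)
            _write_csv(multi.table, outdir / "regression_multivariable.csv", mhash)

        stage = "manifest"
        flow = dict(clean.flow)
        flow.update({
            "tto_included": int(summary.n_included),
            "tto_excluded_negative": int((records["status"] == tto.STATUS_NEGATIVE).sum()),
            "tto_excluded_incomplete": int((records["status"] == tto.STATUS_INCOMPLETE).sum()),
            "tto_excluded_missing": int((records["status"] == tto.STATUS_MISSING).sum()),
            "covariates_selected": selected,
        })
        manifest = config.manifest()
        manifest["manifest_hash"] = mhash
        manifest["flow"] = flow
        (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
        with open(outdir / "flow_log.txt", "w") as fh:
            for k, v in flow.items():
                fh.write(f"{k}: {v}\n")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-tag with stage context
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    return {"clean": clean, "signals_pt": sig_pt, "signals_smq": sig_smq,
            "tto_records": records, "tto_summary": summary,
            "univariable": fits, "selected": selected, "multivariable": multi,
            "flow": flow, "manifest_hash": mhash}
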