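"""End-to-end pipeline runner: filter -> match -> cells -> estimate -> misclassification.

The pipeline is configured by a YAML file (paths plus per-stage parameter
blocks) and is deterministic given the configured seed; every run writes
its stage artifacts plus a manifest carrying the config hash, seed and
package version.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .capture import build_capture_cells, fit_loglinear, coverage_proportions, sensitivity_scan
from .filters import apply_filters
from .matching import MatchRules, match_records, summarize_match_rates
from .misclassification import (
    fit_multilevel_logistic,
    is_legal_intervention,
    marginal_probabilities,
    state_rate_bands,
    tabulate_misclassification,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """Stage failure with a machine-readable stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.message = message


@dataclass
class PipelineConfig:
    incidents: str
    mortality: str
    monthly_counts: str
    counties: str | None
    outdir: str
    study_year: int = 2015
    match: dict = field(default_factory=dict)
    estimate: dict = field(default_factory=dict)
    misclass: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        inputs = raw.get("inputs", {})
        return cls(
            incidents=inputs.get("incidents"),
            mortality=inputs.get("mortality"),
            monthly_counts=inputs.get("monthly_counts"),
            counties=inputs.get("counties"),
            outdir=raw.get("outdir", "."),
            study_year=int(raw.get("study_year", 2015)),
            match=raw.get("match", {}) or {},
            estimate=raw.get("estimate", {}) or {},
            misclass=raw.get("misclass", {}) or {},
            seed=int(raw.get("seed", 0)),
        )

    def digest(self) -> str:
        """Hash of the analysis parameters (paths excluded, so identical
        analyses into different directories share a digest)."""
        payload = repr(
            (self.study_year, sorted(self.match.items()),
             sorted(self.estimate.items()), sorted(self.misclass.items()), self.seed)
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run report (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "package_version": __version__,
            "config_sha256": config.digest(),
            "seed": config.seed,
            "schema_version": io.SCHEMA_VERSION,
        }
    }

    # ---- filter ------------------------------------------------------
    try:
        raw = io.read_incidents(config.incidents)
        included, tally = apply_filters(raw, study_year=config.study_year)
        io.write_incidents(included, outdir / "included.csv")
        io.write_json(
            {"excluded": tally, "included": len(included), "total": len(raw)},
            outdir / "filter_tally.json",
        )
        report["filter"] = {"total": len(raw), "included": len(included), "excluded": tally}
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("filter", str(exc)) from exc

    # ---- match -------------------------------------------------------
    try:
        mortality = io.read_mortality(config.mortality)
        rules = MatchRules(**config.match) if config.match else MatchRules()
        results = match_records(included, mortality, rules, study_year=config.study_year)
        results.to_csv(outdir / "matches.csv", index=False)
        included = included.assign(
            mechanism_group=np.where(included["mechanism"] == "firearm", "firearm", "non_firearm")
        )
        rate_covs = [c for c in ("mechanism_group", "gender", "race_ethnicity") if c in included]
        rates = summarize_match_rates(results, included, rate_covs)
        rates.to_csv(outdir / "match_rates.csv", index=False)
        n_matched = int(results["mortality_id"].notna().sum())
        report["match"] = {
            "incidents": len(included),
            "matched": n_matched,
            "match_rate": n_matched / len(included) if len(included) else float("nan"),
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("match", str(exc)) from exc

    # ---- capture cells + estimate ------------------------------------
    try:
        monthly = io.read_monthly_counts(config.monthly_counts)
        merged = included.merge(
            results[results["mortality_id"].notna()], left_on="record_id", right_on="incident_id"
        ).merge(mortality, left_on="mortality_id", right_on="record_id", suffixes=("", "_mort"))
        merged["classified"] = merged["multiple_causes"].map(is_legal_intervention)
        matched_frame = merged[["death_date", "classified"]]
        unmatched_ids = set(results.loc[results["mortality_id"].isna(), "incident_id"])
        unmatched_dates = included.loc[included["record_id"].isin(unmatched_ids), "injury_date"]
        cells = build_capture_cells(matched_frame, unmatched_dates, monthly)
        cells.to_csv(outdir / "cells.csv", index=False)

        alpha = float(config.estimate.get("alpha", 0.0))
        est = fit_loglinear(cells, alpha=alpha)
        coverage = coverage_proportions(est, len(included), int(monthly["count"].sum()))
        est_report = {
            "alpha": alpha,
            "n_hat": est.n_hat,
            "n_hat_rounded": est.n_hat_rounded,
            "n_hat_ci": list(est.n_hat_ci),
            "n00_hat": est.n00_hat,
            "n00_ci": list(est.n00_ci),
            "coverage": {
                k: {"documented": r.documented, "coverage": r.coverage, "ci": list(r.ci)}
                for k, r in coverage.items()
            },
        }
        grid = config.estimate.get("alpha_grid")
        if grid:
            scan = sensitivity_scan(cells, [float(a) for a in grid])
            scan.to_csv(outdir / "sensitivity.csv", index=False)
            est_report["sensitivity"] = scan.to_dict(orient="records")
        io.write_json(est_report, outdir / "estimate.json")
        report["estimate"] = est_report
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("estimate", str(exc)) from exc

    # ---- misclassification -------------------------------------------
    try:
        merged["misclassified"] = ~merged["classified"]
        covariates = config.misclass.get(
            "covariates", ["mechanism_group", "gender", "race_ethnicity", "age_group"]
        )
        covariates = [c for c in covariates if c in merged.columns]
        tables = pd.concat(
            [tabulate_misclassification(merged, cov) for cov in covariates],
            ignore_index=True,
        )
        tables.to_csv(outdir / "misclass_tables.csv", index=False)
        bands = state_rate_bands(merged)
        bands.to_csv(outdir / "state_bands.csv", index=False)
        report["misclass"] = {
            "n": len(merged),
            "misclassified": int(merged["misclassified"].sum()),
            "rate": float(merged["misclassified"].mean()),
        }

        model_mode = config.misclass.get("model", "none")
        if model_mode != "none":
            if not config.counties:
                raise ValueError("county covariate file required for the multilevel model")
            counties = io.read_counties(config.counties)
            fit = fit_multilevel_logistic(merged, counties, mode=model_mode)
            fits = fit if isinstance(fit, dict) else {"multivariable": fit}
            model_report = {}
            for name, f in fits.items():
                model_report[name] = {
                    "or_table": f.or_table.reset_index().to_dict(orient="records"),
                    "sigma2_county": f.sigma2_county,
                    "sigma2_state": f.sigma2_state,
                    "converged": f.converged,
                }
            io.write_json(model_report, outdir / "misclass_model.json")
            report["misclass"]["model"] = model_report
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("misclass", str(exc)) from exc

    io.write_json(report, outdir / "report.json")
    return report
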