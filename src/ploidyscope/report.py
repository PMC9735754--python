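"""Report layer: scenario presets, pipeline runs, and the study reproduction.

Every number in a report is computed by an operation in the measurement,
ploidy, diagnostics or regression modules — this layer only arranges results.
Reports are plain dicts serialized as sorted-key JSON with no timestamps, so
identical configuration and seeds give byte-identical files.
"""
from __future__ import annotations

import json
from pathlib import Path

from . import diagnostics, ploidy, regression, synthetic
from .config import PipelineConfig
from .diagnostics import round_half_up

__all__ = [
    "population_preset",
    "PRESET_NAMES",
    "run_simulate",
    "run_analyze",
    "run_evaluate",
    "run_regress",
    "run_reproduce_study",
    "write_report",
]

PRESET_NAMES = ("euploid-polyploid", "aneuploid-3.52c", "aneuploid-3.24c-6.5c")

#: printed summary statistics of the source study that the packaged cohort
#: fixture reconstructs; used only for the reproduction report's check column
EXPECTED_STUDY_METRICS = {
    "cytology": {"specificity_pct": 69.4, "sensitivity_pct": 100.0,
                 "ppv_pct": 77.4, "npv_pct": 100.0, "auc": 0.85},
    "icm": {"specificity_pct": 98.0, "sensitivity_pct": 93.5,
            "ppv_pct": 98.0, "npv_pct": 93.5, "auc": 0.96},
    "conditional_or_icm": 201.6,
    "total_cases": 602,
}


def population_preset(name: str, seed: int = 0, n_analysis: int = 300) -> synthetic.PopulationSpec:
    """Named cell-population scenarios mirroring the study's worked histograms.

    - ``euploid-polyploid``: proliferating euploid population — 2c stemline
      with its 4c doubling peak and S phase, a smaller 4c line whose own 8c
      doubling peak and S phase reach single cells above 8c, no cells beyond
      9c.  Expected verdict: non-aneuploid.
    - ``aneuploid-3.52c``: residual diploid cells plus an atypical stemline
      at 3.52c with its 7.04c doubling peak and two rare events above 9c.
      Expected: aneuploid (stemline + single-cell).
    - ``aneuploid-3.24c-6.5c``: atypical stemline at 3.24c with a secondary
      line at 6.5c (its approximate doubling) and several cells above 9c.
      Expected: aneuploid.
    """
    S = synthetic.StemlineSpec
    if name == "euploid-polyploid":
        return synthetic.PopulationSpec(
            stemlines=[
                S(position=2.0, fraction=0.50, doubling_fraction=0.15, s_phase_fraction=0.08),
                S(position=4.0, fraction=0.10, doubling_fraction=0.05, s_phase_fraction=0.04),
            ],
            rare_event_count=0, n_analysis=n_analysis, seed=seed,
        )
    if name == "aneuploid-3.52c":
        return synthetic.PopulationSpec(
            stemlines=[
                S(position=2.0, fraction=0.15),
                S(position=3.52, fraction=0.45, doubling_fraction=0.15, s_phase_fraction=0.08),
            ],
            rare_event_count=2, n_analysis=n_analysis, seed=seed,
        )
    if name == "aneuploid-3.24c-6.5c":
        return synthetic.PopulationSpec(
            stemlines=[
                S(position=3.24, fraction=0.45, doubling_fraction=0.10, s_phase_fraction=0.08),
                S(position=6.5, fraction=0.15),
            ],
            rare_event_count=5, n_analysis=n_analysis, seed=seed,
        )
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


def run_simulate(config: PipelineConfig, out_dir, preset: str | None = None,
                 n_specimens: int = 1) -> dict:
    """Generate synthetic specimens; write the per-cell CSV and truth labels."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    specimens, truth = [], []
    for i in range(n_specimens):
        seed = config.seed + i
        spec = (population_preset(preset, seed=seed) if preset
                else population_preset("euploid-polyploid", seed=seed))
        syn = synthetic.generate_population(spec)
        syn.specimen.specimen_id = f"sim{i:04d}"
        specimens.append(syn.specimen)
        truth.append({
            "specimen_id": syn.specimen.specimen_id,
            "classification": syn.truth_classification,
            "stemline_positions": syn.truth_stemline_positions,
        })
    cells_path = out_dir / "cells.csv"
    ploidy.write_cells_csv(cells_path, specimens)
    with open(out_dir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return {"cells_csv": str(cells_path), "truth_json": str(out_dir / "truth.json"),
            "n_specimens": n_specimens,
            "n_rows": sum(len(s.measurements) for s in specimens)}


def run_analyze(cells_csv, out_path, config: PipelineConfig | None = None) -> dict:
    """Normalize and classify every specimen in a per-cell CSV."""
    config = config or PipelineConfig()
    thresholds = config.thresholds.to_thresholds()
    results = {}
    for specimen in ploidy.read_cells_csv(cells_csv):
        results[specimen.specimen_id] = ploidy.analyze_specimen(
            specimen,
            thresholds,
            min_stemline_fraction=config.min_stemline_fraction,
            min_stemline_cells=config.min_stemline_cells,
            bandwidth=config.kde_bandwidth,
        )
    ploidy.write_results_json(out_path, results)
    return {sid: r.classification for sid, r in results.items()}


def _metrics_block(table, ci_level: float) -> dict:
    m = diagnostics.metrics(table, ci_level)

    def prop(p):
        if p.estimate is None:
            return {"estimate": None}
        return {
            "estimate": p.estimate,
            "pct": round_half_up(100 * p.estimate, 1),
            "ci_pct": [round_half_up(100 * p.ci_low, 1), round_half_up(100 * p.ci_high, 1)],
        }

    return {
        "counts": {"tp": table.tp, "fp": table.fp, "fn": table.fn, "tn": table.tn},
        "specificity": prop(m.specificity),
        "sensitivity": prop(m.sensitivity),
        "ppv": prop(m.ppv),
        "npv": prop(m.npv),
        "auc": {
            "estimate": m.auc.estimate,
            "display": round_half_up(m.auc.estimate, 2),
            "ci": [round_half_up(m.auc.ci_low, 2), round_half_up(m.auc.ci_high, 2)],
        },
    }


def run_evaluate(cohort_df, ci_level: float = 0.95, roc_path=None) -> dict:
    """Summary-table evaluation of both tests on a per-case cohort table."""
    table_cyt = diagnostics.confusion_from_cohort(cohort_df, "cytology")
    table_icm = diagnostics.confusion_from_cohort(cohort_df, "icm")
    report = {
        "n_cases": int(len(cohort_df)),
        "cytology": _metrics_block(table_cyt, ci_level),
        "icm": _metrics_block(table_icm, ci_level),
        "auc_comparison": diagnostics.compare_auc(table_cyt, table_icm, cohort_df),
    }
    if roc_path is not None:
        _plot_roc({"cytology": table_cyt, "DNA-ICM": table_icm}, roc_path)
        report["roc_plot"] = str(roc_path)
    return report


def _plot_roc(tables: dict, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, t in tables.items():
        m = diagnostics.metrics(t)
        x = [0, 1 - m.specificity.estimate, 1]
        y = [0, m.sensitivity.estimate, 1]
        ax.plot(x, y, marker="o", label=f"{name} (AUC {m.auc.estimate:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _fit_block(fit: regression.LogisticFit) -> dict:
    def enc(v):
        if v is None:
            return None
        if v == float("inf"):
            return "inf"
        return v

    return {
        "predictors": fit.predictors,
        "coefficients": {k: enc(v) for k, v in fit.coefficients.items()},
        "odds_ratios": {k: enc(v) for k, v in fit.odds_ratios.items()},
        "wald_ci": {k: list(v) if v else None for k, v in fit.wald_ci.items()},
        "converged": fit.converged,
        "separation": fit.separation,
        "notes": fit.notes,
    }


def run_regress(cohort_df, ci_level: float = 0.95) -> dict:
    """Two-step logistic models plus the identifiable conditional odds ratio."""
    grouped = regression.grouped_cohort_from_frame(cohort_df)
    model1 = regression.fit_logistic_grouped(grouped, ["cytology"])
    model2 = regression.fit_logistic_grouped(grouped, ["cytology", "icm"])
    cond = regression.conditional_odds_ratio(
        grouped, "icm", stratum={"cytology": 1}, ci_level=ci_level
    )
    return {
        "models": [_fit_block(model1), _fit_block(model2)],
        "conditional_or_icm_within_cytology_positive": cond,
    }


def run_reproduce_study(out_dir=None, ci_level: float = 0.95, seed: int = 0) -> dict:
    """Recompute the study's summary statistics from the packaged fixture.

    Loads (and integrity-checks) the reconstructed 602-case cohort, evaluates
    both tests, fits the two-step logistic models, computes the conditional
    odds ratio for the ploidy verdict within cytology-positive cases, and
    compares the recomputed display values against the study's printed ones.
    """
    spec, payload = synthetic.load_study_cohort(verify=True)
    rows = synthetic.generate_cohort(spec, seed=seed)
    df = synthetic.cohort_to_frame(rows)

    evaluation = run_evaluate(df)
    regress = run_regress(df)

    # cytology category x ploidy verdict cross-tabulation
    cyt_by_ploidy = {}
    for cat, label in ((4, "positive"), (3, "suspicious"), (2, "doubtful"), (1, "negative")):
        sub = df[df["cytology"] == cat]
        cyt_by_ploidy[label] = {
            "aneuploid": int((sub["icm"] == "aneuploid").sum()),
            "non_aneuploid": int((sub["icm"] == "non_aneuploid").sum()),
        }

    # criteria-by-outcome cross-tabulation (the part derivable from the fixture)
    criteria = {}
    for verdict in ("aneuploid", "non_aneuploid"):
        sub = df[df["icm"] == verdict]
        criteria[verdict] = {
            "followup_positive": int((sub["followup"] == "positive").sum()),
            "followup_negative": int((sub["followup"] == "negative").sum()),
        }
    criteria["benign_criteria_split"] = payload["benign_criteria_split"]

    cond = regress["conditional_or_icm_within_cytology_positive"]
    checks = _reproduction_checks(evaluation, cond, len(df))

    report = {
        "total_cases": int(len(df)),
        "diagnostic_metrics": {"cytology": evaluation["cytology"], "icm": evaluation["icm"]},
        "cytology_by_ploidy": cyt_by_ploidy,
        "criteria_crosstab": criteria,
        "auc_comparison": evaluation["auc_comparison"],
        "logistic": regress["models"],
        "conditional_or_icm_within_cytology_positive": cond,
        "checks": checks,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_report(out_dir / "study_report.json", report)
    return report


def _reproduction_checks(evaluation: dict, cond: dict, n_cases: int) -> dict:
    checks = {}
    for test in ("cytology", "icm"):
        exp = EXPECTED_STUDY_METRICS[test]
        got = evaluation[test]
        for key in ("specificity", "sensitivity", "ppv", "npv"):
            checks[f"{test}_{key}"] = {
                "expected": exp[f"{key}_pct"],
                "computed": got[key]["pct"],
                "pass": got[key]["pct"] == exp[f"{key}_pct"],
            }
        checks[f"{test}_auc"] = {
            "expected": exp["auc"],
            "computed": got["auc"]["display"],
            "pass": got["auc"]["display"] == exp["auc"],
        }
    or_display = round_half_up(cond["or"], 1) if cond["or"] else None
    checks["conditional_or_icm"] = {
        "expected": EXPECTED_STUDY_METRICS["conditional_or_icm"],
        "computed": or_display,
        "pass": or_display == EXPECTED_STUDY_METRICS["conditional_or_icm"],
    }
    checks["total_cases"] = {
        "expected": EXPECTED_STUDY_METRICS["total_cases"],
        "computed": n_cases,
        "pass": n_cases == EXPECTED_STUDY_METRICS["total_cases"],
    }
    return checks


def write_report(path, report: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
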