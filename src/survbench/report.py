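"""Assembly of the full validation report and the simulate/influence runs.

``run_validate`` executes every stage of the score-comparison protocol on
one cohort — C-index, per-horizon ROC/AUC with confidence intervals,
threshold metrics at the primary cutoff and at a matched-count cutoff for
the comparator, Gini indices, KM overall and tertile curves, subgroup AUC
tables, the lost-to-follow-up sensitivity analysis, and follow-up
summaries — and writes CSV/JSON tables plus ROC/KM plots. Stage failures
are recorded by stage name; completed stages are still emitted. Outputs
embed the resolved configuration, so runs are self-describing, and are
byte-stable under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import label_at_horizon, read_cohort, summarize_cohort, write_cohort
from .discrimination import (
    auc_confidence_interval,
    concordance_confidence_interval,
    harrell_c,
    roc_auc,
    subgroup_auc,
)
from .influence import (
    aggregate_influences,
    fit_discrete_time_model,
    influence_ranking,
    select_l2,
    standardize,
)
from .km import followup_summary, km_estimate, km_survival_at, tertile_curves
from .simulate import SyntheticConfig, generate_cohort, generate_feature_cohort
from .thresholds import confusion_metrics, flag_high_risk, gini_index, matched_count_cutoff

logger = logging.getLogger("survbench")

__all__ = ["RunConfig", "run_validate", "run_simulate", "run_influence"]

SCORE_COLUMNS = ("eolci_score", "stanford_prob")


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration of a validation run."""

    input_path: str | None = None
    column_schema: dict[str, str] | None = None
    horizons_days: tuple[float, ...] = (180.0, 365.0)
    primary_horizon_days: float = 365.0
    cutoff: float = 45.0
    cutoff_inclusive: bool = True
    cutoff_score: str = "eolci_score"
    matched_count: bool = True
    subgroup_columns: tuple[str, ...] = ("age_tertile", "sex", "race", "ethnicity")
    convention: str = "exclude_censored"
    ci_method: str = "bootstrap"
    n_boot: int = 2000
    seed: int = 0
    output_dir: str = "survbench_out"
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("horizons_days", "subgroup_columns"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["horizons_days"] = list(self.horizons_days)
        d["subgroup_columns"] = list(self.subgroup_columns)
        return d


def _json_default(obj: Any):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_json(payload: Mapping, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=_json_default)
    )
    tmp.replace(path)


def _score_block(
    cohort: pd.DataFrame, config: RunConfig, keep_roc: bool = True
) -> dict:
    """Discrimination + threshold metrics for both scores, all horizons."""
    report: dict = {"scores": {}, "counts": {"n_patients": len(cohort)}}
    time = cohort["followup_days"].to_numpy(float)
    event = cohort["event"].to_numpy(bool)

    labeled = {
        h: label_at_horizon(cohort, h, config.convention)
        for h in config.horizons_days
    }
    report["counts"]["evaluable"] = {
        str(int(h)): lab.n_evaluable for h, lab in labeled.items()
    }
    report["counts"]["excluded"] = {
        str(int(h)): lab.n_excluded for h, lab in labeled.items()
    }
    primary = labeled.get(config.primary_horizon_days) or label_at_horizon(
        cohort, config.primary_horizon_days, config.convention
    )
    report["counts"]["deaths_at_primary_horizon"] = primary.n_cases

    # reference flag on the primary score at the primary horizon
    ref_flags = flag_high_risk(
        primary.data[config.cutoff_score].to_numpy(float),
        config.cutoff,
        config.cutoff_inclusive,
    )
    n_flagged_ref = int(ref_flags.sum())
    report["counts"]["flagged_reference"] = n_flagged_ref

    for score in SCORE_COLUMNS:
        entry: dict = {}
        s_all = cohort[score].to_numpy(float)
        conc = harrell_c(s_all, time, event)
        lo, hi = concordance_confidence_interval(
            s_all, time, event, n_boot=config.n_boot, seed=config.seed
        )
        entry["c_index"] = {
            "estimate": conc.c_index, "ci_low": lo, "ci_high": hi,
            "n_comparable_pairs": conc.n_comparable_pairs,
        }
        entry["auc"] = {}
        for h, lab in labeled.items():
            s = lab.data[score].to_numpy(float)
            roc = roc_auc(s, lab.labels)
            ci = auc_confidence_interval(
                s, lab.labels, method=config.ci_method,
                n_boot=config.n_boot, seed=config.seed,
            )
            entry["auc"][str(int(h))] = {
                "estimate": roc.auc, "ci_low": ci[0], "ci_high": ci[1],
                "n_evaluable": lab.n_evaluable,
                "gini": gini_index(roc.auc),
            }
            if keep_roc:
                entry.setdefault("_roc", {})[str(int(h))] = roc

        # threshold block at primary horizon
        s_primary = primary.data[score].to_numpy(float)
        if score == config.cutoff_score:
            flags = ref_flags
            cut = config.cutoff
        elif config.matched_count:
            matched = matched_count_cutoff(s_primary, n_flagged_ref)
            flags = s_primary > matched.cutoff
            cut = matched.cutoff
            entry["matched_cutoff"] = {
                "cutoff": matched.cutoff,
                "n_flagged": matched.n_flagged,
                "n_target": matched.n_target,
                "discrepancy": matched.discrepancy,
            }
        else:
            flags = flag_high_risk(s_primary, config.cutoff, config.cutoff_inclusive)
            cut = config.cutoff
        cm = confusion_metrics(flags, primary.labels, cut, config.primary_horizon_days)
        entry["threshold"] = cm.as_dict()
        report["scores"][score] = entry
    return report


def run_validate(
    config: RunConfig, cohort: pd.DataFrame | None = None
) -> dict:
    """Run the full validation protocol; returns the report dict.

    ``cohort`` may be passed directly (e.g. a synthetic table); otherwise
    ``config.input_path`` is read. Files are written under
    ``config.output_dir``: ``report.json``, per-table CSVs, and (when
    ``make_plots``) ROC and KM figures.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cohort is None:
        if config.input_path is None:
            raise ValueError("no cohort: set input_path or pass a table")
        cohort = read_cohort(config.input_path, config.column_schema)

    report: dict = {
        "survbench_version": __version__,
        "config": config.as_dict(),
        "stages": {},
        "errors": {},
    }

    def stage(name, fn):
        try:
            report["stages"][name] = fn()
            logger.info("stage %s complete", name)
        except Exception as exc:  # stage isolation: later stages still run
            report["errors"][name] = f"{type(exc).__name__}: {exc}"
            logger.warning("stage %s failed: %s", name, exc)

    stage("summary", lambda: summarize_cohort(cohort).to_dict(orient="records"))
    stage("followup", lambda: dataclasses.asdict(followup_summary(cohort)))
    stage("discrimination", lambda: _score_block(cohort, config))

    def km_stage():
        curve = km_estimate(cohort["followup_days"], cohort["event"])
        out = {}
        for h in config.horizons_days + (730.0,):
            sa = km_survival_at(curve, h)
            out[str(int(h))] = {
                "survival": sa.estimate, "ci_low": sa.ci_low,
                "ci_high": sa.ci_high, "extrapolated": sa.extrapolated,
            }
        return out

    stage("km_overall", km_stage)

    def tertile_stage():
        out = {}
        for score in SCORE_COLUMNS:
            tert, curves = tertile_curves(cohort, score)
            out[score] = {
                "boundaries": list(tert.boundaries),
                "score_ranges": [list(r) for r in tert.score_ranges],
                "survival_1y": [
                    km_survival_at(c, config.primary_horizon_days).estimate
                    for c in curves
                ],
                "group_sizes": [int((tert.group == g).sum()) for g in range(3)],
            }
            for label, c in zip(tert.labels, curves):
                pd.DataFrame(
                    {
                        "time": c.event_times,
                        "n_at_risk": c.n_at_risk,
                        "survival": c.survival,
                        "variance": c.variance,
                    }
                ).to_csv(outdir / f"km_{score}_{label}.csv", index=False)
        return out

    stage("km_tertiles", tertile_stage)

    def subgroup_stage():
        frames = []
        for col in config.subgroup_columns:
            t = subgroup_auc(
                cohort, config.primary_horizon_days, col,
                ci_method=config.ci_method, n_boot=config.n_boot, seed=config.seed,
            )
            t.insert(0, "grouping", col)
            frames.append(t)
        table = pd.concat(frames, ignore_index=True)
        table.to_csv(outdir / "subgroup_auc.csv", index=False)
        return table.to_dict(orient="records")

    stage("subgroups", subgroup_stage)

    def sensitivity_stage():
        alt = dataclasses.replace(config, convention="censored_as_alive",
                                  make_plots=False)
        return _score_block(cohort, alt, keep_roc=False)

    stage("sensitivity_censored_as_alive", sensitivity_stage)

    # exports
    disc = report["stages"].get("discrimination")
    if disc:
        for score, entry in disc["scores"].items():
            rocs = entry.pop("_roc", {})
            for h, roc in rocs.items():
                pd.DataFrame(
                    {
                        "threshold": roc.thresholds,
                        "fpr": roc.roc_points[:, 0],
                        "tpr": roc.roc_points[:, 1],
                    }
                ).to_csv(outdir / f"roc_{score}_{h}d.csv", index=False)
                if config.make_plots:
                    _plot_roc(disc, outdir, h)
    if config.make_plots:
        _plot_km_tertiles(cohort, outdir)
    _write_json(report, outdir / "report.json")
    return report


def _plot_roc(disc: dict, outdir: Path, horizon: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for score in SCORE_COLUMNS:
        csv = outdir / f"roc_{score}_{horizon}d.csv"
        if not csv.exists():
            continue
        pts = pd.read_csv(csv)
        auc = disc["scores"][score]["auc"][horizon]["estimate"]
        ax.plot(pts["fpr"], pts["tpr"], label=f"{score} (AUC {auc:.2f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    fig.savefig(outdir / f"roc_{horizon}d.png", dpi=120, bbox_inches="tight")
    plt.close(fig)


def _plot_km_tertiles(cohort: pd.DataFrame, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, score in zip(axes, SCORE_COLUMNS):
        try:
            tert, curves = tertile_curves(cohort, score)
        except ValueError:
            continue
        for label, c in zip(tert.labels, curves):
            t = np.concatenate([[0.0], np.repeat(c.event_times, 2)])
            s = np.concatenate([[1.0, 1.0], np.repeat(c.survival, 2)[:-1]])
            ax.plot(t, s, label=f"{label} risk")
        ax.set_title(score)
        ax.set_xlabel("days")
        ax.legend()
    axes[0].set_ylabel("survival probability")
    fig.savefig(outdir / "km_tertiles.png", dpi=120, bbox_inches="tight")
    plt.close(fig)


def run_simulate(
    config: SyntheticConfig, output_dir: str | Path = "survbench_out"
) -> tuple[Path, Path]:
    """Generate a synthetic cohort CSV plus a truth sidecar JSON.

    Nothing is written unless generation succeeds (invalid configurations
    leave no partial files). Returns (cohort path, sidecar path).
    """
    cohort = generate_cohort(config)  # raises before any file is touched
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort_path = outdir / "synthetic_cohort.csv"
    sidecar_path = outdir / "synthetic_cohort_truth.json"
    write_cohort(cohort, cohort_path)
    truth = {
        k: v for k, v in cohort.attrs["truth"].items() if not isinstance(v, np.ndarray)
    }
    truth["config"] = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in dataclasses.asdict(config).items()
        if not isinstance(v, Mapping)
    }
    _write_json(truth, sidecar_path)
    return cohort_path, sidecar_path


def run_influence(
    config: SyntheticConfig,
    output_dir: str | Path = "survbench_out",
    k: int = 5,
    l2_grid: Sequence[float] = (0.01, 0.1, 1.0, 10.0),
    n_folds: int = 5,
) -> dict:
    """Fit the discrete-time model on a feature cohort and report influences.

    Emits per-patient top-k survival-improving/-worsening feature lists and
    the cohort-level frequency aggregation, plus the fitted coefficients
    against the generating truth.
    """
    fc = generate_feature_cohort(config)
    fm = standardize(fc.features)
    l2 = select_l2(fm, fc.time, fc.event, grid=l2_grid,
                   n_folds=n_folds, seed=config.seed)
    model = fit_discrete_time_model(fm, fc.time, fc.event, l2_strength=l2)
    rankings = [
        influence_ranking(model, fm.values[i], k=k) for i in range(len(fc.time))
    ]
    agg = aggregate_influences(rankings)

    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    agg.to_csv(outdir / "influence_aggregate.csv", index=False)
    coef = pd.DataFrame(
        {"feature": fm.feature_names, "beta": model.beta, "true_beta": fc.true_beta}
    )
    coef.to_csv(outdir / "model_coefficients.csv", index=False)
    report = {
        "survbench_version": __version__,
        "l2_strength": l2,
        "log_likelihood": model.log_likelihood,
        "n_patients": int(len(fc.time)),
        "k": k,
        "aggregate": agg.to_dict(orient="records"),
    }
    _write_json(report, outdir / "influence_report.json")
    return report
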