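"""End-to-end study pipeline: cohort -> univariate comparisons ->
logistic death probabilities -> ROC / cutoff evaluation.

Mirrors the analytic sequence of a severity-score validation study:

1. arm-wise descriptive statistics with Mann-Whitney U (continuous) and
   Fisher's exact (categorical) comparisons between survivors and
   non-survivors;
2. per scoring system, a univariate logistic fit of mortality on the
   score, per-patient predicted death probabilities, and a Mann-Whitney
   comparison of those probabilities between arms (reported both as
   mean (SD) and as median (IQR));
3. per scoring system, the ROC curve, AUROC, Youden-optimal cutoff and
   the confusion-matrix test characteristics at that cutoff.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort
from .estimators import SYSTEMS, ScoreLogisticModel, YoudenCutoffClassifier, score_dataframe
from .stats import (
    ClassifierMetrics,
    GroupComparison,
    LogisticFit,
    RocCurve,
    fisher_exact,
    mann_whitney_u,
)

__all__ = ["StudyReport", "ScoreEvaluation", "run_study_pipeline", "render_report", "write_report_files"]

_CONTINUOUS_VARS = (
    "age",
    "temperature",
    "pulse_rate",
    "respiratory_rate",
    "mean_arterial_pressure",
    "leukocyte_count",
    "platelet_count",
)
_BINARY_VARS = ("sex", "septic_shock", "terminal_illness")
_MULTI_VARS = ("treatment", "etiology", "abscess_multiplicity")


@dataclass
class ScoreEvaluation:
    """Everything the pipeline derives for one scoring system."""

    system: str
    fit: LogisticFit
    prob_summary: pd.DataFrame  # mean/sd/median/q1/q3 of P(death) per arm
    prob_comparison: GroupComparison
    roc: RocCurve
    cutoff: float
    metrics: ClassifierMetrics


@dataclass
class StudyReport:
    """Structured output of :func:`run_study_pipeline`."""

    n: int
    n_survivors: int
    n_nonsurvivors: int
    univariate: pd.DataFrame
    scores: pd.DataFrame  # per-patient score totals + outcome
    evaluations: dict[str, ScoreEvaluation] = field(default_factory=dict)
    seed: int | None = None

    @property
    def auroc(self) -> dict[str, float]:
        return {s: e.roc.auc for s, e in self.evaluations.items()}

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for s, e in self.evaluations.items():
            m = e.metrics
            rows.append(
                {
                    "system": s,
                    "auroc": e.roc.auc,
                    "cutoff": e.cutoff,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "ppv": m.ppv,
                    "npv": m.npv,
                    "accuracy": m.accuracy,
                    "tp": m.tp,
                    "fp": m.fp,
                    "tn": m.tn,
                    "fn": m.fn,
                }
            )
        return pd.DataFrame(rows)


def _univariate_table(df: pd.DataFrame) -> pd.DataFrame:
    """Arm-wise descriptives with between-arm tests, one row per variable/level."""
    died = df["outcome"] == "died"
    rows = []
    for var in _CONTINUOUS_VARS:
        if var not in df or df[var].isna().all():
            continue
        s, ns = df.loc[~died, var].dropna(), df.loc[died, var].dropna()
        cmp = mann_whitney_u(s.to_numpy(), ns.to_numpy())
        rows.append(
            {
                "variable": var,
                "level": "",
                "survivors": f"{s.median():g} ({s.quantile(0.25):g}-{s.quantile(0.75):g})",
                "nonsurvivors": f"{ns.median():g} ({ns.quantile(0.25):g}-{ns.quantile(0.75):g})",
                "test": cmp.method,
                "p_value": cmp.p_value,
            }
        )
    binary_levels = {"sex": "male", "septic_shock": True, "terminal_illness": True}
    multi = {v: sorted(df[v].dropna().unique()) for v in _MULTI_VARS if v in df}
    for var, levels in ({k: [v] for k, v in binary_levels.items()} | multi).items():
        if var not in df or df[var].isna().all():
            continue
        for level in levels:
            a = int(((df[var] == level) & died).sum())
            b = int(((df[var] != level) & died).sum())
            c = int(((df[var] == level) & ~died).sum())
            d = int(((df[var] != level) & ~died).sum())
            cmp = fisher_exact([[a, b], [c, d]])
            n_s, n_ns = c + d, a + b
            rows.append(
                {
                    "variable": var,
                    "level": str(level),
                    "survivors": f"{c} ({100 * c / n_s:.2f}%)" if n_s else "0",
                    "nonsurvivors": f"{a} ({100 * a / n_ns:.2f}%)" if n_ns else "0",
                    "test": cmp.method,
                    "p_value": cmp.p_value,
                }
            )
    return pd.DataFrame(rows)


def run_study_pipeline(cohort: Cohort, systems=SYSTEMS) -> StudyReport:
    """Run the full scoring-and-evaluation sequence on a labelled cohort."""
    df = cohort.to_frame()
    outcomes = np.asarray(cohort.outcomes())
    scored = score_dataframe(df, systems)
    report = StudyReport(
        n=len(cohort),
        n_survivors=cohort.n_survived,
        n_nonsurvivors=cohort.n_died,
        univariate=_univariate_table(df),
        scores=scored[["patient_id", "outcome"] + [s.lower() for s in systems]],
        seed=cohort.seed,
    )
    died = outcomes == 1
    for system in systems:
        x = scored[system.lower()].to_numpy(dtype=float)
        logit = ScoreLogisticModel().fit(x, outcomes)
        p = logit.predict_proba(x)[:, 1]
        summary = pd.DataFrame(
            {
                arm: {
                    "n": int(mask.sum()),
                    "mean": float(np.mean(p[mask])),
                    "sd": float(np.std(p[mask], ddof=1)) if mask.sum() > 1 else float("nan"),
                    "median": float(np.median(p[mask])),
                    "q1": float(np.quantile(p[mask], 0.25)),
                    "q3": float(np.quantile(p[mask], 0.75)),
                }
                for arm, mask in (("survivors", ~died), ("nonsurvivors", died))
            }
        )
        youden = YoudenCutoffClassifier().fit(x, outcomes)
        report.evaluations[system.upper()] = ScoreEvaluation(
            system=system.upper(),
            fit=logit.fit_,
            prob_summary=summary,
            prob_comparison=mann_whitney_u(p[~died], p[died]),
            roc=youden.roc_,
            cutoff=youden.cutoff_,
            metrics=youden.metrics(x, outcomes),
        )
    return report


def _fmt_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def render_report(report: StudyReport) -> str:
    """Plain-text study report mirroring the cohort / probability / metrics tables."""
    buf = io.StringIO()
    w = buf.write
    w(f"edscores {__version__} study report\n")
    if report.seed is not None:
        w(f"seed: {report.seed}\n")
    w(f"patients: {report.n} (survivors {report.n_survivors}, non-survivors {report.n_nonsurvivors})\n")
    w("\n== Cohort characteristics (survivors vs non-survivors) ==\n")
    for _, r in report.univariate.iterrows():
        name = f"{r['variable']}" + (f" = {r['level']}" if r["level"] else "")
        w(f"  {name:<38} {r['survivors']:>22}  {r['nonsurvivors']:>22}  p={_fmt_p(r['p_value'])}\n")
    w("\n== Probability of death from the univariate logistic models ==\n")
    w("  (per arm: mean (SD) and median (IQR) of p = 1/(1+exp(-(b0+b1*score))))\n")
    for s, e in report.evaluations.items():
        ps, pn = e.prob_summary["survivors"], e.prob_summary["nonsurvivors"]
        w(
            f"  {s:<5} b0={e.fit.beta0:+.4f} b1={e.fit.beta1:+.4f}  "
            f"survivors {ps['mean']:.2f} ({ps['sd']:.2f}) / {ps['median']:.2f} ({ps['q1']:.2f}-{ps['q3']:.2f})  "
            f"non-survivors {pn['mean']:.2f} ({pn['sd']:.2f}) / {pn['median']:.2f} ({pn['q1']:.2f}-{pn['q3']:.2f})  "
            f"p={_fmt_p(e.prob_comparison.p_value)}\n"
        )
    w("\n== Mortality prediction (Youden-optimal cutoffs) ==\n")
    w(f"  {'system':<7}{'AUROC':>7}{'cutoff':>8}{'Sen':>9}{'Sp':>9}{'PPV':>9}{'NPV':>9}{'Acc':>9}\n")
    for s, e in report.evaluations.items():
        m = e.metrics
        w(
            f"  {s:<7}{e.roc.auc:>7.2f}{e.cutoff:>8.0f}"
            f"{100 * m.sensitivity:>8.2f}%{100 * m.specificity:>8.2f}%"
            f"{100 * m.ppv:>8.2f}%{100 * m.npv:>8.2f}%{100 * m.accuracy:>8.2f}%\n"
        )
    return buf.getvalue()


def write_report_files(report: StudyReport, outdir) -> None:
    """Write report.txt, metrics.csv and roc.csv under ``outdir``."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# edscores {__version__}" + (f" seed={report.seed}" if report.seed is not None else "")
    (outdir / "report.txt").write_text(render_report(report), encoding="utf-8")
    with open(outdir / "metrics.csv", "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        report.metrics_frame().to_csv(fh, index=False)
    roc_rows = []
    for s, e in report.evaluations.items():
        for t, tpr, fpr in zip(e.roc.thresholds, e.roc.tpr, e.roc.fpr):
            roc_rows.append({"system": s, "threshold": t, "tpr": tpr, "fpr": fpr})
    with open(outdir / "roc.csv", "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        pd.DataFrame(roc_rows).to_csv(fh, index=False)
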