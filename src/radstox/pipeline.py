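"""End-to-end analysis orchestration with machine-readable reports.

``run_analysis`` executes the full chain — population selection, toxicity
scoring, incidence curves and exact tests, relative-risk regression,
probabilistic index modelling, and local-control survival — and writes one
delimited-text table per stage plus a flat key-value summary carrying
provenance (seed, config digest, package version). Reports are
deterministic: the same inputs and seed produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .cohort import TrialCohort, analysis_populations, read_cohort, write_cohort
from .exceptions import NumericalError, RadstoxError
from .incidence import (
    fisher_exact_two_sided,
    incidence_frame,
    km_incidence,
    landmark_counts,
)
from .pim import ProbabilisticIndexModel, build_pseudo_observations
from .relative_risk import ADJUSTERS, adjusted_rr, events_by_term
from .simulate import (
    SUBGROUPS,
    SimulationConfig,
    config_to_yaml,
    fixture_cohort_from_printed_counts,
    simulate_cohort,
)
from .survival import km_curve, logrank, survival_frame
from .toxicity_index import score_cohort, scores_frame

log = logging.getLogger("radstox")

DEFAULT_ADJUSTERS = ("age", "bmi_ge30", "diabetes", "smoking_ever", "ct_planned")


@dataclass
class AnalysisReport:
    scores: pd.DataFrame
    incidence: pd.DataFrame
    fisher: pd.DataFrame
    relative_risk: pd.DataFrame
    pim: pd.DataFrame
    survival: pd.DataFrame
    provenance: Dict[str, str] = field(default_factory=dict)

    def summary_lines(self) -> List[str]:
        lines = [f"{k} = {v}" for k, v in self.provenance.items()]
        for _, row in self.fisher.iterrows():
            lines.append(
                f"fisher_p.{row['comparison']} = {row['p_value']!r}"
            )
        for _, row in self.relative_risk.iterrows():
            if row["term"] in ("alternate", "daily") and not row["boundary"]:
                key = f"rr.{row['endpoint']}.{row['term']}.adj{int(row['adjusted'])}"
                lines.append(
                    f"{key} = {row['rr']!r} ({row['ci_lower']!r}, {row['ci_upper']!r})"
                )
        for _, row in self.pim.iterrows():
            key = f"pi.{row['comparison']}.adj{int(row['adjusted'])}"
            lines.append(
                f"{key} = {row['pi']!r} ({row['ci_lower']!r}, {row['ci_upper']!r})"
            )
        return lines


def _score_design(cohort: TrialCohort, ids: Sequence[str], adjusters) -> pd.DataFrame:
    arms = pd.Series({pid: cohort.patients[pid].arm for pid in ids})
    X = pd.DataFrame(
        {
            "alternate": (arms == "alternate").astype(float),
            "daily": (arms == "daily").astype(float),
        },
        index=list(ids),
    )
    for name in adjusters:
        X[name] = [ADJUSTERS[name](cohort.patients[pid]) for pid in ids]
    return X


def _pim_rows(
    cohort: TrialCohort, toxicity_ids, adjusters: Sequence[str], adjusted_flag: int
) -> List[dict]:
    ids = [pid for pid in cohort.patients if pid in toxicity_ids]
    scores = score_cohort(cohort, ids)
    y = [s.ti for s in scores]
    X = _score_design(cohort, ids, adjusters)
    present_arms = {cohort.patients[pid].arm for pid in ids}
    rows: List[dict] = []
    arm_terms = [a for a in ("alternate", "daily") if a in present_arms]
    if "no_bolus" not in present_arms or not arm_terms:
        log.warning("PIM stage skipped: need a no-bolus reference and a bolus arm")
        return rows
    drop = [a for a in ("alternate", "daily") if a not in present_arms]
    X = X.drop(columns=drop)
    pseudo = build_pseudo_observations(y, X, ids=ids)
    fit = ProbabilisticIndexModel(pseudo).fit()
    for term in arm_terms:
        c = np.zeros(len(X.columns))
        c[list(X.columns).index(term)] = 1.0
        ct = fit.pi_contrast(c)
        rows.append(
            {
                "comparison": f"{term}_vs_no_bolus",
                "pi": ct.pi,
                "ci_lower": ct.ci_lower,
                "ci_upper": ct.ci_upper,
                "p_value": ct.p_value,
                "n_pairs": fit.n_pairs,
                "adjusted": adjusted_flag,
            }
        )
    return rows


def _rr_rows(
    cohort: TrialCohort, toxicity_ids, endpoint: str, arm_coding: str,
    adjusters: Sequence[str], adjusted_flag: int
) -> List[dict]:
    counts = events_by_term(cohort, endpoint, toxicity_ids, arm_coding)
    present_arms = {cohort.patients[pid].arm for pid in toxicity_ids}
    rows: List[dict] = []
    if arm_coding == "per_arm" and (
        "no_bolus" not in present_arms or present_arms == {"no_bolus"}
    ):
        log.warning("RR stage for %s skipped: missing arms", endpoint)
        return rows
    try:
        res = adjusted_rr(
            cohort, endpoint, adjusters=adjusters,
            population=toxicity_ids, arm_coding=arm_coding,
        )
    except NumericalError as err:
        log.warning("RR stage for %s hit a boundary: %s", endpoint, err)
        for term, (ev, tot) in counts.items():
            rows.append(
                {
                    "endpoint": endpoint, "term": term,
                    "events_over_total": f"{ev}/{tot}",
                    "rr": np.nan, "ci_lower": np.nan, "ci_upper": np.nan,
                    "p_value": np.nan, "adjusted": adjusted_flag, "boundary": 1,
                }
            )
        return rows
    ci = res.conf_int()
    for term in res.exog_names:
        if term == "intercept" or term in adjusters:
            continue
        ev, tot = counts.get(term, (np.nan, np.nan))
        rows.append(
            {
                "endpoint": endpoint, "term": term,
                "events_over_total": f"{ev}/{tot}",
                "rr": float(res.rr[term]),
                "ci_lower": float(ci["ci_lower"][term]),
                "ci_upper": float(ci["ci_upper"][term]),
                "p_value": float(res.pvalues[term]),
                "adjusted": adjusted_flag, "boundary": 0,
            }
        )
    return rows


def analyze_cohort(cohort: TrialCohort, seed: int = 0,
                   config_digest: str = "") -> AnalysisReport:
    """Run every analysis stage on an in-memory cohort."""
    t0 = time.perf_counter()
    toxicity_ids, oncologic_ids = analysis_populations(cohort)
    log.info("populations: toxicity n=%d, oncologic n=%d",
             len(toxicity_ids), len(oncologic_ids))

    ordered_tox = [pid for pid in cohort.patients if pid in toxicity_ids]
    scores = scores_frame(score_cohort(cohort, ordered_tox))

    curves = []
    for subgroup in SUBGROUPS:
        ids = [pid for pid in cohort.subgroup_ids(subgroup) if pid in toxicity_ids]
        if not ids:
            continue
        for g in (1, 2, 3):
            curves.append(km_incidence(cohort, ids, g, label=subgroup))
    incidence = incidence_frame(curves)

    schedule = cohort.schedule
    fisher_rows = []
    fisher_spec = [
        ("sr_g2_no_vs_alternate", "sr_no_bolus", "sr_alternate", 2,
         schedule.end_of_treatment_week),
        ("hr_g2_daily_vs_alternate", "hr_daily", "hr_alternate", 2,
         schedule.end_of_treatment_week),
        ("hr_g3_daily_vs_alternate", "hr_daily", "hr_alternate", 3,
         schedule.end_of_acute_followup_week),
    ]
    for name, sub_a, sub_b, g, landmark in fisher_spec:
        ids_a = [p for p in cohort.subgroup_ids(sub_a) if p in toxicity_ids]
        ids_b = [p for p in cohort.subgroup_ids(sub_b) if p in toxicity_ids]
        if not ids_a or not ids_b:
            log.warning("fisher comparison %s skipped: empty subgroup", name)
            continue
        ea, na = landmark_counts(cohort, ids_a, g, landmark)
        eb, nb = landmark_counts(cohort, ids_b, g, landmark)
        fisher_rows.append(
            {
                "comparison": name, "grade_threshold": g, "week": landmark,
                "a": ea, "b": na - ea, "c": eb, "d": nb - eb,
                "p_value": fisher_exact_two_sided(ea, na - ea, eb, nb - eb),
            }
        )
    fisher = pd.DataFrame(fisher_rows)

    rr_rows: List[dict] = []
    rr_rows += _rr_rows(cohort, toxicity_ids, "G2_at_end_of_rt", "per_arm", (), 0)
    rr_rows += _rr_rows(cohort, toxicity_ids, "G2_at_end_of_rt", "per_arm",
                        DEFAULT_ADJUSTERS, 1)
    rr_rows += _rr_rows(cohort, toxicity_ids, "G3_any", "daily_vs_pooled", (), 0)
    rr_rows += _rr_rows(cohort, toxicity_ids, "G3_any", "daily_vs_pooled",
                        DEFAULT_ADJUSTERS, 1)
    relative_risk = pd.DataFrame(rr_rows)

    pim_rows = _pim_rows(cohort, toxicity_ids, (), 0)
    pim_rows += _pim_rows(cohort, toxicity_ids, DEFAULT_ADJUSTERS, 1)
    pim = pd.DataFrame(pim_rows)

    surv_curves = []
    logrank_ps = {}
    strata_groups = {
        "sr": ("sr_no_bolus", "sr_alternate"),
        "hr": ("hr_alternate", "hr_daily"),
    }
    lc_data = {}
    for subgroup in SUBGROUPS:
        ids = [p for p in cohort.subgroup_ids(subgroup) if p in oncologic_ids]
        if not ids:
            continue
        times = [
            cohort.patients[p].local_failure_time_years
            if cohort.patients[p].local_failure
            else cohort.patients[p].followup_years
            for p in ids
        ]
        events = [int(cohort.patients[p].local_failure) for p in ids]
        lc_data[subgroup] = (times, events)
        surv_curves.append(km_curve(times, events, label=subgroup))
    for stratum, (sub_a, sub_b) in strata_groups.items():
        if sub_a in lc_data and sub_b in lc_data:
            res = logrank([lc_data[sub_a], lc_data[sub_b]])
            logrank_ps[stratum] = res.p_value
        pooled_t, pooled_e = [], []
        for sub in (sub_a, sub_b):
            if sub in lc_data:
                pooled_t += list(lc_data[sub][0])
                pooled_e += list(lc_data[sub][1])
        if pooled_t:
            surv_curves.append(km_curve(pooled_t, pooled_e, label=stratum))
    survival = survival_frame(surv_curves, "local_control")

    provenance = {
        "seed": str(seed),
        "config_digest": config_digest or "none",
        "version": __version__,
        "n_toxicity": str(len(toxicity_ids)),
        "n_oncologic": str(len(oncologic_ids)),
    }
    for stratum in ("sr", "hr"):
        curve = next((c for c in surv_curves if c.label == stratum), None)
        if curve is not None:
            provenance[f"local_control_5yr.{stratum}"] = repr(curve.survival_at(5.0))
        if stratum in logrank_ps:
            provenance[f"logrank_p.{stratum}"] = repr(logrank_ps[stratum])
    log.info("analysis finished in %.2f s", time.perf_counter() - t0)
    return AnalysisReport(
        scores=scores,
        incidence=incidence,
        fisher=fisher,
        relative_risk=relative_risk,
        pim=pim,
        survival=survival,
        provenance=provenance,
    )


REPORT_FILES = {
    "scores": "scores.csv",
    "incidence": "incidence.csv",
    "fisher": "fisher.csv",
    "relative_risk": "relative_risk.csv",
    "pim": "pim.csv",
    "survival": "survival.csv",
}


def write_report(report: AnalysisReport, out_dir) -> List[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    try:
        for attr, fname in REPORT_FILES.items():
            path = out / fname
            getattr(report, attr).to_csv(path, index=False)
            written.append(path)
        path = out / "summary.txt"
        path.write_text("\n".join(report.summary_lines()) + "\n", encoding="utf-8")
        written.append(path)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return written


def run_analysis(
    patients_path,
    toxicity_path,
    out_dir,
    config_path=None,
    seed: int = 0,
) -> AnalysisReport:
    """Read the cohort files, run every stage, and write all reports.

    Any stage failure aborts the run, names the stage, and removes partial
    outputs from ``out_dir``.
    """
    cohort = read_cohort(patients_path, toxicity_path)
    digest = ""
    if config_path is not None:
        digest = hashlib.sha256(Path(config_path).read_bytes()).hexdigest()[:16]
    report = analyze_cohort(cohort, seed=seed, config_digest=digest)
    write_report(report, out_dir)
    return report


def simulate_command(
    out_dir, config: Optional[SimulationConfig] = None, seed: int = 0
) -> Tuple[Path, Path]:
    """Emit a synthetic cohort plus the resolved configuration it used."""
    config = (config or SimulationConfig()).resolved()
    cohort = simulate_cohort(config, seed)
    out = Path(out_dir)
    paths = write_cohort(cohort, out)
    config_to_yaml(config, out / "config.yaml")
    return paths


def fixtures_command(out_dir) -> Tuple[Path, Path]:
    """Write the deterministic printed-counts fixture cohort."""
    return write_cohort(fixture_cohort_from_printed_counts(), out_dir)
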