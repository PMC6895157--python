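"""End-to-end orchestration: synthesize → extract → DFA × 2 → MANOVA × 2.

One seed drives the whole run; per-stage child streams are derived from it,
so changing an extraction setting never perturbs the synthesized audio.
Every artifact embeds the seed and a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .discriminant import CrossValenceResult, run_cross_valence_dfa
from .features import extract_table
from .io import read_feature_table, write_dataset, write_feature_table
from .params import CONTEXT_VALENCE, VALENCES
from .stats import ManovaResult, descriptive_stats, manova_pillai, \
    univariate_anovas
from .synth import (SynthConfig, draw_signatures, generate_dataset,
                    generate_feature_table, suggested_pitch_bounds)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    mode: str = "full"              # synth-only | extract-only | stats-only
    out_dir: str = "herdvoice_run"
    seed: int = 0
    synth: SynthConfig | None = None
    use_waveforms: bool = False     # False: fast feature-table route
    features_path: str | None = None  # for stats-only mode
    f_enter: float = 3.84
    f_remove: float = 2.71
    priors: str = "proportional"

    def __post_init__(self) -> None:
        if self.mode not in ("full", "synth-only", "extract-only",
                             "stats-only"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.synth is None and self.mode != "stats-only":
            self.synth = SynthConfig(seed=self.seed)

    def config_hash(self) -> str:
        blob = json.dumps({
            "mode": self.mode, "seed": self.seed,
            "use_waveforms": self.use_waveforms,
            "f_enter": self.f_enter, "f_remove": self.f_remove,
            "priors": self.priors,
            "synth": None if self.synth is None else {
                "n_individuals": self.synth.n_individuals,
                "n_positive": self.synth.n_positive,
                "n_negative": self.synth.n_negative,
                "seed": self.synth.seed,
            },
        }, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _dfa_record(res: CrossValenceResult) -> dict:
    return {
        "train_valence": res.train_valence,
        "selected_variables": res.stepwise.selected,
        "n_steps": len(res.stepwise.steps),
        "step_log": [
            {"step": s, "action": a, "variable": v, "partial_F": f,
             "wilks_lambda": lam}
            for s, a, v, f, lam in res.stepwise.steps],
        "standardized_coefficients": {
            v: res.model.coeffs_std[i].tolist()
            for i, v in enumerate(res.model.variables)},
        "eigenvalues": res.model.eigenvalues.tolist(),
        "function_tests": res.model.function_tests,
        "n_significant_functions": sum(
            1 for t in res.model.function_tests if t["p_value"] < 0.05),
        "chance_percent": res.chance_percent,
        "reports": {
            k: {"percent_correct": r.percent_correct,
                "n": r.n, "n_correct": r.n_correct,
                "confusion": r.confusion.tolist(),
                "per_group_percent": r.per_group_correct.tolist()}
            for k, r in res.reports.items()},
        "binomial_tests": {
            k: {"n_trials": b.n_trials, "n_correct": b.n_correct,
                "chance_p": b.chance_p, "p_value": b.p_value}
            for k, b in res.binomials.items()},
    }


def _manova_record(m: ManovaResult) -> dict:
    return {"pillai_trace": m.pillai_trace, "F": m.f_stat,
            "df1": m.df1, "df2": m.df2, "p_value": m.p_value,
            "n_obs": m.n_obs, "n_groups": m.n_groups, "n_vars": m.n_vars}


def run_full(config: RunConfig) -> dict:
    """Execute the configured stages and write all artifacts.

    Returns the run report (also written to ``report.json``): provenance,
    a per-individual/per-valence call-count table, both cross-valence DFA
    records and both MANOVA records.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {"package": "herdvoice", "version": __version__,
                       "seed": config.seed,
                       "config_hash": config.config_hash()},
    }
    try:
        table = _obtain_features(config, out, report)
        if config.mode == "synth-only":
            _write_report(report, out)
            return report
        counts = (table.groupby(["individual_id", "valence"])
                  .size().unstack(fill_value=0))
        report["dataset"] = {
            "n_calls": int(len(table)),
            "n_individuals": int(table["individual_id"].nunique()),
            "per_valence": {v: int((table["valence"] == v).sum())
                            for v in VALENCES},
            "per_individual": counts.to_dict(),
        }
        if config.mode == "extract-only":
            _write_report(report, out)
            return report

        report["dfa"] = {}
        for tv in VALENCES:
            res = run_cross_valence_dfa(
                table, tv, f_enter=config.f_enter,
                f_remove=config.f_remove, priors=config.priors)
            report["dfa"][tv] = _dfa_record(res)
            res.scores.to_csv(out / f"scores_train_{tv}.csv", index=False)
        report["manova"] = {}
        report["anova"] = {}
        for tv in VALENCES:
            sub = table[table["valence"] == tv]
            report["manova"][tv] = _manova_record(manova_pillai(sub))
            an = univariate_anovas(sub)
            an.to_csv(out / f"anova_{tv}.csv", index=False)
            report["anova"][tv] = {
                "n_significant_0.05":
                    int((an["p_value"] < 0.05).sum()),
                "parameters_not_significant":
                    an.loc[~(an["p_value"] < 0.05), "parameter"].tolist(),
            }
        descriptive_stats(table).to_csv(out / "descriptives.csv",
                                        index=False)
    except Exception as err:
        (out / "FAILED").write_text(f"{type(err).__name__}: {err}\n")
        raise
    _write_report(report, out)
    return report


def _obtain_features(config: RunConfig, out: Path,
                     report: dict) -> pd.DataFrame | None:
    if config.mode == "stats-only":
        if not config.features_path:
            raise ValueError("stats-only mode needs features_path")
        return read_feature_table(config.features_path)
    synth = config.synth
    if config.mode == "synth-only" or config.use_waveforms:
        recs, gt = generate_dataset(synth)
        write_dataset(recs, out)
        gt.to_csv(out / "ground_truth.csv", index=False)
        if config.mode == "synth-only":
            return None
        sigs = synth.signatures or draw_signatures(synth)
        bounds = {s.individual_id: suggested_pitch_bounds(s) for s in sigs}
        table, excluded = extract_table(recs, pitch_bounds=bounds)
        if excluded:
            log.warning("%d calls excluded from statistics", len(excluded))
            report["excluded_calls"] = excluded
    else:
        table = generate_feature_table(synth)
    write_feature_table(table, out / "features.csv")
    return table


def _write_report(report: dict, out: Path) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(manifest: pd.DataFrame,
                    annotations: pd.DataFrame | None = None,
                    features: pd.DataFrame | None = None,
                    onset_times: pd.DataFrame | None = None,
                    min_sequence_gap_s: float = 10.0) -> ValidationReport:
    """Schema/label/coverage checks on user-supplied inputs.

    Errors: unknown valence or context labels, context/valence mismatches,
    individuals present in only one valence.  Warnings: calls from the same
    sequence closer together than the minimum spacing (requires
    ``onset_times`` with columns call_id, sequence_id, onset_s).
    """
    rep = ValidationReport()
    for i, r in manifest.iterrows():
        if r["valence"] not in VALENCES:
            rep.errors.append(f"row {i}: unknown valence {r['valence']!r}")
        elif r["context"] not in CONTEXT_VALENCE:
            rep.errors.append(f"row {i}: unknown context {r['context']!r}")
        elif CONTEXT_VALENCE[r["context"]] != r["valence"]:
            rep.errors.append(
                f"row {i}: context {r['context']!r} is not a "
                f"{r['valence']} context")
    for ind, sub in manifest.groupby("individual_id"):
        have = set(sub["valence"]) & set(VALENCES)
        if have != set(VALENCES):
            rep.errors.append(
                f"{ind}: calls present only in valence(s) {sorted(have)}; "
                "every individual needs both")
    if annotations is not None:
        known = set(manifest["call_id"].astype(str))
        for i, r in annotations.iterrows():
            if str(r["call_id"]) not in known:
                rep.errors.append(
                    f"annotation row {i}: unknown call_id {r['call_id']!r}")
            if r["end_s"] < r["start_s"]:
                rep.errors.append(f"annotation row {i}: end < start")
    if features is not None:
        nan_rows = features.isna().any(axis=1)
        if nan_rows.any():
            rep.warnings.append(
                f"{int(nan_rows.sum())} feature rows contain missing "
                "values and will be excluded listwise")
    if onset_times is not None:
        need = {"call_id", "sequence_id", "onset_s"}
        if not need <= set(onset_times.columns):
            rep.errors.append(
                f"onset-time table needs columns {sorted(need)}")
        else:
            for seq, sub in onset_times.groupby("sequence_id"):
                t = np.sort(sub["onset_s"].to_numpy(float))
                gaps = np.diff(t)
                for k in np.flatnonzero(gaps < min_sequence_gap_s):
                    rep.warnings.append(
                        f"sequence {seq}: calls {gaps[k]:.1f} s apart — "
                        f"closer than the {min_sequence_gap_s:g} s "
                        "selection rule")
    return rep
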