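"""End-to-end orchestration: cohort -> trajectories -> networks -> NIRA.

Stages run in the order of the analysis they reproduce: obtain a cohort
(simulated or loaded), select and fit the trajectory model, assign
groups, quantify the trajectory-depression association, estimate one
symptom network per trajectory group, bootstrap their stability,
compare them by permutation, and rank simulated symptom interventions.
Every stochastic stage derives its seed deterministically from the
global seed and the stage name, so stages are independently
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from . import datasets, gbtm, ising, nira, stability

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (
        2**31)


@dataclass
class PipelineConfig:
    mode: str = "simulate"                 # "simulate" | "load"
    input_dir: str | None = None
    output_dir: str = "ppdnet_out"
    seed: int = 0
    # simulate stage
    n_subjects: int = 372
    missing_rate: float = 0.1
    # trajectory stage
    k_range: tuple[int, ...] = (2, 3, 4)
    start_order: int = 3
    order_selection: str = "bic"
    n_starts: int = 6
    score_bounds: tuple[float, float] = (0.0, 21.0)
    # network stage
    gamma: float = 0.25
    rule: str = "and"
    n_lambda: int = 100
    # stability stage
    drop_proportions: tuple[float, ...] = stability.DEFAULT_PROPORTIONS
    n_boot: int = 250
    # comparison stage
    n_perm: int = 1000
    # intervention stage
    n_gibbs_samples: int = 10_000
    gibbs_sweeps: int = 100
    perturbation_c: float = 2.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        for key in ("k_range", "drop_proportions", "score_bounds"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if self.mode not in ("simulate", "load"):
            raise ValueError(f"mode: expected simulate|load, got {self.mode}")
        if self.mode == "load" and not self.input_dir:
            raise ValueError("input_dir: required in load mode")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate: must be in [0, 1)")
        if any(k < 1 for k in self.k_range):
            raise ValueError("k_range: group counts must be >= 1")


@dataclass
class RunReport:
    stages: list[dict] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps({"seed": self.seed, "stages": self.stages,
                           "manifest": self.manifest}, indent=2)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not serializable: {type(obj)}")


def run_pipeline(config: PipelineConfig, log=None) -> RunReport:
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)
    written: list[Path] = []

    def say(msg: str) -> None:
        if log is not None:
            log(msg)

    def run_stage(name, fn):
        t0 = time.perf_counter()
        seed = stage_seed(config.seed, name)
        say(f"[{name}] seed={seed}")
        try:
            result = fn(seed)
        except Exception as exc:
            report.stages.append({"stage": name, "status": "failed",
                                  "error": str(exc),
                                  "runtime_s": time.perf_counter() - t0})
            raise
        report.stages.append({"stage": name, "status": "ok", "seed": seed,
                              "runtime_s": time.perf_counter() - t0})
        return result

    def emit(path: Path) -> None:
        written.append(path)

    # ---- cohort ----------------------------------------------------------
    def cohort_stage(seed):
        if config.mode == "simulate":
            cfg = datasets.default_two_group_config(
                n_subjects=config.n_subjects,
                missing_rate=config.missing_rate, seed=seed)
            data = datasets.generate_cohort(cfg)
        else:
            data = datasets.read_cohort(config.input_dir)
        for p in datasets.write_cohort(data, out / "cohort"):
            emit(p)
        return data

    data = run_stage("cohort", cohort_stage)

    # ---- trajectory model ------------------------------------------------
    def gbtm_stage(seed):
        report_sel = gbtm.select_model(
            data, k_range=config.k_range, start_order=config.start_order,
            order_selection=config.order_selection,
            bounds=config.score_bounds, n_starts=config.n_starts, seed=seed)
        fit = report_sel.chosen
        post = gbtm.posterior_matrix(fit, data)
        labels = gbtm.assign_groups(post)
        crit = gbtm.criteria(fit, post)
        diag = gbtm.diagnostics(fit, post, labels)

        sel_path = out / "selection_report.json"
        sel_path.write_text(json.dumps({
            "candidates": report_sel.candidates.to_dict("records"),
            "fired_rules": report_sel.fired_rules,
        }, indent=2, default=_json_default))
        emit(sel_path)

        fit_path = out / "gbtm_fit.json"
        fit_path.write_text(json.dumps({
            "orders": list(fit.spec.orders),
            "coefficients": [c.tolist() for c in fit.coefficients],
            "sigma": fit.sigma.tolist(),
            "pi": fit.pi.tolist(),
            "loglik": fit.loglik,
            "n_params": fit.n_params,
            "criteria": dataclasses.asdict(crit),
            "diagnostics": diag.table.to_dict("records"),
        }, indent=2, default=_json_default))
        emit(fit_path)

        post_path = out / "posteriors.csv"
        pd.DataFrame(post, columns=[f"group{j+1}"
                                    for j in range(fit.n_groups)]).assign(
            subject_id=data.subjects()).to_csv(post_path, index=False)
        emit(post_path)
        lab_path = out / "labels.csv"
        pd.DataFrame({"subject_id": data.subjects(),
                      "group": labels + 1}).to_csv(lab_path, index=False)
        emit(lab_path)
        return fit, post, labels

    fit, post, labels = run_stage("gbtm", gbtm_stage)

    # groups are ordered by baseline mean; name the one with the worse
    # (higher) final-wave fitted score the poor trajectory
    final_wave = float(fit.waves_seen.max())
    finals = [float(fit.trajectory_at(j, np.array([final_wave]))[0])
              for j in range(fit.n_groups)]
    poor_idx = int(np.argmax(finals))
    group_names = {j: ("increasingly_poor" if j == poor_idx
                       else f"group{j + 1}" if fit.n_groups > 2
                       else "stably_good") for j in range(fit.n_groups)}
    named_labels = pd.Series([group_names[j] for j in labels],
                             index=pd.Index(data.subjects(),
                                            name="subject_id"), name="group")

    # ---- association -----------------------------------------------------
    def association_stage(seed):
        table = assoc.build_outcome_table(
            named_labels, data.item_table, data.covariate_table,
            poor_label="increasingly_poor")
        poor = table.frame[table.frame.poor_trajectory == 1].total
        good = table.frame[table.frame.poor_trajectory == 0].total
        bf10 = assoc.bayes_factor_ttest(poor.to_numpy(), good.to_numpy())
        result = {"bf10": bf10}
        for adjusted in (False, True):
            key = "adjusted" if adjusted else "crude"
            try:
                or_, ci, p = assoc.logistic_association(table,
                                                        adjusted=adjusted)
                result[f"{key}_or"] = {"or": or_, "ci": ci, "p": p}
            except (ValueError, assoc.SeparationError) as exc:
                result[f"{key}_or"] = {"error": str(exc)}
            b_all, se_all = assoc.linear_association(table, False, adjusted)
            b_no7, se_no7 = assoc.linear_association(table, True, adjusted)
            z, pz = assoc.coef_difference_z(b_all, se_all, b_no7, se_no7)
            result[f"{key}_linear"] = {
                "b_all_items": b_all, "se_all_items": se_all,
                "b_without_item7": b_no7, "se_without_item7": se_no7,
                "z_difference": z, "p_difference": pz}
        path = out / "association_report.json"
        path.write_text(json.dumps(result, indent=2, default=_json_default))
        emit(path)
        return result

    run_stage("association", association_stage)

    # ---- per-group networks ----------------------------------------------
    group_items = {}
    for j in range(fit.n_groups):
        members = data.subjects()[labels == j]
        rows = data.item_table[data.item_table.subject_id.isin(members)]
        group_items[group_names[j]] = ising.binarize_items(rows)

    networks = {}

    def network_stage(seed):
        for name, X in group_items.items():
            net = ising.fit_elasso(X, gamma=config.gamma, rule=config.rule,
                                   n_lambda=config.n_lambda)
            networks[name] = net
            net.edge_table().to_csv(out / f"network_edges_{name}.csv",
                                    index=False)
            emit(out / f"network_edges_{name}.csv")
            pd.DataFrame({"node": net.labels,
                          "threshold": net.thresholds}).to_csv(
                out / f"thresholds_{name}.csv", index=False)
            emit(out / f"thresholds_{name}.csv")
            cent = ising.strength_centrality(net)
            cent.rename_axis("node").to_csv(out / f"centrality_{name}.csv")
            emit(out / f"centrality_{name}.csv")
        return networks

    run_stage("network", network_stage)

    # ---- stability -------------------------------------------------------
    def stability_stage(seed):
        cs = {}
        for name, X in group_items.items():
            res = stability.case_drop_bootstrap(
                X, proportions=config.drop_proportions,
                n_boot=config.n_boot, seed=seed, gamma=config.gamma,
                rule=config.rule, n_lambda=config.n_lambda)
            res.table.to_csv(out / f"stability_{name}.csv", index=False)
            emit(out / f"stability_{name}.csv")
            cs[name] = stability.cs_coefficient(res)
        path = out / "cs.json"
        path.write_text(json.dumps(cs, indent=2))
        emit(path)
        return cs

    run_stage("stability", stability_stage)

    # ---- network comparison ----------------------------------------------
    def nct_stage(seed):
        names = list(group_items)
        if len(names) != 2:
            return {"skipped": "comparison needs exactly two groups"}
        res = ising.network_comparison_test(
            group_items[names[0]], group_items[names[1]],
            n_perm=config.n_perm, seed=seed, gamma=config.gamma,
            rule=config.rule, n_lambda=config.n_lambda)
        payload = {"groups": names, "m_observed": res.m_observed,
                   "s_observed": res.s_observed, "p_m": res.p_m,
                   "p_s": res.p_s, "n_perm": res.n_perm}
        path = out / "nct.json"
        path.write_text(json.dumps(payload, indent=2))
        emit(path)
        return payload

    run_stage("nct", nct_stage)

    # ---- simulated interventions -----------------------------------------
    def nira_stage(seed):
        summary = {}
        for name, net in networks.items():
            cfg = nira.GibbsConfig(n_samples=config.n_gibbs_samples,
                                   sweeps=config.gibbs_sweeps,
                                   seed=stage_seed(seed, name))
            res = nira.simulate_interventions(net, cfg,
                                              c=config.perturbation_c)
            ranked, top_agg, top_alle = nira.rank_interventions(res)
            ranked.to_csv(out / f"nira_results_{name}.csv", index=False)
            emit(out / f"nira_results_{name}.csv")
            summary[name] = {"baseline": res.baseline,
                             "top_aggravating": top_agg,
                             "top_alleviating": top_alle,
                             "magnitude": res.magnitude}
        path = out / "nira_summary.json"
        path.write_text(json.dumps(summary, indent=2))
        emit(path)
        return summary

    run_stage("nira", nira_stage)

    report.manifest = {str(p.relative_to(out)): _sha256(p) for p in written}
    (out / "run_report.json").write_text(report.to_json())
    return report


def verify_manifest(output_dir: str | Path) -> list[str]:
    """Names of manifest entries that are missing or altered."""
    out = Path(output_dir)
    report = json.loads((out / "run_report.json").read_text())
    bad = []
    for rel, digest in report["manifest"].items():
        p = out / rel
        if not p.exists() or _sha256(p) != digest:
            bad.append(rel)
    return bad
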