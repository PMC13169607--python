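"""End-to-end orchestration of the synthetic axis-discovery pipeline.

Runs simulate -> differential expression -> consensus/axes -> coherence ->
survival modeling -> locked external validation -> survival screen as one
reproducible, seeded run.  Every stage writes TSV/JSON artifacts into the
output directory; a manifest records SHA-256 checksums so that reruns with
the same configuration and seed are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import axes as axes_mod
from . import coherence as coh_mod
from . import de as de_mod
from . import survival as surv_mod
from .containers import ExpressionMatrix, MiraxError
from .simulate import SimulationConfig, generate_cohort, generate_validation_cohort

logger = logging.getLogger(__name__)

CONFIG_SCHEMA_VERSION = 1

ALL_STAGES = ("simulate", "de", "axes", "coherence", "survive", "validate", "screen")


@dataclass
class RunConfig:
    """Validated run configuration; unknown YAML keys are errors."""

    outdir: str = "mirax_run"
    seed: int = 0
    cpm_threshold: float = 1.0
    lfc_mrna: float = 1.0
    lfc_mirna: float = float(np.log2(1.5))
    fdr_de: float = 0.05
    fdr_screen: float = 0.01
    min_targets: int = 2
    prior_count: float = 0.5
    alpha_grid: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    n_lambda: int = 50
    k_outer: int = 5
    k_inner: int = 5
    n_boot: int = 1000
    stages: tuple[str, ...] = ALL_STAGES
    simulation: SimulationConfig | None = None
    schema_version: int = CONFIG_SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)
        for name in ("cpm_threshold", "lfc_mrna", "lfc_mirna"):
            if getattr(self, name) <= 0:
                raise MiraxError(f"{name} must be positive")
        for name in ("fdr_de", "fdr_screen"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise MiraxError(f"{name} must be in (0,1)")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise MiraxError(f"unknown stage(s): {sorted(unknown)}")
        if self.schema_version != CONFIG_SCHEMA_VERSION:
            raise MiraxError(f"unsupported config schema version {self.schema_version}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        sim_raw = raw.pop("simulation", {})
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise MiraxError(f"unknown config key(s): {sorted(unknown)}")
        sim_known = {f.name for f in fields(SimulationConfig)}
        sim_unknown = set(sim_raw) - sim_known
        if sim_unknown:
            raise MiraxError(f"unknown simulation key(s): {sorted(sim_unknown)}")
        if "surv_beta" in sim_raw:
            sim_raw["surv_beta"] = tuple(sim_raw["surv_beta"])
        if "lib_size_range" in sim_raw:
            sim_raw["lib_size_range"] = tuple(sim_raw["lib_size_range"])
        cfg = cls(**raw)
        seed = sim_raw.pop("seed", cfg.seed)
        cfg.simulation = SimulationConfig(seed=seed, **sim_raw)
        return cfg


@dataclass
class RunReport:
    seed: int
    stage_summaries: dict[str, dict]
    manifest: dict[str, str]  # relative path -> sha256
    outdir: str


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (frozenset, set)):
        return sorted(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def _logcpm(counts: ExpressionMatrix, cfg: RunConfig) -> ExpressionMatrix:
    filtered = de_mod.filter_low_expression(counts, cpm_threshold=cfg.cpm_threshold)
    factors = de_mod.tmm_factors(filtered)
    return de_mod.cpm(filtered, prior_count=cfg.prior_count, log=True,
                      norm_factors=factors.to_numpy())


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the enabled stages in order on a fully synthetic study.

    The run uses the configured :class:`SimulationConfig` as its study
    conditions: a discovery cohort, replicate cohorts for cross-cohort
    consensus, and a batch-shifted external validation cohort.  Returns a
    :class:`RunReport` with per-stage summaries and the file manifest.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages = set(config.stages)
    summaries: dict[str, dict] = {}
    written: list[Path] = []
    state: dict = {}

    def emit(path: Path) -> None:
        written.append(path)

    # ---- simulate --------------------------------------------------------
    if "simulate" not in stages:
        raise MiraxError("the synthetic pipeline requires the simulate stage")
    sim = config.simulation
    mrna, mirna, targets, surv, truth = generate_cohort(sim, cohort_id="discovery")
    mrna2, mirna2, _, _, _ = generate_cohort(sim, truth=truth, cohort_id="cohort2",
                                             noise_seed=sim.seed + 1)
    mirna_val, surv_val = generate_validation_cohort(sim, truth)
    state.update(mrna=mrna, mirna=mirna, mrna2=mrna2, mirna2=mirna2,
                 targets=targets, surv=surv, truth=truth,
                 mirna_val=mirna_val, surv_val=surv_val)
    for name, em in (("mrna_discovery", mrna), ("mirna_discovery", mirna),
                     ("mrna_cohort2", mrna2), ("mirna_cohort2", mirna2),
                     ("mirna_validation", mirna_val)):
        cpath, mpath = out / f"{name}_counts.tsv", out / f"{name}_meta.tsv"
        em.to_tsv(cpath, mpath)
        emit(cpath); emit(mpath)
    targets.to_tsv(out / "targets.tsv"); emit(out / "targets.tsv")
    for name, df in (("survival_discovery", surv), ("survival_validation", surv_val)):
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t"); emit(p)
    _write_json(truth.to_dict(), out / "ground_truth.json"); emit(out / "ground_truth.json")
    summaries["simulate"] = {
        "n_genes": mrna.n_features, "n_mirnas": mirna.n_features,
        "n_tumor": sim.n_tumor, "n_normal": sim.n_normal,
        "n_validation": sim.n_validation, "seed": sim.seed,
    }

    # ---- differential expression ----------------------------------------
    if "de" in stages:
        de_results = {}
        logcpm = {}
        for label, em in (("mrna_discovery", mrna), ("mrna_cohort2", mrna2),
                          ("mirna_discovery", mirna), ("mirna_cohort2", mirna2)):
            lc = _logcpm(em, config)
            logcpm[label] = lc
            lfc = config.lfc_mrna if em.assay == "mrna" else config.lfc_mirna
            de_results[label] = de_mod.moderated_t(lc, paired=False,
                                                   lfc_threshold=lfc, fdr=config.fdr_de)
        de_results["mirna_discovery_paired"] = de_mod.moderated_t(
            logcpm["mirna_discovery"], paired=True,
            lfc_threshold=config.lfc_mirna, fdr=config.fdr_de)
        for label, res in de_results.items():
            p = out / f"de_{label}.tsv"
            res.to_tsv(p); emit(p)
        state["de"] = de_results
        state["logcpm"] = logcpm
        summaries["de"] = {
            label: {"n_tested": len(r.table), "n_up": len(r.up()), "n_down": len(r.down()),
                    "d0": r.params.d0, "norm": "TMM", "cpm_min_samples": "smaller group"}
            for label, r in de_results.items()
        }

    # ---- axes ------------------------------------------------------------
    if "axes" in stages:
        if "de" not in state:
            raise MiraxError("axes stage requires the de stage")
        de_r = state["de"]
        consensus = axes_mod.consensus_degs(
            [(de_r["mrna_discovery"].up(), de_r["mrna_discovery"].down()),
             (de_r["mrna_cohort2"].up(), de_r["mrna_cohort2"].down())],
            cohort_ids=["discovery", "cohort2"],
        )
        mirna_sets = [
            (de_r["mirna_discovery"].up(), de_r["mirna_discovery"].down()),
            (de_r["mirna_discovery_paired"].up(), de_r["mirna_discovery_paired"].down()),
            (de_r["mirna_cohort2"].up(), de_r["mirna_cohort2"].down()),
        ]
        cons_mirnas = axes_mod.consensus_mirnas(mirna_sets)
        axis_list = axes_mod.build_axes(cons_mirnas, state["targets"], consensus)
        graph = axes_mod.build_bipartite(axis_list) if axis_list else None
        axes_df = pd.DataFrame(
            [(a.mirna_id, a.direction, a.n_targets, ",".join(sorted(a.supported_targets)))
             for a in axis_list],
            columns=["mirna_id", "direction", "n_targets", "targets"],
        )
        p = out / "axes.tsv"; axes_df.to_csv(p, sep="\t", index=False); emit(p)
        if graph is not None:
            axes_mod.write_network(graph, out / "edges.tsv", out / "network.graphml")
            emit(out / "edges.tsv"); emit(out / "network.graphml")
        state["consensus"] = consensus
        state["axes"] = axis_list
        summaries["axes"] = {
            "consensus_up": len(consensus.up), "consensus_down": len(consensus.down),
            "n_mirnas": len(cons_mirnas),
            "n_edges": int(sum(a.n_targets for a in axis_list)),
            "axes": {a.mirna_id: {"direction": a.direction, "n_targets": a.n_targets}
                     for a in axis_list},
        }

    # ---- coherence --------------------------------------------------------
    if "coherence" in stages:
        if "axes" not in state:
            raise MiraxError("coherence stage requires the axes stage")
        mrna_lc = coh_mod.collapse_duplicates(state["logcpm"]["mrna_discovery"])
        z = coh_mod.row_zscore(mrna_lc, tumor_only=True)
        mirna_lc = state["logcpm"]["mirna_discovery"]
        tumor_ids = mirna_lc.tumor_samples()
        mirna_tumor = mirna_lc.values[tumor_ids]
        results = coh_mod.coherence_panel(state["axes"], z, mirna_tumor,
                                          min_targets=config.min_targets)
        table = coh_mod.coherence_table(results)
        p = out / "coherence.tsv"; table.to_csv(p, sep="\t"); emit(p)
        activities = {}
        for axis in state["axes"]:
            prof = coh_mod.target_set_activity(z, axis, min_targets=config.min_targets)
            if prof is not None:
                activities[axis.mirna_id] = prof.activity
        act_df = pd.DataFrame(activities)
        p = out / "activity.tsv"; act_df.to_csv(p, sep="\t"); emit(p)
        state["activities"] = act_df
        state["mirna_tumor_logcpm"] = mirna_tumor
        state["coherence"] = table
        summaries["coherence"] = {
            "n_axes_tested": int((table["status"] == "ok").sum()),
            "n_significant_q05": int(((table["q"] <= 0.05) & (table["status"] == "ok")).sum()),
            "rho": {m: (None if not np.isfinite(r) else round(float(r), 4))
                    for m, r in table["rho"].items()},
        }

    # ---- survival modeling -------------------------------------------------
    if "survive" in stages:
        if "activities" not in state:
            raise MiraxError("survive stage requires the coherence stage")
        axis_ids = [a.mirna_id for a in state["axes"] if a.mirna_id in state["activities"].columns]
        mirna_abund = state["mirna_tumor_logcpm"].loc[axis_ids]
        feats, surv_cc = surv_mod.assemble_axis_matrix(
            mirna_abund, state["activities"][axis_ids], state["surv"])
        cluster = surv_mod.cluster_axes(feats, seed=config.seed)
        cv = surv_mod.nested_cv(
            feats.values, surv_cc, k_outer=config.k_outer, k_inner=config.k_inner,
            alpha_grid=config.alpha_grid, n_lambda=config.n_lambda, seed=config.seed)
        model = surv_mod.final_fit(
            feats.values, surv_cc, spec="axes", cv_report=cv,
            n_lambda=config.n_lambda, k_inner=config.k_inner, seed=config.seed)
        risk = model.linear_predictor(feats.values)
        labels = surv_mod.median_split(risk)
        chi2, p_km = surv_mod.logrank_test(surv_cc, labels)
        p = out / "cv_report.tsv"; cv.to_frame().to_csv(p, sep="\t", index=False); emit(p)
        _write_json(model.to_dict(), out / "model.json"); emit(out / "model.json")
        p = out / "risk_scores.tsv"
        pd.DataFrame({"risk": risk, "group": labels}).to_csv(p, sep="\t"); emit(p)
        sil = pd.DataFrame(sorted(cluster.silhouette.items()), columns=["K", "silhouette"])
        p = out / "cluster_silhouette.tsv"; sil.to_csv(p, sep="\t", index=False); emit(p)
        state["model"] = model
        state["features"] = feats
        summaries["survive"] = {
            "n_complete_cases": len(feats.sample_ids),
            "cv_mean_cindex": {s: round(cv.mean_cindex(s), 4) for s in cv.fold_cindex},
            "final_alpha": model.alpha, "final_lambda": model.lam,
            "median_split_logrank_p": float(p_km),
            "silhouette_k2": round(float(cluster.silhouette[2]), 4),
        }

    # ---- locked external validation ---------------------------------------
    if "validate" in stages:
        if "model" not in state:
            raise MiraxError("validate stage requires the survive stage")
        val_lc = _logcpm(state["mirna_val"], config)
        feats_val = val_lc.values.T.add_prefix("abund_")
        rep = surv_mod.locked_external_validate(
            state["model"], feats_val, state["surv_val"],
            seed=config.seed, n_boot=config.n_boot, allow_subset=True)
        p = out / "validation_risk.tsv"
        pd.DataFrame({"risk": rep.risk, "group": rep.labels}).to_csv(p, sep="\t"); emit(p)
        val_summary = {
            "cindex": rep.cindex, "cindex_ci": list(rep.cindex_ci),
            "cutpoint": rep.cutpoint, "n_high": rep.n_high, "n_low": rep.n_low,
            "logrank_p": rep.logrank_p, "hr_high_vs_low": rep.cox.hr,
            "hr_ci": [rep.cox.ci_low, rep.cox.ci_high],
        }
        _write_json(val_summary, out / "validation_summary.json")
        emit(out / "validation_summary.json")
        summaries["validate"] = {k: (round(v, 4) if isinstance(v, float) else v)
                                 for k, v in val_summary.items()}
        state["validation"] = rep

    # ---- survival screen ----------------------------------------------------
    if "screen" in stages:
        if "axes" not in state:
            raise MiraxError("screen stage requires the axes stage")
        union_targets = sorted(set().union(*(a.supported_targets for a in state["axes"]))) \
            if state["axes"] else []
        mrna_lc = state["logcpm"]["mrna_discovery"]
        tumor_ids = [s for s in mrna_lc.tumor_samples() if s in state["surv"].index]
        present = [g for g in union_targets if g in mrna_lc.values.index]
        genes_df = mrna_lc.values.loc[present, tumor_ids]
        screen = surv_mod.survival_screen(genes_df, state["surv"].loc[tumor_ids],
                                          fdr=config.fdr_screen)
        table = surv_mod.screen_table(screen)
        p = out / "screen.tsv"; table.to_csv(p, sep="\t"); emit(p)
        state["screen"] = table
        summaries["screen"] = {
            "n_screened": len(table),
            "n_shortlisted": int(table["shortlist"].sum()),
            "fdr": config.fdr_screen,
        }

    # ---- manifest and report -----------------------------------------------
    manifest = {str(p.relative_to(out)): _sha256(p) for p in sorted(set(written))}
    _write_json({"seed": config.seed, "files": manifest,
                 "schema_version": CONFIG_SCHEMA_VERSION}, out / "manifest.json")
    report_text = render_report(summaries, config)
    (out / "report.md").write_text(report_text)
    for stage, s in summaries.items():
        logger.info("stage %-10s %s", stage, json.dumps(s, default=_json_default)[:200])
    return RunReport(seed=config.seed, stage_summaries=summaries,
                     manifest=manifest, outdir=str(out))


def render_report(summaries: dict[str, dict], config: RunConfig) -> str:
    """Deterministic human-readable summary of a pipeline run."""
    lines = ["# mirax run report", "",
             f"- seed: {config.seed}",
             f"- thresholds: CPM >= {config.cpm_threshold}, "
             f"|log2FC| mRNA >= {config.lfc_mrna}, miRNA >= {config.lfc_mirna:.4f}, "
             f"DE FDR <= {config.fdr_de}, screen FDR <= {config.fdr_screen}", ""]
    if "simulate" in summaries:
        s = summaries["simulate"]
        lines += ["## Cohorts",
                  f"- {s['n_genes']} genes x ({s['n_tumor']} tumors + {s['n_normal']} normals); "
                  f"{s['n_mirnas']} miRNAs; validation n = {s['n_validation']}", ""]
    if "de" in summaries:
        lines.append("## Differential expression")
        for label, d in summaries["de"].items():
            lines.append(f"- {label}: {d['n_up']} up / {d['n_down']} down "
                         f"of {d['n_tested']} tested (norm={d['norm']})")
        lines.append("")
    if "axes" in summaries:
        a = summaries["axes"]
        lines += ["## Consensus and axes",
                  f"- consensus DEGs: {a['consensus_up']} up, {a['consensus_down']} down",
                  f"- {a['n_mirnas']} direction-consistent miRNA(s); "
                  f"{a['n_edges']} supported miRNA-target pairs"]
        for m, info in a["axes"].items():
            lines.append(f"  - {m} ({info['direction']}): {info['n_targets']} supported targets")
        lines.append("")
    if "coherence" in summaries:
        c = summaries["coherence"]
        lines += ["## Coherence",
                  f"- {c['n_axes_tested']} axes tested; "
                  f"{c['n_significant_q05']} significant at BH q <= 0.05"]
        for m, r in c["rho"].items():
            lines.append(f"  - {m}: Spearman rho = {r}")
        lines.append("")
    if "survive" in summaries:
        s = summaries["survive"]
        lines += ["## Survival modeling",
                  f"- complete cases: {s['n_complete_cases']}",
                  f"- CV mean c-index: " + ", ".join(
                      f"{k}={v}" for k, v in s["cv_mean_cindex"].items()),
                  f"- final model: alpha={s['final_alpha']}, lambda={s['final_lambda']:.5f}",
                  f"- median-split log-rank p = {s['median_split_logrank_p']:.3g}",
                  f"- k-means K=2 silhouette = {s['silhouette_k2']}", ""]
    if "validate" in summaries:
        v = summaries["validate"]
        lines += ["## Locked external validation",
                  f"- c-index = {v['cindex']} [{v['cindex_ci'][0]}, {v['cindex_ci'][1]}]",
                  f"- High n={v['n_high']} vs Low n={v['n_low']}; "
                  f"HR = {v['hr_high_vs_low']} [{v['hr_ci'][0]}, {v['hr_ci'][1]}], "
                  f"log-rank p = {v['logrank_p']:.3g}", ""]
    if "screen" in summaries:
        s = summaries["screen"]
        lines += ["## Survival screen",
                  f"- {s['n_shortlisted']} of {s['n_screened']} union targets shortlisted "
                  f"at FDR <= {s['fdr']}", ""]
    return "\n".join(lines) + "\n"
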