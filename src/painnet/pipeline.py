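"""End-to-end orchestration: simulate -> connectivity -> topology -> statistics.

A run is driven by a :class:`RunConfig`, is deterministic given its seed, and
leaves behind a run directory containing the simulated cohort (TSV), the
per-session topology summary, the three statistical tables (pain-score group
comparisons, covariate-adjusted network-measure comparisons, per-group
stepwise regressions of clinical pain on pain-network topology), and a
manifest recording every analysis-relevant switch.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortDesign, SubjectRecord, simulate_cohort, write_cohort
from .connectivity import subject_adjacency
from .io import write_summary_tsv
from .nodesets import NodeSet, load_nodeset
from .stats import ancova_group, forward_stepwise, mann_whitney
from .topology import summarize

log = logging.getLogger("painnet")

#: The analysis-relevant switches and their defaults.  Each default is the
#: convention the pipeline documents as its primary reading (see
#: docs/methods.md); every run manifest enumerates the values actually used.
ANALYSIS_DECISIONS = {
    "fd_threshold_mm": "scrub frames whose incoming transition has FD strictly > threshold",
    "drop_volumes": "initial field-equilibrium volumes discarded before everything else",
    "scrub_drop_preceding": "whether the frame before a bad transition is also dropped",
    "head_radius_mm": "sphere radius converting rotations (rad) to mm",
    "negative_policy": "non-positive Fisher-z weights: 'zero' = absent edge, 'abs' = magnitude",
    "subnetwork_ge_mode": "'induced' = paths confined to the subnetwork; 'restricted' = whole-brain distances",
    "zscore_ddof": "0 = population-sd z-scoring of BC, 1 = sample-sd",
    "p_enter": "forward-stepwise entry threshold (no removal step by default)",
}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Defaults equal the documented primary analysis choices.  ``design``
    holds the synthetic-cohort generating parameters; the demo default
    simulates 202-frame scans so the 3-volume discard is exercised.
    """

    out_dir: str = "painnet_run"
    seed: int = 0
    fd_threshold_mm: float = 1.5
    drop_volumes: int = 3
    scrub_drop_preceding: bool = False
    head_radius_mm: float = 50.0
    negative_policy: str = "zero"
    subnetwork_ge_mode: str = "induced"
    zscore_ddof: int = 0
    p_enter: float = 0.05
    p_remove: float | None = None
    design: dict = field(default_factory=dict)
    nodesets: list[str] = field(default_factory=lambda: ["pain", "dmn"])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        obj = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**obj)

    def cohort_design(self) -> CohortDesign:
        d = dict(self.design)
        d.setdefault("n_frames", 202)
        d.setdefault("seed", self.seed)
        if "pain_r_by_group" in d:
            d["pain_r_by_group"] = dict(d["pain_r_by_group"])
        if "pain_nodes" in d and d["pain_nodes"] is not None:
            d["pain_nodes"] = tuple(d["pain_nodes"])
        return CohortDesign(**d)


def topology_summaries(
    records: list[SubjectRecord], config: RunConfig, nodesets: dict[str, NodeSet]
) -> pd.DataFrame:
    """Connectivity + topology for every subject-session."""
    rows = []
    for rec in records:
        adj, n_ret, avg_motion = subject_adjacency(
            rec.time_series,
            rec.motion,
            drop_volumes=config.drop_volumes,
            fd_threshold_mm=config.fd_threshold_mm,
            head_radius_mm=config.head_radius_mm,
            drop_preceding=config.scrub_drop_preceding,
        )
        summ = summarize(
            adj,
            nodesets,
            subject_id=rec.subject_id,
            session=rec.session,
            negative_policy=config.negative_policy,
            subnetwork_ge_mode=config.subnetwork_ge_mode,
            zscore_ddof=config.zscore_ddof,
            n_frames_retained=n_ret,
            mean_motion=avg_motion,
        )
        rows.append(summ.to_row())
    return pd.DataFrame(rows)


def _session_frames(summary: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    return summary.merge(
        cohort, on=["subject_id", "session"], how="left", validate="one_to_one"
    )


def compare_pain_scores(cohort: pd.DataFrame) -> pd.DataFrame:
    """Mann-Whitney group comparisons of each pain measure, HC vs each
    patient session (pain-score analogue of a group-difference table)."""
    rows = []
    hc = cohort[cohort["group"] == "control"]
    for session in ("OFF", "ON"):
        pd_rows = cohort[(cohort["group"] == "patient") & (cohort["session"] == session)]
        for measure in ("cas_intensity", "cas_affect", "nwc"):
            u, p = mann_whitney(hc[measure], pd_rows[measure])
            rows.append(
                {
                    "measure": measure,
                    "contrast": f"HC_vs_PD_{session}",
                    "hc_mean": hc[measure].mean(),
                    "hc_sd": hc[measure].std(),
                    "pd_mean": pd_rows[measure].mean(),
                    "pd_sd": pd_rows[measure].std(),
                    "U": u,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)


def compare_network_measures(
    frames: pd.DataFrame, dv_columns: list[str]
) -> pd.DataFrame:
    """Motion-adjusted group comparison of each network measure, HC vs each
    patient session (two two-group models; patient sessions treated as
    independent samples, a documented caveat of the design)."""
    rows = []
    hc = frames[frames["group"] == "control"]
    for session in ("OFF", "ON"):
        pd_rows = frames[(frames["group"] == "patient") & (frames["session"] == session)]
        sub = pd.concat([hc, pd_rows], ignore_index=True)
        res = ancova_group(sub[dv_columns], sub["group"], sub["mean_motion"])
        for dv, term in res.per_dv.items():
            rows.append(
                {
                    "measure": dv,
                    "contrast": f"HC_vs_PD_{session}",
                    "hc_mean": hc[dv].mean(),
                    "hc_sd": hc[dv].std(),
                    "pd_mean": pd_rows[dv].mean(),
                    "pd_sd": pd_rows[dv].std(),
                    "F": term.f,
                    "df_num": term.df_num,
                    "df_den": term.df_den,
                    "p": term.p,
                    "wilks_lambda": res.wilks_lambda,
                    "wilks_p": res.wilks_p,
                }
            )
    return pd.DataFrame(rows)


def stepwise_pain_tables(
    frames: pd.DataFrame, p_enter: float = 0.05, p_remove: float | None = None
) -> pd.DataFrame:
    """Per-group forward-stepwise regression of NWC on pain-network BC and
    GE, with mean motion forced in the first block."""
    analyses = {
        "HC": frames[frames["group"] == "control"],
        "PD_ON": frames[(frames["group"] == "patient") & (frames["session"] == "ON")],
        "PD_OFF": frames[(frames["group"] == "patient") & (frames["session"] == "OFF")],
    }
    rows = []
    for label, sub in analyses.items():
        if len(sub) <= 4:  # 2 candidates + covariate + intercept
            log.warning("skipping stepwise analysis %s: only %d sessions", label, len(sub))
            continue
        res = forward_stepwise(
            sub["nwc"].to_numpy(dtype=float),
            sub[["bc_pain", "ge_pain"]].reset_index(drop=True),
            sub[["mean_motion"]].reset_index(drop=True),
            p_enter=p_enter,
            p_remove=p_remove,
        )
        for step_i, step in enumerate(res.steps, start=1):
            for term, coef in step.coefficients.iterrows():
                rows.append(
                    {
                        "analysis": label,
                        "step": step_i,
                        "term": term,
                        "B": coef["B"],
                        "se_B": coef["se_B"],
                        "std_B": coef["std_B"],
                        "p": coef["p"],
                        "model_r2": step.r_squared,
                        "model_f": step.f,
                        "model_df": step.df_model,
                        "model_p": step.model_p,
                    }
                )
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> Path:
    """Execute the full pipeline into ``config.out_dir``; returns the path.

    Deterministic given the config seed.  Fails loudly (with the offending
    stage named) rather than proceeding past an invalid intermediate state.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    design = config.cohort_design()
    log.info("simulating cohort (seed=%d)", design.seed)
    records, cohort = simulate_cohort(design)
    write_cohort(records, cohort, out / "cohort")

    nodesets: dict[str, NodeSet] = {}
    pain_idx = design.resolved_pain_nodes()
    for name in config.nodesets:
        ns = load_nodeset(name)
        if ns.n_total == design.n_nodes:
            nodesets[ns.name] = ns
        elif ns.name == "pain":
            # scaled-down designs: the pain set is wherever the generator
            # planted the pain block
            nodesets["pain"] = NodeSet("pain", pain_idx, design.n_nodes)
        else:
            # remap onto the non-pain nodes, keeping the set's cardinality
            # where the design allows
            rest = [i for i in range(design.n_nodes) if i not in set(pain_idx)]
            idx = tuple(rest[: min(len(ns), len(rest))])
            if len(idx) < 2:
                raise ValueError(
                    f"design too small to carry node set '{ns.name}'"
                )
            nodesets[ns.name] = NodeSet(ns.name, idx, design.n_nodes)

    log.info("computing connectivity and topology for %d sessions", len(records))
    summary = topology_summaries(records, config, nodesets)
    write_summary_tsv(summary.to_dict("records"), out / "summary.tsv")

    frames = _session_frames(summary, cohort)
    tables = out / "tables"
    tables.mkdir(exist_ok=True)
    compare_pain_scores(cohort).to_csv(
        tables / "pain_scores.tsv", sep="\t", index=False
    )
    dv_cols = [c for c in summary.columns if c.startswith(("ge_", "bc_"))]
    compare_network_measures(frames, dv_cols).to_csv(
        tables / "network_measures.tsv", sep="\t", index=False
    )
    if {"bc_pain", "ge_pain"} <= set(frames.columns):
        stepwise_pain_tables(frames, config.p_enter, config.p_remove).to_csv(
            tables / "stepwise_pain.tsv", sep="\t", index=False
        )

    cfg = asdict(config)
    manifest = {
        "painnet_version": __version__,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "analysis_decisions": {
            k: {"value": cfg.get(k), "meaning": v}
            for k, v in ANALYSIS_DECISIONS.items()
        },
        "n_subject_sessions": len(records),
        "nodesets": {k: len(v) for k, v in nodesets.items()},
        "n_statistical_tests": {
            "pain_scores": 6,
            "network_measures_per_contrast": len(dv_cols),
            "stepwise_analyses": 3,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    log.info("run complete: %s", out)
    return out
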