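"""End-to-end pipelines: atlas subtyping and physiology quantification.

Both pipelines are plain functions over the library modules; the CLI wraps
them thinly. All randomness flows from a single seed, artifacts are
plain-text (TSV/JSON/YAML), and every run writes a manifest with content
hashes so reruns can be checked for byte-identity.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .breath import effect_estimate, group_compare, segment_breaths, select_eupnea
from .cluster import ClusterParams, call_hybrids, iterate_clustering, rescue_rare
from .exceptions import InputError
from .markers import (
    annotate_subtypes,
    dotplot_stats,
    intersect_markers,
    pairwise_de,
    prevalence_screen,
    scale_abundance,
)
from .qc import QCThresholds, apply_qc
from .sim.atlas import default_atlas_config, simulate_atlas
from .sim.physio import (
    PRESETS,
    BreathModel,
    VentilationProtocol,
    default_calcium_cohort,
    simulate_calcium,
    simulate_emg,
    simulate_flow,
)
from .stim import classify_calcium, delta_ti, detect_bursts

log = logging.getLogger("psn_atlas")

__all__ = ["run_atlas_pipeline", "run_physiology_pipeline", "atlas_subtype_labels"]


def atlas_subtype_labels(matrix, params: ClusterParams):
    """Cluster, rescue rare clusters, call hybrids; return (labels, tree, calls).

    Labels: leaf labels, ``R*`` rare-cluster labels, ``hybrid`` for cells
    flip-called between sibling leaves, ``dropped`` for unstable cells.
    """
    tree = iterate_clustering(matrix, params)
    tree = rescue_rare(tree, matrix, params)
    calls = call_hybrids(tree, matrix, params) if len(tree.leaves) >= 2 else []
    labels = tree.assignments()
    for c in calls:
        labels.loc[c.cell_id] = "hybrid"
    return labels.reindex(matrix.obs_names), tree, calls


def run_atlas_pipeline(
    out_dir: str | Path,
    matrix=None,
    seed: int = 0,
    simulate: bool = False,
    qc_thresholds: QCThresholds | None = None,
    cluster_params: ClusterParams | None = None,
    de_alpha: float = 0.01,
    de_min_effect: float = 1.0,
) -> dict:
    """QC -> iterative clustering -> subtype labels -> markers & repertoires.

    With ``simulate=True`` the default synthetic atlas for ``seed`` is
    generated as input. Returns a summary dict; artifacts (QC report,
    cluster tree JSON, label TSV, marker table, dot-plot stats, abundance
    estimates, manifest) land in ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if simulate:
        matrix = simulate_atlas(default_atlas_config(seed=seed))
    if matrix is None:
        raise InputError("provide a matrix or set simulate=True")
    log.info("atlas: %d cells x %d genes", matrix.n_obs, matrix.n_vars)

    qc_thresholds = qc_thresholds or QCThresholds()
    kept, report = apply_qc(matrix, qc_thresholds)
    report.verdicts.to_csv(out / "qc_verdicts.tsv", sep="\t")
    (out / "qc_summary.json").write_text(json.dumps(report.summary(), indent=2, sort_keys=True))
    log.info("qc: retained %d / %d cells", report.n_retained, report.n_input)

    params = cluster_params or ClusterParams(seed=seed)
    labels, tree, calls = atlas_subtype_labels(kept, params)
    labels.to_frame("subtype").to_csv(out / "subtype_labels.tsv", sep="\t")
    (out / "cluster_tree.json").write_text(json.dumps(tree.to_dict(), indent=2, sort_keys=True))
    subtypes = sorted(s for s in labels.unique() if s not in ("dropped",))
    log.info("clustering: %d subtype classes %s", len(subtypes), subtypes)

    # markers on discrete (non-hybrid) subtypes with enough cells
    discrete = labels[~labels.isin(["dropped", "hybrid"])]
    counts = discrete.value_counts()
    usable = counts[counts >= 2].index
    de = pairwise_de(kept[discrete.index], discrete[discrete.isin(usable)])
    marker_table = intersect_markers(de, alpha=de_alpha, min_effect=de_min_effect)
    marker_table.to_csv(out / "marker_table.tsv", sep="\t", index=False)
    if len(marker_table):
        dp = dotplot_stats(kept[discrete.index], discrete, sorted(marker_table["gene"].unique()))
        dp.to_csv(out / "dotplot_stats.tsv", sep="\t", index=False)
    abundance = scale_abundance(labels[labels != "dropped"].value_counts().to_dict())
    abundance.to_csv(out / "abundance.tsv", sep="\t")
    screens = {}
    if "glial_panel" in matrix.uns:
        screens["glial"] = prevalence_screen(
            kept[discrete.index], discrete, list(matrix.uns["glial_panel"])
        )
    annotation = None
    if "Nefh" in kept.var_names and "Phox2b" in kept.var_names:
        annotation = annotate_subtypes(kept[discrete.index], discrete)
        annotation.to_csv(out / "subtype_annotation.tsv", sep="\t")
    (out / "screens.json").write_text(json.dumps(screens, indent=2, sort_keys=True))

    summary = {
        "seed": seed,
        "n_input_cells": int(matrix.n_obs),
        "n_retained": int(report.n_retained),
        "n_leaves": len([s for s in subtypes if s.startswith("C")]),
        "n_rare": len([s for s in subtypes if s.startswith("R")]),
        "n_hybrid_cells": int((labels == "hybrid").sum()),
        "n_subtypes": len(subtypes),
        "n_markers": int(len(marker_table)),
        "subtypes": subtypes,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    pio.write_manifest(out, {"seed": seed, "pipeline": "atlas"})
    return summary


def simulate_animal_pair(
    preset_name: str,
    seed: int,
    n_breaths: int = 2000,
    model: BreathModel | None = None,
):
    """Simulate one animal's pre (control) and post (scenario) recordings."""
    model = model or BreathModel()
    dur = n_breaths * (model.ti + model.te) / (1 - model.irregular_frac * 0.3)
    pre = simulate_flow(model, "control", duration=dur, seed=seed)
    post = simulate_flow(model, preset_name, duration=dur, seed=seed + 500_000)
    return pre, post


def animal_effects(pre, post, parameters, animal_id=None, window: int = 9, cv_max: float = 0.15):
    eff = {}
    tables = []
    for trace in (pre, post):
        tbl = select_eupnea(segment_breaths(trace), window=window, cv_max=cv_max)
        tables.append(tbl)
    for p in parameters:
        eff[p] = effect_estimate(tables[0], tables[1], p, animal_id=animal_id)
    return eff


def run_physiology_pipeline(
    out_dir: str | Path,
    preset: str = "psn6_ablation",
    n_animals: int = 6,
    seed: int = 0,
    n_breaths: int = 2000,
    parameters: tuple[str, ...] = ("tv", "ti", "pif"),
    simulate: bool = True,
    with_emg: bool = True,
    with_calcium: bool = True,
) -> dict:
    """Simulated ablation study: breath effects, EMG challenge, calcium calls.

    Two arms of ``n_animals`` animals each: a control arm (pre and post both
    control) and a treated arm (pre control, post ``preset``). Per-animal
    KDE-peak effect estimates are compared across arms per parameter with
    the Mann-Whitney U test (significant at p < 0.05).
    """
    if not simulate:
        raise InputError("only simulated cohorts are supported in this pipeline entry")
    if preset not in PRESETS:
        raise InputError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    effects: dict[str, dict[str, list]] = {p: {"control": [], "treated": []} for p in parameters}
    for arm, arm_preset in [("control", "control"), ("treated", preset)]:
        for a in range(n_animals):
            s = seed + 1000 * a + (0 if arm == "control" else 7_000_000)
            pre, post = simulate_animal_pair(arm_preset, seed=s + 1, n_breaths=n_breaths)
            eff = animal_effects(pre, post, parameters, animal_id=f"{arm}{a}")
            for p in parameters:
                effects[p][arm].append(eff[p])
                rows.append(
                    {
                        "arm": arm,
                        "animal": f"{arm}{a}",
                        "parameter": p,
                        "pre_peak": eff[p].pre_peak,
                        "post_peak": eff[p].post_peak,
                        "delta_pct": eff[p].delta_pct,
                    }
                )
    effect_table = pd.DataFrame(rows)
    effect_table.to_csv(out / "effect_estimates.tsv", sep="\t", index=False)
    tests = {}
    for p in parameters:
        cmp = group_compare(effects[p]["control"], effects[p]["treated"])
        cmp["significant"] = bool(cmp["p_value"] < 0.05)
        tests[p] = cmp
    (out / "group_tests.json").write_text(json.dumps(tests, indent=2, sort_keys=True))

    summary: dict = {
        "preset": preset,
        "seed": seed,
        "n_animals": n_animals,
        "group_tests": tests,
        "mean_delta_pct_treated": {
            p: float(np.mean([e.delta_pct for e in effects[p]["treated"]])) for p in parameters
        },
    }

    if with_emg:
        protocol = VentilationProtocol(
            hold_schedule=[
                ("deflation", 2.0, 5.0),
                ("inflation", 6.0, 5.0),
                ("inflation", 8.0, 5.0),
                ("inflation", 10.0, 5.0),
                ("inflation", 20.0, 5.0),
            ]
        )
        emg_rows = []
        for arm, arm_preset in [("control", "control"), ("treated", preset)]:
            for a in range(n_animals):
                tr = simulate_emg(protocol, arm_preset, seed=seed + 31 * a + (0 if arm == "control" else 900_000))
                bursts = detect_bursts(tr)
                dt = delta_ti(bursts, tr.hold_windows)
                dt["group"] = arm
                dt["animal"] = f"{arm}{a}"
                emg_rows.append(dt)
        emg_table = pd.concat(emg_rows, ignore_index=True)
        emg_table.to_csv(out / "emg_delta_ti.tsv", sep="\t", index=False)
        summary["emg_delta_ti_mean"] = {
            arm: emg_table[emg_table["group"] == arm]
            .groupby("pressure")["delta_ti_pct"]
            .mean()
            .to_dict()
            for arm in ("control", "treated")
        }

    if with_calcium:
        traces = simulate_calcium(default_calcium_cohort(seed), seed=seed)
        calls = [classify_calcium(tr) for tr in traces]
        ca = pd.DataFrame([vars(c) for c in calls])
        ca.to_csv(out / "calcium_calls.tsv", sep="\t", index=False)
        summary["calcium"] = {
            "n_cells": len(calls),
            "n_responder_20": int(sum(c.responder_20 for c in calls)),
            "n_type_I": int(sum(c.type == "I" for c in calls)),
            "n_type_II": int(sum(c.type == "II" for c in calls)),
        }

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    pio.write_manifest(out, {"seed": seed, "pipeline": "physiology", "preset": preset})
    return summary
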