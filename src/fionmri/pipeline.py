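"""Cohort-level orchestration: simulate → black-pixel quantify → group stats.

This is the end-to-end path the analysis drivers, the command-line interface
and the validation harness all share: a cohort of pre/post scene pairs goes
through the lesion pipeline one subject at a time, the per-lesion black pixel
counts are collected into a table, and the group comparison appropriate to
the number of arms is run on that table.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from . import io as fio
from .blackpixel import run_lesion_pipeline
from .group_stats import GroupComparison, anova_tukey, compare_two_groups
from .synthetic import GroupSpec, SceneSpec, SubjectScenes, simulate_ln_cohort


def quantify_cohort(
    cohort: "list[SubjectScenes]",
    *,
    quantile: float = 0.0,
    rule_threshold: float = 20.0,
    classify: bool = True,
) -> pd.DataFrame:
    """Black-pixel quantification of every subject's pre/post pair.

    Returns one row per lesion with the designed fraction (ground truth),
    the recovered black pixel count and, when requested, the 20%-rule call.
    """
    rows = []
    for subj in cohort:
        pre_series, pre_rois, _ = subj.pre
        post_series, post_rois, _ = subj.post
        report = run_lesion_pipeline(
            pre_series,
            post_series,
            pre_rois,
            post_rois,
            quantile=quantile,
            classify=classify,
            rule_threshold=rule_threshold,
        )
        rows.append(
            {
                "group": subj.group,
                "subject": subj.subject,
                "designed_fraction_pct": 100.0 * subj.designed_fraction,
                "threshold_nsi": report.threshold_nsi,
                "black_pixel_pct": report.result.black_pixel_pct,
                "n_black": report.result.n_black,
                "n_lesion_voxels": report.result.n_total,
                "call": report.call.call if report.call else None,
            }
        )
    return pd.DataFrame(rows)


def compare_cohort(table: pd.DataFrame, value_col: str = "black_pixel_pct") -> GroupComparison:
    """Group comparison matched to the number of arms in the cohort table."""
    labels = list(dict.fromkeys(table["group"]))
    groups = [table.loc[table["group"] == g, value_col].to_numpy() for g in labels]
    if len(groups) == 2:
        return compare_two_groups(*groups, method="auto", labels=labels)
    return anova_tukey(groups, labels=labels)


def _scene_from_config(cfg: dict) -> SceneSpec:
    known = {f.name for f in dataclasses.fields(SceneSpec)}
    scene_cfg = {k: v for k, v in cfg.items() if k in known}
    for key in ("grid", "lesion_center", "muscle_center"):
        if key in scene_cfg:
            scene_cfg[key] = tuple(scene_cfg[key])
    return SceneSpec(**scene_cfg)


def groups_from_config(cfg: "list[dict]") -> "tuple[GroupSpec, ...]":
    return tuple(
        GroupSpec(
            name=g["name"],
            n_subjects=int(g["n_subjects"]),
            mean_fraction=float(g["mean_fraction"]),
            sd_fraction=float(g["sd_fraction"]),
        )
        for g in cfg
    )


def run_pipeline(config: dict, seed: int, out_dir) -> dict:
    """Config-driven end-to-end run; writes cohort CSV, stats JSON, provenance.

    Config keys: ``groups`` (list of name/n_subjects/mean_fraction/sd_fraction),
    optional ``scene`` (SceneSpec overrides), ``quantile``, ``rule_threshold``,
    ``classify``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    groups = groups_from_config(config["groups"])
    scene = _scene_from_config(config.get("scene", {}))
    cohort = simulate_ln_cohort(groups=groups, scene=scene, seed=seed)
    table = quantify_cohort(
        cohort,
        quantile=float(config.get("quantile", 0.0)),
        rule_threshold=float(config.get("rule_threshold", 20.0)),
        classify=bool(config.get("classify", True)),
    )
    table.to_csv(out_dir / "cohort.csv", index=False)

    stats_payload = None
    if len(groups) >= 2 and all(g.n_subjects >= 2 for g in groups):
        cmp = compare_cohort(table)
        stats_payload = comparison_to_dict(cmp)
        (out_dir / "stats.json").write_text(json.dumps(stats_payload, indent=2))
    fio.write_provenance(out_dir, config, seed)
    return {"table": table, "stats": stats_payload, "out_dir": out_dir}


def comparison_to_dict(cmp: GroupComparison) -> dict:
    d = {
        "labels": list(cmp.labels),
        "n": list(cmp.n),
        "means": list(cmp.means),
        "sds": list(cmp.sds),
        "method": cmp.method,
        "statistic": cmp.statistic,
        "p_value": cmp.p_value,
    }
    if cmp.pairwise is not None:
        d["pairwise"] = cmp.pairwise.to_dict(orient="records")
    return d
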