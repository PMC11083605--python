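"""End-to-end orchestration: simulate, score, transpose, match, report.

``run_pipeline`` executes the whole analysis on synthetic inputs (or on
pre-scored measurement tables) and assembles the report bundle: panel
summary, transposition sheet, per-image homogeneity scores, hardness table,
stage summaries, the in vivo/in vitro match tables with per-group final
recommendations, ANOVA results and a provenance manifest.  Runs are
deterministic given a seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import datasets, invivo, matching, stats, synthetic, transposition
from .imaging import InVivoOrigin, channel_variance
from .synthetic import MixSpec, PanelSpec
from .texture import extract_hardness
from .transposition import MasticatorConfig

log = logging.getLogger("chewsim")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

STAGES = (33, 66, 99)


@dataclass
class RunConfig:
    """Configuration of a full synthetic-study run."""

    seed: int = 0
    out_dir: Optional[str] = None
    group_sizes: dict = field(default_factory=lambda: {"child": 30, "adult": 30})
    replicates: int = 2
    compressions: Sequence[int] = datasets.GRID_COMPRESSIONS
    speeds: Sequence[float] = datasets.GRID_SPEEDS
    masticator: MasticatorConfig = field(default_factory=MasticatorConfig)
    child_mix: MixSpec = synthetic.CHILD_MIX
    adult_mix: MixSpec = synthetic.ADULT_MIX
    hardness_noise_sd: float = 2.0
    subject_hardness_sd: float = 5.0
    priority_metric: str = "red_variance"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "masticator" in d and isinstance(d["masticator"], dict):
            d["masticator"] = MasticatorConfig(**d["masticator"])
        for key in ("child_mix", "adult_mix"):
            if key in d and isinstance(d[key], dict):
                d[key] = MixSpec(**d[key])
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class PipelineResult:
    panel_summary: pd.DataFrame
    transposition_sheet: pd.DataFrame
    image_scores: pd.DataFrame
    hardness_scores: pd.DataFrame
    stage_summary: pd.DataFrame
    report: matching.MatchReport
    anova_images: list[stats.AnovaResult]
    anova_hardness: list[stats.AnovaResult]
    triangle_results: list[stats.TriangleTestResult]
    manifest: dict

    @property
    def recommendations(self):
        return self.report.recommendations

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.panel_summary.to_csv(out / "panel_summary.csv", index=False)
        self.transposition_sheet.to_csv(out / "transposition.csv", index=False)
        self.image_scores.to_csv(out / "image_scores.csv", index=False)
        self.hardness_scores.to_csv(out / "hardness_scores.csv", index=False)
        self.stage_summary.to_csv(out / "stage_summary.csv", index=False)
        self.report.to_frame().to_csv(out / "matches.csv", index=False)
        (out / "matches.md").write_text(self.report.to_markdown() + "\n")
        anova = pd.DataFrame(
            {"analysis": name, "effect": r.effect, "F": r.F,
             "df_num": r.df_num, "df_den": r.df_den, "p": r.p}
            for name, results in (
                ("red_variance", self.anova_images),
                ("hardness", self.anova_hardness),
            )
            for r in results
        )
        anova.to_csv(out / "anova.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
        log.info("report bundle written to %s", out)


def _score_images(images) -> pd.DataFrame:
    rows = []
    for img in images:
        score = channel_variance(img, "red")
        o = img.origin
        if isinstance(o, InVivoOrigin):
            rows.append({"kind": "in_vivo", "group": o.group, "stage": o.stage,
                         "subject": o.subject_id, "n_compressions": None,
                         "rotation_speed": None, "replicate": img.replicate,
                         "channel": "red", "variance": score.variance})
        else:
            rows.append({"kind": "in_vitro", "group": None, "stage": None,
                         "subject": None, "n_compressions": o.n_compressions,
                         "rotation_speed": o.rotation_speed,
                         "replicate": img.replicate, "channel": "red",
                         "variance": score.variance})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full synthetic-study analysis."""
    if not config.compressions or not config.speeds:
        raise ValueError("configuration error: the masticator grid is empty")
    rng = np.random.default_rng(config.seed)

    # 1. panels and their summary
    panel = []
    for group, size in config.group_sizes.items():
        panel.extend(synthetic.generate_panel(PanelSpec(group=group, size=size), rng))
    panel_summary = invivo.summarize_panel(panel)

    def _overall(var: str) -> float:
        sel = panel_summary.query("variable == @var and group == 'overall'")
        return float(sel["mean"].iloc[0])

    ratio = _overall("ratio_mouth_per_quantity")
    saliva_rate = _overall("saliva_rate")

    # 2. transposition sheet
    grid = transposition.build_grid(
        config.compressions, config.speeds, config.masticator,
        saliva_rate=saliva_rate, ratio_mouth_per_quantity=ratio,
    )
    sheet = pd.DataFrame(
        {"n_compressions": s.n_compressions, "rotation_speed": s.rotation_speed,
         "saliva_volume_mL": s.saliva_volume, "cheese_mass_g": s.cheese_mass}
        for s in grid
    )

    # 3. images and homogeneity scores
    invivo_images = synthetic.generate_invivo_image_set(
        panel, config.child_mix, config.adult_mix, rng,
        replicates=config.replicates,
    )
    invitro_images = synthetic.generate_invitro_image_set(
        grid, config.adult_mix, rng, replicates=config.replicates
    )
    image_scores = _score_images(invivo_images + invitro_images)

    # 4. hardness from simulated force curves
    hardness_rows = []
    for rec in panel:
        subject_shift = rng.normal(0.0, config.subject_hardness_sd)
        for stage in STAGES:
            mean_h = datasets.INVIVO_HARDNESS[(rec.group, stage)]
            for rep in range(1, config.replicates + 1):
                curve = synthetic.generate_force_curve(
                    max(mean_h + subject_shift, 0.0), "back_extrusion",
                    config.hardness_noise_sd, rng,
                )
                hardness_rows.append(
                    {"kind": "in_vivo", "group": rec.group, "stage": stage,
                     "subject": rec.id, "n_compressions": None,
                     "rotation_speed": None, "replicate": rep,
                     "hardness_N": extract_hardness(curve)}
                )
    for s in grid:
        mean_h = synthetic.invitro_hardness_mean(s.n_compressions, s.rotation_speed)
        for rep in range(1, config.replicates + 1):
            curve = synthetic.generate_force_curve(
                mean_h, "back_extrusion", config.hardness_noise_sd, rng
            )
            hardness_rows.append(
                {"kind": "in_vitro", "group": None, "stage": None,
                 "subject": None, "n_compressions": s.n_compressions,
                 "rotation_speed": s.rotation_speed, "replicate": rep,
                 "hardness_N": extract_hardness(curve)}
            )
    hardness_scores = pd.DataFrame(hardness_rows)

    # 5. stage summaries (replicates averaged per image/subject, then pooled)
    iv_img = image_scores.query("kind == 'in_vivo'")
    iv_hard = hardness_scores.query("kind == 'in_vivo'")
    stage_rows = []
    for (group, stage), sub in iv_img.groupby(["group", "stage"]):
        stage_rows.append({"group": group, "stage": int(stage),
                           "metric": "red_variance",
                           "mean": float(sub["variance"].mean()),
                           "sd": float(sub["variance"].std(ddof=0))})
    for (group, stage), sub in iv_hard.groupby(["group", "stage"]):
        stage_rows.append({"group": group, "stage": int(stage),
                           "metric": "hardness",
                           "mean": float(sub["hardness_N"].mean()),
                           "sd": float(sub["hardness_N"].std(ddof=0))})
    stage_summary = pd.DataFrame(stage_rows)

    # 6. nearest-value matching on the synthetic measurements
    in_vivo_table = {
        (row["group"], row["stage"], row["metric"]): row["mean"]
        for _, row in stage_summary.iterrows()
    }
    vitro_img = (
        image_scores.query("kind == 'in_vitro'")
        .groupby(["n_compressions", "rotation_speed"])["variance"].mean()
    )
    vitro_hard = (
        hardness_scores.query("kind == 'in_vitro'")
        .groupby(["n_compressions", "rotation_speed"])["hardness_N"].mean()
    )
    by_key = {(s.n_compressions, s.rotation_speed): s for s in grid}
    candidates = {
        "red_variance": [(by_key[k], v) for k, v in vitro_img.items()],
        "hardness": [(by_key[k], v) for k, v in vitro_hard.items()],
    }
    report = matching.match_all(
        in_vivo_table, candidates, priority_metric=config.priority_metric
    )

    # 7. inference: mixed three-way ANOVA on images and hardness
    anova_images = stats.mixed_anova(
        iv_img["variance"], iv_img["subject"],
        {"group": iv_img["group"], "stage": iv_img["stage"]},
    )
    anova_hardness = stats.mixed_anova(
        iv_hard["hardness_N"], iv_hard["subject"],
        {"group": iv_hard["group"], "stage": iv_hard["stage"]},
    )

    triangle_results = [
        stats.triangle_test(n_correct, n_panelists)
        for n_panelists, n_correct in datasets.TRIANGLE_SESSIONS
    ]

    manifest = {
        "seed": config.seed,
        "group_sizes": dict(config.group_sizes),
        "replicates": config.replicates,
        "grid": [[s.n_compressions, s.rotation_speed] for s in grid],
        "cheese_mass_g": grid[0].cheese_mass,
        "pooled_ratio_mouth_per_quantity": ratio,
        "pooled_saliva_rate": saliva_rate,
        "n_invivo_images": len(invivo_images),
        "n_invitro_images": len(invitro_images),
        "recommendations": {
            g: [s.n_compressions, s.rotation_speed]
            for g, s in report.recommendations.items()
        },
    }

    result = PipelineResult(
        panel_summary=panel_summary,
        transposition_sheet=sheet,
        image_scores=image_scores,
        hardness_scores=hardness_scores,
        stage_summary=stage_summary,
        report=report,
        anova_images=anova_images,
        anova_hardness=anova_hardness,
        triangle_results=triangle_results,
        manifest=manifest,
    )
    if config.out_dir:
        result.write(config.out_dir)
    return result
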