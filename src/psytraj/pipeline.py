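"""End-to-end pipeline: simulate/read -> aggregate -> MAR check -> model
ladder -> selection -> labelling -> course typology -> cross-tabs ->
covariate associations, with a reproducible report bundle."""

from __future__ import annotations

import json
import logging
import platform
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort, aggregate_cohort, annual_matrix, read_cohort, write_cohort
from .synth import GeneratorConfig, simulate_cohort
from .gmm import GrowthMixtureSpec, avg_posterior_by_modal_class
from .selection import (
    ModelLadderResult,
    SelectionRules,
    bootstrap_lrt,
    default_grid,
    label_classes,
    run_model_ladder,
    select_final_model,
)
from .course import assess_recovery, classify_timeline, crosstab_class_by
from .association import class_association_or, missingness_mar_check, outcome_summaries

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "render_report"]


@dataclass
class PipelineConfig:
    """Exactly one of ``input_paths`` (timeline/baseline/outcome files) or
    ``generator`` must be provided."""

    input_paths: dict | None = None
    generator: GeneratorConfig | None = None
    T: int = 10
    grid_degrees: tuple[int, ...] = (1, 2)
    grid_random_effects: tuple[str, ...] = ("none", "intercept_slope")
    grid_classes: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    n_starts: int = 50
    blrt_draws: int = 0  # 0 disables the bootstrap test in the pipeline
    selection_rules: SelectionRules = field(default_factory=SelectionRules)
    seed: int = 0
    output_dir: str = "psytraj_out"

    def __post_init__(self) -> None:
        if (self.input_paths is None) == (self.generator is None):
            raise ValueError(
                "exactly one of input_paths and generator must be configured"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if d.get("generator") is not None:
            d["generator"] = GeneratorConfig(**d["generator"])
        if d.get("selection_rules") is not None:
            d["selection_rules"] = SelectionRules(**d["selection_rules"])
        for key in ("grid_degrees", "grid_random_effects", "grid_classes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _load_cohort(cfg: PipelineConfig, seeds: dict[str, int]) -> Cohort:
    if cfg.generator is not None:
        gen = GeneratorConfig(**{**asdict(cfg.generator), "seed": seeds["generator"]})
        sim = simulate_cohort(gen)
        return sim.cohort
    paths = cfg.input_paths
    return read_cohort(paths["timeline"], paths["baseline"], paths["outcome"])


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write artefacts to ``cfg.output_dir``.

    Stage failure marks the bundle partial (with the failing stage named)
    instead of raising.  Identical config and seed give identical artefacts.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed)
    sub = ss.spawn(3)
    seeds = {
        "generator": int(sub[0].generate_state(1)[0] % (2**31)),
        "em": int(sub[1].generate_state(1)[0] % (2**31)),
        "blrt": int(sub[2].generate_state(1)[0] % (2**31)),
    }
    bundle: dict = {
        "config": _config_payload(cfg),
        "seeds": seeds,
        "versions": {"psytraj": __version__, "python": platform.python_version()},
        "partial": False,
        "failed_stage": None,
        "stages": {},
    }

    def fail(stage: str, exc: Exception) -> None:
        logger.error("stage %r failed: %s", stage, exc)
        bundle["partial"] = True
        if bundle["failed_stage"] is None:
            bundle["failed_stage"] = stage
        bundle["stages"][stage] = {"error": str(exc)}

    cohort = None
    try:
        cohort = _load_cohort(cfg, seeds)
        write_cohort(
            cohort,
            out / "timelines.csv",
            out / "baselines.csv",
            out / "outcomes.csv",
        )
        bundle["stages"]["cohort"] = {"n_subjects": cohort.n_subjects}
    except Exception as exc:
        fail("cohort", exc)

    series = None
    if cohort is not None:
        try:
            series = aggregate_cohort(cohort, T=cfg.T)
            ids, Y = annual_matrix(series)
            pd.DataFrame(Y, index=ids, columns=[f"year_{t}" for t in range(1, cfg.T + 1)]).to_csv(
                out / "annual_series.csv"
            )
            bundle["stages"]["aggregate"] = {"n_analysed": len(series)}
        except Exception as exc:
            fail("aggregate", exc)

    if cohort is not None and cohort.baselines:
        try:
            mar = missingness_mar_check(cohort.timelines, cohort.baseline_frame(), T=cfg.T)
            mar.to_csv(out / "mar_check.csv", index=False)
            bundle["stages"]["mar_check"] = {
                "n_terms": int(len(mar)),
                "min_p": float(np.nanmin(mar["p"])) if len(mar) else float("nan"),
            }
        except Exception as exc:
            fail("mar_check", exc)

    ladder = None
    if series is not None:
        try:
            grid = default_grid(cfg.grid_degrees, cfg.grid_random_effects, cfg.grid_classes)
            base = GrowthMixtureSpec(n_starts=cfg.n_starts, seed=seeds["em"])
            ladder = run_model_ladder(series, grid=grid, base_spec=base)
            idx, trace = select_final_model(ladder, cfg.selection_rules)
            ladder.to_frame().to_csv(out / "model_ladder.csv")
            (out / "selection_trace.txt").write_text("\n".join(trace) + "\n")
            bundle["stages"]["ladder"] = {
                "n_rows": len(ladder.rows),
                "selected_index": idx,
                "selected": ladder.rows[idx].describe(),
            }
            if cfg.blrt_draws > 0:
                sel = ladder.rows[idx].spec
                if sel.n_classes > 1:
                    from dataclasses import replace as _replace

                    stat, p = bootstrap_lrt(
                        series,
                        sel,
                        _replace(sel, n_classes=sel.n_classes - 1),
                        B=cfg.blrt_draws,
                        seed=seeds["blrt"],
                    )
                    bundle["stages"]["ladder"]["blrt"] = {
                        "k": sel.n_classes,
                        "statistic": stat,
                        "p": p,
                        "draws": cfg.blrt_draws,
                    }
        except Exception as exc:
            fail("ladder", exc)

    labels = None
    fit = None
    if ladder is not None and ladder.selected is not None:
        try:
            fit = ladder.rows[ladder.selected].fit
            label_map = label_classes(fit)
            labels = pd.Series(
                {sid: label_map[int(k)] for sid, k in zip(fit.subject_ids, fit.modal_class)},
                name="trajectory_class",
            )
            post = pd.DataFrame(
                fit.posteriors,
                index=fit.subject_ids,
                columns=[label_map[k] for k in range(fit.n_classes)],
            )
            post.insert(0, "modal_class", labels.loc[post.index])
            post.to_csv(out / "posteriors.csv")
            bundle["stages"]["label"] = {
                "label_map": {int(k): v for k, v in label_map.items()},
                "class_shares_pct": {
                    label_map[k]: round(float(100 * fit.pi[k]), 2)
                    for k in range(fit.n_classes)
                },
                "entropy": float(fit.entropy),
                "avg_posteriors": [
                    float(v) for v in avg_posterior_by_modal_class(fit.posteriors)
                ],
            }
        except Exception as exc:
            fail("label", exc)

    course = None
    if cohort is not None:
        try:
            course_rows = []
            for sid in cohort.subject_ids:
                tl = cohort.timelines[sid]
                course_rows.append(
                    {
                        "subject_id": sid,
                        "course": classify_timeline(tl).value,
                        "recovered": assess_recovery(tl),
                    }
                )
            course = pd.DataFrame(course_rows).set_index("subject_id")
            course.to_csv(out / "course.csv")
            bundle["stages"]["course"] = (
                course["course"].value_counts().to_dict()
            )
        except Exception as exc:
            fail("course", exc)

    if labels is not None and course is not None:
        try:
            xt = crosstab_class_by(labels, course["course"])
            xt.counts.to_csv(out / "crosstab_course.csv")
            rec = crosstab_class_by(labels, course["recovered"].astype("boolean"))
            if rec.counts is not None:
                rec.counts.to_csv(out / "crosstab_recovery.csv")
            bundle["stages"]["crosstab"] = {
                "total": int(xt.counts.to_numpy().sum()),
            }
        except Exception as exc:
            fail("crosstab", exc)

    if labels is not None and cohort is not None and cohort.baselines:
        try:
            rows = []
            for cov in ("sex", "centre", "ethnicity", "diagnosis", "dup_months"):
                for comp in ("late_decline", "late_improvement", "persistent"):
                    if comp not in set(labels):
                        continue
                    for r in class_association_or(
                        labels, cohort.baseline_frame(), cov, comparison=comp
                    ):
                        rows.append(
                            {
                                "covariate": r.covariate,
                                "level": r.level,
                                "comparison": r.comparison,
                                "odds_ratio": r.odds_ratio,
                                "ci_low": r.ci_low,
                                "ci_high": r.ci_high,
                                "p": r.p_value,
                            }
                        )
            assoc = pd.DataFrame(rows)
            assoc.to_csv(out / "associations.csv", index=False)
            summ = outcome_summaries(labels, cohort.outcome_frame())
            summ["gaf_d"].to_csv(out / "gaf_by_class.csv")
            bundle["stages"]["association"] = {
                "n_rows": len(assoc),
                "anova_gaf_F": summ["anova_gaf_d"]["F"],
            }
        except Exception as exc:
            fail("association", exc)

    (out / "bundle.json").write_text(json.dumps(bundle, indent=1, sort_keys=True, default=str))
    return bundle


def _config_payload(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    return d


def render_report(bundle: dict, output_dir: str | Path | None = None) -> str:
    """Render a human-readable summary of a (possibly partial) bundle.

    When ``output_dir`` contains the bundle artefacts, the ladder table and
    the fitted class curves figure are included/produced there.
    """
    lines = ["# Trajectory analysis report", ""]
    if bundle.get("partial"):
        lines.append(
            f"**Partial bundle** — stage {bundle.get('failed_stage')!r} failed; "
            "sections may be missing."
        )
        lines.append("")
    lines.append(f"Seeds: {bundle.get('seeds')}")
    lines.append("")

    stages = bundle.get("stages", {})
    sections = [
        ("cohort", "Cohort"),
        ("mar_check", "Missingness (MAR) check"),
        ("ladder", "Model ladder and selection"),
        ("label", "Trajectory classes"),
        ("course", "Course typology"),
        ("crosstab", "Class-by-course cross-tab"),
        ("association", "Baseline associations"),
    ]
    for key, title in sections:
        lines.append(f"## {title}")
        info = stages.get(key)
        if info is None:
            lines.append("_section missing_")
        elif "error" in info:
            lines.append(f"_failed_: {info['error']}")
        else:
            for k, v in info.items():
                lines.append(f"- {k}: {v}")
        lines.append("")

    if output_dir is not None:
        outdir = Path(output_dir)
        ladder_path = outdir / "model_ladder.csv"
        if ladder_path.exists():
            lines.append("## Ladder table")
            lines.append("```")
            lines.append(ladder_path.read_text().strip())
            lines.append("```")
            lines.append("")
        shares = stages.get("label", {}).get("class_shares_pct")
        if shares:
            try:
                _plot_curves(bundle, outdir)
                lines.append("![class curves](class_curves.png)")
                lines.append("")
            except Exception as exc:  # plotting is best-effort
                logger.warning("could not render class-curve figure: %s", exc)
        report = "\n".join(lines)
        (outdir / "report.md").write_text(report)
        return report
    return "\n".join(lines)


def _plot_curves(bundle: dict, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    post = pd.read_csv(outdir / "posteriors.csv", index_col=0)
    ann = pd.read_csv(outdir / "annual_series.csv", index_col=0)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    years = np.arange(1, ann.shape[1] + 1)
    for cls, grp in ann.join(post["modal_class"]).groupby("modal_class"):
        mean_curve = grp.drop(columns="modal_class").mean(axis=0)
        ax.plot(years, mean_curve, marker="o", label=f"{cls} (n={len(grp)})")
    ax.set_xlabel("follow-up year")
    ax.set_ylabel("months symptomatic per year")
    ax.set_ylim(0, 12)
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "class_curves.png", dpi=120)
    plt.close(fig)
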