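"""End-to-end orchestration: simulate -> preprocess -> fit -> screen ->
derive-rule -> classify -> evaluate, as one reproducible, logged run.

Every stage writes its artifact into the run directory; a manifest
records the configuration, seed, config hash and package versions, and a
human-readable ``report.md`` summarizes the screened components (with
contribution ratios), the per-component and combined AUCs, the derived
rule, the metric table for the graininess call and the Gardner >=3BB
comparator, the paired McNemar test, the fragmentation cross-tab, the
abortion-rate comparison and the covariate screens.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (GraininessRule, classify_graininess, combined_auc,
                       derive_rule, gardner_at_least_3bb)
from .cohort import (FRAG_NONGRAINY_THRESHOLD, CohortConfig, load_cohort,
                     save_cohort, simulate_cohort)
from .eigen import EigenModel, fit_pca
from .evaluation import (EvalReport, correlation_screen, evaluate_predictor,
                         paired_comparison, prop_test_2x2, t_tests)
from .preprocess import PixelMatrix, build_matrix
from .screening import screen_components, screen_frame

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("eigenembryo")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str | Path = "run"
    seed: int = 0
    cohort: CohortConfig | None = None  # None: reuse images already in outdir
    alpha: float = 0.05
    roc_criterion: str = "youden"
    combination_method: str = "max_exceedance"
    rounding: int = 2
    fallback_top: int = 2  # rule fallback when the screen selects nothing
    image_format: str = "png"
    save_images: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outdir"] = str(self.outdir)
        return d


@dataclass
class PipelineResult:
    """In-memory handles to every stage artifact of a finished run."""

    outdir: Path
    meta: pd.DataFrame
    matrix: PixelMatrix
    model: EigenModel
    screens: list
    rule: GraininessRule
    grainy_call: np.ndarray
    gardner_call: np.ndarray
    report_graininess: EvalReport
    report_gardner: EvalReport
    paired: object
    per_component_auc: dict[int, float]
    combined_auc: float
    report_text: str


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _fmt(v, nd=2):
    return "NA" if v is None else f"{v:.{nd}f}"


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage in order, writing artifacts under ``outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    # --- simulate ---------------------------------------------------------
    if config.cohort is not None:
        cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
        log.info("simulate: %d + %d embryos, seed %d", cohort_cfg.n_positive,
                 cohort_cfg.n_negative, cohort_cfg.seed)
        records, meta = simulate_cohort(cohort_cfg)
        if config.save_images:
            save_cohort(records, meta, out / "cohort",
                        image_format=config.image_format)
        else:
            (out / "cohort").mkdir(exist_ok=True)
            meta.to_csv(out / "cohort" / "metadata.csv", index=False)
        cohort_cfg.to_yaml(out / "cohort" / "config.yaml")
    else:
        log.info("simulate: skipped, loading cohort from %s", out / "cohort")
        records, meta = load_cohort(out / "cohort")
    if len(records) == 0:
        raise RuntimeError("stage 'simulate' produced an empty cohort")

    # --- preprocess -------------------------------------------------------
    log.info("preprocess: building %d x 4096 pixel matrix", len(records))
    matrix = build_matrix(records)
    matrix.to_csv(out / "pixel_matrix.csv")

    # --- fit --------------------------------------------------------------
    model = fit_pca(matrix)
    log.info("fit: %d components retained", model.k)
    model.save(out / "eigenmodel.npz")
    model.scores_frame().to_csv(out / "scores.csv")

    # --- screen -----------------------------------------------------------
    labels = meta["hcg"].to_numpy().astype(int)
    screens = screen_components(model, labels, alpha=config.alpha)
    screen_frame(screens).to_csv(out / "screen.csv", index=False)
    selected = [s for s in screens if s.selected]
    log.info("screen: %d/%d components selected at alpha=%g",
             len(selected), len(screens), config.alpha)

    # --- derive rule ------------------------------------------------------
    rule = derive_rule(model, screens, labels, criterion=config.roc_criterion,
                       alpha=config.alpha, fallback_top=config.fallback_top)
    rule.to_json(out / "rule.json")
    per_auc = {c.index: c.auc for c in rule.components}
    combo_auc = (combined_auc(model.scores, labels, rule,
                              method=config.combination_method)
                 if len(rule.components) >= 2
                 else rule.components[0].auc)
    log.info("derive-rule: components %s, combined AUC %.3f",
             [c.index for c in rule.components], combo_auc)

    # --- classify ---------------------------------------------------------
    grainy_call = classify_graininess(model.scores, rule)
    gardner_call = np.array([
        int(gardner_at_least_3bb(g)) for g in meta["gardner"]])
    pd.DataFrame({"id": meta["id"], "grainy": grainy_call,
                  "gardner_ge_3BB": gardner_call}).to_csv(
        out / "classification.csv", index=False)

    # --- evaluate ---------------------------------------------------------
    abortion = meta["abortion"].to_numpy(dtype=float)
    rep_grainy = evaluate_predictor(grainy_call, labels, abortion=abortion,
                                    rounding=config.rounding)
    rep_gardner = evaluate_predictor(gardner_call, labels,
                                     rounding=config.rounding)
    paired = paired_comparison(grainy_call, gardner_call, labels)

    evaluation = {
        "graininess": rep_grainy.to_dict(),
        "gardner_ge_3BB": rep_gardner.to_dict(),
        "paired_mcnemar": {
            "both_correct": paired.both_correct,
            "only_graininess_correct": paired.only_a_correct,
            "only_gardner_correct": paired.only_b_correct,
            "both_wrong": paired.both_wrong,
            "chi2": paired.chi2, "p": paired.p},
        "auc": {"per_component": {f"pc{i}": a for i, a in per_auc.items()},
                "combined": combo_auc},
    }
    (out / "evaluation.json").write_text(json.dumps(evaluation, indent=2))

    report_text = _write_report(out, config, meta, model, screens, rule,
                                per_auc, combo_auc, rep_grainy, rep_gardner,
                                paired, grainy_call)
    manifest = {
        "package": "eigenembryo",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "numpy": np.__version__,
        "n_embryos": int(len(meta)),
        "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return PipelineResult(
        outdir=out, meta=meta, matrix=matrix, model=model, screens=screens,
        rule=rule, grainy_call=grainy_call, gardner_call=gardner_call,
        report_graininess=rep_grainy, report_gardner=rep_gardner,
        paired=paired, per_component_auc=per_auc, combined_auc=combo_auc,
        report_text=report_text)


def _write_report(out, config, meta, model, screens, rule, per_auc,
                  combo_auc, rep_grainy, rep_gardner, paired,
                  grainy_call) -> str:
    lines = ["# Eigenimage analysis report", ""]
    n_pos = int((meta["hcg"] == 1).sum())
    n_neg = int((meta["hcg"] == 0).sum())
    lines += [f"Cohort: {len(meta)} embryos "
              f"({n_pos} hCG-positive, {n_neg} hCG-negative); "
              f"seed {config.seed}.", ""]

    lines += ["## Screened components", ""]
    selected = [s for s in screens if s.selected]
    if selected:
        lines += ["| PC | contribution ratio | KS D | p | BH-adjusted p |",
                  "|---|---|---|---|---|"]
        for s in selected:
            ratio = model.contribution_ratios[s.component_index - 1]
            lines.append(
                f"| PC{s.component_index} | {100 * ratio:.2f}% | "
                f"{s.ks_D:.3f} | {s.p_value:.3f} | {s.p_adjusted:.3f} |")
    else:
        lines.append(f"No component significant at raw p < {config.alpha}; "
                     f"rule built from the top-{config.fallback_top} KS "
                     "statistics.")
    lines.append("")

    lines += ["## ROC thresholds and AUC", ""]
    for c in rule.components:
        lines.append(f"- PC{c.index}: AUC {c.auc:.2f}, cutoff {c.cutoff:.2f} "
                     f"(orientation {c.orientation:+d})")
    if len(rule.components) >= 2:
        names = " + ".join(f"PC{c.index}" for c in rule.components)
        lines.append(f"- combination of {names}: AUC {combo_auc:.2f} "
                     f"({config.combination_method})")
    lines.append("")

    lines += ["## Classification metrics (positive = hCG-positive)", "",
              "| metric | graininess | Gardner >= 3BB |", "|---|---|---|"]
    mg, mr = rep_grainy.metrics.rounded(), rep_gardner.metrics.rounded()
    for key, label in [("accuracy", "accuracy"), ("precision", "precision"),
                       ("recall", "recall"), ("specificity", "specificity"),
                       ("f_half", "F0.5"), ("f1", "F1"), ("f2", "F2")]:
        lines.append(f"| {label} | {_fmt(mg[key])} | {_fmt(mr[key])} |")
    lines.append("")

    lines += ["## Paired comparison (McNemar)", ""]
    if paired.p is None:
        lines.append("No discordant pairs; McNemar undefined.")
    else:
        lines.append(
            f"Discordant pairs: graininess-only correct = "
            f"{paired.only_a_correct}, Gardner-only correct = "
            f"{paired.only_b_correct}; chi2 = {paired.chi2:.2f}, "
            f"p = {paired.p:.3f}.")
    lines.append("")

    # fragmentation cross-tab against the *predicted* graininess call
    frag = meta["frag_pct"].to_numpy(dtype=float)
    has_frag = np.isfinite(frag)
    high = has_frag & (frag >= FRAG_NONGRAINY_THRESHOLD)
    low = has_frag & ~high
    hg = int((high & (grainy_call == 1)).sum())
    hn = int((high & (grainy_call == 0)).sum())
    lg = int((low & (grainy_call == 1)).sum())
    ln_ = int((low & (grainy_call == 0)).sum())
    lines += ["## Fragmentation vs graininess call", "",
              "| | grainy | non-grainy |", "|---|---|---|",
              f"| frag >= 20% | {hg} | {hn} |",
              f"| frag < 20% | {lg} | {ln_} |"]
    if high.any() and low.any():
        chi2, p, disp = prop_test_2x2(hn, hn + hg, ln_, ln_ + lg)
        lines.append(f"\nProp-test for equal non-grainy rates: p {disp}.")
    lines.append("")

    ab = rep_grainy.abortion
    if ab is not None:
        lines += ["## Abortion rate after prediction", "",
                  f"Predicted-grainy implantations: {ab.events_predicted}/"
                  f"{ab.n_predicted} ({ab.rate_predicted_pct()}%); all "
                  f"implantations: {ab.events_actual}/{ab.n_actual} "
                  f"({ab.rate_actual_pct()}%); prop-test p = "
                  f"{_fmt(ab.p, 2)}.", ""]

    lines += ["## Covariate screens", ""]
    age = meta["age"].to_numpy(dtype=float)
    ok = np.isfinite(age)
    if ok.sum() >= 4 and (grainy_call[ok] == 1).sum() >= 2 \
            and (grainy_call[ok] == 0).sum() >= 2:
        t, df, p = t_tests(age[ok & (grainy_call == 1)],
                           age[ok & (grainy_call == 0)], variant="student")
        lines.append(f"- age, grainy vs non-grainy: t = {t:.2f}, p = {p:.2f}")
    nongrainy = (grainy_call == 0).astype(float)
    for col, label in [("bmi", "BMI"), ("amh", "AMH"),
                       ("eval_day", "evaluation day")]:
        v = meta[col].to_numpy(dtype=float)
        ok = np.isfinite(v)
        if ok.sum() >= 3 and v[ok].std() > 0 and nongrainy[ok].std() > 0:
            r, p = correlation_screen(v[ok], nongrainy[ok])
            lines.append(f"- {label} vs non-grainy call: r = {r:.2f}, "
                         f"p = {p:.2f}")
    lines.append("")

    text = "\n".join(lines)
    (out / "report.md").write_text(text)
    return text
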