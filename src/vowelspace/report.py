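"""End-to-end pipeline and report rendering.

``run_pipeline`` chains reading → per-session metrics → change scores →
regression, writing every intermediate artifact (metrics table, change
table, model report, figures, log) to an output directory.
``render_report`` turns the artifacts into a human-readable text/HTML
report with a change-score table and a coefficient table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .io import (
    FormantToken,
    changes_to_frame,
    compute_vowel_means,
    read_formant_table,
    read_gain_table,
)
from .metrics import TOKEN_LEVEL, session_metrics
from .model import IntelligibilityModel, compute_change_scores
from .plots import (
    group_mean_shift_vectors,
    plot_shift_arrows,
    plot_vowel_ellipses,
    plot_vowel_space_overlay,
)

log = logging.getLogger("vowelspace")


@dataclass
class PipelineConfig:
    input_baseline: Path
    input_post: Path
    gains: Path
    out_dir: Path
    aavs_mode: str = TOKEN_LEVEL
    coverage: float = 0.95
    figures: bool = True
    fmt: str = "csv"  # csv | json for tabular outputs
    verbose: bool = False
    seed: Optional[int] = None


@dataclass
class PipelineArtifacts:
    metrics_path: Path
    changes_path: Path
    model_path: Path
    report_path: Path
    log_path: Path
    figure_paths: dict = field(default_factory=dict)
    excluded: list = field(default_factory=list)
    results: Optional[object] = None


def _metrics_frame(metrics) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "speaker": m.speaker,
                "session": m.session,
                "mode": m.mode,
                "aavs_hz2": m.aavs,
                "qvsa_hz2": m.qvsa,
                "vsahull_hz2": m.vsahull,
                "n_tokens": m.n_tokens,
                "warnings": "; ".join(m.notes),
            }
            for m in metrics
        ]
    )


def run_pipeline(config: PipelineConfig) -> PipelineArtifacts:
    """Execute the full analysis and write all artifacts.

    Hard errors propagate; speakers with incomplete data are excluded
    with one provenance line each in the run log.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.DEBUG if config.verbose else logging.INFO)
    try:
        return _run(config, out, log_path)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path, log_path: Path) -> PipelineArtifacts:
    base_tokens, base_report = read_formant_table(config.input_baseline)
    post_tokens, post_report = read_formant_table(config.input_post)
    for rep, name in ((base_report, "baseline"), (post_report, "post")):
        for w in rep.warnings:
            log.warning("[%s] %s: %s", name, w.code, w.message)
    log.info("read %d baseline and %d post tokens", len(base_tokens), len(post_tokens))

    def per_session(tokens: list[FormantToken]):
        grouped: dict = {}
        for t in tokens:
            grouped.setdefault((t.speaker, t.session), []).append(t)
        return [
            session_metrics(g, config.aavs_mode) for _, g in sorted(grouped.items())
        ]

    metrics = per_session(base_tokens) + per_session(post_tokens)
    for m in metrics:
        for note in m.notes:
            log.warning("metrics %s/%s: %s", m.speaker, m.session, note)
    metrics_df = _metrics_frame(metrics)
    metrics_path = out / f"metrics.{config.fmt}"
    _write_table(metrics_df, metrics_path, config.fmt)

    gains = read_gain_table(config.gains)
    baseline_metrics = [m for m in metrics if m.session == "baseline"]
    post_metrics = [m for m in metrics if m.session == "post"]
    records, excluded = compute_change_scores(baseline_metrics, post_metrics, gains)
    for line in excluded:
        log.warning("excluded %s", line)
    changes_df = changes_to_frame(records)
    changes_path = out / f"changes.{config.fmt}"
    _write_table(changes_df, changes_path, config.fmt)

    results = IntelligibilityModel.from_change_records(records).fit()
    model_path = out / "model.json"
    model_payload = results.to_dict()
    try:
        model_payload["diagnostics"] = results.diagnostics().to_dict()
    except Exception as exc:
        log.warning("residual diagnostics unavailable: %s", exc)
        model_payload["diagnostics"] = None
    model_path.write_text(json.dumps(model_payload, indent=2))
    log.info("model fitted on %d speakers (%d excluded)", results.nobs, len(excluded))

    figure_paths: dict = {}
    if config.figures:
        figure_paths = _make_figures(base_tokens, post_tokens, config, out)

    report_path = out / "report.html"
    report_path.write_text(
        render_report(model_payload, changes_df, figure_paths, seed=config.seed)
    )
    return PipelineArtifacts(
        metrics_path=metrics_path,
        changes_path=changes_path,
        model_path=model_path,
        report_path=report_path,
        log_path=log_path,
        figure_paths=figure_paths,
        excluded=excluded,
        results=results,
    )


def _make_figures(base_tokens, post_tokens, config: PipelineConfig, out: Path) -> dict:
    figure_paths = {}
    try:
        base_means, vectors = group_mean_shift_vectors(base_tokens, post_tokens)
        overlay = out / "vowel_space.svg"
        plot_vowel_space_overlay(
            {"baseline": base_means}, overlay
        )
        figure_paths["overlay"] = overlay
        arrows = out / "shift_arrows.svg"
        plot_shift_arrows(base_means, vectors, arrows)
        figure_paths["arrows"] = arrows
    except Exception as exc:  # other figures still produced
        log.error("overlay/arrow figures failed: %s", exc)
    try:
        ellipses = out / "vowel_ellipses.svg"
        plot_vowel_ellipses(base_tokens + post_tokens, ellipses, config.coverage)
        figure_paths["ellipses"] = ellipses
    except Exception as exc:
        log.error("ellipse figure failed: %s", exc)
    return figure_paths


def _write_table(df: pd.DataFrame, path: Path, fmt: str) -> None:
    if fmt == "json":
        path.write_text(df.to_json(orient="records", indent=2))
    else:
        df.to_csv(path, index=False)


def render_report(
    model_payload: dict,
    changes: pd.DataFrame,
    figure_paths: Optional[dict] = None,
    seed: Optional[int] = None,
) -> str:
    """Render an HTML report: change-score table, coefficient table,
    diagnostics, optional figures; stamped with version and seed."""
    ts = datetime.now(timezone.utc).isoformat(timespec="seconds")
    parts = [
        "<html><head><meta charset='utf-8'><title>Vowel-space analysis</title></head><body>",
        "<h1>Vowel-space change and intelligibility gain</h1>",
        f"<p>vowelspace {__version__} | seed: {seed if seed is not None else 'n/a'} "
        f"| <span class='timestamp'>{ts}</span></p>",
        "<h2>Per-speaker change scores</h2>",
        changes.to_html(index=False, float_format=lambda v: f"{v:.2f}"),
        "<h2>Regression: gain ~ dAAVS + dqVSA + dVSAhull</h2>",
        _coef_table_html(model_payload),
        "<p>n = {n}, residual df = {df_resid}, R² = {r_squared:.4f}</p>".format(**model_payload),
        "<h3>VIF</h3>",
        "<ul>"
        + "".join(f"<li>{k}: {v:.3f}</li>" for k, v in model_payload["vif"].items())
        + "</ul>",
    ]
    diag = model_payload.get("diagnostics")
    if diag:
        parts += [
            "<h3>Residual diagnostics</h3>",
            "<ul>"
            f"<li>Shapiro–Wilk: W = {diag['shapiro_stat']:.4f}, p = {diag['shapiro_p']:.4f}</li>"
            f"<li>Breusch–Pagan: LM = {diag['breusch_pagan_stat']:.4f}, "
            f"p = {diag['breusch_pagan_p']:.4f}</li>"
            f"<li>|residual| on fitted slope: {diag['abs_resid_on_fitted_slope']:.4f}</li>"
            "</ul>",
        ]
    if figure_paths:
        parts.append("<h2>Figures</h2>")
        for name, path in sorted(figure_paths.items()):
            parts.append(f"<h3>{name}</h3><img src='{Path(path).name}' alt='{name}'/>")
    parts.append("</body></html>")
    return "\n".join(parts)


def _coef_table_html(payload: dict) -> str:
    rows = "".join(
        "<tr><td>{name}</td><td>{estimate:.5f}</td><td>{std_error:.6f}</td>"
        "<td>{t_value:.3f}</td><td>{p_value:.4f}</td></tr>".format(**t)
        for t in payload["terms"]
    )
    return (
        "<table border='1'><tr><th>Predictor</th><th>Estimate</th>"
        "<th>Std_Error</th><th>t_value</th><th>p_value</th></tr>" + rows + "</table>"
    )
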