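"""Vowel-space figures: group overlay, shift arrows, per-vowel ellipses.

All figures use the traditional vowel-chart orientation — F2 on x and
F1 on y, both axes inverted, so high vowels sit at the top and front
vowels at the right. Figures are deterministic (fixed ordering, no
jitter) and each writer also emits the plotted coordinates as a plain
CSV table next to the image, so figure content can be tested without
image comparison.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.patches import Ellipse

from .io import FormantToken, VowelMeans, compute_vowel_means
from .metrics import ShiftVector, confidence_ellipse, tokens_to_xy
from .vowels import ALL_VOWELS


def _vowel_axes(ax) -> None:
    ax.set_xlabel("F2 (Hz)")
    ax.set_ylabel("F1 (Hz)")
    if not ax.xaxis_inverted():
        ax.invert_xaxis()
    if not ax.yaxis_inverted():
        ax.invert_yaxis()


def plot_vowel_space_overlay(
    groups: Mapping[str, Sequence[VowelMeans]], path: str | Path
) -> pd.DataFrame:
    """Overlay per-vowel mean positions for one or more groups/sessions.

    Returns (and writes alongside the figure) the table of plotted
    points: group, vowel, f2, f1.
    """
    fig, ax = plt.subplots(figsize=(7, 6))
    rows = []
    for gi, (label, means) in enumerate(sorted(groups.items())):
        by_vowel = {m.vowel: m for m in means}
        pts = [(v, by_vowel[v]) for v in ALL_VOWELS if v in by_vowel]
        xs = [m.f2_mean for _, m in pts]
        ys = [m.f1_mean for _, m in pts]
        ax.scatter(xs, ys, label=label, marker="os^v"[gi % 4])
        for v, m in pts:
            ax.annotate(v.ipa, (m.f2_mean, m.f1_mean), textcoords="offset points", xytext=(4, 4))
            rows.append({"group": label, "vowel": v.value, "f2": m.f2_mean, "f1": m.f1_mean})
    _vowel_axes(ax)
    ax.legend()
    ax.set_title("Vowel space (per-vowel mean formants)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    data = pd.DataFrame(rows)
    data.to_csv(Path(path).with_suffix(".csv"), index=False)
    return data


def plot_shift_arrows(
    baseline: Sequence[VowelMeans],
    vectors: Sequence[ShiftVector],
    path: str | Path,
) -> pd.DataFrame:
    """Arrows from baseline vowel means (tail) to post means (head)."""
    base = {m.vowel: m for m in baseline}
    fig, ax = plt.subplots(figsize=(7, 6))
    rows = []
    for vec in sorted(vectors, key=lambda v: v.vowel.value):
        m = base[vec.vowel]
        ax.annotate(
            "",
            xy=(m.f2_mean + vec.d_f2, m.f1_mean + vec.d_f1),
            xytext=(m.f2_mean, m.f1_mean),
            arrowprops={"arrowstyle": "->", "color": "tab:blue"},
        )
        ax.annotate(vec.vowel.ipa, (m.f2_mean, m.f1_mean), textcoords="offset points", xytext=(4, 4))
        rows.append(
            {
                "vowel": vec.vowel.value,
                "f2_tail": m.f2_mean,
                "f1_tail": m.f1_mean,
                "d_f2": vec.d_f2,
                "d_f1": vec.d_f1,
            }
        )
    data = pd.DataFrame(rows)
    if len(data):
        xs = np.concatenate([data["f2_tail"], data["f2_tail"] + data["d_f2"]])
        ys = np.concatenate([data["f1_tail"], data["f1_tail"] + data["d_f1"]])
        pad_x = 0.05 * (xs.max() - xs.min() + 1)
        pad_y = 0.05 * (ys.max() - ys.min() + 1)
        ax.set_xlim(xs.max() + pad_x, xs.min() - pad_x)
        ax.set_ylim(ys.max() + pad_y, ys.min() - pad_y)
    ax.set_xlabel("F2 (Hz)")
    ax.set_ylabel("F1 (Hz)")
    ax.set_title("Per-vowel formant shift, baseline → post")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    data.to_csv(Path(path).with_suffix(".csv"), index=False)
    return data


def plot_vowel_ellipses(
    tokens: Sequence[FormantToken],
    path: str | Path,
    coverage: float = 0.95,
) -> pd.DataFrame:
    """Per-vowel token scatter by session with coverage ellipses.

    One panel per vowel; sessions distinguished by colour. Vowels with
    fewer than 3 tokens in a session get points but no ellipse. Returns
    the ellipse parameter table.
    """
    by_vowel: dict = {}
    for t in tokens:
        by_vowel.setdefault(t.vowel, {}).setdefault(t.session, []).append(t)
    vowels = [v for v in ALL_VOWELS if v in by_vowel]
    ncols = 5
    nrows = int(np.ceil(len(vowels) / ncols)) or 1
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 3 * nrows), squeeze=False)
    rows = []
    colors = {"baseline": "tab:blue", "post": "tab:orange"}
    for idx, vowel in enumerate(vowels):
        ax = axes[idx // ncols][idx % ncols]
        for session in sorted(by_vowel[vowel]):
            toks = by_vowel[vowel][session]
            xy = tokens_to_xy(toks)
            color = colors.get(session, "tab:gray")
            ax.scatter(xy[:, 0], xy[:, 1], s=12, color=color, label=session)
            if len(xy) >= 3:
                try:
                    ell = confidence_ellipse(xy, coverage)
                except Exception:
                    continue
                ax.add_patch(
                    Ellipse(
                        ell.center,
                        2 * ell.semi_major,
                        2 * ell.semi_minor,
                        angle=np.degrees(ell.angle),
                        fill=False,
                        color=color,
                    )
                )
                rows.append(
                    {
                        "vowel": vowel.value,
                        "session": session,
                        "center_f2": ell.center[0],
                        "center_f1": ell.center[1],
                        "semi_major": ell.semi_major,
                        "semi_minor": ell.semi_minor,
                        "angle_rad": ell.angle,
                        "coverage": ell.coverage,
                    }
                )
        _vowel_axes(ax)
        ax.set_title(f"/{vowel.ipa}/")
    for idx in range(len(vowels), nrows * ncols):
        axes[idx // ncols][idx % ncols].axis("off")
    handles, labels = axes[0][0].get_legend_handles_labels()
    if handles:
        fig.legend(handles, labels, loc="lower right")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    data = pd.DataFrame(rows)
    data.to_csv(Path(path).with_suffix(".csv"), index=False)
    return data


def group_mean_shift_vectors(
    baseline_tokens: Sequence[FormantToken], post_tokens: Sequence[FormantToken]
) -> tuple[list[VowelMeans], list[ShiftVector]]:
    """Group-average vowel means and shift vectors, pooling speakers."""
    from .metrics import shift_vectors

    def pooled(tokens):
        relabelled = [
            FormantToken("group", t.session, t.vowel, i, t.f1, t.f2)
            for i, t in enumerate(tokens)
        ]
        return compute_vowel_means(relabelled)

    base = pooled(baseline_tokens)
    post = pooled(post_tokens)
    return base, shift_vectors(base, post)
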