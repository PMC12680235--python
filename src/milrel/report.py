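"""Cross-dataset aggregation, metric-exclusion ranking, model-comparison
statistics and heatmap rendering.

The overall benchmark view averages each model family's per-dataset mean
metrics with equal dataset weight (half-up rounding to the printed
precision), and the reliability ranking sums the selected reliability
metrics across datasets with equal weight; excluding one metric from the
sum probes how much that metric contributes to separating the models.

A transcription of reference benchmark results for the three public
datasets (CAMELYON16, CATCH, TCGA BRCA) ships with the package as
``data/published_means.csv`` so the aggregation arithmetic is exercised
without any training run.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .bagcore import AnnotationSet, InstanceBag, PatchScoreSet

__all__ = [
    "load_published_means",
    "overall_mean",
    "rank_models",
    "rm_anova",
    "render_heatmap",
    "RELIABILITY_METRICS",
]

RELIABILITY_METRICS = ("mi", "spearman", "auprc")
_METRIC_COLS = ("mi", "spearman", "auprc", "auc", "f1")
_COUNT_COLS = ("flops_m", "size_k")


def load_published_means() -> pd.DataFrame:
    """The bundled reference per-dataset mean table (one row per model per
    dataset; `family` collapses head-count variants, e.g. ACMIL/2-4-3)."""
    with resources.files("milrel").joinpath("data/published_means.csv").open() as fh:
        return pd.read_csv(fh)


def round_half_up(x, decimals: int = 2):
    factor = 10.0 ** decimals
    return np.floor(np.asarray(x, dtype=float) * factor + 0.5) / factor


def overall_mean(table: pd.DataFrame, round_output: bool = True) -> pd.DataFrame:
    """Unweighted mean of per-dataset means, one row per model family.

    Metric cells are rounded half-up to 2 decimals and count columns to
    the nearest unit when ``round_output`` is set. A metric missing in
    some datasets is averaged over those available and flagged in the
    ``partial`` column.
    """
    if table.empty:
        raise ValueError("empty benchmark table")
    group_col = "family" if "family" in table.columns else "model"
    rows = []
    for family, grp in table.groupby(group_col, sort=False):
        row: dict = {"model": family, "n_datasets": len(grp)}
        partial = False
        for col in _METRIC_COLS + _COUNT_COLS:
            if col not in grp.columns:
                continue
            vals = grp[col].dropna()
            if len(vals) == 0:
                row[col] = np.nan
                continue
            partial = partial or (len(vals) < len(grp))
            m = vals.mean()
            if round_output:
                m = (float(round_half_up(m, 2)) if col in _METRIC_COLS
                     else int(round_half_up(m, 0)))
            row[col] = m
        row["partial"] = partial
        rows.append(row)
    return pd.DataFrame(rows)


def rank_models(
    table: pd.DataFrame,
    metrics: tuple[str, ...] = RELIABILITY_METRICS,
    exclude: str | None = None,
) -> list[tuple[float, list[str]]]:
    """Reliability ranking by equal-weight metric sums across datasets.

    ``score(model) = sum over included metrics of the per-dataset mean
    values``; models are ordered by descending score and grouped into ties
    when their scores agree after rounding to 2 decimals. Models missing
    any included metric (e.g. mean pooling, which emits no patch scores)
    are dropped. Returns ``[(rounded_score, [model, ...]), ...]``.
    """
    metrics = tuple(m for m in metrics if m != exclude)
    if not metrics:
        raise ValueError("no metrics left to rank on")
    group_col = "family" if "family" in table.columns else "model"
    scores = {}
    for family, grp in table.groupby(group_col, sort=False):
        vals = grp[list(metrics)]
        if vals.isna().any().any():
            continue
        scores[family] = float(vals.to_numpy().sum())
    order = sorted(scores, key=lambda m: -scores[m])
    groups: list[tuple[float, list[str]]] = []
    for m in order:
        r = float(round_half_up(scores[m], 2))
        if groups and groups[-1][0] == r:
            groups[-1][1].append(m)
        else:
            groups.append((r, [m]))
    return groups


def rm_anova(matrix: np.ndarray) -> tuple[float, tuple[int, int], float]:
    """One-way repeated-measures ANOVA on a (models x subjects) matrix.

    Models are the within factor and columns (e.g. datasets) the
    subjects. Returns ``(F, (df_model, df_error), p)``; a matrix with zero
    error sum of squares (e.g. constant) raises, as F is undefined.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a (>=2 models) x (>=2 subjects) matrix")
    if np.isnan(m).any():
        raise ValueError("matrix contains missing cells")
    k, n = m.shape
    grand = m.mean()
    ss_model = n * ((m.mean(axis=1) - grand) ** 2).sum()
    ss_subject = k * ((m.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((m - grand) ** 2).sum()
    ss_error = ss_total - ss_model - ss_subject
    df_model, df_error = k - 1, (k - 1) * (n - 1)
    ms_error = ss_error / df_error
    tol = 1e-12 * max(1.0, abs(ss_total))
    if ms_error <= tol:
        # rows identical but subjects vary: no model effect, F = 0
        if ss_model <= tol and ss_subject > tol:
            return 0.0, (df_model, df_error), 1.0
        raise ValueError("zero error sum of squares: F undefined")
    F = (ss_model / df_model) / ms_error
    p = float(f_dist.sf(F, df_model, df_error))
    return float(F), (df_model, df_error), p


def render_heatmap(
    bag: InstanceBag,
    score_set: PatchScoreSet,
    annotation: AnnotationSet | None = None,
    path: str | Path | None = None,
):
    """Patch-score heatmap on the slide grid, low (blue) to high (red),
    with annotation polygons overlaid in green. Returns the figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if len(score_set.scores) != bag.n_instances:
        raise ValueError("score set does not align with the bag")
    cells = bag.coords // bag.patch_size
    w, h = cells[:, 0].max() + 1, cells[:, 1].max() + 1
    raster = np.full((h, w), np.nan)
    raster[cells[:, 1], cells[:, 0]] = score_set.scores

    fig, ax = plt.subplots(figsize=(6, 6))
    extent = (0, w * bag.patch_size, h * bag.patch_size, 0)
    im = ax.imshow(raster, cmap="coolwarm", extent=extent, interpolation="nearest")
    if annotation is not None:
        for _, poly in annotation.regions:
            xs, ys = poly.exterior.xy
            ax.plot(xs, ys, color="green", linewidth=2)
    ax.set_title(f"{bag.slide_id} — {score_set.channel.value}")
    fig.colorbar(im, ax=ax, shrink=0.8)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
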