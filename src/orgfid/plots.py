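"""Visual outputs: probability-density curves, violins, bin heatmaps,
marker-correlation scatters.

Every plot writes its underlying data table (CSV) next to the figure, so
no scientific claim depends on the smoother or renderer.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns
from scipy.stats import gaussian_kde

from .binning import BinDistribution, BinScheme, LogRatioRecord, records_to_frame


def _save(fig: plt.Figure, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)


def density_plot(
    records: Iterable[LogRatioRecord],
    out: str | Path,
    scheme: BinScheme | None = None,
    group_by: str = "condition",
) -> Path:
    """Per-group Gaussian-KDE densities of log2(K8/K14), Scott bandwidth.

    Quartile boundaries are drawn as vertical lines when a scheme is
    given.  A histogram table (50 shared bins) is written alongside.
    """
    out = Path(out)
    frame = records_to_frame(list(records))
    fig, ax = plt.subplots(figsize=(6, 4))
    lo, hi = frame.log2_ratio.min(), frame.log2_ratio.max()
    grid = np.linspace(lo - 1, hi + 1, 400)
    edges = np.linspace(lo, hi, 51)
    hist_rows = []
    for label, sub in frame.groupby(group_by, sort=True):
        vals = sub.log2_ratio.to_numpy()
        if len(vals) > 1 and np.ptp(vals) > 0:
            ax.plot(grid, gaussian_kde(vals, bw_method="scott")(grid), label=str(label))
        counts, _ = np.histogram(vals, bins=edges)
        for e, c in zip(edges[:-1], counts):
            hist_rows.append({group_by: label, "bin_left": e, "count": int(c)})
    if scheme is not None:
        for b in scheme.boundaries:
            ax.axvline(b, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("log2(K8/K14)")
    ax.set_ylabel("probability density")
    ax.legend(fontsize=8)
    _save(fig, out)
    pd.DataFrame(hist_rows).to_csv(out.with_suffix(".hist.csv"), index=False)
    return out


def violin_plot(
    records: Iterable[LogRatioRecord],
    out: str | Path,
    group_by: str = "patient_id",
) -> Path:
    """Per-sample violins of the log2(K8/K14) ratio."""
    out = Path(out)
    frame = records_to_frame(list(records))
    fig, ax = plt.subplots(figsize=(max(6, frame[group_by].nunique() * 0.6), 4))
    order = sorted(frame[group_by].unique())
    sns.violinplot(
        data=frame, x=group_by, y="log2_ratio", order=order, ax=ax,
        density_norm="width", inner="quartile", cut=0,
    )
    ax.tick_params(axis="x", rotation=90, labelsize=7)
    ax.set_ylabel("log2(K8/K14)")
    _save(fig, out)
    frame.to_csv(out.with_suffix(".data.csv"), index=False)
    return out


def bin_heatmap(
    dists: Mapping[str, BinDistribution] | Sequence[BinDistribution],
    out: str | Path,
) -> Path:
    """Heatmap of bin percentages: rows = conditions, columns = bins 1-4."""
    out = Path(out)
    if isinstance(dists, Mapping):
        dists = [dists[k] for k in sorted(dists)]
    table = pd.DataFrame(
        {d.condition_label: [p * 100 for p in d.probs] for d in dists},
        index=[f"bin{i}" for i in range(1, 5)],
    ).T
    fig, ax = plt.subplots(figsize=(4, max(2, 0.4 * len(table))))
    sns.heatmap(table, annot=True, fmt=".1f", cmap="viridis",
                vmin=0, vmax=100, cbar_kws={"label": "% of sections"}, ax=ax)
    _save(fig, out)
    table.to_csv(out.with_suffix(".data.csv"))
    return out


def correlation_scatter(
    pairs: Sequence[tuple[float, float]],
    marker_x: str,
    marker_y: str,
    out: str | Path,
) -> Path:
    """Scatter of paired marker measurements with a least-squares line."""
    out = Path(out)
    arr = np.asarray(pairs, dtype=float)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(arr[:, 0], arr[:, 1], s=12, alpha=0.6)
    slope, intercept = np.polyfit(arr[:, 0], arr[:, 1], 1)
    xs = np.array([arr[:, 0].min(), arr[:, 0].max()])
    ax.plot(xs, slope * xs + intercept, color="crimson", lw=1)
    ax.set_xlabel(marker_x)
    ax.set_ylabel(marker_y)
    _save(fig, out)
    pd.DataFrame(arr, columns=[marker_x, marker_y]).to_csv(
        out.with_suffix(".data.csv"), index=False
    )
    return out
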