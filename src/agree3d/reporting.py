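"""Run configuration, provenance and report output (CSVs are the
contract; figures are conveniences)."""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, asdict
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .errors import ValidationError  # noqa: E402
from .metrics import AGS_VS_MANUAL, MANUAL_VS_MANUAL, METRIC_LABELS  # noqa: E402
from .pipeline import METRIC_COLUMNS  # noqa: E402

__all__ = ["RunConfig", "write_report", "provenance"]


@dataclass
class RunConfig:
    spacing: float = 1.0
    coverage: float = 0.95
    alpha: float = 0.05
    bonferroni_factor: int = 3
    symmetrize: bool = False
    seed: int = 0

    def validate(self):
        if self.spacing <= 0:
            raise ValidationError("spacing must be > 0")
        if not (0.0 < self.coverage <= 1.0):
            raise ValidationError("coverage must be in (0, 1]")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must be in (0, 1)")
        return self

    def to_dict(self):
        return asdict(self)


def provenance(config: RunConfig | None = None, extra: dict | None = None) -> dict:
    from importlib.metadata import version as _pkg_version

    import matplotlib as mpl
    import scipy

    from . import __version__

    info = {
        "package": {"agree3d": __version__},
        "libraries": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "matplotlib": mpl.__version__,
            "click": _pkg_version("click"),
        },
        "python": platform.python_version(),
        "conventions": {
            "centroid": "volume centroid",
            "mssd": "directed vertex-to-nearest-vertex mean",
            "um_quantile": "nearest-rank (ceil) over target voxels",
            "iqr": "Q3 - Q1, linear-interpolation quantiles, single width",
            "rating_rounding": "round-half-up of two-session mean",
            "pooling": "all pairwise records pooled within a group",
            "heatmap_display_clamp_mm": 10.0,
        },
    }
    if config is not None:
        info["config"] = config.to_dict()
    if extra:
        info.update(extra)
    return info


def write_report(summaries: pd.DataFrame, out_dir, *,
                 stats: pd.DataFrame | None = None,
                 ledger=None, records: pd.DataFrame | None = None,
                 config: RunConfig | None = None) -> Path:
    """Write summary/stats CSVs, the failure ledger, provenance, and one
    boxplot per metric grouped by rating (shaded manual vs white ags)."""
    if summaries is None or summaries.empty:
        raise ValidationError("nothing to report: empty summaries")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_summary_table(summaries, out / "summary.csv")
    if stats is not None:
        stats.to_csv(out / "stats.csv", index=False)
    if ledger is not None:
        (out / "failure_ledger.json").write_text(
            json.dumps(ledger.to_dict(), indent=1, sort_keys=True) + "\n"
        )
    (out / "provenance.json").write_text(
        json.dumps(provenance(config), indent=1, sort_keys=True) + "\n"
    )
    if records is not None and not records.empty:
        for metric in METRIC_COLUMNS:
            _boxplot(records, metric, out / f"boxplot_{metric}.png")
    return out


def _write_summary_table(summaries: pd.DataFrame, path: Path) -> None:
    """Wide table: one row per metric x group, one 'median [IQR]' cell
    per comparison kind; kinds with no data get an explicit marker."""
    rows = []
    groups = ["All Images", "Rating 1", "Rating 2", "Rating 3"]
    for metric in METRIC_COLUMNS:
        for group in groups:
            row = {"metric": metric, "group": group}
            for kind, col in ((MANUAL_VS_MANUAL, "interobserver_manual"),
                              (AGS_VS_MANUAL, "ags_accuracy")):
                sel = summaries[
                    (summaries["metric"] == metric)
                    & (summaries["group"] == group)
                    & (summaries["kind"] == kind)
                ]
                if sel.empty:
                    row[col] = "no data"
                    row[f"{col}_n"] = 0
                else:
                    r = sel.iloc[0]
                    row[col] = f"{r['median']:.2f} [{r['iqr_width']:.2f}]"
                    row[f"{col}_n"] = int(r["n_pairs"])
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _boxplot(records: pd.DataFrame, metric: str, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 4))
    positions, data, colors, labels = [], [], [], []
    pos = 1.0
    for group, sel_fn in [("All", lambda d: d)] + [
        (f"R{r}", lambda d, r=r: d[d["rating"] == r]) for r in (1, 2, 3)
    ]:
        sub = sel_fn(records)
        for kind, color in ((MANUAL_VS_MANUAL, "0.7"), (AGS_VS_MANUAL, "white")):
            vals = sub.loc[sub["kind"] == kind, metric].to_numpy()
            if len(vals):
                positions.append(pos)
                data.append(vals)
                colors.append(color)
                labels.append(f"{group}\n{'man' if color != 'white' else 'ags'}")
            pos += 1.0
        pos += 0.6
    if data:
        bp = ax.boxplot(data, positions=positions, patch_artist=True, widths=0.8)
        for patch, color in zip(bp["boxes"], colors):
            patch.set_facecolor(color)
        ax.set_xticks(positions)
        ax.set_xticklabels(labels, fontsize=7)
    ax.set_ylabel(METRIC_LABELS.get(metric, metric))
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
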