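"""Test-set metrics: pointwise MAE by disease stage, sectoral averages,
MD error, TD-binned error profiles, and grid-search trade-off summaries.

Conventions: a test's pointwise MAE is the mean over its 52 absolute TD
errors; group statistics are the mean +/- standard error of those per-test
MAEs over the tests in the group (so n is the test count, not the point
count).  Sectoral metrics first average TD within each sector per test,
then score the sector means across tests (MAE +/- SE and R^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import r2_score

from .vf_geometry import VFGrid, build_grid, interval_of, stage_of

__all__ = [
    "EvalReport",
    "pointwise_mae",
    "sectoral_metrics",
    "md_metrics",
    "td_binned_error",
    "interval_mae",
    "tradeoff_report",
    "plot_td_binned_error",
    "plot_tradeoff",
    "evaluate",
]

STAGES = ("early_or_none", "moderate", "advanced")


def _mean_se(values: np.ndarray) -> Tuple[float, float]:
    values = np.asarray(values, float)
    n = values.size
    if n == 0:
        return float("nan"), float("nan")
    se = float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return float(values.mean()), se


def pointwise_mae(y_true: np.ndarray, y_hat: np.ndarray,
                  md_true: np.ndarray) -> pd.DataFrame:
    """Overall and per-stage pointwise MAE with standard errors.

    Stages come from the *true* MD of each test.  Empty groups report NaN
    (undefined), never zero.
    """
    y_true = np.asarray(y_true, float)
    y_hat = np.asarray(y_hat, float)
    if y_true.shape != y_hat.shape:
        raise ValueError(f"shape mismatch: {y_true.shape} vs {y_hat.shape}")
    per_test = np.abs(y_true - y_hat).mean(axis=1)
    stages = np.array([stage_of(m) for m in np.asarray(md_true, float)])
    rows = []
    for name in ("overall",) + STAGES:
        sel = slice(None) if name == "overall" else stages == name
        vals = per_test[sel]
        m, se = _mean_se(vals)
        rows.append({"group": name, "mae": m, "se": se, "n": int(np.size(vals))})
    return pd.DataFrame(rows).set_index("group")


def sectoral_metrics(y_true: np.ndarray, y_hat: np.ndarray,
                     grid: Optional[VFGrid] = None) -> pd.DataFrame:
    """Per-sector MAE (+/- SE) and R^2 of the sectoral mean deviations.

    The sectoral mean is the within-sector average TD of a test; both are
    computed on total deviation (not pattern deviation) and scored across
    tests.
    """
    grid = grid if grid is not None else build_grid()
    y_true = np.asarray(y_true, float)
    y_hat = np.asarray(y_hat, float)
    rows = []
    for sector, idx in grid.sector_indices().items():
        if idx.size == 0:
            raise ValueError(f"sector {sector!r} has no member locations")
        t = y_true[:, idx].mean(axis=1)
        h = y_hat[:, idx].mean(axis=1)
        m, se = _mean_se(np.abs(t - h))
        r2 = float(r2_score(t, h)) if t.size > 1 else float("nan")
        rows.append({"sector": sector, "mae": m, "se": se, "r2": r2, "n": t.size})
    return pd.DataFrame(rows).set_index("sector")


def md_metrics(z_true: np.ndarray, z_hat: np.ndarray) -> Dict[str, float]:
    """MAE +/- SE of the MD estimate."""
    err = np.abs(np.asarray(z_true, float) - np.asarray(z_hat, float))
    m, se = _mean_se(err)
    return {"mae": m, "se": se, "n": int(err.size)}


def td_binned_error(y_true: np.ndarray, y_hat: np.ndarray,
                    bin_width: float = 1.0,
                    lo: float = -38.0, hi: float = 6.0) -> pd.DataFrame:
    """Mean absolute error binned by true TD over all (test, location) pairs.

    Also carries each bin's pair count and the pooled overall mean absolute
    error (constant column), for dotted-reference-line style plots.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    t = np.asarray(y_true, float).ravel()
    e = np.abs(t - np.asarray(y_hat, float).ravel())
    edges = np.arange(lo, hi + bin_width, bin_width)
    which = np.clip(np.digitize(t, edges) - 1, 0, len(edges) - 2)
    rows = []
    overall = float(e.mean()) if e.size else float("nan")
    for b in range(len(edges) - 1):
        sel = which == b
        rows.append({
            "bin_lo": edges[b], "bin_hi": edges[b + 1],
            "mae": float(e[sel].mean()) if sel.any() else float("nan"),
            "count": int(sel.sum()), "overall_mae": overall,
        })
    return pd.DataFrame(rows)


def interval_mae(model, dataset) -> Dict[str, float]:
    """Per-MD-interval and overall pointwise MAE of a model on a dataset."""
    pred = model.predict(dataset.rnfl)
    per_test = np.abs(dataset.td - pred).mean(axis=1)
    ids = np.array([interval_of(m) for m in dataset.md])
    out = {"val_mae": float(per_test.mean())}
    for k in (1, 2, 3, 4):
        sel = ids == k
        out[f"mae_interval_{k}"] = float(per_test[sel].mean()) if sel.any() else float("nan")
    return out


def tradeoff_report(grid_results: pd.DataFrame) -> pd.DataFrame:
    """Tidy per-stage/interval MAE across grid cells for trade-off plots.

    Keeps the (alpha, beta, gamma) of each cell, flags the basic
    (alpha=0, beta=0) cell, and orders rows by advanced-group (interval 4)
    MAE.  Missing metric columns are flagged with NaN rather than dropped.
    """
    expected = ["alpha", "beta", "gamma"]
    for c in expected:
        if c not in grid_results.columns:
            raise ValueError(f"grid results lack column {c!r}")
    out = grid_results.copy()
    if "basic" not in out.columns:
        out["basic"] = (out["alpha"] == 0.0) & (out["beta"] == 0.0)
    sort_col = "mae_interval_4" if "mae_interval_4" in out.columns else "val_mae"
    return out.sort_values(sort_col, kind="mergesort").reset_index(drop=True)


@dataclass
class EvalReport:
    """Full evaluation of one model on one dataset split."""

    pointwise: pd.DataFrame
    sectoral: pd.DataFrame
    md: Dict[str, float]
    td_bins: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "pointwise": self.pointwise.reset_index().to_dict(orient="records"),
            "sectoral": self.sectoral.reset_index().to_dict(orient="records"),
            "md": self.md,
            "td_bins": self.td_bins.to_dict(orient="records"),
        }


def plot_td_binned_error(table: pd.DataFrame, ax=None):
    """Bar plot of the TD-binned error curve with the overall-MAE reference."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    busy = table[table["count"] > 0]
    centers = (busy["bin_lo"] + busy["bin_hi"]) / 2
    ax.bar(centers, busy["mae"], width=(busy["bin_hi"] - busy["bin_lo"]).iloc[0] * 0.9)
    ax.axhline(busy["overall_mae"].iloc[0], ls=":", color="k", label="overall MAE")
    ax.set_xlabel("true TD (dB)")
    ax.set_ylabel("mean |error| (dB)")
    ax.legend()
    return ax


def plot_tradeoff(report: pd.DataFrame, x: str = "mae_interval_1",
                  y: str = "mae_interval_4", ax=None):
    """Scatter of per-cell MAE trade-offs, highlighting the basic cell."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    basic = report[report["basic"]]
    rest = report[~report["basic"]]
    ax.scatter(rest[x], rest[y], c=rest["alpha"], cmap="viridis", label="(alpha, beta) cells")
    if len(basic):
        ax.scatter(basic[x], basic[y], marker="*", s=160, color="red", label="basic (0, 0)")
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    ax.legend()
    return ax


def evaluate(model, dataset, grid: Optional[VFGrid] = None,
             mask: Optional[np.ndarray] = None,
             bin_width: float = 1.0) -> EvalReport:
    """Run the full metric suite for a model on a dataset."""
    grid = grid if grid is not None else build_grid()
    pred = model.predict(dataset.rnfl)
    z_hat = model.predict_md(dataset.rnfl, mask=mask)
    return EvalReport(
        pointwise=pointwise_mae(dataset.td, pred, dataset.md),
        sectoral=sectoral_metrics(dataset.td, pred, grid),
        md=md_metrics(dataset.md, z_hat),
        td_bins=td_binned_error(dataset.td, pred, bin_width=bin_width),
    )
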