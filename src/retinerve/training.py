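"""Training protocol: weighted mini-batch optimization, early stopping,
multi-run selection, and the (alpha, beta, gamma) grid search.

The objective is the weighted multi-task loss of :mod:`retinerve.losses`;
per-record weights lambda_i are computed once on the training split (from
label MD) and per-location weights rho_j once per gamma.  Each mini-batch
contributes the *sum* of its records' weighted losses, so the expected
stochastic gradient matches the full-data objective up to a constant.
Validation loss (same objective, lambda recomputed from validation interval
counts) drives both early stopping and the selection of the best of the
independent runs.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .architectures import build_model, RetiNerveNetSpec
from .losses import LossConfig, location_weights, sample_weights
from .nn import Adam, Tensor
from .vf_geometry import VFGrid, build_grid

__all__ = ["TrainConfig", "TrainResult", "train", "grid_search", "GridSpec"]

#: The printed hyperparameter grids of the loss sweep.
ALPHA_BETA_GRID: Tuple[float, ...] = (0.01, 0.25, 0.5, 0.75, 0.99)
GAMMA_GRID: Tuple[float, ...] = (0.5, 5.0, 50.0)


@dataclass
class TrainConfig:
    """Optimization settings.

    The run protocol is seed-controlled end to end: each of ``n_runs``
    independent runs draws its initialization and batch order from one seed,
    and the run with the lowest best validation loss is returned.
    """

    max_epochs: int = 2000
    lr: float = 1e-3
    batch_size: int = 256
    patience: int = 50
    n_runs: int = 5
    seeds: Optional[Sequence[int]] = None
    loss: LossConfig = field(default_factory=LossConfig)
    spec: Optional[RetiNerveNetSpec] = None

    def __post_init__(self):
        if self.max_epochs < 1 or self.n_runs < 1:
            raise ValueError("max_epochs and n_runs must be >= 1")
        if self.seeds is not None and len(self.seeds) != self.n_runs:
            raise ValueError("need one seed per run")

    def run_seeds(self) -> List[int]:
        return list(self.seeds) if self.seeds is not None else list(range(self.n_runs))


@dataclass
class TrainResult:
    """Winning parameters plus the per-run training history."""

    model: object
    state: Dict[str, np.ndarray]
    best_val_loss: float
    best_run: int
    best_epoch: int
    history: List[pd.DataFrame]
    seeds: List[int]


@dataclass
class GridSpec:
    """The hyperparameter sweep: gamma first at (0, 0), then alpha x beta."""

    alphas: Tuple[float, ...] = ALPHA_BETA_GRID
    betas: Tuple[float, ...] = ALPHA_BETA_GRID
    gammas: Tuple[float, ...] = GAMMA_GRID
    fixed_gamma: float = 5.0


def _epoch_loss(model, X, Y, Z, lam, rho, beta, mask) -> float:
    """Full-split objective, computed without recording gradients."""
    pred = model.predict(X)
    vf = float(lam @ ((Y - pred) ** 2 @ rho))
    if beta > 0:
        zhat = pred @ mask
        return (1.0 - beta) * vf + beta * float(lam @ (Z - zhat) ** 2)
    return vf


def _fit_linear_wls(dataset, loss_cfg: LossConfig, grid: VFGrid) -> TrainResult:
    """Exact weighted-least-squares fit of the linear baseline.

    The single-task objective is a convex quadratic in the weights, and the
    per-location weights rho_j only rescale each output's independent
    sub-problem, so the minimizer is the sqrt(lambda)-row-scaled least
    squares solution per hemifield -- computed directly rather than by
    iterative descent (whose convergence along the data's near-null
    directions is impractically slow for this model).
    """
    from .architectures import INPUT_SCALE, build_model

    tr, va = dataset.subset("train"), dataset.subset("val")
    lam_tr = sample_weights(tr.md, loss_cfg.alpha)
    lam_va = sample_weights(va.md, loss_cfg.alpha)
    rho = location_weights(grid, loss_cfg.gamma)
    model = build_model("linear", seed=0, dtype="float64")
    sw = np.sqrt(lam_tr)[:, None]
    X = tr.rnfl / INPUT_SCALE
    for half, block in (((slice(None, 384)), slice(None, 26)),
                        ((slice(384, None)), slice(26, None))):
        W, *_ = np.linalg.lstsq(sw * X[:, half], sw * tr.td[:, block], rcond=None)
        sub = model.sub_superior if block.start is None else model.sub_inferior
        sub.weight.data = W
    mask = np.full(52, 1 / 52)
    val = _epoch_loss(model, va.rnfl, va.td, va.md, lam_va, rho, 0.0, mask)
    tr_loss = _epoch_loss(model, tr.rnfl, tr.td, tr.md, lam_tr, rho, 0.0, mask)
    hist = pd.DataFrame([{"run": 0, "epoch": 0, "train_loss": tr_loss,
                          "val_loss": val}])
    return TrainResult(model=model, state=model.state_dict(),
                       best_val_loss=float(val), best_run=0, best_epoch=0,
                       history=[hist], seeds=[0])


def train(arch: str, dataset, config: TrainConfig,
          grid: Optional[VFGrid] = None, verbose: bool = False) -> TrainResult:
    """Train an architecture on a dataset with train/val split labels.

    ``dataset`` is a :class:`retinerve.records.Dataset` whose ``split``
    column contains at least ``train`` and ``val`` labels.  Returns the
    parameters of the epoch/run with the lowest validation loss.

    The linear baseline with ``beta == 0`` is fitted exactly by weighted
    least squares (see :func:`_fit_linear_wls`); the other architectures are
    optimized by seeded mini-batch Adam with early stopping.
    """
    grid = grid if grid is not None else build_grid()
    tr, va = dataset.subset("train"), dataset.subset("val")
    if len(tr) == 0 or len(va) == 0:
        raise ValueError("dataset needs non-empty 'train' and 'val' splits")
    loss_cfg = config.loss
    if arch == "linear" and loss_cfg.beta == 0.0:
        return _fit_linear_wls(dataset, loss_cfg, grid)
    rho = location_weights(grid, loss_cfg.gamma)
    lam_tr = sample_weights(tr.md, loss_cfg.alpha)
    lam_va = sample_weights(va.md, loss_cfg.alpha)
    X_tr, Y_tr, Z_tr = tr.rnfl, tr.td, tr.md
    X_va, Y_va, Z_va = va.rnfl, va.td, va.md

    spec = config.spec
    if spec is None and arch in ("conv", "retinn"):
        spec = RetiNerveNetSpec(multi_task=loss_cfg.beta > 0)
    mask = spec.mask() if spec is not None else np.full(52, 1 / 52)

    best_overall = None
    histories: List[pd.DataFrame] = []
    seeds = config.run_seeds()
    for run, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        model = build_model(arch, spec=spec, seed=seed)
        dt = model.parameters()[0].dtype
        opt = Adam(model.parameters(), lr=config.lr)
        rho_t = rho.astype(dt)
        mask_t = Tensor(mask.astype(dt))
        n = len(tr)
        best_state, best_val, best_epoch = None, np.inf, -1
        since_best = 0
        log: List[dict] = []
        for epoch in range(config.max_epochs):
            order = rng.permutation(n)
            train_loss = 0.0
            for start in range(0, n, config.batch_size):
                idx = order[start:start + config.batch_size]
                xb = X_tr[idx].astype(dt)
                yb = Y_tr[idx].astype(dt)
                wb = (lam_tr[idx][:, None] * rho_t[None, :]).astype(dt)
                pred = model.forward(xb)
                resid = pred - Tensor(yb)
                loss = (resid.square() * Tensor(wb)).sum()
                if loss_cfg.beta > 0:
                    zb = Z_tr[idx].astype(dt)
                    zhat = pred @ mask_t
                    md_term = ((zhat - Tensor(zb)).square() * Tensor(lam_tr[idx].astype(dt))).sum()
                    loss = loss * (1.0 - loss_cfg.beta) + md_term * loss_cfg.beta
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite training loss in run {run} epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                train_loss += float(loss.data)
            val_loss = _epoch_loss(model, X_va, Y_va, Z_va, lam_va, rho,
                                   loss_cfg.beta, mask)
            log.append({"run": run, "epoch": epoch, "train_loss": train_loss,
                        "val_loss": val_loss})
            if val_loss < best_val:
                best_val, best_epoch = val_loss, epoch
                best_state = model.state_dict()
                since_best = 0
            else:
                since_best += 1
                if since_best > config.patience:
                    break
            if verbose and epoch % 20 == 0:
                print(f"run {run} epoch {epoch}: train {train_loss:.5f} val {val_loss:.5f}")
        histories.append(pd.DataFrame(log))
        if best_overall is None or best_val < best_overall[0]:
            best_overall = (best_val, run, best_epoch, best_state, model)

    best_val, best_run, best_epoch, best_state, model = best_overall
    model.load_state_dict(best_state)
    return TrainResult(model=model, state=best_state, best_val_loss=float(best_val),
                       best_run=best_run, best_epoch=best_epoch,
                       history=histories, seeds=seeds)


def grid_search(arch: str, dataset, base_config: TrainConfig,
                grid_spec: Optional[GridSpec] = None,
                grid: Optional[VFGrid] = None,
                eval_fn=None) -> pd.DataFrame:
    """Sweep the loss hyperparameters and tabulate validation metrics.

    Mirrors the study protocol: gamma is swept first with (alpha, beta) =
    (0, 0), then held at ``fixed_gamma`` while (alpha, beta) ranges over the
    printed grid.  ``eval_fn(model, dataset) -> dict`` may add columns (e.g.
    per-interval validation MAE); the default records per-interval and
    overall validation MAE of the TD predictions.
    """
    from dataclasses import replace as _replace

    from .evaluation import interval_mae

    grid_spec = grid_spec if grid_spec is not None else GridSpec()
    vf_grid = grid if grid is not None else build_grid()
    eval_fn = eval_fn if eval_fn is not None else interval_mae
    rows = []

    def run_cell(alpha, beta, gamma, phase):
        cfg = _replace(base_config,
                       loss=LossConfig(alpha=alpha, beta=beta, gamma=gamma))
        t0 = time.time()
        try:
            res = train(arch, dataset, cfg, grid=vf_grid)
        except Exception as exc:  # annotate failures with their cell
            raise RuntimeError(
                f"grid cell (alpha={alpha}, beta={beta}, gamma={gamma}) failed"
            ) from exc
        row = {"phase": phase, "alpha": alpha, "beta": beta, "gamma": gamma,
               "basic": alpha == 0.0 and beta == 0.0,
               "val_loss": res.best_val_loss, "seconds": time.time() - t0}
        row.update(eval_fn(res.model, dataset.subset("val")))
        rows.append(row)

    for gamma in grid_spec.gammas:
        run_cell(0.0, 0.0, gamma, phase="gamma_sweep")
    for alpha in grid_spec.alphas:
        for beta in grid_spec.betas:
            run_cell(alpha, beta, grid_spec.fixed_gamma, phase="alpha_beta")
    return pd.DataFrame(rows)
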