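"""Model/Results front end for structure-function estimation.

``StructureFunctionModel`` binds one architecture and loss configuration to
a paired SDOCT-SAP dataset; ``fit`` runs the seeded training protocol and
returns a ``StructureFunctionResults`` carrying the selected parameters,
the training history, and the evaluation suite, with a ``summary()`` table
in the spirit of classical regression results objects.

Example
-------
>>> from retinerve import synthetic, records, StructureFunctionModel
>>> ds, _ = synthetic.generate_dataset(synthetic.GeneratorConfig(n_patients=50))
>>> ds = records.split_by_patient(ds, seed=0)
>>> model = StructureFunctionModel(ds, arch="linear")
>>> res = model.fit(max_epochs=50, n_runs=1)
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .architectures import RetiNerveNetSpec, count_parameters
from .evaluation import EvalReport, evaluate
from .losses import LossConfig
from .records import Dataset
from .training import TrainConfig, TrainResult, train
from .vf_geometry import VFGrid, build_grid

__all__ = ["StructureFunctionModel", "StructureFunctionResults"]


class StructureFunctionModel:
    """A structure-function regression of 24-2 TD values on RNFL profiles.

    Parameters
    ----------
    dataset:
        A :class:`retinerve.records.Dataset` with ``train``/``val`` (and
        usually ``test``) split labels, in right-eye convention.
    arch:
        ``"linear"``, ``"fc"``, ``"conv"`` or ``"retinn"``.
    loss:
        The (alpha, beta, gamma) loss configuration.
    spec:
        Architecture hyperparameters for the convolutional models.
    """

    def __init__(self, dataset: Dataset, arch: str = "retinn",
                 loss: Optional[LossConfig] = None,
                 spec: Optional[RetiNerveNetSpec] = None,
                 grid: Optional[VFGrid] = None):
        self.dataset = dataset
        self.arch = arch
        self.loss = loss if loss is not None else LossConfig()
        self.spec = spec
        self.grid = grid if grid is not None else build_grid()

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "StructureFunctionModel":
        return cls(Dataset(frame), **kwargs)

    def fit(self, max_epochs: int = 2000, n_runs: int = 5,
            seeds: Optional[Sequence[int]] = None, lr: float = 1e-3,
            batch_size: int = 256, patience: int = 50,
            verbose: bool = False) -> "StructureFunctionResults":
        cfg = TrainConfig(max_epochs=max_epochs, lr=lr, batch_size=batch_size,
                          patience=patience, n_runs=n_runs, seeds=seeds,
                          loss=self.loss, spec=self.spec)
        result = train(self.arch, self.dataset, cfg, grid=self.grid,
                       verbose=verbose)
        return StructureFunctionResults(self, result)


class StructureFunctionResults:
    """Fitted parameters, training history and metric suite."""

    def __init__(self, model: StructureFunctionModel, result: TrainResult):
        self.model = model
        self.result = result
        self.network = result.model
        self._reports: dict = {}

    @property
    def params(self) -> dict:
        """Named trainable arrays of the selected network."""
        return self.result.state

    @property
    def n_parameters(self) -> int:
        return count_parameters(self.network)

    @property
    def history(self) -> pd.DataFrame:
        return pd.concat(self.result.history, ignore_index=True)

    def predict(self, rnfl: np.ndarray) -> np.ndarray:
        """TD estimates (N, 52) for raw thickness profiles (N, 768)."""
        return self.network.predict(np.atleast_2d(rnfl))

    def predict_md(self, rnfl: np.ndarray) -> np.ndarray:
        return self.network.predict_md(np.atleast_2d(rnfl))

    def report(self, split: str = "test") -> EvalReport:
        if split not in self._reports:
            subset = self.model.dataset.subset(split)
            if len(subset) == 0:
                raise ValueError(f"no records labelled {split!r}")
            self._reports[split] = evaluate(self.network, subset,
                                            grid=self.model.grid)
        return self._reports[split]

    def summary(self, split: str = "test") -> str:
        """Human-readable fit summary."""
        rep = self.report(split)
        loss = self.model.loss
        lines = [
            "Structure-function regression results",
            "=" * 53,
            f"architecture: {self.model.arch:>10s}    trainable params: {self.n_parameters:,}",
            f"loss: alpha={loss.alpha} beta={loss.beta} gamma={loss.gamma}",
            f"runs: {len(self.result.seeds)} (best run {self.result.best_run}, "
            f"epoch {self.result.best_epoch}, val loss {self.result.best_val_loss:.5f})",
            "-" * 53,
            f"pointwise MAE ({split} split, dB):",
        ]
        for group, row in rep.pointwise.iterrows():
            se = f"{row['se']:.3f}" if np.isfinite(row["se"]) else "--"
            lines.append(f"  {group:>14s}: {row['mae']:.3f} ({se})   n={int(row['n'])}")
        lines.append(f"MD MAE: {rep.md['mae']:.3f} ({rep.md['se']:.3f})")
        lines.append("sectoral mean deviation (MAE, R^2):")
        for sector, row in rep.sectoral.iterrows():
            lines.append(f"  {sector:>14s}: {row['mae']:.3f}, {row['r2']:.3f}")
        return "\n".join(lines)
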