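"""The four structure-function architectures.

Every model maps a 768-sample peripapillary RNFL thickness profile (TSNIT
order, micrometres) to the 52 total-deviation (TD) values of the 24-2 chart,
through two independent hemiretina sub-networks: the superior half of the
profile (samples 0..383) predicts the inferior chart hemifield and the
inferior half predicts the superior hemifield (lateral inversion of the eye).
No connection crosses the horizontal raphe.

Architectures
-------------
``LinearModel``
    Per hemifield, each of the 26 TD values is a linear function (no
    intercept) of all 384 opposite-half thickness samples.
``FullyConnectedModel``
    Per sub-network: 384 -> 32 -> 32 -> 26 dense layers, ReLU on the hidden
    layers, biases everywhere.
``RecursiveNet``
    The recursive model.  Each sub-network has four blocks: (1) conv + pool
    stack with a strided convolutional skip connection reducing 384 -> 96;
    (2) the Recursive Progression Layer (RPL) -- a single length-preserving
    convolution with linear activation that is applied repeatedly, each pass
    modelling one step of outward movement along the arcuate fiber bundles;
    (3) a second conv/pool/skip stack reducing 96 -> 24; (4) a single-channel
    convolution and max pools reducing 24 -> 5.  After pass t the first
    {5,4,4,4,4,4,1}[t-1] of the 5 outputs are emitted as chart points, so 7
    passes produce all 26 points of a hemifield, ordered from the blind spot
    outward.  A fixed MD mask applied to the 52 outputs gives the multi-task
    MD estimate.
``VanillaConvNet``
    Ablation of ``RecursiveNet``: both skip connections removed and the
    recursion replaced by 7 *independent* convolutions of the RPL's shape;
    the (shared) head is applied after each of the 7 layers with the same
    emission slicing.

With the reference hyperparameters the trainable-parameter totals are
19,968 (linear), 28,468 (fully connected), 27,840 (vanilla convolutional)
and 18,864 (recursive).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import List, Optional, Tuple

import numpy as np

from .nn import Tensor, concatenate, Module, Conv1d, MaxPool1d, Linear
from .vf_geometry import PASS_SIZES, uniform_md_mask

__all__ = [
    "RetiNerveNetSpec",
    "RPLState",
    "LinearModel",
    "FullyConnectedModel",
    "VanillaConvNet",
    "RecursiveNet",
    "build_model",
    "count_parameters",
    "INPUT_SCALE",
]

#: Thickness values are divided by this before entering any network,
#: keeping activations O(1).
INPUT_SCALE = 100.0

_N_PASSES = 7


@dataclass
class RetiNerveNetSpec:
    """Hyperparameters of one hemiretina sub-network.

    The reference values reproduce the architecture totals above; they are an
    integer solution consistent with the block structure (channel widths C1,
    C2 and kernel sizes per layer), found by constraint search over the
    closed-form parameter-count arithmetic.
    """

    c1: int = 12          # channels of blocks 1-2
    c2: int = 24          # channels of block 3
    k1: int = 9           # block1 conv1 kernel (ReLU)
    k2: int = 10          # block1 conv2 kernel (linear)
    ks1: int = 13         # block1 skip kernel (stride 4, linear)
    kr: int = 6           # RPL kernel (linear, length-preserving)
    k3: int = 9           # block3 conv1 kernel (ReLU)
    k4: int = 6           # block3 conv2 kernel (linear)
    ks3: int = 2          # block3 skip kernel (stride 4, linear)
    k5: int = 5           # block4 conv kernel (linear, no bias)
    multi_task: bool = False
    md_mask: Optional[np.ndarray] = None
    dtype: str = "float32"

    def mask(self) -> np.ndarray:
        return uniform_md_mask() if self.md_mask is None else np.asarray(self.md_mask, float)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["md_mask"] is not None:
            d["md_mask"] = list(map(float, d["md_mask"]))
        return d


@dataclass
class RPLState:
    """Recursion state r^(t): the 96-long, C1-channel feature map after t
    passes (stored channels-last as (B, 96, C1))."""

    r: Tensor
    t: int = 0


def _np_dtype(spec: RetiNerveNetSpec):
    return np.dtype(spec.dtype)


class _SubNetwork(Module):
    """One hemiretina sub-network of the recursive model."""

    def __init__(self, spec: RetiNerveNetSpec, rng: np.random.Generator):
        dt = _np_dtype(spec)
        self.spec = spec
        # block 1: 384 -> 96
        self.b1_conv1 = Conv1d(1, spec.c1, spec.k1, activation="relu", rng=rng, dtype=dt)
        self.b1_pool1 = MaxPool1d(2, 2)
        self.b1_conv2 = Conv1d(spec.c1, spec.c1, spec.k2, activation="linear", rng=rng, dtype=dt)
        self.b1_pool2 = MaxPool1d(2, 2)
        self.b1_skip = Conv1d(1, spec.c1, spec.ks1, stride=4, activation="linear", rng=rng, dtype=dt)
        # block 2: the RPL (shape-preserving)
        self.rpl = Conv1d(spec.c1, spec.c1, spec.kr, activation="linear", rng=rng, dtype=dt)
        # block 3: 96 -> 24
        self.b3_conv1 = Conv1d(spec.c1, spec.c2, spec.k3, activation="relu", rng=rng, dtype=dt)
        self.b3_pool1 = MaxPool1d(2, 2)
        self.b3_conv2 = Conv1d(spec.c2, spec.c2, spec.k4, activation="linear", rng=rng, dtype=dt)
        self.b3_pool2 = MaxPool1d(2, 2)
        self.b3_skip = Conv1d(spec.c1, spec.c2, spec.ks3, stride=4, activation="linear", rng=rng, dtype=dt)
        # block 4: 24 -> 5
        self.b4_conv = Conv1d(spec.c2, 1, spec.k5, bias=False, activation="linear", rng=rng, dtype=dt)
        self.b4_pool1 = MaxPool1d(2, 2)
        self.b4_pool2 = MaxPool1d(2, 2)
        self.b4_pool3 = MaxPool1d(2, 1)

    def block1(self, x_half: Tensor) -> RPLState:
        """x_half: (B, 384) scaled thickness -> r^(0) of shape (B, 96, C1)."""
        if x_half.shape[-1] != 384:
            raise ValueError(f"expected input length 384, got {x_half.shape[-1]}")
        x = x_half.reshape(x_half.shape[0], 384, 1)
        h = self.b1_pool2(self.b1_conv2(self.b1_pool1(self.b1_conv1(x))))
        return RPLState(h + self.b1_skip(x), t=0)

    def rpl_step(self, state: RPLState) -> RPLState:
        """One recursive pass r^(t) -> r^(t+1) through the shared convolution."""
        if state.t >= _N_PASSES:
            raise ValueError(f"recursion exhausted: t={state.t}")
        return RPLState(self.rpl(state.r), t=state.t + 1)

    def head(self, state: RPLState) -> Tensor:
        """Blocks 3-4: (B, 96, C1) -> (B, 5)."""
        if state.r.shape[1:] != (96, self.spec.c1):
            raise ValueError(f"bad state shape {state.r.shape}")
        h = self.b3_pool2(self.b3_conv2(self.b3_pool1(self.b3_conv1(state.r))))
        h = h + self.b3_skip(state.r)
        h = self.b4_pool3(self.b4_pool2(self.b4_pool1(self.b4_conv(h))))
        return h.reshape(h.shape[0], 5)

    def forward(self, x_half: Tensor) -> Tensor:
        """Full sub-network: (B, 384) -> (B, 26) hemifield TD estimates.

        The head is shared across passes, so the seven recursion states are
        stacked along the batch axis and sent through blocks 3-4 in a single
        call; the per-pass output slices are then gathered back.  This is
        numerically identical to applying the head after every pass.
        """
        B = x_half.shape[0]
        state = self.block1(x_half)
        states: List[Tensor] = []
        for _ in range(_N_PASSES):
            state = self.rpl_step(state)
            states.append(state.r)
        stacked = self.head(RPLState(concatenate(states, axis=0), t=1))
        outs = [stacked[t * B:(t + 1) * B, :PASS_SIZES[t]] for t in range(_N_PASSES)]
        return concatenate(outs, axis=1)


class _HemiModel(Module):
    """Base: two sub-models, superior RNFL half -> inferior chart block."""

    multi_task = False

    def _halves(self, x: Tensor) -> Tuple[Tensor, Tensor]:
        if x.shape[-1] != 768:
            raise ValueError(f"expected 768 thickness samples, got {x.shape[-1]}")
        return x[:, :384], x[:, 384:]

    def forward(self, x: "Tensor | np.ndarray") -> Tensor:
        """x: (B, 768) raw thickness in micrometres -> (B, 52) TD in dB.

        Output is in canonical grid order: inferior-chart block (from the
        superior profile half) then superior-chart block.
        """
        if not isinstance(x, Tensor):
            dt = self.parameters()[0].dtype
            x = Tensor(np.asarray(x, dtype=dt))
        x = x * np.asarray(1.0 / INPUT_SCALE, dtype=x.dtype)
        sup_half, inf_half = self._halves(x)
        inf_chart = self.sub_superior(sup_half)
        sup_chart = self.sub_inferior(inf_half)
        return concatenate([inf_chart, sup_chart], axis=1)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Numpy convenience wrapper around forward (inference mode)."""
        from .nn import no_grad

        with no_grad():
            return self.forward(np.asarray(x)).data

    def predict_md(self, x: np.ndarray, mask: Optional[np.ndarray] = None) -> np.ndarray:
        mask = uniform_md_mask() if mask is None else np.asarray(mask, float)
        return self.predict(x) @ mask


class LinearModel(_HemiModel):
    """Per-hemifield linear map, no intercepts (2 x 26 x 384 weights)."""

    def __init__(self, rng: Optional[np.random.Generator] = None, dtype: str = "float32"):
        rng = rng if rng is not None else np.random.default_rng()
        dt = np.dtype(dtype)
        self.sub_superior = Linear(384, 26, bias=False, rng=rng, dtype=dt)
        self.sub_inferior = Linear(384, 26, bias=False, rng=rng, dtype=dt)


class FullyConnectedModel(_HemiModel):
    """Two 384-32-32-26 dense sub-networks with ReLU hidden layers."""

    def __init__(self, rng: Optional[np.random.Generator] = None, dtype: str = "float32"):
        rng = rng if rng is not None else np.random.default_rng()
        dt = np.dtype(dtype)

        class _FC(Module):
            def __init__(self):
                self.l1 = Linear(384, 32, activation="relu", rng=rng, dtype=dt)
                self.l2 = Linear(32, 32, activation="relu", rng=rng, dtype=dt)
                self.l3 = Linear(32, 26, rng=rng, dtype=dt)

            def forward(self, x):
                return self.l3(self.l2(self.l1(x)))

        self.sub_superior = _FC()
        self.sub_inferior = _FC()


class RecursiveNet(_HemiModel):
    """The recursive architecture (two sub-networks sharing nothing)."""

    def __init__(self, spec: Optional[RetiNerveNetSpec] = None,
                 rng: Optional[np.random.Generator] = None):
        rng = rng if rng is not None else np.random.default_rng()
        self.spec = spec if spec is not None else RetiNerveNetSpec()
        self.multi_task = self.spec.multi_task
        self.sub_superior = _SubNetwork(self.spec, rng)
        self.sub_inferior = _SubNetwork(self.spec, rng)

    def forward_md(self, x: "Tensor | np.ndarray") -> Tuple[Tensor, Tensor]:
        """TD estimates plus the masked MD estimate (multi-task head)."""
        td = self.forward(x)
        mask = Tensor(self.spec.mask().astype(td.dtype))
        return td, td @ mask


class _VanillaSub(Module):
    """Sub-network of the non-recursive ablation: no skips, 7 free convs."""

    def __init__(self, spec: RetiNerveNetSpec, rng: np.random.Generator):
        dt = _np_dtype(spec)
        self.spec = spec
        self.b1_conv1 = Conv1d(1, spec.c1, spec.k1, activation="relu", rng=rng, dtype=dt)
        self.b1_pool1 = MaxPool1d(2, 2)
        self.b1_conv2 = Conv1d(spec.c1, spec.c1, spec.k2, activation="linear", rng=rng, dtype=dt)
        self.b1_pool2 = MaxPool1d(2, 2)
        self.stack = [
            Conv1d(spec.c1, spec.c1, spec.kr, activation="linear", rng=rng, dtype=dt)
            for _ in range(_N_PASSES)
        ]
        self.b3_conv1 = Conv1d(spec.c1, spec.c2, spec.k3, activation="relu", rng=rng, dtype=dt)
        self.b3_pool1 = MaxPool1d(2, 2)
        self.b3_conv2 = Conv1d(spec.c2, spec.c2, spec.k4, activation="linear", rng=rng, dtype=dt)
        self.b3_pool2 = MaxPool1d(2, 2)
        self.b4_conv = Conv1d(spec.c2, 1, spec.k5, bias=False, activation="linear", rng=rng, dtype=dt)
        self.b4_pool1 = MaxPool1d(2, 2)
        self.b4_pool2 = MaxPool1d(2, 2)
        self.b4_pool3 = MaxPool1d(2, 1)

    def head(self, r: Tensor) -> Tensor:
        h = self.b3_pool2(self.b3_conv2(self.b3_pool1(self.b3_conv1(r))))
        h = self.b4_pool3(self.b4_pool2(self.b4_pool1(self.b4_conv(h))))
        return h.reshape(h.shape[0], 5)

    def forward(self, x_half: Tensor) -> Tensor:
        B = x_half.shape[0]
        x = x_half.reshape(B, 384, 1)
        r = self.b1_pool2(self.b1_conv2(self.b1_pool1(self.b1_conv1(x))))
        rs: List[Tensor] = []
        for conv in self.stack:
            r = conv(r)
            rs.append(r)
        stacked = self.head(concatenate(rs, axis=0))
        outs = [stacked[t * B:(t + 1) * B, :PASS_SIZES[t]] for t in range(_N_PASSES)]
        return concatenate(outs, axis=1)


class VanillaConvNet(_HemiModel):
    """Non-recursive convolutional ablation (7 successive free convolutions)."""

    def __init__(self, spec: Optional[RetiNerveNetSpec] = None,
                 rng: Optional[np.random.Generator] = None):
        rng = rng if rng is not None else np.random.default_rng()
        self.spec = spec if spec is not None else RetiNerveNetSpec()
        self.multi_task = self.spec.multi_task
        self.sub_superior = _VanillaSub(self.spec, rng)
        self.sub_inferior = _VanillaSub(self.spec, rng)

    def forward_md(self, x: "Tensor | np.ndarray") -> Tuple[Tensor, Tensor]:
        td = self.forward(x)
        mask = Tensor(self.spec.mask().astype(td.dtype))
        return td, td @ mask


_ARCHS = {
    "linear": LinearModel,
    "fc": FullyConnectedModel,
    "conv": VanillaConvNet,
    "retinn": RecursiveNet,
}


def build_model(arch: str, spec: Optional[RetiNerveNetSpec] = None,
                seed: Optional[int] = None, dtype: str = "float32"):
    """Instantiate an architecture by name: linear / fc / conv / retinn."""
    if arch not in _ARCHS:
        raise ValueError(f"unknown architecture {arch!r}; choose from {sorted(_ARCHS)}")
    rng = np.random.default_rng(seed)
    if arch in ("linear", "fc"):
        return _ARCHS[arch](rng=rng, dtype=dtype)
    spec = spec if spec is not None else RetiNerveNetSpec(dtype=dtype)
    return _ARCHS[arch](spec=spec, rng=rng)


def count_parameters(model: Module) -> int:
    """Number of trainable scalars in a model."""
    return model.n_parameters()
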