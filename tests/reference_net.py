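"""Independent forward-only reference implementation used as an oracle.

Re-implements 1D convolution, max pooling and the recursive sub-network
directly from their definitions with explicit per-position loops (no shared
code with the package's autodiff engine beyond numpy itself), materializing
the recursion states r^(1..7) one pass at a time.
"""

import numpy as np


def ref_pad(x, pl, pr):
    """x: (L, C) -> zero-padded copy."""
    L, C = x.shape
    out = np.zeros((L + pl + pr, C), dtype=x.dtype)
    out[pl:pl + L] = x
    return out


def ref_same_pad(kernel, stride=1):
    total = max(kernel - stride, 0)
    return total // 2, total - total // 2


def ref_conv(x, w, b=None, stride=1):
    """x: (L, C_in); w: (C_out, C_in, K); length-preserving padding."""
    C_out, C_in, K = w.shape
    pl, pr = ref_same_pad(K, stride)
    xp = ref_pad(x, pl, pr)
    L_out = (xp.shape[0] - K) // stride + 1
    out = np.zeros((L_out, C_out), dtype=np.float64)
    for i in range(L_out):
        window = xp[i * stride:i * stride + K, :]  # (K, C_in)
        for o in range(C_out):
            out[i, o] = np.sum(window * w[o].T)
    if b is not None:
        out += b
    return out


def ref_maxpool(x, size, stride):
    L, C = x.shape
    L_out = (L - size) // stride + 1
    out = np.empty((L_out, C), dtype=x.dtype)
    for i in range(L_out):
        out[i] = x[i * stride:i * stride + size].max(axis=0)
    return out


def ref_relu(x):
    return np.where(x > 0, x, 0.0)


class RefSubNetwork:
    """Forward-only mirror of one hemiretina sub-network, from its weights."""

    def __init__(self, params, prefix):
        # params: dict of named arrays from Module.state_dict()
        def get(name):
            return np.asarray(params[f"{prefix}{name}"], dtype=np.float64)

        self.w = {k: get(k) for k in (
            "b1_conv1.weight", "b1_conv1.bias", "b1_conv2.weight", "b1_conv2.bias",
            "b1_skip.weight", "b1_skip.bias", "rpl.weight", "rpl.bias",
            "b3_conv1.weight", "b3_conv1.bias", "b3_conv2.weight", "b3_conv2.bias",
            "b3_skip.weight", "b3_skip.bias", "b4_conv.weight",
        )}

    def block1(self, x_half):
        x = x_half[:, None]  # (384, 1)
        h = ref_relu(ref_conv(x, self.w["b1_conv1.weight"], self.w["b1_conv1.bias"]))
        h = ref_maxpool(h, 2, 2)
        h = ref_conv(h, self.w["b1_conv2.weight"], self.w["b1_conv2.bias"])
        h = ref_maxpool(h, 2, 2)
        skip = ref_conv(x, self.w["b1_skip.weight"], self.w["b1_skip.bias"], stride=4)
        return h + skip

    def rpl(self, r):
        return ref_conv(r, self.w["rpl.weight"], self.w["rpl.bias"])

    def head(self, r):
        h = ref_relu(ref_conv(r, self.w["b3_conv1.weight"], self.w["b3_conv1.bias"]))
        h = ref_maxpool(h, 2, 2)
        h = ref_conv(h, self.w["b3_conv2.weight"], self.w["b3_conv2.bias"])
        h = ref_maxpool(h, 2, 2)
        h = h + ref_conv(r, self.w["b3_skip.weight"], self.w["b3_skip.bias"], stride=4)
        h = ref_conv(h, self.w["b4_conv.weight"], None)
        h = ref_maxpool(h, 2, 2)
        h = ref_maxpool(h, 2, 2)
        h = ref_maxpool(h, 2, 1)
        return h[:, 0]  # (5,)

    def forward(self, x_half, pass_sizes=(5, 4, 4, 4, 4, 4, 1)):
        """Materialize r^(1..7) explicitly and emit the pass slices."""
        r = self.block1(x_half)
        outs = []
        for size in pass_sizes:
            r = self.rpl(r)
            outs.append(self.head(r)[:size])
        return np.concatenate(outs)


def ref_forward(model, x):
    """Full-network reference: x (768,) raw thickness -> (52,) TD estimate."""
    params = model.state_dict()
    sup = RefSubNetwork(params, "sub_superior.")
    inf = RefSubNetwork(params, "sub_inferior.")
    xs = np.asarray(x, dtype=np.float64) / 100.0
    return np.concatenate([sup.forward(xs[:384]), inf.forward(xs[384:])])
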