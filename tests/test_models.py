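"""Architectures: parameter counts, shapes, recursion/unroll equivalence,
hemisphere isolation, and baseline semantics."""

import numpy as np
import pytest

from retinerve.architectures import (
    LinearModel,
    RecursiveNet,
    RetiNerveNetSpec,
    VanillaConvNet,
    build_model,
    count_parameters,
)
from retinerve.nn import Tensor

from reference_net import ref_forward


@pytest.fixture(scope="module")
def retinn():
    return build_model("retinn", seed=42, dtype="float64")


class TestParameterCounts:
    @pytest.mark.parametrize(
        "arch,total",
        [("linear", 19_968), ("fc", 28_468), ("conv", 27_840), ("retinn", 18_864)],
    )
    def test_totals_match_closed_form(self, arch, total):
        assert count_parameters(build_model(arch, seed=0)) == total

    def test_per_layer_arithmetic_of_recursive_subnetwork(self, retinn):
        s = retinn.spec
        expected = {
            "b1_conv1": s.k1 * 1 * s.c1 + s.c1,
            "b1_conv2": s.k2 * s.c1 * s.c1 + s.c1,
            "b1_skip": s.ks1 * 1 * s.c1 + s.c1,
            "rpl": s.kr * s.c1 * s.c1 + s.c1,
            "b3_conv1": s.k3 * s.c1 * s.c2 + s.c2,
            "b3_conv2": s.k4 * s.c2 * s.c2 + s.c2,
            "b3_skip": s.ks3 * s.c1 * s.c2 + s.c2,
            "b4_conv": s.k5 * s.c2 * 1,  # final conv carries no bias
        }
        named = dict(retinn.named_parameters())
        for layer, count in expected.items():
            got = sum(v.data.size for k, v in named.items()
                      if k.startswith(f"sub_superior.{layer}."))
            assert got == count, layer
        assert sum(expected.values()) * 2 == 18_864

    def test_multitask_md_head_adds_no_parameters(self):
        base = build_model("retinn", seed=0)
        multi = build_model("retinn", spec=RetiNerveNetSpec(multi_task=True), seed=0)
        assert count_parameters(base) == count_parameters(multi)


class TestShapes:
    def test_block1_output_shape(self, retinn, rng):
        x = Tensor(rng.normal(size=(3, 384)))
        state = retinn.sub_superior.block1(x)
        assert state.r.shape == (3, 96, retinn.spec.c1)
        assert state.t == 0

    def test_rpl_preserves_shape_and_counts_passes(self, retinn, rng):
        state = retinn.sub_superior.block1(Tensor(rng.normal(size=(2, 384))))
        for t in range(1, 8):
            state = retinn.sub_superior.rpl_step(state)
            assert state.r.shape == (2, 96, retinn.spec.c1)
            assert state.t == t
        with pytest.raises(ValueError):
            retinn.sub_superior.rpl_step(state)

    def test_head_emits_five_values(self, retinn, rng):
        state = retinn.sub_superior.block1(Tensor(rng.normal(size=(2, 384))))
        state = retinn.sub_superior.rpl_step(state)
        out = retinn.sub_superior.head(state)
        assert out.shape == (2, 5)

    def test_final_pool_window_count(self, rng):
        # a size-2 stride-1 pool maps length 6 to length 5
        from retinerve.nn import MaxPool1d

        out = MaxPool1d(2, 1)(Tensor(rng.normal(size=(1, 6, 1))))
        assert out.shape == (1, 5, 1)

    @pytest.mark.parametrize("arch", ["linear", "fc", "conv", "retinn"])
    def test_forward_emits_52_values(self, arch, rng):
        model = build_model(arch, seed=1)
        out = model.predict(rng.uniform(50, 120, (3, 768)))
        assert out.shape == (3, 52)

    @pytest.mark.parametrize("arch", ["linear", "fc", "conv", "retinn"])
    def test_wrong_input_length_rejected(self, arch, rng):
        model = build_model(arch, seed=1)
        with pytest.raises(ValueError):
            model.predict(rng.uniform(50, 120, (3, 700)))


class TestRecursionSemantics:
    def test_identity_kernel_leaves_state_unchanged(self, retinn, rng):
        sub = retinn.sub_superior
        w = np.zeros_like(sub.rpl.weight.data)
        # with padding (pl, pr), output i reads input i - pl + tap, so the
        # identity tap sits at index pl
        for c in range(retinn.spec.c1):
            w[c, c, sub.rpl.padding[0]] = 1.0
        old_w = sub.rpl.weight.data.copy()
        old_b = sub.rpl.bias.data.copy()
        sub.rpl.weight.data = w
        sub.rpl.bias.data = np.zeros_like(old_b)
        try:
            state = sub.block1(Tensor(rng.normal(size=(2, 384))))
            stepped = sub.rpl_step(state)
            assert np.allclose(stepped.r.data, state.r.data, atol=1e-12)
        finally:
            sub.rpl.weight.data = old_w
            sub.rpl.bias.data = old_b

    def test_zero_kernel_zeroes_state(self, retinn, rng):
        sub = retinn.sub_superior
        old_w, old_b = sub.rpl.weight.data.copy(), sub.rpl.bias.data.copy()
        sub.rpl.weight.data = np.zeros_like(old_w)
        sub.rpl.bias.data = np.zeros_like(old_b)
        try:
            state = sub.block1(Tensor(rng.normal(size=(1, 384))))
            assert np.all(sub.rpl_step(state).r.data == 0)
        finally:
            sub.rpl.weight.data, sub.rpl.bias.data = old_w, old_b

    def test_three_steps_equal_unrolled_composition(self, retinn, rng):
        from reference_net import RefSubNetwork

        sub = retinn.sub_superior
        x = rng.normal(loc=0.9, scale=0.1, size=384)
        state = sub.block1(Tensor(x[None, :]))
        for _ in range(3):
            state = sub.rpl_step(state)
        ref = RefSubNetwork(retinn.state_dict(), "sub_superior.")
        r = ref.block1(x)
        for _ in range(3):
            r = ref.rpl(r)
        assert np.allclose(state.r.data[0], r, atol=1e-9)

    def test_forward_matches_independent_unrolled_oracle(self, retinn, rng):
        x = rng.uniform(40, 130, size=(5, 768))
        ours = retinn.predict(x)
        for i in range(5):
            ref = ref_forward(retinn, x[i])
            assert np.allclose(ours[i], ref, atol=1e-8)


class TestHemisphereIsolation:
    @pytest.mark.parametrize("arch", ["linear", "fc", "conv", "retinn"])
    def test_perturbing_one_half_leaves_other_chart_block_fixed(self, arch, rng):
        model = build_model(arch, seed=3)
        x = rng.uniform(50, 120, (4, 768))
        base = model.predict(x)
        pert = x.copy()
        pert[:, :384] += rng.normal(0, 15, (4, 384))  # superior half
        out = model.predict(pert)
        # superior-chart block (last 26) is fed by the untouched inferior half
        assert np.array_equal(out[:, 26:], base[:, 26:])
        assert not np.array_equal(out[:, :26], base[:, :26])


class TestBaselines:
    def test_linear_zero_input_zero_output(self):
        model = LinearModel(rng=np.random.default_rng(0))
        assert np.array_equal(model.predict(np.zeros((2, 768))), np.zeros((2, 52)))

    def test_linear_is_homogeneous(self, rng):
        model = LinearModel(rng=np.random.default_rng(0), dtype="float64")
        x = rng.uniform(50, 120, (3, 768))
        assert np.allclose(model.predict(2 * x), 2 * model.predict(x), atol=1e-9)

    def test_fc_output_length(self, rng):
        assert build_model("fc", seed=0).predict(rng.uniform(0, 1, (2, 768))).shape == (2, 52)

    def test_vanilla_with_tied_weights_matches_skipless_recursive(self, rng):
        spec = RetiNerveNetSpec(dtype="float64")
        retinn = RecursiveNet(spec=spec, rng=np.random.default_rng(5))
        vanilla = VanillaConvNet(spec=spec, rng=np.random.default_rng(6))
        # zero the recursive model's skip connections
        for sub in (retinn.sub_superior, retinn.sub_inferior):
            for layer in (sub.b1_skip, sub.b3_skip):
                layer.weight.data[...] = 0.0
                layer.bias.data[...] = 0.0
        # copy shared layers and tie all 7 stack convolutions to the RPL
        for r_sub, v_sub in ((retinn.sub_superior, vanilla.sub_superior),
                             (retinn.sub_inferior, vanilla.sub_inferior)):
            for name in ("b1_conv1", "b1_conv2", "b3_conv1", "b3_conv2", "b4_conv"):
                v_layer, r_layer = getattr(v_sub, name), getattr(r_sub, name)
                v_layer.weight.data = r_layer.weight.data.copy()
                if v_layer.bias is not None:
                    v_layer.bias.data = r_layer.bias.data.copy()
            for conv in v_sub.stack:
                conv.weight.data = r_sub.rpl.weight.data.copy()
                conv.bias.data = r_sub.rpl.bias.data.copy()
        x = rng.uniform(50, 120, (3, 768))
        assert np.allclose(vanilla.predict(x), retinn.predict(x), atol=1e-10)

    def test_uniform_mask_md_is_mean_of_td(self, rng):
        model = build_model("retinn", spec=RetiNerveNetSpec(multi_task=True), seed=2)
        x = rng.uniform(50, 120, (3, 768))
        td, md = model.forward_md(x)
        assert np.allclose(md.data, td.data.mean(axis=1), atol=1e-6)
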