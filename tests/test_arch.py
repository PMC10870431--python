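"""Fake quantization, network construction, and cost accounting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from picocall.arch import (FP32, ArchitectureSpec, BlockSpec, ConstructionError,
                           LayerSpec, QuantSpec, bops, build_network,
                           chain_spec, layer_size_report, load_network,
                           model_size_bits, param_count, random_spec,
                           save_network, with_uniform_quant)
from picocall.nn import fake_quantize


class TestFakeQuantize:
    def test_fp32_is_identity(self):
        x = np.random.default_rng(0).normal(size=100)
        assert np.array_equal(fake_quantize(x, 32), x)

    def test_representable_endpoints_unchanged(self):
        x = np.array([-1.0, 0.0, 1.0])
        assert np.array_equal(fake_quantize(x, 8), x)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_4bit_error_bounded_by_step(self, seed):
        x = np.random.default_rng(seed).normal(size=64)
        q = fake_quantize(x, 4)
        # 4-bit symmetric grid: step = max|x| / (2^3 - 1); rounding error <= step/2
        assert np.max(np.abs(q - x)) <= np.max(np.abs(x)) / (2 ** 3 - 1)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            fake_quantize(np.array([1.0, np.inf]), 8)

    def test_invalid_bits_rejected(self):
        with pytest.raises(ValueError):
            fake_quantize(np.ones(3), 7)


def _conv(cin, cout, k, groups=1, quant=FP32, norm=False):
    return LayerSpec(kind="conv", in_channels=cin, out_channels=cout,
                     kernel=k, groups=groups, quant=quant, has_norm=norm)


class TestAccountingExamples:
    def test_param_count_formula(self):
        # conv in=4,out=8,k=3,groups=4 with bias, no norm: 24 weights + 8 biases
        spec = ArchitectureSpec(blocks=[
            BlockSpec(layers=[_conv(1, 4, 3), _conv(4, 8, 3, groups=4)])])
        head = 8 * 5 + 5
        first = 1 * 4 * 3 + 4
        assert param_count(spec) == first + 32 + head

    def test_param_count_additivity(self):
        spec = ArchitectureSpec(blocks=[BlockSpec(layers=[
            _conv(1, 4, 3), _conv(4, 8, 3, groups=4), _conv(8, 8, 3, groups=4)])])
        # stacking a copy of the grouped layer (8/4*8*3 + 8 = 56) adds exactly it
        base = ArchitectureSpec(blocks=[BlockSpec(layers=[
            _conv(1, 4, 3), _conv(4, 8, 3, groups=4)])])
        assert param_count(spec) - param_count(base) == 48 + 8

    def test_identity_layer_contributes_nothing(self):
        with_id = ArchitectureSpec(blocks=[BlockSpec(layers=[
            _conv(1, 4, 3), LayerSpec(kind="identity", in_channels=4,
                                      out_channels=4)])])
        without = ArchitectureSpec(blocks=[BlockSpec(layers=[_conv(1, 4, 3)])])
        assert param_count(with_id) == param_count(without)

    def test_size_bits_simple_cases(self):
        spec = ArchitectureSpec(blocks=[BlockSpec(layers=[_conv(1, 4, 3)])])
        n = param_count(spec)
        assert model_size_bits(spec) == 32 * n
        q8 = with_uniform_quant(spec, QuantSpec(8, 8))
        assert model_size_bits(q8) == 8 * n

    def test_mixed_precision_sums_per_layer(self):
        spec = ArchitectureSpec(blocks=[BlockSpec(layers=[
            _conv(1, 4, 3, quant=QuantSpec(8, 8)),
            _conv(4, 4, 3, quant=QuantSpec(4, 4))])],
            head_quant=QuantSpec(8, 8))
        rows = layer_size_report(spec)
        assert sum(r["bits"] for r in rows) == model_size_bits(spec)
        assert {r["wbits"] for r in rows} == {8, 4}

    def test_16bit_halves_size_for_any_spec(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            spec = random_spec(rng)
            half = with_uniform_quant(spec, QuantSpec(16, 16))
            full = with_uniform_quant(spec, QuantSpec(32, 32))
            assert model_size_bits(full) == 2 * model_size_bits(half)

    def test_bops_defined_formula(self):
        # single layer, 1000 MACs at <8,8> -> 64000; fp32 -> 1,024,000
        spec = ArchitectureSpec(blocks=[BlockSpec(layers=[
            LayerSpec(kind="conv", in_channels=1, out_channels=10, kernel=1,
                      quant=QuantSpec(8, 8), has_norm=False)])])
        frames = 100  # MACs = 100*1*10*1 = 1000
        head = frames * 10 * 5 * 1 * 32 * 32
        assert bops(spec, frames) == 1000 * 64 + head
        fp = with_uniform_quant(spec, QuantSpec(32, 32))
        assert bops(fp, frames) == 1000 * 1024 + head


class TestAccountingOracle:
    """Brute-force recomputation from raw layer dimensions."""

    @staticmethod
    def oracle(spec, input_length):
        params = size = total_bops = 0
        frames = input_length

        def one(cin, cout, k, groups, wb, ab, norm, f_in, f_out):
            nonlocal params, size, total_bops
            w = (cin // groups) * cout * k
            p = w + cout + (2 * cout if norm else 0)
            params += p
            size += p * wb
            total_bops += f_out * w * wb * ab

        for block in spec.blocks:
            f_block_in = frames
            for l in block.layers:
                if l.kind == "identity":
                    continue
                f_out = -(-frames // l.stride)
                one(l.in_channels, l.out_channels, l.kernel, l.groups,
                    l.quant.wbits, l.quant.abits, l.has_norm, frames, f_out)
                frames = f_out
            if block.skip and block.in_channels != block.out_channels:
                q = block.layers[-1].quant
                one(block.in_channels, block.out_channels, 1, 1,
                    q.wbits, q.abits, False, f_block_in, frames)
        one(spec.out_channels, 5, 1, 1, spec.head_quant.wbits,
            spec.head_quant.abits, False, frames, frames)
        return params, size, total_bops

    def test_matches_on_random_specs(self):
        rng = np.random.default_rng(1234)
        for _ in range(120):
            spec = random_spec(rng)
            length = int(rng.integers(50, 400))
            p, s, b = self.oracle(spec, length)
            assert param_count(spec) == p
            assert model_size_bits(spec) == s
            assert bops(spec, length) == b


class TestBuildNetwork:
    def test_identity_only_blocks_forward_unchanged(self):
        spec = ArchitectureSpec(blocks=[BlockSpec(layers=[
            LayerSpec(kind="identity", in_channels=1, out_channels=1)])])
        net = build_network(spec, seed=0)
        assert sum(p.value.size for p in net.parameters()
                   if p.prunable) == net.head.w.value.size
        x = np.random.default_rng(0).normal(size=(2, 30))
        assert net.forward(x).shape == (2, 30, 5)

    def test_output_frame_count_follows_decimation(self):
        spec = chain_spec([8, 8], kernel=9, stride_first=2)
        net = build_network(spec, seed=0)
        x = np.zeros((1, 4000))
        assert net.forward(x).shape == (1, 2000, 5)
        assert spec.decimation == 2

    def test_forward_is_pure(self):
        net = build_network(chain_spec([8], kernel=3), seed=1)
        x = np.random.default_rng(3).normal(size=(2, 50))
        assert np.array_equal(net.forward(x), net.forward(x))

    def test_invalid_spec_names_offending_layer(self):
        spec = ArchitectureSpec(blocks=[BlockSpec(layers=[
            _conv(1, 4, 3), _conv(8, 4, 3)])])  # channel mismatch at layer 1
        with pytest.raises(ConstructionError, match="block 0 layer 1"):
            build_network(spec)

    def test_forward_shapes_on_random_specs(self):
        rng = np.random.default_rng(7)
        for _ in range(15):
            spec = random_spec(rng)
            net = build_network(spec, seed=0)
            x = rng.normal(size=(2, 64))
            out = net.forward(x)
            assert out.shape == (2, 64, 5)
            assert np.allclose(np.exp(out).sum(axis=2), 1.0)

    def test_log_probs_normalized(self, trained_net):
        x = np.random.default_rng(0).normal(size=(1, 240))
        out = trained_net.forward(x)
        assert np.allclose(np.exp(out).sum(axis=2), 1.0)


class TestSerialization:
    def test_yaml_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        spec = random_spec(rng)
        p = tmp_path / "arch.yaml"
        spec.save(p)
        back = ArchitectureSpec.load(p)
        assert back.to_dict() == spec.to_dict()
        assert param_count(back) == param_count(spec)

    def test_checkpoint_round_trip(self, tmp_path):
        net = build_network(chain_spec([4, 8], kernel=3), seed=2)
        x = np.random.default_rng(1).normal(size=(1, 40))
        before = net.forward(x)
        path = tmp_path / "net.npz"
        save_network(net, path)
        back = load_network(path)
        assert np.allclose(back.forward(x), before)
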