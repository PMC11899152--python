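"""Two-stage fusion: attention contracts, gates, calibration, composition."""

import numpy as np
import pytest

from mmlmh._tensor import Tensor
from mmlmh.fusion import AttentionMap, FusionModule, concat_features


@pytest.fixture()
def fusion(rng):
    return FusionModule(d_shared=6, d_fused=5, d_environment=4, rng=rng,
                        calibration_hidden=8, dropout=0.0).eval()


class TestConcat:
    def test_ordered_concatenation(self):
        out = concat_features(np.array([[1.0, 2.0]]), np.array([[3.0, 4.0]]))
        assert np.array_equal(out, [[1.0, 2.0, 3.0, 4.0]])

    def test_length_is_sum_of_parts(self, rng):
        out = concat_features(rng.normal(size=(3, 6)), rng.normal(size=(3, 6)))
        assert out.shape == (3, 12)

    def test_missing_component_rejected(self, rng):
        with pytest.raises(ValueError):
            concat_features(None, rng.normal(size=(1, 6)))


class TestSelfAttend:
    def test_attention_rows_sum_to_one(self, fusion, rng):
        omega = Tensor(rng.normal(size=(4, 12)))
        fusion.self_attend(omega, "text")
        amap = AttentionMap(fusion.self_attn["text"].last_attention, scale=fusion.d_fused**-0.5)
        amap.validate(tol=1e-6)

    def test_identical_tokens_attend_uniformly(self, fusion, rng):
        half = rng.normal(size=(2, 6))
        omega = Tensor(np.concatenate([half, half], axis=1))  # shared == specific
        fusion.self_attend(omega, "audio")
        att = fusion.self_attn["audio"].last_attention
        assert np.allclose(att, 0.5, atol=1e-12)

    def test_output_width_and_determinism(self, fusion, rng):
        omega = Tensor(rng.normal(size=(3, 12)))
        a = fusion.self_attend(omega, "visual")
        b = fusion.self_attend(omega, "visual")
        assert a.shape == (3, 5)
        assert np.array_equal(a.data, b.data)


class TestCrossAttend:
    def test_single_key_weight_is_exactly_one(self, fusion, rng):
        xi_t = Tensor(rng.normal(size=(3, 5)))
        xi_a = Tensor(rng.normal(size=(3, 5)))
        fusion.cross_attend(xi_t, xi_a, "audio")
        assert np.all(fusion._last_cross_attention == 1.0)

    def test_output_is_value_projection_regardless_of_query(self, fusion, rng):
        xi_a = Tensor(rng.normal(size=(2, 5)))
        out1 = fusion.cross_attend(Tensor(rng.normal(size=(2, 5))), xi_a, "audio")
        out2 = fusion.cross_attend(Tensor(rng.normal(size=(2, 5))), xi_a, "audio")
        assert np.allclose(out1.data, out2.data, atol=1e-12)
        assert np.allclose(out1.data, fusion.cross_v(xi_a).data, atol=1e-12)

    def test_text_as_target_rejected(self, fusion, rng):
        xi = Tensor(rng.normal(size=(1, 5)))
        with pytest.raises(ValueError, match="anchor"):
            fusion.cross_attend(xi, xi, "text")


class TestGateAndCalibration:
    def test_zero_input_zero_bias_gives_half(self, fusion):
        fusion.gate_net.bias.data[:] = 0.0
        w = fusion.gate(Tensor(np.zeros((1, 5))))
        assert w.data[0] == pytest.approx(0.5)

    def test_gate_strictly_inside_unit_interval(self, fusion, rng):
        w = fusion.gate(Tensor(rng.normal(size=(50, 5)) * 3))
        assert np.all(w.data > 0) and np.all(w.data < 1)

    def test_gate_monotone_in_preactivation(self, fusion):
        direction = fusion.gate_net.weight.data[:, 0]
        base = np.zeros((1, 5))
        lo = fusion.gate(Tensor(base - direction)).data[0]
        hi = fusion.gate(Tensor(base + direction)).data[0]
        assert hi > lo

    def test_calibration_in_unit_interval_and_flag_sensitive(self, fusion, rng):
        xi = Tensor(rng.normal(size=(6, 5)))
        c0 = fusion.calibrate(xi, np.zeros(6)).data
        c1 = fusion.calibrate(xi, np.ones(6)).data
        assert np.all((c0 > 0) & (c0 < 1)) and np.all((c1 > 0) & (c1 < 1))
        assert not np.allclose(c0, c1)  # the flag is a real input

    def test_non_binary_flag_rejected(self, fusion, rng):
        with pytest.raises(ValueError, match="binary"):
            fusion.calibrate(Tensor(rng.normal(size=(2, 5))), np.array([0.5, 1.0]))


class TestFuse:
    def _features(self, fusion, rng, b=4):
        shared = {m: Tensor(rng.normal(size=(b, 6))) for m in ("text", "audio", "visual")}
        specific = {m: Tensor(rng.normal(size=(b, 6))) for m in ("text", "audio", "visual")}
        flags = rng.integers(0, 2, size=(b, 3))
        env = rng.normal(size=(b, 4))
        return shared, specific, flags, env

    def test_adjusted_gate_is_product(self, fusion, rng):
        shared, specific, flags, env = self._features(fusion, rng)
        _, state = fusion.forward(shared, specific, flags, env)
        for m in ("audio", "visual"):
            assert np.allclose(
                state.adjusted_gates[m], state.gates[m] * state.calibrations[m], atol=1e-12
            )

    def test_gates_and_calibrations_open_interval(self, fusion, rng):
        shared, specific, flags, env = self._features(fusion, rng)
        _, state = fusion.forward(shared, specific, flags, env)
        for v in (*state.gates.values(), *state.calibrations.values()):
            assert np.all((v > 0.0) & (v < 1.0))

    def test_ablated_gates_and_calibration_are_unity(self, fusion, rng):
        shared, specific, flags, env = self._features(fusion, rng)
        xi_final, state = fusion.forward(
            shared, specific, flags, env,
            adaptive=False, calibration=False, use_environment=False,
        )
        expected = state.xi["text"] + state.xi["audio"] + state.xi["visual"]
        assert np.allclose(xi_final.data, expected, atol=1e-12)

    def test_fusion_continuous_in_weights(self, fusion, rng):
        """xi_final -> xi_text as the adjusted gates and env weight -> 0."""
        shared, specific, flags, env = self._features(fusion, rng)
        gaps = []
        for scale in (1.0, 1e-2, 1e-4, 1e-6):
            _, state = fusion.forward(shared, specific, flags, env)
            xi = state.xi["text"] + sum(
                scale * state.adjusted_gates[m][:, None] * state.xi[m]
                for m in ("audio", "visual")
            )
            gaps.append(np.linalg.norm(xi - state.xi["text"]))
        assert gaps == sorted(gaps, reverse=True)
        assert gaps[-1] < 1e-4

    def test_environment_term_added_with_learned_weight(self, fusion, rng):
        shared, specific, flags, env = self._features(fusion, rng)
        with_env, _ = fusion.forward(shared, specific, flags, env, use_environment=True)
        without, _ = fusion.forward(shared, specific, flags, env, use_environment=False)
        delta = with_env.data - without.data
        expected = fusion.env_proj(Tensor(env)).data * float(fusion.env_weight.data)
        assert np.allclose(delta, expected, atol=1e-12)
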