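"""Shared/specific encoders and the collaborative representation losses."""

import numpy as np
import pytest

from mmlmh._tensor import Tensor
from mmlmh.cmd_metrics import CmdConfig, cmd
from mmlmh.representation import (
    LossBreakdown,
    RepresentationModule,
    inter_loss,
    inter_loss_batch,
    intra_diff_loss,
    intra_sim_loss,
    recon_loss,
    total_representation_loss,
)
from mmlmh.synthetic import padded_contrastive_indices

WIDTHS = {"text": 12, "audio": 6, "visual": 9}
K5 = CmdConfig(5, 1.0, "samples")


@pytest.fixture()
def module(rng):
    return RepresentationModule(WIDTHS, d_utterance=10, d_shared=8, hidden=16,
                                dropout=0.0, rng=rng).eval()


class TestEncoders:
    def test_shared_encoder_is_one_parameter_set(self, module):
        # the same Parameter objects serve every modality
        p1 = module.shared_encoder.parameters()
        assert all(a is b for a, b in zip(p1, module.shared_encoder.parameters()))
        omega = Tensor(np.ones((2, 10)))
        out_as_text = module.shared_encode(omega)
        out_as_audio = module.shared_encode(omega)
        assert np.array_equal(out_as_text.data, out_as_audio.data)

    def test_specific_encoders_share_nothing(self, module):
        ids = {
            m: {id(p) for p in module.specific_encoders[m].parameters()}
            for m in WIDTHS
        }
        assert not (ids["text"] & ids["audio"]) and not (ids["audio"] & ids["visual"])
        omega = Tensor(np.ones((2, 10)))
        t = module.specific_encode(omega, "text").data
        a = module.specific_encode(omega, "audio").data
        assert not np.allclose(t, a)

    def test_output_widths(self, module, rng):
        tokens = rng.normal(size=(3, 5, 12))
        omega = module.encode_modality(tokens, "text")
        assert omega.shape == (3, 10)
        assert module.shared_encode(omega).shape == (3, 8)
        assert module.specific_encode(omega, "text").shape == (3, 8)

    def test_unknown_modality_rejected(self, module, rng):
        with pytest.raises(ValueError, match="modality"):
            module.encode_modality(rng.normal(size=(1, 4, 12)), "haptics")

    def test_token_width_mismatch_raises(self, module, rng):
        with pytest.raises(ValueError, match="width"):
            module.encode_modality(rng.normal(size=(1, 4, 7)), "text")

    def test_duplicating_tokens_leaves_utterance_unchanged(self, module, rng):
        tokens = rng.normal(size=(2, 4, 6))
        doubled = np.concatenate([tokens, tokens], axis=1)
        a = module.encode_modality(tokens, "audio").data
        b = module.encode_modality(doubled, "audio").data
        assert np.allclose(a, b, atol=1e-10)

    def test_single_token_sequence_supported(self, module, rng):
        out = module.encode_modality(rng.normal(size=(1, 1, 9)), "visual")
        assert out.shape == (1, 10) and np.all(np.isfinite(out.data))

    def test_eval_mode_is_deterministic(self, module, rng):
        tokens = rng.normal(size=(2, 4, 12))
        a = module.encode_modality(tokens, "text").data
        b = module.encode_modality(tokens, "text").data
        assert np.array_equal(a, b)


class TestIntraSample:
    def test_sim_zero_for_identical_batches(self, rng):
        g = rng.normal(size=(8, 5))
        assert float(intra_sim_loss({"text": g, "audio": g, "visual": g}, K5)) == 0.0

    def test_sim_equals_mean_of_pairwise_cmd(self, rng):
        shared = {m: rng.normal(size=(10, 4)) for m in ("text", "audio", "visual")}
        via_module = float(intra_sim_loss(shared, K5))
        by_hand = (
            cmd(shared["text"], shared["audio"], K5)
            + cmd(shared["text"], shared["visual"], K5)
            + cmd(shared["audio"], shared["visual"], K5)
        ) / 3.0
        assert via_module == pytest.approx(by_hand, abs=1e-10)

    def test_sim_invariant_to_joint_row_permutation(self, rng):
        shared = {m: rng.normal(size=(10, 4)) for m in ("text", "audio", "visual")}
        perm = rng.permutation(10)
        permuted = {m: v[perm] for m, v in shared.items()}
        assert float(intra_sim_loss(shared, K5)) == pytest.approx(
            float(intra_sim_loss(permuted, K5)), abs=1e-12
        )

    def test_sim_requires_two_rows(self, rng):
        tiny = {m: rng.normal(size=(1, 4)) for m in ("text", "audio", "visual")}
        with pytest.raises(ValueError, match="batch"):
            intra_sim_loss(tiny, K5)

    def test_diff_zero_when_all_orthogonal(self):
        e = np.eye(6)
        shared = {"text": e[[0]], "audio": e[[1]], "visual": e[[2]]}
        specific = {"text": e[[3]], "audio": e[[4]], "visual": e[[5]]}
        assert float(intra_diff_loss(shared, specific)) == pytest.approx(0.0)

    def test_diff_half_when_specific_equals_shared_but_modalities_orthogonal(self):
        e = np.eye(3)
        shared = {"text": e[[0]], "audio": e[[1]], "visual": e[[2]]}
        specific = dict(shared)  # within-modality cosines 1, cross-specific 0
        assert float(intra_diff_loss(shared, specific)) == pytest.approx(0.5)

    def test_diff_one_when_everything_identical(self, rng):
        v = rng.normal(size=(1, 7))
        same = {"text": v, "audio": v, "visual": v}
        assert float(intra_diff_loss(same, same)) == pytest.approx(1.0)

    def test_diff_zero_norm_vector_warns_and_counts_zero(self, rng):
        v = rng.normal(size=(1, 4))
        z = np.zeros((1, 4))
        shared = {"text": v, "audio": v, "visual": v}
        specific = {"text": z, "audio": z, "visual": z}
        with pytest.warns(UserWarning, match="zero-norm"):
            val = float(intra_diff_loss(shared, specific))
        assert val == pytest.approx(0.0)

    def test_diff_bounded_unit_interval(self, rng):
        for _ in range(20):
            shared = {m: rng.normal(size=(6, 5)) for m in ("text", "audio", "visual")}
            specific = {m: rng.normal(size=(6, 5)) for m in ("text", "audio", "visual")}
            assert 0.0 <= float(intra_diff_loss(shared, specific)) <= 1.0


KEYS = [(n, m) for n in ("shared", "specific") for m in ("text", "audio", "visual")]


class TestInterSample:
    def test_hinge_floor_when_positives_identical(self, rng):
        anchor = {k: rng.normal(size=8) for k in KEYS}
        pos = {k: np.tile(anchor[k], (2, 1)) for k in KEYS}
        neg = {k: anchor[k] + 5.0 * rng.normal(size=(2, 8)) for k in KEYS}
        assert inter_loss(anchor, pos, neg, margin=0.0) == 0.0

    def test_clamped_when_negatives_farther(self, rng):
        # positive distance < negative distance for every term, margin 0
        anchor = {k: rng.normal(size=10) for k in KEYS}
        pos = {k: (anchor[k] + 0.01 * rng.normal(size=(3, 10))) for k in KEYS}
        neg = {k: rng.normal(size=(3, 10)) * 4.0 for k in KEYS}
        assert inter_loss(anchor, pos, neg, margin=0.0) == 0.0

    def test_never_negative(self, rng):
        for _ in range(10):
            anchor = {k: rng.normal(size=6) for k in KEYS}
            pos = {k: rng.normal(size=(2, 6)) for k in KEYS}
            neg = {k: rng.normal(size=(2, 6)) for k in KEYS}
            assert inter_loss(anchor, pos, neg, margin=0.2) >= 0.0

    def test_batched_version_warns_and_zeroes_without_anchors(self, rng):
        feats = {k: Tensor(rng.normal(size=(4, 6))) for k in KEYS}
        labels = np.zeros(4, dtype=int)  # no negatives exist
        idx = padded_contrastive_indices(labels, 2, 2, rng, "classification")
        with pytest.warns(UserWarning, match="anchors"):
            val = inter_loss_batch(feats, *idx)
        assert float(val.data) == 0.0


class TestReconstruction:
    def test_zero_reconstruction_gives_mean_squared_norm(self, rng):
        omega = {m: rng.normal(size=(5, 7)) for m in ("text", "audio", "visual")}
        zeros = {m: np.zeros((5, 7)) for m in omega}
        want = np.mean(sum((omega[m] ** 2).sum(axis=1) for m in omega) / 3.0)
        assert float(recon_loss(omega, zeros)) == pytest.approx(want, abs=1e-12)

    def test_perfect_reconstruction_leaves_only_regulariser(self, rng):
        omega = {m: rng.normal(size=(4, 6)) for m in ("text", "audio", "visual")}
        norm_sq = 2.5
        val = recon_loss(omega, omega, lam=0.1, decoder_param_norm_sq=norm_sq)
        assert float(val) == pytest.approx(0.05 * norm_sq)

    def test_decode_shapes_and_recon_nonnegative(self, module, rng):
        gs = Tensor(rng.normal(size=(3, 8)))
        gu = Tensor(rng.normal(size=(3, 8)))
        out = module.decode(gs, gu)
        assert out.shape == (3, 10)
        omega = {m: rng.normal(size=(3, 10)) for m in ("text", "audio", "visual")}
        recon = {m: rng.normal(size=(3, 10)) for m in ("text", "audio", "visual")}
        assert float(recon_loss(omega, recon)) >= 0.0


class TestComposite:
    def test_reference_weights_compose_to_two(self):
        parts = LossBreakdown(l_intra_sim=0.5, l_intra_diff=0.5, l_inter=1.0, l_recon=1.0)
        assert total_representation_loss(parts) == pytest.approx(0.7 + 0.8 + 0.5)

    def test_all_zero_components_give_zero(self):
        assert total_representation_loss(LossBreakdown()) == 0.0

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            total_representation_loss(LossBreakdown(beta2=-0.1))

    def test_zero_weight_drops_exactly_one_term(self):
        parts = LossBreakdown(l_intra_sim=0.3, l_intra_diff=0.2, l_inter=0.9, l_recon=0.4)
        without_inter = LossBreakdown(
            l_intra_sim=0.3, l_intra_diff=0.2, l_inter=0.9, l_recon=0.4, beta2=0.0
        )
        expected = total_representation_loss(parts) - 0.8 * 0.9
        assert total_representation_loss(without_inter) == pytest.approx(expected)
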