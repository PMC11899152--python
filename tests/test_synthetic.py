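"""Generative contract of the synthetic consultation-data module."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from mmlmh.synthetic import (
    ModalitySpec,
    SyntheticDatasetSpec,
    generate,
    make_contrastive_batch,
    padded_contrastive_indices,
    simplex_vertices,
)


def _pooled(ds, modality):
    return ds.modality(modality).mean(axis=1)


class TestGenerate:
    def test_identical_spec_gives_bit_identical_data(self):
        spec = SyntheticDatasetSpec(n_samples=50, seed=42)
        a, b = generate(spec), generate(spec)
        for m in ("text", "audio", "visual"):
            assert np.array_equal(a.modality(m), b.modality(m))
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.environment, b.environment)

    def test_zero_synthetic_fraction_means_no_flags(self):
        ds = generate(SyntheticDatasetSpec(n_samples=100, synthetic_fraction=0.0, seed=1))
        assert ds.synthetic_flags.sum() == 0

    def test_shapes_match_spec(self):
        spec = SyntheticDatasetSpec(
            n_samples=30,
            text=ModalitySpec(5, 20, 0.1, True),
            audio=ModalitySpec(7, 10, 0.1, True),
            visual=ModalitySpec(3, 40, 0.1, True),
            d_environment=9,
            seed=2,
        )
        ds = generate(spec)
        assert ds.text.shape == (30, 5, 20)
        assert ds.audio.shape == (30, 7, 10)
        assert ds.visual.shape == (30, 3, 40)
        assert ds.environment.shape == (30, 9)
        for m in ("text", "audio", "visual"):
            assert np.all(np.isfinite(ds.modality(m)))

    def test_uninformative_modality_independent_of_label(self):
        """Monte-Carlo: per-dimension class-mean differences within sampling error."""
        spec = SyntheticDatasetSpec(
            n_samples=2000, n_classes=2, visual=ModalitySpec(8, 48, 0.1, False), seed=3
        )
        ds = generate(spec)
        x = _pooled(ds, "visual")
        diff = x[ds.labels == 0].mean(axis=0) - x[ds.labels == 1].mean(axis=0)
        sem = np.sqrt(
            x[ds.labels == 0].var(axis=0) / (ds.labels == 0).sum()
            + x[ds.labels == 1].var(axis=0) / (ds.labels == 1).sum()
        )
        assert np.all(np.abs(diff) < 5 * sem)

    def test_informative_modality_linearly_separable(self):
        """Strong separation, low noise: a linear probe reaches >= 95%."""
        spec = SyntheticDatasetSpec(
            n_samples=1000, delta=4.0, sigma_consult=0.05, synthetic_fraction=0.0,
            text=ModalitySpec(8, 32, 0.05, True), seed=4,
        )
        ds = generate(spec)
        x, y = _pooled(ds, "text"), ds.labels
        clf = LogisticRegression(max_iter=2000).fit(x[:700], y[:700])
        assert clf.score(x[700:], y[700:]) >= 0.95

    def test_uninformative_modality_probe_at_chance(self):
        spec = SyntheticDatasetSpec(
            n_samples=1000, n_classes=2, visual=ModalitySpec(8, 48, 0.1, False), seed=5
        )
        ds = generate(spec)
        x, y = _pooled(ds, "visual"), ds.labels
        clf = LogisticRegression(max_iter=2000).fit(x[:700], y[:700])
        assert abs(clf.score(x[700:], y[700:]) - 0.5) < 0.1

    def test_flagged_channels_carry_less_label_information(self):
        """Fidelity corruption: a channel model fitted on real data predicts
        the score far worse on synthetic-flagged samples of that channel."""
        from sklearn.linear_model import Ridge

        spec = SyntheticDatasetSpec(
            n_samples=1500, task="regression", synthetic_fraction=0.5,
            synthetic_noise_multiplier=4.0, seed=6,
        )
        ds = generate(spec)
        for j, m in enumerate(("text", "audio", "visual")):
            pooled = _pooled(ds, m)
            clean = ds.synthetic_flags[:, j] == 0
            fit = Ridge(alpha=1.0).fit(pooled[clean][:300], ds.labels[clean][:300])
            err_clean = np.mean((fit.predict(pooled[clean][300:]) - ds.labels[clean][300:]) ** 2)
            err_flagged = np.mean((fit.predict(pooled[~clean]) - ds.labels[~clean]) ** 2)
            assert err_flagged > 1.5 * err_clean

    def test_flagged_features_match_real_distribution(self):
        """Synthetic content is plausible: mean and variance of flagged
        channel features match the real ones (no amplitude artefact)."""
        spec = SyntheticDatasetSpec(
            n_samples=4000, task="regression", synthetic_fraction=0.5,
            synthetic_noise_multiplier=4.0, seed=16,
        )
        ds = generate(spec)
        pooled = _pooled(ds, "audio")
        fl = ds.synthetic_flags[:, 1] == 1
        gap = np.abs(pooled[fl].mean(axis=0) - pooled[~fl].mean(axis=0))
        assert gap.max() < 0.1
        ratio = pooled[fl].var(axis=0).mean() / pooled[~fl].var(axis=0).mean()
        assert 0.8 < ratio < 1.25

    def test_regression_scores_clipped_to_range(self):
        ds = generate(SyntheticDatasetSpec(n_samples=400, task="regression", sigma_z=3.0, seed=7))
        assert ds.labels.min() >= -3.0 and ds.labels.max() <= 3.0

    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_samples", 0),
            ("synthetic_fraction", 1.5),
            ("delta", -1.0),
            ("d_z", 1),  # below n_classes - 1 for C=3
            ("sigma_label", -0.1),
        ],
    )
    def test_invalid_spec_names_offending_field(self, field, value):
        spec = SyntheticDatasetSpec(**{field: value})
        with pytest.raises(ValueError, match=field.split("_")[0]):
            generate(spec)


class TestSimplex:
    def test_vertices_unit_norm_equidistant(self):
        v = simplex_vertices(4, 8)
        assert np.allclose(np.linalg.norm(v, axis=1), 1.0)
        dists = [np.linalg.norm(v[i] - v[j]) for i in range(4) for j in range(i + 1, 4)]
        assert np.allclose(dists, dists[0])

    def test_dimension_too_small_rejected(self):
        with pytest.raises(ValueError):
            simplex_vertices(5, 3)


class TestContrastiveSelection:
    def test_two_class_balanced_n1_m1(self):
        labels = np.array([0, 0, 1, 1])
        picks = make_contrastive_batch(labels, np.arange(4), 1, 1, seed=0)
        for a, pos, neg in picks:
            assert len(pos) == 1 and len(neg) == 1
            assert labels[pos[0]] == labels[a] and labels[neg[0]] != labels[a]
            assert pos[0] != a

    def test_deterministic_under_seed(self):
        labels = np.repeat([0, 1, 2], 10)
        a = make_contrastive_batch(labels, np.arange(30), 3, 3, seed=9)
        b = make_contrastive_batch(labels, np.arange(30), 3, 3, seed=9)
        for (_, p1, n1), (_, p2, n2) in zip(a, b):
            assert np.array_equal(p1, p2) and np.array_equal(n1, n2)

    def test_anchor_never_its_own_positive(self):
        labels = np.zeros(6, dtype=int)
        labels[3:] = 1
        picks = make_contrastive_batch(labels, np.arange(6), 2, 2, seed=1)
        for a, pos, _ in picks:
            assert a not in pos

    def test_short_pools_yield_fewer_candidates(self):
        labels = np.array([0, 1, 1, 1])
        picks = make_contrastive_batch(labels, [0], 3, 3, seed=2)
        _, pos, neg = picks[0]
        assert len(pos) == 0 and len(neg) == 3

    def test_regression_positive_window(self):
        scores = np.array([0.0, 0.2, 0.4, 2.0])
        picks = make_contrastive_batch(scores, [0], 3, 3, seed=3, task="regression")
        _, pos, neg = picks[0]
        assert set(pos) <= {1, 2} and set(neg) == {3}

    def test_padded_indices_masks_consistent(self, rng):
        labels = np.array([0, 0, 0, 1, 1, 2])
        pos_idx, pos_mask, neg_idx, neg_mask, anchor = padded_contrastive_indices(
            labels, 2, 2, rng, "classification"
        )
        assert pos_idx.shape == (6, 2) and neg_idx.shape == (6, 2)
        # anchors with a lone class still have negatives -> valid if >=1 positive
        assert anchor[5] == 0.0  # class 2 has no positives
        assert np.all((pos_mask == 0) | (pos_mask == 1))
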