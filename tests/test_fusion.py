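import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from conftest import make_labels, make_measure
from mmfuse.datamodel import assemble_dataset
from mmfuse.evaluation import CVConfig, ELMSpec, minmax_scale_fit_apply
from mmfuse.fusion import (AccuracyVector, WeightVector, column_weights,
                           compute_weights, hybrid_weighted_concat,
                           nested_cv_fused, per_measure_accuracy,
                           simple_concat, simple_weighted_concat)
from mmfuse.synthdata import MeasureSpec, SynthSpec, generate_dataset

accuracy_lists = st.lists(
    st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1,
    max_size=12)


class TestComputeWeights:
    def test_direct_substitution(self):
        w = compute_weights(AccuracyVector({"a": 1.0, "b": 0.5}))
        assert w["a"] == pytest.approx(1.0)
        assert w["b"] == pytest.approx(0.5)

    def test_equal_accuracies_give_unit_weights(self):
        w = compute_weights(AccuracyVector({"a": 0.7, "b": 0.7, "c": 0.7}))
        assert all(v == pytest.approx(1.0) for v in w.weights.values())

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(accuracy_lists)
    def test_argmax_weight_is_exactly_one(self, accs):
        acc = AccuracyVector({f"m{i}": a for i, a in enumerate(accs)})
        w = compute_weights(acc)
        best = max(acc.accuracies, key=acc.accuracies.get)
        assert w[best] == 1.0

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(accuracy_lists,
           st.floats(min_value=-0.3, max_value=0.0, allow_nan=False))
    def test_shift_consistency(self, accs, shift):
        base = {f"m{i}": a for i, a in enumerate(accs)}
        shifted = {k: max(a + shift, 0.0) for k, a in base.items()}
        if any(a + shift < 0 for a in base.values()):
            return  # clamping would break the pure-shift premise
        w0 = compute_weights(AccuracyVector(base)).weights
        w1 = compute_weights(AccuracyVector(shifted)).weights
        for k in base:
            assert w1[k] == pytest.approx(w0[k], abs=1e-12)

    def test_residuals_definition(self):
        acc = AccuracyVector({"a": 0.9, "b": 0.8})
        assert acc.residuals == {"a": 0.0, "b": pytest.approx(0.1)}

    def test_out_of_range_accuracy_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            AccuracyVector({"a": 1.2})

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            AccuracyVector({})


def unit_weights(dataset):
    return WeightVector({k: 1.0 for k in dataset.weight_keys})


class TestSimpleConcat:
    def test_column_count_and_block_order(self, tiny_dataset):
        fused = simple_concat(tiny_dataset)
        assert fused.shape == (40, 10 + 10 + 8 + 6)
        first, _, _ = minmax_scale_fit_apply(tiny_dataset["CortA"].values)
        np.testing.assert_array_equal(fused[:, :10], first)

    def test_single_measure_identity_unscaled(self, tiny_dataset):
        fused = simple_concat(tiny_dataset, ["SubA"], scale=False)
        np.testing.assert_array_equal(fused, tiny_dataset["SubA"].values)

    def test_unknown_label_rejected(self, tiny_dataset):
        with pytest.raises(KeyError, match="Nope"):
            simple_concat(tiny_dataset, ["Nope"])

    def test_empty_subset_rejected(self, tiny_dataset):
        with pytest.raises(ValueError, match="empty"):
            simple_concat(tiny_dataset, [])


class TestSimpleWeightedConcat:
    def test_unit_weights_equal_simple_concat(self, tiny_dataset):
        fused = simple_weighted_concat(tiny_dataset, unit_weights(tiny_dataset))
        np.testing.assert_array_equal(fused, simple_concat(tiny_dataset))

    def test_scalar_weight_scales_raw_column(self):
        labels = make_labels(2, 2)
        ones = make_measure("M", "cortical", np.ones((4, 1)))
        other = make_measure("N", "cortical", np.arange(8.0).reshape(4, 2))
        ds = assemble_dataset([ones, other], labels)
        fused = simple_weighted_concat(
            ds, WeightVector({"M": 0.5, "N": 1.0}), scale=False)
        np.testing.assert_array_equal(fused[:, 0], 0.5)

    def test_blocks_equal_weight_times_scaled_block(self, tiny_dataset, rng):
        weights = WeightVector(
            {k: w for k, w in zip(tiny_dataset.weight_keys,
                                  rng.uniform(0.3, 1.0, size=4))})
        fused = simple_weighted_concat(tiny_dataset, weights)
        start = 0
        for m in tiny_dataset.measures:
            scaled, _, _ = minmax_scale_fit_apply(m.values)
            block = fused[:, start:start + m.n_features]
            np.testing.assert_allclose(block, weights[m.weight_key] * scaled,
                                       atol=1e-14)
            start += m.n_features

    def test_missing_weight_rejected(self, tiny_dataset):
        with pytest.raises(KeyError, match="ICA"):
            simple_weighted_concat(
                tiny_dataset,
                WeightVector({"CortA": 1.0, "CortB": 0.9, "SubA": 0.8}))


class TestHybridWeightedConcat:
    def test_column_count_preserved(self, tiny_dataset):
        fused = hybrid_weighted_concat(tiny_dataset, unit_weights(tiny_dataset))
        assert fused.shape == simple_concat(tiny_dataset).shape

    def test_single_measure_block_normalizes_to_identity(self):
        labels = make_labels(3, 3)
        rng = np.random.default_rng(0)
        cort = make_measure("C", "cortical", rng.normal(size=(6, 4)))
        sub = make_measure("S", "subcortical", rng.normal(size=(6, 3)))
        ica = make_measure("I", "gica", rng.normal(size=(6, 2)))
        ds = assemble_dataset([cort, sub, ica], labels)
        fused = hybrid_weighted_concat(
            ds, WeightVector({"C": 0.6, "S": 0.3, "I": 1.0}))
        scaled_c, _, _ = minmax_scale_fit_apply(cort.values)
        # one measure per block: w/w = 1 regardless of the weight value
        np.testing.assert_allclose(fused[:, :4], scaled_c, atol=1e-14)

    def test_two_cortical_weights_normalized_by_their_sum(self):
        labels = make_labels(2, 2)
        a = make_measure("A", "cortical", np.ones((4, 1)))
        b = make_measure("B", "cortical", np.ones((4, 1)))
        s = make_measure("S", "subcortical", np.ones((4, 1)))
        ds = assemble_dataset([a, b, s], labels)
        fused = hybrid_weighted_concat(
            ds, WeightVector({"A": 0.25, "B": 0.75, "S": 1.0}), scale=False)
        np.testing.assert_allclose(fused[:, 0], 0.25)
        np.testing.assert_allclose(fused[:, 1], 0.75)

    def test_equal_weights_reduce_blocks_to_mean_scaling(self, tiny_dataset):
        w = WeightVector({k: 0.5 for k in tiny_dataset.weight_keys})
        fused = hybrid_weighted_concat(tiny_dataset, w)
        # cortical block has two measures with equal weights: each column
        # is (1/2) * its scaled value
        scaled, _, _ = minmax_scale_fit_apply(tiny_dataset["CortA"].values)
        np.testing.assert_allclose(fused[:, :10], scaled / 2, atol=1e-14)

    def test_gica_block_appended_unweighted(self, tiny_dataset, rng):
        weights = WeightVector(
            {k: w for k, w in zip(tiny_dataset.weight_keys,
                                  rng.uniform(0.3, 0.9, size=4))})
        fused = hybrid_weighted_concat(tiny_dataset, weights)
        scaled_ica, _, _ = minmax_scale_fit_apply(tiny_dataset["ICA"].values)
        np.testing.assert_array_equal(fused[:, -6:], scaled_ica)

    def test_rescale_after_fusion_cancels_weighting(self, tiny_dataset, rng):
        weights = WeightVector(
            {k: w for k, w in zip(tiny_dataset.weight_keys,
                                  rng.uniform(0.3, 0.9, size=4))})
        rescaled = hybrid_weighted_concat(tiny_dataset, weights,
                                          rescale_after_fusion=True)
        unweighted = hybrid_weighted_concat(tiny_dataset,
                                            unit_weights(tiny_dataset),
                                            rescale_after_fusion=True)
        np.testing.assert_allclose(rescaled, unweighted, atol=1e-12)

    def test_missing_anatomical_group_rejected(self):
        labels = make_labels(2, 2)
        rng = np.random.default_rng(1)
        cort = make_measure("C", "cortical", rng.normal(size=(4, 3)))
        ds = assemble_dataset([cort], labels)
        with pytest.raises(ValueError, match="subcortical"):
            hybrid_weighted_concat(ds, WeightVector({"C": 1.0}))

    def test_row_order_preserved(self, tiny_dataset):
        fused = hybrid_weighted_concat(tiny_dataset, unit_weights(tiny_dataset))
        assert fused.shape[0] == tiny_dataset.n_subjects


class TestPerMeasureAccuracy:
    CV = CVConfig(n_folds=3, n_repeats=1, seed=5)
    CLF = ELMSpec(n_hidden=10)

    def test_separable_vs_noise_measure(self, tiny_dataset):
        acc = per_measure_accuracy(tiny_dataset, self.CLF, self.CV)
        assert acc.accuracies["CortA"] >= 0.9
        assert abs(acc.accuracies["CortB"] - 0.5) <= 0.25

    def test_single_measure_is_its_own_maximum(self):
        spec = SynthSpec(measures=(MeasureSpec("Only", "cortical", 6,
                                               effect_size=1.0),),
                         n_per_group=(12, 12), seed=3)
        ds = generate_dataset(spec)
        acc = per_measure_accuracy(ds, self.CLF, self.CV)
        assert list(acc.accuracies) == ["Only"]
        assert acc.a_max == acc.accuracies["Only"]

    def test_deterministic_given_seeds(self, tiny_dataset):
        a = per_measure_accuracy(tiny_dataset, self.CLF, self.CV)
        b = per_measure_accuracy(tiny_dataset, self.CLF, self.CV)
        assert a.accuracies == b.accuracies

    def test_shared_weight_key_blocks_evaluated_jointly(self):
        rng = np.random.default_rng(2)
        labels = make_labels(10, 10)
        sub = make_measure("SC X", "subcortical", rng.normal(size=(20, 4)))
        whole = make_measure("Overall X", "wholebrain",
                             rng.normal(size=(20, 3)), weight_key="SC X")
        cort = make_measure("C", "cortical", rng.normal(size=(20, 4)))
        ds = assemble_dataset([sub, whole, cort], labels)
        acc = per_measure_accuracy(ds, self.CLF, self.CV)
        assert set(acc.accuracies) == {"SC X", "C"}


class TestColumnWeights:
    def test_factorization_matches_concat_functions(self, tiny_dataset, rng):
        """Every fusion variant equals 'scale columns, multiply by the
        column-weight vector' because min-max scaling is per feature."""
        weights = WeightVector(
            {k: w for k, w in zip(tiny_dataset.weight_keys,
                                  rng.uniform(0.3, 1.0, size=4))})
        scaled = simple_concat(tiny_dataset)
        np.testing.assert_allclose(
            scaled * column_weights(tiny_dataset, weights, "weighted"),
            simple_weighted_concat(tiny_dataset, weights), atol=1e-14)
        np.testing.assert_allclose(
            scaled * column_weights(tiny_dataset, weights, "hybrid"),
            hybrid_weighted_concat(tiny_dataset, weights), atol=1e-14)

    def test_simple_method_is_all_ones(self, tiny_dataset):
        np.testing.assert_array_equal(
            column_weights(tiny_dataset, None, "simple"), 1.0)

    def test_unknown_method_rejected(self, tiny_dataset):
        with pytest.raises(ValueError, match="method"):
            column_weights(tiny_dataset, None, "stacking")


class TestNestedCVFused:
    CV = CVConfig(n_folds=3, n_repeats=1, seed=2)
    CLF = ELMSpec(n_hidden=10)

    def test_fixed_weights_reproduce_plain_cv_on_fused_matrix(self,
                                                              tiny_dataset):
        """With precomputed weights and global block scaling, the fused CV
        must equal plain nested CV on the explicitly fused matrix."""
        from dataclasses import replace
        from mmfuse.evaluation import nested_cv
        weights = WeightVector({k: w for k, w in zip(
            tiny_dataset.weight_keys, (1.0, 0.7, 0.9, 0.8))})
        cfg = replace(self.CV, scaling_mode="none")
        fused_matrix = hybrid_weighted_concat(tiny_dataset, weights)
        direct = nested_cv(fused_matrix, tiny_dataset.labels.y, self.CLF, cfg)
        # scaling_mode none + explicit pre-scaled matrix on both routes
        via_fused = nested_cv_fused(
            assemble_scaled(tiny_dataset), self.CLF, cfg, method="hybrid",
            weights=weights)
        assert [c for _, _, c in direct.fold_counts] == \
            [c for _, _, c in via_fused.fold_counts]

    def test_within_fold_weights_are_leakage_free(self, tiny_dataset):
        """Re-running with a corrupted test half must not change the
        weights estimated from the training half; proxy check: results are
        deterministic and only depend on training data through the seed."""
        a = nested_cv_fused(tiny_dataset, self.CLF, self.CV, method="hybrid")
        b = nested_cv_fused(tiny_dataset, self.CLF, self.CV, method="hybrid")
        assert a.metric_means == b.metric_means

    def test_simple_method_ignores_weights(self, tiny_dataset):
        a = nested_cv_fused(tiny_dataset, self.CLF, self.CV, method="simple")
        b = nested_cv_fused(tiny_dataset, self.CLF, self.CV, method="simple",
                            weights=WeightVector(
                                {k: 0.5 for k in tiny_dataset.weight_keys}))
        assert a.metric_means == b.metric_means


def assemble_scaled(dataset):
    """Dataset with every measure pre-scaled to [-1, 1], so downstream
    fusion with scale already applied matches explicit concat output."""
    from mmfuse.datamodel import assemble_dataset as _ad
    import dataclasses
    measures = []
    for m in dataset.measures:
        scaled, _, _ = minmax_scale_fit_apply(m.values)
        measures.append(dataclasses.replace(m, values=scaled))
    return _ad(measures, dataset.labels)


class TestEffectSizeWeightMonotonicity:
    def test_programmed_effect_size_ranks_weights(self):
        """Across generator seeds, measures with larger programmed effect
        sizes must on average receive larger fusion weights."""
        deltas = [0.0, 0.5, 1.0, 1.5, 2.0, 3.0]
        clf = ELMSpec(n_hidden=10)
        cv = CVConfig(n_folds=3, n_repeats=1, seed=0)
        weight_sums = np.zeros(len(deltas))
        n_seeds = 10
        for seed in range(n_seeds):
            spec = SynthSpec(
                measures=tuple(
                    MeasureSpec(f"M{i}", "cortical", 8, effect_size=d)
                    for i, d in enumerate(deltas)),
                n_per_group=(15, 15), seed=seed)
            ds = generate_dataset(spec)
            acc = per_measure_accuracy(ds, clf, cv)
            w = compute_weights(acc)
            weight_sums += [w[f"M{i}"] for i in range(len(deltas))]
        rho, _ = spearmanr(deltas, weight_sums / n_seeds)
        assert rho > 0
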