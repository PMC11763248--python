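"""Grad-CAM, layer averaging, and relevance-value aggregation oracles."""

import numpy as np
import pandas as pd
import pytest

from parcelcam.explain import (
    LayerHeatmap, gradcam_all_layers, gradcam_layer, mean_heatmap,
    minmax_normalize, parcel_rv_graph, parcel_rv_volume,
)
from parcelcam.synthetic import make_synthetic_atlas


class LinearScoreModel:
    """Toy model whose class score is a fixed linear functional of its
    activation maps: s = sum_k c_k * sum_xy a_k(x, y).

    The analytic relevance weight of channel k is then exactly c_k (the
    spatial mean of a constant gradient field), making the expected heatmap
    ReLU(sum_k c_k a_k) computable in closed form.
    """

    def __init__(self, activations: dict[str, np.ndarray],
                 coeffs: dict[str, np.ndarray]):
        self.activations = activations
        self.coeffs = coeffs

    @property
    def tap_names(self):
        return list(self.activations)

    def gradcam_taps(self, x, label):
        sign = 1.0 if label == "AD" else -1.0
        out = {}
        for name, a in self.activations.items():
            c = self.coeffs[name]
            grads = sign * np.ones_like(a) * c.reshape((-1,) + (1,) * (a.ndim - 1))
            out[name] = (a, grads)
        return out


class TestGradCamOracle:
    def test_weights_equal_linear_coefficients_and_heatmap_matches(self, rng):
        a = rng.standard_normal((4, 10, 10))
        c = rng.standard_normal(4)
        model = LinearScoreModel({"L": a}, {"L": c})
        hm = gradcam_layer(model, np.zeros((10, 10)), "AD", "L")
        assert np.abs(hm.weights - c).max() < 1e-6
        expected = np.maximum(np.tensordot(c, a, axes=1), 0.0)
        assert np.abs(hm.values - expected).max() < 1e-6

    def test_hc_attribution_negates_the_functional(self, rng):
        a = rng.standard_normal((3, 6, 6))
        c = rng.standard_normal(3)
        model = LinearScoreModel({"L": a}, {"L": c})
        hm = gradcam_layer(model, np.zeros((6, 6)), "HC", "L")
        expected = np.maximum(np.tensordot(-c, a, axes=1), 0.0)
        assert np.abs(hm.values - expected).max() < 1e-6

    def test_zero_gradients_give_zero_heatmap_with_warning(self, rng):
        a = np.abs(rng.standard_normal((2, 5, 5)))
        model = LinearScoreModel({"L": a}, {"L": np.zeros(2)})
        with pytest.warns(RuntimeWarning, match="all-zero"):
            hm = gradcam_layer(model, np.zeros((5, 5)), "AD", "L")
        assert np.all(hm.values == 0.0)

    def test_single_nonnegative_channel_is_proportional(self, rng):
        a = np.abs(rng.standard_normal((1, 7, 7)))
        model = LinearScoreModel({"L": a}, {"L": np.array([2.0])})
        hm = gradcam_layer(model, np.zeros((7, 7)), "AD", "L")
        assert np.allclose(hm.values, 2.0 * a[0], atol=1e-10)

    def test_unregistered_layer_rejected(self, rng):
        model = LinearScoreModel({"L": np.ones((1, 4, 4))}, {"L": np.ones(1)})
        with pytest.raises(ValueError, match="not a registered tap"):
            gradcam_layer(model, np.zeros((4, 4)), "AD", "M")

    def test_coarse_map_resampled_to_input_size_nonnegative(self, rng):
        a = rng.standard_normal((2, 4, 4))
        c = rng.standard_normal(2)
        model = LinearScoreModel({"L": a}, {"L": c})
        hm = gradcam_layer(model, np.zeros((12, 12)), "AD", "L")
        assert hm.values.shape == (12, 12)
        assert hm.values.min() >= 0.0  # cubic overshoot clipped


class TestMeanHeatmap:
    def _hm(self, values, label="AD"):
        return LayerHeatmap(values=values, layer="L", class_label=label,
                            weights=np.zeros(1))

    def test_identical_layers_average_to_themselves(self, rng):
        v = np.abs(rng.standard_normal((5, 5)))
        out = mean_heatmap([self._hm(v)] * 4)
        assert out.n_layers == 4
        assert np.allclose(out.values, v, atol=1e-12)

    def test_linearity(self, rng):
        v = np.abs(rng.standard_normal((5, 5)))
        out = mean_heatmap([self._hm(np.zeros((5, 5))), self._hm(2.0 * v)])
        assert np.allclose(out.values, v, atol=1e-12)

    def test_mixed_classes_rejected(self, rng):
        v = np.abs(rng.standard_normal((4, 4)))
        with pytest.raises(ValueError, match="mixed classes"):
            mean_heatmap([self._hm(v, "AD"), self._hm(v, "HC")])

    def test_volume_model_yields_four_layer_average(self, rng):
        from parcelcam.model_volume import PRESETS, VolumeNetConfig, build_volume_net

        cfg = VolumeNetConfig(stage_channels=PRESETS["tiny"],
                              blocks_per_stage=1, input_shape=(16, 16, 16))
        model = build_volume_net(cfg, seed=0)
        hms = gradcam_all_layers(model, rng.standard_normal((16,) * 3), "AD")
        out = mean_heatmap(hms)
        assert out.n_layers == 4
        assert out.values.shape == (16, 16, 16)
        assert out.values.min() >= 0.0


class TestParcelRvVolume:
    def test_uniform_heatmap_gives_uniform_rv(self, tiny_atlas):
        g = np.full(tiny_atlas.label_volume.shape, 0.5)
        rv = parcel_rv_volume(g, tiny_atlas)
        assert np.allclose(rv.to_numpy(), 0.5)

    def test_indicator_heatmap_isolates_one_parcel(self, tiny_atlas):
        g = (tiny_atlas.label_volume == 1).astype(float)
        rv = parcel_rv_volume(g, tiny_atlas)
        assert rv[1] == pytest.approx(1.0)
        assert rv[2] == pytest.approx(0.0)

    def test_matches_brute_force_voxel_loop(self, rng):
        """Independent oracle: an explicit triple loop over voxels."""
        atlas = make_synthetic_atlas(3, shape=(8, 8, 8), seed=5)
        g = np.abs(rng.standard_normal((8, 8, 8)))
        rv = parcel_rv_volume(g, atlas)
        for p in atlas.parcel_ids:
            num = den = 0.0
            for x in range(8):
                for y in range(8):
                    for z in range(8):
                        if atlas.label_volume[x, y, z] == p:
                            num += g[x, y, z]
                            den += 1.0
            assert abs(rv[int(p)] - num / den) < 1e-12

    def test_conservation_identity(self, rng, small_atlas):
        """Sum of RV_p * |M_p| equals the heatmap mass over labeled voxels."""
        g = np.abs(rng.standard_normal(small_atlas.label_volume.shape))
        rv = parcel_rv_volume(g, small_atlas)
        lhs = sum(rv[int(p)] * small_atlas.mask(p).sum()
                  for p in small_atlas.parcel_ids)
        rhs = g[small_atlas.label_volume > 0].sum()
        assert abs(lhs - rhs) < 1e-9

    def test_empty_mask_names_parcel(self, tiny_atlas):
        table = tiny_atlas.parcel_table.copy()
        table.loc[len(table)] = [3, "Ghost", "left", "frontal", "cortical"]
        from parcelcam.atlas import AtlasParcellation

        atlas = AtlasParcellation(label_volume=tiny_atlas.label_volume,
                                  parcel_table=table)
        with pytest.raises(ValueError, match="parcel 3"):
            parcel_rv_volume(np.ones((6, 6, 6)), atlas)


class TestParcelRvGraph:
    def test_uniform_unit_heatmap_gives_unit_rv_denominator_131(self):
        rv = parcel_rv_graph(np.ones((132, 132)))
        assert len(rv) == 132
        assert np.allclose(rv.to_numpy(), 1.0, atol=1e-12)

    def test_single_hot_entry_row_convention(self):
        n = 10
        g = np.zeros((n, n))
        g[0, 1] = n - 1
        rv = parcel_rv_graph(g)
        assert rv[1] == pytest.approx(1.0)  # row 0 sums to n-1 over n-1
        assert rv[2] == pytest.approx(0.0)  # row 1 is all zero

    def test_zero_matrix_gives_zero_rv(self):
        assert np.all(parcel_rv_graph(np.zeros((6, 6))).to_numpy() == 0.0)

    def test_diagonal_never_contributes(self, rng):
        g = np.abs(rng.standard_normal((9, 9)))
        g2 = g.copy()
        np.fill_diagonal(g2, 1e6)
        assert np.allclose(parcel_rv_graph(g).to_numpy(),
                           parcel_rv_graph(g2).to_numpy(), atol=1e-9)

    def test_symmetrize_option_averages_with_transpose(self, rng):
        g = np.abs(rng.standard_normal((7, 7)))
        direct = parcel_rv_graph(0.5 * (g + g.T))
        assert np.allclose(parcel_rv_graph(g, symmetrize=True).to_numpy(),
                           direct.to_numpy(), atol=1e-12)


class TestMinMaxNormalize:
    def _table(self, values):
        return pd.DataFrame({
            "session_id": [f"s{i}" for i in range(len(values))],
            "subject_id": [f"p{i}" for i in range(len(values))],
            "class_label": ["AD"] * len(values),
            "parcel_id": [1] * len(values),
            "rv": values,
        })

    def test_direct_formula(self):
        out = minmax_normalize(self._table([2.0, 4.0, 6.0]))
        assert list(out["rv"]) == [0.0, 0.5, 1.0]

    def test_idempotent_on_normalized_table(self):
        once = minmax_normalize(self._table([2.0, 4.0, 6.0]))
        twice = minmax_normalize(once)
        assert np.allclose(once["rv"], twice["rv"], atol=1e-12)

    def test_scope_restricted_to_correct_sessions(self):
        out = minmax_normalize(self._table([0.0, 5.0, 10.0, 99.0]),
                               correct_session_ids={"s0", "s1", "s2"})
        assert list(out["rv"]) == [0.0, 0.5, 1.0]

    def test_degenerate_scope_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            minmax_normalize(self._table([1.0, 1.0]))
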