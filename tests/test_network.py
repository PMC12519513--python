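"""Coordinated deformation model, rewired nulls, variogram surrogates."""

import numpy as np
import pytest

import cortsub as cs
from cortsub.network import (
    VariogramGenerator,
    _p_greater,
    cdm_correlation,
    cdm_predict,
    distance_weight_spearman,
    rewire_null,
    spatial_test,
    variogram_surrogates,
)
from cortsub.synthetic import _coupled_rates, spatial_field


def _template_from(weights, modality="functional"):
    n = weights.shape[0]
    coords = np.column_stack([np.arange(n, dtype=float),
                              np.zeros(n), np.zeros(n)])
    parc = cs.types.Parcellation(
        roi_names=[f"roi_{i}" for i in range(n)],
        network_labels=["Default"] * n,
        centroids=coords,
    )
    return cs.types.ConnectivityTemplate(weights=np.asarray(weights, float),
                                         modality=modality,
                                         distances=parc.distances)


FOUR_NODE_W = np.array(
    [
        [0.0, 2.0, 0.0, 1.0],
        [2.0, 0.0, 3.0, 0.0],
        [0.0, 3.0, 0.0, 4.0],
        [1.0, 0.0, 4.0, 0.0],
    ]
)
FOUR_NODE_BETA = np.array([0.5, -1.0, 2.0, 0.25])
# hand-computed weighted neighbour means / sums for the template above
FOUR_NODE_PRED_NORM = np.array([-7.0 / 12.0, 1.4, -2.0 / 7.0, 1.7])
FOUR_NODE_PRED_RAW = np.array([-1.75, 7.0, -2.0, 8.5])


class TestCDMPredict:
    def test_frozen_four_node_oracle_normalized(self):
        tpl = _template_from(FOUR_NODE_W)
        pred = cdm_predict(FOUR_NODE_BETA, tpl, normalized=True)
        np.testing.assert_allclose(pred, FOUR_NODE_PRED_NORM, atol=1e-12)

    def test_frozen_four_node_oracle_unnormalized(self):
        tpl = _template_from(FOUR_NODE_W)
        pred = cdm_predict(FOUR_NODE_BETA, tpl, normalized=False)
        np.testing.assert_allclose(pred, FOUR_NODE_PRED_RAW, atol=1e-12)

    def test_star_graph_hub_gets_leaf_mean(self):
        W = np.zeros((4, 4))
        W[0, 1:] = W[1:, 0] = 1.0
        tpl = _template_from(W)
        beta = np.array([0.0, 1.0, 2.0, 3.0])
        pred = cdm_predict(beta, tpl)
        assert pred[0] == pytest.approx(2.0)
        np.testing.assert_allclose(pred[1:], 0.0, atol=1e-12)

    def test_eigenvector_map_has_correlation_one(self):
        rng = np.random.default_rng(0)
        W = rng.uniform(0.1, 1.0, (12, 12))
        W = np.triu(W, 1)
        W = W + W.T
        tpl = _template_from(W)
        vals, vecs = np.linalg.eigh(W)
        v = vecs[:, -1] * np.sign(vecs[:, -1].sum())  # Perron vector, positive
        # W v = lambda v, so the raw prediction is proportional to v
        assert cdm_correlation(v, tpl, normalized=False) == pytest.approx(1.0)

    def test_constant_map_rejected_in_correlation(self):
        tpl = _template_from(FOUR_NODE_W)
        with pytest.raises(cs.InvalidInputError, match="zero variance"):
            cdm_correlation(np.ones(4), tpl)

    def test_dimension_mismatch_rejected(self):
        tpl = _template_from(FOUR_NODE_W)
        with pytest.raises(cs.InvalidArgumentError):
            cdm_predict(np.ones(5), tpl)

    def test_isolated_node_rejected(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        tpl = _template_from(W)
        with pytest.raises(cs.InvalidInputError, match="isolated"):
            cdm_predict(np.ones(3), tpl)


@pytest.fixture(scope="module")
def nulls(template):
    return rewire_null(template, n_perm=20, seed=42)


@pytest.fixture(scope="module")
def sa_map(parcellation):
    rng = np.random.default_rng(3)
    return spatial_field(parcellation.distances, 20.0, rng)[0]


class TestRewireNull:
    def test_degree_sequence_preserved_exactly(self, template, nulls):
        deg = (template.weights > 0).sum(axis=1)
        for t in nulls:
            np.testing.assert_array_equal((t.weights > 0).sum(axis=1), deg)

    def test_weight_multiset_preserved_exactly(self, template, nulls):
        iu, ju = np.triu_indices(template.n_rois, 1)
        orig = np.sort(template.weights[iu, ju])
        for t in nulls:
            np.testing.assert_array_equal(np.sort(t.weights[iu, ju]), orig)

    def test_symmetric_zero_diagonal(self, nulls):
        for t in nulls:
            np.testing.assert_allclose(t.weights, t.weights.T)
            np.testing.assert_array_equal(np.diag(t.weights), 0.0)

    def test_geometry_untouched(self, template, nulls):
        for t in nulls:
            np.testing.assert_array_equal(t.distances, template.distances)

    def test_distance_weight_spearman_within_tolerance(self, template, nulls):
        target = distance_weight_spearman(template)
        for t in nulls:
            assert abs(distance_weight_spearman(t) - target) <= 0.1

    def test_topology_actually_randomized(self, template, nulls):
        iu, ju = np.triu_indices(template.n_rois, 1)
        orig = template.weights[iu, ju] > 0
        overlaps = [
            ((t.weights[iu, ju] > 0) & orig).sum() / orig.sum() for t in nulls
        ]
        assert np.mean(overlaps) < 0.9

    def test_deterministic(self, template):
        a = rewire_null(template, n_perm=2, seed=7)
        b = rewire_null(template, n_perm=2, seed=7)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.weights, y.weights)

    def test_invalid_arguments(self, template):
        with pytest.raises(cs.InvalidArgumentError):
            rewire_null(template, n_perm=0)
        with pytest.raises(cs.InvalidArgumentError):
            rewire_null(template, n_perm=1, n_bins=0)


class TestVariogramSurrogates:
    def test_moments_pinned(self, parcellation, sa_map):
        surr = variogram_surrogates(sa_map, parcellation.distances, 20, seed=1)
        np.testing.assert_allclose(surr.mean(axis=1), sa_map.mean(), atol=1e-9)
        np.testing.assert_allclose(surr.std(axis=1), sa_map.std(), atol=1e-9)

    def test_variogram_matched_within_25_percent(self, parcellation, sa_map):
        gen = VariogramGenerator(parcellation.distances)
        surr = gen(sa_map, 50, seed=2)
        v_emp = gen.variogram(sa_map - sa_map.mean())
        v_surr = np.mean([gen.variogram(s - s.mean()) for s in surr], axis=0)
        mare = np.mean(np.abs(v_surr - v_emp) / v_emp)
        assert mare <= 0.25

    def test_surrogates_decorrelated_from_original(self, parcellation, sa_map):
        surr = variogram_surrogates(sa_map, parcellation.distances, 100, seed=3)
        rs = [np.corrcoef(s, sa_map)[0, 1] for s in surr]
        assert abs(np.mean(rs)) < 0.15

    def test_deterministic(self, parcellation, sa_map):
        a = variogram_surrogates(sa_map, parcellation.distances, 3, seed=5)
        b = variogram_surrogates(sa_map, parcellation.distances, 3, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_constant_map_rejected(self, parcellation):
        with pytest.raises(cs.InvalidInputError, match="constant"):
            variogram_surrogates(np.ones(parcellation.n_rois),
                                 parcellation.distances, 2)

    def test_too_few_rois_rejected(self):
        with pytest.raises(cs.InvalidArgumentError):
            VariogramGenerator(np.zeros((5, 5)))

    def test_zero_surrogates_rejected(self, parcellation, sa_map):
        with pytest.raises(cs.InvalidArgumentError):
            variogram_surrogates(sa_map, parcellation.distances, 0)


class TestPermutationP:
    def test_observed_beats_all(self):
        assert _p_greater(np.zeros(99), 1.0) == pytest.approx(0.01)

    def test_observed_beats_none(self):
        assert _p_greater(np.ones(9), 0.0) == 1.0

    def test_ties_count_against(self):
        assert _p_greater(np.array([0.5, 0.5, 0.1]), 0.5) == pytest.approx(3 / 4)

    def test_two_sided_uses_magnitude(self):
        null = np.array([-0.9, 0.1, 0.2])
        assert _p_greater(null, 0.5, two_sided=True) == pytest.approx(2 / 4)


class TestSpatialTest:
    def test_network_coupled_map_detected(self, template):
        # beta from the generative coupled-rates process: heterogeneous
        # per-ROI rates diffused through this template's topology
        rng = np.random.default_rng(11)
        rates = -0.02 * rng.uniform(0.5, 1.5, template.n_rois)
        beta = _coupled_rates(rates, template, 0.8)
        res = spatial_test(beta, template, n_perm=100, seed=1)
        assert res.observed_r > 0.3
        assert res.p_rewired <= 0.05
        assert res.p_autocorr <= 0.05

    def test_pure_autocorrelation_not_mistaken_for_coupling(self, parcellation,
                                                            template):
        # a smooth map unrelated to the graph: the SA null should absorb it
        rng = np.random.default_rng(4)
        field = spatial_field(parcellation.distances, 20.0, rng)[0]
        res = spatial_test(field, template, n_perm=100, seed=2)
        assert res.p_autocorr > 0.05

    def test_consistency_of_reported_pvalues(self, template):
        rng = np.random.default_rng(5)
        beta = cdm_predict(rng.standard_normal(template.n_rois), template)
        res = spatial_test(beta, template, n_perm=100, seed=3)
        assert res.p_rewired == _p_greater(res.null_r_rewired, res.observed_r)
        assert res.p_autocorr == _p_greater(res.null_r_autocorr, res.observed_r)
        assert res.n_perm == 100 and res.modality == template.modality

    def test_precomputed_rewired_templates_reused(self, template):
        rng = np.random.default_rng(6)
        beta = cdm_predict(rng.standard_normal(template.n_rois), template)
        pre = rewire_null(template, n_perm=100, seed=9)
        a = spatial_test(beta, template, n_perm=100, seed=0,
                         rewired_templates=pre)
        b = spatial_test(beta, template, n_perm=100, seed=0,
                         rewired_templates=pre)
        np.testing.assert_array_equal(a.null_r_rewired, b.null_r_rewired)

    def test_small_n_perm_rejected(self, template):
        with pytest.raises(cs.InvalidArgumentError, match="n_perm"):
            spatial_test(np.arange(template.n_rois, dtype=float), template,
                         n_perm=50)


class TestDistanceWeightSpearman:
    def test_negative_under_distance_decay(self, template):
        assert distance_weight_spearman(template) < -0.2
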