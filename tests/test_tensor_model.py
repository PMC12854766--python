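import numpy as np
import pytest

from aoptox.hill import HillParams, build_grid, hill_response
from aoptox.tensor_model import (LayerTensor, MappingMatrix, TrainConfig,
                                 fit_pathway_layer, fit_protein_layer, fit_tox_layer,
                                 minmax_normalize, summarize_over_concentration)

from conftest import masked_r2


def _tensor(values, mask=None, grid=None):
    values = np.asarray(values, dtype=float)
    mask = np.ones_like(values, dtype=bool) if mask is None else mask
    return LayerTensor(values=values, mask=mask,
                       entity_ids=[f"e{i}" for i in range(values.shape[0])],
                       chemical_ids=[f"c{i}" for i in range(values.shape[2])],
                       grid=grid)


@pytest.fixture(scope="module")
def cfg():
    return TrainConfig(seed=0)


class TestMappingMatrix:
    def test_weights_outside_mask_rejected(self):
        with pytest.raises(ValueError):
            MappingMatrix(weights=np.ones((2, 2)),
                          structure_mask=np.eye(2, dtype=bool), layer="M1")

    def test_binarized_validation(self):
        with pytest.raises(ValueError):
            MappingMatrix(weights=np.zeros((2, 2)),
                          structure_mask=np.eye(2, dtype=bool), layer="M3",
                          binarized=np.array([[2, 0], [0, 0]]))


class TestProteinLayer:
    def test_noiseless_synthetic_reaches_optimum(self, cfg):
        rng = np.random.default_rng(3)
        m1 = np.where(rng.random((6, 3)) < 0.4, rng.uniform(0.5, 1.5, (6, 3)), 0.0)
        m1[np.arange(3), np.arange(3)] = 1.0  # ensure coverage both ways
        for i in np.flatnonzero(~m1.any(axis=1)):
            m1[i, rng.integers(3)] = 1.0
        prot_true = rng.uniform(0, 100, (3, 10, 20))
        assay = _tensor(np.einsum("ap,pck->ack", m1, prot_true))
        m1_fit, prot, trace = fit_protein_layer(assay, m1 > 0, cfg)
        assert trace.loss_trace[-1] < 1e-4
        rec = np.einsum("ap,pck->ack", m1_fit.weights, prot.values)
        assert masked_r2(rec, assay.values, assay.mask) > 0.99

    def test_zero_tensor_gives_zero_loss(self, cfg):
        assay = _tensor(np.zeros((2, 5, 3)))
        _, prot, trace = fit_protein_layer(assay, np.ones((2, 2), dtype=bool), cfg)
        assert trace.loss_trace[-1] < 1e-8
        # latent stays at the scale of the seeded init jitter
        assert np.abs(prot.values).max() < 0.05

    def test_scalar_factorization_reproduces_curve(self, cfg):
        grid = build_grid()
        curve = hill_response(HillParams(ac50=1e-8, slope=1.2, top=80.0), grid.points)
        assay = _tensor(curve.reshape(1, 45, 1), grid=grid)
        m1, prot, _ = fit_protein_layer(assay, np.ones((1, 1), dtype=bool), cfg)
        rec = (m1.weights @ prot.values.reshape(1, 45)).ravel()
        assert np.abs(rec - curve).max() < 1e-3

    def test_infeasible_row_rejected(self, cfg):
        assay = _tensor(np.ones((2, 4, 3)))
        mask = np.array([[True, False], [False, False]])
        with pytest.raises(ValueError, match="row 1"):
            fit_protein_layer(assay, mask, cfg)

    def test_masked_entries_never_influence_fit(self, cfg):
        """Perturbing unobserved entries leaves every fitted array bitwise equal."""
        rng = np.random.default_rng(7)
        values = rng.uniform(0, 100, (4, 8, 6))
        mask = rng.random((4, 8, 6)) < 0.8
        struct = np.ones((4, 2), dtype=bool)
        a1 = _tensor(values, mask=mask)
        perturbed = values + np.where(mask, 0.0, 1e6 * rng.random((4, 8, 6)))
        a2 = _tensor(perturbed, mask=mask)
        f1 = fit_protein_layer(a1, struct, TrainConfig(seed=1))
        f2 = fit_protein_layer(a2, struct, TrainConfig(seed=1))
        assert np.array_equal(f1[0].weights, f2[0].weights)
        assert np.array_equal(f1[1].values, f2[1].values)

    def test_structure_mask_conserved_and_loss_nonincreasing(self, cfg, small_noisy_study):
        _, study, truth = small_noisy_study
        from aoptox.io import harmonize_stage
        records = [(a, k, p) for (a, k), p in truth.hill_params.items()]
        tensor, _ = harmonize_stage(records, study.grid)
        m1, prot, trace = fit_protein_layer(tensor, truth.M1_true.structure_mask, cfg)
        assert np.all(m1.weights[~m1.structure_mask] == 0.0)
        assert trace.loss_trace[-1] <= trace.loss_trace[0]


class TestPathwayAndToxLayers:
    def test_identity_mask_recovers_proportional_path(self, cfg):
        rng = np.random.default_rng(5)
        prot = _tensor(rng.uniform(0, 50, (1, 6, 4)))
        m2, path, _ = fit_pathway_layer(prot, np.ones((1, 1), dtype=bool), cfg)
        rec = np.einsum("pq,qck->pck", m2.weights, path.values)
        assert np.abs(rec - prot.values).max() < 1e-3

    def test_zero_prot_zero_path(self, cfg):
        prot = _tensor(np.zeros((2, 4, 3)))
        _, _, trace = fit_pathway_layer(prot, np.ones((2, 2), dtype=bool), cfg)
        assert trace.loss_trace[-1] < 1e-8

    def test_tox_identity_mapping_equals_path(self, cfg):
        rng = np.random.default_rng(6)
        path = _tensor(rng.uniform(0, 80, (3, 5, 7)))
        tox, trace = fit_tox_layer(path, np.eye(3, dtype=int), cfg)
        assert np.abs(tox.values - path.values).max() < 1e-3

    def test_tox_shared_fiber_least_squares(self, cfg):
        rng = np.random.default_rng(8)
        fiber = rng.uniform(0, 60, (1, 5, 7))
        path = _tensor(np.concatenate([fiber, fiber]))  # two identical pathway fibers
        m3 = np.array([[1], [1]])
        tox, trace = fit_tox_layer(path, m3, cfg)
        rec = np.einsum("pe,eck->pck", m3.astype(float), tox.values)
        assert np.mean((rec - path.values) ** 2) < 1e-4

    def test_zero_path_zero_tox(self, cfg):
        path = _tensor(np.zeros((2, 4, 3)))
        tox, trace = fit_tox_layer(path, np.array([[1, 0], [0, 1]]), cfg)
        assert trace.loss_trace[-1] < 1e-8

    def test_unlinked_endpoint_rejected(self, cfg):
        path = _tensor(np.ones((2, 4, 3)))
        with pytest.raises(ValueError, match="zero retained pathways"):
            fit_tox_layer(path, np.array([[1, 0], [1, 0]]), cfg)


class TestSummaries:
    def test_mean_over_concentration(self):
        t = _tensor(np.full((1, 45, 1), 7.0))
        assert summarize_over_concentration(t)[0, 0] == pytest.approx(7.0)
        ramp = np.linspace(0, 100, 45).reshape(1, 45, 1)
        assert summarize_over_concentration(_tensor(ramp))[0, 0] == pytest.approx(50.0)

    def test_fully_masked_fiber_is_missing(self):
        vals = np.ones((1, 5, 2))
        mask = np.ones_like(vals, dtype=bool)
        mask[0, :, 1] = False
        out = summarize_over_concentration(_tensor(vals, mask=mask))
        assert out[0, 0] == pytest.approx(1.0)
        assert np.isnan(out[0, 1])

    @pytest.mark.parametrize("scores,expected", [
        ([2, 4, 6], [0, 0.5, 1]),
        ([5, 5, 5], [0.5, 0.5, 0.5]),
        ([-1, 0, 3], [0, 0.25, 1]),
    ])
    def test_minmax_normalize(self, scores, expected):
        np.testing.assert_allclose(minmax_normalize(np.array(scores, float)), expected)

    def test_minmax_empty_rejected(self):
        with pytest.raises(ValueError):
            minmax_normalize(np.array([np.nan, np.nan]))
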