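import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aoptox.hill import (AssayTopSummary, HillParams, build_assay_tensor, build_grid,
                         classify_assay, hill_response, merge_replicates,
                         normalize_curve, summarize_assay_tops)


class TestHillResponse:
    @pytest.mark.parametrize("params,conc,expected", [
        (HillParams(ac50=1.0, slope=1.0, top=100.0), 1.0, 50.0),
        (HillParams(ac50=1.0, slope=2.0, top=100.0), 10.0, 100.0 * 100 / 101),
        (HillParams(ac50=0.5, slope=1.0, top=-120.0), 0.0, 0.0),
    ])
    def test_pointwise_values(self, params, conc, expected):
        assert hill_response(params, conc) == pytest.approx(expected, abs=1e-9)

    @settings(deadline=None, max_examples=200)
    @given(log_ac50=st.floats(-11, -5), slope=st.floats(0.1, 10),
           top=st.floats(-200, 200).filter(lambda t: abs(t) > 1e-6))
    def test_half_maximum_at_ac50(self, log_ac50, slope, top):
        """The response at C = AC50 is Top/2 for any slope and sign of Top."""
        p = HillParams(ac50=10 ** log_ac50, slope=slope, top=top)
        assert hill_response(p, p.ac50) == pytest.approx(top / 2, abs=1e-9)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            hill_response(HillParams(ac50=1, slope=1, top=10), -1.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            HillParams(ac50=0.0, slope=1, top=10)
        with pytest.raises(ValueError):
            HillParams(ac50=1.0, slope=-1, top=10)


class TestGrid:
    def test_standard_grid(self):
        g = build_grid()
        assert g.n == 45
        assert g.points[0] == pytest.approx(1e-12)
        assert g.points[-1] == pytest.approx(1e-4)
        steps = np.diff(np.log10(g.points))
        assert np.allclose(steps, steps[0], rtol=1e-12)

    def test_two_point_grid(self):
        g = build_grid(n=2, c_min=1e-9, c_max=1e-6)
        assert np.allclose(g.points, [1e-9, 1e-6])

    def test_geometric_midpoint(self):
        g = build_grid()
        assert g.points[22] == pytest.approx(1e-8, rel=1e-12)

    @pytest.mark.parametrize("kw", [dict(n=1), dict(c_min=0.0), dict(c_min=1e-3, c_max=1e-6)])
    def test_bad_configuration(self, kw):
        with pytest.raises(ValueError):
            build_grid(**kw)


class TestNormalize:
    def test_half_max_after_scaling(self, grid):
        curve = normalize_curve(HillParams(ac50=1e-8, slope=1.0, top=50.0), grid)
        i = np.argmin(np.abs(grid.points - 1e-8))
        assert curve.responses[i] == pytest.approx(50.0, abs=1e-9)
        assert curve.responses.max() <= 100.0 + 1e-9

    def test_sign_invariance_of_responses(self, grid):
        up = normalize_curve(HillParams(ac50=2e-7, slope=1.4, top=120.0), grid)
        down = normalize_curve(HillParams(ac50=2e-7, slope=1.4, top=-120.0), grid)
        np.testing.assert_allclose(up.responses, down.responses)
        assert up.direction == "activation"
        assert down.direction == "inhibition"

    @settings(deadline=None, max_examples=100)
    @given(log_ac50=st.floats(-12, -4), slope=st.floats(0.1, 10),
           top=st.floats(-200, 200).filter(lambda t: abs(t) > 1e-6))
    def test_monotone_and_bounded(self, log_ac50, slope, top, grid):
        c = normalize_curve(HillParams(ac50=10 ** log_ac50, slope=slope, top=top), grid)
        assert np.all(np.diff(c.responses) >= -1e-12)
        assert c.responses[0] >= 0.0
        assert c.responses[-1] <= 100.0 + 1e-9

    def test_zero_top_rejected(self, grid):
        with pytest.raises(ValueError):
            normalize_curve(HillParams(ac50=1e-8, slope=1.0, top=0.0), grid)


class TestMergeReplicates:
    def test_single_and_identical(self, grid):
        c = normalize_curve(HillParams(ac50=1e-8, slope=1, top=100), grid)
        assert merge_replicates([c]) is c
        assert np.array_equal(merge_replicates([c, c, c]).responses, c.responses)

    def test_outlier_excluded(self, grid):
        a = normalize_curve(HillParams(ac50=1e-8, slope=1, top=100), grid, source=("A", "c"))
        b = normalize_curve(HillParams(ac50=1e-8, slope=1, top=100), grid, source=("A", "c"))
        outlier = normalize_curve(HillParams(ac50=1e-6, slope=3, top=100), grid, source=("A", "c"))
        kept = merge_replicates([outlier, a, b])
        np.testing.assert_allclose(kept.responses, a.responses)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            merge_replicates([])


class TestAssayClassification:
    @pytest.mark.parametrize("min_top,max_top,expected", [
        (37.3, 116.0, "positive"),
        (-120.0, 120.0, "mixed"),
        (-120.0, -16.9, "negative"),
        (0.0, 0.0, "excluded"),
        (-0.5, 0.5, "excluded"),
    ])
    def test_categories(self, min_top, max_top, expected):
        assert classify_assay(min_top, max_top) == expected

    def test_min_above_max_rejected(self):
        with pytest.raises(ValueError):
            classify_assay(10.0, -10.0)

    @settings(deadline=None, max_examples=300)
    @given(a=st.floats(-200, 200), b=st.floats(-200, 200))
    def test_partition_of_half_plane(self, a, b):
        """Every valid (minTop, maxTop) maps to exactly one of four categories."""
        lo, hi = min(a, b), max(a, b)
        assert classify_assay(lo, hi) in {"positive", "negative", "mixed", "excluded"}

    def test_summarize_tops(self):
        params = {
            "c1": HillParams(ac50=1e-8, slope=1, top=37.3),
            "c2": HillParams(ac50=1e-7, slope=2, top=116.0),
        }
        s = summarize_assay_tops("AID1", params)
        assert s == AssayTopSummary("AID1", 37.3, 116.0, "positive")


class TestAssayTensor:
    def test_shape_mask_and_duplicates(self, grid):
        curves = {}
        for a in ("A0", "A1"):
            for c in ("c0", "c1", "c2"):
                if (a, c) == ("A1", "c2"):
                    continue
                curves[(a, c)] = normalize_curve(
                    HillParams(ac50=1e-8, slope=1, top=100), grid, source=(a, c))
        t = build_assay_tensor(curves, grid, ["A0", "A1"], ["c0", "c1", "c2"])
        assert t.shape == (2, 45, 3)
        assert t.mask[0].all() and t.mask[1, :, :2].all()
        assert not t.mask[1, :, 2].any()
        with pytest.raises(ValueError):
            build_assay_tensor(list(curves.items()) + [next(iter(curves.items()))],
                               grid, ["A0", "A1"], ["c0", "c1", "c2"])

    def test_noiseless_roundtrip_matches_generating_product(self, single_chain_study):
        """Single-chain noiseless study: tensor from emitted Hill fits equals
        M1_true . M2_true . path_true to numerical precision."""
        cfg, study, truth = single_chain_study
        curves = {pair: normalize_curve(p, study.grid, source=pair)
                  for pair, p in truth.hill_params.items()}
        t = build_assay_tensor(curves, study.grid, study.assay_ids,
                               study.chemical_ids, scale="response")
        np.testing.assert_allclose(t.values, truth.assay_true.values, atol=1e-6)
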