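"""Microstructure formulas, weighting, and the grid transform with its inverse."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import connectocam as cc
from connectocam.core import GRID_SIDE, INDEX_MAP, N_EDGES, N_PAD, PAD_CELLS
from connectocam.errors import (DegenerateInputError, DomainError,
                                ValidationError)

from conftest import random_connectome

unit = st.floats(0.0, 1.0, allow_nan=False)


class TestMicrostructureFormulas:
    @pytest.mark.parametrize("mvf,isovf,icvf,expected", [
        (0.0, 0.0, 1.0, 1.0),
        (1.0, 0.3, 0.9, 0.0),
        (0.2, 0.1, 0.5, 0.36),
    ])
    def test_avf_values(self, mvf, isovf, icvf, expected):
        avf = cc.compute_avf(cc.MicrostructureEdgeParams(mvf, isovf, icvf))
        assert avf == pytest.approx(expected)

    def test_avf_rejects_out_of_range(self):
        with pytest.raises(DomainError, match="isovf"):
            cc.MicrostructureEdgeParams(0.2, 1.4, 0.5)

    @pytest.mark.parametrize("mvf,avf,expected", [
        (0.0, 0.5, 1.0),                 # zero-myelin limit
        (0.4, 0.4, np.sqrt(0.5)),        # equal fractions
        (0.51, 0.49, 0.7),               # corpus-callosum calibration point
    ])
    def test_gratio_values(self, mvf, avf, expected):
        assert cc.compute_gratio(mvf, avf) == pytest.approx(expected)

    def test_gratio_undefined_at_zero(self):
        with pytest.raises(DomainError):
            cc.compute_gratio(0.0, 0.0)

    @settings(derandomize=True, max_examples=200)
    @given(unit, unit, unit)
    def test_avf_and_gratio_stay_in_unit_interval(self, mvf, isovf, icvf):
        avf = cc.compute_avf(cc.MicrostructureEdgeParams(mvf, isovf, icvf))
        assert 0.0 <= avf <= 1.0
        if mvf + avf > 0:
            assert 0.0 <= cc.compute_gratio(mvf, avf) <= 1.0


class TestWeighting:
    def test_identity_weighting(self, rng):
        nos = random_connectome(rng)
        ones = cc.ConnectomeMatrix("s1", "FA", 1.0 - np.eye(84))
        out = cc.weight_connectome(nos, ones)
        off = ~np.eye(84, dtype=bool)
        assert np.array_equal(out.values[off], nos.values[off])
        assert out.metric == "FA"

    def test_zero_pattern_and_symmetry_preserved(self, rng):
        nos = random_connectome(rng)
        param = random_connectome(rng, metric="MK", density=1.0)
        out = cc.weight_connectome(nos, param)
        assert np.array_equal(out.values == 0, nos.values == 0)
        assert np.array_equal(out.values, out.values.T)

    def test_single_edge_product(self):
        nos_vals = np.zeros((84, 84))
        nos_vals[2, 5] = nos_vals[5, 2] = 100.0
        p_vals = np.zeros((84, 84))
        p_vals[2, 5] = p_vals[5, 2] = 0.45
        out = cc.weight_connectome(cc.ConnectomeMatrix("s", "NOS", nos_vals),
                                   cc.ConnectomeMatrix("s", "RK", p_vals))
        assert out.values[2, 5] == pytest.approx(45.0)

    def test_requires_nos_first(self, rng):
        fa = random_connectome(rng, metric="FA")
        with pytest.raises(ValidationError):
            cc.weight_connectome(fa, fa)

    def test_full_suite_has_fourteen_matrices(self, rng):
        nos = random_connectome(rng)
        params = {}
        for name in cc.core.MEASURED_PARAMS:
            vals = np.triu(rng.random((84, 84)), k=1)
            params[name] = cc.ConnectomeMatrix("s1", name, vals + vals.T)
        suite = cc.build_matrix_suite(nos, params)
        assert len(suite) == 14
        assert set(suite) == set(cc.METRICS)
        # Derived g-ratio weighting stays within NOS magnitude (g <= 1).
        assert np.all(suite["GRATIO"].values <= nos.values + 1e-9)


class TestGridTransform:
    def test_edge_vector_length(self, rng):
        v = cc.vectorize_upper(random_connectome(rng))
        assert v.values.shape == (3486,)
        assert v.index_map.shape == (3486, 2)
        assert np.all(v.index_map[:, 0] < v.index_map[:, 1])

    def test_index_map_is_bijection_onto_upper_triangle(self):
        pairs = {tuple(p) for p in INDEX_MAP}
        assert len(pairs) == N_EDGES
        assert pairs == {(i, j) for i in range(84) for j in range(i + 1, 84)}

    def test_single_edge_lands_once(self):
        vals = np.zeros((84, 84))
        vals[10, 20] = vals[20, 10] = 5.0
        v = cc.vectorize_upper(cc.ConnectomeMatrix("s", "NOS", vals))
        assert np.count_nonzero(v.values) == 1

    def test_devectorize_roundtrip(self, rng):
        for _ in range(5):
            m = random_connectome(rng)
            off = m.values * (1 - np.eye(84))
            assert np.array_equal(cc.devectorize(cc.vectorize_upper(m)), off)

    def test_pad_length_and_row_major_layout(self, rng):
        v = cc.vectorize_upper(random_connectome(rng))
        x = cc.pad_and_reshape(v)
        assert x.grid.size == 3600 == 3486 + 114
        flat = x.grid.reshape(-1)
        assert np.array_equal(flat[:N_EDGES], v.values)
        assert np.all(flat[N_EDGES:] == 0)
        # element at vector position p lands at (p // 60, p % 60)
        for p in (0, 59, 60, 1234, N_EDGES - 1):
            assert x.grid[p // GRID_SIDE, p % GRID_SIDE] == v.values[p]
        assert len(PAD_CELLS) == N_PAD == 114

    def test_normalize_scales_max_to_one(self, rng):
        x = cc.pad_and_reshape(cc.vectorize_upper(random_connectome(rng)))
        n = cc.normalize_input(x)
        assert n.grid.max() == pytest.approx(1.0)
        assert np.all(n.grid[tuple(zip(*PAD_CELLS))] == 0)
        # idempotent and scale-invariant
        again = cc.normalize_input(n)
        assert np.allclose(again.grid, n.grid)
        scaled = cc.normalize_input(cc.ModelInput(x.grid * 7.3))
        assert np.allclose(scaled.grid, n.grid)

    def test_normalize_rejects_all_zero(self):
        with pytest.raises(DegenerateInputError):
            cc.normalize_input(cc.ModelInput(np.zeros((60, 60))))

    def test_full_roundtrip_is_bit_exact(self, rng):
        for _ in range(5):
            m = random_connectome(rng)
            grid = cc.pad_and_reshape(cc.vectorize_upper(m)).grid
            back = cc.reorganize_to_connectome(grid)
            assert np.array_equal(back, m.values * (1 - np.eye(84)))
            assert np.array_equal(back, back.T)

    def test_reorganize_all_zero(self):
        assert np.all(cc.reorganize_to_connectome(np.zeros((60, 60))) == 0)


class TestConnectomeMatrixValidation:
    def test_rejects_asymmetric(self):
        vals = np.zeros((84, 84))
        vals[0, 1] = 1.0
        with pytest.raises(ValidationError, match="symmetric"):
            cc.ConnectomeMatrix("s", "NOS", vals)

    def test_rejects_negative(self):
        vals = -np.ones((84, 84))
        with pytest.raises(ValidationError, match="non-negative"):
            cc.ConnectomeMatrix("s", "NOS", vals)

    def test_rejects_wrong_shape(self):
        with pytest.raises(ValidationError, match="84"):
            cc.ConnectomeMatrix("s", "NOS", np.zeros((83, 83)))

    def test_tolerates_rounding_noise(self, rng):
        m = random_connectome(rng)
        noisy = m.values.copy()
        noisy[1, 0] *= 1 + 1e-12
        cc.ConnectomeMatrix("s", "NOS", noisy)  # must not raise


class TestAtlas:
    def test_default_atlas_composition(self, atlas):
        assert len(atlas.labels) == 84
        assert "Left cerebellar cortex" in atlas.labels
        assert "Right pallidum" in atlas.labels
        left = sum(h == "left" for h in atlas.hemisphere)
        assert left == 42
        sub = [l for l in atlas.labels if any(
            s in l for s in ("thalamus", "caudate", "putamen", "pallidum",
                             "hippocampus", "amygdala", "accumbens", "cerebellar"))]
        assert len(sub) == 16
        assert len(atlas.labels) - len(sub) == 68

    def test_atlas_file_roundtrip(self, atlas, tmp_path):
        path = tmp_path / "atlas.tsv"
        cc.write_atlas(atlas, path)
        assert cc.read_atlas(path) == atlas

    def test_unknown_label_raises(self, atlas):
        with pytest.raises(ValidationError):
            atlas.index("Left nucleus basalis")
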