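"""3D HOG descriptor: cell grid, histograms, full-descriptor oracle, layout."""

import numpy as np
import pytest

from hogpet import (
    HOGParams,
    Volume,
    build_integral,
    cell_histogram,
    compute_gradient,
    descriptor_length,
    enumerate_param_grid,
    extract_descriptor,
    make_polyhedron,
    partition_cells,
    quantize_gradient,
)
from hogpet.errors import VolumeError
from hogpet.hog3d import features_to_frame, load_feature_matrix, save_feature_matrix


def loop_descriptor(data, params):
    """From-scratch descriptor: per-voxel finite differences, direct means,
    per-vector quantization; no integral volumes."""
    gx, gy, gz = np.gradient(data, edge_order=1)
    poly = make_polyhedron(params.polyhedron, half=params.half)
    shape = data.shape
    counts = [n // params.k for n in shape]
    offsets = [(n % params.k) // 2 for n in shape]
    m = params.k // params.S
    out = []
    for iz in range(counts[2]):
        for iy in range(counts[1]):
            for ix in range(counts[0]):
                hist = np.zeros(poly.n_bins)
                for bz in range(params.S):
                    for by in range(params.S):
                        for bx in range(params.S):
                            x0 = offsets[0] + ix * params.k + bx * m
                            y0 = offsets[1] + iy * params.k + by * m
                            z0 = offsets[2] + iz * params.k + bz * m
                            sl = (slice(x0, x0 + m), slice(y0, y0 + m), slice(z0, z0 + m))
                            g = np.array([gx[sl].mean(), gy[sl].mean(), gz[sl].mean()])
                            hist += quantize_gradient(g, poly)
                out.append(hist)
    return np.concatenate(out)


class TestPartitionCells:
    def test_exact_division(self):
        cells = partition_cells((32, 32, 32), 16)
        assert len(cells) == 8
        assert all(c.size == (16, 16, 16) for c in cells)

    def test_non_divisible_extents_floor_and_center(self):
        cells = partition_cells((80, 96, 80), 16)
        assert len(cells) == 5 * 6 * 5

    def test_symmetric_margins(self):
        cells = partition_cells((21, 16, 16), 16)
        assert len(cells) == 1
        assert cells[0].origin == (2, 0, 0)  # (21 % 16) // 2 = 2

    def test_too_small_extent_raises(self):
        with pytest.raises(VolumeError):
            partition_cells((10, 10, 10), 16)

    def test_cells_disjoint_and_x_fastest(self):
        cells = partition_cells((32, 48, 32), 16)
        # first two cells differ only in x
        assert cells[1].origin[0] == cells[0].origin[0] + 16
        assert cells[1].origin[1:] == cells[0].origin[1:]
        seen = set()
        for c in cells:
            key = c.origin
            assert key not in seen
            seen.add(key)


class TestCellHistogram:
    def test_constant_volume_zero_histogram(self):
        params = HOGParams(k=8)
        vol = Volume(np.full((8, 8, 8), 2.0), spacing=(2, 2, 2))
        ivol = build_integral(compute_gradient(vol))
        poly = params.make_quantizer()
        h = cell_histogram(ivol, partition_cells(vol.shape, 8)[0], params, poly)
        np.testing.assert_array_equal(h, 0.0)

    def test_ramp_single_cell_unit_norm(self):
        """Interior cell of v=x has mean gradient (1,0,0); the vote norm is 1."""
        x = np.arange(24, dtype=float)
        vol = Volume(np.broadcast_to(x[:, None, None], (24, 24, 24)).copy(), spacing=(2, 2, 2))
        params = HOGParams(k=8, S=1)
        poly = params.make_quantizer()
        ivol = build_integral(compute_gradient(vol))
        center_cell = [c for c in partition_cells(vol.shape, 8) if c.origin == (8, 8, 8)][0]
        h = cell_histogram(ivol, center_cell, params, poly)
        assert np.linalg.norm(h) == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(h, quantize_gradient([1.0, 0.0, 0.0], poly), atol=1e-9)

    def test_subblocks_on_ramp_sum_to_s_cubed_votes(self):
        """On a linear ramp every sub-block sees the same gradient, so the
        S=2 cell histogram is 8x the S=1 histogram."""
        x = np.arange(24, dtype=float)
        vol = Volume(np.broadcast_to(x[:, None, None], (24, 24, 24)).copy(), spacing=(2, 2, 2))
        ivol = build_integral(compute_gradient(vol))
        center = [c for c in partition_cells(vol.shape, 8) if c.origin == (8, 8, 8)][0]
        p1 = HOGParams(k=8, S=1)
        p2 = HOGParams(k=8, S=2)
        poly = p1.make_quantizer()
        h1 = cell_histogram(ivol, center, p1, poly)
        h2 = cell_histogram(ivol, center, p2, poly)
        np.testing.assert_allclose(h2, 8 * h1, atol=1e-9)


class TestExtractDescriptor:
    def test_optimum_parameters_length_1500(self, rng):
        vol = Volume(rng.normal(size=(80, 96, 80)), spacing=(2, 2, 2))
        desc = extract_descriptor(vol, HOGParams())
        assert len(desc) == 1500
        assert desc.grid_shape == (5, 6, 5)

    def test_dodecahedron_half_length(self, rng):
        vol = Volume(rng.normal(size=(32, 32, 32)), spacing=(2, 2, 2))
        desc = extract_descriptor(vol, HOGParams(k=16, polyhedron="dodecahedron", half=True))
        assert len(desc) == 8 * 6

    @pytest.mark.parametrize(
        "params",
        [
            HOGParams(k=8, S=1, polyhedron="icosahedron", half=True),
            HOGParams(k=8, S=2, polyhedron="dodecahedron", half=False),
            HOGParams(k=16, S=4, polyhedron="icosahedron", half=False),
            HOGParams(k=12, S=2, polyhedron="dodecahedron", half=True),
            HOGParams(k=16, S=1, polyhedron="icosahedron", half=True),
        ],
    )
    def test_matches_loop_oracle(self, rng, params):
        data = rng.normal(size=(33, 40, 35))
        desc = extract_descriptor(Volume(data, spacing=(2, 2, 2)), params)
        oracle = loop_descriptor(data, params)
        np.testing.assert_allclose(desc.values, oracle, rtol=1e-6, atol=1e-9)

    def test_length_formula_over_param_draws(self, rng):
        for params in [HOGParams(k=k, S=s) for k in (8, 16) for s in (1, 2)]:
            shape = (40, 48, 40)
            desc = extract_descriptor(Volume(rng.normal(size=shape), spacing=(2, 2, 2)), params)
            assert len(desc) == descriptor_length(shape, params)

    def test_translation_equivariance_by_one_cell(self, rng):
        """Content shifted by exactly k voxels along x permutes cell histograms."""
        k = 8
        shape = (40, 24, 24)
        data = np.zeros(shape)
        data[8:16, 8:16, 8:16] = rng.normal(size=(8, 8, 8))
        shifted = np.roll(data, k, axis=0)
        params = HOGParams(k=k)
        d0 = extract_descriptor(Volume(data, spacing=(2, 2, 2)), params).values
        d1 = extract_descriptor(Volume(shifted, spacing=(2, 2, 2)), params).values
        nb = params.n_bins
        nx = shape[0] // k
        h0 = d0.reshape(-1, nb)
        h1 = d1.reshape(-1, nb)
        # cell (ix, iy, iz) of the shifted volume equals cell (ix-1, iy, iz);
        # compare interior cells only (border cells see the edge stencil).
        ncells = h0.shape[0]
        for flat in range(ncells):
            ix = flat % nx
            if 1 <= ix < nx - 1:
                np.testing.assert_allclose(h1[flat], h0[flat - 1], atol=1e-9)

    def test_half_orientation_intensity_inversion_invariance(self, rng):
        data = rng.normal(size=(32, 32, 32))
        params = HOGParams(k=16, half=True)
        d_pos = extract_descriptor(Volume(data, spacing=(2, 2, 2)), params).values
        d_neg = extract_descriptor(Volume(-data, spacing=(2, 2, 2)), params).values
        np.testing.assert_allclose(d_pos, d_neg, atol=1e-9)

    def test_volume_smaller_than_cell_raises(self, rng):
        with pytest.raises(VolumeError):
            extract_descriptor(Volume(rng.normal(size=(8, 8, 8)), spacing=(2, 2, 2)), HOGParams(k=16))

    def test_concat_subblocks_alternative_layout(self, rng):
        data = rng.normal(size=(16, 16, 16))
        params = HOGParams(k=16, S=2, concat_subblocks=True)
        desc = extract_descriptor(Volume(data, spacing=(2, 2, 2)), params)
        assert len(desc) == 8 * params.n_bins  # S^3 sub-blocks concatenated

    def test_per_cell_l2_normalization_flag(self, rng):
        data = rng.normal(size=(32, 32, 32))
        params = HOGParams(k=16, normalize_cells=True)
        desc = extract_descriptor(Volume(data, spacing=(2, 2, 2)), params)
        norms = np.linalg.norm(desc.values.reshape(-1, params.n_bins), axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-6)


class TestParamGrid:
    def test_grid_has_96_combinations(self):
        assert len(enumerate_param_grid()) == 96

    def test_grid_contains_the_optimum(self):
        grid = enumerate_param_grid()
        assert HOGParams(k=16, S=1, polyhedron="icosahedron", half=True) in grid

    def test_all_combinations_have_k_divisible_by_s(self):
        assert all(p.k % p.S == 0 for p in enumerate_param_grid())

    def test_grid_order_deterministic(self):
        assert enumerate_param_grid() == enumerate_param_grid()


class TestFeatureCSV:
    def test_round_trip_and_column_names(self, tmp_path, rng):
        vols = [Volume(rng.normal(size=(32, 32, 32)), spacing=(2, 2, 2)) for _ in range(3)]
        params = HOGParams(k=16)
        feats = [extract_descriptor(v, params) for v in vols]
        path = tmp_path / "features.csv"
        save_feature_matrix(feats, str(path), subject_ids=["a", "b", "c"])
        frame = load_feature_matrix(str(path))
        assert list(frame.index) == ["a", "b", "c"]
        assert frame.shape == (3, 8 * 10)
        assert frame.columns[0] == "cell_0_0_0_bin_0"
        np.testing.assert_allclose(frame.to_numpy()[0], feats[0].values, atol=1e-12)
        assert (tmp_path / "features.csv.json").exists()

    def test_inconsistent_layouts_rejected(self, rng):
        v1 = extract_descriptor(Volume(rng.normal(size=(32, 32, 32)), spacing=(2, 2, 2)), HOGParams(k=16))
        v2 = extract_descriptor(Volume(rng.normal(size=(48, 48, 48)), spacing=(2, 2, 2)), HOGParams(k=16))
        with pytest.raises(VolumeError):
            features_to_frame([v1, v2])
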