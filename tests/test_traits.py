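"""Point-cloud readers and the eight plot traits."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from canopynet.errors import (EmptyInputError, PointCloudFormatError,
                              PointCloudValidationError)
from canopynet.traits import (PointCloud, compute_spectral_indices,
                              compute_structural_traits, extract_plot_traits,
                              read_point_cloud, write_point_cloud)
from _oracles import spectral_indices_scalar, structural_traits_scalar


def random_cloud(rng, n):
    xyz = rng.uniform([0, 0, 0], [1000, 1000, 800], size=(n, 3))
    bands = rng.uniform(0.01, 1.0, size=(n, 4))
    return PointCloud(xyz=xyz, bands=bands)


# -- readers -----------------------------------------------------------------

@pytest.mark.parametrize("fmt,binary", [("ply", False), ("ply", True),
                                        ("xyz-csv", False)])
def test_point_cloud_round_trip(tmp_path, rng, fmt, binary):
    cloud = random_cloud(rng, 3)
    if binary:
        cloud = PointCloud(xyz=cloud.xyz.astype("<f4").astype(float),
                           bands=cloud.bands.astype("<f4").astype(float))
    ext = ".ply" if fmt == "ply" else ".csv"
    path = tmp_path / f"cloud{ext}"
    write_point_cloud(cloud, path, format=fmt, binary=binary)
    back = read_point_cloud(path, format=fmt)
    np.testing.assert_allclose(back.xyz, cloud.xyz, rtol=1e-7)
    np.testing.assert_allclose(back.bands, cloud.bands, rtol=1e-7)


def test_reader_rejects_wrong_column_count(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("x,y,z,b,g,r\n1,2,3,0.1,0.2,0.3\n")
    with pytest.raises(PointCloudFormatError):
        read_point_cloud(path)


def test_reader_rejects_out_of_range_reflectance(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("x,y,z,b,g,r,nir\n1,2,3,0.1,0.2,0.3,1.7\n")
    with pytest.raises(PointCloudValidationError):
        read_point_cloud(path)


def test_empty_file_reads_as_empty_cloud(tmp_path):
    path = tmp_path / "empty.csv"
    path.write_text("x,y,z,b,g,r,nir\n")
    cloud = read_point_cloud(path)
    assert len(cloud) == 0
    with pytest.raises(EmptyInputError):
        compute_spectral_indices(cloud)
    with pytest.raises(EmptyInputError):
        compute_structural_traits(cloud)


# -- hand-checked values -----------------------------------------------------

def _single_point(b=0.1, g=0.25, r=0.2, nir=0.5):
    return PointCloud(xyz=[[0, 0, 100]], bands=[[b, g, r, nir]])


def test_gndvi_hand_value_and_symmetry():
    gndvi, _, _, _ = compute_spectral_indices(_single_point(g=0.25, nir=0.5))
    assert gndvi == pytest.approx((0.5 - 0.25) / 0.75, abs=1e-12)
    gndvi_eq, _, _, _ = compute_spectral_indices(_single_point(g=0.4, nir=0.4))
    assert gndvi_eq == 0.0


def test_ncpi_and_mcari_hand_values():
    _, _, ncpi, _ = compute_spectral_indices(_single_point(b=0.3, r=0.3))
    assert ncpi == 0.0
    _, _, _, mcari = compute_spectral_indices(
        _single_point(b=0.1, g=0.3, r=0.2, nir=0.6))
    assert mcari == pytest.approx((0.4 - 0.2 * 0.3) * 3.0, abs=1e-12)


def test_zero_denominator_points_are_excluded():
    cloud = PointCloud(xyz=[[0, 0, 1], [1, 1, 2]],
                       bands=[[0.1, 0.3, 0.0, 0.6],   # r=0: MCARI excluded
                              [0.1, 0.3, 0.2, 0.6]])
    _, cvi, _, mcari = compute_spectral_indices(cloud)
    _, cvi1, _, mcari1 = compute_spectral_indices(
        PointCloud(xyz=[[1, 1, 2]], bands=[[0.1, 0.3, 0.2, 0.6]]))
    assert mcari == pytest.approx(mcari1)
    # CVI's denominator is G^2, so the r=0 point still contributes (a zero)
    assert cvi == pytest.approx(cvi1 / 2)


def test_structural_hand_values():
    cloud = PointCloud(xyz=[[0, 0, 100], [20, 0, 200], [0, 20, 300]],
                       bands=np.full((3, 4), 0.5))
    hmean, _, _, _ = compute_structural_traits(cloud)
    assert hmean == 200.0
    z = np.arange(1, 101, dtype=float)
    cloud2 = PointCloud(xyz=np.column_stack([z, z, z]),
                        bands=np.full((100, 4), 0.5))
    _, h99, _, _ = compute_structural_traits(cloud2)
    assert h99 == pytest.approx(99.01, abs=1e-9)


def test_pla_counts_occupied_cells():
    xyz = [[1, 1, 5], [15, 1, 5], [1, 15, 5], [15, 15, 5]]
    cloud = PointCloud(xyz=xyz, bands=np.full((4, 4), 0.5))
    _, _, pla, _ = compute_structural_traits(cloud, grid_cell=10.0)
    assert pla == pytest.approx(4 * 0.01 ** 2, abs=1e-15)


# -- oracle equivalence & invariants ----------------------------------------

@pytest.mark.parametrize("seed", range(5))
def test_all_traits_match_scalar_oracle(seed):
    rng = np.random.default_rng(seed)
    cloud = random_cloud(rng, int(rng.integers(1, 21)))
    points = [tuple(np.concatenate([p, q]))
              for p, q in zip(cloud.xyz, cloud.bands[:, [0, 1, 2, 3]])]
    traits = extract_plot_traits(cloud)
    spectral = spectral_indices_scalar(points)
    structural = structural_traits_scalar(points, 5.0, 10.0)
    for name, expect in {**spectral, **structural}.items():
        assert getattr(traits, name) == pytest.approx(expect, abs=1e-9), name


@given(st.integers(0, 10_000))
def test_indices_invariant_to_order_and_duplication(seed):
    rng = np.random.default_rng(seed)
    cloud = random_cloud(rng, 8)
    base = compute_spectral_indices(cloud)
    perm = rng.permutation(8)
    shuffled = PointCloud(xyz=cloud.xyz[perm], bands=cloud.bands[perm])
    doubled = PointCloud(xyz=np.vstack([cloud.xyz] * 2),
                         bands=np.vstack([cloud.bands] * 2))
    np.testing.assert_allclose(compute_spectral_indices(shuffled), base)
    np.testing.assert_allclose(compute_spectral_indices(doubled), base)


@given(st.integers(0, 10_000), st.floats(0.1, 10.0))
def test_height_traits_scale_with_z(seed, c):
    rng = np.random.default_rng(seed)
    cloud = random_cloud(rng, 10)
    scaled = PointCloud(xyz=cloud.xyz * [1, 1, c], bands=cloud.bands)
    h0 = compute_structural_traits(cloud)
    h1 = compute_structural_traits(scaled)
    assert h1[0] == pytest.approx(c * h0[0])
    assert h1[1] == pytest.approx(c * h0[1])


@given(st.integers(0, 10_000))
def test_adding_a_point_never_shrinks_pla_or_volume(seed):
    rng = np.random.default_rng(seed)
    cloud = random_cloud(rng, 10)
    extra = random_cloud(rng, 1)
    grown = PointCloud(xyz=np.vstack([cloud.xyz, extra.xyz]),
                       bands=np.vstack([cloud.bands, extra.bands]))
    _, _, pla0, vol0 = compute_structural_traits(cloud)
    _, _, pla1, vol1 = compute_structural_traits(grown)
    assert pla1 >= pla0 and vol1 >= vol0
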