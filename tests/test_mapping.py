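import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from lumifrontal.mapping import (
    MAPPING_SDS_UM,
    affiliation_probability,
    fit_track_line,
    incidence_per_session,
    incidence_pooled,
    locate_units,
    read_label_volume,
    write_label_volume,
)
from lumifrontal.simulate import make_label_volume, sample_track_points


@pytest.fixture(scope="module")
def two_region_volume():
    # two boxes split by the plane AP = 1000 um, inside a 2 x 2 x 1 mm volume
    return make_label_volume(
        {"regionA": ((0, 0, 0), (1000, 2000, 1000)),
         "regionB": ((1000, 0, 0), (2000, 2000, 1000))},
        extent_um=(2000, 2000, 1000), voxel_um=10.0,
    )


class TestTrackLine:
    def test_collinear_points_exact(self):
        pts = sample_track_points((100, 50, 200), (0.3, 0.9, 0.1), 800, jitter_um=0)
        track = fit_track_line(pts)
        resid = pts - track.at((pts - track.point) @ track.direction)
        assert np.allclose(resid, 0, atol=1e-9)

    def test_direction_recovered_under_jitter(self):
        d_true = np.array([0.3, 0.9, 0.1])
        d_true = d_true / np.linalg.norm(d_true)
        pts = sample_track_points((0, 0, 0), d_true, 800, n_points=35,
                                  jitter_um=20.0, seed=1)
        track = fit_track_line(pts)
        angle = np.degrees(np.arccos(abs(np.dot(track.direction, d_true))))
        assert angle < 2.0

    def test_point_order_invariance(self):
        pts = sample_track_points((0, 0, 0), (0, 1, 0), 800, jitter_um=10.0, seed=2)
        t1 = fit_track_line(pts)
        t2 = fit_track_line(pts[::-1])
        assert abs(abs(np.dot(t1.direction, t2.direction)) - 1) < 1e-12

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            fit_track_line(np.ones((5, 3)))


class TestLocateUnits:
    def test_zero_jitter_ground_truth(self):
        d = np.array([0.0, 1.0, 0.0])
        pts = sample_track_points((100, 0, 100), d, 800, jitter_um=0)
        track = fit_track_line(pts)
        offsets = np.array([0.0, 50.0, 100.0])
        s0 = (pts[0] - track.point) @ track.direction
        coords, flagged = locate_units(track, s0 + offsets, [0, 1, 2])
        expected = pts[0] + offsets[:, None] * d
        assert np.allclose(coords, expected, atol=1e-9)
        assert not flagged.any()

    def test_same_site_identical_coordinates(self):
        pts = sample_track_points((0, 0, 0), (0, 1, 0), 800, jitter_um=0)
        track = fit_track_line(pts)
        coords, _ = locate_units(track, [0.0, 50.0], [1, 1])
        assert np.allclose(coords[0], coords[1])

    def test_site_spacing_preserved(self):
        pts = sample_track_points((0, 0, 0), (0.2, 0.9, 0.4), 800, jitter_um=0)
        track = fit_track_line(pts)
        offsets = np.arange(10) * 50.0
        coords, _ = locate_units(track, offsets, np.arange(10))
        spacing = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        assert np.allclose(spacing, 50.0)

    def test_beyond_extent_flagged(self):
        pts = sample_track_points((0, 0, 0), (0, 1, 0), 100, jitter_um=0)
        track = fit_track_line(pts)
        _, flagged = locate_units(track, [0.0, 5000.0], [0, 1])
        assert not flagged[0] and flagged[1]

    def test_unknown_channel_rejected(self):
        pts = sample_track_points((0, 0, 0), (0, 1, 0), 100, jitter_um=0)
        track = fit_track_line(pts)
        with pytest.raises(IndexError):
            locate_units(track, [0.0], [3])


class TestAffiliation:
    def test_deep_interior_probability_one(self, two_region_volume):
        aff = affiliation_probability((500, 1000, 500), two_region_volume, seed=0)
        assert aff.probabilities["regionA"] > 0.999

    def test_planar_boundary_half_half(self, two_region_volume):
        aff = affiliation_probability((1000, 1000, 500), two_region_volume,
                                      n_points=100_000, seed=1)
        se = 3 * aff.mc_se("regionA")
        assert abs(aff.probabilities["regionA"] - 0.5) < se + 0.005
        assert abs(aff.probabilities["regionB"] - 0.5) < se + 0.005

    def test_box_matches_gaussian_cdf_product(self, two_region_volume):
        """MC probability of an axis-aligned box equals the product of the
        per-axis Gaussian CDF differences (analytic oracle)."""
        coord = np.array([950.0, 1900.0, 480.0])
        sds = np.array(MAPPING_SDS_UM)
        aff = affiliation_probability(coord, two_region_volume,
                                      n_points=100_000, seed=2)
        lo = np.array([0.0, 0.0, 0.0])
        hi = np.array([1000.0, 2000.0, 1000.0])
        analytic = np.prod(
            norm.cdf((hi - coord) / sds) - norm.cdf((lo - coord) / sds)
        )
        mc_se = np.sqrt(analytic * (1 - analytic) / 100_000)
        assert abs(aff.probabilities["regionA"] - analytic) < 3 * mc_se + 1e-3

    def test_partition_of_unity(self, two_region_volume):
        aff = affiliation_probability((1990, 1990, 990), two_region_volume, seed=3)
        assert sum(aff.probabilities.values()) == pytest.approx(1.0)
        assert aff.probabilities["outside"] > 0

    def test_mc_convergence_rate(self, two_region_volume):
        """MC error shrinks roughly as n^-1/2."""
        coord = (1000, 1000, 500)
        errs = []
        for n in (1000, 100_000):
            reps = [
                affiliation_probability(coord, two_region_volume, n_points=n,
                                        seed=10 + r).probabilities["regionA"]
                for r in range(5)
            ]
            errs.append(np.std(reps))
        assert errs[1] < errs[0] / 3  # expect ~1/10, allow slack


class TestIncidence:
    def test_per_session_fraction(self):
        units = pd.DataFrame({
            "session_id": ["s0"] * 10,
            "unit_id": [f"u{i}" for i in range(10)],
            "flag": [True] * 3 + [False] * 7,
        })
        per = incidence_per_session(units, "flag")
        assert per["fraction"].iloc[0] == pytest.approx(0.30)

    def test_mean_across_sessions(self):
        units = pd.DataFrame({
            "session_id": ["a"] * 5 + ["b"] * 5,
            "unit_id": [f"u{i}" for i in range(10)],
            "flag": [True, False, False, False, False] + [True, True, False, False, False],
        })
        per = incidence_per_session(units, "flag")
        assert per.attrs["mean"] == pytest.approx(0.3)

    def test_pooled_counts_conserved(self, two_region_volume):
        coords = [(500, 500, 500), (520, 510, 480), (1500, 500, 500), (1480, 520, 510)]
        units = pd.DataFrame({
            "unit_id": [f"u{i}" for i in range(4)],
            "flag": [True, False, True, True],
        })
        affs = {
            f"u{i}": affiliation_probability(c, two_region_volume, n_points=5000,
                                             seed=20 + i, unit_id=f"u{i}")
            for i, c in enumerate(coords)
        }
        pooled = incidence_pooled(units, "flag", affs)
        assert pooled["n_total"].sum() == 4
        assert pooled.set_index("region").loc["regionA", "fraction"] == pytest.approx(0.5)

    def test_min_prob_excludes_boundary_units(self, two_region_volume):
        units = pd.DataFrame({"unit_id": ["u0"], "flag": [True]})
        affs = {"u0": affiliation_probability((1000, 1000, 500), two_region_volume,
                                              n_points=5000, seed=30, unit_id="u0")}
        pooled = incidence_pooled(units, "flag", affs, min_prob=0.9)
        assert pooled.empty


def test_nrrd_round_trip(tmp_path, two_region_volume):
    path = tmp_path / "atlas.nrrd"
    write_label_volume(two_region_volume, path)
    back = read_label_volume(path)
    assert back.voxel_um == two_region_volume.voxel_um
    assert back.labels == two_region_volume.labels
    assert np.array_equal(np.sort(np.unique(back.data)),
                          np.sort(np.unique(two_region_volume.data)))
    assert back.data.sum() == two_region_volume.data.sum()
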